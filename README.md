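# cstnet

Discovery of recurrent gut-microbiome compositional patterns — community
state types (CSTs) — from species-level relative-abundance tables, together
with the statistics that characterize them: silhouette-guided hierarchical
clustering, high prevalence cluster (HPC) flagging, driver-taxon ranking by
variance explained, Bray-Curtis / PCoA / PERMANOVA beta-diversity analysis,
and signed Kendall-tau co-occurrence networks with modularity clustering.

It is aimed at microbiome researchers comparing cohorts (here: athletes vs
non-athletes) who want the full distance-based CST workflow as a tested,
scriptable library instead of a chain of GUI tools, plus a synthetic-cohort
generator that reproduces the statistical structure the analysis assumes so
every stage can be validated without downloading data.

## The method

Given a samples × species matrix of relative abundances *P* (rows sum to 1):

* **Richness**: `#{ j : p_ij > t }` per sample, default t = 0.5%.
* **Beta diversity**: Bray-Curtis `d(p,q) = 1 − Σ_j min(p_j, q_j)`; PCoA by
  eigendecomposition of the Gower-centered matrix `−½ J d² J`; group effects
  tested by the PERMANOVA pseudo-F
  `F = ((SS_T − SS_W)/(a−1)) / (SS_W/(N−a))` with permutation p-values
  (1,000 permutations, +1/+1 convention).
* **CSTs**: average-linkage hierarchical clustering on `1 − r` (Pearson
  correlation between samples over species); k chosen to maximize the mean
  silhouette width `s(i) = (b(i)−a(i))/max(a(i),b(i))` on the same
  distances; clusters covering ≥ 15% of samples are HPCs.
* **Driver taxa**: per species, adjusted R² of the one-way linear model of
  abundance on cluster membership; species with adj. R² > 0.15 are drivers,
  and their summed abundance per cluster is the driver coverage.
* **Networks**: all prevalent species pairs tested with Kendall's tau-b
  (tie-corrected); Benjamini-Hochberg across all pairs, edges kept at
  q ≤ 0.05, signed by the direction of tau; modules by greedy modularity
  maximization on |tau| weights; keystone taxa ranked by degree.

See `docs/methods.md` for conventions, parameter defaults and limitations.

## Worked example

Simulate a 207-sample cohort with three planted community states (a
Prevotella-like, a Bacteroides-like and a Faecalibacterium/Eubacterium-like
dominance pattern, athlete probabilities 0.52 / 0.18 / 0.87) and run the
whole pipeline:

```sh
cstnet --seed 7 simulate --out-prefix demo/cohort
cstnet --seed 7 report --abundance demo/cohort_abundance.tsv \
       --metadata demo/cohort_metadata.tsv --out-dir demo/report
```

prints:

```
samples: 207   species: 330
richness (mean over samples, >0.5%): 28.1
PERMANOVA athlete vs non-athlete: F=17.230 p=0.0010
selected k (CSTs): 3
HPCs: [1, 2, 3] covering 100.0% of samples
driver taxa (adj R2 > 0.15): 8
driver coverage by cluster (%): 1: 29.0, 2: 37.3, 3: 48.8
network: 31 edges, 35.5% positive, 316 modules (Q=0.544)
```

Reading this: the silhouette criterion recovers exactly the three planted
states (k = 3), all of them prevalent enough to be HPCs; the athlete/
non-athlete split is strongly associated with composition (pseudo-F 17.2,
p = 0.001, the smallest value attainable with 1,000 permutations); the 8
selected driver taxa are precisely the planted dominance taxa and account
for 29–49% of each cluster's composition; the network recovers the planted
correlation edges plus the dominance-induced associations (most nodes are
isolated, hence the large module count).

The same stages are available as library calls (`cstnet.simulate`,
`cstnet.diversity`, `cstnet.cst`, `cstnet.drivers`, `cstnet.networks`) and
as per-stage subcommands (`diversity`, `cluster`, `drivers`, `network`)
writing TSV/GraphML outputs; `--config` takes a YAML file with
`simulate`/`cluster`/`network` sections.

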