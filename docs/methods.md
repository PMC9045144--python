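# Methods

`cstnet` implements a distance-based pipeline for discovering recurrent
compositional patterns ("community state types", CSTs) in species-level gut
microbiome profiles, attributing them to driver taxa, and characterizing
group-specific co-occurrence structure. This note records the models, the
parameters that matter, and the design choices made where the procedure was
genuinely open.

## Data model

The pipeline's currency is a samples × species matrix of relative abundances
stored as fractions. Rows are renormalized unconditionally on input (so
tables produced by classifiers that drop unclassified reads still satisfy the
unit-sum invariant); absent species are explicit zeros. Sample metadata
carries a mandatory two-level `group` factor (`athlete` / `non_athlete`) plus
optional categoricals (sport, study, sex).

## Diversity

**Alpha diversity** is threshold richness: the number of species whose
relative abundance strictly exceeds a cutoff. The default cutoff is 0.005
(0.5%); 0.0005 (0.05%) is offered as a preset because both conventions
circulate for shotgun profiles and the choice materially changes the count.
Richness is deliberately not rarefied — the inputs are relative abundances,
not counts.

**Beta diversity** is Bray-Curtis dissimilarity, which on unit-sum profiles
equals `1 − Σ min(p_i, q_i)` and lies in [0, 1]. Sample clustering instead
uses `1 − r` with r the Pearson correlation of two samples' abundance
vectors over all species (range [0, 2]); a zero-variance sample is an error
under this metric, not a silent NaN.

**PCoA** is classical metric MDS: Gower double-centering of `−d²/2`,
symmetric eigendecomposition, axes scaled by the square root of their
eigenvalue. Numerical conventions: eigenvalues ≤ 1e-10 are dropped; negative
eigenvalues (non-Euclidean input) are discarded without Lingoes/Cailliez
correction and excluded from the proportion-explained denominator, which is
the sum of positive eigenvalues; each axis is sign-fixed so its first
nonzero loading is positive, making coordinates platform-reproducible up to
that convention.

**PERMANOVA** uses the one-way distance-based pseudo-F
(`SS_total = Σ_{i<j} d²_ij / N`, `SS_within = Σ_g Σ_{i<j∈g} d²_ij / n_g`).
The Monte Carlo p-value uses the +1/+1 convention with ties counted as
extreme (conservative), so p ∈ [1/(n_perm+1), 1]; default 1,000
permutations. Permutation is free by default; a `strata` argument permutes
within strata (e.g. study of origin) for sensitivity analyses. An
`exhaustive` mode enumerates all distinct relabellings for small n and is
the reference against which the Monte Carlo path is tested.

## Community state types

Samples are clustered agglomeratively on the 1−Pearson distance matrix.
The linkage method is a parameter defaulting to average (UPGMA), the
conventional choice for abundance profiles. One tree is fitted; cutting it
at k and k+1 therefore yields nested partitions. Cluster ids are contiguous
integers ordered by decreasing size.

k is selected by cutting the single dendrogram at every k in a candidate
range (default 2–15) and maximizing the mean silhouette width computed on
the same 1−Pearson distances — the criterion is kept internally consistent
with the clustering geometry rather than re-embedding in Euclidean space.
Ties break toward smaller k. Silhouette conventions: singleton clusters
score 0, and the degenerate a = b = 0 case (identical points) scores 0.

Clusters holding at least 15% of samples (inclusive threshold) are flagged
as high prevalence clusters (HPCs); the collective coverage (sum of HPC
prevalences) and the per-cluster composition of metadata groups are
reported alongside.

## Driver taxa

Each species' relative abundance is regressed on cluster membership
(indicator-coded one-way linear model) and summarized by adjusted R²
(`1 − (1−R²)(n−1)/(n−p−1)`, p = number of indicator predictors). For a
categorical predictor, polynomial terms are vacuous, so the default mode
ignores the degree; an alternative `pcoa_poly` mode regresses abundance on
powers 1..degree of the first PCoA coordinate for a continuous-gradient
reading. Zero-variance species score 0 by convention rather than erroring.
Species with adjusted R² strictly above 0.15 form the driver set.

Driver coverage of a cluster is, by default, the mean over member samples
of the summed driver abundance (×100); a pooled variant (total driver
abundance over total abundance) is available, since the two readings differ
for uneven sample sums only in count mode but answer subtly different
questions.

Group differences per taxon use Welch's unequal-variance t-test — abundance
variances differ strongly between groups, making the pooled variant
unsafe — with optional Benjamini-Hochberg q-values (off by default, so raw
p-values mirror single-test reporting).

## Co-occurrence networks

Species present in at least 20% of the subset's samples (default) are
nodes; the prevalence filter avoids tau degenerating on all-tied sparse
vectors. Every node pair is tested with Kendall's tau-b; tie corrections
enter both the denominator and the null variance of C − D. p-values use
exact enumeration for tie-free vectors with n ≤ 10 and otherwise the
tie-corrected normal approximation with a continuity correction of 1 on
|C − D|. The all-pairs screen computes C − D for every pair via a single
matrix product of pairwise sign patterns, which is exact (integer-valued)
and fast for a few hundred taxa; the scalar and all-pairs routes are tested
to agree to 1e-12. Spearman's rho is a selectable alternative engine.

p-values are Benjamini-Hochberg adjusted across all tested pairs and edges
retained at q ≤ 0.05 (alpha and the correction are parameters; raw-p
filtering is available). Edges carry tau, p, q and a sign (positive ⟺
tau > 0). Module structure is found by greedy (Clauset-Newman-Moore)
modularity maximization on |tau| weights — sign-aware modularity is not
used; the sign is an edge attribute only. The greedy agglomeration is
deterministic. Keystone taxa are ranked by degree, ties broken by higher
mean abundance then name.

## Synthetic cohorts

The generator emulates the downstream product of species-level profiling of
a mixed athlete/non-athlete cohort. Each sample draws a latent state from a
categorical distribution; its profile is a symmetric Dirichlet draw
(concentration `dirichlet_base`, default 1.0) whose concentrations for the
state's dominant taxa are multiplied by boost factors — a boosted taxon's
expected share is roughly `boost / (Σ boosts + #unboosted)`. Group labels
are Bernoulli draws with a per-state athlete probability. Targeted pairwise
dependence, which Dirichlet draws cannot encode, is injected by a Gaussian
copula on the underlying gamma variates: a planted edge maps a correlated
standard-normal pair through the gamma quantile function, preserving the
marginals while imposing rank correlation of chosen sign and strength
(Kendall's tau of the latent pair is `(2/π) arcsin(ρ)`, mildly attenuated
by compositional closure). An optional multinomial resampling step at a
given read depth produces count-like zeros.

The default configuration is a 207-sample × 330-species cohort with three
states (weights 0.30/0.37/0.33, athlete probabilities 0.52/0.18/0.87) whose
dominance archetypes mirror the recurring gut patterns of such cohorts — a
Prevotella-dominated state (leading taxon ≈ 44% mean abundance), a
Bacteroides/Alistipes state (≈ 18%/6%) and a
Faecalibacterium/Eubacterium/Blautia state (≈ 15%/14%/7%) — plus six
planted correlation edges (strengths 0.8–0.9, four positive, two negative)
between otherwise unremarkable taxa. A truth record (states, driver taxa,
planted edges) is a first-class output so recovery can be scored without
reaching into generator internals.

What the generator does *not* emulate: sequencing noise and classifier
misassignment, sparsity/zero-inflation in relative mode (gamma draws are
continuous), phylogenetic correlation among taxa, study batch effects, and
uneven library sizes. Passing recovery tests therefore demonstrates that
the pipeline's inference is correct under its own statistical assumptions,
not that those assumptions hold for any particular real cohort.

## Verification strategy and problem sizes

Correctness rests on three layers: (i) oracle equivalence — the silhouette
against a brute-force double loop (50×50, 1e-12), tau-b against exhaustive
pair counting (1,000 random vectors, n ≤ 8, 1e-12), PERMANOVA against full
permutation enumeration at n = 6, and cross-checks against skbio
(PCoA, PERMANOVA statistic), sklearn (silhouette) and statsmodels (adjusted
R²); (ii) frequentist calibration — PERMANOVA type-I error over 500 null
cohorts (n = 30, 199 permutations) and Welch type-I error over 200 null
cohorts, both required to land in [0.03, 0.07] at α = 0.05; (iii) planted
recovery on the default cohort configuration — k = 3 in ≥ 18/20 seeds with
ARI ≥ 0.9, exact HPC flags, all planted drivers and no false drivers at the
0.15 cutoff, and ≥ 80% of planted edges recovered with correct sign at
BH q ≤ 0.05 over 10 seeds. These problem sizes keep the full suite under a
minute on one core while leaving the assertions statistically meaningful.

## Known limitations

* Rank-correlation networks on compositional data inherit closure-induced
  negative bias; no SparCC/SPIEC-EASI-style compositional correction is
  applied, by design — the method is plain rank correlation.
* Dominance-state structure itself induces genuine monotone associations
  between dominant taxa, so a cohort-level network contains more edges than
  the planted set; per-state subsetting (`subset`/`--subset`) is the way to
  study within-state structure.
* Average-linkage + silhouette can be insensitive to small genuine clusters
  below the silhouette's resolution; the HPC prevalence threshold is the
  guard against over-interpreting such clusters.
* PERMANOVA assumes exchangeability under the null; with strong study
  batch structure, use the stratified permutation option.
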