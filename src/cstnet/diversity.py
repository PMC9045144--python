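"""Alpha diversity, Bray-Curtis beta diversity, PCoA and PERMANOVA.

Alpha diversity is threshold-based species richness: the number of species
whose relative abundance exceeds a cutoff (default 0.5%; 0.05% is offered
as a preset because both conventions circulate for shotgun profiles).
Between-sample dissimilarity is Bray-Curtis, which for unit-sum profiles
reduces to ``1 - sum_i min(p_i, q_i)``.  Ordination is classical principal
coordinates analysis (Gower double-centering of ``-d^2/2`` followed by an
eigendecomposition), and group effects on a distance matrix are tested with
the distance-based pseudo-F of permutational multivariate ANOVA.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _scipy_braycurtis
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RICHNESS_THRESHOLD_DEFAULT",
    "RICHNESS_THRESHOLD_PERMISSIVE",
    "species_richness",
    "richness_per_sample",
    "bray_curtis",
    "distance_matrix",
    "OrdinationResult",
    "pcoa",
    "PermanovaResult",
    "permanova",
]

#: Richness cutoff of 0.5% relative abundance.
RICHNESS_THRESHOLD_DEFAULT = 0.005
#: Permissive preset: 0.05% relative abundance.
RICHNESS_THRESHOLD_PERMISSIVE = 0.0005


def species_richness(profile, threshold: float = RICHNESS_THRESHOLD_DEFAULT) -> int:
    """Count species with relative abundance strictly greater than ``threshold``.

    ``profile`` is a single sample's relative-abundance vector (sums to 1).
    """
    if not 0 <= threshold < 1:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    values = np.asarray(profile, dtype=float)
    return int((values > threshold).sum())


def richness_per_sample(table, threshold: float = RICHNESS_THRESHOLD_DEFAULT) -> pd.Series:
    """Threshold richness for every sample of an abundance table."""
    if not 0 <= threshold < 1:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    counts = (table.values > threshold).sum(axis=1)
    return pd.Series(counts, index=table.sample_ids, name="richness")


def bray_curtis(p, q) -> float:
    """Bray-Curtis dissimilarity between two relative-abundance profiles.

    For profiles over the same species set that each sum to one this equals
    ``1 - sum_i min(p_i, q_i)``; it is symmetric and lies in [0, 1].
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"profiles have mismatched species sets: {p.shape} vs {q.shape}")
    return float(_scipy_braycurtis(p, q))


def _pearson_distances(values: np.ndarray, sample_ids) -> np.ndarray:
    """1 - Pearson r between sample rows, computed over species abundances."""
    sd = values.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        names = [sample_ids[i] for i in flat[:5]]
        raise ValueError(f"zero-variance sample(s) under pearson metric: {names}")
    r = np.corrcoef(values)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    # numerical symmetry for downstream validating containers
    return (d + d.T) / 2.0


def distance_matrix(table, metric: str = "bray_curtis") -> DistanceMatrix:
    """Pairwise sample dissimilarities as a validated ``skbio.DistanceMatrix``.

    ``bray_curtis`` applies the Bray-Curtis dissimilarity; ``pearson``
    uses ``1 - r`` where r is the Pearson correlation of the two samples'
    species abundance vectors (range [0, 2]).
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    values = table.values
    if metric in ("bray_curtis", "bray"):
        d = squareform(pdist(values, metric="braycurtis"))
    elif metric == "pearson":
        d = _pearson_distances(values, table.sample_ids)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(np.clip(d, 0.0, None), ids=[str(s) for s in table.sample_ids])


@dataclass
class OrdinationResult:
    """PCoA embedding: sample coordinates plus the eigenvalue spectrum.

    ``proportion_explained`` divides each retained (positive) eigenvalue by
    the sum of all positive eigenvalues; negative eigenvalues are dropped.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


_EIG_TOL = 1e-10


def pcoa(dm: DistanceMatrix, n_axes: int = 3) -> OrdinationResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    The Gower-centered matrix ``-0.5 * J d^2 J`` (J the centering projector)
    is eigendecomposed; axes with eigenvalue <= 1e-10 are dropped and
    negative eigenvalues are excluded from the proportion-explained
    denominator.  Sign convention: the first nonzero loading of each axis is
    made positive, so coordinates are reproducible across platforms.
    """
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    g = j @ a @ j
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    positive = eigvals > _EIG_TOL
    pos_vals = eigvals[positive]
    pos_vecs = eigvecs[:, positive]
    if n_axes > pos_vals.size:
        logger.warning(
            "requested %d axes but only %d positive eigenvalues; returning all",
            n_axes, pos_vals.size,
        )
        n_axes = pos_vals.size
    coords = pos_vecs[:, :n_axes] * np.sqrt(pos_vals[:n_axes])
    for ax in range(coords.shape[1]):
        col = coords[:, ax]
        nonzero = np.flatnonzero(np.abs(col) > 1e-12)
        if nonzero.size and col[nonzero[0]] < 0:
            coords[:, ax] = -col
    total = pos_vals.sum()
    proportion = pos_vals[:n_axes] / total if total > 0 else np.zeros(n_axes)
    frame = pd.DataFrame(
        coords, index=list(dm.ids), columns=[f"PC{i+1}" for i in range(coords.shape[1])]
    )
    return OrdinationResult(frame, pos_vals[:n_axes], proportion)


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    seed: int | None


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    """Distance-based pseudo-F from the squared distance matrix.

    SS_total = sum_{i<j} d2_ij / N; SS_within = sum_g (1/n_g) sum_{i<j in g} d2_ij;
    F = ((SS_total - SS_within)/(a-1)) / (SS_within/(N-a)).
    """
    n = d2.shape[0]
    a = groups.size
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in groups:
        mask = labels == g
        ng = int(mask.sum())
        ss_within += d2[np.ix_(mask, mask)].sum() / (2.0 * ng)
    return ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))


def permanova(
    dm: DistanceMatrix,
    labels,
    n_perm: int = 1000,
    seed: int | None = None,
    strata=None,
    method: str = "monte_carlo",
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    The pseudo-F statistic follows the distance-based formulation of
    one-way PERMANOVA.  The Monte Carlo p-value uses the +1/+1 convention
    ``p = (1 + #{F_perm >= F_obs}) / (n_perm + 1)``, counting ties as
    extreme, so ``p >= 1/(n_perm+1)`` always.  ``strata`` restricts label
    permutations to occur within each stratum (e.g. study of origin).
    ``method='exhaustive'`` enumerates every distinct relabelling instead
    (identity included in the reference set; feasible only for small n).
    """
    labels = np.asarray(labels)
    n = len(dm.ids)
    if labels.shape[0] != n:
        raise ValueError("labels length does not match distance matrix")
    groups, counts = np.unique(labels, return_counts=True)
    if groups.size < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = groups[counts < 2].tolist()
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    d2 = np.asarray(dm.data, dtype=float) ** 2
    f_obs = _pseudo_f(d2, labels, groups)

    if method == "exhaustive":
        if strata is not None:
            raise ValueError("exhaustive enumeration does not support strata")
        seen_f = []
        for perm in set(itertools.permutations(labels.tolist())):
            seen_f.append(_pseudo_f(d2, np.asarray(perm), groups))
        seen_f = np.asarray(seen_f)
        p = float((seen_f >= f_obs - 1e-12).sum()) / seen_f.size
        return PermanovaResult(float(f_obs), p, seen_f.size, seed)

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    if strata is None:
        perm_indices = np.argsort(rng.random((n_perm, n)), axis=1)
    else:
        strata = np.asarray(strata)
        perm_indices = np.tile(np.arange(n), (n_perm, 1))
        for s in np.unique(strata):
            idx = np.flatnonzero(strata == s)
            sub = np.argsort(rng.random((n_perm, idx.size)), axis=1)
            perm_indices[:, idx] = idx[sub]

    # vectorized within-group sums: for permuted membership indicators B_g,
    # sum_{i<j in g} d2_ij = (B_g D2 B_g^T)_pp / 2
    ge = 0
    f_perm = np.empty(n_perm)
    n_groups = groups.size
    ss_total = d2.sum() / (2.0 * n)
    within = np.zeros(n_perm)
    for g in groups:
        base = (labels == g).astype(float)
        b = base[perm_indices]  # n_perm x n indicator rows
        ng = base.sum()
        within += np.einsum("pn,nm,pm->p", b, d2, b) / (2.0 * ng)
    f_perm = ((ss_total - within) / (n_groups - 1)) / (within / (n - n_groups))
    ge = int((f_perm >= f_obs - 1e-12).sum())
    p = (1.0 + ge) / (n_perm + 1.0)
    return PermanovaResult(float(f_obs), float(p), n_perm, seed)
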