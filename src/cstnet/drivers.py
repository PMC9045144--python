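"""Driver-taxon ranking and per-taxon group tests.

A driver taxon is a species whose abundance variation across samples tracks
the cluster (CST/HPC) structure.  Each species' relative abundance is
regressed on cluster membership (indicator-coded one-way linear model) and
ranked by adjusted R-squared; species above a cutoff (default 0.15, strict
inequality) form the driver set.  An alternative mode regresses abundance
on polynomial functions of the first PCoA coordinate for a continuous-axis
reading of "variance explained".  Per-taxon athlete/non-athlete differences
use Welch's two-sample t-test, optionally with Benjamini-Hochberg q-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AbundanceTable, align_metadata

__all__ = [
    "DriverTaxaResult",
    "variance_explained",
    "select_drivers",
    "driver_coverage",
    "taxon_group_test",
]

DRIVER_R2_THRESHOLD = 0.15


@dataclass
class DriverTaxaResult:
    adj_r2: pd.Series
    selected: list
    coverage_by_hpc: pd.Series
    threshold: float


def _adjusted_r2(r2: np.ndarray, n: int, n_predictors: int) -> np.ndarray:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_predictors - 1)


def variance_explained(
    table: AbundanceTable,
    labels,
    degree: int = 1,
    mode: str = "categorical",
    axis_values=None,
) -> pd.Series:
    """Adjusted R-squared of each species with respect to cluster structure.

    ``mode='categorical'`` (default) fits the one-way linear model of the
    species' abundance on cluster indicators; with a categorical predictor,
    polynomial terms are vacuous, so ``degree`` is ignored.  In
    ``mode='pcoa_poly'`` the abundance is regressed on powers 1..degree of a
    continuous axis (``axis_values``, typically the first PCoA coordinate).
    Zero-variance species get adjusted R-squared 0 by convention.
    """
    y = table.values  # n x p
    n = y.shape[0]
    if mode == "categorical":
        labels = np.asarray(labels)
        codes, inv = np.unique(labels, return_inverse=True)
        if codes.size < 2:
            raise ValueError("need at least 2 clusters")
        _, counts = np.unique(inv, return_counts=True)
        if (counts < 2).any():
            raise ValueError("every cluster needs at least 2 samples")
        onehot = np.zeros((n, codes.size))
        onehot[np.arange(n), inv] = 1.0
        group_means = (onehot.T @ y) / counts[:, None]
        fitted = onehot @ group_means
        n_predictors = codes.size - 1
    elif mode == "pcoa_poly":
        if axis_values is None:
            raise ValueError("pcoa_poly mode needs axis_values")
        if degree < 1:
            raise ValueError("degree must be >= 1")
        x = np.asarray(axis_values, dtype=float)
        design = np.column_stack([np.ones(n)] + [x**d for d in range(1, degree + 1)])
        q, _ = np.linalg.qr(design)
        fitted = q @ (q.T @ y)
        n_predictors = degree
    else:
        raise ValueError(f"unknown mode {mode!r}")

    ss_res = ((y - fitted) ** 2).sum(axis=0)
    ss_tot = ((y - y.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = 1.0 - ss_res / ss_tot
    adj = _adjusted_r2(r2, n, n_predictors)
    adj = np.where(ss_tot == 0, 0.0, adj)  # constant species explain nothing
    return pd.Series(adj, index=table.species_ids, name="adj_r2")


def select_drivers(adj_r2: pd.Series, threshold: float = DRIVER_R2_THRESHOLD) -> list:
    """Species with adjusted R-squared strictly above ``threshold``.

    Returned in descending adjusted-R-squared order.
    """
    chosen = adj_r2[adj_r2 > threshold]
    return list(chosen.sort_values(ascending=False).index)


def driver_coverage(
    table: AbundanceTable,
    labels,
    drivers,
    mode: str = "per_sample_mean",
) -> pd.Series:
    """Percent of each cluster's composition contributed by the driver set.

    ``per_sample_mean`` (default) averages, over a cluster's members, the
    summed relative abundance of driver species; ``pooled`` instead sums
    driver abundance over all member samples and divides by the pooled
    total.  Values are percentages in [0, 100].
    """
    drivers = list(drivers)
    unknown = [s for s in drivers if s not in table.data.columns]
    if unknown:
        raise ValueError(f"unknown driver species: {unknown[:5]}")
    labels = pd.Series(np.asarray(labels), index=table.sample_ids)
    driver_sum = table.data[drivers].sum(axis=1) if drivers else pd.Series(0.0, index=table.data.index)
    if mode == "per_sample_mean":
        cov = driver_sum.groupby(labels).mean()
    elif mode == "pooled":
        total = table.data.sum(axis=1).groupby(labels).sum()
        cov = driver_sum.groupby(labels).sum() / total
    else:
        raise ValueError(f"unknown mode {mode!r}")
    cov.index.name = "cluster"
    return 100.0 * cov


def taxon_group_test(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    group_col: str = "group",
    correction: str = "none",
) -> pd.DataFrame:
    """Welch two-sample t-test per species between the two metadata groups.

    Returns a DataFrame with columns ``t``, ``p`` and (if
    ``correction='bh'``) Benjamini-Hochberg ``q``.  Species with zero
    variance in both groups are reported with t = 0, p = 1.
    """
    meta = align_metadata(table, metadata)
    groups = meta[group_col].astype(str)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, found {levels}")
    mask_a = (groups == levels[0]).to_numpy()
    mask_b = ~mask_a
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("both groups need at least 2 samples")
    ya, yb = table.values[mask_a], table.values[mask_b]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(ya, yb, equal_var=False, axis=0)
    degenerate = (ya.var(axis=0) == 0) & (yb.var(axis=0) == 0)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    out = pd.DataFrame({"t": t, "p": p}, index=table.species_ids)
    if correction == "bh":
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    return out
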