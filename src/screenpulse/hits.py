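"""Differential β-scores, mean±kσ hit calling, the 2-of-3-day
high-fidelity filter, and trajectory clustering.

The differential β at day *t*, Δβ = β(drug, t) − β(vehicle, t), isolates
drug-specific selection from baseline knockout fitness.  Per day, genes
beyond mean ± kσ of the Δβ distribution (population σ, strict
inequalities) are called positively (+1) or negatively (−1) selected; a
*high-fidelity* hit repeats the same direction on at least ``min_days``
of the late sampling days (default two of Days 6, 8, 10).  High-fidelity
trajectories are grouped by Ward-linkage hierarchical clustering on the
replicate-averaged Δβ time course.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .errors import ConfigError, ConsistencyError
from .beta import BetaTable

__all__ = [
    "differential_beta", "differential_beta_from_table", "average_replicates",
    "select_hits", "high_fidelity_hits", "cluster_trajectories",
    "HitTable", "ClusterAssignment",
]


def differential_beta(beta_treat: pd.DataFrame,
                      beta_control: pd.DataFrame) -> pd.DataFrame:
    """Δβ = treated − control, on gene × day matrices.

    Genes missing from either side are dropped with a warning; no shared
    day is an error.
    """
    days = [d for d in beta_treat.columns if d in set(beta_control.columns)]
    if not days:
        raise ConfigError("no shared days between the two beta tables")
    genes = beta_treat.index.intersection(beta_control.index)
    dropped = (len(beta_treat.index) - len(genes)) + (len(beta_control.index) - len(genes))
    if dropped:
        warnings.warn(f"dropping {dropped} gene rows missing from one side")
    return beta_treat.loc[genes, days] - beta_control.loc[genes, days]


def differential_beta_from_table(bt: BetaTable, treat: str = "DAC",
                                 control: str = "DMSO") -> pd.DataFrame:
    """Convenience: split a BetaTable's ``{COND}_D{day}`` contrasts and
    subtract control from treated per day."""
    return differential_beta(bt.by_day(treat), bt.by_day(control))


def average_replicates(diff_tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Arithmetic mean of per-replicate Δβ tables (identical indices required)."""
    tables = list(diff_tables)
    if not tables:
        raise ConfigError("no replicate tables given")
    first = tables[0]
    for t in tables[1:]:
        if not (t.index.equals(first.index) and list(t.columns) == list(first.columns)):
            raise ConsistencyError("replicate tables have mismatching gene/day index")
    return sum(tables) / len(tables)


@dataclass
class HitTable:
    """Per-day selection calls and the thresholds that produced them.

    ``calls``: gene × day in {+1, 0, −1}.  ``thresholds``: per day —
    mean, sigma (population), lo = mean − kσ, hi = mean + kσ.
    ``flags``: per gene — ``hf_pos``, ``hf_neg``, ``ambiguous`` (set by
    :func:`high_fidelity_hits`).
    """

    calls: pd.DataFrame
    thresholds: pd.DataFrame
    k_sigma: float
    flags: pd.DataFrame | None = None

    def to_tsv(self, path) -> None:
        out = self.calls.copy()
        out.columns = [f"D{d}" for d in out.columns]
        if self.flags is not None:
            out = out.join(self.flags)
        out.index.name = "gene"
        out.to_csv(path, sep="\t")

    def thresholds_to_tsv(self, path) -> None:
        t = self.thresholds.copy()
        t.index.name = "day"
        t.to_csv(path, sep="\t")


def select_hits(diff: pd.DataFrame, k_sigma: float = 2.0) -> HitTable:
    """Call per-day hits by the mean ± kσ rule on the Δβ distribution.

    σ is the population standard deviation over all genes of that day;
    calls use strict inequalities.  A zero-σ day yields no calls (warning).
    """
    if diff.shape[0] < 2:
        raise ConfigError("need at least 2 genes per day to estimate sigma")
    calls = pd.DataFrame(0, index=diff.index, columns=diff.columns, dtype=np.int8)
    rows = []
    for day in diff.columns:
        x = diff[day].to_numpy(dtype=float)
        finite = np.isfinite(x)
        mean = float(x[finite].mean())
        sigma = float(x[finite].std(ddof=0))
        lo, hi = mean - k_sigma * sigma, mean + k_sigma * sigma
        rows.append((day, mean, sigma, lo, hi))
        if sigma == 0.0:
            warnings.warn(f"day {day}: sigma is zero, no calls made")
            continue
        calls.loc[finite & (x > hi), day] = 1
        calls.loc[finite & (x < lo), day] = -1
    thresholds = pd.DataFrame(rows, columns=["day", "mean", "sigma", "lo", "hi"]
                              ).set_index("day")
    return HitTable(calls=calls, thresholds=thresholds, k_sigma=k_sigma)


def high_fidelity_hits(hits: HitTable, days: Iterable[int] = (6, 8, 10),
                       min_days: int = 2) -> HitTable:
    """Flag genes called in the same direction on >= ``min_days`` of
    ``days``.  A gene qualifying in both directions is flagged ambiguous
    instead (direction consistency is the point of the filter)."""
    days = list(days)
    present = [d for d in days if d in list(hits.calls.columns)]
    if not present:
        raise ConfigError(f"none of days {days} present in the hit table")
    if len(present) < min_days:
        raise ConfigError(
            f"only {len(present)} of days {days} present; need >= {min_days}")
    sub = hits.calls[present]
    n_pos = (sub == 1).sum(axis=1)
    n_neg = (sub == -1).sum(axis=1)
    hf_pos = n_pos >= min_days
    hf_neg = n_neg >= min_days
    ambiguous = hf_pos & hf_neg
    hf_pos = hf_pos & ~ambiguous
    hf_neg = hf_neg & ~ambiguous
    flags = pd.DataFrame({"hf_pos": hf_pos, "hf_neg": hf_neg,
                          "ambiguous": ambiguous})
    return HitTable(calls=hits.calls, thresholds=hits.thresholds,
                    k_sigma=hits.k_sigma, flags=flags)


@dataclass
class ClusterAssignment:
    """Cluster labels (1..k) for high-fidelity genes plus per-cluster
    centroid trajectories; labels are ordered by descending centroid value
    at the final day, so cluster 1 is the most enriched late trajectory."""

    labels: pd.Series
    centroids: pd.DataFrame

    def to_tsv(self, path) -> None:
        out = self.labels.rename("cluster").to_frame()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")


def cluster_trajectories(diff_hf: pd.DataFrame, k: int = 6) -> ClusterAssignment:
    """Ward-linkage agglomerative clustering of Δβ trajectories.

    ``diff_hf``: gene × day replicate-averaged Δβ with no missing cells.
    The tree is cut at ``k`` clusters; deterministic for fixed input.
    """
    if k < 1:
        raise ConfigError("k must be >= 1")
    if k > diff_hf.shape[0]:
        raise ConfigError(f"k={k} exceeds number of genes ({diff_hf.shape[0]})")
    X = diff_hf.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ConsistencyError("trajectories contain missing values")
    if k == diff_hf.shape[0]:
        raw = np.arange(1, k + 1)
    elif k == 1:
        raw = np.ones(diff_hf.shape[0], dtype=int)
    else:
        Z = linkage(X, method="ward")
        raw = fcluster(Z, t=k, criterion="maxclust")
    cents = pd.DataFrame(
        [X[raw == c].mean(axis=0) for c in range(1, raw.max() + 1)],
        columns=diff_hf.columns,
    )
    order = np.argsort(-cents.iloc[:, -1].to_numpy(), kind="stable")
    relabel = {int(old) + 1: rank + 1 for rank, old in enumerate(order)}
    labels = pd.Series([relabel[int(c)] for c in raw], index=diff_hf.index,
                       name="cluster")
    centroids = cents.iloc[order].reset_index(drop=True)
    centroids.index = pd.RangeIndex(1, len(order) + 1, name="cluster")
    return ClusterAssignment(labels=labels, centroids=centroids)
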