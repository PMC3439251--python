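"""Stability class derivation: PSI, hierarchical clustering of 7-bin
distributions and the stable/unstable/non-assigned assignment rule.

Proteins are clustered on the Euclidean geometry of their normalized
7-bin FACS distributions (complete-linkage agglomeration). The tree is cut
into ``k`` groups; the group whose centroid puts the most mass in the
fast-turnover bins R1+R2 is labelled unstable, the group with the most
mass in R5+R6+R7 stable, and every other group non-assigned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .io import GpspRecord, N_BINS


@dataclass
class StabilityAssignment:
    protein_id: str
    label: str  # "stable" / "unstable" / "non_assigned"
    psi: float


@dataclass
class Dendrogram:
    """Agglomerative merge tree in scipy linkage-matrix form."""

    merges: np.ndarray  # (n-1, 4) scipy linkage matrix
    n_leaves: int

    def __post_init__(self) -> None:
        heights = self.merges[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise ValueError("merge heights must be non-decreasing")


def compute_psi(bins: Sequence[float]) -> float:
    """Protein stability index: the bin-weighted mean ``sum_i R_i * i``.

    ``bins`` holds the proportions over bins R1..R7; the PSI lies in
    [1, 7] and grows with stability.
    """
    bins = np.asarray(bins, dtype=float)
    if bins.shape != (N_BINS,):
        raise ValueError(f"expected {N_BINS} bins")
    if np.any(bins < 0) or abs(bins.sum() - 1.0) > 1e-6:
        raise ValueError("bins must be non-negative and sum to 1")
    return float(bins @ np.arange(1, N_BINS + 1))


def cluster_distributions(records: Sequence[GpspRecord]) -> Dendrogram:
    """Complete-linkage agglomerative clustering under Euclidean distance."""
    if len(records) < 2:
        raise ValueError("need at least 2 records to cluster")
    ids = [r.protein_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids in GPSP records")
    X = np.vstack([r.bins for r in records])
    merges = linkage(X, method="complete", metric="euclidean")
    return Dendrogram(merges=merges, n_leaves=len(records))


# mass windows that define the extreme groups
_UNSTABLE_BINS = slice(0, 2)  # R1, R2
_STABLE_BINS = slice(4, 7)  # R5, R6, R7


def assign_classes(
    dendrogram: Dendrogram,
    records: Sequence[GpspRecord],
    k: int = 3,
) -> list[StabilityAssignment]:
    """Cut the tree into ``k`` groups and label the extreme ones.

    The unstable group maximizes centroid mass over R1+R2, the stable one
    over R5+R6+R7; they must differ (an error otherwise flags data with no
    extreme structure). All remaining groups are non-assigned.
    """
    if k < 3:
        raise ValueError("k must be >= 3 (stable, unstable, non-assigned)")
    if dendrogram.n_leaves != len(records):
        raise ValueError("dendrogram and record list disagree in size")
    groups = fcluster(dendrogram.merges, t=k, criterion="maxclust")
    found = np.unique(groups)
    if len(found) != k:
        raise ValueError(
            f"degenerate cut: requested {k} groups but obtained {len(found)}"
        )
    X = np.vstack([r.bins for r in records])
    unstable_mass = {g: X[groups == g, _UNSTABLE_BINS].sum(axis=1).mean() for g in found}
    stable_mass = {g: X[groups == g, _STABLE_BINS].sum(axis=1).mean() for g in found}
    unstable_group = max(found, key=lambda g: unstable_mass[g])
    stable_group = max(found, key=lambda g: stable_mass[g])
    if unstable_group == stable_group:
        raise ValueError(
            "the same group maximizes both extreme-bin masses; "
            "no stable/unstable split exists at this cut"
        )
    assignments = []
    for record, g in zip(records, groups):
        if g == unstable_group:
            label = "unstable"
        elif g == stable_group:
            label = "stable"
        else:
            label = "non_assigned"
        assignments.append(
            StabilityAssignment(record.protein_id, label, compute_psi(record.bins))
        )
    return assignments
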