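"""Network construction: symmetrization, thresholding and basic checks.

Raw tractography matrices are directed counts (seed-to-target streamlines).
The construction pipeline is fixed as: symmetrize by arithmetic averaging,
proportional thresholding (keep a fixed fraction of the strongest edges),
per-group prevalence masking (keep edges present in at least a fraction tau
of a group's subjects), and optional binarization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Cohort, Connectome

__all__ = [
    "ThresholdReport",
    "symmetrize",
    "proportional_threshold",
    "prevalence_mask",
    "apply_mask",
    "binarize",
    "density",
    "total_connectivity",
    "connectedness_check",
    "construct_cohort",
]


@dataclass
class ThresholdReport:
    """Edge counts before/after each construction step (per subject means)."""

    edges_before: float
    edges_after_proportional: float
    edges_after_prevalence: dict[str, float]
    threshold_proportion: float
    prevalence_tau: float


def symmetrize(W_directed: np.ndarray, subject_id: str = "", group: str = "") -> Connectome:
    """Average directed streamline counts into an undirected network.

    W[i, j] = (W_dir[i, j] + W_dir[j, i]) / 2, with the diagonal zeroed.
    """
    W_directed = np.asarray(W_directed, dtype=float)
    if W_directed.ndim != 2 or W_directed.shape[0] != W_directed.shape[1]:
        raise ValueError("directed matrix must be square")
    if np.any(W_directed < 0):
        raise ValueError("negative streamline count")
    W = (W_directed + W_directed.T) / 2.0
    np.fill_diagonal(W, 0.0)
    return Connectome(subject_id=subject_id, group=group, W=W)


def _upper_edges(W: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    i, j = np.nonzero(np.triu(W, k=1))
    return i, j, W[i, j]


def proportional_threshold(C: Connectome, p: float) -> Connectome:
    """Retain exactly floor(p * M) of the M strongest edges; zero the rest.

    Ties at the cut are broken deterministically by (weight descending,
    then smaller i, then smaller j) so runs are reproducible.
    """
    if not 0 < p <= 1:
        raise ValueError("proportion must be in (0, 1]")
    i, j, w = _upper_edges(C.W)
    m = len(w)
    keep = int(np.floor(p * m))
    # lexsort: last key is primary
    order = np.lexsort((j, i, -w))
    sel = order[:keep]
    W = np.zeros_like(C.W)
    W[i[sel], j[sel]] = w[sel]
    W += W.T
    return C.replace(W)


def prevalence_mask(cohort: Cohort, tau: float) -> dict[str, np.ndarray]:
    """Per-group binary edge masks: edge kept iff present (weight > 0) in at
    least a fraction ``tau`` of that group's subjects (boundary inclusive)."""
    if not 0 <= tau <= 1:
        raise ValueError("tau must be in [0, 1]")
    masks: dict[str, np.ndarray] = {}
    for g in cohort.group_levels:
        members = cohort.subjects(g)
        if not members:
            raise ValueError(f"group {g!r} is empty")
        presence = np.mean([(c.W > 0) for c in members], axis=0)
        masks[g] = (presence >= tau).astype(float) if tau > 0 else np.ones_like(presence, dtype=float)
    return masks


def apply_mask(C: Connectome, mask: np.ndarray) -> Connectome:
    """Zero every edge outside the mask support."""
    if mask.shape != C.W.shape:
        raise ValueError("mask shape mismatch")
    return C.replace(C.W * (mask > 0))


def binarize(C: Connectome) -> Connectome:
    """A[i, j] = 1 iff W[i, j] > 0. Idempotent."""
    return C.binarized()


def density(C: Connectome) -> float:
    """Fraction of present edges among possible edges, ignoring weights."""
    n = C.n_nodes
    if n < 2:
        raise ValueError("density undefined for N < 2")
    e = int((C.W > 0).sum()) // 2
    return 2.0 * e / (n * (n - 1))


def total_connectivity(C: Connectome) -> float:
    """Sum of edge weights over undirected edges (each counted once)."""
    return float(C.W.sum()) / 2.0


def connectedness_check(C: Connectome, min_frac: float = 0.80) -> tuple[bool, float]:
    """Fraction of non-isolated nodes, and whether it exceeds ``min_frac``."""
    n = C.n_nodes
    if n == 0:
        return False, 0.0
    frac = float((C.degrees() >= 1).mean())
    return frac > min_frac, frac


def construct_cohort(cohort: Cohort, proportion: float, tau: float) -> tuple[Cohort, ThresholdReport]:
    """Run the full construction pipeline on every subject of a cohort.

    Each subject is proportionally thresholded, then masked by its own
    group's prevalence mask (computed on the thresholded networks).
    Input connectomes are assumed already symmetric (undirected).
    """
    thresholded = [proportional_threshold(c, proportion) for c in cohort.connectomes]
    inter = Cohort(thresholded, cohort.group_levels, cohort.clinical, cohort.nodes)
    masks = prevalence_mask(inter, tau)
    final = [apply_mask(c, masks[c.group]) for c in thresholded]
    report = ThresholdReport(
        edges_before=float(np.mean([(c.W > 0).sum() / 2 for c in cohort.connectomes])),
        edges_after_proportional=float(np.mean([(c.W > 0).sum() / 2 for c in thresholded])),
        edges_after_prevalence={
            g: float(np.mean([(c.W > 0).sum() / 2 for c in final if c.group == g]))
            for g in cohort.group_levels
        },
        threshold_proportion=proportion,
        prevalence_tau=tau,
    )
    return Cohort(final, cohort.group_levels, cohort.clinical, cohort.nodes), report
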