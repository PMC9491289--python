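"""Rich-club coefficients, hub selection, and edge-class connectivity.

The topological rich-club coefficient at degree level k is the edge density
among the club S(k) = {nodes with degree > k}:

    phi(k) = 2 * E(S) / (|S| * (|S| - 1)),       defined when |S| >= 2.

The weighted variant divides the total weight inside the club by the sum of
the same number of strongest weights anywhere in the network:

    phi_w(k) = W_in(S) / sum of the E(S) largest edge weights,

defined when the club contains at least one edge (degrees always computed
on the binarized network). Both are normalized by the average coefficient
of a degree-preserving (and, for phi_w, weight-multiset-preserving) null
ensemble; a normalized coefficient above 1 indicates rich-club
organization — hubs are more densely / strongly interconnected than their
degrees alone require.

Hubs ("rich-club nodes") are the top fraction f of highest-degree nodes per
subject; the group-level hub set is the intersection across subjects.
Edges are then classed as rich-club (hub-hub), feeder (hub-periphery) or
local (periphery-periphery), and per-class connectivity strength (weight
sum) and weighted connectivity density (share of total strength) are the
subject-level measures compared between groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Cohort, Connectome
from .nulls import NullEnsemble

__all__ = [
    "RichClubCurve",
    "HubPartition",
    "EdgeClassSummary",
    "phi_topological",
    "phi_weighted",
    "rich_club_curve",
    "normalized_curve",
    "significant_range",
    "select_hubs",
    "common_hubs",
    "classify_edges",
    "class_connectivity",
    "auc_over_k",
]

EDGE_CLASSES = ("rich_club", "feeder", "local")


@dataclass
class RichClubCurve:
    """Per-k rich-club coefficients with null normalization.

    Arrays are indexed by k = 0 .. k_max; undefined levels hold NaN.
    ``p_emp`` is the one-sided empirical p-value: the (add-one smoothed)
    proportion of null networks whose coefficient reaches the empirical one.
    """

    subject_id: str
    variant: str  # "topological" | "weighted"
    k: np.ndarray
    phi: np.ndarray
    phi_rand_mean: np.ndarray | None = None
    phi_rand_sd: np.ndarray | None = None
    phi_norm: np.ndarray | None = None
    p_emp: np.ndarray | None = None
    n_club_nodes: np.ndarray | None = None
    n_club_edges: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        cols = {"k": self.k, "phi": self.phi}
        for name in ("phi_rand_mean", "phi_rand_sd", "phi_norm", "p_emp",
                     "n_club_nodes", "n_club_edges"):
            v = getattr(self, name)
            if v is not None:
                cols[name] = v
        df = pd.DataFrame(cols)
        df.insert(0, "variant", self.variant)
        df.insert(0, "subject_id", self.subject_id)
        return df


@dataclass
class HubPartition:
    hub_fraction: float
    per_subject: dict[str, frozenset[int]]
    common_set: frozenset[int]
    cutoffs: dict[str, int] = field(default_factory=dict)


@dataclass
class EdgeClassSummary:
    """Per-subject strength and weighted density of the three edge classes."""

    subject_id: str
    strength: dict[str, float]       # per class, NOS units
    density: dict[str, float]        # per class, fractions of total strength
    strength_total: float
    counts: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Coefficients


def _club(C: Connectome, k: int) -> np.ndarray:
    return np.flatnonzero(C.degrees() > k)


def phi_topological(A: Connectome, k: int) -> float:
    """Edge density among nodes of degree > k; NaN when the club has < 2 nodes."""
    members = _club(A, k)
    m = len(members)
    if m < 2:
        return float("nan")
    e_in = (A.W[np.ix_(members, members)] > 0).sum() / 2
    return float(2.0 * e_in / (m * (m - 1)))


def phi_weighted(W: Connectome, k: int) -> float:
    """Club weight sum over the sum of the equally many strongest weights.

    Degrees are computed on the binarized network; NaN when the club spans
    no edge.
    """
    members = _club(W, k)
    if len(members) < 2:
        return float("nan")
    sub = W.W[np.ix_(members, members)]
    e_in = int((sub > 0).sum() // 2)
    if e_in == 0:
        return float("nan")
    w_in = sub.sum() / 2.0
    i, j = np.nonzero(np.triu(W.W, k=1))
    top = np.sort(W.W[i, j])[::-1][:e_in]
    return float(w_in / top.sum())


def rich_club_curve(C: Connectome, variant: str = "topological") -> RichClubCurve:
    """phi(k) for every k = 0 .. max degree, in one O(N^2 + E log E) pass.

    Nodes are sorted by descending degree, so each club S(k) is a prefix of
    the sorted order; club edge and weight counts accumulate incrementally.
    """
    if variant not in ("topological", "weighted"):
        raise ValueError("variant must be 'topological' or 'weighted'")
    W = C.W
    deg = C.degrees()
    n = C.n_nodes
    k_max = int(deg.max()) if n else 0
    order = np.argsort(-deg, kind="stable")
    deg_sorted = deg[order]
    Wo = W[np.ix_(order, order)]
    Ao = Wo > 0
    # prefix[m]: edges / weight among the m highest-degree nodes
    e_pref = np.zeros(n + 1)
    w_pref = np.zeros(n + 1)
    for m in range(1, n + 1):
        e_pref[m] = e_pref[m - 1] + Ao[m - 1, : m - 1].sum()
        w_pref[m] = w_pref[m - 1] + Wo[m - 1, : m - 1].sum()
    i, j = np.nonzero(np.triu(W, k=1))
    w_desc = np.sort(W[i, j])[::-1]
    cum_top = np.concatenate([[0.0], np.cumsum(w_desc)])

    ks = np.arange(k_max + 1)
    phi = np.full(k_max + 1, np.nan)
    n_nodes_k = np.zeros(k_max + 1, dtype=int)
    n_edges_k = np.zeros(k_max + 1, dtype=int)
    # club size for level k: number of nodes with degree > k
    club_size = np.searchsorted(-deg_sorted, -ks, side="left")
    for k in ks:
        m = int(club_size[k])
        n_nodes_k[k] = m
        if m < 2:
            continue
        e_in = int(e_pref[m])
        n_edges_k[k] = e_in
        if variant == "topological":
            phi[k] = 2.0 * e_in / (m * (m - 1))
        elif e_in > 0:
            phi[k] = w_pref[m] / cum_top[e_in]
    return RichClubCurve(subject_id=C.subject_id, variant=variant, k=ks, phi=phi,
                         n_club_nodes=n_nodes_k, n_club_edges=n_edges_k)


def normalized_curve(C: Connectome, ensemble: NullEnsemble,
                     variant: str = "topological") -> RichClubCurve:
    """Normalize the empirical curve by the null-ensemble average.

    phi_norm(k) = phi(k) / mean over nulls of phi_rand(k); levels where a
    null's coefficient is undefined are excluded from that level's mean.
    p_emp(k) = (1 + #{nulls with phi_rand(k) >= phi(k)}) / (n_nulls + 1).
    """
    if ensemble.source_id != C.subject_id:
        raise ValueError("ensemble was built from a different network")
    emp = rich_club_curve(C, variant)
    k_max = len(emp.k) - 1
    null_phi = np.full((len(ensemble.members), k_max + 1), np.nan)
    for r, member in enumerate(ensemble.members):
        cur = rich_club_curve(member, variant)
        upto = min(len(cur.phi), k_max + 1)
        null_phi[r, :upto] = cur.phi[:upto]
    defined = ~np.isnan(null_phi)
    n_def = defined.sum(axis=0)
    rand_mean = np.full(k_max + 1, np.nan)
    rand_sd = np.full(k_max + 1, np.nan)
    has = n_def > 0
    if has.any():
        filled = np.where(defined, null_phi, 0.0)
        rand_mean[has] = filled.sum(axis=0)[has] / n_def[has]
        sq = np.where(defined, (null_phi - rand_mean[None, :]) ** 2, 0.0)
        rand_sd[has] = np.sqrt(sq.sum(axis=0)[has] / n_def[has])
    with np.errstate(invalid="ignore", divide="ignore"):
        phi_norm = np.where(rand_mean > 0, emp.phi / rand_mean, np.nan)
    n = len(ensemble.members)
    exceed = (np.where(defined, null_phi, -np.inf) >= emp.phi[None, :]).sum(axis=0)
    p_emp = np.where(np.isnan(emp.phi), np.nan, (1.0 + exceed) / (n + 1.0))
    return RichClubCurve(subject_id=C.subject_id, variant=variant, k=emp.k, phi=emp.phi,
                         phi_rand_mean=rand_mean, phi_rand_sd=rand_sd,
                         phi_norm=phi_norm, p_emp=p_emp,
                         n_club_nodes=emp.n_club_nodes, n_club_edges=emp.n_club_edges)


def significant_range(curves: list[RichClubCurve], coverage: float = 0.97) -> tuple[int, int] | None:
    """Maximal contiguous k-range where at least ``coverage`` of subjects
    show phi_norm > 1. Returns (k_lo, k_hi) inclusive, or None if no level
    qualifies. Undefined levels count against a subject."""
    if not curves:
        return None
    n_sub = len(curves)
    k_max = max(len(c.k) - 1 for c in curves)
    above = np.zeros((n_sub, k_max + 1))
    for r, c in enumerate(curves):
        if c.phi_norm is None:
            raise ValueError("curves must be normalized")
        upto = len(c.phi_norm)
        with np.errstate(invalid="ignore"):
            above[r, :upto] = np.nan_to_num(c.phi_norm, nan=0.0) > 1.0
    frac = above.mean(axis=0)
    ok = frac >= coverage
    best: tuple[int, int] | None = None
    start = None
    for k in range(k_max + 2):
        if k <= k_max and ok[k]:
            if start is None:
                start = k
        elif start is not None:
            if best is None or (k - 1 - start) > (best[1] - best[0]):
                best = (start, k - 1)
            start = None
    return best


# ---------------------------------------------------------------------------
# Hubs and edge classes


def select_hubs(C: Connectome, f: float) -> frozenset[int]:
    """The ceil(f * N) highest-degree nodes.

    Ties at the cutoff are broken by higher strength, then lower node index,
    so the selection is deterministic.
    """
    if not 0 < f < 1:
        raise ValueError("hub fraction must be in (0, 1)")
    n = C.n_nodes
    size = math.ceil(f * n)
    deg = C.degrees()
    s = C.strengths()
    order = np.lexsort((np.arange(n), -s, -deg))
    return frozenset(int(v) for v in order[:size])


def common_hubs(cohort: Cohort, f: float) -> HubPartition:
    """Per-subject hub sets and their intersection across all subjects."""
    per_subject: dict[str, frozenset[int]] = {}
    cutoffs: dict[str, int] = {}
    common: frozenset[int] | None = None
    for c in cohort.connectomes:
        hubs = select_hubs(c, f)
        per_subject[c.subject_id] = hubs
        deg = c.degrees()
        cutoffs[c.subject_id] = int(min(deg[list(hubs)])) if hubs else 0
        common = hubs if common is None else (common & hubs)
    return HubPartition(hub_fraction=f, per_subject=per_subject,
                        common_set=common or frozenset(), cutoffs=cutoffs)


def classify_edges(C: Connectome, R: frozenset[int] | set[int]) -> dict[str, np.ndarray]:
    """Label each present edge rich_club / feeder / local by membership of
    its endpoints in the hub set R. Returns boolean N x N masks per class
    (upper+lower symmetric, present edges only)."""
    if R and (min(R) < 0 or max(R) >= C.n_nodes):
        raise ValueError("hub set contains out-of-range nodes")
    present = C.W > 0
    in_r = np.zeros(C.n_nodes, dtype=bool)
    in_r[list(R)] = True
    both = np.outer(in_r, in_r)
    neither = np.outer(~in_r, ~in_r)
    return {
        "rich_club": present & both,
        "feeder": present & ~both & ~neither,
        "local": present & neither,
    }


def class_connectivity(C: Connectome, labels: dict[str, np.ndarray]) -> EdgeClassSummary:
    """Connectivity strength (weight sum) and weighted connectivity density
    (share of whole-network strength) per edge class."""
    strength = {cls: float(C.W[mask].sum()) / 2.0 for cls, mask in labels.items()}
    counts = {cls: int(mask.sum()) // 2 for cls, mask in labels.items()}
    # classes partition the present edges, so their sum IS the whole-brain
    # strength; summing this way keeps the conservation identity exact
    total = sum(strength.values())
    if total == 0:
        raise ValueError("zero total strength: densities undefined")
    density = {cls: strength[cls] / total for cls in labels}
    return EdgeClassSummary(subject_id=C.subject_id, strength=strength,
                            density=density, strength_total=total, counts=counts)


def auc_over_k(values: np.ndarray, k_range: tuple[int, int]) -> float:
    """Trapezoidal area of a per-k measure over an inclusive integer range.

    ``values`` must be indexed by k (values[k] is the measure at level k)
    and defined on every level of the range.
    """
    lo, hi = k_range
    if lo > hi:
        raise ValueError("empty k range")
    if hi >= len(values):
        raise ValueError(f"values not defined up to k={hi}")
    seg = np.asarray(values[lo:hi + 1], dtype=float)
    if np.any(np.isnan(seg)):
        raise ValueError("measure undefined inside the k range")
    if len(seg) == 1:
        return 0.0
    return float(np.trapezoid(seg, dx=1.0))
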