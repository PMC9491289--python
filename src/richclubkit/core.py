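"""Domain containers and text I/O for connectome analyses.

The in-memory model is deliberately small: a :class:`NodeTable` fixes the
region set, a :class:`Connectome` is one subject's symmetric nonnegative
weighted adjacency over that set (weights in streamline-count, "NOS", units),
and a :class:`Cohort` bundles connectomes with an *ordered* group factor and
a clinical covariate table. All file formats are delimited text (TSV/CSV
matrices or three-column edge lists) so that datasets remain inspectable and
diff-able.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "NodeTable",
    "Connectome",
    "Cohort",
    "AnalysisConfig",
    "read_connectome",
    "read_node_table",
    "read_manifest",
    "write_results",
]


@dataclass(frozen=True)
class NodeTable:
    """Region (node) metadata: names, optional hemisphere and coordinates.

    Node ids are implicit 0..N-1 row positions; names must be unique.
    Coordinates are informational only (mm), never used in computation.
    """

    names: tuple[str, ...]
    hemisphere: tuple[str, ...] | None = None
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("node names must be unique")
        if self.hemisphere is not None:
            bad = set(self.hemisphere) - {"L", "R", "midline"}
            if bad:
                raise ValueError(f"invalid hemisphere labels: {sorted(bad)}")
            if len(self.hemisphere) != len(self.names):
                raise ValueError("hemisphere length mismatch")
        if self.coords is not None and np.asarray(self.coords).shape != (len(self.names), 3):
            raise ValueError("coords must be (N, 3)")

    @property
    def n_nodes(self) -> int:
        return len(self.names)

    @classmethod
    def default(cls, n_nodes: int) -> "NodeTable":
        """A generic table with auto-generated region names."""
        return cls(names=tuple(f"region_{i:03d}" for i in range(n_nodes)))


@dataclass
class Connectome:
    """One subject's undirected weighted network over a fixed node set.

    ``W`` is a dense symmetric N x N matrix with zero diagonal and
    nonnegative weights (streamline counts; stored as floats because
    distance-corrected tract counts need not be integral). ``binary`` marks
    0/1 matrices produced by :func:`richclubkit.construction.binarize`.
    """

    subject_id: str
    group: str
    W: np.ndarray
    binary: bool = False
    nodes: NodeTable | None = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        validate_adjacency(self.W)
        if self.nodes is not None and self.nodes.n_nodes != self.W.shape[0]:
            raise ValueError("node table size does not match matrix")
        if self.binary and not np.isin(self.W, (0.0, 1.0)).all():
            raise ValueError("binary connectome has non-0/1 weights")

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]

    def degrees(self) -> np.ndarray:
        """Binary degree: number of nonzero incident edges per node."""
        return (self.W > 0).sum(axis=0).astype(int)

    def strengths(self) -> np.ndarray:
        """Weighted degree: sum of incident edge weights per node."""
        return self.W.sum(axis=0)

    def binarized(self) -> "Connectome":
        return Connectome(self.subject_id, self.group, (self.W > 0).astype(float),
                          binary=True, nodes=self.nodes)

    def replace(self, W: np.ndarray, binary: bool | None = None) -> "Connectome":
        return Connectome(self.subject_id, self.group, W,
                          binary=self.binary if binary is None else binary,
                          nodes=self.nodes)


def validate_adjacency(W: np.ndarray) -> None:
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {W.shape}")
    if np.any(W < 0):
        i, j = np.argwhere(W < 0)[0]
        raise ValueError(f"negative weight at ({i}, {j})")
    if np.any(np.diag(W) != 0):
        i = int(np.flatnonzero(np.diag(W))[0])
        raise ValueError(f"nonzero diagonal at node {i}")
    if not np.allclose(W, W.T, rtol=0, atol=0):
        raise ValueError("matrix is not symmetric")


@dataclass
class Cohort:
    """Connectomes plus an ordered group factor and clinical covariates.

    ``group_levels`` is ordered: its order encodes the hypothesized monotone
    trend used by the Jonckheere-Terpstra test (e.g. controls < patients).
    ``clinical`` is indexed by subject_id and may carry age, sex, education
    and symptom-severity scores (Y-BOCS, OCI-R, MADRS, disease duration).
    """

    connectomes: list[Connectome]
    group_levels: tuple[str, ...]
    clinical: pd.DataFrame | None = None
    nodes: NodeTable | None = None

    def __post_init__(self) -> None:
        levels = set(self.group_levels)
        for c in self.connectomes:
            if c.group not in levels:
                raise ValueError(f"subject {c.subject_id}: group {c.group!r} not in levels")
        sizes = {c.n_nodes for c in self.connectomes}
        if len(sizes) > 1:
            raise ValueError(f"connectomes disagree on node count: {sorted(sizes)}")

    @property
    def n_subjects(self) -> int:
        return len(self.connectomes)

    @property
    def n_nodes(self) -> int:
        return self.connectomes[0].n_nodes

    def subjects(self, group: str | None = None) -> list[Connectome]:
        if group is None:
            return list(self.connectomes)
        return [c for c in self.connectomes if c.group == group]

    def group_sizes(self) -> dict[str, int]:
        return {g: len(self.subjects(g)) for g in self.group_levels}


@dataclass
class AnalysisConfig:
    """Tunable parameters of the full pipeline, with conventional defaults.

    threshold_proportion
        Fraction of strongest edges retained by proportional thresholding.
    prevalence_tau
        Minimum within-group fraction of subjects in which an edge must be
        present to survive the group-prevalence mask.
    hub_fraction
        Fraction of highest-degree nodes labelled as rich-club hubs
        (sensitivity sweeps typically cover 0.05-0.25).
    n_nulls / n_permutations
        Sizes of the rewired null ensemble and the permutation null.
    fdr_q
        Benjamini-Hochberg false-discovery threshold.
    coverage
        Fraction of subjects that must show normalized rich-club coefficient
        above 1 for a degree level k to enter the tested k-range.
    """

    threshold_proportion: float = 0.23
    prevalence_tau: float = 0.60
    hub_fraction: float = 0.16
    n_nulls: int = 1000
    n_permutations: int = 50_000
    fdr_q: float = 0.05
    coverage: float = 0.97
    n_nulls_small_world: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.threshold_proportion <= 1:
            raise ValueError("threshold_proportion must be in (0, 1]")
        if not 0 <= self.prevalence_tau <= 1:
            raise ValueError("prevalence_tau must be in [0, 1]")
        if not 0 < self.hub_fraction < 1:
            raise ValueError("hub_fraction must be in (0, 1)")
        if self.n_nulls < 1 or self.n_permutations < 1:
            raise ValueError("n_nulls and n_permutations must be >= 1")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must be in (0, 1)")
        if not 0 < self.coverage <= 1:
            raise ValueError("coverage must be in (0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Readers


def read_connectome(path: str | Path, nodes: NodeTable,
                    subject_id: str | None = None, group: str = "") -> Connectome:
    """Read a connectome from a square matrix file or a 3-column edge list.

    Matrix files are N x N delimited numerics (comma or tab/whitespace).
    Edge lists carry ``i j weight`` records, interpreted as undirected;
    duplicate (i, j)/(j, i) records are averaged. Missing pairs are zero.
    """
    path = Path(path)
    if subject_id is None:
        subject_id = path.stem
    with open(path) as fh:
        lines = [ln for ln in (l.strip() for l in fh) if ln]
    if not lines:
        raise ValueError(f"{path}: empty file")
    start = 0
    # optional header: skip a first line that is not fully numeric
    if not _is_numeric_row(lines[0]):
        start = 1
    rows = [_split_row(ln) for ln in lines[start:]]
    n = nodes.n_nodes
    widths = {len(r) for r in rows}
    if widths == {3} and len(rows) != n:
        W = _densify_edge_list(rows, n, path)
    elif len(widths) == 1 and widths == {len(rows)}:
        W = _parse_matrix(rows, n, path)
    elif widths == {3} and len(rows) == 3 and n == 3:
        # ambiguous 3x3: prefer matrix interpretation
        W = _parse_matrix(rows, n, path)
    else:
        raise ValueError(
            f"{path}: expected an {n}x{n} matrix or 3-column edge list; "
            f"got {len(rows)} rows with widths {sorted(widths)}")
    return Connectome(subject_id=subject_id, group=group, W=W, nodes=nodes)


def _is_numeric_row(line: str) -> bool:
    try:
        [float(x) for x in _split_row(line)]
        return True
    except ValueError:
        return False


def _split_row(line: str) -> list[str]:
    if "," in line:
        return [x.strip() for x in line.split(",")]
    return line.split()


def _parse_matrix(rows: list[list[str]], n: int, path: Path) -> np.ndarray:
    if len(rows) != n:
        raise ValueError(f"{path}: matrix has {len(rows)} rows, node table has {n}")
    W = np.array([[float(x) for x in r] for r in rows])
    if W.shape != (n, n):
        raise ValueError(f"{path}: non-square matrix {W.shape}")
    if np.any(W < 0):
        i, j = np.argwhere(W < 0)[0]
        raise ValueError(f"{path}: negative weight at row {i}, column {j}")
    if np.any(np.diag(W) != 0):
        i = int(np.flatnonzero(np.diag(W))[0])
        raise ValueError(f"{path}: nonzero diagonal at node {i}")
    return (W + W.T) / 2.0 if not np.array_equal(W, W.T) else W


def _densify_edge_list(rows: list[list[str]], n: int, path: Path) -> np.ndarray:
    W = np.zeros((n, n))
    counts = np.zeros((n, n))
    for rec_no, r in enumerate(rows, start=1):
        i, j, w = int(float(r[0])), int(float(r[1])), float(r[2])
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"{path}: record {rec_no}: node index ({i}, {j}) out of range 0..{n - 1}")
        if i == j:
            raise ValueError(f"{path}: record {rec_no}: self-loop at node {i}")
        if w < 0:
            raise ValueError(f"{path}: record {rec_no}: negative weight {w}")
        a, b = min(i, j), max(i, j)
        W[a, b] += w
        counts[a, b] += 1
    present = counts > 0
    W[present] /= counts[present]
    return W + W.T


def read_node_table(path: str | Path) -> NodeTable:
    """Read a node table TSV with columns: name [hemisphere] [x y z]."""
    df = pd.read_csv(path, sep="\t")
    hemi = tuple(df["hemisphere"]) if "hemisphere" in df.columns else None
    coords = df[["x", "y", "z"]].to_numpy() if {"x", "y", "z"} <= set(df.columns) else None
    return NodeTable(names=tuple(df["name"].astype(str)), hemisphere=hemi, coords=coords)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a subject manifest TSV: subject_id, group, plus covariates."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise ValueError(f"manifest is missing required column {col!r}")
    return df.set_index("subject_id")


# ---------------------------------------------------------------------------
# Writers


def write_results(tables: Mapping[str, pd.DataFrame], outdir: str | Path,
                  config: Mapping | None = None,
                  seeds: Mapping[str, int] | None = None,
                  extra: Mapping | None = None) -> dict:
    """Write result tables as deterministic TSVs plus a JSON run manifest.

    Returns the manifest dict (also written to ``run_manifest.json``). The
    manifest records the config snapshot, seeds and a SHA-256 per output so
    that byte-identical reruns are verifiable.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hashes: dict[str, str] = {}
    for name, df in sorted(tables.items()):
        p = outdir / f"{name}.tsv"
        text = df.to_csv(sep="\t", index=False, lineterminator="\n", float_format="%.12g")
        p.write_text(text)
        hashes[name] = hashlib.sha256(text.encode()).hexdigest()
    manifest = {
        "config": dict(config) if config else {},
        "seeds": dict(seeds) if seeds else {},
        "outputs": hashes,
    }
    if extra:
        manifest.update(extra)
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return manifest
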