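"""End-to-end orchestration: construction -> metrics -> nulls -> rich-club
curves -> k-range -> hub/edge classes -> AUC -> group statistics.

Every stochastic stage draws from a named sub-seed of the master seed, so a
given (config, cohort seed) pair reproduces byte-identical output tables.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from . import construction, metrics, richclub, stats
from .core import AnalysisConfig, Cohort, write_results
from .nulls import build_ensemble

__all__ = ["run_pipeline", "PipelineResult"]

_STAGE_SEEDS = ("nulls", "small_world", "permutations")


@dataclasses.dataclass
class PipelineResult:
    cohort: Cohort
    report: construction.ThresholdReport
    curves: dict[str, list[richclub.RichClubCurve]]       # variant -> per subject
    k_ranges: dict[str, tuple[int, int] | None]
    hubs: richclub.HubPartition
    class_summaries: list[richclub.EdgeClassSummary]
    global_metrics: pd.DataFrame
    comparisons: pd.DataFrame
    trends: dict[str, stats.TrendResult]
    auc: pd.DataFrame
    tables: dict[str, pd.DataFrame]
    manifest: dict | None = None


def _stage_seed(master: int, name: str) -> int:
    ss = np.random.SeedSequence([master, _STAGE_SEEDS.index(name)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_pipeline(cohort: Cohort, config: AnalysisConfig,
                 outdir: str | Path | None = None,
                 compute_small_world: bool = True,
                 variants: tuple[str, ...] = ("topological", "weighted")) -> PipelineResult:
    """Run the complete analysis on an (already symmetric) cohort."""
    built, report = construction.construct_cohort(
        cohort, config.threshold_proportion, config.prevalence_tau)

    # --- global metrics per subject
    sw_seed = _stage_seed(config.seed, "small_world")
    gm_rows = []
    for idx, c in enumerate(built.connectomes):
        row = {"subject_id": c.subject_id, "group": c.group,
               "density": construction.density(c),
               "total_connectivity": construction.total_connectivity(c),
               "connected_fraction": construction.connectedness_check(c)[1],
               "global_clustering": metrics.clustering(c, "weighted")[1],
               "global_efficiency": metrics.efficiency(c, weighted=True)}
        if compute_small_world:
            row["small_world_index"] = metrics.small_world_index(
                c, n_nulls=config.n_nulls_small_world, seed=sw_seed + idx)
        gm_rows.append(row)
    gm = pd.DataFrame(gm_rows)

    # --- null ensembles and normalized curves
    null_seed = _stage_seed(config.seed, "nulls")
    curves: dict[str, list[richclub.RichClubCurve]] = {v: [] for v in variants}
    for idx, c in enumerate(built.connectomes):
        if "topological" in variants:
            ens_b = build_ensemble(c.binarized(), config.n_nulls, seed=null_seed + 2 * idx)
            curves["topological"].append(richclub.normalized_curve(c.binarized(), ens_b, "topological"))
        if "weighted" in variants:
            ens_w = build_ensemble(c, config.n_nulls, seed=null_seed + 2 * idx + 1, weighted=True)
            curves["weighted"].append(richclub.normalized_curve(c, ens_w, "weighted"))

    k_ranges = {v: richclub.significant_range(curves[v], config.coverage) for v in variants}

    # --- hubs and edge classes (fixed hub fraction)
    hubs = richclub.common_hubs(built, config.hub_fraction)
    class_summaries = []
    for c in built.connectomes:
        labels = richclub.classify_edges(c, hubs.common_set)
        class_summaries.append(richclub.class_connectivity(c, labels))

    # --- per-subject measure table
    meas = {}
    for summ, c in zip(class_summaries, built.connectomes):
        row = {f"strength_{cls}": summ.strength[cls] for cls in richclub.EDGE_CLASSES}
        row |= {f"density_{cls}": summ.density[cls] for cls in richclub.EDGE_CLASSES}
        row["strength_total"] = summ.strength_total
        meas[c.subject_id] = row
    measures = pd.DataFrame(meas).T
    for v in variants:
        rng_k = k_ranges[v]
        if rng_k is None:
            continue
        lo, hi = rng_k
        for c_curve in curves[v]:
            for k in range(lo, hi + 1):
                col = f"phi_norm_{v}@k{k}"
                measures.loc[c_curve.subject_id, col] = (
                    c_curve.phi_norm[k] if k < len(c_curve.phi_norm) else np.nan)
    measures = measures.fillna(0.0)

    # --- AUC of normalized curves and class measures over the k-range
    auc_rows = []
    for v in variants:
        if k_ranges[v] is None:
            continue
        for c_curve in curves[v]:
            vals = np.nan_to_num(c_curve.phi_norm, nan=0.0)
            auc_rows.append({"subject_id": c_curve.subject_id, "variant": v,
                             "measure": "phi_norm",
                             "auc": richclub.auc_over_k(vals, k_ranges[v])})
    auc = pd.DataFrame(auc_rows)

    # --- group statistics
    groups = pd.Series({c.subject_id: c.group for c in built.connectomes})
    groups = groups.loc[measures.index]
    perm_seed = _stage_seed(config.seed, "permutations")
    comparisons, trends = stats.compare_cohort(
        measures, groups, built.group_levels,
        n_perm=config.n_permutations, seed=perm_seed, fdr_q=config.fdr_q)

    # --- result tables
    curve_frames = [c.to_frame() for v in variants for c in curves[v]]
    tables = {
        "global_metrics": gm,
        "rich_club_curves": pd.concat(curve_frames, ignore_index=True),
        "edge_class_measures": measures.reset_index(names="subject_id"),
        "group_comparisons": comparisons,
        "auc": auc,
        "k_ranges": pd.DataFrame(
            [{"variant": v,
              "k_lo": (k_ranges[v][0] if k_ranges[v] else np.nan),
              "k_hi": (k_ranges[v][1] if k_ranges[v] else np.nan)}
             for v in variants]),
        "trend_tests": pd.DataFrame(
            [{"measure": m, "jt_statistic": t.statistic, "p": t.p,
              "order": "<".join(t.order), "method": t.method}
             for m, t in trends.items()]),
        "hub_sets": pd.DataFrame(
            [{"subject_id": sid, "hubs": ",".join(map(str, sorted(s)))}
             for sid, s in sorted(hubs.per_subject.items())]
            + [{"subject_id": "__common__", "hubs": ",".join(map(str, sorted(hubs.common_set)))}]),
    }

    manifest = None
    if outdir is not None:
        manifest = write_results(
            tables, outdir, config=config.to_dict(),
            seeds={name: _stage_seed(config.seed, name) for name in _STAGE_SEEDS},
            extra={"threshold_report": dataclasses.asdict(report)})

    return PipelineResult(cohort=built, report=report, curves=curves,
                          k_ranges=k_ranges, hubs=hubs,
                          class_summaries=class_summaries, global_metrics=gm,
                          comparisons=comparisons, trends=trends, auc=auc,
                          tables=tables, manifest=manifest)
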