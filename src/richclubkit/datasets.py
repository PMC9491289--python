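"""Bundled example data.

``clinical_summary()`` returns demographic and clinical summary statistics
(n, mean, SD per group, plus the F statistic reported alongside them) for a
cohort of unmedicated OCD patients, their unaffected siblings and matched
healthy controls. Only group-level summaries are bundled — no subject-level
data — which is exactly what the summary-statistics mode of
:func:`richclubkit.stats.oneway_anova` consumes, making the table a worked
example for reconstructing one-way F values from printed group summaries.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["clinical_summary", "summary_triples"]

GROUPS = ("ocd", "sib", "hc")


def clinical_summary() -> pd.DataFrame:
    """The bundled (n, mean, SD) summary table, indexed by variable."""
    ref = resources.files("richclubkit").joinpath("data/clinical_summary.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t").set_index("variable")


def summary_triples(row: pd.Series) -> list[tuple[int, float, float]]:
    """Extract the per-group (n, mean, sd) triples from one summary row."""
    return [(int(row[f"{g}_n"]), float(row[f"{g}_mean"]), float(row[f"{g}_sd"]))
            for g in GROUPS]
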