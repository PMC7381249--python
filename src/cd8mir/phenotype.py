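"""Naive-memory point scoring over median-thresholded markers.

Variant A scores CD27+ frequency plus IL7R/FOXO1/TCF7 mRNA (call at >= 2
points); variant B scores IL7R/FOXO1/BCL6/TCF7 mRNA (call at >= 3 points).
"Above the median" is strictly greater; ties at the median score 0, and a
missing marker scores 0 but is flagged. Because thresholding uses only
ranks, scores are invariant under any strictly monotone per-marker
transformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import pandas as pd

from cd8mir.io_core import ExpressionMatrix, SampleTable, ValidationError, logger
from cd8mir.stats_tests import ContingencyTable2x2, TestResult, fisher_exact, odds_ratio

NAIVE_MEMORY = "naive_memory"
EFFECTOR = "effector"


@dataclass
class ScoreConfig:
    markers: list[str]
    min_points: int
    variant_name: str = "custom"

    def __post_init__(self) -> None:
        if not 1 <= self.min_points <= len(self.markers):
            raise ValidationError("min_points must be in [1, number of markers]")


def variant_a() -> ScoreConfig:
    return ScoreConfig(
        markers=["CD27_freq", "IL7R", "FOXO1", "TCF7"], min_points=2, variant_name="A"
    )


def variant_b() -> ScoreConfig:
    return ScoreConfig(
        markers=["IL7R", "FOXO1", "BCL6", "TCF7"], min_points=3, variant_name="B"
    )


@dataclass
class PhenotypeCall:
    sample_id: str
    points: int
    label: str
    per_marker: dict[str, dict[str, bool]] = field(default_factory=dict)


def score_naive_memory(
    markers: ExpressionMatrix,
    config: ScoreConfig,
    cohort: Sequence[str] | None = None,
    leave_one_out: bool = False,
) -> list[PhenotypeCall]:
    """Score each cohort sample one point per marker strictly above the
    cohort median of that marker.

    Medians are computed over non-missing cohort values, including the
    scored sample itself unless ``leave_one_out``.
    """
    cohort = list(cohort) if cohort is not None else markers.sample_ids
    missing_markers = [m for m in config.markers if m not in markers.data.index]
    if missing_markers:
        raise ValidationError(f"config markers absent from table: {missing_markers}")
    unknown = set(cohort) - set(markers.sample_ids)
    if unknown:
        raise ValidationError(f"cohort samples absent from table: {sorted(unknown)}")
    if len(cohort) < 2:
        raise ValidationError("cohort must contain at least 2 samples")

    sub = markers.data.loc[config.markers, cohort]
    calls = []
    for s in cohort:
        per_marker = {}
        points = 0
        for m in config.markers:
            v = sub.loc[m, s]
            if pd.isna(v):
                per_marker[m] = {"above_median": False, "missing": True}
                continue
            if leave_one_out:
                med = sub.loc[m].drop(s).median(skipna=True)
            else:
                med = sub.loc[m].median(skipna=True)
            above = bool(v > med)
            per_marker[m] = {"above_median": above, "missing": False}
            points += above
        label = NAIVE_MEMORY if points >= config.min_points else EFFECTOR
        calls.append(PhenotypeCall(sample_id=s, points=points, label=label, per_marker=per_marker))
    return calls


def phenotype_smoking_association(
    calls: list[PhenotypeCall], meta: SampleTable
) -> tuple[ContingencyTable2x2, "Fraction", TestResult]:
    """2x2 of phenotype label x smoker status, with odds ratio and Fisher p.

    Rows: naive-memory (smokers, non-smokers) over effector
    (smokers, non-smokers).
    """
    counts = {(NAIVE_MEMORY, True): 0, (NAIVE_MEMORY, False): 0,
              (EFFECTOR, True): 0, (EFFECTOR, False): 0}
    dropped = []
    for call in calls:
        if call.sample_id not in meta.data.index:
            dropped.append(call.sample_id)
            continue
        counts[(call.label, meta.smoker(call.sample_id))] += 1
    if dropped:
        logger.warning("samples without smoker metadata dropped: %s", dropped)
    table = ContingencyTable2x2(
        a=counts[(NAIVE_MEMORY, True)],
        b=counts[(NAIVE_MEMORY, False)],
        c=counts[(EFFECTOR, True)],
        d=counts[(EFFECTOR, False)],
    )
    haldane = table.b * table.c == 0
    return table, odds_ratio(table, haldane=haldane), fisher_exact(table)


def calls_frame(calls: list[PhenotypeCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {"sample_id": c.sample_id, "points": c.points, "label": c.label}
        for m, flags in c.per_marker.items():
            row[f"{m}_above_median"] = flags["above_median"]
            row[f"{m}_missing"] = flags["missing"]
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")
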