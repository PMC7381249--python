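"""mRNA/miR ratio statistic, three-group classification, and the paired
nicotine-response shift analysis.

The ratio for a sample is median RQ over the panel mRNAs divided by median
RQ over the panel miRs. Groups use a high cutoff of 1.5 and a low cutoff of
exactly 2/3 (strict inequalities; boundary values are intermediate).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from cd8mir.io_core import AnalytePanel, SampleTable, ValidationError, logger
from cd8mir.qpcr import RQMatrix
from cd8mir.stats_tests import TestResult, wilcoxon_signed_rank

HI_CUT_DEFAULT = 1.5
LO_CUT_DEFAULT = float(Fraction(2, 3))

HIGH = "high"
INTERMEDIATE = "intermediate"
LOW = "low"


@dataclass
class RatioResult:
    sample_id: str
    median_rq_mrna: float
    median_rq_mir: float
    ratio: float
    group: str | None = None


@dataclass
class ShiftSummary:
    group: str
    n_pairs: int
    pair_ratios: list[tuple[str, float, float]]  # (pair_id, control, nicotine)
    direction_counts: tuple[int, int, int]  # decreased, increased, tied
    test: TestResult


def mrna_mir_ratio(rq: RQMatrix, panel: AnalytePanel) -> list[RatioResult]:
    """Per-sample ratio of median mRNA RQ to median miR RQ (ungrouped)."""
    if rq.normalization_scope != "vs_cohort_median":
        raise ValidationError("ratio requires RQ normalized vs the cohort median")
    data = rq.matrix.data
    mrna = [m for m in panel.mrna_ids if m in data.index]
    mir = [m for m in panel.mir_ids if m in data.index]
    if not mrna or not mir:
        raise ValidationError("panel analytes absent from RQ matrix")
    results = []
    for s in rq.matrix.sample_ids:
        m_vals = data.loc[mrna, s].dropna()
        r_vals = data.loc[mir, s].dropna()
        if m_vals.empty or r_vals.empty:
            logger.warning("sample %s dropped: empty panel side", s)
            continue
        med_m = float(m_vals.median())
        med_r = float(r_vals.median())
        results.append(
            RatioResult(
                sample_id=s,
                median_rq_mrna=med_m,
                median_rq_mir=med_r,
                ratio=med_m / med_r,
            )
        )
    return results


def classify_ratio(
    results: list[RatioResult],
    hi_cut: float = HI_CUT_DEFAULT,
    lo_cut: float = LO_CUT_DEFAULT,
) -> tuple[list[RatioResult], dict[str, int]]:
    """Assign high/intermediate/low groups by strict cutoffs.

    Output ordered by ratio descending (deterministic; ties broken by
    sample id).
    """
    if not hi_cut > lo_cut > 0:
        raise ValidationError("need hi_cut > lo_cut > 0")
    out = []
    for r in results:
        if r.ratio > hi_cut:
            group = HIGH
        elif r.ratio < lo_cut:
            group = LOW
        else:
            group = INTERMEDIATE
        out.append(
            RatioResult(
                sample_id=r.sample_id,
                median_rq_mrna=r.median_rq_mrna,
                median_rq_mir=r.median_rq_mir,
                ratio=r.ratio,
                group=group,
            )
        )
    out.sort(key=lambda r: (-r.ratio, r.sample_id))
    sizes = {
        HIGH: sum(r.group == HIGH for r in out),
        INTERMEDIATE: sum(r.group == INTERMEDIATE for r in out),
        LOW: sum(r.group == LOW for r in out),
    }
    return out, sizes


def nicotine_response_shift(
    control: list[RatioResult],
    nicotine: list[RatioResult],
    meta: SampleTable,
) -> list[ShiftSummary]:
    """Paired shift of the ratio under nicotine, per control-defined group.

    Pairs are matched by pair_id; group membership is frozen at the
    control condition. Each group's paired differences
    (nicotine - control) are tested with the exact two-sided Wilcoxon
    signed-rank test.
    """
    if "pair_id" not in meta.data.columns:
        raise ValidationError("metadata lacks pair_id; cannot match pairs")
    pair_of = meta.data["pair_id"].to_dict()
    ctrl_by_pair = {}
    for r in control:
        pid = pair_of.get(r.sample_id)
        if pid is None or (isinstance(pid, float) and np.isnan(pid)):
            logger.warning("control sample %s unpaired; excluded", r.sample_id)
            continue
        ctrl_by_pair[pid] = r
    nic_by_pair = {}
    for r in nicotine:
        pid = pair_of.get(r.sample_id)
        if pid is None or (isinstance(pid, float) and np.isnan(pid)):
            logger.warning("nicotine sample %s unpaired; excluded", r.sample_id)
            continue
        nic_by_pair[pid] = r

    summaries = []
    for group in (HIGH, INTERMEDIATE, LOW):
        pairs = []
        for pid, ctrl in sorted(ctrl_by_pair.items()):
            if ctrl.group != group:
                continue
            nic = nic_by_pair.get(pid)
            if nic is None:
                logger.warning("pair %s lacks a nicotine sample; excluded", pid)
                continue
            pairs.append((pid, ctrl.ratio, nic.ratio))
        if not pairs:
            continue
        diffs = [nic - ctrl for _, ctrl, nic in pairs]
        decreased = sum(d < 0 for d in diffs)
        increased = sum(d > 0 for d in diffs)
        tied = sum(d == 0 for d in diffs)
        test = wilcoxon_signed_rank(diffs)
        summaries.append(
            ShiftSummary(
                group=group,
                n_pairs=len(pairs),
                pair_ratios=pairs,
                direction_counts=(decreased, increased, tied),
                test=test,
            )
        )
    return summaries


def ratio_frame(results: list[RatioResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "median_rq_mrna": [r.median_rq_mrna for r in results],
            "median_rq_mir": [r.median_rq_mir for r in results],
            "ratio": [r.ratio for r in results],
            "group": [r.group for r in results],
        }
    ).set_index("sample_id")
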