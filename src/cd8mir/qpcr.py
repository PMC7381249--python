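"""ddCT relative quantification and relative-quantity-to-median (RQ) computation.

CT tables arrive as feature x sample matrices tagged value_kind=ct with an
analyte panel naming the reference targets (GAPDH for the mRNA side, RNU6b
for the miR side). Fold changes use FC = 2^(-ddCT).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from cd8mir.io_core import (
    AnalytePanel,
    Cd8mirError,
    ExpressionMatrix,
    ValidationError,
    ValueKind,
    logger,
)


@dataclass
class CtTable:
    """CT matrix plus the panel that identifies each target's reference."""

    matrix: ExpressionMatrix
    panel: AnalytePanel

    def __post_init__(self) -> None:
        self.matrix.require_kind(ValueKind.CT)

    def reference_for(self, target: str) -> str:
        if target in self.panel.mrna_ids or target == self.panel.mrna_reference:
            return self.panel.mrna_reference
        if target in self.panel.mir_ids or target == self.panel.mir_reference:
            return self.panel.mir_reference
        raise ValidationError(f"target '{target}' is not in the panel")

    @property
    def targets(self) -> list[str]:
        return [t for t in self.matrix.feature_ids
                if t not in (self.panel.mrna_reference, self.panel.mir_reference)]


@dataclass
class RQMatrix:
    """Relative quantities (value_kind=rq) with their normalization scope."""

    matrix: ExpressionMatrix
    normalization_scope: str  # "vs_calibrator" | "vs_cohort_median"

    def __post_init__(self) -> None:
        self.matrix.require_kind(ValueKind.RQ)
        if self.normalization_scope not in ("vs_calibrator", "vs_cohort_median"):
            raise ValidationError(f"unknown normalization scope {self.normalization_scope!r}")


def delta_ct(ct: CtTable, target: str) -> pd.Series:
    """dCT_s = CT_target,s - CT_reference,s per sample (NaN where either missing)."""
    ref = ct.reference_for(target)
    if target not in ct.matrix.data.index:
        raise ValidationError(f"target '{target}' not measured")
    if ref not in ct.matrix.data.index:
        raise ValidationError(f"reference '{ref}' not measured")
    d = ct.matrix.data.loc[target] - ct.matrix.data.loc[ref]
    missing_ref = ct.matrix.data.loc[ref].isna() & ct.matrix.data.loc[target].notna()
    if missing_ref.any():
        logger.warning(
            "samples with missing reference CT for %s: %s", target,
            list(missing_ref.index[missing_ref]),
        )
    return d


def delta_delta_ct(
    ct: CtTable,
    target: str,
    calibrator_samples: Sequence[str],
    calibrator_summary: str = "mean_dct",
) -> pd.Series:
    """Per-sample fold change 2^(-ddCT) of ``target`` against calibrators.

    ddCT_s = dCT_s - mean(dCT over calibrator samples). With
    ``calibrator_summary='geomean_fc'`` the calibrator baseline is the
    geometric mean of the calibrators' fold changes instead (equivalent to
    the arithmetic mean of dCT; kept for symmetry with common practice).
    """
    d = delta_ct(ct, target)
    cal = d.reindex(list(calibrator_samples))
    if cal.notna().sum() < 1:
        raise ValidationError(
            f"target '{target}': no calibrator sample has a complete dCT"
        )
    baseline = float(cal.mean())  # both summaries coincide on the dCT scale
    if calibrator_summary not in ("mean_dct", "geomean_fc"):
        raise ValidationError(f"unknown calibrator summary {calibrator_summary!r}")
    ddct = d - baseline
    return np.exp2(-ddct)


def fold_change_table(
    ct: CtTable,
    calibrator_samples: Sequence[str],
    targets: Sequence[str] | None = None,
) -> ExpressionMatrix:
    """ddCT fold changes for every panel target; value_kind=rq."""
    targets = list(targets) if targets is not None else ct.targets
    rows = {t: delta_delta_ct(ct, t, calibrator_samples) for t in targets}
    df = pd.DataFrame(rows).T
    df = df.reindex(columns=ct.matrix.sample_ids)
    return ExpressionMatrix(df, ValueKind.RQ)


def quantity_table(ct: CtTable, targets: Sequence[str] | None = None) -> ExpressionMatrix:
    """Calibrator-free relative quantities 2^(-dCT); value_kind=rq."""
    targets = list(targets) if targets is not None else ct.targets
    rows = {t: np.exp2(-delta_ct(ct, t)) for t in targets}
    df = pd.DataFrame(rows).T.reindex(columns=ct.matrix.sample_ids)
    return ExpressionMatrix(df, ValueKind.RQ)


def relative_quantity_to_median(
    values: ExpressionMatrix, sample_scope: Sequence[str]
) -> RQMatrix:
    """Divide each analyte by its median over ``sample_scope``.

    Medians use non-missing scope values only; analytes with no usable
    scope value are dropped with a warning. Samples outside the scope are
    normalized against the scope medians, so the scope acts as the
    reference cohort.
    """
    values.require_kind(ValueKind.RQ)
    scope = [s for s in sample_scope]
    unknown = set(scope) - set(values.sample_ids)
    if unknown:
        raise ValidationError(f"scope samples absent from matrix: {sorted(unknown)}")
    sub = values.data[scope]
    finite = sub.to_numpy()
    if np.nanmin(finite, initial=np.inf) <= 0:
        raise ValidationError("all in-scope values must be > 0")
    medians = sub.median(axis=1, skipna=True)
    dropped = medians.index[medians.isna()].tolist()
    if dropped:
        logger.warning("analytes with no non-missing scope value dropped: %s", dropped)
    keep = medians.index[medians.notna()]
    rq = values.data.loc[keep].div(medians.loc[keep], axis=0)
    return RQMatrix(ExpressionMatrix(rq, ValueKind.RQ), "vs_cohort_median")
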