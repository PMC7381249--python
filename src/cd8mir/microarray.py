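"""Microarray preprocessing: detection calling, background subtraction,
sample QC, expression filtering, log2 transform and cyclic loess
normalization.

Stage order detection -> QC -> filter -> log2 -> loess is enforced by the
value_kind tag on :class:`~cd8mir.io_core.ExpressionMatrix`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from cd8mir.io_core import (
    Cd8mirError,
    ExpressionMatrix,
    NoiseStats,
    ValidationError,
    ValueKind,
    logger,
)


@dataclass
class DetectionResult:
    """Outcome of detection calling: mask, background-corrected matrix, counts."""

    mask: pd.DataFrame  # boolean, feature x sample
    corrected: ExpressionMatrix  # raw_intensity kind, NaN where undetected
    detected_count_per_sample: pd.Series


def detection_call(raw: ExpressionMatrix, noise: NoiseStats, k_sd: float = 2.0) -> DetectionResult:
    """Call detected spots and subtract per-sample background.

    A spot is detected iff its intensity strictly exceeds
    ``noise_mean + k_sd * noise_sd`` for its sample. Detected spots are
    background-corrected by subtracting ``noise_mean`` (floored at 0);
    undetected spots become missing.
    """
    raw.require_kind(ValueKind.RAW_INTENSITY)
    means = []
    sds = []
    for s in raw.sample_ids:
        m, sd = noise.for_sample(s)  # raises if a sample lacks a record
        means.append(m)
        sds.append(sd)
    mean_row = np.asarray(means)
    thresh = mean_row + k_sd * np.asarray(sds)
    vals = raw.data.to_numpy()
    mask = vals > thresh[np.newaxis, :]
    corrected = np.where(mask, np.maximum(vals - mean_row[np.newaxis, :], 0.0), np.nan)
    mask_df = pd.DataFrame(mask & np.isfinite(vals), index=raw.data.index, columns=raw.data.columns)
    corrected_df = pd.DataFrame(corrected, index=raw.data.index, columns=raw.data.columns)
    counts = mask_df.sum(axis=0)
    return DetectionResult(
        mask=mask_df,
        corrected=ExpressionMatrix(corrected_df, ValueKind.RAW_INTENSITY),
        detected_count_per_sample=counts,
    )


@dataclass
class QcReport:
    retained: list[str]
    excluded: dict[str, int] = field(default_factory=dict)
    min_detected: int = 0


def qc_filter_samples(det: DetectionResult, min_detected: int) -> QcReport:
    """Drop samples whose detected-spot count falls below ``min_detected``."""
    if min_detected < 0:
        raise ValidationError("min_detected must be >= 0")
    counts = det.detected_count_per_sample
    excluded = {s: int(c) for s, c in counts.items() if c < min_detected}
    retained = [s for s in counts.index if s not in excluded]
    if not retained:
        raise Cd8mirError(
            f"all samples excluded at min_detected={min_detected}; counts={counts.to_dict()}"
        )
    for s, c in excluded.items():
        logger.info("QC excluded sample %s (detected %d < %d)", s, c, min_detected)
    return QcReport(retained=retained, excluded=excluded, min_detected=min_detected)


def default_min_detected(n_features: int, fraction: float = 0.10) -> int:
    """Default sample-QC threshold: 10% of total features."""
    return int(np.ceil(fraction * n_features))


def filter_top_expressed(
    mat: ExpressionMatrix,
    mean_threshold: float = 80.0,
    top_n: int | None = None,
) -> ExpressionMatrix:
    """Keep highly expressed features.

    Default mode keeps features whose mean over non-missing corrected
    intensities strictly exceeds ``mean_threshold`` (AU); ``top_n`` keeps
    the n largest means instead.
    """
    mat.require_kind(ValueKind.RAW_INTENSITY)
    means = mat.data.mean(axis=1, skipna=True)
    if top_n is not None:
        keep = means.sort_values(ascending=False, kind="stable").index[:top_n]
        keep = [f for f in mat.data.index if f in set(keep)]
    else:
        keep = means.index[means > mean_threshold].tolist()
    if not keep:
        raise Cd8mirError(
            f"no features retained (mean_threshold={mean_threshold}, "
            f"max observed mean={means.max():.3g}, n_features={len(means)})"
        )
    logger.info("expression filter kept %d / %d features", len(keep), mat.shape[0])
    return mat.copy_with(mat.data.loc[keep], ValueKind.RAW_INTENSITY)


def log2_transform(mat: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """log2(value + offset); missing propagates."""
    mat.require_kind(ValueKind.RAW_INTENSITY)
    vals = mat.data.to_numpy()
    shifted = vals + offset
    if np.nanmin(shifted, initial=np.inf) <= 0:
        raise Cd8mirError(f"nonpositive value after offset {offset}; cannot log2")
    out = pd.DataFrame(np.log2(shifted), index=mat.data.index, columns=mat.data.columns)
    return mat.copy_with(out, ValueKind.LOG2)


def inverse_log2_transform(mat: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    mat.require_kind(ValueKind.LOG2)
    out = np.exp2(mat.data) - offset
    return mat.copy_with(out, ValueKind.RAW_INTENSITY)


def _lowess_predict(a_fit: np.ndarray, m_fit: np.ndarray, a_new: np.ndarray, span: float) -> np.ndarray:
    """Fit lowess of M on A and evaluate at a_new (flat extrapolation)."""
    fitted = lowess(m_fit, a_fit, frac=span, it=0, return_sorted=True)
    xs, ys = fitted[:, 0], fitted[:, 1]
    # np.interp needs strictly usable xs; duplicates are harmless for interp
    return np.interp(a_new, xs, ys)


def cyclic_loess_normalize(
    mat: ExpressionMatrix,
    span: float = 0.7,
    iterations: int = 3,
    min_complete: int = 10,
) -> ExpressionMatrix:
    """Cyclic loess normalization on the log2 scale.

    For each unordered sample pair (i, j) a loess curve of
    M = x_i - x_j on A = (x_i + x_j)/2 is fitted on features complete in
    both samples; half the fitted M is subtracted from i and added to j.
    All pairs are swept ``iterations`` times. Features missing in one
    sample of a pair still receive the adjustment predicted at their
    available value; fully missing entries stay missing.
    """
    mat.require_kind(ValueKind.LOG2)
    if mat.shape[1] < 2:
        raise Cd8mirError("cyclic loess needs at least 2 samples")
    x = mat.data.to_numpy().copy()
    n = x.shape[1]
    pairs = list(combinations(range(n), 2))
    for pair in pairs:
        i, j = pair
        complete = np.isfinite(x[:, i]) & np.isfinite(x[:, j])
        if complete.sum() < min_complete:
            raise Cd8mirError(
                f"pair ({mat.sample_ids[i]}, {mat.sample_ids[j]}) has only "
                f"{int(complete.sum())} complete features (< {min_complete})"
            )
    for _ in range(iterations):
        for i, j in pairs:
            xi, xj = x[:, i], x[:, j]
            both = np.isfinite(xi) & np.isfinite(xj)
            a_fit = (xi[both] + xj[both]) / 2.0
            m_fit = xi[both] - xj[both]
            fit_m = _lowess_predict(a_fit, m_fit, a_fit, span)
            xi[both] -= fit_m / 2.0
            xj[both] += fit_m / 2.0
            only_i = np.isfinite(xi) & ~np.isfinite(xj)
            if only_i.any():
                xi[only_i] -= _lowess_predict(a_fit, m_fit, xi[only_i], span) / 2.0
            only_j = np.isfinite(xj) & ~np.isfinite(xi)
            if only_j.any():
                xj[only_j] += _lowess_predict(a_fit, m_fit, xj[only_j], span) / 2.0
    out = pd.DataFrame(x, index=mat.data.index, columns=mat.data.columns)
    return mat.copy_with(out, ValueKind.NORMALIZED_LOG2)


def qc_report_dict(det: DetectionResult, qc: QcReport, kept_features: int | None = None) -> dict:
    """JSON-serializable QC summary for the normalize CLI."""
    return {
        "detected_counts": {s: int(c) for s, c in det.detected_count_per_sample.items()},
        "min_detected": qc.min_detected,
        "excluded_samples": qc.excluded,
        "retained_samples": qc.retained,
        "kept_features": kept_features,
    }
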