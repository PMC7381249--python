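"""Two-group differential expression with empirical-Bayes variance moderation.

Per-feature ordinary least squares followed by shrinkage of residual
variances toward a pooled prior estimated by the method of moments on
log variances, yielding moderated t statistics with augmented degrees
of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from cd8mir.io_core import Cd8mirError, ExpressionMatrix, ValidationError, ValueKind, logger

REFERENCE = "reference"
TEST = "test"

#: variance floor applied to degenerate zero-variance features before moderation
S2_FLOOR = 1e-8


@dataclass
class DesignSpec:
    """Two-group design: sample -> reference/test, optional numeric covariates."""

    group: dict[str, str]
    covariates: dict[str, dict[str, float]] | None = None

    def __post_init__(self) -> None:
        labels = set(self.group.values())
        if not labels <= {REFERENCE, TEST}:
            raise ValidationError(f"group labels must be '{REFERENCE}'/'{TEST}', got {labels}")
        if REFERENCE not in labels or TEST not in labels:
            raise ValidationError("both groups must be non-empty")

    @classmethod
    def from_smoker(cls, meta) -> "DesignSpec":
        """Smoker contrast: non-smoker = reference, smoker = test."""
        return cls(
            group={s: (TEST if meta.smoker(s) else REFERENCE) for s in meta.sample_ids}
        )

    @classmethod
    def from_diagnosis(cls, meta) -> "DesignSpec":
        """RA-vs-HC contrast: HC = reference, RA = test."""
        return cls(
            group={
                s: (TEST if meta.data.loc[s, "diagnosis"] == "RA" else REFERENCE)
                for s in meta.sample_ids
            }
        )


@dataclass
class FeatureFit:
    feature_id: str
    logfc: float
    s2: float
    df_resid: int
    stdev_unscaled: float  # SE factor of the contrast per unit residual SD
    n_used: int


@dataclass
class ModeratedResult:
    feature_id: str
    logfc: float
    t_mod: float
    p: float
    p_adj: float = math.nan
    direction: str = "ns"


def _design_matrix(samples: list[str], design: DesignSpec) -> np.ndarray:
    cols = [np.ones(len(samples)), np.array([design.group[s] == TEST for s in samples], float)]
    if design.covariates:
        names = sorted({k for v in design.covariates.values() for k in v})
        for name in names:
            cols.append(np.array([design.covariates.get(s, {}).get(name, 0.0) for s in samples]))
    return np.column_stack(cols)


def fit_feature_models(
    mat: ExpressionMatrix, design: DesignSpec
) -> tuple[list[FeatureFit], dict[str, str]]:
    """Per-feature OLS on non-missing samples.

    Returns fits plus a mapping of skipped feature -> reason (too few
    observations in a group, or rank deficiency after dropping missing
    samples).
    """
    mat.require_kind(ValueKind.NORMALIZED_LOG2)
    samples = [s for s in mat.sample_ids if s in design.group]
    missing_design = set(mat.sample_ids) - set(samples)
    if missing_design:
        logger.warning("samples without design assignment ignored: %s", sorted(missing_design))
    if not samples:
        raise ValidationError("no analyzed sample carries a design assignment")
    X_full = _design_matrix(samples, design)
    y_all = mat.data[samples].to_numpy()
    group_vec = np.array([design.group[s] == TEST for s in samples])

    fits: list[FeatureFit] = []
    skipped: dict[str, str] = {}
    p_rank_needed = X_full.shape[1]
    complete = np.isfinite(y_all).all(axis=1)

    # fast path: complete features share one design matrix
    if complete.any():
        Xc = X_full
        XtX_inv = np.linalg.inv(Xc.T @ Xc)
        H = XtX_inv @ Xc.T
        c_var = XtX_inv[1, 1]
        betas = (H @ y_all[complete].T).T
        resid = y_all[complete] - betas @ Xc.T
        df = len(samples) - p_rank_needed
        if df < 1:
            for fid in mat.data.index[complete]:
                skipped[fid] = "df_resid < 1"
        else:
            ss = (resid**2).sum(axis=1)
            for fid, b, s in zip(mat.data.index[complete], betas, ss):
                fits.append(
                    FeatureFit(
                        feature_id=fid,
                        logfc=float(b[1]),
                        s2=float(s / df),
                        df_resid=df,
                        stdev_unscaled=float(np.sqrt(c_var)),
                        n_used=len(samples),
                    )
                )

    for idx in np.nonzero(~complete)[0]:
        fid = mat.data.index[idx]
        y = y_all[idx]
        obs = np.isfinite(y)
        if group_vec[obs].sum() < 1 or (~group_vec[obs]).sum() < 1:
            skipped[fid] = "a group has no non-missing value"
            continue
        X = X_full[obs]
        if np.linalg.matrix_rank(X) < p_rank_needed:
            skipped[fid] = "design rank-deficient after dropping missing samples"
            continue
        df = int(obs.sum()) - p_rank_needed
        if df < 1:
            skipped[fid] = "df_resid < 1"
            continue
        beta, _, _, _ = np.linalg.lstsq(X, y[obs], rcond=None)
        resid = y[obs] - X @ beta
        c_var = np.linalg.inv(X.T @ X)[1, 1]
        fits.append(
            FeatureFit(
                feature_id=fid,
                logfc=float(beta[1]),
                s2=float((resid**2).sum() / df),
                df_resid=df,
                stdev_unscaled=float(np.sqrt(c_var)),
                n_used=int(obs.sum()),
            )
        )
    order = {f: i for i, f in enumerate(mat.data.index)}
    fits.sort(key=lambda f: order[f.feature_id])
    return fits, skipped


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma_inverse needs y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if -dif / x < 1e-12:
            break
    return x


def estimate_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) to the scaled-F model on log s^2.

    Returns ``(d0, s0_sq)``; ``d0 = inf`` when the observed spread of log
    variances is no larger than expected under a common variance.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        raise Cd8mirError("need >= 2 features with positive variance to estimate the prior")
    s2 = s2[ok]
    df = df[ok].astype(float)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    n = len(e)
    evar = float(((e - emean) ** 2).sum() / (n - 1)) - float(
        np.mean(special.polygamma(1, df / 2.0))
    )
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = math.exp(emean)
    return d0, s0_sq


def ebayes_moderate(
    fits: list[FeatureFit],
    d0_override: float | None = None,
    s0_sq_override: float | None = None,
) -> tuple[list[ModeratedResult], dict]:
    """Moderated t statistics via empirical-Bayes variance shrinkage.

    Posterior variance ``(d0*s0^2 + df*s2) / (d0 + df)``;
    ``t = logfc / (sqrt(s2_post) * stdev_unscaled)`` referred to a t
    distribution with ``d0 + df`` degrees of freedom. ``d0_override = 0``
    recovers the ordinary t; ``d0_override = inf`` gives the pooled-s0
    normal-reference statistic.
    """
    if not fits:
        raise ValidationError("no feature fits supplied")
    s2 = np.array([max(f.s2, S2_FLOOR) for f in fits])
    df = np.array([f.df_resid for f in fits], float)

    if d0_override is not None:
        d0 = float(d0_override)
        if math.isinf(d0):
            if s0_sq_override is None:
                _, s0_sq = estimate_prior(s2, df)
            else:
                s0_sq = float(s0_sq_override)
        else:
            s0_sq = float(s0_sq_override) if s0_sq_override is not None else (
                estimate_prior(s2, df)[1] if d0 > 0 else math.nan
            )
    else:
        d0, s0_sq = estimate_prior(s2, df)

    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.full_like(df, math.inf)
    elif d0 == 0:
        s2_post = s2
        df_total = df
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = df + d0

    results = []
    for f, v, dft in zip(fits, s2_post, df_total):
        t = f.logfc / (math.sqrt(v) * f.stdev_unscaled)
        if math.isinf(dft):
            p = 2.0 * stats.norm.sf(abs(t))
        else:
            p = 2.0 * stats.t.sf(abs(t), dft)
        results.append(ModeratedResult(feature_id=f.feature_id, logfc=f.logfc, t_mod=t, p=float(p)))
    pvals = np.array([r.p for r in results])
    p_adj = multipletests(pvals, method="fdr_bh")[1]
    for r, pa in zip(results, p_adj):
        r.p_adj = float(pa)
    prior = {"d0": d0, "s0_sq": s0_sq}
    return results, prior


def select_differential(
    results: list[ModeratedResult],
    lfc_cut: float = 0.5,
    p_cut: float = 0.05,
    use_adjusted: bool = False,
) -> tuple[list[ModeratedResult], list[ModeratedResult]]:
    """Strict-inequality selection: up = p < p_cut and logfc > lfc_cut; down mirrored.

    Sets ``direction`` on every result; output lists ordered by p then
    feature_id.
    """
    if not results:
        raise ValidationError("empty result set")
    up, down = [], []
    for r in results:
        p = r.p_adj if use_adjusted else r.p
        if p < p_cut and r.logfc > lfc_cut:
            r.direction = "up"
            up.append(r)
        elif p < p_cut and r.logfc < -lfc_cut:
            r.direction = "down"
            down.append(r)
        else:
            r.direction = "ns"
    key = (lambda r: (r.p_adj, r.feature_id)) if use_adjusted else (lambda r: (r.p, r.feature_id))
    up.sort(key=key)
    down.sort(key=key)
    return up, down


def results_frame(results: list[ModeratedResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "logfc": [r.logfc for r in results],
            "t_mod": [r.t_mod for r in results],
            "p": [r.p for r in results],
            "p_adj": [r.p_adj for r in results],
            "direction": [r.direction for r in results],
        }
    ).set_index("feature_id")
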