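"""Seeded synthetic-data generators for the microarray, qPCR and
phenotype-marker stages.

All generators are pure functions of (config, seed): repeated calls with
the same inputs return identical output. Each emits a truth record listing
what was planted so recovery can be scored automatically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from cd8mir.io_core import (
    AnalytePanel,
    ExpressionMatrix,
    NoiseStats,
    SampleTable,
    ValidationError,
    ValueKind,
    default_panel,
)
from cd8mir.phenotype import ScoreConfig, variant_a

# the eight features the smoker contrast plants by default: six up, two down
DEFAULT_PLANTED_UP = [
    "miR-181a-5p",
    "let-7c-5p",
    "miR-92a-3p",
    "let-7d-5p",
    "let-7e-5p",
    "miR-150-5p",
]
DEFAULT_PLANTED_DOWN = ["miR-3196", "miR-4723-5p"]


def default_planted_effects(rng: np.random.Generator) -> dict[str, float]:
    """Six up-regulated features at logFC +0.6..+1.0, two down at -0.6..-1.0."""
    effects = {}
    for name in DEFAULT_PLANTED_UP:
        effects[name] = float(rng.uniform(0.6, 1.0))
    for name in DEFAULT_PLANTED_DOWN:
        effects[name] = float(-rng.uniform(0.6, 1.0))
    return effects


@dataclass
class MicroarraySimConfig:
    n_features: int = 2656
    n_expressed: int = 125
    n_smokers: int = 7
    n_nonsmokers: int = 6
    planted_effects: dict[str, float] | None = None  # None -> paper-style default
    noise_mean_range: tuple[float, float] = (8.0, 15.0)
    noise_sd_range: tuple[float, float] = (1.0, 2.5)
    expressed_mean_range: tuple[float, float] = (150.0, 3000.0)
    residual_sd_log2: float = 0.3
    background_sd_log: float = 0.4  # lognormal sigma of undetectable features
    n_bad_samples: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_expressed > self.n_features:
            raise ValidationError("n_expressed must not exceed n_features")
        if self.n_smokers < 2 or self.n_nonsmokers < 2:
            raise ValidationError("group sizes must be >= 2")
        if self.expressed_mean_range[0] <= 80:
            raise ValidationError("expressed_mean_range minimum must exceed 80 AU")
        if self.planted_effects is not None and len(self.planted_effects) > self.n_expressed:
            raise ValidationError("planted features must fit within the expressed set")


@dataclass
class MicroarrayTruth:
    planted_effects: dict[str, float]
    expressed_features: list[str]
    bad_samples: list[str]
    smokers: list[str]
    nonsmokers: list[str]

    def to_dict(self) -> dict:
        return {
            "planted_effects": self.planted_effects,
            "expressed_features": self.expressed_features,
            "bad_samples": self.bad_samples,
            "smokers": self.smokers,
            "nonsmokers": self.nonsmokers,
        }


def simulate_microarray(
    cfg: MicroarraySimConfig,
) -> tuple[ExpressionMatrix, NoiseStats, SampleTable, MicroarrayTruth]:
    """Raw intensity cohort with planted smoker effects and optional bad samples.

    Unexpressed features are lognormal around the per-sample noise level
    (mostly below the detection threshold). Expressed features carry log2
    means drawn so their background-corrected averages exceed 80 AU, a
    smoker shift equal to the planted logFC, and normal log2 residuals.
    Bad samples lose the expressed signal entirely and draw a tightened
    background, so their detected counts fall below the default QC cut.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    planted = cfg.planted_effects if cfg.planted_effects is not None else default_planted_effects(rng)

    n_samples = cfg.n_smokers + cfg.n_nonsmokers
    sample_ids = [f"S{i + 1:02d}" for i in range(n_samples)]
    smoker_flags = np.array([True] * cfg.n_smokers + [False] * cfg.n_nonsmokers)
    rng.shuffle(smoker_flags)
    smokers = [s for s, f in zip(sample_ids, smoker_flags) if f]
    nonsmokers = [s for s, f in zip(sample_ids, smoker_flags) if not f]

    if cfg.n_bad_samples > n_samples:
        raise ValidationError("n_bad_samples exceeds sample count")
    bad = sorted(rng.choice(sample_ids, size=cfg.n_bad_samples, replace=False).tolist())

    expressed = list(planted.keys())
    extra = cfg.n_expressed - len(expressed)
    expressed += [f"miR-sim-{i + 1:04d}" for i in range(extra)]
    null_features = [f"probe-{i + 1:04d}" for i in range(cfg.n_features - cfg.n_expressed)]
    feature_ids = expressed + null_features

    noise_mean = rng.uniform(*cfg.noise_mean_range, size=n_samples)
    noise_sd = rng.uniform(*cfg.noise_sd_range, size=n_samples)

    lo, hi = np.log2(cfg.expressed_mean_range)
    base_log2 = rng.uniform(lo, hi, size=cfg.n_expressed)
    effect = np.array([planted.get(f, 0.0) for f in expressed])

    vals = np.empty((cfg.n_features, n_samples))
    for j, s in enumerate(sample_ids):
        if s in bad:
            # degraded hybridization: everything sits below the noise floor
            vals[:, j] = rng.lognormal(
                mean=math.log(0.5 * noise_mean[j]), sigma=0.25, size=cfg.n_features
            )
            continue
        log2_sig = base_log2 + effect * smoker_flags[j] + rng.normal(
            0.0, cfg.residual_sd_log2, size=cfg.n_expressed
        )
        vals[: cfg.n_expressed, j] = np.exp2(log2_sig) + noise_mean[j]
        vals[cfg.n_expressed :, j] = rng.lognormal(
            mean=math.log(noise_mean[j]), sigma=cfg.background_sd_log,
            size=cfg.n_features - cfg.n_expressed,
        )

    mat = ExpressionMatrix(
        pd.DataFrame(vals, index=feature_ids, columns=sample_ids), ValueKind.RAW_INTENSITY
    )
    noise = NoiseStats(
        pd.DataFrame(
            {"noise_mean": noise_mean, "noise_sd": noise_sd}, index=pd.Index(sample_ids, name="sample_id")
        )
    )
    diagnosis = np.where(np.arange(n_samples) % 2 == 0, "RA", "HC")
    meta = SampleTable(
        pd.DataFrame(
            {
                "diagnosis": diagnosis,
                "smoker": smoker_flags,
                "condition": "control",
                "pooled_n": rng.integers(1, 4, size=n_samples),
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    truth = MicroarrayTruth(
        planted_effects=planted,
        expressed_features=expressed,
        bad_samples=bad,
        smokers=smokers,
        nonsmokers=nonsmokers,
    )
    return mat, noise, meta, truth


@dataclass
class QpcrSimConfig:
    panel: AnalytePanel = field(default_factory=default_panel)
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"high": 8, "intermediate": 11, "low": 6}
    )
    group_effect: float = 3.0  # multiplicative shift of the boosted panel side
    nicotine_inversion_strength: float = 1.0
    ct_noise_sd: float = 0.15
    reference_ct_mean: float = 20.0
    smoker_prob: dict[str, float] = field(
        default_factory=lambda: {"high": 0.7, "intermediate": 0.2, "low": 0.7}
    )
    seed: int = 0

    def validate(self) -> None:
        if any(v < 1 for v in self.n_per_group.values()):
            raise ValidationError("group sizes must be >= 1")
        if not 0 < self.nicotine_inversion_strength <= 1:
            raise ValidationError("inversion strength must be in (0, 1]")
        if self.group_effect <= 1.5:
            raise ValidationError("group_effect must exceed the 1.5 cutoff")


@dataclass
class QpcrTruth:
    groups: dict[str, str]  # donor -> planted control group
    smokers: list[str]

    def to_dict(self) -> dict:
        return {"groups": self.groups, "smokers": self.smokers}


def _ct_from_quantity(q: np.ndarray, ref_ct: np.ndarray, rng: np.random.Generator, noise_sd: float) -> np.ndarray:
    """Invert the quantification model: CT_target = CT_ref - log2(q) + noise."""
    return ref_ct - np.log2(q) + rng.normal(0.0, noise_sd, size=q.shape)


def simulate_qpcr_cohort(
    cfg: QpcrSimConfig,
) -> tuple["CtTableLike", "CtTableLike", SampleTable, QpcrTruth]:
    """Paired control/nicotine CT tables with a planted ratio-group structure.

    Control cultures: the high group's mRNA quantities (or the low group's
    miR quantities) are multiplied by ``group_effect`` so the mRNA/miR
    ratio lands clear of the 1.5 and 2/3 cutoffs. Nicotine cultures invert
    the boosted side by ``group_effect**(-2 * strength)``, so at full
    strength every high-group pair's ratio decreases and every low-group
    pair's increases; the intermediate group receives no systematic shift.
    Returned tables are :class:`~cd8mir.qpcr.CtTable`.
    """
    from cd8mir.qpcr import CtTable  # local import to avoid a cycle

    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    donors = []
    group_of = {}
    i = 0
    for group in ("high", "intermediate", "low"):
        for _ in range(cfg.n_per_group.get(group, 0)):
            i += 1
            donor = f"P{i:02d}"
            donors.append(donor)
            group_of[donor] = group
    analytes = cfg.panel.mrna_ids + cfg.panel.mir_ids
    is_mrna = np.array([a in cfg.panel.mrna_ids for a in analytes])

    # per-analyte baseline quantity (cancels in RQ normalization)
    base = np.exp2(rng.uniform(-2.0, 2.0, size=len(analytes)))

    def quantities(donor: str, condition: str) -> np.ndarray:
        g = group_of[donor]
        q = base * np.exp2(rng.normal(0.0, 0.2, size=len(analytes)))
        boost = np.ones(len(analytes))
        if g == "high":
            boost[is_mrna] = cfg.group_effect
        elif g == "low":
            boost[~is_mrna] = cfg.group_effect
        if condition == "nicotine" and g in ("high", "low"):
            side = is_mrna if g == "high" else ~is_mrna
            boost[side] *= cfg.group_effect ** (-2.0 * cfg.nicotine_inversion_strength)
        return q * boost

    def build_table(condition: str, suffix: str) -> tuple[pd.DataFrame, list[str]]:
        cols = {}
        ids = []
        for donor in donors:
            sid = donor + suffix
            ids.append(sid)
            q = quantities(donor, condition)
            ref_mrna = cfg.reference_ct_mean + rng.normal(0.0, 0.3)
            ref_mir = cfg.reference_ct_mean + 5.0 + rng.normal(0.0, 0.3)
            ct = np.empty(len(analytes))
            ct[is_mrna] = _ct_from_quantity(q[is_mrna], ref_mrna, rng, cfg.ct_noise_sd)
            ct[~is_mrna] = _ct_from_quantity(q[~is_mrna], ref_mir, rng, cfg.ct_noise_sd)
            col = pd.Series(ct, index=analytes)
            col[cfg.panel.mrna_reference] = ref_mrna
            col[cfg.panel.mir_reference] = ref_mir
            cols[sid] = col
        order = analytes + [cfg.panel.mrna_reference, cfg.panel.mir_reference]
        return pd.DataFrame(cols).loc[order], ids

    ctrl_df, ctrl_ids = build_table("control", "c")
    nic_df, nic_ids = build_table("nicotine", "n")

    smoker_of = {d: bool(rng.random() < cfg.smoker_prob.get(group_of[d], 0.5)) for d in donors}
    rows = []
    for donor, sid in zip(donors + donors, ctrl_ids + nic_ids):
        rows.append(
            {
                "sample_id": sid,
                "diagnosis": "RA",
                "smoker": smoker_of[sid[:-1]],
                "condition": "control" if sid.endswith("c") else "nicotine",
                "pair_id": sid[:-1],
            }
        )
    meta = SampleTable(pd.DataFrame(rows).set_index("sample_id"))

    control = CtTable(
        ExpressionMatrix(ctrl_df, ValueKind.CT), cfg.panel
    )
    nicotine = CtTable(
        ExpressionMatrix(nic_df, ValueKind.CT), cfg.panel
    )
    truth = QpcrTruth(
        groups=group_of, smokers=sorted(d for d, f in smoker_of.items() if f)
    )
    return control, nicotine, meta, truth


@dataclass
class PhenotypeTruth:
    planted_labels: dict[str, str]
    smokers: list[str]

    def to_dict(self) -> dict:
        return {"planted_labels": self.planted_labels, "smokers": self.smokers}


def simulate_phenotype_markers(
    n_samples: int,
    n_naive_memory: int,
    variant: ScoreConfig | None = None,
    seed: int = 0,
    separation: float = 4.0,
    marker_sd: float = 1.0,
    smoker_counts: tuple[int, int] | None = None,
    smoker_probs: tuple[float, float] = (9 / 13, 5 / 16),
) -> tuple[ExpressionMatrix, SampleTable, PhenotypeTruth]:
    """Marker table with planted naive-memory samples.

    Planted naive-memory samples draw every marker from
    N(separation, marker_sd); effectors from N(0, marker_sd), so with the
    default separation the cohort median splits the groups and scoring
    recovers the plant with high probability.

    Effectors share an exact per-marker baseline; as long as they are the
    cohort majority that baseline is the cohort median, ties score zero
    under the strictly-greater rule, and scoring recovers the plant for
    every seed. Planted naive-memory samples sit a positive offset of
    ``separation/2 .. separation`` above the baseline on every marker.

    ``smoker_counts = (k_naive, k_effector)`` forces exactly that many
    smokers within each planted group (deterministic mode, so forced 2x2
    counts survive the score round trip); otherwise smoker labels are
    Bernoulli with per-group probabilities ``smoker_probs`` (defaults
    matching a 9/13 vs 5/16 enrichment).
    """
    if variant is None:
        variant = variant_a()
    if n_naive_memory > n_samples:
        raise ValidationError("n_naive_memory must not exceed n_samples")
    if n_naive_memory == n_samples and n_samples > 0:
        raise ValidationError("cannot plant all samples naive_memory: no effector reference")
    rng = np.random.default_rng(seed)
    sample_ids = [f"D{i + 1:02d}" for i in range(n_samples)]
    labels = np.array(["naive_memory"] * n_naive_memory + ["effector"] * (n_samples - n_naive_memory))
    rng.shuffle(labels)

    vals = np.empty((len(variant.markers), n_samples))
    base = rng.normal(0.0, marker_sd, size=len(variant.markers))
    for j, lab in enumerate(labels):
        if lab == "naive_memory":
            vals[:, j] = base + rng.uniform(
                separation / 2, separation, size=len(variant.markers)
            )
        else:
            vals[:, j] = base
    mat = ExpressionMatrix(
        pd.DataFrame(vals, index=variant.markers, columns=sample_ids),
        ValueKind.NORMALIZED_LOG2,
    )

    naive_ids = [s for s, l in zip(sample_ids, labels) if l == "naive_memory"]
    eff_ids = [s for s, l in zip(sample_ids, labels) if l == "effector"]
    smoker = {s: False for s in sample_ids}
    if smoker_counts is not None:
        k_naive, k_eff = smoker_counts
        if k_naive > len(naive_ids) or k_eff > len(eff_ids):
            raise ValidationError("smoker_counts exceed planted group sizes")
        for s in rng.permutation(naive_ids)[:k_naive]:
            smoker[s] = True
        for s in rng.permutation(eff_ids)[:k_eff]:
            smoker[s] = True
    else:
        p_naive, p_eff = smoker_probs
        for s in naive_ids:
            smoker[s] = bool(rng.random() < p_naive)
        for s in eff_ids:
            smoker[s] = bool(rng.random() < p_eff)

    meta = SampleTable(
        pd.DataFrame(
            {
                "diagnosis": ["RA" if i % 2 == 0 else "HC" for i in range(n_samples)],
                "smoker": [smoker[s] for s in sample_ids],
                "condition": "control",
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    truth = PhenotypeTruth(
        planted_labels=dict(zip(sample_ids, labels)),
        smokers=sorted(s for s, f in smoker.items() if f),
    )
    return mat, meta, truth
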