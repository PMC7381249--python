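"""Shared data model, table readers/writers, configuration and logging.

The canonical in-memory layout is features x samples, values as float64
with NaN as the single missing sentinel regardless of which token encoded
the gap on disk.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("cd8mir")

DEFAULT_MISSING_TOKENS = ("", "NA")
#: opt-in missing token used by some published marker tables
X_MISSING_TOKEN = "X"


class Cd8mirError(Exception):
    """Base class for all package errors."""


class ParseError(Cd8mirError):
    """A cell could not be interpreted as a number."""


class SchemaError(Cd8mirError):
    """A table is missing required structure (columns, rows)."""


class ValidationError(Cd8mirError):
    """Values violate a contract (duplicate ids, bad enum, range)."""


class ValueKind(str, Enum):
    RAW_INTENSITY = "raw_intensity"
    LOG2 = "log2"
    NORMALIZED_LOG2 = "normalized_log2"
    CT = "ct"
    RQ = "rq"


class Orientation(str, Enum):
    FEATURES_IN_ROWS = "features_in_rows"
    SAMPLES_IN_ROWS = "samples_in_rows"


class Diagnosis(str, Enum):
    RA = "RA"
    HC = "HC"


class Condition(str, Enum):
    CONTROL = "control"
    NICOTINE = "nicotine"


@dataclass
class ExpressionMatrix:
    """Numeric features x samples grid with a value-kind tag.

    Parameters
    ----------
    data
        DataFrame indexed by feature id with sample ids as columns;
        missing values are NaN.
    value_kind
        What the numbers mean; downstream stages check this tag before
        operating (e.g. normalization refuses CT tables).
    """

    data: pd.DataFrame
    value_kind: ValueKind

    def __post_init__(self) -> None:
        self.value_kind = ValueKind(self.value_kind)
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dupes[:5]}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes[:5]}")
        self.data = self.data.astype(float)
        vals = self.data.to_numpy()
        if self.value_kind is ValueKind.RAW_INTENSITY:
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValidationError("raw intensities must be >= 0")
        elif self.value_kind is ValueKind.CT:
            finite = vals[np.isfinite(vals)]
            if finite.size and ((finite <= 0).any() or (finite > 45).any()):
                raise ValidationError("CT values must lie in (0, 45]")
        elif self.value_kind is ValueKind.RQ:
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite <= 0).any():
                raise ValidationError("RQ values must be > 0")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def require_kind(self, *kinds: ValueKind) -> None:
        if self.value_kind not in kinds:
            wanted = ", ".join(k.value for k in kinds)
            raise ValidationError(
                f"expected value_kind in {{{wanted}}}, got {self.value_kind.value}"
            )

    def copy_with(self, data: pd.DataFrame, value_kind: ValueKind) -> "ExpressionMatrix":
        return ExpressionMatrix(data=data, value_kind=value_kind)


@dataclass
class SampleTable:
    """Per-sample metadata: diagnosis, smoker flag, culture condition, pairing."""

    data: pd.DataFrame  # indexed by sample_id

    REQUIRED = ("diagnosis", "smoker", "condition")

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample_id in metadata")
        for col in self.REQUIRED:
            if col not in self.data.columns:
                raise SchemaError(f"metadata missing required column '{col}'")
        for v in self.data["diagnosis"]:
            Diagnosis(v)
        for v in self.data["condition"]:
            Condition(v)
        if not self.data["smoker"].map(lambda x: isinstance(x, (bool, np.bool_))).all():
            raise ValidationError("smoker column must be boolean")
        if "pair_id" in self.data.columns:
            pairs = self.data["pair_id"].dropna()
            for pid, grp in self.data.loc[pairs.index].groupby("pair_id"):
                if len(grp) > 2:
                    raise ValidationError(f"pair_id '{pid}' occurs more than twice")
                if len(grp) == 2 and grp["condition"].iloc[0] == grp["condition"].iloc[1]:
                    raise ValidationError(
                        f"pair_id '{pid}' has two samples with the same condition"
                    )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def smoker(self, sample_id: str) -> bool:
        return bool(self.data.loc[sample_id, "smoker"])

    def subset(self, sample_ids: Sequence[str]) -> "SampleTable":
        return SampleTable(self.data.loc[list(sample_ids)].copy())


@dataclass
class NoiseStats:
    """Per-sample scanner noise mean and SD (arbitrary units)."""

    data: pd.DataFrame  # indexed by sample_id, columns noise_mean, noise_sd

    def __post_init__(self) -> None:
        for col in ("noise_mean", "noise_sd"):
            if col not in self.data.columns:
                raise SchemaError(f"noise stats missing column '{col}'")
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample_id in noise stats")
        if (self.data["noise_sd"] < 0).any() or (self.data["noise_mean"] < 0).any():
            raise ValidationError("noise statistics must be nonnegative")

    def for_sample(self, sample_id: str) -> tuple[float, float]:
        if sample_id not in self.data.index:
            raise ValidationError(f"no noise record for sample '{sample_id}'")
        row = self.data.loc[sample_id]
        return float(row["noise_mean"]), float(row["noise_sd"])


@dataclass
class AnalytePanel:
    """mRNA and miR analyte ids plus the reference target for each side."""

    mrna_ids: list[str]
    mir_ids: list[str]
    mrna_reference: str = "GAPDH"
    mir_reference: str = "RNU6b"

    def __post_init__(self) -> None:
        if not self.mrna_ids or not self.mir_ids:
            raise ValidationError("both panel sides must be non-empty")
        if set(self.mrna_ids) & set(self.mir_ids):
            raise ValidationError("mRNA and miR panels must be disjoint")
        if self.mrna_reference in self.mrna_ids or self.mir_reference in self.mir_ids:
            raise ValidationError("reference targets must not be panel members")


def default_panel() -> AnalytePanel:
    """The FOXO-pathway mRNA panel and its targeting miR panel."""
    return AnalytePanel(
        mrna_ids=["FOXO1", "BCL6", "IL7R", "TCF7", "PDCD1"],
        mir_ids=[
            "let-7c-5p",
            "let-7d-5p",
            "let-7e-5p",
            "miR-92a-3p",
            "miR-150-5p",
            "miR-181a-5p",
        ],
    )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_table(
    path: str | Path,
    value_kind: ValueKind | str,
    orientation: Orientation | str = Orientation.FEATURES_IN_ROWS,
    missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS,
    accept_x: bool = False,
) -> ExpressionMatrix:
    """Read a delimited expression table into canonical orientation.

    ``missing_tokens`` (plus ``"X"`` when ``accept_x``) become NaN; any
    other non-numeric cell raises :class:`ParseError` naming its row and
    column. Duplicate ids on either axis are rejected.
    """
    path = Path(path)
    orientation = Orientation(orientation)
    tokens = set(missing_tokens)
    if accept_x:
        tokens.add(X_MISSING_TOKEN)
    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str, index_col=0, keep_default_na=False)
    if raw.shape[1] == 0:
        raise SchemaError(f"{path}: no data columns")
    parsed = {}
    for col in raw.columns:
        cells = raw[col].str.strip()
        cleaned = cells.where(~cells.isin(tokens), other=np.nan)
        numeric = pd.to_numeric(cleaned, errors="coerce")
        bad = numeric.isna() & cleaned.notna()
        if bad.any():
            row = bad.idxmax()
            raise ParseError(
                f"{path}: non-numeric cell {raw.loc[row, col]!r} at row '{row}', column '{col}'"
            )
        parsed[col] = numeric
    df = pd.DataFrame(parsed, index=raw.index)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if orientation is Orientation.SAMPLES_IN_ROWS:
        df = df.T
    return ExpressionMatrix(data=df, value_kind=ValueKind(value_kind))


def write_expression_table(mat: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    out = mat.data.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep=_sep_for(path), na_rep="NA", float_format="%.12g")


_TRUTHY = {"true", "yes", "y", "1"}
_FALSY = {"false", "no", "n", "0"}


def _parse_bool(value: object, context: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValidationError(f"{context}: cannot interpret {value!r} as boolean")


def read_sample_metadata(path: str | Path) -> SampleTable:
    """Read sample metadata; unknown columns are preserved as annotations."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty metadata file") from exc
    if "sample_id" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'sample_id'")
    for col in SampleTable.REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")
    if df.empty:
        raise SchemaError(f"{path}: metadata has no sample rows")
    df = df.set_index("sample_id")
    try:
        df["diagnosis"] = [Diagnosis(v).value for v in df["diagnosis"]]
        df["condition"] = [Condition(v).value for v in df["condition"]]
    except ValueError as exc:
        raise ValidationError(f"{path}: {exc}") from exc
    df["smoker"] = [_parse_bool(v, f"{path} smoker") for v in df["smoker"]]
    if "pair_id" in df.columns:
        df["pair_id"] = df["pair_id"].replace("", np.nan)
    if "pooled_n" in df.columns:
        df["pooled_n"] = pd.to_numeric(df["pooled_n"].replace("", np.nan)).astype("Int64")
    return SampleTable(df)


def write_sample_metadata(meta: SampleTable, path: str | Path) -> None:
    path = Path(path)
    out = meta.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep=_sep_for(path))


def read_noise_stats(path: str | Path) -> NoiseStats:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if "sample_id" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'sample_id'")
    return NoiseStats(df.set_index("sample_id"))


def write_noise_stats(noise: NoiseStats, path: str | Path) -> None:
    path = Path(path)
    out = noise.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep=_sep_for(path))


def check_sample_overlap(mat: ExpressionMatrix, meta: SampleTable) -> list[str]:
    """Return (and warn about) metadata samples absent from the matrix and vice versa."""
    unmatched = sorted(
        set(meta.sample_ids).symmetric_difference(mat.sample_ids)
    )
    if unmatched:
        logger.warning("unmatched sample ids between matrix and metadata: %s", unmatched)
    return unmatched


def read_geo_series_matrix(path: str | Path, value_kind: ValueKind | str = ValueKind.RAW_INTENSITY) -> ExpressionMatrix:
    """Parse the expression block of a GEO series-matrix text file.

    Only the ``!series_matrix_table_begin`` .. ``end`` block is read; probe
    ids become feature ids and GSM accessions become sample ids.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    try:
        start = next(i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_begin"))
        stop = next(i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_end"))
    except StopIteration as exc:
        raise SchemaError(f"{path}: no series-matrix table block found") from exc
    block = "\n".join(lines[start + 1 : stop])
    from io import StringIO

    df = pd.read_csv(StringIO(block), sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip('"')
    df.columns = df.columns.astype(str).str.strip('"')
    return ExpressionMatrix(data=df.astype(float), value_kind=ValueKind(value_kind))


# ---------------------------------------------------------------------------
# configuration, logging, manifest
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return cfg


def load_panel(path: str | Path) -> AnalytePanel:
    cfg = load_config(path)
    try:
        return AnalytePanel(
            mrna_ids=list(cfg["mrna_ids"]),
            mir_ids=list(cfg["mir_ids"]),
            mrna_reference=cfg.get("mrna_reference", "GAPDH"),
            mir_reference=cfg.get("mir_reference", "RNU6b"),
        )
    except KeyError as exc:
        raise SchemaError(f"{path}: panel config missing {exc}") from exc


def setup_logging(level: str = "INFO") -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level.upper())


def write_run_manifest(path: str | Path, *, config: Mapping, seed: int | None, stages: Iterable[Mapping]) -> dict:
    """Write the machine-readable run manifest tying outputs to config and seed."""
    import cd8mir

    manifest = {
        "tool": "cd8mir",
        "version": cd8mir.__version__,
        "seed": seed,
        "config": dict(config),
        "stages": list(stages),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
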