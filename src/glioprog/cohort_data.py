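"""Patient-level clinical tables: reading, validation, derived variables,
summaries, and the missingness filter.

The cohort substrate is a pandas DataFrame, one row per patient, with an
explicit missing-cell mask.  Fields follow a REDCap-style flat export for a
multi-site glioblastoma study: demographics, lesion features, molecular
markers (ATRX, p53, Ki-67, EGFR amplification, MGMT promoter methylation),
post-surgical complete blood counts (CBC), treatment (radiation,
temozolomide, steroids) and outcomes (overall survival, progression-free
survival, enhancement status).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

MISSING_TOKENS = {"", "na", "n/a"}

CENTERS = ("OSU", "UMMC", "Barretos", "FLENI")

#: field -> (kind, vocabulary-or-None).  kind in {"string","numeric","int",
#: "bool","categorical"}.
DEFAULT_SCHEMA: dict[str, tuple[str, tuple | None]] = {
    "patient_id": ("string", None),
    "center": ("categorical", CENTERS),
    "age_at_surgery": ("numeric", None),
    "gender": ("categorical", ("Male", "Female")),
    "race": ("categorical", ("Native American", "Asian", "Black or African",
                             "Caucasian", "More than One Race", "Unknown")),
    "ethnicity": ("categorical", ("Hispanic/Latino", "Non-Hispanic/Latino")),
    "weight": ("numeric", None),
    "height": ("numeric", None),
    "bmi": ("numeric", None),
    "cci_score": ("int", None),
    "lesion_side": ("categorical", ("Left", "Right", "Both")),
    "lesion_lobe": ("categorical", ("Frontal", "Temporal", "Parietal",
                                    "Occipital", "Brain Stem", "Cerebellum",
                                    "Mixed")),
    "lesion_size": ("numeric", None),
    "midline_shift": ("bool", None),
    "atrx": ("categorical", ("intact", "loss")),
    "p53_positive": ("bool", None),
    "ki67": ("numeric", None),
    "egfr_amplified": ("bool", None),
    "mgmt_methylated": ("bool", None),
    "wbc": ("numeric", None),
    "neutrophils": ("numeric", None),
    "lymphocytes": ("numeric", None),
    "platelets": ("numeric", None),
    "nlr": ("numeric", None),
    "steroid_dose": ("numeric", None),
    "radiation_dose": ("numeric", None),
    "radiation_fractions": ("int", None),
    "radiation_time": ("numeric", None),
    "tmz_dose": ("numeric", None),
    "tmz_cycles": ("int", None),
    "os_days": ("numeric", None),
    "os_event": ("bool", None),
    "pfs_days": ("numeric", None),
    "pfs_event": ("bool", None),
    "enhancement_status": ("categorical", ("recurrent", "reactive", "stable")),
}

MANDATORY_COLUMNS = ("patient_id", "os_days", "os_event")

#: molecular markers summarized over the tested (non-missing) denominator;
#: everything else uses the whole-cohort denominator.
TESTED_ONLY_FEATURES = ("atrx", "p53_positive", "egfr_amplified",
                        "mgmt_methylated")

#: default feature set over which row-wise missingness is computed and over
#: which imputation/PCA operate.
ANALYSIS_FEATURES = (
    "age_at_surgery", "gender", "weight", "height", "bmi", "cci_score",
    "lesion_side", "lesion_size", "midline_shift", "atrx", "p53_positive",
    "ki67", "egfr_amplified", "mgmt_methylated", "wbc", "neutrophils",
    "lymphocytes", "platelets", "nlr", "steroid_dose", "radiation_dose",
    "radiation_fractions", "radiation_time", "tmz_dose", "tmz_cycles",
    "os_days", "pfs_days", "enhancement_status",
)


class SchemaError(ValueError):
    """A required column is absent or a field violates the schema."""


class ValidationError(ValueError):
    """Row-level constraint violated (e.g. duplicate patient id)."""


@dataclass
class CohortTable:
    """One row per patient plus a per-cell missingness mask.

    ``df`` holds typed columns (numerics as float, booleans/categoricals as
    pandas nullable types); ``missing_mask`` is a same-shaped boolean frame,
    True where the cell is missing.
    """

    df: pd.DataFrame
    schema: Mapping[str, tuple[str, tuple | None]] = field(
        default_factory=lambda: dict(DEFAULT_SCHEMA))
    schema_version: str = "1.0"

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.df.isna()

    @property
    def n(self) -> int:
        return len(self.df)

    def copy(self) -> "CohortTable":
        return CohortTable(self.df.copy(), dict(self.schema),
                           self.schema_version)

    def validate(self) -> None:
        ids = self.df["patient_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValidationError(f"duplicate patient_id {dup!r}")
        if self.n and self.missing_mask.all(axis=1).any():
            raise ValidationError("a row is entirely missing")
        for col in ("os_days", "pfs_days"):
            if col in self.df and (self.df[col].dropna() < 0).any():
                raise ValidationError(f"{col} must be >= 0")


@dataclass
class CohortSummary:
    """Per-feature summary entries.

    Categorical features map to ``{level: (count, percent)}``; numeric
    features map to ``{"mean": m, "min": lo, "max": hi}``.  ``denominators``
    records the denominator used per categorical feature (whole cohort vs
    tested-only subset).
    """

    entries: dict[str, dict]
    denominators: dict[str, int]
    n: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for feat, entry in self.entries.items():
            if "mean" in entry:
                rows.append((feat, "", np.nan, np.nan,
                             entry["mean"], entry["min"], entry["max"]))
            else:
                for level, (count, pct) in entry.items():
                    rows.append((feat, level, count, pct,
                                 np.nan, np.nan, np.nan))
        return pd.DataFrame(
            rows, columns=["feature", "level", "count", "percent",
                           "mean", "min", "max"])


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero (table-cell convention)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _coerce(series: pd.Series, kind: str, vocab: tuple | None,
            name: str) -> pd.Series:
    s = series.copy()
    if s.dtype == object:
        stripped = s.astype("string").str.strip()
        s = stripped.mask(stripped.str.lower().isin(MISSING_TOKENS))
    if kind in ("numeric", "int"):
        return pd.to_numeric(s, errors="coerce").astype(float)
    if kind == "bool":
        mapping = {"true": True, "false": False, "yes": True, "no": False,
                   "1": True, "0": False, "1.0": True, "0.0": False}
        if s.dtype == bool:
            return s.astype("boolean")
        out = s.astype("string").str.lower().map(mapping)
        return out.astype("boolean")
    if kind == "categorical":
        s = s.astype("string")
        if vocab is not None:
            bad = set(s.dropna().unique()) - set(vocab)
            if bad:
                raise SchemaError(
                    f"field {name!r}: values {sorted(bad)} outside the "
                    f"declared vocabulary {vocab}")
        return s
    return s.astype("string")


def read_schema(path: str | Path) -> dict[str, tuple[str, tuple | None]]:
    """Load a field specification from a plain-text key/value (YAML) file.

    Each entry is ``field: kind`` or ``field: {kind: categorical,
    vocabulary: [...]}``.
    """
    raw = yaml.safe_load(Path(path).read_text())
    schema: dict[str, tuple[str, tuple | None]] = {}
    for name, val in raw.items():
        if isinstance(val, str):
            schema[name] = (val, None)
        else:
            schema[name] = (val["kind"], tuple(val.get("vocabulary", ()))
                            or None)
    return schema


def read_cohort(path: str | Path,
                schema: Mapping[str, tuple[str, tuple | None]] | None = None,
                ) -> CohortTable:
    """Read a delimited clinical table into a typed :class:`CohortTable`.

    Empty cells and the tokens ``NA``/``N/A`` (case-insensitive) are
    missing.  Unknown columns are ignored with a warning; missing mandatory
    columns raise :class:`SchemaError`; duplicated patient ids raise
    :class:`ValidationError`.  Derived fields (NLR, BMI) are *not*
    populated here — see :func:`derive_variables`.
    """
    schema = dict(schema or DEFAULT_SCHEMA)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise SchemaError(f"mandatory columns absent: {missing_cols}")
    unknown = [c for c in raw.columns if c not in schema]
    if unknown:
        warnings.warn(f"ignoring unknown columns {unknown}", stacklevel=2)
        raw = raw.drop(columns=unknown)
    out = pd.DataFrame(index=raw.index)
    for name in schema:
        if name not in raw.columns:
            continue
        kind, vocab = schema[name]
        out[name] = _coerce(raw[name], kind, vocab, name)
    table = CohortTable(out, schema)
    table.validate()
    return table


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write the table as UTF-8 CSV with empty cells for missing values."""
    df = table.df.copy()
    for col in df.columns:
        if str(df[col].dtype) == "boolean":
            df[col] = df[col].map({True: "True", False: "False"})
    df.to_csv(path, index=False, na_rep="")


def derive_variables(table: CohortTable) -> CohortTable:
    """Populate derived fields: NLR = neutrophils / lymphocytes and
    BMI = weight / height(m)^2, wherever both parents are present.

    A zero lymphocyte count leaves NLR missing (division guard, logged).
    Idempotent; non-derived cells are untouched.
    """
    out = table.copy()
    df = out.df
    if {"neutrophils", "lymphocytes"} <= set(df.columns):
        neut, lymph = df["neutrophils"], df["lymphocytes"]
        zero = lymph == 0
        if zero.any():
            log.warning("NLR left missing for %d rows with zero lymphocytes",
                        int(zero.sum()))
        ok = neut.notna() & lymph.notna() & ~zero
        nlr = df.get("nlr", pd.Series(np.nan, index=df.index, dtype=float))
        nlr = nlr.astype(float)
        nlr[ok] = neut[ok] / lymph[ok]
        df["nlr"] = nlr
    if {"weight", "height"} <= set(df.columns):
        w, h = df["weight"], df["height"]
        ok = w.notna() & h.notna() & (h > 0)
        bmi = df.get("bmi", pd.Series(np.nan, index=df.index, dtype=float))
        bmi = bmi.astype(float)
        bmi[ok] = w[ok] / (h[ok] / 100.0) ** 2
        df["bmi"] = bmi
    return out


def summarize_cohort(table: CohortTable,
                     group_by: str | None = None,
                     tested_only: Sequence[str] = TESTED_ONLY_FEATURES,
                     ) -> CohortSummary | dict[str, CohortSummary]:
    """Summarize features: categoricals as count (percent), numerics as
    mean [min–max].

    Percentages use the whole-cohort denominator except for the
    ``tested_only`` molecular markers, which use the non-missing
    denominator.  Percents are rounded half-up to two decimals.  When
    ``group_by`` is given, returns one summary per group level.
    """
    if table.n == 0:
        raise ValidationError("cannot summarize an empty cohort")
    if group_by is not None:
        out = {}
        for level, sub in table.df.groupby(group_by, observed=True):
            out[level] = summarize_cohort(
                CohortTable(sub.reset_index(drop=True), table.schema),
                tested_only=tested_only)
        return out

    entries: dict[str, dict] = {}
    denoms: dict[str, int] = {}
    n = table.n
    for name in table.df.columns:
        if name == "patient_id":
            continue
        kind, _ = table.schema.get(name, ("numeric", None))
        col = table.df[name]
        if kind in ("categorical", "bool"):
            denom = int(col.notna().sum()) if name in tested_only else n
            denoms[name] = denom
            counts = col.value_counts(dropna=True)
            entry = {}
            for level, count in counts.items():
                pct = round_half_up(100.0 * count / denom) if denom else 0.0
                entry[level] = (int(count), pct)
            entries[name] = entry
        else:
            obs = col.dropna()
            if len(obs):
                entries[name] = {"mean": float(obs.mean()),
                                 "min": float(obs.min()),
                                 "max": float(obs.max())}
            else:
                entries[name] = {"mean": np.nan, "min": np.nan,
                                 "max": np.nan}
    return CohortSummary(entries, denoms, n)


def filter_missingness(table: CohortTable,
                       threshold: float = 0.30,
                       features: Iterable[str] = ANALYSIS_FEATURES,
                       ) -> tuple[CohortTable, list[str]]:
    """Drop rows whose per-row missing fraction over the analysis-feature
    set is strictly greater than ``threshold`` ("over 30%" is strict).

    Returns the kept table (row order preserved) and the dropped ids.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    feats = [f for f in features if f in table.df.columns]
    frac = table.df[feats].isna().mean(axis=1)
    keep = frac <= threshold
    dropped = table.df.loc[~keep, "patient_id"].tolist()
    kept = CohortTable(table.df.loc[keep].reset_index(drop=True),
                       table.schema, table.schema_version)
    return kept, dropped
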