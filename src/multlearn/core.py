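"""Data model, readers/writers, marker encoding, cohort filtering and
min-max normalization shared by every pipeline stage.

A cohort couples four aligned tables for one set of patients: an encoded
clinical-marker matrix, a non-negative gene-expression matrix, a first-line
treatment label and an ordered treatment-response (TR) class.  Optional
columns carry the derived binary treatment-sensitivity (TS) outcome and
days-to-disease-progression survival data.  All matrices share the same
patient row order (lexicographic by patient id) so that feature blocks built
by later stages can be concatenated column-wise without re-alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Ordered treatment-response vocabulary, worst to best depth of response.
RESPONSE_CLASSES = ["PD", "SD", "PR", "VGPR", "CR", "SCR"]

ID_COLUMN = "patient_id"


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class MultError(Exception):
    """Base class for every error raised by this package."""


class ConfigError(MultError):
    """Invalid configuration or schema."""


class SchemaError(ConfigError):
    """A clinical-marker schema does not match the data."""


class DataError(MultError):
    """Invalid or degenerate input data."""


class FormatError(DataError):
    """A file could not be parsed; the message names file and cell."""


class ContractError(MultError):
    """A function was called outside its contract."""


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """Aligned per-patient tables.

    Parameters
    ----------
    clinical
        Patients x clinical-marker numeric matrix (encoded; may contain NaN
        until :func:`filter_cohort` imputes).
    expression
        Patients x genes non-negative matrix with no missing entries.
    treatment
        First-line treatment label per patient ("Non-treatment" is valid).
    response
        Ordered TR class per patient, one of :data:`RESPONSE_CLASSES`, or NaN.
    ts
        Optional binary treatment-sensitivity outcome.
    ddp_days, ddp_event
        Optional days to disease progression and event flag.
    fish
        Optional patients x FISH-marker binary matrix.
    """

    clinical: pd.DataFrame
    expression: pd.DataFrame
    treatment: pd.Series
    response: pd.Series
    ts: pd.Series | None = None
    ddp_days: pd.Series | None = None
    ddp_event: pd.Series | None = None
    fish: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    @property
    def patient_ids(self) -> list:
        return list(self.clinical.index)

    @property
    def n_patients(self) -> int:
        return len(self.clinical)

    def validate(self) -> None:
        idx = self.clinical.index
        for name in ("expression", "treatment", "response", "ts",
                     "ddp_days", "ddp_event", "fish"):
            obj = getattr(self, name)
            if obj is None:
                continue
            if len(obj) != len(idx) or not (obj.index == idx).all():
                raise ContractError(
                    f"cohort table '{name}' is not aligned with the clinical "
                    f"matrix ({len(obj)} vs {len(idx)} patients)")
        if not idx.is_unique:
            raise DataError("duplicate patient ids in cohort")

    def subset(self, ids) -> "Cohort":
        """Return the cohort restricted to ``ids`` (order preserved)."""
        ids = list(ids)

        def take(obj):
            return None if obj is None else obj.loc[ids]

        return Cohort(
            clinical=self.clinical.loc[ids],
            expression=self.expression.loc[ids],
            treatment=self.treatment.loc[ids],
            response=self.response.loc[ids],
            ts=take(self.ts), ddp_days=take(self.ddp_days),
            ddp_event=take(self.ddp_event), fish=take(self.fish))

    def with_ts(self, ts: pd.Series) -> "Cohort":
        ts = ts.loc[self.clinical.index].astype(int)
        return replace(self, ts=ts)

    # -- I/O ---------------------------------------------------------------

    def write(self, out_dir) -> None:
        """Write the cohort as uncompressed TSV tables under ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.clinical.rename_axis(ID_COLUMN).to_csv(out / "clinical.tsv", sep="\t")
        self.expression.rename_axis(ID_COLUMN).to_csv(out / "expression.tsv", sep="\t")
        self.treatment.rename("treatment").rename_axis(ID_COLUMN).to_csv(
            out / "treatment.tsv", sep="\t")
        self.response.rename("response").rename_axis(ID_COLUMN).to_csv(
            out / "response.tsv", sep="\t")
        if self.ddp_days is not None:
            surv = pd.DataFrame({
                "ddp_days": self.ddp_days,
                "ddp_event": self.ddp_event,
            })
            surv.rename_axis(ID_COLUMN).to_csv(out / "survival.tsv", sep="\t")
        if self.fish is not None:
            self.fish.rename_axis(ID_COLUMN).to_csv(out / "fish.tsv", sep="\t")


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    if ID_COLUMN not in df.columns:
        raise FormatError(
            f"{path}: missing required id column '{ID_COLUMN}' "
            f"(found: {list(df.columns)[:5]}...)")
    df[ID_COLUMN] = df[ID_COLUMN].astype(str)
    if df[ID_COLUMN].duplicated().any():
        dup = df[ID_COLUMN][df[ID_COLUMN].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicated patient id '{dup}'")
    return df.set_index(ID_COLUMN)


def _require_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            pid = bad.idxmax()
            raise FormatError(
                f"{path}: non-numeric value {df.at[pid, col]!r} at "
                f"patient '{pid}', column '{col}'")
        out[col] = coerced
    return pd.DataFrame(out, index=df.index)


def load_cohort(clinical_path, expression_path, treatment_path,
                response_path, survival_path=None, fish_path=None) -> Cohort:
    """Load a cohort from per-table CSV/TSV files, inner-joined on patient id.

    Row order is deterministic: patients sorted lexicographically by id.
    Raises :class:`FormatError` on parse problems (naming file and cell) and
    :class:`DataError` when the tables share no patients.
    """
    clinical = _require_numeric(_read_table(clinical_path), clinical_path)
    expression = _require_numeric(_read_table(expression_path), expression_path)
    tr = _read_table(treatment_path)
    if "treatment" not in tr.columns:
        raise FormatError(f"{treatment_path}: missing 'treatment' column")
    resp = _read_table(response_path)
    if "response" not in resp.columns:
        raise FormatError(f"{response_path}: missing 'response' column")

    ids = clinical.index.intersection(expression.index)
    ids = ids.intersection(tr.index).intersection(resp.index)
    surv = None
    if survival_path is not None:
        surv = _require_numeric(_read_table(survival_path), survival_path)
        for col in ("ddp_days", "ddp_event"):
            if col not in surv.columns:
                raise FormatError(f"{survival_path}: missing '{col}' column")
        ids = ids.intersection(surv.index)
    fish = None
    if fish_path is not None:
        fish = _require_numeric(_read_table(fish_path), fish_path)
        ids = ids.intersection(fish.index)
    if len(ids) == 0:
        raise DataError("no patients shared by all input tables (empty join)")
    ids = sorted(ids)

    return Cohort(
        clinical=clinical.loc[ids],
        expression=expression.loc[ids],
        treatment=tr.loc[ids, "treatment"].astype(str),
        response=resp.loc[ids, "response"],
        ddp_days=None if surv is None else surv.loc[ids, "ddp_days"],
        ddp_event=None if surv is None else surv.loc[ids, "ddp_event"].astype(int),
        fish=None if fish is None else fish.loc[ids])


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def encode_markers(raw: pd.DataFrame, schema: dict, impute: bool = True) -> pd.DataFrame:
    """Encode a raw clinical table into a numeric feature matrix.

    ``schema`` maps each column name to ``{"type": "nominal" | "ordinal" |
    "numeric", "levels": [...]}`` where ``levels`` is required for ordinal
    columns (the rank order) and optional for nominal ones (defaults to the
    observed values, sorted).  Nominal columns expand to one 0/1 column per
    level, ordinal levels map to 1, 2, 3, ... and missing values become 0
    (or stay NaN with ``impute=False``, so callers can measure missingness
    before zero-fill).
    """
    blocks: list[pd.DataFrame] = []
    for col in raw.columns:
        if col not in schema:
            raise SchemaError(f"column '{col}' missing from schema")
        spec = schema[col]
        kind = spec["type"] if isinstance(spec, dict) else spec
        values = raw[col]
        if kind == "numeric":
            enc = pd.to_numeric(values, errors="coerce").to_frame(col)
        elif kind == "ordinal":
            levels = list(spec["levels"])
            unknown = set(values.dropna()) - set(levels)
            if unknown:
                raise SchemaError(
                    f"ordinal column '{col}': value {sorted(unknown)[0]!r} "
                    f"not in declared levels {levels}")
            mapping = {lev: i + 1 for i, lev in enumerate(levels)}
            enc = values.map(mapping).astype(float).to_frame(col)
        elif kind == "nominal":
            levels = (list(spec.get("levels"))
                      if isinstance(spec, dict) and spec.get("levels")
                      else sorted(values.dropna().unique()))
            enc = pd.DataFrame(index=raw.index)
            for lev in levels:
                onehot = (values == lev).astype(float)
                onehot[values.isna()] = np.nan  # missing: unknown level
                enc[f"{col}={lev}"] = onehot
        else:
            raise SchemaError(f"column '{col}': unknown type {kind!r}")
        blocks.append(enc)
    out = pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=raw.index)
    if impute:
        out = out.fillna(0.0)
    return out


def one_hot_treatment(treatment: pd.Series, vocabulary: list[str]) -> pd.DataFrame:
    """One-hot treatment block **T** over a fixed (training) vocabulary."""
    unknown = set(treatment) - set(vocabulary)
    if unknown:
        raise ContractError(
            f"treatment value(s) {sorted(unknown)} outside the vocabulary")
    return pd.DataFrame(
        {f"treatment={t}": (treatment == t).astype(float) for t in vocabulary},
        index=treatment.index)


# ---------------------------------------------------------------------------
# Cohort filtering
# ---------------------------------------------------------------------------

def filter_cohort(cohort: Cohort, min_treatment_n: int = 10,
                  max_missing_frac: float = 0.10) -> tuple[Cohort, pd.DataFrame]:
    """Apply the cohort inclusion rules and return (cohort, filter log).

    In order: drop patients with a missing TR response, drop treatments with
    fewer than ``min_treatment_n`` patients, drop clinical markers whose
    pre-imputation missing fraction exceeds ``max_missing_frac``, then
    zero-fill the remaining missing clinical values.  The log records each
    dropped entity with its reason.
    """
    log: list[dict] = []

    keep = cohort.response.notna() & (cohort.response.astype(str) != "")
    if (~keep).any():
        log.append({"entity": "patients", "reason": "missing_response",
                    "count": int((~keep).sum())})
    ids = cohort.clinical.index[keep]
    sub = cohort.subset(ids)

    counts = sub.treatment.value_counts()
    small = counts[counts < min_treatment_n]
    for t, n in small.items():
        log.append({"entity": f"treatment:{t}",
                    "reason": f"fewer_than_{min_treatment_n}_patients",
                    "count": int(n)})
    keep_t = ~sub.treatment.isin(small.index)
    sub = sub.subset(sub.clinical.index[keep_t])
    if sub.n_patients == 0:
        raise DataError("all patients removed by cohort filters (empty cohort)")

    miss = sub.clinical.isna().mean()
    bad_markers = miss[miss > max_missing_frac].index
    for m in bad_markers:
        log.append({"entity": f"marker:{m}",
                    "reason": f"missing_fraction_above_{max_missing_frac}",
                    "count": int(sub.clinical[m].isna().sum())})
    clinical = sub.clinical.drop(columns=list(bad_markers)).fillna(0.0)

    out = replace(sub, clinical=clinical)
    log_df = pd.DataFrame(log, columns=["entity", "reason", "count"])
    return out, log_df


# ---------------------------------------------------------------------------
# Min-max normalization
# ---------------------------------------------------------------------------

@dataclass
class Normalizer:
    """Per-marker min-max bounds learned on training data.

    ``n(m) = (m - min_M) / (max_M - min_M)``; constant markers
    (``max_M == min_M``) map to 0.  Validation data is transformed with
    ``clip=True``, i.e. ``min(1, max(0, n(m)))``.
    """

    min_: pd.Series = field(default_factory=pd.Series)
    max_: pd.Series = field(default_factory=pd.Series)

    def fit(self, train: pd.DataFrame) -> "Normalizer":
        if train.shape[0] == 0 or train.shape[1] == 0:
            raise ContractError("cannot fit a normalizer on an empty matrix")
        self.min_ = train.min(axis=0)
        self.max_ = train.max(axis=0)
        return self

    def transform(self, data: pd.DataFrame, clip: bool) -> pd.DataFrame:
        unseen = data.columns.difference(self.min_.index)
        if len(unseen):
            raise ContractError(
                f"marker(s) not seen at fit time: {list(unseen)[:5]}")
        lo = self.min_[data.columns]
        span = self.max_[data.columns] - lo
        out = (data - lo) / span.replace(0.0, np.inf)  # constant marker -> 0
        if clip:
            out = out.clip(0.0, 1.0)
        return out


def fit_normalizer(train: pd.DataFrame) -> Normalizer:
    return Normalizer().fit(train)


def apply_normalizer(norm: Normalizer, data: pd.DataFrame, clip: bool) -> pd.DataFrame:
    return norm.transform(data, clip=clip)
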