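"""Cohort tables, schemas, and CSV round-trip IO.

A cohort is four tables:

* ``static.csv`` -- one row per patient: demographics, baseline GCS,
  Marshall CT class, six-month GOSE, ordinal-prognosis probabilities
  Pr(GOSE > 1/3/4/5/6/7), the refractory-intracranial-hypertension
  label, WLST decision day and ICU length of stay.
* ``therapy_daily.csv`` -- one row per patient-day (days 1-7): the
  twelve ICP-treatment items that feed the scale scores.
* ``physio.csv`` -- timestamped ICP/blood-pressure samples; the
  end-hour (EH) stream carries SBP/DBP, the high-frequency (HR) stream
  carries CPP directly.
* ``concerns.csv`` -- daily physician concern for ICP and CPP (1-10).

Missing cells are written as empty strings and read back as pandas NA;
no numeric sentinels are used.  Every file starts with a one-line
schema marker (``# tilscale-cohort-v1``) so that drifted files fail
loudly rather than parse differently.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .scales import ITEM_COLUMNS, ITEM_LEVELS

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "tilscale-cohort-v1"

PROGNOSIS_COLUMNS = (
    "pr_gose_gt1",
    "pr_gose_gt3",
    "pr_gose_gt4",
    "pr_gose_gt5",
    "pr_gose_gt6",
    "pr_gose_gt7",
)

MARSHALL_LEVELS = ("I", "II", "III", "IV", "V", "VI")
SEX_LEVELS = ("female", "male")
STREAM_LEVELS = ("EH", "HR")

#: column -> pandas dtype, per table.  Binary flags are nullable Int64
#: holding 0/1 so that missingness survives a CSV round trip.
STATIC_SCHEMA = {
    "patient_id": "string",
    "center_id": "string",
    "age": "Float64",
    "sex": "string",
    "gcs_baseline": "Int64",
    "marshall": "string",
    "gose_6mo": "Int64",
    **{c: "Float64" for c in PROGNOSIS_COLUMNS},
    "refractory_ich": "Int64",
    "wlst_day": "Int64",
    "icu_los_days": "Int64",
}

_ITEM_DTYPES = {
    item: ("Int64" if levels == ("present",) else "string")
    for item, levels in ITEM_LEVELS.items()
}

THERAPY_SCHEMA = {
    "patient_id": "string",
    "day": "Int64",
    **_ITEM_DTYPES,
    "dc_refractory": "Int64",
}

PHYSIO_SCHEMA = {
    "patient_id": "string",
    "timestamp_s": "Float64",
    "stream": "string",
    "icp": "Float64",
    "sbp": "Float64",
    "dbp": "Float64",
    "cpp": "Float64",
}

CONCERNS_SCHEMA = {
    "patient_id": "string",
    "day": "Int64",
    "icp_concern": "Int64",
    "cpp_concern": "Int64",
}

FILE_NAMES = {
    "static": "static.csv",
    "therapy": "therapy_daily.csv",
    "physio": "physio.csv",
    "concerns": "concerns.csv",
}

_SCHEMAS = {
    "static": STATIC_SCHEMA,
    "therapy": THERAPY_SCHEMA,
    "physio": PHYSIO_SCHEMA,
    "concerns": CONCERNS_SCHEMA,
}


class CohortSchemaError(ValueError):
    """A cohort file violates the documented schema."""


@dataclass
class Cohort:
    """The four validated cohort tables."""

    static: pd.DataFrame
    therapy: pd.DataFrame
    physio: pd.DataFrame
    concerns: pd.DataFrame

    def validate(self) -> "Cohort":
        _validate_cohort(self)
        return self


def _empty(table: str) -> pd.DataFrame:
    schema = _SCHEMAS[table]
    return pd.DataFrame({c: pd.Series(dtype=d) for c, d in schema.items()})


def _check_enum(df: pd.DataFrame, table: str, column: str, allowed: tuple) -> None:
    col = df[column]
    bad = col.notna() & ~col.isin(allowed)
    if bad.any():
        rows = (df.index[bad] + 1).tolist()[:5]
        raise CohortSchemaError(
            f"{table}: column {column!r} has value(s) "
            f"{sorted(col[bad].unique())} at row(s) {rows}; "
            f"permitted values: {list(allowed)}"
        )


def _check_range(df, table, column, lo=None, hi=None):
    col = pd.to_numeric(df[column], errors="coerce")
    bad = df[column].notna() & (
        (col < lo if lo is not None else False) | (col > hi if hi is not None else False)
    )
    if np.asarray(bad).any():
        rows = (df.index[bad] + 1).tolist()[:5]
        raise CohortSchemaError(
            f"{table}: column {column!r} out of range [{lo}, {hi}] at row(s) {rows}"
        )


def _validate_cohort(cohort: Cohort) -> None:
    s, t, p, c = cohort.static, cohort.therapy, cohort.physio, cohort.concerns

    if s["patient_id"].duplicated().any():
        dupes = s["patient_id"][s["patient_id"].duplicated()].tolist()
        raise CohortSchemaError(f"static: duplicate patient_id(s) {dupes[:5]}")
    _check_enum(s, "static", "sex", SEX_LEVELS)
    _check_enum(s, "static", "marshall", MARSHALL_LEVELS)
    _check_range(s, "static", "gcs_baseline", 3, 15)
    _check_range(s, "static", "gose_6mo", 1, 8)
    for col in PROGNOSIS_COLUMNS:
        _check_range(s, "static", col, 0.0, 1.0)
    _check_range(s, "static", "wlst_day", 1, None)
    _check_range(s, "static", "icu_los_days", 1, None)

    # prognosis probabilities must be non-increasing over the thresholds
    prog = s[list(PROGNOSIS_COLUMNS)].astype(float).to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # NaN comparisons
        increasing = np.nanmax(np.diff(prog, axis=1), axis=1) > 1e-9
    if np.any(increasing & ~np.isnan(prog).all(axis=1)):
        rows = (s.index[increasing] + 1).tolist()[:5]
        raise CohortSchemaError(
            f"static: prognosis probabilities increase over thresholds at row(s) {rows}"
        )
    both = s["wlst_day"].notna() & s["icu_los_days"].notna()
    if (s.loc[both, "wlst_day"] > s.loc[both, "icu_los_days"]).any():
        raise CohortSchemaError("static: wlst_day exceeds icu_los_days")

    _check_range(t, "therapy", "day", 1, 7)
    if t.duplicated(subset=["patient_id", "day"]).any():
        pairs = t.loc[
            t.duplicated(subset=["patient_id", "day"]), ["patient_id", "day"]
        ].values.tolist()
        raise CohortSchemaError(f"therapy: duplicate (patient, day) pair(s) {pairs[:5]}")
    for item, levels in ITEM_LEVELS.items():
        if levels == ("present",):
            _check_range(t, "therapy", item, 0, 1)
        else:
            _check_enum(t, "therapy", item, ("none",) + levels)
    _check_range(t, "therapy", "dc_refractory", 0, 1)
    dcr = (t["dc_refractory"].fillna(0) == 1) & (t["dc"].fillna(0) != 1)
    if dcr.any():
        rows = (t.index[dcr] + 1).tolist()[:5]
        raise CohortSchemaError(
            f"therapy: dc_refractory without dc on the index day at row(s) {rows}"
        )

    _check_enum(p, "physio", "stream", STREAM_LEVELS)
    order = p.sort_values(["patient_id", "stream", "timestamp_s"])
    nondec = order.groupby(["patient_id", "stream"])["timestamp_s"].diff()
    if (nondec <= 0).any():
        raise CohortSchemaError(
            "physio: timestamps not strictly increasing within a patient stream"
        )

    _check_range(c, "concerns", "day", 1, 7)
    _check_range(c, "concerns", "icp_concern", 1, 10)
    _check_range(c, "concerns", "cpp_concern", 1, 10)

    known = set(s["patient_id"])
    for name, df in (("therapy", t), ("physio", p), ("concerns", c)):
        unknown = set(df["patient_id"]) - known
        if unknown:
            raise CohortSchemaError(
                f"{name}: patient_id(s) {sorted(unknown)[:5]} not present in static table"
            )


def _read_table(path: Path, table: str) -> pd.DataFrame:
    schema = _SCHEMAS[table]
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline().strip()
    if not first.startswith("#"):
        raise CohortSchemaError(
            f"{path}: missing schema marker line (expected '# {SCHEMA_VERSION}')"
        )
    version = first.lstrip("# ").strip()
    if version != SCHEMA_VERSION:
        raise CohortSchemaError(
            f"{path}: schema version {version!r} does not match {SCHEMA_VERSION!r}"
        )
    df = pd.read_csv(path, skiprows=1, dtype="string", keep_default_na=True)
    missing_cols = [c for c in schema if c not in df.columns]
    if missing_cols:
        raise CohortSchemaError(f"{path}: missing column(s) {missing_cols}")
    extra = [c for c in df.columns if c not in schema]
    if extra:
        raise CohortSchemaError(f"{path}: unexpected column(s) {extra}")
    out = {}
    for col, dtype in schema.items():
        ser = df[col]
        if dtype == "string":
            out[col] = ser.astype("string")
        else:
            num = pd.to_numeric(ser, errors="coerce")
            bad = ser.notna() & num.isna()
            if bad.any():
                rows = (df.index[bad] + 1).tolist()[:5]
                raise CohortSchemaError(
                    f"{path}: non-numeric value(s) in column {col!r} at row(s) {rows}"
                )
            out[col] = num.astype(dtype)
    if len(df) == 0:
        logger.warning("cohort table %s (%s) is empty", table, path)
        warnings.warn(f"cohort table {table!r} is empty", stacklevel=3)
    return pd.DataFrame(out)


def read_cohort(directory: str | Path, schema_version: str = SCHEMA_VERSION) -> Cohort:
    """Read and validate the four cohort CSVs from ``directory``.

    Raises :class:`CohortSchemaError` naming the offending file, column
    and row for any schema violation; malformed values are never
    silently coerced.
    """
    if schema_version != SCHEMA_VERSION:
        raise CohortSchemaError(
            f"unsupported schema version {schema_version!r}; this build "
            f"reads {SCHEMA_VERSION!r}"
        )
    directory = Path(directory)
    tables = {}
    for key, fname in FILE_NAMES.items():
        path = directory / fname
        if not path.exists():
            raise FileNotFoundError(f"cohort file not found: {path}")
        tables[key] = _read_table(path, key)
    cohort = Cohort(
        static=tables["static"],
        therapy=tables["therapy"],
        physio=tables["physio"],
        concerns=tables["concerns"],
    )
    cohort.validate()
    return cohort


def _write_table(df: pd.DataFrame, path: Path, table: str) -> None:
    schema = _SCHEMAS[table]
    df = df.reindex(columns=list(schema))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# {SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False, na_rep="", lineterminator="\n")


def write_cohort(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Write the four cohort CSVs; returns the written paths.

    Output is byte-stable under a fixed column order, and a write
    followed by :func:`read_cohort` reproduces every cell including its
    missingness.
    """
    cohort.validate()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for key, fname in FILE_NAMES.items():
        path = directory / fname
        _write_table(getattr(cohort, _ATTR[key]), path, key)
        paths[key] = path
    return paths


_ATTR = {"static": "static", "therapy": "therapy", "physio": "physio", "concerns": "concerns"}


def empty_cohort() -> Cohort:
    """A cohort with all four tables empty (correct dtypes)."""
    return Cohort(
        static=_empty("static"),
        therapy=_empty("therapy"),
        physio=_empty("physio"),
        concerns=_empty("concerns"),
    )
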