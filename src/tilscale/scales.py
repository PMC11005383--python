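"""Scoring engine for therapy intensity level (TIL) scales.

Five scoring configurations are supported: the 38-point TIL scale, its
unweighted variant (uwTIL, max 21), the condensed five-category TILBasic
(0-4), and the two predecessor scales PILOT (max 38) and TIL1987 (max 15)
adapted to the TIL item set.  A daily score is computed from one day's
record of ICP-directed treatments; weekly summaries take the maximum and
median of the daily scores over ICU days 1-7.

Scoring rules
-------------
* ``sum_of_item_maxima`` -- per item, take the highest applicable
  sub-item score, then sum across the scale's items.  Items excluded
  from a configuration contribute 0.
* ``max_over_subitems`` -- the maximum score among administered
  sub-items, 0 when no sub-item is administered (TILBasic).

Two conventions from the source data model are implemented here rather
than at analysis time:

* A decompressive craniectomy performed as a last resort for refractory
  intracranial hypertension contributes its score on the operation day
  and on every subsequent day of ICU stay (``apply_dc_carryforward``).
* Days on or after a documented decision to withdraw life-sustaining
  therapies are censored and never scored (``censor_at_wlst``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ScaleConfig",
    "ITEM_COLUMNS",
    "ITEM_LEVELS",
    "SCALE_NAMES",
    "load_scale_configs",
    "apply_dc_carryforward",
    "censor_at_wlst",
    "score_daily",
    "score_table",
    "summarize",
    "summarize_table",
    "categorize_til24",
    "derive_ranges",
    "DERIVED_RANGES",
    "EXPERT_RANGES",
]

SCALE_NAMES = ("TIL", "uwTIL", "TILBasic", "PILOT", "TIL1987")

#: TILBasic category lower bounds for a daily TIL score, keyed by
#: category.  "derived" are the empirically optimized ranges
#: (1-2 -> 1, 3-6 -> 2, 7-8 -> 3, >=9 -> 4); "expert" are the ranges
#: previously proposed by the consensus panel (1-3, 4-7, 8-10, >=11).
DERIVED_RANGES = {1: 1, 2: 3, 3: 7, 4: 9}
EXPERT_RANGES = {1: 1, 2: 4, 3: 8, 4: 11}


@dataclass(frozen=True)
class ScaleConfig:
    """One named scoring configuration.

    Parameters
    ----------
    name
        Scale identifier, one of :data:`SCALE_NAMES`.
    subitem_scores
        Mapping ``item -> {level: score}``.  Binary items use the single
        level ``"present"``.  Items absent from the mapping are excluded
        from the scale.
    aggregation
        ``"sum_of_item_maxima"`` or ``"max_over_subitems"``.
    max_total
        Score of the all-maximal treatment day; checked at load time.
    """

    name: str
    subitem_scores: Mapping[str, Mapping[str, int]]
    aggregation: str
    max_total: int

    def item_score(self, item: str, level: str | None) -> int:
        """Score contributed by ``item`` at ``level`` (None -> 0)."""
        if level is None:
            return 0
        return int(self.subitem_scores.get(item, {}).get(level, 0))


def _load_yaml() -> dict:
    text = resources.files("tilscale").joinpath("data/scale_configs.yaml").read_text()
    return yaml.safe_load(text)


_RAW = _load_yaml()

#: Therapy items in canonical order, and the ordinal levels of each.
ITEM_LEVELS: dict[str, tuple[str, ...]] = {
    item: tuple(spec["levels"]) if spec["kind"] == "ordinal" else ("present",)
    for item, spec in _RAW["items"].items()
}
ITEM_COLUMNS: tuple[str, ...] = tuple(ITEM_LEVELS)
_BINARY_ITEMS = tuple(i for i, s in _RAW["items"].items() if s["kind"] == "binary")
_ORDINAL_ITEMS = tuple(i for i, s in _RAW["items"].items() if s["kind"] == "ordinal")


def load_scale_configs() -> dict[str, ScaleConfig]:
    """Load and validate the five shipped scale configurations."""
    configs = {}
    for name, spec in _RAW["scales"].items():
        cfg = ScaleConfig(
            name=name,
            subitem_scores={k: dict(v) for k, v in spec["scores"].items()},
            aggregation=spec["aggregation"],
            max_total=int(spec["max_total"]),
        )
        maximal = _all_maximal_record()
        achieved = score_daily(maximal, cfg)
        if achieved != cfg.max_total:
            raise ValueError(
                f"scale {name}: all-maximal record scores {achieved}, "
                f"declared max_total is {cfg.max_total}"
            )
        configs[name] = cfg
    return configs


def _all_maximal_record() -> dict:
    """The treatment day with every item at its highest level."""
    rec: dict[str, object] = {}
    for item in _BINARY_ITEMS:
        rec[item] = 1
    for item in _ORDINAL_ITEMS:
        rec[item] = ITEM_LEVELS[item][-1]
    return rec


def _active_level(record: Mapping, item: str) -> str | None:
    """The administered level of ``item`` in a record, or None.

    Missing values (None / NaN / pandas NA) contribute no level: a
    missing sub-item scores 0 on an otherwise scoreable day; whole-day
    missingness is handled upstream by the imputation stage.
    """
    val = record.get(item) if isinstance(record, Mapping) else record[item]
    if val is None or (isinstance(val, float) and np.isnan(val)) or val is pd.NA:
        return None
    if item in _BINARY_ITEMS:
        return "present" if int(val) == 1 else None
    if val == "none":
        return None
    if val not in ITEM_LEVELS[item]:
        raise ValueError(
            f"invalid level {val!r} for item {item!r}; "
            f"permitted: {('none',) + ITEM_LEVELS[item]}"
        )
    return str(val)


def score_daily(record: Mapping, config: ScaleConfig) -> int:
    """Score one day's therapy record under one scale configuration.

    ``record`` maps item names to values: 0/1 for binary items and a
    level name (or ``"none"``) for ordinal items.
    """
    levels = {item: _active_level(record, item) for item in ITEM_COLUMNS}
    scores = [config.item_score(item, lv) for item, lv in levels.items() if lv]
    if config.aggregation == "sum_of_item_maxima":
        return int(sum(scores))
    if config.aggregation == "max_over_subitems":
        return int(max(scores, default=0))
    raise ValueError(f"unknown aggregation {config.aggregation!r}")


def score_table(therapy: pd.DataFrame, config: ScaleConfig) -> pd.DataFrame:
    """Score every row of a daily-therapy table under one configuration.

    Returns a frame with patient_id, day, scale, value and censored
    columns.  Rows in which *every* therapy item is missing get a
    missing value (the whole assessment is absent, eligible for
    imputation); rows flagged ``censored`` keep no value.
    """
    out = therapy[["patient_id", "day"]].copy()
    all_missing = therapy[list(ITEM_COLUMNS)].isna().all(axis=1).to_numpy()
    mat = np.zeros((len(therapy), len(ITEM_COLUMNS)))
    for j, item in enumerate(ITEM_COLUMNS):
        col = therapy[item]
        if item in _BINARY_ITEMS:
            on = col.fillna(0).astype(float).to_numpy() == 1
            mat[:, j] = np.where(on, config.item_score(item, "present"), 0)
        else:
            mapping = {lv: config.item_score(item, lv) for lv in ITEM_LEVELS[item]}
            mapping["none"] = 0
            mapped = col.map(mapping)
            bad = col.notna() & mapped.isna()
            if bad.any():
                raise ValueError(
                    f"invalid level(s) {sorted(col[bad].unique())} for item "
                    f"{item!r}; permitted: {('none',) + ITEM_LEVELS[item]}"
                )
            mat[:, j] = mapped.fillna(0).to_numpy(dtype=float)
    if config.aggregation == "sum_of_item_maxima":
        values = mat.sum(axis=1)
    else:
        values = mat.max(axis=1)
    values[all_missing] = np.nan
    censored = (
        therapy["censored"].fillna(False).to_numpy(dtype=bool)
        if "censored" in therapy.columns
        else np.zeros(len(therapy), dtype=bool)
    )
    values[censored] = np.nan
    out["scale"] = config.name
    out["value"] = values
    out["censored"] = censored
    return out


def apply_dc_carryforward(records: pd.DataFrame) -> pd.DataFrame:
    """Propagate last-resort decompressive craniectomy to later days.

    If ``dc_refractory`` is true on day *d* for a patient, ``dc`` (and
    ``dc_refractory``) are set true on every later recorded day of that
    patient.  A craniectomy that was not performed as a last resort is
    not propagated.
    """
    df = records.sort_values(["patient_id", "day"]).copy()
    for _, idx in df.groupby("patient_id").groups.items():
        sub = df.loc[idx]
        flag = sub["dc_refractory"].fillna(0).astype(int).to_numpy()
        if flag.any():
            first = sub["day"].to_numpy()[flag.argmax()]
            later = idx[sub["day"].to_numpy() >= first]
            df.loc[later, "dc"] = 1
    return df


def censor_at_wlst(records: pd.DataFrame, wlst_day: int | None) -> pd.DataFrame:
    """Flag a patient's records on or after the WLST decision day.

    Censored days are excluded from scoring and from the weekly
    summaries.  ``wlst_day`` of ``None`` censors nothing; a first-day
    WLST decision (``wlst_day == 1``) censors the entire first week,
    which removes the patient from the validation population.
    """
    df = records.copy()
    if wlst_day is None or (isinstance(wlst_day, float) and np.isnan(wlst_day)):
        df["censored"] = False
        return df
    wlst_day = int(wlst_day)
    if wlst_day < 1:
        raise ValueError(f"wlst_day must be >= 1, got {wlst_day}")
    df["censored"] = df["day"] >= wlst_day
    return df


def summarize(daily_values: Sequence[float]) -> tuple[float, float]:
    """Weekly (max, median) of one patient-scale's non-censored days.

    The median uses midpoint interpolation for even day counts, so
    half-integers arise (e.g. a summary-score threshold of 7.5).
    """
    vals = np.asarray(
        [v for v in daily_values if v is not None and not np.isnan(v)], dtype=float
    )
    if vals.size == 0:
        raise ValueError("no scoreable days: summary undefined")
    return float(vals.max()), float(np.median(vals))


def summarize_table(daily: pd.DataFrame) -> pd.DataFrame:
    """Per-patient weekly summaries of a daily-score table.

    Patients with zero scoreable (non-censored, non-missing) days are
    dropped and reported via a warning.
    """
    ok = daily[(~daily["censored"]) & daily["value"].notna()]
    dropped = set(daily["patient_id"]) - set(ok["patient_id"])
    if dropped:
        warnings.warn(
            f"{len(dropped)} patient(s) with zero scoreable days dropped "
            "from summaries",
            stacklevel=2,
        )
    g = ok.groupby(["patient_id", "scale"])["value"]
    out = g.agg(max_score="max", median_score="median").reset_index()
    return out


def categorize_til24(til24: int, ranges: Mapping[int, int] = DERIVED_RANGES) -> int:
    """Map a daily TIL score onto the condensed 0-4 category scale.

    Default boundaries are the empirically derived ranges
    (1-2 -> 1, 3-6 -> 2, 7-8 -> 3, >=9 -> 4); pass
    :data:`EXPERT_RANGES` for the previously proposed consensus ranges.
    A score of 0 (no ICP-directed therapy) maps to category 0.
    """
    til24 = int(til24)
    if til24 < 0:
        raise ValueError("daily TIL score cannot be negative")
    cat = 0
    for category in sorted(ranges):
        if til24 >= ranges[category]:
            cat = category
    return cat


def derive_ranges(
    til24: Sequence[int], tilbasic24: Sequence[int]
) -> dict[int, int]:
    """Derive TIL -> TILBasic category boundaries from paired scores.

    For each observed daily TIL value the median condensed-scale score
    is computed; boundaries are placed where that median (rounded half
    up to a category) increases.  Returns ``{category: lowest TIL}``
    in the same form as :data:`DERIVED_RANGES`.  Unobserved TIL values
    are skipped and reported via a warning.
    """
    t = np.asarray(til24, dtype=float)
    b = np.asarray(tilbasic24, dtype=float)
    keep = ~(np.isnan(t) | np.isnan(b))
    t, b = t[keep], b[keep]
    if t.size == 0:
        raise ValueError("no paired observations")
    observed = np.unique(t[t >= 1])
    if observed.size:
        full = np.arange(observed.min(), observed.max() + 1)
        gaps = sorted(set(full) - set(observed))
        if gaps:
            warnings.warn(
                f"no observations at daily TIL value(s) {gaps}; skipped",
                stacklevel=2,
            )
    if observed.size < 2:
        warnings.warn("fewer than two distinct TIL values; no boundaries", stacklevel=2)
        return {}
    medians = {v: float(np.median(b[t == v])) for v in observed}
    bounds: dict[int, int] = {}
    prev_cat = None
    for v in observed:
        cat = int(np.floor(medians[v] + 0.5))  # half-up to a category
        if prev_cat is None or cat > prev_cat:
            bounds[cat] = int(v)
        prev_cat = max(cat, prev_cat) if prev_cat is not None else cat
    return bounds
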