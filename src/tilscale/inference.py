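"""Bootstrap inference over patients and imputations jointly.

Confidence intervals follow the resampling scheme of the validation
design: for each of B bootstrap resamples, draw patients with
replacement (all of a patient's rows travel together) and draw one of
the m completed imputation copies uniformly at random, then evaluate
the statistic on that resample of that copy.  The percentile interval
of the B values therefore reflects both sampling and missing-data
uncertainty.  The point estimate is the statistic averaged across all
m copies on the original (unresampled) patients.

Undefined evaluations (a statistic can be legitimately undefined on a
resample, e.g. a constant input) are counted and excluded; if more
than half of the resamples are undefined the interval is suppressed
with a diagnostic.

Randomness is organized as named substreams spawned deterministically
from one master seed (:func:`seeded_streams`), so every pipeline stage
is independently reproducible and insensitive to evaluation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BootstrapConfig",
    "BootstrapPlan",
    "EstimateWithCI",
    "seeded_streams",
    "stream",
    "bootstrap_ci",
    "resample_tables",
]


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap settings; the resampling unit is always the patient."""

    n_resamples: int = 1000
    level: float = 95.0
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.level < 100):
            raise ValueError("confidence level must be in (0, 100)")
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be positive")


@dataclass(frozen=True)
class EstimateWithCI:
    """A statistic with its percentile bootstrap interval."""

    name: str
    estimate: float
    ci_low: float
    ci_high: float
    n_resamples: int
    n_undefined: int = 0
    method: str = "percentile-bootstrap"
    suppressed: bool = False


def stream(master_seed: int, name: str) -> np.random.Generator:
    """A named, deterministic substream of the master seed.

    The mapping hashes the stage name (CRC-32) into a SeedSequence
    spawn key, so streams are independent of each other and of the
    order in which stages run.
    """
    key = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), key]))


def seeded_streams(master_seed: int, stage_names: Sequence[str]) -> dict[str, np.random.Generator]:
    """Independent named substreams for a set of pipeline stages."""
    return {name: stream(master_seed, name) for name in stage_names}


class _TableSampler:
    """Pre-indexed patient-level resampler for one table."""

    def __init__(self, table: pd.DataFrame):
        self.table = table.reset_index(drop=True)
        codes, uniques = pd.factorize(self.table["patient_id"])
        order = np.argsort(codes, kind="stable")
        bounds = np.searchsorted(codes[order], np.arange(len(uniques) + 1))
        self.row_idx = {
            pid: order[bounds[i] : bounds[i + 1]] for i, pid in enumerate(uniques)
        }
        self._empty_idx = np.array([], dtype=int)

    def take(self, drawn: np.ndarray) -> pd.DataFrame:
        idx_parts = [self.row_idx.get(pid, self._empty_idx) for pid in drawn]
        lens = np.array([len(a) for a in idx_parts])
        rows = np.concatenate(idx_parts) if idx_parts else self._empty_idx
        out = self.table.take(rows)
        # fresh ids so a patient drawn twice counts as two subjects
        out["patient_id"] = np.repeat([f"bs{j}" for j in range(len(drawn))], lens)
        return out.reset_index(drop=True)


def resample_tables(
    tables: Sequence[pd.DataFrame],
    patient_ids: Sequence[str],
    rng: np.random.Generator,
) -> tuple[list[pd.DataFrame], np.ndarray]:
    """Draw patients with replacement and rebuild each table.

    A patient drawn twice contributes all of their rows twice, under
    fresh unique patient identifiers so that within-patient statistics
    treat the copies as distinct subjects.
    """
    ids = np.asarray(patient_ids)
    drawn = rng.choice(ids, size=ids.size, replace=True)
    out = [_TableSampler(tbl).take(drawn) for tbl in tables]
    return out, drawn


class BootstrapPlan:
    """Pre-indexed resamplers over the m imputation copies.

    Building the per-patient row indices is much more expensive than a
    single resample, so pipelines construct one plan and share it
    across every bootstrapped statistic.
    """

    def __init__(self, static_copies, daily_copies):
        if len(static_copies) != len(daily_copies) or not static_copies:
            raise ValueError("need matching, non-empty imputation copies")
        self.m = len(static_copies)
        self.static_copies = list(static_copies)
        self.daily_copies = list(daily_copies)
        self.patient_ids = static_copies[0]["patient_id"].to_numpy()
        self.samplers = [
            (_TableSampler(s), _TableSampler(d))
            for s, d in zip(static_copies, daily_copies)
        ]


def _as_value(result) -> float:
    if result is None:
        return np.nan
    if hasattr(result, "value"):
        return float(result.value)
    if hasattr(result, "beta"):
        return float(result.beta)
    return float(result)


def bootstrap_ci(
    statistic: Callable[[pd.DataFrame, pd.DataFrame], object],
    static_copies: Sequence[pd.DataFrame],
    daily_copies: Sequence[pd.DataFrame],
    config: BootstrapConfig,
    name: str = "statistic",
    plan: BootstrapPlan | None = None,
) -> EstimateWithCI:
    """Percentile bootstrap CI of ``statistic(static, daily)``.

    ``static_copies``/``daily_copies`` are the m completed copies of
    the cohort tables (m >= 2 when missing data were imputed; a single
    copy is accepted for complete data).  The statistic may return a
    float or any result object exposing ``.value`` or ``.beta``;
    NaN returns count as undefined.  Pass a shared :class:`BootstrapPlan`
    when bootstrapping many statistics over the same copies.
    """
    if plan is None:
        plan = BootstrapPlan(static_copies, daily_copies)
    m = plan.m
    rng = stream(config.seed, f"bootstrap:{name}")
    patient_ids = plan.patient_ids

    # point estimate: across-copy mean on the original sample
    points = []
    for s, d in zip(plan.static_copies, plan.daily_copies):
        try:
            points.append(_as_value(statistic(s, d)))
        except (ValueError, np.linalg.LinAlgError):
            points.append(np.nan)
    estimate = float(np.nanmean(points)) if np.isfinite(points).any() else np.nan

    values = np.empty(config.n_resamples)
    for b in range(config.n_resamples):
        copy = int(rng.integers(m))
        drawn = rng.choice(patient_ids, size=patient_ids.size, replace=True)
        s_b = plan.samplers[copy][0].take(drawn)
        d_b = plan.samplers[copy][1].take(drawn)
        try:
            values[b] = _as_value(statistic(s_b, d_b))
        except (ValueError, np.linalg.LinAlgError):
            values[b] = np.nan
    defined = values[np.isfinite(values)]
    n_undef = config.n_resamples - defined.size
    if defined.size < config.n_resamples / 2:
        return EstimateWithCI(
            name=name,
            estimate=estimate,
            ci_low=np.nan,
            ci_high=np.nan,
            n_resamples=config.n_resamples,
            n_undefined=n_undef,
            suppressed=True,
        )
    alpha = (100.0 - config.level) / 2.0
    lo, hi = np.percentile(defined, [alpha, 100.0 - alpha])
    return EstimateWithCI(
        name=name,
        estimate=estimate,
        ci_low=float(lo),
        ci_high=float(hi),
        n_resamples=config.n_resamples,
        n_undefined=n_undef,
    )
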