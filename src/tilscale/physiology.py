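"""Daily and weekly ICP/CPP summaries from monitoring streams.

Two streams are supported.  The end-hour (EH) stream holds
clinician-charted samples roughly every 2 h, carrying ICP plus systolic
and diastolic blood pressure; mean arterial pressure and cerebral
perfusion pressure are derived as

    MAP = (SBP + 2 DBP) / 3
    CPP = MAP - ICP

The high-frequency (HR) stream holds averaged monitor samples carrying
ICP and CPP directly.  Daily values (ICP_24, CPP_24) are arithmetic
means over admission-anchored 24 h windows; weekly summaries are the
maximum/median of ICP_24 and the minimum/median of CPP_24 over ICU days
1-7 (medians midpoint-interpolated).

Negative CPP values are physiologically implausible but retained with a
flag; artefact cleaning is outside this package's scope.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "map_from_pressures",
    "cpp_from_map_icp",
    "daily_means",
    "daily_physio_table",
    "summarize_physio",
    "SECONDS_PER_DAY",
]

SECONDS_PER_DAY = 86_400.0


def map_from_pressures(sbp, dbp):
    """Mean arterial pressure from systolic/diastolic pressures.

    MAP = (SBP + 2 DBP) / 3.  Samples with SBP < DBP are flagged via a
    warning (the value is still computed).
    """
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        bad = np.asarray(sbp < dbp)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} sample(s) with SBP < DBP", stacklevel=2
        )
    out = (sbp + 2.0 * dbp) / 3.0
    return float(out) if out.ndim == 0 else out


def cpp_from_map_icp(map_, icp):
    """Cerebral perfusion pressure, CPP = MAP - ICP.

    Negative results are kept and flagged via a warning rather than
    clipped.
    """
    map_ = np.asarray(map_, dtype=float)
    icp = np.asarray(icp, dtype=float)
    out = map_ - icp
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        neg = np.asarray(out < 0)
    if neg.any():
        warnings.warn(
            f"{int(neg.sum())} physiologically implausible (negative) CPP value(s)",
            stacklevel=2,
        )
    return float(out) if out.ndim == 0 else out


def _day_of(timestamp_s: np.ndarray) -> np.ndarray:
    """Admission-anchored calendar day (1-based) of a timestamp."""
    return np.floor(np.asarray(timestamp_s, dtype=float) / SECONDS_PER_DAY).astype(int) + 1


def daily_means(samples: pd.DataFrame, day: int) -> dict:
    """Daily mean ICP/CPP for one patient-day from one stream's samples.

    ``samples`` must be a single patient's rows of one stream.  EH rows
    derive CPP per sample from SBP/DBP/ICP; HR rows use the provided
    CPP.  Zero samples in the window yield missing daily values
    (eligible for imputation downstream).
    """
    sub = samples[_day_of(samples["timestamp_s"].astype(float)) == day]
    n = len(sub)
    if n == 0:
        return {"day": day, "icp24": np.nan, "cpp24": np.nan, "n_samples": 0}
    icp = sub["icp"].astype(float).to_numpy()
    stream = sub["stream"].iloc[0]
    if stream == "EH":
        map_ = map_from_pressures(
            sub["sbp"].astype(float).to_numpy(), sub["dbp"].astype(float).to_numpy()
        )
        cpp = cpp_from_map_icp(map_, icp)
    else:
        cpp = sub["cpp"].astype(float).to_numpy()
    return {
        "day": day,
        "icp24": float(np.nanmean(icp)),
        "cpp24": float(np.nanmean(cpp)),
        "n_samples": n,
    }


def daily_physio_table(physio: pd.DataFrame, max_day: int = 7) -> pd.DataFrame:
    """Daily ICP_24/CPP_24 per patient, day and stream (vectorized).

    Days beyond ``max_day`` are dropped; patient-days with no samples
    are absent from the result (their daily values are missing).
    """
    if len(physio) == 0:
        return pd.DataFrame(
            columns=["patient_id", "stream", "day", "icp24", "cpp24", "n_samples"]
        )
    df = physio.copy()
    df["day"] = _day_of(df["timestamp_s"].astype(float).to_numpy())
    df = df[(df["day"] >= 1) & (df["day"] <= max_day)]
    icp = df["icp"].astype(float).to_numpy()
    eh = (df["stream"] == "EH").to_numpy()
    cpp = np.full(len(df), np.nan)
    if eh.any():
        map_eh = map_from_pressures(
            df.loc[eh, "sbp"].astype(float).to_numpy(),
            df.loc[eh, "dbp"].astype(float).to_numpy(),
        )
        cpp[eh] = cpp_from_map_icp(map_eh, icp[eh])
    if (~eh).any():
        cpp[~eh] = df.loc[~eh, "cpp"].astype(float).to_numpy()
    df = df.assign(_icp=icp, _cpp=cpp)
    out = (
        df.groupby(["patient_id", "stream", "day"], observed=True)
        .agg(icp24=("_icp", "mean"), cpp24=("_cpp", "mean"), n_samples=("_icp", "size"))
        .reset_index()
    )
    out["patient_id"] = out["patient_id"].astype("string")
    return out


def summarize_physio(daily: pd.DataFrame) -> pd.DataFrame:
    """Weekly summaries per patient and stream.

    Returns icp_max, icp_median, cpp_min and cpp_median over the
    available daily values of days 1-7 (median midpoint-interpolated).
    """
    if len(daily) == 0:
        return pd.DataFrame(
            columns=["patient_id", "stream", "icp_max", "icp_median", "cpp_min", "cpp_median"]
        )
    g = daily.groupby(["patient_id", "stream"], observed=True)
    out = g.agg(
        icp_max=("icp24", "max"),
        icp_median=("icp24", "median"),
        cpp_min=("cpp24", "min"),
        cpp_median=("cpp24", "median"),
    ).reset_index()
    return out
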