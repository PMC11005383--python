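"""Multiple imputation of static and longitudinal study variables.

Two imputers produce m completed copies of the analysis tables:

* :func:`impute_static` -- independent stochastic predictive mean
  matching (PMM) for the once-per-patient variables (baseline GCS,
  six-month GOSE, prognosis probabilities, Marshall CT class and the
  refractory-hypertension label).  For each variable a linear model is
  fit on complete cases; regression coefficients are drawn from their
  approximate posterior, and each missing cell receives the observed
  value of one of the k nearest donors by predicted value.  Donor
  draws keep imputed values inside the observed support (ordinal
  variables stay ordinal).  The six prognosis probabilities are
  imputed as a block from a single donor, which preserves their
  non-increasing ordering across thresholds.

* :func:`impute_longitudinal` -- a ridge-stabilized EM fit of a
  multivariate normal over the patient x (day, variable) matrix of the
  first ICU week, with each of the m imputations drawn from
  parameters re-estimated on a bootstrap resample of patients (so the
  imputations reflect estimation uncertainty).  Ordinal or bounded
  variables are rounded and clipped to their valid ranges after the
  draw.  Cells that are structurally absent -- days after a WLST
  decision or after ICU discharge, which are not missing but
  nonexistent -- are represented by absent rows and are never imputed.

Observed cells are identical across all m copies; imputed cells vary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import MARSHALL_LEVELS, PROGNOSIS_COLUMNS
from .inference import stream

__all__ = [
    "ImputationSet",
    "impute_static",
    "impute_longitudinal",
    "STATIC_TARGETS",
]

#: statically imputable variables (prognosis columns move as one block)
STATIC_TARGETS = ("gcs_baseline", "gose_6mo", "prognosis", "marshall", "refractory_ich")


@dataclass
class ImputationSet:
    """m completed copies of the analysis tables."""

    m: int
    static: list[pd.DataFrame] = field(default_factory=list)
    daily: list[pd.DataFrame] = field(default_factory=list)
    method_tags: dict[str, str] = field(default_factory=dict)


def _design_matrix(static: pd.DataFrame, aux: pd.DataFrame | None, exclude: set[str]) -> pd.DataFrame:
    """Numeric predictor matrix from all usable static columns plus auxiliaries."""
    df = static.copy()
    parts = {}
    if "sex" in df.columns:
        parts["sex_male"] = (df["sex"] == "male").astype(float)
    if "marshall" in df.columns and "marshall" not in exclude:
        code = {lv: i + 1 for i, lv in enumerate(MARSHALL_LEVELS)}
        parts["marshall_code"] = df["marshall"].map(code).astype(float)
    numeric = [
        c
        for c in df.columns
        if c not in exclude
        and c not in ("patient_id", "center_id", "sex", "marshall", "wlst_day")
        and pd.api.types.is_numeric_dtype(df[c].dtype)
    ]
    for c in numeric:
        parts[c] = df[c].astype(float)
    X = pd.DataFrame(parts, index=df.index)
    if aux is not None:
        aux = aux.set_index("patient_id").reindex(df["patient_id"]).reset_index(drop=True)
        for c in aux.columns:
            if pd.api.types.is_numeric_dtype(aux[c].dtype):
                X[f"aux_{c}"] = aux[c].astype(float).to_numpy()
    # predictors are mean-filled for prediction purposes only
    X = X.apply(lambda col: col.fillna(col.mean()))
    X = X.loc[:, X.std(ddof=0) > 0]
    return X


def _pmm_draw(y_obs, X_obs, X_mis, k, rng):
    """One stochastic-PMM draw of imputed values for the missing rows."""
    n, p = X_obs.shape
    Xo = np.column_stack([np.ones(n), X_obs])
    Xm = np.column_stack([np.ones(len(X_mis)), X_mis])
    XtX = Xo.T @ Xo + 1e-6 * np.eye(p + 1)
    XtX_inv = np.linalg.inv(XtX)
    beta_hat = XtX_inv @ (Xo.T @ y_obs)
    resid = y_obs - Xo @ beta_hat
    dof = max(n - p - 1, 1)
    sigma2 = float(resid @ resid) / dof
    # approximate posterior draw of (sigma2, beta)
    sigma2_star = float(resid @ resid) / rng.chisquare(dof)
    L = np.linalg.cholesky(XtX_inv * sigma2_star + 1e-12 * np.eye(p + 1))
    beta_star = beta_hat + L @ rng.standard_normal(p + 1)
    yhat_obs = Xo @ beta_hat
    yhat_mis = Xm @ beta_star
    out = np.empty(len(X_mis))
    for i, yh in enumerate(yhat_mis):
        order = np.argsort(np.abs(yhat_obs - yh), kind="stable")[:k]
        out[i] = y_obs[order[rng.integers(len(order))]]
    return out


def impute_static(
    static: pd.DataFrame,
    m: int,
    seed: int,
    k_donors: int = 5,
    aux: pd.DataFrame | None = None,
) -> list[pd.DataFrame]:
    """m PMM-completed copies of the static table.

    ``aux`` may carry patient-level auxiliary predictors (e.g. weekly
    score summaries, a raised-ICP indicator) keyed by ``patient_id``.
    A variable that is 100% missing is an error; a donor pool smaller
    than ``k_donors`` is shrunk with a warning.
    """
    rng = stream(seed, "impute-static")
    copies = []
    for _ in range(m):
        copies.append(static.copy())
    for var in STATIC_TARGETS:
        if var == "prognosis":
            cols = list(PROGNOSIS_COLUMNS)
            miss = static[cols].isna().any(axis=1)
            obs_mask = ~static[cols].isna().any(axis=1)
            y_frame = static[cols].astype(float)
            y_model = y_frame["pr_gose_gt3"].astype(float)
        elif var == "marshall":
            code = {lv: i + 1 for i, lv in enumerate(MARSHALL_LEVELS)}
            y_model = static["marshall"].map(code).astype(float)
            miss = static["marshall"].isna()
            obs_mask = ~miss
        else:
            y_model = static[var].astype(float)
            miss = static[var].isna()
            obs_mask = ~miss
        if not miss.any():
            continue
        if not obs_mask.any():
            raise ValueError(f"variable {var!r} is 100% missing; cannot impute")
        n_obs = int(obs_mask.sum())
        k = k_donors
        if n_obs < k_donors:
            warnings.warn(
                f"variable {var!r}: only {n_obs} complete cases; donor pool "
                f"shrunk from {k_donors}",
                stacklevel=2,
            )
            k = n_obs
        X = _design_matrix(
            static, aux, exclude={var} if var != "prognosis" else set(PROGNOSIS_COLUMNS)
        )
        X_obs = X[obs_mask.to_numpy()].to_numpy(dtype=float)
        X_mis = X[miss.to_numpy()].to_numpy(dtype=float)
        y_obs = y_model[obs_mask].to_numpy(dtype=float)
        obs_idx = static.index[obs_mask]
        for copy in copies:
            drawn = _pmm_draw(y_obs, X_obs, X_mis, k, rng)
            if var == "prognosis":
                # donor's whole probability block preserves monotonicity
                donor_rows = []
                for val in drawn:
                    pool = obs_idx[np.isclose(y_obs, val)]
                    donor_rows.append(pool[rng.integers(len(pool))])
                for c in cols:
                    copy.loc[miss, c] = static.loc[donor_rows, c].to_numpy()
            elif var == "marshall":
                inv = {i + 1: lv for i, lv in enumerate(MARSHALL_LEVELS)}
                copy.loc[miss, "marshall"] = [inv[int(v)] for v in drawn]
            else:
                copy.loc[miss, var] = pd.array(drawn, dtype=float).astype(copy[var].dtype)
    return copies


# ---------------------------------------------------------------------------
# longitudinal EM imputer


def _em_mvnorm(X: np.ndarray, ridge: float, maxiter: int, tol: float):
    """EM estimates (mu, Sigma) of a MVN from a matrix with NaN cells."""
    n, p = X.shape
    mu = np.nanmean(X, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    var = np.nanvar(X, axis=0)
    var = np.where(np.isnan(var) | (var <= 0), 1.0, var)
    Sigma = np.diag(var)
    miss = np.isnan(X)
    patterns: dict[bytes, np.ndarray] = {}
    for key, rows in pd.DataFrame(miss).groupby(list(range(p)), sort=False).groups.items():
        patterns[np.asarray(key, dtype=bool).tobytes()] = np.asarray(rows)
    for it in range(maxiter):
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        for key, rows in patterns.items():
            mpat = np.frombuffer(key, dtype=bool)
            o = ~mpat
            Xr = X[rows]
            nr = len(rows)
            if not mpat.any():
                sum_x += Xr.sum(axis=0)
                sum_xx += Xr.T @ Xr
                continue
            E = np.tile(mu, (nr, 1))
            C = np.zeros((p, p))
            if o.any():
                Soo = Sigma[np.ix_(o, o)] + ridge * np.eye(o.sum())
                Smo = Sigma[np.ix_(mpat, o)]
                B = np.linalg.solve(Soo, Smo.T).T
                E[:, o] = Xr[:, o]
                E[:, mpat] = mu[mpat] + (Xr[:, o] - mu[o]) @ B.T
                C[np.ix_(mpat, mpat)] = Sigma[np.ix_(mpat, mpat)] - B @ Smo.T
            else:
                C[np.ix_(mpat, mpat)] = Sigma[np.ix_(mpat, mpat)]
            sum_x += E.sum(axis=0)
            sum_xx += E.T @ E + nr * C
        mu_new = sum_x / n
        Sigma_new = sum_xx / n - np.outer(mu_new, mu_new)
        Sigma_new = (Sigma_new + Sigma_new.T) / 2 + ridge * np.eye(p)
        delta = max(np.abs(mu_new - mu).max(), np.abs(Sigma_new - Sigma).max())
        mu, Sigma = mu_new, Sigma_new
        if delta < tol:
            return mu, Sigma, it + 1, True
    return mu, Sigma, maxiter, False


def _conditional_draw(X, mu, Sigma, rng, ridge):
    """Fill NaN cells of X with conditional MVN draws (in place copy)."""
    out = X.copy()
    p = X.shape[1]
    miss = np.isnan(X)
    df = pd.DataFrame(miss)
    for key, rows in df.groupby(list(range(p)), sort=False).groups.items():
        mpat = np.asarray(key, dtype=bool)
        if not mpat.any():
            continue
        rows = np.asarray(rows)
        o = ~mpat
        if o.any():
            Soo = Sigma[np.ix_(o, o)] + ridge * np.eye(o.sum())
            Smo = Sigma[np.ix_(mpat, o)]
            B = np.linalg.solve(Soo, Smo.T).T
            cond_mean = mu[mpat] + (X[np.ix_(rows, np.where(o)[0])] - mu[o]) @ B.T
            cond_cov = Sigma[np.ix_(mpat, mpat)] - B @ Smo.T
        else:
            cond_mean = np.tile(mu[mpat], (len(rows), 1))
            cond_cov = Sigma[np.ix_(mpat, mpat)]
        cond_cov = (cond_cov + cond_cov.T) / 2 + 1e-8 * np.eye(mpat.sum())
        L = np.linalg.cholesky(cond_cov)
        draws = cond_mean + rng.standard_normal((len(rows), int(mpat.sum()))) @ L.T
        out[np.ix_(rows, np.where(mpat)[0])] = draws
    return out


def impute_longitudinal(
    daily: pd.DataFrame,
    columns: list[str],
    m: int,
    seed: int,
    bounds: dict[str, tuple[float | None, float | None, bool]] | None = None,
    max_day: int = 7,
    maxiter: int = 500,
    tol: float = 1e-3,
    ridge: float = 1e-3,
) -> list[pd.DataFrame]:
    """m EM-completed copies of the daily long table.

    ``daily`` holds one row per *eligible* patient-day (absent rows are
    structurally absent and never imputed) with NaN for missing values
    in ``columns``.  ``bounds`` maps a column to (lo, hi, integer) for
    post-draw rounding/clipping.  Raises if EM fails to converge,
    reporting the iteration trace.
    """
    bounds = bounds or {}
    wide = daily.pivot(index="patient_id", columns="day", values=columns)
    # eligibility mask: a (patient, day) slot exists iff the row exists
    exists = daily.assign(_one=1.0).pivot(index="patient_id", columns="day", values="_one")
    X = wide.to_numpy(dtype=float)
    n, p = X.shape
    col_names = [f"{v}@{d}" for v, d in wide.columns]
    eligible = np.zeros((n, p), dtype=bool)
    for j, (v, d) in enumerate(wide.columns):
        if d in exists.columns:
            eligible[:, j] = exists[d].notna().to_numpy()
    to_impute = np.isnan(X) & eligible
    if not to_impute.any():
        return [daily.copy() for _ in range(m)]

    rng = stream(seed, "impute-longitudinal")
    # standardize columns for EM stability
    scale_mu = np.nanmean(X, axis=0)
    scale_sd = np.nanstd(X, axis=0)
    scale_mu = np.where(np.isnan(scale_mu), 0.0, scale_mu)
    scale_sd = np.where(np.isnan(scale_sd) | (scale_sd <= 0), 1.0, scale_sd)
    Z = (X - scale_mu) / scale_sd

    copies = []
    for j in range(m):
        rows = rng.integers(n, size=n)
        mu, Sigma, iters, ok = _em_mvnorm(Z[rows], ridge, maxiter, tol)
        if not ok:
            raise RuntimeError(
                f"EM failed to converge for imputation {j + 1}/{m} after "
                f"{iters} iterations (tol={tol}); consider raising maxiter"
            )
        filled_z = _conditional_draw(Z, mu, Sigma, rng, ridge)
        filled = filled_z * scale_sd + scale_mu
        Xj = X.copy()
        Xj[to_impute] = filled[to_impute]
        copy = daily.copy()
        for col_j, (v, d) in enumerate(wide.columns):
            lo, hi, as_int = bounds.get(v, (None, None, False))
            vals = Xj[:, col_j]
            if as_int:
                vals = np.round(vals)
            if lo is not None:
                vals = np.maximum(vals, lo)
            if hi is not None:
                vals = np.minimum(vals, hi)
            Xj[:, col_j] = vals
        long = (
            pd.DataFrame(Xj, index=wide.index, columns=wide.columns)
            .stack(future_stack=True)
            .reset_index()
        )
        merged = copy.merge(long, on=["patient_id", "day"], how="left", suffixes=("", "_imp"))
        for v in columns:
            src = merged[f"{v}_imp"]
            copy[v] = np.where(copy[v].notna(), copy[v], src)
        copies.append(copy)
    return copies
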