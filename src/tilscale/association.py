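"""Construct- and criterion-validity statistics.

Implements the association measures used to appraise a formative
clinical scale:

* Spearman's rank correlation for static (once-per-patient) variables.
* Repeated-measures correlation ``r_rm`` -- the common within-subject
  association, estimated by analysis of covariance: regress y on
  subject indicators plus a common slope for x, then
  ``r_rm = sign(b) * sqrt(SS_x / (SS_x + SS_err))`` with
  ``df = N - k - 1`` for N pairs over k subjects.
* Linear mixed-effects slope ``beta_LMER`` of a daily scale score when
  regressing a daily physiological outcome on day-of-ICU-stay and the
  score, with patient random intercepts (REML).
* Cronbach's alpha for internal reliability among scale items.
* Adjusted item-total correlations (item removed from the total before
  correlating) and per-sub-item mixed-model effects with categorical
  dummy encoding.

Undefined statistics (constant inputs, degenerate designs) are
first-class results carrying a reason, never silently dropped, so the
bootstrap layer can count them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StatResult",
    "spearman",
    "rm_corr",
    "lmer_beta",
    "LmerResult",
    "cronbach_alpha",
    "adjusted_item_total",
    "item_effects",
]


@dataclass(frozen=True)
class StatResult:
    """A statistic value with its effective n, possibly undefined."""

    value: float
    n: int
    reason: str | None = None
    df: int | None = None

    @property
    def defined(self) -> bool:
        return self.reason is None and np.isfinite(self.value)

    def __float__(self) -> float:
        return float(self.value)


def _complete_pairs(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def spearman(x, y) -> StatResult:
    """Spearman's rank correlation with average-rank ties.

    Requires at least three complete pairs; a constant input makes the
    coefficient undefined and is reported as such.
    """
    x, y = _complete_pairs(x, y)
    n = x.size
    if n < 3:
        return StatResult(np.nan, n, reason=f"only {n} complete pairs (need >=3)")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return StatResult(np.nan, n, reason="constant input")
    rho = stats.spearmanr(x, y).statistic
    return StatResult(float(rho), n)


def rm_corr(subjects, x, y) -> StatResult:
    """Repeated-measures correlation (subject-adjusted ANCOVA).

    Subjects with fewer than two complete pairs are dropped (and
    counted via the returned ``n``); at least two subjects with two or
    more pairs each are required.  Equivalent to the correlation of
    within-subject-centered x and y, with ``df = N - k - 1``.
    """
    df = pd.DataFrame({"s": np.asarray(subjects), "x": x, "y": y}).dropna()
    counts = df.groupby("s").size()
    df = df[df["s"].isin(counts[counts >= 2].index)]
    k = df["s"].nunique()
    n = len(df)
    if k < 2:
        return StatResult(np.nan, n, reason=f"only {k} subject(s) with >=2 pairs")
    xc = df["x"] - df.groupby("s")["x"].transform("mean")
    yc = df["y"] - df.groupby("s")["y"].transform("mean")
    ssx_all = float((xc**2).sum())
    ssy_all = float((yc**2).sum())
    if ssx_all == 0:
        return StatResult(np.nan, n, reason="x constant within every subject")
    if ssy_all == 0:
        return StatResult(np.nan, n, reason="y constant within every subject")
    # ANCOVA decomposition: common slope b, SS explained by x, residual SS
    b = float((xc * yc).sum() / ssx_all)
    ss_x = b * b * ssx_all
    ss_err = ssy_all - ss_x
    r = np.sign(b) * np.sqrt(ss_x / (ss_x + ss_err))
    return StatResult(float(r), n, df=n - k - 1)


@dataclass(frozen=True)
class LmerResult:
    """Fixed-effect slope from a random-intercept mixed model."""

    beta: float
    se: float
    ci_low: float
    ci_high: float
    n_obs: int
    n_subjects: int
    converged: bool
    singular: bool = False

    def __float__(self) -> float:
        return float(self.beta)


def _fit_mixed(model):
    """REML fit with an optimizer fallback for boundary variance fits."""
    try:
        return model.fit(reml=True, method="lbfgs")
    except (np.linalg.LinAlgError, ValueError):
        return model.fit(reml=True, method="powell")


def lmer_beta(outcome, day, score, subjects) -> LmerResult:
    """Score coefficient from ``outcome ~ day + score + (1 | subject)``.

    REML fit with patient random intercepts; the returned slope is the
    expected outcome change (e.g. mm Hg of daily mean ICP) per scale
    point, net of day of ICU stay and between-patient variation.
    Singular random-effect fits are flagged, not hidden.
    """
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {"outcome": outcome, "day": day, "score": score, "subject": np.asarray(subjects)}
    ).dropna()
    n_subj = df["subject"].nunique()
    if n_subj < 10 or len(df) < 2 * n_subj:
        raise ValueError(
            f"mixed model needs >=10 subjects with repeated observations; "
            f"got {n_subj} subjects, {len(df)} rows"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("outcome ~ day + score", df, groups=df["subject"])
        fit = _fit_mixed(model)
    beta = float(fit.params["score"])
    se = float(fit.bse["score"])
    ci = fit.conf_int().loc["score"]
    singular = bool(np.min(np.diag(fit.cov_re)) < 1e-8)
    return LmerResult(
        beta=beta,
        se=se,
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        n_obs=len(df),
        n_subjects=n_subj,
        converged=bool(fit.converged),
        singular=singular,
    )


def cronbach_alpha(item_matrix) -> StatResult:
    """Cronbach's alpha over a (rows x items) score matrix.

    alpha = k/(k-1) * (1 - sum of item variances / total-score
    variance), complete rows only.  Zero total variance makes alpha
    undefined.
    """
    m = pd.DataFrame(item_matrix).dropna()
    n, k = m.shape
    if k < 2:
        return StatResult(np.nan, n, reason=f"need >=2 items, got {k}")
    if n < 3:
        return StatResult(np.nan, n, reason=f"need >=3 complete rows, got {n}")
    total_var = float(m.sum(axis=1).var(ddof=1))
    if total_var == 0:
        return StatResult(np.nan, n, reason="zero total-score variance")
    item_var = float(m.var(ddof=1).sum())
    alpha = k / (k - 1) * (1.0 - item_var / total_var)
    return StatResult(float(alpha), n)


def adjusted_item_total(items: pd.DataFrame, total, subjects) -> dict[str, StatResult]:
    """Adjusted item-total repeated-measures correlations.

    For each item column, correlates the item with the total minus that
    item (so the item does not correlate with itself), adjusting for
    subject.  ``total`` must equal the row-wise sum of ``items``.
    """
    items = pd.DataFrame(items)
    total = np.asarray(total, dtype=float)
    rowsum = items.sum(axis=1, skipna=False).to_numpy(dtype=float)
    both = ~(np.isnan(rowsum) | np.isnan(total))
    if not np.allclose(rowsum[both], total[both]):
        raise ValueError("total does not equal the row-wise sum of the item scores")
    out = {}
    for col in items.columns:
        out[col] = rm_corr(subjects, items[col], total - items[col].to_numpy(dtype=float))
    return out


@dataclass(frozen=True)
class ItemEffectsResult:
    """Per-sub-item mixed-model coefficients plus any aliased dummies."""

    effects: dict[str, LmerResult] = field(default_factory=dict)
    aliased: tuple[str, ...] = ()


def item_effects(outcome, day, dummies: pd.DataFrame, subjects) -> ItemEffectsResult:
    """Per-sub-item effects from one joint random-intercept model.

    ``dummies`` holds one 0/1 column per sub-item level (reference =
    level absent).  Collinear (aliased) columns -- e.g. treatments that
    are always co-administered -- are dropped and reported.  The model
    is ``outcome ~ day + all retained dummies + (1 | subject)``, so each
    coefficient is the outcome change associated with that treatment
    net of all other treatments, time and patient.
    """
    import statsmodels.api as sm

    dummies = pd.DataFrame(dummies).astype(float)
    df = pd.concat(
        [
            pd.DataFrame(
                {"outcome": outcome, "day": day, "subject": np.asarray(subjects)}
            ).reset_index(drop=True),
            dummies.reset_index(drop=True),
        ],
        axis=1,
    ).dropna()
    cols = list(dummies.columns)
    # drop constant and rank-deficient columns
    aliased = [c for c in cols if df[c].nunique() <= 1]
    kept = [c for c in cols if c not in aliased]
    X = df[["day"] + kept].to_numpy(dtype=float)
    rank_keep = ["day"] + kept
    while len(rank_keep) > 1:
        X = df[rank_keep].to_numpy(dtype=float)
        r = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X]))
        if r == X.shape[1] + 1:
            break
        # find a column whose removal restores rank
        for c in reversed(rank_keep):
            if c == "day":
                continue
            trial = [k for k in rank_keep if k != c]
            Xt = np.column_stack([np.ones(len(df)), df[trial].to_numpy(dtype=float)])
            if np.linalg.matrix_rank(Xt) == Xt.shape[1]:
                aliased.append(c)
                rank_keep = trial
                break
        else:
            break
    kept = [c for c in rank_keep if c != "day"]
    exog = sm.add_constant(df[["day"] + kept].to_numpy(dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(
            df["outcome"].to_numpy(dtype=float),
            exog,
            groups=df["subject"].to_numpy(),
        )
        fit = _fit_mixed(model)
    effects = {}
    names = ["const", "day"] + kept
    ci = fit.conf_int()
    for i, name in enumerate(names):
        if name in ("const", "day"):
            continue
        effects[name] = LmerResult(
            beta=float(fit.params[i]),
            se=float(fit.bse[i]),
            ci_low=float(ci[i][0]),
            ci_high=float(ci[i][1]),
            n_obs=len(df),
            n_subjects=df["subject"].nunique(),
            converged=bool(fit.converged),
        )
    return ItemEffectsResult(effects=effects, aliased=tuple(aliased))
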