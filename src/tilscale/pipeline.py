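"""End-to-end validation pipeline: score, impute, validate, report.

Orchestrates the full clinimetric analysis on a cohort (synthetic or
read from CSV):

1. last-resort-craniectomy carry-forward and WLST censoring;
2. daily scores under all five scale configurations, plus daily
   ICP_24/CPP_24 from both monitoring streams and physician concerns,
   assembled into one long patient-day table;
3. multiple imputation of static and longitudinal variables;
4. association statistics (convergent, discriminant and criterion
   validity), known-groups ROC analysis, component-item analysis and
   information coverage, with bootstrap confidence intervals drawn
   over patients and imputations jointly;
5. tidy long-format CSV outputs plus a run manifest.

Mixed-model slopes report their model-based (Wald) intervals by
default; bootstrap intervals for them are available behind a flag
because refitting a mixed model inside every resample dominates the
runtime without changing the qualitative picture.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, discrimination, information, scales
from .cohort import Cohort, PROGNOSIS_COLUMNS
from .imputation import ImputationSet, impute_longitudinal, impute_static
from .inference import BootstrapConfig, BootstrapPlan, EstimateWithCI, bootstrap_ci
from .physiology import daily_physio_table
from .synthetic import GeneratorConfig, generate_cohort, inject_missingness

logger = logging.getLogger(__name__)

SCALE_PREFIX = {
    "TIL": "til",
    "uwTIL": "uwtil",
    "TILBasic": "tilbasic",
    "PILOT": "pilot",
    "TIL1987": "til1987",
}


@dataclass
class RunConfig:
    """Configuration of one full validation run."""

    seed: int = 0
    n_patients: int = 300
    m_imputations: int = 5
    n_resamples: int = 200
    ci_level: float = 95.0
    scales_evaluated: tuple[str, ...] = tuple(SCALE_PREFIX)
    streams: tuple[str, ...] = ("EH", "HR")
    lmer_bootstrap: bool = False
    out_dir: str | Path = "til_run"
    generator: GeneratorConfig | None = None

    def __post_init__(self):
        if not self.scales_evaluated:
            raise ValueError("at least one scale must be evaluated")


# ---------------------------------------------------------------------------
# table assembly


def prepared_therapy(cohort: Cohort) -> pd.DataFrame:
    """Therapy table with DC carry-forward applied and censor flags set."""
    ther = scales.apply_dc_carryforward(cohort.therapy)
    wlst = cohort.static.set_index("patient_id")["wlst_day"]
    wd = ther["patient_id"].map(wlst)
    ther["censored"] = wd.notna() & (ther["day"] >= wd)
    ther["censored"] = ther["censored"].astype(bool)
    return ther


def daily_score_table(cohort: Cohort, scale_names=tuple(SCALE_PREFIX)) -> pd.DataFrame:
    """Wide patient-day table of daily scores for the requested scales."""
    ther = prepared_therapy(cohort)
    configs = scales.load_scale_configs()
    out = ther[["patient_id", "day", "censored"]].copy()
    for name in scale_names:
        scored = scales.score_table(ther, configs[name])
        out[f"{SCALE_PREFIX[name]}_24"] = scored["value"].to_numpy()
    return out


def build_daily_table(cohort: Cohort, scale_names=tuple(SCALE_PREFIX)) -> pd.DataFrame:
    """One row per eligible (non-censored) patient-day with all daily measures.

    Columns: daily scale scores, EH/HR daily ICP/CPP means, and the two
    physician concern ratings.  Censored (post-WLST) days are dropped:
    they are structurally absent, not missing.
    """
    scored = daily_score_table(cohort, scale_names)
    scored = scored[~scored["censored"]].drop(columns=["censored"])
    phys = daily_physio_table(cohort.physio)
    if len(phys):
        wide = phys.pivot_table(
            index=["patient_id", "day"], columns="stream", values=["icp24", "cpp24"]
        )
        wide.columns = [f"{v}_{s.lower()}" for v, s in wide.columns]
        wide = wide.reset_index()
        scored = scored.merge(wide, on=["patient_id", "day"], how="left")
    for col in ("icp24_eh", "cpp24_eh", "icp24_hr", "cpp24_hr"):
        if col not in scored.columns:
            scored[col] = np.nan
    conc = cohort.concerns.copy()
    conc["icp_concern"] = conc["icp_concern"].astype(float)
    conc["cpp_concern"] = conc["cpp_concern"].astype(float)
    scored = scored.merge(
        conc[["patient_id", "day", "icp_concern", "cpp_concern"]],
        on=["patient_id", "day"],
        how="left",
    )
    scored["patient_id"] = scored["patient_id"].astype("string")
    return scored.sort_values(["patient_id", "day"]).reset_index(drop=True)


def patient_summaries(daily: pd.DataFrame, scale_names=tuple(SCALE_PREFIX)) -> pd.DataFrame:
    """Weekly summary columns per patient from the (possibly imputed) daily table."""
    g = daily.groupby("patient_id")
    out = pd.DataFrame(index=g.size().index)
    for name in scale_names:
        p = SCALE_PREFIX[name]
        out[f"{p}_max"] = g[f"{p}_24"].max()
        out[f"{p}_median"] = g[f"{p}_24"].median()
    for stream_tag in ("eh", "hr"):
        icp, cpp = f"icp24_{stream_tag}", f"cpp24_{stream_tag}"
        out[f"icp_max_{stream_tag}"] = g[icp].max()
        out[f"icp_median_{stream_tag}"] = g[icp].median()
        out[f"cpp_min_{stream_tag}"] = g[cpp].min()
        out[f"cpp_median_{stream_tag}"] = g[cpp].median()
    return out.reset_index()


def attach_summaries(static: pd.DataFrame, daily: pd.DataFrame, scale_names=tuple(SCALE_PREFIX)) -> pd.DataFrame:
    summ = patient_summaries(daily, scale_names)
    merged = static.merge(summ, on="patient_id", how="left")
    return merged


DAILY_BOUNDS = {
    "til_24": (0, 38, True),
    "uwtil_24": (0, 21, True),
    "tilbasic_24": (0, 4, True),
    "pilot_24": (0, 38, True),
    "til1987_24": (0, 15, True),
    "icp_concern": (1, 10, True),
    "cpp_concern": (1, 10, True),
}


def impute_analysis_tables(
    static: pd.DataFrame,
    daily: pd.DataFrame,
    m: int,
    seed: int,
    scale_names=tuple(SCALE_PREFIX),
) -> ImputationSet:
    """m completed (static, daily) copies with per-copy weekly summaries.

    Longitudinal variables are imputed first; static predictive-mean
    matching then uses observed-data weekly summaries as auxiliary
    predictors.  Each completed static copy carries the summary columns
    recomputed from its own completed daily copy.
    """
    daily_cols = [f"{SCALE_PREFIX[s]}_24" for s in scale_names]
    daily_cols += ["icp24_eh", "cpp24_eh", "icp_concern", "cpp_concern"]
    daily_cols = [c for c in daily_cols if c in daily.columns and daily[c].notna().any()]
    daily_copies = impute_longitudinal(
        daily, daily_cols, m=m, seed=seed, bounds=DAILY_BOUNDS
    )
    # high-frequency ICP/CPP exist only for the monitored sub-population;
    # other patients' HR cells are structurally absent, never imputed
    hr_cols = [c for c in ("icp24_hr", "cpp24_hr") if c in daily.columns and daily[c].notna().any()]
    if hr_cols:
        hr_patients = daily.loc[daily[hr_cols].notna().any(axis=1), "patient_id"].unique()
        hr_daily = daily[daily["patient_id"].isin(hr_patients)]
        predictors = [c for c in ("til_24", "icp24_eh", "cpp24_eh") if c in daily_cols]
        hr_copies = impute_longitudinal(
            hr_daily, predictors + hr_cols, m=m, seed=seed + 1,
            bounds=DAILY_BOUNDS, ridge=1e-2,
        )
        for full, hr in zip(daily_copies, hr_copies):
            for c in hr_cols:
                fill = hr.set_index(["patient_id", "day"])[c]
                key = pd.MultiIndex.from_frame(full[["patient_id", "day"]])
                mapped = fill.reindex(key).to_numpy()
                full[c] = np.where(full[c].notna(), full[c], mapped)
    aux = patient_summaries(daily, scale_names)  # observed-data auxiliaries
    aux["raised_icp"] = (aux.get("icp_max_eh", pd.Series(dtype=float)) > 20).astype(float)
    static_copies = impute_static(static, m=m, seed=seed, aux=aux)
    full_static = [
        attach_summaries(s, d, scale_names) for s, d in zip(static_copies, daily_copies)
    ]
    return ImputationSet(
        m=m,
        static=full_static,
        daily=daily_copies,
        method_tags={"static": "pmm", "daily": "em-mvn-bootstrap"},
    )


# ---------------------------------------------------------------------------
# statistics assembly


def _row(est: EstimateWithCI, **meta) -> dict:
    return {
        **meta,
        "estimate": est.estimate,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "n_resamples": est.n_resamples,
        "n_undefined": est.n_undefined,
        "method": est.method,
    }


def _boot(plan: BootstrapPlan, cfg: BootstrapConfig, fn, name):
    return bootstrap_ci(fn, plan.static_copies, plan.daily_copies, cfg, name=name, plan=plan)


def association_table(imp: ImputationSet, cfg: BootstrapConfig, run: RunConfig, plan: BootstrapPlan | None = None) -> pd.DataFrame:
    """Convergent, discriminant and criterion validity associations."""
    plan = plan or BootstrapPlan(imp.static, imp.daily)
    rows = []
    stream_tags = [s.lower() for s in run.streams]

    static_pairs = [("gcs_baseline", "gcs"), ("gose_6mo", "gose")] + [
        (c, c) for c in PROGNOSIS_COLUMNS
    ]
    for name in run.scales_evaluated:
        p = SCALE_PREFIX[name]
        for summ in ("max", "median"):
            col = f"{p}_{summ}"
            for counterpart, label in static_pairs:
                fn = (lambda c0, c1: lambda s, d: association.spearman(s[c0], s[c1]))(col, counterpart)
                est = _boot(plan, cfg, fn, f"rho:{col}:{label}")
                rows.append(
                    _row(est, statistic="spearman_rho", scale=name, summary=summ,
                         counterpart=label, stream="")
                )
            icp_c = f"icp_{'max' if summ == 'max' else 'median'}"
            cpp_c = f"cpp_{'min' if summ == 'max' else 'median'}"
            for tag in stream_tags:
                for base, label in ((icp_c, icp_c), (cpp_c, cpp_c)):
                    ccol = f"{base}_{tag}"
                    fn = (lambda c0, c1: lambda s, d: association.spearman(s[c0], s[c1]))(col, ccol)
                    est = _boot(plan, cfg, fn, f"rho:{col}:{ccol}")
                    rows.append(
                        _row(est, statistic="spearman_rho", scale=name, summary=summ,
                             counterpart=label, stream=tag)
                    )
        # criterion validity: against the predecessor scales
        if name == "TIL":
            for other in ("PILOT", "TIL1987"):
                if other not in run.scales_evaluated:
                    continue
                q = SCALE_PREFIX[other]
                for summ in ("max", "median"):
                    fn = (lambda c0, c1: lambda s, d: association.spearman(s[c0], s[c1]))(
                        f"{p}_{summ}", f"{q}_{summ}"
                    )
                    est = _boot(plan, cfg, fn, f"rho:til_{summ}:{q}_{summ}")
                    rows.append(
                        _row(est, statistic="spearman_rho", scale=name, summary=summ,
                             counterpart=f"{other}_{summ}", stream="")
                    )
                fn = (lambda c0, c1: lambda s, d: association.rm_corr(
                    d["patient_id"], d[c0], d[c1]
                ))(f"{p}_24", f"{q}_24")
                est = _boot(plan, cfg, fn, f"rmcorr:til_24:{q}_24")
                rows.append(
                    _row(est, statistic="rm_corr", scale=name, summary="daily",
                         counterpart=f"{other}_24", stream="")
                )
        # daily within-patient associations
        daily_counterparts = ["icp_concern", "cpp_concern"] + [
            f"{v}_{t}" for t in stream_tags for v in ("icp24", "cpp24")
        ]
        for counterpart in daily_counterparts:
            fn = (lambda c0, c1: lambda s, d: association.rm_corr(
                d["patient_id"], d[c0], d[c1]
            ))(f"{p}_24", counterpart)
            est = _boot(plan, cfg, fn, f"rmcorr:{p}_24:{counterpart}")
            rows.append(
                _row(est, statistic="rm_corr", scale=name, summary="daily",
                     counterpart=counterpart,
                     stream=counterpart.split("_")[-1] if counterpart.endswith(("_eh", "_hr")) else "")
            )
        # mixed-model slopes: outcome ~ day + score + (1 | patient)
        for tag in stream_tags:
            for outcome in (f"icp24_{tag}", f"cpp24_{tag}"):
                ests = []
                for s_c, d_c in zip(imp.static, imp.daily):
                    sub = d_c[["patient_id", "day", outcome, f"{p}_24"]].dropna()
                    if sub["patient_id"].nunique() < 10:
                        continue
                    try:
                        ests.append(
                            association.lmer_beta(
                                sub[outcome], sub["day"], sub[f"{p}_24"], sub["patient_id"]
                            )
                        )
                    except (ValueError, np.linalg.LinAlgError):
                        continue
                if not ests:
                    continue
                beta = float(np.mean([e.beta for e in ests]))
                lo = float(np.mean([e.ci_low for e in ests]))
                hi = float(np.mean([e.ci_high for e in ests]))
                rows.append(
                    {
                        "statistic": "lmer_beta",
                        "scale": name,
                        "summary": "daily",
                        "counterpart": outcome,
                        "stream": tag,
                        "estimate": beta,
                        "ci_low": lo,
                        "ci_high": hi,
                        "n_resamples": 0,
                        "n_undefined": 0,
                        "method": "reml-wald-pooled",
                    }
                )
    return pd.DataFrame(rows)


def threshold_table(imp: ImputationSet, cfg: BootstrapConfig, run: RunConfig, cohort: Cohort, plan: BootstrapPlan | None = None) -> pd.DataFrame:
    """Known-groups ROC grids and selected thresholds."""
    plan = plan or BootstrapPlan(imp.static, imp.daily)
    rows = []
    for name in run.scales_evaluated:
        p = SCALE_PREFIX[name]
        for summ in ("max", "median"):
            col = f"{p}_{summ}"

            def auc_fn(s, d, c=col):
                r = discrimination.roc(s[c].astype(float), s["refractory_ich"].astype(float))
                return r.auc

            est = _boot(plan, cfg, auc_fn, f"auc:{col}")
            s0, d0 = imp.static[0], imp.daily[0]
            try:
                r = discrimination.roc(
                    s0[col].astype(float),
                    s0["refractory_ich"].astype(float),
                    score_name=col,
                    label_name="refractory_ich",
                )
            except ValueError:
                continue
            grid = r.as_frame()
            best = discrimination.best_threshold(r)
            grid["selected"] = np.isclose(grid["threshold"], best["threshold"])
            grid["auc_estimate"] = est.estimate
            grid["auc_ci_low"] = est.ci_low
            grid["auc_ci_high"] = est.ci_high
            rows.append(grid)
    # surgical ICP-control day detection on the daily TIL score
    if "TIL" in run.scales_evaluated:
        d0 = imp.daily[0]
        scored = d0[["patient_id", "day"]].copy()
        scored["value"] = d0["til_24"].astype(float)
        try:
            r = discrimination.surgical_day_detection(scored, cohort.therapy)
            grid = r.as_frame()
            best = discrimination.best_threshold(r)
            grid["selected"] = np.isclose(grid["threshold"], best["threshold"])
            grid["auc_estimate"] = r.auc
            grid["auc_ci_low"] = np.nan
            grid["auc_ci_high"] = np.nan
            rows.append(grid)
        except ValueError as exc:
            logger.warning("surgical-day ROC unavailable: %s", exc)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()


def item_analysis_table(imp: ImputationSet, cohort: Cohort, run: RunConfig) -> pd.DataFrame:
    """Component-item analysis on the first completed copy.

    Median item score per daily-TIL stratum, adjusted item-total
    correlations, per-day internal reliability, and per-sub-item
    mixed-model effects on daily mean ICP.
    """
    ther = prepared_therapy(cohort)
    ther = ther[~ther["censored"]]
    configs = scales.load_scale_configs()
    til_cfg = configs["TIL"]
    rows = []

    # per-item daily scores
    item_scores = pd.DataFrame({"patient_id": ther["patient_id"], "day": ther["day"]})
    for item in scales.ITEM_COLUMNS:
        single = {i: ({} if i != item else til_cfg.subitem_scores.get(item, {})) for i in scales.ITEM_COLUMNS}
        cfg_i = scales.ScaleConfig(
            name=f"TIL[{item}]", subitem_scores=single,
            aggregation="sum_of_item_maxima", max_total=0,
        )
        item_scores[item] = scales.score_table(ther, cfg_i)["value"].to_numpy()
    total = item_scores[list(scales.ITEM_COLUMNS)].sum(axis=1, skipna=False)
    item_scores["til_24"] = total

    complete = item_scores.dropna()
    for til_val, sub in complete.groupby("til_24"):
        for item in scales.ITEM_COLUMNS:
            rows.append(
                {
                    "analysis": "median_item_score",
                    "item": item,
                    "til_24": int(til_val),
                    "day": np.nan,
                    "value": float(sub[item].median()),
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                }
            )
    adj = association.adjusted_item_total(
        complete[list(scales.ITEM_COLUMNS)], complete["til_24"], complete["patient_id"]
    )
    for item, res in adj.items():
        rows.append(
            {
                "analysis": "adjusted_item_total_rmcorr",
                "item": item,
                "til_24": np.nan,
                "day": np.nan,
                "value": res.value,
                "ci_low": np.nan,
                "ci_high": np.nan,
            }
        )
    for day, sub in complete.groupby("day"):
        alpha = association.cronbach_alpha(sub[list(scales.ITEM_COLUMNS)])
        rows.append(
            {
                "analysis": "cronbach_alpha",
                "item": "",
                "til_24": np.nan,
                "day": int(day),
                "value": alpha.value,
                "ci_low": np.nan,
                "ci_high": np.nan,
            }
        )
    # per-sub-item mixed-model effects on EH daily mean ICP
    d0 = imp.daily[0]
    dummies = pd.DataFrame(index=ther.index)
    for item, levels in scales.ITEM_LEVELS.items():
        if levels == ("present",):
            dummies[item] = ther[item].fillna(0).astype(float)
        else:
            for lv in levels:
                dummies[f"{item}__{lv}"] = (ther[item] == lv).astype(float)
    merged = pd.concat(
        [ther[["patient_id", "day"]].reset_index(drop=True), dummies.reset_index(drop=True)], axis=1
    ).merge(d0[["patient_id", "day", "icp24_eh"]], on=["patient_id", "day"], how="left")
    if merged["icp24_eh"].notna().sum() > 50:
        try:
            res = association.item_effects(
                merged["icp24_eh"], merged["day"], merged[dummies.columns], merged["patient_id"]
            )
            for sub_item, eff in res.effects.items():
                rows.append(
                    {
                        "analysis": "subitem_lmer_beta_icp24_eh",
                        "item": sub_item,
                        "til_24": np.nan,
                        "day": np.nan,
                        "value": eff.beta,
                        "ci_low": eff.ci_low,
                        "ci_high": eff.ci_high,
                    }
                )
            for sub_item in res.aliased:
                rows.append(
                    {
                        "analysis": "subitem_lmer_beta_icp24_eh",
                        "item": sub_item,
                        "til_24": np.nan,
                        "day": np.nan,
                        "value": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                    }
                )
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("sub-item mixed model unavailable: %s", exc)
    return pd.DataFrame(rows)


def information_table(imp: ImputationSet, cfg: BootstrapConfig, run: RunConfig, plan: BootstrapPlan | None = None) -> pd.DataFrame:
    """Information coverage of the condensed scale, plus derived ranges."""
    info_columns = ["kind", "pairing", "mi_bits", "entropy_full_bits", "value", "ci_low", "ci_high"]
    if "TILBasic" not in run.scales_evaluated or "TIL" not in run.scales_evaluated:
        return pd.DataFrame(columns=info_columns)
    plan = plan or BootstrapPlan(imp.static, imp.daily)
    rows = []
    pairings = {
        "daily": lambda s, d: information.information_coverage(d["til_24"], d["tilbasic_24"], "daily"),
        "max": lambda s, d: information.information_coverage(s["til_max"], s["tilbasic_max"], "max"),
        "median": lambda s, d: information.information_coverage(s["til_median"], s["tilbasic_median"], "median"),
    }
    for pairing, fn in pairings.items():
        wrapped = (lambda f: lambda s, d: f(s, d).ic)(fn)
        est = _boot(plan, cfg, wrapped, f"ic:{pairing}")
        res = fn(imp.static[0], imp.daily[0])
        rows.append(
            {
                "kind": "information_coverage",
                "pairing": pairing,
                "mi_bits": res.mi,
                "entropy_full_bits": res.entropy_full,
                "value": est.estimate,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
            }
        )
    d0 = imp.daily[0]
    bounds = scales.derive_ranges(d0["til_24"].astype(float), d0["tilbasic_24"].astype(float))
    for category, lowest in bounds.items():
        rows.append(
            {
                "kind": "derived_range_lower_bound",
                "pairing": f"category_{category}",
                "mi_bits": np.nan,
                "entropy_full_bits": np.nan,
                "value": lowest,
                "ci_low": np.nan,
                "ci_high": np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the full run


def run_validation(run: RunConfig, cohort: Cohort | None = None) -> dict:
    """Execute the full pipeline; returns the result tables and writes CSVs."""
    t0 = time.time()
    out_dir = Path(run.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = {}

    if cohort is None:
        gen = run.generator or GeneratorConfig.for_n(run.n_patients)
        cohort, truth = generate_cohort(gen, seed=run.seed)
        cohort = inject_missingness(cohort, gen, seed=run.seed)
        truth.to_frame().to_csv(out_dir / "ground_truth.csv", index=False)
        stages["simulate"] = time.time() - t0

    daily = build_daily_table(cohort, run.scales_evaluated)
    static = cohort.static.copy()
    # first-day WLST decisions are outside the validation population
    excluded = static["wlst_day"].notna() & (static["wlst_day"] <= 1)
    static = static[~excluded]
    daily = daily[daily["patient_id"].isin(static["patient_id"])]
    stages["score"] = time.time() - t0

    imp = impute_analysis_tables(
        static, daily, m=run.m_imputations, seed=run.seed, scale_names=run.scales_evaluated
    )
    stages["impute"] = time.time() - t0

    boot = BootstrapConfig(n_resamples=run.n_resamples, level=run.ci_level, seed=run.seed)
    plan = BootstrapPlan(imp.static, imp.daily)
    tables = {
        "associations": association_table(imp, boot, run, plan),
        "thresholds": threshold_table(imp, boot, run, cohort, plan),
        "item_analysis": item_analysis_table(imp, cohort, run),
        "information": information_table(imp, boot, run, plan),
    }
    stages["validate"] = time.time() - t0

    for name, df in tables.items():
        df.to_csv(out_dir / f"{name}.csv", index=False)
    manifest = {
        "seed": run.seed,
        "n_patients_analyzed": int(len(static)),
        "m_imputations": run.m_imputations,
        "n_resamples": run.n_resamples,
        "ci_level": run.ci_level,
        "scales": list(run.scales_evaluated),
        "streams": list(run.streams),
        "stage_seconds": {k: round(v, 2) for k, v in stages.items()},
        "config_hash": hashlib.sha256(
            json.dumps(asdict(run), default=str, sort_keys=True).encode()
        ).hexdigest()[:16],
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    tables["manifest"] = manifest
    tables["imputations"] = imp
    return tables
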