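"""Synthetic neuro-ICU cohort generator with known ground truth.

The generator emulates the statistical structure that the validation
pipeline assumes of an ICP-monitored TBI cohort, without fitting any
real data:

* A latent per-patient *severity* drives baseline GCS (negatively),
  the ordinal six-month outcome, the prognosis probabilities and the
  initial intracranial-pressure *burden*.
* Burden (the untreated ICP elevation, mm Hg) follows a stationary
  AR(1) process across ICU days 1-7.
* A deterministic treatment policy escalates therapies in a staircase
  order -- positioning, sedation, CPP management, ventilation,
  neuromuscular blockade, CSF drainage, hyperosmolar therapy,
  temperature control, and finally surgery -- until the modelled ICP
  (baseline + burden - treatment_effect x TIL) is controlled.
  Center-level random propensities gate CSF drainage and decompressive
  craniectomy, making them the most variably applied therapies.
* Observed daily mean ICP is coupled to the daily TIL score with a
  fixed within-patient slope ``coupling_beta`` (mm Hg per TIL point)
  around a patient random intercept that is independent of treatment
  intensity, so mixed-model recovery of the slope is well defined.
* Daily physician concerns are noisy monotone transforms of the same
  day's ICP (ICP concern, tighter) and CPP (CPP concern, looser).
* The refractory-hypertension label is true when burden exceeds a
  threshold on any day despite maximal medical (non-surgical) therapy;
  last-resort decompressive craniectomy is recorded on its index day
  only (downstream scoring carries it forward).
* A configured fraction of the highest-severity patients receive a
  WLST decision on a day >= 2; their post-decision days are
  structurally absent from every longitudinal table.

Missingness is injected separately (:func:`inject_missingness`) and is
missing-at-random: masking probabilities depend only on observed
covariates (center, day, age), never on the masked value itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import scales
from .cohort import Cohort, MARSHALL_LEVELS, PROGNOSIS_COLUMNS, STATIC_SCHEMA, THERAPY_SCHEMA, PHYSIO_SCHEMA, CONCERNS_SCHEMA
from .inference import stream

__all__ = ["GeneratorConfig", "GroundTruth", "ESCALATION_LADDER", "generate_cohort", "inject_missingness"]

#: (item, level) escalation steps in staircase order.  CSF-drainage
#: steps are additionally gated by a center-level propensity.
ESCALATION_LADDER: tuple[tuple[str, str], ...] = (
    ("head_position", "present"),
    ("sedation", "low"),
    ("sedation", "higher"),
    ("fluid_loading", "present"),
    ("vasopressor", "present"),
    ("hypocapnia", "mild"),
    ("hypocapnia", "moderate"),
    ("nmb", "present"),
    ("csf_drainage", "low"),
    ("mannitol", "low"),
    ("hypertonic_saline", "low"),
    ("temperature", "fever_control"),
    ("mannitol", "high"),
    ("hypertonic_saline", "high"),
    ("csf_drainage", "high"),
    ("temperature", "cooling"),
    ("hypocapnia", "intensive"),
    ("sedation", "metabolic"),
    ("temperature", "hypothermia"),
)

_GOSE_PMF = {1: 0.26, 2: 0.12, 3: 0.12, 4: 0.09, 5: 0.16, 6: 0.10, 7: 0.07, 8: 0.08}
_MARSHALL_PMF = {"I": 0.02, "II": 0.37, "III": 0.13, "IV": 0.03, "V": 0.23, "VI": 0.22}


@dataclass(frozen=True)
class GeneratorConfig:
    """All tunable knobs of the synthetic cohort, with study-like defaults."""

    n_patients: int = 873
    n_centers: int = 52
    severity_sd: float = 1.0
    icp_baseline: float = 12.0  # mm Hg, untreated/uninjured operating point
    burden_mean: float = 10.5  # mm Hg mean untreated ICP elevation
    burden_sd: float = 3.2
    burden_ar1: float = 0.55
    burden_severity_weight: float = 0.6  # share of burden sd carried by severity
    treatment_effect: float = 0.45  # policy-modelled mm Hg relief per TIL point
    coupling_beta: float = 0.22  # observed mm Hg ICP_24 change per TIL_24 point
    icp_target: float = 20.0  # escalation stops once modelled ICP <= target
    icp_intercept_sd: float = 2.0  # patient random intercept of daily ICP
    icp_noise_sd: float = 2.5  # day-level ICP noise
    day_slope: float = -0.15  # secular ICP trend per ICU day
    within_day_sd: float = 3.0  # sample-level noise around the daily mean
    map_mean: float = 90.0
    map_patient_sd: float = 5.0
    map_day_sd: float = 6.0
    pulse_mean: float = 45.0
    pulse_sd: float = 6.0
    concern_noise_sd: float = 1.25
    refractory_burden_threshold: float = 16.0  # mm Hg burden => medically refractory
    op_burden_threshold: float = 14.0  # mass-lesion surgery trigger
    dc_relief: float = 6.0  # burden relief on days after craniectomy
    center_sd_csf: float = 1.0
    center_sd_dc: float = 1.0
    csf_logit_mean: float = 0.0
    dc_logit_mean: float = -1.0
    hr_fraction: float = 0.3  # share of patients with a high-frequency stream
    eh_interval_s: float = 7200.0
    hr_interval_s: float = 600.0  # emulated HR stream, down-sampled cadence
    wlst_fraction: float = 0.10
    los_log_mean: float = float(np.log(14.0))
    los_log_sd: float = 0.55
    missing_rate_static: float = 0.10
    missing_rate_daily: float = 0.024
    missing_rate_concern: float = 0.08
    missing_rate_physio: float = 0.05
    hr_day1_drop_rate: float = 0.67
    max_day: int = 7

    @classmethod
    def for_n(cls, n_patients: int, **overrides) -> "GeneratorConfig":
        """A default config scaled to ``n_patients`` (centers capped at n)."""
        overrides.setdefault("n_centers", min(52, n_patients))
        return cls(n_patients=n_patients, **overrides)

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not (1 <= self.n_centers <= self.n_patients):
            raise ValueError("need 1 <= n_centers <= n_patients")
        if not (-1.0 < self.burden_ar1 < 1.0):
            raise ValueError("burden_ar1 must lie in (-1, 1)")
        for name in (
            "wlst_fraction",
            "hr_fraction",
            "missing_rate_static",
            "missing_rate_daily",
            "missing_rate_concern",
            "missing_rate_physio",
            "hr_day1_drop_rate",
        ):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Latent quantities the pipeline's estimates are checked against."""

    severity: pd.Series  # per patient
    burden: pd.DataFrame  # patient_id, day, burden (post-surgical relief)
    refractory: pd.Series  # per patient, bool
    coupling_beta: float
    daily: pd.DataFrame  # patient_id, day, til24, tilbasic24, icp24, cpp24
    tilbasic_boundaries: dict[int, int]  # ungated-ladder TIL -> category onsets

    def to_frame(self) -> pd.DataFrame:
        df = self.daily.copy()
        df = df.merge(self.burden, on=["patient_id", "day"])
        df["severity"] = df["patient_id"].map(self.severity)
        df["refractory"] = df["patient_id"].map(self.refractory).astype(int)
        return df


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _empty_record() -> dict:
    rec = {}
    for item, levels in scales.ITEM_LEVELS.items():
        rec[item] = 0 if levels == ("present",) else "none"
    return rec


def _ladder_boundaries(til_cfg, basic_cfg) -> dict[int, int]:
    """TILBasic category onsets along the ungated escalation ladder."""
    rec = _empty_record()
    bounds: dict[int, int] = {}
    prev = 0
    steps = list(ESCALATION_LADDER) + [("intracranial_op", "present"), ("dc", "present")]
    for item, level in steps:
        rec[item] = 1 if level == "present" else level
        til = scales.score_daily(rec, til_cfg)
        basic = scales.score_daily(rec, basic_cfg)
        if basic > prev:
            bounds[basic] = til
            prev = basic
    return bounds


def generate_cohort(config: GeneratorConfig, seed: int) -> tuple[Cohort, GroundTruth]:
    """Generate a complete (no missingness) cohort plus its ground truth.

    Deterministic given (config, seed); every stage draws from its own
    named substream of the seed.
    """
    cfg = config
    n = cfg.n_patients
    rng_pat = stream(seed, "patients")
    rng_burden = stream(seed, "burden")
    rng_policy = stream(seed, "policy")
    rng_icp = stream(seed, "icp")
    rng_phys = stream(seed, "physio")
    rng_conc = stream(seed, "concerns")

    configs = scales.load_scale_configs()
    til_cfg = configs["TIL"]
    basic_cfg = configs["TILBasic"]

    patient_ids = np.array([f"P{i:04d}" for i in range(n)])
    center_ids = np.array([f"C{c:02d}" for c in rng_pat.integers(cfg.n_centers, size=n)])
    severity = rng_pat.normal(0.0, cfg.severity_sd, size=n)

    # --- static table -----------------------------------------------------
    age = np.clip(rng_pat.normal(47, 19, size=n), 16, 95).round(0)
    sex = np.where(rng_pat.random(n) < 0.25, "female", "male")
    gcs = np.clip(np.round(7.5 - 2.2 * severity + rng_pat.normal(0, 2.2, size=n)), 3, 15)
    marshall = rng_pat.choice(list(_MARSHALL_PMF), p=list(_MARSHALL_PMF.values()), size=n)

    # ordinal outcome and prognosis share a latent "recovery" scale:
    # higher severity -> lower latent -> worse GOSE category
    latent_good = -0.9 * severity + rng_pat.normal(0, 1.0, size=n)
    latent_sd = float(np.sqrt(0.81 * cfg.severity_sd**2 + 1.0))
    cum = np.cumsum([_GOSE_PMF[k] for k in range(1, 9)])[:-1]
    cuts = np.asarray([_norm_ppf(c) for c in cum]) * latent_sd  # ascending
    gose = 1 + np.searchsorted(cuts, latent_good)
    # Pr(GOSE > k) = P(latent above the k|k+1 cutpoint), per patient
    prog_latent = -severity + rng_pat.normal(0, 0.5, size=n)
    prognosis = {}
    for col, k in zip(PROGNOSIS_COLUMNS, (1, 3, 4, 5, 6, 7)):
        prognosis[col] = np.round(_sigmoid(1.1 * (prog_latent - cuts[k - 1])), 4)

    los = np.maximum(1, np.round(np.exp(rng_pat.normal(cfg.los_log_mean, cfg.los_log_sd, size=n)))).astype(int)

    # WLST: the configured fraction of highest-severity patients, day >= 2
    n_wlst = int(round(cfg.wlst_fraction * n))
    wlst_day = np.full(n, np.nan)
    if n_wlst > 0:
        order = np.argsort(-(severity + rng_pat.normal(0, 0.3, size=n)))
        chosen = order[:n_wlst]
        wlst_day[chosen] = rng_pat.integers(2, cfg.max_day + 1, size=n_wlst)
        gose[chosen] = 1
        los[chosen] = np.minimum(los[chosen], wlst_day[chosen].astype(int))
        los[chosen] = np.maximum(los[chosen], wlst_day[chosen].astype(int))

    # --- latent burden (AR(1), severity-loaded) ---------------------------
    w = cfg.burden_severity_weight
    u = np.empty((n, cfg.max_day))
    u[:, 0] = rng_burden.normal(0, 1, size=n)
    for d in range(1, cfg.max_day):
        u[:, d] = cfg.burden_ar1 * u[:, d - 1] + np.sqrt(1 - cfg.burden_ar1**2) * rng_burden.normal(0, 1, size=n)
    z = w * severity[:, None] / cfg.severity_sd + np.sqrt(1 - w**2) * u
    burden = np.maximum(0.0, cfg.burden_mean + cfg.burden_sd * z)

    refractory = (burden > cfg.refractory_burden_threshold).any(axis=1)

    # --- center propensities for the variably-applied therapies ----------
    centers = sorted(set(center_ids))
    rng_center = stream(seed, "centers")
    csf_logit = {c: cfg.csf_logit_mean + rng_center.normal(0, cfg.center_sd_csf) for c in centers}
    dc_logit = {c: cfg.dc_logit_mean + rng_center.normal(0, cfg.center_sd_dc) for c in centers}
    uses_csf = rng_policy.random(n) < _sigmoid(np.array([csf_logit[c] for c in center_ids]))
    uses_dc = rng_policy.random(n) < _sigmoid(np.array([dc_logit[c] for c in center_ids]))
    mass_lesion = np.isin(marshall, ("V", "VI"))

    # --- daily treatment policy ------------------------------------------
    therapy_rows = []
    truth_rows = []
    op_done = np.zeros(n, dtype=bool)
    dc_done = np.zeros(n, dtype=bool)
    dc_day = np.full(n, np.inf)
    for i in range(n):
        last_day = int(min(cfg.max_day, los[i]))
        if not np.isnan(wlst_day[i]):
            last_day = min(last_day, int(wlst_day[i]) - 1)
        for d in range(1, last_day + 1):
            b = burden[i, d - 1]
            if d > dc_day[i]:
                b = max(0.0, b - cfg.dc_relief)
                burden[i, d - 1] = b
            rec = _empty_record()
            til = 0
            for item, level in ESCALATION_LADDER:
                if item == "csf_drainage" and not uses_csf[i]:
                    continue
                if cfg.icp_baseline + b - cfg.treatment_effect * til <= cfg.icp_target:
                    break
                rec[item] = 1 if level == "present" else level
                til = scales.score_daily(rec, til_cfg)
            # surgery tier: mass-lesion evacuation, then last-resort DC
            if mass_lesion[i] and not op_done[i] and b >= cfg.op_burden_threshold:
                rec["intracranial_op"] = 1
                op_done[i] = True
            dc_refr = 0
            if uses_dc[i] and not dc_done[i] and b > cfg.refractory_burden_threshold and d >= 2:
                rec["dc"] = 1
                dc_refr = 1
                dc_done[i] = True
                dc_day[i] = d
            # the record shows the craniectomy on its index day only;
            # scoring applies the carry-forward rule downstream
            row = {"patient_id": patient_ids[i], "day": d, **rec, "dc_refractory": dc_refr}
            therapy_rows.append(row)
            eff = dict(rec)
            if dc_done[i] and d > dc_day[i]:
                eff["dc"] = 1
            til_eff = scales.score_daily(eff, til_cfg)
            basic_eff = scales.score_daily(eff, basic_cfg)
            truth_rows.append(
                {
                    "patient_id": patient_ids[i],
                    "day": d,
                    "til24": til_eff,
                    "tilbasic24": basic_eff,
                }
            )

    therapy = pd.DataFrame(therapy_rows)
    truth_daily = pd.DataFrame(truth_rows)

    # --- observed daily ICP/CPP coupled to treatment intensity -----------
    alpha = rng_icp.normal(0, cfg.icp_intercept_sd, size=n)  # independent of severity
    pid_index = {p: i for i, p in enumerate(patient_ids)}
    rows_i = truth_daily["patient_id"].map(pid_index).to_numpy()
    days = truth_daily["day"].to_numpy()
    icp24 = (
        cfg.icp_baseline
        + alpha[rows_i]
        + cfg.day_slope * (days - 1)
        + cfg.coupling_beta * truth_daily["til24"].to_numpy()
        + rng_icp.normal(0, cfg.icp_noise_sd, size=len(truth_daily))
    )
    map_pat = cfg.map_mean + rng_icp.normal(0, cfg.map_patient_sd, size=n)
    map24 = map_pat[rows_i] + rng_icp.normal(0, cfg.map_day_sd, size=len(truth_daily))
    cpp24 = map24 - icp24
    truth_daily["icp24"] = icp24
    truth_daily["cpp24"] = cpp24

    # --- physiology samples ----------------------------------------------
    hr_patients = set(patient_ids[rng_phys.random(n) < cfg.hr_fraction])
    physio_parts = []
    for stream_name, interval in (("EH", cfg.eh_interval_s), ("HR", cfg.hr_interval_s)):
        k = int(round(86400.0 / interval))
        offsets = (np.arange(k) + 1.0) * interval - interval / 2.0
        sub = truth_daily if stream_name == "EH" else truth_daily[
            truth_daily["patient_id"].isin(hr_patients)
        ]
        if len(sub) == 0:
            continue
        reps = len(sub)
        ts = ((sub["day"].to_numpy() - 1) * 86400.0)[:, None] + offsets[None, :]
        icp_s = sub["icp24"].to_numpy()[:, None] + rng_phys.normal(0, cfg.within_day_sd, size=(reps, k))
        map_s = (sub["icp24"].to_numpy() + sub["cpp24"].to_numpy())[:, None] + rng_phys.normal(
            0, 2.0, size=(reps, k)
        )
        part = pd.DataFrame(
            {
                "patient_id": np.repeat(sub["patient_id"].to_numpy(), k),
                "timestamp_s": ts.ravel(),
                "stream": stream_name,
                "icp": np.round(icp_s.ravel(), 2),
            }
        )
        if stream_name == "EH":
            pp = cfg.pulse_mean + rng_phys.normal(0, cfg.pulse_sd, size=reps * k)
            part["sbp"] = np.round(map_s.ravel() + 2.0 * pp / 3.0, 2)
            part["dbp"] = np.round(map_s.ravel() - pp / 3.0, 2)
            part["cpp"] = np.nan
        else:
            part["sbp"] = np.nan
            part["dbp"] = np.nan
            part["cpp"] = np.round(map_s.ravel() - icp_s.ravel(), 2)
        physio_parts.append(part)
    physio = pd.concat(physio_parts, ignore_index=True)
    physio = physio.sort_values(["patient_id", "stream", "timestamp_s"]).reset_index(drop=True)

    # --- physician concerns ----------------------------------------------
    icp_concern = np.clip(
        np.round(1 + 9 * _sigmoid((icp24 - 17.0) / 3.0) + rng_conc.normal(0, cfg.concern_noise_sd, size=len(truth_daily))),
        1,
        10,
    )
    cpp_concern = np.clip(
        np.round(1 + 9 * _sigmoid((62.0 - cpp24) / 4.0) + rng_conc.normal(0, 2.0 * cfg.concern_noise_sd, size=len(truth_daily))),
        1,
        10,
    )
    concerns = pd.DataFrame(
        {
            "patient_id": truth_daily["patient_id"],
            "day": truth_daily["day"],
            "icp_concern": icp_concern.astype(int),
            "cpp_concern": cpp_concern.astype(int),
        }
    )

    static = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "center_id": center_ids,
            "age": age,
            "sex": sex,
            "gcs_baseline": gcs.astype(int),
            "marshall": marshall,
            "gose_6mo": gose.astype(int),
            **prognosis,
            "refractory_ich": refractory.astype(int),
            "wlst_day": pd.array(
                [int(v) if not np.isnan(v) else pd.NA for v in wlst_day], dtype="Int64"
            ),
            "icu_los_days": los,
        }
    )

    cohort = Cohort(
        static=_coerce(static, STATIC_SCHEMA),
        therapy=_coerce(therapy, THERAPY_SCHEMA),
        physio=_coerce(physio, PHYSIO_SCHEMA),
        concerns=_coerce(concerns, CONCERNS_SCHEMA),
    )
    cohort.validate()

    truth = GroundTruth(
        severity=pd.Series(severity, index=patient_ids),
        burden=pd.DataFrame(
            {
                "patient_id": np.repeat(patient_ids, cfg.max_day),
                "day": np.tile(np.arange(1, cfg.max_day + 1), n),
                "burden": burden.ravel(),
            }
        ).merge(truth_daily[["patient_id", "day"]], on=["patient_id", "day"]),
        refractory=pd.Series(refractory, index=patient_ids),
        coupling_beta=cfg.coupling_beta,
        daily=truth_daily,
        tilbasic_boundaries=_ladder_boundaries(til_cfg, basic_cfg),
    )
    return cohort, truth


def _norm_ppf(q: float) -> float:
    from scipy.stats import norm

    return float(norm.ppf(q))


def _coerce(df: pd.DataFrame, schema: dict) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index)
    for col, dtype in schema.items():
        if col in df.columns:
            out[col] = df[col].astype(dtype)
        else:
            out[col] = pd.Series(dtype=dtype, index=df.index)
    return out


def inject_missingness(cohort: Cohort, config: GeneratorConfig, seed: int) -> Cohort:
    """Mask cells missing-at-random; returns a new cohort.

    Masking probabilities depend only on observed covariates -- center,
    age and day -- never on the value being masked.  Day-1
    high-frequency physiology is dropped at an elevated rate to emulate
    monitor hookup delay.  Post-WLST cells are structurally absent in
    the generated cohort already, so nothing is masked there.
    """
    cfg = config
    rng = stream(seed, "missingness")
    static = cohort.static.copy()
    therapy = cohort.therapy.copy()
    physio = cohort.physio.copy()
    concerns = cohort.concerns.copy()
    n = len(static)

    centers = sorted(set(static["center_id"].dropna()))
    center_z = {c: rng.normal(0, 1) for c in centers}
    cz = static["center_id"].map(center_z).astype(float).to_numpy()
    age_z = (static["age"].astype(float).to_numpy() - 47.0) / 19.0

    def mask_prob(base: float) -> np.ndarray:
        return np.clip(base * np.exp(0.4 * cz + 0.2 * age_z), 0.0, 0.9)

    var_scale = {
        "gcs_baseline": 0.6,
        "marshall": 1.9,
        "gose_6mo": 1.3,
        "prognosis": 1.4,
        "refractory_ich": 0.1,
    }
    for var, scale_f in var_scale.items():
        p = mask_prob(cfg.missing_rate_static * scale_f)
        hit = rng.random(n) < p
        if var == "prognosis":
            static.loc[hit, list(PROGNOSIS_COLUMNS)] = pd.NA
        else:
            static.loc[hit, var] = pd.NA

    # whole-day therapy assessments
    t_cz = therapy["patient_id"].map(dict(zip(static["patient_id"], cz))).to_numpy(dtype=float)
    day_f = 1.0 + 0.05 * (therapy["day"].astype(float).to_numpy() - 1.0)
    p_day = np.clip(cfg.missing_rate_daily * np.exp(0.3 * t_cz) * day_f, 0.0, 0.5)
    hit_day = rng.random(len(therapy)) < p_day
    item_cols = list(scales.ITEM_COLUMNS) + ["dc_refractory"]
    therapy.loc[hit_day, item_cols] = pd.NA

    for col in ("icp_concern", "cpp_concern"):
        c_cz = concerns["patient_id"].map(dict(zip(static["patient_id"], cz))).to_numpy(dtype=float)
        p_c = np.clip(cfg.missing_rate_concern * np.exp(0.3 * c_cz), 0.0, 0.5)
        hit = rng.random(len(concerns)) < p_c
        concerns.loc[hit, col] = pd.NA

    # EH: drop whole patient-days; HR: drop day 1 per patient at high rate
    from .physiology import SECONDS_PER_DAY

    day_of = np.floor(physio["timestamp_s"].astype(float).to_numpy() / SECONDS_PER_DAY).astype(int) + 1
    keep = np.ones(len(physio), dtype=bool)
    eh = (physio["stream"] == "EH").to_numpy()
    eh_days = physio.loc[eh, ["patient_id"]].assign(day=day_of[eh]).drop_duplicates()
    drop_pairs = set()
    for _, r in eh_days.iterrows():
        if rng.random() < cfg.missing_rate_physio:
            drop_pairs.add((r["patient_id"], int(r["day"])))
    if drop_pairs:
        pairkey = list(zip(physio["patient_id"].tolist(), day_of.tolist()))
        in_drop = np.array([pk in drop_pairs for pk in pairkey])
        keep &= ~(in_drop & eh)
    hr = ~eh
    hr_patients = sorted(set(physio.loc[hr, "patient_id"]))
    late = {p for p in hr_patients if rng.random() < cfg.hr_day1_drop_rate}
    if late:
        is_late = physio["patient_id"].isin(late).to_numpy()
        keep &= ~(hr & is_late & (day_of == 1))
    physio = physio[keep].reset_index(drop=True)

    out = Cohort(static=static, therapy=therapy, physio=physio, concerns=concerns)
    out.validate()
    return out
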