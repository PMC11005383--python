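"""Generator: determinism, ground-truth consistency, MAR missingness,
and the qualitative structure the validation pipeline assumes."""

import numpy as np
import pandas as pd
import pytest

from tilscale import scales
from tilscale.association import lmer_beta, rm_corr, spearman
from tilscale.pipeline import build_daily_table, patient_summaries
from tilscale.synthetic import (
    GeneratorConfig,
    generate_cohort,
    inject_missingness,
)

MODALITY_OF_ITEM = {
    "head_position": "positioning",
    "sedation": "sedation",
    "fluid_loading": "cpp_management",
    "vasopressor": "cpp_management",
    "hypocapnia": "ventilation",
    "nmb": "nmb",
    "csf_drainage": "csf",
    "mannitol": "hyperosmolar",
    "hypertonic_saline": "hyperosmolar",
    "temperature": "temperature",
    "intracranial_op": "surgery",
    "dc": "surgery",
}
STAIRCASE = ["positioning", "sedation", "cpp_management", "ventilation",
             "nmb", "hyperosmolar", "temperature", "surgery"]


class TestDeterminismAndLimits:
    def test_same_seed_reproduces_cohort_exactly(self):
        cfg = GeneratorConfig.for_n(120)
        c1, t1 = generate_cohort(cfg, seed=5)
        c2, t2 = generate_cohort(cfg, seed=5)
        for name in ("static", "therapy", "physio", "concerns"):
            pd.testing.assert_frame_equal(getattr(c1, name), getattr(c2, name))
        pd.testing.assert_frame_equal(t1.daily, t2.daily)

    def test_different_seeds_differ(self):
        cfg = GeneratorConfig.for_n(50)
        c1, _ = generate_cohort(cfg, seed=1)
        c2, _ = generate_cohort(cfg, seed=2)
        assert not c1.static["gcs_baseline"].equals(c2.static["gcs_baseline"])

    def test_infinite_refractory_threshold_yields_no_refractory_patients(self):
        cfg = GeneratorConfig.for_n(80, refractory_burden_threshold=np.inf)
        cohort, truth = generate_cohort(cfg, seed=3)
        assert truth.refractory.sum() == 0
        assert (cohort.static["refractory_ich"] == 0).all()

    def test_zero_patient_config_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n_patients=0)

    def test_generated_cohort_passes_schema_validation(self, small_cohort):
        cohort, _, _ = small_cohort
        cohort.validate()  # raises on violation

    def test_wlst_assigned_to_high_severity_patients_day_ge_2(self, small_cohort):
        cohort, truth, cfg = small_cohort
        st = cohort.static
        wlst = st["wlst_day"].notna()
        assert wlst.sum() == round(cfg.wlst_fraction * len(st))
        assert (st.loc[wlst, "wlst_day"] >= 2).all()
        sev = truth.severity
        assert sev[st.loc[wlst, "patient_id"]].mean() > sev.mean()

    def test_no_therapy_rows_on_or_after_wlst_day(self, small_cohort):
        cohort, _, _ = small_cohort
        merged = cohort.therapy.merge(
            cohort.static[["patient_id", "wlst_day"]], on="patient_id"
        )
        has = merged["wlst_day"].notna()
        assert (merged.loc[has, "day"] < merged.loc[has, "wlst_day"]).all()


class TestGroundTruthConsistency:
    def test_refractory_label_matches_burden_exceeding_threshold(self, small_cohort):
        cohort, truth, cfg = small_cohort
        peak = truth.burden.groupby("patient_id")["burden"].max()
        want = peak > cfg.refractory_burden_threshold
        got = truth.refractory.reindex(peak.index)
        # burden relief after craniectomy can only lower post-DC burden,
        # never create a refractory label
        assert (got[want.index] | ~want).all() or (got == want).all()

    def test_truth_daily_scores_match_rescoring_the_therapy_table(self, small_cohort):
        cohort, truth, _ = small_cohort
        configs = scales.load_scale_configs()
        ther = scales.apply_dc_carryforward(cohort.therapy)
        scored = scales.score_table(ther, configs["TIL"])
        merged = truth.daily.merge(
            scored[["patient_id", "day", "value"]], on=["patient_id", "day"]
        )
        np.testing.assert_array_equal(
            merged["til24"].to_numpy(float), merged["value"].to_numpy(float)
        )

    def test_last_resort_dc_recorded_on_index_day_only(self, small_cohort):
        cohort, _, _ = small_cohort
        dcr = cohort.therapy[cohort.therapy["dc_refractory"] == 1]
        assert (dcr.groupby("patient_id").size() == 1).all()
        assert (dcr["dc"] == 1).all()

    def test_ladder_boundaries_exposed_as_truth(self, small_cohort):
        _, truth, _ = small_cohort
        b = truth.tilbasic_boundaries
        assert b[1] == 1 and b[2] == 3 and b[3] == 7
        assert sorted(b) == [1, 2, 3, 4]

    def test_within_patient_regression_recovers_coupling_beta(self):
        """Empirical ICP-on-TIL slope matches the generator's coupling."""
        cfg = GeneratorConfig.for_n(300)  # ~2000 patient-days
        cohort, truth = generate_cohort(cfg, seed=13)
        d = truth.daily
        res = lmer_beta(d["icp24"], d["day"], d["til24"], d["patient_id"])
        assert res.ci_low <= truth.coupling_beta <= res.ci_high
        assert res.beta == pytest.approx(truth.coupling_beta, abs=0.05)


class TestStructure:
    def test_til_max_negatively_correlated_with_gcs(self, small_cohort):
        cohort, _, _ = small_cohort
        daily = build_daily_table(cohort)
        summ = patient_summaries(daily)
        st = cohort.static.merge(summ, on="patient_id")
        rho = spearman(st["til_max"], st["gcs_baseline"]).value
        assert rho < -0.2

    def test_icp_concern_more_coupled_to_daily_score_than_cpp_concern(self, small_cohort):
        cohort, _, _ = small_cohort
        daily = build_daily_table(cohort)
        r_icp = rm_corr(daily["patient_id"], daily["til_24"], daily["icp_concern"]).value
        r_cpp = rm_corr(daily["patient_id"], daily["til_24"], daily["cpp_concern"]).value
        assert r_icp > r_cpp

    def test_staircase_ordering_of_item_onsets(self, small_cohort):
        """Median modality scores activate in the configured ladder order
        as the daily TIL stratum increases."""
        cohort, _, _ = small_cohort
        # therapy as initiated: carried-forward craniectomy days would
        # blur the onset strata with post-operative de-escalated days
        ther = cohort.therapy
        configs = scales.load_scale_configs()
        til = scales.score_table(ther, configs["TIL"])["value"]
        onsets = {}
        for item in scales.ITEM_COLUMNS:
            single = {
                i: (configs["TIL"].subitem_scores.get(item, {}) if i == item else {})
                for i in scales.ITEM_COLUMNS
            }
            cfg_i = scales.ScaleConfig(
                name=item, subitem_scores=single,
                aggregation="sum_of_item_maxima", max_total=0,
            )
            iscore = scales.score_table(ther, cfg_i)["value"]
            med = pd.DataFrame({"til": til, "s": iscore}).groupby("til")["s"].median()
            active = med[med > 0]
            if len(active):
                modality = MODALITY_OF_ITEM[item]
                onset = float(active.index.min())
                onsets[modality] = min(onset, onsets.get(modality, np.inf))
        observed_order = [m for m in STAIRCASE if m in onsets]
        onset_values = [onsets[m] for m in observed_order]
        assert all(a <= b for a, b in zip(onset_values, onset_values[1:])), onsets

    def test_prognosis_block_monotone_and_in_unit_interval(self, small_cohort):
        cohort, _, _ = small_cohort
        cols = [f"pr_gose_gt{k}" for k in (1, 3, 4, 5, 6, 7)]
        prog = cohort.static[cols].to_numpy(float)
        assert np.nanmin(prog) >= 0 and np.nanmax(prog) <= 1
        assert (np.diff(prog, axis=1) <= 1e-9).all()

    def test_center_propensity_knob_drives_csf_variability(self):
        """Raising the center-level CSF propensity spread increases the
        cross-center variability of CSF drainage use."""

        def csf_spread(center_sd):
            cfg = GeneratorConfig.for_n(400, n_centers=10, center_sd_csf=center_sd)
            cohort, _ = generate_cohort(cfg, seed=71)
            merged = cohort.therapy.merge(
                cohort.static[["patient_id", "center_id"]], on="patient_id"
            )
            return (
                merged.groupby("center_id")["csf_drainage"]
                .apply(lambda s: (s != "none").mean())
                .std()
            )

        assert csf_spread(2.5) > csf_spread(0.0)


class TestMissingness:
    def test_zero_rates_leave_cohort_unchanged(self, small_cohort):
        cohort, _, _ = small_cohort
        cfg = GeneratorConfig.for_n(
            120,
            missing_rate_static=0.0,
            missing_rate_daily=0.0,
            missing_rate_concern=0.0,
            missing_rate_physio=0.0,
            hr_day1_drop_rate=0.0,
        )
        out = inject_missingness(cohort, cfg, seed=1)
        for name in ("static", "therapy", "physio", "concerns"):
            pd.testing.assert_frame_equal(getattr(out, name), getattr(cohort, name))

    def test_daily_masking_rate_near_configured_value(self):
        cfg = GeneratorConfig.for_n(873)
        cohort, _ = generate_cohort(cfg, seed=61)
        masked = inject_missingness(cohort, cfg, seed=61)
        frac = masked.therapy["sedation"].isna().mean()
        assert frac == pytest.approx(0.024, abs=0.015)

    def test_day1_hr_stream_dropped_at_elevated_rate(self):
        cfg = GeneratorConfig.for_n(400)
        cohort, _ = generate_cohort(cfg, seed=62)
        masked = inject_missingness(cohort, cfg, seed=62)
        hr = masked.physio[masked.physio["stream"] == "HR"]
        full_hr = cohort.physio[cohort.physio["stream"] == "HR"]
        day = (hr["timestamp_s"] // 86400).astype(int) + 1
        full_day = (full_hr["timestamp_s"] // 86400).astype(int) + 1
        had_day1 = full_hr.loc[full_day == 1, "patient_id"].nunique()
        kept_day1 = hr.loc[day == 1, "patient_id"].nunique()
        assert 1 - kept_day1 / had_day1 == pytest.approx(0.67, abs=0.12)

    def test_masking_independent_of_masked_value_given_observables(self):
        """MAR diagnostic: within center, the true (pre-mask) value does
        not predict whether a daily assessment was masked."""
        cfg = GeneratorConfig.for_n(873, missing_rate_daily=0.1)
        cohort, truth = generate_cohort(cfg, seed=63)
        masked = inject_missingness(cohort, cfg, seed=63)
        ind = masked.therapy["sedation"].isna().astype(float)
        merged = pd.DataFrame(
            {
                "patient_id": masked.therapy["patient_id"],
                "day": masked.therapy["day"],
                "masked": ind,
            }
        ).merge(truth.daily[["patient_id", "day", "til24"]], on=["patient_id", "day"])
        merged = merged.merge(
            cohort.static[["patient_id", "center_id"]], on="patient_id"
        )
        # partial correlation of masking with the true value, net of center
        import statsmodels.api as sm

        centers = pd.get_dummies(merged["center_id"], drop_first=True).astype(float)
        X = sm.add_constant(
            np.column_stack([merged["til24"].to_numpy(float), centers.to_numpy()])
        )
        fit = sm.OLS(merged["masked"].to_numpy(), X).fit()
        tval = fit.tvalues[1]
        assert abs(tval) < 3.0
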