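"""Statistical pipeline: scale choice, contrasts, BCa, effect sizes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from judoperf.dataset import StudyDataset
from judoperf.errors import DesignError
from judoperf.inference import (
    AnalysisConfig,
    adjusted_contrast,
    bca_bootstrap_ci,
    bca_interval,
    bootstrap_contrast_ci,
    choose_scale,
    classify_effect_size,
    fit_adjusted_model,
    geometric_summary,
    pooled_baseline_sd,
    run_outcome_analysis,
    standardized_mean_difference,
)
from judoperf.synthetic import default_study_config, null_study_config, simulate_study


class TestChooseScale:
    def test_additive_noise_keeps_raw(self):
        data, _ = simulate_study(null_study_config(seed=1, outcomes=("jump_height_cm",)))
        fit = fit_adjusted_model(data, "jump_height_cm", "raw")
        assert choose_scale(fit) == "raw"

    def test_multiplicative_noise_selects_log(self):
        from judoperf.synthetic import OutcomeSpec

        cfg = default_study_config(seed=2, n_per_group=(100, 100))
        spec = OutcomeSpec("accel_peak", "log", 24.0, 2.5)  # strongly multiplicative
        cfg = cfg.replace(outcome_specs={"accel_peak": spec})
        data, _ = simulate_study(cfg)
        fit = fit_adjusted_model(data, "accel_peak", "raw")
        assert choose_scale(fit) == "log"

    def test_nonpositive_values_fall_back_to_raw(self):
        data, _ = simulate_study(null_study_config(seed=3, outcomes=("jump_height_cm",)))
        frame = data.frame.copy()
        # heteroscedastic but with a zero: log is illegal
        sub = frame["outcome"] == "jump_height_cm"
        vals = frame.loc[sub, "value"].to_numpy()
        rng = np.random.default_rng(0)
        vals = vals + np.abs(vals) * rng.normal(0, 0.4, size=vals.size)
        vals[0] = 0.0
        frame.loc[sub, "value"] = vals
        data2 = StudyDataset(frame=frame, scales={})
        fit = fit_adjusted_model(data2, "jump_height_cm", "raw")
        with pytest.warns(UserWarning, match="non-positive"):
            # threshold forced below any correlation: log is indicated but illegal
            assert choose_scale(fit, threshold=-1.1) == "raw"


class TestAdjustedModel:
    def test_null_simulation_estimates_near_zero(self):
        """Across null replicates, contrasts rarely exceed 2 SE (no bias)."""
        exceed = total = 0
        for seed in range(10):
            data, _ = simulate_study(null_study_config(seed=seed))
            fit = fit_adjusted_model(data, "jump_height_cm", "raw")
            for tp in ("Post-0", "Post-1", "Post-2"):
                con = adjusted_contrast(fit, tp)
                exceed += abs(con.estimate) > 2.0 * con.se
                total += 1
        assert total == 30
        assert exceed <= 5  # ~5% expected under the null

    def test_injected_raw_effect_recovered_at_large_n(self):
        ests = []
        for seed in range(20):
            cfg = default_study_config(seed=100 + seed, n_per_group=(200, 200))
            cfg = cfg.replace(outcome_specs={"jump_height_cm": cfg.outcome_specs["jump_height_cm"]})
            data, _ = simulate_study(cfg)
            fit = fit_adjusted_model(data, "jump_height_cm", "raw")
            ests.append(adjusted_contrast(fit, "Post-0").estimate)
        assert np.mean(ests) == pytest.approx(3.22, abs=0.25)

    def test_injected_log_ratio_recovered_at_large_n(self):
        cfg = default_study_config(seed=21, n_per_group=(200, 200))
        cfg = cfg.replace(outcome_specs={"max2_G": cfg.outcome_specs["max2_G"]})
        data, _ = simulate_study(cfg)
        fit = fit_adjusted_model(data, "max2_G", "log")
        con = adjusted_contrast(fit, "Post-1")
        assert con.ratio == pytest.approx(0.73, rel=0.05)

    def test_single_subject_group_rejected(self):
        data, _ = simulate_study(null_study_config(seed=4))
        frame = data.frame
        keep = frame["subject"] != "S001"
        hyp = sorted(frame.loc[frame["group"] == "hypoxia", "subject"].unique())
        small = frame[frame["subject"].isin(hyp[:1] + list(
            frame.loc[frame["group"] == "normoxia", "subject"].unique()))]
        with pytest.raises(DesignError):
            fit_adjusted_model(StudyDataset(frame=small, scales={}), "jump_height_cm", "raw")


class TestBcaBootstrap:
    def test_constant_statistic_zero_width(self):
        with pytest.warns(UserWarning):
            lo, hi = bca_interval(1.0, np.ones(100), np.ones(10))
        assert lo == hi == 1.0

    def test_symmetric_case_matches_percentile(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=50)
        boot = np.array([rng.choice(x, 50).mean() for _ in range(2000)])
        jack = np.array([np.delete(x, i).mean() for i in range(50)])
        lo, hi = bca_interval(x.mean(), boot, jack, 0.90)
        plo, phi = np.quantile(boot, [0.05, 0.95])
        width = phi - plo
        assert lo == pytest.approx(plo, abs=0.10 * width)
        assert hi == pytest.approx(phi, abs=0.10 * width)

    def test_matches_scipy_bca(self):
        """Same replicate logic as scipy.stats.bootstrap's BCa on plain means."""
        rng = np.random.default_rng(5)
        x = rng.exponential(size=40)  # skewed so the correction matters
        res = stats.bootstrap((x,), np.mean, n_resamples=4000, confidence_level=0.90,
                              method="BCa", random_state=np.random.default_rng(1))
        rng2 = np.random.default_rng(2)
        boot = np.array([rng2.choice(x, x.size).mean() for _ in range(4000)])
        jack = np.array([np.delete(x, i).mean() for i in range(x.size)])
        lo, hi = bca_interval(x.mean(), boot, jack, 0.90)
        width = res.confidence_interval.high - res.confidence_interval.low
        assert lo == pytest.approx(res.confidence_interval.low, abs=0.08 * width)
        assert hi == pytest.approx(res.confidence_interval.high, abs=0.08 * width)

    def test_generic_and_fast_paths_agree_in_distribution(self):
        """Model-refit statistic through the generic API stays near the fast path."""
        data, _ = simulate_study(null_study_config(seed=9))

        def statistic(ds):
            fit = fit_adjusted_model(ds, "jump_height_cm", "raw")
            return adjusted_contrast(fit, "Post-0").estimate

        lo_g, hi_g = bca_bootstrap_ci(data, statistic, B=60, seed=3)
        lo_f, hi_f, _ = bootstrap_contrast_ci(data, "jump_height_cm", "Post-0", B=400, seed=3)
        # different resample streams: agreement only to bootstrap noise
        width = hi_f - lo_f
        assert lo_g == pytest.approx(lo_f, abs=0.5 * width)
        assert hi_g == pytest.approx(hi_f, abs=0.5 * width)


class TestEffectSizes:
    @pytest.mark.parametrize(
        "args, expected",
        [((5.02, 13, 5.97, 11), 5.472), ((0.31, 13, 0.24, 11), 0.2804), ((3.0, 5, 3.0, 9), 3.0)],
    )
    def test_pooled_baseline_sd(self, args, expected):
        assert pooled_baseline_sd(*args) == pytest.approx(expected, abs=5e-4)

    def test_pooled_sd_needs_two_per_group(self):
        with pytest.raises(ValueError):
            pooled_baseline_sd(1.0, 1, 1.0, 5)

    @pytest.mark.parametrize(
        "effect, sd1, sd2, scale, expected",
        [
            (3.22, 5.02, 5.97, "raw", 0.59),
            (0.73, 1.31, 1.35, "log", -1.11),
            (0.0, 5.0, 5.0, "raw", 0.0),
            (1.0, 1.3, 1.3, "log", 0.0),
        ],
    )
    def test_smd_reproduces_printed_values(self, effect, sd1, sd2, scale, expected):
        es = standardized_mean_difference(effect, sd1, 13, sd2, 11, scale)
        assert round(es, 2) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "es, label",
        [
            (0.1, "trivial"), (-0.1, "trivial"), (0.2, "small"), (0.59, "small"),
            (-1.11, "moderate"), (1.2, "large"), (-1.99, "large"), (2.0, "very large"),
            (4.0, "nearly perfect"), (7.5, "nearly perfect"),
        ],
    )
    def test_magnitude_labels(self, es, label):
        assert classify_effect_size(es) == label

    def test_nonfinite_es_rejected(self):
        with pytest.raises(ValueError):
            classify_effect_size(np.nan)

    @settings(max_examples=50, deadline=None)
    @given(a=st.floats(-6, 6), b=st.floats(-6, 6))
    def test_label_is_monotone_in_magnitude(self, a, b):
        order = ["trivial", "small", "moderate", "large", "very large", "nearly perfect"]
        la, lb = classify_effect_size(a), classify_effect_size(b)
        if abs(a) <= abs(b):
            assert order.index(la) <= order.index(lb)


class TestGeometricSummary:
    def test_constant_sample(self):
        gm, gsd = geometric_summary([np.e, np.e, np.e])
        assert gm == pytest.approx(np.e)
        assert gsd == pytest.approx(1.0)

    def test_two_point_sample(self):
        gm, gsd = geometric_summary([2.0, 8.0])
        assert gm == pytest.approx(4.0)
        assert gsd == pytest.approx(np.exp(np.std(np.log([2.0, 8.0]), ddof=1)))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            geometric_summary([2.0, -1.0])


class TestRunOutcomeAnalysis:
    def test_full_study_rows_satisfy_invariants(self, study_with_effects):
        data, _ = study_with_effects
        cfg = AnalysisConfig(seed=17, bootstrap_reps=100)
        for outcome in ("jump_height_cm", "max2_G"):
            effects = run_outcome_analysis(data, outcome, cfg)
            assert [e.timepoint for e in effects] == ["Post-0", "Post-1", "Post-2"]
            for e in effects:
                lo, hi = e.ci90
                assert lo <= hi
                if e.scale == "log":
                    assert 0 < lo and 0 < e.estimate
                assert e.es_label == classify_effect_size(e.es)
                assert 0 <= e.p <= 1

    def test_log_outcome_auto_detected_and_exponentiated(self, study_with_effects):
        data, _ = study_with_effects
        effects = run_outcome_analysis(data, "max3_G", AnalysisConfig(seed=23, bootstrap_reps=100))
        assert all(e.scale == "log" for e in effects)
        assert all(e.estimate > 0 for e in effects)

    def test_missing_outcome_error_names_it(self, study_with_effects):
        data, _ = study_with_effects
        with pytest.raises(KeyError, match="no_such_outcome"):
            run_outcome_analysis(data, "no_such_outcome", AnalysisConfig(seed=1))

    def test_scale_coherence_ratio_equals_geometric_mean_ratio(self, study_with_effects):
        """exp(log-scale contrast) equals the adjusted geometric-mean ratio."""
        data, _ = study_with_effects
        fit = fit_adjusted_model(data, "max2_G", "log")
        con = adjusted_contrast(fit, "Post-1")
        # EMM difference on the log scale, exponentiated
        assert con.ratio == pytest.approx(np.exp(con.estimate), rel=1e-12)
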