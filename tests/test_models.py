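"""Closed-form Bayesian machinery against independent numerical oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bayestime import (
    GaussianBelief,
    ct_slope,
    ct_wf_curve,
    estimate_prior_width,
    expected_reproduction_slope,
    likelihood_width,
    mle_combine,
    mle_weights,
    posterior,
    predict_model1,
    predict_model2,
    predict_optimal_wf,
)
from _oracles import gaussian_product_peak_width


class TestCueCombination:
    def test_equal_widths_split_evenly(self):
        w = mle_weights(100.0, 100.0)
        assert w.w_a == pytest.approx(0.5)
        assert w.w_v == pytest.approx(0.5)

    def test_weights_follow_precision(self):
        w = mle_weights(100.0, 200.0)
        assert w.w_a == pytest.approx(0.8)
        assert w.w_v == pytest.approx(0.2)

    def test_unreliable_cue_loses_weight(self):
        w = mle_weights(100.0, 1e9)
        assert w.w_a == pytest.approx(1.0, abs=1e-10)

    def test_combine_example(self):
        c = mle_combine(GaussianBelief(600, 100), GaussianBelief(700, 200))
        assert c.mean_ms == pytest.approx(620.0)
        assert c.sd_ms == pytest.approx(89.44271909999159)

    def test_combine_identical_beliefs(self):
        c = mle_combine(GaussianBelief(640, 80), GaussianBelief(640, 80))
        assert c.mean_ms == pytest.approx(640.0)
        assert c.sd_ms == pytest.approx(80 / np.sqrt(2))

    @given(
        st.floats(20, 400), st.floats(20, 400),
        st.floats(300, 1000), st.floats(300, 1000),
    )
    @settings(max_examples=50, derandomize=True)
    def test_combined_width_below_both_inputs(self, sa, sv, ma, mv):
        c = mle_combine(GaussianBelief(ma, sa), GaussianBelief(mv, sv))
        assert c.sd_ms < min(sa, sv)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            mle_weights(0.0, 100.0)


class TestOptimalWeberFraction:
    def test_equal_inputs(self):
        assert predict_optimal_wf(0.17, 0.17) == pytest.approx(0.17 / np.sqrt(2))

    def test_single_cue_limit(self):
        assert predict_optimal_wf(0.17, 1e9) == pytest.approx(0.17, rel=1e-6)

    def test_never_exceeds_smaller_input(self):
        rng = np.random.default_rng(1)
        for wf_v, wf_a in rng.uniform(0.02, 0.6, size=(100, 2)):
            assert predict_optimal_wf(wf_v, wf_a) <= min(wf_v, wf_a)

    def test_consistent_with_combination_at_any_duration(self):
        # combining widths WF_V*D and WF_A*D implies the same audiovisual WF
        # regardless of D (scale invariance of scalar timing noise)
        for d in (100.0, 640.0, 1500.0):
            c = mle_combine(GaussianBelief(d, 0.23 * d), GaussianBelief(d, 0.11 * d))
            assert c.sd_ms / d == pytest.approx(predict_optimal_wf(0.11, 0.23), rel=1e-12)


class TestPosterior:
    def test_no_pull_at_prior_mean(self):
        p = posterior(GaussianBelief(640, 100), GaussianBelief(640, 238))
        assert p.mean_ms == pytest.approx(640.0)

    def test_pull_toward_prior_example(self):
        p = posterior(GaussianBelief(450, 76.5), GaussianBelief(675, 238))
        assert p.mean_ms == pytest.approx(471.07, abs=0.01)

    def test_flat_prior_limit(self):
        p = posterior(GaussianBelief(500, 100), GaussianBelief(675, 1e9))
        assert p.mean_ms == pytest.approx(500.0, abs=1e-6)

    def test_matches_grid_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            ml, sl = rng.uniform(300, 1000), rng.uniform(20, 400)
            mp, sp = rng.uniform(400, 900), rng.uniform(50, 500)
            peak, width = gaussian_product_peak_width(ml, sl, mp, sp)
            p = posterior(GaussianBelief(ml, sl), GaussianBelief(mp, sp))
            assert abs(p.mean_ms - peak) / abs(peak) < 1e-6
            assert abs(p.sd_ms - width) / width < 1e-6

    def test_likelihood_width_scaling(self):
        assert likelihood_width(0.17, 640) == pytest.approx(108.8)
        assert likelihood_width(0.17, 1280) == pytest.approx(2 * 108.8)
        with pytest.raises(ValueError):
            likelihood_width(0.17, 0.0)


class TestCentralTendencySlope:
    def test_equal_widths_give_half(self):
        assert ct_slope(100.0, 100.0) == pytest.approx(0.5)

    def test_reference_value(self):
        assert ct_slope(238.0, 108.8) == pytest.approx(0.827, abs=5e-4)

    def test_decreasing_in_likelihood_width(self):
        widths = np.linspace(10, 500, 30)
        slopes = [ct_slope(238.0, w) for w in widths]
        assert np.all(np.diff(slopes) < 0)

    @given(st.floats(50, 500), st.floats(0.05, 0.4))
    @settings(max_examples=100, derandomize=True)
    def test_prior_width_round_trip(self, prior_sd, wf):
        dbar = 653.5
        ct = ct_slope(prior_sd, likelihood_width(wf, dbar))
        assert estimate_prior_width(ct, wf, dbar) == pytest.approx(prior_sd, rel=1e-9)

    def test_inverse_reference_value(self):
        assert estimate_prior_width(0.8271438, 0.17, 640) == pytest.approx(238.0, abs=0.01)

    def test_equal_width_point(self):
        assert estimate_prior_width(0.5, 0.17, 640) == pytest.approx(0.17 * 640)

    @pytest.mark.parametrize("ct", [1.0, 1.3, 0.0, -0.2])
    def test_unidentifiable_slopes_rejected(self, ct):
        with pytest.raises(ValueError, match="prior width"):
            estimate_prior_width(ct, 0.17, 640)


class TestArchitecturePredictions:
    def test_model1_equal_parameters_reduce_to_unisensory_slope(self, design):
        # with fixed likelihood widths and identical modalities, combining
        # two equally-shrunk posteriors returns the common unisensory slope
        dbar = design.mean_duration_ms
        prior = GaussianBelief(dbar, 238.0)
        m1 = predict_model1(
            0.17, 0.17, prior, prior, design.reproduction_levels_ms,
            effective_duration_ms=dbar,
        )
        assert m1.predicted_av_slope == pytest.approx(
            ct_slope(238.0, likelihood_width(0.17, dbar)), rel=1e-9
        )

    def test_flat_priors_remove_bias(self, design):
        dbar = design.mean_duration_ms
        flat = GaussianBelief(dbar, 1e8)
        m1 = predict_model1(0.17, 0.25, flat, flat, design.reproduction_levels_ms)
        assert m1.predicted_av_slope == pytest.approx(1.0, abs=1e-5)
        m2 = predict_model2(0.17, 0.25, 1e8, 1e8, design.reproduction_levels_ms, dbar)
        assert m2.predicted_av_slope == pytest.approx(1.0, abs=1e-5)

    def test_perfect_evidence_limit(self, design):
        m2 = predict_model2(
            0.17, 1e-4, 238.0, 238.0, design.reproduction_levels_ms,
            design.mean_duration_ms,
        )
        assert m2.predicted_av_slope == pytest.approx(1.0, abs=1e-3)

    def test_effective_duration_reference_values(self, design):
        # evaluating both architectures at one effective duration (640 ms):
        # combination-first yields a weaker central tendency (larger slope)
        prior = GaussianBelief(640.0, 238.0)
        m1 = predict_model1(
            0.17, 0.17, prior, prior, design.reproduction_levels_ms,
            effective_duration_ms=640.0,
        )
        m2 = predict_model2(
            0.17, 0.17, 238.0, 238.0, design.reproduction_levels_ms, 640.0,
            effective_duration_ms=640.0,
        )
        assert m1.predicted_av_slope == pytest.approx(0.827, abs=5e-4)
        assert m2.predicted_av_slope == pytest.approx(0.905, abs=5e-4)

    def test_model2_slope_never_below_model1(self, design):
        # combining first shrinks the likelihood before the single prior
        # integration, so the prediction is always less biased
        dbar = design.mean_duration_ms
        durations = design.reproduction_levels_ms
        for wf_v in np.geomspace(0.05, 0.5, 8):
            for wf_a in np.geomspace(0.05, 0.5, 8):
                for sp in (100.0, 238.0, 500.0):
                    prior = GaussianBelief(dbar, sp)
                    m1 = predict_model1(wf_v, wf_a, prior, prior, durations)
                    m2 = predict_model2(wf_v, wf_a, sp, sp, durations, dbar)
                    assert m2.predicted_av_slope >= m1.predicted_av_slope - 1e-12

    def test_slope_in_unit_interval(self, design):
        m2 = predict_model2(0.3, 0.2, 150.0, 300.0, design.reproduction_levels_ms,
                            design.mean_duration_ms)
        assert 0.0 < m2.predicted_av_slope <= 1.0
        assert 0.0 < m2.predicted_av_wf < min(0.3, 0.2)


class TestCtWfCurves:
    def test_wider_prior_weakens_central_tendency(self):
        grid = np.linspace(0.05, 0.4, 20)
        c100 = dict(ct_wf_curve(100.0, grid, 640.0))
        c500 = dict(ct_wf_curve(500.0, grid, 640.0))
        for wf in grid:
            assert c500[wf] > c100[wf]

    def test_curves_decrease_in_wf(self):
        for sp in (100.0, 300.0, 500.0):
            slopes = [s for _, s in ct_wf_curve(sp, np.linspace(0.05, 0.4, 20), 640.0)]
            assert np.all(np.diff(slopes) < 0)

    def test_prior_width_ranking_at_common_wf(self):
        # at a matched Weber fraction (~0.17) three conditions with prior
        # widths 177, 238 and 282 ms order their slopes the same way
        slopes = {
            sp: ct_slope(sp, likelihood_width(0.17, 640.0)) for sp in (177.0, 282.0, 238.0)
        }
        assert slopes[177.0] < slopes[238.0] < slopes[282.0]


class TestExpectedReproductionSlope:
    def test_matches_grid_oracle(self, design):
        from _oracles import oracle_reproduction_slope

        dbar = design.mean_duration_ms
        for wf, sp in [(0.1, 177.0), (0.17, 238.0), (0.25, 282.0)]:
            closed = expected_reproduction_slope(wf, sp, dbar, design.reproduction_levels_ms)
            grid = oracle_reproduction_slope(wf, sp, dbar, design.reproduction_levels_ms)
            assert closed == pytest.approx(grid, rel=1e-9)
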