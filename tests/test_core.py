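"""Gaussian fusion core: closed forms, limits, and oracle equivalence."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pelbayes import (
    GaussianBelief,
    LineStimulus,
    ModelParams,
    a_of_l,
    combine_gaussians,
    posterior,
    predict_pel,
    predict_pel_varying,
    visual_likelihood,
)

from conftest import (
    LONG_LEN,
    PRIOR_MEAN,
    PRIOR_SD,
    SHORT_LEN,
    SIGMA_LONG,
    SIGMA_SHORT,
    grid_fusion,
)


class TestCombineGaussians:
    def test_two_identical_beliefs_halve_the_variance(self):
        b = GaussianBelief(3.0, 4.0)
        out = combine_gaussians([b, b])
        assert out.mean == pytest.approx(3.0)
        assert out.variance == pytest.approx(2.0)

    def test_prior_plus_long_line_matches_grid_oracle(self):
        """Fusion of the dark prior with one long-line likelihood at 10 deg."""
        prior = GaussianBelief(PRIOR_MEAN, PRIOR_SD**2)
        like = GaussianBelief(10.0, SIGMA_LONG**2)
        out = combine_gaussians([prior, like])
        # frozen from the grid oracle (step 0.001 deg over -90..90)
        assert out.mean == pytest.approx(0.3232 * 10.0 + 0.6768 * PRIOR_MEAN, abs=2e-3)
        g_mean, g_var = grid_fusion([prior.mean, like.mean], [prior.variance, like.variance])
        assert out.mean == pytest.approx(g_mean, abs=1e-9)
        assert out.variance == pytest.approx(g_var, abs=1e-7)

    def test_uninformative_input_leaves_belief_unchanged(self):
        prior = GaussianBelief(PRIOR_MEAN, PRIOR_SD**2)
        out = combine_gaussians([prior, GaussianBelief.uninformative()])
        assert out.mean == pytest.approx(prior.mean)
        assert out.variance == pytest.approx(prior.variance)

    def test_empty_and_all_uninformative_raise(self):
        with pytest.raises(ValueError):
            combine_gaussians([])
        with pytest.raises(ValueError, match="uninformative"):
            combine_gaussians([GaussianBelief.uninformative()] * 2)

    @settings(derandomize=True, max_examples=50)
    @given(
        means=st.lists(st.floats(-30, 30), min_size=1, max_size=4),
        sds=st.data(),
    )
    def test_fusion_never_loses_information_and_stays_bounded(self, means, sds):
        variances = [
            sds.draw(st.floats(0.25, 64.0)) for _ in means
        ]
        beliefs = [GaussianBelief(m, v) for m, v in zip(means, variances)]
        out = combine_gaussians(beliefs)
        assert out.variance <= min(variances) + 1e-12
        assert min(means) - 1e-9 <= out.mean <= max(means) + 1e-9


class TestVisualLikelihood:
    def test_single_line_is_identity(self, published_params):
        out = visual_likelihood([LineStimulus(20.0, LONG_LEN)], published_params)
        assert out.mean == pytest.approx(20.0)
        assert out.variance == pytest.approx(SIGMA_LONG**2)

    def test_symmetric_pitches_average(self, published_params):
        out = visual_likelihood(
            [LineStimulus(-10.0, LONG_LEN), LineStimulus(30.0, LONG_LEN)],
            published_params,
        )
        assert out.mean == pytest.approx(10.0)

    def test_equal_pitch_pair_halves_variance_and_matches_oracle(self, published_params):
        out = visual_likelihood(
            [LineStimulus(20.0, SHORT_LEN), LineStimulus(20.0, SHORT_LEN)],
            published_params,
        )
        assert out.mean == pytest.approx(20.0)
        assert out.variance == pytest.approx(SIGMA_SHORT**2 / 2)
        g_mean, g_var = grid_fusion([20.0, 20.0], [SIGMA_SHORT**2] * 2)
        assert out.mean == pytest.approx(g_mean, abs=1e-7)
        assert out.variance == pytest.approx(g_var, abs=1e-6)

    def test_unknown_length_raises_with_known_lengths(self, published_params):
        with pytest.raises(KeyError, match="no calibrated sigma_vi"):
            visual_likelihood([LineStimulus(0.0, 33.0)], published_params)

    def test_empty_stimulus_list_raises(self, published_params):
        with pytest.raises(ValueError):
            visual_likelihood([], published_params)


class TestPredictPel:
    def test_no_stimuli_returns_prior_mean(self, published_params):
        assert predict_pel([], published_params) == pytest.approx(PRIOR_MEAN)

    def test_two_long_lines_at_20_degrees(self, published_params):
        """Frozen against the grid oracle: prior x two long-line likelihoods."""
        stim = [LineStimulus(20.0, LONG_LEN)] * 2
        value = predict_pel(stim, published_params)
        assert value == pytest.approx(9.45, abs=0.005)
        g_mean, _ = grid_fusion(
            [PRIOR_MEAN, 20.0, 20.0],
            [PRIOR_SD**2, SIGMA_LONG**2, SIGMA_LONG**2],
        )
        assert value == pytest.approx(g_mean, abs=1e-9)

    @pytest.mark.parametrize(
        "length,sigma", [(SHORT_LEN, SIGMA_SHORT), (LONG_LEN, SIGMA_LONG)]
    )
    def test_single_line_sweep_slope_is_relative_precision(
        self, published_params, length, sigma
    ):
        pitches = np.arange(-30.0, 31.0, 10.0)
        pels = [
            predict_pel([LineStimulus(p, length)], published_params) for p in pitches
        ]
        fit = stats.linregress(pitches, pels)
        expected = PRIOR_SD**2 / (PRIOR_SD**2 + sigma**2)
        assert fit.slope == pytest.approx(expected, abs=1e-12)

    def test_prediction_bounded_by_prior_and_pitches(self, published_params):
        value = predict_pel([LineStimulus(30.0, SHORT_LEN)], published_params)
        assert PRIOR_MEAN < value < 30.0

    def test_mixed_lengths_on_per_length_path_raise(self, published_params):
        stim = [LineStimulus(10.0, SHORT_LEN), LineStimulus(10.0, LONG_LEN)]
        with pytest.raises(ValueError, match="predict_pel_varying"):
            predict_pel(stim, published_params)


class TestLengthScaledPath:
    def make_params(self, sigma_vl: float) -> ModelParams:
        return ModelParams(
            prior=GaussianBelief(PRIOR_MEAN, PRIOR_SD**2), sigma_vl=sigma_vl
        )

    def test_consistent_with_per_length_path_for_equal_lengths(self, published_params):
        sigma_vl = SIGMA_LONG * math.sqrt(LONG_LEN)
        scaled = self.make_params(sigma_vl)
        stim = [LineStimulus(15.0, LONG_LEN), LineStimulus(-5.0, LONG_LEN)]
        assert predict_pel_varying(stim, scaled) == pytest.approx(
            predict_pel(stim, published_params), abs=1e-9
        )

    def test_mixed_lengths_lie_between_single_line_predictions_and_pitch(self):
        scaled = self.make_params(24.08)
        theta = 20.0
        short_only = predict_pel_varying([LineStimulus(theta, SHORT_LEN)], scaled)
        long_only = predict_pel_varying([LineStimulus(theta, LONG_LEN)], scaled)
        both = predict_pel_varying(
            [LineStimulus(theta, SHORT_LEN), LineStimulus(theta, LONG_LEN)], scaled
        )
        assert min(short_only, long_only) < both < theta

    def test_zero_pitch_pair_matches_a_of_l_and_grid_oracle(self):
        scaled = self.make_params(24.08)
        stim = [LineStimulus(0.0, LONG_LEN), LineStimulus(0.0, LONG_LEN)]
        value = predict_pel_varying(stim, scaled)
        assert value == pytest.approx(a_of_l(LONG_LEN, 2, scaled), abs=1e-12)
        sd = 24.08 / math.sqrt(LONG_LEN)
        g_mean, _ = grid_fusion([PRIOR_MEAN, 0.0, 0.0], [PRIOR_SD**2, sd**2, sd**2])
        assert value == pytest.approx(g_mean, abs=1e-9)

    def test_requires_sigma_vl(self, published_params):
        with pytest.raises(ValueError, match="sigma_vl"):
            predict_pel_varying([LineStimulus(0.0, SHORT_LEN)], published_params)

    def test_a_of_l_limits(self):
        scaled = self.make_params(24.08)
        assert a_of_l(SHORT_LEN, 0, scaled) == pytest.approx(PRIOR_MEAN)
        assert a_of_l(1e9, 2, scaled) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("n", [1, 2, 3])
    @pytest.mark.parametrize("length", [SHORT_LEN, LONG_LEN, 30.0])
    def test_simplified_form_identical_to_full_fusion(self, n, length):
        """a(l) + sum(theta)/(k/l + n) must equal the posterior mean exactly."""
        scaled = self.make_params(24.08)
        k = scaled.k
        rng = np.random.default_rng(7)
        thetas = rng.uniform(-30, 30, size=n)
        simplified = a_of_l(length, n, scaled) + thetas.sum() / (k / length + n)
        stim = [LineStimulus(t, length) for t in thetas]
        assert predict_pel_varying(stim, scaled) == pytest.approx(simplified, abs=1e-9)


class TestPosterior:
    def test_variance_with_n_equal_cues(self, published_params):
        n = 3
        stim = [LineStimulus(5.0, LONG_LEN)] * n
        post = posterior(stim, published_params)
        expected = 1.0 / (1.0 / PRIOR_SD**2 + n / SIGMA_LONG**2)
        assert post.variance == pytest.approx(expected, abs=1e-12)

    def test_averaging_limit_small_noise(self):
        params = ModelParams(
            prior=GaussianBelief(PRIOR_MEAN, PRIOR_SD**2), sigma_vi={SHORT_LEN: 1e-4}
        )
        stim = [LineStimulus(10.0, SHORT_LEN), LineStimulus(20.0, SHORT_LEN)]
        assert predict_pel(stim, params) == pytest.approx(15.0, abs=1e-4)

    def test_prior_limit_large_noise(self):
        params = ModelParams(
            prior=GaussianBelief(PRIOR_MEAN, PRIOR_SD**2), sigma_vi={SHORT_LEN: 1e6}
        )
        stim = [LineStimulus(30.0, SHORT_LEN)]
        assert predict_pel(stim, params) == pytest.approx(PRIOR_MEAN, abs=1e-6)
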