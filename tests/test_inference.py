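"""Likelihood, goodness of fit, priors, and the ADVI optimizer."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fscvmodels import (
    PriorSpec,
    ReleaseModel,
    Trace,
    get_preset,
    log_likelihood,
    make_single_burst,
    r_squared,
)
from fscvmodels.inference import ParamPrior, _Bijection
from fscvmodels.synthetic import generate_trace

V = 0.05


class TestLogLikelihood:
    def test_perfect_prediction_value(self):
        y = np.array([0.1, 0.5, 1.2, 0.3])
        expected = y.size * np.log(1.0 / (V * np.sqrt(2 * np.pi)))
        assert log_likelihood(y, y, v=V) == pytest.approx(expected, rel=1e-12)

    def test_one_sd_miss_costs_half(self):
        y = np.zeros(10)
        yhat = y.copy()
        yhat[3] += V  # one sample off by exactly v
        assert log_likelihood(y, y, v=V) - log_likelihood(y, yhat, v=V) == pytest.approx(0.5)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            log_likelihood(np.array([]), np.array([]))

    def test_grid_mismatch_rejected(self):
        a = Trace(times=np.arange(0, 1.05, 0.1), values=np.zeros(11))
        b = Trace(times=np.arange(5, 6.05, 0.1), values=np.zeros(11))
        with pytest.raises(ValueError):
            log_likelihood(a, b)
        with pytest.raises(ValueError):
            log_likelihood(np.zeros(5), np.zeros(6))

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            log_likelihood(np.zeros(3), np.zeros(3), v=0.0)


class TestRSquared:
    def test_perfect_fit_is_one(self):
        y = np.array([0.0, 1.0, 2.0])
        assert r_squared(y, y) == 1.0

    def test_mean_prediction_is_zero(self):
        y = np.array([0.0, 1.0, 2.0])
        assert r_squared(y, np.full(3, y.mean())) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        assert r_squared(np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 3.0])) == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            r_squared(np.ones(5), np.zeros(5))


class TestPriorSpec:
    def test_unknown_parameter_rejected(self):
        with pytest.raises(KeyError):
            PriorSpec(free={"bogus": ParamPrior(1.0, 0.1, 0.0, 2.0)}, fixed={})

    def test_every_parameter_must_be_assigned(self):
        with pytest.raises(ValueError, match="neither free nor fixed"):
            PriorSpec(free={}, fixed={"da_p": 0.4})

    def test_free_and_fixed_must_not_overlap(self):
        spec = PriorSpec.from_preset(get_preset("WT-sweep1-S"))
        fixed = dict(spec.fixed)
        fixed["da_p"] = 0.4
        with pytest.raises(ValueError, match="both free and fixed"):
            PriorSpec(free=dict(spec.free), fixed=fixed)

    def test_from_preset_centers_on_published_values(self):
        spec = PriorSpec.from_preset(get_preset("WT-sweep1-S"), free=("da_p", "v_m"))
        assert spec.free["da_p"].mean == pytest.approx(0.420)
        assert spec.free["v_m"].mean == pytest.approx(4.8)
        assert spec.fixed["tau2"] == pytest.approx(15.0)
        assert spec.km == pytest.approx(0.2)  # the literature-consensus default

    def test_assemble_merges_free_and_fixed(self):
        spec = PriorSpec.from_preset(get_preset("WT-sweep1-S"), free=("da_p",))
        theta = spec.assemble(np.array([0.37]))
        assert theta["da_p"] == 0.37
        assert theta["v_m"] == pytest.approx(4.8)
        assert theta["km"] == pytest.approx(0.2)

    def test_prior_mean_must_sit_inside_bounds(self):
        with pytest.raises(ValueError):
            ParamPrior(mean=2.0, sd=0.1, lower=0.0, upper=1.0)


class TestBijections:
    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(z=st.floats(min_value=-20, max_value=20))
    def test_interval_transform_stays_inside_bounds(self, z):
        b = _Bijection(-0.05, 0.005)
        theta = b.forward(z)
        assert -0.05 <= theta <= 0.005

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(theta=st.floats(min_value=0.01, max_value=0.99))
    def test_interval_round_trip(self, theta):
        b = _Bijection(0.0, 1.0)
        assert b.forward(b.inverse(theta)) == pytest.approx(theta, rel=1e-6)

    def test_half_open_transform(self):
        b = _Bijection(0.5, None)
        assert b.forward(-30.0) >= 0.5
        assert b.forward(b.inverse(7.0)) == pytest.approx(7.0)


@pytest.fixture(scope="module")
def noiseless_trace():
    return generate_trace(model="sur", preset="WT-sweep1-S", noise_sd=0.0)


class TestADVIFit:
    def test_single_parameter_noiseless_recovery(self, noiseless_trace):
        """DA_P alone, prior centered off-truth: likelihood pulls it within 5%."""
        priors = PriorSpec.from_preset(
            get_preset("WT-sweep1-S"), free=("da_p",), center={"da_p": 0.6}, sd_frac=0.5
        )
        m = ReleaseModel(noiseless_trace, make_single_burst(5.0), priors=priors)
        res = m.fit(seed=3, max_iter=400)
        assert abs(res.params["da_p"] - 0.420) / 0.420 < 0.05
        assert res.rsquared > 0.99

    def test_posterior_means_respect_bounds(self, noiseless_trace):
        priors = PriorSpec.from_preset(get_preset("WT-sweep1-S"), free=("da_p", "v_m"))
        m = ReleaseModel(noiseless_trace, make_single_burst(5.0), priors=priors)
        res = m.fit(seed=5, max_iter=200)
        for name in res.params.index:
            lo, hi = res.fit_result.bounds[name]
            assert lo < res.params[name]
            assert hi is None or res.params[name] < hi
            assert res.bse[name] > 0.0

    def test_running_max_elbo_non_decreasing(self, noiseless_trace):
        priors = PriorSpec.from_preset(get_preset("WT-sweep1-S"), free=("da_p",))
        m = ReleaseModel(noiseless_trace, make_single_burst(5.0), priors=priors)
        res = m.fit(seed=1, max_iter=300)
        running_max = np.maximum.accumulate(res.elbo_trace)
        assert np.all(np.diff(running_max) >= 0.0)
        assert res.elbo_trace[-1] > res.elbo_trace[0]

    def test_non_convergence_is_reported_not_silent(self, noiseless_trace):
        priors = PriorSpec.from_preset(get_preset("WT-sweep1-S"), free=("da_p",))
        m = ReleaseModel(noiseless_trace, make_single_burst(5.0), priors=priors)
        with pytest.warns(RuntimeWarning, match="no ELBO plateau"):
            res = m.fit(seed=1, max_iter=50)  # far too few iterations
        assert not res.converged
        assert "no ELBO plateau" in res.fit_result.message

    def test_zero_signal_pushes_release_to_lower_bound(self):
        observed = Trace(times=np.arange(0, 12.1, 0.1), values=np.zeros(121))
        priors = PriorSpec.from_preset(get_preset("WT-sweep1-S"), free=("da_p",))
        m = ReleaseModel(observed, make_single_burst(5.0), priors=priors)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = m.fit(seed=0, max_iter=300)
        # posterior collapses toward the lower bound (0), well below the prior mean
        assert res.params["da_p"] < 0.420 / 3
        assert np.isnan(res.rsquared)

    def test_seed_reproducibility(self, noiseless_trace):
        priors = PriorSpec.from_preset(get_preset("WT-sweep1-S"), free=("da_p",))
        m = ReleaseModel(noiseless_trace, make_single_burst(5.0), priors=priors)
        r1 = m.fit(seed=9, max_iter=150)
        r2 = m.fit(seed=9, max_iter=150)
        assert r1.params.equals(r2.params)
        assert np.array_equal(r1.elbo_trace, r2.elbo_trace)
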