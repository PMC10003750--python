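"""Synthetic trace generation and parameter-recovery experiments."""

import warnings

import numpy as np
import pytest

from fscvmodels import PriorSpec, ReleaseModel, get_preset, r_squared, run_recovery
from fscvmodels.electrode import ElectrodeParams
from fscvmodels.synthetic import generate_trace


class TestGenerateTrace:
    def test_same_seed_is_bit_identical(self):
        a = generate_trace(noise_sd=0.05, seed=123)
        b = generate_trace(noise_sd=0.05, seed=123)
        assert np.array_equal(a.values, b.values)
        assert a.meta == b.meta

    def test_different_seeds_differ(self):
        a = generate_trace(noise_sd=0.05, seed=1)
        b = generate_trace(noise_sd=0.05, seed=2)
        assert not np.array_equal(a.values, b.values)

    def test_zero_release_zero_noise_is_flat(self):
        tr = generate_trace(theta={"da_p": 0.0}, noise_sd=0.0)
        assert np.all(tr.values == 0.0)

    def test_noiseless_trace_is_self_consistent(self):
        tr = generate_trace(noise_sd=0.0)
        assert r_squared(tr.values, tr.values) == 1.0

    def test_residual_sd_matches_noise_level(self):
        clean = generate_trace(noise_sd=0.0)
        noisy = generate_trace(noise_sd=0.05, seed=8)
        resid = noisy.values - clean.values
        assert np.std(resid) == pytest.approx(0.05, rel=0.25)

    def test_repeated_burst_shows_six_locked_transients(self):
        tr = generate_trace(preset="WT-sweep1-R", noise_sd=0.0)
        onsets = np.array(tr.meta["protocol"]["onsets"])
        assert onsets.size == 6
        assert np.allclose(np.diff(onsets), 5.6)
        # each burst produces a local rise shortly after its onset
        for t0 in onsets:
            pre = tr.values[np.searchsorted(tr.times, t0) - 1]
            post = tr.values[np.searchsorted(tr.times, t0 + 1.0)]
            assert post > pre

    def test_negative_noisy_samples_are_kept(self):
        tr = generate_trace(theta={"da_p": 0.0}, noise_sd=0.05, seed=4)
        assert np.any(tr.values < 0.0)

    def test_metadata_carries_ground_truth(self):
        tr = generate_trace(noise_sd=0.05, seed=6)
        assert tr.meta["preset"] == "WT-sweep1-S"
        assert tr.meta["generating_params"]["da_p"] == pytest.approx(0.420)
        assert tr.meta["seed"] == 6

    def test_invalid_preset_rejected(self):
        with pytest.raises(KeyError):
            generate_trace(preset="WT-sweep7-S")

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            generate_trace(noise_sd=-0.1)

    def test_spatial_variant_generates(self):
        tr = generate_trace(model="stur", preset="WT-sweep1-S", noise_sd=0.0, t_end=10.0)
        assert tr.values.max() > 0.5


class TestRecovery:
    @pytest.fixture(scope="class")
    def small_report(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return run_recovery(n_replicates=2, seed=3, max_iter=400)

    def test_report_has_one_row_per_replicate_and_parameter(self, small_report):
        assert len(small_report.table) == 2 * 2  # 2 replicates x (da_p, v_m)
        assert set(small_report.table.parameter) == {"da_p", "v_m"}
        assert {"truth", "mean", "sd", "abs_error", "rel_error", "covered"} <= set(
            small_report.table.columns
        )

    def test_noisy_recovery_is_accurate(self, small_report):
        assert small_report.median_relative_error("da_p") < 0.15
        assert small_report.median_relative_error("v_m") < 0.15

    def test_matched_model_shows_no_mismatch(self, small_report):
        assert small_report.residual_sd.median() < 2 * 0.05
        assert not small_report.mismatch_flag

    def test_summary_mentions_models_and_replicates(self, small_report):
        text = small_report.summary()
        assert "SUR" in text and "replicates: 2" in text

    def test_noiseless_recovery_within_five_percent(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            report = run_recovery(
                noise_sd=0.0, n_replicates=1, seed=5, free=("da_p", "v_m"),
                max_iter=400,
            )
        assert report.median_relative_error("da_p") < 0.05
        assert report.median_relative_error("v_m") < 0.05

    def test_wrong_fixed_electrode_kinetics_flag_mismatch(self):
        """Data from a sluggish electrode, fitted with the default fast one."""
        slow = ElectrodeParams(k_s=1.0, k_e=1.0)
        tr = generate_trace(
            theta={"k_s": slow.k_s, "k_e": slow.k_e}, noise_sd=0.05, seed=9
        )
        priors = PriorSpec.from_preset(get_preset("WT-sweep1-S"), free=("da_p", "v_m"))
        m = ReleaseModel(tr, get_preset("WT-sweep1-S").protocol(), priors=priors)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = m.fit(seed=1, max_iter=300)
        resid_sd = float(np.std(tr.values - res.predict().values, ddof=1))
        assert resid_sd > 2 * 0.05  # residuals well above the noise floor

    def test_requires_at_least_one_replicate(self):
        with pytest.raises(ValueError):
            run_recovery(n_replicates=0)

    def test_uncertainty_grows_with_noise(self):
        """Posterior SD of DA_P increases with the measurement noise level."""
        sds = []
        for noise, seed in ((0.01, 31), (0.15, 32)):
            tr = generate_trace(noise_sd=noise, seed=seed)
            priors = PriorSpec.from_preset(get_preset("WT-sweep1-S"), free=("da_p",))
            m = ReleaseModel(
                tr, get_preset("WT-sweep1-S").protocol(), priors=priors,
                likelihood_sd=noise,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = m.fit(seed=7, max_iter=300)
            sds.append(float(res.bse["da_p"]))
        assert sds[1] > sds[0]
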