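"""Dataset generation, Rician noise statistics and Monte-Carlo machinery."""

import numpy as np
import pytest

from t2ivim.fitting import fit_ivim_1d
from t2ivim.presets import TR_SET, liver_state, simulation_grid
from t2ivim.signal_models import AcquisitionGrid, ivim_signal
from t2ivim.simulator import (MCSummary, NoiseModel, SignalDataset,
                              add_rician_noise, generate_dataset,
                              make_image_phantom, run_monte_carlo,
                              summarize_comparison)


class TestGenerateDataset:
    def test_anchor_node_is_one(self, liver, grid_16b_6te):
        ds = generate_dataset(liver_state(delta_t1=300, delta_t2=20), grid_16b_6te)
        assert ds.values[0, 0, 0] == pytest.approx(1.0, rel=1e-12)

    def test_full_phantom_grid_shape(self, liver):
        grid = AcquisitionGrid(
            b_values=simulation_grid().b_values,
            te_values=simulation_grid().te_values, tr_values=TR_SET)
        ds = generate_dataset(liver, grid)
        assert ds.values.shape == (16, 6, 5)

    def test_matched_relaxation_reduces_to_conventional(self, liver, grid_16b_6te):
        ds = generate_dataset(liver, grid_16b_6te)
        i100 = grid_16b_6te.b_values.index(100.0)
        assert ds.values[i100, 0, 0] == pytest.approx(0.8189948, abs=1e-6)

    def test_per_te_normalization_starts_every_slab_at_one(self, grid_16b_6te):
        ds = generate_dataset(liver_state(delta_t2=30), grid_16b_6te,
                              normalization="per_te")
        np.testing.assert_allclose(ds.values[0], 1.0, rtol=1e-12)

    def test_shape_mismatch_rejected(self, grid_16b_6te):
        with pytest.raises(ValueError, match="shape"):
            SignalDataset(grid=grid_16b_6te, values=np.ones((3, 2, 1)))


class TestRicianNoise:
    def test_zero_sigma_identity(self, liver, grid_16b_6te):
        ds = generate_dataset(liver, grid_16b_6te)
        out = add_rician_noise(ds, NoiseModel(sigma=0.0, seed=3))
        np.testing.assert_array_equal(out.values, ds.values)

    def test_seeded_reproducibility(self, liver, grid_16b_6te):
        ds = generate_dataset(liver, grid_16b_6te)
        a = add_rician_noise(ds, NoiseModel(sigma=0.025, seed=9))
        b = add_rician_noise(ds, NoiseModel(sigma=0.025, seed=9))
        np.testing.assert_array_equal(a.values, b.values)
        c = add_rician_noise(ds, NoiseModel(sigma=0.025, seed=10))
        assert not np.array_equal(a.values, c.values)

    def test_noised_values_nonnegative(self, liver, grid_16b_6te):
        ds = generate_dataset(liver, grid_16b_6te)
        out = add_rician_noise(ds, NoiseModel(sigma=0.3, seed=2))
        assert np.all(out.values >= 0)

    def test_rician_floor_mean_at_zero_signal(self):
        """At zero underlying signal the magnitude mean is sigma*sqrt(pi/2)."""
        from t2ivim.simulator import rician_sample
        sigma, n = 0.025, 10**5
        draws = rician_sample(np.zeros(n), sigma, np.random.default_rng(0))
        expected = sigma * np.sqrt(np.pi / 2)
        se = sigma * np.sqrt(2 - np.pi / 2) / np.sqrt(n)
        assert abs(draws.mean() - expected) < 3 * se

    def test_snr_is_reciprocal_sigma(self):
        assert NoiseModel(sigma=0.025).snr_at_s0 == pytest.approx(40.0)


class TestMonteCarlo:
    @staticmethod
    def _fit_ref_te(ds):
        return fit_ivim_1d(ds.te_slice(ds.grid.reference_te), ds.grid.b_values).estimates

    def test_zero_noise_gives_zero_sd(self, liver, grid_16b_6te):
        mc = run_monte_carlo(liver, grid_16b_6te, NoiseModel(sigma=0.0), 5,
                             fitter=self._fit_ref_te)
        assert float(mc.sd["f"]) == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_1d_bias_matches_oracle(self, grid_16b_6te):
        """Conventional fit of relaxation-weighted data at TE=52 shows the
        closed-form +30.7% overestimation of f."""
        st = liver_state(delta_t2=5.0)

        def fit52(ds):
            return fit_ivim_1d(ds.te_slice(52.0), ds.grid.b_values).estimates

        mc = run_monte_carlo(st, grid_16b_6te, NoiseModel(sigma=0.0), 1, fitter=fit52)
        assert float(mc.bias_percent["f"]) == pytest.approx(30.75, abs=0.1)

    def test_parameter_recovery_within_mc_ci(self, liver, grid_16b_6te):
        mc = run_monte_carlo(liver, grid_16b_6te, NoiseModel(sigma=0.025, seed=5),
                             200, fitter=self._fit_ref_te)
        se = float(mc.sd["f"]) / np.sqrt(mc.n_rep)
        assert abs(float(mc.mean["f"]) - 0.095) < 4 * se

    def test_seed_reproducible_and_seeds_statistically_compatible(self, liver, grid_16b_6te):
        kw = dict(n_rep=150, fitter=self._fit_ref_te)
        a = run_monte_carlo(liver, grid_16b_6te, NoiseModel(0.02, seed=1), **kw)
        a2 = run_monte_carlo(liver, grid_16b_6te, NoiseModel(0.02, seed=1), **kw)
        b = run_monte_carlo(liver, grid_16b_6te, NoiseModel(0.02, seed=2), **kw)
        assert a.estimates.equals(a2.estimates)
        se = np.hypot(a.sd["f"] / np.sqrt(a.n_rep), b.sd["f"] / np.sqrt(b.n_rep))
        assert abs(a.mean["f"] - b.mean["f"]) < 3 * se

    def test_sd_decreases_with_noise(self, liver, grid_16b_6te):
        sds = []
        for sigma in (0.03, 0.015, 0.005):
            mc = run_monte_carlo(liver, grid_16b_6te, NoiseModel(sigma, seed=4),
                                 120, fitter=self._fit_ref_te)
            sds.append(float(mc.sd["f"]))
        assert sds[0] > sds[1] > sds[2]

    def test_failed_fits_are_counted_not_fatal(self, liver, grid_16b_6te):
        calls = {"n": 0}

        def flaky(ds):
            calls["n"] += 1
            if calls["n"] % 3 == 0:
                raise RuntimeError("synthetic failure")
            return {"f": 0.1}

        mc = run_monte_carlo(liver, grid_16b_6te, NoiseModel(0.01, seed=0), 9,
                             fitter=flaky)
        assert mc.n_failed == 3 and mc.n_rep == 6
        assert mc.failure_rate == pytest.approx(1 / 3)


class TestSummarizeComparison:
    @staticmethod
    def _summary(values):
        import pandas as pd
        return MCSummary(estimates=pd.DataFrame({"f": values}))

    def test_delta_sigma_formula(self, rng):
        a = self._summary(8.0 * rng.standard_normal(5000))
        b = self._summary(10.0 * rng.standard_normal(5000))
        out = summarize_comparison(a, b, "f")
        assert out["delta_sigma_percent"] == pytest.approx(-20.0, abs=2.0)

    def test_exactly_equal_variance_p_near_half(self, rng):
        values = rng.standard_normal(20000)
        a, b = self._summary(values), self._summary(values.copy())
        assert summarize_comparison(a, b, "f")["p_value"] == pytest.approx(0.5, abs=0.01)

    def test_type_i_error_rate(self, rng):
        """Equal-variance ensembles are rejected at alpha=0.05 about 5% of
        the time (one-sided F-test calibration)."""
        n_trials, n = 1000, 400
        rejections = 0
        for _ in range(n_trials):
            a = self._summary(rng.standard_normal(n))
            b = self._summary(rng.standard_normal(n))
            if summarize_comparison(a, b, "f")["p_value"] < 0.05:
                rejections += 1
        rate = rejections / n_trials
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_trials)

    def test_zero_reference_sd_rejected(self):
        a = self._summary([1.0, 2.0])
        b = self._summary([1.0, 1.0])
        with pytest.raises(ValueError):
            summarize_comparison(a, b, "f")


class TestImagePhantom:
    def test_constant_phantom_matches_forward_series(self, grid_consensus_3te):
        st = liver_state(delta_t2=30, s0=2.0)
        layout = np.ones((4, 4), int)
        stack = make_image_phantom(layout, {1: st}, grid_consensus_3te,
                                   NoiseModel(sigma=0.0))
        series = stack.values[0, 0]
        for iy in range(4):
            for ix in range(4):
                np.testing.assert_allclose(stack.values[iy, ix], series, rtol=1e-13)

    def test_truth_maps_echo_requested_parameters(self, grid_consensus_3te):
        st = liver_state(delta_t2=30)
        layout = np.zeros((6, 6), int)
        layout[2:4, 2:4] = 1
        stack = make_image_phantom(layout, {1: st}, grid_consensus_3te,
                                   NoiseModel(sigma=0.0))
        assert stack.truth["f"][3, 3] == 0.095
        assert stack.truth["f"][0, 0] == 0.0
        assert stack.truth["T2_fluid"][2, 2] == 57.0

    def test_background_rician_floor(self, grid_consensus_3te):
        layout = np.zeros((40, 40), int)
        layout[:2, :2] = 1
        stack = make_image_phantom(layout, {1: liver_state()}, grid_consensus_3te,
                                   NoiseModel(sigma=0.025, seed=6))
        bg = stack.values[layout == 0]
        assert bg.mean() == pytest.approx(0.025 * np.sqrt(np.pi / 2), rel=0.02)

    def test_unknown_label_rejected(self, grid_consensus_3te):
        layout = np.full((2, 2), 7)
        with pytest.raises(ValueError, match="unknown region labels"):
            make_image_phantom(layout, {1: liver_state()}, grid_consensus_3te,
                               NoiseModel(sigma=0.0))
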