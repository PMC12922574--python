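"""CRLB machinery, design objective and TE-subset optimization."""

import itertools

import numpy as np
import pytest

from t2ivim.fitting import fit_t2ivim_2d
from t2ivim.presets import (B_CONSENSUS_LIVER, B_SET_1, TE_SET_1, TE_SET_2,
                            T2_FLUID_GRID_LIVER, liver_state, simulation_grid)
from t2ivim.protocol_design import (DesignSpace, GAOptions, crlb_sd_f,
                                    fisher_information, nrmse_objective,
                                    optimize_tes_exhaustive, optimize_tes_ga,
                                    validate_protocol_mc)
from t2ivim.signal_models import AcquisitionGrid
from t2ivim.simulator import NoiseModel, run_monte_carlo


@pytest.fixture(scope="module")
def liver_space_te1():
    return DesignSpace(candidates=TE_SET_1, b_values=B_SET_1, k=3,
                       state=liver_state(), t2_fluid_grid=T2_FLUID_GRID_LIVER)


class TestFisherInformation:
    def test_symmetric_positive_semidefinite(self, liver, grid_16b_6te):
        F = fisher_information(liver, grid_16b_6te, sigma=0.025, t2_fluid=47.0)
        np.testing.assert_allclose(F, F.T, rtol=1e-10)
        assert np.all(np.linalg.eigvalsh(F) > -1e-8)

    def test_sigma_scale_law(self, liver, grid_16b_6te):
        F1 = fisher_information(liver, grid_16b_6te, sigma=0.01, t2_fluid=40.0)
        F2 = fisher_information(liver, grid_16b_6te, sigma=0.02, t2_fluid=40.0)
        np.testing.assert_allclose(F1, 4.0 * F2, rtol=1e-12)

    def test_averages_weight_the_information(self, liver):
        plain = simulation_grid()
        weighted = AcquisitionGrid(b_values=plain.b_values,
                                   te_values=plain.te_values,
                                   averages=(2,) * 16)
        F1 = fisher_information(liver, plain, 0.025, t2_fluid=40.0)
        F2 = fisher_information(liver, weighted, 0.025, t2_fluid=40.0)
        np.testing.assert_allclose(F2, 2.0 * F1, rtol=1e-12)

    def test_too_few_points_rejected(self, liver):
        grid = AcquisitionGrid(b_values=(0.0, 100.0), te_values=(47.0, 72.0))
        with pytest.raises(ValueError, match="more points"):
            fisher_information(liver, grid, 0.025)


class TestCrlbSdF:
    def test_adding_a_design_point_never_increases_bound(self, liver):
        base = simulation_grid(te_values=(47.0, 57.0, 72.0))
        bigger = simulation_grid(te_values=(47.0, 52.0, 57.0, 72.0))
        sd_base = crlb_sd_f(liver, base, 0.025, t2_fluid=42.0)
        sd_big = crlb_sd_f(liver, bigger, 0.025, t2_fluid=42.0)
        assert sd_big <= sd_base + 1e-12

    def test_mc_variance_respects_and_approaches_bound_at_low_noise(self, grid_16b_6te):
        """Empirical SD of the joint fit sits above the matching CRLB and
        within 20% of it in the near-Gaussian low-noise regime."""
        st = liver_state(delta_t2=15.0)
        sigma = 0.005
        bound = crlb_sd_f(st, grid_16b_6te, sigma, model="self_normalized")
        mc = run_monte_carlo(st, grid_16b_6te, NoiseModel(sigma, seed=21), 400,
                             fitter=lambda ds: fit_t2ivim_2d(ds).estimates)
        sd = float(mc.sd["f"])
        se = sd / np.sqrt(2 * (mc.n_rep - 1))
        # small slack below the bound: bounded NLS is not exactly unbiased
        assert sd >= 0.95 * bound - 3 * se
        assert sd <= 1.2 * bound + 3 * se

    def test_mc_variance_above_bound_at_snr40(self, grid_16b_6te):
        st = liver_state(delta_t2=15.0)
        bound = crlb_sd_f(st, grid_16b_6te, 0.025, model="self_normalized")
        mc = run_monte_carlo(st, grid_16b_6te, NoiseModel(0.025, seed=22), 300,
                             fitter=lambda ds: fit_t2ivim_2d(ds).estimates)
        sd = float(mc.sd["f"])
        se = sd / np.sqrt(2 * (mc.n_rep - 1))
        assert sd >= bound - 3 * se


class TestNrmseObjective:
    def test_zero_bias_arithmetic(self, liver_space_te1, monkeypatch):
        """With beta=0 and a constant sigma_f the objective is
        n_scenarios * sigma_f / f."""
        import t2ivim.protocol_design as pd_mod
        monkeypatch.setattr(pd_mod, "_crlb_sd_f_from_jac",
                            lambda J, w, sigma: 0.0095)
        obj = nrmse_objective((47.0, 57.0, 72.0), liver_space_te1)
        assert obj == pytest.approx(13 * 0.0095 / 0.095, rel=1e-12)

    def test_linear_in_sigma_when_unbiased(self, liver_space_te1):
        from dataclasses import replace
        half = replace(liver_space_te1, sigma=liver_space_te1.sigma / 2)
        subset = (47.0, 62.0, 72.0)
        assert nrmse_objective(subset, half) == pytest.approx(
            nrmse_objective(subset, liver_space_te1) / 2, rel=1e-10)

    def test_permutation_invariant_and_positive(self, liver_space_te1):
        a = nrmse_objective((47.0, 62.0, 72.0), liver_space_te1)
        b = nrmse_objective((72.0, 47.0, 62.0), liver_space_te1)
        assert a == b and a > 0


class TestExhaustiveSearch:
    def test_full_candidate_set_is_single_subset(self, liver):
        space = DesignSpace(candidates=(47.0, 52.0), b_values=B_SET_1, k=2,
                            state=liver, t2_fluid_grid=T2_FLUID_GRID_LIVER)
        res = optimize_tes_exhaustive(space)
        assert res.te_subset == (47.0, 52.0) and res.n_evaluations == 1

    def test_invivo_space_optimum(self, liver_space_te1):
        res = optimize_tes_exhaustive(liver_space_te1)
        assert res.te_subset == (47.0, 67.0, 72.0)
        assert res.n_evaluations == 20

    def test_consensus_space_longest_te_is_100(self, liver):
        space = DesignSpace(candidates=TE_SET_2, b_values=B_CONSENSUS_LIVER,
                            k=3, state=liver, t2_fluid_grid=T2_FLUID_GRID_LIVER)
        res = optimize_tes_exhaustive(space)
        assert res.n_evaluations == 165
        assert max(res.te_subset) == 100.0
        assert min(res.te_subset) == 50.0


class TestGeneticAlgorithm:
    def test_same_seed_same_result(self, liver_space_te1):
        a = optimize_tes_ga(liver_space_te1, GAOptions(population=100,
                                                       generations=20, seed=5))
        b = optimize_tes_ga(liver_space_te1, GAOptions(population=100,
                                                       generations=20, seed=5))
        assert a.te_subset == b.te_subset and a.objective == b.objective

    @pytest.mark.parametrize("candidates,b_values", [
        (TE_SET_1, B_SET_1),             # C(6,3) = 20 subsets
        (TE_SET_2, B_CONSENSUS_LIVER),   # C(11,3) = 165 subsets
    ])
    def test_matches_exhaustive_oracle(self, liver, candidates, b_values):
        space = DesignSpace(candidates=candidates, b_values=b_values, k=3,
                            state=liver, t2_fluid_grid=T2_FLUID_GRID_LIVER)
        oracle = optimize_tes_exhaustive(space)
        for seed in range(5):
            ga = optimize_tes_ga(space, GAOptions(population=200,
                                                  generations=50, seed=seed))
            assert ga.te_subset == oracle.te_subset, f"seed {seed}"

    def test_larger_subsets_dominate(self, liver):
        """The optimal k-TE objective is no worse than any augmentation of
        the optimal (k-1)-TE design."""
        prev = None
        for k in (2, 3, 4, 5):
            space = DesignSpace(candidates=TE_SET_1, b_values=B_SET_1, k=k,
                                state=liver, t2_fluid_grid=T2_FLUID_GRID_LIVER)
            res = optimize_tes_exhaustive(space)
            if prev is not None:
                for extra in set(TE_SET_1) - set(prev.te_subset):
                    augmented = tuple(sorted(prev.te_subset + (extra,)))
                    assert res.objective <= nrmse_objective(augmented, space) + 1e-12
            prev = res


class TestValidateProtocol:
    def test_noiseless_validation_is_deterministic(self, liver):
        # sigma must stay positive for the CRLB, so validate with a tiny one
        space = DesignSpace(candidates=(47.0, 57.0, 72.0), b_values=B_SET_1,
                            k=3, state=liver, t2_fluid_grid=T2_FLUID_GRID_LIVER,
                            sigma=1e-9)
        mc = validate_protocol_mc((47.0, 57.0, 72.0), space, n_rep=3, seed=0,
                                  t2_fluid=42.0)
        assert float(mc.sd["f"]) == pytest.approx(0.0, abs=1e-6)
        assert abs(float(mc.bias_percent["f"])) < 0.5

    def test_more_tes_reduce_validated_sd(self, liver):
        """Monte-Carlo SD of f shrinks as TEs are added to the protocol."""
        sds = []
        for subset in [(47.0, 72.0), (47.0, 57.0, 72.0),
                       (47.0, 52.0, 57.0, 67.0, 72.0)]:
            space = DesignSpace(candidates=subset, b_values=B_SET_1,
                                k=len(subset), state=liver,
                                t2_fluid_grid=T2_FLUID_GRID_LIVER)
            mc = validate_protocol_mc(subset, space, n_rep=150, seed=3,
                                      t2_fluid=42.0)
            sds.append(float(mc.sd["f"]))
        assert sds[0] > sds[1] > sds[2]

    def test_crlb_ranking_agrees_with_mc_ranking(self, liver):
        """The CRLB objective and validated MC SD order candidate subsets
        the same way."""
        subsets = [(47.0, 52.0, 57.0), (47.0, 62.0, 72.0), (57.0, 62.0, 67.0)]
        space = DesignSpace(candidates=TE_SET_1, b_values=B_SET_1, k=3,
                            state=liver, t2_fluid_grid=(42.0,))
        pred = [nrmse_objective(s, space) for s in subsets]
        meas = [float(validate_protocol_mc(s, space, n_rep=150, seed=9,
                                           t2_fluid=42.0).sd["f"])
                for s in subsets]
        assert np.argsort(pred).tolist() == np.argsort(meas).tolist()
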