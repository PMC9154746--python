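"""Core reaction-transport model: binding, effective rates, steady states."""

import numpy as np
import pytest
from scipy.stats import nbinom

import golgicode as gc
from conftest import random_params


class TestBindingProbability:
    @pytest.mark.parametrize(
        "k,l,sigma,expected",
        [
            (5, 5.0, 3.0, 1.0),  # zero mismatch
            (7, 2.0, 0.0, 1.0),  # fully promiscuous enzyme
            (3, 5.0, 1.0, np.exp(-2.0)),  # |k-l|=2 at sigma=1
        ],
    )
    def test_values(self, k, l, sigma, expected):
        assert gc.binding_probability(k, l, sigma) == pytest.approx(expected, rel=1e-12)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            gc.binding_probability(3, 5.0, -1.0)

    def test_never_underflows_to_zero(self):
        assert gc.binding_probability(1, 200.0, 50.0) > 0.0


class TestEffectiveRates:
    def test_promiscuous_single_enzyme(self):
        system = gc.GolgiSystem(NC=2, NE=1, Ns=10)
        params = gc.ParameterSet(mu=[0.5, 0.5], R=[[2.0, 2.0]], L=[[3.0, 3.0]],
                                 sigma=0.0)
        Reff = gc.effective_rates(system, params)
        assert np.allclose(Reff[:, :-1], 2.0)
        assert np.all(Reff[:, -1] == 0.0)  # chain end is absorbing

    def test_high_specificity_selects_matched_enzyme(self):
        system = gc.GolgiSystem(NC=1, NE=2, Ns=10)
        params = gc.ParameterSet(mu=[0.5], R=[[1.0], [1.0]], L=[[3.0], [6.0]],
                                 sigma=50.0)
        Reff = gc.effective_rates(system, params)
        assert Reff[0, 2] == pytest.approx(1.0, rel=1e-10)  # k=3 matches l=3

    def test_hand_summed_mixture(self):
        # k=2, enzymes at l=1 and l=4 with R=2,3 at sigma=1: 2e^-1 + 3e^-2
        system = gc.GolgiSystem(NC=1, NE=2, Ns=10)
        params = gc.ParameterSet(mu=[0.5], R=[[2.0], [3.0]], L=[[1.0], [4.0]],
                                 sigma=1.0)
        Reff = gc.effective_rates(system, params)
        assert Reff[0, 1] == pytest.approx(2 * np.exp(-1) + 3 * np.exp(-2), rel=1e-12)

    def test_activity_mask_silences_enzyme(self):
        system = gc.GolgiSystem(NC=2, NE=1, Ns=10)
        params = gc.ParameterSet(mu=[0.5, 0.5], R=[[2.0, 2.0]], L=[[3.0, 3.0]],
                                 sigma=0.0, activity=[[1.0, 0.0]])
        Reff = gc.effective_rates(system, params)
        assert np.allclose(Reff[0, :-1], 2.0)
        assert np.allclose(Reff[1], 0.0)

    def test_dimension_mismatch_rejected(self):
        system = gc.GolgiSystem(NC=3, NE=2, Ns=10)
        params = gc.ParameterSet(mu=[0.5], R=[[2.0], [3.0]], L=[[1.0], [4.0]],
                                 sigma=1.0)
        with pytest.raises(ValueError):
            gc.effective_rates(system, params)


class TestSteadyStateLinear:
    def test_single_cisterna_geometric_transit(self):
        # NC=1, sigma=0, R=mu=1: cbar_k = mu R^(k-1) / (R+mu)^k = 2^-k
        system = gc.GolgiSystem(NC=1, NE=1, Ns=60)
        params = gc.ParameterSet(mu=[1.0], R=[[1.0]], L=[[1.0]], sigma=0.0)
        ss = gc.steady_state_linear(system, params)
        k = np.arange(1, 60)
        assert np.max(np.abs(ss.displayed.abundance[:-1] - 2.0**-k)) < 1e-12

    def test_two_cisternae_negative_binomial(self):
        # identical cisternae convolve two geometrics: cbar_k = k 2^-(k+1)
        system = gc.GolgiSystem(NC=2, NE=1, Ns=60)
        params = gc.ParameterSet(mu=[1.0, 1.0], R=[[1.0, 1.0]], L=[[1.0, 1.0]],
                                 sigma=0.0)
        ss = gc.steady_state_linear(system, params)
        k = np.arange(1, 60)
        expected = k * 2.0 ** -(k + 1)
        assert np.max(np.abs(ss.displayed.abundance[:-1] - expected)) < 1e-12

    def test_mean_transit_matches_negative_binomial_mean(self):
        # sigma=0 uniform rates: mean displayed index - 1 = NC * R / mu
        system = gc.GolgiSystem(NC=3, NE=1, Ns=200)
        params = gc.ParameterSet(mu=[0.5] * 3, R=[[2.0] * 3], L=[[1.0] * 3],
                                 sigma=0.0)
        ss = gc.steady_state_linear(system, params)
        k = np.arange(1, 201)
        mean = float(k @ ss.displayed.abundance)
        assert mean - 1 == pytest.approx(3 * 2.0 / 0.5, rel=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_flux_conservation_and_nonnegativity(self, seed):
        system = gc.GolgiSystem(NC=4, NE=2, Ns=40)
        params = random_params(system, sigma=1.5, seed=seed)
        ss = gc.steady_state_linear(system, params)
        exit_flux = params.mu[-1] * ss.conc[-1].sum()
        assert exit_flux == pytest.approx(system.q, rel=1e-8)
        assert np.all(ss.conc >= 0)
        assert ss.displayed.abundance.sum() == pytest.approx(1.0, abs=1e-10)

    def test_nonpositive_mu_rejected(self):
        with pytest.raises(ValueError):
            gc.ParameterSet(mu=[0.0], R=[[1.0]], L=[[1.0]], sigma=0.0)


class TestSteadyStateMM:
    def test_dilute_limit_matches_linear(self):
        system = gc.GolgiSystem(NC=3, NE=2, Ns=30)
        lin = random_params(system, sigma=1.3, seed=0)
        mm = gc.MMParameterSet(mu=lin.mu, M=np.full((2, 3), 1e6), V=lin.R * 1e6,
                               L=lin.L, sigma=1.3)
        d_lin = gc.steady_state_linear(system, lin).displayed.abundance
        d_mm = gc.steady_state_mm(system, mm).displayed.abundance
        assert 0.5 * np.sum(np.abs(d_lin - d_mm)) < 1e-4

    def test_flux_conservation_saturated(self):
        system = gc.GolgiSystem(NC=2, NE=1, Ns=10)
        mm = gc.MMParameterSet(mu=[0.3, 0.3], M=[[0.05, 0.05]], V=[[2.0, 2.0]],
                               L=[[1.0, 5.0]], sigma=0.4)
        ss = gc.steady_state_mm(system, mm)
        assert mm.mu[-1] * ss.conc[-1].sum() == pytest.approx(system.q, rel=1e-8)

    def test_saturated_matches_ode_integration(self):
        # independent oracle: brute-force time integration of the kinetics
        from scipy.integrate import solve_ivp

        system = gc.GolgiSystem(NC=1, NE=1, Ns=3)
        M, V, mu, q = 0.02, 1.5, 0.4, 1.0
        mm = gc.MMParameterSet(mu=[mu], M=[[M]], V=[[V]], L=[[1.0]], sigma=0.0)
        ss = gc.steady_state_mm(system, mm)

        def rhs(_t, c):
            S = 1.0 + c.sum() / M  # sigma=0: all binding probabilities are 1
            flux = V * c / (M * S)
            flux[-1] = 0.0
            return (np.array([q, 0.0, 0.0])
                    + np.concatenate(([0.0], flux[:-1])) - flux - mu * c)

        sol = solve_ivp(rhs, (0, 5e4), np.zeros(3), method="LSODA",
                        rtol=1e-12, atol=1e-14)
        oracle = mu * sol.y[:, -1] / q
        assert np.max(np.abs(ss.displayed.abundance - oracle / oracle.sum())) < 1e-8

    def test_nonconvergence_reports_residual(self):
        system = gc.GolgiSystem(NC=1, NE=1, Ns=5)
        mm = gc.MMParameterSet(mu=[0.5], M=[[0.1]], V=[[2.0]], L=[[1.0]], sigma=0.0)
        with pytest.raises(RuntimeError, match="residual"):
            gc.steady_state_mm(system, mm, max_iter=2, ode_fallback=False)


class TestSwapCisternae:
    def test_identity_swap(self):
        system = gc.GolgiSystem(NC=3, NE=2, Ns=20)
        params = random_params(system, sigma=1.0, seed=1)
        out = gc.swap_cisternae(params, 2, 2)
        assert np.array_equal(out.R, params.R) and np.array_equal(out.L, params.L)

    def test_swapping_identical_cisternae_preserves_display(self):
        system = gc.GolgiSystem(NC=3, NE=2, Ns=20)
        params = random_params(system, sigma=1.0, seed=2)
        params.R[:, 2] = params.R[:, 0]
        params.L[:, 2] = params.L[:, 0]
        params.mu[2] = params.mu[0]
        before = gc.steady_state_linear(system, params).displayed.abundance
        after = gc.steady_state_linear(
            system, gc.swap_cisternae(params, 1, 3)).displayed.abundance
        assert np.array_equal(before, after)

    def test_out_of_range_rejected(self):
        system = gc.GolgiSystem(NC=3, NE=2, Ns=20)
        params = random_params(system, sigma=1.0, seed=3)
        with pytest.raises(ValueError):
            gc.swap_cisternae(params, 0, 2)
        with pytest.raises(ValueError):
            gc.swap_cisternae(params, 1, 4)

    def test_original_untouched(self):
        system = gc.GolgiSystem(NC=3, NE=2, Ns=20)
        params = random_params(system, sigma=1.0, seed=4)
        snapshot = params.R.copy()
        gc.swap_cisternae(params, 1, 3)
        assert np.array_equal(params.R, snapshot)


class TestProfileValidation:
    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError):
            gc.GlycanProfile(np.array([0.5, -0.1, 0.6]))

    def test_normalized_flag_checked(self):
        with pytest.raises(ValueError):
            gc.GlycanProfile(np.array([0.5, 0.2]), normalized=True)

    def test_normalize_zero_profile_rejected(self):
        with pytest.raises(ValueError):
            gc.GlycanProfile(np.zeros(4)).normalize()


def test_system_invariants_enforced():
    with pytest.raises(ValueError):
        gc.GolgiSystem(NC=0, NE=1, Ns=10)
    with pytest.raises(ValueError):
        gc.GolgiSystem(NC=1, NE=1, Ns=1)
    with pytest.raises(ValueError):
        gc.GolgiSystem(NC=1, NE=1, Ns=10, mu_bounds=(1.0, 0.01))
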