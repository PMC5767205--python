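"""Free-energy estimators against analytic and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.special import logsumexp

from fepnet import (
    ReducedPotentialSet,
    bar_estimate,
    combine_legs,
    exp_estimate,
    mbar_estimate,
    statistical_inefficiency,
)
from fepnet.estimators import FreeEnergyEstimate, decorrelate
from fepnet.synthetic import gen_gaussian_work, gen_harmonic_chain


def mbar_oracle(u, states):
    """Independent MBAR solve: generic BFGS on the convex objective.

    The objective sum_n ln sum_k N_k e^{f_k - u_nk} - sum_k N_k f_k attains
    its minimum at the MBAR solution; no self-consistent iteration or Newton
    step is shared with the implementation under test.
    """
    n_k = np.bincount(states).astype(float)

    def obj(f_free):
        f = np.concatenate([[0.0], f_free])
        return float(
            logsumexp(f + np.log(n_k) - u, axis=1).sum() - n_k @ f
        )

    res = minimize(obj, np.zeros(u.shape[1] - 1), method="BFGS", tol=1e-12)
    return np.concatenate([[0.0], res.x])


class TestStatisticalInefficiency:
    def test_white_noise_has_g_near_one(self):
        x = np.random.default_rng(11).standard_normal(10_000)
        assert 0.9 <= statistical_inefficiency(x) <= 1.2

    def test_ar1_matches_analytic_integrated_autocorrelation(self):
        # AR(1) with phi: g = (1+phi)/(1-phi) = 19 for phi = 0.9
        rng = np.random.default_rng(5)
        phi, n = 0.9, 100_000
        x = np.empty(n)
        x[0] = rng.standard_normal()
        eps = rng.standard_normal(n)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        g = statistical_inefficiency(x)
        assert g == pytest.approx(19.0, rel=0.15)

    def test_constant_series_is_g_one_by_convention(self):
        assert statistical_inefficiency(np.full(100, 3.14)) == 1.0

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            statistical_inefficiency([1.0, 2.0, 3.0])

    def test_decorrelate_thins_correlated_states(self):
        rng = np.random.default_rng(3)
        n = 4000
        # state-0 samples strongly autocorrelated, state-1 i.i.d.
        x = np.cumsum(rng.standard_normal(n)) * 0.05
        u = np.zeros((2 * n, 2))
        u[:n, 1] = x
        u[n:, 0] = rng.standard_normal(n)
        data = ReducedPotentialSet(u=u, sampled_state=np.repeat([0, 1], n))
        thin = decorrelate(data)
        assert (thin.sampled_state == 0).sum() < n / 5
        # i.i.d. state: g ~ 1, so stride ceil(g) is at most 2
        assert (thin.sampled_state == 1).sum() >= n / 2


class TestExp:
    def test_zero_work_gives_zero_exactly(self):
        assert exp_estimate(np.zeros(10)).value == 0.0

    def test_single_sample_returns_that_work(self):
        assert exp_estimate([3.0]).value == pytest.approx(3.0)

    def test_gaussian_identity_mu_minus_half_sigma2(self):
        # dF = mu - sigma^2/2 = 0 for mu=2, sigma^2=4
        rng = np.random.default_rng(1234)
        du = rng.normal(2.0, 2.0, size=1_000_000)
        assert exp_estimate(du).value == pytest.approx(0.0, abs=0.05)

    def test_backward_direction_estimates_the_same_delta_f(self):
        fwd, bwd = gen_gaussian_work(1.5, 0.5, 200_000, 9)
        f_f = exp_estimate(fwd, "forward").value
        f_b = exp_estimate(bwd, "backward").value
        assert f_f == pytest.approx(1.5, abs=0.02)
        assert f_b == pytest.approx(1.5, abs=0.02)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            exp_estimate([])


class TestBar:
    def test_degenerate_distributions_give_exact_answer(self):
        c = 2.5
        est = bar_estimate(np.full(50, c), np.full(50, -c))
        assert est.value == pytest.approx(c, abs=1e-9)

    def test_identical_zero_sequences_give_zero(self):
        assert bar_estimate(np.zeros(20), np.zeros(20)).value == pytest.approx(0.0, abs=1e-12)

    def test_crooks_consistent_gaussians_recover_delta_f(self):
        fwd, bwd = gen_gaussian_work(1.5, 1.0, 100_000, 42)
        est = bar_estimate(fwd, bwd)
        assert est.value == pytest.approx(1.5, abs=0.03)
        assert 0 < est.se < 0.02

    def test_exp_estimates_bracket_bar(self):
        # finite-sample EXP is biased outward on both sides for overlapping
        # unimodal work distributions
        fwd, bwd = gen_gaussian_work(0.8, 2.0, 2_000, 17)
        bar = bar_estimate(fwd, bwd).value
        lo = exp_estimate(bwd, "backward").value
        hi = exp_estimate(fwd, "forward").value
        assert lo <= bar <= hi


class TestMbar:
    def test_all_states_identical_gives_zero_free_energies(self):
        u = np.tile(np.random.default_rng(0).standard_normal(60)[:, None], (1, 3))
        data = ReducedPotentialSet(u=u, sampled_state=np.arange(60) % 3)
        result = mbar_estimate(data)
        assert np.allclose(result.f, 0.0, atol=1e-12)

    def test_harmonic_pair_matches_analytic_partition_function(self):
        data, f_true = gen_harmonic_chain([1.0, 4.0], 100_000, 7)
        result = mbar_estimate(data)
        assert f_true[1] == pytest.approx(0.5 * np.log(4.0))
        assert result.f[1] == pytest.approx(f_true[1], abs=0.02)

    def test_two_state_mbar_equals_bar(self, rng):
        n = 400
        x0 = rng.normal(0.0, 1.0, n)
        x1 = rng.normal(0.7, 1.3, n)
        xs = np.concatenate([x0, x1])
        u = np.column_stack(
            [xs**2 / 2.0, (xs - 0.7) ** 2 / (2 * 1.3**2) + np.log(1.3)]
        )
        data = ReducedPotentialSet(u=u, sampled_state=np.repeat([0, 1], n))
        f_mbar = mbar_estimate(data).f[1]
        f_bar = bar_estimate(u[:n, 1] - u[:n, 0], u[n:, 0] - u[n:, 1]).value
        assert abs(f_mbar - f_bar) < 1e-6

    def test_agrees_with_independent_convex_minimisation(self, rng):
        for _ in range(5):
            k_states = int(rng.integers(2, 5))
            n = int(rng.integers(50, 200))
            means = rng.normal(0.0, 1.0, k_states)
            xs = np.concatenate(
                [rng.normal(m, 1.0, n) for m in means]
            )
            u = 0.5 * (xs[:, None] - means[None, :]) ** 2
            data = ReducedPotentialSet(
                u=u, sampled_state=np.repeat(np.arange(k_states), n)
            )
            f = mbar_estimate(data).f
            f_ref = mbar_oracle(u, np.repeat(np.arange(k_states), n))
            assert np.allclose(f, f_ref, atol=1e-6)

    def test_unsampled_state_is_an_error(self):
        with pytest.raises(ValueError):
            ReducedPotentialSet(u=np.zeros((4, 3)), sampled_state=[0, 0, 1, 1])

    def test_bootstrap_se_is_reproducible_and_close_to_asymptotic(self):
        data, _ = gen_harmonic_chain([1.0, 2.0], 2_000, 21)
        r1 = mbar_estimate(data, bootstrap=100, seed=5)
        r2 = mbar_estimate(data, bootstrap=100, seed=5)
        assert np.array_equal(r1.bootstrap_se, r2.bootstrap_se)
        asym = r1.se(prefer_bootstrap=False)[1]
        assert r1.bootstrap_se[1] == pytest.approx(asym, rel=0.5)


class TestShiftInvariance:
    @given(c=st.floats(-30, 30))
    @settings(max_examples=20, deadline=None)
    def test_mbar_shifts_by_exactly_c(self, c):
        data, _ = gen_harmonic_chain([1.0, 3.0], 300, 13)
        u_shifted = data.u.copy()
        u_shifted[:, 1] += c
        shifted = ReducedPotentialSet(u=u_shifted, sampled_state=data.sampled_state)
        f0 = mbar_estimate(data).f[1]
        f1 = mbar_estimate(shifted).f[1]
        assert f1 - f0 == pytest.approx(c, abs=1e-8)

    @given(c=st.floats(-30, 30))
    @settings(max_examples=20, deadline=None)
    def test_bar_and_exp_shift_by_exactly_c(self, c):
        fwd, bwd = gen_gaussian_work(0.5, 1.0, 500, 3)
        assert bar_estimate(fwd + c, bwd - c).value - bar_estimate(
            fwd, bwd
        ).value == pytest.approx(c, abs=1e-8)
        assert exp_estimate(fwd + c).value - exp_estimate(fwd).value == pytest.approx(
            c, abs=1e-10
        )


class TestCombineLegs:
    def test_difference_with_quadrature_error(self):
        bound = FreeEnergyEstimate(5.0, 0.3, "MBAR", "bound", "kJ/mol")
        free = FreeEnergyEstimate(2.0, 0.4, "MBAR", "free", "kJ/mol")
        out = combine_legs(bound, free)
        assert out.value == pytest.approx(3.0)
        assert out.se == pytest.approx(0.5)
        assert out.leg == "combined"

    def test_equal_legs_cancel(self):
        e = FreeEnergyEstimate(16.7, 0.2, "BAR", "bound", "kJ/mol")
        out = combine_legs(e, e)
        assert out.value == 0.0
        assert out.se == pytest.approx(0.2 * np.sqrt(2))

    def test_identity_leg(self):
        bound = FreeEnergyEstimate(16.7, 0.25, "MBAR", "bound", "kJ/mol")
        free = FreeEnergyEstimate(0.0, 0.0, "MBAR", "free", "kJ/mol")
        out = combine_legs(bound, free)
        assert (out.value, out.se) == (16.7, 0.25)

    def test_per_interval_lists_are_summed(self):
        bound = [FreeEnergyEstimate(1.0, 0.1, "MBAR", "bound") for _ in range(4)]
        free = [FreeEnergyEstimate(0.5, 0.1, "MBAR", "free") for _ in range(2)]
        out = combine_legs(bound, free)
        assert out.value == pytest.approx(3.0)
        assert out.se == pytest.approx(np.sqrt(6 * 0.01))

    def test_unit_mismatch_rejected(self):
        bound = FreeEnergyEstimate(1.0, 0.1, "MBAR", "bound", "kJ/mol")
        free = FreeEnergyEstimate(0.5, 0.1, "MBAR", "free", "reduced")
        with pytest.raises(ValueError, match="unit"):
            combine_legs(bound, free)

    def test_reduced_to_kj_conversion(self):
        e = FreeEnergyEstimate(1.0, 0.1, "MBAR", "bound", "reduced")
        kj = e.to_kj_per_mol(300.0)
        assert kj.value == pytest.approx(2.4943, abs=1e-3)
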