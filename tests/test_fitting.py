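"""KS distance, coupling/bifurcation fitting, residual analysis, controls."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hopfbrain import (
    HopfModelSpec,
    evaluate_fcd_fit,
    extract_phases,
    fcd,
    fcd_values,
    fit_effective_parameters,
    fit_global_coupling,
    fit_local_bifurcation,
    ks_distance,
    make_ground_truth_dataset,
    phase_interaction_series,
    power_proportions,
    shuffle_local_parameters,
    strength_residual_analysis,
)
from hopfbrain.exceptions import InvalidArgumentError


def brute_force_ks(a, b):
    """Max empirical-CDF gap over all breakpoints (independent oracle)."""
    a, b = np.sort(a), np.sort(b)
    points = np.concatenate([a, b])
    gaps = [
        abs((a <= x).mean() - (b <= x).mean()) for x in points
    ]
    return max(gaps)


class TestKSDistance:
    def test_identical_samples(self):
        assert ks_distance([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_disjoint_supports(self):
        assert ks_distance([0.0, 0.1], [5.0, 6.0]) == 1.0

    def test_repeated_values_equal_cdfs(self):
        assert ks_distance([0.0, 1.0], [0.0, 0.0, 1.0, 1.0]) == 0.0

    @given(
        st.lists(st.integers(0, 5).map(float), min_size=1, max_size=8),
        st.lists(st.integers(0, 5).map(float), min_size=1, max_size=8),
    )
    def test_matches_brute_force_oracle(self, a, b):
        assert ks_distance(a, b) == pytest.approx(brute_force_ks(a, b))

    def test_empty_sample_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ks_distance([], [1.0])


class TestGlobalCouplingFit:
    def test_deterministic(self, small_sc):
        rng = np.random.default_rng(0)
        emp = rng.uniform(0, 1, 500)
        template = HopfModelSpec(
            a=np.zeros(10), omega=np.full(10, 2 * np.pi * 0.05), g=0.0, C=small_sc
        )
        kwargs = dict(trials=2, n_volumes=100, tr=2.0, seed=4)
        f1 = fit_global_coupling(emp, template, np.array([0.5, 1.5]), **kwargs)
        f2 = fit_global_coupling(emp, template, np.array([0.5, 1.5]), **kwargs)
        np.testing.assert_array_equal(f1.ks_mean, f2.ks_mean)
        assert f1.g_opt == f2.g_opt

    def test_result_invariants(self, small_sc):
        rng = np.random.default_rng(1)
        emp = rng.uniform(0, 1, 500)
        template = HopfModelSpec(
            a=np.zeros(10), omega=np.full(10, 2 * np.pi * 0.05), g=0.0, C=small_sc
        )
        fit = fit_global_coupling(
            emp, template, np.array([0.0, 1.0, 2.0]), trials=2, n_volumes=100, seed=4
        )
        assert np.all((fit.ks_mean >= 0) & (fit.ks_mean <= 1))
        assert fit.g_opt in fit.g_grid
        assert fit.ks_mean[np.where(fit.g_grid == fit.g_opt)[0][0]] == np.nanmin(
            fit.ks_mean
        )

    def test_unsorted_grid_rejected(self, small_sc):
        template = HopfModelSpec(
            a=np.zeros(10), omega=np.full(10, 2 * np.pi * 0.05), g=0.0, C=small_sc
        )
        with pytest.raises(InvalidArgumentError):
            fit_global_coupling([0.5], template, np.array([1.0, 0.5]))


class TestLocalFit:
    def _spec(self, sc, g=1.5, seed=0):
        rng = np.random.default_rng(seed)
        omega = 2 * np.pi * rng.uniform(0.04, 0.07, sc.shape[0])
        return HopfModelSpec(a=np.zeros(sc.shape[0]), omega=omega, g=g, C=sc)

    def test_matched_target_converges_immediately(self, small_sc):
        """p_emp equal to the first iteration's p_sim: zero gradient, a unchanged."""
        spec = self._spec(small_sc)
        probe = fit_local_bifurcation(
            np.full(10, 0.5), spec, max_iter=1, seed=21, n_volumes=100
        )
        fitted = fit_local_bifurcation(
            probe.p_sim, spec, max_iter=5, seed=21, n_volumes=100, tol=0.01
        )
        assert fitted.converged and fitted.iterations == 1
        np.testing.assert_array_equal(fitted.a_hat, spec.a)

    def test_single_update_follows_gradient_rule(self, small_sc):
        """One step applies a_new = a_old + eta (p_emp - p_sim) exactly."""
        spec = self._spec(small_sc)
        p_emp = np.full(10, 0.9)
        fit = fit_local_bifurcation(
            p_emp, spec, eta=0.1, max_iter=1, seed=8, n_volumes=100, tol=1e-9
        )
        np.testing.assert_allclose(
            fit.a_hat, spec.a + 0.1 * (p_emp - fit.p_sim), atol=1e-15
        )

    def test_trace_shrinks_on_recoverable_target(self, fixture_sc):
        truth, bold = make_ground_truth_dataset(
            fixture_sc, g=1.5, a_spec={"heterogeneous": (-0.2, 0.1)}, seed=201
        )
        spec = HopfModelSpec(
            a=np.zeros(40), omega=truth.omega_true, g=1.5, C=fixture_sc
        )
        fit = fit_local_bifurcation(
            power_proportions(bold), spec, max_iter=20, seed=77
        )
        assert fit.trace[-1] < fit.trace[0]

    def test_invalid_p_emp_rejected(self, small_sc):
        with pytest.raises(InvalidArgumentError):
            fit_local_bifurcation(np.full(10, 1.5), self._spec(small_sc))


class TestEffectiveParameters:
    def test_fit_starts_from_homogeneous_line(self, small_sc):
        spec = HopfModelSpec(
            a=np.zeros(10),
            omega=np.full(10, 2 * np.pi * 0.05),
            g=1.5,
            C=small_sc,
        )
        probe = fit_effective_parameters(
            np.full(10, 0.5), spec, max_iter=1, seed=3, n_volumes=100, tol=1e-9
        )
        expected_start = -1.5 * small_sc.sum(axis=1)
        np.testing.assert_allclose(
            probe.a_hat, expected_start + 0.1 * (0.5 - probe.p_sim), atol=1e-12
        )

    def test_homogeneous_truth_gives_strength_anticorrelation(self, fixture_sc):
        from scipy.stats import pearsonr

        truth, bold = make_ground_truth_dataset(
            fixture_sc, g=1.5, a_spec={"homogeneous": 0.0}, seed=301
        )
        spec = HopfModelSpec(
            a=np.zeros(40), omega=truth.omega_true, g=1.5, C=fixture_sc
        )
        efit = fit_effective_parameters(
            power_proportions(bold), spec, max_iter=40, seed=55
        )
        S = fixture_sc.sum(axis=1)
        assert pearsonr(efit.a_hat, S).statistic <= -0.7


class TestStrengthResiduals:
    def test_exact_line_has_zero_residuals(self):
        S = np.linspace(0.5, 3.0, 12)
        res = strength_residual_analysis(-1.5 * S, S)
        assert res.slope == pytest.approx(-1.5)
        np.testing.assert_allclose(res.residuals, 0.0, atol=1e-12)
        assert res.median_abs_residual == pytest.approx(0.0, abs=1e-12)

    def test_single_outlier_dominates(self):
        S = np.linspace(-1.0, 1.0, 11)  # symmetric design: low leverage at centre
        a_eff = -2.0 * S
        a_eff[5] += 0.3
        res = strength_residual_analysis(a_eff, S)
        assert np.argmax(np.abs(res.residuals)) == 5

    def test_residuals_sum_to_zero(self, rng):
        S = rng.uniform(0, 5, 20)
        a_eff = -1.2 * S + rng.standard_normal(20)
        res = strength_residual_analysis(a_eff, S)
        assert res.residuals.sum() == pytest.approx(0.0, abs=1e-9)

    def test_constant_strengths_rejected(self):
        with pytest.raises(InvalidArgumentError):
            strength_residual_analysis(np.arange(5.0), np.ones(5))


class TestShuffleControl:
    def test_multiset_preserved_and_reproducible(self, rng):
        a = rng.standard_normal(30)
        s1 = shuffle_local_parameters(a, seed=4)
        s2 = shuffle_local_parameters(a, seed=4)
        np.testing.assert_array_equal(np.sort(s1), np.sort(a))
        np.testing.assert_array_equal(s1, s2)

    def test_shuffled_parameters_fit_worse(self, fixture_sc):
        """The spatial arrangement of a_j carries information when it is
        structured (hubs more stable, as fitted on wakeful data): permuting
        it degrades the FCD fit to data generated with the true arrangement.
        An i.i.d. arrangement would be exchangeable and show no effect."""
        from hopfbrain import node_strengths, simulate

        S = node_strengths(fixture_sc)
        a_true = 0.05 - 0.4 * S / S.max()  # strongest nodes most stable
        rng = np.random.default_rng(401)
        omega = 2 * np.pi * rng.uniform(0.04, 0.07, 40)
        spec = HopfModelSpec(a=a_true, omega=omega, g=1.5, C=fixture_sc)
        bold = simulate(spec, duration=600, tr=2.0, seed=401).bold
        emp = fcd_values(fcd(phase_interaction_series(extract_phases(bold))))
        ks_true = evaluate_fcd_fit(emp, spec, trials=5, seed=11)
        ks_shuf = np.mean(
            [
                evaluate_fcd_fit(
                    emp,
                    spec.with_params(a=shuffle_local_parameters(a_true, seed=s)),
                    trials=5,
                    seed=11,
                )
                for s in (123, 124, 125)
            ]
        )
        assert ks_true < ks_shuf


class TestMeanFCDGrowsWithCoupling:
    def test_direction(self, fixture_sc):
        """Stronger coupling makes synchronization patterns more recurrent."""
        from hopfbrain.fitting import simulated_fcd_values

        rng = np.random.default_rng(0)
        omega = 2 * np.pi * rng.uniform(0.04, 0.07, 40)
        template = HopfModelSpec(a=np.zeros(40), omega=omega, g=0.0, C=fixture_sc)
        low = np.mean(
            [
                simulated_fcd_values(template.with_params(g=0.5), 300, 2.0, 50 + t).mean()
                for t in range(5)
            ]
        )
        high = np.mean(
            [
                simulated_fcd_values(template.with_params(g=2.0), 300, 2.0, 60 + t).mean()
                for t in range(5)
            ]
        )
        assert high > low
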