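import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crneutral import (
    build_generalist_matrix,
    build_specialist_matrix,
    calibrate_community,
    equilibrium_residual,
    fit_logseries_p,
    jacobian_at,
    ode_rhs,
    predict_generalist_threshold,
    predict_specialist_threshold,
    drift_timescale,
    spectrum_split,
)
from crneutral.theory import gamma_coefficient


def _numeric_jacobian(params, C, R0, N0, h=1e-6):
    K, S = params.K, params.S
    x0 = np.concatenate([R0, N0])

    def f(x):
        dR, dN = ode_rhs(x[:K], x[K:], params, C)
        return np.concatenate([dR, dN])

    J = np.zeros((K + S, K + S))
    for j in range(K + S):
        step = h * max(1.0, abs(x0[j]))
        xp, xm = x0.copy(), x0.copy()
        xp[j] += step
        xm[j] -= step
        J[:, j] = (f(xp) - f(xm)) / (2 * step)
    return J


class TestOdeRhs:
    def test_zero_at_calibrated_point(self):
        C = build_generalist_matrix(4, 4, mean=1.0, cv=0.3, seed=2)
        params = calibrate_community(C, n=30, r=12, eps=0.7)
        assert equilibrium_residual(params, C, np.full(4, 12.0), np.full(4, 30.0)) < 1e-9

    def test_extinct_consumer_is_absorbing(self):
        C = build_specialist_matrix(3, 2.0, 1.0)
        params = calibrate_community(C, n=10, r=5)
        _, dN = ode_rhs(np.full(3, 5.0), np.zeros(3), params, C)
        assert np.all(dN == 0)

    def test_term_by_term_hand_evaluation(self):
        C = build_specialist_matrix(2, 2.0, 1.0)
        params = calibrate_community(C, n=1, r=1, eps=1.0)  # rho=(3,3), eta=(3,3)
        R, N = np.array([2.0, 1.0]), np.array([3.0, 4.0])
        dR, dN = ode_rhs(R, N, params, C)
        # dR_1 = 3 - 2*(2*3 + 1*4) = -17 ; dR_2 = 3 - 1*(1*3 + 2*4) = -8
        assert np.allclose(dR, [-17.0, -8.0])
        # dN_1 = 3*(2*2 + 1*1) - 3*3 = 6 ; dN_2 = 4*(1*2 + 2*1) - 3*4 = 4
        assert np.allclose(dN, [6.0, 4.0])

    def test_residual_detects_perturbation(self):
        C = build_specialist_matrix(3, 2.0, 1.0)
        params = calibrate_community(C, n=10, r=5)
        assert equilibrium_residual(params, C, np.full(3, 5.5), np.full(3, 10.0)) > 0

    def test_residual_at_root_finder_solution(self):
        from scipy import optimize

        C = build_generalist_matrix(3, 3, mean=1.0, cv=0.4, seed=5)
        params = calibrate_community(C, n=20, r=8, eps=0.9)

        def f(x):
            dR, dN = ode_rhs(x[:3], x[3:], params, C)
            return np.concatenate([dR, dN])

        sol = optimize.fsolve(
            f, np.concatenate([np.full(3, 9.0), np.full(3, 18.0)]), xtol=1e-13
        )
        # residual relative to the rate scale of the system
        assert equilibrium_residual(params, C, sol[:3], sol[3:]) < 1e-8 * params.rho.max()


class TestJacobian:
    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10**6), S=st.integers(2, 6), eps=st.floats(0.2, 1.0))
    def test_analytic_matches_finite_differences(self, seed, S, eps):
        C = build_generalist_matrix(S, S, mean=1.0, cv=0.3, seed=seed)
        params = calibrate_community(C, n=25, r=10, eps=eps)
        rng = np.random.default_rng(seed)
        R0 = rng.uniform(5, 15, S)
        N0 = rng.uniform(10, 40, S)
        J = jacobian_at(params, C, R0, N0)
        J_num = _numeric_jacobian(params, C, R0, N0)
        assert np.allclose(J, J_num, rtol=1e-5, atol=1e-5 * np.abs(J).max())

    def test_consumer_block_vanishes_at_neutral_fixed_point(self):
        C = build_specialist_matrix(4, 1.0, 1.0)
        params = calibrate_community(C, n=10, r=5)
        J = jacobian_at(params, C)
        assert np.allclose(J[4:, 4:], 0.0, atol=1e-12)

    def test_shape(self):
        C = build_generalist_matrix(3, 5, mean=1.0, cv=0.1, seed=0)
        params = calibrate_community(C, n=10, r=5)
        assert jacobian_at(params, C).shape == (8, 8)


class TestSpectrum:
    def test_neutral_2x2_closed_form(self):
        # neutral S=K=2, mu=1, n=10, r=5: spectrum {-20, 0, -10 +- 10i}
        C = build_specialist_matrix(2, 1.0, 1.0)
        params = calibrate_community(C, n=10, r=5)
        eig = np.linalg.eigvals(jacobian_at(params, C))
        expected = np.array([-20.0, 0.0, -10 + 10j, -10 - 10j])
        assert np.allclose(np.sort_complex(eig), np.sort_complex(expected), atol=1e-9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sp = spectrum_split(jacobian_at(params, C), 2, 2)
        assert 0.0 in np.round(sp.eigenvalues[sp.consumer_bulk].real, 9)

    @pytest.mark.parametrize("S", [5, 20, 50])
    def test_neutral_limit_has_s_minus_1_zero_modes(self, S):
        C = build_specialist_matrix(S, 1.0, 1.0)
        params = calibrate_community(C, n=100, r=100)
        sp = spectrum_split(jacobian_at(params, C), S, S)
        assert np.sum(np.abs(sp.eigenvalues) < 1e-8) == S - 1
        assert sp.lambda_plus == pytest.approx(0.0, abs=1e-8)

    def test_specialist_spectrum_continuous_at_neutral_limit(self):
        base = build_specialist_matrix(6, 1.0, 1.0)
        params = calibrate_community(base, n=50, r=50)
        eig0 = np.sort(np.linalg.eigvals(jacobian_at(params, base)).real)
        C = build_specialist_matrix(6, 1.0 + 1e-6, 1.0)
        p2 = calibrate_community(C, n=50, r=50)
        eig1 = np.sort(np.linalg.eigvals(jacobian_at(p2, C)).real)
        assert np.allclose(eig0, eig1, atol=1e-3)

    def test_lambda_plus_grows_with_specialisation(self):
        vals = []
        for ratio in (1.5, 2.0, 4.0, 8.0):
            C = build_specialist_matrix(20, ratio, 1.0)
            params = calibrate_community(C, n=50, r=50)
            vals.append(abs(spectrum_split(jacobian_at(params, C), 20, 20).lambda_plus))
        assert np.all(np.diff(vals) > 0)

    def test_lambda_plus_grows_with_cv(self):
        medians = []
        for cv in (0.05, 0.15, 0.3, 0.5):
            lams = [
                abs(
                    spectrum_split(
                        jacobian_at(
                            calibrate_community(
                                build_generalist_matrix(20, 20, 1.0, cv, seed=s), 50, 50
                            ),
                            build_generalist_matrix(20, 20, 1.0, cv, seed=s),
                        ),
                        20,
                        20,
                    ).lambda_plus
                )
                for s in range(7)
            ]
            medians.append(np.median(lams))
        assert np.all(np.diff(medians) > 0)

    @pytest.mark.parametrize("n,r", [(100, 100), (245, 100), (500, 100)])
    def test_timescale_separation_structural(self, n, r):
        C = build_generalist_matrix(50, 50, mean=1.0, cv=0.2, seed=4)
        params = calibrate_community(C, n=n, r=r)
        sp = spectrum_split(jacobian_at(params, C), 50, 50)
        assert sp.separation_ratio >= 10


class TestThresholds:
    def test_generalist_leading_term(self):
        assert predict_generalist_threshold(50, 245, 100, correction=False) == pytest.approx(
            np.sqrt(50 / 980), rel=1e-12
        )

    def test_generalist_power_law_exponent(self):
        t_n = predict_generalist_threshold(50, 100, 10, correction=False)
        t_4n = predict_generalist_threshold(50, 400, 10, correction=False)
        assert t_n / t_4n == pytest.approx(2.0, rel=1e-12)

    def test_generalist_increasing_in_s(self):
        ts = [predict_generalist_threshold(S, 100, 50) for S in (10, 20, 50, 100)]
        assert np.all(np.diff(ts) > 0)

    def test_generalist_invalid_correction_raises(self):
        with pytest.raises(ValueError):
            predict_generalist_threshold(50, 10, 100, eps=1.0)

    def test_gamma_value(self):
        assert gamma_coefficient(100, 100, 1.0) == pytest.approx(0.005)

    def test_specialist_neutral_limit(self):
        # gamma = 0 when eps*r = 2n
        assert predict_specialist_threshold(50, 100, 200, 1.0) == pytest.approx(1.0)

    def test_specialist_hand_value(self):
        # gamma = 0.005 at n = r = 100: (1 + 0.005*49)/0.995
        assert predict_specialist_threshold(50, 100, 100, 1.0) == pytest.approx(1.2512562814, rel=1e-9)

    def test_specialist_linear_in_s(self):
        g = gamma_coefficient(100, 100, 1.0)
        diff = predict_specialist_threshold(100, 100, 100) - predict_specialist_threshold(50, 100, 100)
        assert diff == pytest.approx(g * 50 / (1 - g), rel=1e-12)


class TestDriftTimescale:
    def test_t1_reduction(self):
        p = 0.5
        assert drift_timescale(1, p, eta_bar=2.0) == pytest.approx(-np.log(0.5) / 0.5 / 2.0)

    def test_monotone_in_n(self):
        p = fit_logseries_p(50.0)
        ts = [drift_timescale(n, p, 1.0) for n in (5, 20, 80, 320)]
        assert np.all(np.diff(ts) > 0)

    def test_stabilization_vs_drift_ratio_decreases_with_cv(self):
        """Timescale ratio predicting drift dominance falls as CV grows."""
        p = fit_logseries_p(50.0)
        ratios = []
        for cv in (0.05, 0.2, 0.4):
            meds = []
            for s in range(5):
                C = build_generalist_matrix(20, 20, 1.0, cv, seed=s)
                params = calibrate_community(C, 50, 50)
                sp = spectrum_split(jacobian_at(params, C), 20, 20)
                meds.append(sp.stabilization_timescale / drift_timescale(50, p, params.eta_bar))
            ratios.append(np.median(meds))
        assert np.all(np.diff(ratios) < 0)
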