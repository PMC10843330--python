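"""Forward model, parameter mappings and fitting of the recoil circuit."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from wingrheo.rheology import (
    DisplacementTrace,
    FitError,
    MechanicalParams,
    RelaxationParams,
    active_stress,
    compare_exponential_orders,
    displacement,
    fast_fraction,
    fit_relaxation,
    initial_recoil_velocity,
    recoil_anisotropy,
    relaxation_from_mechanics,
    relaxed_fraction,
)
from wingrheo.synthetic import generate_trace

from conftest import random_mechanics


def ode_displacement(mech: MechanicalParams, t_eval: np.ndarray) -> np.ndarray:
    """Independent oracle: stiff-safe integration of the two force-balance
    ODEs (sigma = k_i x_i + eta_i dx_i/dt) from the pre-ablation equilibrium."""
    kappa = mech.kappa
    x0 = [mech.sigma * (1 - kappa) / mech.kf, mech.sigma * (1 - kappa) / mech.ks]

    def rhs(t, x):
        return [
            (mech.sigma - mech.kf * x[0]) / mech.eta_f,
            (mech.sigma - mech.ks * x[1]) / mech.eta_s,
        ]

    sol = solve_ivp(
        rhs, (0, float(t_eval[-1])), x0, t_eval=t_eval, method="LSODA",
        rtol=1e-11, atol=1e-13,
    )
    return sol.y.sum(axis=0) - sum(x0)


class TestDisplacement:
    def test_zero_at_t0(self, midband_params):
        assert displacement(0.0, midband_params) == 0.0

    def test_saturates_to_total(self, midband_params):
        t_inf = 1e6 * midband_params.tau_s
        assert displacement(t_inf, midband_params) == pytest.approx(9.2, abs=1e-6)

    def test_matches_ode_oracle_at_gap(self, midband_params):
        """dx(0.65 s) from the closed form agrees with direct ODE integration.

        Mechanics are constructed to realise the midband observables: with
        sigma, k free and c = sigma*kappa, the constraint kbar = c/(Xf+Xs)
        gives the quadratic c^2/S + c*k - sigma*k = 0.
        """
        sigma, k, S = 10.0, 1.0, 2.2 + 7.0
        c = (-k + np.sqrt(k**2 + 4 * sigma * k / S)) * S / 2
        kf, ks = c / 2.2, c / 7.0
        mech = MechanicalParams(sigma=sigma, k=k, kf=kf, ks=ks,
                                eta_f=0.65 * kf, eta_s=20.0 * ks)
        p = relaxation_from_mechanics(mech)
        assert p.X_f == pytest.approx(2.2, rel=1e-9)
        assert p.X_s == pytest.approx(7.0, rel=1e-9)
        oracle = ode_displacement(mech, np.array([1e-9, 0.65]))[-1]
        assert displacement(0.65, midband_params) == pytest.approx(oracle, rel=1e-4)
        assert displacement(0.65, midband_params) == pytest.approx(1.615, abs=5e-4)

    def test_ode_oracle_equivalence_random_parameter_sets(self):
        """Closed form vs stiff ODE integration to 1e-4 relative on a 1000-point
        grid over [0, 5*tau_s], for 20 random valid mechanical parameter sets."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            mech = random_mechanics(rng)
            p = relaxation_from_mechanics(mech)
            t = np.linspace(1e-6, 5 * p.tau_s, 1000)
            closed = displacement(t, p)
            oracle = ode_displacement(mech, t)
            scale = p.X_f + p.X_s
            assert np.max(np.abs(closed - oracle)) / scale < 1e-4

    def test_rejects_negative_time(self, midband_params):
        with pytest.raises(ValueError):
            displacement(-0.1, midband_params)

    @given(st.floats(0.01, 100), st.floats(1.01, 10))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_strictly_increasing_in_t(self, t, factor):
        p = RelaxationParams(2.2, 7.0, 0.65, 20.0)
        assert displacement(t * factor, p) > displacement(t, p)


class TestMechanicsMapping:
    def test_exact_rational_example(self):
        """sigma=10, k=1, kf=10, ks=1, eta_f=6.5, eta_s=20: recompute the
        algebra with exact rational arithmetic as the oracle."""
        kbar = Fraction(10 * 1, 10 + 1)
        kappa = Fraction(1, 1) / (1 + kbar)
        assert kappa == Fraction(11, 21)
        p = relaxation_from_mechanics(MechanicalParams(10, 1, 10, 1, 6.5, 20))
        assert p.X_f == pytest.approx(float(10 * kappa / 10), rel=1e-12)
        assert p.X_s == pytest.approx(float(10 * kappa / 1), rel=1e-12)
        assert p.tau_f == pytest.approx(0.65)
        assert p.tau_s == pytest.approx(20.0)

    def test_vanishing_ablated_spring_releases_nothing(self):
        mech = MechanicalParams(sigma=10, k=1e-12, kf=10, ks=1, eta_f=6.5, eta_s=20)
        p = relaxation_from_mechanics(mech)
        assert mech.kappa < 2e-12
        assert p.X_f + p.X_s < 1e-10

    def test_total_displacement_conservation(self):
        """Xf + Xs equals the new-minus-old equilibrium length
        sigma/kbar - sigma/(k + kbar) for any valid mechanics."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            mech = random_mechanics(rng)
            p = relaxation_from_mechanics(mech)
            expected = mech.sigma / mech.kbar - mech.sigma / (mech.k + mech.kbar)
            assert p.X_f + p.X_s == pytest.approx(expected, rel=1e-10)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            MechanicalParams(1, 1, -1, 1, 1, 1)
        m = MechanicalParams(1, 1, 2, 3, 1, 1)
        assert m.kbar < min(m.kf, m.ks)
        assert 0 < m.kappa < 1


class TestVelocityProxies:
    def test_small_gap_limit(self, midband_params):
        v = initial_recoil_velocity(midband_params, 1e-6)
        assert v == pytest.approx(2.2 / 0.65 + 7.0 / 20.0, rel=1e-5)

    def test_midband_value(self, midband_params):
        assert initial_recoil_velocity(midband_params, 0.65) == pytest.approx(
            displacement(0.65, midband_params) / 0.65, rel=1e-12
        )
        assert initial_recoil_velocity(midband_params, 0.65) == pytest.approx(2.484, abs=5e-4)

    def test_pure_fast_element(self):
        p = RelaxationParams(2.2, 1e-9, 0.65, 20.0)
        v = initial_recoil_velocity(p, 0.65)
        assert v == pytest.approx(2.2 * (1 - np.exp(-1)) / 0.65, rel=1e-6)

    @given(st.floats(0.05, 5), st.floats(1.1, 5))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_strictly_decreasing_in_gap(self, dt, factor):
        p = RelaxationParams(2.2, 7.0, 0.65, 20.0)
        assert initial_recoil_velocity(p, dt * factor) < initial_recoil_velocity(p, dt)

    def test_rejects_nonpositive_gap(self, midband_params):
        with pytest.raises(ValueError):
            initial_recoil_velocity(midband_params, 0.0)


class TestFastFraction:
    def test_pure_fast_is_one(self):
        p = RelaxationParams(2.2, 1e-300, 0.65, 20.0)
        assert fast_fraction(p, 0.65) == pytest.approx(1.0)

    def test_symmetric_is_half(self):
        p = RelaxationParams(3.0, 3.0, 5.0, 5.0)
        assert fast_fraction(p, 1.0) == pytest.approx(0.5)

    def test_midband_dominated_by_fast_element(self, midband_params):
        assert fast_fraction(midband_params, 0.65) == pytest.approx(0.861, abs=5e-4)

    @given(st.floats(0.1, 3), st.floats(1.1, 4))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_decreasing_in_gap_when_timescales_separated(self, dt, factor):
        p = RelaxationParams(2.2, 7.0, 0.65, 20.0)
        assert fast_fraction(p, dt * factor) < fast_fraction(p, dt)


class TestRelaxedFraction:
    def test_one_timescale_elapsed(self):
        assert relaxed_fraction(0.65, 0.65) == pytest.approx(1 - np.exp(-1), rel=1e-12)
        assert round(100 * relaxed_fraction(0.65, 0.65)) == 63

    def test_slow_element_barely_relaxed(self):
        frac = relaxed_fraction(20.0, 0.65)
        assert frac == pytest.approx(0.032, abs=5e-4)
        assert frac <= 0.05

    def test_zero_gap(self):
        assert relaxed_fraction(5.0, 0.0) == 0.0

    def test_rejects_nonpositive_tau(self):
        with pytest.raises(ValueError):
            relaxed_fraction(0.0, 1.0)


class TestScalars:
    def test_recoil_anisotropy(self):
        assert recoil_anisotropy(2.5, 2.5) == 0.0
        assert recoil_anisotropy(3.0, 1.0) == 2.0
        assert recoil_anisotropy(1.0, 3.0) == -recoil_anisotropy(3.0, 1.0)

    def test_active_stress_sign_convention(self):
        assert active_stress(0.1, 0.1) == pytest.approx(0.0)
        assert active_stress(0.15, 0.05) == pytest.approx(0.10)
        assert active_stress(0.0, 0.05) == pytest.approx(-0.05)


class TestFit:
    truth = RelaxationParams(X_f=2.0, X_s=6.5, tau_f=0.7, tau_s=18.0)

    def test_noiseless_recovery(self):
        trace = generate_trace(self.truth, duration=120.0, noise_sd=0.0)
        fit = fit_relaxation(trace)
        assert fit.converged
        for attr in ("X_f", "X_s", "tau_f", "tau_s"):
            assert getattr(fit.params, attr) == pytest.approx(
                getattr(self.truth, attr), rel=1e-3
            )

    def test_noisy_recovery_within_calibrated_tolerance(self):
        trace = generate_trace(self.truth, duration=120.0, noise_sd=0.15, seed=11)
        fit = fit_relaxation(trace)
        assert abs(fit.params.X_s - self.truth.X_s) / self.truth.X_s < 0.05
        assert abs(fit.params.tau_s - self.truth.tau_s) / self.truth.tau_s < 0.15

    def test_fit_is_deterministic(self):
        trace = generate_trace(self.truth, duration=60.0, noise_sd=0.15, seed=3)
        f1, f2 = fit_relaxation(trace), fit_relaxation(trace)
        assert f1.params == f2.params

    def test_round_trip_from_mechanics(self):
        mech = MechanicalParams(sigma=10, k=1, kf=10, ks=1, eta_f=6.5, eta_s=20)
        p = relaxation_from_mechanics(mech)
        trace = generate_trace(p, duration=5 * p.tau_s, noise_sd=0.0)
        fit = fit_relaxation(trace)
        for attr in ("X_f", "X_s", "tau_f", "tau_s"):
            assert getattr(fit.params, attr) == pytest.approx(getattr(p, attr), rel=1e-3)

    def test_nested_models_on_single_exponential_truth(self):
        single = RelaxationParams(3.0, 3.0, 12.0, 12.0)
        trace = generate_trace(single, duration=120.0, noise_sd=0.05, seed=5)
        f1 = fit_relaxation(trace, model_order=1)
        f2 = fit_relaxation(trace, model_order=2)
        assert f2.residual_rms <= f1.residual_rms + 1e-6
        assert f1.residual_rms / f2.residual_rms < 1.05  # no real gain from order 2

    def test_identifiability_noisy_replicates(self):
        """Median relative bias of Xf+Xs < 5% over noisy replicates when the
        timescales are separated by >= 10x and both X terms >= 0.5 um."""
        rng = np.random.default_rng(0)
        biases = []
        for s in range(40):
            trace = generate_trace(self.truth, duration=90.0, noise_sd=0.15, seed=int(rng.integers(2**31)))
            fit = fit_relaxation(trace)
            total = fit.params.X_f + fit.params.X_s
            biases.append((total - 8.5) / 8.5)
        assert np.median(np.abs(biases)) < 0.05

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            fit_relaxation(
                DisplacementTrace(times=np.arange(4.0), displacements=np.arange(4.0))
            )

    def test_constant_trace_rejected(self):
        with pytest.raises(FitError):
            fit_relaxation(
                DisplacementTrace(times=np.arange(10.0), displacements=np.ones(10))
            )

    def test_monotone_decreasing_trace_flagged(self):
        trace = DisplacementTrace(
            times=np.arange(10.0), displacements=np.linspace(5, 1, 10)
        )
        fit = fit_relaxation(trace)
        assert "monotone_decreasing_trace" in fit.flags


class TestModelSelection:
    def test_double_exponential_truth_prefers_order_two(self, midband_params):
        trace = generate_trace(midband_params, duration=90.0, noise_sd=0.05, seed=1)
        assert compare_exponential_orders(trace)["preferred_order"] == 2

    def test_single_exponential_truth_prefers_order_one(self):
        p = RelaxationParams(4.0, 4.0, 15.0, 15.0)
        trace = generate_trace(p, duration=90.0, noise_sd=0.05, seed=2)
        assert compare_exponential_orders(trace)["preferred_order"] == 1

    def test_degenerate_equal_timescales_prefer_order_one(self):
        p = RelaxationParams(2.0, 6.5, 10.0, 10.0)
        trace = generate_trace(p, duration=90.0, noise_sd=0.02, seed=3)
        assert compare_exponential_orders(trace)["preferred_order"] == 1


class TestRelaxationParamsType:
    def test_canonical_ordering_swaps_elements(self):
        p = RelaxationParams(X_f=7.0, X_s=2.2, tau_f=20.0, tau_s=0.65)
        assert p.tau_f == 0.65 and p.tau_s == 20.0
        assert p.X_f == 2.2 and p.X_s == 7.0

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            RelaxationParams(0.0, 1.0, 1.0, 2.0)

    def test_trace_validation(self):
        with pytest.raises(ValueError):
            DisplacementTrace(times=np.array([0.0, 0.0, 1.0]), displacements=np.zeros(3))
        with pytest.raises(ValueError):
            DisplacementTrace(times=np.array([0.0, 1.0]), displacements=np.array([np.nan, 1.0]))
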