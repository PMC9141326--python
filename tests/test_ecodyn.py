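"""Predator-prey dynamics: conservation, trait gradients, damping contrast."""

import numpy as np
import pytest

from metatempo.ecodyn import (
    EcoEvoParams,
    EcoEvoState,
    LVParams,
    integrate,
    lv_derivatives,
    lv_equilibrium,
    lv_invariant,
    oscillation_peaks,
    predator_fitness,
    prey_fitness,
    trait_gradients,
)
from metatempo.envstreams import ValidationError

LV = LVParams(alpha0=1.0, beta0=0.1, gamma0=1.5, delta0=0.075)
DAMPED = EcoEvoParams(lv=LV, V1=0.25, V2=0.03, c1=1.0, c2=3.0, conversion=0.75)
INIT = EcoEvoState(x=10.0, y=5.0)


class TestDerivativesAndInvariant:
    def test_hand_arithmetic(self):
        dx, dy = lv_derivatives(EcoEvoState(x=10.0, y=5.0), LV)
        assert (dx, dy) == (5.0, -3.75)

    def test_coexistence_equilibrium_is_stationary(self):
        xeq, yeq = lv_equilibrium(LV)
        assert (xeq, yeq) == (20.0, 10.0)
        dx, dy = lv_derivatives(EcoEvoState(x=xeq, y=yeq), LV)
        assert dx == pytest.approx(0.0, abs=1e-14)
        assert dy == pytest.approx(0.0, abs=1e-14)

    def test_predator_free_limit_is_exponential_growth(self):
        dx, dy = lv_derivatives(EcoEvoState(x=7.0, y=0.0), LV)
        assert dx == pytest.approx(LV.alpha0 * 7.0)
        assert dy == 0.0

    def test_invariant_time_derivative_vanishes(self):
        """Finite-difference oracle: V is constant along the vector field."""
        rng = np.random.default_rng(0)
        h = 1e-6
        for _ in range(30):
            x, y = rng.uniform(1.0, 40.0, size=2)
            dx, dy = lv_derivatives(EcoEvoState(x=x, y=y), LV)
            v0 = lv_invariant(EcoEvoState(x=x, y=y), LV)
            v1 = lv_invariant(EcoEvoState(x=x + h * dx, y=y + h * dy), LV)
            assert abs(v1 - v0) / h < 1e-4 * max(abs(v0), 1.0)

    def test_invariant_minimized_at_equilibrium(self):
        rng = np.random.default_rng(1)
        veq = lv_invariant(EcoEvoState(*lv_equilibrium(LV)), LV)
        for _ in range(200):
            x, y = rng.uniform(0.5, 60.0, size=2)
            assert lv_invariant(EcoEvoState(x=x, y=y), LV) >= veq

    def test_invariant_rejects_nonpositive_densities(self):
        with pytest.raises(ValidationError):
            lv_invariant(EcoEvoState(x=0.0, y=1.0), LV)


class TestTraitGradients:
    def test_zero_variance_freezes_traits(self):
        frozen = EcoEvoParams(lv=LV, V1=0.0, V2=0.0, conversion=0.75)
        assert trait_gradients(EcoEvoState(x=10, y=5, u=0.3, v=-0.2), frozen) == (0.0, 0.0)

    def test_gradients_vanish_at_trait_equilibrium(self):
        # Choose (x, y) that zero both mutant gradients at given (u, v).
        u, v = 0.4, 0.2
        beta = DAMPED.beta(u, v)
        y = 2 * DAMPED.c1 * u / beta
        x = 2 * DAMPED.c2 * v / (DAMPED.conversion * beta)
        du, dv = trait_gradients(EcoEvoState(x=x, y=y, u=u, v=v), DAMPED)
        assert du == pytest.approx(0.0, abs=1e-12)
        assert dv == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("response", ["mass_action", "holling2"])
    def test_analytic_gradients_match_finite_differences(self, response):
        params = EcoEvoParams(
            lv=LV, V1=0.7, V2=0.4, c1=0.8, c2=1.3, conversion=0.6,
            functional_response=response, K=50.0, h=0.2,
        )
        rng = np.random.default_rng(2)
        h = 1e-6
        for _ in range(100):
            state = EcoEvoState(
                x=rng.uniform(1, 40), y=rng.uniform(1, 20),
                u=rng.uniform(-0.5, 0.5), v=rng.uniform(-0.5, 0.5),
            )
            du, dv = trait_gradients(state, params)
            fd_u = (prey_fitness(state.u + h, state, params) - prey_fitness(state.u - h, state, params)) / (2 * h)
            fd_v = (predator_fitness(state.v + h, state, params) - predator_fitness(state.v - h, state, params)) / (2 * h)
            assert du == pytest.approx(params.V1 * fd_u, rel=1e-6, abs=1e-9)
            assert dv == pytest.approx(params.V2 * fd_v, rel=1e-6, abs=1e-9)


class TestIntegration:
    def test_conserved_quantity_bounds_integration_error(self):
        traj = integrate("lv", INIT, LV, (0.0, 100.0), n_points=4001)
        v0 = lv_invariant(INIT, LV)
        drift = max(
            abs(lv_invariant(EcoEvoState(x=x, y=y), LV) - v0)
            for x, y in zip(traj.column("x"), traj.column("y"))
        )
        assert drift / abs(v0) <= 1e-6

    def test_prey_peaks_precede_predator_peaks(self):
        traj = integrate("lv", INIT, LV, (0.0, 100.0), n_points=4001)
        px, _ = oscillation_peaks(traj, "x")
        py, _ = oscillation_peaks(traj, "y")
        assert len(px) >= 3
        for t_prey, _ in px:
            following = [t for t, _ in py if t > t_prey]
            if following:  # each prey peak is chased by a predator peak
                assert following[0] - t_prey < 5.5  # within the same cycle (~5.5 time units)
        # pairwise: k-th predator peak strictly after k-th prey peak
        for (tp, _), (tq, _) in zip(px, py):
            assert tq > tp

    def test_pure_lv_amplitude_envelope_is_flat(self):
        traj = integrate("lv", INIT, LV, (0.0, 100.0), n_points=4001)
        _, amps = oscillation_peaks(traj, "x")
        amps = np.array(amps)
        assert len(amps) >= 5
        assert (amps.max() - amps.min()) / amps.mean() < 0.05

    def test_damped_coevolution_contrast(self):
        """Trait feedback turns neutral cycles into damped oscillations."""
        coevo = integrate("lv_coevo", INIT, DAMPED, (0.0, 100.0), n_points=4001)
        _, amps = oscillation_peaks(coevo, "x")
        assert len(amps) >= 3
        assert amps[1] < amps[0] and amps[2] < amps[1]
        x = coevo.column("x")
        n = len(x)
        cv_first = x[: n // 5].std() / x[: n // 5].mean()
        cv_last = x[-n // 5 :].std() / x[-n // 5 :].mean()
        assert cv_last < 0.1 * cv_first
        lv_traj = integrate("lv", INIT, LV, (0.0, 100.0), n_points=4001)
        xl = lv_traj.column("x")
        cv_first_lv = xl[: n // 5].std() / xl[: n // 5].mean()
        cv_last_lv = xl[-n // 5 :].std() / xl[-n // 5 :].mean()
        assert cv_last_lv >= 0.8 * cv_first_lv

    def test_vanishing_variance_recovers_pure_lv(self):
        tiny = EcoEvoParams(lv=LV, V1=1e-6, V2=1e-6, c1=1.0, c2=3.0, conversion=0.75)
        coevo = integrate("lv_coevo", INIT, tiny, (0.0, 50.0), n_points=1001)
        pure = integrate("lv", INIT, LV, (0.0, 50.0), n_points=1001)
        sup = np.max(np.abs(coevo.column("x") - pure.column("x")))
        bigger = EcoEvoParams(lv=LV, V1=1e-3, V2=1e-3, c1=1.0, c2=3.0, conversion=0.75)
        coevo2 = integrate("lv_coevo", INIT, bigger, (0.0, 50.0), n_points=1001)
        sup2 = np.max(np.abs(coevo2.column("x") - pure.column("x")))
        assert sup < sup2  # discrepancy shrinks with the variance
        assert sup < 0.05  # and is already tiny at V = 1e-6

    def test_rm_equilibrium_agrees_with_root_finding(self):
        params = EcoEvoParams(
            lv=LV, V1=0.0, V2=0.0, conversion=0.75, functional_response="holling2", K=100.0, h=0.1
        )
        # closed-form interior equilibrium of the Holling-II system
        b, g, c = LV.beta0, LV.gamma0, params.conversion
        x_star = g / (b * (c - g * params.h))
        y_star = LV.alpha0 * (1 - x_star / params.K) * (1 + b * params.h * x_star) / b
        from scipy.optimize import fsolve

        def rhs(z):
            x, y = z
            denom = 1 + b * params.h * x
            return [
                LV.alpha0 * x * (1 - x / params.K) - b * x * y / denom,
                c * b * x * y / denom - g * y,
            ]

        root = fsolve(rhs, [x_star * 1.1, y_star * 0.9], full_output=False, xtol=1e-12)
        assert root == pytest.approx([x_star, y_star], abs=1e-8)
        assert np.max(np.abs(rhs([x_star, y_star]))) < 1e-10

    def test_bad_system_and_params_rejected(self):
        with pytest.raises(ValidationError):
            integrate("foo", INIT, LV, (0, 10))
        with pytest.raises(ValidationError):
            integrate("lv", INIT, DAMPED, (0, 10))
        with pytest.raises(ValidationError):
            integrate("rm", INIT, DAMPED, (0, 10))  # mass-action params for a holling2 system


class TestPeaks:
    def test_constant_trajectory_has_no_peaks(self):
        traj = integrate("lv", EcoEvoState(*lv_equilibrium(LV)), LV, (0.0, 10.0), n_points=101)
        peaks, amps = oscillation_peaks(traj, "x")
        assert peaks == [] and amps == []

    def test_sine_fixture_recovered_at_sample_resolution(self):
        import pandas as pd

        from metatempo.ecodyn import Trajectory

        t = np.linspace(0, 4 * np.pi, 1001)
        series = np.sin(t)
        traj = Trajectory(times=t, states=pd.DataFrame({"t": t, "x": series, "y": series}))
        peaks, amps = oscillation_peaks(traj, "x")
        expected = [np.pi / 2, 2 * np.pi + np.pi / 2]
        assert len(peaks) == 2
        for (tp, vp), te in zip(peaks, expected):
            assert tp == pytest.approx(te, abs=t[1] - t[0])
            assert vp == pytest.approx(1.0, abs=1e-4)
        assert amps == pytest.approx([2.0, 2.0], abs=1e-3)
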