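"""Eco-evolutionary predator-prey dynamics.

Ecology is the classic Lotka-Volterra pair

    dx/dt = alpha*x - beta*x*y
    dy/dt = delta*x*y - gamma*y

with prey density ``x``, predator density ``y`` and positive rates alpha
(prey growth), beta (attack), gamma (predator death), delta (conversion of
prey into predators). The pure system is conservative: it admits the first
integral ``V = delta*x - gamma*ln x + beta*y - alpha*ln y``, which the
integrator must hold constant and which therefore doubles as an accuracy
oracle. A Rosenzweig-MacArthur variant replaces exponential prey growth
with logistic growth to carrying capacity ``K`` and mass-action attack with
a Holling type-II (handling-time-saturated) functional response.

Coevolution enters through two quantitative traits — prey defense ``u`` and
predator offense ``v`` — that deform the rates:

    alpha(u) = alpha0 - c1*u**2        (defense costs growth)
    beta(u, v) = beta0 * exp(v - u)    (attack = offense minus defense)
    gamma(v) = gamma0 + c2*v**2        (offense costs maintenance)
    delta(u, v) = conversion * beta(u, v)

Each trait follows the standard quantitative-genetics / adaptive-dynamics
gradient: its rate of change is the population's genetic variance times the
derivative of an individual's per-capita growth rate with respect to *its
own* (mutant) trait, evaluated at the resident value. The quadratic costs
guarantee interior trait equilibria; the trait feedback damps the neutral
ecological cycles, which is the qualitative contrast the shipped
``coevo_damped`` configuration demonstrates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .envstreams import ValidationError

__all__ = [
    "LVParams",
    "EcoEvoParams",
    "EcoEvoState",
    "Trajectory",
    "lv_derivatives",
    "lv_invariant",
    "prey_fitness",
    "predator_fitness",
    "trait_gradients",
    "integrate",
    "oscillation_peaks",
    "lv_equilibrium",
]

SystemName = Literal["lv", "lv_coevo", "rm", "rm_coevo"]

EXTINCTION_FLOOR = 1e-9


class IntegrationError(RuntimeError):
    """Solver failure; carries the last accepted time and state."""

    def __init__(self, message: str, t_last: float, y_last: np.ndarray):
        super().__init__(f"{message} (last accepted t={t_last:.6g}, state={y_last.tolist()})")
        self.t_last = t_last
        self.y_last = y_last


@dataclass(frozen=True)
class LVParams:
    """Baseline Lotka-Volterra rates; all strictly positive."""

    alpha0: float
    beta0: float
    gamma0: float
    delta0: float

    def __post_init__(self) -> None:
        for name in ("alpha0", "beta0", "gamma0", "delta0"):
            val = getattr(self, name)
            if not (np.isfinite(val) and val > 0):
                raise ValidationError(f"{name} must be a positive real, got {val!r}")


@dataclass(frozen=True)
class EcoEvoParams:
    """Trait-coupled parameters.

    ``V1``/``V2`` are the genetic variances of the prey and predator trait
    (each multiplies its own population's fitness gradient); ``c1``/``c2``
    the quadratic trait cost coefficients; ``conversion`` the fixed
    efficiency turning attack into predator growth. ``functional_response``
    selects mass-action or Holling type II (with carrying capacity ``K``
    and handling time ``h``).
    """

    lv: LVParams
    V1: float = 0.0
    V2: float = 0.0
    c1: float = 0.1
    c2: float = 0.1
    conversion: float = 0.5
    functional_response: Literal["mass_action", "holling2"] = "mass_action"
    K: float = 100.0
    h: float = 0.1

    def __post_init__(self) -> None:
        if self.V1 < 0 or self.V2 < 0:
            raise ValidationError("genetic variances V1, V2 must be non-negative")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValidationError("trait cost coefficients c1, c2 must be positive")
        if self.conversion <= 0:
            raise ValidationError("conversion must be positive")
        if self.functional_response not in ("mass_action", "holling2"):
            raise ValidationError(f"unknown functional_response {self.functional_response!r}")
        if self.functional_response == "holling2" and (self.K <= 0 or self.h <= 0):
            raise ValidationError("K and h must be positive for the holling2 response")

    # Trait-dependent rates.
    def alpha(self, u: float) -> float:
        return self.lv.alpha0 - self.c1 * u * u

    def beta(self, u: float, v: float) -> float:
        return self.lv.beta0 * math.exp(v - u)

    def gamma(self, v: float) -> float:
        return self.lv.gamma0 + self.c2 * v * v

    def delta(self, u: float, v: float) -> float:
        return self.conversion * self.beta(u, v)


@dataclass(frozen=True)
class EcoEvoState:
    """Densities (x prey, y predator) and traits (u defense, v offense)."""

    x: float
    y: float
    u: float = 0.0
    v: float = 0.0

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValidationError("densities x, y must be non-negative")


@dataclass(frozen=True)
class Trajectory:
    """Integrated time series with solver metadata."""

    times: np.ndarray = field(repr=False)
    states: pd.DataFrame = field(repr=False)  # columns t, x, y[, u, v]
    system: str = "lv"
    rtol: float = 1e-8
    atol: float = 1e-10
    n_steps: int = 0

    def column(self, name: str) -> np.ndarray:
        return self.states[name].to_numpy()

    def to_csv(self, path) -> None:
        self.states.to_csv(path, index=False)


def lv_derivatives(state: EcoEvoState, params: LVParams) -> tuple[float, float]:
    """Pure Lotka-Volterra growth rates (dx/dt, dy/dt)."""
    x, y = state.x, state.y
    return (
        params.alpha0 * x - params.beta0 * x * y,
        params.delta0 * x * y - params.gamma0 * y,
    )


def lv_invariant(state: EcoEvoState, params: LVParams) -> float:
    """First integral V = delta*x - gamma*ln x + beta*y - alpha*ln y.

    Constant along exact trajectories of the pure system; its drift along a
    numerical trajectory bounds the integration error. Minimized at the
    coexistence equilibrium (gamma/delta, alpha/beta).
    """
    if state.x <= 0 or state.y <= 0:
        raise ValidationError("lv_invariant requires strictly positive densities")
    return (
        params.delta0 * state.x
        - params.gamma0 * math.log(state.x)
        + params.beta0 * state.y
        - params.alpha0 * math.log(state.y)
    )


def lv_equilibrium(params: LVParams) -> tuple[float, float]:
    """Coexistence equilibrium (x*, y*) = (gamma/delta, alpha/beta)."""
    return params.gamma0 / params.delta0, params.alpha0 / params.beta0


def prey_fitness(u_mutant: float, state: EcoEvoState, params: EcoEvoParams) -> float:
    """Per-capita growth of a rare prey mutant with defense ``u_mutant``.

    The mutant carries its own growth and attack rates, but the predator's
    saturation (Holling II denominator) is set by the resident prey.
    """
    x, y, u, v = state.x, state.y, state.u, state.v
    a = params.lv.alpha0 - params.c1 * u_mutant * u_mutant
    b_mut = params.lv.beta0 * math.exp(v - u_mutant)
    if params.functional_response == "mass_action":
        return a - b_mut * y
    b_res = params.beta(u, v)
    return a * (1.0 - x / params.K) - b_mut * y / (1.0 + b_res * params.h * x)


def predator_fitness(v_mutant: float, state: EcoEvoState, params: EcoEvoParams) -> float:
    """Per-capita growth of a rare predator mutant with offense ``v_mutant``."""
    x, u = state.x, state.u
    b_mut = params.lv.beta0 * math.exp(v_mutant - u)
    g = params.lv.gamma0 + params.c2 * v_mutant * v_mutant
    if params.functional_response == "mass_action":
        return params.conversion * b_mut * x - g
    return params.conversion * b_mut * x / (1.0 + b_mut * params.h * x) - g


def trait_gradients(state: EcoEvoState, params: EcoEvoParams) -> tuple[float, float]:
    """(du/dt, dv/dt): genetic variance times the mutant fitness gradient.

    Analytic derivatives of :func:`prey_fitness` / :func:`predator_fitness`
    with respect to the mutant trait, evaluated at the resident value.
    """
    x, y, u, v = state.x, state.y, state.u, state.v
    b = params.beta(u, v)
    if params.functional_response == "mass_action":
        dw1 = -2.0 * params.c1 * u + b * y
        dw2 = params.conversion * b * x - 2.0 * params.c2 * v
    else:
        denom = 1.0 + b * params.h * x
        dw1 = -2.0 * params.c1 * u * (1.0 - x / params.K) + b * y / denom
        dw2 = params.conversion * b * x / (denom * denom) - 2.0 * params.c2 * v
    return params.V1 * dw1, params.V2 * dw2


def _eco_derivatives(x: float, y: float, u: float, v: float, params: EcoEvoParams) -> tuple[float, float]:
    a, b, g = params.alpha(u), params.beta(u, v), params.gamma(v)
    if params.functional_response == "mass_action":
        return a * x - b * x * y, params.conversion * b * x * y - g * y
    denom = 1.0 + b * params.h * x
    return a * x * (1.0 - x / params.K) - b * x * y / denom, (
        params.conversion * b * x * y / denom - g * y
    )


def _rhs(system: SystemName, params, t: float, z: np.ndarray) -> np.ndarray:
    if system == "lv":
        x, y = z
        return np.array(
            [params.alpha0 * x - params.beta0 * x * y, params.delta0 * x * y - params.gamma0 * y]
        )
    if system == "rm":
        x, y = z
        frozen = replace(params, V1=0.0, V2=0.0)
        dx, dy = _eco_derivatives(x, y, 0.0, 0.0, frozen)
        return np.array([dx, dy])
    x, y, u, v = z
    dx, dy = _eco_derivatives(x, y, u, v, params)
    du, dv = trait_gradients(EcoEvoState(x=max(x, 0.0), y=max(y, 0.0), u=u, v=v), params)
    return np.array([dx, dy, du, dv])


def integrate(
    system: SystemName,
    init: EcoEvoState,
    params,
    t_span: tuple[float, float],
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_points: int = 2001,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate one of the four systems over ``t_span``.

    ``lv``/``rm`` are the 2-d ecological systems (``rm`` takes
    :class:`EcoEvoParams` with ``functional_response='holling2'``);
    ``lv_coevo``/``rm_coevo`` append the two trait equations. The solver is
    adaptive and stiff-capable (LSODA by default). Densities below the
    extinction floor (1e-9) are clamped to zero in the output.
    """
    if system not in ("lv", "lv_coevo", "rm", "rm_coevo"):
        raise ValidationError(f"unknown system {system!r}")
    if system == "lv" and not isinstance(params, LVParams):
        raise ValidationError("system 'lv' requires LVParams")
    if system != "lv" and not isinstance(params, EcoEvoParams):
        raise ValidationError(f"system {system!r} requires EcoEvoParams")
    if system in ("rm", "rm_coevo") and params.functional_response != "holling2":
        raise ValidationError(f"system {system!r} requires functional_response='holling2'")
    if system == "lv_coevo" and params.functional_response != "mass_action":
        raise ValidationError("system 'lv_coevo' requires functional_response='mass_action'")
    t0, t1 = map(float, t_span)
    if not (np.isfinite(t0) and np.isfinite(t1) and t1 > t0):
        raise ValidationError(f"t_span must be a finite increasing pair, got {t_span!r}")

    with_traits = system.endswith("coevo")
    z0 = [init.x, init.y] + ([init.u, init.v] if with_traits else [])
    t_eval = np.linspace(t0, t1, n_points)
    sol = solve_ivp(
        lambda t, z: _rhs(system, params, t, z),
        (t0, t1),
        z0,
        method=method,
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
    )
    if not sol.success:
        raise IntegrationError(sol.message, float(sol.t[-1]) if sol.t.size else t0, sol.y[:, -1] if sol.t.size else np.array(z0))

    y = sol.y.copy()
    y[:2][y[:2] < EXTINCTION_FLOOR] = 0.0
    columns = {"t": sol.t, "x": y[0], "y": y[1]}
    if with_traits:
        columns["u"], columns["v"] = y[2], y[3]
    return Trajectory(
        times=sol.t,
        states=pd.DataFrame(columns),
        system=system,
        rtol=rtol,
        atol=atol,
        n_steps=int(sol.t.size),
    )


def oscillation_peaks(
    traj: Trajectory, variable: str, smooth: int = 0
) -> tuple[list[tuple[float, float]], list[float]]:
    """Local maxima of one trajectory variable plus peak-to-trough amplitudes.

    Peaks are strict three-point local maxima of the (optionally
    moving-average smoothed) sampled series. The returned amplitudes are
    each peak height minus the following trough. Too-short trajectories
    give an empty result.
    """
    series = traj.column(variable)
    t = traj.times
    if series.size < 3:
        return [], []
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        series = np.convolve(series, kernel, mode="same")
    peak_idx, _ = find_peaks(series)
    trough_idx, _ = find_peaks(-series)
    peaks = [(float(t[i]), float(series[i])) for i in peak_idx]
    amplitudes = []
    for i in peak_idx:
        later = trough_idx[trough_idx > i]
        if later.size:
            amplitudes.append(float(series[i] - series[later[0]]))
    return peaks, amplitudes
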