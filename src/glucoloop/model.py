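"""Model dynamics: functional components, full and reduced ODEs, simulation.

The full model tracks blood glucose x (mmol/L), insulin y (mU/L) and
glucagon z (glucagon-units):

    dx/dt = I(t) - E(x) - delta*x*y + epsilon*z
    dy/dt = beta*b(x, x0) - lambda*y  (+ u(t) under infusion)
    dz/dt = alpha*exp(-beta*b(x, x0)/m) - gamma*z

with b(x, x0) = max(0, x - x0) the glucose excess driving insulin release,
I(t) a Gamma-profile meal inflow, and E(x) = q*(1 - exp(-p*(x - x0))) the
glucose-based share of a constant calorie expenditure.  Insulin and glucagon
turn over on a minutes time scale while glucose moves on an hours time scale;
replacing the two fast equations by their instantaneous equilibria (the
quasi-steady-state approximation) collapses the system to one ODE,

    dx/dt = I(t) - E(x) - omega*b(x, x0)*x + sigma*exp(-b(x, x0)/n),

and under proportional insulin infusion u(t) the drain term becomes
(omega*b + kappa*u)*x.

E is deliberately NOT clamped below x0 — its negative values there are what
pushes glucose back up, and with sigma = 0 they place the equilibrium exactly
at x0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.stats import gamma as gamma_dist

from .params import LumpedParams, MealSpec, ModelParams, reduce_params

__all__ = [
    "Trajectory",
    "NoEquilibriumError",
    "meal_inflow",
    "expenditure",
    "insulin_drive",
    "glucagon_drive",
    "full_rhs",
    "reduced_rhs",
    "baseline",
    "baseline_controlled",
    "simulate",
    "simulate_full",
    "qss_gap",
]

#: Default integrator tolerances: tight enough that route-equivalence checks
#: (controlled vs effective-omega dynamics) resolve below 1e-6 mmol/L.
RTOL = 1e-8
ATOL = 1e-10
#: Dense output grid spacing for peak detection, hours (1 minute).
GRID_DT = 1.0 / 60.0


class NoEquilibriumError(RuntimeError):
    """The autonomous reduced equation has no root in the searched bracket."""


@dataclass(frozen=True)
class Trajectory:
    """A simulated or measured glucose time course with summary features.

    ``times`` (h) is strictly increasing; ``glucose`` (mmol/L) matches its
    length.  ``insulin`` (mU/L) and ``glucagon`` (glucagon-units) are present
    only for full-model simulations.  ``baseline`` is the equilibrium
    concentration of the generating parameter set; ``peak_value``/``peak_time``
    locate the glucose maximum (parabolically refined on the dense grid for
    simulations).
    """

    times: np.ndarray
    glucose: np.ndarray
    insulin: Optional[np.ndarray] = None
    glucagon: Optional[np.ndarray] = None
    baseline: float = float("nan")
    peak_value: float = float("nan")
    peak_time: float = float("nan")

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        g = np.asarray(self.glucose, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "glucose", g)
        if t.ndim != 1 or g.shape != t.shape:
            raise ValueError("times and glucose must be 1-d arrays of equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        for name in ("insulin", "glucagon"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                object.__setattr__(self, name, v)
                if v.shape != t.shape:
                    raise ValueError(f"{name} must match times in length")

    def __len__(self) -> int:
        return self.times.size


def meal_inflow(t, meal: MealSpec):
    """Rate of glucose appearance in blood at time ``t`` (h), mmol/h.

    The profile is the meal's total glucose ``w`` times a Gamma density with
    shape ``a`` and rate ``k``; it integrates to ``w`` over [0, inf).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("meal_inflow is defined for t >= 0 only")
    out = meal.w * gamma_dist.pdf(t, a=meal.a, scale=1.0 / meal.k)
    return out if out.ndim else float(out)


def expenditure(x, params: Union[ModelParams, LumpedParams]):
    """Glucose-based calorie expenditure E(x) = q*(1 - exp(-p*(x - x0))), mmol/h.

    Zero at the threshold x0, saturating at q for high glucose; negative below
    x0 by design (see module docstring).
    """
    x = np.asarray(x, dtype=float)
    out = params.q * (1.0 - np.exp(-params.p * (x - params.x0)))
    return out if out.ndim else float(out)


def insulin_drive(x, x0: float):
    """Glucose excess b(x, x0) = max(0, x - x0) driving insulin production."""
    x = np.asarray(x, dtype=float)
    out = np.maximum(0.0, x - x0)
    return out if out.ndim else float(out)


def glucagon_drive(insulin_production, m: float):
    """Glucagon production fraction exp(-insulin_production / m) in (0, 1]."""
    if not m > 0:
        raise ValueError(f"scale m must be strictly positive, got {m}")
    prod = np.asarray(insulin_production, dtype=float)
    out = np.exp(-prod / m)
    return out if out.ndim else float(out)


def full_rhs(
    t: float,
    state: Sequence[float],
    params: ModelParams,
    meal: Optional[MealSpec] = None,
    infusion: Optional[Callable[[float, float], float]] = None,
):
    """Right-hand side of the full three-variable model.

    ``infusion(t, x)`` is an optional exogenous insulin delivery rate (mU/h)
    added to the insulin equation.
    """
    x, y, z = state
    b = max(0.0, x - params.x0)
    production = params.beta * b
    inflow = meal_inflow(t, meal) if meal is not None and t >= 0 else 0.0
    dx = inflow - expenditure(x, params) - params.delta * x * y + params.epsilon * z
    dy = production - params.lambda_y * y
    if infusion is not None:
        dy += infusion(t, x)
    dz = params.alpha * glucagon_drive(production, params.m) - params.gamma_z * z
    return np.array([dx, dy, dz])


def reduced_rhs(
    t: float,
    x: float,
    lumped: LumpedParams,
    meal: Optional[MealSpec] = None,
    control=None,
):
    """Right-hand side of the reduced single glucose ODE.

    With a control policy, the insulin infusion u enters as an extra drain
    kappa*u*x alongside the endogenous omega*b*x.
    """
    b = max(0.0, x - lumped.x0)
    inflow = meal_inflow(t, meal) if meal is not None and t >= 0 else 0.0
    drain = lumped.omega * b
    if control is not None:
        dxdt_free = (inflow - expenditure(x, lumped) - drain * x
                     + lumped.sigma * np.exp(-b / lumped.n))
        u = control.rate(x, dxdt_free, lumped.x0)
        drain = drain + lumped.kappa * u
    return (inflow - expenditure(x, lumped) - drain * x
            + lumped.sigma * np.exp(-b / lumped.n))


def _stationary(x: float, lumped: LumpedParams, control=None) -> float:
    """Autonomous part of the reduced RHS (no meal forcing)."""
    return reduced_rhs(0.0, x, lumped, meal=None, control=control)


def baseline(lumped: LumpedParams) -> float:
    """Equilibrium blood glucose x_b of the autonomous reduced model, mmol/L.

    With sigma = 0 the hepatic release vanishes and the signed expenditure
    places the equilibrium exactly at x0.  Otherwise the stationary equation
    -E(x) - omega*b*x + sigma*exp(-b/n) = 0 is bracketed on (x0, 12] (widened
    to 30 if needed) and solved to machine precision.
    """
    return baseline_controlled(lumped, None)


def baseline_controlled(lumped: LumpedParams, control) -> float:
    """Equilibrium of the autonomous reduced model under a control policy."""
    if lumped.sigma == 0.0:
        return lumped.x0
    f = lambda x: _stationary(x, lumped, control)
    lo = lumped.x0
    f_lo = f(lo)  # = sigma > 0 at x0
    for hi in (12.0, 20.0, 30.0):
        if f(hi) < 0.0:
            root = brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16)
            return float(root)
    raise NoEquilibriumError(
        f"no equilibrium in ({lo}, 30] for omega={lumped.omega}, "
        f"sigma={lumped.sigma}: stationary function does not change sign "
        f"(f({lo})={f_lo:.3g})")


def _refine_peak(times: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    """Locate the maximum with local parabolic interpolation on a dense grid."""
    i = int(np.argmax(values))
    if i == 0 or i == values.size - 1:
        return float(values[i]), float(times[i])
    t0, t1, t2 = times[i - 1: i + 2]
    v0, v1, v2 = values[i - 1: i + 2]
    denom = (v0 - 2.0 * v1 + v2)
    if denom >= 0:  # flat or non-concave: keep the grid point
        return float(v1), float(t1)
    h = t1 - t0
    shift = 0.5 * h * (v0 - v2) / denom
    shift = float(np.clip(shift, -h, h))
    t_pk = t1 + shift
    v_pk = v1 - 0.25 * (v0 - v2) * shift / h
    return float(v_pk), float(t_pk)


def simulate(
    lumped: LumpedParams,
    meal: Optional[MealSpec] = None,
    control=None,
    horizon: float = 10.0,
    x_init: Optional[float] = None,
    rtol: float = RTOL,
    atol: float = ATOL,
    grid_dt: float = GRID_DT,
) -> Trajectory:
    """Integrate the reduced model over ``horizon`` hours.

    The initial condition defaults to the active parameter set's own
    equilibrium (including the control policy's effect on it), matching the
    protocol of meal-response measurements that start and end at rest.  The
    adaptive-step solution is resampled to a uniform dense grid (default
    1-minute spacing) on which the peak is parabolically refined.
    """
    if not horizon > 0:
        raise ValueError("horizon must be positive")
    xb = baseline_controlled(lumped, control)
    x_start = xb if x_init is None else float(x_init)
    sol = solve_ivp(
        reduced_rhs, (0.0, horizon), [x_start],
        args=(lumped, meal, control),
        method="LSODA", rtol=rtol, atol=atol, dense_output=True,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed: {sol.message} "
            f"(omega={lumped.omega}, sigma={lumped.sigma}, "
            f"meal={meal}, horizon={horizon})")
    times = np.arange(0.0, horizon + 0.5 * grid_dt, grid_dt)
    times[-1] = min(times[-1], horizon)
    glucose = sol.sol(times)[0]
    peak_value, peak_time = _refine_peak(times, glucose)
    return Trajectory(times=times, glucose=glucose, baseline=xb,
                      peak_value=peak_value, peak_time=peak_time)


def simulate_full(
    params: ModelParams,
    meal: Optional[MealSpec] = None,
    infusion: Optional[Callable[[float, float], float]] = None,
    horizon: float = 10.0,
    state_init: Optional[Sequence[float]] = None,
    rtol: float = RTOL,
    atol: float = ATOL,
    grid_dt: float = GRID_DT,
) -> Trajectory:
    """Integrate the full three-variable model over ``horizon`` hours.

    Starts at the model's own equilibrium (x_b, beta*b/lambda, alpha*d/gamma)
    unless ``state_init`` is given.  The hormone equations are stiff relative
    to glucose, so a stiff-capable adaptive solver is used.
    """
    if not horizon > 0:
        raise ValueError("horizon must be positive")
    lumped = reduce_params(params)
    if state_init is None:
        xb = baseline(lumped)
        b = max(0.0, xb - params.x0)
        y0 = params.beta * b / params.lambda_y
        z0 = (params.alpha * glucagon_drive(params.beta * b, params.m)
              / params.gamma_z)
        state_init = [xb, y0, z0]
    sol = solve_ivp(
        full_rhs, (0.0, horizon), state_init,
        args=(params, meal, infusion),
        method="LSODA", rtol=rtol, atol=atol, dense_output=True,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed: {sol.message} (params={params}, meal={meal})")
    times = np.arange(0.0, horizon + 0.5 * grid_dt, grid_dt)
    times[-1] = min(times[-1], horizon)
    dense = sol.sol(times)
    glucose = dense[0]
    peak_value, peak_time = _refine_peak(times, glucose)
    return Trajectory(times=times, glucose=glucose,
                      insulin=dense[1], glucagon=dense[2],
                      baseline=float(state_init[0]),
                      peak_value=peak_value, peak_time=peak_time)


def qss_gap(
    params: ModelParams,
    meal: MealSpec,
    scale: float = 1.0,
    horizon: float = 10.0,
) -> float:
    """Sup-norm glucose gap between the full model and its QSS reduction.

    ``scale`` multiplies the fast rates (lambda, gamma) while co-scaling
    (beta, alpha, m) so the lumped parameters — and hence the reduced
    dynamics — are unchanged; as scale grows the hormones relax ever faster
    and the full solution converges to the reduced one (Tikhonov limit).
    """
    if not scale >= 1:
        raise ValueError("scale must be >= 1")
    scaled = ModelParams(
        lambda_y=params.lambda_y * scale,
        beta=params.beta * scale,
        x0=params.x0,
        delta=params.delta,
        alpha=params.alpha * scale,
        gamma_z=params.gamma_z * scale,
        epsilon=params.epsilon,
        m=params.m * scale,
        p=params.p,
        q=params.q,
    )
    lumped = reduce_params(scaled)
    full = simulate_full(scaled, meal, horizon=horizon)
    red = simulate(lumped, meal, horizon=horizon)
    return float(np.max(np.abs(full.glucose - red.glucose)))
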