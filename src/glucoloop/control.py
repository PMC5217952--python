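"""Proportional closed-loop insulin infusion.

The feedback law delivers exogenous insulin at a rate proportional to the
glucose excess above the production threshold,

    u(t) = rho * b(x(t), x0),    b(x, x0) = max(0, x - x0),

mirroring the pancreas's own linear response (a "pedelec"-style assist rather
than a set-point controller).  In the reduced glucose equation the infusion
adds a drain kappa*u*x, so constant-gain control is algebraically identical
to raising the endogenous uptake coefficient omega to omega + kappa*rho.
That identity underpins gain selection (pick rho for a target effective
omega or target peak) and the kappa-calibration experiment: re-fitting omega
on a controlled meal response yields omega_c = omega + kappa*rho, hence
kappa = (omega_c - omega)/rho and the insulin resistance R = 1/delta with
delta = kappa*lambda.

Variants: long-acting insulin with decay rate lambda1 < lambda scales the
delivered rate by lambda1/lambda; an optional low-glucose cutoff zeroes the
dose below a floor; an adaptive mode raises the amplification fraction
mu = rho/(rho + beta) while glucose is still rising, anticipating the load.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .fitting import fit_profile
from .model import Trajectory, baseline_controlled, simulate
from .params import LumpedParams, MealSpec

__all__ = [
    "AdaptiveSchedule",
    "ControlPolicy",
    "infusion_rate",
    "infusion_fraction",
    "rho_from_fraction",
    "effective_omega",
    "gain_for_target_omega",
    "gain_for_target_peak",
    "calibrate_kappa",
    "ControlAuthorityError",
    "CalibrationError",
]

#: Insulin decay rate assumed when scaling long-acting infusions, 1/h.
DEFAULT_LAMBDA = 8.3
#: Beta-cell coefficient used by the adaptive schedule's rho = mu/(1-mu)*beta.
DEFAULT_BETA = 34.9


class ControlAuthorityError(ValueError):
    """Requested control action cannot be realized (e.g. kappa = 0)."""


class CalibrationError(RuntimeError):
    """The probe infusion produced no measurable increase in fitted omega."""


@dataclass(frozen=True)
class AdaptiveSchedule:
    """Two-level amplification schedule mu(x, dx/dt) = mu0 + dmu*[dx/dt > threshold].

    One concrete realization of gain scheduling on the glucose trend: while
    glucose rises faster than ``slope_threshold`` (mmol/L/h) the infusion
    fraction steps up from ``mu0`` to ``mu0 + dmu``, anticipating the insulin
    need before the peak.
    """

    mu0: float = 0.1
    dmu: float = 0.1
    slope_threshold: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu0 < 1.0 and 0.0 <= self.mu0 + self.dmu < 1.0):
            raise ValueError("mu levels must lie in [0, 1)")

    def mu(self, x: float, dxdt: float) -> float:
        return self.mu0 + (self.dmu if dxdt > self.slope_threshold else 0.0)


@dataclass(frozen=True)
class ControlPolicy:
    """Infusion gain and feedback-law variants.

    ``rho`` is the proportional gain (mU/h per mmol/L of glucose excess).
    ``lambda1`` switches to long-acting insulin with the given decay rate
    (must not exceed ``lambda_y``); ``low_cutoff`` zeroes the dose below the
    given glucose level; ``adaptive`` replaces the constant gain by a
    trend-dependent schedule (``rho`` is then ignored).
    """

    rho: float = 0.0
    lambda1: Optional[float] = None
    low_cutoff: Optional[float] = None
    adaptive: Optional[AdaptiveSchedule] = None
    lambda_y: float = DEFAULT_LAMBDA
    beta: float = DEFAULT_BETA

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError(f"gain rho must be >= 0, got {self.rho}")
        if self.lambda1 is not None and not (0 < self.lambda1 <= self.lambda_y):
            raise ValueError(
                f"lambda1 must lie in (0, lambda_y={self.lambda_y}], "
                f"got {self.lambda1}")

    def rate(self, x: float, dxdt: float, x0: float) -> float:
        """Infusion rate u(x, dx/dt) in mU/h; always >= 0."""
        return infusion_rate(x, dxdt, self, x0)


def infusion_rate(x: float, dxdt: float, policy: ControlPolicy, x0: float) -> float:
    """Evaluate the feedback law u = rho*b(x, x0) with the policy's variants."""
    if policy.low_cutoff is not None and x < policy.low_cutoff:
        return 0.0
    b = max(0.0, x - x0)
    if b == 0.0:
        return 0.0
    rho = policy.rho
    if policy.adaptive is not None:
        rho = rho_from_fraction(policy.adaptive.mu(x, dxdt), policy.beta)
    u = rho * b
    if policy.lambda1 is not None:
        u *= policy.lambda1 / policy.lambda_y
    return u


def infusion_fraction(rho: float, beta: float) -> float:
    """Share mu = rho/(rho + beta) of circulating insulin that is infused."""
    if rho + beta <= 0:
        raise ValueError("rho + beta must be positive for a defined fraction")
    return rho / (rho + beta)


def rho_from_fraction(mu: float, beta: float) -> float:
    """Invert the infusion fraction: rho = mu/(1 - mu) * beta."""
    if not 0.0 <= mu < 1.0:
        raise ValueError(f"mu must lie in [0, 1), got {mu}")
    return mu / (1.0 - mu) * beta


def effective_omega(omega: float, kappa: float, rho: float) -> float:
    """Effective uptake coefficient omega + kappa*rho under constant-gain control."""
    if min(omega, kappa, rho) < 0:
        raise ValueError("omega, kappa and rho must all be >= 0")
    return omega + kappa * rho


def gain_for_target_omega(omega: float, omega_target: float, kappa: float) -> float:
    """Gain rho = (omega_target - omega)/kappa that realizes a target effective omega."""
    if omega_target < omega:
        raise ValueError("omega_target must be >= omega (control only adds drain)")
    if kappa <= 0:
        raise ControlAuthorityError(
            "kappa = 0: infusion has no effect on glucose (no control authority)")
    return (omega_target - omega) / kappa


def gain_for_target_peak(
    lumped: LumpedParams,
    meal: MealSpec,
    peak_target: float,
    horizon: float = 10.0,
    tol: float = 0.01,
    rho_max: float = 200.0,
) -> float:
    """Smallest gain rho whose controlled meal-response peak is <= ``peak_target``.

    The controlled peak decreases monotonically in rho, so bisection applies.
    Raises if the target is above the uncontrolled peak minus nothing to do,
    below the baseline, or unreachable within ``rho_max``.
    """
    if lumped.kappa <= 0:
        raise ControlAuthorityError("kappa = 0: no control authority")

    def peak(rho: float) -> float:
        return simulate(lumped, meal, control=ControlPolicy(rho=rho),
                        horizon=horizon).peak_value

    p0 = peak(0.0)
    if peak_target >= p0:
        return 0.0
    xb = baseline_controlled(lumped, None)
    if peak_target <= xb:
        raise ValueError(
            f"target {peak_target} is at or below the baseline {xb:.3g}")
    if peak(rho_max) > peak_target:
        raise ValueError(
            f"target {peak_target} mmol/L unreachable with rho <= {rho_max}")
    lo, hi = 0.0, rho_max
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if peak(mid) > peak_target:
            lo = mid
        else:
            hi = mid
    return hi


def calibrate_kappa(
    uncontrolled: Trajectory,
    controlled: Trajectory,
    meal: MealSpec,
    rho_probe: float,
    lambda_y: float = DEFAULT_LAMBDA,
    **fit_kwargs,
):
    """Estimate kappa (and hence delta, R) from a repeated-meal experiment.

    The same meal is taken twice, once free-running and once under
    proportional infusion with a known small gain ``rho_probe``.  Fitting the
    uncontrolled profile gives omega (with a, k, sigma); re-fitting only
    omega on the controlled profile, all other parameters held at the first
    fit's values, gives omega_c = omega + kappa*rho_probe.  Returns
    ``(kappa, delta, R, fit_unc, fit_con)`` with delta = kappa*lambda and the
    insulin resistance R = 1/delta.
    """
    if not rho_probe > 0:
        raise ValueError(f"rho_probe must be positive, got {rho_probe}")
    fit_unc = fit_profile(uncontrolled, meal_w=meal.w, **fit_kwargs)
    fit_con = fit_profile(
        controlled, meal_w=meal.w,
        free=("omega",),
        fixed_values={"a": fit_unc.a, "k": fit_unc.k, "sigma": fit_unc.sigma},
        **fit_kwargs,
    )
    omega, omega_c = fit_unc.omega, fit_con.omega
    if omega_c - omega <= 1e-6 * max(omega, 1.0):
        raise CalibrationError(
            f"fitted omega_c={omega_c:.6g} does not measurably exceed "
            f"omega={omega:.6g}: the probe infusion had no detectable effect")
    kappa = (omega_c - omega) / rho_probe
    delta = kappa * lambda_y
    return kappa, delta, 1.0 / delta, fit_unc, fit_con
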