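"""Parameter containers for the glucose–insulin–glucagon model.

Two levels of description are used.  The full three-variable model carries
physiological rate constants (:class:`ModelParams`).  After the quasi-steady-
state (QSS) reduction of the fast insulin and glucagon equations, only the
lumped combinations

    omega = delta * beta / lambda,   n = m / beta,   sigma = alpha * epsilon / gamma

are identifiable from glucose data (:class:`LumpedParams`); ``kappa =
delta / lambda`` converts an exogenous insulin-infusion rate into an
additional glucose drain in the reduced equation.

Units follow the data the model is fitted to: time in hours, glucose in
mmol/L of venous whole blood, insulin in mU/L.  Because the meal inflow
(mmol/h) enters the concentration equation without an explicit distribution
volume, the fitted omega and sigma absorb that volume: they are
profile-specific constants, not per-litre physiological rates.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ModelParams",
    "LumpedParams",
    "MealSpec",
    "reduce_params",
    "disaggregate",
    "grams_to_mmol",
    "PRESETS",
    "get_preset",
    "FITTED_MEAL",
    "GLUCOSE_MOLAR_MASS",
]

#: Molar mass of D-glucose, g/mol.
GLUCOSE_MOLAR_MASS = 180.16


def grams_to_mmol(grams: float, molar_mass: float = GLUCOSE_MOLAR_MASS) -> float:
    """Convert a mass of glucose in grams to millimoles."""
    return grams / molar_mass * 1e3


@dataclass(frozen=True)
class ModelParams:
    """Rate constants of the full three-variable model.

    Attributes
    ----------
    lambda_y : insulin decay rate, 1/h (half-life ~5 min -> 8.3/h).
    beta : beta-cell production coefficient, mU h^-1 mmol^-1;
        100% beta-cell function corresponds to beta = 34.9.
    x0 : glucose threshold for insulin production, mmol/L (whole blood: 3).
    delta : insulin-mediated uptake coefficient, L mU^-1 h^-1; the insulin
        resistance is R = 1/delta.
    alpha : maximal glucagon production rate, glucagon-units/h.
    gamma_z : glucagon decay rate, 1/h.
    epsilon : hepatic glucose release per glucagon-unit, mmol L^-1 h^-1.
    m : e-folding scale of glucagon suppression vs insulin production, mU/h.
    p : expenditure saturation rate, L/mmol.
    q : total glucose-based expenditure ceiling, mmol/h.
    """

    lambda_y: float = 8.3
    beta: float = 34.9
    x0: float = 3.0
    delta: float = 8.30 * 8.3 / 34.9  # reduces to the fitted omega = 8.30
    alpha: float = 382.0 * 8.3       # sigma * gamma_z at epsilon = 1
    gamma_z: float = 8.3
    epsilon: float = 1.0
    m: float = 1.75 * 34.9           # n * beta at the fitted n
    p: float = 0.7
    q: float = 100.0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        for name in ("lambda_y", "x0", "delta", "alpha", "gamma_z",
                     "epsilon", "m", "p", "q"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if self.x0 >= 4.0:
            raise ValueError(
                f"x0={self.x0} mmol/L is at or above admissible baselines")


@dataclass(frozen=True)
class LumpedParams:
    """Identifiable parameters of the reduced single-ODE model.

    ``omega`` scales the insulin-mediated glucose drain omega*b(x,x0)*x,
    ``sigma`` the glucagon-mediated hepatic release sigma*exp(-b/n), and
    ``kappa`` converts an infusion rate u (mU/h) into the extra drain
    kappa*u*x.  ``p``, ``q`` and ``x0`` carry over unchanged from the full
    model.
    """

    omega: float = 8.30
    sigma: float = 382.0
    n: float = 1.75
    kappa: float = 0.24096385542168675  # delta/lambda at delta=2, lambda=8.3
    p: float = 0.7
    q: float = 100.0
    x0: float = 3.0

    def __post_init__(self) -> None:
        if self.omega < 0 or self.sigma < 0 or self.kappa < 0:
            raise ValueError("omega, sigma and kappa must be >= 0")
        if not self.n > 0:
            raise ValueError(f"n must be strictly positive, got {self.n}")
        for name in ("p", "q"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class MealSpec:
    """A meal's glucose load and Gamma-shaped absorption profile.

    The rate of glucose appearance in blood is w * Gamma(t; a, k) with shape
    ``a`` (dimensionless, > 1 so absorption starts and ends at zero) and RATE
    ``k`` (1/h); the absorption peak sits at (a - 1)/k hours after the meal.

    The fitted fast-absorption meal has shape 4.11 and rate 5.69/h, putting
    the absorption mode at 0.55 h — this assignment of the fitted pair is
    the one that reproduces the study's peak values and peak-vs-size
    regression (see docs/methods.md).
    """

    w: float = 280.3
    a: float = 4.11
    k: float = 5.69

    def __post_init__(self) -> None:
        if self.w < 0:
            raise ValueError(f"meal glucose w must be >= 0, got {self.w}")
        if not self.a > 1:
            raise ValueError(
                f"shape a must exceed 1 for a single interior peak, got {self.a}")
        if not self.k > 0:
            raise ValueError(f"rate k must be strictly positive, got {self.k}")

    @property
    def absorption_peak_time(self) -> float:
        """Mode of the absorption profile, hours: (a - 1) / k."""
        return (self.a - 1.0) / self.k


def reduce_params(params: ModelParams) -> LumpedParams:
    """QSS-reduce full-model rate constants to the lumped parameters.

    Raises
    ------
    ValueError
        If ``beta == 0``: ``n = m / beta`` is then undefined; total beta-cell
        failure must be expressed directly in lumped form (omega = 0).
    """
    if params.beta == 0:
        raise ValueError(
            "beta = 0 (total beta-cell failure): n = m/beta is undefined; "
            "construct LumpedParams directly with omega = 0")
    return LumpedParams(
        omega=params.delta * params.beta / params.lambda_y,
        sigma=params.alpha * params.epsilon / params.gamma_z,
        n=params.m / params.beta,
        kappa=params.delta / params.lambda_y,
        p=params.p,
        q=params.q,
        x0=params.x0,
    )


def disaggregate(
    lumped: LumpedParams,
    lambda_y: float = 8.3,
    gamma_z: float = 8.3,
    epsilon: float = 1.0,
    beta: float = 34.9,
) -> ModelParams:
    """Reconstruct one full-model parameter set consistent with ``lumped``.

    Only the lumped combinations are identifiable from glucose data, so the
    split is a gauge choice: fixing (lambda_y, gamma_z, epsilon, beta) pins
    down delta = omega*lambda/beta, m = n*beta and alpha = sigma*gamma/epsilon
    while leaving the reduced dynamics invariant.
    """
    return ModelParams(
        lambda_y=lambda_y,
        beta=beta,
        x0=lumped.x0,
        delta=lumped.omega * lambda_y / beta,
        alpha=lumped.sigma * gamma_z / epsilon,
        gamma_z=gamma_z,
        epsilon=epsilon,
        m=lumped.n * beta,
        p=lumped.p,
        q=lumped.q,
    )


#: Fitted meal: 50.5 g (= 280.3 mmol) of fast-absorbing carbohydrate.
FITTED_MEAL = MealSpec(w=280.3, a=4.11, k=5.69)

#: Named parameter presets.
#:
#: "healthy_fitted" is the nondiabetic fit (omega=8.30, sigma=382, n=1.75);
#: its kappa = omega/beta at full beta-cell function.  "diabetic_omega2"
#: models reduced beta-cell function: omega drops to 2 with no insulin
#: resistance (delta = 2), giving kappa = 2/8.3 ~ 0.24.
PRESETS: dict[str, LumpedParams] = {
    "healthy_fitted": LumpedParams(
        omega=8.30, sigma=382.0, n=1.75, kappa=8.30 / 34.9,
        p=0.7, q=100.0, x0=3.0),
    "diabetic_omega2": LumpedParams(
        omega=2.0, sigma=382.0, n=1.75, kappa=2.0 / 8.3,
        p=0.7, q=100.0, x0=3.0),
}


def get_preset(name: str) -> LumpedParams:
    """Look up a shipped parameter preset by name."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
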