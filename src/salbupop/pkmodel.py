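"""Structural kinetic models for extravascular (inhaled depot) drug input.

The central object is the two-compartment model with first-order absorption
and linear elimination, parameterized by (ka, Cl, V1, Q, V2):

    depot --ka--> central (V1) <--Q--> peripheral (V2)
                     |
                    Cl

Concentrations refer to the central compartment.  The internal unit canon is
micrograms, litres and hours, so concentrations are ug/L.  Bioavailability is
absorbed into the apparent parameters (Cl/F convention); no explicit F is
carried.

Closed-form solutions are used throughout (tri-exponential for the
two-compartment model); a generic eigendecomposition solver covers the one-
and three-compartment variants and absorption-lag models exposed through the
model registry for structure selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "StructuralParams",
    "DoseEvent",
    "ConcentrationProfile",
    "micro_constants",
    "hybrid_rates",
    "hybrid_rates_from_micro",
    "predict_concentration",
    "ode_rhs",
    "StructuralModel",
    "MODEL_REGISTRY",
    "get_model",
]

#: relative gap below which the absorption rate is considered tied with a
#: disposition eigenvalue; the tri-exponential has a removable singularity
#: there and ka is nudged by the same relative amount.
_TIE_REL = 1e-9


class DomainError(ValueError):
    """Raised for structurally invalid kinetic parameters."""


@dataclass(frozen=True)
class StructuralParams:
    """Two-compartment structural parameters.

    ka : first-order absorption rate constant (1/h)
    cl : clearance (L/h)
    v1 : central volume of distribution (L)
    q  : intercompartmental clearance (L/h); q = 0 collapses to one
         compartment and is tolerated as a limit case
    v2 : peripheral volume of distribution (L)
    """

    ka: float
    cl: float
    v1: float
    q: float
    v2: float

    def __post_init__(self) -> None:
        for name in ("ka", "cl", "v1", "v2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise DomainError(f"{name} must be finite and > 0, got {v}")
        if not np.isfinite(self.q) or self.q < 0:
            raise DomainError(f"q must be finite and >= 0, got {self.q}")


@dataclass(frozen=True)
class DoseEvent:
    """An extravascular dose into the absorption depot."""

    amount: float
    time: float = 0.0
    route: str = "depot"

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise DomainError(f"dose amount must be > 0, got {self.amount}")
        if self.time < 0:
            raise DomainError(f"dose time must be >= 0, got {self.time}")


@dataclass
class ConcentrationProfile:
    """Ordered concentration-time profile (times h, concentrations ug/L)."""

    times: np.ndarray
    conc: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.conc.shape:
            raise DomainError("times and conc must be matching 1-d arrays")
        if np.any(np.diff(self.times) <= 0):
            raise DomainError("times must be strictly increasing")
        if np.any(self.conc < 0):
            raise DomainError("concentrations must be nonnegative")


def micro_constants(params: StructuralParams) -> tuple[float, float, float]:
    """Micro rate constants (k10, k12, k21) of the two-compartment model.

    k10 = Cl/V1, k12 = Q/V1, k21 = Q/V2.
    """
    return params.cl / params.v1, params.q / params.v1, params.q / params.v2


def hybrid_rates_from_micro(k10: float, k12: float, k21: float) -> tuple[float, float]:
    """Hybrid (macro) rate constants alpha >= beta from micro constants.

    Roots of lambda^2 - (k10+k12+k21) lambda + k10*k21 = 0.  beta is computed
    as k10*k21/alpha to avoid cancellation when beta << alpha.
    """
    if min(k10, k12, k21) < 0:
        raise DomainError("micro constants must be nonnegative")
    s = k10 + k12 + k21
    disc = s * s - 4.0 * k10 * k21
    alpha = 0.5 * (s + np.sqrt(max(disc, 0.0)))
    beta = (k10 * k21 / alpha) if alpha > 0 else 0.0
    return alpha, beta


def hybrid_rates(params: StructuralParams) -> tuple[float, float]:
    """Hybrid rate constants (alpha, beta) of a parameter set."""
    return hybrid_rates_from_micro(*micro_constants(params))


def _untie(ka: float, rates: Sequence[float]) -> float:
    """Nudge ka off any disposition eigenvalue (removable singularity)."""
    for _ in range(4):
        if all(abs(ka - r) > _TIE_REL * max(abs(r), 1.0) for r in rates):
            return ka
        ka = ka * (1.0 + 1e-9) + 1e-15
    return ka


def predict_concentration(
    params: StructuralParams, dose: DoseEvent, times: Sequence[float]
) -> ConcentrationProfile:
    """Closed-form central concentration after a single depot dose.

    Tri-exponential solution; linear in dose amount; zero at (and before)
    the dose time for extravascular input.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise DomainError("negative times are not allowed")
    if np.any(t < dose.time):
        raise DomainError("prediction times must be >= dose time")
    conc = _conc2(
        np.array([[params.ka, params.cl, params.v1, params.q, params.v2]]),
        np.array([dose.amount]),
        t[None, :] - dose.time,
    )[0]
    # tiny negative values from cancellation are clipped
    return ConcentrationProfile(t, np.maximum(conc, 0.0))


def _conc2(theta: np.ndarray, dose: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Vectorized two-compartment closed form.

    theta: (n, 5) columns ka, cl, v1, q, v2; dose: (n,); t: (n, m) or (1, m)
    time since dose.  Returns (n, m) concentrations.
    """
    ka = theta[:, 0].copy()
    cl, v1, q, v2 = theta[:, 1], theta[:, 2], theta[:, 3], theta[:, 4]
    k10 = cl / v1
    k12 = q / v1
    k21 = q / v2
    s = k10 + k12 + k21
    disc = s * s - 4.0 * k10 * k21
    alpha = 0.5 * (s + np.sqrt(np.maximum(disc, 0.0)))
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(alpha > 0, k10 * k21 / alpha, 0.0)
    # resolve removable ka ties by a relative nudge
    for r in (alpha, beta):
        tie = np.abs(ka - r) <= _TIE_REL * np.maximum(np.abs(r), 1.0)
        ka = np.where(tie, ka * (1.0 + 1e-9) + 1e-15, ka)
    A = (k21 - alpha) / ((ka - alpha) * (beta - alpha))
    B = (k21 - beta) / ((ka - beta) * (alpha - beta))
    C = (k21 - ka) / ((alpha - ka) * (beta - ka))
    pref = (dose * ka / v1)[:, None]
    tt = np.maximum(t, 0.0)
    out = pref * (
        A[:, None] * np.exp(-alpha[:, None] * tt)
        + B[:, None] * np.exp(-beta[:, None] * tt)
        + C[:, None] * np.exp(-ka[:, None] * tt)
    )
    return np.where(t < 0, 0.0, out)


def _conc1(theta: np.ndarray, dose: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Vectorized one-compartment first-order-absorption closed form.

    theta: (n, 3) columns ka, cl, v1.
    """
    ka = theta[:, 0].copy()
    k = theta[:, 1] / theta[:, 2]
    tie = np.abs(ka - k) <= _TIE_REL * np.maximum(np.abs(k), 1.0)
    ka = np.where(tie, ka * (1.0 + 1e-9) + 1e-15, ka)
    pref = (dose / theta[:, 2]) * ka / (ka - k)
    tt = np.maximum(t, 0.0)
    out = pref[:, None] * (np.exp(-k[:, None] * tt) - np.exp(-ka[:, None] * tt))
    return np.where(t < 0, 0.0, out)


def _conc3(theta: np.ndarray, dose: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Three-compartment model via eigendecomposition of the rate matrix.

    theta: (n, 7) columns ka, cl, v1, q2, v2, q3, v3.
    """
    n = theta.shape[0]
    t = np.broadcast_to(t, (n, t.shape[-1]))
    out = np.empty_like(t, dtype=float)
    for i in range(n):
        ka, cl, v1, q2, v2, q3, v3 = theta[i]
        k10, k12, k21 = cl / v1, q2 / v1, q2 / v2
        k13, k31 = q3 / v1, q3 / v3
        M = np.array(
            [
                [-ka, 0.0, 0.0, 0.0],
                [ka, -(k10 + k12 + k13), k21, k31],
                [0.0, k12, -k21, 0.0],
                [0.0, k13, 0.0, -k31],
            ]
        )
        w, V = np.linalg.eig(M)
        y0 = np.array([dose[i], 0.0, 0.0, 0.0])
        c = np.linalg.solve(V, y0)
        tt = np.maximum(t[i], 0.0)
        amounts = (V[1, :] * c) @ np.exp(np.outer(w, tt))
        out[i] = np.where(t[i] < 0, 0.0, np.real(amounts) / v1)
    return out


def ode_rhs(params: StructuralParams) -> Callable[[float, np.ndarray], np.ndarray]:
    """Right-hand side of the two-compartment system in amount form.

    State: (depot, central, peripheral, eliminated).  The four amounts sum to
    the dose at all times (mass balance), which is how the closed form is
    cross-checked.
    """
    k10, k12, k21 = micro_constants(params)
    ka = params.ka

    def rhs(_t: float, x: np.ndarray) -> np.ndarray:
        depot, a1, a2, _ = x
        return np.array(
            [
                -ka * depot,
                ka * depot - (k10 + k12) * a1 + k21 * a2,
                k12 * a1 - k21 * a2,
                k10 * a1,
            ]
        )

    return rhs


def _with_lag(fn: Callable) -> Callable:
    """Wrap a closed-form predictor: last theta column is absorption lag."""

    def predict(theta: np.ndarray, dose: np.ndarray, t: np.ndarray) -> np.ndarray:
        lag = theta[:, -1]
        return fn(theta[:, :-1], dose, t - lag[:, None])

    return predict


@dataclass(frozen=True)
class StructuralModel:
    """A registered structural model: parameter names plus a vectorized
    predictor conc = f(theta_matrix, dose_vector, time_matrix)."""

    name: str
    param_names: tuple[str, ...]
    predict: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray] = field(
        repr=False
    )
    n_compartments: int = 2

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def predict_subjects(
        self, theta: np.ndarray, dose: np.ndarray, times: np.ndarray
    ) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        dose = np.asarray(dose, dtype=float)
        t = np.asarray(times, dtype=float)
        if t.ndim == 1:
            t = t[None, :]
        return self.predict(theta, dose, t)


MODEL_REGISTRY: dict[str, StructuralModel] = {
    m.name: m
    for m in [
        StructuralModel("one_compartment", ("ka", "cl", "v1"), _conc1, 1),
        StructuralModel("two_compartment", ("ka", "cl", "v1", "q", "v2"), _conc2, 2),
        StructuralModel(
            "three_compartment",
            ("ka", "cl", "v1", "q", "v2", "q3", "v3"),
            _conc3,
            3,
        ),
        StructuralModel(
            "one_compartment_lag", ("ka", "cl", "v1", "tlag"), _with_lag(_conc1), 1
        ),
        StructuralModel(
            "two_compartment_lag",
            ("ka", "cl", "v1", "q", "v2", "tlag"),
            _with_lag(_conc2),
            2,
        ),
    ]
}


def get_model(name: str) -> StructuralModel:
    """Look up a structural model by registry name."""
    try:
        return MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown structural model {name!r}; available: {sorted(MODEL_REGISTRY)}"
        ) from None
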