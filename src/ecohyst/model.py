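"""The bistable driver-state mechanism model.

An ecosystem with two alternative stable states ``C0 < C1`` is described by
a curve that gives, for every system state ``Y`` in ``[C0, C1)``, the driver
value ``x`` at which that state is an equilibrium:

    x = f(Y) = g(Y) * h(Y),
    g(Y) = (Y - C0) / (C1 - Y),      positive feedback (increasing)
    h(Y) = exp(K / Y),               negative feedback (decreasing)

``K >= 0`` is the *irreversible potential*: the dimensionless intensity of
the negative feedback that must be overcome before a state transition, and
hence of the hysteresis it causes.  Setting ``f'(Y) = 0`` reduces to the
quadratic

    (C1 - C0 + K) Y^2 - K (C0 + C1) Y + K C0 C1 = 0,

whose two real roots (the fold/tipping states) exist iff ``K`` exceeds the
critical constant ``K* = 4 C0 C1 / (C1 - C0)``.  Below ``K*`` the curve is
monotone and the state tracks the driver continuously; above it the curve is
S-shaped and the system jumps between branches at the two tipping points,
tracing a hysteresis loop.

This module evaluates the curve, locates the tipping points analytically,
classifies the regime, inverts the stable branches, and splits the slope
``f'`` into its inertial (positive-feedback) and conservative
(negative-feedback) contributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from .exceptions import DomainError, ParameterError, RangeError, RegimeError

__all__ = [
    "E",
    "ModelParams",
    "TippingPoint",
    "TippingPointPair",
    "RegimeClass",
    "ForceTriple",
    "evaluate_driver",
    "critical_constant",
    "classify_regime",
    "tipping_points",
    "invert_branch",
    "force_decomposition",
]

E = math.e

#: relative tolerance for classifying K == K* as the degenerate (critical) case
CRITICAL_RTOL = 1e-9

#: fraction of (C1 - C0) kept clear of C1 when a driver cap is needed
_UPPER_GUARD = 1e-6


@dataclass(frozen=True)
class ModelParams:
    """The triple (C0, C1, K) defining one hysteresis model instance.

    Parameters
    ----------
    c0 : float
        Lower stable state, in state units. Must be positive.
    c1 : float
        Upper stable state; must exceed ``c0``.
    k : float
        Irreversible potential, dimensionless, ``>= 0``.
    """

    c0: float
    c1: float
    k: float

    def __post_init__(self) -> None:
        for name in ("c0", "c1", "k"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise ParameterError(f"{name} must be a finite number, got {v!r}")
        if not 0 < self.c0 < self.c1:
            raise ParameterError(
                f"stable states must satisfy 0 < C0 < C1, got C0={self.c0}, C1={self.c1}"
            )
        if self.k < 0:
            raise ParameterError(f"irreversible potential K must be >= 0, got {self.k}")

    @classmethod
    def normalized(cls, k: float) -> "ModelParams":
        """The standardized form with C0 = 1 and C1 = e."""
        return cls(1.0, E, k)

    @property
    def k_star(self) -> float:
        """Critical constant for this (C0, C1) pair."""
        return critical_constant(self.c0, self.c1)


@dataclass(frozen=True)
class TippingPoint:
    """A fold point: the state and driver at which a stable branch ends."""

    state: float
    driver: float


@dataclass(frozen=True)
class TippingPointPair:
    """Forward and backward fold bifurcation points of a hysteretic model.

    ``forward`` is the local maximum of f (end of the lower branch, where the
    low-to-high jump occurs); ``backward`` is the local minimum (end of the
    upper branch, high-to-low jump). ``degenerate`` is set when K equals the
    critical constant and the two coincide.
    """

    forward: TippingPoint
    backward: TippingPoint
    degenerate: bool = False


@dataclass(frozen=True)
class RegimeClass:
    """Regime label from comparing K against the critical constant K*."""

    label: Literal["continuous", "critical", "hysteretic"]
    k_star: float


@dataclass(frozen=True)
class ForceTriple:
    """Decomposition of the curve slope f'(Y) into feedback contributions.

    ``inertial`` is the positive-feedback term g'(Y) h(Y) (> 0 inside the
    state interval); ``conservative`` is the negative-feedback term
    g(Y) h'(Y) (< 0 whenever K > 0); ``total`` is their sum, f'(Y), which
    vanishes exactly at the tipping states.
    """

    inertial: float
    conservative: float
    total: float


def _as_state_array(y, params: ModelParams, *, open_left: bool = False):
    y = np.asarray(y, dtype=float)
    lo_bad = (y < params.c0) | (open_left & (y == params.c0))
    if np.any(lo_bad) or np.any(y >= params.c1):
        raise DomainError(
            f"state must lie in {'(' if open_left else '['}{params.c0}, {params.c1}), "
            f"got value(s) outside"
        )
    return y


def evaluate_driver(y, params: ModelParams):
    """Driver value x = f(Y) at which state ``y`` is an equilibrium.

    Accepts scalars or arrays. ``y`` must lie in ``[C0, C1)``; f is zero at
    C0 and diverges as ``y`` approaches C1.
    """
    arr = _as_state_array(y, params)
    out = (arr - params.c0) / (params.c1 - arr) * np.exp(params.k / arr)
    return out if isinstance(out, np.ndarray) and out.ndim else float(out)


def critical_constant(c0: float, c1: float) -> float:
    """Critical constant K* = 4 C0 C1 / (C1 - C0).

    Hysteresis (two distinct fold points) exists iff K > K*.
    """
    if not (0 < c0 < c1):
        raise ParameterError(f"require 0 < C0 < C1, got C0={c0}, C1={c1}")
    return 4.0 * c0 * c1 / (c1 - c0)


def classify_regime(params: ModelParams, tol: float = CRITICAL_RTOL) -> RegimeClass:
    """Classify the state-transition regime by comparing K with K*.

    ``K > K*`` gives a hysteretic (bistable) system, ``K < K*`` a continuous
    one; equality within relative tolerance ``tol`` is the critical case
    where the two fold points merge.
    """
    if tol <= 0:
        raise ParameterError("tol must be positive")
    ks = params.k_star
    if abs(params.k - ks) <= tol * ks:
        label = "critical"
    elif params.k > ks:
        label = "hysteretic"
    else:
        label = "continuous"
    return RegimeClass(label=label, k_star=ks)


def tipping_points(params: ModelParams) -> TippingPointPair | None:
    """Analytic fold points of f, or ``None`` when the regime is continuous.

    Solves the quadratic (C1-C0+K) Y^2 - K(C0+C1) Y + K C0 C1 = 0 with the
    numerically stable form of the quadratic formula.  The smaller root is
    the forward tipping state (local maximum of f), the larger the backward
    one (local minimum).
    """
    regime = classify_regime(params)
    if regime.label == "continuous":
        return None
    c0, c1, k = params.c0, params.c1, params.k
    a = c1 - c0 + k
    if regime.label == "critical":
        y = k * (c0 + c1) / (2.0 * a)
        pt = TippingPoint(state=y, driver=float(evaluate_driver(y, params)))
        return TippingPointPair(forward=pt, backward=pt, degenerate=True)
    b = -k * (c0 + c1)
    c = k * c0 * c1
    disc = b * b - 4.0 * a * c
    # b < 0 always, so q = (-b + sqrt(disc)) / 2 avoids cancellation
    q = (-b + math.sqrt(disc)) / 2.0
    y_plus = q / a
    y_minus = c / q
    fwd = TippingPoint(state=y_minus, driver=float(evaluate_driver(y_minus, params)))
    bwd = TippingPoint(state=y_plus, driver=float(evaluate_driver(y_plus, params)))
    return TippingPointPair(forward=fwd, backward=bwd, degenerate=False)


def _branch_interval(params: ModelParams, branch: str) -> tuple[float, float]:
    """Closed state interval on which f is monotone for the given branch."""
    cap = params.c1 - _UPPER_GUARD * (params.c1 - params.c0)
    tp = tipping_points(params)
    if branch == "lower":
        hi = tp.forward.state if tp is not None else cap
        return params.c0, hi
    if branch == "upper":
        if tp is None:
            raise RegimeError(
                "no upper branch: the regime is continuous (K <= K*); "
                "use branch='lower' for the single monotone branch"
            )
        return tp.backward.state, cap
    raise ParameterError(f"branch must be 'lower' or 'upper', got {branch!r}")


def invert_branch(
    x: float,
    params: ModelParams,
    branch: Literal["lower", "upper"] = "lower",
    rtol: float = 1e-12,
) -> float:
    """State Y on the requested stable branch with f(Y) = x.

    f is strictly increasing on each branch, so the inverse is computed by
    bracketed root finding (Brent's method), which cannot fail to converge
    on a monotone segment.
    """
    lo, hi = _branch_interval(params, branch)
    x_lo = float(evaluate_driver(lo, params))
    x_hi = float(evaluate_driver(hi, params))
    if not (x_lo <= x <= x_hi):
        raise RangeError(
            f"driver {x} outside the {branch}-branch range [{x_lo:.6g}, {x_hi:.6g}]"
        )
    if x == x_lo:
        return lo
    if x == x_hi:
        return hi
    return float(
        brentq(lambda y: float(evaluate_driver(y, params)) - x, lo, hi, rtol=rtol)
    )


def force_decomposition(y, params: ModelParams):
    """Split f'(Y) into inertial and conservative feedback contributions.

    By the product rule f' = g' h + g h': the first term,
    ``inertial = ((C1-C0)/(C1-Y)^2) e^{K/Y}``, is the rate contribution of
    the positive feedback; the second, ``conservative = -(K/Y^2) f(Y)``, is
    the (non-positive) contribution of the negative feedback.  Their sum is
    the total force f'(Y), zero exactly at the tipping states.

    Returns a :class:`ForceTriple` for scalar input, or a triple of arrays.
    """
    arr = _as_state_array(y, params, open_left=True)
    f_val = (arr - params.c0) / (params.c1 - arr) * np.exp(params.k / arr)
    inertial = (params.c1 - params.c0) / (params.c1 - arr) ** 2 * np.exp(params.k / arr)
    conservative = -params.k / arr**2 * f_val
    total = inertial + conservative
    if np.ndim(y) == 0:
        return ForceTriple(float(inertial), float(conservative), float(total))
    return inertial, conservative, total
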