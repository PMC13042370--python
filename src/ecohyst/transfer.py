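"""One-sided (history-dependent) state-transition functions.

In normalized space (C0 = 1, C1 = e) a hysteretic system does not follow the
full S-shaped curve f: sweeping the driver up, the state tracks the lower
branch until the forward tipping driver, jumps vertically to the upper
branch, and continues there; sweeping down it follows the mirror-image path
through the backward tipping point.  Each direction therefore has its own
transfer function alpha mapping state to driver:

    alpha_forward(Y)  = f(Y)            on [1, Y-]
                      = x_forward_TP    on (Y-, Y_jump_up)      (the jump)
                      = f(Y)            on [Y_jump_up, e)

and symmetrically for alpha_backward with a plateau at the backward tipping
driver between the low jump target and Y+.  For K <= K* no tipping points
exist and both functions reduce to f itself, so the family varies
continuously with K and fitting can proceed on non-hysteretic data.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from .exceptions import DomainError, RegimeError
from .model import (
    E,
    ModelParams,
    TippingPointPair,
    evaluate_driver,
    tipping_points,
)

__all__ = ["TransferSpec", "jump_target", "alpha_forward", "alpha_backward", "landmarks"]

Direction = Literal["forward", "backward"]


@dataclass(frozen=True)
class TransferSpec:
    """Geometry of one one-sided transfer function.

    ``tipping_state``/``tipping_driver`` locate the active fold point;
    ``jump_state`` is the state on the opposite branch reached by the
    vertical jump at the same driver.
    """

    k: float
    direction: Direction
    tipping_state: float
    tipping_driver: float
    jump_state: float


def jump_target(params: ModelParams, direction: Direction) -> float:
    """State on the opposite branch at the active tipping driver.

    For a forward transition this is the upper-branch state reached by the
    vertical jump at the forward tipping driver; for a backward transition,
    the lower-branch state at the backward tipping driver.  Solved by
    bracketed root finding on the (monotone) opposite branch.
    """
    tp = tipping_points(params)
    if tp is None or tp.degenerate:
        raise RegimeError(
            f"no jump target: K={params.k} does not exceed the critical "
            f"constant K*={params.k_star:.6g}"
        )
    cap = params.c1 - 1e-13 * (params.c1 - params.c0)
    if direction == "forward":
        x = tp.forward.driver
        lo, hi = tp.backward.state, cap
    elif direction == "backward":
        x = tp.backward.driver
        lo, hi = params.c0, tp.forward.state
    else:
        raise ValueError(f"direction must be 'forward' or 'backward', got {direction!r}")
    # just above K* the two fold drivers nearly coincide and the residual at
    # the bracket edge can lose its sign to roundoff; the jump then has zero
    # length and the edge itself is the target
    f_lo = float(evaluate_driver(lo, params)) - x
    f_hi = float(evaluate_driver(hi, params)) - x
    if f_lo >= 0:
        return lo
    if f_hi <= 0:
        # the target sits closer to C1 than the evaluation cap (extreme K);
        # the cap is the closest representable branch state
        return hi
    return float(
        brentq(lambda y: float(evaluate_driver(y, params)) - x, lo, hi, rtol=1e-14)
    )


@dataclass(frozen=True)
class _Landmarks:
    """Cached geometry of the normalized model at one K."""

    params: ModelParams
    tp: TippingPointPair | None
    jump_up: float | None   # upper-branch state reached at the forward TP driver
    jump_low: float | None  # lower-branch state reached at the backward TP driver


# -- fast vectorized branch evaluation/inversion (normalized, unchecked) ----

_CAP = E - 1e-9 * (E - 1.0)


def _f(y, k):
    return (y - 1.0) / (E - y) * np.exp(k / y)


@lru_cache(maxsize=16384)
def _branch_tables(k: float):
    """Monotone (state, driver) tables for the two stable branches.

    The lower table extends below the normalized floor state 1 (the curve
    continues smoothly there with weakly negative drivers); both tables are
    densified near the fold, where the inverse has a square-root
    singularity.  Requires a hysteretic K.
    """
    tp = tipping_points(ModelParams.normalized(k))
    ym, yp = tp.forward.state, tp.backward.state
    floor = max(0.2, k / 700.0)
    t = np.linspace(0.0, 1.0, 256)
    y_lower = ym - (ym - floor) * (1.0 - t) ** 2
    y_upper = yp + (_CAP - yp) * t**2
    return y_lower, _f(y_lower, k), y_upper, _f(y_upper, k)


def _invert_branch_fast(x, k: float, branch: str, steps: int = 3):
    """Vectorized branch inverse: interpolation start plus Newton polish.

    Drivers outside the tabulated range clamp to the nearest branch
    endpoint state.
    """
    y_lo, x_lo, y_up, x_up = _branch_tables(k)
    y_tab, x_tab = (y_lo, x_lo) if branch == "lower" else (y_up, x_up)
    y = np.interp(x, x_tab, y_tab)
    lo, hi = y_tab[0], y_tab[-1]
    for _ in range(steps):
        # fused f and f' sharing one exponential
        ey = np.exp(k / y)
        gap = E - y
        fy = (y - 1.0) / gap * ey
        fp = (E - 1.0) / (gap * gap) * ey - k / (y * y) * fy
        delta = (fy - x) / np.where(np.abs(fp) > 1e-12, fp, np.inf)
        y = np.minimum(np.maximum(y - delta, lo), hi)
    return y


@lru_cache(maxsize=16384)
def landmarks(k: float) -> _Landmarks:
    """Tipping points and jump targets of the normalized model at K = ``k``."""
    params = ModelParams.normalized(k)
    tp = tipping_points(params)
    if tp is None or tp.degenerate:
        return _Landmarks(params, tp, None, None)
    jump_up = float(_invert_branch_fast(tp.forward.driver, k, "upper"))
    jump_low = float(_invert_branch_fast(tp.backward.driver, k, "lower"))
    return _Landmarks(params, tp, jump_up=jump_up, jump_low=max(jump_low, 1.0))


def _alpha(ys, k: float, direction: Direction, extended: bool = False):
    arr = np.asarray(ys, dtype=float)
    if extended:
        # fitting support: the curve (Y-1)/(e-Y) e^{K/Y} continues smoothly
        # and monotonically below Y = 1 (weakly negative drivers), so noisy
        # states standardized slightly below the lower anchor stay evaluable;
        # the floor keeps exp(K/Y) within floating-point range
        floor = max(1e-3, k / 700.0)
        if np.any(arr <= floor) or np.any(arr >= E):
            raise DomainError("normalized state outside the evaluable interval")
    elif np.any(arr < 1.0) or np.any(arr >= E):
        raise DomainError("normalized state must lie in [1, e)")
    lm = landmarks(k)
    f_vals = (arr - 1.0) / (E - arr) * np.exp(k / arr)
    if lm.tp is None or lm.tp.degenerate:
        out = f_vals
    elif direction == "forward":
        on_plateau = (arr > lm.tp.forward.state) & (arr < lm.jump_up)
        out = np.where(on_plateau, lm.tp.forward.driver, f_vals)
    else:
        on_plateau = (arr > lm.jump_low) & (arr < lm.tp.backward.state)
        out = np.where(on_plateau, lm.tp.backward.driver, f_vals)
    return out if out.ndim else float(out)


def alpha_forward(ys, k: float):
    """Driver along the low-to-high transition path at normalized state ``ys``.

    Equals f outside the jump interval and is constant at the forward
    tipping driver across it; non-decreasing on [1, e).  Scalar or array.
    """
    return _alpha(ys, k, "forward")


def alpha_backward(ys, k: float):
    """Driver along the high-to-low transition path at normalized state ``ys``."""
    return _alpha(ys, k, "backward")


def transfer_spec(k: float, direction: Direction) -> TransferSpec:
    """Geometry record for the one-sided transfer function at K = ``k``."""
    lm = landmarks(k)
    if lm.tp is None or lm.tp.degenerate:
        raise RegimeError(
            f"K={k} does not exceed the normalized critical constant; "
            "the transfer function reduces to f and has no jump"
        )
    if direction == "forward":
        tp = lm.tp.forward
        jump = lm.jump_up
    elif direction == "backward":
        tp = lm.tp.backward
        jump = lm.jump_low
    else:
        raise ValueError(f"direction must be 'forward' or 'backward', got {direction!r}")
    return TransferSpec(
        k=k,
        direction=direction,
        tipping_state=tp.state,
        tipping_driver=tp.driver,
        jump_state=jump,
    )
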