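"""Opposite-branch prediction from unidirectional sweep data.

Given observations of only one transition direction (say the low-to-high
forward sweep, including its abrupt jump) and an irreversible potential K,
the normalized model supplies the geometry of the unobserved return path.
The observed pre-jump/post-jump pair anchors the affine state transform phi
onto the model's tipping state and jump target; the observed driver extremes
and tipping driver anchor two affine driver maps back to data units, which
are averaged.  The unobserved tipping point and the return trajectory are
then read off the model and mapped into the data's units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .dataset import BACKWARD, FORWARD, LoopDataset
from .exceptions import DataError, NoTransitionError, RegimeError
from .model import E
from .transfer import alpha_backward, alpha_forward, landmarks
from .transform import StateTransform, averaged_inverse_alignment

__all__ = ["PredictionResult", "BranchPredictor", "detect_observed_tipping", "predict_opposite_branch"]


def _detect_sorted(drivers, states, direction: str, threshold: float):
    """Locate the abrupt jump of a one-directional sweep.

    Sorts by driver (ascending for forward sweeps, descending for backward,
    stably so tied drivers keep sweep order) and finds the largest
    consecutive state change in the transition direction.  Returns the
    pre-jump record's (driver, state, position-in-sorted-order, order).
    """
    drivers = np.asarray(drivers, dtype=float)
    states = np.asarray(states, dtype=float)
    if len(drivers) < 4:
        raise DataError("need at least 4 points to locate a transition")
    order = np.argsort(drivers, kind="stable")
    if direction == BACKWARD:
        order = order[::-1].copy()
        # re-assert sweep order within tied drivers after the reversal
        tied = drivers[order]
        for v in np.unique(tied):
            pos = np.flatnonzero(tied == v)
            if len(pos) > 1:
                order[pos] = order[pos][::-1]
    s = states[order]
    diffs = np.diff(s) if direction == FORWARD else -np.diff(s)
    span = float(states.max() - states.min())
    if span == 0:
        raise NoTransitionError("states are constant; no transition present")
    idx = int(np.argmax(diffs))  # first occurrence wins ties
    if diffs[idx] <= threshold * span:
        raise NoTransitionError(
            f"largest consecutive state jump ({diffs[idx]:.4g}) does not exceed "
            f"{threshold:.0%} of the state range ({span:.4g})"
        )
    return float(drivers[order[idx]]), float(states[order[idx]]), idx, order


def detect_observed_tipping(
    data: LoopDataset | pd.DataFrame,
    direction: str | None = None,
    jump_threshold: float = 0.25,
) -> tuple[float, float, int]:
    """Observed tipping point of a one-directional sweep.

    Returns the (driver, state, index) of the record immediately preceding
    the largest consecutive state jump, where the jump must exceed
    ``jump_threshold`` times the state range.  The index refers to the
    driver-sorted sweep order.  Ties break toward the earliest (first
    encountered) jump.
    """
    frame = data.frame if isinstance(data, LoopDataset) else data
    if direction is None:
        present = set(frame["direction"].unique())
        if len(present) != 1:
            raise DataError(
                "direction is ambiguous: pass direction= or a one-directional dataset"
            )
        direction = present.pop()
    sub = frame[frame["direction"] == direction]
    x, y, idx, _ = _detect_sorted(
        sub["driver"].to_numpy(), sub["state"].to_numpy(), direction, jump_threshold
    )
    return x, y, idx


@dataclass(frozen=True)
class PredictionResult:
    """Predicted opposite-branch tipping point and trajectory, in data units."""

    predicted_tp: tuple[float, float]  # (driver, state)
    trajectory: pd.DataFrame           # columns: driver, state
    k_used: float
    observed_tp: tuple[float, float]

    def to_dict(self) -> dict[str, Any]:
        return {
            "predicted_TP": {
                "driver": self.predicted_tp[0],
                "state": self.predicted_tp[1],
            },
            "observed_TP": {
                "driver": self.observed_tp[0],
                "state": self.observed_tp[1],
            },
            "K_used": self.k_used,
            "n_trajectory": len(self.trajectory),
        }


class BranchPredictor(BaseEstimator):
    """Predict the unobserved transition branch from one-sided data.

    Parameters
    ----------
    k : float
        Irreversible potential to assume; must exceed the normalized
        critical constant so tipping points exist.
    jump_threshold : float
        Minimum consecutive state jump, as a fraction of the state range,
        for the observed tipping point to be detected.
    n_samples : int
        Normalized states sampled per branch segment of the output
        trajectory.

    After ``fit`` the attributes ``observed_tp_``, ``predicted_tp_``,
    ``trajectory_``, ``state_transform_`` and ``result_`` are available;
    ``predict()`` returns the trajectory table.
    """

    def __init__(
        self,
        k: float = 9.0,
        jump_threshold: float = 0.25,
        n_samples: int = 200,
    ):
        self.k = k
        self.jump_threshold = jump_threshold
        self.n_samples = n_samples

    def fit(self, X, y=None) -> "BranchPredictor":
        frame = X.frame if isinstance(X, LoopDataset) else X
        present = set(frame["direction"].unique())
        if len(present) != 1:
            raise DataError("BranchPredictor requires one-directional data")
        direction = present.pop()

        lm = landmarks(self.k)
        if lm.tp is None or lm.tp.degenerate:
            raise RegimeError(
                f"K={self.k} does not exceed the normalized critical constant "
                f"({lm.params.k_star:.4g}); no tipping points exist to predict"
            )

        drivers = frame["driver"].to_numpy(dtype=float)
        states = frame["state"].to_numpy(dtype=float)
        x_tp, y_pre, idx, order = _detect_sorted(
            drivers, states, direction, self.jump_threshold
        )
        y_post = float(states[order[idx + 1]])

        if direction == FORWARD:
            phi = StateTransform.from_anchors(
                y_pre, lm.tp.forward.state, y_post, lm.jump_up
            )
            model_tp_driver = lm.tp.forward.driver
            opposite_tp = (lm.tp.backward.driver, lm.tp.backward.state)
        else:
            phi = StateTransform.from_anchors(
                y_pre, lm.tp.backward.state, y_post, lm.jump_low
            )
            model_tp_driver = lm.tp.backward.driver
            opposite_tp = (lm.tp.forward.driver, lm.tp.forward.state)

        ys = np.clip(phi.standardize(states), 1.0, E * (1.0 - 1e-12))
        alpha = alpha_forward if direction == FORWARD else alpha_backward
        model_drivers = alpha(ys, self.k)

        def to_data_driver(x_model):
            return averaged_inverse_alignment(
                x_model, drivers, model_drivers, x_tp, model_tp_driver
            )

        pred_driver = float(to_data_driver(opposite_tp[0]))
        pred_state = float(phi.destandardize(opposite_tp[1]))

        traj = self._trajectory(
            direction, lm, ys, phi, to_data_driver
        )

        self.direction_ = direction
        self.state_transform_ = phi
        self.observed_tp_ = (x_tp, y_pre)
        self.predicted_tp_ = (pred_driver, pred_state)
        self.trajectory_ = traj
        self.result_ = PredictionResult(
            predicted_tp=self.predicted_tp_,
            trajectory=traj,
            k_used=self.k,
            observed_tp=self.observed_tp_,
        )
        return self

    def _trajectory(self, direction, lm, ys, phi, to_data_driver) -> pd.DataFrame:
        """Sample the opposite-branch sweep within the observed state range."""
        ys_lo = float(ys.min())
        ys_hi = float(ys.max())
        k = self.k
        n = self.n_samples
        y_minus, y_plus = lm.tp.forward.state, lm.tp.backward.state

        def f(y):
            y = np.asarray(y, dtype=float)
            return (y - 1.0) / (E - y) * np.exp(k / y)

        segments: list[tuple[np.ndarray, np.ndarray]] = []
        if direction == FORWARD:
            # unobserved return path: down the upper branch, jump at the
            # backward tipping driver, down the lower branch
            upper = np.linspace(ys_hi, y_plus, n)
            segments.append((f(upper), upper))
            lower_top = min(lm.jump_low, ys_hi)
            lower_end = min(ys_lo, lower_top)
            lower = np.linspace(lower_top, lower_end, n)
            segments.append((np.full(1, lm.tp.backward.driver), np.array([lm.jump_low])))
            segments.append((f(lower), lower))
        else:
            lower = np.linspace(ys_lo, y_minus, n)
            segments.append((f(lower), lower))
            upper_lo = max(lm.jump_up, ys_lo)
            upper_end = max(ys_hi, upper_lo)
            upper = np.linspace(upper_lo, upper_end, n)
            segments.append((np.full(1, lm.tp.forward.driver), np.array([lm.jump_up])))
            segments.append((f(upper), upper))

        x_model = np.concatenate([s[0] for s in segments])
        y_model = np.concatenate([s[1] for s in segments])
        return pd.DataFrame(
            {
                "driver": np.asarray(to_data_driver(x_model), dtype=float),
                "state": np.asarray(phi.destandardize(y_model), dtype=float),
            }
        )

    def predict(self, X=None) -> pd.DataFrame:
        if not hasattr(self, "trajectory_"):
            raise DataError("predictor is not fitted")
        return self.trajectory_


def predict_opposite_branch(
    data: LoopDataset | pd.DataFrame,
    k: float,
    jump_threshold: float = 0.25,
    n_samples: int = 200,
) -> PredictionResult:
    """Functional wrapper over :class:`BranchPredictor`."""
    pred = BranchPredictor(
        k=k, jump_threshold=jump_threshold, n_samples=n_samples
    ).fit(data)
    return pred.result_
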