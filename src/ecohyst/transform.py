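"""Affine maps between data units and normalized model units.

Observed states are mapped onto the normalized state interval [1, e] by an
order-preserving affine transform (phi); observed drivers are related to
model drivers by an affine alignment fitted by least squares, or — for
prediction from one-sided data — by the pair of anchored maps that match
the extreme driver and the tipping driver of data and model, averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import DegenerateError
from .model import E

__all__ = [
    "StateTransform",
    "DriverAlignment",
    "fit_driver_alignment",
    "averaged_inverse_alignment",
]


@dataclass(frozen=True)
class StateTransform:
    """Affine map sending data states [y_low, y_high] onto a margin-inset [1, e].

    ``margin`` is the fraction of (e - 1) kept clear of both ends so that
    data extremes never land exactly on e, where f diverges.
    """

    y_low: float
    y_high: float
    margin: float = 0.0

    def __post_init__(self) -> None:
        if not self.y_low < self.y_high:
            raise DegenerateError(
                f"state range is degenerate: y_low={self.y_low} >= y_high={self.y_high}"
            )
        if not 0 <= self.margin < 0.5:
            raise DegenerateError(f"margin must lie in [0, 0.5), got {self.margin}")

    @property
    def _targets(self) -> tuple[float, float]:
        inset = self.margin * (E - 1.0)
        return 1.0 + inset, E - inset

    @property
    def scale(self) -> float:
        lo, hi = self._targets
        return (hi - lo) / (self.y_high - self.y_low)

    @classmethod
    def from_anchors(
        cls, y_a: float, target_a: float, y_b: float, target_b: float
    ) -> "StateTransform":
        """The affine map with phi(y_a) = target_a and phi(y_b) = target_b.

        Expressed as the equivalent zero-margin range transform (the data
        values that would map to exactly 1 and e).
        """
        if y_a == y_b or target_a == target_b:
            raise DegenerateError("anchor pairs must be distinct in both coordinates")
        slope = (target_b - target_a) / (y_b - y_a)
        if slope <= 0:
            raise DegenerateError("anchors must define an order-preserving map")
        y_low = y_a + (1.0 - target_a) / slope
        y_high = y_a + (E - target_a) / slope
        return cls(y_low=y_low, y_high=y_high, margin=0.0)

    def standardize(self, y):
        """Map data state(s) to normalized state(s)."""
        lo, _ = self._targets
        return lo + (np.asarray(y, dtype=float) - self.y_low) * self.scale

    def destandardize(self, ys):
        """Exact inverse of :meth:`standardize`."""
        lo, _ = self._targets
        return self.y_low + (np.asarray(ys, dtype=float) - lo) / self.scale


@dataclass(frozen=True)
class DriverAlignment:
    """Affine driver map: model_driver = scale * data_driver + offset."""

    scale: float
    offset: float

    @property
    def feasible(self) -> bool:
        """Orientation-preserving alignments (scale > 0) are feasible."""
        return self.scale > 0

    def apply(self, x_data):
        return self.scale * np.asarray(x_data, dtype=float) + self.offset

    def invert(self, x_model):
        return (np.asarray(x_model, dtype=float) - self.offset) / self.scale


def fit_driver_alignment(
    model_values: Sequence[float], data_drivers: Sequence[float]
) -> DriverAlignment:
    """Least-squares affine alignment of data drivers to model drivers.

    Minimizes sum((model - (scale * data + offset))^2) in closed form.
    A non-positive best-fit scale is returned with ``feasible`` False so the
    caller can treat the candidate model as inadmissible.
    """
    m = np.asarray(model_values, dtype=float)
    d = np.asarray(data_drivers, dtype=float)
    if m.shape != d.shape or m.size < 2:
        raise DegenerateError("need >= 2 paired points to fit an alignment")
    var = np.var(d)
    if var == 0:
        raise DegenerateError("data drivers are all equal; alignment is singular")
    scale = float(np.cov(d, m, bias=True)[0, 1] / var)
    offset = float(np.mean(m) - scale * np.mean(d))
    return DriverAlignment(scale=scale, offset=offset)


def averaged_inverse_alignment(
    x,
    data_drivers: Sequence[float],
    model_drivers: Sequence[float],
    data_tp_driver: float,
    model_tp_driver: float,
):
    """Map a model driver back to data units using tipping-anchored ratios.

    Two affine maps are built, each fixing the tipping-driver anchor: one
    scales by the max-to-anchor span ratio, the other by the min-to-anchor
    ratio; their average is returned.  If one span is degenerate (the data
    or model extreme coincides with its anchor) the other map is used alone;
    if both are, a DegenerateError is raised.
    """
    d = np.asarray(data_drivers, dtype=float)
    m = np.asarray(model_drivers, dtype=float)
    x = np.asarray(x, dtype=float)

    maps = []
    for data_ext, model_ext in ((d.max(), m.max()), (d.min(), m.min())):
        denom = model_ext - model_tp_driver
        numer = data_ext - data_tp_driver
        if denom != 0 and numer != 0:
            maps.append(numer / denom * (x - model_tp_driver) + data_tp_driver)
    if not maps:
        raise DegenerateError(
            "both driver extremes coincide with the tipping anchor; "
            "no inverse alignment can be built"
        )
    if len(maps) == 1:
        warnings.warn(
            "one driver extreme coincides with the tipping anchor; "
            "using the single well-defined inverse alignment instead of the average",
            stacklevel=2,
        )
    out = sum(maps) / len(maps)
    return out if out.ndim else float(out)
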