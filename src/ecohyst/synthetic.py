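"""Synthetic hysteresis-loop generator.

Emulates driver-controlled sweep experiments on a bistable system: the
driver is stepped monotonically while the state tracks the active stable
branch, with a deterministic vertical jump to the opposite branch exactly
at the tipping driver.  Both fold endpoints are recorded at the tipping
driver — the branch endpoint (the tipping state itself) and the jump
target on the opposite branch — so a noiseless sweep contains the exact
jump geometry.  Optional Gaussian noise is added to the states (the driver
is the controlled variable) and clipped to keep them strictly inside
(C0, C1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import BACKWARD, FORWARD, LoopDataset
from .exceptions import DataError, RegimeError
from .model import ModelParams, invert_branch, tipping_points

__all__ = ["SyntheticConfig", "generate_loop", "generate_one_sided"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of one synthetic sweep experiment.

    ``driver_low_frac`` and ``driver_high_frac`` set the sweep endpoints as
    fractions of the backward and forward tipping drivers respectively, so
    the sweep brackets the whole loop by default (0.5 and 1.2).
    """

    params: ModelParams = field(default_factory=lambda: ModelParams.normalized(9.0))
    n_per_branch: int = 50
    noise_sd: float = 0.0
    seed: int = 0
    driver_low_frac: float = 0.5
    driver_high_frac: float = 1.2

    def __post_init__(self) -> None:
        if self.n_per_branch < 4:
            raise DataError(f"n_per_branch must be >= 4, got {self.n_per_branch}")
        if self.noise_sd < 0:
            raise DataError("noise_sd must be non-negative")
        if not (0 < self.driver_low_frac < 1 < self.driver_high_frac):
            raise DataError(
                "sweep fractions must satisfy 0 < driver_low_frac < 1 < driver_high_frac"
            )


def _sweep_geometry(cfg: SyntheticConfig):
    tp = tipping_points(cfg.params)
    if tp is None or tp.degenerate:
        raise RegimeError(
            f"synthetic loops require a hysteretic regime; K={cfg.params.k} "
            f"does not exceed K*={cfg.params.k_star:.6g}"
        )
    x_lo = cfg.driver_low_frac * tp.backward.driver
    x_hi = cfg.driver_high_frac * tp.forward.driver
    return tp, x_lo, x_hi


def _split(n: int, frac: float) -> int:
    """Points allocated to the first sweep segment, proportional to its span."""
    return int(np.clip(round(n * frac), 2, n - 2))


def _forward_sweep(cfg: SyntheticConfig):
    """Ascending sweep: lower branch up to the fold, jump, upper branch."""
    tp, x_lo, x_hi = _sweep_geometry(cfg)
    p = cfg.params
    n = cfg.n_per_branch
    n_low = _split(n, (tp.forward.driver - x_lo) / (x_hi - x_lo))
    x_lower = np.linspace(x_lo, tp.forward.driver, n_low)
    x_upper = np.linspace(tp.forward.driver, x_hi, n - n_low)
    y_lower = np.array([invert_branch(x, p, "lower") for x in x_lower])
    y_upper = np.array([invert_branch(x, p, "upper") for x in x_upper])
    drivers = np.concatenate([x_lower, x_upper])
    states = np.concatenate([y_lower, y_upper])
    return drivers, states, n_low - 1  # index of the pre-jump record


def _backward_sweep(cfg: SyntheticConfig):
    """Descending sweep: upper branch down to the fold, jump, lower branch."""
    tp, x_lo, x_hi = _sweep_geometry(cfg)
    p = cfg.params
    n = cfg.n_per_branch
    n_up = _split(n, (x_hi - tp.backward.driver) / (x_hi - x_lo))
    x_upper = np.linspace(x_hi, tp.backward.driver, n_up)
    x_lower = np.linspace(tp.backward.driver, x_lo, n - n_up)
    y_upper = np.array([invert_branch(x, p, "upper") for x in x_upper])
    y_lower = np.array([invert_branch(x, p, "lower") for x in x_lower])
    drivers = np.concatenate([x_upper, x_lower])
    states = np.concatenate([y_upper, y_lower])
    return drivers, states, n_up - 1


def _add_noise(states: np.ndarray, cfg: SyntheticConfig, rng: np.random.Generator):
    if cfg.noise_sd == 0:
        return states
    noisy = states + rng.normal(0.0, cfg.noise_sd, size=states.shape)
    buf = 1e-6 * (cfg.params.c1 - cfg.params.c0)
    return np.clip(noisy, cfg.params.c0 + buf, cfg.params.c1 - buf)


def generate_loop(cfg: SyntheticConfig) -> LoopDataset:
    """Generate a full hysteresis loop (forward then backward sweep).

    Returns a dataset with exactly ``2 * n_per_branch`` records, labeled by
    direction, deterministic for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    xf, yf, _ = _forward_sweep(cfg)
    xb, yb, _ = _backward_sweep(cfg)
    yf = _add_noise(yf, cfg, rng)
    yb = _add_noise(yb, cfg, rng)
    return LoopDataset.from_arrays(
        np.concatenate([xf, xb]),
        np.concatenate([yf, yb]),
        np.array([FORWARD] * len(xf) + [BACKWARD] * len(xb), dtype=object),
        provenance=f"synthetic loop (K={cfg.params.k}, seed={cfg.seed})",
    )


def generate_one_sided(
    cfg: SyntheticConfig, direction: str
) -> tuple[LoopDataset, int]:
    """Generate a unidirectional sweep; also return the true pre-jump index.

    The pre-jump index points at the record sitting exactly on the fold
    (tipping state); the next record is the jump target at the same driver.
    """
    rng = np.random.default_rng(cfg.seed)
    if direction == FORWARD:
        x, y, pre_jump = _forward_sweep(cfg)
    elif direction == BACKWARD:
        x, y, pre_jump = _backward_sweep(cfg)
    else:
        raise DataError(f"direction must be 'forward' or 'backward', got {direction!r}")
    y = _add_noise(y, cfg, rng)
    data = LoopDataset.from_arrays(
        x,
        y,
        np.array([direction] * len(x), dtype=object),
        provenance=f"synthetic {direction} sweep (K={cfg.params.k}, seed={cfg.seed})",
    )
    return data, pre_jump
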