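"""Loop datasets and delimited-table input/output.

The canonical exchange format is a delimited text table (comma by default,
tab accepted) with a header row and three columns: the driver value, the
state value, and the sweep direction ("forward" for the low-to-high
transition, "backward" for the return path).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError, ParseError, SchemaError

__all__ = ["TableSchema", "LoopDataset", "read_loop_table", "write_loop_table"]

FORWARD = "forward"
BACKWARD = "backward"


@dataclass(frozen=True)
class TableSchema:
    """Column names and direction tokens of a loop table."""

    driver_col: str = "driver"
    state_col: str = "state"
    direction_col: str = "direction"
    forward_label: str = FORWARD
    backward_label: str = BACKWARD

    def __post_init__(self) -> None:
        cols = (self.driver_col, self.state_col, self.direction_col)
        if len(set(cols)) != 3:
            raise SchemaError(f"column names must be distinct, got {cols}")


@dataclass
class LoopDataset:
    """Observed (driver, state, direction) records of a hysteresis sweep.

    ``frame`` holds the records in sweep order with canonical columns
    ``driver`` (float), ``state`` (float) and ``direction`` ("forward" or
    "backward").  A dataset may hold one full loop (both directions) or a
    single unidirectional branch.
    """

    frame: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        required = {"driver", "state", "direction"}
        missing = required - set(self.frame.columns)
        if missing:
            raise DataError(f"LoopDataset frame missing columns: {sorted(missing)}")
        f = self.frame
        for col in ("driver", "state"):
            vals = pd.to_numeric(f[col], errors="coerce")
            if not np.isfinite(vals.to_numpy(dtype=float)).all():
                raise DataError(f"non-finite or non-numeric values in column {col!r}")
        bad = set(f["direction"].unique()) - {FORWARD, BACKWARD}
        if bad:
            raise DataError(f"unknown direction tokens: {sorted(bad)}")
        self.frame = pd.DataFrame(
            {
                "driver": f["driver"].to_numpy(dtype=float),
                "state": f["state"].to_numpy(dtype=float),
                "direction": f["direction"].to_numpy(dtype=object),
            }
        )

    @classmethod
    def from_arrays(cls, driver, state, direction, provenance: str = "") -> "LoopDataset":
        direction = np.asarray(direction, dtype=object)
        return cls(
            pd.DataFrame(
                {"driver": driver, "state": state, "direction": direction}
            ),
            provenance=provenance,
        )

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, direction: str) -> pd.DataFrame:
        if direction not in (FORWARD, BACKWARD):
            raise DataError(f"direction must be 'forward' or 'backward', got {direction!r}")
        return self.frame[self.frame["direction"] == direction]

    @property
    def forward(self) -> pd.DataFrame:
        return self.subset(FORWARD)

    @property
    def backward(self) -> pd.DataFrame:
        return self.subset(BACKWARD)

    @property
    def directions(self) -> set[str]:
        return set(self.frame["direction"].unique())

    def require_min_per_direction(self, n: int) -> None:
        for d in sorted(self.directions):
            count = (self.frame["direction"] == d).sum()
            if count < n:
                raise DataError(
                    f"need at least {n} records in direction {d!r}, got {count}"
                )


def _read_raw(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # comma is canonical; fall back to tab when the header has a single field
    frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if len(frame.columns) == 1 and "\t" in frame.columns[0]:
        frame = pd.read_csv(path, dtype=str, sep="\t", skipinitialspace=True)
    return frame


def read_loop_table(path: str | Path, schema: TableSchema | None = None) -> LoopDataset:
    """Parse and validate a delimited loop table into a :class:`LoopDataset`.

    Raises :class:`SchemaError` for missing columns, :class:`ParseError`
    (with the 1-based file line number) for non-numeric cells, and
    :class:`DataError` for unknown direction tokens.  Row order is
    preserved; direction tokens are matched case-insensitively.
    """
    schema = schema or TableSchema()
    raw = _read_raw(path)
    for col in (schema.driver_col, schema.state_col, schema.direction_col):
        if col not in raw.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")

    def _numeric(col: str) -> np.ndarray:
        probe = pd.to_numeric(raw[col], errors="coerce").to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(probe))
        if bad.size:
            line = int(bad[0]) + 2  # +1 header, +1 one-based
            raise ParseError(
                f"non-numeric value {raw[col].iloc[bad[0]]!r} in column {col!r} "
                f"at line {line} of {path}"
            )
        # numpy's parser is correctly rounded, so written tables round-trip
        return raw[col].to_numpy(dtype=float)

    driver = _numeric(schema.driver_col)
    state = _numeric(schema.state_col)

    tokens = raw[schema.direction_col].astype(str).str.strip().str.lower()
    mapping = {
        schema.forward_label.lower(): FORWARD,
        schema.backward_label.lower(): BACKWARD,
    }
    direction = tokens.map(mapping)
    bad = np.flatnonzero(direction.isna().to_numpy())
    if bad.size:
        line = int(bad[0]) + 2
        raise DataError(
            f"unknown direction token {tokens.iloc[bad[0]]!r} at line {line} of {path}; "
            f"expected {schema.forward_label!r} or {schema.backward_label!r}"
        )
    return LoopDataset.from_arrays(
        driver, state, direction.to_numpy(dtype=object), provenance=str(path)
    )


def write_loop_table(
    data: LoopDataset, path: str | Path, schema: TableSchema | None = None
) -> None:
    """Write a loop dataset as a comma-delimited table with full precision."""
    schema = schema or TableSchema()
    out = pd.DataFrame(
        {
            schema.driver_col: data.frame["driver"],
            schema.state_col: data.frame["state"],
            schema.direction_col: data.frame["direction"].map(
                {FORWARD: schema.forward_label, BACKWARD: schema.backward_label}
            ),
        }
    )
    out.to_csv(path, index=False, float_format="%.17g")
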