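"""Monthly climate cubes.

A :class:`ClimateCube` holds monthly ``tmin``/``tmax``/``tmean``/``prec``
fields for a run of years on one grid.  Temperatures are in °C,
precipitation in mm/month.  Arrays are indexed ``(year, month, row, col)``
with 12 months per year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError
from .grid import GridSpec

CLIMATE_VARS = ("tmin", "tmax", "tmean", "prec")


@dataclass
class ClimateCube:
    grid: GridSpec
    years: np.ndarray
    data: dict[str, np.ndarray]
    label: str = ""

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        missing = set(CLIMATE_VARS) - set(self.data)
        if missing:
            raise ValueError(f"cube missing variables: {sorted(missing)}")
        shape = (len(self.years), 12, self.grid.n_rows, self.grid.n_cols)
        for var in CLIMATE_VARS:
            arr = np.asarray(self.data[var], dtype=float)
            if arr.shape != shape:
                raise ValueError(
                    f"{var} has shape {arr.shape}, expected {shape}"
                )
            self.data[var] = arr

    def validate(self) -> None:
        """Check physical invariants: tmin <= tmean <= tmax, prec >= 0."""
        if np.any(self.data["tmin"] > self.data["tmean"] + 1e-9):
            raise ValueError("tmin exceeds tmean somewhere")
        if np.any(self.data["tmean"] > self.data["tmax"] + 1e-9):
            raise ValueError("tmean exceeds tmax somewhere")
        if np.any(self.data["prec"] < 0):
            raise ValueError("negative precipitation")

    def year_slice(self, start: int, stop: int) -> "ClimateCube":
        """Sub-cube for years in the half-open interval ``[start, stop)``."""
        sel = (self.years >= start) & (self.years < stop)
        if not sel.any():
            raise AlignmentError(f"no years of {self.label or 'cube'} in [{start}, {stop})")
        return ClimateCube(
            grid=self.grid,
            years=self.years[sel],
            data={v: a[sel] for v, a in self.data.items()},
            label=self.label,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClimateCube):
            return NotImplemented
        return (
            self.grid == other.grid
            and np.array_equal(self.years, other.years)
            and all(np.array_equal(self.data[v], other.data[v]) for v in CLIMATE_VARS)
        )
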