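"""From monthly cubes to bias-corrected, horizon-averaged bioclimatic stacks.

The pipeline works with five bioclimatic indices: annual mean temperature
(bio1, °C), maximum temperature of the warmest month (bio5, °C), minimum
temperature of the coldest month (bio6, °C), annual precipitation
(bio12, mm) and precipitation seasonality (bio15, %).  Future projections
are delta-bias-corrected against an observed baseline climatology before
the indices are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cube import CLIMATE_VARS, ClimateCube
from .errors import AlignmentError, ParameterError
from .grid import GridSpec

BIOCLIM_VARS = ("bio1", "bio5", "bio6", "bio12", "bio15")


@dataclass
class PeriodClimatology:
    """Twelve monthly mean fields per variable for one averaging window."""

    grid: GridSpec
    data: dict[str, np.ndarray]  # var -> (12, n_rows, n_cols)
    center_year: int
    width: int
    label: str = ""

    def __post_init__(self) -> None:
        shape = (12, self.grid.n_rows, self.grid.n_cols)
        for var, arr in self.data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{var} climatology has shape {arr.shape}, expected {shape}")
            self.data[var] = arr


@dataclass
class BioclimStack:
    """Per-cell bio1/bio5/bio6/bio12/bio15 fields for one period."""

    grid: GridSpec
    data: dict[str, np.ndarray]  # bio var -> (n_rows, n_cols)
    label: str = ""
    mask: np.ndarray | None = None  # True where cell is valid; None = all valid

    def __post_init__(self) -> None:
        missing = set(BIOCLIM_VARS) - set(self.data)
        if missing:
            raise ValueError(f"stack missing variables: {sorted(missing)}")
        for var in BIOCLIM_VARS:
            arr = np.asarray(self.data[var], dtype=float)
            if arr.shape != self.grid.shape:
                raise ValueError(f"{var} has shape {arr.shape}, expected {self.grid.shape}")
            self.data[var] = arr

    def features(self, cell_ids: np.ndarray | None = None) -> np.ndarray:
        """Feature matrix ``(n_cells, 5)`` in BIOCLIM_VARS order.

        With ``cell_ids`` given, rows follow that order; otherwise all grid
        cells in row-major order.
        """
        flat = np.column_stack([self.data[v].ravel() for v in BIOCLIM_VARS])
        if cell_ids is None:
            return flat
        return flat[np.asarray(cell_ids)]


def horizon_mean(cube: ClimateCube, center_year: int, width: int = 30) -> PeriodClimatology:
    """Per-calendar-month mean over the half-open window
    ``[center - width//2, center - width//2 + width)``.

    The default 30-year window centered on a horizon year mirrors standard
    climatological averaging of projection output.
    """
    if width < 1:
        raise ParameterError("width must be >= 1")
    start = center_year - width // 2
    stop = start + width
    if start < cube.years.min() or stop > cube.years.max() + 1:
        raise AlignmentError(
            f"window [{start}, {stop}) outside cube years "
            f"[{cube.years.min()}, {cube.years.max()}]"
        )
    sub = cube.year_slice(start, stop)
    data = {var: sub.data[var].mean(axis=0) for var in CLIMATE_VARS}
    return PeriodClimatology(
        grid=cube.grid,
        data=data,
        center_year=center_year,
        width=width,
        label=f"{cube.label} {center_year} horizon" if cube.label else f"{center_year} horizon",
    )


def delta_bias_correct(
    model_clim_baseline: PeriodClimatology,
    obs_clim_baseline: PeriodClimatology,
    model_clim_target: PeriodClimatology,
) -> PeriodClimatology:
    """Additive delta correction of a target climatology.

    The target is shifted by the mean bias between the modeled and observed
    baseline climatology, per calendar month per cell:
    ``corrected = target - (model_baseline - obs_baseline)``.
    Precipitation is clamped at zero after shifting.  Applied to the model
    baseline itself the correction returns the observed baseline exactly
    (before any clamping).
    """
    for clim in (obs_clim_baseline, model_clim_target):
        if clim.grid != model_clim_baseline.grid:
            raise AlignmentError("climatologies live on different grids")
    corrected: dict[str, np.ndarray] = {}
    for var in CLIMATE_VARS:
        bias = model_clim_baseline.data[var] - obs_clim_baseline.data[var]
        out = model_clim_target.data[var] - bias
        if var == "prec":
            out = np.maximum(out, 0.0)
        corrected[var] = out
    return PeriodClimatology(
        grid=model_clim_target.grid,
        data=corrected,
        center_year=model_clim_target.center_year,
        width=model_clim_target.width,
        label=f"{model_clim_target.label} (bias-corrected)",
    )


def compute_bioclim(clim: PeriodClimatology) -> BioclimStack:
    """Compute the five bioclim indices from a 12-month climatology.

    bio15 follows the ANUCLIM/biovars convention: the coefficient of
    variation of monthly precipitation after adding 1 mm to every month
    (avoiding division by zero in arid cells), with the sample standard
    deviation (n-1), expressed in percent.
    """
    for var in CLIMATE_VARS:
        if var not in clim.data:
            raise ParameterError(f"climatology missing {var}")
    tmean, tmax, tmin, prec = (
        clim.data["tmean"],
        clim.data["tmax"],
        clim.data["tmin"],
        clim.data["prec"],
    )
    prec1 = prec + 1.0
    bio15 = 100.0 * prec1.std(axis=0, ddof=1) / prec1.mean(axis=0)
    return BioclimStack(
        grid=clim.grid,
        data={
            "bio1": tmean.mean(axis=0),
            "bio5": tmax.max(axis=0),
            "bio6": tmin.min(axis=0),
            "bio12": prec.sum(axis=0),
            "bio15": bio15,
        },
        label=clim.label,
    )


def _block_mean(arr: np.ndarray, factor: int) -> np.ndarray:
    """Mean over ``factor x factor`` blocks, NaN-aware (NaN = masked cell)."""
    r, c = arr.shape
    blocks = arr.reshape(r // factor, factor, c // factor, factor)
    blocks = blocks.transpose(0, 2, 1, 3).reshape(r // factor, c // factor, -1)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN block -> NaN
        return np.nanmean(blocks, axis=-1)


def aggregate_grid(stack: BioclimStack, factor: int) -> BioclimStack:
    """Up-scale a bioclim stack by block-averaging ``factor x factor`` cells.

    Masked cells (NaN) are excluded from each block mean; a fully masked
    block stays masked.  Grid dims must be divisible by ``factor``.
    """
    if factor < 1:
        raise ParameterError("aggregation factor must be >= 1")
    if factor == 1:
        return stack
    if stack.grid.n_rows % factor or stack.grid.n_cols % factor:
        raise ParameterError(
            f"grid {stack.grid.shape} not divisible by factor {factor}"
        )
    coarse = stack.grid.coarsen(factor)
    data = {var: _block_mean(stack.data[var], factor) for var in BIOCLIM_VARS}
    mask = None
    if stack.mask is not None:
        # a coarse cell is valid if any subcell is valid
        mask = _block_mean(stack.mask.astype(float), factor) > 0
    return BioclimStack(grid=coarse, data=data, label=stack.label, mask=mask)
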