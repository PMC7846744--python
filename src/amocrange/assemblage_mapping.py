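"""Stacked-SDM richness grids and species-loss (diversity-deficit) maps.

Binary per-species maps on the analysis grid are stacked into species
richness on a coarser (1°) grid — a species counts as present in a coarse
cell if it is present in any of its subcells — and per-cell percentage
species loss is computed against current richness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .binarization import BinaryRangeMap
from .errors import AlignmentError, ParameterError
from .grid import GridSpec


@dataclass
class RichnessMap:
    grid: GridSpec
    counts: np.ndarray  # int, grid shape
    scenario: str = ""
    horizon: int | str = "current"
    algorithm: str = ""
    dispersal: str = ""
    criterion: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != self.grid.shape:
            raise AlignmentError("richness counts do not match grid shape")


@dataclass
class DeficitMap:
    """Percent species loss per cell; NaN where current richness is zero."""

    grid: GridSpec
    percent_loss: np.ndarray  # float, NaN = masked
    scenario: str = ""
    horizon: int | str = ""
    algorithm: str = ""
    dispersal: str = ""


def _coarsen_presence(presence: np.ndarray, factor: int) -> np.ndarray:
    """Any-subcell aggregation of a boolean map to a coarser grid."""
    r, c = presence.shape
    if r % factor or c % factor:
        raise ParameterError(f"grid {presence.shape} not divisible by factor {factor}")
    blocks = presence.reshape(r // factor, factor, c // factor, factor)
    return blocks.any(axis=(1, 3))


def stack_richness(
    maps: Sequence[BinaryRangeMap],
    factor: int = 3,
    **meta,
) -> RichnessMap:
    """Species richness per coarse cell from stacked binary maps.

    All maps must share the analysis grid and threshold criterion; each is
    aggregated to the coarse grid by the any-subcell rule and the boolean
    stacks are summed.  ``factor`` is the coarsening ratio (3 for
    0.33° -> 1°); 1 stacks on the native grid.
    """
    if not maps:
        raise ParameterError("no binary maps to stack")
    shape = maps[0].presence.shape
    criterion = maps[0].criterion
    for m in maps:
        if m.presence.shape != shape:
            raise AlignmentError("binary maps on different grids")
        if m.criterion != criterion:
            raise ParameterError(
                f"mixed threshold criteria in stack: {m.criterion} vs {criterion}"
            )
    counts = np.zeros((shape[0] // factor, shape[1] // factor), dtype=np.int32)
    for m in maps:
        counts += _coarsen_presence(m.presence, factor)
    coarse = GridSpec(
        shape[0] // factor,
        shape[1] // factor,
        meta.pop("cell_size", 1.0),
    )
    return RichnessMap(
        grid=coarse,
        counts=counts,
        criterion=criterion,
        **meta,
    )


def deficit_map(current: RichnessMap, future: RichnessMap) -> DeficitMap:
    """Percentage species loss 100 (S_now - S_future) / S_now per cell.

    Cells with zero current richness are masked (NaN), never 0 or inf.
    Negative values (richness gains under full dispersal) are allowed; the
    deficit is bounded above by 100.
    """
    if current.counts.shape != future.counts.shape:
        raise AlignmentError("richness maps on different grids")
    if current.criterion != future.criterion:
        raise ParameterError("richness maps use different threshold criteria")
    if current.dispersal and future.dispersal and current.dispersal != future.dispersal:
        raise ParameterError("richness maps assume different dispersal modes")
    s_now = current.counts.astype(float)
    s_fut = future.counts.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        loss = 100.0 * (s_now - s_fut) / s_now
    loss[s_now == 0] = np.nan
    return DeficitMap(
        grid=current.grid,
        percent_loss=loss,
        scenario=future.scenario,
        horizon=future.horizon,
        algorithm=future.algorithm,
        dispersal=future.dispersal,
    )


def algorithm_average_map(maps: Sequence[DeficitMap]) -> DeficitMap:
    """Cellwise mean deficit across algorithms.

    A cell is averaged over the algorithms for which it is unmasked and
    stays masked only where every input masks it.
    """
    if not maps:
        raise ParameterError("no deficit maps to average")
    shape = maps[0].percent_loss.shape
    for m in maps:
        if m.percent_loss.shape != shape:
            raise AlignmentError("deficit maps on different grids")
    stack = np.stack([m.percent_loss for m in maps])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells stay NaN
        mean = np.nanmean(stack, axis=0)
    return DeficitMap(
        grid=maps[0].grid,
        percent_loss=mean,
        scenario=maps[0].scenario,
        horizon=maps[0].horizon,
        algorithm="ENSEMBLE",
        dispersal=maps[0].dispersal,
    )
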