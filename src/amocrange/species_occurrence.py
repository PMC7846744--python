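"""Modeling datasets: rasterized ranges, filters, pseudoabsences, splits.

Species enter the pipeline as presence cell sets.  A species is retained
only if it is endemic to a single biogeographic realm and occupies at
least 50 grid cells; the realm then serves as the background area from
which pseudoabsences are drawn (three per presence), and each species gets
ten random 70/30 calibration/validation splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import ParameterError, SamplingError
from .grid import GridSpec, RealmMask

try:  # polygon rasterization is optional; cell-set input needs no shapely
    from shapely import contains_xy as _contains_xy
    from shapely.geometry.base import BaseGeometry
except Exception:  # pragma: no cover
    _contains_xy = None
    BaseGeometry = ()  # type: ignore[assignment]

DEFAULT_MIN_PRESENCE = 50
DEFAULT_PA_RATIO = 3
DEFAULT_TRAIN_FRAC = 0.7
DEFAULT_N_RUNS = 10


@dataclass
class SpeciesRecord:
    species_id: str
    family: str
    status: str
    realm: str
    presence_cells: np.ndarray

    def __post_init__(self) -> None:
        self.presence_cells = np.sort(np.asarray(self.presence_cells, dtype=int))

    @property
    def n_presence(self) -> int:
        return len(self.presence_cells)


@dataclass
class Split:
    """One calibration/validation split of presences and pseudoabsences."""

    train_presence: np.ndarray
    test_presence: np.ndarray
    train_background: np.ndarray
    test_background: np.ndarray


@dataclass
class OccurrenceDesign:
    """Everything needed to fit and validate one species' models."""

    species_id: str
    presence_cells: np.ndarray
    pseudoabsence_cells: np.ndarray
    runs: list[Split] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.presence_cells = np.asarray(self.presence_cells, dtype=int)
        self.pseudoabsence_cells = np.asarray(self.pseudoabsence_cells, dtype=int)
        if np.intersect1d(self.presence_cells, self.pseudoabsence_cells).size:
            raise ValueError("pseudoabsences overlap presences")


def rasterize_range(
    geometry: "BaseGeometry", grid: GridSpec
) -> np.ndarray:
    """Cells whose centers fall inside a range polygon (cell ids)."""
    if _contains_xy is None:  # pragma: no cover
        raise ImportError("shapely is required for polygon rasterization")
    lon, lat = grid.cell_centers()
    inside = _contains_xy(geometry, lon.ravel(), lat.ravel())
    return np.nonzero(inside)[0]


def rasterize_and_filter(
    ranges: Mapping[str, object],
    grid: GridSpec,
    realm_mask: RealmMask,
    metadata: Mapping[str, Mapping[str, str]] | None = None,
    min_presence: int = DEFAULT_MIN_PRESENCE,
) -> tuple[list[SpeciesRecord], list[dict]]:
    """Build SpeciesRecords from ranges; exclude small or non-endemic species.

    ``ranges`` maps species id to either a shapely geometry, a boolean
    presence raster of the grid's shape, or an iterable of presence cell
    ids.  ``metadata`` optionally supplies family/status per species.
    Returns the retained records and an exclusion log whose entries carry
    ``species_id`` and ``reason`` in {"outside_grid", "min_presence",
    "not_endemic"}.  Retained records and the log exactly partition the
    input species list.
    """
    records: list[SpeciesRecord] = []
    exclusions: list[dict] = []
    for sid, rng_obj in ranges.items():
        if isinstance(rng_obj, BaseGeometry):
            cells = rasterize_range(rng_obj, grid)
        else:
            arr = np.asarray(rng_obj)
            if arr.dtype == bool or (arr.ndim == 2 and arr.shape == grid.shape):
                cells = np.nonzero(arr.astype(bool).ravel())[0]
            else:
                cells = np.unique(arr.astype(int))
                if cells.size and (cells.min() < 0 or cells.max() >= grid.n_cells):
                    exclusions.append({"species_id": sid, "reason": "outside_grid"})
                    continue
        if cells.size == 0:
            exclusions.append({"species_id": sid, "reason": "outside_grid"})
            continue
        realms = np.unique(realm_mask.realm_of_cells(cells))
        if len(realms) > 1:
            exclusions.append({"species_id": sid, "reason": "not_endemic"})
            continue
        if len(cells) < min_presence:
            exclusions.append({"species_id": sid, "reason": "min_presence"})
            continue
        meta = dict(metadata.get(sid, {})) if metadata else {}
        records.append(
            SpeciesRecord(
                species_id=sid,
                family=meta.get("family", "unknown"),
                status=meta.get("status", "DD"),
                realm=realm_mask.names[int(realms[0])],
                presence_cells=cells,
            )
        )
    return records, exclusions


def sample_pseudoabsences(
    record: SpeciesRecord,
    realm_mask: RealmMask,
    ratio: int = DEFAULT_PA_RATIO,
    seed: int = 0,
) -> np.ndarray:
    """Uniform sample of ``ratio * n_presence`` background cells.

    The background is the species' realm minus its presence cells; sampling
    is without replacement and deterministic given the seed.
    """
    realm_cells = realm_mask.cells_for(record.realm)
    background = np.setdiff1d(realm_cells, record.presence_cells, assume_unique=True)
    n_needed = ratio * record.n_presence
    if len(background) < n_needed:
        raise SamplingError(
            f"{record.species_id}: background of {len(background)} cells in "
            f"{record.realm} cannot supply {n_needed} pseudoabsences"
        )
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(background, size=n_needed, replace=False))


def partition_runs(
    design: OccurrenceDesign,
    train_frac: float = DEFAULT_TRAIN_FRAC,
    n_runs: int = DEFAULT_N_RUNS,
    seed: int | None = None,
) -> OccurrenceDesign:
    """Attach ``n_runs`` random 70/30 splits to a design.

    Presences and pseudoabsences are split independently; each set
    contributes ``floor(train_frac * n)`` cells to calibration and the
    remainder to validation, so the 1:ratio class balance carries over to
    both sides up to rounding.
    """
    if not (0.0 < train_frac < 1.0):
        raise ParameterError(f"train_frac must be in (0, 1), got {train_frac}")
    if len(design.presence_cells) < 2 or len(design.pseudoabsence_cells) < 2:
        raise ParameterError("need at least 2 presences and 2 pseudoabsences")
    seed = design.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    runs: list[Split] = []
    for _ in range(n_runs):
        runs.append(
            Split(
                *_split(design.presence_cells, train_frac, rng),
                *_split(design.pseudoabsence_cells, train_frac, rng),
            )
        )
    design.runs = runs
    design.seed = seed
    return design


def _split(cells: np.ndarray, train_frac: float, rng: np.random.Generator):
    perm = rng.permutation(cells)
    n_train = int(np.floor(train_frac * len(cells)))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def build_design(
    record: SpeciesRecord,
    realm_mask: RealmMask,
    seed: int,
    ratio: int = DEFAULT_PA_RATIO,
    train_frac: float = DEFAULT_TRAIN_FRAC,
    n_runs: int = DEFAULT_N_RUNS,
) -> OccurrenceDesign:
    """Pseudoabsence sampling + run partitioning in one call.

    Pseudoabsences are drawn once per species and shared across runs; the
    runs differ only in the random calibration/validation split.
    """
    pa = sample_pseudoabsences(record, realm_mask, ratio=ratio, seed=seed)
    design = OccurrenceDesign(
        species_id=record.species_id,
        presence_cells=record.presence_cells,
        pseudoabsence_cells=pa,
        seed=seed,
    )
    return partition_runs(design, train_frac=train_frac, n_runs=n_runs, seed=seed)
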