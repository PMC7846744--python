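"""Regular lon-lat analysis grids and realm masks.

Cells are indexed 0-based, row-major from the north-west corner; bounding
boxes are half-open.  All raster-like arrays in the package are 2-D numpy
arrays of shape ``(n_rows, n_cols)`` with row 0 at the northern edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Biogeographic realm names used when a world is split into six realms.
REALM_NAMES = (
    "Afrotropical",
    "Australasian",
    "Indomalayan",
    "Nearctic",
    "Neotropical",
    "Palearctic",
)


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lon-lat grid.

    Parameters
    ----------
    n_rows, n_cols
        Grid shape.
    cell_size
        Cell edge length in degrees.
    lon0, lat0
        Coordinates of the north-west corner (outer edge of cell ``(0, 0)``).
    """

    n_rows: int
    n_cols: int
    cell_size: float
    lon0: float = 0.0
    lat0: float = 60.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid shape must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_id(self, row: np.ndarray | int, col: np.ndarray | int) -> np.ndarray | int:
        """Row-major cell id from row/col indices."""
        return np.asarray(row) * self.n_cols + np.asarray(col)

    def rowcol(self, cell_id: np.ndarray | int) -> tuple[np.ndarray, np.ndarray]:
        cid = np.asarray(cell_id)
        return cid // self.n_cols, cid % self.n_cols

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Longitude/latitude of every cell center as 2-D arrays."""
        lon = self.lon0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        lat = self.lat0 - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(lon, lat)

    def lat_centers(self) -> np.ndarray:
        return self.lat0 - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def lon_centers(self) -> np.ndarray:
        return self.lon0 + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def coarsen(self, factor: int) -> "GridSpec":
        if factor < 1:
            raise ValueError("factor must be >= 1")
        if self.n_rows % factor or self.n_cols % factor:
            raise ValueError("grid dims not divisible by aggregation factor")
        return GridSpec(
            self.n_rows // factor,
            self.n_cols // factor,
            self.cell_size * factor,
            self.lon0,
            self.lat0,
        )


@dataclass
class RealmMask:
    """Partition of a grid into labeled biogeographic realms.

    ``labels[r, c]`` is an integer realm index into :attr:`names`.  The
    partition is contiguous, non-overlapping and collectively exhaustive by
    construction (see :func:`make_realm_mask`).
    """

    grid: GridSpec
    labels: np.ndarray
    names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.shape != self.grid.shape:
            raise ValueError("label array does not match grid shape")
        present = np.unique(self.labels)
        if present.min() < 0 or present.max() >= len(self.names):
            raise ValueError("realm labels outside the name table")

    @property
    def n_realms(self) -> int:
        return len(self.names)

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown realm {name!r}; known: {self.names}") from None

    def mask_for(self, name: str) -> np.ndarray:
        """Boolean mask of the named realm."""
        return self.labels == self.index_of(name)

    def cells_for(self, name: str) -> np.ndarray:
        """Sorted cell ids belonging to the named realm."""
        rows, cols = np.nonzero(self.mask_for(name))
        return np.sort(self.grid.cell_id(rows, cols))

    def realm_of_cells(self, cell_ids: np.ndarray) -> np.ndarray:
        rows, cols = self.grid.rowcol(np.asarray(cell_ids))
        return self.labels[rows, cols]


def realm_names_for(n_realms: int) -> tuple[str, ...]:
    """Realm name table: the six canonical realm names when ``n_realms == 6``,
    otherwise the first ``n_realms`` of them (or generated names beyond six)."""
    if n_realms < 1:
        raise ValueError("n_realms must be >= 1")
    if n_realms <= len(REALM_NAMES):
        return REALM_NAMES[:n_realms]
    extra = tuple(f"Realm{i}" for i in range(len(REALM_NAMES), n_realms))
    return REALM_NAMES + extra


def make_realm_mask(grid: GridSpec, n_realms: int) -> RealmMask:
    """Split the grid into ``n_realms`` contiguous longitudinal blocks.

    Blocks are vertical stripes of near-equal width (western stripes get the
    remainder cells), giving contiguous, non-overlapping, exhaustive realms
    without any real geography.
    """
    names = realm_names_for(n_realms)
    edges = np.linspace(0, grid.n_cols, n_realms + 1).round().astype(int)
    labels = np.zeros(grid.shape, dtype=np.int32)
    for k in range(n_realms):
        labels[:, edges[k] : edges[k + 1]] = k
    return RealmMask(grid=grid, labels=labels, names=names)
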