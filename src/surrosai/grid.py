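"""Gridded range data: occurrence matrices, richness maps, abiotic layers.

All spatial computation runs on a planar ``n_rows x n_cols`` lat-lon-style
grid with row-major integer cell ids. Species ranges are binary incidence
rows of a sparse species-by-cell matrix; richness is the per-cell count of
overlapping ranges. No equal-area correction is applied: a 0.5-degree
lat-lon grid is itself not equal-area, and the analyses here operate on
cell counts, not areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Grid",
    "RangeFeature",
    "OccurrenceMatrix",
    "AbioticLayer",
    "build_matrix",
    "richness_map",
    "relative_richness",
]

#: IUCN mapping-standard attribute codes admitted on ingest.
VALID_PRESENCE = frozenset({1, 2, 4})   # extant, probably extant, possibly extinct
VALID_ORIGIN = frozenset({1, 2, 6})     # native, reintroduced, assisted colonization
VALID_SEASONALITY = frozenset({1, 2, 3, 4})  # resident, breeding, non-breeding, passage

#: presence codes unioned per analysis mode; surrogacy drops possibly-extinct ranges
PRESENCE_BY_MODE = {"richness": frozenset({1, 2, 4}), "surrogacy": frozenset({1, 2})}


@dataclass(frozen=True)
class Grid:
    """A planar row-major grid of ``n_rows * n_cols`` cells.

    ``cell_size`` is carried as metadata only (default 0.5 degrees); all
    computation is in cell units.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 0.5

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_id(self, row: int, col: int) -> int:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"cell ({row}, {col}) outside grid")
        return row * self.n_cols + col

    def rowcol(self, cell: int) -> tuple[int, int]:
        if not (0 <= cell < self.n_cells):
            raise ValueError(f"cell id {cell} outside grid")
        return divmod(cell, self.n_cols)


@dataclass(frozen=True)
class RangeFeature:
    """One coded range polygon, already reduced to grid cells.

    Geometry is either an explicit cell-id list or an axis-aligned half-open
    box ``(r0, r1, c0, c1)`` rasterized on demand. Presence, origin and
    seasonality follow the IUCN mapping-standard codes; anything outside the
    admitted sets is rejected at construction so filters stay auditable.
    """

    species_id: str
    cells: tuple[int, ...] | None = None
    box: tuple[int, int, int, int] | None = None
    presence: int = 1
    origin: int = 1
    seasonality: int = 1

    def __post_init__(self) -> None:
        if (self.cells is None) == (self.box is None):
            raise ValueError("exactly one of cells or box must be given")
        if self.presence not in VALID_PRESENCE:
            raise ValueError(f"presence code {self.presence} not in {sorted(VALID_PRESENCE)}")
        if self.origin not in VALID_ORIGIN:
            raise ValueError(f"origin code {self.origin} not in {sorted(VALID_ORIGIN)}")
        if self.seasonality not in VALID_SEASONALITY:
            raise ValueError(
                f"seasonality code {self.seasonality} not in {sorted(VALID_SEASONALITY)}"
            )

    def resolve_cells(self, grid: Grid) -> np.ndarray:
        """Cell ids covered by this feature on ``grid`` (validated)."""
        if self.cells is not None:
            cells = np.asarray(self.cells, dtype=np.int64)
            if cells.size and (cells.min() < 0 or cells.max() >= grid.n_cells):
                raise ValueError(f"feature for {self.species_id} references out-of-grid cells")
            return cells
        r0, r1, c0, c1 = self.box  # half-open box
        if not (0 <= r0 < r1 <= grid.n_rows and 0 <= c0 < c1 <= grid.n_cols):
            raise ValueError(f"box {self.box} outside grid for {self.species_id}")
        rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        return (rr * grid.n_cols + cc).ravel()


@dataclass
class OccurrenceMatrix:
    """Binary species-by-cell incidence on a grid.

    ``matrix`` is sparse CSR with one row per indexed species; values are
    0/1. ``included`` masks the cells that take part in analyses (all True
    unless a layer with missing data restricts the landscape).
    """

    grid: Grid
    matrix: sp.csr_matrix
    species_ids: list[str]
    included: np.ndarray = field(default=None)  # type: ignore[assignment]
    flagged_empty: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix, dtype=np.int8)
        self.matrix.data[:] = 1
        self.matrix.eliminate_zeros()
        if self.matrix.shape != (len(self.species_ids), self.grid.n_cells):
            raise ValueError(
                f"matrix shape {self.matrix.shape} inconsistent with "
                f"{len(self.species_ids)} species on {self.grid.n_cells} cells"
            )
        if self.included is None:
            self.included = np.ones(self.grid.n_cells, dtype=bool)
        else:
            self.included = np.asarray(self.included, dtype=bool)
            if self.included.shape != (self.grid.n_cells,):
                raise ValueError("included mask inconsistent with grid size")

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def range_sizes(self) -> np.ndarray:
        """Occupied-cell count per species (over all cells, ignoring mask)."""
        return np.asarray(self.matrix.sum(axis=1)).ravel().astype(np.int64)

    def subset(self, species: list[str]) -> "OccurrenceMatrix":
        index = {s: i for i, s in enumerate(self.species_ids)}
        missing = [s for s in species if s not in index]
        if missing:
            raise KeyError(f"species not in matrix: {missing[:5]}")
        rows = [index[s] for s in species]
        return OccurrenceMatrix(
            grid=self.grid,
            matrix=self.matrix[rows],
            species_ids=list(species),
            included=self.included.copy(),
        )

    def restrict_cells(self, keep: np.ndarray) -> "OccurrenceMatrix":
        """Return a copy whose included-cell mask is ANDed with ``keep``."""
        keep = np.asarray(keep, dtype=bool)
        return OccurrenceMatrix(
            grid=self.grid,
            matrix=self.matrix.copy(),
            species_ids=list(self.species_ids),
            included=self.included & keep,
            flagged_empty=list(self.flagged_empty),
        )


@dataclass
class AbioticLayer:
    """A scalar per-cell environmental layer with a missing-data mask.

    Missing cells carry no value (NaN) and are excluded from any ranking
    built on the layer.
    """

    grid: Grid
    values: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.missing = np.asarray(self.missing, dtype=bool).ravel()
        if self.values.shape != (self.grid.n_cells,) or self.missing.shape != self.values.shape:
            raise ValueError("layer arrays inconsistent with grid size")
        self.values = self.values.copy()
        self.values[self.missing] = np.nan

    @property
    def present(self) -> np.ndarray:
        return ~self.missing


def build_matrix(
    features: list[RangeFeature], grid: Grid, mode: str = "richness"
) -> OccurrenceMatrix:
    """Union coded range features into a binary occurrence matrix.

    ``mode='richness'`` admits presence codes {1, 2, 4}; ``mode='surrogacy'``
    drops possibly-extinct ranges (code 4). A species whose every feature is
    excluded by the mode keeps an all-zero row and is flagged in
    ``flagged_empty`` so downstream denominators can account for it.
    """
    if mode not in PRESENCE_BY_MODE:
        raise ValueError(f"mode must be one of {sorted(PRESENCE_BY_MODE)}")
    admit = PRESENCE_BY_MODE[mode]

    species_ids: list[str] = []
    index: dict[str, int] = {}
    for f in features:
        if f.species_id not in index:
            index[f.species_id] = len(species_ids)
            species_ids.append(f.species_id)

    rows: list[int] = []
    cols: list[int] = []
    for f in features:
        cells = f.resolve_cells(grid)  # validate geometry regardless of filter
        if f.presence not in admit:
            continue
        rows.extend([index[f.species_id]] * len(cells))
        cols.extend(cells.tolist())

    matrix = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(species_ids), grid.n_cells),
    )
    out = OccurrenceMatrix(grid=grid, matrix=matrix, species_ids=species_ids)
    occupancy = out.range_sizes()
    out.flagged_empty = [s for s, n in zip(species_ids, occupancy) if n == 0]
    return out


def richness_map(m: OccurrenceMatrix, subset: list[str] | None = None) -> np.ndarray:
    """Per-cell count of overlapping ranges, optionally over a species subset."""
    mm = m if subset is None else m.subset(subset)
    if mm.n_species == 0:
        raise ValueError("richness map over an empty species set")
    return np.asarray(mm.matrix.sum(axis=0)).ravel().astype(np.int64)


def relative_richness(numerator: np.ndarray, denominator: np.ndarray) -> np.ma.MaskedArray:
    """Cellwise ratio of two richness maps, masked where the denominator is 0."""
    numerator = np.asarray(numerator, dtype=float)
    denominator = np.asarray(denominator, dtype=float)
    if numerator.shape != denominator.shape:
        raise ValueError("richness maps on different grids")
    mask = denominator <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mask, np.nan, numerator / np.where(mask, 1.0, denominator))
    return np.ma.masked_array(ratio, mask=mask)
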