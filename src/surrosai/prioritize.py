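"""Complementarity-based cell rankings by iterative greedy removal.

Both rules follow the backward-elimination idea of Zonation-style spatial
prioritization: repeatedly delete the cell whose loss hurts least, then
read the removal order in reverse as a best-first priority ranking. Let
Q_j be the number of not-yet-removed cells occupied by species j (its
remaining range). Deleting cell i costs

    CAZ:  delta_i = max_j  x_ij / Q_j     (core-area zonation)
    ABF:  delta_i = sum_j  x_ij / Q_j     (additive benefit function)

with x_ij the 0/1 incidence. CAZ protects the cells that hold large
fractions of the most range-restricted species; ABF protects
rarity-weighted richness. Q_j is dynamic — it shrinks as occupied cells
are removed — which is what makes the ranking complementarity-based; a
static-Q variant is available behind a flag for sensitivity checks.

Ties in delta are broken uniformly at random under a seed (Zonation's
stochastic iterations are emulated by re-running with different tie-break
seeds); empty cells have delta = 0 and fall out first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .grid import AbioticLayer, Grid, OccurrenceMatrix

__all__ = [
    "PriorityRanking",
    "rank_caz",
    "rank_abf",
    "rank_abiotic",
    "rank_random",
]


@dataclass(frozen=True)
class PriorityRanking:
    """Best-first permutation of the included cell ids of a landscape."""

    cells: np.ndarray
    algorithm: str
    seed: int | None = None
    excluded: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells, dtype=np.int64)
        if len(np.unique(cells)) != cells.size:
            raise ValueError("ranking contains duplicate cells")
        object.__setattr__(self, "cells", cells)
        object.__setattr__(self, "excluded", np.asarray(self.excluded, dtype=np.int64))

    def __len__(self) -> int:
        return int(self.cells.size)


def _greedy_removal(
    m: OccurrenceMatrix,
    rule: str,
    seed: int | None,
    tie_break: str,
    dynamic_q: bool,
) -> PriorityRanking:
    if m.n_species == 0:
        raise ValueError("cannot rank an empty occurrence matrix")
    rng = np.random.default_rng(seed)
    included = np.flatnonzero(m.included)
    excluded = np.flatnonzero(~m.included)
    n_inc = included.size
    if n_inc == 0:
        raise ValueError("no included cells to rank")

    # column-compressed view restricted to included cells
    csc = sp.csc_matrix(m.matrix[:, included])
    indptr, indices = csc.indptr, csc.indices  # species row ids per local cell
    q = np.asarray(csc.sum(axis=1)).ravel().astype(np.int64)  # remaining range per species
    # species occupying no included cell contribute nothing; guard the division
    inv_q = np.zeros(q.size, dtype=float)
    np.divide(1.0, q, out=inv_q, where=q > 0)

    agg = np.max if rule == "CAZ" else np.sum

    def cell_delta(local: int) -> float:
        spp = indices[indptr[local] : indptr[local + 1]]
        if spp.size == 0:
            return 0.0
        return float(agg(inv_q[spp]))

    delta = np.array([cell_delta(i) for i in range(n_inc)])
    alive = np.ones(n_inc, dtype=bool)
    # cells (local ids) each species still occupies, for incremental updates
    csr_local = sp.csr_matrix(csc)
    sp_indptr, sp_indices = csr_local.indptr, csr_local.indices

    removal: list[int] = []
    for _ in range(n_inc):
        live = np.flatnonzero(alive)
        best = np.min(delta[live])
        ties = live[delta[live] == best]
        if ties.size == 1 or tie_break == "index":
            pick = int(ties[0])
        else:
            pick = int(rng.choice(ties))
        removal.append(pick)
        alive[pick] = False

        spp = indices[indptr[pick] : indptr[pick + 1]]
        if spp.size == 0 or not dynamic_q:
            continue
        q[spp] -= 1
        np.divide(1.0, q, out=inv_q, where=q > 0)
        inv_q[q <= 0] = 0.0
        dirty: set[int] = set()
        for j in spp:
            dirty.update(sp_indices[sp_indptr[j] : sp_indptr[j + 1]].tolist())
        for i in dirty:
            if alive[i]:
                delta[i] = cell_delta(i)

    best_first = included[np.asarray(removal[::-1], dtype=np.int64)]
    return PriorityRanking(cells=best_first, algorithm=rule, seed=seed, excluded=excluded)


def rank_caz(
    m: OccurrenceMatrix,
    seed: int | None = None,
    tie_break: str = "random",
    dynamic_q: bool = True,
) -> PriorityRanking:
    """Core-area zonation ranking: minimize the worst proportional loss."""
    return _greedy_removal(m, "CAZ", seed, tie_break, dynamic_q)


def rank_abf(
    m: OccurrenceMatrix,
    seed: int | None = None,
    tie_break: str = "random",
    dynamic_q: bool = True,
) -> PriorityRanking:
    """Additive-benefit-function ranking: minimize the summed proportional loss."""
    return _greedy_removal(m, "ABF", seed, tie_break, dynamic_q)


def rank_abiotic(layer: AbioticLayer, seed: int | None = None) -> PriorityRanking:
    """Rank cells by descending layer value; shuffle only within ties.

    Missing cells are excluded from the ranking entirely; cells with a
    value but no species are retained (their worth is decided by the
    accumulation curve, not here).
    """
    present = np.flatnonzero(layer.present)
    if present.size == 0:
        raise ValueError("all cells missing in abiotic layer")
    rng = np.random.default_rng(seed)
    jitter = rng.random(present.size)  # breaks equal-value runs at random
    order = np.lexsort((jitter, -layer.values[present]))
    return PriorityRanking(
        cells=present[order],
        algorithm="ABIOTIC",
        seed=seed,
        excluded=np.flatnonzero(layer.missing),
    )


def rank_random(
    grid: Grid,
    n_sequences: int,
    seed: int | None = None,
    included: np.ndarray | None = None,
) -> list[PriorityRanking]:
    """Independent uniform cell permutations (the random-curve null)."""
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    cells = np.arange(grid.n_cells) if included is None else np.flatnonzero(included)
    excluded = (
        np.empty(0, dtype=np.int64) if included is None else np.flatnonzero(~np.asarray(included))
    )
    rng = np.random.default_rng(seed)
    return [
        PriorityRanking(
            cells=rng.permutation(cells), algorithm="RANDOM", seed=seed, excluded=excluded
        )
        for _ in range(n_sequences)
    ]
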