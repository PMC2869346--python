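"""Hexagonal lattice geometry and the chemoreceptor trimer-of-dimers mask.

The simulated cytoplasm is a finite two-dimensional hexagonal lattice in
"odd-r" offset coordinates (odd rows shifted half a cell to the right),
0-based, with hard non-wrapping boundaries.  Every cell carries two layers:

* a *foreground* that holds at most one mobile agent at a time, and
* a *background* that holds fixed entities (receptor dimers, anchored
  kinase complexes) with no multiplicity limit.

Chemoreceptor dimers are laid down as trimers of dimers: triples of
mutually adjacent cells tiled periodically so that every interior receptor
has exactly two intra-trimer neighbors (receptors in adjacent cells) and
exactly two inter-trimer neighbors (receptors separated by a single lattice
cell).  Cells adjacent to receptors of two distinct trimers are *bridge
sites* — the only positions where a CheW-CheA-CheW complex can anchor and
couple two trimers.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "HexCoord",
    "Grid",
    "ReceptorTopology",
    "neighbors",
    "neighbor_table",
    "hex_distance",
    "build_receptor_mask",
    "find_bridge_sites",
    "save_mask_csv",
    "load_mask_csv",
]

HexCoord = tuple[int, int]
"""(col, row) in odd-r offset coordinates."""

# Neighbor offsets (dcol, drow) by row parity: even rows first.
_OFFSETS_EVEN = ((1, 0), (-1, 0), (0, -1), (-1, -1), (0, 1), (-1, 1))
_OFFSETS_ODD = ((1, 0), (-1, 0), (1, -1), (0, -1), (1, 1), (0, 1))


@dataclass
class Grid:
    """Finite hex lattice with a mobile foreground and a fixed background.

    ``foreground`` maps cell -> mobile agent id (at most one per cell);
    ``background`` maps cell -> set of fixed entity ids.
    """

    columns: int
    rows: int
    foreground: dict[HexCoord, int] = field(default_factory=dict)
    background: dict[HexCoord, set[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.columns < 1 or self.rows < 1:
            raise ValueError("grid dimensions must be positive")

    def __contains__(self, coord: HexCoord) -> bool:
        c, r = coord
        return 0 <= c < self.columns and 0 <= r < self.rows

    @property
    def n_cells(self) -> int:
        return self.columns * self.rows

    def foreground_free(self, coord: HexCoord) -> bool:
        return coord not in self.foreground


def neighbors(coord: HexCoord, grid: Grid) -> list[HexCoord]:
    """In-bounds hex neighbors of ``coord`` (6 for interior cells, fewer on
    the boundary; never includes ``coord`` itself)."""
    if coord not in grid:
        raise ValueError(f"coordinate {coord} out of bounds for "
                         f"{grid.columns}x{grid.rows} grid")
    c, r = coord
    offs = _OFFSETS_EVEN if r % 2 == 0 else _OFFSETS_ODD
    out = []
    for dc, dr in offs:
        nc, nr = c + dc, r + dr
        if 0 <= nc < grid.columns and 0 <= nr < grid.rows:
            out.append((nc, nr))
    return out


def neighbor_table(columns: int, rows: int) -> np.ndarray:
    """Dense (columns*rows, 6) int32 table of neighbor cell indices, -1
    padded, with cell index = col * rows + row.  Used by the simulation
    kernels."""
    tab = np.full((columns * rows, 6), -1, dtype=np.int32)
    for c in range(columns):
        for r in range(rows):
            offs = _OFFSETS_EVEN if r % 2 == 0 else _OFFSETS_ODD
            k = 0
            for dc, dr in offs:
                nc, nr = c + dc, r + dr
                if 0 <= nc < columns and 0 <= nr < rows:
                    tab[c * rows + r, k] = nc * rows + nr
                    k += 1
    return tab


def _axial(coord: HexCoord) -> tuple[int, int]:
    c, r = coord
    return c - (r - (r & 1)) // 2, r


def hex_distance(a: HexCoord, b: HexCoord) -> int:
    """Hex lattice distance (minimum number of steps between cells)."""
    q1, r1 = _axial(a)
    q2, r2 = _axial(b)
    dq, dr = q1 - q2, r1 - r2
    return max(abs(dq), abs(dr), abs(dq + dr))


@dataclass
class ReceptorTopology:
    """Receptor placement and its interaction topology.

    ``sites`` lists receptor cells grouped by trimer (``trimer_id[i]`` is the
    trimer of ``sites[i]``); ``intra``/``inter`` give, per receptor index,
    the indices of its same-trimer neighbors (adjacent cells) and of the
    receptors separated from it by exactly one lattice cell in other
    trimers.  ``bridge_sites`` are the anchoring cells for CheA, each with
    the receptor indices it touches.
    """

    columns: int
    rows: int
    sites: list[HexCoord]
    trimer_id: list[int]
    intra: list[list[int]]
    inter: list[list[int]]
    bridge_sites: list[HexCoord] = field(default_factory=list)
    bridge_receptors: list[list[int]] = field(default_factory=list)

    @property
    def n_receptors(self) -> int:
        return len(self.sites)

    @property
    def n_trimers(self) -> int:
        return len(set(self.trimer_id))

    def site_index(self) -> dict[HexCoord, int]:
        return {s: i for i, s in enumerate(self.sites)}


def _trimer_cells(c0: int, r0: int) -> list[HexCoord]:
    """Three mutually adjacent cells: two in row r0 plus their common
    neighbor in row r0+1 (parity dependent)."""
    third = (c0, r0 + 1) if r0 % 2 == 0 else (c0 + 1, r0 + 1)
    return [(c0, r0), (c0 + 1, r0), third]


# Periodic tiling unit: one trimer per 3x3 block of cells (density 1/3).
_COL_PERIOD = 3
_ROW_PERIOD = 3


def build_receptor_mask(
    columns: int,
    rows: int,
    receptor_region_columns: int = 60,
    n_receptors: int = 1083,
) -> ReceptorTopology:
    """Deterministic trimer-of-dimers mask on the left pole of the grid.

    Trimer anchor cells repeat every 3 columns and 3 rows inside the
    receptor region (the leftmost ``receptor_region_columns`` columns);
    trimers are filled in row-major scan order until ``n_receptors`` / 3
    trimers are placed.  The default 100x60 grid with a 60-column region
    holds 361 trimers = 1083 receptor dimers, and every interior receptor
    has exactly 2 intra- and 2 inter-trimer neighbors.
    """
    if n_receptors % 3 != 0:
        raise ValueError("n_receptors must be a multiple of 3 "
                         "(receptors are placed as trimers of dimers)")
    if receptor_region_columns > columns:
        raise ValueError("receptor region wider than grid")
    n_trimers = n_receptors // 3

    anchors = []
    for r0 in range(0, rows - 1, _ROW_PERIOD):
        for c0 in range(0, receptor_region_columns - 1, _COL_PERIOD):
            anchors.append((c0, r0))
    if len(anchors) < n_trimers:
        raise ValueError(
            f"receptor region holds only {len(anchors)} trimers; "
            f"{n_trimers} requested")

    sites: list[HexCoord] = []
    trimer_id: list[int] = []
    for t, (c0, r0) in enumerate(anchors[:n_trimers]):
        for cell in _trimer_cells(c0, r0):
            sites.append(cell)
            trimer_id.append(t)

    index = {s: i for i, s in enumerate(sites)}
    grid = Grid(columns, rows)
    intra: list[list[int]] = []
    inter: list[list[int]] = []
    for i, cell in enumerate(sites):
        same = [index[n] for n in neighbors(cell, grid)
                if n in index and trimer_id[index[n]] == trimer_id[i]]
        intra.append(same)
        inter.append([])
    # Inter-trimer partners: receptors of a different trimer at hex
    # distance exactly 2 (separated by a single lattice cell).
    for i, cell in enumerate(sites):
        for j in _nearby_receptor_indices(cell, index, radius=2):
            if trimer_id[j] != trimer_id[i] and hex_distance(cell, sites[j]) == 2:
                inter[i].append(j)

    topo = ReceptorTopology(columns, rows, sites, trimer_id, intra, inter)
    topo.bridge_sites, topo.bridge_receptors = find_bridge_sites(topo, grid)
    return topo


def _nearby_receptor_indices(cell: HexCoord, index: dict[HexCoord, int],
                             radius: int) -> Iterable[int]:
    c, r = cell
    for dc in range(-radius - 1, radius + 2):
        for dr in range(-radius, radius + 1):
            other = (c + dc, r + dr)
            if other != cell and other in index:
                yield index[other]


def find_bridge_sites(
    topology: ReceptorTopology, grid: Grid | None = None
) -> tuple[list[HexCoord], list[list[int]]]:
    """Cells adjacent to >=2 receptors belonging to >=2 distinct trimers.

    These are the only cells where a CheA can anchor (via receptor-bound
    CheW on both flanks) to form an inter-trimer bridge.  Returns the cell
    list and, per cell, the indices of all receptors it touches.
    """
    if grid is None:
        grid = Grid(topology.columns, topology.rows)
    index = topology.site_index()
    candidates: set[HexCoord] = set()
    for cell in topology.sites:
        for n in neighbors(cell, grid):
            if n not in index:
                candidates.add(n)
    cells: list[HexCoord] = []
    recs: list[list[int]] = []
    for cell in sorted(candidates):
        touching = [index[n] for n in neighbors(cell, grid) if n in index]
        trimers = {topology.trimer_id[i] for i in touching}
        if len(touching) >= 2 and len(trimers) >= 2:
            cells.append(cell)
            recs.append(touching)
    return cells, recs


def save_mask_csv(topology: ReceptorTopology, path, receptor_types=None) -> None:
    """Write the mask as CSV: col,row,trimer_id,receptor_type."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["col", "row", "trimer_id", "receptor_type"])
        for i, (c, r) in enumerate(topology.sites):
            rtype = "" if receptor_types is None else receptor_types[i]
            w.writerow([c, r, topology.trimer_id[i], rtype])


def load_mask_csv(path) -> tuple[list[HexCoord], list[int], list[str]]:
    """Read a mask CSV back as (sites, trimer_ids, receptor_types)."""
    sites, tids, types = [], [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            sites.append((int(row["col"]), int(row["row"])))
            tids.append(int(row["trimer_id"]))
            types.append(row["receptor_type"])
    return sites, tids, types
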