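"""Coupled high/low-resolution lattices and cluster classification.

Cells live on a high-resolution grid (default spacing 10 μm, one node per
cell).  A coarser lattice (nesting ratio r high-res nodes per low-res cell
edge, default 6, i.e. a 60 μm site) groups cells into clusters:

* a site whose affiliated r×r block of high-res nodes is fully occupied is
  *dense*;
* a dense site all of whose neighboring sites are dense is *homogeneous* —
  its cells sit deep inside the tumor, are treated as one aggregated source
  and are exempt from per-cell intracellular computation;
* every other occupied site is *heterogeneous* — the active tumor rim where
  the full multiscale machinery runs.

Sites on the lattice edge are never homogeneous: a missing neighbor counts as
non-dense.  The neighborhood is 8-connected (Moore) by default, 4-connected
behind a flag.

The published lattice spacings (62.5 μm low-res over 10 μm high-res) imply a
non-integer nesting of 6.25; this implementation requires integer nesting and
defaults to r = 6 (a 60 μm site), since sub-node alignment of the two grids
is otherwise undefined.  r is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "DualLattice",
    "ClusterMap",
    "high_to_low",
    "classify_clusters",
    "active_cells",
    "StaleClusterMapError",
    "EMPTY",
    "HETEROGENEOUS",
    "HOMOGENEOUS",
]

EMPTY = 0
HETEROGENEOUS = 1
HOMOGENEOUS = 2

_NO_CELL = -1


class StaleClusterMapError(RuntimeError):
    """The occupancy changed after the cluster map was computed."""


@dataclass
class DualLattice:
    """Occupancy bookkeeping on the dual-resolution lattice.

    `occupancy[r, c]` holds the occupying cell id or -1; at most one cell per
    high-res node.  `version` increments on every occupancy change so that
    derived products (cluster maps) can detect staleness.
    """

    shape: tuple[int, int]
    r: int = 6
    occupancy: np.ndarray = field(init=False)
    version: int = field(default=0, init=False)

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValueError("nesting ratio r must be >= 1")
        self.shape = (int(self.shape[0]), int(self.shape[1]))
        self.occupancy = np.full(self.shape, _NO_CELL, dtype=np.int64)

    @property
    def low_shape(self) -> tuple[int, int]:
        return (-(-self.shape[0] // self.r), -(-self.shape[1] // self.r))

    def in_bounds(self, pos: tuple[int, int]) -> bool:
        return 0 <= pos[0] < self.shape[0] and 0 <= pos[1] < self.shape[1]

    def is_free(self, pos: tuple[int, int]) -> bool:
        return self.in_bounds(pos) and self.occupancy[pos] == _NO_CELL

    def place(self, cell_id: int, pos: tuple[int, int]) -> None:
        if not self.in_bounds(pos):
            raise IndexError(f"position {pos} off the {self.shape} lattice")
        if self.occupancy[pos] != _NO_CELL:
            raise ValueError(f"node {pos} already occupied by cell {self.occupancy[pos]}")
        self.occupancy[pos] = cell_id
        self.version += 1

    def remove(self, pos: tuple[int, int]) -> int:
        cid = int(self.occupancy[pos])
        if cid == _NO_CELL:
            raise ValueError(f"node {pos} is empty")
        self.occupancy[pos] = _NO_CELL
        self.version += 1
        return cid

    def move(self, old: tuple[int, int], new: tuple[int, int]) -> None:
        if not self.is_free(new):
            raise ValueError(f"target node {new} is not free")
        self.occupancy[new] = self.occupancy[old]
        self.occupancy[old] = _NO_CELL
        self.version += 1

    def occupied_count(self) -> int:
        return int((self.occupancy != _NO_CELL).sum())


def high_to_low(coord: tuple[int, int], lattice: DualLattice) -> tuple[int, int]:
    """Low-res site affiliated with a high-res node (floor division per axis)."""
    if not lattice.in_bounds(coord):
        raise IndexError(f"coordinate {coord} off the {lattice.shape} lattice")
    return (coord[0] // lattice.r, coord[1] // lattice.r)


@dataclass
class ClusterMap:
    """Per-low-res-site occupant counts and density/homogeneity labels."""

    labels: np.ndarray  # int8: EMPTY / HETEROGENEOUS / HOMOGENEOUS
    counts: np.ndarray
    dense: np.ndarray  # bool
    r: int
    version: int  # lattice version at classification time

    def site_of(self, pos: tuple[int, int]) -> tuple[int, int]:
        return (pos[0] // self.r, pos[1] // self.r)

    def is_homogeneous(self, site: tuple[int, int]) -> bool:
        return self.labels[site] == HOMOGENEOUS

    def footprint(self, site: tuple[int, int], high_shape: tuple[int, int]) -> tuple[slice, slice]:
        """High-res slice of the r×r block affiliated with `site`."""
        r = self.r
        return (
            slice(site[0] * r, min((site[0] + 1) * r, high_shape[0])),
            slice(site[1] * r, min((site[1] + 1) * r, high_shape[1])),
        )


def _block_counts(occ: np.ndarray, r: int) -> tuple[np.ndarray, np.ndarray]:
    """Occupant count and node capacity per low-res block (handles ragged
    edge blocks when the high-res extent is not a multiple of r)."""
    H, W = occ.shape
    lh, lw = -(-H // r), -(-W // r)
    occupied = (occ != _NO_CELL).astype(np.int64)
    rows = np.arange(H) // r
    cols = np.arange(W) // r
    counts = np.zeros((lh, lw), dtype=np.int64)
    np.add.at(counts, (rows[:, None], cols[None, :]), occupied)
    cap_r = np.minimum((np.arange(lh) + 1) * r, H) - np.arange(lh) * r
    cap_c = np.minimum((np.arange(lw) + 1) * r, W) - np.arange(lw) * r
    capacity = cap_r[:, None] * cap_c[None, :]
    return counts, capacity


def classify_clusters(lattice: DualLattice, connectivity: int = 8) -> ClusterMap:
    """Label every low-res site as empty, heterogeneous or homogeneous.

    dense ⇔ every affiliated high-res node is occupied; homogeneous ⇔ dense
    and all `connectivity` neighbors dense (lattice-edge sites never qualify);
    every other occupied site is heterogeneous.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    counts, capacity = _block_counts(lattice.occupancy, lattice.r)
    dense = counts == capacity
    dense &= counts > 0
    lh, lw = dense.shape
    padded = np.zeros((lh + 2, lw + 2), dtype=bool)
    padded[1:-1, 1:-1] = dense
    if connectivity == 8:
        shifts = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        shifts = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    all_nb_dense = np.ones((lh, lw), dtype=bool)
    for dr, dc in shifts:
        all_nb_dense &= padded[1 + dr : 1 + dr + lh, 1 + dc : 1 + dc + lw]
    labels = np.full((lh, lw), EMPTY, dtype=np.int8)
    labels[counts > 0] = HETEROGENEOUS
    labels[dense & all_nb_dense] = HOMOGENEOUS
    return ClusterMap(labels, counts, dense, lattice.r, lattice.version)


def active_cells(lattice: DualLattice, cluster_map: ClusterMap) -> list[int]:
    """Ids of all cells in heterogeneous clusters — the cells whose
    intracellular pathway is computed this step."""
    if cluster_map.version != lattice.version:
        raise StaleClusterMapError(
            "cluster map was computed for an earlier occupancy; reclassify first"
        )
    r = lattice.r
    het = cluster_map.labels == HETEROGENEOUS
    rows, cols = np.nonzero(lattice.occupancy != _NO_CELL)
    mask = het[rows // r, cols // r]
    return [int(cid) for cid in lattice.occupancy[rows[mask], cols[mask]]]
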