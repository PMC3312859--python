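"""Deterministic synthetic fixtures: initial tumors, test fields, random
occupancies.

Every fixture is a pure function of its spec (geometry + seed), so the same
spec always reconstructs the identical object — fixtures are generated at run
time, never stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .agents import Cell
from .diffusion import ChemoField
from .lattice import DualLattice
from .pathway import PathwayState, Phenotype

__all__ = ["FixtureSpec", "make_fixture", "disc_tumor", "gaussian_field", "sine_field", "random_occupancy"]


@dataclass(frozen=True)
class FixtureSpec:
    kind: str  # disc-tumor | random-occupancy | gaussian-field | sine-field
    shape: tuple[int, int] = (120, 120)
    seed: int = 0
    params: dict = field(default_factory=dict)

    _KINDS = ("disc-tumor", "random-occupancy", "gaussian-field", "sine-field")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown fixture kind '{self.kind}'; choose from {self._KINDS}")


def disc_tumor(
    shape: tuple[int, int],
    radius: int,
    r_nest: int = 6,
    initial: np.ndarray | None = None,
    cycle_interval: int = 12,
) -> tuple[DualLattice, dict[int, Cell]]:
    """Filled disc of proliferative cells centered at ⌊shape/2⌋.

    A node (i, j) belongs to the disc iff its squared distance to the center
    is ≤ radius²; radius 0 seeds a single cell.
    """
    lattice = DualLattice(shape, r_nest)
    cr, cc = shape[0] // 2, shape[1] // 2
    if radius > min(cr, cc, shape[0] - 1 - cr, shape[1] - 1 - cc):
        raise ValueError(f"disc radius {radius} exceeds the {shape} lattice")
    cells: dict[int, Cell] = {}
    cid = 0
    for i in range(cr - radius, cr + radius + 1):
        for j in range(cc - radius, cc + radius + 1):
            if (i - cr) ** 2 + (j - cc) ** 2 <= radius**2:
                x = PathwayState.initial() if initial is None else PathwayState(np.array(initial))
                cells[cid] = Cell(id=cid, pos=(i, j), phenotype=Phenotype.PROLIFERATIVE,
                                  pathway=x, cycle_clock=cycle_interval)
                lattice.place(cid, (i, j))
                cid += 1
    return lattice, cells


def gaussian_field(
    shape: tuple[int, int],
    amplitude: float = 1.0,
    sigma: float | None = None,
    center: tuple[float, float] | None = None,
    dx: float = 10.0,
    D: float = 1e-7,
) -> ChemoField:
    """Radially symmetric Gaussian bump A·exp(−r²/2σ²) in lattice units."""
    H, W = shape
    if sigma is None:
        sigma = min(H, W) / 4.0
    if center is None:
        center = ((H - 1) / 2.0, (W - 1) / 2.0)
    ii, jj = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    r2 = (ii - center[0]) ** 2 + (jj - center[1]) ** 2
    return ChemoField(amplitude * np.exp(-r2 / (2.0 * sigma**2)), D=D, dx=dx)


def sine_field(shape: tuple[int, int], amplitude: float = 1.0, dx: float = 10.0,
               D: float = 1e-7) -> ChemoField:
    """Fundamental Dirichlet eigenmode sin(πx/L)·sin(πy/L) with the mode zero
    on the ghost frame: node i sits at (i+1)/(N+1) of the domain span."""
    H, W = shape
    x = np.sin(np.pi * (np.arange(H) + 1) / (H + 1))
    y = np.sin(np.pi * (np.arange(W) + 1) / (W + 1))
    return ChemoField(amplitude * np.outer(x, y), D=D, dx=dx)


def random_occupancy(shape: tuple[int, int], r_nest: int, seed: int,
                     p_full: float = 0.45, p_empty: float = 0.30) -> DualLattice:
    """Random occupancy exercising the cluster classifier: each low-res block
    is independently full, empty, or partially filled uniformly at random."""
    rng = np.random.default_rng(seed)
    lattice = DualLattice(shape, r_nest)
    occ = np.full(shape, -1, dtype=np.int64)
    lh, lw = lattice.low_shape
    cid = 0
    for bi in range(lh):
        for bj in range(lw):
            rows = slice(bi * r_nest, min((bi + 1) * r_nest, shape[0]))
            cols = slice(bj * r_nest, min((bj + 1) * r_nest, shape[1]))
            u = rng.random()
            block = np.zeros((rows.stop - rows.start, cols.stop - cols.start), dtype=bool)
            if u < p_full:
                block[:] = True
            elif u < p_full + p_empty:
                pass
            else:
                block = rng.random(block.shape) < rng.uniform(0.1, 0.95)
            n = int(block.sum())
            ids = np.full(block.shape, -1, dtype=np.int64)
            ids[block] = np.arange(cid, cid + n)
            cid += n
            occ[rows, cols] = ids
    lattice.occupancy = occ
    lattice.version += 1
    return lattice


def make_fixture(spec: FixtureSpec) -> Any:
    """Build the fixture described by `spec` (see module docstring)."""
    p = dict(spec.params)
    if spec.kind == "disc-tumor":
        return disc_tumor(spec.shape, p.pop("radius", 5), p.pop("r_nest", 6), **p)
    if spec.kind == "gaussian-field":
        return gaussian_field(spec.shape, **p)
    if spec.kind == "sine-field":
        return sine_field(spec.shape, **p)
    if spec.kind == "random-occupancy":
        return random_occupancy(spec.shape, p.pop("r_nest", 6), spec.seed, **p)
    raise AssertionError("unreachable")
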