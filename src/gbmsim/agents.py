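"""Intercellular behavior: attraction, target selection, migration and
division.

A cell evaluates the attractiveness T = ψ·E + (1−ψ)·ε of each free node in
its Moore neighborhood, where E is the local TGFα concentration, ψ ∈ (0, 1)
the search precision (default 0.7) and ε a normally distributed error term.
The free neighbor with the highest T becomes the migration target or the
birthplace of the daughter cell; a cell with no free neighbor turns quiescent
for the step.  Migration and proliferation are mutually exclusive within a
step (the glioma migration–proliferation dichotomy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .lattice import DualLattice
from .pathway import PathwayState, Phenotype

__all__ = ["Cell", "AttractionParams", "attraction", "select_target", "act", "MOORE_OFFSETS"]

#: Moore neighborhood in fixed (row, col) scan order — also the tie-break order
MOORE_OFFSETS = tuple(
    (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
)


@dataclass(frozen=True)
class AttractionParams:
    """Parameters of the attraction rule.

    The error term is ε ~ N(mu, sigma²).  When `sigma` is None the noise
    scale adapts to the field: sigma = max(sigma_rel · mean(local E),
    sigma_min), so the stochastic term stays proportionate to the signal
    instead of drowning it (or vanishing) as the field evolves.
    """

    psi: float = 0.7
    mu: float = 0.0
    sigma: Optional[float] = None
    sigma_rel: float = 0.1
    sigma_min: float = 1e-3

    def __post_init__(self) -> None:
        if not 0.0 < self.psi < 1.0:
            raise ValueError(f"search precision psi must be in (0, 1), got {self.psi}")

    def sigma_for(self, local_mean_E: float) -> float:
        if self.sigma is not None:
            return self.sigma
        return max(self.sigma_rel * local_mean_E, self.sigma_min)


@dataclass
class Cell:
    """One tumor cell agent on the high-resolution lattice."""

    id: int
    pos: tuple[int, int]
    phenotype: Phenotype = Phenotype.PROLIFERATIVE
    pathway: PathwayState = field(default_factory=PathwayState.initial)
    prev_pathway: PathwayState | None = None
    cycle_clock: int = 0
    birth_step: int = 0
    #: sparse history [(step, row, col)] — appended at birth and on each move
    trajectory: list[tuple[int, int, int]] = field(default_factory=list)
    #: phenotype to resume when a quiescent cell re-enters decision making
    resume_phenotype: Phenotype | None = None

    def __post_init__(self) -> None:
        if not self.trajectory:
            self.trajectory.append((self.birth_step, *self.pos))

    @property
    def alive(self) -> bool:
        return self.phenotype is not Phenotype.DEAD

    def record_move(self, step: int, new_pos: tuple[int, int]) -> None:
        self.pos = new_pos
        self.trajectory.append((step, *new_pos))


def attraction(E: float, params: AttractionParams, rng: np.random.Generator,
               sigma: float | None = None) -> float:
    """Attractiveness T = ψ·E + (1−ψ)·ε of one candidate location."""
    if E < 0:
        raise ValueError("chemoattractant concentration must be nonnegative")
    s = params.sigma_for(E) if sigma is None else sigma
    eps = rng.normal(params.mu, s) if s > 0 else params.mu
    return params.psi * E + (1.0 - params.psi) * eps


def select_target(
    cell: Cell,
    field_Y: np.ndarray,
    lattice: DualLattice,
    params: AttractionParams,
    rng: np.random.Generator,
) -> Optional[tuple[int, int]]:
    """Most attractive free Moore neighbor of the cell, or None if boxed in.

    Candidates are scanned in fixed (row, col) order; noise is drawn per
    candidate in that order, and exact ties go to the first (lowest row, then
    column) candidate, so results are reproducible for a given generator
    state.
    """
    if not cell.alive:
        raise ValueError("dead cells do not select targets")
    r0, c0 = cell.pos
    candidates = []
    for dr, dc in MOORE_OFFSETS:
        p = (r0 + dr, c0 + dc)
        if lattice.is_free(p):
            candidates.append(p)
    if not candidates:
        return None
    local_mean = float(np.mean([field_Y[p] for p in candidates]))
    sigma = params.sigma_for(local_mean)
    best, best_T = None, -np.inf
    for p in candidates:
        T = attraction(float(field_Y[p]), params, rng, sigma=sigma)
        if T > best_T:  # strict: earlier candidate wins ties
            best, best_T = p, T
    return best


@dataclass(frozen=True)
class ActionOutcome:
    kind: str  # "moved" | "divided" | "quiescent"
    cell_id: int
    daughter: Optional[Cell] = None


def act(
    cell: Cell,
    target: Optional[tuple[int, int]],
    lattice: DualLattice,
    step: int,
    *,
    next_id: int = -1,
    cycle_interval: int = 12,
    daughter_reset: bool = False,
    retarget=None,
) -> ActionOutcome:
    """Commit a cell's phenotype action for this step.

    Migratory cells move to `target`; proliferative cells spawn a daughter
    there (inheriting a copy of the parent's pathway state unless
    `daughter_reset`); a cell without a target becomes quiescent in place. If
    the target is occupied at commit time the optional `retarget` callable is
    consulted once; failing that the cell quiesces.  A cell never both moves
    and divides in one step.
    """
    if target is not None and not lattice.is_free(target):
        target = retarget() if retarget is not None else None
        if target is not None and not lattice.is_free(target):
            target = None
    if target is None:
        if cell.phenotype is not Phenotype.QUIESCENT:
            cell.resume_phenotype = cell.phenotype
            cell.phenotype = Phenotype.QUIESCENT
        return ActionOutcome("quiescent", cell.id)
    if cell.phenotype is Phenotype.MIGRATORY:
        lattice.move(cell.pos, target)
        cell.record_move(step, target)
        return ActionOutcome("moved", cell.id)
    if cell.phenotype is Phenotype.PROLIFERATIVE:
        pathway = PathwayState.initial() if daughter_reset else cell.pathway.copy()
        daughter = Cell(
            id=next_id,
            pos=target,
            phenotype=Phenotype.PROLIFERATIVE,
            pathway=pathway,
            prev_pathway=None if daughter_reset else (
                cell.prev_pathway.copy() if cell.prev_pathway is not None else None
            ),
            cycle_clock=cycle_interval,
            birth_step=step,
        )
        lattice.place(daughter.id, target)
        cell.cycle_clock = cycle_interval
        return ActionOutcome("divided", cell.id, daughter)
    raise ValueError(f"cell {cell.id} has no actionable phenotype ({cell.phenotype})")
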