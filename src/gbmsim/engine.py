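"""Simulation orchestration: the hourly multiscale loop.

Each agent step (= 1 simulated hour) executes a fixed sub-step order:

1. rebuild chemoattractant uptake/secretion maps from the cell population
   (homogeneous clusters deposit as one aggregated source);
2. advance the TGFα field by the configured diffusion sub-steps (monolithic
   ADI or Schwarz-tiled);
3. reclassify low-res clusters (dense / homogeneous / heterogeneous);
4. for every cell in a heterogeneous cluster, reconcile its free-ligand
   species X1 with the local field value (receptor coupling) and integrate
   the intracellular network for one hour;
5. compute the population threshold Avg — the mean PLCγ-P rate statistic of
   all cells whose cycle clock expired this step (the decision cohort);
6. phenotype decisions and actions (migrate / divide / quiesce) in a
   seed-randomized cell order;
7. record a :class:`StepRecord`.

Cells in homogeneous clusters are frozen — no ODE, no decisions, aggregated
sources only — and thaw automatically when their cluster turns heterogeneous.
The published threshold definition is circular (the switching cohort is only
known after comparison with Avg); it is resolved here as: the cohort is every
cell making a decision this step, and Avg is that cohort's mean rate.
"""

from __future__ import annotations

import copy
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io as gio
from .agents import MOORE_OFFSETS, ActionOutcome, AttractionParams, Cell, act, select_target
from .config import SimulationConfig, validate_config
from .diffusion import ChemoField, SourceParams, TileLayout, adi_step, deposit_sources, schwarz_step
from .fixtures import disc_tumor, gaussian_field
from .lattice import ClusterMap, DualLattice, active_cells, classify_clusters
from .pathway import (
    KineticParameters,
    PathwayState,
    Phenotype,
    RateOfChange,
    batch_integrate,
    decide_phenotype,
    percentage_rate_of_change,
)

log = logging.getLogger(__name__)

__all__ = [
    "Simulation",
    "StepRecord",
    "SwitchEvent",
    "RunResult",
    "compute_avg_threshold",
    "couple_receptor_input",
    "run",
    "records_equal",
]


@dataclass(frozen=True)
class SwitchEvent:
    """One phenotype switch: direction PM (proliferation→migration) or MP,
    with the cell's per-species rate statistics at the decision."""

    step: int
    cell_id: int
    direction: str  # "PM" | "MP"
    rates: np.ndarray  # shape (11,), relative per-step rates
    undefined: np.ndarray  # bool mask of species with no defined relative rate


@dataclass
class StepRecord:
    step: int
    n_migratory: int
    n_proliferative: int
    n_quiescent: int
    n_total: int
    occupied_nodes: int
    avg_threshold: float
    n_decisions: int
    switch_events: list[SwitchEvent]
    cluster_labels: np.ndarray
    moved_ids: frozenset[int]
    divided_ids: frozenset[int]
    field_uptake_nM: float
    cell_deposit_nM: float
    clamp_events: int
    field_snapshot: Optional[np.ndarray] = None


def records_equal(a: StepRecord, b: StepRecord) -> bool:
    """Bitwise equality of two step records (determinism harness)."""
    if (a.step, a.n_migratory, a.n_proliferative, a.n_quiescent, a.n_total,
            a.occupied_nodes, a.n_decisions, a.moved_ids, a.divided_ids) != (
            b.step, b.n_migratory, b.n_proliferative, b.n_quiescent, b.n_total,
            b.occupied_nodes, b.n_decisions, b.moved_ids, b.divided_ids):
        return False
    if a.avg_threshold != b.avg_threshold:
        return False
    if not np.array_equal(a.cluster_labels, b.cluster_labels):
        return False
    if len(a.switch_events) != len(b.switch_events):
        return False
    for ea, eb in zip(a.switch_events, b.switch_events):
        if (ea.step, ea.cell_id, ea.direction) != (eb.step, eb.cell_id, eb.direction):
            return False
        if not (np.array_equal(ea.rates, eb.rates) and np.array_equal(ea.undefined, eb.undefined)):
            return False
    return True


def compute_avg_threshold(candidate_rates: Sequence[float]) -> float:
    """Mean PLCγ-P rate statistic of the decision cohort; 0 for an empty
    cohort (in which case no decisions occur)."""
    rates = [r for r in candidate_rates]
    if not rates:
        return 0.0
    return float(np.mean(rates))


def couple_receptor_input(cell: Cell, field: ChemoField, conversion_factor: float = 1.0
                          ) -> tuple[float, float]:
    """Reconcile a cell's free-ligand species X1 with the local field node.

    The node's concentration is captured by the cell's receptors:
    X1 ← max(0, conversion_factor · Y[node]).  The captured tissue amount is
    returned so the caller can record it in the uptake map U, which drains
    the field by exactly that amount over the following hour of diffusion
    (smooth removal keeps the ADI field free of sharp craters).  Returns
    (new X1, tissue amount to drain in nM).
    """
    val = float(field.Y[cell.pos])
    new_x1 = max(0.0, conversion_factor * val)
    removed = max(0.0, val) if conversion_factor > 0 else 0.0
    cell.pathway.X[1] = new_x1
    return new_x1, removed


class Simulation:
    """One replicate of the multiscale tumor simulation.

    Deterministic for a fixed (config, seed): all randomness flows from one
    seed sequence split into fixed per-purpose streams (cell update order,
    attraction noise), so adding a consumer never perturbs existing streams.
    """

    def __init__(self, config: SimulationConfig, seed: int | None = None,
                 replicate: int = 0):
        self.config = validate_config(copy.deepcopy(config))
        self.seed = config.seed if seed is None else seed
        self.replicate = replicate
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(replicate,))
        order_ss, noise_ss = ss.spawn(2)
        self.order_rng = np.random.Generator(np.random.PCG64(order_ss))
        self.noise_rng = np.random.Generator(np.random.PCG64(noise_ss))

        lat = config.lattice
        self.lattice, self.cells = disc_tumor(
            tuple(lat.shape), config.tumor_seed.radius, lat.nesting,
            initial=np.asarray(config.initial_pathway, dtype=float),
            cycle_interval=config.cycle.decision_interval,
        )
        self._next_id = max(self.cells, default=-1) + 1
        fi = config.field_init
        H, W = lat.shape
        if fi.kind == "gaussian":
            self.field = gaussian_field(
                (H, W), amplitude=fi.amplitude_nM,
                sigma=fi.sigma_frac * min(H, W),
                center=(fi.center_frac[0] * (H - 1), fi.center_frac[1] * (W - 1)),
                dx=lat.dx_um, D=config.diffusion.diffusivity_cm2_s,
            )
        else:
            self.field = ChemoField(np.full((H, W), fi.amplitude_nM),
                                    D=config.diffusion.diffusivity_cm2_s, dx=lat.dx_um)
        self.source_params = SourceParams(
            secretion=config.diffusion.secretion_nM_s,
            uptake_rate=config.diffusion.uptake_rate_per_s,
            uptake_mode=config.diffusion.uptake_mode,
        )
        self.attraction_params = AttractionParams(
            psi=config.attraction.psi, mu=config.attraction.mu,
            sigma=config.attraction.sigma, sigma_rel=config.attraction.sigma_rel,
            sigma_min=config.attraction.sigma_min,
        )
        sz = config.diffusion.schwarz
        self.tile_layout = None if sz is None else TileLayout(
            tuple(sz["tile_shape"]), int(sz.get("overlap", 2)), int(sz.get("iterations", 3)))
        self.cluster_map: ClusterMap = classify_clusters(self.lattice)
        #: receptor-capture amounts (nM) awaiting removal from the field
        self._pending_uptake = np.zeros(tuple(lat.shape))
        self.step_index = 0
        self.records: list[StepRecord] = []

    # -- sub-procedures ----------------------------------------------------

    def _diffuse(self) -> None:
        d = self.config.diffusion
        for _ in range(d.n_substeps):
            if self.tile_layout is None:
                self.field = adi_step(self.field, d.dt_substep_s, d.boundary)
            else:
                self.field = schwarz_step(self.field, self.tile_layout, d.dt_substep_s, d.boundary)

    def _rate_statistic(self, roc: RateOfChange, cell: Cell) -> tuple[float, bool]:
        """PLCγ-P decision statistic and whether it is defined."""
        if self.config.ode.rate_mode == "absolute":
            return float(cell.pathway.X[9] - cell.prev_pathway.X[9]), True
        return roc.x9, roc.x9_defined

    def _has_free_neighbor(self, cell: Cell) -> bool:
        r0, c0 = cell.pos
        return any(self.lattice.is_free((r0 + dr, c0 + dc)) for dr, dc in MOORE_OFFSETS)

    # -- one ABM step ------------------------------------------------------

    def step(self) -> StepRecord:
        t0 = time.perf_counter()
        self.step_index += 1
        step = self.step_index
        cfg = self.config
        try:
            # (1) sources from the previous step's classification; last step's
            # receptor captures drain as part of the uptake map
            self.field = deposit_sources(
                self.field, self.cells.values(), self.cluster_map, self.source_params,
                extra_uptake=self._pending_uptake / cfg.ode.seconds_per_step,
            )
            drained_total = float(self._pending_uptake.sum())
            self._pending_uptake = np.zeros_like(self._pending_uptake)
            # (2) tissue diffusion
            clamp_before = self.field.clamp_events
            self._diffuse()
            # (3) cluster reclassification
            self.cluster_map = classify_clusters(self.lattice)
            active = sorted(active_cells(self.lattice, self.cluster_map))
            # (4) receptor coupling + intracellular integration
            deposit_total = 0.0
            for cid in active:
                cell = self.cells[cid]
                cell.prev_pathway = cell.pathway.copy()
                new_x1, removed = couple_receptor_input(cell, self.field, cfg.conversion_factor)
                self._pending_uptake[cell.pos] += removed
                deposit_total += new_x1
            if active:
                states = batch_integrate(
                    [self.cells[cid].pathway for cid in active], cfg.kinetics,
                    cfg.ode.seconds_per_step, cfg.ode.dt_s,
                )
                for cid, st in zip(active, states):
                    self.cells[cid].pathway = st
            # (5) clocks, cohort, population threshold
            rates: dict[int, tuple[float, bool, RateOfChange]] = {}
            cohort: list[int] = []
            for cid in active:
                cell = self.cells[cid]
                cell.cycle_clock -= 1
                if cell.phenotype is Phenotype.QUIESCENT and self._has_free_neighbor(cell):
                    cell.cycle_clock = 0  # re-enter decision making
                if cell.cycle_clock <= 0:
                    roc = percentage_rate_of_change(cell.prev_pathway, cell.pathway)
                    stat, defined = self._rate_statistic(roc, cell)
                    rates[cid] = (stat, defined, roc)
                    cohort.append(cid)
            avg = compute_avg_threshold([s for s, d, _ in rates.values() if d])
            cohort_set = set(cohort)
            # (6) decisions and actions in randomized order
            order = self.order_rng.permutation(sorted(self.cells))
            moved: set[int] = set()
            divided: set[int] = set()
            events: list[SwitchEvent] = []
            for cid in order:
                cell = self.cells[int(cid)]
                if not cell.alive:
                    continue
                if cell.id in cohort_set:
                    stat, defined, roc = rates[cell.id]
                    old = (cell.resume_phenotype if cell.phenotype is Phenotype.QUIESCENT
                           else cell.phenotype)
                    new = decide_phenotype(stat, avg) if defined else Phenotype.PROLIFERATIVE
                    if old is Phenotype.PROLIFERATIVE and new is Phenotype.MIGRATORY:
                        events.append(SwitchEvent(step, cell.id, "PM", roc.rates.copy(),
                                                  roc.undefined.copy()))
                    elif old is Phenotype.MIGRATORY and new is Phenotype.PROLIFERATIVE:
                        events.append(SwitchEvent(step, cell.id, "MP", roc.rates.copy(),
                                                  roc.undefined.copy()))
                    cell.phenotype = new
                    cell.resume_phenotype = None
                    cell.cycle_clock = cfg.cycle.decision_interval
                    outcome = self._act(cell, step)
                elif cell.phenotype is Phenotype.MIGRATORY:
                    outcome = self._act(cell, step)
                else:
                    continue
                if outcome.kind == "moved":
                    moved.add(cell.id)
                elif outcome.kind == "divided":
                    divided.add(cell.id)
            # (7) bookkeeping
            rec = self._record(step, avg, len(cohort), events, moved, divided,
                               drained_total, deposit_total,
                               self.field.clamp_events - clamp_before)
            self.records.append(rec)
            log.info("step %d: %d cells (%dM/%dP/%dQ), %d decisions, %.3f s",
                     step, rec.n_total, rec.n_migratory, rec.n_proliferative,
                     rec.n_quiescent, rec.n_decisions, time.perf_counter() - t0)
            return rec
        except Exception as exc:
            raise RuntimeError(f"simulation step {step} failed") from exc

    def _act(self, cell: Cell, step: int) -> ActionOutcome:
        target = select_target(cell, self.field.Y, self.lattice,
                               self.attraction_params, self.noise_rng)
        outcome = act(
            cell, target, self.lattice, step, next_id=self._next_id,
            cycle_interval=self.config.cycle.decision_interval,
            daughter_reset=self.config.daughter_reset,
            retarget=lambda: select_target(cell, self.field.Y, self.lattice,
                                           self.attraction_params, self.noise_rng),
        )
        if outcome.daughter is not None:
            self.cells[outcome.daughter.id] = outcome.daughter
            self._next_id += 1
        return outcome

    def _record(self, step, avg, n_decisions, events, moved, divided,
                uptake, deposit, clamps) -> StepRecord:
        counts = {Phenotype.MIGRATORY: 0, Phenotype.PROLIFERATIVE: 0, Phenotype.QUIESCENT: 0}
        total = 0
        for cell in self.cells.values():
            if cell.alive:
                counts[cell.phenotype] += 1
                total += 1
        snap = None
        if self.config.snapshot_every and step % self.config.snapshot_every == 0:
            snap = self.field.Y.copy()
        return StepRecord(
            step=step,
            n_migratory=counts[Phenotype.MIGRATORY],
            n_proliferative=counts[Phenotype.PROLIFERATIVE],
            n_quiescent=counts[Phenotype.QUIESCENT],
            n_total=total,
            occupied_nodes=self.lattice.occupied_count(),
            avg_threshold=avg,
            n_decisions=n_decisions,
            switch_events=events,
            cluster_labels=self.cluster_map.labels.copy(),
            moved_ids=frozenset(moved),
            divided_ids=frozenset(divided),
            field_uptake_nM=uptake,
            cell_deposit_nM=deposit,
            clamp_events=clamps,
            field_snapshot=snap,
        )

    def run_steps(self, n: int) -> list[StepRecord]:
        return [self.step() for _ in range(n)]

    def snapshot(self) -> "Simulation":
        """Deep checkpoint; continuing the copy reproduces the original run."""
        return copy.deepcopy(self)


@dataclass
class RunResult:
    config: SimulationConfig
    replicates: list[list[StepRecord]]
    seeds: list[tuple[int, int]]

    def population_mean(self):
        """Across-replicate mean population curves as a DataFrame."""
        import pandas as pd

        frames = []
        for rep, recs in enumerate(self.replicates):
            frames.append(pd.DataFrame({
                "step": [r.step for r in recs],
                "replicate": rep,
                "migratory": [r.n_migratory for r in recs],
                "proliferative": [r.n_proliferative for r in recs],
                "quiescent": [r.n_quiescent for r in recs],
                "total": [r.n_total for r in recs],
            }))
        df = pd.concat(frames, ignore_index=True)
        return df.groupby("step")[["migratory", "proliferative", "quiescent", "total"]].mean().reset_index()


def run(config: SimulationConfig, out_dir: str | Path | None = None,
        replicates: int | None = None, steps: int | None = None) -> RunResult:
    """Execute the configured number of steps for each replicate (independent
    seeds derived from the run seed) and optionally write all outputs."""
    config = validate_config(copy.deepcopy(config))
    if replicates is not None:
        config.replicates = replicates
    if steps is not None:
        config.steps = steps
    all_records: list[list[StepRecord]] = []
    seeds = []
    sims = []
    for rep in range(config.replicates):
        sim = Simulation(config, seed=config.seed, replicate=rep)
        seeds.append((config.seed, rep))
        sim.run_steps(config.steps)
        all_records.append(sim.records)
        sims.append(sim)
    result = RunResult(config, all_records, seeds)
    if out_dir is not None:
        try:
            gio.write_run(result, sims, Path(out_dir))
        except OSError:
            log.exception("failed writing outputs to %s; in-memory results preserved", out_dir)
    return result
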