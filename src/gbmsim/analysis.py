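"""Multiscale analysis products: population curves and their crossings,
switch-event molecular profiles, single-cell trajectories, and figure
rendering.

The crossing detector finds the steps at which the proliferative and
migratory population curves exchange order; the switch profiles summarize,
per switch direction (PM = proliferation→migration, MP = the reverse), the
cohort-mean relative rate of change of every network species X1..X10 at the
moment of the decision — the molecular fingerprint of the phenotype switch.
Rates are per ABM step (one hour) and labeled as such on all outputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .engine import StepRecord, Simulation, SwitchEvent
from .pathway import Phenotype

__all__ = [
    "PopulationSeries",
    "SwitchProfile",
    "find_crossings",
    "switch_profiles",
    "trajectory",
    "render",
]

_PROFILE_SPECIES = [f"X{i}" for i in range(1, 11)]


@dataclass(frozen=True)
class PopulationSeries:
    """Per-step migratory / proliferative / total counts."""

    steps: np.ndarray
    migratory: np.ndarray
    proliferative: np.ndarray
    total: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.steps)
        if not (len(self.migratory) == len(self.proliferative) == len(self.total) == n):
            raise ValueError("population series components must have equal length")
        if np.any(self.total < self.migratory) or np.any(self.total < self.proliferative):
            raise ValueError("total count below a component count")

    @classmethod
    def from_records(cls, records: Sequence[StepRecord]) -> "PopulationSeries":
        return cls(
            np.array([r.step for r in records]),
            np.array([r.n_migratory for r in records]),
            np.array([r.n_proliferative for r in records]),
            np.array([r.n_total for r in records]),
        )


def find_crossings(series: PopulationSeries) -> list[int]:
    """Steps at which the proliferation and migration curves cross.

    A crossing is flagged at step t (the later step of the pair) when the
    sign of (proliferative − migratory) differs from the previous step; an
    exact tie (difference zero) counts as a crossing, so identical curves
    flag every step after the first — documented degenerate behavior.
    """
    if len(series.steps) == 0:
        raise ValueError("empty population series")
    d = series.proliferative.astype(np.int64) - series.migratory.astype(np.int64)
    out = []
    for i in range(1, len(d)):
        if np.sign(d[i]) != np.sign(d[i - 1]) or d[i] == 0:
            out.append(int(series.steps[i]))
    return out


@dataclass(frozen=True)
class SwitchProfile:
    """Cohort-mean per-species rate of change for one switch direction."""

    step: int
    direction: str  # "PM" | "MP"
    means: dict[str, float]  # species X1..X10 -> mean defined rate
    cohort_size: int
    excluded: dict[str, int]  # species -> count of undefined rates excluded

    def as_series(self) -> pd.Series:
        return pd.Series(self.means, name=f"{self.direction}@{self.step}")


def switch_profiles(events: Iterable[SwitchEvent], step: int | None = None
                    ) -> tuple[SwitchProfile, SwitchProfile]:
    """(PM, MP) molecular profiles of the switch events of one step.

    Species rates flagged undefined (growth from exactly zero) are excluded
    from the means; the exclusion counts are reported per species.
    """
    events = list(events)
    if step is None:
        step = events[0].step if events else 0
    profiles = []
    for direction in ("PM", "MP"):
        sub = [e for e in events if e.direction == direction]
        means: dict[str, float] = {}
        excluded: dict[str, int] = {}
        for i, name in enumerate(_PROFILE_SPECIES, start=1):
            vals = [float(e.rates[i]) for e in sub if not e.undefined[i]]
            excluded[name] = sum(1 for e in sub if e.undefined[i])
            means[name] = float(np.mean(vals)) if vals else float("nan")
        profiles.append(SwitchProfile(step, direction, means, len(sub), excluded))
    return profiles[0], profiles[1]


def profiles_to_frame(profiles: Iterable[SwitchProfile]) -> pd.DataFrame:
    """Heatmap-ready matrix: rows = species, columns = direction@step."""
    return pd.DataFrame({p.as_series().name: p.as_series() for p in profiles})


def trajectory(cell_id: int, sim: Simulation) -> list[tuple[int, int, int]]:
    """Gap-free (step, x, y) history of one cell from its birth step through
    the last simulated step; positions persist between moves."""
    if cell_id not in sim.cells:
        raise KeyError(f"unknown cell id {cell_id}")
    cell = sim.cells[cell_id]
    sparse = cell.trajectory
    out = []
    k = 0
    pos = sparse[0][1:]
    for step in range(cell.birth_step, sim.step_index + 1):
        while k < len(sparse) and sparse[k][0] <= step:
            pos = sparse[k][1:]
            k += 1
        out.append((step, pos[0], pos[1]))
    return out


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_PHENOTYPE_COLORS = {
    Phenotype.MIGRATORY: (0.85, 0.1, 0.1),     # red
    Phenotype.PROLIFERATIVE: (0.1, 0.2, 0.85),  # blue
    Phenotype.QUIESCENT: (0.1, 0.65, 0.15),     # green
}


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def render(sim: Simulation, out_dir: str | Path, cell_id: int | None = None) -> list[Path]:
    """Write the standard figure set for a finished simulation.

    Products: population curves (red migratory / blue proliferative / black
    total), switch-profile heatmaps with the numeric matrix alongside as CSV,
    the final cluster map (black heterogeneous / green homogeneous), the
    final high-res phenotype map (red/blue/green), and one cell's (step, x,
    y) trajectory in 3D.  Rendering never mutates its inputs.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    records = sim.records

    # population curves
    fig, ax = plt.subplots(figsize=(6, 4))
    if records:
        s = PopulationSeries.from_records(records)
        ax.plot(s.steps, s.migratory, color="red", label="migratory")
        ax.plot(s.steps, s.proliferative, color="blue", label="proliferative")
        ax.plot(s.steps, s.total, color="black", label="total")
        ax.legend()
        pd.DataFrame({"step": s.steps, "migratory": s.migratory,
                      "proliferative": s.proliferative, "total": s.total}
                     ).to_csv(out_dir / "population.csv", index=False)
        written.append(out_dir / "population.csv")
    ax.set_xlabel("time step (h)")
    ax.set_ylabel("cell count")
    fig.savefig(out_dir / "population.png", dpi=120)
    plt.close(fig)
    written.append(out_dir / "population.png")

    # switch-profile heatmap (all events pooled per step with events)
    profs = []
    for r in records:
        if r.switch_events:
            pm, mp = switch_profiles(r.switch_events, r.step)
            if pm.cohort_size:
                profs.append(pm)
            if mp.cohort_size:
                profs.append(mp)
    if profs:
        mat = profiles_to_frame(profs)
        mat.to_csv(out_dir / "switch_profiles.csv")
        written.append(out_dir / "switch_profiles.csv")
        fig, ax = plt.subplots(figsize=(1 + 0.5 * mat.shape[1], 4))
        vals = mat.to_numpy(dtype=float)
        finite = np.isfinite(vals)
        vmin = np.nanmin(vals) if finite.any() else 0.0
        vmax = np.nanmax(vals) if finite.any() else 1.0
        im = ax.imshow(vals, aspect="auto", cmap="viridis", vmin=vmin, vmax=vmax)
        ax.set_yticks(range(len(mat.index)), mat.index)
        ax.set_xticks(range(len(mat.columns)), mat.columns, rotation=90)
        fig.colorbar(im, ax=ax, label="relative rate of change per step (1/h)")
        fig.tight_layout()
        fig.savefig(out_dir / "switch_profiles.png", dpi=120)
        plt.close(fig)
        written.append(out_dir / "switch_profiles.png")

    # cluster map: white empty, black heterogeneous, green homogeneous
    labels = sim.cluster_map.labels
    before = _checksum(labels)
    cmap = ListedColormap([(1, 1, 1), (0, 0, 0), (0.1, 0.65, 0.15)])
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(labels, cmap=cmap, vmin=0, vmax=2, interpolation="none")
    ax.set_title(f"clusters, step {sim.step_index}")
    fig.savefig(out_dir / "clusters.png", dpi=120)
    plt.close(fig)
    assert _checksum(labels) == before  # render is side-effect-only
    written.append(out_dir / "clusters.png")

    # high-res phenotype map
    H, W = sim.lattice.shape
    rgb = np.ones((H, W, 3))
    for cell in sim.cells.values():
        if cell.alive:
            rgb[cell.pos] = _PHENOTYPE_COLORS[cell.phenotype]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(rgb, interpolation="none")
    ax.set_title(f"phenotypes, step {sim.step_index}")
    fig.savefig(out_dir / "phenotypes.png", dpi=120)
    plt.close(fig)
    written.append(out_dir / "phenotypes.png")

    # single-cell trajectory, (step, x, y) in 3D
    if cell_id is None and sim.cells:
        cell_id = min(sim.cells)
    if cell_id is not None and sim.cells:
        traj = trajectory(cell_id, sim)
        arr = np.array(traj)
        fig = plt.figure(figsize=(6, 5))
        ax3 = fig.add_subplot(projection="3d")
        ax3.plot(arr[:, 0], arr[:, 1], arr[:, 2])
        ax3.set_xlabel("time step (h)")
        ax3.set_ylabel("x (node)")
        ax3.set_zlabel("y (node)")
        fig.savefig(out_dir / f"trajectory_cell{cell_id}.png", dpi=120)
        plt.close(fig)
        pd.DataFrame(traj, columns=["step", "x", "y"]).to_csv(
            out_dir / f"trajectory_cell{cell_id}.csv", index=False)
        written.append(out_dir / f"trajectory_cell{cell_id}.png")
        written.append(out_dir / f"trajectory_cell{cell_id}.csv")
    return written
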