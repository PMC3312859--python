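"""Readers/writers shared by the CLI: CSV tables, field containers, run
manifests.  All tabular writers round-trip at double precision (`repr`
formatting); field snapshots use the NumPy ``.npy`` container with a JSON
metadata sidecar (dx, t, D)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .diffusion import ChemoField
from .pathway import SPECIES_NAMES

if TYPE_CHECKING:  # pragma: no cover
    from .engine import RunResult, Simulation

__all__ = [
    "write_field", "read_field", "write_cluster_csv", "read_cluster_csv",
    "write_cells_csv", "write_population_csv", "write_switch_events_csv",
    "write_run", "read_population_csv",
]


def write_field(field: ChemoField, path: str | Path) -> None:
    path = Path(path)
    np.save(path.with_suffix(".npy"), field.Y)
    meta = {"dx_um": field.dx, "t_s": field.t, "D_cm2_s": field.D,
            "clamp_events": field.clamp_events}
    path.with_suffix(".json").write_text(json.dumps(meta))


def read_field(path: str | Path) -> ChemoField:
    path = Path(path)
    Y = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    f = ChemoField(Y, D=meta["D_cm2_s"], dx=meta["dx_um"], t=meta["t_s"])
    f.clamp_events = meta["clamp_events"]
    return f


def write_cluster_csv(labels: np.ndarray, path: str | Path) -> None:
    """Label matrix as CSV: 0 empty / 1 heterogeneous / 2 homogeneous."""
    np.savetxt(path, labels, fmt="%d", delimiter=",")


def read_cluster_csv(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, dtype=np.int8, delimiter=",", ndmin=2)


def write_cells_csv(cells, path: str | Path) -> None:
    """Per-cell table: id, x, y, phenotype, cycle_clock, X0..X10."""
    rows = []
    for c in sorted(cells, key=lambda c: c.id):
        rows.append({
            "id": c.id, "x": c.pos[0], "y": c.pos[1],
            "phenotype": c.phenotype.value, "cycle_clock": c.cycle_clock,
            **{name: repr(float(v)) for name, v in zip(SPECIES_NAMES, c.pathway.X)},
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_population_csv(records_per_replicate, path: str | Path) -> None:
    rows = []
    for rep, recs in enumerate(records_per_replicate):
        for r in recs:
            rows.append({"replicate": rep, "step": r.step, "migratory": r.n_migratory,
                         "proliferative": r.n_proliferative, "quiescent": r.n_quiescent,
                         "total": r.n_total})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_population_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_switch_events_csv(records_per_replicate, path: str | Path) -> None:
    rows = []
    for rep, recs in enumerate(records_per_replicate):
        for r in recs:
            for e in r.switch_events:
                row = {"replicate": rep, "step": e.step, "cell_id": e.cell_id,
                       "direction": e.direction}
                for i in range(1, 11):
                    row[f"rate_X{i}"] = "" if e.undefined[i] else repr(float(e.rates[i]))
                rows.append(row)
    cols = ["replicate", "step", "cell_id", "direction"] + [f"rate_X{i}" for i in range(1, 11)]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_run(result: "RunResult", sims: list["Simulation"], out_dir: Path) -> None:
    """Write the complete run product set: population curves (per replicate
    and mean), switch events, snapshots, and a manifest echoing the config."""
    out_dir.mkdir(parents=True, exist_ok=True)
    write_population_csv(result.replicates, out_dir / "population.csv")
    result.population_mean().to_csv(out_dir / "population_mean.csv", index=False)
    write_switch_events_csv(result.replicates, out_dir / "switch_events.csv")
    every = result.config.snapshot_every
    if every:
        for rep, sim in enumerate(sims):
            for rec in sim.records:
                if rec.step % every == 0:
                    tag = f"rep{rep}_step{rec.step:03d}"
                    write_cluster_csv(rec.cluster_labels, out_dir / f"clusters_{tag}.csv")
                    if rec.field_snapshot is not None:
                        f = sim.field.copy()
                        f.Y = rec.field_snapshot
                        write_field(f, out_dir / f"field_{tag}")
            write_cells_csv(sim.cells.values(), out_dir / f"cells_rep{rep}_final.csv")
    manifest = {
        "config": result.config.to_dict(),
        "seeds": [list(s) for s in result.seeds],
        "steps": result.config.steps,
        "replicates": result.config.replicates,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
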