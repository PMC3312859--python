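"""Simulation engine: threshold cohort semantics, step invariants, receptor
coupling balance, determinism and restart equivalence."""

import numpy as np
import pytest

from gbmsim.agents import Cell
from gbmsim.config import SimulationConfig
from gbmsim.diffusion import ChemoField
from gbmsim.engine import (
    Simulation,
    compute_avg_threshold,
    couple_receptor_input,
    records_equal,
    run,
)
from gbmsim.pathway import Phenotype, decide_phenotype


class TestAvgThreshold:
    def test_mean_of_cohort_rates(self):
        assert compute_avg_threshold([0.1, 0.3]) == pytest.approx(0.2)

    def test_single_candidate_always_proliferates(self):
        # with itself as the whole cohort, rate == Avg, and ties proliferate
        rate = 0.42
        avg = compute_avg_threshold([rate])
        assert avg == rate
        assert decide_phenotype(rate, avg) is Phenotype.PROLIFERATIVE

    def test_empty_cohort_threshold_is_zero(self):
        assert compute_avg_threshold([]) == 0.0


class TestReceptorCoupling:
    def test_zero_field_zeroes_ligand(self):
        cell = Cell(id=0, pos=(2, 2))
        f = ChemoField(np.zeros((5, 5)))
        new_x1, removed = couple_receptor_input(cell, f)
        assert new_x1 == 0.0 and removed == 0.0
        assert cell.pathway.X[1] == 0.0

    def test_unit_conversion_transfers_node_value(self):
        cell = Cell(id=0, pos=(2, 2))
        f = ChemoField(np.full((5, 5), 50.0))
        new_x1, removed = couple_receptor_input(cell, f, conversion_factor=1.0)
        assert new_x1 == 50.0 and removed == 50.0

    def test_field_cell_mass_balance(self, small_config):
        """With unit conversion, the amount drained from the field in a step
        equals what cells captured when they last read it (one-step lag of
        the uptake-map drain)."""
        sim = Simulation(small_config, seed=3)
        sim.run_steps(6)
        for prev, curr in zip(sim.records, sim.records[1:]):
            assert curr.field_uptake_nM == pytest.approx(prev.cell_deposit_nM, rel=1e-12)


class TestStepInvariants:
    def test_zero_cell_simulation_steps_cleanly(self, small_config):
        cfg = small_config
        cfg.tumor_seed.radius = 0
        sim = Simulation(cfg, seed=1)
        sim.cells.clear()
        sim.lattice.occupancy[:] = -1
        sim.lattice.version += 1
        rec = sim.step()
        assert rec.n_total == 0 and rec.n_decisions == 0 and not rec.switch_events

    def test_single_cell_growth_bounded_by_decision_interval(self, small_config):
        cfg = small_config
        cfg.tumor_seed.radius = 0
        cfg.cycle.decision_interval = 4
        sim = Simulation(cfg, seed=1)
        sim.run_steps(9)  # two decision rounds
        assert sim.records[-1].n_total <= 1 + 9 // 4 + 1

    def test_population_identity_and_occupancy_bijection(self, small_run):
        sim = small_run
        for rec in sim.records:
            assert rec.n_migratory + rec.n_proliferative + rec.n_quiescent == rec.n_total
            assert rec.occupied_nodes == rec.n_total
        # occupancy <-> cells is a bijection at the end of the run
        occ = sim.lattice.occupancy
        ids_on_lattice = sorted(int(v) for v in occ[occ != -1])
        assert ids_on_lattice == sorted(sim.cells)
        for cid, cell in sim.cells.items():
            assert occ[cell.pos] == cid

    def test_migration_and_division_are_disjoint(self, small_run):
        for rec in small_run.records:
            assert not (rec.moved_ids & rec.divided_ids)

    def test_tumor_area_never_shrinks(self, small_run):
        counts = [r.occupied_nodes for r in small_run.records]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_no_clamping_in_shipped_configuration(self, small_run):
        assert small_run.field.clamp_events == 0


class TestDeterminismAndRestart:
    def test_equal_seeds_equal_records(self, small_config):
        a = Simulation(small_config, seed=11)
        b = Simulation(small_config, seed=11)
        a.run_steps(12)
        b.run_steps(12)
        assert all(records_equal(x, y) for x, y in zip(a.records, b.records))

    def test_different_seeds_diverge(self, small_config):
        a = Simulation(small_config, seed=1)
        b = Simulation(small_config, seed=2)
        a.run_steps(15)
        b.run_steps(15)
        assert not all(records_equal(x, y) for x, y in zip(a.records, b.records))

    def test_checkpoint_restart_equivalence(self, small_config):
        full = Simulation(small_config, seed=5)
        full.run_steps(14)
        part = Simulation(small_config, seed=5)
        part.run_steps(7)
        resumed = part.snapshot()
        resumed.run_steps(7)
        assert all(records_equal(x, y) for x, y in zip(full.records, resumed.records))

    def test_step_errors_carry_step_index(self, small_config):
        sim = Simulation(small_config, seed=1)
        sim.field.Y[0, 0] = np.nan
        with pytest.raises(RuntimeError, match="step 1"):
            sim.step()


class TestRun:
    def test_single_step_single_cell(self, small_config):
        cfg = small_config
        cfg.tumor_seed.radius = 0
        res = run(cfg, replicates=1, steps=1)
        assert len(res.replicates) == 1 and len(res.replicates[0]) == 1
        rec = res.replicates[0][0]
        assert rec.n_total == 1

    def test_replicates_share_config_but_differ(self, small_config):
        # divergence needs at least one decision round (interval 12) so the
        # per-replicate noise streams are actually consumed
        res = run(small_config, replicates=2, steps=15)
        assert res.seeds == [(small_config.seed, 0), (small_config.seed, 1)]
        a, b = res.replicates
        assert not all(records_equal(x, y) for x, y in zip(a, b))
        mean = res.population_mean()
        assert list(mean.columns) == ["step", "migratory", "proliferative", "quiescent", "total"]
        assert len(mean) == 15

    def test_outputs_written(self, small_config, tmp_path):
        cfg = small_config
        cfg.snapshot_every = 4
        run(cfg, out_dir=tmp_path, replicates=1, steps=4)
        assert (tmp_path / "population.csv").exists()
        assert (tmp_path / "switch_events.csv").exists()
        assert (tmp_path / "manifest.json").exists()
        assert (tmp_path / "clusters_rep0_step004.csv").exists()
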