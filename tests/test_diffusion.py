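"""Reaction-diffusion solver: Thomas algorithm, ADI accuracy/conservation,
Schwarz-tile equivalence, and source deposition."""

import numpy as np
import pytest

from gbmsim.diffusion import (
    ChemoField,
    SourceParams,
    TileLayout,
    adi_step,
    deposit_sources,
    schwarz_step,
    thomas_solve,
)
from gbmsim.fixtures import gaussian_field, sine_field
from gbmsim.lattice import DualLattice, classify_clusters
from gbmsim.agents import Cell
from gbmsim.pathway import Phenotype


class TestThomas:
    def test_identity_system(self):
        r = np.array([3.0, -1.0, 2.0])
        x = thomas_solve(np.zeros(3), np.ones(3), np.zeros(3), r)
        assert np.array_equal(x, r)

    def test_known_small_system(self):
        # [[2,-1,0],[-1,2,-1],[0,-1,2]] x = [1,0,1] has solution [1,1,1]
        x = thomas_solve(np.array([0.0, -1, -1]), np.full(3, 2.0),
                         np.array([-1.0, -1, 0]), np.array([1.0, 0, 1]))
        assert np.allclose(x, 1.0, atol=1e-14)

    def test_matches_dense_solver_on_random_dominant_systems(self, rng):
        for _ in range(5):
            n = 50
            sub, sup = rng.normal(size=n), rng.normal(size=n)
            diag = np.abs(sub) + np.abs(sup) + rng.uniform(1, 2, n)
            rhs = rng.normal(size=n)
            A = np.diag(diag) + np.diag(sub[1:], -1) + np.diag(sup[:-1], 1)
            x = thomas_solve(sub, diag, sup, rhs)
            assert np.max(np.abs(x - np.linalg.solve(A, rhs))) < 1e-10

    def test_zero_pivot_raises(self):
        with pytest.raises(np.linalg.LinAlgError, match="pivot"):
            thomas_solve(np.zeros(2), np.array([0.0, 1.0]), np.zeros(2), np.ones(2))

    def test_non_dominant_system_warns(self):
        with pytest.warns(UserWarning, match="dominant"):
            thomas_solve(np.array([0.0, 5.0]), np.ones(2), np.array([5.0, 0.0]), np.ones(2))


class TestAdi:
    def test_uniform_field_is_steady_state(self):
        f = ChemoField(np.full((32, 32), 3.0), D=1e-7, dx=10.0)
        g = adi_step(f, 600.0)
        assert np.allclose(g.Y, 3.0, rtol=1e-13)

    def test_zero_flux_conserves_mass(self):
        f = gaussian_field((64, 64), amplitude=5.0, dx=10.0, D=1e-7)
        m0 = f.total_mass()
        for _ in range(5):
            f = adi_step(f, 600.0)
        assert abs(f.total_mass() - m0) <= 1e-10 * m0

    def test_dirichlet_eigenmode_decay_matches_analytic(self):
        # fundamental mode of the unit-style square decays as exp(-2Dπ²t/L²)
        N = 128
        f = sine_field((N, N), dx=1.0, D=1e-8)  # 1 μm²/s in lattice units
        L = (N + 1) * f.dx
        rate = 2.0 * f.D_lattice * np.pi**2 / L**2
        dt, nsteps = 100.0, 10
        g = f.copy()
        for _ in range(nsteps):
            g = adi_step(g, dt, "dirichlet-zero")
        ratio = g.Y[N // 2, N // 2] / f.Y[N // 2, N // 2]
        assert ratio == pytest.approx(np.exp(-rate * dt * nsteps), rel=0.01)

    def test_second_order_in_space(self):
        """Error against the analytic eigenmode drops ~4x when dx halves."""
        errs = []
        for N in (32, 64):
            f = sine_field((N, N), dx=1.0, D=1e-8)
            L = (N + 1) * f.dx
            rate = 2.0 * f.D_lattice * np.pi**2 / L**2
            t_final = 0.05 * L**2  # same physical time relative to the domain
            nsteps = 400
            g = f.copy()
            for _ in range(nsteps):
                g = adi_step(g, t_final / nsteps, "dirichlet-zero")
            exact = f.Y * np.exp(-rate * t_final)
            errs.append(np.max(np.abs(g.Y - exact)))
        assert 3.0 < errs[0] / errs[1] < 5.5

    def test_source_term_injects_expected_mass(self):
        f = ChemoField(np.zeros((16, 16)), D=1e-7, dx=10.0)
        f.S = np.zeros((16, 16))
        f.S[8, 8] = 0.05  # nM/s
        g = adi_step(f, 600.0)
        assert g.total_mass() == pytest.approx(0.05 * 600.0 * f.dx**2, rel=1e-12)

    def test_negative_values_are_clamped_and_counted(self):
        f = ChemoField(np.zeros((8, 8)), D=1e-7, dx=10.0)
        f.U = np.full((8, 8), 1.0)  # drain an empty field
        g = adi_step(f, 10.0)
        assert g.clamp_events == 64
        assert np.all(g.Y >= 0)

    def test_bad_inputs_rejected(self):
        f = ChemoField(np.zeros((8, 8)))
        with pytest.raises(ValueError):
            adi_step(f, -1.0)
        with pytest.raises(ValueError):
            adi_step(f, 1.0, bc="periodic")
        f.Y[0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            adi_step(f, 1.0)


@pytest.fixture
def bump():
    # a = D*dt/(2*dx²) = 0.25 with the dt used below: resolved tile coupling
    return gaussian_field((64, 64), amplitude=1.0, sigma=8.0, dx=1.0, D=1e-8)


class TestSchwarz:
    DT = 0.5

    def test_whole_domain_tile_is_bitwise_monolithic(self, bump):
        mono = adi_step(bump, self.DT)
        tiled = schwarz_step(bump, TileLayout((64, 64)), self.DT)
        assert np.array_equal(mono.Y, tiled.Y)

    def test_two_by_two_tiles_match_monolithic(self, bump):
        mono = adi_step(bump, self.DT)
        tiled = schwarz_step(bump, TileLayout((32, 32), overlap=2, iterations=3), self.DT)
        assert np.max(np.abs(tiled.Y - mono.Y)) < 1e-4 * bump.Y.max()

    def test_deviation_decreases_with_overlap_and_iterations(self, bump):
        mono = adi_step(bump, self.DT)

        def dev(overlap, iterations):
            t = schwarz_step(bump, TileLayout((32, 32), overlap, iterations), self.DT)
            return np.max(np.abs(t.Y - mono.Y))

        by_overlap = [dev(ov, 2) for ov in (1, 2, 3)]
        assert all(b <= a for a, b in zip(by_overlap, by_overlap[1:]))
        by_iters = [dev(1, it) for it in (1, 2, 3)]
        assert all(b <= a for a, b in zip(by_iters, by_iters[1:]))
        assert by_overlap[-1] < by_overlap[0] or by_overlap[0] < 1e-14

    def test_invalid_layout_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            TileLayout((8, 8), overlap=0)


def _make_cell(cid, pos):
    return Cell(id=cid, pos=pos, phenotype=Phenotype.PROLIFERATIVE)


class TestDepositSources:
    def test_no_cells_no_sources(self):
        f = ChemoField(np.ones((12, 12)))
        g = deposit_sources(f, [], None)
        assert not g.U.any() and not g.S.any()

    def test_single_cell_secretes_at_its_node(self):
        f = ChemoField(np.zeros((12, 12)))
        g = deposit_sources(f, [_make_cell(0, (3, 4))], None, SourceParams(secretion=0.05))
        assert g.S[3, 4] == 0.05
        assert np.count_nonzero(g.S) == 1

    def test_homogeneous_cluster_aggregates_uniformly(self):
        """A frozen dense cluster deposits n·u spread over its footprint,
        matching the total of per-cell deposition."""
        r = 3
        lat = DualLattice((9, 9), r)
        cells = []
        for i in range(9):
            for j in range(9):
                cells.append(_make_cell(i * 9 + j, (i, j)))
                lat.place(i * 9 + j, (i, j))
        cmap = classify_clusters(lat)
        assert cmap.labels[1, 1] == 2  # center site homogeneous
        params = SourceParams(secretion=0.05, uptake_rate=0.02, uptake_mode="constant")
        f = ChemoField(np.zeros((9, 9)))
        g = deposit_sources(f, cells, cmap, params)
        fp = (slice(3, 6), slice(3, 6))
        n = r * r
        assert np.allclose(g.U[fp], n * 0.02 / n)  # uniform spread of n·u
        assert np.allclose(g.S[fp], n * 0.05 / n)
        # totals identical to naive per-cell deposition
        assert g.U.sum() == pytest.approx(len(cells) * 0.02)
        assert g.S.sum() == pytest.approx(len(cells) * 0.05)

    def test_linear_uptake_scales_with_local_concentration(self):
        f = ChemoField(np.full((6, 6), 200.0))
        g = deposit_sources(f, [_make_cell(0, (2, 2))], None,
                            SourceParams(uptake_rate=0.001, uptake_mode="linear"))
        assert g.U[2, 2] == pytest.approx(0.2)
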