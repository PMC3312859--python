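"""EGFR network kinetics: reaction velocities, derivative assembly, RK4
integration, moiety conservation and the phenotype-switch statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gbmsim.pathway import (
    DEFAULT_INITIAL,
    KineticParameters,
    PathwayError,
    PathwayState,
    Phenotype,
    StiffnessError,
    batch_integrate,
    decide_phenotype,
    integrate_pathway,
    moiety_totals,
    pathway_derivatives,
    percentage_rate_of_change,
    reaction_rates,
)

#: moiety weight vectors (species 0..10); each is a conserved linear form
MOIETY_WEIGHTS = {
    "egfr": np.array([0, 0, 1, 1, 2, 2, 0, 2, 2, 0, 0], dtype=float),
    "plcg": np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1], dtype=float),
    "tgfa": np.array([0, 1, 0, 1, 2, 2, 0, 2, 2, 0, 0], dtype=float),
}


def state_with(**species) -> PathwayState:
    x = np.zeros(11)
    for name, val in species.items():
        x[int(name[1:])] = val
    return PathwayState(x)


class TestReactionRates:
    def test_initial_state_only_ligand_binding_active(self):
        # v1 = k1*X1*X2 = 0.003 * 9010.55 * 100; every complex is empty
        r = reaction_rates(PathwayState.initial())
        assert r.v1 == pytest.approx(2703.165, abs=1e-9)
        assert np.allclose(r.v[1:], 0.0)

    def test_zero_state_all_rates_vanish(self):
        r = reaction_rates(state_with())
        assert np.array_equal(r.v, np.zeros(9))

    def test_dephosphorylation_is_michaelis_menten(self):
        # X5 = K4 = 50 nM puts the enzyme at half saturation: v4 = V4/2
        r = reaction_rates(state_with(X5=50.0))
        assert r.v4 == pytest.approx(225.0)

    def test_negative_concentration_rejected(self):
        bad = PathwayState(np.append(np.zeros(10), -1.0))
        with pytest.raises(PathwayError, match="negative"):
            reaction_rates(bad)


class TestDerivatives:
    def test_initial_state_routes_binding_flux(self):
        d = pathway_derivatives(PathwayState.initial())
        assert d[1] == pytest.approx(-2703.165)
        assert d[2] == pytest.approx(-2703.165)
        assert d[3] == pytest.approx(+2703.165)
        assert np.allclose(np.delete(d, [1, 2, 3]), 0.0)

    def test_zero_state_is_stationary(self):
        assert np.array_equal(pathway_derivatives(state_with()), np.zeros(11))

    @given(
        x=st.lists(st.floats(min_value=0, max_value=1e4, allow_nan=False), min_size=11, max_size=11)
    )
    @settings(max_examples=60, deadline=None)
    def test_moiety_weighted_derivatives_cancel(self, x):
        """The reaction stoichiometry conserves receptor, ligand and PLCγ
        totals: each moiety-weighted derivative sum cancels symbolically."""
        d = pathway_derivatives(PathwayState(np.array(x)))
        scale = max(1.0, float(np.max(np.abs(d))))
        for w in MOIETY_WEIGHTS.values():
            assert abs(float(w @ d)) <= 1e-9 * scale


class TestIntegration:
    def test_hour_long_integration_conserves_moieties(self):
        out = integrate_pathway(PathwayState.initial(), duration=3600.0, dt=0.01)
        m = moiety_totals(out)
        assert m.egfr_total == pytest.approx(100.0, rel=1e-6)
        assert m.plcg_total == pytest.approx(10.0, rel=1e-6)
        assert m.tgfa_total == pytest.approx(9010.55, rel=1e-6)
        assert np.all(out.X >= 0)

    def test_zero_duration_is_identity(self):
        s = PathwayState.initial()
        out = integrate_pathway(s, duration=0.0, dt=0.01)
        assert np.array_equal(out.X, s.X) and out.t == s.t

    def test_partition_independence(self):
        whole = integrate_pathway(PathwayState.initial(), duration=60.0, dt=0.01)
        half = integrate_pathway(PathwayState.initial(), duration=30.0, dt=0.01)
        split = integrate_pathway(half, duration=30.0, dt=0.01)
        assert np.array_equal(whole.X, split.X)

    def test_step_halving_convergence_order(self):
        """Observed order of the fixed-step scheme on this system is ~4
        (asserted >= 3) during the fast initial transient."""
        ends = [
            integrate_pathway(PathwayState.initial(), duration=10.0, dt=dt).X
            for dt in (0.04, 0.02, 0.01)
        ]
        e1 = np.linalg.norm(ends[0] - ends[1])
        e2 = np.linalg.norm(ends[1] - ends[2])
        assert np.log2(e1 / e2) >= 3.0

    def test_oversized_step_raises_stiffness_error(self):
        with pytest.raises(StiffnessError, match="dt"):
            integrate_pathway(PathwayState.initial(), duration=100.0, dt=1.0)

    def test_non_multiple_duration_rejected(self):
        with pytest.raises(PathwayError, match="multiple"):
            integrate_pathway(PathwayState.initial(), duration=1.0, dt=0.3)

    def test_long_horizon_stays_nonnegative(self):
        # 100 simulated hours from the default initial conditions
        out = integrate_pathway(PathwayState.initial(), duration=360000.0, dt=0.01)
        assert np.all(out.X >= 0)
        assert moiety_totals(out).tgfa_total == pytest.approx(9010.55, rel=1e-6)


class TestBatchIntegration:
    def test_batch_matches_per_cell_loop_bitwise(self, rng):
        states = [PathwayState(np.abs(rng.normal(5, 3, size=11))) for _ in range(5)]
        batch = batch_integrate([s.copy() for s in states], duration=10.0, dt=0.05)
        for s, b in zip(states, batch):
            single = integrate_pathway(s, duration=10.0, dt=0.05)
            assert np.array_equal(single.X, b.X)

    def test_identical_inputs_identical_outputs(self):
        batch = batch_integrate([PathwayState.initial() for _ in range(3)],
                                duration=5.0, dt=0.05)
        assert np.array_equal(batch[0].X, batch[1].X)
        assert np.array_equal(batch[0].X, batch[2].X)

    def test_empty_batch_rejected(self):
        with pytest.raises(PathwayError, match="nonempty"):
            batch_integrate([], duration=1.0, dt=0.1)


class TestRateStatistic:
    def test_relative_rate_per_step(self):
        prev = state_with(X9=10.0)
        curr = state_with(X9=11.0)
        curr.t = 3600.0
        roc = percentage_rate_of_change(prev, curr)
        assert roc.rates[9] == pytest.approx(0.10)
        assert not roc.undefined[9]

    def test_unchanged_state_has_zero_rates(self):
        prev = PathwayState.initial()
        curr = prev.copy()
        curr.t = 3600.0
        roc = percentage_rate_of_change(prev, curr)
        assert np.array_equal(roc.rates, np.zeros(11))
        assert not roc.undefined.any()

    def test_growth_from_zero_is_flagged_undefined(self):
        prev = state_with()
        curr = state_with(X3=5.0)
        curr.t = 3600.0
        roc = percentage_rate_of_change(prev, curr)
        assert roc.undefined[3]
        assert roc.rates[3] == 0.0

    def test_time_ordering_required(self):
        with pytest.raises(PathwayError):
            percentage_rate_of_change(PathwayState.initial(), PathwayState.initial())


class TestPhenotypeDecision:
    @pytest.mark.parametrize(
        "rate, avg, expected",
        [
            (0.12, 0.10, Phenotype.MIGRATORY),   # strict inequality -> migrate
            (0.10, 0.10, Phenotype.PROLIFERATIVE),  # tie -> proliferate
            (-0.05, 0.0, Phenotype.PROLIFERATIVE),
        ],
    )
    def test_switch_rule_branches(self, rate, avg, expected):
        assert decide_phenotype(rate, avg) is expected

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(PathwayError):
            decide_phenotype(float("nan"), 0.0)


class TestParameters:
    def test_defaults_match_published_table(self):
        p = KineticParameters()
        assert (p.k1, p.km1, p.K4, p.V4, p.K8, p.V8) == (0.003, 0.06, 50.0, 450.0, 100.0, 1.0)
        assert PathwayState.initial().X[1] == 9010.55

    def test_nonpositive_parameter_rejected(self):
        with pytest.raises(PathwayError):
            KineticParameters(k3=0.0)

    def test_initial_moieties(self):
        m = moiety_totals(PathwayState(np.array(DEFAULT_INITIAL)))
        assert m.as_tuple() == (100.0, 10.0, 9010.55)
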