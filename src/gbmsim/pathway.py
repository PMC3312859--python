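"""Intracellular EGFR/PLCγ signaling network.

The module implements the 11-species gene–protein interaction network that
drives each tumor cell's phenotype decision: TGFα binds EGFR, the ligand–
receptor complex dimerizes and autophosphorylates, recruits and phosphorylates
PLCγ, and phosphorylated PLCγ (X9) is reversibly inactivated.  The relative
rate of change of X9 over one agent-based-model step is the statistic that
separates migratory from proliferative cells.

Species indexing (all nM except glucose X0 in mM):

====  =======================  =========================================
 i    symbol                   meaning
====  =======================  =========================================
 0    X0                       glucose (inert; carried, never reacts)
 1    X1                       TGFα (free ligand)
 2    X2                       EGFR (free receptor)
 3    X3                       TGFα–EGFR complex
 4    X4                       (TGFα–EGFR)² dimer
 5    X5                       phosphorylated dimer TGFα–EGFR-P
 6    X6                       PLCγ
 7    X7                       TGFα–EGFR–PLCγ
 8    X8                       TGFα–EGFR–PLCγ-P
 9    X9                       PLCγ-P (phosphorylated PLCγ)
10    X10                      PLCγ-P-I (inactivated PLCγ-P)
====  =======================  =========================================

Three moieties are conserved by the reaction scheme and are used as the
primary correctness oracle of the integrator:

* total EGFR   = X2 + X3 + 2·(X4 + X5 + X7 + X8)
* total PLCγ   = X6 + X7 + X8 + X9 + X10
* total TGFα   = X1 + X3 + 2·(X4 + X5 + X7 + X8)

The dimeric species (X4, X5 and the PLCγ-bound complexes derived from X5)
carry two receptors and two ligands, hence the weight 2.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

try:  # pragma: no cover - exercised implicitly by every integration test
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "N_SPECIES",
    "SPECIES_NAMES",
    "KineticParameters",
    "PathwayState",
    "ReactionRates",
    "MoietyTotals",
    "Phenotype",
    "RateOfChange",
    "reaction_rates",
    "pathway_derivatives",
    "integrate_pathway",
    "batch_integrate",
    "percentage_rate_of_change",
    "decide_phenotype",
    "moiety_totals",
    "PathwayError",
    "StiffnessError",
]

N_SPECIES = 11
SPECIES_NAMES = tuple(f"X{i}" for i in range(N_SPECIES))

#: undershoot below -CLAMP_TOL nM is treated as an integration failure rather
#: than silently zeroed
CLAMP_TOL = 1e-9


class PathwayError(ValueError):
    """Invalid pathway state or parameters."""


class StiffnessError(RuntimeError):
    """Integration diverged; retry with a smaller micro-step dt."""


class Phenotype(enum.Enum):
    MIGRATORY = "migratory"
    PROLIFERATIVE = "proliferative"
    QUIESCENT = "quiescent"
    DEAD = "dead"


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants of the EGFR network (mass action + two enzymatic steps).

    Defaults are the literature values used throughout; `k_i`/`km_i` are
    forward/reverse rates (1/s, or 1/(nM·s) for bimolecular steps), `K4`/`K8`
    Michaelis constants (nM) and `V4`/`V8` maximal enzyme rates (nM/s).
    """

    k1: float = 0.003
    km1: float = 0.06
    k2: float = 0.01
    km2: float = 0.1
    k3: float = 1.0
    km3: float = 0.01
    K4: float = 50.0
    V4: float = 450.0
    k5: float = 0.06
    km5: float = 0.2
    k6: float = 1.0
    km6: float = 0.05
    k7: float = 0.3
    km7: float = 0.006
    K8: float = 100.0
    V8: float = 1.0
    k9: float = 1.0
    km9: float = 0.03

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise PathwayError(f"kinetic parameter {f.name} must be strictly positive, got {v!r}")

    _ORDER = (
        "k1", "km1", "k2", "km2", "k3", "km3", "K4", "V4", "k5", "km5",
        "k6", "km6", "k7", "km7", "K8", "V8", "k9", "km9",
    )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self._ORDER], dtype=np.float64)

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParameters":
        unknown = set(d) - set(cls._ORDER)
        if unknown:
            raise PathwayError(f"unknown kinetic parameter(s): {sorted(unknown)}")
        return cls(**d)


#: default initial conditions: abundant free ligand, 100 nM receptor,
#: 10 nM PLCγ, all complexes empty; glucose 25 mM inert.
DEFAULT_INITIAL = (25.0, 9010.55, 100.0, 0.0, 0.0, 0.0, 10.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class PathwayState:
    """Concentration vector of one cell's EGFR network at elapsed time t (s)."""

    X: np.ndarray = field(default_factory=lambda: np.array(DEFAULT_INITIAL))
    t: float = 0.0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.shape != (N_SPECIES,):
            raise PathwayError(f"state must have {N_SPECIES} species, got shape {self.X.shape}")

    @classmethod
    def initial(cls) -> "PathwayState":
        return cls()

    def copy(self) -> "PathwayState":
        return PathwayState(self.X.copy(), self.t)

    def __getitem__(self, i: int) -> float:
        return float(self.X[i])


@dataclass(frozen=True)
class ReactionRates:
    """Instantaneous reaction velocities v1..v9 (nM/s)."""

    v: np.ndarray  # shape (9,), v[i] == v_{i+1}

    def __getattr__(self, name: str) -> float:
        if name.startswith("v") and name[1:].isdigit():
            i = int(name[1:])
            if 1 <= i <= 9:
                return float(self.v[i - 1])
        raise AttributeError(name)


@dataclass(frozen=True)
class MoietyTotals:
    egfr_total: float
    plcg_total: float
    tgfa_total: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.egfr_total, self.plcg_total, self.tgfa_total)


def moiety_totals(state: PathwayState | np.ndarray) -> MoietyTotals:
    """Conserved moiety sums (nM) of a state; constant along any trajectory."""
    x = state.X if isinstance(state, PathwayState) else np.asarray(state, dtype=float)
    dimers = x[3 + 1] + x[5] + x[7] + x[8]  # X4 + X5 + X7 + X8
    return MoietyTotals(
        egfr_total=float(x[2] + x[3] + 2.0 * dimers),
        plcg_total=float(x[6] + x[7] + x[8] + x[9] + x[10]),
        tgfa_total=float(x[1] + x[3] + 2.0 * dimers),
    )


def _check_state(x: np.ndarray) -> None:
    if not np.all(np.isfinite(x)):
        raise PathwayError("non-finite concentration in pathway state")
    if np.any(x < 0):
        i = int(np.argmin(x))
        raise PathwayError(f"negative concentration X{i} = {x[i]:g}")


def _rates_vec(x: np.ndarray, p: np.ndarray) -> np.ndarray:
    k1, km1, k2, km2, k3, km3, K4, V4, k5, km5, k6, km6, k7, km7, K8, V8, k9, km9 = p
    v = np.empty(9)
    v[0] = k1 * x[1] * x[2] - km1 * x[3]
    v[1] = k2 * x[3] * x[3] - km2 * x[4]
    v[2] = k3 * x[4] - km3 * x[5]
    v[3] = V4 * x[5] / (K4 + x[5])
    v[4] = k5 * x[5] * x[6] - km5 * x[7]
    v[5] = k6 * x[7] - km6 * x[8]
    v[6] = k7 * x[8] - km7 * x[5] * x[9]
    v[7] = V8 * x[9] / (K8 + x[9])
    v[8] = k9 * x[9] - km9 * x[10]
    return v


def _derivs_from_rates(v: np.ndarray) -> np.ndarray:
    d = np.empty(N_SPECIES)
    d[0] = 0.0  # glucose never appears in a kinetic equation
    d[1] = -v[0]
    d[2] = -v[0]
    d[3] = v[0] - 2.0 * v[1]
    d[4] = v[1] + v[3] - v[2]
    d[5] = v[2] + v[6] - v[3] - v[4]
    d[6] = v[7] - v[4]
    d[7] = v[4] - v[5]
    d[8] = v[5] - v[6]
    d[9] = v[6] - v[7] - v[8]
    d[10] = v[8]
    return d


def reaction_rates(state: PathwayState, params: KineticParameters | None = None) -> ReactionRates:
    """Instantaneous velocities of the nine reactions at `state`.

    Raises :class:`PathwayError` on negative or non-finite concentrations.
    """
    params = params or KineticParameters()
    _check_state(state.X)
    return ReactionRates(_rates_vec(state.X, params.as_array()))


def pathway_derivatives(state: PathwayState, params: KineticParameters | None = None) -> np.ndarray:
    """dX/dt (nM/s per species; glucose inert, dX0/dt = 0)."""
    params = params or KineticParameters()
    _check_state(state.X)
    return _derivs_from_rates(_rates_vec(state.X, params.as_array()))


# ---------------------------------------------------------------------------
# fixed-step RK4 integration kernel
# ---------------------------------------------------------------------------
# The kernel advances a batch of independent cells; each cell is a scalar
# loop, so a batch of one is bit-identical to the corresponding row of any
# larger batch.  Status codes: 0 ok, 1 non-finite (stiffness), 2 undershoot
# beyond the clamp tolerance.


def _rk4_kernel(X, p, n_steps, dt):  # noqa: C901 - flat numeric kernel
    k1, km1, k2, km2, k3, km3, K4, V4, k5, km5, k6, km6, k7, km7, K8, V8, k9, km9 = (
        p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7], p[8], p[9],
        p[10], p[11], p[12], p[13], p[14], p[15], p[16], p[17],
    )
    n_cells = X.shape[0]
    y = np.empty(N_SPECIES)
    d = np.empty((4, N_SPECIES))
    for c in range(n_cells):
        x = X[c]
        for _ in range(n_steps):
            for stage in range(4):
                if stage == 0:
                    for j in range(N_SPECIES):
                        y[j] = x[j]
                elif stage == 1 or stage == 2:
                    for j in range(N_SPECIES):
                        y[j] = x[j] + 0.5 * dt * d[stage - 1, j]
                else:
                    for j in range(N_SPECIES):
                        y[j] = x[j] + dt * d[2, j]
                v1 = k1 * y[1] * y[2] - km1 * y[3]
                v2 = k2 * y[3] * y[3] - km2 * y[4]
                v3 = k3 * y[4] - km3 * y[5]
                v4 = V4 * y[5] / (K4 + y[5])
                v5 = k5 * y[5] * y[6] - km5 * y[7]
                v6 = k6 * y[7] - km6 * y[8]
                v7 = k7 * y[8] - km7 * y[5] * y[9]
                v8 = V8 * y[9] / (K8 + y[9])
                v9 = k9 * y[9] - km9 * y[10]
                d[stage, 0] = 0.0
                d[stage, 1] = -v1
                d[stage, 2] = -v1
                d[stage, 3] = v1 - 2.0 * v2
                d[stage, 4] = v2 + v4 - v3
                d[stage, 5] = v3 + v7 - v4 - v5
                d[stage, 6] = v8 - v5
                d[stage, 7] = v5 - v6
                d[stage, 8] = v6 - v7
                d[stage, 9] = v7 - v8 - v9
                d[stage, 10] = v9
            for j in range(N_SPECIES):
                x[j] = x[j] + (dt / 6.0) * (d[0, j] + 2.0 * d[1, j] + 2.0 * d[2, j] + d[3, j])
                if not np.isfinite(x[j]):
                    return 1, c, j
                if x[j] < 0.0:
                    if x[j] < -CLAMP_TOL:
                        return 2, c, j
                    x[j] = 0.0
    return 0, -1, -1


if _HAVE_NUMBA:
    _rk4_kernel = numba.njit(cache=True, fastmath=False)(_rk4_kernel)


def _n_steps_for(duration: float, dt: float) -> int:
    if dt <= 0 or duration < 0:
        raise PathwayError(f"require duration >= 0 and dt > 0, got duration={duration}, dt={dt}")
    if duration == 0:
        return 0
    if dt > duration:
        raise PathwayError(f"dt={dt} exceeds duration={duration}")
    n = int(round(duration / dt))
    if abs(n * dt - duration) > 1e-9 * max(1.0, duration):
        raise PathwayError(
            f"duration {duration} is not an integer multiple of dt {dt}; "
            "partition-independence of the fixed-step scheme would be lost"
        )
    return n


def _run_kernel(X: np.ndarray, params: KineticParameters, duration: float, dt: float) -> None:
    n = _n_steps_for(duration, dt)
    if n == 0:
        return
    status, c, j = _rk4_kernel(X, params.as_array(), n, dt)
    if status == 1:
        raise StiffnessError(
            f"non-finite X{j} during integration (cell index {c}); use a smaller dt than {dt} s"
        )
    if status == 2:
        raise StiffnessError(
            f"X{j} undershot below -{CLAMP_TOL:g} nM during integration (cell index {c}); "
            f"use a smaller dt than {dt} s"
        )


def integrate_pathway(
    state: PathwayState,
    params: KineticParameters | None = None,
    duration: float = 3600.0,
    dt: float = 0.01,
) -> PathwayState:
    """Advance one cell's network by `duration` seconds of fixed-step RK4.

    Tiny negative overshoot (≤ 1e-9 nM) is clamped to zero after every step;
    anything larger, or a non-finite value, raises :class:`StiffnessError`.
    The result depends only on (state, params, dt, total duration), not on how
    the duration is split across calls.
    """
    params = params or KineticParameters()
    _check_state(state.X)
    X = state.X.copy().reshape(1, N_SPECIES)
    _run_kernel(X, params, duration, dt)
    return PathwayState(X[0], state.t + duration)


def batch_integrate(
    states: Sequence[PathwayState],
    params: KineticParameters | None = None,
    duration: float = 3600.0,
    dt: float = 0.01,
) -> list[PathwayState]:
    """Integrate many independent cells; element-wise identical to a loop of
    :func:`integrate_pathway` calls (cells do not interact inside the ODE)."""
    if len(states) == 0:
        raise PathwayError("batch_integrate requires a nonempty batch")
    params = params or KineticParameters()
    X = np.empty((len(states), N_SPECIES))
    for i, s in enumerate(states):
        _check_state(s.X)
        X[i] = s.X
    _run_kernel(X, params, duration, dt)
    return [PathwayState(X[i].copy(), s.t + duration) for i, s in enumerate(states)]


@dataclass(frozen=True)
class RateOfChange:
    """Per-species relative rates of change over one ABM step.

    `rates[i]` is (curr − prev)/prev for species i; `undefined[i]` marks
    species that grew from exactly zero, for which a relative rate does not
    exist (they are excluded from cohort averages).
    """

    rates: np.ndarray
    undefined: np.ndarray  # bool mask

    @property
    def x9(self) -> float:
        return float(self.rates[9])

    @property
    def x9_defined(self) -> bool:
        return not bool(self.undefined[9])


def percentage_rate_of_change(prev: PathwayState, curr: PathwayState, dt_step: float = 1.0) -> RateOfChange:
    """Relative per-step change of every species between two pathway states.

    `dt_step` is carried in hours for bookkeeping only: the statistic is per
    ABM step by convention, so the value is not divided by it.
    """
    if not curr.t > prev.t:
        raise PathwayError(f"require prev.t < curr.t, got {prev.t} >= {curr.t}")
    rates = np.zeros(N_SPECIES)
    undefined = np.zeros(N_SPECIES, dtype=bool)
    for i in range(N_SPECIES):
        p, c = prev.X[i], curr.X[i]
        if p > 0:
            rates[i] = (c - p) / p
        elif c > 0:
            undefined[i] = True
        # p == 0 and c == 0 -> rate 0
    return RateOfChange(rates, undefined)


def decide_phenotype(cell_rate: float, avg: float) -> Phenotype:
    """Phenotype switch rule: migrate iff the cell's PLCγ-P rate statistic
    strictly exceeds the cohort average, else proliferate."""
    if not (np.isfinite(cell_rate) and np.isfinite(avg)):
        raise PathwayError("decide_phenotype requires finite inputs")
    return Phenotype.MIGRATORY if cell_rate > avg else Phenotype.PROLIFERATIVE


# ---------------------------------------------------------------------------
# external interfaces: Table-style key/value kinetics files, trajectory CSV
# ---------------------------------------------------------------------------

def load_kinetics(path: str | Path) -> tuple[KineticParameters, PathwayState]:
    """Read kinetic constants and initial concentrations from a flat key-value
    file (`k1: 0.003`-style YAML/JSON mapping using the symbol names k1..km9,
    K4, V4, K8, V8 and X0..X10).  Missing keys keep their defaults."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise PathwayError(f"{path}: expected a flat mapping of symbols to numbers")
    kin = {k: float(v) for k, v in raw.items() if k in KineticParameters._ORDER}
    xs = {k: float(v) for k, v in raw.items() if k in SPECIES_NAMES}
    unknown = set(raw) - set(kin) - set(xs)
    if unknown:
        raise PathwayError(f"{path}: unknown symbol(s) {sorted(unknown)}")
    x = np.array(DEFAULT_INITIAL)
    for name, val in xs.items():
        x[int(name[1:])] = val
    return KineticParameters.from_dict(kin), PathwayState(x)


def export_trajectory(states: Iterable[PathwayState], path: str | Path) -> None:
    """Write a pathway trajectory as CSV with columns t,X0..X10."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["t", *SPECIES_NAMES])
        for s in states:
            w.writerow([repr(s.t), *[repr(float(v)) for v in s.X]])
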