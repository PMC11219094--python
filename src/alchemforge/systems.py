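"""Sampleable systems: the interface the replica-exchange engine drives.

A system exposes K thermodynamic states (the alchemical protocol, with or
without REST scaling) through reduced energies and forces, plus dU/dlambda
and named degree-of-freedom observables for the diagnostics workflow.
Everything runs in reduced units (kT at 300 K = 1, masses = 1), so reduced
energy and potential energy coincide and the Langevin thermostat samples
exp(-u_k(x)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .energy import (
    ElectrostaticsParams,
    LambdaProtocol,
    PairTable,
    SoftcoreParams,
    _pair_energies_and_derivs,
    _TERM_ENERGY,
    valence_term_weight,
)
from .rest import RESTConfig, RestScaling, rest_scale_factor, select_rest_region
from .topology import HybridTopology


@dataclass
class DofObservable:
    name: str
    category: str
    fn: Callable[[np.ndarray], float]


class ReplicaExchangeSystem:
    """Base interface; subclasses fill in energies and forces."""

    protocol: LambdaProtocol

    @property
    def n_states(self) -> int:
        return self.protocol.n_states

    def initial_positions(self) -> np.ndarray:
        raise NotImplementedError

    def reduced_energy(self, x: np.ndarray, k: int) -> float:
        raise NotImplementedError

    def reduced_force(self, x: np.ndarray, k: int) -> np.ndarray:
        raise NotImplementedError

    def du_dlambda(self, x: np.ndarray, k: int) -> float:
        return 0.0

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.ones(self.initial_positions().shape[0], dtype=bool)

    dof_observables: list[DofObservable]

    def register_dof(self, name: str, category: str, fn) -> None:
        if any(d.name == name for d in self.dof_observables):
            raise ValueError(f"duplicate DOF name {name!r}")
        self.dof_observables.append(DofObservable(name, category, fn))


# ---------------------------------------------------------------------------


class HarmonicLadderSystem(ReplicaExchangeSystem):
    """K one-dimensional harmonic states with analytic free energies.

    State k has potential (K_k/2)(x - c_k)^2 in reduced units; the exact
    reduced free energy is f_k = 0.5 ln(K_k) + const, so ladders provide an
    analytic oracle for the whole sampling + MBAR pipeline.
    """

    def __init__(self, spring_constants, centers=None):
        springs = np.asarray(spring_constants, dtype=float)
        if springs.ndim != 1 or springs.size < 1:
            raise ValueError("spring_constants must be a 1-D sequence")
        if np.any(springs <= 0):
            raise ValueError("spring constants must be positive")
        self.springs = springs
        self.centers = (
            np.zeros_like(springs) if centers is None else np.asarray(centers, dtype=float)
        )
        K = springs.size
        # a ladder is indexed by state, not by a continuous lambda; the
        # protocol is only used for its length when K >= 2
        lambdas = tuple(np.linspace(0.0, 1.0, K)) if K >= 2 else (0.0, 1.0)
        self.protocol = LambdaProtocol(lambdas)
        self._K = K
        self.dof_observables = []

    @property
    def n_states(self) -> int:
        return self._K

    def exact_f(self) -> np.ndarray:
        """Exact reduced free energies relative to state 0 (beta = 1)."""
        f = 0.5 * np.log(self.springs)
        return f - f[0]

    def initial_positions(self) -> np.ndarray:
        return np.array([[self.centers[0]]])

    def reduced_energy(self, x: np.ndarray, k: int) -> float:
        v = float(x[0, 0]) - self.centers[k]
        return 0.5 * self.springs[k] * v * v

    def reduced_force(self, x: np.ndarray, k: int) -> np.ndarray:
        v = float(x[0, 0]) - self.centers[k]
        return np.array([[-self.springs[k] * v]])

    def sample_state(self, k: int, n: int, rng: np.random.Generator) -> np.ndarray:
        """Exact iid draws from state k's Boltzmann distribution."""
        return rng.normal(self.centers[k], 1.0 / math.sqrt(self.springs[k]), size=n)

    def reduced_potentials(self, samples_per_state, rng=None):
        """Build (u_kn, n_k) from exact iid sampling of every state."""
        rng = rng or np.random.default_rng()
        xs = [self.sample_state(k, samples_per_state, rng) for k in range(self._K)]
        pooled = np.concatenate(xs)
        u_kn = 0.5 * self.springs[:, None] * (pooled[None, :] - self.centers[:, None]) ** 2
        n_k = np.full(self._K, samples_per_state)
        return u_kn, n_k


# ---------------------------------------------------------------------------


class PlantedSlowDofSystem(ReplicaExchangeSystem):
    """Double well with a lambda-coupled slow coordinate plus spectators.

    U(x, y; lambda) = B (x^2 - 1)^2 + lambda * c * x + sum_i (w^2/2) y_i^2

    The barrier between the wells at x = +/-1 is B kT; the linear coupling
    makes dU/dlambda = c * x exactly, so x is the planted slow degree of
    freedom and the spectator coordinates y_i are uncorrelated with
    dU/dlambda by construction.  Under REST the x-terms form the heated
    region (class rest) while spectators are nonrest, mimicking solute
    tempering of the slow coordinate.
    """

    def __init__(
        self,
        barrier_height: float,
        coupling: float,
        n_spectators: int = 3,
        n_states: int = 8,
        spectator_omega: float = 2.0,
        rest_config: RESTConfig | None = None,
    ):
        if barrier_height <= 0:
            raise ValueError("barrier_height must be > 0")
        from .energy import build_lambda_protocol

        self.barrier = float(barrier_height)
        self.coupling = float(coupling)
        self.n_spectators = int(n_spectators)
        self.omega2 = float(spectator_omega) ** 2
        self.protocol = build_lambda_protocol(n_states)
        self.rest_config = rest_config
        self.dof_observables = [
            DofObservable("planted_x", "custom", lambda x: float(x[0, 0]))
        ] + [
            DofObservable(f"spectator_{i}", "custom", _spectator_fn(i))
            for i in range(self.n_spectators)
        ]

    def _alpha(self, k: int) -> float:
        if self.rest_config is None:
            return 1.0
        return rest_scale_factor(self.protocol.lambdas[k], self.rest_config)

    def initial_positions(self) -> np.ndarray:
        x0 = np.zeros((1 + self.n_spectators, 1))
        x0[0, 0] = -1.0
        return x0

    def reduced_energy(self, x: np.ndarray, k: int) -> float:
        lam = self.protocol.lambdas[k]
        xv = float(x[0, 0])
        u_rest = self.barrier * (xv * xv - 1.0) ** 2 + lam * self.coupling * xv
        y = x[1:, 0]
        u_nonrest = 0.5 * self.omega2 * float(np.sum(y * y))
        return self._alpha(k) * u_rest + u_nonrest

    def reduced_force(self, x: np.ndarray, k: int) -> np.ndarray:
        lam = self.protocol.lambdas[k]
        xv = float(x[0, 0])
        f = np.zeros_like(x)
        f[0, 0] = -self._alpha(k) * (
            4.0 * self.barrier * xv * (xv * xv - 1.0) + lam * self.coupling
        )
        f[1:, 0] = -self.omega2 * x[1:, 0]
        return f

    def du_dlambda(self, x: np.ndarray, k: int) -> float:
        # derivative of the unscaled alchemical potential: exactly c * x
        return self.coupling * float(x[0, 0])


def _spectator_fn(i: int):
    return lambda x: float(x[1 + i, 0])


# ---------------------------------------------------------------------------


class HybridSystem(ReplicaExchangeSystem):
    """A hybrid topology made sampleable: pairwise alchemical potential,
    optional REST scaling, analytic nonbonded/bond forces (angles and
    torsions are differentiated by per-term central differences — they are
    few and local on desk-scale systems)."""

    def __init__(
        self,
        hybrid: HybridTopology,
        protocol: LambdaProtocol,
        positions0: np.ndarray,
        energy_params: ElectrostaticsParams | None = None,
        softcore: SoftcoreParams | None = None,
        rest_config: RESTConfig | None = None,
    ):
        self.hybrid = hybrid
        self.protocol = protocol
        self.positions0 = np.asarray(positions0, dtype=float)
        self.energy_params = energy_params or ElectrostaticsParams()
        self.softcore = softcore or SoftcoreParams()
        self.rest_config = rest_config
        self.pair_table = PairTable.from_topology(hybrid)
        region = (
            select_rest_region(self.positions0, hybrid, rest_config.radius)
            if rest_config is not None
            else None
        )
        self.rest_region = region
        self.scaling = RestScaling.build(hybrid, self.pair_table, region, rest_config)
        self._terms = hybrid.valence.all_terms()
        self._dummies = frozenset(
            a.index
            for a in hybrid.atoms
            if a.atom_class in ("unique_old", "unique_new")
        )
        self.dof_observables = []

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([a.is_heavy for a in self.hybrid.atoms], dtype=bool)

    def initial_positions(self) -> np.ndarray:
        return self.positions0.copy()

    # -- energies -----------------------------------------------------------

    def _nb(self, x: np.ndarray, lam: float):
        pt = self.pair_table
        d = x[pt.j] - x[pt.i]
        r = np.sqrt(np.sum(d * d, axis=1))
        u, du_dr = _pair_energies_and_derivs(pt, r, lam, self.energy_params, self.softcore)
        return d, r, u, du_dr

    def reduced_energy(self, x: np.ndarray, k: int) -> float:
        lam = self.protocol.lambdas[k]
        pair_scales, term_scales = self.scaling.scales(lam)
        u = 0.0
        if self.pair_table.i.size:
            _, _, u_pairs, _ = self._nb(x, lam)
            u = float(np.sum(u_pairs * pair_scales))
        for t, s in zip(self._terms, term_scales):
            w = valence_term_weight(t, lam, self._dummies)
            if w != 0.0:
                u += float(s) * w * _TERM_ENERGY[t.kind](x, t)
        return u

    def reduced_force(self, x: np.ndarray, k: int) -> np.ndarray:
        lam = self.protocol.lambdas[k]
        pair_scales, term_scales = self.scaling.scales(lam)
        f = np.zeros_like(x)
        pt = self.pair_table
        if pt.i.size:
            d, r, _, du_dr = self._nb(x, lam)
            g = (pair_scales * du_dr / r)[:, None] * d  # dU/dx_j direction
            np.add.at(f, pt.i, g)
            np.add.at(f, pt.j, -g)
        h = 1e-6
        for t, s in zip(self._terms, term_scales):
            w = valence_term_weight(t, lam, self._dummies)
            if w == 0.0:
                continue
            coef = float(s) * w
            if t.kind == "bond":
                i, j = t.atoms
                kb, r0 = t.params
                dv = x[j] - x[i]
                rb = float(np.linalg.norm(dv))
                if rb > 0:
                    fb = coef * kb * (rb - r0) / rb * dv
                    f[i] += fb
                    f[j] -= fb
            else:
                # central difference on the involved atoms only
                efun = _TERM_ENERGY[t.kind]
                for a in t.atoms:
                    for dim in range(x.shape[1]):
                        xp = x.copy(); xp[a, dim] += h
                        xm = x.copy(); xm[a, dim] -= h
                        f[a, dim] -= coef * (efun(xp, t) - efun(xm, t)) / (2 * h)
        return f

    def du_dlambda(self, x: np.ndarray, k: int) -> float:
        """dU/dlambda of the unscaled alchemical potential, central FD."""
        from .energy import du_dlambda as _dudl

        return _dudl(
            x,
            self.hybrid,
            self.protocol.lambdas[k],
            self.energy_params,
            self.softcore,
            pair_table=self.pair_table,
        )
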