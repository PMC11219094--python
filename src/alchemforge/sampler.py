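"""AREX/AREST replica-exchange sampling.

The engine is a Gibbs sampler over the joint distribution of replica
positions X and the permutation S of alchemical state indices: each
iteration first propagates every replica with Langevin dynamics under its
current state's Hamiltonian, then redraws the permutation by attempting
many Metropolis swaps of state-index pairs, which approximates an
independent draw of S given X and markedly improves state mixing over
neighbour-only swap schemes.  State labels move during swaps, coordinates
and velocities stay with their replica.

Propagation uses the BAOAB splitting of Langevin dynamics at the reference
temperature; in reduced units the thermostat targets exp(-u_k(x)) for the
state the replica currently holds.  An optional harmonic restraint tethers
(heavy) atoms to the initial coordinates, used by the restraint experiment
that tests whether slow protein-like motion causes poor convergence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components

from .archive import SimulationArchive
from .systems import ReplicaExchangeSystem


@dataclass
class RestraintConfig:
    """Harmonic position restraint to the initial conformation.

    ``force_constant`` in reduced energy / nm^2 (use
    ``units.kcal_per_mol_to_kt`` to convert the conventional
    kcal/(mol A^2) values).
    """

    force_constant: float
    heavy_atoms_only: bool = True


@dataclass
class SamplerConfig:
    n_iterations: int = 200
    md_steps_per_iteration: int = 10
    timestep: float = 0.01
    friction: float = 2.0
    seed: int = 0
    swap_attempts_per_iteration: int | None = None  # default K**3
    restraint: RestraintConfig | None = None
    record_interval: int = 1

    def __post_init__(self) -> None:
        for name in ("n_iterations", "md_steps_per_iteration", "record_interval"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.timestep <= 0 or self.friction <= 0:
            raise ValueError("timestep and friction must be positive")


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------


def propagate(
    positions: np.ndarray,
    velocities: np.ndarray,
    system: ReplicaExchangeSystem,
    state: int,
    md_steps: int,
    config: SamplerConfig,
    rng: np.random.Generator,
    restraint_ref: np.ndarray | None = None,
    restraint_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """BAOAB Langevin propagation under one state's potential."""
    if md_steps == 0:
        return positions, velocities
    dt = config.timestep
    c1 = math.exp(-config.friction * dt)
    c2 = math.sqrt(1.0 - c1 * c1)  # kT = 1, m = 1
    x = positions.copy()
    v = velocities.copy()

    def force(xx):
        f = system.reduced_force(xx, state)
        if restraint_ref is not None:
            kr = config.restraint.force_constant
            dev = xx - restraint_ref
            if restraint_mask is not None:
                dev = dev * restraint_mask[:, None]
            f = f - kr * dev
        if not np.all(np.isfinite(f)):
            raise FloatingPointError(
                f"non-finite force at state {state}; positions:\n{xx}"
            )
        return f

    f = force(x)
    for _ in range(md_steps):
        v += 0.5 * dt * f
        x += 0.5 * dt * v
        v = c1 * v + c2 * rng.standard_normal(v.shape)
        x += 0.5 * dt * v
        f = force(x)
        v += 0.5 * dt * f
    return x, v


def restraint_energy(
    x: np.ndarray,
    ref: np.ndarray,
    config: RestraintConfig,
    mask: np.ndarray | None,
) -> float:
    dev = x - ref
    if mask is not None:
        dev = dev * mask[:, None]
    return 0.5 * config.force_constant * float(np.sum(dev * dev))


# ---------------------------------------------------------------------------
# state permutation
# ---------------------------------------------------------------------------


def swap_log_ratio(s_i: int, s_j: int, u_row_i, u_row_j) -> float:
    """Log Metropolis ratio for exchanging the state labels of two replicas.

    ``u_row_i[l]`` is replica i's reduced potential at state l.  Returns
    -[u_{s_i}(x_j) + u_{s_j}(x_i) - u_{s_i}(x_i) - u_{s_j}(x_j)].
    """
    return -(u_row_j[s_i] + u_row_i[s_j] - u_row_i[s_i] - u_row_j[s_j])


def gibbs_permute(
    state_indices: np.ndarray,
    u_matrix: np.ndarray,
    n_attempts: int,
    rng: np.random.Generator,
    acceptance_counts: np.ndarray | None = None,
    attempt_counts: np.ndarray | None = None,
) -> np.ndarray:
    """Redraw the state permutation by many Metropolised pair swaps.

    Uniformly random (unordered) replica pairs are proposed ``n_attempts``
    times; each accepted proposal exchanges the two state labels.  The
    output is always a permutation and the update leaves the joint
    replica-exchange distribution invariant.
    """
    if n_attempts < 1:
        raise ValueError("n_attempts must be >= 1")
    K = len(state_indices)
    s = [int(v) for v in state_indices]
    if K == 1:
        return np.asarray(s)
    u = u_matrix.tolist()
    pairs_i = rng.integers(0, K, size=n_attempts)
    pairs_j = rng.integers(0, K - 1, size=n_attempts)
    logs = np.log1p(-rng.random(size=n_attempts))  # log of (0, 1]
    for a in range(n_attempts):
        i = int(pairs_i[a])
        j = int(pairs_j[a])
        if j >= i:
            j += 1  # uniform over distinct pairs
        si, sj = s[i], s[j]
        lr = -(u[j][si] + u[i][sj] - u[i][si] - u[j][sj])
        if attempt_counts is not None:
            attempt_counts[min(si, sj), max(si, sj)] += 1
        if lr >= 0.0 or logs[a] < lr:
            s[i], s[j] = sj, si
            if acceptance_counts is not None:
                acceptance_counts[min(si, sj), max(si, sj)] += 1
    return np.asarray(s)


# ---------------------------------------------------------------------------
# the full run
# ---------------------------------------------------------------------------


def run(
    system: ReplicaExchangeSystem,
    config: SamplerConfig,
    initial_positions: list[np.ndarray] | None = None,
) -> SimulationArchive:
    """Run AREX (or AREST, if the system carries REST scaling) and record.

    Deterministic given ``config.seed``: one seed sequence is split into
    per-replica propagation streams plus a swap stream.
    """
    K = system.n_states
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(K + 1)
    rep_rngs = [np.random.default_rng(c) for c in children[:K]]
    swap_rng = np.random.default_rng(children[K])

    if initial_positions is None:
        x0 = system.initial_positions()
        X = [x0.copy() for _ in range(K)]
    else:
        X = [np.asarray(p, dtype=float).copy() for p in initial_positions]
    V = [rep_rngs[k].standard_normal(X[k].shape) for k in range(K)]
    S = np.arange(K)

    restraint_ref = None
    restraint_mask = None
    if config.restraint is not None:
        restraint_ref = X[0].copy()
        if config.restraint.heavy_atoms_only:
            restraint_mask = system.heavy_mask.astype(float)

    n_attempts = config.swap_attempts_per_iteration or K**3
    acc = np.zeros((K, K), dtype=int)
    att = np.zeros((K, K), dtype=int)

    rec_u, rec_s, rec_du = [], [], []
    dof_names = [d.name for d in system.dof_observables]
    rec_dof: dict[str, list] = {n: [] for n in dof_names}

    for it in range(config.n_iterations):
        for k in range(K):
            X[k], V[k] = propagate(
                X[k],
                V[k],
                system,
                int(S[k]),
                config.md_steps_per_iteration,
                config,
                rep_rngs[k],
                restraint_ref,
                restraint_mask,
            )
        u_matrix = np.empty((K, K))
        for k in range(K):
            extra = (
                restraint_energy(X[k], restraint_ref, config.restraint, restraint_mask)
                if restraint_ref is not None
                else 0.0
            )
            for l in range(K):
                u_matrix[k, l] = system.reduced_energy(X[k], l) + extra
        S = gibbs_permute(S, u_matrix, n_attempts, swap_rng, acc, att)
        if (it + 1) % config.record_interval == 0:
            rec_u.append(u_matrix)
            rec_s.append(S.copy())
            rec_du.append([system.du_dlambda(X[k], int(S[k])) for k in range(K)])
            for d in system.dof_observables:
                rec_dof[d.name].append([d.fn(X[k]) for k in range(K)])

    archive = SimulationArchive(
        u_kln=np.array(rec_u),
        state_trace=np.array(rec_s),
        du_dl=np.array(rec_du),
        dof_traces={n: np.array(v) for n, v in rec_dof.items()},
        dof_categories={d.name: d.category for d in system.dof_observables},
        acceptance_counts=acc,
        attempt_counts=att,
        metadata={
            "seed": config.seed,
            "n_iterations": config.n_iterations,
            "md_steps_per_iteration": config.md_steps_per_iteration,
            "timestep": config.timestep,
            "friction": config.friction,
            "swap_attempts_per_iteration": n_attempts,
            "n_states": K,
            "lambdas": list(getattr(system.protocol, "lambdas", [])),
            "rest": getattr(system, "rest_config", None) is not None,
        },
    )
    archive.validate()
    return archive


# ---------------------------------------------------------------------------
# mixing diagnostics on the state trace
# ---------------------------------------------------------------------------


@dataclass
class MixingStatistics:
    transition_matrix: np.ndarray
    subdominant_eigenvalue: float
    bottleneck: bool
    reducible: bool
    min_adjacent_rate: float


def mixing_statistics(state_trace: np.ndarray, floor: float = 0.01) -> MixingStatistics:
    """Empirical state-transition statistics from replica trajectories.

    Builds the row-stochastic transition matrix of consecutive recorded
    state indices pooled over replicas, reports the magnitude of its
    subdominant eigenvalue, and flags a bottleneck when the matrix is
    reducible or when any adjacent-state pair exchanges at an empirical
    rate below ``floor``.
    """
    st = np.asarray(state_trace, dtype=int)
    if st.ndim != 2 or st.shape[0] < 2:
        raise ValueError("need at least 2 recorded iterations")
    n, K = st.shape
    counts = np.zeros((K, K))
    np.add.at(counts, (st[:-1].ravel(), st[1:].ravel()), 1)
    row = counts.sum(axis=1, keepdims=True)
    T = np.divide(counts, row, out=np.zeros_like(counts), where=row > 0)
    # rows for never-left states stay as self-loops
    for k in range(K):
        if row[k, 0] == 0:
            T[k, k] = 1.0
    ev = np.sort(np.abs(np.linalg.eigvals(T)))[::-1]
    sub = float(ev[1]) if K > 1 else 0.0
    sym = counts + counts.T
    n_comp, _ = connected_components((sym > 0).astype(int), directed=False)
    reducible = n_comp > 1
    if K > 1:
        adj = [
            (counts[k, k + 1] + counts[k + 1, k]) / max(1.0, row[k, 0] + row[k + 1, 0])
            for k in range(K - 1)
        ]
        min_adj = float(min(adj))
    else:
        min_adj = 1.0
    bottleneck = reducible or min_adj < floor
    return MixingStatistics(T, sub, bottleneck, reducible, min_adj)
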