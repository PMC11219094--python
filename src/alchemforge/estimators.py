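"""Free energy estimation with MBAR.

The multistate Bennett acceptance ratio (MBAR) estimator solves the
self-consistent equations

    f_k = -ln sum_n exp(-u_k(x_n)) / sum_j N_j exp(f_j - u_j(x_n))

for the reduced free energies f_k of K states given the reduced potential
of every pooled sample evaluated at every state.  The solver minimises the
equivalent convex objective with BFGS and polishes by self-consistent
iteration to a max-norm tolerance; the gauge is f_0 = 0.

Uncertainties come from bootstrap: samples are resampled with replacement
within each state block of the (already decorrelated) dataset and MBAR is
re-solved per replicate.  Convergence of a run is judged on the "DG time
series": the estimate recomputed on growing data prefixes, whose trailing
slope should be statistically indistinguishable from zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import linregress

from .archive import SimulationArchive
from .units import KT_IN_KCAL_PER_MOL


class MBARConvergenceError(RuntimeError):
    def __init__(self, residual: float, max_iter: int):
        super().__init__(
            f"MBAR did not converge after {max_iter} iterations (residual {residual:.3g})"
        )
        self.residual = residual


@dataclass
class ReducedPotentialDataset:
    """Pooled decorrelated samples: ``u_kn[k, n]`` is sample n at state k."""

    u_kn: np.ndarray
    n_k: np.ndarray
    decorrelation_g: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.u_kn = np.asarray(self.u_kn, dtype=float)
        self.n_k = np.asarray(self.n_k, dtype=int)
        if self.u_kn.ndim != 2:
            raise ValueError("u_kn must be 2-D (K x N)")
        if int(self.n_k.sum()) != self.u_kn.shape[1]:
            raise ValueError("sum(n_k) must equal the number of pooled samples")
        if not np.all(np.isfinite(self.u_kn)):
            raise ValueError("non-finite reduced potentials")

    @property
    def n_states(self) -> int:
        return self.u_kn.shape[0]

    def state_blocks(self) -> list[slice]:
        edges = np.concatenate([[0], np.cumsum(self.n_k)])
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


@dataclass
class FreeEnergyEstimate:
    """Reduced state free energies with bootstrap uncertainty.

    ``delta_g`` is f_{K-1} - f_0 in the units given by ``units`` ("kT"
    internally; convert with :attr:`delta_g_kcal_mol` for reports).
    """

    f_k: np.ndarray
    delta_g: float
    sigma: float
    n_bootstrap: int
    ci95: tuple[float, float]
    units: str = "kT"
    n_effective: int = 0

    @property
    def delta_g_kcal_mol(self) -> float:
        if self.units == "kcal/mol":
            return self.delta_g
        return self.delta_g * KT_IN_KCAL_PER_MOL


@dataclass
class DeltaDeltaG:
    ddg: float
    sigma: float
    phase_estimates: tuple[FreeEnergyEstimate, FreeEnergyEstimate]
    units: str = "kT"

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.ddg - 1.96 * self.sigma, self.ddg + 1.96 * self.sigma)


# ---------------------------------------------------------------------------
# MBAR core
# ---------------------------------------------------------------------------


def mbar_solve(
    dataset: ReducedPotentialDataset,
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> np.ndarray:
    """Solve the MBAR self-consistent equations; returns f_k with f_0 = 0."""
    if tol <= 0:
        raise ValueError("tol must be > 0")
    u_kn, n_k = dataset.u_kn, dataset.n_k
    K, N = u_kn.shape
    if np.any(n_k <= 0):
        raise ValueError("every state must contribute samples")
    if K == 1:
        return np.zeros(1)
    log_n = np.log(n_k)

    def sc_update(f):
        # log denominator per sample: logsumexp_j [log N_j + f_j - u_jn]
        log_denom = logsumexp(log_n[:, None] + f[:, None] - u_kn, axis=0)
        f_new = -logsumexp(-u_kn - log_denom[None, :], axis=1)
        return f_new - f_new[0]

    # convex objective (free energies of the mixture distribution)
    n_tot = float(N)

    def objective(f):
        log_denom = logsumexp(log_n[:, None] + f[:, None] - u_kn, axis=0)
        return float(np.sum(log_denom) / n_tot + np.dot(n_k, -f) / n_tot)

    def gradient(f):
        log_denom = logsumexp(log_n[:, None] + f[:, None] - u_kn, axis=0)
        w = np.exp(log_n[:, None] + f[:, None] - u_kn - log_denom[None, :])
        return (w.sum(axis=1) - n_k) / n_tot

    f0 = np.zeros(K)
    res = minimize(objective, f0, jac=gradient, method="L-BFGS-B", options={"maxiter": 1000})
    f = res.x - res.x[0]
    residual = np.inf
    for _ in range(max_iter):
        f_new = sc_update(f)
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        if residual < tol:
            return f
    raise MBARConvergenceError(residual, max_iter)


# ---------------------------------------------------------------------------
# decorrelation
# ---------------------------------------------------------------------------


def subsample_decorrelated(data, g: float):
    """Keep indices 0, ceil(g), 2 ceil(g), ... along the first axis."""
    if g < 1:
        raise ValueError("g must be >= 1")
    data = np.asarray(data)
    n = data.shape[0]
    if g > n / 2:
        raise ValueError(f"g={g} too large for {n} samples (needs g <= n/2)")
    stride = int(np.ceil(g))
    return data[np.arange(0, n, stride)]


def dataset_from_archive(
    archive: SimulationArchive,
    equilibration: int = 0,
    decorrelate: bool = True,
) -> ReducedPotentialDataset:
    """Regroup a replica-exchange archive into MBAR input.

    Samples are attributed to the state their replica occupied when
    recorded.  Per state, the statistical inefficiency of the reduced
    potential at the generating state is estimated and the state's samples
    are subsampled at that stride before pooling.
    """
    from .diagnostics import statistical_inefficiency

    n, K, _ = archive.u_kln.shape
    if equilibration >= n:
        raise ValueError("equilibration discards the whole archive")
    u_kln = archive.u_kln[equilibration:]
    st = archive.state_trace[equilibration:]

    cols: list[np.ndarray] = []
    n_k = np.zeros(K, dtype=int)
    gs = np.ones(K)
    for s in range(K):
        iters, reps = np.where(st == s)
        if iters.size == 0:
            raise ValueError(f"state {s} contributed no samples")
        order = np.argsort(iters, kind="stable")
        rows = u_kln[iters[order], reps[order], :]  # (n_s, K)
        own = rows[:, s]
        if decorrelate and own.size >= 4 and np.std(own) > 0:
            gs[s] = statistical_inefficiency(own).g
            if own.size / np.ceil(gs[s]) >= 2:
                rows = subsample_decorrelated(rows, gs[s])
        cols.append(rows)
        n_k[s] = rows.shape[0]
    u_kn = np.concatenate(cols, axis=0).T
    return ReducedPotentialDataset(u_kn=u_kn, n_k=n_k, decorrelation_g=gs)


# ---------------------------------------------------------------------------
# bootstrap and estimates
# ---------------------------------------------------------------------------


def bootstrap_delta_g(
    dataset: ReducedPotentialDataset,
    n_boot: int = 200,
    seed: int | np.random.Generator = 0,
    tol: float = 1e-8,
) -> tuple[float, tuple[float, float], int]:
    """Bootstrap sigma and 95% CI of DG = f_{K-1} - f_0.

    Columns are resampled with replacement within each state block and
    MBAR re-solved per replicate; a failed replicate is retried once with
    fresh draws, then dropped.  Returns (sigma, ci95, n_dropped).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    blocks = dataset.state_blocks()
    reps = []
    dropped = 0
    for _ in range(n_boot):
        for attempt in range(2):
            idx = np.concatenate(
                [rng.integers(b.start, b.stop, size=b.stop - b.start) for b in blocks]
            )
            boot = ReducedPotentialDataset(dataset.u_kn[:, idx], dataset.n_k)
            try:
                f = mbar_solve(boot, tol=tol)
                reps.append(f[-1] - f[0])
                break
            except MBARConvergenceError:
                if attempt == 1:
                    dropped += 1
    if not reps:
        raise MBARConvergenceError(np.nan, 0)
    reps = np.asarray(reps)
    sigma = float(np.std(reps, ddof=1)) if reps.size > 1 else 0.0
    ci = (float(np.percentile(reps, 2.5)), float(np.percentile(reps, 97.5)))
    return sigma, ci, dropped


def estimate_free_energy(
    dataset: ReducedPotentialDataset,
    n_boot: int = 200,
    seed: int = 0,
    tol: float = 1e-10,
) -> FreeEnergyEstimate:
    """Point estimate plus bootstrap uncertainty for one phase."""
    f = mbar_solve(dataset, tol=tol)
    if n_boot > 0:
        sigma, ci, _ = bootstrap_delta_g(dataset, n_boot=n_boot, seed=seed)
    else:
        sigma, ci = 0.0, (float(f[-1]), float(f[-1]))
    return FreeEnergyEstimate(
        f_k=f,
        delta_g=float(f[-1] - f[0]),
        sigma=sigma,
        n_bootstrap=n_boot,
        ci95=ci,
        units="kT",
        n_effective=int(dataset.n_k.sum()),
    )


# ---------------------------------------------------------------------------
# convergence analysis
# ---------------------------------------------------------------------------


@dataclass
class DeltaGTimeSeries:
    """DG estimated on growing prefixes of an archive."""

    times: np.ndarray  # prefix lengths, in iterations
    values: np.ndarray  # reduced units
    sigmas: np.ndarray
    units: str = "kT"


def delta_g_time_series(
    archive: SimulationArchive,
    n_points: int = 10,
    n_boot: int = 50,
    seed: int = 0,
    equilibration: int = 0,
) -> DeltaGTimeSeries:
    """DG(t): the full estimator re-run on growing data prefixes.

    The last point uses the complete archive and therefore equals the
    standalone full-data estimate exactly.
    """
    n = archive.n_iterations
    if n < n_points:
        raise ValueError(f"archive has {n} iterations but {n_points} points requested")
    lo = min(n, max(equilibration + 2, int(np.ceil(n / n_points))))
    lengths = np.unique(np.linspace(lo, n, n_points).astype(int))
    lengths[-1] = n  # the last point always uses the complete archive
    times, values, sigmas = [], [], []
    for m in lengths:
        ds = dataset_from_archive(archive.truncated(int(m)), equilibration=equilibration)
        est = estimate_free_energy(ds, n_boot=n_boot, seed=seed)
        times.append(m)
        values.append(est.delta_g)
        sigmas.append(est.sigma)
    return DeltaGTimeSeries(np.array(times, dtype=float), np.array(values), np.array(sigmas))


def slope_last_window(
    series: DeltaGTimeSeries, window_fraction: float = 0.5
) -> tuple[float, float]:
    """OLS slope of the trailing window of DG(t), with its 2-SE uncertainty."""
    if not 0 < window_fraction <= 1:
        raise ValueError("window_fraction must be in (0, 1]")
    n = len(series.times)
    start = int(np.floor(n * (1 - window_fraction)))
    if n - start < 3:
        start = max(0, n - 3)
    if n - start < 3:
        raise ValueError("need at least 3 points in the trailing window")
    t, y = series.times[start:], series.values[start:]
    res = linregress(t, y)
    return float(res.slope), float(2.0 * res.stderr)


def combine_ddg(
    phase_a: FreeEnergyEstimate, phase_b: FreeEnergyEstimate
) -> DeltaDeltaG:
    """DDG = DG_b - DG_a with uncertainties added in quadrature.

    For a binding calculation phase_a is apo and phase_b is complex, so the
    result is the change in binding free energy.
    """
    if phase_a.units != phase_b.units:
        raise ValueError(f"unit mismatch: {phase_a.units} vs {phase_b.units}")
    ddg = phase_b.delta_g - phase_a.delta_g
    sigma = float(np.hypot(phase_a.sigma, phase_b.sigma))
    return DeltaDeltaG(float(ddg), sigma, (phase_a, phase_b), units=phase_a.units)
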