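"""Sampling-problem identification workflow.

Given a replica-exchange archive, the diagnostics answer, in order:

1. Did the free energy converge?  The trailing slope of the DG(t) series
   must be statistically indistinguishable from zero (0 +/- threshold).
2. Are forward and reverse transformations internally consistent?  The
   forward DDG and the negated reverse DDG must agree within the stated
   tolerance of each other's 95% CI.
3. Do replicas mix across alchemical states (no bottleneck)?
4. Which degrees of freedom are slow?  The statistical inefficiency
   g = 2 tau + 1 of dU/dlambda flags slowly-varying runs; the Pearson
   correlation (PCC) between dU/dlambda and each catalogued degree of
   freedom — sidechain/backbone torsions, residue contacts, nearby waters
   — averaged over replicas via Fisher z, points at the coupled slow
   coordinate.  The category report tabulates, per category, the largest
   |PCC| and the responsible observable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .archive import SimulationArchive

DOF_CATEGORIES = (
    "backbone_torsion",
    "sidechain_torsion",
    "intra_contact",
    "inter_contact",
    "neighboring_waters",
    "custom",
)


# ---------------------------------------------------------------------------
# statistical inefficiency
# ---------------------------------------------------------------------------


@dataclass
class StatisticalInefficiency:
    """g = 2 tau + 1 in samples; ``g_time`` converts to time units.

    When g_time equals the sampling interval the samples are completely
    decorrelated; larger values mean proportionally fewer independent
    samples.
    """

    g: float
    tau: float
    sampling_interval: float = 1.0

    @property
    def g_time(self) -> float:
        return self.g * self.sampling_interval


def statistical_inefficiency(
    series, sampling_interval: float = 1.0
) -> StatisticalInefficiency:
    """Autocorrelation-based statistical inefficiency of a time series.

    tau = sum_{t>=1} (1 - t/N) rho(t), accumulated until the first
    non-positive autocorrelation (initial-positive-sequence truncation);
    g = 1 + 2 tau, floored at 1.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("need a 1-D series of length >= 4")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in series")
    n = x.size
    x = x - x.mean()
    var = float(np.dot(x, x) / n)
    if var == 0.0:
        raise ValueError("series has zero variance")
    # FFT autocovariance
    m = 1 << (2 * n - 1).bit_length()
    fx = np.fft.rfft(x, m)
    acov = np.fft.irfft(fx * np.conj(fx), m)[:n] / n
    rho = acov / var
    tau = 0.0
    for t in range(1, n):
        if rho[t] <= 0.0:
            break
        tau += (1.0 - t / n) * rho[t]
    g = max(1.0, 1.0 + 2.0 * tau)
    return StatisticalInefficiency(g=g, tau=tau, sampling_interval=sampling_interval)


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    pcc: float
    ci95: tuple[float, float]
    n_effective: int
    per_replica_pccs: list[float] = field(default_factory=list)


_Z_CLIP = 1.0 - 1e-12


def _fisher_ci(r: float, n_eff: int) -> tuple[float, float]:
    if n_eff <= 3:
        return (-1.0, 1.0)
    z = math.atanh(max(-_Z_CLIP, min(_Z_CLIP, r)))
    se = 1.0 / math.sqrt(n_eff - 3)
    return (math.tanh(z - 1.96 * se), math.tanh(z + 1.96 * se))


def pcc_with_ci(x_series, y_series) -> CorrelationResult:
    """Pearson r with a Fisher-z 95% CI at autocorrelation-reduced n.

    The effective sample size is n / g_max with g_max the larger
    statistical inefficiency of the two series, so strongly autocorrelated
    series get appropriately wide intervals.
    """
    x = np.asarray(x_series, dtype=float)
    y = np.asarray(y_series, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need equal-length 1-D series of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance series")
    r = float(stats.pearsonr(x, y).statistic)
    g = 1.0
    if x.size >= 4:
        g = max(statistical_inefficiency(x).g, statistical_inefficiency(y).g)
    n_eff = max(1, int(x.size / g))
    return CorrelationResult(pcc=r, ci95=_fisher_ci(r, n_eff), n_effective=n_eff)


def replica_averaged_pcc(du_dl_per_replica, dof_per_replica) -> CorrelationResult:
    """Per-replica PCCs combined by Fisher-z averaging.

    Replicas whose series have zero variance are skipped (with all skipped
    being an error); the combined CI uses the summed effective sample size.
    """
    rs, n_effs = [], []
    n_rep = len(du_dl_per_replica)
    if n_rep == 0 or len(dof_per_replica) != n_rep:
        raise ValueError("need aligned, non-empty per-replica series")
    for xr, yr in zip(du_dl_per_replica, dof_per_replica):
        try:
            res = pcc_with_ci(xr, yr)
        except ValueError:
            continue
        rs.append(res.pcc)
        n_effs.append(res.n_effective)
    if not rs:
        raise ValueError("all replicas had zero-variance series")
    zs = np.arctanh(np.clip(rs, -_Z_CLIP, _Z_CLIP))
    r_bar = float(np.tanh(np.mean(zs)))
    n_eff = int(np.sum(n_effs))
    return CorrelationResult(
        pcc=r_bar, ci95=_fisher_ci(r_bar, n_eff), n_effective=n_eff, per_replica_pccs=rs
    )


# ---------------------------------------------------------------------------
# geometric observables
# ---------------------------------------------------------------------------


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed dihedral in degrees, in (-180, 180], IUPAC sign convention."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12 or nb2 < 1e-12:
        raise ValueError("collinear points: dihedral undefined")
    y = float(np.dot(np.cross(n1, n2), b2 / nb2))
    x = float(np.dot(n1, n2))
    phi = math.degrees(math.atan2(y, x))
    if phi <= -180.0:
        phi += 360.0
    return phi


def min_pair_distance(coords, group_a, group_b) -> float:
    """Minimum Euclidean cross-pair distance between two atom groups."""
    coords = np.asarray(coords, dtype=float)
    a = np.fromiter(group_a, dtype=int)
    b = np.fromiter(group_b, dtype=int)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    if np.intersect1d(a, b).size:
        raise ValueError("groups must be disjoint")
    d = coords[a][:, None, :] - coords[b][None, :, :]
    return float(np.min(np.sqrt(np.sum(d * d, axis=2))))


def count_within_radius(coords, center_group, candidate_group, radius: float) -> int:
    """Candidates whose minimum distance to the center group is <= radius."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    coords = np.asarray(coords, dtype=float)
    c = np.fromiter(center_group, dtype=int)
    cand = np.fromiter(candidate_group, dtype=int)
    if cand.size == 0:
        return 0
    d = coords[cand][:, None, :] - coords[c][None, :, :]
    dmin = np.min(np.sqrt(np.sum(d * d, axis=2)), axis=1)
    return int(np.sum(dmin <= radius))


def unwrap_angles(series_deg: np.ndarray) -> np.ndarray:
    """Shortest-path continuity unwrapping of an angle series in degrees."""
    return np.degrees(np.unwrap(np.radians(np.asarray(series_deg, dtype=float))))


# ---------------------------------------------------------------------------
# verdicts
# ---------------------------------------------------------------------------


def convergence_verdict(slope: float, two_se: float, threshold: float = 0.1) -> bool:
    """Flat-slope test: converged iff slope +/- 2SE intersects [-thr, thr]."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    lo, hi = slope - two_se, slope + two_se
    return lo <= threshold and hi >= -threshold


def internal_consistency_verdict(fwd, rev, tolerance: float = 1.0):
    """Forward vs negated-reverse agreement check.

    ``fwd`` and ``rev`` carry ``ddg`` (or ``delta_g``) and a 95% CI.  The
    pair is *inconsistent* only when the forward value lies more than
    ``tolerance`` outside the negated reverse CI AND the negated reverse
    value lies more than ``tolerance`` outside the forward CI; the
    discrepancy fwd + rev is returned alongside.
    """

    def _value_ci(est):
        v = getattr(est, "ddg", None)
        if v is None:
            v = est.delta_g
        return float(v), tuple(est.ci95)

    v_f, ci_f = _value_ci(fwd)
    v_r, ci_r = _value_ci(rev)
    neg_r = -v_r
    neg_ci_r = (-ci_r[1], -ci_r[0])

    def outside(value, ci):
        if value < ci[0]:
            return ci[0] - value
        if value > ci[1]:
            return value - ci[1]
        return 0.0

    inconsistent = (
        outside(v_f, neg_ci_r) > tolerance and outside(neg_r, ci_f) > tolerance
    )
    return (not inconsistent), v_f + v_r


# ---------------------------------------------------------------------------
# the category report
# ---------------------------------------------------------------------------


@dataclass
class DofCatalogEntry:
    name: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in DOF_CATEGORIES:
            raise ValueError(f"unknown DOF category {self.category!r}")


@dataclass
class DofCatalog:
    entries: list[DofCatalogEntry]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate DOF names in catalog")

    @classmethod
    def from_archive(cls, archive: SimulationArchive) -> "DofCatalog":
        return cls(
            [
                DofCatalogEntry(name, archive.dof_categories.get(name, "custom"))
                for name in archive.dof_traces
            ]
        )


@dataclass
class CategoryRow:
    category: str
    max_abs_pcc: float | None
    ci95: tuple[float, float] | None
    argmax_dof: str | None


@dataclass
class DiagnosticsReport:
    converged: bool | None
    slope: float | None
    slope_two_se: float | None
    mixing_bottleneck: bool
    min_adjacent_rate: float
    du_dl_g: float | None
    category_table: list[CategoryRow]
    degenerate_du_dl: bool
    internal_consistency: tuple[bool, float] | None = None

    def to_json(self, path) -> None:
        d = {
            "converged": self.converged,
            "slope": self.slope,
            "slope_two_se": self.slope_two_se,
            "mixing_bottleneck": self.mixing_bottleneck,
            "min_adjacent_rate": self.min_adjacent_rate,
            "du_dl_g": self.du_dl_g,
            "degenerate_du_dl": self.degenerate_du_dl,
            "internal_consistency": self.internal_consistency,
            "category_table": [
                {
                    "category": r.category,
                    "max_abs_pcc": r.max_abs_pcc,
                    "ci95": r.ci95,
                    "argmax_dof": r.argmax_dof,
                }
                for r in self.category_table
            ],
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    def category_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "category": r.category,
                    "max_abs_pcc": r.max_abs_pcc,
                    "ci_low": r.ci95[0] if r.ci95 else None,
                    "ci_high": r.ci95[1] if r.ci95 else None,
                    "argmax_dof": r.argmax_dof,
                }
                for r in self.category_table
            ]
        )


def slow_dof_report(
    archive: SimulationArchive,
    catalog: DofCatalog | None = None,
    convergence_threshold: float = 0.1,
    n_time_points: int = 8,
    n_boot: int = 30,
    seed: int = 0,
    compute_convergence: bool = True,
) -> DiagnosticsReport:
    """Full diagnostics: convergence, mixing, dU/dlambda inefficiency and
    the per-category max-|PCC| table identifying candidate slow DOFs."""
    from .estimators import delta_g_time_series, slope_last_window
    from .sampler import mixing_statistics

    catalog = catalog or DofCatalog.from_archive(archive)
    for e in catalog.entries:
        if e.name not in archive.dof_traces:
            raise KeyError(f"catalog observable {e.name!r} missing from archive")

    K = archive.n_states
    du_cols = [archive.du_dl[:, k] for k in range(K)]
    degenerate = all(np.std(c) == 0 for c in du_cols)

    du_g = None
    if not degenerate:
        gs = [
            statistical_inefficiency(c).g for c in du_cols if np.std(c) > 0 and c.size >= 4
        ]
        du_g = float(np.mean(gs)) if gs else None

    rows: list[CategoryRow] = []
    for cat in DOF_CATEGORIES:
        names = [e.name for e in catalog.entries if e.category == cat]
        if not names:
            continue
        best: tuple[float, CorrelationResult, str] | None = None
        for name in names:
            dof_cols = [archive.dof_traces[name][:, k] for k in range(K)]
            if degenerate:
                continue
            try:
                res = replica_averaged_pcc(du_cols, dof_cols)
            except ValueError:
                continue
            if best is None or abs(res.pcc) > best[0]:
                best = (abs(res.pcc), res, name)
        if degenerate or best is None:
            rows.append(CategoryRow(cat, None, None, None))
        else:
            rows.append(CategoryRow(cat, best[0], best[1].ci95, best[2]))

    mix = mixing_statistics(archive.state_trace)

    converged = slope = two_se = None
    if compute_convergence and archive.n_iterations >= n_time_points:
        series = delta_g_time_series(
            archive, n_points=n_time_points, n_boot=n_boot, seed=seed
        )
        slope, two_se = slope_last_window(series)
        converged = convergence_verdict(slope, two_se, convergence_threshold)

    return DiagnosticsReport(
        converged=converged,
        slope=slope,
        slope_two_se=two_se,
        mixing_bottleneck=mix.bottleneck,
        min_adjacent_rate=mix.min_adjacent_rate,
        du_dl_g=du_g,
        category_table=rows,
        degenerate_du_dl=degenerate,
    )


def order_reports_by_inefficiency(
    reports: dict[str, DiagnosticsReport]
) -> list[tuple[str, DiagnosticsReport]]:
    """Order labelled reports from highest to lowest dU/dlambda inefficiency,
    the presentation convention for multi-run category heatmaps."""
    return sorted(
        reports.items(),
        key=lambda kv: (kv[1].du_dl_g is None, -(kv[1].du_dl_g or 0.0)),
    )
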