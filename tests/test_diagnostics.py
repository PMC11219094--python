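"""Diagnostics: inefficiency, correlations, geometry, verdicts, reports."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from alchemforge.diagnostics import (
    DofCatalog,
    DofCatalogEntry,
    convergence_verdict,
    count_within_radius,
    dihedral_angle,
    internal_consistency_verdict,
    min_pair_distance,
    order_reports_by_inefficiency,
    pcc_with_ci,
    replica_averaged_pcc,
    slow_dof_report,
    statistical_inefficiency,
)
from alchemforge.estimators import DeltaDeltaG, FreeEnergyEstimate
from alchemforge.sampler import SamplerConfig, run
from alchemforge.systems import PlantedSlowDofSystem


def ar1(phi, n, rng, sigma=1.0):
    x = np.empty(n)
    x[0] = rng.normal()
    noise = rng.normal(0, sigma, size=n)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + noise[i]
    return x


class TestStatisticalInefficiency:
    def test_white_noise_is_unit(self, rng):
        g = statistical_inefficiency(rng.standard_normal(10_000)).g
        assert g == pytest.approx(1.0, abs=0.1)

    @pytest.mark.parametrize("phi", [0.5, 0.9])
    def test_ar1_matches_analytic(self, phi, rng):
        """AR(1): g = (1 + phi) / (1 - phi)."""
        x = ar1(phi, 100_000, rng)
        g = statistical_inefficiency(x).g
        assert g == pytest.approx((1 + phi) / (1 - phi), rel=0.25)

    def test_g_time_reports_decorrelation_scale(self, rng):
        r = statistical_inefficiency(rng.standard_normal(5000), sampling_interval=0.1)
        # iid samples at 0.1 time units: g_time at the sampling interval
        assert r.g_time == pytest.approx(0.1, abs=0.02)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            statistical_inefficiency(np.ones(100))

    def test_g_floor_and_tau_relation(self, rng):
        r = statistical_inefficiency(rng.standard_normal(2000))
        assert r.g >= 1.0
        assert r.g == pytest.approx(max(1.0, 1 + 2 * r.tau))


class TestPCC:
    def test_perfect_correlation(self, rng):
        x = rng.standard_normal(100)
        assert pcc_with_ci(x, x).pcc == pytest.approx(1.0)

    def test_affine_anticorrelation(self, rng):
        x = rng.standard_normal(100)
        assert pcc_with_ci(x, -2 * x + 7).pcc == pytest.approx(-1.0)

    def test_null_pair_small_and_ci_covers_zero(self, rng):
        hits = 0
        trials = 200
        for _ in range(trials):
            x, y = rng.standard_normal((2, 1000))
            res = pcc_with_ci(x, y)
            assert abs(res.pcc) < 0.15
            if res.ci95[0] <= 0.0 <= res.ci95[1]:
                hits += 1
        assert hits / trials >= 0.9

    @given(seed=st.integers(0, 10_000))
    def test_bounds_respected(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal((2, 50))
        res = pcc_with_ci(x, y)
        assert -1.0 <= res.pcc <= 1.0
        assert res.ci95[0] <= res.pcc <= res.ci95[1]

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(ValueError):
            pcc_with_ci(np.ones(10), rng.standard_normal(10))


class TestReplicaAveragedPCC:
    def test_identical_replicas_equal_single(self, rng):
        x = rng.standard_normal(500)
        y = 0.7 * x + rng.standard_normal(500)
        single = pcc_with_ci(x, y).pcc
        combined = replica_averaged_pcc([x, x, x], [y, y, y])
        assert combined.pcc == pytest.approx(single, abs=1e-12)
        assert len(combined.per_replica_pccs) == 3

    def test_symmetric_pccs_cancel(self, rng):
        x = rng.standard_normal(800)
        noise = rng.standard_normal(800)
        y_pos = 0.6 * x + noise
        combined = replica_averaged_pcc([x, x], [y_pos, -y_pos])
        assert combined.pcc == pytest.approx(0.0, abs=1e-10)

    def test_zero_variance_replicas_skipped(self, rng):
        x = rng.standard_normal(100)
        y = 0.5 * x + rng.standard_normal(100)
        res = replica_averaged_pcc([x, np.ones(100)], [y, np.ones(100)])
        assert len(res.per_replica_pccs) == 1
        with pytest.raises(ValueError):
            replica_averaged_pcc([np.ones(100)], [np.ones(100)])


class TestGeometry:
    def test_planar_cis_is_zero(self):
        assert dihedral_angle((0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)) == pytest.approx(0.0)

    def test_planar_trans_is_180(self):
        phi = dihedral_angle((0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 1, 0))
        assert abs(phi) == pytest.approx(180.0)

    def test_right_handed_quarter_turn_sign(self):
        phi = dihedral_angle((0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1))
        assert phi == pytest.approx(90.0)

    def test_collinear_rejected(self):
        with pytest.raises(ValueError):
            dihedral_angle((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))

    def test_min_pair_distance_singletons(self):
        coords = np.array([[0.0, 0, 0], [0.5, 0, 0]])
        assert min_pair_distance(coords, [0], [1]) == pytest.approx(0.5)

    def test_min_pair_distance_matches_exhaustive_scan(self, rng):
        coords = rng.standard_normal((6, 3))
        a, b = [0, 1, 2], [3, 4, 5]
        brute = min(np.linalg.norm(coords[i] - coords[j]) for i in a for j in b)
        assert min_pair_distance(coords, a, b) == pytest.approx(brute)

    def test_count_within_radius_grid_shells(self):
        # candidates on a 1-D grid at distances 1..5 from the center
        coords = np.array([[0.0, 0, 0]] + [[float(d), 0, 0] for d in range(1, 6)])
        n = count_within_radius(coords, [0], [1, 2, 3, 4, 5], radius=3.0)
        assert n == 3  # boundary inclusive: distances 1, 2, 3

    def test_count_within_radius_empty_candidates(self):
        assert count_within_radius(np.zeros((1, 3)), [0], [], 1.0) == 0


class TestVerdicts:
    def test_flat_slope_converged(self):
        assert convergence_verdict(0.0, 0.05, threshold=0.1)

    def test_clear_drift_not_converged(self):
        assert not convergence_verdict(0.3, 0.05, threshold=0.1)

    def test_interval_reaching_band_converged(self):
        assert convergence_verdict(0.15, 0.06, threshold=0.1)  # reaches 0.09

    def _ddg(self, v, lo, hi):
        est = FreeEnergyEstimate(np.array([0.0, v]), v, 0.1, 0, (lo, hi))
        return DeltaDeltaG(v, 0.1, (est, est))

    def test_consistent_forward_reverse_pair(self):
        ok, disc = internal_consistency_verdict(
            self._ddg(2.0, 1.5, 2.5), self._ddg(-2.1, -2.6, -1.6)
        )
        assert ok and disc == pytest.approx(-0.1)

    def test_zero_pair_trivially_consistent(self):
        ok, disc = internal_consistency_verdict(
            self._ddg(0.0, -0.5, 0.5), self._ddg(0.0, -0.5, 0.5)
        )
        assert ok and disc == 0.0

    def test_grossly_discrepant_pair_flagged(self):
        ok, disc = internal_consistency_verdict(
            self._ddg(5.0, 4.8, 5.2), self._ddg(-1.0, -1.2, -0.8)
        )
        assert not ok and disc == pytest.approx(4.0)


@pytest.fixture(scope="module")
def planted_archive():
    sys_ = PlantedSlowDofSystem(6.0, 2.0, n_spectators=3, n_states=6)
    return run(sys_, SamplerConfig(n_iterations=150, md_steps_per_iteration=10,
                                   timestep=0.05, friction=1.0, seed=17))


class TestSlowDofReport:

    def test_planted_coordinate_tops_the_table(self, planted_archive):
        rep = slow_dof_report(planted_archive, compute_convergence=False)
        custom = [r for r in rep.category_table if r.category == "custom"][0]
        assert custom.argmax_dof == "planted_x"
        assert custom.max_abs_pcc > 0.9

    def test_degenerate_du_dl_flagged(self):
        sys_ = PlantedSlowDofSystem(6.0, 0.0, n_spectators=1, n_states=4)
        arch = run(sys_, SamplerConfig(n_iterations=40, timestep=0.05, seed=1))
        rep = slow_dof_report(arch, compute_convergence=False)
        assert rep.degenerate_du_dl
        assert all(r.max_abs_pcc is None for r in rep.category_table)

    def test_missing_catalog_entry_rejected(self, planted_archive):
        cat = DofCatalog([DofCatalogEntry("not_recorded", "custom")])
        with pytest.raises(KeyError):
            slow_dof_report(planted_archive, catalog=cat)

    def test_report_serializes(self, tmp_path, planted_archive):
        rep = slow_dof_report(planted_archive, compute_convergence=False)
        rep.to_json(tmp_path / "report.json")
        df = rep.category_dataframe()
        assert "max_abs_pcc" in df.columns and len(df) >= 1

    def test_reports_ordered_by_inefficiency(self, planted_archive):
        rep = slow_dof_report(planted_archive, compute_convergence=False)
        import copy

        rep2 = copy.deepcopy(rep)
        rep2.du_dl_g = (rep.du_dl_g or 1.0) + 10.0
        ordered = order_reports_by_inefficiency({"a": rep, "b": rep2})
        assert [k for k, _ in ordered] == ["b", "a"]
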