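"""Replica exchange: propagation, Gibbs permutation, mixing, archives."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from alchemforge.archive import SimulationArchive
from alchemforge.energy import build_lambda_protocol
from alchemforge.rest import RESTConfig
from alchemforge.sampler import (
    RestraintConfig,
    SamplerConfig,
    gibbs_permute,
    mixing_statistics,
    propagate,
    run,
    swap_log_ratio,
)
from alchemforge.systems import HarmonicLadderSystem, HybridSystem, PlantedSlowDofSystem
from alchemforge.toys import build_bead_residue_chain, make_bead_residue_chain
from alchemforge.units import kcal_per_mol_to_kt


class TestPropagate:
    def test_zero_steps_leaves_positions_unchanged(self, rng):
        sys_ = HarmonicLadderSystem([1.0, 2.0])
        x = np.array([[0.7]])
        v = np.array([[0.1]])
        cfg = SamplerConfig()
        x2, v2 = propagate(x, v, sys_, 0, 0, cfg, rng)
        assert np.array_equal(x, x2) and np.array_equal(v, v2)

    def test_harmonic_equipartition(self, rng):
        """Long Langevin run samples variance kT / K_spring."""
        k_spring = 3.0
        sys_ = HarmonicLadderSystem([k_spring])
        cfg = SamplerConfig(timestep=0.05, friction=1.0)
        x = np.array([[0.0]])
        v = np.array([[0.0]])
        samples = []
        for _ in range(4000):
            x, v = propagate(x, v, sys_, 0, 5, cfg, rng)
            samples.append(x[0, 0])
        samples = np.asarray(samples[200:])
        var = samples.var()
        # 3 standard errors of the variance with a correlation-time cushion
        se = var * np.sqrt(2.0 / (len(samples) / 5))
        assert abs(var - 1.0 / k_spring) < 3 * se

    def test_restraint_bounds_heavy_atom_excursions(self):
        from alchemforge.toys import build_system

        spec = make_bead_residue_chain(3, 1, "A", "T", n_states=4)
        sys_ = build_system(spec)
        pos = sys_.initial_positions()
        k_rest = kcal_per_mol_to_kt(50.0) * 100.0  # 50 kcal/mol/A^2 in kT/nm^2
        heavy = sys_.heavy_mask

        def max_heavy_rmsd(restraint):
            cfg = SamplerConfig(
                n_iterations=60, md_steps_per_iteration=10, timestep=0.004,
                friction=5.0, seed=9, restraint=restraint,
            )
            arch_positions = []
            x = pos.copy()
            v = np.zeros_like(x)
            rng = np.random.default_rng(9)
            ref = pos.copy()
            for _ in range(cfg.n_iterations):
                x, v = propagate(
                    x, v, sys_, 1, cfg.md_steps_per_iteration, cfg, rng,
                    restraint_ref=ref if restraint else None,
                    restraint_mask=heavy.astype(float) if restraint else None,
                )
                d = x[heavy] - pos[heavy]
                arch_positions.append(np.sqrt(np.mean(np.sum(d * d, axis=1))))
            return max(arch_positions)

        restrained = max_heavy_rmsd(RestraintConfig(force_constant=k_rest))
        free = max_heavy_rmsd(None)
        assert restrained < 0.5 * free


class TestSwapLogRatio:
    def test_identical_states_always_accepted(self):
        row = np.array([1.0, 2.0, 3.0])
        assert swap_log_ratio(1, 1, row, row) == 0.0

    def test_symmetric_cross_energies(self):
        # both cross-energies equal both self-energies -> log ratio 0
        row_i = np.array([5.0, 5.0])
        row_j = np.array([5.0, 5.0])
        assert swap_log_ratio(0, 1, row_i, row_j) == 0.0

    def test_favourable_swap_positive(self):
        row_i = np.array([10.0, 1.0])
        row_j = np.array([1.0, 10.0])
        assert swap_log_ratio(0, 1, row_i, row_j) == pytest.approx(18.0)


class TestGibbsPermute:
    def test_single_replica_identity(self, rng):
        out = gibbs_permute(np.array([0]), np.zeros((1, 1)), 5, rng)
        assert list(out) == [0]

    def test_requires_at_least_one_attempt(self, rng):
        with pytest.raises(ValueError):
            gibbs_permute(np.arange(3), np.zeros((3, 3)), 0, rng)

    @given(seed=st.integers(0, 500))
    def test_output_is_always_a_permutation(self, seed):
        rng = np.random.default_rng(seed)
        K = int(rng.integers(2, 6))
        u = rng.normal(size=(K, K)) * 3
        out = gibbs_permute(np.arange(K), u, K**3, rng)
        assert sorted(out) == list(range(K))

    def test_equal_energies_uniform_over_reachable_permutations(self, rng):
        """With all energies equal every transposition is accepted; an odd
        attempt count therefore lands uniformly on the odd permutations."""
        K = 3
        u = np.zeros((K, K))
        n_attempts = 27  # odd => odd permutations of S3: the 3 transpositions
        counts = {}
        for _ in range(3000):
            out = tuple(gibbs_permute(np.arange(K), u, n_attempts, rng))
            counts[out] = counts.get(out, 0) + 1
        assert set(counts) == {(1, 0, 2), (2, 1, 0), (0, 2, 1)}
        chi2, p = stats.chisquare(list(counts.values()))
        assert p > 1e-3


class TestRun:
    def test_seed_determinism_bit_exact(self):
        sys_ = HarmonicLadderSystem([1.0, 2.0, 4.0])
        cfg = SamplerConfig(n_iterations=50, md_steps_per_iteration=5, timestep=0.05, seed=123)
        a = run(sys_, cfg)
        b = run(sys_, cfg)
        assert np.array_equal(a.u_kln, b.u_kln)
        assert np.array_equal(a.state_trace, b.state_trace)
        assert np.array_equal(a.du_dl, b.du_dl)

    def test_state_trace_rows_are_permutations(self):
        sys_ = HarmonicLadderSystem([1.0, 2.0, 4.0])
        arch = run(sys_, SamplerConfig(n_iterations=40, timestep=0.05, seed=1))
        ref = np.arange(3)
        for row in arch.state_trace:
            assert np.array_equal(np.sort(row), ref)

    def test_two_state_occupancy_balanced(self):
        sys_ = HarmonicLadderSystem([1.0, 1.5])
        arch = run(sys_, SamplerConfig(n_iterations=3000, md_steps_per_iteration=5,
                                       timestep=0.05, friction=1.0, seed=5))
        occ = (arch.state_trace[:, 0] == 0).mean()
        assert abs(occ - 0.5) < 0.05

    def test_every_replica_visits_all_states(self):
        """Replicas perform a random walk through all alchemical states."""
        sys_ = PlantedSlowDofSystem(6.0, 2.0, n_states=5)
        arch = run(sys_, SamplerConfig(n_iterations=400, md_steps_per_iteration=10,
                                       timestep=0.05, friction=1.0, seed=7))
        for k in range(5):
            assert len(set(arch.state_trace[:, k])) == 5

    def test_arest_with_tmax_t0_bitwise_matches_arex(self):
        spec_kwargs = dict(barrier_height=4.0, coupling=1.0, n_states=4)
        cfg = SamplerConfig(n_iterations=30, timestep=0.05, seed=3)
        a = run(PlantedSlowDofSystem(**spec_kwargs), cfg)
        b = run(PlantedSlowDofSystem(**spec_kwargs,
                                     rest_config=RESTConfig(t0=300, tmax=300)), cfg)
        assert np.array_equal(a.u_kln, b.u_kln)
        assert np.array_equal(a.state_trace, b.state_trace)

    def test_arest_endstate_sampling_has_unscaled_statistics(self):
        """Configurations assigned to lambda=0 obey the cold distribution."""
        sys_ = PlantedSlowDofSystem(2.0, 0.5, n_spectators=2, n_states=4,
                                    rest_config=RESTConfig(t0=300, tmax=600))
        arch = run(sys_, SamplerConfig(n_iterations=2500, md_steps_per_iteration=8,
                                       timestep=0.05, friction=1.0, seed=11))
        # spectator variance at any state must be 1/omega^2 (they are nonrest)
        spect = arch.dof_traces["spectator_0"]
        at_state0 = spect[arch.state_trace == 0]
        var = at_state0.var()
        se = var * np.sqrt(2.0 / (len(at_state0) / 4))
        assert abs(var - 1.0 / 4.0) < 3 * se  # omega = 2


class TestMixingStatistics:
    def test_frozen_trace_flagged(self):
        st_trace = np.tile(np.arange(4), (50, 1))
        m = mixing_statistics(st_trace)
        assert m.bottleneck
        assert np.allclose(m.transition_matrix, np.eye(4))

    def test_iid_uniform_trace_unflagged(self, rng):
        n, K = 4000, 4
        st_trace = np.stack([rng.permutation(K) for _ in range(n)])
        m = mixing_statistics(st_trace)
        assert not m.bottleneck
        assert np.allclose(m.transition_matrix, 1.0 / K, atol=0.05)

    def test_two_block_trace_reducible_and_flagged(self, rng):
        n = 400
        rows = []
        for _ in range(n):
            a = rng.permutation(2)            # states {0,1} among replicas 0,1
            b = rng.permutation(2) + 2        # states {2,3} among replicas 2,3
            rows.append(np.concatenate([a, b]))
        m = mixing_statistics(np.stack(rows))
        assert m.reducible and m.bottleneck

    def test_single_iteration_rejected(self):
        with pytest.raises(ValueError):
            mixing_statistics(np.array([[0, 1]]))


class TestArchive:
    def _archive(self):
        sys_ = HarmonicLadderSystem([1.0, 2.0])
        sys_.register_dof("x", "custom", lambda x: float(x[0, 0]))
        return run(sys_, SamplerConfig(n_iterations=25, timestep=0.05, seed=2))

    def test_hdf5_round_trip(self, tmp_path):
        a = self._archive()
        p = tmp_path / "arch.h5"
        a.to_hdf5(p)
        b = SimulationArchive.from_hdf5(p)
        assert np.array_equal(a.u_kln, b.u_kln)
        assert np.array_equal(a.state_trace, b.state_trace)
        assert np.array_equal(a.dof_traces["x"], b.dof_traces["x"])
        assert b.dof_categories["x"] == "custom"
        assert b.metadata["seed"] == 2

    def test_csv_export(self, tmp_path):
        a = self._archive()
        written = a.export_csv(tmp_path / "traces")
        assert {p.name for p in written} == {"state_trace.csv", "du_dl.csv", "x.csv"}

    def test_validation_rejects_non_permutation_rows(self):
        a = self._archive()
        a.state_trace[3] = [0, 0]
        with pytest.raises(ValueError):
            a.validate()

    def test_truncated_prefix(self):
        a = self._archive()
        t = a.truncated(10)
        assert t.n_iterations == 10
        assert np.array_equal(t.u_kln, a.u_kln[:10])
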