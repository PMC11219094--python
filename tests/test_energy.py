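"""Alchemical energies: interpolation rules, softcore, endpoint identities."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from alchemforge.energy import (
    ElectrostaticsParams,
    PairTable,
    SingularGeometryError,
    SoftcoreParams,
    build_lambda_protocol,
    direct_electrostatics,
    du_dlambda,
    dummy_valence_energy,
    effective_distance,
    endstate_energy,
    interpolate_charge,
    lifting_distance,
    preset_protocol,
    sterics_energy,
    total_energy,
)
from alchemforge.topology import AtomMap, AtomRecord, HybridTopology, ValenceTermSet
from alchemforge.toys import (
    build_bead_residue_chain,
    build_charge_change_trio,
    build_softcore_dimer,
    make_bead_residue_chain,
    make_charge_change_trio,
    make_softcore_dimer,
)

PLAIN = ElectrostaticsParams(use_plain_coulomb=True)
SC = SoftcoreParams()


def atom(cls, q_old=0.0, q_new=0.0, eps_old=0.0, eps_new=0.0, sig=0.3, idx=0):
    return AtomRecord(idx, "X", 0, True, q_old, q_new, sig, sig, eps_old, eps_new, cls)


class TestInterpolation:
    def test_unique_old_charge_scales_out(self):
        a = atom("unique_old", q_old=0.5)
        assert interpolate_charge(a, 0.0) == 0.5
        assert interpolate_charge(a, 1.0) == 0.0

    def test_core_charge_blend(self):
        a = atom("core", q_old=-0.3, q_new=0.1)
        assert interpolate_charge(a, 0.5) == pytest.approx(-0.1)

    def test_environment_charge_fixed(self):
        a = atom("environment", q_old=0.4, q_new=0.4)
        for lam in (0.0, 0.3, 1.0):
            assert interpolate_charge(a, lam) == 0.4

    def test_lambda_out_of_range(self):
        with pytest.raises(ValueError):
            interpolate_charge(atom("core"), 1.2)


class TestLifting:
    def test_fully_interacting_endstate_unlifted(self):
        assert lifting_distance("unique_old", "environment", 0.0, SC) == 0.0

    def test_unique_old_fully_lifted_at_lambda_one(self):
        assert lifting_distance("unique_old", "environment", 1.0, SC) == pytest.approx(0.4)

    def test_core_pairs_never_lifted(self):
        for lam in (0.0, 0.5, 1.0):
            assert lifting_distance("core", "core", lam, SC) == 0.0

    def test_mixed_unique_pair_is_an_error(self):
        with pytest.raises(ValueError):
            lifting_distance("unique_old", "unique_new", 0.5, SC)

    def test_effective_distance_pythagoras(self):
        assert effective_distance(0.0, 0.4) == pytest.approx(0.4)
        assert effective_distance(0.3, 0.4) == pytest.approx(0.5)  # 3-4-5
        assert effective_distance(0.7, 0.0) == 0.7


class TestPairEnergies:
    def test_zero_charge_zero_energy(self):
        e = direct_electrostatics(0.3, atom("core"), atom("core", idx=1), 0.5, PLAIN, SC)
        assert e == 0.0

    def test_unique_old_scaled_out_at_lambda_one(self):
        a = atom("unique_old", q_old=0.5)
        b = atom("environment", q_old=0.3, q_new=0.3, idx=1)
        assert direct_electrostatics(0.3, a, b, 1.0, PLAIN, SC) == 0.0

    def test_plain_coulomb_scalar_oracle(self):
        # hand arithmetic: C * q_i(0.5) * q_j(0.5) / 0.3 for unit core charges
        a = atom("core", q_old=1.0, q_new=1.0)
        b = atom("core", q_old=1.0, q_new=1.0, idx=1)
        expected = PLAIN.coulomb_constant * 1.0 * 1.0 / 0.3
        assert direct_electrostatics(0.3, a, b, 0.5, PLAIN, SC) == pytest.approx(expected)

    def test_plain_coulomb_limit_alpha_to_zero(self):
        a = atom("environment", q_old=0.7, q_new=0.7)
        b = atom("environment", q_old=-0.2, q_new=-0.2, idx=1)
        erfc_params = ElectrostaticsParams(alpha_pme=1e-12, use_plain_coulomb=False)
        e1 = direct_electrostatics(0.52, a, b, 0.4, erfc_params, SC)
        e2 = PLAIN.coulomb_constant * 0.7 * -0.2 / 0.52
        assert e1 == pytest.approx(e2, rel=1e-12)

    def test_singular_geometry(self):
        a = atom("core", q_old=1.0, q_new=1.0)
        b = atom("core", q_old=1.0, q_new=1.0, idx=1)
        with pytest.raises(SingularGeometryError):
            direct_electrostatics(0.0, a, b, 0.5, PLAIN, SC)

    def test_lj_zero_crossing_and_minimum(self):
        a = atom("environment", eps_old=0.5, eps_new=0.5)
        b = atom("environment", eps_old=0.5, eps_new=0.5, idx=1)
        sig = 0.3
        assert sterics_energy(sig, a, b, 0.2, SC) == pytest.approx(0.0, abs=1e-12)
        rmin = 2 ** (1 / 6) * sig
        assert sterics_energy(rmin, a, b, 0.2, SC) == pytest.approx(-0.5)

    def test_softcore_prevents_singularity_at_contact(self):
        a = atom("unique_new", eps_new=0.5)
        b = atom("environment", eps_old=0.5, eps_new=0.5, idx=1)
        e = sterics_energy(0.0, a, b, 0.0, SC)
        # r_eff = w_lifting at lambda=0; energy from Eq with x=(0.3/0.4)^6
        x = (0.3 / 0.4) ** 6
        # epsilon_new scales with lambda=0 -> 0, so energy must be exactly 0
        assert e == 0.0
        e_mid = sterics_energy(0.0, a, b, 0.4, SC)
        assert np.isfinite(e_mid)

    def test_negative_epsilon_rejected(self):
        bad = atom("environment", eps_old=-0.1, eps_new=-0.1)
        with pytest.raises(ValueError):
            sterics_energy(0.3, bad, bad, 0.5, SC)


class TestLambdaProtocol:
    def test_two_state(self):
        assert build_lambda_protocol(2).lambdas == (0.0, 1.0)

    def test_five_state_uniform(self):
        assert build_lambda_protocol(5).lambdas == (0.0, 0.25, 0.5, 0.75, 1.0)

    def test_presets_for_neutral_and_charge_mutations(self):
        assert preset_protocol("neutral").n_states == 24
        assert preset_protocol("charge").n_states == 36

    def test_too_few_states(self):
        with pytest.raises(ValueError):
            build_lambda_protocol(1)


@pytest.fixture(scope="module")
def fixtures_with_positions():
    out = [
        build_bead_residue_chain(make_bead_residue_chain(3, 1, "A", "T")),
        build_bead_residue_chain(make_bead_residue_chain(5, 2, "R", "A", phase="complex")),
        build_charge_change_trio(make_charge_change_trio()),
        build_softcore_dimer(make_softcore_dimer()),
    ]
    return out


class TestTotalEnergy:
    def test_endpoint_identity_both_ends(self, fixtures_with_positions):
        """U(x;0) = plain WT energy + dummy-new valence, and the mirror at 1."""
        for hybrid, pos in fixtures_with_positions:
            for lam, end in ((0.0, "old"), (1.0, "new")):
                u = total_energy(pos, hybrid, lam, PLAIN)
                ref = endstate_energy(pos, hybrid, end, PLAIN) + dummy_valence_energy(
                    pos, hybrid, end
                )
                assert u == pytest.approx(ref, rel=1e-10)

    def test_continuity_in_lambda(self, fixtures_with_positions):
        hybrid, pos = fixtures_with_positions[1]
        lams = np.arange(0.0, 1.0 + 1e-9, 1e-3)
        us = np.array([total_energy(pos, hybrid, l, PLAIN) for l in lams])
        # no jumps beyond what a bounded dU/dlambda allows at 1e-3 steps
        dmax = np.max(np.abs(np.diff(us)))
        scale = max(1.0, np.max(np.abs(us)))
        assert dmax < 0.05 * scale

    def test_valence_only_when_no_pairs(self):
        a = [atom("environment", q_old=0.2, q_new=0.2),
             atom("environment", q_old=-0.2, q_new=-0.2, idx=1)]
        from alchemforge.topology import ValenceTerm

        valence = ValenceTermSet(bonds=[ValenceTerm("bond", (0, 1), (10.0, 0.3), "shared")])
        h = HybridTopology(a, valence, AtomMap([(0, 0), (1, 1)], 0),
                           exclusions={(0, 1)})
        pos = np.array([[0.0, 0, 0], [0.4, 0, 0]])
        assert total_energy(pos, h, 0.3, PLAIN) == pytest.approx(0.5 * 10 * 0.1**2)

    def test_nan_positions_rejected(self, fixtures_with_positions):
        hybrid, pos = fixtures_with_positions[0]
        bad = pos.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            total_energy(bad, hybrid, 0.5, PLAIN)


class TestDuDlambda:
    def test_matches_analytic_on_core_pair(self):
        a = [atom("core", q_old=-0.3, q_new=0.1), atom("core", q_old=0.2, q_new=0.4, idx=1)]
        h = HybridTopology(a, ValenceTermSet(), AtomMap([(0, 0), (1, 1)], 0))
        r = 0.4
        pos = np.array([[0.0, 0, 0], [r, 0, 0]])
        qi = lambda l: (1 - l) * -0.3 + l * 0.1
        qj = lambda l: (1 - l) * 0.2 + l * 0.4
        for lam in (0.2, 0.5, 0.9):
            analytic = PLAIN.coulomb_constant * (0.4 * qj(lam) + qi(lam) * 0.2) / r
            assert du_dlambda(pos, h, lam, PLAIN) == pytest.approx(analytic, rel=1e-6)

    def test_zero_without_alchemical_atoms(self):
        a = [atom("environment", q_old=0.2, q_new=0.2),
             atom("environment", q_old=-0.1, q_new=-0.1, idx=1)]
        h = HybridTopology(a, ValenceTermSet(), AtomMap([(0, 0), (1, 1)], 0))
        pos = np.array([[0.0, 0, 0], [0.5, 0, 0]])
        for lam in (0.0, 0.4, 1.0):
            assert du_dlambda(pos, h, lam, PLAIN) == pytest.approx(0.0, abs=1e-9)

    def test_one_sided_at_endpoints(self):
        a = [atom("core", q_old=0.3, q_new=0.5), atom("core", q_old=0.3, q_new=0.5, idx=1)]
        h = HybridTopology(a, ValenceTermSet(), AtomMap([(0, 0), (1, 1)], 0))
        pos = np.array([[0.0, 0, 0], [0.4, 0, 0]])
        assert np.isfinite(du_dlambda(pos, h, 0.0, PLAIN))
        assert np.isfinite(du_dlambda(pos, h, 1.0, PLAIN))


class TestSoftcoreBoundedness:
    @given(lam=st.floats(0.01, 0.99), w=st.floats(0.05, 1.0))
    def test_unique_pair_finite_at_contact(self, lam, w):
        sc = SoftcoreParams(w_lifting=w)
        a = atom("unique_old", q_old=0.5, eps_old=0.5)
        b = atom("environment", q_old=-0.5, q_new=-0.5, eps_old=0.5, eps_new=0.5, idx=1)
        e = sterics_energy(0.0, a, b, lam, sc) + direct_electrostatics(
            0.0, a, b, lam, PLAIN, sc
        )
        assert np.isfinite(e)


class TestForcesAgainstGradient:
    def test_analytic_forces_match_numerical_gradient(self, rng):
        from alchemforge.systems import HybridSystem

        hybrid, pos = build_bead_residue_chain(
            make_bead_residue_chain(3, 1, "A", "T")
        )
        sys_ = HybridSystem(hybrid, build_lambda_protocol(5), pos)
        x = pos + 0.01 * rng.standard_normal(pos.shape)
        k = 2
        f = sys_.reduced_force(x, k)
        h = 1e-6
        for a in range(0, x.shape[0], 7):  # spot-check a subset of atoms
            for d in range(3):
                xp = x.copy(); xp[a, d] += h
                xm = x.copy(); xm[a, d] -= h
                num = -(sys_.reduced_energy(xp, k) - sys_.reduced_energy(xm, k)) / (2 * h)
                assert f[a, d] == pytest.approx(num, abs=5e-5)
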