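"""Synthetic test systems with known answers.

Every fixture the engine is validated on is generated here, in code:

* **harmonic ladders** — K Gaussian states with exact analytic free
  energies, the oracle for MBAR and the sampling pipeline;
* **softcore dimers** — two-particle systems exercising the lifting
  scheme's boundedness and endpoint limits;
* **charge-change trios** — a bead "residue" whose charge changes by one
  elementary charge, requiring the water -> counterion transform; forward
  and reverse specs are generated as a pair so internal consistency
  (DG_fwd = -DG_rev) can be checked at engine level;
* **planted slow-DOF landscapes** — a double well coupled linearly to
  lambda so the slow coordinate is known by construction and the
  diagnostics must recover it;
* **bead residue chains** — minimal amino-acid-like bead residues (named
  atoms, charges, LJ parameters, a few valence terms) supporting the full
  mutation workflow in an "apo" (chain alone) and "complex" (chain plus a
  tethered partner cluster) phase.

The bead residue templates are deliberately synthetic: they mimic the
*bookkeeping* of amino acids (atom names, backbone/sidechain split, beta
hydrogens, net charges) at desk scale, not their geometry or force-field
physics.  All analytic references are recomputed from parameters at load
time and never stored as opaque numbers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Any

import numpy as np

from .energy import ElectrostaticsParams, build_lambda_protocol
from .rest import RESTConfig
from .systems import HarmonicLadderSystem, HybridSystem, PlantedSlowDofSystem
from .topology import (
    AtomMap,
    AtomRecord,
    HybridTopology,
    ValenceTerm,
    ValenceTermSet,
    apply_counterion_transform,
    build_atom_map,
    classify_atoms,
)

SCHEMA_VERSION = "alchemforge-toy-1"

TOY_KINDS = (
    "harmonic_ladder",
    "softcore_dimer",
    "charge_change_trio",
    "planted_slow_dof",
    "bead_residue_chain",
)


@dataclass
class ToySystemSpec:
    """Serializable description of one toy system."""

    kind: str
    parameters: dict[str, Any]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in TOY_KINDS:
            raise ValueError(f"unknown toy kind {self.kind!r}")

    @property
    def analytic_reference(self) -> dict[str, float] | None:
        """Exact reference values recomputed from the parameters."""
        if self.kind == "harmonic_ladder":
            springs = np.asarray(self.parameters["spring_constants"], dtype=float)
            f = 0.5 * np.log(springs)
            f -= f[0]
            return {"delta_f": float(f[-1]), "f_k": [float(v) for v in f]}
        if self.kind == "planted_slow_dof":
            return {"du_dlambda_coefficient": float(self.parameters["coupling"])}
        return None

    def to_dict(self) -> dict:
        return {
            "schema": SCHEMA_VERSION,
            "kind": self.kind,
            "parameters": self.parameters,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ToySystemSpec":
        if d.get("schema") != SCHEMA_VERSION:
            raise ValueError(f"unsupported toy schema {d.get('schema')!r}")
        return cls(kind=d["kind"], parameters=d["parameters"], seed=d.get("seed", 0))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ToySystemSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# factories
# ---------------------------------------------------------------------------


def make_harmonic_ladder(
    n_states: int, spring_constants=None, centers=None, beta: float = 1.0
) -> ToySystemSpec:
    """Gaussian state ladder; exact reduced free energies f_k = ln(K_k)/2."""
    if n_states < 2:
        raise ValueError("need at least 2 states")
    if beta != 1.0:
        raise ValueError("the ladder is defined in reduced units (beta = 1)")
    if spring_constants is None:
        spring_constants = list(np.geomspace(1.0, 4.0, n_states))
    springs = [float(s) for s in spring_constants]
    if len(springs) != n_states or any(s <= 0 for s in springs):
        raise ValueError("need one positive spring constant per state")
    centers = [0.0] * n_states if centers is None else [float(c) for c in centers]
    return ToySystemSpec(
        kind="harmonic_ladder",
        parameters={"spring_constants": springs, "centers": centers},
    )


def make_planted_slow_dof(
    barrier_height: float,
    coupling: float,
    n_spectators: int = 3,
    seed: int = 0,
    n_states: int = 8,
) -> ToySystemSpec:
    """Double well (barrier in kT) with dU/dlambda = coupling * x planted."""
    if barrier_height <= 0:
        raise ValueError("barrier_height must be > 0")
    return ToySystemSpec(
        kind="planted_slow_dof",
        parameters={
            "barrier_height": float(barrier_height),
            "coupling": float(coupling),
            "n_spectators": int(n_spectators),
            "n_states": int(n_states),
        },
        seed=seed,
    )


def make_softcore_dimer(
    charge_old: float = 0.3,
    epsilon: float = 0.5,
    sigma: float = 0.3,
    separation: float = 0.35,
) -> ToySystemSpec:
    """A vanishing particle next to an environment particle."""
    return ToySystemSpec(
        kind="softcore_dimer",
        parameters={
            "charge_old": charge_old,
            "epsilon": epsilon,
            "sigma": sigma,
            "separation": separation,
        },
    )


def make_charge_change_trio(seed: int = 0) -> ToySystemSpec:
    """Charge-changing bead toy: +1 residue bead -> neutral, plus counterion.

    Three charged beads and one transformable water bead in a bonded chain;
    the forward and reverse hybrids are built from the same spec.
    """
    return ToySystemSpec(
        kind="charge_change_trio",
        parameters={
            "residue_charge_old": 1.0,
            "residue_charge_new": 0.0,
            "environment_charges": [-0.1, -0.1],
            "spacing": 0.35,
            "bond_k": 100.0,
            "sigma": 0.3,
            "epsilon": 0.5,
            "coulomb_constant": 15.0,
            "n_states": 11,
        },
        seed=seed,
    )


def make_bead_residue_chain(
    n_residues: int,
    mutation_site: int,
    wt_type: str,
    mut_type: str,
    seed: int = 0,
    phase: str = "apo",
    n_states: int = 8,
) -> ToySystemSpec:
    """Bead-residue chain mutation fixture (apo or complex phase)."""
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    if not 0 < mutation_site < n_residues - 1:
        raise ValueError("mutation site must be interior")
    for t in (wt_type, mut_type):
        if t not in RESIDUE_TEMPLATES:
            raise KeyError(f"unknown residue type {t!r}")
    if phase not in ("apo", "complex"):
        raise ValueError("phase must be 'apo' or 'complex'")
    return ToySystemSpec(
        kind="bead_residue_chain",
        parameters={
            "n_residues": int(n_residues),
            "mutation_site": int(mutation_site),
            "wt_type": wt_type,
            "mut_type": mut_type,
            "phase": phase,
            "n_states": int(n_states),
            "coulomb_constant": 10.0,
        },
        seed=seed,
    )


# ---------------------------------------------------------------------------
# bead residue templates (synthetic stand-ins, see module docstring)
# ---------------------------------------------------------------------------

# atom tuples: (name, charge, sigma_nm, epsilon_kT, offset_xyz_nm)
_BB = [
    ("N", -0.4, 0.18, 0.3, (0.00, 0.00, 0.0)),
    ("H", 0.3, 0.10, 0.1, (0.00, 0.12, 0.0)),
    ("CA", 0.1, 0.20, 0.3, (0.15, 0.00, 0.0)),
    ("HA", 0.05, 0.10, 0.1, (0.15, 0.10, 0.08)),
    ("C", 0.5, 0.19, 0.3, (0.30, 0.00, 0.0)),
    ("O", -0.55, 0.17, 0.4, (0.30, 0.12, 0.0)),
]

_BB_BONDS = [("N", "H", 100.0, 0.10), ("N", "CA", 100.0, 0.15), ("CA", "HA", 100.0, 0.11),
             ("CA", "C", 100.0, 0.15), ("C", "O", 100.0, 0.12)]


def _sidechain(atoms, bonds):
    return {
        "atoms": _BB + atoms,
        "bonds": _BB_BONDS + bonds,
    }


RESIDUE_TEMPLATES: dict[str, dict] = {
    # glycine-like: backbone only
    "G": {"atoms": list(_BB), "bonds": list(_BB_BONDS)},
    # alanine-like: CB with three beta hydrogens
    "A": _sidechain(
        [
            ("CB", -0.1, 0.20, 0.3, (0.15, -0.15, 0.0)),
            ("HB1", 0.033, 0.10, 0.1, (0.05, -0.21, 0.0)),
            ("HB2", 0.033, 0.10, 0.1, (0.20, -0.21, 0.09)),
            ("HB3", 0.034, 0.10, 0.1, (0.20, -0.21, -0.09)),
        ],
        [("CA", "CB", 100.0, 0.15), ("CB", "HB1", 100.0, 0.11),
         ("CB", "HB2", 100.0, 0.11), ("CB", "HB3", 100.0, 0.11)],
    ),
    # threonine-like: branched polar sidechain, one beta hydrogen
    "T": _sidechain(
        [
            ("CB", 0.15, 0.20, 0.3, (0.15, -0.15, 0.0)),
            ("HB", 0.05, 0.10, 0.1, (0.05, -0.20, 0.0)),
            ("OG1", -0.55, 0.17, 0.4, (0.24, -0.24, 0.10)),
            ("HG1", 0.35, 0.08, 0.05, (0.24, -0.34, 0.10)),
            ("CG2", -0.15, 0.20, 0.3, (0.24, -0.24, -0.12)),
            ("HG21", 0.05, 0.10, 0.1, (0.16, -0.31, -0.16)),
            ("HG22", 0.05, 0.10, 0.1, (0.32, -0.18, -0.18)),
            ("HG23", 0.05, 0.10, 0.1, (0.30, -0.33, -0.08)),
        ],
        [("CA", "CB", 100.0, 0.15), ("CB", "HB", 100.0, 0.11),
         ("CB", "OG1", 100.0, 0.14), ("OG1", "HG1", 100.0, 0.096),
         ("CB", "CG2", 100.0, 0.15), ("CG2", "HG21", 100.0, 0.11),
         ("CG2", "HG22", 100.0, 0.11), ("CG2", "HG23", 100.0, 0.11)],
    ),
    # arginine-like: long +1 sidechain, two beta hydrogens
    "R": _sidechain(
        [
            ("CB", -0.05, 0.20, 0.3, (0.15, -0.15, 0.0)),
            ("HB2", 0.03, 0.10, 0.1, (0.05, -0.20, 0.06)),
            ("HB3", 0.03, 0.10, 0.1, (0.24, -0.20, 0.06)),
            ("CG", -0.05, 0.20, 0.3, (0.19, -0.29, 0.04)),
            ("CD", 0.05, 0.20, 0.3, (0.13, -0.43, 0.01)),
            ("NE", -0.35, 0.18, 0.3, (0.19, -0.56, 0.04)),
            ("CZ", 0.60, 0.19, 0.3, (0.15, -0.69, 0.0)),
            ("NH1", 0.37, 0.18, 0.3, (0.05, -0.77, 0.03)),
            ("NH2", 0.37, 0.18, 0.3, (0.25, -0.77, -0.03)),
        ],
        [("CA", "CB", 100.0, 0.15), ("CB", "HB2", 100.0, 0.11),
         ("CB", "HB3", 100.0, 0.11), ("CB", "CG", 100.0, 0.15),
         ("CG", "CD", 100.0, 0.15), ("CD", "NE", 100.0, 0.14),
         ("NE", "CZ", 100.0, 0.13), ("CZ", "NH1", 100.0, 0.13),
         ("CZ", "NH2", 100.0, 0.13)],
    ),
    # aspartate-like: -1 sidechain
    "D": _sidechain(
        [
            ("CB", -0.1, 0.20, 0.3, (0.15, -0.15, 0.0)),
            ("HB2", 0.03, 0.10, 0.1, (0.05, -0.20, 0.06)),
            ("HB3", 0.03, 0.10, 0.1, (0.24, -0.20, 0.06)),
            ("CG", 0.54, 0.19, 0.3, (0.19, -0.29, 0.03)),
            ("OD1", -0.75, 0.17, 0.4, (0.08, -0.37, 0.05)),
            ("OD2", -0.75, 0.17, 0.4, (0.28, -0.36, 0.0)),
        ],
        [("CA", "CB", 100.0, 0.15), ("CB", "HB2", 100.0, 0.11),
         ("CB", "HB3", 100.0, 0.11), ("CB", "CG", 100.0, 0.15),
         ("CG", "OD1", 100.0, 0.125), ("CG", "OD2", 100.0, 0.125)],
    ),
}

#: Constrained bond lengths for hydrogens, shared by all templates so a
#: mapped backbone hydrogen keeps its constraint across any mutation.
HYDROGEN_CONSTRAINT_LENGTHS = {
    "H": 0.10,
    "HA": 0.11,
    "HB": 0.11, "HB1": 0.11, "HB2": 0.11, "HB3": 0.11,
    "HG1": 0.096, "HG21": 0.11, "HG22": 0.11, "HG23": 0.11,
}


def residue_net_charge(res_type: str) -> float:
    return float(sum(a[1] for a in RESIDUE_TEMPLATES[res_type]["atoms"]))


# ---------------------------------------------------------------------------
# system construction
# ---------------------------------------------------------------------------


def build_system(spec: ToySystemSpec, rest_config: RESTConfig | None = None):
    """Instantiate the sampleable system a spec describes."""
    p = spec.parameters
    if spec.kind == "harmonic_ladder":
        return HarmonicLadderSystem(p["spring_constants"], p["centers"])
    if spec.kind == "planted_slow_dof":
        return PlantedSlowDofSystem(
            p["barrier_height"],
            p["coupling"],
            n_spectators=p["n_spectators"],
            n_states=p["n_states"],
            rest_config=rest_config,
        )
    if spec.kind == "charge_change_trio":
        hybrid, positions = build_charge_change_trio(spec, direction="forward")
        return _trio_system(spec, hybrid, positions, rest_config)
    if spec.kind == "softcore_dimer":
        hybrid, positions = build_softcore_dimer(spec)
        return HybridSystem(
            hybrid, build_lambda_protocol(8), positions, rest_config=rest_config
        )
    if spec.kind == "bead_residue_chain":
        hybrid, positions = build_bead_residue_chain(spec)
        return HybridSystem(
            hybrid,
            build_lambda_protocol(p["n_states"]),
            positions,
            energy_params=ElectrostaticsParams(
                coulomb_constant=p.get("coulomb_constant", 10.0)
            ),
            rest_config=rest_config,
        )
    raise ValueError(f"unknown toy kind {spec.kind!r}")


def _trio_system(spec, hybrid, positions, rest_config):
    params = ElectrostaticsParams(
        coulomb_constant=spec.parameters["coulomb_constant"]
    )
    return HybridSystem(
        hybrid,
        build_lambda_protocol(spec.parameters["n_states"]),
        positions,
        energy_params=params,
        rest_config=rest_config,
    )


def build_softcore_dimer(spec: ToySystemSpec):
    """Two particles: one environment, one unique_old that vanishes."""
    p = spec.parameters
    atoms = [
        AtomRecord(0, "ENV", 0, True, -p["charge_old"], -p["charge_old"],
                   p["sigma"], p["sigma"], p["epsilon"], p["epsilon"], "environment"),
        AtomRecord(1, "OLD", 1, True, p["charge_old"], 0.0,
                   p["sigma"], p["sigma"], p["epsilon"], 0.0, "unique_old"),
    ]
    valence = ValenceTermSet(
        bonds=[ValenceTerm("bond", (0, 1), (20.0, p["separation"]), "shared")]
    )
    amap = AtomMap(pairs=[(0, 0)], mutating_residue_id=1)
    hybrid = HybridTopology(atoms, valence, amap, exclusions=set())
    positions = np.array([[0.0, 0.0, 0.0], [p["separation"], 0.0, 0.0]])
    return hybrid, positions


def build_charge_change_trio(spec: ToySystemSpec, direction: str = "forward"):
    """Hybrid topology for the charge-change toy (forward or reverse)."""
    from .topology import swap_endstates

    p = spec.parameters
    q_old, q_new = p["residue_charge_old"], p["residue_charge_new"]
    e1, e2 = p["environment_charges"]
    s, eps, sig = p["spacing"], p["epsilon"], p["sigma"]
    atoms = [
        AtomRecord(0, "RES", 0, True, q_old, q_new, sig, sig, eps, eps, "core"),
        AtomRecord(1, "E1", 1, True, e1, e1, sig, sig, eps, eps, "environment"),
        AtomRecord(2, "E2", 1, True, e2, e2, sig, sig, eps, eps, "environment"),
        AtomRecord(3, "WAT", 2, True, 0.0, 0.0, sig, sig, eps, eps, "environment"),
    ]
    k = p["bond_k"]
    valence = ValenceTermSet(
        bonds=[
            ValenceTerm("bond", (0, 1), (k, s), "shared"),
            ValenceTerm("bond", (1, 2), (k, s), "shared"),
            ValenceTerm("bond", (2, 3), (k, s), "shared"),
        ]
    )
    amap = AtomMap(pairs=[(i, i) for i in range(4)], mutating_residue_id=0)
    exclusions = {(0, 1), (1, 2), (2, 3)}
    hybrid = HybridTopology(atoms, valence, amap, exclusions=exclusions)
    hybrid = apply_counterion_transform(hybrid, water_like_particles=[3])
    hybrid.validate()
    if direction == "reverse":
        hybrid = swap_endstates(hybrid)
        hybrid.validate()
    positions = np.array([[i * s, 0.0, 0.0] for i in range(4)])
    return hybrid, positions


def build_trio_pair(spec: ToySystemSpec, rest_config=None):
    """Forward and reverse trio systems for internal-consistency checks."""
    fwd_h, pos = build_charge_change_trio(spec, "forward")
    rev_h, _ = build_charge_change_trio(spec, "reverse")
    return (
        _trio_system_from(spec, fwd_h, pos, rest_config),
        _trio_system_from(spec, rev_h, pos, rest_config),
    )


def _trio_system_from(spec, hybrid, positions, rest_config):
    return _trio_system(spec, hybrid, positions, rest_config)


# -- bead residue chains ----------------------------------------------------


def build_bead_residue_chain(spec: ToySystemSpec):
    """Assemble the hybrid topology + coordinates for a chain mutation.

    Non-mutating residues are alanine-like beads; the mutation site carries
    the WT template's atoms (old side) merged with the mutant template's
    atoms (new side) through the atom map.  The complex phase adds a small
    tethered partner cluster near the mutation site; charge-changing
    mutations get a water bead that the counterion transform converts.
    """
    p = spec.parameters
    n_res, site = p["n_residues"], p["mutation_site"]
    spacing = 0.45  # nm between residue origins along x

    wt_tpl = RESIDUE_TEMPLATES[p["wt_type"]]
    mut_tpl = RESIDUE_TEMPLATES[p["mut_type"]]
    wt_names = [a[0] for a in wt_tpl["atoms"]]
    mut_names = [a[0] for a in mut_tpl["atoms"]]
    amap_local = build_atom_map(
        wt_names, mut_names, HYDROGEN_CONSTRAINT_LENGTHS, mutating_residue_id=site
    )
    mapped_wt = {a for a, _ in amap_local.pairs}
    mapped_mut = {b for _, b in amap_local.pairs}
    mut_params = {a[0]: a for a in mut_tpl["atoms"]}

    atoms: list[AtomRecord] = []
    positions: list[tuple[float, float, float]] = []
    residue_ids: list[bool] = []
    mapped_flags: list[bool] = []
    from_wt_flags: list[bool] = []
    site_index: dict[str, int] = {}   # site residue, WT-side + mapped labels
    mut_index: dict[str, int] = {}    # site residue, mutant-side labels
    chain_index: dict[tuple[int, str], int] = {}

    def _add(name, rid, qo, qn, so, sn, eo, en, pos, mapped, from_wt):
        idx = len(atoms)
        atoms.append(
            AtomRecord(idx, name, rid, not name.startswith("H"),
                       qo, qn, so, sn, eo, en, "environment")
        )
        positions.append(tuple(pos))
        residue_ids.append(rid)
        mapped_flags.append(mapped)
        from_wt_flags.append(from_wt)
        return idx

    for rid in range(n_res):
        tpl = wt_tpl if rid == site else RESIDUE_TEMPLATES["A"]
        for li, (name, q, sg, ep, off) in enumerate(tpl["atoms"]):
            pos = (off[0] + rid * spacing, off[1], off[2])
            if rid == site and li in mapped_wt:
                m = mut_params[name]
                idx = _add(name, rid, q, m[1], sg, m[2], ep, m[3], pos, True, True)
                site_index[name] = idx
                mut_index[name] = idx
            elif rid == site:
                idx = _add(name, rid, q, 0.0, sg, sg, ep, 0.0, pos, False, True)
                site_index[name] = idx
            else:
                idx = _add(name, rid, q, q, sg, sg, ep, ep, pos, True, True)
            chain_index[(rid, name)] = idx
    for li, (name, q, sg, ep, off) in enumerate(mut_tpl["atoms"]):
        if li not in mapped_mut:
            pos = (off[0] + site * spacing, off[1], off[2])
            idx = _add(name, site, 0.0, q, sg, sg, 0.0, ep, pos, False, False)
            mut_index[name] = idx

    flanking = [r for r in (site - 1, site + 1) if 0 <= r < n_res]
    classes = classify_atoms(residue_ids, mapped_flags, from_wt_flags, site, flanking)
    for a, c in zip(atoms, classes):
        a.atom_class = c

    # -- valence terms -------------------------------------------------------
    bonds: list[ValenceTerm] = []
    mut_bond_params = {
        frozenset((x, y)): (kk, rr) for x, y, kk, rr in mut_tpl["bonds"]
    }
    for rid in range(n_res):
        tpl = wt_tpl if rid == site else RESIDUE_TEMPLATES["A"]
        for (na, nb, kb, r0) in tpl["bonds"]:
            ia, ib = chain_index[(rid, na)], chain_index[(rid, nb)]
            tag = "shared"
            if rid == site:
                both_mapped = (
                    atoms[ia].atom_class != "unique_old"
                    and atoms[ib].atom_class != "unique_old"
                )
                same = mut_bond_params.get(frozenset((na, nb))) == (kb, r0)
                tag = "shared" if (both_mapped and same) else "old"
            bonds.append(ValenceTerm("bond", (ia, ib), (kb, r0), tag))
    wt_bond_keys = {frozenset((na, nb)) for na, nb, _, _ in wt_tpl["bonds"]}
    for (na, nb, kb, r0) in mut_tpl["bonds"]:
        ia, ib = mut_index[na], mut_index[nb]
        both_mapped = (
            atoms[ia].atom_class != "unique_new"
            and atoms[ib].atom_class != "unique_new"
        )
        if both_mapped and frozenset((na, nb)) in wt_bond_keys \
                and mut_bond_params[frozenset((na, nb))] == _wt_bond(wt_tpl, na, nb):
            continue  # identical shared bond already emitted
        bonds.append(ValenceTerm("bond", (ia, ib), (kb, r0), "new"))
    for rid in range(n_res - 1):
        bonds.append(
            ValenceTerm(
                "bond",
                (chain_index[(rid, "C")], chain_index[(rid + 1, "N")]),
                (100.0, 0.15),
                "shared",
            )
        )

    # chi1-like torsions N-CA-CB-gamma on whichever sidechains support them
    torsions: list[ValenceTerm] = []
    for gamma in ("CG", "OG1"):
        if gamma in site_index:
            tag = "old" if atoms[site_index[gamma]].atom_class == "unique_old" else "shared"
            torsions.append(
                ValenceTerm(
                    "torsion",
                    (site_index["N"], site_index["CA"], site_index["CB"], site_index[gamma]),
                    (1.5, 3.0, 0.0),
                    tag,
                )
            )
        if gamma in mut_index and atoms[mut_index[gamma]].atom_class == "unique_new":
            torsions.append(
                ValenceTerm(
                    "torsion",
                    (site_index["N"], site_index["CA"], site_index["CB"], mut_index[gamma]),
                    (1.5, 3.0, 0.0),
                    "new",
                )
            )
    valence = ValenceTermSet(bonds=bonds, torsions=torsions)

    # -- complex-phase partner cluster --------------------------------------
    if p["phase"] == "complex":
        anchor = chain_index[(site, "CA")]
        prev = None
        for i, q in enumerate((-0.3, 0.1, -0.1)):
            pos = (site * spacing + 0.15 + 0.12 * i, 0.45, 0.0)
            idx = _add(f"P{i+1}", n_res, q, q, 0.25, 0.25, 0.3, 0.3, pos, True, True)
            atoms[idx].atom_class = "environment"
            if prev is None:
                valence.bonds.append(ValenceTerm("bond", (anchor, idx), (5.0, 0.45), "shared"))
            else:
                valence.bonds.append(ValenceTerm("bond", (prev, idx), (50.0, 0.12), "shared"))
            prev = idx

    amap = AtomMap(
        pairs=[(site_index[wt_names[a]], mut_index[mut_names[b]]) for a, b in amap_local.pairs],
        mutating_residue_id=site,
    )

    def _exclusions() -> set[tuple[int, int]]:
        adj: dict[int, set[int]] = {}
        for b in valence.bonds:
            i, j = b.atoms
            adj.setdefault(i, set()).add(j)
            adj.setdefault(j, set()).add(i)
        excl: set[tuple[int, int]] = set()
        for i, nbrs in adj.items():
            for j in nbrs:
                excl.add((min(i, j), max(i, j)))
                for k2 in adj.get(j, ()):
                    if k2 != i:
                        excl.add((min(i, k2), max(i, k2)))
        uo = [a.index for a in atoms if a.atom_class == "unique_old"]
        un = [a.index for a in atoms if a.atom_class == "unique_new"]
        for i in uo:
            for j in un:
                excl.add((min(i, j), max(i, j)))
        return excl

    hybrid = HybridTopology(atoms, valence, amap, exclusions=_exclusions())
    dq = hybrid.net_charge("new") - hybrid.net_charge("old")
    if abs(dq) > 1e-10:
        ca = chain_index[(site, "CA")]
        widx = _add("WAT", n_res + 1, 0.0, 0.0, 0.25, 0.25, 0.2, 0.2,
                    (site * spacing + 0.15, -0.5, 0.3), True, True)
        atoms[widx].atom_class = "environment"
        valence.bonds.append(ValenceTerm("bond", (ca, widx), (2.0, 0.6), "shared"))
        hybrid = HybridTopology(atoms, valence, amap, exclusions=_exclusions())
        hybrid = apply_counterion_transform(hybrid, water_like_particles=[widx])
    hybrid.validate()
    return hybrid, np.array(positions, dtype=float)


def _wt_bond(wt_tpl, na, nb):
    for x, y, kk, rr in wt_tpl["bonds"]:
        if frozenset((x, y)) == frozenset((na, nb)):
            return (kk, rr)
    return None


# ---------------------------------------------------------------------------
# synthetic archives for convergence-verdict calibration
# ---------------------------------------------------------------------------


def make_stationary_archive(
    n_iterations: int = 1000, seed: int = 0, springs=(1.0, 2.0)
) -> "SimulationArchive":
    """Archive of exact iid equilibrium samples from a 2-state ladder.

    Its DG(t) series is flat up to estimator noise, so the flat-slope
    convergence verdict must pass on it.
    """
    return _ladder_archive(n_iterations, seed, springs, offset=None)


def make_drift_archive(
    n_iterations: int = 1000,
    seed: int = 0,
    springs=(1.0, 2.0),
    drift_magnitude: float = 2.0,
    tau_fraction: float = 0.7,
) -> "SimulationArchive":
    """Archive with a planted, still-relaxing drift in one state.

    An exponentially decaying offset (initial size ``drift_magnitude`` kT,
    time constant ``tau_fraction`` of the run) is added to the last state's
    reduced-potential column, emulating a run whose end state is still
    equilibrating at the end of the simulation: the DG(t) series trends
    through the trailing window and the convergence verdict must fail.
    """
    n = n_iterations
    offset = drift_magnitude * np.exp(-np.arange(n) / (tau_fraction * n))
    return _ladder_archive(n, seed, springs, offset=offset)


def make_two_regime_archive(
    n_iterations: int = 400, seed: int = 0, springs=(1.0, 2.0), shift: float = 2.5
) -> "SimulationArchive":
    """Archive whose first half samples state 0 from a shifted distribution.

    Early DG(t) prefixes are biased, so early points differ from the final
    estimate by more than their uncertainty; by the end the contamination
    is diluted and the estimate recovers.
    """
    rng = np.random.default_rng(seed)
    n = n_iterations
    k = np.asarray(springs, dtype=float)
    xs = np.stack(
        [rng.normal(0.0, 1.0 / np.sqrt(kk), size=n) for kk in k], axis=1
    )
    xs[: n // 2, 0] += shift
    u = 0.5 * k[None, None, :] * xs[:, :, None] ** 2
    from .archive import SimulationArchive

    st = np.tile(np.arange(len(k)), (n, 1))
    return SimulationArchive(u_kln=u, state_trace=st, du_dl=np.zeros((n, len(k))))


def _ladder_archive(n, seed, springs, offset):
    from .archive import SimulationArchive

    rng = np.random.default_rng(seed)
    k = np.asarray(springs, dtype=float)
    xs = np.stack(
        [rng.normal(0.0, 1.0 / np.sqrt(kk), size=n) for kk in k], axis=1
    )
    u = 0.5 * k[None, None, :] * xs[:, :, None] ** 2
    if offset is not None:
        u[:, :, -1] += offset[:, None]
    st = np.tile(np.arange(len(k)), (n, 1))
    return SimulationArchive(u_kln=u, state_trace=st, du_dl=np.zeros((n, len(k))))
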