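"""Hybrid topologies for residue-like alchemical mutations.

A relative free energy calculation transforms a wild-type (WT) residue into
a mutant residue through a single *hybrid* system that contains both
endstates at once.  Atoms shared between the two residues are *mapped* and
carry two parameter sets (old/new charge, sigma, epsilon); atoms present in
only one endstate become dummy particles at the other endstate, retaining
only their valence terms.  Every atom is assigned to one of four classes
that drive the lambda interpolation rules downstream:

* ``unique_old``  — present only in the WT residue,
* ``unique_new``  — present only in the mutant residue,
* ``core``        — mapped atoms in the mutating residue or its immediate
  neighbours,
* ``environment`` — all other mapped atoms (parameters never change).

Charge-changing mutations additionally transform one water-like particle
into a counterion so the net charge is identical at both endstates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

SCHEMA_VERSION = "alchemforge-topology-1"

ATOM_CLASSES = ("unique_old", "unique_new", "core", "environment")

#: Backbone atom labels shared by all residue templates; mapping always
#: covers these plus the beta carbon.
BACKBONE_LABELS = ("N", "H", "CA", "HA", "C", "O")

#: Standard water partial charge used for the transformable particle (a
#: single-bead water stand-in carries net charge 0).
WATER_BEAD_CHARGE = 0.0


class TopologyError(ValueError):
    """Structural problem in a residue template or hybrid topology."""


class ValidationError(ValueError):
    """Inconsistent user input (duplicate labels, bad classes, ...)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class AtomRecord:
    """One particle of the hybrid system with both endstate parameter sets.

    Units: charges in elementary charge, sigma in nm, epsilon in reduced
    energy (kT at 300 K).
    """

    index: int
    name: str
    residue_id: int
    is_heavy: bool
    charge_old: float
    charge_new: float
    sigma_old: float
    sigma_new: float
    epsilon_old: float
    epsilon_new: float
    atom_class: str

    def validate(self) -> None:
        if self.atom_class not in ATOM_CLASSES:
            raise ValidationError(f"unknown atom class {self.atom_class!r}")
        if self.atom_class == "unique_old":
            if self.charge_new != 0.0 or self.epsilon_new != 0.0:
                raise ValidationError(
                    f"unique_old atom {self.name} must be a dummy at the new endstate"
                )
        elif self.atom_class == "unique_new":
            if self.charge_old != 0.0 or self.epsilon_old != 0.0:
                raise ValidationError(
                    f"unique_new atom {self.name} must be a dummy at the old endstate"
                )
        elif self.atom_class == "environment":
            if (
                self.charge_old != self.charge_new
                or self.sigma_old != self.sigma_new
                or self.epsilon_old != self.epsilon_new
            ):
                raise ValidationError(
                    f"environment atom {self.name} must have identical endstate parameters"
                )


@dataclass
class AtomMap:
    """Pairs of WT/mutant atom indices that share coordinates."""

    pairs: list[tuple[int, int]]
    mutating_residue_id: int

    def validate(self) -> None:
        wt = [p[0] for p in self.pairs]
        mut = [p[1] for p in self.pairs]
        if len(set(wt)) != len(wt) or len(set(mut)) != len(mut):
            raise ValidationError("an atom index appears more than once in the map")


@dataclass
class ValenceTerm:
    """A bond, angle or torsion with an endstate tag.

    ``endstate_tag``: ``shared`` terms exist at both endstates; ``old`` /
    ``new`` terms belong to one endstate.  Terms involving a dummy atom are
    always evaluated (dummy atoms retain their valence terms); purely
    core/environment ``old``/``new`` terms are switched linearly in lambda.
    Parameter conventions: bond (k, r0) with U = k/2 (r-r0)^2; angle
    (k, theta0) with U = k/2 (theta-theta0)^2; torsion (k, n, phi0) with
    U = k (1 + cos(n*phi - phi0)).
    """

    kind: str  # bond | angle | torsion
    atoms: tuple[int, ...]
    params: tuple[float, ...]
    endstate_tag: str = "shared"

    def validate(self) -> None:
        n_expected = {"bond": 2, "angle": 3, "torsion": 4}
        if self.kind not in n_expected:
            raise ValidationError(f"unknown valence kind {self.kind!r}")
        if len(self.atoms) != n_expected[self.kind]:
            raise ValidationError(f"{self.kind} needs {n_expected[self.kind]} atoms")
        if self.endstate_tag not in ("old", "new", "shared"):
            raise ValidationError(f"bad endstate tag {self.endstate_tag!r}")


@dataclass
class ValenceTermSet:
    bonds: list[ValenceTerm] = field(default_factory=list)
    angles: list[ValenceTerm] = field(default_factory=list)
    torsions: list[ValenceTerm] = field(default_factory=list)

    def all_terms(self) -> list[ValenceTerm]:
        return [*self.bonds, *self.angles, *self.torsions]


@dataclass
class CounterionTransform:
    """Record of the water -> ion transformation neutralising a charge change."""

    water_index: int | None = None
    ion_charge: float = 0.0
    ion_lj: tuple[float, float] = (0.0, 0.0)

    @property
    def active(self) -> bool:
        return self.water_index is not None


@dataclass
class HybridTopology:
    """The single hybrid system containing both mutation endstates."""

    atoms: list[AtomRecord]
    valence: ValenceTermSet
    atom_map: AtomMap
    counterion: CounterionTransform = field(default_factory=CounterionTransform)
    exclusions: set[tuple[int, int]] = field(default_factory=set)

    # -- invariants ---------------------------------------------------------

    def net_charge(self, end: str) -> float:
        attr = "charge_old" if end == "old" else "charge_new"
        return float(sum(getattr(a, attr) for a in self.atoms))

    def validate(self, check_neutrality: bool = True) -> None:
        for a in self.atoms:
            a.validate()
        for t in self.valence.all_terms():
            t.validate()
        self.atom_map.validate()
        # every unique_old/unique_new cross pair must be excluded
        uo = [a.index for a in self.atoms if a.atom_class == "unique_old"]
        un = [a.index for a in self.atoms if a.atom_class == "unique_new"]
        for i in uo:
            for j in un:
                if _key(i, j) not in self.exclusions:
                    raise ValidationError(
                        f"unique_old/unique_new pair ({i},{j}) is not excluded"
                    )
        if check_neutrality:
            dq = self.net_charge("new") - self.net_charge("old")
            if abs(dq) > 1e-10:
                raise ValidationError(
                    f"endstate net charges differ by {dq:+.3g} e; "
                    "apply a counterion transform"
                )
        # dummy atoms must be anchored by valence terms of their endstate
        self._check_dummy_anchoring()

    def _check_dummy_anchoring(self) -> None:
        for cls, tag in (("unique_old", "old"), ("unique_new", "new")):
            dummies = {a.index for a in self.atoms if a.atom_class == cls}
            core = {a.index for a in self.atoms if a.atom_class == "core"}
            for d in dummies:
                anchored = any(
                    d in t.atoms
                    and t.endstate_tag in (tag, "shared")
                    and any(x in core or x in dummies for x in t.atoms if x != d)
                    for t in self.valence.all_terms()
                )
                if not anchored:
                    raise ValidationError(
                        f"dummy atom {d} ({cls}) has no valence term anchoring it"
                    )

    def atom_class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in ATOM_CLASSES}
        for a in self.atoms:
            counts[a.atom_class] += 1
        return counts

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema": SCHEMA_VERSION,
            "atoms": [vars(a) for a in self.atoms],
            "valence": {
                kind: [
                    {
                        "kind": t.kind,
                        "atoms": list(t.atoms),
                        "params": list(t.params),
                        "endstate_tag": t.endstate_tag,
                    }
                    for t in getattr(self.valence, kind)
                ]
                for kind in ("bonds", "angles", "torsions")
            },
            "atom_map": {
                "pairs": [list(p) for p in self.atom_map.pairs],
                "mutating_residue_id": self.atom_map.mutating_residue_id,
            },
            "counterion": {
                "water_index": self.counterion.water_index,
                "ion_charge": self.counterion.ion_charge,
                "ion_lj": list(self.counterion.ion_lj),
            },
            "exclusions": sorted(list(p) for p in self.exclusions),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HybridTopology":
        if d.get("schema") != SCHEMA_VERSION:
            raise ValidationError(f"unsupported topology schema {d.get('schema')!r}")
        atoms = [AtomRecord(**a) for a in d["atoms"]]
        valence = ValenceTermSet(
            **{
                kind: [
                    ValenceTerm(
                        kind=t["kind"],
                        atoms=tuple(t["atoms"]),
                        params=tuple(t["params"]),
                        endstate_tag=t["endstate_tag"],
                    )
                    for t in d["valence"][kind]
                ]
                for kind in ("bonds", "angles", "torsions")
            }
        )
        amap = AtomMap(
            pairs=[tuple(p) for p in d["atom_map"]["pairs"]],
            mutating_residue_id=d["atom_map"]["mutating_residue_id"],
        )
        ct = CounterionTransform(
            water_index=d["counterion"]["water_index"],
            ion_charge=d["counterion"]["ion_charge"],
            ion_lj=tuple(d["counterion"]["ion_lj"]),
        )
        exclusions = {tuple(p) for p in d["exclusions"]}
        return cls(atoms, valence, amap, ct, exclusions)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "HybridTopology":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _key(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _is_beta_hydrogen(name: str) -> bool:
    return name.startswith("HB")


def _is_hydrogen(name: str) -> bool:
    return name.startswith("H")


def build_atom_map(
    wt_residue_atoms: Sequence[str],
    mut_residue_atoms: Sequence[str],
    hydrogen_constraint_lengths: dict[str, float] | None = None,
    mutating_residue_id: int = 0,
) -> AtomMap:
    """Map WT and mutant residue atoms that will share coordinates.

    The mapping pairs atoms by label.  For a genuine mutation it covers the
    backbone up to and including the beta carbon; beta hydrogens are never
    mapped (their count/geometry differs across residue types and leaving
    them unmapped grants free sidechain sampling when non-interacting).  For
    an identity "mutation" every equally-named atom except the beta
    hydrogens is mapped.  Because bonds to hydrogen are treated as
    constrained, any mapped hydrogen whose constrained bond length differs
    between endstates is un-mapped again.

    Parameters are label lists in template order; indices in the returned
    map refer to positions in these lists.
    """
    for side, labels in (("WT", wt_residue_atoms), ("mutant", mut_residue_atoms)):
        if len(set(labels)) != len(labels):
            raise ValidationError(f"duplicate atom labels on the {side} side")
    wt_set, mut_set = set(wt_residue_atoms), set(mut_residue_atoms)
    for side, labels in (("WT", wt_set), ("mutant", mut_set)):
        # glycine-like templates carry no CB and are allowed; anything with
        # sidechain atoms but no CB is malformed
        has_sidechain = any(
            l not in BACKBONE_LABELS and not l.startswith("HA") for l in labels
        )
        if has_sidechain and "CB" not in labels:
            raise TopologyError(f"{side} residue has sidechain atoms but no CB")

    identical = wt_set == mut_set
    if identical:
        candidates = [l for l in wt_residue_atoms if not _is_beta_hydrogen(l)]
    else:
        allowed = set(BACKBONE_LABELS) | {"CB"}
        candidates = [
            l
            for l in wt_residue_atoms
            if l in allowed and l in mut_set and not _is_beta_hydrogen(l)
        ]

    constraints = hydrogen_constraint_lengths or {}
    pairs: list[tuple[int, int]] = []
    wt_index = {l: i for i, l in enumerate(wt_residue_atoms)}
    mut_index = {l: i for i, l in enumerate(mut_residue_atoms)}
    for label in candidates:
        if _is_hydrogen(label):
            # un-map hydrogens whose constrained bond length changes
            l_wt = constraints.get(f"wt:{label}", constraints.get(label))
            l_mut = constraints.get(f"mut:{label}", constraints.get(label))
            if l_wt is not None and l_mut is not None and l_wt != l_mut:
                continue
        pairs.append((wt_index[label], mut_index[label]))
    return AtomMap(pairs=pairs, mutating_residue_id=mutating_residue_id)


def classify_atoms(
    residue_ids: Sequence[int],
    mapped: Sequence[bool],
    from_wt: Sequence[bool],
    mutating_residue_id: int,
    flanking_residue_ids: Iterable[int],
) -> list[str]:
    """Assign every hybrid atom to an atom class.

    ``residue_ids``/``mapped``/``from_wt`` are parallel arrays over hybrid
    atoms: ``mapped[i]`` marks atoms shared by both endstates; for unmapped
    atoms ``from_wt[i]`` says which endstate owns them.  Mapped atoms of the
    mutating residue and of the residues immediately preceding/following it
    are core; all other mapped atoms are environment.
    """
    flanking = set(flanking_residue_ids)
    classes: list[str] = []
    for rid, m, wt in zip(residue_ids, mapped, from_wt):
        if not m:
            classes.append("unique_old" if wt else "unique_new")
        elif rid == mutating_residue_id or rid in flanking:
            classes.append("core")
        else:
            classes.append("environment")
    if len(classes) != len(residue_ids):  # pragma: no cover - internal
        raise TopologyError("atom left unclassified")
    return classes


def apply_counterion_transform(
    hybrid: HybridTopology,
    water_like_particles: Sequence[int],
    selection: str | int = "first",
) -> HybridTopology:
    """Neutralise a charge-changing mutation by turning a water into an ion.

    The net charge change of the mutation dq = sum(q_new) - sum(q_old) is
    computed over the whole topology; for dq = -1 one water-like particle
    becomes a sodium (+1) in the mutant endstate, for dq = +1 a chloride
    (-1).  Charge-preserving mutations are returned unchanged.  ``selection``
    picks the transformed particle: ``"first"`` or an explicit index into
    ``water_like_particles`` (no physical criterion forces a particular
    water at desk scale, so the policy is explicit here).
    """
    dq = hybrid.net_charge("new") - hybrid.net_charge("old")
    if abs(dq) < 1e-10:
        return hybrid
    if abs(abs(dq) - 1.0) > 1e-10:
        raise TopologyError(
            f"unsupported transform: |charge change| = {abs(dq):.3g} (only +/-1 supported)"
        )
    if not water_like_particles:
        raise TopologyError("charge-changing mutation but no water-like particles")
    if selection == "first":
        widx = water_like_particles[0]
    else:
        widx = water_like_particles[int(selection)]

    ion_charge = -dq  # Na+ for dq=-1, Cl- for dq=+1
    # ion LJ parameters: Na+/Cl- bead radii (nm) and well depth in kT
    ion_lj = (0.23, 0.2) if ion_charge > 0 else (0.40, 0.2)

    atoms = [replace(a) for a in hybrid.atoms]
    w = atoms[widx]
    if w.atom_class == "environment":
        w.atom_class = "core"  # its parameters now change with lambda
    w.charge_new = w.charge_old + ion_charge
    w.sigma_new, w.epsilon_new = ion_lj
    out = HybridTopology(
        atoms=atoms,
        valence=hybrid.valence,
        atom_map=hybrid.atom_map,
        counterion=CounterionTransform(widx, ion_charge, ion_lj),
        exclusions=set(hybrid.exclusions),
    )
    if abs(out.net_charge("new") - out.net_charge("old")) > 1e-10:
        raise TopologyError("counterion transform failed to neutralise the system")
    return out


def swap_endstates(hybrid: HybridTopology) -> HybridTopology:
    """Return the reverse transformation (old/new parameter sets swapped).

    unique_old atoms become unique_new and vice versa; valence tags flip.
    Running the reverse hybrid yields DG_rev = -DG_fwd in distribution.
    """
    flip_class = {"unique_old": "unique_new", "unique_new": "unique_old"}
    flip_tag = {"old": "new", "new": "old", "shared": "shared"}
    atoms = [
        AtomRecord(
            index=a.index,
            name=a.name,
            residue_id=a.residue_id,
            is_heavy=a.is_heavy,
            charge_old=a.charge_new,
            charge_new=a.charge_old,
            sigma_old=a.sigma_new,
            sigma_new=a.sigma_old,
            epsilon_old=a.epsilon_new,
            epsilon_new=a.epsilon_old,
            atom_class=flip_class.get(a.atom_class, a.atom_class),
        )
        for a in hybrid.atoms
    ]
    def _flip(terms: list[ValenceTerm]) -> list[ValenceTerm]:
        return [
            ValenceTerm(t.kind, t.atoms, t.params, flip_tag[t.endstate_tag])
            for t in terms
        ]

    valence = ValenceTermSet(
        bonds=_flip(hybrid.valence.bonds),
        angles=_flip(hybrid.valence.angles),
        torsions=_flip(hybrid.valence.torsions),
    )
    amap = AtomMap(
        pairs=[(b, a) for a, b in hybrid.atom_map.pairs],
        mutating_residue_id=hybrid.atom_map.mutating_residue_id,
    )
    ct = hybrid.counterion
    rev_ct = CounterionTransform(ct.water_index, -ct.ion_charge, ct.ion_lj) if ct.active else CounterionTransform()
    return HybridTopology(atoms, valence, amap, rev_ct, set(hybrid.exclusions))
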