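"""Solute-tempering (REST) scaling layered on the alchemical potential.

AREST heats a user-defined region around the mutating residue at the
intermediate alchemical states: every bond, angle, torsion and nonbonded
interaction is classified once, on an initial conformation, as

* ``rest``    — all atoms of the interaction are in the REST region,
* ``inter``   — some atoms in, some out,
* ``nonrest`` — none in,

and the total potential becomes

    u_total(lambda) = alpha * u_rest + alpha**p * u_inter + u_nonrest

where alpha is the effective-temperature scale factor and p is the
``inter_exponent``.  The scale factor follows a triangular inverse-
temperature schedule: beta_eff interpolates linearly from beta(T0) at
lambda = 0 down to beta(Tmax) at lambda = 0.5 and back up to beta(T0) at
lambda = 1, so alpha(0) = alpha(1) = 1 (the endstates are exactly
unscaled) and alpha(0.5) = T0/Tmax.

The printed form of the scaling applies alpha to both the rest and inter
terms; the common solute-tempering (REST2) convention uses sqrt(alpha) for
the inter terms.  Both are supported through ``inter_exponent`` (0.5
default, the REST2 convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy import (
    ElectrostaticsParams,
    PairTable,
    SoftcoreParams,
    _pair_energies_and_derivs,
    _TERM_ENERGY,
    valence_term_weight,
)
from .topology import HybridTopology


@dataclass
class RESTConfig:
    """REST region and temperature ladder configuration."""

    t0: float = 300.0
    tmax: float = 600.0
    radius: float = 0.5  # nm
    inter_exponent: float = 0.5

    def __post_init__(self) -> None:
        if not (self.tmax >= self.t0 > 0):
            raise ValueError("need tmax >= t0 > 0")
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if self.inter_exponent not in (0.5, 1.0):
            raise ValueError("inter_exponent must be 0.5 or 1.0")


def rest_scale_factor(lam: float, config: RESTConfig) -> float:
    """alpha(lambda): triangular inverse-temperature schedule.

    alpha = beta_eff(lambda)/beta(T0); 1 at the endstates, T0/Tmax at the
    midpoint.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda {lam} outside [0, 1]")
    amin = config.t0 / config.tmax
    s = lam if lam <= 0.5 else 1.0 - lam
    return 1.0 + (amin - 1.0) * (2.0 * s)


def select_rest_region(
    positions: np.ndarray, hybrid: HybridTopology, radius: float
) -> frozenset[int]:
    """REST region: mutating-residue atoms plus all atoms within ``radius``.

    Distances are evaluated on the supplied (initial) conformation only;
    the region is fixed for the whole run.
    """
    positions = np.asarray(positions, dtype=float)
    rid = hybrid.atom_map.mutating_residue_id
    seed = [a.index for a in hybrid.atoms if a.residue_id == rid]
    if not seed:
        raise ValueError(f"mutating residue {rid} has no atoms")
    if radius == 0.0:
        return frozenset(seed)
    d = positions[:, None, :] - positions[None, seed, :]
    dist = np.sqrt(np.sum(d * d, axis=2))
    near = np.where(np.min(dist, axis=1) <= radius)[0]
    return frozenset(int(i) for i in near) | frozenset(seed)


def classify_interaction(term_atom_indices, rest_region) -> str:
    """rest / inter / nonrest by region membership of the term's atoms."""
    atoms = tuple(term_atom_indices)
    if not atoms:
        raise ValueError("empty interaction term")
    inside = sum(1 for a in atoms if a in rest_region)
    if inside == len(atoms):
        return "rest"
    if inside == 0:
        return "nonrest"
    return "inter"


_CLASS_EXP = {"rest": 1.0, "inter": None, "nonrest": 0.0}  # exponent on alpha


@dataclass
class RestScaling:
    """Frozen interaction classification for one hybrid + region.

    Exponent arrays give, per nonbonded pair / valence term, the power of
    alpha applied to that interaction (1 for rest, p for inter, 0 for
    nonrest); with REST disabled all exponents are 0 and the scale vector
    is exactly 1, making AREX and endstate-AREST energies bit-identical.
    """

    config: RESTConfig | None
    pair_exponent: np.ndarray
    term_exponent: np.ndarray

    @classmethod
    def build(
        cls,
        hybrid: HybridTopology,
        pair_table: PairTable,
        region: frozenset[int] | None,
        config: RESTConfig | None,
    ) -> "RestScaling":
        n_pairs = pair_table.i.size
        terms = hybrid.valence.all_terms()
        if config is None or region is None:
            return cls(None, np.zeros(n_pairs), np.zeros(len(terms)))
        p = config.inter_exponent

        def exponent(atoms) -> float:
            c = classify_interaction(atoms, region)
            return {"rest": 1.0, "inter": p, "nonrest": 0.0}[c]

        pair_exp = np.array(
            [exponent((int(a), int(b))) for a, b in zip(pair_table.i, pair_table.j)]
        )
        term_exp = np.array([exponent(t.atoms) for t in terms])
        return cls(config, pair_exp, term_exp)

    def scales(self, lam: float) -> tuple[np.ndarray, np.ndarray]:
        if self.config is None:
            return np.ones_like(self.pair_exponent), np.ones_like(self.term_exponent)
        alpha = rest_scale_factor(lam, self.config)
        return alpha**self.pair_exponent, alpha**self.term_exponent


def scaled_total_energy(
    positions: np.ndarray,
    hybrid: HybridTopology,
    lam: float,
    rest_config: RESTConfig | None,
    energy_params: ElectrostaticsParams | None = None,
    softcore: SoftcoreParams | None = None,
    region: frozenset[int] | None = None,
    pair_table: PairTable | None = None,
    scaling: RestScaling | None = None,
) -> float:
    """REST-scaled total alchemical potential (reduced units).

    With ``rest_config=None`` this is exactly the unscaled alchemical
    energy, evaluated through the identical code path so endstate energies
    agree bitwise between AREX and AREST.
    """
    positions = np.asarray(positions, dtype=float)
    energy_params = energy_params or ElectrostaticsParams()
    softcore = softcore or SoftcoreParams()
    pt = pair_table or PairTable.from_topology(hybrid)
    if scaling is None:
        if rest_config is not None and region is None:
            region = select_rest_region(positions, hybrid, rest_config.radius)
        scaling = RestScaling.build(hybrid, pt, region, rest_config)
    pair_scales, term_scales = scaling.scales(lam)

    if pt.i.size:
        d = positions[pt.j] - positions[pt.i]
        r = np.sqrt(np.sum(d * d, axis=1))
        u_pairs, _ = _pair_energies_and_derivs(pt, r, lam, energy_params, softcore)
        u = float(np.sum(u_pairs * pair_scales))
    else:
        u = 0.0

    dummies = frozenset(
        a.index for a in hybrid.atoms if a.atom_class in ("unique_old", "unique_new")
    )
    for t, s in zip(hybrid.valence.all_terms(), term_scales):
        w = valence_term_weight(t, lam, dummies)
        if w != 0.0:
            u += float(s) * w * _TERM_ENERGY[t.kind](positions, t)
    return u
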