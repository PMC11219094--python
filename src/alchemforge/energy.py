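"""Lambda-dependent alchemical potential energy.

The nonbonded interactions of a hybrid topology are interpolated in the
alchemical parameter lambda in [0, 1]:

* charges are linearly interpolated per atom class: unique_old atoms carry
  (1-lambda) q_old, unique_new atoms lambda q_new, core atoms the linear
  blend, environment atoms their fixed charge;
* Lennard-Jones epsilon follows the same per-class rule, sigma interpolates
  only for core atoms (unique atoms keep their own sigma);
* singularities from vanishing particles are avoided by a softcore scheme
  that lifts distances into a 4th dimension: the effective distance is
  r_eff = sqrt(r^2 + w(lambda)^2) with w = w_lifting * lambda when the pair
  involves a unique_old atom and w = w_lifting * (1 - lambda) when it
  involves a unique_new atom (pairs containing both kinds are excluded).

Electrostatics use the direct-space Ewald form C q_i q_j erfc(alpha r_eff)
/ r_eff; with ``use_plain_coulomb`` the erfc factor is 1, which is the
appropriate limit for non-periodic desk systems (reciprocal-space and
self-energy terms of a full PME treatment are out of scope here).

At lambda = 0 the total potential equals the plain WT potential plus the
valence terms of the dummy new atoms; symmetrically at lambda = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erfc

from .topology import HybridTopology, ValenceTerm
from .units import COULOMB_CONSTANT_REDUCED

_CLS_CODE = {"unique_old": 0, "unique_new": 1, "core": 2, "environment": 3}


class SingularGeometryError(ArithmeticError):
    """r_eff = 0 encountered (coincident atoms with no lifting)."""


@dataclass
class ElectrostaticsParams:
    """Direct-space electrostatics configuration.

    ``alpha_pme`` is the Ewald screening parameter (1/nm); ``coulomb_constant``
    is in reduced energy * nm / e^2; ``cutoff`` in nm (``inf`` disables).
    """

    alpha_pme: float = 0.0
    coulomb_constant: float = COULOMB_CONSTANT_REDUCED
    cutoff: float = math.inf
    use_plain_coulomb: bool = True

    def __post_init__(self) -> None:
        if self.alpha_pme < 0:
            raise ValueError("alpha_pme must be >= 0")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")


@dataclass
class SoftcoreParams:
    """Softcore lifting configuration; ``w_lifting`` is the maximal lifting
    distance in nm (0.4 nm default, chosen to keep r=0 energies modest while
    preserving neighbouring-state overlap on the desk toys)."""

    w_lifting: float = 0.4

    def __post_init__(self) -> None:
        if self.w_lifting < 0:
            raise ValueError("w_lifting must be >= 0")


@dataclass
class LambdaProtocol:
    """Ordered alchemical schedule, lambda_0 = 0 to lambda_{K-1} = 1."""

    lambdas: tuple[float, ...]

    def __post_init__(self) -> None:
        lam = tuple(float(x) for x in self.lambdas)
        if len(lam) < 2:
            raise ValueError("a protocol needs at least 2 states")
        if lam[0] != 0.0 or lam[-1] != 1.0:
            raise ValueError("protocol must start at 0 and end at 1")
        if any(b <= a for a, b in zip(lam, lam[1:])):
            raise ValueError("lambdas must be strictly increasing")
        self.lambdas = lam

    @property
    def n_states(self) -> int:
        return len(self.lambdas)


def build_lambda_protocol(n_states: int) -> LambdaProtocol:
    """Evenly spaced lambdas from a simple linear function: k/(K-1)."""
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    return LambdaProtocol(tuple(k / (n_states - 1) for k in range(n_states)))


#: Protocol presets with the state counts commonly used in production
#: calculations for neutral and charge-changing mutations.
PROTOCOL_PRESETS = {"neutral": 24, "charge": 36}


def preset_protocol(kind: str) -> LambdaProtocol:
    return build_lambda_protocol(PROTOCOL_PRESETS[kind])


# ---------------------------------------------------------------------------
# scalar per-pair operations (reference semantics; the vectorised pair table
# below is what the sampler actually calls)
# ---------------------------------------------------------------------------


def _check_lambda(lam: float) -> None:
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda {lam} outside [0, 1]")


def interpolate_charge(atom, lam: float) -> float:
    """Per-class linearly interpolated charge q_i(lambda)."""
    _check_lambda(lam)
    c = atom.atom_class
    if c == "unique_old":
        return (1.0 - lam) * atom.charge_old
    if c == "unique_new":
        return lam * atom.charge_new
    if c == "core":
        return (1.0 - lam) * atom.charge_old + lam * atom.charge_new
    return atom.charge_old


def interpolate_epsilon(atom, lam: float) -> float:
    _check_lambda(lam)
    c = atom.atom_class
    if atom.epsilon_old < 0 or atom.epsilon_new < 0:
        raise ValueError("negative epsilon")
    if c == "unique_old":
        return (1.0 - lam) * atom.epsilon_old
    if c == "unique_new":
        return lam * atom.epsilon_new
    if c == "core":
        return (1.0 - lam) * atom.epsilon_old + lam * atom.epsilon_new
    return atom.epsilon_old


def interpolate_sigma(atom, lam: float) -> float:
    _check_lambda(lam)
    c = atom.atom_class
    if c == "unique_old":
        return atom.sigma_old
    if c == "unique_new":
        return atom.sigma_new
    if c == "core":
        return (1.0 - lam) * atom.sigma_old + lam * atom.sigma_new
    return atom.sigma_old


def lifting_distance(class_i: str, class_j: str, lam: float, softcore: SoftcoreParams) -> float:
    """w(lambda) for one pair; nonzero only for pairs with a unique atom."""
    _check_lambda(lam)
    has_old = "unique_old" in (class_i, class_j)
    has_new = "unique_new" in (class_i, class_j)
    if has_old and has_new:
        raise ValueError("unique_old/unique_new pairs must be excluded upstream")
    if has_old:
        return softcore.w_lifting * lam
    if has_new:
        return softcore.w_lifting * (1.0 - lam)
    return 0.0


def effective_distance(r: float, w: float) -> float:
    """r_eff = sqrt(r^2 + w^2)."""
    if r < 0:
        raise ValueError("r must be >= 0")
    return math.hypot(r, w)


def direct_electrostatics(
    r: float,
    atom_i,
    atom_j,
    lam: float,
    params: ElectrostaticsParams,
    softcore: SoftcoreParams,
) -> float:
    """Direct-space electrostatic pair energy at lambda (reduced units)."""
    qi = interpolate_charge(atom_i, lam)
    qj = interpolate_charge(atom_j, lam)
    if qi == 0.0 or qj == 0.0:
        return 0.0
    w = lifting_distance(atom_i.atom_class, atom_j.atom_class, lam, softcore)
    reff = effective_distance(r, w)
    if reff == 0.0:
        raise SingularGeometryError("coincident atoms with zero lifting distance")
    screen = 1.0 if params.use_plain_coulomb else erfc(params.alpha_pme * reff)
    if r > params.cutoff:
        return 0.0
    return params.coulomb_constant * qi * qj * screen / reff


def sterics_energy(r: float, atom_i, atom_j, lam: float, softcore: SoftcoreParams) -> float:
    """Softcore Lennard-Jones pair energy: 4 eps_ij x (x - 1), x = (sig/r_eff)^6."""
    eps = math.sqrt(interpolate_epsilon(atom_i, lam) * interpolate_epsilon(atom_j, lam))
    if eps == 0.0:
        return 0.0
    sig = 0.5 * (interpolate_sigma(atom_i, lam) + interpolate_sigma(atom_j, lam))
    w = lifting_distance(atom_i.atom_class, atom_j.atom_class, lam, softcore)
    reff = effective_distance(r, w)
    if reff == 0.0:
        raise SingularGeometryError("coincident atoms with zero lifting distance")
    x = (sig / reff) ** 6
    return 4.0 * eps * x * (x - 1.0)


# ---------------------------------------------------------------------------
# vectorised evaluation over a whole hybrid topology
# ---------------------------------------------------------------------------


@dataclass
class PairTable:
    """Precomputed nonbonded pair arrays for a hybrid topology."""

    i: np.ndarray
    j: np.ndarray
    q_old_i: np.ndarray
    q_new_i: np.ndarray
    q_old_j: np.ndarray
    q_new_j: np.ndarray
    sig_old_i: np.ndarray
    sig_new_i: np.ndarray
    sig_old_j: np.ndarray
    sig_new_j: np.ndarray
    eps_old_i: np.ndarray
    eps_new_i: np.ndarray
    eps_old_j: np.ndarray
    eps_new_j: np.ndarray
    cls_i: np.ndarray
    cls_j: np.ndarray
    has_old: np.ndarray  # pair involves a unique_old atom
    has_new: np.ndarray

    @classmethod
    def from_topology(cls, hybrid: HybridTopology) -> "PairTable":
        n = len(hybrid.atoms)
        ii, jj = np.triu_indices(n, k=1)
        excl = hybrid.exclusions
        keep = np.array(
            [(int(a), int(b)) not in excl for a, b in zip(ii, jj)], dtype=bool
        )
        ii, jj = ii[keep], jj[keep]

        def arr(attr):
            return np.array([getattr(a, attr) for a in hybrid.atoms], dtype=float)

        code = np.array([_CLS_CODE[a.atom_class] for a in hybrid.atoms])
        q_old, q_new = arr("charge_old"), arr("charge_new")
        s_old, s_new = arr("sigma_old"), arr("sigma_new")
        e_old, e_new = arr("epsilon_old"), arr("epsilon_new")
        ci, cj = code[ii], code[jj]
        return cls(
            i=ii,
            j=jj,
            q_old_i=q_old[ii], q_new_i=q_new[ii],
            q_old_j=q_old[jj], q_new_j=q_new[jj],
            sig_old_i=s_old[ii], sig_new_i=s_new[ii],
            sig_old_j=s_old[jj], sig_new_j=s_new[jj],
            eps_old_i=e_old[ii], eps_new_i=e_new[ii],
            eps_old_j=e_old[jj], eps_new_j=e_new[jj],
            cls_i=ci, cls_j=cj,
            has_old=(ci == 0) | (cj == 0),
            has_new=(ci == 1) | (cj == 1),
        )

    def atom_indices(self) -> tuple[np.ndarray, np.ndarray]:
        return self.i, self.j


def _interp(v_old, v_new, code, lam, interpolate_for_unique):
    """Per-class interpolation of a per-atom parameter array."""
    out = np.where(code == 3, v_old, 0.0)
    core = code == 2
    out = np.where(core, (1 - lam) * v_old + lam * v_new, out)
    if interpolate_for_unique:  # charge / epsilon rule
        out = np.where(code == 0, (1 - lam) * v_old, out)
        out = np.where(code == 1, lam * v_new, out)
    else:  # sigma rule: unique atoms keep their own sigma
        out = np.where(code == 0, v_old, out)
        out = np.where(code == 1, v_new, out)
    return out


def _pair_energies_and_derivs(
    pt: PairTable,
    r: np.ndarray,
    lam: float,
    params: ElectrostaticsParams,
    softcore: SoftcoreParams,
):
    """Vectorised pair energies and dU/dr_pair at one lambda.

    Returns (u_pair, du_dr) arrays over the pair table.
    """
    qi = _interp(pt.q_old_i, pt.q_new_i, pt.cls_i, lam, True)
    qj = _interp(pt.q_old_j, pt.q_new_j, pt.cls_j, lam, True)
    ei = _interp(pt.eps_old_i, pt.eps_new_i, pt.cls_i, lam, True)
    ej = _interp(pt.eps_old_j, pt.eps_new_j, pt.cls_j, lam, True)
    si = _interp(pt.sig_old_i, pt.sig_new_i, pt.cls_i, lam, False)
    sj = _interp(pt.sig_old_j, pt.sig_new_j, pt.cls_j, lam, False)

    w = softcore.w_lifting * (pt.has_old * lam + pt.has_new * (1.0 - lam))
    reff2 = r * r + w * w
    if np.any(reff2 == 0.0):
        raise SingularGeometryError("coincident atoms with zero lifting distance")
    reff = np.sqrt(reff2)

    # electrostatics
    qq = params.coulomb_constant * qi * qj
    if params.use_plain_coulomb:
        u_el = qq / reff
        du_el_dreff = -qq / reff2
    else:
        a = params.alpha_pme
        sc = erfc(a * reff)
        u_el = qq * sc / reff
        du_el_dreff = -qq * (
            sc / reff2 + (2.0 * a / math.sqrt(math.pi)) * np.exp(-(a * reff) ** 2) / reff
        )

    # sterics
    eps = np.sqrt(ei * ej)
    sig = 0.5 * (si + sj)
    x = (sig / reff) ** 6
    u_lj = 4.0 * eps * x * (x - 1.0)
    du_lj_dreff = 4.0 * eps * (2.0 * x - 1.0) * (-6.0 * x / reff)

    in_range = r <= params.cutoff
    u = np.where(in_range, u_el + u_lj, 0.0)
    du_dreff = np.where(in_range, du_el_dreff + du_lj_dreff, 0.0)
    # chain rule through r_eff(r) = sqrt(r^2 + w^2)
    du_dr = du_dreff * (r / reff)
    return u, du_dr


# ---------------------------------------------------------------------------
# valence terms
# ---------------------------------------------------------------------------


def _bond_energy(x: np.ndarray, t: ValenceTerm) -> float:
    i, j = t.atoms
    k, r0 = t.params
    r = float(np.linalg.norm(x[j] - x[i]))
    return 0.5 * k * (r - r0) ** 2


def _angle_energy(x: np.ndarray, t: ValenceTerm) -> float:
    i, j, k_ = t.atoms
    k, th0 = t.params
    v1 = x[i] - x[j]
    v2 = x[k_] - x[j]
    c = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    th = math.acos(max(-1.0, min(1.0, c)))
    return 0.5 * k * (th - th0) ** 2


def _torsion_energy(x: np.ndarray, t: ValenceTerm) -> float:
    from .diagnostics import dihedral_angle  # geometry helper

    i, j, k_, l = t.atoms
    k, n, phi0 = t.params
    phi = math.radians(dihedral_angle(x[i], x[j], x[k_], x[l]))
    return k * (1.0 + math.cos(n * phi - phi0))


_TERM_ENERGY = {"bond": _bond_energy, "angle": _angle_energy, "torsion": _torsion_energy}


def valence_term_weight(t: ValenceTerm, lam: float, dummy_atoms: frozenset[int]) -> float:
    """Endstate presence weight of a valence term.

    Shared terms are always on.  Terms touching a dummy atom are always on
    regardless of tag (dummy atoms retain their valence terms so the
    non-interacting residue stays intact).  Remaining old/new terms (core
    atoms whose valence parameters change) switch linearly.
    """
    if t.endstate_tag == "shared" or any(a in dummy_atoms for a in t.atoms):
        return 1.0
    return 1.0 - lam if t.endstate_tag == "old" else lam


def valence_energy(
    positions: np.ndarray, hybrid: HybridTopology, lam: float
) -> float:
    dummies = frozenset(
        a.index for a in hybrid.atoms if a.atom_class in ("unique_old", "unique_new")
    )
    u = 0.0
    for t in hybrid.valence.all_terms():
        w = valence_term_weight(t, lam, dummies)
        if w != 0.0:
            u += w * _TERM_ENERGY[t.kind](positions, t)
    return u


# ---------------------------------------------------------------------------
# totals
# ---------------------------------------------------------------------------


def total_energy(
    positions: np.ndarray,
    hybrid: HybridTopology,
    lam: float,
    params: ElectrostaticsParams | None = None,
    softcore: SoftcoreParams | None = None,
    pair_table: PairTable | None = None,
) -> float:
    """Total alchemical potential U(x; lambda) in reduced units."""
    _check_lambda(lam)
    positions = np.asarray(positions, dtype=float)
    if not np.all(np.isfinite(positions)):
        raise ValueError("non-finite positions")
    params = params or ElectrostaticsParams()
    softcore = softcore or SoftcoreParams()
    pt = pair_table or PairTable.from_topology(hybrid)
    if pt.i.size:
        d = positions[pt.j] - positions[pt.i]
        r = np.sqrt(np.sum(d * d, axis=1))
        u_pairs, _ = _pair_energies_and_derivs(pt, r, lam, params, softcore)
        u_nb = float(np.sum(u_pairs))
    else:
        u_nb = 0.0
    return u_nb + valence_energy(positions, hybrid, lam)


def du_dlambda(
    positions: np.ndarray,
    hybrid: HybridTopology,
    lam: float,
    params: ElectrostaticsParams | None = None,
    softcore: SoftcoreParams | None = None,
    dl: float = 1e-4,
    pair_table: PairTable | None = None,
) -> float:
    """dU/dlambda by central finite difference (one-sided at the endpoints)."""
    if dl <= 0:
        raise ValueError("dl must be > 0")
    lo, hi = lam - dl, lam + dl
    if lo < 0.0:
        lo = lam
    if hi > 1.0:
        hi = lam
    if lo == hi:
        raise ValueError("dl too large for the interval")
    u_lo = total_energy(positions, hybrid, lo, params, softcore, pair_table)
    u_hi = total_energy(positions, hybrid, hi, params, softcore, pair_table)
    return (u_hi - u_lo) / (hi - lo)


# ---------------------------------------------------------------------------
# plain (non-alchemical) endstate evaluation — used for endpoint-identity
# checks; deliberately coded without the lambda interpolation machinery
# ---------------------------------------------------------------------------


def endstate_energy(
    positions: np.ndarray,
    hybrid: HybridTopology,
    end: str,
    params: ElectrostaticsParams | None = None,
) -> float:
    """Physical potential of one endstate (no softcore, no interpolation).

    ``end='old'`` evaluates the WT system: nonbonded interactions among the
    atoms present at the old endstate (unique_old, core, environment) with
    their old parameters, plus the old-side and shared valence terms.
    """
    if end not in ("old", "new"):
        raise ValueError("end must be 'old' or 'new'")
    params = params or ElectrostaticsParams()
    positions = np.asarray(positions, dtype=float)
    absent_cls = "unique_new" if end == "old" else "unique_old"
    present = [a for a in hybrid.atoms if a.atom_class != absent_cls]
    q = {a.index: getattr(a, f"charge_{end}") for a in present}
    sig = {a.index: getattr(a, f"sigma_{end}") for a in present}
    eps = {a.index: getattr(a, f"epsilon_{end}") for a in present}
    u = 0.0
    idx = [a.index for a in present]
    for ai in range(len(idx)):
        for aj in range(ai + 1, len(idx)):
            i, j = idx[ai], idx[aj]
            key = (i, j) if i < j else (j, i)
            if key in hybrid.exclusions:
                continue
            r = float(np.linalg.norm(positions[j] - positions[i]))
            if r > params.cutoff:
                continue
            screen = 1.0 if params.use_plain_coulomb else float(erfc(params.alpha_pme * r))
            u += params.coulomb_constant * q[i] * q[j] * screen / r
            e = math.sqrt(eps[i] * eps[j])
            if e > 0.0:
                s = 0.5 * (sig[i] + sig[j])
                x6 = (s / r) ** 6
                u += 4.0 * e * x6 * (x6 - 1.0)
    present_idx = {a.index for a in present}
    tag = end
    for t in hybrid.valence.all_terms():
        if t.endstate_tag in (tag, "shared") and all(a in present_idx for a in t.atoms):
            u += _TERM_ENERGY[t.kind](positions, t)
    return u


def dummy_valence_energy(positions: np.ndarray, hybrid: HybridTopology, end: str) -> float:
    """Valence energy of the dummy atoms absent at ``end``.

    At the old endstate the unique_new atoms are dummies: their 'new'-tagged
    (or shared) valence terms are the extra energy on top of the WT physical
    potential.
    """
    absent_cls = "unique_new" if end == "old" else "unique_old"
    absent_tag = "new" if end == "old" else "old"
    dummy_idx = {a.index for a in hybrid.atoms if a.atom_class == absent_cls}
    positions = np.asarray(positions, dtype=float)
    u = 0.0
    for t in hybrid.valence.all_terms():
        if any(a in dummy_idx for a in t.atoms) and t.endstate_tag in (absent_tag, "shared"):
            u += _TERM_ENERGY[t.kind](positions, t)
    return u
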