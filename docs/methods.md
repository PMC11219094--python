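# Methods

## Scope and model

`alchemforge` implements, at desk scale, the machinery of relative
alchemical free energy calculations for residue-like mutations: a single
*hybrid* system carries both the wild-type (WT) and mutant endstates, an
alchemical parameter λ ∈ [0, 1] interpolates between them, replica
exchange samples the K intermediate states, and MBAR estimates the free
energy difference between the two physical endstates.  The package also
implements the accompanying diagnostics workflow — convergence slopes of
ΔG(t), internal consistency of forward/reverse transformations, replica
mixing statistics, statistical inefficiency, and ∂U/∂λ–DOF correlation
scans — which identifies the slow degrees of freedom responsible for poor
sampling.

Everything is validated on analytic or planted-structure toy systems.
Protein-scale simulation (explicit solvent, PME reciprocal space, force
field assignment) is deliberately out of scope.

## Hybrid topology

Atoms are mapped between the WT and mutant residue by label.  For a
genuine mutation the map covers the backbone up to and including the beta
carbon; beta hydrogens are never mapped, which costs a little
thermodynamic length but buys enhanced sidechain sampling while the
unmapped atoms are non-interacting.  Because bonds to hydrogen are treated
as constrained, a mapped hydrogen whose constrained bond length differs
between endstates is un-mapped again.  An identity "mutation" maps every
equally-named atom except the beta hydrogens.

Atom classes drive the interpolation: `unique_old` / `unique_new` atoms
exist at one endstate and become *dummy* particles at the other (retaining
only valence terms, so the non-interacting residue stays geometrically
intact); mapped atoms of the mutating residue and its two sequence
neighbours are `core`; all other mapped atoms are `environment`.
`unique_old`–`unique_new` pairs are always excluded from nonbonded
interactions — the two dummies must never bias each other or the physical
endstates (published descriptions of the scheme leave this implicit; it is
required for the endpoint identity to hold).

Charge-changing mutations (|Δq| = 1) transform one water-like particle
into a counterion (charge −Δq: sodium for Δq = −1, chloride for Δq = +1)
so the net charge is identical at both endstates; which water is chosen is
a policy argument (first of the supplied list by default) since no
physical criterion is forced at desk scale.

## Alchemical potential

Charges interpolate linearly per class; Lennard-Jones ε likewise; σ
interpolates only for core atoms (unique atoms keep their own σ).
Singularities at vanishing sites are avoided by lifting distances into a
4th dimension: r_eff = √(r² + w(λ)²) with w = w_lifting·λ for pairs
containing a `unique_old` atom and w = w_lifting·(1−λ) for pairs with a
`unique_new` atom, so each endstate sees its own physical geometry
unlifted.  `w_lifting` defaults to 0.4 nm — large enough that a contact
(r = 0) at mid-λ costs only a few kT on the toy parameters, small enough
to preserve neighbour-state overlap; the boundedness and continuity tests
run at whatever value is configured.

Electrostatics use the direct-space Ewald form C·q_i(λ)q_j(λ)·
erfc(α·r_eff)/r_eff with configurable screening α, plus a plain-Coulomb
mode (α-factor = 1) that is the default for the non-periodic desk systems.
Reciprocal-space and self-energy sums belong to periodic protein systems
and are not implemented.

Valence terms carry an endstate tag.  Shared terms are always on; terms
touching a dummy atom are always on regardless of tag; remaining old/new
terms switch linearly in λ.  With these rules U(x; λ=0) equals the plain
WT potential plus the dummy-new valence terms *exactly* (to floating-point
round-off), and symmetrically at λ=1 — verified to 1e-10 relative on every
fixture.

∂U/∂λ is a central finite difference with step 1e-4 (one-sided at the
endpoints).  On a single-pair system it matches the symbolic derivative to
1e-6 relative; an analytic derivative was not implemented because the
finite difference is exact enough for correlation analysis and keeps the
energy code single-sourced.

The λ protocol is uniform, λ_k = k/(K−1).  Presets with K = 24 (neutral)
and K = 36 (charge-changing) mirror the state counts commonly used in
production calculations;
the desk toys use 5–11 states, chosen so that neighbouring states overlap
well (verified by the mixing diagnostics, mean swap acceptance ≈ 0.5–0.8).

## Units

Internal units are reduced: energy in kT at T₀ = 300 K, lengths in nm,
charges in e, masses 1.  `units.py` provides kcal/mol conversions for
reports (1 kT ≈ 0.596 kcal/mol).  The default Coulomb constant is the
physical one expressed in these units (≈ 55.7 kT·nm/e²); the bead-chain
and trio toys use smaller values (10 and 15) as part of their definition —
synthetic bead residues lack the full exclusion networks of a real force
field, and at full electrostatic strength close contacts (e.g. a backbone
carbonyl oxygen against the next residue's amide hydrogen) develop forces
that would demand impractically small timesteps.

## REST scaling (AREST)

The REST region is the mutating residue plus every atom within a radius
(default 0.5 nm) of it, evaluated once on the initial conformation and
frozen for the run.  Interactions are classified `rest` / `inter` /
`nonrest` by whether all / some / none of their atoms lie in the region,
and the total potential is α·u_rest + α^p·u_inter + u_nonrest.  The
schedule α(λ) is triangular in inverse temperature: β_eff interpolates
linearly from β(T₀) to β(T_max) on [0, ½] and back on [½, 1], giving
α(0) = α(1) = 1 exactly and α(½) = T₀/T_max.  Published descriptions of
this scaling print α on both the rest and inter terms, while the common
solute-tempering (REST2) convention uses √α for inter terms; both are
supported via `inter_exponent` (default 0.5, the REST2 convention).

AREX is the α ≡ 1 special case of the same code path, so AREST reduced
potentials at the endstates are *bitwise* identical to AREX — MBAR then
targets exactly the same endstate distributions under either scheme.

## Replica exchange

The sampler is a Gibbs chain on (X, S): positions X of the K replicas are
propagated by BAOAB Langevin dynamics at T₀ under their current state's
Hamiltonian, then the permutation S of state indices is redrawn by
attempting K³ Metropolis swaps of uniformly random replica pairs per
iteration (an approximation to an independent permutation draw, which
mixes states far better than neighbour-only swaps).  Coordinates and
velocities stay with their replica; only labels move.  A single seed
sequence is split into per-replica streams plus a swap stream, so archives
are bit-reproducible on one platform.

The optional harmonic restraint tethers (heavy) atoms to the initial
coordinates and is added identically to every state's reduced potential,
so swap ratios are unaffected; it exists for the restraint experiment that
asks whether conformational motion is the source of slow convergence.

Mixing statistics: the empirical state-transition matrix of consecutive
recorded state indices (pooled over replicas), its subdominant eigenvalue,
and a bottleneck flag raised when the transition graph is reducible or any
adjacent-state pair exchanges at a rate below a configurable floor
(default 0.01).

## Free energy estimation

MBAR is solved by minimising the convex mixture-free-energy objective
(L-BFGS with analytic gradient) followed by self-consistent iteration to a
max-norm tolerance of 1e-10, gauge f₀ = 0.  On two-state data it agrees
with an independently coded Bennett (BAR) solver to better than 1e-8.

Samples are attributed to the state their replica occupied when recorded.
Per state, the statistical inefficiency g of the reduced potential at the
generating state sets the subsampling stride (indices 0, ⌈g⌉, 2⌈g⌉, …);
the decorrelation observable is a package choice — the reduced potential
is the natural scalar available at every state.  Uncertainties are pure
bootstrap (200 replicates by default): columns are resampled with
replacement within each state block and MBAR re-solved per replicate.
Analytic MBAR covariance is not implemented.

ΔG(t) re-runs the full estimator on growing prefixes of the archive (10
evenly spaced prefixes by default); the last point equals the full-data
estimate exactly.  Convergence verdict: the OLS slope of the trailing half
of the series, with 2 standard errors, must be statistically compatible
with a flat band (±0.1 kcal/mol/ns for production-scale data; the toy
calibration uses a reduced-unit threshold of 1.2e-4 per iteration sized to
its fixtures).  ΔΔG combines two phases by subtraction with quadrature
errors.

## Diagnostics

Statistical inefficiency g = 1 + 2τ with τ = Σ_{t≥1} (1 − t/N)·ρ(t),
truncated at the first non-positive autocorrelation (initial positive
sequence); g is floored at 1 sample.  With a 0.1 ns recording interval,
g_time = 0.1 ns means completely decorrelated samples.  White noise gives
g → 1; AR(1) matches (1+φ)/(1−φ) within 25% at n = 1e5.

Pearson correlations between ∂U/∂λ and each catalogued degree of freedom
are computed per replica trajectory and combined by Fisher-z averaging
(the averaging convention is a package choice); the 95% CI uses an
effective sample size n/g_max with g_max the larger inefficiency of the
two series.  Angles are unwrapped by shortest-path continuity before
correlation — circular quantities are *not* embedded via sin/cos, a
documented limitation for angles that diffuse across the ±180° seam.
Contact distances are minimum heavy-atom cross-pair distances; radius
counts are boundary-inclusive.  The category report tabulates, per DOF
category (backbone/sidechain torsions, intra/inter contacts, neighbouring
waters, custom), the maximum |replica-averaged PCC| with its CI and the
responsible observable; multi-run reports are ordered by descending
∂U/∂λ inefficiency.

## Toy systems and what they do (not) show

* **Harmonic ladders** have exact free energies f_k = ½ ln K_k and exact
  iid samplers, isolating the estimator from the dynamics.
* **Charge-change trios** exercise the counterion transform and the
  forward/reverse antisymmetry ΔG_fwd = −ΔG_rev at engine level.
* **Planted slow-DOF landscapes** put a double well of known barrier
  height (6 kT in the validation runs) on x with ∂U/∂λ = c·x exactly, so
  the diagnostics must rank x first and the spectators at zero.
* **Bead residue chains** mimic the *bookkeeping* of amino-acid mutations
  (atom names, backbone/sidechain split, β-hydrogens, ±1 net charges) so
  the full apo/complex ΔΔG workflow runs end to end.

None of these reproduce real solvation, dielectric screening, or the
interaction networks of a protein:protein interface: passing tests show
the machinery is correct (estimators unbiased on analytic references,
identities exact, planted structure recovered), not that production
predictions on proteins would be accurate.

Two synthetic archives calibrate the convergence verdict: a stationary
archive of exact equilibrium samples, and a drift archive in which an
exponentially relaxing offset (2 kT initial, time constant 0.7 of the run)
is planted on the last state's reduced-potential column — a run still
equilibrating at its end, the phenomenology the flat-slope test exists to
catch.  A transient confined to the first half of a run is *not* a good
slope fixture: by the trailing window the estimator has genuinely
recovered and the tail slope is near zero; such a two-regime archive is
instead used to show that early ΔG(t) points differ from the final
estimate by more than their uncertainty.

## Validation problem sizes

The validation experiments use: 5 000 samples/state and 200 bootstrap
replicates for the MBAR oracle; 10⁴ swap attempts, each separated by 15
Langevin steps so successive attempts are effectively independent, for
the Gibbs acceptance check; 20 seeded 150-iteration runs for planted-DOF
recovery; 5 seeds × 300 iterations × 11 states for the charge-trio
consistency check; and 5 matched seeds × 2 000 iterations × 8 states for
the AREST-vs-AREX comparison.  The AREST comparison length is set by
physics: the planted coordinate must cross its barrier several times
before its autocorrelation time is measurable, and at 6 kT the heated
(T_max = 600 K) runs cross roughly six times more often than the
unheated ones.

## Known limitations

* O(N²) pair evaluation, no neighbour lists, no periodic boundaries.
* Angle/torsion forces via per-term central differences (their energies
  are analytic); exact for practical purposes but slower than closed-form
  gradients.
* Bootstrap-only uncertainties can mildly underestimate error when the
  decorrelation estimate itself is noisy.
* REST region is never recomputed during a run (by design, matching the
  fixed-at-start convention).
* Proline-like backbone-cycle mutations and |Δq| > 1 transforms are
  rejected, not modelled.
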