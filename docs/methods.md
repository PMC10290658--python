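# Methods

This note records the models, conventions and numerical choices behind
`hybridsheet`, and what the synthetic validation does and does not show
about real simulation data.

## Scientific setting

γ-Secretase (catalytic subunit presenilin-1, aspartate dyad D257/D385)
cleaves transmembrane substrates such as the APP fragment C99 in steps
of typically three residues. Immediately C-terminal of the scissile
bond the substrate contributes a β-strand (β3, register positions
P1′–P4′) to a hybrid β-sheet with two presenilin strands (β1, β2);
β3 also hydrogen-bonds to L432 next to the PAL motif. The stability of
this sheet controls (a) whether the active site adopts a
cleavage-compatible geometry and (b) how much water reaches the
catalytic dyad through the gap between K380 (on β2) and L432. The
package quantifies these couplings and estimates the β3
association/dissociation free energy along the reaction coordinate
RC = Cα(L418)–Cα(P2′).

## Feature definitions and conventions

* **Active geometry.** `d1` is measured proton-to-acceptor: from the
  carboxyl hydrogen of the protonated aspartate to the scissile
  carbonyl O. A 2.5 Å criterion is physically an H···O hydrogen-bond
  distance; when the model carries no carboxyl proton, the minimum
  carboxyl-O to carbonyl-O distance is used instead and flagged in the
  result — never silently. `d2` is the deprotonated-Asp Cγ to carbonyl
  C distance. Both thresholds are strict inequalities (`d1 < 2.5`,
  `d2 < 5.6` Å): boundary values are inactive.
* **Secondary structure.** Kabsch–Sander hydrogen-bond energies,
  `E = 27.888·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol with a
  −0.5 kcal/mol bond cutoff; amide hydrogens absent from the model are
  constructed 1.01 Å from N, anti to the preceding carbonyl (a chain's
  first residue has no amide proton and cannot donate). Antiparallel
  *and* parallel bridges reduce to E (isolated bridges included), two
  consecutive 4-turns mark residues i…i+3 as H, everything else is C.
  The full DSSP alphabet (G, I, T, S distinctions) is out of scope.
  Chain breaks (consecutive C–N > 2.5 Å) delimit segments; residues
  flanking a break are simply excluded from patterns that would span
  it.
* **β3 statistic.** Mean E-occupancy of P2′ and P3′. For substrates
  whose chain ends before P3′ the statistic reduces to the single
  available occupancy, i.e. β3 = β(P2′); this follows the published
  formula for the shortest substrate even though the accompanying
  prose labels that residue P3′ — the formula, not the label, is
  implemented.
* **Hydration.** A water (residue names HOH/WAT/TIP3/SOL, configurable)
  is in the catalytic shell if any of its atoms is within 5 Å of any
  atom of either aspartate. Residence times are maximal runs of
  consecutive shell-resident frames × timestep, with a configurable
  grace period that defaults to zero (a single outside frame ends a
  dwell) because the source protocol states no tolerance.
* **Cadences.** The HREUS feature cadence is a config parameter
  (default 0.2 ns) because the source protocol states two mutually
  inconsistent values (50 ps and 0.2 ns).

## Sampling engine

The sampler is Metropolis Monte Carlo, not Langevin dynamics: on a 1-D
toy potential it has an exactly known stationary distribution, which is
the whole point of the validation stack. Gaussian proposals are tuned
by a short pre-run toward ~40% acceptance. The bias convention is
`U_bias = k·(x−c)²` — no ½ — matching the restraint convention in which
the window force constants (6, 8, 10 kcal mol⁻¹ Å⁻²) are quoted; all
WHAM code uses the same convention. Replica exchange is
nearest-neighbour only, with deterministic alternation of even/odd
pairs at every attempt; the Metropolis criterion uses
Δ = β[(Hⁱ(r_j)+Hʲ(r_i)) − (Hʲ(r_j)+Hⁱ(r_i))]. One master seed spawns
independent per-replica streams, so runs are bit-reproducible per
(seed, config). Exchange-attempt statistics cover the production span
only, and recordings coinciding with an exchange attempt are dropped,
so a 40 ns production recorded per 2 ps with attempts per 10 ps retains
exactly 20,000 − 4,000 = 16,000 samples per replica. The reference
protocol's positional restraints (10 kcal mol⁻¹ Å⁻² on K380/L418 Cα)
have no 1-D analogue and are carried as config metadata only.

## WHAM and ΔΔG_res

Standard self-consistent iteration on a fixed grid (bin width 0.1 Å,
spanning [min center − 0.5, max center + 0.5] Å; the source protocol
states no bin width), convergence when window free energies move less
than 1e-6 kcal/mol, at most 1e5 iterations; failure to converge raises
with the residual. The PMF is anchored min = 0 (the anchor is a free
convention and is recorded in the profile metadata). Unpopulated bins
are NaN; a gap inside the populated range sets a `disconnected` flag
with a warning. For a single unbiased window the iteration reduces
exactly to the normalised-histogram estimator (tested). Per-bin
standard errors from a single run use a crude Poisson estimate
kT/√n_b; the real error bars come from the time-slice protocol: one
WHAM profile per cumulative slice (reference protocol: 20→22.5 … 60 ns
at 2.5 ns increments, n = 16) and the per-bin standard deviation across
them. ΔΔG_res is PMF(16 Å) − PMF(min) if the global minimum lies
strictly below 11 Å, else exactly 0; PMF(16 Å) is linearly interpolated
(0.1 Å bins make higher-order interpolation immaterial). T = 303.15 K
throughout, matching the simulation thermostat setting.

## Synthetic data: what it emulates, what it does not

The generators produce the *test conditions*, not physics:

* **Active-site fixtures** place the named atoms (Asp Cγ/Oδ/Hδ, the
  scissile carbonyl, 3-site waters) at exact requested distances using
  idealised bond lengths — no rotamers, no sterics.
* **β-sheet fixtures** realise the exact hydrogen-bond topology of an
  ideal antiparallel sheet: facing residues on alternating "narrow"
  pairs carry mutual N–H···O=C bonds at 1.9 Å H···O; sheet twist is
  applied as a rigid per-cross-section rotation about the mid-sheet
  axis, which preserves every intra-pair bond exactly. An ideal α-helix
  (φ = −57°, ψ = −47°, grown from standard internal coordinates) serves
  as the negative control for strand assignment.
* **Planted trajectories** switch between an associated template
  (gap 11 Å, RC 9 Å, d1/d2 = 1.9/4.8 Å, one resident water, intact
  strand) and a dissociated template (gap 14 Å, RC 16 Å, six shell
  waters, broken strand) at a planted event frame, plus isotropic
  Gaussian coordinate noise (σ = 0.2 Å, seeded). σ was chosen below the
  decision margins of every threshold except d1, where occasional
  single-frame flips (a few percent) realistically blur the planted
  signal without hiding it; the noise-free variant recovers the planted
  truth exactly and is tested as such.
* **Toy potentials** are C² piecewise forms: harmonic wall below the
  association minimum, smootherstep rise of height `ddg_target`
  completed by the dissociation plateau (≤ 16 Å, so PMF(16) − min
  equals the target by construction), plus a compactly supported sin²
  barrier in the transition band. For a 1-D system the analytic PMF
  *is* the potential.

Passing these tests demonstrates the statistical machinery is correct
(estimators, bookkeeping, thresholds, exchange detailed balance). It
does **not** demonstrate anything about force fields, membrane
environments, sampling convergence of all-atom systems, or the
magnitude of real ΔΔG_res values — those require the microsecond MD
this package deliberately does not perform. Problem sizes used in the
validation (1e5 samples/window for WHAM and ΔΔG recovery, 1e5 exchange
trials, 100-frame planted trajectories) were chosen as the smallest
sizes at which the stochastic tolerances (0.2 kcal/mol PMF deviation,
0.3 kcal/mol recovery, 3σ binomial) are comfortably resolved.

## Energy decomposition

The per-residue decomposition implements only the molecular-mechanics
gas-phase terms: Lennard-Jones 12-6 with Lorentz–Berthelot combination
and Coulomb 332.0636·q_iq_j/(ε·r) with ε = 1 by default. The
Poisson–Boltzmann polar-solvation term of a full MMPBSA treatment is
intentionally absent (a PB solver is out of scope); the solvent
dielectric (80) and salt concentration (0.15 M) that would parameterise
it are carried as metadata only. Consequently absolute energies are not
comparable to MMPBSA output — the testable content is the VDW/EEL
split, sign structure, and the exact whole-vs-parts additivity
(per-residue terms sum to the total substrate–enzyme pair energy to
machine precision). LJ/charge parameters come from a small built-in
per-element table (C/N/O/H/S); there is no force-field file parser.
Ensemble means are unweighted per-frame averages.

## Structure I/O

Fixed-column PDB v3.3 is the only structure format; a trajectory is a
multi-MODEL file with uniform topology. Alternate locations keep the
highest occupancy (ties → first seen); insertion codes are rejected
explicitly (none occur in the systems of interest); CONECT/ANISOU are
ignored; waters (HETATM) are retained. Coordinates round-trip to
0.001 Å (the PDB field precision). Coordinates are treated as
orthorhombic and unwrapped: no periodic-image handling, because the
analysed region sits far from any box edge in the systems of interest.
Selections are explicit `"chain:residue"` strings — deposited and
modelled files disagree on chain naming, so nothing is defaulted.

## Known limitations

* No mmCIF, no Amber topology parsing, no binary trajectory formats.
* The DSSP reduction covers E/H/C only.
* The survey of deposited structures computes distances from whatever
  PDB files it is given; it ships with none.
* WHAM has no MBAR alternative and no autocorrelation correction —
  samples are assumed strided to near-independence, as in the source
  protocol.
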