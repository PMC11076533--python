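# Methods

## Problem setting

In a constant-velocity steered molecular dynamics (SMD) pulling experiment a
harmonic spring, attached to a ligand's centre of mass and moving at velocity
v, pulls the ligand out of a receptor's binding site while the receptor is
held by harmonic position restraints.  Which receptor atoms to restrain is a
genuine modelling choice: restraining everything rigidifies the active site
and inflates rupture forces, works and unbinding barriers; restraining too
little lets the whole complex drift or spin in the solvent so the external
force stretches the protein instead of breaking the protein–ligand
interaction.  `restraintkit` implements six selection rules ("modes") of
decreasing rigidity, the ensemble analysis needed to compare them, and a toy
pulling simulator that reproduces the relevant phenomenology at desk scale.

## Restraint modes

All selections act on a structure rotated so the pulling direction is +Z
(`align_pull_axis_to_z`, Rodrigues rotation about the axis–Z cross product).
With d_ax = 1.2 nm (1.8 nm for mode 6) and d_rad = 1.2 nm:

| mode | restrained set |
|------|----------------|
| 1 | all protein heavy atoms (C, N, O, S) |
| 2 | all protein C-alpha atoms |
| 3 | C-alpha with 3-D distance to the ligand > d_ax |
| 4 | C-alpha with along-axis (Z) separation from the ligand > d_ax |
| 5 | mode 4 atoms whose in-plane (X–Y) radial distance is < d_rad |
| 6 | mode 5 with the along-axis cutoff at 1.8 nm |

"Distance to the ligand" is the minimum over ligand heavy atoms by default;
a ligand centre-of-mass reference is available (`reference="com"`).  Modes 5
and 6 intersect the axial and radial conditions — the only reading under
which the selections nest (6 ⊆ 5 ⊆ 4, 3 ⊆ 2 ⊆ 1) and shrink monotonically
from mode 1 to mode 6, which the test suite asserts on every fixture.
Cutoff comparisons are strict; an atom exactly at a cutoff is not selected
by a greater-than rule.  The default per-axis restraint force constant is
1000 kJ/mol/nm²; selections are emitted as GROMACS-style index groups and
position-restraint include files (1-based indices there; 0-based in
memory).

Ligand identification is explicit (residue name and/or chain); waters and
common monatomic ions are excluded on read; alternate locations resolve to
the highest-occupancy conformer.  Internal units are nm throughout, so the
1.2/1.8/0.6/0.35 nm criteria are used as written.

## Ensemble analysis

A pulling trace records time (ps), spring force (kJ/mol/nm, reported in pN
via 1 kJ/mol/nm = 1.660539 pN) and ligand displacement along the axis (nm).
Per trace the toolkit computes the rupture force Fmax (global maximum,
earliest-time tie-break, no smoothing by default) and the external pulling
work W = v ∫F dt (trapezoidal, reported in kcal/mol).  Across an ensemble it
provides running means for convergence monitoring, a maximum-likelihood
skew-normal fit for the "distorted Gaussian" shape of Fmax and W
distributions, and free-energy profiles.

Two free-energy estimators are implemented and always labelled:

* mean work: G(z) = ⟨W(z)⟩;
* Jarzynski second-order cumulant: G(z) = ⟨W(z)⟩ − Var W(z) / (2 k_B T),
  exact for Gaussian work distributions, evaluated at T = 300 K by default.

The unbinding barrier is max_z G(z) − G(0) with G(0) = 0 by construction;
the cumulant profile is bounded above by the mean-work profile pointwise
because the variance is non-negative.  By default per-trace work is indexed
onto the displacement grid by the spring-anchor position v·t (the
stiff-spring convention): re-indexing by the fluctuating ligand coordinate
(first crossing) is available but conditions on thermal excursions and
carries a small systematic bias, which the translated-harmonic-trap
calibration resolves statistically at a few hundred trajectories.  The grid
is uniform with 0.05 nm bins.  Profile standard errors, when requested, are
leave-one-out jackknife estimates.  Reported uncertainties on Fmax and W
are standard errors of the mean.

RMSD implements the plain square-root-of-mean-squared-deviation formula;
optional rigid superposition uses the Kabsch algorithm
(`scipy.spatial.transform.Rotation.align_vectors`).

## Interaction metrics

* Contact: a protein heavy atom within 0.6 nm of any ligand atom; the
  census over an ensemble is the union of per-frame contact residues.
* Hydrogen bond: donor–acceptor distance < 0.35 nm and the angle at the
  hydrogen (donor–hydrogen–acceptor) > 135°; donor/hydrogen pairing is
  supplied explicitly or inferred geometrically (N/O with a hydrogen within
  0.12 nm); N and O act as acceptors.  Both donation directions are counted
  by listing donors and acceptors from both molecules.
* Interaction energy: IE = V_LJ + V_Coulomb over protein–ligand pairs
  strictly inside 1.0 nm, Lennard-Jones 12-6 with Lorentz–Berthelot mixing
  plus Coulomb q_i q_j/(4πε₀ε_r r), reported in kcal/mol.  Energies are
  computed directly from user-supplied per-atom parameter tables (charge,
  sigma, epsilon); equivalence with an MD engine's PME/exclusion-aware
  energies is not claimed.
* Potential length L0: the smallest displacement-bin centre from which
  |IE| stays below a threshold (default 1 kcal/mol — the decay tolerance is
  a free choice and is exposed) for all larger displacements; profiles that
  never decay are flagged undefined rather than assigned a value.
* Displacement binning uses half-open bins [lo, hi); empty bins carry NaN
  means and zero counts so that the count-weighted mean of bin means equals
  the global mean exactly.

## Toy pulling simulator

The generator produces synthetic pulling data with the statistical
structure the analysis assumes, with no MD engine.  Every bead follows
overdamped Langevin dynamics, dx = (F/γ)dt + √(2 k_B T dt/γ) ξ; friction
plus noise stand in for explicit solvent.  Forces: a harmonic elastic
network between receptor beads within a cutoff; Morse potentials (finite
rupture force, analytic) between the ligand bead and receptor beads within
the binding cutoff; a bounded harmonic excluded-volume term between the
ligand and every receptor bead; harmonic tethers on the masked beads; and
the moving pulling spring along +Z, whose force is what gets recorded.

The default receptor (~106 beads) is built so that the phenomenology of
interest emerges from mechanism rather than prescription:

* a "claw" of eight three-bead fingers surrounds the ligand, tips curving
  inward above it as an exit gate.  Because central-force springs are stiff
  along the bond and soft transverse to it, and finger bonds run along the
  escape wall, an unrestrained finger splays aside at low force while
  resisting being dragged upward.  Restraining the fingers (modes 1–2)
  forces the ligand to compress past the gate and break all Morse contacts
  near-simultaneously: larger rupture force and work.
* four lid-loop beads above the gate are anchored by near-horizontal bonds
  — the opposite anisotropy — so, when free, they trail the departing
  ligand and prolong the interaction, lengthening the contact census and
  the potential length L0.
* plates, collar and flank arms beneath and beside the claw give the six
  modes strictly decreasing restrained-bead counts under the exact
  selection rules used for real structures (beads pose as C-alpha atoms;
  six sidechain-like beads are heavy-but-not-C-alpha so mode 1 exceeds
  mode 2 strictly).

Key defaults (all configurable): pulling v = 1.0 nm/ns with k = 600
kJ/mol/nm² for 3 ns; force recorded every 10 fs and frames every 10 ps;
restraint k = 1000 kJ/mol/nm²; network k = 400 kJ/mol/nm² with a 0.5 nm
nearest-neighbour cutoff; Morse depth 4 kcal/mol and width 8 nm⁻¹;
excluded-volume radius 0.45 nm at 3000 kJ/mol/nm²; γ = 1000 kJ/mol·ps/nm²
and T = 300 K with a 10 fs timestep (the Euler–Maruyama stability number
k_eff·dt/γ stays well below 1 for every interaction).  The network
stiffness balances two regimes observed during construction: a much softer
network lets the receptor be dragged wholesale (work in flexible modes then
exceeds the rigid modes — the drift pathology, which remains reproducible
on demand by zeroing the network stiffness), while a much stiffer one
removes the local compliance that distinguishes restrained from free
binding-site beads.

Randomness: a master seed expands into per-trajectory seeds through a fixed
splitmix64 stream (collisions skipped), each feeding a PCG64 generator whose
noise is drawn outside the compiled integrator — trajectories are therefore
bit-reproducible per seed across platforms.  The integrator core is
JIT-compiled with numba; a 3 ns default trajectory takes roughly 1–2 s on
one CPU.

### What the toy does and does not emulate

It reproduces: rupture events with trajectory-to-trajectory variation;
equipartition at the configured temperature; zero free-energy change for a
translated harmonic trap (Jarzynski calibration); decreasing Fmax and work
from rigid to flexible restraints; growing contact census and potential
length with flexibility; receptor drift when under-restrained.  It does not
contain explicit solvent, hydrodynamics, atomistic force fields, hydrogen
bonds (toy beads carry no hydrogens) or the absolute force/work scales of
any real protein–ligand complex — passing tests demonstrate correctness of
the analysis machinery and the qualitative physics of restraint choice,
not quantitative agreement with any particular system.

## Problem sizes used in tests and the acceptance script

Ensemble comparisons use 50 trajectories per restraint mode at the default
3 ns duration; pattern checks over paired seeds use 20 seeds at 2.5 ns;
the Jarzynski calibration uses 250 half-nanosecond trajectories of a single
bead; the equipartition run integrates 20 ns of a single tethered bead.
These sizes put every stochastic assertion several standard errors away
from its threshold while a full run of the suite stays in the minutes
range.

## Numerical and design notes

* Work integrals use the trapezoidal rule; on the exactly linear
  frozen-ligand force ramp it is exact to rounding, and doubling the
  sampling density changes results by < 1e-4 relative.
* The skew-normal MLE has a flat likelihood ridge in (location, shape) for
  near-symmetric samples; consumers should interpret the fitted
  distribution's moments, which are stable, rather than raw parameters.
* XVG-style readers ignore `#`/`@` lines; force/position series on
  different time grids are joined at the nearest time within half the force
  sampling step, and unmatched samples are dropped.
* Degenerate inputs raise rather than return silently: empty index sets,
  empty restraint groups, non-monotone time axes, zero-variance samples for
  distribution fits, hydrogens without a donor parent, missing non-bonded
  parameters (named by atom index), and integrator blow-ups (named by
  step).
* Mode selection on the toy system reuses the production selector
  verbatim, so the generator cannot drift out of sync with the restraint
  rules it is meant to exercise.

## Limitations

PDB input only (no mmCIF, no binary trajectory formats); no tunnel or
pathway detection (the pulling direction is user input); no
umbrella-sampling/WHAM analysis or loading-rate extrapolation; interaction
energies use a plain cutoff without long-range electrostatics corrections;
the toy simulator's scales are phenomenological.  Real-system restraint
counts depend on the exact prepared structure (protonation, repaired
residues, conformer choices), so counts computed from raw PDB entries may
differ slightly from any particular preparation.
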