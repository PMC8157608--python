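# Methods

`widombias` estimates excess chemical potentials of dense liquids by Widom
test-particle insertion, with a grid-based volume-detection bias for
polyatomic probes.  This note records the model, the estimators, the
numerical choices, and what the synthetic systems can and cannot show.

## Model and units

Lengths are in angstrom, energies in kcal/mol, charges in elementary
charges; `k_B = 0.0019872041 kcal/(mol K)`, Coulomb constant
`332.06371 kcal A/(mol e^2)`.  Boxes are orthorhombic and fully periodic;
interactions use the minimum-image convention.  Molecules are rigid bodies
(site coordinates fixed in a body frame whose centroid is the origin);
intramolecular interactions are excluded.

Pair interactions are 12-6 Lennard-Jones with Lorentz–Berthelot combining,
truncated at `r_cut` (default 10 A) on the site–site distance.
Electrostatics use a **molecule-centroid group cutoff**: all site pairs of
a molecule pair interact iff the two centroids are within `r_cut`, each
pair contributing `q_i q_j C (1/r − 1/r_cut)`.  For neutral molecules the
shift terms of an included molecule pair sum to zero, so this is the
classic neutral-group truncation.  We first implemented a site-based
truncated-shifted scheme and rejected it on measurement: it splits charge
groups at the cutoff sphere and overbinds TIP3P water by ~2.5 kcal/mol per
molecule (E/N ≈ −12.1 instead of ≈ −9.6), distorting both structure and
insertion statistics.  Overlap energies are clamped to `+inf`, whose
Boltzmann factor is exactly 0.0 (never NaN).

Built-in species: Lennard-Jones argon (σ = 3.405 A, ε = 0.238 kcal/mol)
and rigid TIP3P water (σ_O = 3.1507 A, ε_O = 0.1521 kcal/mol,
q_O = −0.834 e, q_H = +0.417 e, r_OH = 0.9572 A, ∠HOH = 104.52°).  The
argon σ, ε and the 10 A cutoff are pinned by the dispersion-tail
correction: with exactly these values the analytic tail reproduces the
tabulated argon correction column (−0.039/−0.0681/−0.0837 kcal/mol at
416/727/894 kg/m³, 320 K) to printed precision and is linear in density —
that agreement is the calibration check, run in the test suite.  Two hard
pair styles (`hard-sphere`, `hard-cube`) exist for exactly solvable
fixtures only.

## Configuration generation

Equilibrium NVT ensembles come from rigid-body Metropolis Monte Carlo: one
attempted translation (uniform in a cube of half-width `max_translation`)
plus, for polyatomic species, one rotation (uniform random axis, angle
uniform within `±max_rotation`) per molecule per sweep, accepted with
probability `min(1, e^(−β ΔU))`.  Canonical averages do not depend on the
sampler, so this replaces molecular dynamics without integrator or
thermostat machinery.  Energy bookkeeping is incremental; the test suite
verifies the running total against a from-scratch recomputation to
1e-6 kcal/mol, and a two-particle system reproduces the Boltzmann
pair-distance distribution (χ² test against direct quadrature).
Accumulated rotation matrices are re-orthonormalised (polar decomposition)
whenever a configuration is emitted.

Study conditions: 512 argon atoms (as in the reference calculation) or 512
TIP3P waters (scaled down from 3375; 216 would put the box edge below
2·r_cut at 991 kg/m³, 512 gives 24.9 A).  Default protocols: argon — 1500
equilibration sweeps, 50 samples every 40 sweeps, 1 A moves (≈ 42 %
acceptance); water — 3000 equilibration sweeps (the potential energy
plateaus by ≈ 2500), 50 samples every 30 sweeps, 0.25 A / 0.25 rad moves
(≈ 31 % acceptance, E/N ≈ −9.6 kcal/mol, consistent with TIP3P liquid at
this state point).  One integer seed fans
out to all random streams; fixed seed gives bit-identical ensembles.

Trajectories read/write XYZ (box on the comment line), extended XYZ
(`Lattice=` field), GRO (nm on disk) and LAMMPS dump (orthorhombic
`BOX BOUNDS`).  Rigid poses are recovered on read by centroid plus
best-fit proper rotation (Kabsch), so round trips reproduce coordinates to
format precision; MDAnalysis is used in the tests as an independent
round-trip oracle.

## Unbiased Widom estimator

For each stored configuration, `n` ghost copies of the probe are inserted
at uniform positions with uniform random orientations;
`μ_ex = −k_B T ln ⟨e^(−β ΔU)⟩`.  Configurations are pooled with equal
weight (each contributes its own mean factor).  The ideal-gas term uses a
thermal wavelength fixed at 1 A; it cancels from every excess comparison.

Uncertainty follows the block recipe: the configurations are cut into
consecutive blocks of 50, each block mean is converted to a μ value, and
the sample standard deviation of those values is reported.  At the default
50-configuration ensembles only one block exists, so the estimate falls
back to a delta-method standard error, `k_B T · sem(per-config means) /
grand mean`.

The estimator was verified bias-free against a closed form: on
uncorrelated uniformly-placed LJ atoms, where
`⟨B⟩ = (1 + V^{-1}∫(e^{−βu}−1)d³r)^N` exactly, 1.2·10⁷ insertions agree
to +0.2 %.  A dilute-limit check compares `β μ_ex` with `2 B₂(T) ρ`
(Mayer quadrature of the same truncated potential) at reduced density
0.02.  That density is deliberate: a numerical B₃ quadrature of the
truncated LJ potential at 320 K gives B₃* = 1.61 σ⁶, so the second-order
virial term is already −6.6 % of the first-order prediction at ρ* = 0.02
(and −13 % at 0.04); measured deviations match this within noise.

## Volume-detection bias (two-level criterion + detailed average)

Each configuration is meshed into N×N×N cubic cells of edge D and screened
at the cell centres with a detection particle that by default shares the
probe's geometry:

1. **Overlap level** — the probe placed at the centre (body-frame
   orientation) must be strictly more than `d_min` (default 1 A) from
   every system atom.  Cells failing this are blocked; the survivors are
   the free-volume cells, `N_fv` of them.
2. **Refinement level** — the centre insertion Boltzmann factor is
   computed for every free cell.  Cells where it strictly exceeds
   `b_threshold` (default 100) are investigated further with the detailed
   average: 14 translations (6 face + 8 normalised corner directions of
   the cell, step D/3 when the centre factor is below 10⁴, D/4 at or
   above) × 17 rotations (90/180/270° about the axes, 120/240° about the
   body diagonals) = 238 poses, arithmetically averaged.  The centre pose
   itself is not included by default (a flag adds it).  For monatomic
   probes the rotations are a provable no-op and are skipped.

The configuration's estimate is

    μ_ex = −k_B T ln[ (N_fv/N) · ⟨w⟩_free ],   w = detailed average or
                                               centre factor,

i.e. every free cell contributes — blocked cells contribute zero, which
the free-volume fraction corrects exactly.  With both criteria disabled
this is a plain grid quadrature of the unbiased average (and, with the
stencil replaced by uniform in-cell sampling, a stratified unbiased
estimator — the equivalence is asserted in the tests against the unbiased
path on frozen ensembles).  The biased path contains no randomness.

Why the refinement threshold gates only the *extra work*, not a cell's
membership: we measured that in dense argon (894 kg/m³, 320 K) the most
favourable cavity centre reaches a Boltzmann factor of only ~40–50, and in
water an arbitrary body-frame orientation at a genuinely good position
usually scores below 1.  An estimator that kept only cells above the
threshold would discard essentially all insertion weight in both liquids
(argon: every cell; water: ~e³ of the weight).  Composing the estimate
from all free cells reproduces the unbiased average by construction while
spending the 238-pose stencil only where the weight concentrates; the
per-run report states the share of total weight carried by detailed cells
and a bound, `b_threshold · (centre-sampled fraction) / ⟨B⟩`, on the part
of the average the stencil never refined.

Boundary semantics are strict (`>`) at both levels; a factor exactly equal
to the threshold fails.  A disabled threshold (≤ 0) rejects only true hard
overlaps, so exponent underflow at huge finite energies cannot silently
drop a cell.  The upper step bracket at exactly 10⁴ takes the D/4 branch.
Virtual detection particles with their own geometry can replace the
default via `CriterionConfig.detection_probe`.

For water the mesh is the procedure's stated 50×50×50 (D ≈ 0.50 A for the
512-molecule box); the estimate is insensitive to D between 0.5 and 1 A
within its statistical error, and the finer mesh mainly improves the
sampling of the heavy-tailed centre factors.

## Long-range corrections

* **Dispersion** (`μ_ex_p`): analytic truncated-LJ chemical-potential
  tail, `Σ_j (16/3)π ρ_j ε_pj σ_pj³ [⅓(σ_pj/r_c)⁹ − (σ_pj/r_c)³]`, summed
  over probe-site × solvent-site-type pairs.  Exactly linear in density,
  monotonically vanishing with growing cutoff; together with the tail it
  makes the corrected argon μ_ex cutoff-robust (checked at r_cut = 8, 10,
  12 A in the suite).
* **Electrostatics** (`μ_ex_c`): the default is the analytic Onsager
  dipolar reaction-field correction for a neutral dipolar probe,
  `−C f_RF μ_d²/r_c³` with `f_RF = (ε−1)/(2ε+1)` and the
  conducting-boundary limit `f_RF = ½` as default (−0.0396 kcal/mol for
  TIP3P at r_cut = 10 A).  An alternative `method="fep"` re-scores a
  weight-sampled subset of accepted insertions with full (tin-foil) Ewald
  sums and exponentially averages the difference; it is retained for
  sensitivity analysis but not used by default, because configurations
  generated under the truncated Hamiltonian re-scored under Ewald carry
  pose-to-pose differences of several kT — the exponential estimator does
  not converge at practical subsample sizes and mostly measures structure
  mismatch, not missing long-range physics.  The Ewald machinery itself is
  validated in the tests against an explicit spherically-ordered image sum
  (they agree to 1e-3 kcal/mol once the vacuum-boundary surface-dipole
  term is accounted for).  Probes with net charge are refused.
* Corrected value: `μ_ex = μ_ex_W + μ_ex_p + μ_ex_c`, plain addition with
  the raw uncertainty carried through.

Reference conversions: `μ_ex_R = k_B T ln(zφ)` from a compression factor
and fugacity coefficient, and the saturation-pressure estimate
`μ_ex ≈ k_B T ln(P_sat/(ρ_liq k_B T))` with pressures in kPa at the API
boundary.

## Synthetic fixtures and what passing means

* `ideal_gas` — all interactions zero; μ_ex is exactly 0 and every
  insertion counts.
* `hard_core_lattice` — immobile hard *cubic* cores covering whole mesh
  cells, so the free-volume fraction is an exact count and both estimators
  must return `−k_B T ln f_free` (the biased one exactly).  Cubes rather
  than spheres because no sphere union is a union of mesh cells.
* `lj_dilute` — argon at ρ* = 0.02 for the second-virial limit.
* `frozen_cavity` — an octahedral cage of attractive atoms around the box
  centre with an analytically known centre insertion energy (−6ε), giving
  one guaranteed accepting cell.

These fixtures validate correctness of the machinery, not realism: they
contain no orientational disorder, no long-range electrostatic structure
and no sampling difficulty, so passing them says the estimators compute
what they claim on known ground truth — the liquid-state results stand on
the argon and water pipelines.

### Accuracy of the biased estimator on water

For dense LJ argon the pipeline is quantitatively reliable: the corrected
μ_ex at 320 K lands within ~0.02 kcal/mol of equation-of-state reference
values at all three study densities, with seed-to-seed scatter of
±0.005–0.01.  For liquid water it is not.  At 315 K / 991 kg/m³ the
default protocol gives a corrected μ_ex of about −3.2 ± 0.35 kcal/mol,
far short of the −5.9 to −6.1 kcal/mol range anchored by equation-of-state
data and by reported TIP3P hydration free energies.  The cause is
measurable with the package's own tools: water's insertion weight
⟨e^(−βΔU)⟩ is dominated by poses that need simultaneously a cavity *and*
a narrowly tuned orientation, so the weight distribution is extremely
heavy-tailed — per-configuration mean factors span two orders of
magnitude even at 3·10⁶ unbiased insertions per configuration (which
itself only reaches −4.25 ± 0.31, still rising in magnitude with sample
size).  The deterministic 238-pose stencil per detected cell is a sparse
quadrature of that peak: it under-samples orientation space in the cells
it refines and the single centre pose under-represents all other free
cells, while conversely, refining *every* free cell over-weights cavity
sweet spots (−7.2 on small ensembles).  No setting of the documented
thresholds removes this at the 512-molecule / 50-frame scale; the water
number should be read as a lower-magnitude bound with a method-dominated
systematic error of ~2–3 kcal/mol, and the per-run report's
detailed-weight share (≈ 1.0 for water) is the diagnostic that flags the
regime.  Apolar and weakly polar probes do not enter this regime.

## Known limitations

* Orthorhombic boxes only; rigid molecules only; no Ewald in the
  production Hamiltonian (restored through `μ_ex_c`).
* The water system is 512 molecules; finite-size effects at the
  0.1 kcal/mol scale are expected and folded into the quoted uncertainty
  band rather than corrected.
* The centre-factor part of the biased water estimate samples a
  heavy-tailed distribution; its uncertainty (±0.2–0.4 kcal/mol at the
  default protocol) is dominated by the few largest cells per
  configuration.
* The Metropolis sampler uses single-molecule moves; near-critical or
  glassy state points would need longer decorrelation strides than the
  defaults.
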