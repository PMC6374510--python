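# Methods

## The synthetic surfactant and micelle

The generator does not attempt chemistry; it reproduces the *length
scales and symmetry* of a four-armed calix[4]arene surfactant at one
bead per heavy-atom group.  A molecule is built from

* four aromatic panels of three `CALIX_C` beads (aromatic-CH form
  factor, 7 e⁻) at 3.0 Å from the molecular axis, each panel tilted by
  a per-panel angle: `C4v` uses four equal tilts (45°), `C2v` uses an
  (a, b, a, b) pattern (15°, 75°) so two opposite panels are nearly
  parallel and the other two nearly perpendicular — the pinched-cone
  conformation the ring prefers in the absence of coordinated sodium;
* four `CALIX_O` beads on the lower rim;
* four tails of `tail_length_beads` CH₂ beads (default 3, a propyl
  tail) descending along −z;
* four head arms of `head_arm_beads` beads (default 4) rising outward,
  each terminated by a protonated `AMINE_N` bead with formal charge +1,
  so every molecule carries +4 and the hexamer +24.

`assemble_micelle` places `aggregation_number` copies at
`placement_radius` (default 12 Å) along the six cube-face normals for
N = 6, tails inward, and refuses arrangements with inter-molecule
contacts below `clash_distance` (2.0 Å — "as tight as possible without
steric clashes" made concrete).  For N ≠ 6 the placement generalises to
good spherical-cap coverings: exact Platonic directions for
N ∈ {2, 3, 4, 6, 12}, a Fibonacci lattice otherwise.

The resulting ideal hexamer spans Dmax ≈ 39 Å with a shell-weighted
Guinier Rg ≈ 20 Å — the same scale as the experimental micelle
(Rg = 16.7 Å, Dmax = 45 Å) without being calibrated to it; the bead
model is deliberately not refined against any measured curve.

**Pseudo-trajectories.** `generate_pool` perturbs the ideal micelle per
frame: each molecule receives a rigid-body rotation (rotation-vector
components ~ N(0, σ/placement_radius) rad) and translation
(~ N(0, σ) Å), then every bead gets isotropic N(0, σ) jitter
(σ = `perturbation_sigma`, default 0.5 Å).  A Bernoulli
(`deform_fraction`) subset of frames is stretched by
`elongation_factor` (default 1.5) along a random axis with 1/√f lateral
compression (volume preserving), emulating the rare elongated micelles
that fit the data poorly.  All randomness flows through one seeded
generator; pools are bit-reproducible under (spec, seed).

What the generator does **not** emulate: force-field energetics,
tail conformational entropy, explicit solvent/counter-ion structure,
association–dissociation events, and experimental noise or smearing.
Tests passing on these pools therefore demonstrate the correctness of
the *pipeline machinery* (forward model, scoring, selection,
descriptors), not the realism of any particular MD force field.

## Forward SAXS model

`debye_intensity` evaluates the exact O(N²) Debye sum — no multipole or
sampling approximations — grouped by scatterer label and chunked over q
to bound memory.  Amplitudes are q-independent electron counts minus
the Fraser–MacRae–Suzuki Gaussian-sphere excluded-volume term
`ρₛ v exp(−q² v^{2/3}/4π)`; displaced volumes follow the dummy-atom
radii conventional in SAXS software.  The unit bead `"B"` (f = 1,
v = 0) makes the analytic oracles exact.

The hydration shell is a layer of explicit contrast beads rather than a
border-function expansion: candidate points on a cubic grid of pitch
`shell_bead_spacing` (2.0 Å) are kept when (i) their distance to the
nearest solute bead lies in `(shell_contact, shell_contact +
shell_thickness]` (1.6 Å and 3.0 Å) and (ii) they fall outside the
solute's convex hull, so interior voids of the coarse bead packing
collect no water.  Each bead carries amplitude `shell_contrast ×
spacing³`; the default contrast 0.06 e/Å³ is the low end of the
0.06–0.075 range that micellar systems typically require.  This choice
is bit-reproducible and directly testable (shell-bead radii bounds; Rg
monotone in contrast; Guinier-vs-coordinate-Rg agreement within 3 %).

The default q-grid is 256 linear points on 0.005–0.5 Å⁻¹, covering the
feature range of a ~45 Å particle.  Guinier fitting iterates the
window until q·Rg ≤ 1.3 (weighted ln I vs q² fit); a flat profile
yields Rg = 0 and a rising one is rejected.  P(r) is a straight
histogram of pair distances (self-pairs excluded, optional contrast
weights), with Dmax the right edge of the last occupied bin — so the
histogram Dmax can exceed the exact coordinate Dmax by at most one bin,
and both estimators are exposed.

Near the analytic sphere's form-factor zero (qR ≈ 4.49) relative
deviations are ill-conditioned — the oracle tests bound the absolute
deviation of normalised intensities everywhere (< 2 %) and the relative
deviation away from the minimum.

## Fit scoring

The Jaccard index is evaluated on base-10 logarithms.  Two
normalisation choices are deliberate, since the bare formula is not
scale-invariant:

* the calculated profile is least-squares scaled onto the experimental
  one (`s = ΣIₑI_c / ΣI_c²`) first, as CRYSOL does internally;
* both profiles are then rescaled so the experimental maximum sits at
  10⁴, keeping log-intensities positive over the usual dynamic range.
  The [0, 1] range of J is guaranteed only for positive logs; points
  with I ≤ 0 are dropped (not clamped, which would bias J).

The reduced χ² `Σ((Iₑ − s·I_c)/σ)²/(N−1)` is the reference metric and
the GA's default fitness whenever experimental uncertainties exist.

## Ensemble selection

`select_by_threshold` keeps frames with J strictly above τ (ties
excluded); an empty selection is a valid outcome.  `ga_optimize` evolves
multisets of `ensemble_size` frame indices (default 20): tournament
selection (k = 3), single-point crossover on the sorted index lists,
per-gene mutation to a uniform random frame (rate 0.1), elitism 2,
population 50, 500 generations by default.  Fitness is χ² when σ is
available, else 1 − J; the best-ever chromosome is returned, so the
reported fitness is non-increasing across generations by construction.
Repeats inside a multiset implement ensemble weights without a
constrained optimiser, which is why a 50/50 two-family mixture is
recovered as ≈10 + 10 members rather than as explicit weights.

## Structural descriptors

Coordinate Dmax is the exact maximum pairwise distance.  "Hexagonal
packing" is operationalised as an octahedral order score: the six
calixarene centroids are centred, scaled to unit mean radius, and
fitted to the octahedron vertices minimising RMSD over rotation
(Kabsch), vertex assignment (Hungarian) and uniform scale, iterated
from a fixed set of rotation starts; the score is 0 for the ideal
cube-face arrangement and invariant to rigid motion and scaling.
Histogram comparisons (full pool vs selection) enforce identical
binning (default 30 bins over the pooled range) and report Δmean, Δsd,
sd ratio and mode shift — descriptive deltas only, no hypothesis test.
Frames are weighted uniformly in histograms; GA multiplicity weighting
is available by passing the multiset indices directly.

## Problem sizes and numerical choices

The validation suite uses pools of 60–200 frames of the 264-bead
hexamer on 101-point q-grids, a ~1 200-bead sphere for unit oracles and
a ~3 100-bead sphere (R = 20 Å, spacing 2.2 Å) for the form-factor
check; these sizes were chosen so every closed-form comparison is
well-converged while the whole suite stays interactive.  GA acceptance
experiments run 10 seeds × 200 generations on a 200-frame two-family
pool.  Degenerate inputs are explicit errors (empty selections,
non-covering q-ranges, missing σ for χ², aggregation number ≠ 6 for the
packing score) rather than silent fallbacks.

## Known limitations

* Bead-level coarse-graining: absolute intensities and fine features
  above q ≈ 0.4 Å⁻¹ are not meaningful; the pipeline's comparisons are
  all relative.
* The hydration envelope is convex per construction, an approximation
  for strongly non-convex conformers.
* Calculated profiles will not numerically match CRYSOL's multipole
  implementation; validation is against analytic oracles instead.
* No maximum-entropy/Bayesian re-weighting, no flexible-linker pool
  generation, no WAXS, no binary trajectory formats.
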