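# micelle-ensemble

SAXS-guided ensemble analysis of hexameric calix[4]arene micelles.

Small, highly charged calix[4]arene surfactants self-assemble into
remarkably monodisperse "Platonic" micelles whose preferred aggregation
number (six, here) corresponds to a good spherical-cap covering — six
molecules each occupying one face of a cube.  Solution SAXS sees only
the ensemble average, so connecting a measured profile to structures
from a conformer pool (in practice, MD snapshots) requires three
ingredients, all implemented here for structural modellers who want a
transparent, fully scriptable version of that workflow:

1. **Forward scattering** — the exact Debye sum over scatterer pairs,

   `I(q) = Σᵢ Σⱼ gᵢ(q) gⱼ(q) · sin(q·rᵢⱼ)/(q·rᵢⱼ)`,

   with `gᵢ(q) = fᵢ − ρₛ vᵢ exp(−q² vᵢ^{2/3}/4π)` the contrast amplitude
   (Gaussian-sphere excluded-volume convention, ρₛ = 0.334 e/Å³ for
   water) and an explicit hydration shell of contrast beads
   (default excess density 0.06 e/Å³) on the solvent envelope.

2. **Goodness of fit** — a Tanimoto/Jaccard similarity of the two
   log-intensity curves,

   `J = Σxy / (Σx² + Σy² − Σxy)`,  `x = log I(qᵢ)`, `y = log I_c(qᵢ)`,

   which equals 1 exactly for a perfect fit and stays in [0, 1] for
   positive-log profiles; the conventional reduced χ² is computed
   alongside it.

3. **Ensemble selection** — either every frame scoring above a Jaccard
   threshold τ, or a genetic algorithm in the style of the Ensemble
   Optimization Method: fixed-size multisets of frame indices evolved
   so that the *average* intensity of the members fits the data.

Selected ensembles are then characterised structurally: per-frame Rg
and Dmax histograms, pair distance distributions P(r) of tagged atom
groups (calixarene O/C, amine N), an octahedral packing-order score,
RMSD series, Kratky/Porod transforms and RDFs.

Because no public trajectories or scattering data exist for this
system, the package ships a first-class synthetic generator: a
coarse-grained (one bead per heavy-atom group) four-armed surfactant
with C2v/C4v ring conformers, assembled into a cube-face hexamer
(+4 per molecule, +24 per micelle) and perturbed into
pseudo-trajectories with optional elongated "incompatible" frames.
Every stage is validated against closed-form oracles (analytic sphere
form factor, brute-force pair enumeration, binomial counts).

## Worked example

```python
import numpy as np
import micelle_ensemble as me

spec = me.MicelleSpec()                          # hexamer, C2v rings
micelle = me.assemble_micelle(spec)
print(f"{micelle.n_atoms} beads, net charge +{micelle.total_charge}")

cfg = me.SaxsConfig(n_q=101, q_max=0.3, shell_contrast=0.0)
reference = me.compute_profile(micelle, cfg, hydration=False)

noisy = me.MicelleSpec(perturbation_sigma=0.4, deform_fraction=0.3)
pool = me.generate_pool(noisy, 60, rng_seed=1)
scores = me.score_trajectory(pool, reference, cfg, hydration=False)
print(f"Jaccard range over 60 frames: "
      f"{scores.jaccard.min():.5f} - {scores.jaccard.max():.5f}")

selected = me.select_by_threshold(scores, tau=0.9995)
rg, dmax = me.per_frame_descriptors(pool)
pos = np.searchsorted(pool.frame_index, selected.member_indices)
print(f"selected {selected.size}/60 frames, ensemble J = {selected.fit.jaccard:.5f}")
print(f"Dmax sd: full pool {dmax.std():.2f} A -> selected {dmax[pos].std():.2f} A")
```

prints

```
264 beads, net charge +24
Jaccard range over 60 frames: 0.99309 - 1.00000
selected 37/60 frames, ensemble J = 0.99997
Dmax sd: full pool 6.89 A -> selected 0.46 A
```

The reference profile is computed from the ideal cube-face hexamer; the
pool mixes thermally jittered frames with 30 % elongated ones.  Frames
above the threshold are overwhelmingly the compact, symmetric ones, so
the selected ensemble's Dmax spread collapses (6.89 → 0.46 Å) while its
average profile fits the reference almost perfectly — the synthetic
version of picking the hexagonally packed snapshots out of a trajectory.

A `micelle-ensemble` CLI wraps the same stages
(`generate | saxs | fit | select | analyze | run`); `run --config
config.json` executes the whole pipeline into a stamped run directory
(scores.csv, ensemble.json, histograms/, report.json).

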