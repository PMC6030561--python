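# icmscope

Quantitative single-cell mapping of **intracytoplasmic membrane (ICM)
localization** in purple nonsulfur bacteria (PNSB) from the natural
autofluorescence of bacteriochlorophyll a (BChl).

PNSB such as *Rhodopseudomonas palustris* house their photosynthetic
machinery in ICMs. Because BChl is both autofluorescent and ICM-resident,
a fluorescence micrograph reads out where the ICM sits inside each live cell
without any genetic labeling. Some species elaborate ICMs along the whole
cell (*nonrestricted* localization); others confine them to discrete sites
at conserved distances from the cell poles (*longitudinally restricted*
localization). `icmscope` turns multi-channel micrographs (phase contrast,
BChl fluorescence, optional fluorescent-lectin adhesin stain) into the
population statistics that distinguish these patterns, and maps the
resulting trait onto a species tree.

## What it computes

For each field the pipeline performs:

1. **registration** — a least-squares affine (optionally quadratic) map from
   landmark pairs aligns the fluorescence channels to phase coordinates;
2. **segmentation** — cells are detected in the phase channel (Otsu on the
   inverted, smoothed image), touching cells are divided by marker-based
   watershed, and each cell gets a medial axis (pruned skeleton extended to
   the poles), length *L*, width, and pole coordinates;
3. **quantification** — background-corrected mean cellular intensity and a
   medial-axis intensity profile *I(s)*, *s* ∈ [0, *L*]; ICM foci are
   prominent maxima of the smoothed profile with sub-pixel positions;
4. **orientation** — the brightest adhesin spot near a pole marks the old
   pole (PNSB deposit a unipolar polysaccharide adhesin there), and profiles
   are flipped so *s* = 0 is the old pole;
5. **population statistics** — length-sorted demographs, pole-aligned focus
   centroid maps, focus-count vs length tables with Tukey outliers, the
   inter-focus spacing vs length regression (spacing = *L* − *d*_old −
   *d*_new when each focus keeps a fixed pole distance), old/new focus
   intensity comparison, the A770/OD660 BChl-content vs fluorescence
   correlation, and a restricted/nonrestricted population classifier based
   on axial occupancy;
6. **trait mapping** — Fitch (minimum-change) parsimony of discrete ICM
   traits on a rooted species tree, exact on multifurcations, with
   enumeration of all maximum-parsimony labelings.

A fully ground-truthed **synthetic scene generator** renders fields of
spherocylindrical cells with either localization pattern (axial Gaussian
foci of extent σ at *d*_old from the old pole, a second weaker focus —
intensity ratio ρ — beyond the length threshold *L**, or uniform whole-cell
signal), polar adhesin spots, Gaussian PSF blur and Poisson + read noise,
so every stage is testable without microscope data.

## Worked example

```python
from icmscope import SceneConfig, LocalizationModel, generate_scene, analyze_field
from icmscope.popstats import (pole_distance_stats, spacing_pairs,
                               spacing_regression, old_new_intensity_compare,
                               classify_localization)

cfg = SceneConfig(n_cells=100, field_shape=(1280, 1280),
                  adhesin_fraction=1.0, seed=8)
model = LocalizationModel(pattern="restricted", d_old=0.6, d_new=0.5,
                          L_star=2.5, rho=0.6)
field, truth = generate_scene(cfg, model)
res = analyze_field(field)

print(f"cells detected: {len(res.cells)} (simulated: {len(truth.cells)})")
dist = pole_distance_stats(res.foci, res.cells, res.calls)
print(f"median old-pole focus distance: {dist['old']['median']:.3f} um")
reg = spacing_regression(spacing_pairs(res.cells, res.foci))
print(f"spacing vs length: slope {reg.slope:.3f}, intercept {reg.intercept:.3f} um")
print(f"median new/old ratio:",
      round(old_new_intensity_compare(res.cells, res.foci, res.calls)['median_ratio'], 3))
print(f"population classified as: {classify_localization(res.profiles).label}")
```

Output:

```
cells detected: 100 (simulated: 100)
median old-pole focus distance: 0.579 um
spacing vs length: slope 0.989, intercept -1.044 um
median new/old ratio: 0.609
population classified as: restricted
```

Read it as: the pipeline re-measured, from rendered noisy images alone, the
model parameters it was never told — the conserved 0.6 µm old-pole distance,
the spacing-vs-length line implied by two pole-anchored foci (slope 1,
intercept −(0.6 + 0.5) µm), and the 0.6 intensity ratio of new to old focus —
and labeled the population's localization pattern correctly.

A command-line interface wraps the same pipeline
(`icmscope simulate | register | all | parsimony | evaluate ...`); runs are
config-driven (YAML), seeded, and write a manifest alongside the CSV/PNG
outputs.

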