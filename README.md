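# vamorph

Vestibular-aqueduct (VA) morphometry from volumetric CT, validated end to
end on synthetic temporal-bone phantoms with analytic ground truth.

The vestibular aqueduct is a thin bony canal running from the vestibule of
the inner ear to the posterior cranial fossa. An enlarged VA (EVA) is the
most common inner-ear malformation found in children with sensorineural
hearing loss, and it is conventionally diagnosed by caliper measurements on
axial CT slices: the Valvassori rule (midpoint width > 1.5 mm) or the
Cincinnati rule (operculum width > 1.9 mm and/or midpoint width > 0.9 mm).
Two fixed caliper stations, however, ignore the shape of the duct — a
centrally dilated duct can have a normal operculum, and two ducts with
identical openings can enclose very different volumes. `vamorph`
implements the volumetric alternative and everything needed to study it:

- **`volio`** — NIfTI-1/MetaImage volumes, label maps and PLY/STL meshes
  with an explicit axis-aligned world-geometry convention.
- **`segment`** — the semi-automatic protocol: Hounsfield-band threshold
  (−1024 to 700 HU, inclusive), 26-connected components, seeded component
  selection, and plane clipping at the vestibule exit and the operculum.
- **`morpho`** — VA volume by voxel counting and by watertight
  marching-cubes mesh integration (divergence theorem); a skeleton-based
  centerline; sub-voxel caliper widths at the course midpoint and the
  operculum, measured on axial slices perpendicular to the local course.
- **`criteria`** — Cincinnati, Valvassori and the volumetric rule
  (VA volume > 15.4 mm³), all with strict inequalities.
- **`stats`** — five-number summaries, tie-corrected Kruskal–Wallis with
  Dunn's post hoc (exact permutation paths at small n), Hodges–Lehmann
  shift estimates with Moses order-statistic CIs, Spearman correlation,
  inter-rater ICC(2,1), ROC with the Youden-index cutoff, and
  Clopper–Pearson intervals.
- **`phantom`** — a synthetic temporal-bone generator: a bright bone block
  containing an ellipsoidal vestibule and a VA tube whose radius profile
  follows one of three shape archetypes (uniform, central dilatation,
  operculum funnel), digitized with partial-volume supersampling, blur and
  noise, plus cohort simulation calibrated to published group-wise
  diameter distributions and a two-rater landmark-perturbation model.
- **`pipeline`** — the full study: simulate → segment → measure under two
  raters → classify → statistics, plus a replicate reliability experiment.

## Worked example

```bash
vamorph all --seed 7 --outdir study_out --log-level warning
```

prints

```
study complete: 98 ears; ROC cutoff 6.63 mm^3 (sens 1.00, spec 1.00); outputs in study_out
```

and writes `cohort.csv` (one row per ear per rater with truth, measured
diameters and volumes, and the three rule classifications),
`descriptives.csv`, `correlations.csv` and `summary.json`. For this seed
the summary contains

```
reliability: {'volume': 0.9996, 'midpoint': 0.9908, 'operculum': 0.8555}
kw:          {'H': 78.41, 'df': 4, 'p': 3.8e-16}
concordance: {'both_enlarged': 37, 'cincinnati_only': 9, 'volumetric_only': 0,
              'both_normal': 52, 'agreement': 0.908}
```

Reading: the volume across the five groups (control and four malformation
types) differs strongly (Kruskal–Wallis H = 78.4); volumetry separates the
EVA-syndrome group from controls perfectly (sensitivity = specificity =
1.0 at the Youden cutoff of 6.6 mm³, which lies in the gap between the
largest control and the smallest EVAS volume); and the inter-rater
reliability of the volume (ICC 1.00) exceeds that of the two caliper
diameters (0.99 and 0.86) — the volumetric measurement is the most
reproducible, and the operculum caliper the least.

The same machinery is available as a library:

```python
from vamorph import (PhantomSpec, build_radius_profile, rasterize_phantom,
                     SegmentationParams, CutPlane, isolate_va,
                     skeleton_centerline, measure_record, classify_cincinnati)

profile = build_radius_profile("central_dilatation", 0.4, 1.6, 0.5)  # radii in mm
spec = PhantomSpec(profile, blur_sigma_mm=0, noise_sd_hu=0, spacing=(0.2, 0.2, 0.2))
image, truth_lumen, gt = rasterize_phantom(spec)

lm = gt.landmarks
va = isolate_va(image, SegmentationParams(), lm.seed_point,
                CutPlane(tuple(lm.vestibule_exit), tuple(lm.exit_normal)),
                CutPlane(tuple(lm.operculum), tuple(lm.operculum_normal)))
centerline = skeleton_centerline(va, lm.vestibule_exit, lm.operculum)
record = measure_record(image, va, centerline)
print(record.midpoint_diameter_mm, record.operculum_diameter_mm)
# 3.24 1.03   -> enlarged by the Cincinnati midpoint clause only
print(classify_cincinnati(record.midpoint_diameter_mm, record.operculum_diameter_mm).trigger)
# 'midpoint'
```

CLI subcommands `simulate`, `measure`, `classify` and `stats` expose the
individual stages; `--config` accepts a YAML/JSON `StudyConfig` dump.

## Documentation

`docs/methods.md` describes the phantom model, the measurement
conventions, the cohort calibration, the rater model and the numerical
choices, together with known limitations.
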