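# rectvar

Interfraction positional-variation analysis for rectal primary tumor
volumes (GTVp) in radiotherapy.

Rectal tumors are irregular and deformable; their day-to-day position and
shape changes between treatment fractions drive the planning-target-volume
(PTV) margins used for dose escalation. `rectvar` quantifies that
variation from repeat-MRI delineations — one baseline structure plus
repeat structures rigidly co-registered to it — by two complementary
methods and decomposes the cohort variation into the standard geometric
uncertainties:

* **COM path** — volume-centroid (center-of-mass) shift per scan, a
  rigid-motion surrogate;
* **surface path** — per-point surface displacement by the bidirectional
  local distance (BLD): for each baseline surface point, the farthest of
  {its nearest test point} ∪ {test points reverse-assigned to it}, as a
  signed 3D vector decomposed into right–left (RL), anterior–posterior
  (AP) and cranial–caudal (CC) components (+ = out of the baseline
  structure in-plane; + = away from the COM plane in CC).

Cohort statistics follow the Van Herk methodology: with m_p and s_p the
per-patient mean and SD of a displacement measure per direction,

    GM = mean_p(m_p)        (group mean)
    Σ  = SD_p(m_p)          (systematic error)
    σ  = sqrt(mean_p s_p²)  (random error)

For the surface path, each patient is summarized by the 95th percentile
over baseline points of the per-point means and SDs across scans.
Location-resolved analysis maps every patient's surface statistics onto a
common tubular reference rectum (120 points per slice, central-axis
distance from the anal verge) and reports segment tables by wall
direction (anterior/posterior/left/right 180° halves) × height band
(low 28–51, mid 52–100, high 102–130 mm), plus cranial/caudal rows from
the tumors' top and bottom slices.

Because real repeat delineations are not distributable, the package
includes a first-class synthetic cohort generator with known ground truth
(per-patient systematic offsets, per-scan random offsets, group-mean
drift, volume-balanced local deformations on wall-hugging crescent
tumors), used by the test suite for parameter-recovery and
mechanism-contrast validation. See `docs/methods.md` for the model
details and conventions.

## Worked example

```python
import rectvar as rv
from rectvar.pipeline import analyze_patient, aggregate_cohort

records, truth = rv.make_study_like_cohort(seed=7)   # 16 patients x 6 scans
analyses = [analyze_patient(r, spacing_mm=1.0) for r in records]
res = aggregate_cohort(analyses)
print(res.population_table.round(2).to_string(index=False))
```

```
     method direction  Sigma_mm  sigma_mm  gm_mm  n_patients
        com        rl      1.60      1.39  -0.04          16
        com        ap      2.13      2.19  -0.79          16
        com        cc      1.91      2.30   0.73          16
surface_p95        rl      0.42      2.16   1.24          16
surface_p95        ap      0.59      2.43   1.57          16
surface_p95        cc      0.52      2.34   1.02          16
```

Reading the table: the COM rows estimate the cohort's systematic (Σ),
random (σ) and group-mean (GM) errors in mm from centroid shifts — here
dominated by the generator's configured rigid motion. The surface rows
use the 95th-percentile surface summaries: selecting each patient's most
displaced regions *reduces* inter-patient spread (smaller Σ) while
*inflating* random and group-mean errors — the characteristic signature
of extreme-value selection, and the reason location-resolved segment
tables (`res.segment_table`) are computed on the reference rectum.
`res.refmap` holds the per-reference-point Σ/σ/GM maps with the
≥5-patient validity mask; `res.reference_table` and `res.segment_table`
are their CSV-ready forms.

The same pipeline runs from the shell:

```bash
rectvar simulate  --out cohort/  --seed 7
rectvar analyze   --cohort cohort/ --out analysis/ --spacing 1.0
rectvar aggregate --results analysis/ --out results/
```

`analyze` accepts any directory of patient files in the documented JSON
dialect (see `rectvar.structures`); `ingest_rtstruct` converts DICOM
RT-STRUCT ROIs into that form.

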