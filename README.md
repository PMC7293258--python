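# hallerquant

Quantitative analysis of the large choroidal vessels of Haller's layer on
**en face OCT** images, for research on central serous chorioretinopathy
(CSC) and other pachychoroid-spectrum disease.

Eyes with CSC carry a thick, congested choroid.  On a coronal (en face)
slice through the top quarter of Haller's layer the large vessels appear as
dark bands, and two things distinguish diseased from healthy eyes: the
vessels are *wider*, and their *running pattern* is less mirror-symmetric
about the horizontal line through the fovea (healthy maculae sit over a
watershed zone between the upper-temporal and lower-temporal vortex-vein
drainage territories).  `hallerquant` turns a slab image into four numbers
that capture this:

- **vessel area** `A` (mm²) — footprint of the binarized dark-vessel phase;
- **vessel length** `L` (mm) — total length of the thinned (one-pixel-wide)
  centerline network;
- **mean vessel diameter** `D = A / L` (mm) — caliber of the equivalent
  uniform-width network;
- **symmetry index** (%) — the thinned network is cut into branch-free
  segments at branch points; each segment's endpoint-chord angle θ ∈
  (−90°, 90°] to the horizontal is measured in a laterality-normalized
  frame (temporal = +x, superior = +y).  A segment is a *natural oblique
  vessel* when it points into its hemifield's temporal-ward quadrant
  (superior hemifield: θ ∈ (0°, 90°); inferior: θ ∈ (−90°, 0°)).  The index
  is 100 × (natural-oblique segment length) / (total segment length).

The package also ships the cohort statistics used to compare groups
(Mann-Whitney U, Yates-corrected χ², Spearman rank correlation against
central choroidal thickness, ROC with the Youden-index cutoff) and a
synthetic-data layer — vessel-scene images with exact ground truth and
per-eye metric cohorts with controllable group moments and rank
correlations — so the whole pipeline is testable without patient data.

## Worked example

Simulate a 41-eyes-per-group cohort (control / CSC fellow eyes / CSC eyes)
at realistic group moments and run the full statistical flow:

```bash
hallerquant demo --seed 7 --out-dir demo_out
```

prints (abridged):

```
hallerquant end-to-end demo (seed=7, n=41/group)

Group comparisons (Mann-Whitney, two-sided):
  mean_diameter_mm     control    0.136 ± 0.023   vs     csc    0.186 ± 0.035    p=6.18e-10
  symmetry_index_pct   control   58.039 ± 5.749   vs     csc   52.034 ± 6.273    p=7.791e-05
  ...

ROC (mean vessel diameter, CSC vs control):
  AUC = 0.897
  Youden cutoff = 0.1593 mm (J = 0.707)
  sensitivity 78.0%  specificity 92.7%
  quadrant: tp=32 fp=3 tn=38 fn=9
```

Diseased eyes show the expected signature: larger mean vessel diameter,
lower symmetry index, and a diameter cutoff near 0.15–0.16 mm that
separates CSC from normal eyes.

Image-level analysis works the same way from the shell:

```bash
hallerquant simulate --out-dir scenes --n-images 3 --seed 1   # synthetic slabs + ground truth
hallerquant analyze scenes --out-dir metrics --segments       # per-eye metrics CSV + segment tables
```

or from Python:

```python
from hallerquant import compute_eye_metrics
from hallerquant.io import load_enface

image = load_enface("scenes/scene_000.png")   # reads the JSON sidecar too
m = compute_eye_metrics(image)
print(m.vessel_area_mm2, m.vessel_length_mm, m.mean_diameter_mm, m.symmetry_index_pct)
```

Real slab images are accepted as 8-bit grayscale PNG/BMP/TIFF with an
optional sidecar (`eye_side`, `pixel_size_mm`, `cct_um`, `fovea_xy`,
`group`); the default scale is the 7 × 7 mm / 512 × 512 px scan mode
(7/512 mm per pixel).

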