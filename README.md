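# lvtrab

Automatic quantification of left-ventricular (LV) hyper-trabeculation from
short-axis end-diastole cardiac MR stacks, with a box-counting
fractal-dimension comparator.

Left ventricular non-compaction (LVNC) shows up on bright-blood CMR as
excessive trabeculation: dark muscle strands riddling the bright LV blood
pool. Cardiologists traditionally delineate the LV cavity, the right
ventricle (RV), and the epicardial "external layer" by hand on every slice —
tens of minutes per slice. `lvtrab` automates the whole chain and reports,
per patient, the trabecular volume VT, compact-zone volume VCZ, the
trabeculated-myocardium percentage

TM% = 100 · VT / (VT + VCZ)

with masses TM = VT·ρ and CM = VCZ·ρ (ρ = 1.05 g/mL myocardial density),
and the diagnostic label **LVNC iff TM% ≥ 27.4** (inclusive).

The per-slice pipeline:

1. **LV cavity** — bright maximally stable extremal regions (MSERs) in a
   centered ROI, scored by circularity and centrality; a convex hull over the
   blood pool spans the trabecular recesses and gives the endocardial outline.
2. **External layer** — radial rays cast from the LV centroid through the
   compact wall; each ray extends to `l = r·d` (d ≈ 1.60, the *e-expand*
   reach multiplier on the cavity's equivalent radius) and stops where
   intensity falls below half the local myocardium level. Rays crossing the
   RV blood pool are bridged from their angular neighbors.
3. **RV cavity** — the largest bright region adjacent to the external
   contour, anywhere around it.
4. **Trabeculae / compact zone** — Otsu separation of dark tissue inside the
   hull (trabeculae) and between hull and external contour (compact wall).

The **fractal comparator** implements the rival diagnostic rule: box-counting
fractal dimension (FD) of the trabeculated endocardial border per slice,
global FD = mean over slices (LVNC iff ≥ 1.26), and maximal FD per
basal/mid/apical third (LVNC iff ≥ 1.30).

A **synthetic phantom** generator renders slice stacks with exactly known
geometry (closed-form compact and trabecular areas, apical tapering, RV
crescent at any angle, seeded noise) so that every stage is testable without
patient data, including a sweep that dials the trabecular fraction.

## Worked example

Generate a phantom study (written as a small DICOM series), quantify it, and
run the diagnostic-rule comparison on the packaged 27-patient reference
table:

```sh
$ lvtrab phantom --out study --format dicom
wrote 9 slices to study (dicom)

$ lvtrab quantify --input study --out report
TM% = 29.28  VT = 34.98 mL  VCZ = 84.48 mL  TM = 36.73 g  CM = 88.70 g  label = LVNC

$ lvtrab compare --table cohort.csv --out cmp
{"n_patients": 27, "n_fd_non_lvnc": 6, "fd_accuracy_pct": 78, "tm_accuracy_pct": 100}
```

The default phantom is rendered with an analytic trabecular fraction of
29.1%, so the pipeline's TM% of 29.28 recovers it to a fraction of a
percentage point and correctly labels the stack LVNC. The same study's
global fractal dimension comes out at 1.24 (`report/fd_report.csv`), below
the 1.26 threshold — the phantom is a live example of the two rules
disagreeing. On the reference cohort of 27 patients with established LVNC,
the TM% rule labels all 27 correctly (100%) while the global-FD rule misses
six (78%).

`report/` also contains per-slice CSV/JSON records and overlay PNGs
(external layer in gray, trabecular contours in blue, cavity contour in
red). `lvtrab fractal --input study --out fd` writes the per-slice FD table
with per-third maxima and labels.

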