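# mitomorph

Integrative 2D/3D quantification of mitochondrial shape and network
properties from calibrated fluorescence z-stacks.

Mitochondria shift between fragmented (globular) and filamentous
(reticular) morphologies, and these shifts track cell physiology and
stress. Quantifying them from confocal images of fluorescently labelled
mitochondria (e.g. matrix-targeted GFP) is routine in flat cells using
2D image analysis, but thicker cells need genuinely 3D measurement:
collapsing a z-stack into a single projection merges objects that
overlap only in the axial direction and misreports counts and sizes.
`mitomorph` implements the full measurement chain in both modes — for
microscopists and image analysts who want per-object morphology numbers
and network topology out of a TIFF stack — and ships a synthetic-data
generator with exact ground truth so every stage of the chain can be
validated without microscope data.

## The measurements

Per segmented object (2D / 3D):

| descriptor | definition | interpretation |
|---|---|---|
| A_m, V_m | pixel/voxel count × calibration | size (µm², µm³) |
| P_m, S_m | sub-pixel contour length / iso-surface mesh area | boundary (µm, µm²) |
| F | P_m² / (4π·A_m) | formfactor: 1 for circles, >1 when elongated/branched |
| D_m | (6·V_m/π)^⅓ | equivalent (equal-volume-sphere) diameter |
| SF | 6·V_m / (D_m·S_m) | sphericity: 1 for spheres, <1 otherwise |

Per skeletonized network: branch count N_BR, branch points N_BP (≥3
branches meeting), end points N_EP, branch length L_BR (unfolded
centre-line length), branch diameter D_BR (2× distance-map value along
the centre line) and branch volume V_BR = (π·D_BR²/4)·L_BR.

Six integrative indexes combine both: branch length / branches / branch
points per mitochondrion and per biomass (total area in 2D, total
volume in 3D).

The processing chain is: raw stack → blind Richardson–Lucy
deconvolution (image and PSF estimated jointly, anisotropic Gaussian
initial guess) → optional contrast stretch → fraction-of-brightest-pixels
threshold → size filter → connected components → per-object shape
descriptors (2D on a maximum-intensity composite; 3D on the iso-surface
model) and, with the same threshold, skeletonization → pruning →
vectorization into a branch graph.

## Worked example

Simulate a z-stack of a cell with a filamentous mitochondrial reticulum
(4 branched tubules, known centre-line length, realistic anisotropic
PSF blur) and run the full 3D analysis:

```python
import mitomorph as mm

bundle = mm.run_pipeline({"synth": {"phenotype": "filamentous", "seed": 1}})
r3 = bundle["results"][0]["3d"]
gt = bundle["ground_truth"]
```

This prints (unit voxels, so µm numbers equal voxel numbers):

```
ground truth: 4 tubules, total centre-line length 600.0 um
3D analysis:  N_ROI=4  V_m,ROI=24445 um^3  S_m,ROI=14983 um^2  SF_mean=0.432
network:      N_BR=12  N_BP=4  N_EP=12  L_BR,ROI=590.4 um  V_BR,ROI=16264 um^3
indexes:      L/N=147.6  L/V=0.0242  NBP/L=0.0068
```

All 4 tubules are recovered as separate 3D objects; the measured total
branch length (590.4) is within 2% of the generator's ground truth
(600.0); the low mean sphericity (0.43) and 4 branch points per 4
objects correctly describe an elongated, branched phenotype. Running
the same pipeline on `{"phenotype": "fragmented"}` yields N_ROI = 25
spheres, SF ≈ 0.99 and an empty network — the two phenotypes the
method is designed to discriminate.

For real data, point the config at a calibrated TIFF instead:

```python
bundle = mm.run_pipeline(
    {"input": {"path": "cell.tif", "pixel_size_xy": 0.0845, "z_step": 0.364}},
    rois=mm.read_rois("rois.csv"),
    outdir="results/",
)
```

Per-object, per-branch and per-ROI CSV tables plus a parameter log are
written to `outdir`. Two conditions are compared with
`mm.compare_conditions(table_a, table_b)` (two-tailed t-tests per
descriptor, no multiple-testing correction — flagged in the output).

The same operations are available from the shell:

```bash
mitomorph synth --phenotype fragmented --seed 3 --out frag.tif
mitomorph analyze3d frag.tif --out results/ --config config.json
mitomorph report ctr/roi_summary.csv rot/roi_summary.csv --out cmp.csv
```

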