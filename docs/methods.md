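# Methods

This note records the models, estimators, parameter choices and known
limitations behind `mitomorph`'s measurement chain, in the order the
pipeline applies them.

## Image model and restoration

A z-stack is modelled as a non-negative intensity grid with lateral
pixel size and axial step in µm (the classic confocal acquisition this
is built around: 0.0845 µm pixels, 0.364 µm steps, 8-bit). The blur is
an anisotropic Gaussian point-spread function (PSF), wider axially than
laterally; the parametric initial guess derives from the objective
numerical aperture and emission wavelength as
σ_xy ≈ 0.21·λ/NA and σ_z ≈ 0.66·λ·n/NA², converted to voxels with the
calibration. When the blur is known in voxel units (synthetic data,
measured beads), it can be supplied directly (`psf_sigma`).

Restoration is blind Richardson–Lucy (RL): per cycle, one
multiplicative RL update of the image with the current PSF, then one RL
update of the PSF with the current image, with the PSF clipped to
non-negative values and renormalized to unit sum. Properties relied on
elsewhere, and tested: `cycles=0` is the identity; output is
non-negative; total intensity is conserved to well within 1% for
structures away from the stack border; the peak of a blurred point
source increases strictly with cycle count. Default cycles = 10 (at
least 8 are needed before the peak/background contrast levels off on
the bead fixture). Equivalence with commercial blind-deconvolution
implementations is claimed only at the level of these properties, not
voxel-for-voxel.

After deconvolution, RL tends to concentrate intensity into sharp
ridges while leaving a faint sub-quantization residue around
structures. The default pipeline therefore applies a contrast stretch
to 8-bit with robust automatic limits: the upper limit is the 99.5th
percentile of the deconvolved stack (the raw maximum is dominated by RL
ridge spikes), the lower limit 5% of that (a minimum-intensity
threshold that removes the faint residue and background haze). Both
limits are configurable; explicit values switch the automatics off. The
stretch maps linearly, rounds half-to-even (the midpoint of the range
maps to 128) and clips.

Two alternative 2D enhancement paths are provided for comparison work,
both off in the default pipeline: a spatial filter (median
pre-smoothing, then a white top-hat with a disk element larger than the
mitochondrial cross-section — a rolling background subtraction), and a
frequency-domain filter that suppresses (high-pass) or keeps (low-pass)
a circular area of interest at the centre of the 2D spectrum with a
smooth logistic roll-off. On rod fixtures, shrinking the high-pass AOI
radius from 10 to 5 to 2 increases peak/valley contrast monotonically;
this matches the qualitative behaviour reported for such filters, but
the exact transfer function of any particular commercial
implementation is not reproduced, and the default pipeline omits FFT
filtering entirely.

## Segmentation

The binarization threshold is a gray value chosen so that a given
fraction (default 20%) of the pixels of a reference section — by
default the section with the highest cumulative intensity, ties broken
toward the lower index — lies at or above it; formally, the smallest
present gray value t with P(I ≥ t) ≤ fraction, or the maximum intensity
when even the top bin exceeds the fraction. The fraction is computed
over all pixels of the section (a `nonzero_only` flag gives the
alternative reading) and the resulting t is applied to every section.
This rule presumes the reference section is signal-rich — on the order
of the chosen fraction covered by structure, which is what selecting a
mitochondria-rich region of interest achieves; on sparse fields the
threshold falls into the PSF halo and segmentation dilates. The
synthetic study conditions below are designed to sit in the signal-rich
regime.

Masks are size-filtered (defaults: 4 px in 2D, 8 voxels in 3D — small
enough to keep real fragments, large enough to drop single-voxel noise)
and labelled with full connectivity (8-neighbour in 2D, 26-neighbour in
3D; configurable), labels ordered by raster scan.

## Boundary estimators

Perimeter (2D) is the total polyline length of the marching-squares
iso-contour at level 0.5 of the object's indicator field after Gaussian
boundary smoothing. Surface area (3D) is the triangle area of the
marching-cubes iso-surface of the same smoothed indicator, with vertex
coordinates scaled by the anisotropic voxel calibration; meshes are
neither decimated nor smoothed afterwards. The smoothing is the load-
bearing choice: raw boundary-pixel counting overestimates perimeter
(breaking F ≈ 1 for disks), and marching squares/cubes applied to the
raw binary indicator trace the voxelization staircase (≈ +8% surface
area on a radius-20 ball, which alone would push SF to 0.92).

The smoothing width is 0.8 px/voxel, capped at one tenth of the
object's inradius (maximum of its Euclidean distance transform).
Gaussian level-set smoothing displaces the 0.5 level by roughly
σ²·curvature, so σ must stay well below the local radius; the cap keeps
the displacement ≲1% while still suppressing staircase noise on
well-resolved objects. Measured accuracy: disk r=50 → F = 1.021;
100×10 rectangle → F = 3.797 (continuum 3.852); ball r=20 → SF = 0.996;
100×20 cylinder → SF = 0.703 (continuum 0.697). Sub-resolution objects
(a few pixels) fall back to the unsmoothed indicator and are flagged
`small_object`; there the estimator bias is largest (a single voxel
yields the octahedral midpoint mesh of area √3, and single-pixel F can
deviate by tens of percent). F is reported unclamped, so values
slightly below 1 can occur on tiny objects.

D_m is defined as the diameter of the equal-volume sphere, which makes
SF the classical sphericity π^⅓(6V)^⅔/S and guarantees SF = 1 exactly
for ideal spheres. V_m is voxel-derived (count × voxel volume), not
mesh-derived.

## Network analysis

Thinning (skimage's topology-preserving skeletonization) runs to
convergence — a fixed small number of thinning iterations cannot give a
unit-width skeleton — followed by the configured number of pruning
iterations (default 2) of end-point erosion, which removes spurs caused
by boundary irregularities at the cost of shortening every open branch
end by up to that many pixels. Pruning is sequential in spirit and
never erases a whole component, so the degenerate point-like skeletons
of round objects survive and are reported as *unrepresented* objects
(zero branches) rather than fabricated branches; an optional minimum
branch-length filter exists but is off by default. Thinning operates in
voxel space ignoring axial anisotropy (standard practice); lengths and
diameters are calibrated afterwards, which slightly distorts strongly
anisotropic skeletons.

Vectorization clusters adjacent junction pixels (≥3 skeleton
neighbours) into single branch points — the descriptor counts points
where three or more branches attach, not raw junction pixels, and under
8/26-connectivity a crossing is typically a small pixel cluster.
Degree-1 pixels are end points; maximal paths between nodes are
branches with L_BR the sum of centre-to-centre Euclidean steps under
the anisotropic spacing; junction-free cycles become single closed
branches. Branch diameter is D_BR = 2 × the mean Euclidean
distance-map value along the branch polyline, with the distance map
using the centre-to-background-centre convention (a single isolated
voxel has value 1). That convention overestimates the true diameter of
a w-pixel-wide branch by up to one pixel (a 3-px rod measures ≈4); the
bias is the documented estimator tolerance and cancels in comparative
work. V_BR applies the cylindrical model (π·D_BR²/4)·L_BR.

## Synthetic data: what it emulates, and what not

The layered test stack (a binary panel of disks, rods and branched Y/X
shapes, three copies stacked between blank sections, unit voxels) gives
exact ground truth: V_m = 3·A_m per object by construction. Disk
diameters are 5/7/9 px so their 3-section extrusions stay
near-isotropic; larger disks would be flat pancakes whose SF is
legitimately far below 1, which is also why the F-vs-SF relationship
across the panel is a strong inverse correlation (Spearman ≤ −0.8)
rather than an exact rank inversion.

The cell simulator draws either spheres ("fragmented", the morphology
of metabolically stressed cells) or smooth persistent-random-walk
tubules with side branches ("filamentous", the normal reticulum),
convolves with the anisotropic Gaussian PSF and optionally adds Poisson
photon noise and Gaussian read noise (both off by default, so default
stacks are deterministic given the seed). Rasterization everywhere is
pixel-centre-in-shape, making ground-truth areas/volumes exact counts.
Tubes whose walk would approach itself closer than one diameter are
rejected and redrawn, since a self-overlapping tube's centre-line
length is unrecoverable from any image. Defaults are chosen to emulate
a mitochondria-rich perinuclear field whose brightest section is ~20%
covered by signal (the regime the threshold rule presumes): 25 spheres
of radius 5.8 voxels in a (32, 104, 104) stack within an 8-section
slab, or 4 tubules of length 110 and radius 2.5 voxels with one
40-voxel side branch each in (32, 128, 128) within a 2-section slab
(flat cells keep their reticulum near the substrate; the "rounding up"
of stressed cells is emulated by widening the slab). Optional intensity
modulation along tubes and dim-based side branches emulate the uneven
labelling that makes real segmentations threshold-sensitive; a uniform
background term emulates cytosolic haze.

Not emulated: photophysics (bleaching, blinking), cell boundaries,
spectral crosstalk, stage drift, time series. Passing the recovery
tests therefore shows the chain is correct under known blur and
Poisson/Gaussian noise — not that it is robust to every real-world
artifact.

## Validation design choices

- Ground-truth recovery is asserted at the defaults: all 25 spheres
  recovered (3D count exact across seeds), filamentous total branch
  length within 15% of the generator's centre-line ground truth (the
  irreducible losses are medial-axis end retraction ≈ tube radius plus
  pruning, a fixed ~4–5 px per branch end).
- The threshold-sensitivity sweep (10→35% included pixels) asserts
  monotone non-increasing N_ROI and non-decreasing V_m,ROI across the
  whole sweep, and net growth of L_BR,ROI and N_BR between the
  endpoints, on a fixed dense-arbor stack whose side branches are
  dimmest at their bases (lowering the threshold reveals *connected*
  structure). Strict per-step monotonicity of the skeleton totals is
  not asserted: once the threshold passes below the full structure,
  mask fattening in the PSF halo shortens skeletons by a few percent,
  which can invert adjacent steps on a noiseless stack.
- The projection-artifact experiment redistributes the same 25 spheres
  over a 3× wider axial slab and holds the gray threshold fixed at the
  value derived from the thin condition, so the two conditions differ
  only in axial distribution: 3D count and total volume stay within 10%
  of ground truth in both, while the 2D maximum-intensity-composite
  count drops by well over 10% in the thick condition — the merging
  artifact that motivates 3D analysis.
- Statistics are limited to per-descriptor two-tailed two-sample
  t-tests across ROIs with no multiple-testing correction (the
  comparison report notes this); treating ROIs of one cell as
  replicates is the user's scientific call, and the report simply
  records n.

## Degenerate inputs and numerical conventions

Empty masks yield empty tables and zeroed totals; zero-denominator
integrative indexes are reported as missing (NaN) with a warning, never
as 0. Thresholding a constant section is an error (no meaningful
fraction exists). Ties in the brightest-section search break toward the
lower index. Contrast stretching rounds half-to-even. ROI coordinates
are 0-based half-open; ROI selection is explicit (file or API), with a
seeded proposal helper instead of interactive picking, so analyses are
reproducible. Problem sizes throughout the test and benchmark suites
(stacks of ≈10⁵–10⁶ voxels, 25 objects, 4 tubules) are the package's
reference configurations; all scale linearly in voxel count except
deconvolution (FFT-bound) and vectorization (skeleton-pixel-bound).
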