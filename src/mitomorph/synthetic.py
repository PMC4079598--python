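"""Ground-truthed synthetic mitochondria-like images and z-stacks.

Two families of fixtures are produced:

* a binary 2D test image of simple geometric objects (disks, rods,
  branched Y/X shapes) and its layered z-stack, with exact per-object
  pixel/voxel ground truth — used to validate every descriptor against
  known geometry;
* simulated cell-like stacks with either *filamentous* (smooth 3D tubes,
  optionally branched) or *fragmented* (spheres) mitochondria, blurred by
  an anisotropic Gaussian point-spread function and optionally corrupted
  by Poisson + Gaussian noise, with ground-truth counts, volumes and
  centre-line lengths.

Rasterization rule (everywhere): a pixel/voxel belongs to an object iff
its *centre* lies inside the continuous shape. This makes ground-truth
areas/volumes exact integer counts and avoids anti-aliasing ambiguity.

The noise model is Poisson statistics on signal photons followed by
additive Gaussian read noise; both are off by default so that the default
fixtures are deterministic given the seed and geometry alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .stack import ZStack

__all__ = [
    "ObjectSpec",
    "GroundTruth",
    "make_test_image_2d",
    "default_test_specs",
    "build_test_stack",
    "simulate_cell_stack",
    "binary_ball",
    "binary_cylinder",
    "write_ground_truth",
    "read_ground_truth",
]


# ---------------------------------------------------------------------
# object specs and rasterization
# ---------------------------------------------------------------------

_KINDS = ("disk", "rod", "branched-Y", "branched-X")


@dataclass(frozen=True)
class ObjectSpec:
    """Continuous-geometry description of one synthetic 2D object.

    ``kind`` is one of ``disk`` (length = width = diameter), ``rod``
    (length × width rectangle), ``branched-Y`` (three arms of ``length``
    at 120° spacing) or ``branched-X`` (four arms at 90°). ``orientation``
    rotates the shape counter-clockwise, in degrees. ``center`` is
    ``(x, y)`` in pixel coordinates.
    """

    kind: str
    center: tuple[float, float]
    length: float
    width: float
    orientation: float = 0.0
    intensity: int = 255

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown object kind {self.kind!r}; use one of {_KINDS}")
        if not self.length >= self.width >= 1:
            raise ValueError(
                f"need length >= width >= 1, got length={self.length}, width={self.width}"
            )
        if self.intensity < 1:
            raise ValueError("intensity must be positive")

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of pixels whose centre lies inside the shape."""
        ny, nx = shape
        yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
        cx, cy = self.center
        dx, dy = xx - cx, yy - cy
        th = np.deg2rad(self.orientation)
        # rotate into the object frame
        u = dx * np.cos(th) + dy * np.sin(th)
        v = -dx * np.sin(th) + dy * np.cos(th)
        if self.kind == "disk":
            r = self.width / 2.0
            return u**2 + v**2 <= r**2
        if self.kind == "rod":
            return (np.abs(u) <= self.length / 2.0) & (np.abs(v) <= self.width / 2.0)
        arm_angles = (
            (0.0, 120.0, 240.0) if self.kind == "branched-Y" else (0.0, 90.0, 180.0, 270.0)
        )
        mask = np.zeros(shape, bool)
        for a in arm_angles:
            ca, sa = np.cos(np.deg2rad(a)), np.sin(np.deg2rad(a))
            ua = u * ca + v * sa
            va = -u * sa + v * ca
            mask |= (ua >= 0) & (ua <= self.length) & (np.abs(va) <= self.width / 2.0)
        return mask


@dataclass
class GroundTruth:
    """Per-object ground truth attached to a synthetic image or stack."""

    objects: pd.DataFrame  # one row per object
    rng_seed: int | None = None
    extras: dict = field(default_factory=dict)

    @property
    def object_count(self) -> int:
        return len(self.objects)

    def total(self, column: str) -> float:
        return float(self.objects[column].sum()) if self.object_count else 0.0


def make_test_image_2d(
    specs: list[ObjectSpec], canvas: tuple[int, int] = (256, 256)
) -> tuple[np.ndarray, GroundTruth]:
    """Rasterize non-overlapping object specs onto a binary test image.

    Returns an 8-bit image (background 0, objects at full ``intensity``)
    plus ground truth recording each object's rasterized pixel area.
    Overlapping specs and specs leaving the canvas are errors.
    """
    ny, nx = canvas
    image = np.zeros(canvas, np.uint8)
    occupancy = np.zeros(canvas, np.int32)
    rows = []
    for i, spec in enumerate(specs):
        mask = spec.rasterize(canvas)
        if mask.sum() == 0:
            raise ValueError(f"object {i} ({spec.kind}) rasterizes to zero pixels")
        ys, xs = np.nonzero(mask)
        if ys.min() == 0 or xs.min() == 0 or ys.max() == ny - 1 or xs.max() == nx - 1:
            raise ValueError(f"object {i} ({spec.kind}) touches the canvas edge")
        clash = occupancy[mask]
        if clash.any():
            other = int(clash[clash > 0][0]) - 1
            raise ValueError(f"objects {other} and {i} overlap")
        occupancy[mask] = i + 1
        image[mask] = spec.intensity
        rows.append(
            {
                "object": i,
                "kind": spec.kind,
                "area_px": int(mask.sum()),
                "filamentous": spec.kind != "disk",
            }
        )
    gt = GroundTruth(pd.DataFrame(rows, columns=["object", "kind", "area_px", "filamentous"]))
    return image, gt


def default_test_specs(canvas: tuple[int, int] = (256, 256)) -> list[ObjectSpec]:
    """Default test-object panel: disks of 3 diameters, rods of 3 lengths
    × 2 widths, one Y and one X branched shape.

    Sizes are in the range of mitochondrial cross-sections at typical
    confocal sampling (a few to a few tens of pixels); disks are kept
    small so that, extruded over the 3-section test stack, they stay
    near-isotropic (sphere-like) rather than becoming flat pancakes. The
    exact layout is a documented choice of this package.
    """
    specs = [
        ObjectSpec("disk", (30, 30), 5, 5),
        ObjectSpec("disk", (75, 30), 7, 7),
        ObjectSpec("disk", (130, 30), 9, 9),
        ObjectSpec("rod", (45, 75), 21, 3),
        ObjectSpec("rod", (110, 75), 35, 3),
        ObjectSpec("rod", (190, 75), 49, 3),
        ObjectSpec("rod", (45, 115), 21, 7),
        ObjectSpec("rod", (110, 115), 35, 7),
        ObjectSpec("rod", (190, 115), 49, 7),
        ObjectSpec("branched-Y", (70, 180), 20, 3, orientation=90.0),
        ObjectSpec("branched-X", (170, 185), 18, 3, orientation=45.0),
    ]
    return specs


def build_test_stack(
    image: np.ndarray,
    copies: int = 3,
    pad: int = 1,
    pixel_size_xy: float = 1.0,
    z_step: float = 1.0,
    ground_truth: GroundTruth | None = None,
) -> tuple[ZStack, GroundTruth | None]:
    """Layer ``copies`` of a 2D image between ``pad`` empty sections.

    With the defaults (3 copies, 1 empty section top and bottom) this
    yields the 5-section unit-voxel test stack in which each object's
    voxel volume is exactly ``copies ×`` its 2D pixel area.
    """
    if copies < 1 or pad < 0:
        raise ValueError("need copies >= 1 and pad >= 0")
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("input image must be 2D")
    empty = np.zeros_like(image)
    sections = [empty] * pad + [image] * copies + [empty] * pad
    stack = ZStack(np.stack(sections), pixel_size_xy=pixel_size_xy, z_step=z_step)
    gt = None
    if ground_truth is not None:
        objects = ground_truth.objects.copy()
        if "area_px" in objects:
            objects["volume_vox"] = objects["area_px"] * copies
        gt = GroundTruth(objects, ground_truth.rng_seed, dict(ground_truth.extras))
    return stack, gt


# ---------------------------------------------------------------------
# 3D voxelization primitives
# ---------------------------------------------------------------------


def binary_ball(radius: float, shape: tuple[int, int, int] | None = None) -> np.ndarray:
    """Voxelized ball: voxels whose centre lies within ``radius`` of the
    grid centre. Default grid leaves a 2-voxel margin."""
    if shape is None:
        n = int(2 * radius) + 5
        shape = (n, n, n)
    zz, yy, xx = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]].astype(float)
    c = [(s - 1) / 2.0 for s in shape]
    return (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= radius**2


def binary_cylinder(
    length: float,
    diameter: float,
    shape: tuple[int, int, int] | None = None,
    axis: int = 0,
) -> np.ndarray:
    """Voxelized flat-capped cylinder with its axis along ``axis``."""
    r = diameter / 2.0
    if shape is None:
        n = int(diameter) + 5
        l = int(length) + 5
        dims = [n, n, n]
        dims[axis] = l
        shape = tuple(dims)
    grids = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]].astype(float)
    c = [(s - 1) / 2.0 for s in shape]
    along = grids[axis] - c[axis]
    radial = [grids[i] - c[i] for i in range(3) if i != axis]
    return (np.abs(along) <= length / 2.0) & (radial[0] ** 2 + radial[1] ** 2 <= r**2)


# ---------------------------------------------------------------------
# simulated cell stacks
# ---------------------------------------------------------------------


def _stamp_sphere(canvas: np.ndarray, center: np.ndarray, radius: float) -> None:
    """Mark voxels within ``radius`` of ``center`` (in-place, bounds-safe)."""
    lo = np.maximum(np.floor(center - radius).astype(int), 0)
    hi = np.minimum(np.ceil(center + radius).astype(int) + 1, canvas.shape)
    if (hi <= lo).any():
        return
    zz, yy, xx = np.mgrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]].astype(float)
    d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    canvas[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] |= d2 <= radius**2


def _tube_polyline(
    rng: np.random.Generator,
    start: np.ndarray,
    direction: np.ndarray,
    length: float,
    shape: tuple[int, int, int],
    margin: float,
    curvature: float,
    step: float = 1.0,
) -> np.ndarray:
    """Persistent random-walk centre-line, reflected off the canvas margin."""
    pts = [start.astype(float)]
    d = direction / np.linalg.norm(direction)
    travelled = 0.0
    lo = np.full(3, margin)
    hi = np.array(shape, float) - 1 - margin
    # mitochondrial tubules in adherent cells run mostly in-plane; damp
    # the axial (z) component of the walk
    z_damp = np.array([0.3, 1.0, 1.0])
    while travelled < length:
        if curvature > 0:
            d = d + rng.normal(scale=curvature, size=3) * z_damp
            d[0] *= 0.95
            d /= np.linalg.norm(d)
        nxt = pts[-1] + d * step
        for ax in range(3):
            if nxt[ax] < lo[ax] or nxt[ax] > hi[ax]:
                d[ax] = -d[ax]
                nxt = pts[-1] + d * step
        pts.append(nxt)
        travelled += step
    return np.array(pts)


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.sqrt(((pts[1:] - pts[:-1]) ** 2).sum(axis=1)).sum())


def _tube_self_clear(polylines: list[np.ndarray], radius: float) -> bool:
    """True if a tube's centre-lines never approach themselves or each
    other closer than one diameter (excluding neighbouring points along
    the same curve and the branch attachment zone) — self-overlapping
    tubes would make the ground-truth length unrecoverable."""
    from scipy.spatial.distance import cdist

    min_d = 2 * radius + 1
    window = max(8, int(3 * min_d))
    for pl in polylines:
        n = len(pl)
        if n > window:
            d = cdist(pl, pl)
            i, j = np.triu_indices(n, k=window)
            if (d[i, j] < min_d).any():
                return False
    main = polylines[0]
    for br in polylines[1:]:
        d = cdist(br, main)
        # ignore the attachment zone: points of either curve near the
        # branch origin
        near_origin = np.linalg.norm(main - br[0], axis=1) < window
        keep_main = ~near_origin
        keep_br = np.linalg.norm(br - br[0], axis=1) >= window
        if keep_br.any() and keep_main.any():
            if (d[np.ix_(keep_br, keep_main)] < min_d).any():
                return False
    # side branches must keep clear of each other entirely
    for a in range(1, len(polylines)):
        for b in range(a + 1, len(polylines)):
            if cdist(polylines[a], polylines[b]).min() < min_d:
                return False
    return True


def _draw_tube(canvas: np.ndarray, pts: np.ndarray, radius: float) -> None:
    for p in pts:
        _stamp_sphere(canvas, p, radius)


def _paint_tube(
    canvas: np.ndarray, pts: np.ndarray, radius: float, values: np.ndarray
) -> None:
    """Paint a tube into a float canvas, per-point intensity, max-combine."""
    for p, val in zip(pts, values):
        lo = np.maximum(np.floor(p - radius).astype(int), 0)
        hi = np.minimum(np.ceil(p + radius).astype(int) + 1, canvas.shape)
        if (hi <= lo).any():
            continue
        zz, yy, xx = np.mgrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]].astype(float)
        d2 = (zz - p[0]) ** 2 + (yy - p[1]) ** 2 + (xx - p[2]) ** 2
        region = canvas[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        np.maximum(region, np.where(d2 <= radius**2, val, 0.0), out=region)


def simulate_cell_stack(
    phenotype: str,
    shape: tuple[int, int, int] | None = None,
    n_objects: int = 25,
    sphere_radius: float = 5.8,
    n_tubes: int = 4,
    tube_length: float = 110.0,
    tube_radius: float = 2.5,
    branches_per_tube: int = 1,
    branch_length: float = 40.0,
    curvature: float = 0.05,
    z_extent: float | None = None,
    intensity: int = 200,
    intensity_variation: float = 0.0,
    variation_period: float = 40.0,
    branch_base_dim: float = 0.0,
    background: float = 0.0,
    psf_sigma_xy: float = 1.0,
    psf_sigma_z: float = 2.0,
    apply_psf: bool = True,
    poisson_noise: bool = False,
    gaussian_noise_sd: float = 0.0,
    seed: int = 0,
    pixel_size_xy: float = 1.0,
    z_step: float = 1.0,
    max_tries: int = 2000,
    min_gap: int = 6,
) -> tuple[ZStack, GroundTruth]:
    """Simulate a z-stack of a cell with known mitochondrial content.

    ``phenotype`` is ``"fragmented"`` (spheres, the morphology of
    metabolically stressed cells) or ``"filamentous"`` (smooth branched
    tubes, the normal reticular morphology). The signal is blurred with an
    anisotropic Gaussian PSF (wider axially, as in confocal optics) and
    optionally corrupted with Poisson photon noise and Gaussian read
    noise. ``intensity_variation`` (0..1) modulates the brightness along
    each tube sinusoidally (period ``variation_period`` voxels) between
    ``intensity`` and ``(1 − variation)·intensity``, emulating the uneven
    labelling of a real reticulum; 0 (default) paints uniform tubes.
    Ground truth records true object counts, per-object voxel volumes
    and — for tubes — total centre-line length.

    ``z_extent`` confines object centres to a slab of that thickness (in
    sections) around the stack middle. A thin slab emulates a flat
    adherent cell, a thick one a rounded-up cell; the default is 2
    sections for the filamentous phenotype (the mitochondrial reticulum
    of a flat, healthy cell hugs the substrate) and 8 for the fragmented
    one (stressed cells round up and spread their organelles axially).
    Objects are placed without 3D overlap; placement failures after
    ``max_tries`` retries raise an error.
    """
    if phenotype not in ("fragmented", "filamentous"):
        raise ValueError("phenotype must be 'fragmented' or 'filamentous'")
    rng = np.random.default_rng(seed)
    if shape is None:
        # defaults emulate a mitochondria-rich perinuclear region whose
        # brightest section is ~20% covered by signal — the regime the
        # fraction-of-brightest-pixels threshold rule is designed for
        shape = (32, 128, 128) if phenotype == "filamentous" else (32, 104, 104)
    nz, ny, nx = shape
    zc = (nz - 1) / 2.0
    if z_extent is None:
        z_extent = 2.0 if phenotype == "filamentous" else 8.0
    half_z = min(z_extent, nz) / 2.0

    canvas = np.zeros(shape, bool)
    rows = []
    extras: dict = {}

    if phenotype == "fragmented":
        r = sphere_radius
        margin = r + 2
        centers: list[np.ndarray] = []
        min_d = 2 * r + 3  # keep blurred halos separable in 3D
        for i in range(n_objects):
            for attempt in range(max_tries):
                z = zc + rng.uniform(-half_z, half_z)
                z = float(np.clip(z, margin, nz - 1 - margin))
                y = rng.uniform(margin, ny - 1 - margin)
                x = rng.uniform(margin, nx - 1 - margin)
                c = np.array([z, y, x])
                if all(np.linalg.norm(c - o) >= min_d for o in centers):
                    centers.append(c)
                    break
            else:
                raise RuntimeError(
                    f"could not place sphere {i} without overlap after {max_tries} tries; "
                    "reduce n_objects or enlarge the canvas"
                )
            before = canvas.sum()
            _stamp_sphere(canvas, centers[-1], r)
            rows.append(
                {
                    "object": i,
                    "kind": "sphere",
                    "volume_vox": int(canvas.sum() - before),
                    "center_z": centers[-1][0],
                    "center_y": centers[-1][1],
                    "center_x": centers[-1][2],
                }
            )
    else:
        margin = tube_radius + 3
        total_length = 0.0
        paint = np.zeros(shape, np.float64)
        masks: list[np.ndarray] = []
        for i in range(n_tubes):
            for attempt in range(max_tries):
                start = np.array(
                    [
                        np.clip(zc + rng.uniform(-half_z, half_z), margin, nz - 1 - margin),
                        rng.uniform(margin, ny - 1 - margin),
                        rng.uniform(margin, nx - 1 - margin),
                    ]
                )
                d0 = rng.normal(size=3)
                d0[0] *= 0.3  # tubes run mostly in-plane, like mitochondria
                pts = _tube_polyline(rng, start, d0, tube_length, shape, margin, curvature)
                polylines = [pts]
                for ib in range(branches_per_tube):
                    # staggered attachment points along the main tubule
                    j = int(len(pts) * (ib + 1) / (branches_per_tube + 1))
                    bd = rng.normal(size=3)
                    bd[0] *= 0.3
                    bpts = _tube_polyline(
                        rng, pts[j], bd, branch_length, shape, margin, curvature
                    )
                    polylines.append(bpts)
                if not _tube_self_clear(polylines, tube_radius):
                    continue
                trial = np.zeros(shape, bool)
                for pl in polylines:
                    _draw_tube(trial, pl, tube_radius)
                # enforce separation from existing tubes (with halo gap)
                from scipy.ndimage import binary_dilation

                if not (binary_dilation(trial, iterations=min_gap) & canvas).any():
                    break
            else:
                raise RuntimeError(
                    f"could not place tube {i} without overlap after {max_tries} tries"
                )
            canvas |= trial
            masks.append(trial)
            # per-point brightness: constant, or modulated along the
            # centre-line (mitoGFP intensity varies along the reticulum,
            # which is what makes segmentation threshold-sensitive)
            for ip, pl in enumerate(polylines):
                s = np.concatenate(
                    [[0.0], np.cumsum(np.sqrt(((pl[1:] - pl[:-1]) ** 2).sum(axis=1)))]
                )
                vals = np.full(len(pl), float(intensity))
                if intensity_variation > 0:
                    phase = rng.uniform(0, 2 * np.pi)
                    mod = 0.5 * (1 + np.sin(2 * np.pi * s / variation_period + phase))
                    vals *= 1.0 - intensity_variation * mod
                if branch_base_dim > 0 and ip > 0:
                    # side branches dimmest at their attachment point and
                    # brightening toward the tip: raising the segmentation
                    # threshold detaches them from the main tubule first,
                    # the way weakly labelled junction regions behave
                    dim = branch_base_dim * rng.uniform(0.6, 1.0)
                    frac = s / max(s[-1], 1e-9)
                    vals *= 1.0 - dim * (1.0 - frac)
                _paint_tube(paint, pl, tube_radius, vals)
            tube_len = sum(_polyline_length(pl) for pl in polylines)
            total_length += tube_len
            rows.append(
                {
                    "object": i,
                    "kind": "tube",
                    "volume_vox": int(trial.sum()),
                    "branch_count": 1 + 2 * branches_per_tube if branches_per_tube else 1,
                    "length_vox": tube_len,
                }
            )
        extras["total_length_vox"] = total_length

    if phenotype == "filamentous":
        signal = paint
    else:
        signal = canvas.astype(np.float64) * intensity
    if background > 0:
        # diffuse cytosolic haze (residual unlocalized fluorophore);
        # fills the low end of the intensity histogram as in real cells
        signal = np.maximum(signal, background)
    if apply_psf:
        signal = gaussian_filter(signal, sigma=(psf_sigma_z, psf_sigma_xy, psf_sigma_xy))
    if poisson_noise:
        signal = rng.poisson(signal).astype(np.float64)
    if gaussian_noise_sd > 0:
        signal = signal + rng.normal(scale=gaussian_noise_sd, size=signal.shape)
    data = np.clip(np.rint(signal), 0, 255).astype(np.uint8)

    columns = rows[0].keys() if rows else ["object", "kind", "volume_vox"]
    gt = GroundTruth(pd.DataFrame(rows, columns=list(columns)), rng_seed=seed, extras=extras)
    gt.extras["true_mask_volume_vox"] = int(canvas.sum())
    stack = ZStack(data, pixel_size_xy=pixel_size_xy, z_step=z_step)
    return stack, gt


# ---------------------------------------------------------------------
# ground-truth sidecar files
# ---------------------------------------------------------------------


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    payload = {
        "object_count": gt.object_count,
        "rng_seed": gt.rng_seed,
        "extras": gt.extras,
        "objects": gt.objects.to_dict("records"),
    }
    Path(path).write_text(json.dumps(payload, indent=1, default=float))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        pd.DataFrame(payload["objects"]),
        rng_seed=payload.get("rng_seed"),
        extras=payload.get("extras", {}),
    )
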