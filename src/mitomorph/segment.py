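"""Intensity thresholding, object labeling and iso-surface construction.

The threshold convention follows the fraction-of-brightest-pixels rule:
the gray value is chosen so that a given fraction of *all* pixels of a
reference section (by default the brightest section of the stack) lies at
or above it, and that single value is then applied to every section.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.ndimage import distance_transform_edt, find_objects, gaussian_filter
from skimage import measure, morphology

from .stack import ZStack

__all__ = [
    "threshold_from_fraction",
    "binarize",
    "size_filter",
    "LabeledObjects",
    "label_objects",
    "SurfaceMesh",
    "make_isosurface",
]


def threshold_from_fraction(
    stack: ZStack | np.ndarray,
    fraction: float,
    reference: int | str = "argmax",
    nonzero_only: bool = False,
) -> float:
    """Gray value including (at most) the given fraction of brightest pixels.

    Returns the smallest gray value ``t`` present in the reference
    section such that the proportion of its pixels with intensity >= t
    does not exceed ``fraction`` — i.e. the threshold that includes as
    many pixels as possible without overshooting the fraction by more
    than one histogram bin. If even the brightest bin exceeds the
    fraction, the maximum intensity is returned.

    ``reference`` selects the section the fraction is computed over: an
    index, or ``"argmax"`` for the brightest section (for a 2D image the
    image itself is used). ``nonzero_only=True`` computes the fraction
    over nonzero pixels only (configurable alternative reading of the
    rule; default is all pixels).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if isinstance(stack, ZStack):
        data = stack.data
    else:
        data = np.asarray(stack)
        if data.ndim == 2:
            data = data[None]
    if reference == "argmax":
        sums = data.reshape(data.shape[0], -1).sum(axis=1)
        ref = data[int(np.argmax(sums))]
    else:
        ref = data[int(reference)]
    vals = ref.ravel()
    if nonzero_only:
        vals = vals[vals > 0]
    if vals.size == 0 or vals.min() == vals.max():
        raise ValueError(
            "reference section has no intensity spread; cannot place a "
            "fraction-based threshold"
        )
    uniq, counts = np.unique(vals, return_counts=True)
    # proportion of pixels >= each unique value (ascending values)
    ge = counts[::-1].cumsum()[::-1] / vals.size
    ok = np.nonzero(ge <= fraction)[0]
    if ok.size == 0:
        return float(uniq[-1])
    return float(uniq[ok[0]])


def binarize(data: ZStack | np.ndarray, t: float) -> np.ndarray:
    """Boolean mask of pixels/voxels with intensity >= ``t``."""
    arr = data.data if isinstance(data, ZStack) else np.asarray(data)
    return arr >= t


def size_filter(mask: np.ndarray, min_size: int) -> np.ndarray:
    """Remove connected components smaller than ``min_size`` pixels/voxels
    (full 8/26-connectivity)."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    mask = np.asarray(mask, bool)
    if min_size == 1:
        return mask.copy()
    labels = measure.label(mask, connectivity=mask.ndim)
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_size
    keep[0] = False
    return keep[labels]


@dataclass
class LabeledObjects:
    """Connected-component labels with calibration.

    ``labels`` holds integers 1..``object_count`` assigned in raster-scan
    order of each component's first-encountered pixel; the spacing tuple
    is ``(y, x)`` µm in 2D and ``(z, y, x)`` µm in 3D.
    """

    labels: np.ndarray
    object_count: int
    spacing: tuple[float, ...]

    @property
    def ndim(self) -> int:
        return self.labels.ndim

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def sizes(self) -> np.ndarray:
        """Pixel/voxel count per object, index 0 = label 1."""
        return np.bincount(self.labels.ravel(), minlength=self.object_count + 1)[1:]

    def slices(self) -> list[tuple[slice, ...]]:
        return find_objects(self.labels)


def label_objects(
    mask: np.ndarray,
    spacing: tuple[float, ...] | None = None,
    connectivity: int | None = None,
) -> LabeledObjects:
    """Label connected components (default 8-connectivity in 2D,
    26-connectivity in 3D)."""
    mask = np.asarray(mask, bool)
    if spacing is None:
        spacing = (1.0,) * mask.ndim
    if len(spacing) != mask.ndim:
        raise ValueError("spacing must match mask dimensionality")
    conn = mask.ndim if connectivity is None else connectivity
    labels, n = measure.label(mask, connectivity=conn, return_num=True)
    return LabeledObjects(labels=labels, object_count=int(n), spacing=tuple(spacing))


@dataclass
class SurfaceMesh:
    """Triangulated iso-surface of one labeled object (vertices in µm)."""

    vertices: np.ndarray
    faces: np.ndarray
    label: int

    @property
    def area(self) -> float:
        return float(measure.mesh_surface_area(self.vertices, self.faces))

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @property
    def is_closed(self) -> bool:
        return bool(self.to_trimesh().is_watertight)

    def export(self, path) -> None:
        self.to_trimesh().export(path)


def smooth_indicator(mask: np.ndarray, smoothing_sigma: float) -> np.ndarray:
    """Padded, boundary-smoothed indicator field of a binary object.

    The effective smoothing is ``min(smoothing_sigma, 0.1 × inradius)``:
    Gaussian level-set smoothing displaces the 0.5 iso-level by roughly
    σ²·curvature, so σ must stay well below the object's inradius or
    small objects shrink and their measured boundary collapses. Capping
    at a tenth of the inradius keeps that displacement ≲1% while still
    suppressing the voxelization staircase on well-resolved objects. If
    even the capped smoothing erases the object, the raw indicator is
    used.
    """
    mask = np.asarray(mask, bool)
    inradius = float(distance_transform_edt(np.pad(mask, 1)).max())
    sigma = min(smoothing_sigma, 0.1 * inradius)
    pad = max(2, int(np.ceil(3 * max(sigma, 0.1))))
    field = np.pad(mask.astype(np.float64), pad)
    if sigma > 0:
        smoothed = gaussian_filter(field, sigma)
        if smoothed.max() > 0.5:
            return smoothed
    return field


def make_isosurface(
    labeled: LabeledObjects, smoothing_sigma: float = 0.8
) -> list[SurfaceMesh]:
    """Per-object triangulated iso-surface at the binary object boundary.

    Marching cubes is run on each object's boundary-smoothed indicator
    field (see :func:`smooth_indicator`) so that the surface interpolates
    the digitized boundary instead of tracing its staircase — without
    smoothing, voxelization inflates the measured area of smooth objects
    by ~8–10%. Sub-resolution objects fall back to the raw indicator (a
    single voxel yields the octahedral midpoint mesh of area √3; this
    small-object bias is the documented estimator tolerance). Vertex
    coordinates honour the anisotropic voxel calibration and are in µm.
    No decimation or mesh smoothing is applied afterwards.
    """
    if labeled.ndim != 3:
        raise ValueError("iso-surfaces require 3D labels; 2D objects have no surface")
    meshes: list[SurfaceMesh] = []
    for lbl, sl in enumerate(labeled.slices(), start=1):
        if sl is None:
            continue
        mask = labeled.labels[sl] == lbl
        smoothed = smooth_indicator(mask, smoothing_sigma)
        verts, faces, _, _ = measure.marching_cubes(
            smoothed, level=0.5, spacing=labeled.spacing
        )
        meshes.append(SurfaceMesh(vertices=verts, faces=faces, label=lbl))
    return meshes
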