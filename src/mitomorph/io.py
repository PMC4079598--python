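"""Reading/writing calibrated TIFF z-stacks, ROI lists and descriptor tables.

Calibration is taken from TIFF/OME-TIFF metadata when present and can be
overridden (or supplied for uncalibrated files) via keyword arguments.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .stack import ROI, ZStack

__all__ = [
    "read_stack",
    "write_stack",
    "crop",
    "read_rois",
    "write_rois",
    "propose_rois",
    "write_table",
]


def _calibration_from_tiff(tif: tifffile.TiffFile) -> dict:
    """Best-effort extraction of voxel calibration from TIFF metadata."""
    out: dict = {}
    try:
        if tif.ome_metadata:
            import re

            m = re.search(r'PhysicalSizeX="([\d.eE+-]+)"', tif.ome_metadata)
            if m:
                out["pixel_size_xy"] = float(m.group(1))
            m = re.search(r'PhysicalSizeZ="([\d.eE+-]+)"', tif.ome_metadata)
            if m:
                out["z_step"] = float(m.group(1))
    except Exception:  # pragma: no cover - malformed vendor metadata
        pass
    ij = tif.imagej_metadata or {}
    if "spacing" in ij:
        out.setdefault("z_step", float(ij["spacing"]))
    page = tif.pages[0]
    res = page.tags.get("XResolution")
    if res is not None and "pixel_size_xy" not in out:
        num, den = res.value
        if num:
            out["pixel_size_xy"] = den / num  # resolution is px per unit
    return out


def read_stack(
    path: str | Path,
    pixel_size_xy: float | None = None,
    z_step: float | None = None,
) -> ZStack:
    """Read a grayscale multi-page TIFF as a calibrated :class:`ZStack`.

    Calibration overrides take precedence over file metadata; if neither
    source provides a value, an error is raised rather than silently
    assuming unit spacing.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = _calibration_from_tiff(tif)
    if data.ndim == 2:
        data = data[None]
    if data.ndim == 4 or (data.ndim == 3 and data.shape[-1] in (3, 4) and data.shape[0] > 8):
        raise ValueError(
            f"{path.name} appears to be multi-channel/RGB; select a single "
            "channel before analysis (e.g. data[..., channel])."
        )
    px = pixel_size_xy if pixel_size_xy is not None else meta.get("pixel_size_xy")
    dz = z_step if z_step is not None else meta.get("z_step")
    if px is None or dz is None:
        raise ValueError(
            f"no voxel calibration in {path.name} metadata; pass "
            "pixel_size_xy=... and z_step=... explicitly"
        )
    bit_depth = 16 if data.dtype.itemsize >= 2 else 8
    return ZStack(data, pixel_size_xy=px, z_step=dz, bit_depth=bit_depth)


def write_stack(stack: ZStack, path: str | Path) -> None:
    """Write a stack as ImageJ-flavoured TIFF carrying its calibration."""
    data = stack.data
    if not np.issubdtype(data.dtype, np.integer):
        data = np.clip(np.rint(data), 0, 2**stack.bit_depth - 1)
        data = data.astype(np.uint8 if stack.bit_depth <= 8 else np.uint16)
    tifffile.imwrite(
        str(path),
        data,
        imagej=True,
        resolution=(1.0 / stack.pixel_size_xy, 1.0 / stack.pixel_size_xy),
        metadata={"spacing": stack.z_step, "unit": "um", "axes": "ZYX"},
    )


def crop(stack: ZStack, roi: ROI) -> ZStack:
    """Crop a stack to an ROI; calibration is preserved.

    ROI coordinates are 0-based and half-open; the output has shape
    ``(sections, y1-y0, x1-x0)`` (or the selected section range).
    """
    nz, ny, nx = stack.shape
    if roi.x1 > nx or roi.y1 > ny:
        raise ValueError(f"ROI {roi} exceeds stack bounds {(ny, nx)}")
    z0, z1 = (roi.z0, roi.z1) if roi.z0 is not None else (0, nz)
    if z1 > nz:
        raise ValueError(f"ROI section range {(z0, z1)} exceeds {nz} sections")
    return stack.with_data(stack.data[z0:z1, roi.y0 : roi.y1, roi.x0 : roi.x1].copy())


# -- ROI lists --------------------------------------------------------


def read_rois(path: str | Path) -> list[ROI]:
    """Read ROIs from JSON (list of objects) or CSV (``x0,y0,x1,y1`` columns)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
    else:
        records = pd.read_csv(path).to_dict("records")
    return [ROI(**{k: int(v) for k, v in r.items() if v == v}) for r in records]


def write_rois(rois: list[ROI], path: str | Path) -> None:
    path = Path(path)
    records = [
        {k: v for k, v in vars(r).items() if v is not None} for r in rois
    ]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(records, indent=1))
    else:
        pd.DataFrame(records).to_csv(path, index=False)


def propose_rois(
    stack: ZStack,
    n: int = 5,
    size: int = 64,
    seed: int = 0,
    min_signal_fraction: float = 0.02,
    max_tries: int = 500,
) -> list[ROI]:
    """Propose ``n`` square ROIs in signal-rich parts of the stack.

    Stands in for the manual/stochastic ROI picking of an interactive
    analysis, but from a seeded RNG so runs are reproducible. Candidate
    ROIs are accepted if at least ``min_signal_fraction`` of their
    maximum-projection pixels exceed the stack mean.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = stack.shape
    if size > min(ny, nx):
        raise ValueError("ROI size exceeds stack extent")
    mip = stack.data.max(axis=0)
    thr = stack.data.mean()
    rois: list[ROI] = []
    for _ in range(max_tries):
        if len(rois) == n:
            break
        x0 = int(rng.integers(0, nx - size + 1))
        y0 = int(rng.integers(0, ny - size + 1))
        window = mip[y0 : y0 + size, x0 : x0 + size]
        if (window > thr).mean() >= min_signal_fraction:
            rois.append(ROI(x0, y0, x0 + size, y0 + size))
    if len(rois) < n:
        raise RuntimeError(
            f"could only place {len(rois)}/{n} signal-rich ROIs; lower "
            "min_signal_fraction or ROI size"
        )
    return rois


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Persist a descriptor table as CSV (one row per object/branch/ROI)."""
    pd.DataFrame(df).to_csv(path, index=False)
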