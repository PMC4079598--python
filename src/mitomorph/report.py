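"""Integrative indexes, condition comparison and the end-to-end pipeline.

The six integrative indexes combine network totals with shape totals of
the same ROI and analysis mode (2D biomass = total area A_m,ROI; 3D
biomass = total volume V_m,ROI):

* branch length per mitochondrion  L_BR,ROI / N_ROI
* branch length per biomass        L_BR,ROI / biomass
* branches per mitochondrion       N_BR / N_ROI
* branches per biomass             N_BR / biomass
* branching-point frequency per branch length  N_BP / L_BR,ROI
* branching-point frequency per biomass        N_BP / biomass

Undefined ratios (zero denominator) are propagated as missing values,
never silently zeroed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import io as mio
from . import preprocess, segment, shape, synthetic
from . import network as net
from .segment import LabeledObjects
from .shape import ShapeSummary
from .stack import ROI, ZStack

__all__ = [
    "integrative_indexes",
    "compare_conditions",
    "analyze_2d",
    "analyze_3d",
    "RoiResult",
    "run_pipeline",
]

INDEX_NAMES = [
    "branch_length_per_mito",
    "branch_length_per_biomass",
    "branches_per_mito",
    "branches_per_biomass",
    "branching_freq_per_length",
    "branching_freq_per_biomass",
]


def integrative_indexes(
    shape_summary: ShapeSummary, graph: net.SkeletonGraph, mode: str
) -> dict:
    """The six network/shape indexes with the mode-appropriate biomass."""
    if mode not in ("2d", "3d"):
        raise ValueError("mode must be '2d' or '3d'")
    n_roi = shape_summary.n_roi
    biomass = shape_summary.totals["A_m_ROI" if mode == "2d" else "V_m_ROI"]
    l_br = graph.l_br_roi
    n_br, n_bp = graph.n_br, graph.n_bp

    def ratio(num: float, den: float) -> float:
        if den <= 0:
            warnings.warn(
                "zero denominator in integrative index; reporting as undefined",
                stacklevel=3,
            )
            return np.nan
        return num / den

    return {
        "branch_length_per_mito": ratio(l_br, n_roi),
        "branch_length_per_biomass": ratio(l_br, biomass),
        "branches_per_mito": ratio(n_br, n_roi),
        "branches_per_biomass": ratio(n_br, biomass),
        "branching_freq_per_length": ratio(n_bp, l_br),
        "branching_freq_per_biomass": ratio(n_bp, biomass),
    }


def compare_conditions(
    a: pd.DataFrame, b: pd.DataFrame, names: tuple[str, str] = ("A", "B"), alpha: float = 0.05
) -> pd.DataFrame:
    """Per-descriptor two-tailed two-sample t-test between two conditions.

    ``a`` and ``b`` are per-ROI tables (one row per ROI, one column per
    descriptor) with identical column sets and >= 2 rows each. Returns
    mean/SD per group, the t statistic, the two-tailed p-value and a
    significance flag at ``alpha``. No multiple-testing correction is
    applied (noted in the output attribute ``attrs['correction']``).
    """
    cols_a = [c for c in a.columns if pd.api.types.is_numeric_dtype(a[c])]
    cols_b = [c for c in b.columns if pd.api.types.is_numeric_dtype(b[c])]
    if set(cols_a) != set(cols_b):
        raise ValueError(f"descriptor sets differ: {sorted(cols_a)} vs {sorted(cols_b)}")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 ROIs per condition")
    rows = []
    for c in cols_a:
        xa, xb = a[c].dropna().to_numpy(float), b[c].dropna().to_numpy(float)
        if len(xa) >= 2 and len(xb) >= 2 and (np.ptp(xa) > 0 or np.ptp(xb) > 0):
            t, p = stats.ttest_ind(xa, xb)
        else:
            t, p = np.nan, 1.0
        rows.append(
            {
                "descriptor": c,
                f"mean_{names[0]}": xa.mean() if len(xa) else np.nan,
                f"sd_{names[0]}": xa.std(ddof=1) if len(xa) > 1 else np.nan,
                f"n_{names[0]}": len(xa),
                f"mean_{names[1]}": xb.mean() if len(xb) else np.nan,
                f"sd_{names[1]}": xb.std(ddof=1) if len(xb) > 1 else np.nan,
                f"n_{names[1]}": len(xb),
                "t": t,
                "p": float(p),
                "significant": bool(p < alpha),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["correction"] = "none (per-descriptor two-tailed t-tests)"
    return out


# ---------------------------------------------------------------------
# per-ROI analysis paths
# ---------------------------------------------------------------------


@dataclass
class RoiResult:
    """Descriptor bundle for one ROI in one analysis mode."""

    mode: str
    threshold: float
    objects: pd.DataFrame
    summary: ShapeSummary
    graph: net.SkeletonGraph
    indexes: dict
    unrepresented: int  # labeled objects with no skeleton branch

    def descriptor_row(self) -> dict:
        """Flat per-ROI descriptor record (for condition tables)."""
        row = {"mode": self.mode, "threshold": self.threshold}
        row.update(self.summary.as_series().to_dict())
        row.update(
            {
                "N_BR": self.graph.n_br,
                "N_BP": self.graph.n_bp,
                "N_EP": self.graph.n_ep,
                "L_BR_ROI": self.graph.l_br_roi,
                "V_BR_ROI": self.graph.v_br_roi if self.graph.branches else 0.0,
                "unrepresented": self.unrepresented,
            }
        )
        row.update(self.indexes)
        return row


def _network_from_mask(
    mask: np.ndarray,
    spacing: tuple[float, ...],
    labeled: LabeledObjects,
    prune_iterations: int,
) -> net.SkeletonGraph:
    sk = net.skeletonize(mask, prune_iterations=prune_iterations)
    graph = net.vectorize(sk, spacing=spacing, labeled=labeled)
    dmap = net.distance_map(mask, spacing=spacing)
    return net.branch_metrics(graph, dmap)


def analyze_2d(
    image: np.ndarray,
    pixel_size_xy: float = 1.0,
    fraction: float = 0.2,
    threshold: float | None = None,
    min_size: int = 4,
    prune_iterations: int = 2,
) -> RoiResult:
    """2D shape + network analysis of a single image or projection.

    The binarization threshold is either given explicitly or derived from
    the brightest-pixel ``fraction`` of the image itself; the same
    threshold drives binarization and skeletonization, as in the
    pipeline's design.
    """
    image = np.asarray(image)
    t = (
        float(threshold)
        if threshold is not None
        else segment.threshold_from_fraction(image, fraction)
    )
    mask = segment.size_filter(segment.binarize(image, t), min_size)
    spacing = (pixel_size_xy, pixel_size_xy)
    labeled = segment.label_objects(mask, spacing=spacing)
    objects, summary = shape.shape2d(labeled)
    graph = _network_from_mask(mask, spacing, labeled, prune_iterations)
    idx = (
        integrative_indexes(summary, graph, "2d")
        if summary.n_roi
        else dict.fromkeys(INDEX_NAMES, np.nan)
    )
    unrep = labeled.object_count - len(graph.represented_objects() - {0})
    return RoiResult("2d", t, objects, summary, graph, idx, unrep)


def analyze_3d(
    stack: ZStack,
    fraction: float = 0.2,
    threshold: float | None = None,
    min_size: int = 8,
    prune_iterations: int = 2,
) -> RoiResult:
    """3D shape + network analysis of a (processed) z-stack.

    The threshold is set from the brightest-pixel fraction of the
    highest-intensity section and applied to every section; the same
    threshold drives the iso-surface and the 3D skeleton.
    """
    t = (
        float(threshold)
        if threshold is not None
        else segment.threshold_from_fraction(stack, fraction)
    )
    mask = segment.size_filter(segment.binarize(stack, t), min_size)
    labeled = segment.label_objects(mask, spacing=stack.spacing)
    meshes = segment.make_isosurface(labeled)
    objects, summary = shape.shape3d(labeled, meshes)
    graph = _network_from_mask(mask, stack.spacing, labeled, prune_iterations)
    idx = (
        integrative_indexes(summary, graph, "3d")
        if summary.n_roi
        else dict.fromkeys(INDEX_NAMES, np.nan)
    )
    unrep = labeled.object_count - len(graph.represented_objects() - {0})
    return RoiResult("3d", t, objects, summary, graph, idx, unrep)


# ---------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------

_DEFAULT_CONFIG = {
    "deconv": {"cycles": 10, "psf": {"na": 1.4, "wavelength_nm": 510.0, "sigma": None}},
    "stretch": {"enabled": True, "min": None, "max": None},
    "fft": {"enabled": False, "radius": 5, "hipass": True},
    "project": {"method": "mic", "sections": None},
    "segment": {"fraction": 0.2, "fraction_2d": 0.2, "min_size_2d": 4, "min_size_3d": 8},
    "network": {"prune_iterations": 2, "min_branch_length": 0.0},
}


def _merge(base: dict, override: dict) -> dict:
    out = {}
    for k, v in base.items():
        if isinstance(v, dict):
            out[k] = _merge(v, override.get(k, {}) if isinstance(override.get(k), dict) else {})
        else:
            out[k] = override.get(k, v)
    for k, v in override.items():
        out.setdefault(k, v)
    return out


def run_pipeline(
    config: dict,
    stack: ZStack | None = None,
    rois: list[ROI] | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Execute the full RAW → deconvolution → {2D, 3D} analysis chain.

    ``config`` follows the keys of the default configuration (missing
    entries take defaults); the input stack comes either from
    ``config['input']['path']``, ``config['synth']`` (a
    :func:`mitomorph.synthetic.simulate_cell_stack` parameter dict) or
    the ``stack`` argument. Each ROI (default: the full frame) is
    deconvolved, optionally contrast-stretched, then analyzed along the
    2D-MIC path and the 3D path; descriptor tables, integrative indexes
    and a parameter log are written to ``outdir`` when given.

    Returns a dict with per-ROI :class:`RoiResult` pairs, the per-ROI
    descriptor table and (for synthetic input) the ground truth.
    """
    cfg = _merge(_DEFAULT_CONFIG, config or {})
    ground_truth = None
    stage = "input"
    try:
        psf_sigma = cfg["deconv"]["psf"].get("sigma")
        if stack is None:
            if "synth" in cfg:
                params = dict(cfg["synth"])
                stack, ground_truth = synthetic.simulate_cell_stack(**params)
                if psf_sigma is None and params.get("apply_psf", True):
                    # the simulated instrument's blur is known; use it as
                    # the blind-RL starting guess
                    psf_sigma = (
                        params.get("psf_sigma_z", 2.4),
                        params.get("psf_sigma_xy", 1.2),
                    )
            elif "input" in cfg:
                inp = dict(cfg["input"])
                stack = mio.read_stack(
                    inp["path"],
                    pixel_size_xy=inp.get("pixel_size_xy"),
                    z_step=inp.get("z_step"),
                )
            else:
                raise ValueError("no input: provide stack=, config['synth'] or config['input']")
        if rois is None:
            nz, ny, nx = stack.shape
            rois = [ROI(0, 0, nx, ny)]

        results = []
        rows = []
        for i, roi in enumerate(rois):
            stage = f"crop(roi {i})"
            sub = mio.crop(stack, roi)
            stage = f"deconvolve(roi {i})"
            dec = preprocess.blind_deconvolve(
                sub,
                cycles=cfg["deconv"]["cycles"],
                psf_sigma=psf_sigma,
                na=cfg["deconv"]["psf"]["na"],
                wavelength_nm=cfg["deconv"]["psf"]["wavelength_nm"],
            )
            if cfg["stretch"]["enabled"]:
                stage = f"contrast_stretch(roi {i})"
                lo, hi = cfg["stretch"]["min"], cfg["stretch"]["max"]
                if hi is None:
                    # robust upper limit: deconvolution can concentrate
                    # intensity into sharp ridges, so the raw maximum is
                    # an unstable reference
                    hi = float(np.quantile(dec.data, 0.995))
                if lo is None:
                    # minimum intensity threshold removing faint
                    # out-of-focus/deconvolution residue
                    lo = 0.05 * hi
                dec = preprocess.contrast_stretch(dec, lo, hi)
            stage = f"project(roi {i})"
            mic = preprocess.project(
                dec, cfg["project"]["method"], cfg["project"]["sections"]
            )
            if cfg["fft"]["enabled"]:
                stage = f"fft_filter(roi {i})"
                mic = preprocess.fft_filter(
                    mic, cfg["fft"]["radius"], hipass=cfg["fft"]["hipass"]
                )
            seg = cfg["segment"]
            stage = f"analyze2d(roi {i})"
            r2 = analyze_2d(
                mic,
                pixel_size_xy=stack.pixel_size_xy,
                fraction=seg["fraction_2d"],
                min_size=seg["min_size_2d"],
                prune_iterations=cfg["network"]["prune_iterations"],
            )
            stage = f"analyze3d(roi {i})"
            r3 = analyze_3d(
                dec,
                fraction=seg["fraction"],
                min_size=seg["min_size_3d"],
                prune_iterations=cfg["network"]["prune_iterations"],
            )
            if cfg["network"]["min_branch_length"] > 0:
                r2.graph = r2.graph.filter_min_length(cfg["network"]["min_branch_length"])
                r3.graph = r3.graph.filter_min_length(cfg["network"]["min_branch_length"])
            results.append({"roi": roi, "2d": r2, "3d": r3})
            for r in (r2, r3):
                rows.append({"roi": i, **r.descriptor_row()})

        table = pd.DataFrame(rows)
        bundle = {
            "config": cfg,
            "stack": stack,
            "rois": rois,
            "results": results,
            "table": table,
            "ground_truth": ground_truth,
        }
        if outdir is not None:
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            table.to_csv(outdir / "roi_summary.csv", index=False)
            for i, res in enumerate(results):
                res["2d"].objects.to_csv(outdir / f"roi{i}_objects_2d.csv", index=False)
                res["3d"].objects.to_csv(outdir / f"roi{i}_objects_3d.csv", index=False)
                res["2d"].graph.branch_table().to_csv(
                    outdir / f"roi{i}_branches_2d.csv", index=False
                )
                res["3d"].graph.branch_table().to_csv(
                    outdir / f"roi{i}_branches_3d.csv", index=False
                )
            log = {
                "config": cfg,
                "n_rois": len(rois),
                "stack_shape": list(stack.shape),
                "calibration_um": list(stack.spacing),
            }
            (outdir / "run_log.json").write_text(json.dumps(log, indent=1, default=str))
        return bundle
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e
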