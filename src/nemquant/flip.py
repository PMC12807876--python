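"""Fluorescence-loss-in-photobleaching (FLIP) trace analysis.

Repeated bleaching of a small spot combined with intensity monitoring
elsewhere tests whether two membrane compartments exchange material by
diffusion.  The ROI scheme mirrors the source assay: ROI 1 at the bleach
centre (2.5 um radius bleach spot, 5 um measurement ROIs), ROI 2 on the
median axis between bleach spot and nucleus centre, ROI 3 diametrically
opposite the bleach spot across the nucleus, plus an Otsu nuclear mask and
a control ROI in a non-bleached neighbouring cell.  Traces are normalized
to their frame-0 value; a connected compartment pair drains the opposite
site, a disconnected one leaves it at baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from scipy.stats import t as t_dist
from skimage import filters

from .errors import ValidationError
from .io import ImageStack

__all__ = [
    "FlipExperiment",
    "FlipROISet",
    "plan_rois",
    "extract_flip_traces",
    "normalize_traces",
    "summarize_flip",
]

ROI_NAMES = ("bleach_site", "median_axis_site", "opposite_site", "nuclear_mask", "control_cell")


@dataclass
class FlipExperiment:
    """Per-ROI intensity traces of one FLIP run."""

    traces: Dict[str, np.ndarray]
    bleach_schedule: List[int] = field(default_factory=list)
    normalized: bool = False

    def __post_init__(self) -> None:
        if any(b2 <= b1 for b1, b2 in zip(self.bleach_schedule, self.bleach_schedule[1:])):
            raise ValidationError("bleach schedule must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.traces.values())))


@dataclass
class FlipROISet:
    """Circular ROI centres (y, x in px) and radius; fixed across frames."""

    bleach_site: Tuple[float, float]
    median_axis_site: Tuple[float, float]
    opposite_site: Tuple[float, float]
    control_cell: Optional[Tuple[float, float]]
    radius_px: float
    nucleus_label: int


def plan_rois(
    stack: ImageStack,
    bleach_centre: Tuple[float, float],
    nucleus_labels: np.ndarray,
    roi_diameter_um: float = 5.0,
    bleach_radius_um: float = 2.5,
) -> FlipROISet:
    """Place the invariant FLIP ROIs around the bleached nucleus.

    ROI 1 sits at the bleach centre; ROI 3 is its reflection through the
    nearest nucleus centroid (2c - p); ROI 2 is the midpoint between
    bleach centre and centroid.  The control ROI goes to the centroid of a
    different labelled cell, or is omitted with a warning when none exists.
    """
    ny, nx = stack.data.shape[-2:]
    by, bx = bleach_centre
    if not (0 <= by < ny and 0 <= bx < nx):
        raise ValidationError(f"bleach centre {bleach_centre} lies outside the FOV")
    dy, dx = stack.voxel_size[1], stack.voxel_size[2]
    px = (dy + dx) / 2.0
    radius_px = roi_diameter_um / 2.0 / px

    lab2d = nucleus_labels[0].max(axis=0) if nucleus_labels.ndim == 4 else nucleus_labels
    ids = [i for i in np.unique(lab2d) if i != 0]
    if not ids:
        raise ValidationError("no nucleus labels available for ROI planning")
    cents = {i: ndi.center_of_mass(lab2d == i) for i in ids}
    target = min(ids, key=lambda i: np.hypot(cents[i][0] - by, cents[i][1] - bx))
    cy, cx = cents[target]
    opposite = (2 * cy - by, 2 * cx - bx)
    median_axis = ((by + cy) / 2.0, (bx + cx) / 2.0)
    others = [i for i in ids if i != target]
    control = None
    if others:
        far = max(others, key=lambda i: np.hypot(cents[i][0] - by, cents[i][1] - bx))
        control = cents[far]
    else:
        warnings.warn("no second cell for the control ROI; Ctr omitted", stacklevel=2)
    return FlipROISet(bleach_site=(by, bx), median_axis_site=median_axis,
                      opposite_site=opposite, control_cell=control,
                      radius_px=radius_px, nucleus_label=int(target))


def _disk_mask(shape: Tuple[int, int], centre: Tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - centre[0]) ** 2 + (xx - centre[1]) ** 2 <= radius**2


def extract_flip_traces(
    stack: ImageStack,
    rois: FlipROISet,
    er_channel: str = "er_lumen",
    bleach_schedule: Optional[Sequence[int]] = None,
    statistic: str = "mean",
) -> FlipExperiment:
    """Per-frame ROI intensities of the ER channel, normalized to frame 0.

    The nuclear trace uses a binary Otsu mask of the frame-0 mid-plane.
    ``statistic`` selects the within-ROI reducer (mean by default, median
    selectable).
    """
    er = stack.channel(er_channel)
    T, nz = er.shape[0], er.shape[1]
    zmid = nz // 2
    reduce = np.mean if statistic == "mean" else np.median
    shape = er.shape[-2:]
    masks = {
        "bleach_site": _disk_mask(shape, rois.bleach_site, rois.radius_px),
        "median_axis_site": _disk_mask(shape, rois.median_axis_site, rois.radius_px),
        "opposite_site": _disk_mask(shape, rois.opposite_site, rois.radius_px),
    }
    if rois.control_cell is not None:
        masks["control_cell"] = _disk_mask(shape, rois.control_cell, rois.radius_px)
    ref = er[0, zmid]
    try:
        nuc_mask = ref > filters.threshold_otsu(ref)
    except ValueError:
        nuc_mask = np.zeros(shape, bool)
    traces = {name: np.zeros(T) for name in masks}
    traces["nuclear_mask"] = np.zeros(T)
    for t in range(T):
        sl = er[t, zmid]
        for name, m in masks.items():
            traces[name][t] = reduce(sl[m]) if m.any() else np.nan
        traces["nuclear_mask"][t] = reduce(sl[nuc_mask]) if nuc_mask.any() else np.nan
    exp = FlipExperiment(traces=traces, bleach_schedule=list(bleach_schedule or []))
    return normalize_traces(exp)


def normalize_traces(exp: FlipExperiment) -> FlipExperiment:
    """Divide every trace by its frame-0 value (idempotent)."""
    if exp.normalized:
        return exp
    out = {}
    for name, tr in exp.traces.items():
        tr = np.asarray(tr, float)
        base = tr[0]
        if not np.isfinite(base) or base <= 0:
            raise ValidationError(f"trace {name!r} has a non-positive frame-0 baseline")
        out[name] = tr / base
    return FlipExperiment(traces=out, bleach_schedule=exp.bleach_schedule, normalized=True)


def summarize_flip(experiments: Sequence[FlipExperiment]) -> Dict[str, Dict[str, np.ndarray]]:
    """Pointwise mean and t-based 95% CI across experiments (cells), per ROI.

    With a single experiment the mean is returned and the CI omitted.
    """
    if len(experiments) < 1:
        raise ValidationError("need at least one experiment")
    exps = [normalize_traces(e) for e in experiments]
    names = set.intersection(*(set(e.traces) for e in exps))
    out: Dict[str, Dict[str, np.ndarray]] = {}
    n = len(exps)
    for name in sorted(names):
        mat = np.vstack([e.traces[name] for e in exps])
        mean = mat.mean(axis=0)
        entry = {"mean": mean, "n": np.full(mat.shape[1], n)}
        if n >= 2:
            sem = mat.std(axis=0, ddof=1) / np.sqrt(n)
            half = t_dist.ppf(0.975, n - 1) * sem
            entry["ci_low"], entry["ci_high"] = mean - half, mean + half
        out[name] = entry
    return out
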