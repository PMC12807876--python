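"""ER segmentation and vesiculation morphometrics.

The ER is segmented either from a luminal marker (filled tubes; coarse
threshold + marker-controlled watershed) or from a membrane marker (thin
filaments; ridge filter at the 1.6 thickness scale + automatic threshold).
Per-object area and circularity Cir = 4*pi*A/P^2 are measured on the
representative mid-section -- the z slice with the largest total segmented
area -- with the Crofton perimeter estimator (chain-length perimeters bias
Cir above 1 for small disks).  Vesiculation of the network shows up as a
falling largest-object area and a rising mean circularity, summarized per
field of view.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import feature, filters, measure, morphology, segmentation

from .errors import ValidationError
from .io import ImageStack
from ._util import remove_small
from .nuclei import preprocess

__all__ = [
    "ERObject",
    "ERFovSummary",
    "circularity",
    "segment_er",
    "er_object_metrics",
    "er_fov_summary",
    "normalize_er_series",
    "summaries_to_table",
]


def circularity(area: float, perimeter: float, clip: float = 1.05) -> float:
    """Cir = 4*pi*A/P^2: 1 for a perfect circle, -> 0 for elongated shapes.

    Rasterized near-circles can exceed 1 slightly; values are clipped at
    ``clip`` (analytic geometry obeys Cir <= 1).
    """
    if perimeter <= 0:
        raise ValidationError(f"perimeter must be positive, got {perimeter}")
    return min(4.0 * np.pi * area / perimeter**2, clip)


@dataclass
class ERObject:
    object_id: int
    area_px2: float
    area_um2: float
    perimeter_px: float
    circularity: float


@dataclass
class ERFovSummary:
    """One area value and one circularity value per FOV per time point."""

    frame: int
    largest_object_area: float
    mean_circularity: float
    n_objects: int
    normalized_area: Optional[float] = None
    normalized_circularity: Optional[float] = None

    @property
    def defined(self) -> bool:
        return self.n_objects > 0


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _segment_luminal_frame(vol: np.ndarray) -> np.ndarray:
    """Coarse threshold + marker-controlled watershed, markers from local
    maxima of the smoothed luminal signal above the coarse threshold."""
    if vol.max() <= 0:
        return np.zeros(vol.shape, np.int32)
    try:
        thr = filters.threshold_otsu(vol)
    except ValueError:
        return np.zeros(vol.shape, np.int32)
    coarse = vol > thr
    coarse = remove_small(coarse, 8)
    if not coarse.any():
        return np.zeros(vol.shape, np.int32)
    peaks = feature.peak_local_max(vol, min_distance=3, labels=coarse)
    markers = np.zeros(vol.shape, np.int32)
    for i, p in enumerate(peaks, start=1):
        markers[tuple(p)] = i
    if markers.max() == 0:
        markers, _ = ndi.label(coarse, structure=np.ones((3, 3, 3), int))
    labels = segmentation.watershed(-vol, markers=markers, mask=coarse)
    # merge watershed fragments that touch: connectivity defines an object
    merged, _ = ndi.label(labels > 0, structure=np.ones((3, 3, 3), int))
    return merged.astype(np.int32)


def _fill_small_holes(mask2d: np.ndarray, max_hole_px2: float) -> np.ndarray:
    """Fill only holes up to ``max_hole_px2`` (vesicle lumens, not network pockets)."""
    filled = ndi.binary_fill_holes(mask2d)
    holes, n = ndi.label(filled & ~mask2d)
    if n == 0:
        return mask2d
    sizes = np.bincount(holes.ravel())
    small = sizes <= max_hole_px2
    small[0] = False
    return mask2d | small[holes]


def _segment_membrane_frame(vol: np.ndarray, thickness: float,
                            max_hole_px2: float = 150.0) -> np.ndarray:
    """Per-slice ridge filter at the filament scale, triangle threshold,
    26-connected component labels."""
    response = np.zeros_like(vol)
    for z in range(vol.shape[0]):
        sl = vol[z]
        if sl.max() > sl.min():
            response[z] = filters.sato(sl, sigmas=[thickness], black_ridges=False)
    if response.max() <= 0:
        return np.zeros(vol.shape, np.int32)
    # tubeness vanishes at junctions and crossings although the membrane is
    # bright there; blending a fraction of the raw intensity keeps those
    # pixels above threshold so one network segments as one object
    response = response / response.max() + 0.5 * vol
    thr = filters.threshold_triangle(response[response > 0])
    mask = response > thr
    # the ridge response dips at junctions; close small gaps per slice so one
    # tube network stays one object.  Membrane labelling outlines vesicles as
    # rings, so lumen-sized holes are filled to measure them as disks -- but
    # only small ones: large pockets enclosed by network loops must stay open
    # or their stochastic sealing makes object areas jump between frames.
    for z in range(mask.shape[0]):
        mask[z] = morphology.closing(mask[z], morphology.disk(3))
        mask[z] = _fill_small_holes(mask[z], max_hole_px2=max_hole_px2)
    mask = remove_small(mask, 8)
    labels, _ = ndi.label(mask, structure=np.ones((3, 3, 3), int))
    return labels.astype(np.int32)


def segment_er(
    stack: ImageStack,
    channel: Optional[str] = None,
    mode: str = "luminal",
    thickness: float = 1.6,
    gaussian_radius_px: float = 1.0,
) -> np.ndarray:
    """Segment the ER per frame; returns (t, z, y, x) int32 labels.

    ``mode='luminal'`` expects a filled-tube marker (e.g. a KDEL lumen
    label), ``mode='membrane'`` a thin-filament marker (e.g. SEC61B).
    Preprocessing is intensity normalization + 3-D Gaussian blur only
    (no rolling ball: the ER fills the field and would be eaten by it).
    """
    if mode not in ("luminal", "membrane"):
        raise ValidationError(f"unknown ER segmentation mode {mode!r}")
    if channel is None:
        channel = "er_lumen" if mode == "luminal" else "er_membrane"
    pp = preprocess(stack, channel, gaussian_radius_px=gaussian_radius_px, rollball_radius_px=0)
    seg = _segment_luminal_frame if mode == "luminal" else lambda v: _segment_membrane_frame(v, thickness)
    return np.stack([seg(pp[t]) for t in range(pp.shape[0])])


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def er_object_metrics(
    labels: np.ndarray,
    frame: int = 0,
    min_area_px2: float = 40.0,
    pixel_area_um2: float = 1.0,
    circularity_clip: float = 1.05,
) -> List[ERObject]:
    """Per-object area and circularity on the representative mid-section.

    The mid-section is the z slice with the largest total segmented area
    (ties -> lower index).  Objects below ``min_area_px2`` (the
    small-vesicle cutoff, stated range 30-50 px^2) are dropped.
    """
    vol = labels[frame] if labels.ndim == 4 else labels
    areas_per_slice = (vol > 0).reshape(vol.shape[0], -1).sum(axis=1)
    zmid = int(np.argmax(areas_per_slice))
    section = vol[zmid]
    # re-label in 2-D: one 3-D object can present as several mid-section pieces
    lab2d, _ = ndi.label(section > 0, structure=np.ones((3, 3), int))
    out = []
    for p in measure.regionprops(lab2d):
        if p.area < min_area_px2:
            continue
        per = p.perimeter_crofton
        if per <= 0:
            continue
        out.append(ERObject(
            object_id=p.label,
            area_px2=float(p.area),
            area_um2=float(p.area) * pixel_area_um2,
            perimeter_px=float(per),
            circularity=circularity(p.area, per, clip=circularity_clip),
        ))
    return out


def er_fov_summary(objects_per_frame: Sequence[List[ERObject]]) -> List[ERFovSummary]:
    """Largest object area and unweighted mean circularity per frame.

    ER metrics are FOV-level (no single-cell attribution); a frame with no
    retained objects yields an undefined (NaN) summary flagged by
    ``n_objects == 0``.
    """
    out = []
    for frame, objs in enumerate(objects_per_frame):
        if objs:
            out.append(ERFovSummary(
                frame=frame,
                largest_object_area=max(o.area_px2 for o in objs),
                mean_circularity=float(np.mean([o.circularity for o in objs])),
                n_objects=len(objs),
            ))
        else:
            out.append(ERFovSummary(frame=frame, largest_object_area=np.nan,
                                    mean_circularity=np.nan, n_objects=0))
    return out


def normalize_er_series(
    series: Sequence[ERFovSummary],
    scheme: str = "to_t0",
    control: Optional[Sequence[ERFovSummary]] = None,
) -> List[ERFovSummary]:
    """Normalize a per-FOV summary series.

    ``to_t0`` divides every frame by the frame-0 value (the frame-0
    normalized value is exactly 1, the baseline); ``to_control`` divides by
    the control series' mean.  Raw circularity lives in (0, 1]; after
    to_t0 normalization a value of 1 is baseline and > 1 means rounder.
    """
    if scheme not in ("to_t0", "to_control"):
        raise ValidationError(f"unknown normalization scheme {scheme!r}")
    if scheme == "to_control":
        if control is None:
            raise ValidationError("scheme 'to_control' requires a control series")
        ref_area = float(np.nanmean([s.largest_object_area for s in control]))
        ref_cir = float(np.nanmean([s.mean_circularity for s in control]))
    else:
        base = series[0]
        if not base.defined:
            raise ValidationError("frame 0 of this FOV has no objects; cannot normalize to t0")
        ref_area, ref_cir = base.largest_object_area, base.mean_circularity
    if not ref_area or not ref_cir or not np.isfinite(ref_area) or not np.isfinite(ref_cir):
        raise ValidationError("zero or undefined baseline in this FOV")
    out = []
    for s in series:
        out.append(ERFovSummary(
            frame=s.frame, largest_object_area=s.largest_object_area,
            mean_circularity=s.mean_circularity, n_objects=s.n_objects,
            normalized_area=s.largest_object_area / ref_area,
            normalized_circularity=s.mean_circularity / ref_cir,
        ))
    return out


def summaries_to_table(series: Sequence[ERFovSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "frame": s.frame,
        "largest_object_area_px2": s.largest_object_area,
        "mean_circularity": s.mean_circularity,
        "n_objects": s.n_objects,
        "normalized_area": s.normalized_area,
        "normalized_circularity": s.normalized_circularity,
    } for s in series])
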