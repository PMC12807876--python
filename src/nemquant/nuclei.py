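"""Nuclear segmentation, tracking and ratiometric adsorption measurement.

The pipeline follows the confocal NE analysis it re-implements: intensity
normalization, a 1-px 3-D Gaussian blur and per-slice rolling-ball
background subtraction; masked-object thresholding followed by a
marker-controlled watershed to segment nuclei in 3-D; greedy
mutual-nearest-neighbour centroid tracking; and a ratiometric adsorption
signal S = median(sensor on a 3-px membrane contour at the mid-slice) /
median(sensor on a 3-px nucleoplasmic background ring).  QC exclusions
mirror the stated rules: mid-slice area < 8,000 px^2, border contact,
frame-to-frame displacement > 130 px, or broken tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import filters, measure, morphology, restoration, segmentation, transform

from .config import AnalysisConfig
from .errors import ValidationError
from .io import ImageStack
from ._util import fill_holes_3d, remove_small

__all__ = [
    "QCFlags",
    "NucleusTrack",
    "preprocess",
    "segment_nuclei",
    "track_nuclei",
    "measure_nucleus",
    "apply_qc",
    "roi_traces",
    "tracks_to_table",
]


@dataclass
class QCFlags:
    too_small: bool = False
    border_touching: bool = False
    jump_exceeded: bool = False
    broken_track: bool = False
    marker_leakage: bool = False

    @property
    def retained(self) -> bool:
        return not (self.too_small or self.border_touching or self.jump_exceeded
                    or self.broken_track or self.marker_leakage)

    def reasons(self) -> List[str]:
        return [name for name in ("too_small", "border_touching", "jump_exceeded",
                                  "broken_track", "marker_leakage") if getattr(self, name)]


@dataclass
class NucleusTrack:
    """Per-nucleus time series of position, volume and adsorption signal."""

    track_id: int
    frames: List[int] = field(default_factory=list)
    labels: List[int] = field(default_factory=list)        # label id per frame
    centroids: List[Tuple[float, float, float]] = field(default_factory=list)  # (z,y,x) px
    volume_px3: List[float] = field(default_factory=list)
    volume_um3: List[float] = field(default_factory=list)
    mid_slice: List[int] = field(default_factory=list)
    mid_area_px2: List[float] = field(default_factory=list)
    s_ratio: List[float] = field(default_factory=list)     # rim / centre sensor median
    s_alt: List[float] = field(default_factory=list)       # rim sensor / NE-marker mid-slice median
    jump_displacements: List[float] = field(default_factory=list)  # per made link
    qc: QCFlags = field(default_factory=QCFlags)

    def max_displacement(self) -> float:
        return max(self.jump_displacements, default=0.0)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def _rolling_ball_2d(img: np.ndarray, radius: float) -> np.ndarray:
    """Rolling-ball background of one slice; large radii run on a 4x
    downsampled copy (standard speedup) and the background is upsampled."""
    if radius >= 16:
        small = transform.rescale(img, 0.25, anti_aliasing=True, preserve_range=True)
        bg = restoration.rolling_ball(small, radius=max(1.0, radius / 4.0))
        return transform.resize(bg, img.shape, preserve_range=True)
    return restoration.rolling_ball(img, radius=radius)


def preprocess(
    stack: ImageStack,
    channel: str,
    gaussian_radius_px: float = 1.0,
    rollball_radius_px: float = 50.0,
    clip_percentiles: Tuple[float, float] = (0.5, 99.5),
) -> np.ndarray:
    """Intensity-normalize, blur and background-subtract one channel.

    Returns a (t, z, y, x) array in [0, 1]: percentile-clipped min-max
    rescaling (robust to hot pixels), 3-D Gaussian smoothing, then a
    per-slice rolling-ball background subtraction.
    """
    raw = stack.channel(channel).astype(float)
    lo, hi = np.percentile(raw, clip_percentiles)
    if hi <= lo:
        raise ValidationError(f"channel {channel!r} has no dynamic range (constant image)")
    out = np.clip((raw - lo) / (hi - lo), 0.0, 1.0)
    for t in range(out.shape[0]):
        out[t] = ndi.gaussian_filter(out[t], sigma=gaussian_radius_px)
        if rollball_radius_px and rollball_radius_px > 0:
            for z in range(out.shape[1]):
                out[t, z] = out[t, z] - _rolling_ball_2d(out[t, z], rollball_radius_px)
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _segment_frame(vol: np.ndarray, min_marker_vox: int = 27) -> np.ndarray:
    """Two-pass masked-object threshold + marker-controlled watershed (3-D)."""
    finite = vol[np.isfinite(vol)]
    if finite.max() <= 0:
        return np.zeros(vol.shape, np.int32)
    try:
        coarse_thr = filters.threshold_otsu(vol)
    except ValueError:
        return np.zeros(vol.shape, np.int32)
    coarse = vol > coarse_thr
    coarse = remove_small(coarse, min_marker_vox)
    if not coarse.any():
        return np.zeros(vol.shape, np.int32)
    coarse = fill_holes_3d(coarse)
    comp, n = ndi.label(coarse, structure=np.ones((3, 3, 3), int))
    markers = np.zeros(vol.shape, bool)
    for i in range(1, n + 1):
        region = comp == i
        vals = vol[region]
        try:
            local_thr = filters.threshold_otsu(vals)
        except ValueError:
            local_thr = vals.mean()
        markers |= region & (vol > local_thr)
    markers = remove_small(markers, min_marker_vox)
    if not markers.any():
        markers = comp > 0
    # noise fragments the strict shell; label a dilated copy so the pieces
    # of one nucleus share a marker id (geometry of the markers unchanged)
    joined, _ = ndi.label(ndi.binary_dilation(markers, structure=np.ones((3, 3, 3), int), iterations=2),
                          structure=np.ones((3, 3, 3), int))
    marker_labels = np.where(markers, joined, 0)
    labels = segmentation.watershed(-vol, markers=marker_labels, mask=coarse)
    # second pass: clip each object back to its stricter local threshold and
    # refill, so the label boundary sits on the bright NE rim rather than at
    # the generous global-threshold edge (blur would otherwise push the
    # membrane contour into the cytoplasm)
    refined = np.zeros(vol.shape, np.int32)
    for i in np.unique(labels):
        if i == 0:
            continue
        m = fill_holes_3d((labels == i) & markers)
        refined[m] = i
    return refined


def segment_nuclei(preprocessed: np.ndarray | ImageStack, channel: Optional[str] = None) -> np.ndarray:
    """Segment nuclei per frame; returns (t, z, y, x) int32 labels.

    Accepts either the (t,z,y,x) output of :func:`preprocess` or an
    :class:`ImageStack` plus the channel role to preprocess on the fly.
    Labels are 26-connected and non-overlapping; a blank frame yields
    zero labels.
    """
    if isinstance(preprocessed, ImageStack):
        if channel is None:
            raise ValidationError("channel role required when passing an ImageStack")
        preprocessed = preprocess(preprocessed, channel)
    return np.stack([_segment_frame(preprocessed[t]) for t in range(preprocessed.shape[0])])


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------

def _frame_centroids(labels_t: np.ndarray) -> Dict[int, np.ndarray]:
    out = {}
    for p in measure.regionprops(labels_t):
        out[p.label] = np.asarray(p.centroid, float)
    return out


def track_nuclei(
    labels: np.ndarray,
    max_link_px: float = 130.0,
    jump_link_factor: float = 4.0,
) -> List[NucleusTrack]:
    """Greedy mutual-nearest-neighbour centroid linking, no gap closing.

    Links within ``max_link_px`` are made normally.  A mutual-nearest pair
    farther apart but within ``jump_link_factor * max_link_px`` is still
    linked and the displacement recorded, so the QC stage can exclude the
    nucleus as a single track with reason jump_exceeded rather than as two
    broken fragments.  Anything farther ends/starts tracks.
    """
    T = labels.shape[0]
    tracks: List[NucleusTrack] = []
    open_tracks: Dict[int, NucleusTrack] = {}  # current label -> track
    next_id = 0
    prev_cent: Dict[int, np.ndarray] = {}
    hard_limit = max_link_px * jump_link_factor

    for t in range(T):
        cent = _frame_centroids(labels[t])
        assignments: Dict[int, int] = {}  # prev label -> cur label
        if prev_cent and cent:
            prev_ids = list(prev_cent)
            cur_ids = list(cent)
            dmat = np.linalg.norm(
                np.asarray([prev_cent[i] for i in prev_ids])[:, None, :]
                - np.asarray([cent[j] for j in cur_ids])[None, :, :], axis=2)
            # mutual nearest neighbours within the hard limit
            for ip, pid in enumerate(prev_ids):
                jc = int(np.argmin(dmat[ip]))
                if int(np.argmin(dmat[:, jc])) == ip and dmat[ip, jc] <= hard_limit:
                    assignments[pid] = cur_ids[jc]
        new_open: Dict[int, NucleusTrack] = {}
        for pid, tr in open_tracks.items():
            if pid in assignments:
                cid = assignments[pid]
                tr.frames.append(t)
                tr.labels.append(cid)
                tr.centroids.append(tuple(cent[cid]))
                tr.jump_displacements.append(float(np.linalg.norm(cent[cid] - prev_cent[pid])))
                new_open[cid] = tr
        matched_cur = set(assignments.values())
        for cid, c in cent.items():
            if cid not in matched_cur:
                tr = NucleusTrack(track_id=next_id)
                next_id += 1
                tr.frames.append(t)
                tr.labels.append(cid)
                tr.centroids.append(tuple(c))
                tracks.append(tr)
                new_open[cid] = tr
        open_tracks = new_open
        prev_cent = cent
    return tracks


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

def _mid_slice(mask3d: np.ndarray) -> int:
    areas = mask3d.reshape(mask3d.shape[0], -1).sum(axis=1)
    return int(np.argmax(areas))  # ties -> lowest index (argmax convention)


def _membrane_contour(mask2d: np.ndarray, width: int = 3, inset_px: int = 1) -> np.ndarray:
    """Width-px band centred ``inset_px`` inside the 2-D label boundary.

    Automatic thresholds place the label boundary at the outer tail of the
    blurred NE rim, so a band centred exactly on the boundary would sample
    half cytoplasm; the one-pixel inset keeps it on the bright rim.
    """
    half = (width - 1) // 2
    core = morphology.erosion(mask2d, morphology.disk(inset_px)) if inset_px else mask2d
    boundary = core & ~morphology.erosion(core, morphology.disk(1))
    return morphology.dilation(boundary, morphology.disk(half)) if half else boundary


def _background_ring(mask2d: np.ndarray, width: int = 3, ring_fraction: float = 0.2) -> np.ndarray:
    """3-px-wide ring at ``ring_fraction`` of the equivalent radius, centred
    on the 2-D centroid -- well inside the nucleoplasm for convex nuclei."""
    area = mask2d.sum()
    if area == 0:
        return np.zeros_like(mask2d)
    cy, cx = ndi.center_of_mass(mask2d)
    r_eq = np.sqrt(area / np.pi)
    r_ring = max(ring_fraction * r_eq, 1.0)
    yy, xx = np.ogrid[: mask2d.shape[0], : mask2d.shape[1]]
    d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    ring = np.abs(d - r_ring) <= (width - 1) / 2.0 + 0.5
    return ring & mask2d


def measure_nucleus(
    stack: ImageStack,
    labels: np.ndarray,
    track: NucleusTrack,
    sensor_channel: str = "sensor",
    ne_channel: str = "ne_marker",
    contour_width_px: int = 3,
    centre_ring_fraction: float = 0.2,
) -> NucleusTrack:
    """Fill a track with volume, mid-slice and ratiometric signals.

    V is the voxel count scaled by the voxel volume; the mid-slice is the
    plane with the largest segmented area; S divides the sensor median on
    the membrane contour by its median on the nucleoplasmic background
    ring; S_alt divides the same rim median by the NE-marker median over
    the whole mid-slice section (robust to nucleoplasm dimming).
    """
    sensor = stack.channel(sensor_channel)
    try:
        ne = stack.channel(ne_channel)
    except ValidationError:
        ne = None
    vox_vol = stack.voxel_volume_um3
    for frame, lab in zip(track.frames, track.labels):
        mask3d = labels[frame] == lab
        nvox = int(mask3d.sum())
        track.volume_px3.append(float(nvox))
        track.volume_um3.append(nvox * vox_vol)
        z = _mid_slice(mask3d)
        track.mid_slice.append(z)
        mask2d = mask3d[z]
        track.mid_area_px2.append(float(mask2d.sum()))
        mem = _membrane_contour(mask2d, contour_width_px)
        ring = _background_ring(mask2d, contour_width_px, centre_ring_fraction)
        s_img = sensor[frame, z]
        mem_med = float(np.median(s_img[mem])) if mem.any() else np.nan
        ring_med = float(np.median(s_img[ring])) if ring.any() else np.nan
        if not np.isfinite(ring_med) or ring_med <= 0:
            track.qc.marker_leakage = True
            track.s_ratio.append(np.nan)
        else:
            track.s_ratio.append(mem_med / ring_med)
        if ne is not None:
            ne_med = float(np.median(ne[frame, z][mask2d])) if mask2d.any() else np.nan
            track.s_alt.append(mem_med / ne_med if ne_med and np.isfinite(ne_med) and ne_med > 0 else np.nan)
        else:
            track.s_alt.append(np.nan)
    return track


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def apply_qc(
    tracks: Sequence[NucleusTrack],
    labels: np.ndarray,
    min_area_px2: float = 8000.0,
    max_jump_px: float = 130.0,
) -> Tuple[List[NucleusTrack], pd.DataFrame]:
    """Apply the exclusion rules; returns retained tracks + an exclusion report.

    A nucleus is excluded when its mid-slice area falls below the size
    threshold, it touches the image border (y/x bounds of any frame), any
    linked displacement exceeds the jump threshold, or its track is broken
    (does not span the full movie contiguously).
    """
    T = labels.shape[0]
    ny, nx = labels.shape[-2:]
    retained, rows = [], []
    for tr in tracks:
        if not tr.mid_area_px2:
            raise ValidationError(f"track {tr.track_id} is unmeasured; run measure_nucleus first")
        if min(tr.mid_area_px2) < min_area_px2:
            tr.qc.too_small = True
        for frame, lab in zip(tr.frames, tr.labels):
            m = labels[frame] == lab
            if m[:, 0, :].any() or m[:, -1, :].any() or m[:, :, 0].any() or m[:, :, -1].any():
                tr.qc.border_touching = True
                break
        if tr.max_displacement() > max_jump_px:
            tr.qc.jump_exceeded = True
        contiguous = tr.frames == list(range(tr.frames[0], tr.frames[-1] + 1))
        if T > 1 and (not contiguous or len(tr.frames) < T):
            tr.qc.broken_track = True
        if tr.qc.retained:
            retained.append(tr)
        else:
            rows.append({"track_id": tr.track_id, "n_frames": len(tr.frames),
                         "reason": "+".join(tr.qc.reasons())})
    report = pd.DataFrame(rows, columns=["track_id", "n_frames", "reason"])
    return retained, report


# ---------------------------------------------------------------------------
# projection ROI traces and rim profiles
# ---------------------------------------------------------------------------

def roi_traces(
    stack: ImageStack,
    labels: np.ndarray,
    profile_line: Optional[Tuple[Tuple[float, float], Tuple[float, float]]] = None,
    profile_width_px: int = 20,
    dilate_px: int = 5,
) -> Dict[str, np.ndarray]:
    """Per-frame MIP traces: intranuclear lysis dye, extranuclear sensor,
    and (optionally) a 20-px-wide rim line profile per frame.

    The intranuclear ROI is the projected label mask; the extranuclear ROI
    is the projection minus the dilated mask.
    """
    try:
        lysis = stack.channel("lysis_dye")
    except ValidationError as exc:
        raise ValidationError("roi_traces requires a lysis_dye channel") from exc
    sensor = stack.channel("sensor")
    T = stack.n_frames
    nuclear_lysis = np.zeros(T)
    extranuclear_sensor = np.zeros(T)
    profiles = []
    for t in range(T):
        proj_mask = labels[t].max(axis=0) > 0
        lys_mip = lysis[t].max(axis=0)
        sen_mip = sensor[t].max(axis=0)
        nuclear_lysis[t] = lys_mip[proj_mask].mean() if proj_mask.any() else 0.0
        outside = ~morphology.dilation(proj_mask, morphology.disk(dilate_px))
        extranuclear_sensor[t] = sen_mip[outside].mean() if outside.any() else 0.0
        if profile_line is not None:
            prof = measure.profile_line(sen_mip, profile_line[0], profile_line[1],
                                        linewidth=profile_width_px, mode="constant")
            profiles.append(prof)
    out = {"nuclear_lysis": nuclear_lysis, "extranuclear_sensor": extranuclear_sensor}
    if profiles:
        out["rim_profile"] = np.asarray(profiles)
    return out


def tracks_to_table(tracks: Sequence[NucleusTrack]) -> pd.DataFrame:
    """Flatten tracks into a tidy per-frame table."""
    rows = []
    for tr in tracks:
        for i, frame in enumerate(tr.frames):
            rows.append({
                "track_id": tr.track_id, "frame": frame,
                "z": tr.centroids[i][0], "y": tr.centroids[i][1], "x": tr.centroids[i][2],
                "volume_px3": tr.volume_px3[i] if tr.volume_px3 else np.nan,
                "volume_um3": tr.volume_um3[i] if tr.volume_um3 else np.nan,
                "mid_slice": tr.mid_slice[i] if tr.mid_slice else -1,
                "mid_area_px2": tr.mid_area_px2[i] if tr.mid_area_px2 else np.nan,
                "S": tr.s_ratio[i] if tr.s_ratio else np.nan,
                "S_alt": tr.s_alt[i] if tr.s_alt else np.nan,
                "retained": tr.qc.retained,
            })
    return pd.DataFrame(rows)
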