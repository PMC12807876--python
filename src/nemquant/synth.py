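"""Synthetic microscopy generator with known ground truth.

Each generator emulates the statistical structure of one assay so the
downstream analysis stages have a recovery oracle:

* nuclei as ellipsoidal shells (NE marker) with a nucleoplasmic sensor
  whose rim enrichment rho is set analytically,
* NE folds as radial ridge spurs on the mid-plane shell (one skeleton
  junction per spur, hence a countable truth),
* the ER as a connected random-walk tube network that vesiculates into
  disjoint spheres as the vesiculation fraction phi goes 0 -> 1,
* GUV titrations drawn from a Hill-Langmuir isotherm,
* FLIP experiments as a two-pool bleach/exchange recurrence.

Noise is Poisson on the scaled signal plus additive Gaussian plus a planar
background gradient, applied last; identical seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi

from .errors import ValidationError
from .io import ConditionMeta, ImageStack

__all__ = [
    "NoiseSpec",
    "NucleusSpec",
    "ERSpec",
    "SynthScene",
    "GroundTruth",
    "synth_nucleus_timelapse",
    "qc_toy_scene",
    "synth_er_scene",
    "synth_guv_titration",
    "render_guv",
    "synth_flip_experiment",
    "hill_langmuir",
    "GUV_PRESETS",
]


# ---------------------------------------------------------------------------
# scene specification
# ---------------------------------------------------------------------------

@dataclass
class NoiseSpec:
    """Poisson-Gaussian noise plus a planar background gradient.

    ``poisson_scale`` is the photon budget per unit intensity (0 disables
    shot noise); ``gaussian_sd`` the read-noise s.d.; ``background_gradient``
    the peak amplitude of an additive planar ramp across the field.
    """

    gaussian_sd: float = 0.01
    poisson_scale: float = 200.0
    background_gradient: float = 0.1

    @classmethod
    def none(cls) -> "NoiseSpec":
        return cls(gaussian_sd=0.0, poisson_scale=0.0, background_gradient=0.0)


@dataclass
class NucleusSpec:
    centre: Tuple[float, float, float]          # (z, y, x) px at frame 0
    semi_axes: Tuple[float, float, float]       # (az, ay, ax) px
    rim_width: float = 3.0                      # ~3-4 px NE rims at confocal sampling
    rim_enrichment: float = 2.0                 # rho: rim / nucleoplasm sensor ratio
    fold_spur_count: int = 0
    spur_length: float = 12.0
    displacement: Optional[Sequence[Tuple[float, float, float]]] = None  # per-frame offsets
    volume_scale: Optional[Sequence[float]] = None                       # per-frame V multiplier
    lysis_frame: Optional[int] = None
    border_touching: bool = False               # flag: geometry may leave the FOV

    def offset(self, frame: int) -> np.ndarray:
        if self.displacement is None or frame >= len(self.displacement):
            return np.zeros(3)
        return np.asarray(self.displacement[frame], dtype=float)

    def scale(self, frame: int) -> float:
        if self.volume_scale is None or frame >= len(self.volume_scale):
            return 1.0
        return float(self.volume_scale[frame])


@dataclass
class ERSpec:
    mode: str = "network"                       # network | vesicles | mixture
    vesiculation_fraction: float = 0.0          # phi in [0, 1]
    tube_radius: float = 1.5
    n_vesicles: int = 20
    n_branches: int = 10                        # convertible branch units on the backbone
    vesicle_radius: Tuple[float, float] = (4.0, 7.0)
    walk_steps: int = 1800

    def __post_init__(self) -> None:
        if not 0.0 <= self.vesiculation_fraction <= 1.0:
            raise ValidationError(f"vesiculation_fraction must lie in [0,1], got {self.vesiculation_fraction}")
        if self.mode not in ("network", "vesicles", "mixture"):
            raise ValidationError(f"unknown ER mode {self.mode!r}")


@dataclass
class SynthScene:
    fov_shape: Tuple[int, int, int] = (24, 128, 128)  # (z, y, x) px
    n_frames: int = 1
    nuclei: List[NucleusSpec] = field(default_factory=list)
    er_spec: ERSpec = field(default_factory=ERSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    voxel_size: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def validate(self) -> None:
        nz, ny, nx = self.fov_shape
        for nuc in self.nuclei:
            if nuc.rim_enrichment < 0:
                raise ValidationError("rim_enrichment must be >= 0")
            if nuc.fold_spur_count < 0:
                raise ValidationError("fold_spur_count must be >= 0")
            if not nuc.border_touching:
                c, a = np.asarray(nuc.centre), np.asarray(nuc.semi_axes)
                if np.any(c - a < 0) or np.any(c + a > (nz, ny, nx)):
                    raise ValidationError(
                        f"nucleus at {nuc.centre} with semi-axes {nuc.semi_axes} "
                        "leaves the FOV; set border_touching=True if intended")


@dataclass
class GroundTruth:
    """Generator-side truth used by recovery tests.

    ``labels`` holds per-frame integer label volumes with ids stable across
    frames for the same object.
    """

    labels: Optional[np.ndarray] = None                 # (t, z, y, x) uint16
    volumes_px3: Dict[int, List[float]] = field(default_factory=dict)     # analytic, per frame
    rim_enrichment: Dict[int, float] = field(default_factory=dict)
    fold_count: Dict[int, int] = field(default_factory=dict)
    centroids: Dict[int, List[Tuple[float, float, float]]] = field(default_factory=dict)
    lysis_frame: Dict[int, Optional[int]] = field(default_factory=dict)
    er_object_area: Dict[int, float] = field(default_factory=dict)        # mid-plane px^2
    er_object_circularity: Dict[int, float] = field(default_factory=dict)
    isotherm_params: Optional[Tuple[float, float, float]] = None          # (B_max, Kd', H)
    binding_true: Optional[np.ndarray] = None
    connected: Optional[bool] = None
    exchange_rate: Optional[float] = None

    def jump_frames(self, label: int, threshold: float) -> List[int]:
        """Frames at which the true centroid moved more than ``threshold`` px."""
        cs = np.asarray(self.centroids.get(label, []))
        if len(cs) < 2:
            return []
        d = np.linalg.norm(np.diff(cs, axis=0), axis=1)
        return [int(i) + 1 for i in np.nonzero(d > threshold)[0]]


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

def apply_noise(clean: np.ndarray, noise: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    """Signal-dependent shot noise, Gaussian read noise and a planar ramp.

    Shot noise uses the Gaussian approximation of a Poisson count at the
    given photon budget (variance = signal / poisson_scale), which keeps
    the generator's random-number consumption independent of the rendered
    content -- scenes that share a seed share their noise field, so
    parameter sweeps are paired.
    """
    out = clean.astype(float)
    if noise.poisson_scale > 0:
        shot_sd = np.sqrt(np.clip(out, 0.0, None) / noise.poisson_scale)
        out = out + rng.standard_normal(out.shape) * shot_sd
    if noise.gaussian_sd > 0:
        out = out + rng.normal(0.0, noise.gaussian_sd, size=out.shape)
    if noise.background_gradient > 0:
        ny, nx = out.shape[-2:]
        yy, xx = np.meshgrid(np.linspace(0, 1, ny), np.linspace(0, 1, nx), indexing="ij")
        a, b = rng.uniform(0.2, 1.0, size=2)
        ramp = noise.background_gradient * (a * yy + b * xx) / (a + b)
        out = out + ramp
    return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# nuclei
# ---------------------------------------------------------------------------

def _ellipsoid_mask(shape, centre, semi_axes) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = centre
    az, ay, ax = (max(a, 1e-6) for a in semi_axes)
    d = ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
    return d <= 1.0


def _render_spurs(ne: np.ndarray, mask2d: np.ndarray, centre_yx, n_spurs: int,
                  length: float, zmid: int, value: float) -> None:
    """Draw ``n_spurs`` radial inward ridges on the mid-plane NE shell."""
    if n_spurs <= 0:
        return
    from skimage import draw, measure, morphology

    cy, cx = centre_yx
    # boundary radius per angle from the 2-D mask
    for j in range(n_spurs):
        # the +0.1 keeps spur axes off exact pixel diagonals, where
        # rasterization can fuse the spur smoothly into the rim outline
        theta = 2 * np.pi * j / n_spurs + np.pi / (2 * n_spurs) + 0.1
        # march outward to find the boundary along this ray
        r = 1.0
        while True:
            y, x = cy + r * np.sin(theta), cx + r * np.cos(theta)
            yi, xi = int(round(y)), int(round(x))
            if not (0 <= yi < mask2d.shape[0] and 0 <= xi < mask2d.shape[1]) or not mask2d[yi, xi]:
                break
            r += 0.5
        r_out = r
        y0, x0 = cy + r_out * np.sin(theta), cx + r_out * np.cos(theta)
        y1, x1 = cy + (r_out - length) * np.sin(theta), cx + (r_out - length) * np.cos(theta)
        rr, cc = draw.line(int(round(y0)), int(round(x0)), int(round(y1)), int(round(x1)))
        ok = (rr >= 0) & (rr < ne.shape[-2]) & (cc >= 0) & (cc < ne.shape[-1])
        spur = np.zeros(mask2d.shape, bool)
        spur[rr[ok], cc[ok]] = True
        spur = morphology.dilation(spur, morphology.disk(2))
        for dz in (-1, 0, 1):
            z = zmid + dz
            if 0 <= z < ne.shape[0]:
                ne[z][spur] = np.maximum(ne[z][spur], value)


def synth_nucleus_timelapse(scene: SynthScene) -> Tuple[ImageStack, GroundTruth]:
    """Render a nuclear time-lapse with NE-marker, sensor and lysis-dye channels.

    The NE channel is an ellipsoidal shell of the spec'd rim width; the
    sensor channel has nucleoplasm intensity I0 and rim intensity rho*I0,
    so the rim-to-centre ratio of a clean nucleus is rho by construction.
    Motion and volume schedules shift and scale the ellipsoid per frame;
    a lysis frame switches on intranuclear lysis dye and decays the
    extranuclear sensor.  Noise is applied last.
    """
    scene.validate()
    rng = np.random.default_rng(scene.seed)
    nz, ny, nx = scene.fov_shape
    T = scene.n_frames
    I0, CYT = 0.5, 0.15
    data = np.zeros((T, 3, nz, ny, nx), float)
    labels = np.zeros((T, nz, ny, nx), np.uint16)
    gt = GroundTruth(labels=labels)

    for lab, nuc in enumerate(scene.nuclei, start=1):
        gt.rim_enrichment[lab] = nuc.rim_enrichment
        gt.fold_count[lab] = nuc.fold_spur_count
        gt.lysis_frame[lab] = nuc.lysis_frame
        gt.volumes_px3[lab] = []
        gt.centroids[lab] = []

    for t in range(T):
        ne = np.zeros((nz, ny, nx))
        sensor = np.full((nz, ny, nx), CYT)
        lysis = np.zeros((nz, ny, nx))
        for lab, nuc in enumerate(scene.nuclei, start=1):
            s = nuc.scale(t) ** (1.0 / 3.0)
            centre = np.asarray(nuc.centre) + nuc.offset(t)
            semi = np.asarray(nuc.semi_axes) * s
            outer = _ellipsoid_mask((nz, ny, nx), centre, semi)
            inner = _ellipsoid_mask((nz, ny, nx), centre, semi - nuc.rim_width)
            shell = outer & ~inner
            ne[shell] = 1.0
            lysed = nuc.lysis_frame is not None and t >= nuc.lysis_frame
            sensor[inner] = I0
            sensor[shell] = nuc.rim_enrichment * I0
            if lysed:
                decay = float(np.exp(-(t - nuc.lysis_frame + 1)))
                sensor[~outer] = CYT * decay
                lysis[outer] = 0.8
            labels[t][outer] = lab
            gt.volumes_px3[lab].append(4.0 / 3.0 * np.pi * float(np.prod(semi)))
            gt.centroids[lab].append(tuple(centre))
            if nuc.fold_spur_count > 0:
                zmid = int(round(centre[0]))
                _render_spurs(ne, outer[zmid], (centre[1], centre[2]),
                              nuc.fold_spur_count, nuc.spur_length, zmid, 1.0)
        data[t, 0] = apply_noise(ne, scene.noise, rng)
        data[t, 1] = apply_noise(sensor, scene.noise, rng)
        data[t, 2] = apply_noise(lysis, scene.noise, rng)

    stack = ImageStack(
        data=data, voxel_size=scene.voxel_size,
        channel_roles={0: "ne_marker", 1: "sensor", 2: "lysis_dye"},
        condition=ConditionMeta(),
    )
    return stack, gt


# ---------------------------------------------------------------------------
# ER
# ---------------------------------------------------------------------------

def _walk_path(shape_yx, n_steps, rng, start=None, theta0=None,
               margin=8, wobble=0.35):
    """Persistent random-walk path (list of (y, x)), bounced off the margins."""
    ny, nx = shape_yx
    y, x = start if start is not None else (ny / 2.0, nx / 2.0)
    theta = theta0 if theta0 is not None else rng.uniform(0, 2 * np.pi)
    pts = [(y, x)]
    guard = 0
    while len(pts) <= n_steps and guard < 10 * n_steps:
        guard += 1
        theta += rng.normal(0.0, wobble)
        y2, x2 = y + np.sin(theta), x + np.cos(theta)
        if not (margin <= y2 < ny - margin and margin <= x2 < nx - margin):
            theta += np.pi / 2  # bounce off the margin
            continue
        pts.append((y2, x2))
        y, x = y2, x2
    return pts


def _rasterize_path(shape_yx, pts) -> np.ndarray:
    sk = np.zeros(shape_yx, bool)
    for y, x in pts:
        sk[int(round(y)), int(round(x))] = True
    return sk


def synth_er_scene(scene: SynthScene) -> Tuple[ImageStack, GroundTruth]:
    """Render an ER field in both luminal and membrane styles.

    The tube network is a connected backbone walk carrying ``n_vesicles``
    short branch segments.  Vesiculation converts branch units one-for-one
    into disjoint filled spheres: at fraction phi, the first
    ``round(phi * n_vesicles)`` branches are detached and the same number
    of vesicles from a fixed layout is rendered; at phi = 1 the backbone
    itself is consumed and only vesicles remain.  Because the backbone,
    the branch geometries and the vesicle layout are each drawn from their
    own seeded stream, a phi sweep at fixed seed is perfectly paired
    (nested geometry), which makes the ground-truth direction of the
    morphometrics monotone by construction: every conversion step removes
    low-circularity tube material and adds a circular object, so the
    truth mean circularity is non-decreasing and the largest-object area
    non-increasing in phi.  Ground truth records per-object mid-plane
    area and circularity measured on the clean labels.
    """
    scene.validate()
    er = scene.er_spec
    ss = np.random.SeedSequence(scene.seed).spawn(4)
    walk_rng, branch_rng, ves_rng, noise_rng = (np.random.default_rng(q) for q in ss)
    nz, ny, nx = scene.fov_shape
    zmid = nz // 2

    from skimage import measure, morphology

    phi = {"network": 0.0, "vesicles": 1.0}.get(er.mode, er.vesiculation_fraction)
    n_units = max(er.n_vesicles, 1)
    n_br = max(er.n_branches, 1)
    k = int(round(n_units * phi))          # vesicles rendered
    k_br = int(round(n_br * phi))          # branches detached
    disk = morphology.disk(max(1, int(round(er.tube_radius))))

    # backbone and branch geometry are fixed across phi; branches are few and
    # long so each detachment dwarfs segmentation jitter on the tube area
    backbone_steps = er.walk_steps // 3
    branch_steps = max((er.walk_steps - backbone_steps) // n_br, 10)
    backbone_pts = _walk_path((ny, nx), backbone_steps, walk_rng)
    anchors = np.linspace(len(backbone_pts) // 10, len(backbone_pts) - 1, n_br).astype(int)
    branches = []
    for a in anchors:
        theta0 = branch_rng.uniform(0, 2 * np.pi)
        branches.append(_walk_path((ny, nx), branch_steps, branch_rng,
                                   start=backbone_pts[a], theta0=theta0, wobble=0.2))

    labels3d = np.zeros((nz, ny, nx), np.uint16)
    lumen = np.zeros((nz, ny, nx))
    membrane = np.zeros((nz, ny, nx))
    gt = GroundTruth()
    next_label = 1

    tube2d = None
    if phi < 1.0:
        sk = _rasterize_path((ny, nx), backbone_pts)
        for br in branches[k_br:]:
            sk |= _rasterize_path((ny, nx), br)
        tube2d = morphology.dilation(sk, disk)
        zlo, zhi = max(0, zmid - 1), min(nz, zmid + 2)
        for z in range(zlo, zhi):
            labels3d[z][tube2d] = next_label
            lumen[z][tube2d] = 1.0
            membrane[z][tube2d] = 1.0  # thin tubes: membrane marker fills them at confocal scale
        gt.er_object_area[next_label] = float(tube2d.sum())
        props = measure.regionprops(tube2d.astype(np.uint8))
        if props:
            per = max(props[0].perimeter_crofton, 1e-9)
            gt.er_object_circularity[next_label] = min(4 * np.pi * props[0].area / per**2, 1.05)
        next_label += 1

    # fixed vesicle layout, clear of the full tube structure; the first k
    # entries are rendered so adjacent phi steps share every vesicle
    full_sk = _rasterize_path((ny, nx), backbone_pts)
    for br in branches:
        full_sk |= _rasterize_path((ny, nx), br)
    full_tube2d = morphology.dilation(full_sk, disk) if er.mode != "vesicles" else None
    layout: List[Tuple[float, float, float]] = []
    rmax = er.vesicle_radius[1]
    tries = 0
    while len(layout) < n_units and tries < 20000:
        tries += 1
        r = ves_rng.uniform(*er.vesicle_radius)
        cy = ves_rng.uniform(rmax + 4, ny - rmax - 4)
        cx = ves_rng.uniform(rmax + 4, nx - rmax - 4)
        # separation must out-reach blur + segmentation closing, or
        # neighbouring vesicles merge into low-circularity dumbbells
        if any((cy - py) ** 2 + (cx - px) ** 2 < (r + pr + 12) ** 2 for py, px, pr in layout):
            continue
        if full_tube2d is not None:
            # clearance must out-reach ridge halos + closing, or a fresh
            # vesicle gets bridged onto the tube and its area jumps
            ys = slice(max(0, int(cy - r - 12)), int(cy + r + 12))
            xs = slice(max(0, int(cx - r - 12)), int(cx + r + 12))
            if full_tube2d[ys, xs].any():
                continue
        layout.append((cy, cx, r))
    for cy, cx, r in layout[:k]:
        rz = min(r, max(zmid, 1))
        sphere = _ellipsoid_mask((nz, ny, nx), (zmid, cy, cx), (rz, r, r))
        shell = sphere & ~_ellipsoid_mask((nz, ny, nx), (zmid, cy, cx),
                                          (rz - 1.5, r - 1.5, r - 1.5))
        labels3d[sphere] = next_label
        lumen[sphere] = 1.0
        membrane[shell] = 1.0
        gt.er_object_area[next_label] = float(np.pi * r * r)
        gt.er_object_circularity[next_label] = 1.0
        next_label += 1

    T = max(1, scene.n_frames)
    data = np.zeros((T, 2, nz, ny, nx))
    for t in range(T):
        data[t, 0] = apply_noise(lumen, scene.noise, noise_rng)
        data[t, 1] = apply_noise(membrane, scene.noise, noise_rng)
    gt.labels = np.repeat(labels3d[None], T, axis=0)
    stack = ImageStack(data=data, voxel_size=scene.voxel_size,
                       channel_roles={0: "er_lumen", 1: "er_membrane"})
    return stack, gt


def qc_toy_scene(seed: int = 0) -> SynthScene:
    """Four-nucleus QC scene: one under the mid-slice size cutoff, one
    touching the image border, one jumping farther than the displacement
    cutoff, and one compliant.  Geometry keeps every nucleus its own
    mutual nearest neighbour across the jump, so the jumper stays one
    track and is excluded for the jump, not as two broken fragments."""
    return SynthScene(
        fov_shape=(20, 420, 420), n_frames=3, seed=seed,
        nuclei=[
            NucleusSpec(centre=(10, 60, 60), semi_axes=(7, 40, 40)),       # ~5,000 px^2 mid-slice
            NucleusSpec(centre=(10, 90, 330), semi_axes=(7, 55, 55)),      # compliant (~9,500 px^2)
            NucleusSpec(centre=(10, 210, 363), semi_axes=(7, 56, 56),      # reaches the last x column
                        border_touching=True),
            NucleusSpec(centre=(10, 330, 60), semi_axes=(7, 55, 55),       # 150 px jump at frame 1
                        displacement=[(0, 0, 0), (0, -106, 106), (0, -106, 106)]),
        ],
        noise=NoiseSpec())


# ---------------------------------------------------------------------------
# GUV titrations
# ---------------------------------------------------------------------------

def hill_langmuir(c, b_max: float, k_d: float, h: float):
    """Hill-expanded Langmuir adsorption isotherm B(c) = B_max c^H / (c^H + Kd'^H)."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ch = np.power(c, h)
        out = b_max * ch / (ch + k_d ** h)
    return np.where(c > 0, out, 0.0) if np.ndim(c) else (float(out) if c > 0 else 0.0)


#: Titration design printed in the methods: 8 protein concentrations (nM)
#: and the per-concentration GUV replicate counts of the two assay arms.
TITRATION_CONCS_NM = (0.0, 25.0, 50.0, 100.0, 200.0, 300.0, 400.0, 500.0)
TITRATION_N_CA0 = (47, 14, 28, 57, 61, 87, 89, 74)
TITRATION_N_CA20 = (41, 28, 39, 54, 73, 86, 73, 64)

#: Named generating presets: (B_max, Kd' in nM, H) plus the replicate design.
#: "alps-hypotonic" mirrors the ALPS1-2 GUV affinity (Kd' ~ 150 nM, Ca2+-free
#: hypotonic arm); "c2-ca20" mirrors the cPla2 C2 domain at 20 uM Ca2+
#: (Kd' ~ 20 nM).  B_max = 1 on the 1 uM-reference-normalized scale.
GUV_PRESETS = {
    "alps-hypotonic": {"params": (1.0, 150.0, 1.0), "n_per_conc": TITRATION_N_CA0},
    "c2-ca20": {"params": (1.0, 20.0, 1.0), "n_per_conc": TITRATION_N_CA20},
}


def synth_guv_titration(
    concs: Sequence[float],
    n_per_conc: Sequence[int],
    params: Tuple[float, float, float],
    noise_cv: float = 0.15,
    seed: int = 0,
) -> Tuple["pd.DataFrame", GroundTruth]:
    """Draw per-GUV rim-binding measurements from the isotherm.

    Observed binding is B*(1 + eps) with eps ~ Normal(0, noise_cv),
    clipped at 0.  Returns a tidy table (concentration_nM, binding) plus
    the generating truth.
    """
    import pandas as pd

    if noise_cv < 0:
        raise ValidationError(f"noise_cv must be >= 0, got {noise_cv}")
    if any(c < 0 for c in concs):
        raise ValidationError("concentrations must be non-negative")
    b_max, k_d, h = params
    if min(b_max, k_d, h) <= 0:
        raise ValidationError("isotherm parameters must be positive")
    if len(concs) != len(n_per_conc):
        raise ValidationError("concs and n_per_conc must have equal length")
    rng = np.random.default_rng(seed)
    rows = []
    for c, n in zip(concs, n_per_conc):
        b_true = hill_langmuir(c, b_max, k_d, h)
        obs = b_true * (1.0 + rng.normal(0.0, noise_cv, size=int(n)))
        for v in np.clip(obs, 0.0, None):
            rows.append({"concentration_nM": float(c), "binding": float(v)})
    df = pd.DataFrame(rows)
    gt = GroundTruth(isotherm_params=(b_max, k_d, h),
                     binding_true=hill_langmuir(np.asarray(concs, float), b_max, k_d, h))
    return df, gt


def render_guv(
    rim_binding: float,
    radius_px: float = 30.0,
    fov: Tuple[int, int, int] = (9, 96, 96),
    rim_width: float = 3.0,
    solution_level: float = 0.05,
    noise: Optional[NoiseSpec] = None,
    seed: int = 0,
) -> ImageStack:
    """Render a spherical-shell GUV: constant membrane-dye rim plus a protein
    channel whose rim intensity equals ``rim_binding``."""
    rng = np.random.default_rng(seed)
    nz, ny, nx = fov
    centre = (nz / 2.0 - 0.5, ny / 2.0 - 0.5, nx / 2.0 - 0.5)
    rz = min(radius_px, nz / 2.0 - 1.0)
    outer = _ellipsoid_mask(fov, centre, (rz, radius_px, radius_px))
    inner = _ellipsoid_mask(fov, centre, (rz - rim_width, radius_px - rim_width, radius_px - rim_width))
    shell = outer & ~inner
    mem = np.where(shell, 1.0, 0.0)
    prot = np.full(fov, solution_level)
    prot[shell] = rim_binding
    if noise is None:
        noise = NoiseSpec.none()
    data = np.stack([apply_noise(mem, noise, rng), apply_noise(prot, noise, rng)])[None]
    return ImageStack(data=data, voxel_size=(1.0, 0.3, 0.3),
                      channel_roles={0: "guv_membrane", 1: "protein"})


# ---------------------------------------------------------------------------
# FLIP
# ---------------------------------------------------------------------------

def synth_flip_experiment(
    connected: bool,
    n_cycles: int = 15,
    exchange_rate: float = 0.3,
    noise_sd: float = 0.01,
    seed: int = 0,
):
    """Two-pool FLIP model: a bleach-site pool and a measured (opposite) pool.

    Each bleach cycle zeroes the bleach-site pool; between cycles the two
    pools exchange a fraction ``exchange_rate`` of their contents if the
    compartments are connected, and evolve independently otherwise, so the
    measured pool follows m_{k+1} = (1 - r) m_k under connectivity.  The
    control-cell trace stays at baseline up to noise.
    """
    from .flip import FlipExperiment

    if not 0.0 <= exchange_rate <= 1.0:
        raise ValidationError(f"exchange_rate must lie in [0,1], got {exchange_rate}")
    rng = np.random.default_rng(seed)
    r = exchange_rate if connected else 0.0
    b, m = 1.0, 1.0
    bleach_trace, measured_trace = [b], [m]
    schedule = []
    for k in range(n_cycles):
        schedule.append(k + 1)
        b = 0.0                                   # bleach event
        b, m = r * m, (1.0 - r) * m               # exchange moves fraction r of m into b
        bleach_trace.append(b)
        measured_trace.append(m)
    frames = len(bleach_trace)
    noise = lambda: rng.normal(0.0, noise_sd, size=frames)  # noqa: E731
    traces = {
        "bleach_site": np.clip(np.asarray(bleach_trace) + noise(), 0, None),
        "median_axis_site": np.clip((np.asarray(bleach_trace) + np.asarray(measured_trace)) / 2 + noise(), 0, None),
        "opposite_site": np.clip(np.asarray(measured_trace) + noise(), 0, None),
        "nuclear_mask": np.clip(np.asarray(measured_trace) + noise(), 0, None),
        "control_cell": np.clip(1.0 + noise(), 0, None),
    }
    exp = FlipExperiment(traces=traces, bleach_schedule=schedule)
    gt = GroundTruth(connected=connected, exchange_rate=exchange_rate)
    return exp, gt
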