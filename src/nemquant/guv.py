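"""GUV rim-binding quantification and Hill-Langmuir isotherm fitting.

A user line from the GUV centre to its edge defines a square crop; the
membrane channel is segmented per slice, the slice with the largest GUV
area becomes the middle section, and protein binding is the median
intensity along a 3-px-wide rim contour there, normalized by a reference
signal (a 1 uM protein solution in the source assay).  Equilibrium
titrations are then fit with

    B_bound(c) = B_max * c^H / (c^H + Kd'^H)

by bounded nonlinear least squares; at c = Kd' the model gives B_max/2
for any Hill coefficient H.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.optimize import curve_fit
from scipy.stats import t as t_dist
from skimage import filters, morphology

from ._util import remove_small
from .errors import ValidationError
from .io import ImageStack
from .nuclei import _membrane_contour, _mid_slice
from .synth import hill_langmuir

__all__ = [
    "GUVMeasurement",
    "IsothermFit",
    "extract_guv",
    "guv_rim_binding",
    "fit_isotherm",
    "isotherm_predict",
]


@dataclass
class GUVMeasurement:
    guv_id: int
    concentration_nM: float
    rim_median: float
    normalized_binding: float
    valid: bool = True


@dataclass
class IsothermFit:
    b_max: float
    k_d: float          # apparent dissociation constant, nM
    hill: float         # apparent Hill coefficient
    ci_b_max: Tuple[float, float]
    ci_k_d: Tuple[float, float]
    ci_hill: Tuple[float, float]
    rss: float
    n: int
    converged: bool
    message: str = ""

    def __post_init__(self) -> None:
        if self.converged:
            assert self.ci_b_max[0] <= self.b_max <= self.ci_b_max[1]
            assert self.ci_k_d[0] <= self.k_d <= self.ci_k_d[1]
            assert self.ci_hill[0] <= self.hill <= self.ci_hill[1]


# ---------------------------------------------------------------------------
# image-side quantification
# ---------------------------------------------------------------------------

def extract_guv(
    stack: ImageStack,
    user_line: Tuple[Tuple[float, float], Tuple[float, float]],
    crop_factor: float = 2.4,
) -> ImageStack:
    """Crop one GUV given a user line from its centre to its edge.

    The crop window is a square of side ``crop_factor`` times the line
    length, centred on the line origin, clipped to the image.
    """
    (y0, x0), (y1, x1) = user_line
    ny, nx = stack.data.shape[-2:]
    for y, x in user_line:
        if not (0 <= y < ny and 0 <= x < nx):
            raise ValidationError(f"line endpoint ({y}, {x}) lies outside the image")
    length = float(np.hypot(y1 - y0, x1 - x0))
    if length <= 0:
        raise ValidationError("degenerate (zero-length) user line")
    half = crop_factor * length / 2.0
    ys = slice(max(0, int(round(y0 - half))), min(ny, int(round(y0 + half))))
    xs = slice(max(0, int(round(x0 - half))), min(nx, int(round(x0 + half))))
    return ImageStack(
        data=stack.data[:, :, :, ys, xs],
        voxel_size=stack.voxel_size,
        time_interval=stack.time_interval,
        channel_roles=dict(stack.channel_roles),
        condition=stack.condition,
    )


def guv_rim_binding(
    cropped: ImageStack,
    reference_signal: float,
    membrane_channel: str = "guv_membrane",
    protein_channel: str = "protein",
    guv_id: int = 0,
    concentration_nM: float = 0.0,
    gaussian_radius_px: float = 3.0,
    contour_width_px: int = 3,
) -> GUVMeasurement:
    """Median protein intensity along the GUV rim, over the reference signal.

    The membrane channel is blurred (3-px 3-D Gaussian) and segmented per
    slice (Otsu + hole fill); the slice with the largest GUV area is the
    middle section, a 3-px boundary-centred contour is transferred to the
    protein channel and its median is divided by ``reference_signal``.
    Ratio invariance: scaling protein image and reference together leaves
    the result unchanged.
    """
    if reference_signal <= 0:
        raise ValidationError(f"reference_signal must be positive, got {reference_signal}")
    mem = cropped.channel(membrane_channel)[0].astype(float)
    prot = cropped.channel(protein_channel)[0].astype(float)
    smoothed = ndi.gaussian_filter(mem, sigma=gaussian_radius_px)
    mask3d = np.zeros(smoothed.shape, bool)
    for z in range(smoothed.shape[0]):
        sl = smoothed[z]
        if sl.max() <= sl.min():
            continue
        try:
            thr = filters.threshold_otsu(sl)
        except ValueError:
            continue
        m = ndi.binary_fill_holes(sl > thr)
        mask3d[z] = remove_small(m, 16)
    if not mask3d.any():
        return GUVMeasurement(guv_id=guv_id, concentration_nM=concentration_nM,
                              rim_median=np.nan, normalized_binding=np.nan, valid=False)
    zmid = _mid_slice(mask3d)
    # the segmentation boundary can sit a pixel or two off the rim, so the
    # contour is anchored to the membrane dye itself: a band around the
    # boundary restricted to bright membrane pixels
    band = morphology.dilation(
        _membrane_contour(mask3d[zmid], width=2 * contour_width_px + 1, inset_px=0),
        morphology.disk(1))
    mem_mid = mem[zmid]
    in_band = mem_mid[band]
    contour = band & (mem_mid > in_band.max() * 0.5) if in_band.size else band
    if not contour.any():
        contour = band
    rim_median = float(np.median(prot[zmid][contour]))
    return GUVMeasurement(guv_id=guv_id, concentration_nM=concentration_nM,
                          rim_median=rim_median,
                          normalized_binding=rim_median / reference_signal)


# ---------------------------------------------------------------------------
# isotherm fitting
# ---------------------------------------------------------------------------

def _init_guess(c: np.ndarray, b: np.ndarray) -> Tuple[float, float]:
    """B_max0 = max per-concentration mean; Kd'0 = concentration at
    interpolated half-max of those means."""
    df = pd.DataFrame({"c": c, "b": b}).groupby("c")["b"].mean()
    b_max0 = float(df.max())
    half = b_max0 / 2.0
    cs, bs = df.index.to_numpy(float), df.to_numpy(float)
    k0 = float(cs[-1] / 2.0) if cs[-1] > 0 else 1.0
    above = np.nonzero(bs >= half)[0]
    if len(above) and above[0] > 0:
        i = above[0]
        c1, c2, b1, b2 = cs[i - 1], cs[i], bs[i - 1], bs[i]
        if b2 > b1:
            k0 = c1 + (half - b1) * (c2 - c1) / (b2 - b1)
    elif len(above):
        k0 = max(cs[above[0]], 1.0)
    return b_max0, max(k0, 1e-3)


def fit_isotherm(
    measurements: pd.DataFrame | Sequence[GUVMeasurement],
    hill_bounds: Tuple[float, float] = (0.5, 4.0),
    conc_col: str = "concentration_nM",
    binding_col: str = "binding",
) -> IsothermFit:
    """Bounded nonlinear least-squares fit of the Hill-Langmuir isotherm.

    Requires >= 4 distinct concentrations.  Fits per-GUV measurements
    unweighted.  95% CIs come from the parameter covariance (t-based).
    A degenerate titration (e.g. all-zero binding) returns a
    non-converged fit with diagnostics instead of raising.
    """
    if not isinstance(measurements, pd.DataFrame):
        measurements = pd.DataFrame([
            {conc_col: m.concentration_nM, binding_col: m.normalized_binding}
            for m in measurements if m.valid
        ])
    c = measurements[conc_col].to_numpy(float)
    b = measurements[binding_col].to_numpy(float)
    ok = np.isfinite(c) & np.isfinite(b)
    c, b = c[ok], b[ok]
    if len(np.unique(c)) < 4:
        raise ValidationError(
            f"need >= 4 distinct concentrations, got {len(np.unique(c))}")
    failed = IsothermFit(b_max=np.nan, k_d=np.nan, hill=np.nan,
                         ci_b_max=(np.nan, np.nan), ci_k_d=(np.nan, np.nan),
                         ci_hill=(np.nan, np.nan), rss=np.nan, n=len(b),
                         converged=False)
    if b.max() <= 0:
        failed.message = "no positive binding signal"
        return failed
    b_max0, k0 = _init_guess(c, b)
    lo_h, hi_h = hill_bounds
    try:
        popt, pcov = curve_fit(
            hill_langmuir, c, b,
            p0=[max(b_max0, 1e-6), k0, 1.0],
            bounds=([1e-9, 1e-9, lo_h], [np.inf, np.inf, hi_h]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        failed.message = f"fit did not converge: {exc}"
        return failed
    resid = b - hill_langmuir(c, *popt)
    rss = float(resid @ resid)
    dof = max(len(b) - 3, 1)
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    tcrit = t_dist.ppf(0.975, dof)
    cis = [(float(p - tcrit * s), float(p + tcrit * s)) for p, s in zip(popt, se)]
    return IsothermFit(
        b_max=float(popt[0]), k_d=float(popt[1]), hill=float(popt[2]),
        ci_b_max=cis[0], ci_k_d=cis[1], ci_hill=cis[2],
        rss=rss, n=len(b), converged=True,
    )


def isotherm_predict(fit: IsothermFit, concentration) -> np.ndarray | float:
    """Evaluate the fitted isotherm; strictly increasing in c, bounded by B_max."""
    if not fit.converged:
        raise ValidationError("cannot predict from a non-converged fit")
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise ValidationError("concentration must be non-negative")
    return hill_langmuir(concentration, fit.b_max, fit.k_d, fit.hill)
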