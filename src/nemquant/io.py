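"""Image-stack and table I/O.

In memory every stack is a 5-axis array ordered ``(time, channel, plane,
row, column)`` -- abbreviated TCZYX -- with 0-based indices.  Lower-rank
TIFFs are promoted on read by inserting length-1 axes.  Voxel sizes are
mandatory metadata (raw pixel sizes differ per microscope, so none is ever
guessed); they are carried in the TIFF description on write and recovered
on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile

from .errors import ValidationError

__all__ = [
    "CHANNEL_ROLES",
    "ConditionMeta",
    "ImageStack",
    "read_stack",
    "write_stack",
    "write_table",
]

#: Recognized channel roles.
CHANNEL_ROLES = (
    "ne_marker",    # nuclear-envelope marker (e.g. eGFP-Lmnb1)
    "sensor",       # nucleoplasmic tension sensor (cPla2-mKate2 / ALPIN)
    "er_lumen",     # luminal ER marker (eGFP-KDEL)
    "er_membrane",  # ER membrane marker (eGFP-SEC61B)
    "lysis_dye",    # plasma-membrane integrity dye (Sytox blue)
    "guv_membrane", # GUV membrane dye (Liss Rhod PE)
    "protein",      # soluble protein channel in GUV assays
)

_DESC_KEY = "nemquant"


@dataclass
class ConditionMeta:
    """Experimental condition attached to a stack.

    delta_pi
        Osmotic differential (mOsm), >= 0.
    ca_conc
        Free Ca2+ concentration (uM).
    pvp_percent
        Colloid (PVP360) concentration (%).
    treatment
        Free-text treatment label (e.g. "ML162", "latrunculin").
    """

    delta_pi: Optional[float] = None
    ca_conc: Optional[float] = None
    pvp_percent: Optional[float] = None
    treatment: str = ""
    is_baseline_control: bool = False

    def __post_init__(self) -> None:
        for name in ("delta_pi", "ca_conc", "pvp_percent"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be non-negative, got {v}")


@dataclass
class ImageStack:
    """A 5-axis (t, c, z, y, x) fluorescence intensity grid with metadata."""

    data: np.ndarray
    voxel_size: Tuple[float, float, float]  # (dz, dy, dx) in um
    time_interval: float = 1.0              # frame spacing (caller-defined unit)
    channel_roles: Dict[int, str] = field(default_factory=dict)
    condition: ConditionMeta = field(default_factory=ConditionMeta)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValidationError(f"stack data must be 5-D (t,c,z,y,x), got {self.data.ndim}-D")
        if any(s < 1 for s in self.data.shape):
            raise ValidationError("every stack axis must have length >= 1")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("stack contains non-finite values")
        if np.any(self.data < 0):
            raise ValidationError("stack intensities must be non-negative")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValidationError(f"voxel_size must be 3 strictly positive values, got {self.voxel_size}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        roles = list(self.channel_roles.values())
        if len(roles) != len(set(roles)):
            raise ValidationError(f"duplicate channel roles: {roles}")
        for c, role in self.channel_roles.items():
            if role not in CHANNEL_ROLES:
                raise ValidationError(f"unknown channel role {role!r}")
            if not 0 <= c < self.n_channels:
                raise ValidationError(f"channel index {c} outside 0..{self.n_channels - 1}")

    # -- convenience accessors -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def channel_index(self, role: str) -> int:
        """Index of the channel with the given role."""
        for c, r in self.channel_roles.items():
            if r == role:
                return c
        raise ValidationError(f"stack has no channel with role {role!r}")

    def channel(self, role: str) -> np.ndarray:
        """(t, z, y, x) view of the channel with the given role."""
        return self.data[:, self.channel_index(role)]


def _promote(data: np.ndarray, axes: Optional[str]) -> np.ndarray:
    """Promote a 2-5 D array to TCZYX, inserting length-1 axes."""
    if axes is None:
        axes = {2: "YX", 3: "ZYX", 4: "CZYX", 5: "TCZYX"}.get(data.ndim)
    if axes is None:
        raise ValidationError(f"cannot interpret a {data.ndim}-D image as a stack")
    axes = axes.upper()
    if len(axes) != data.ndim or any(a not in "TCZYX" for a in axes):
        raise ValidationError(f"invalid axes string {axes!r} for {data.ndim}-D data")
    out = data
    for i, a in enumerate("TCZYX"):
        if a not in axes:
            out = np.expand_dims(out, i)
            axes = axes[:i] + a + axes[i:]
    order = [axes.index(a) for a in "TCZYX"]
    return np.transpose(out, order)


def read_stack(
    path: str | Path,
    role_map: Optional[Dict[int, str]] = None,
    voxel_size: Optional[Tuple[float, float, float]] = None,
    time_interval: Optional[float] = None,
    axes: Optional[str] = None,
) -> ImageStack:
    """Read a TIFF / OME-TIFF into a canonical (t, c, z, y, x) stack.

    Metadata written by :func:`write_stack` is recovered from the file;
    explicit arguments override it.  For foreign TIFFs ``voxel_size`` is
    required and axes default by rank (2D->YX, 3D->ZYX, 4D->CZYX, 5D->TCZYX)
    unless tifffile reports an axes string.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        file_axes = series.axes if set(series.axes) <= set("TCZYX") else None
        meta = {}
        desc = tf.pages[0].description or ""
        if _DESC_KEY in desc:
            try:
                meta = json.loads(desc).get(_DESC_KEY, {})
            except (json.JSONDecodeError, AttributeError):
                meta = {}
    data = _promote(data, axes or meta.get("axes") or file_axes)
    roles = role_map if role_map is not None else {int(k): v for k, v in meta.get("channel_roles", {}).items()}
    vsize = voxel_size if voxel_size is not None else meta.get("voxel_size")
    if vsize is None:
        raise ValidationError(f"{path}: voxel size is mandatory metadata and the file carries none")
    dt = time_interval if time_interval is not None else meta.get("time_interval", 1.0)
    cond = ConditionMeta(**meta.get("condition", {})) if "condition" in meta else ConditionMeta()
    return ImageStack(data=data, voxel_size=tuple(vsize), time_interval=dt,
                      channel_roles=roles, condition=cond)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as TIFF with the package's metadata in the description."""
    meta = {
        _DESC_KEY: {
            "axes": "TCZYX",
            "voxel_size": list(stack.voxel_size),
            "time_interval": stack.time_interval,
            "channel_roles": {str(k): v for k, v in stack.channel_roles.items()},
            "condition": {
                "delta_pi": stack.condition.delta_pi,
                "ca_conc": stack.condition.ca_conc,
                "pvp_percent": stack.condition.pvp_percent,
                "treatment": stack.condition.treatment,
                "is_baseline_control": stack.condition.is_baseline_control,
            },
        }
    }
    tifffile.imwrite(Path(path), stack.data, description=json.dumps(meta),
                     photometric="minisblack")


def write_table(records: Sequence[dict] | pd.DataFrame, path: str | Path) -> None:
    """Write keyed measurement records as UTF-8 CSV with a header row.

    Values round-trip at full precision ('.' decimal separator).  An empty
    record list with a known schema yields a header-only file.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    df.to_csv(Path(path), index=False, encoding="utf-8", float_format="%.17g")
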