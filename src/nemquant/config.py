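"""Pipeline configuration.

Every tunable used by the analysis stages lives in :class:`AnalysisConfig`
with the defaults the pipeline was designed around: a 3-pixel-wide
membrane/background contour, a filament-filter thickness of 1.6 (~3-4 px),
an 8,000 px^2 minimum nuclear mid-slice area, a 130 px frame-to-frame
displacement cutoff, and a 40 px^2 small-ER-object cutoff.  Configs
round-trip losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import yaml

from .errors import ConfigError

__all__ = ["AnalysisConfig", "load_config", "save_config"]


@dataclass
class AnalysisConfig:
    # preprocessing
    gaussian_radius_px: float = 1.0      # 3-D blur radius for nuclei / ER channels
    guv_gaussian_radius_px: float = 3.0  # 3-D blur radius for GUV crops
    rollball_radius_px: float = 50.0     # per-slice rolling-ball background radius
    clip_percentiles: Tuple[float, float] = (0.5, 99.5)

    # nuclear measurement
    contour_width_px: int = 3            # membrane & background contour width
    centre_ring_fraction: float = 0.2    # background ring radius / equivalent radius
    min_area_px2: float = 8000.0         # mid-slice size exclusion
    max_jump_px: float = 130.0           # frame-to-frame displacement exclusion
    max_link_px: float = 130.0           # tracker nominal link distance
    jump_link_factor: float = 4.0        # links up to factor*max_link are made but flagged

    # lamina fold counting
    filament_thickness: float = 1.6      # ridge-filter scale (~3-4 px structures)
    branch_neighbour_threshold: int = 3  # skeleton neighbours defining a junction
    condense_radius_px: float = 4.0      # single-linkage merge radius for branch points

    # ER morphometrics
    er_min_area_px2: float = 40.0        # small-vesicle cutoff (stated range 30-50 px^2)
    circularity_clip: float = 1.05       # rasterization tolerance on 4*pi*A/P^2

    # GUV binding
    guv_crop_factor: float = 2.4         # crop side = factor * user line length
    hill_bounds: Tuple[float, float] = (0.5, 4.0)

    # FLIP
    roi_diameter_um: float = 5.0
    bleach_radius_um: float = 2.5

    # statistics
    alpha: float = 0.05                  # gate level for Shapiro-Wilk / Levene
    rate_window_min: Tuple[float, float] = (4.0, 5.0)

    # connectivity conventions
    connectivity_2d: int = 2             # skimage ndim-connectivity: 2 -> 8-connected
    connectivity_3d: int = 3             # 3 -> 26-connected

    seed: int = 0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not isinstance(v, bool):
                if f.name != "seed" and v <= 0 and f.name not in ("alpha",):
                    raise ConfigError(f"config field {f.name!r} must be strictly positive, got {v}")
        lo, hi = self.hill_bounds
        if not 0 < lo < hi:
            raise ConfigError(f"hill_bounds must be increasing and positive, got {self.hill_bounds}")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


_TUPLE_FIELDS = {"clip_percentiles", "hill_bounds", "rate_window_min"}
_KNOWN_KEYS = {f.name for f in dataclasses.fields(AnalysisConfig)}


def load_config(path: Optional[str | Path] = None) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from YAML.

    Keys absent from the file keep their defaults; unknown keys raise
    :class:`ConfigError` naming the offending key.  ``path=None`` returns
    the default configuration.
    """
    if path is None:
        return AnalysisConfig()
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed config file {path}: {exc}") from exc
    if raw is None:
        return AnalysisConfig()
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    unknown = sorted(set(raw) - _KNOWN_KEYS)
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {', '.join(unknown)}")
    kwargs = {}
    for k, v in raw.items():
        if k in _TUPLE_FIELDS and isinstance(v, (list, tuple)):
            v = tuple(v)
        kwargs[k] = v
    return AnalysisConfig(**kwargs)


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    """Serialize a config to YAML such that :func:`load_config` round-trips it."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
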