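"""Pipeline configuration: defaults, YAML overlay, validation, fingerprint.

Every tunable of the detection pipeline lives here with its default.  A YAML
file may override any subset; unknown keys and out-of-range values are
rejected with the offending key named.  The fingerprint is a stable hash of
the canonicalized configuration, recorded in every detection report so runs
are attributable to an exact parameterization.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from typing import Any, Mapping

import yaml

from .errors import ConfigError

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class ResizeConfig:
    #: standard working height in pixels; every image is scaled to this height
    height: int = 565


@dataclass(frozen=True)
class NormalizeConfig:
    #: disc SE radius for the bottom-hat term (fills dark thin structures)
    theta_radius: int = 8
    #: disc SE radius for the morphological opening term
    sigma_radius: int = 8
    #: side of the square average filter estimating the illumination background
    bg_filter: int = 89


@dataclass(frozen=True)
class ODConfig:
    #: fraction of max(Ic) used to binarize for the coarse disc candidate
    candidate_threshold: float = 0.89
    #: disc SE radius of the closing applied to the Otsu mask of the OD ROI
    close_radius: int = 10
    #: disc SE radius of the opening that follows the closing
    open_radius: int = 15
    #: disc SE radius of the grayscale opening that removes vessels pre-Otsu
    vessel_open_radius: int = 8
    #: DD = FOV width / dd_divisor
    dd_divisor: float = 12.0
    #: use the measured disc-blob width as DD instead of FOV/dd_divisor
    use_measured_dd: bool = False
    clahe_clip: float = 1.0
    clahe_tiles: tuple[int, int] = (8, 8)


@dataclass(frozen=True)
class TemporalConfig:
    #: disc SE radius of the bottom-hat emphasizing vessels on the disc
    bottomhat_radius: int = 5
    #: (rows, cols) of the opening SE that keeps vertically elongated vessels
    open_se: tuple[int, int] = (15, 1)
    #: (rows, cols) of the closing SE that consolidates the survivors
    close_se: tuple[int, int] = (50, 15)
    #: minimum raw bottom-hat amplitude (gray levels) for a crop to count
    #: as containing vessels at all; below it the mask is empty
    min_vessel_contrast: float = 16.0
    clahe_clip: float = 1.0
    clahe_tiles: tuple[int, int] = (8, 8)


@dataclass(frozen=True)
class RoiConfig:
    #: abscissa factor: macular ROI center sits p×DD temporal of the OD
    p: float = 3.8
    #: ordinate factor: ROI center sits q×DD below the OD
    q: float = 0.25
    #: box factor: ROI is a square of side r×DD
    r: float = 2.0
    # exhaustive tuner grids
    p_grid: tuple[float, ...] = (3.6, 3.8, 4.0)
    q_grid: tuple[float, ...] = (0.25, 0.5)
    r_grid: tuple[float, ...] = (2.0, 2.25, 2.5)


@dataclass(frozen=True)
class MaculaConfig:
    #: binarization threshold as a fraction of max(Im)
    tau_factor: float = 0.98
    clahe_clip: float = 1.0
    clahe_tiles: tuple[int, int] = (8, 8)
    #: disc SE radius for the dilation enlarging macular candidates
    dilate_radius: int = 5
    #: disc SE radius for the opening that follows
    open_radius: int = 5


@dataclass(frozen=True)
class EvalConfig:
    #: a detection within this many pixels of ground truth is correct
    radius: float = 50.0
    #: scale at which the radius applies: "original" or "resized"
    scale: str = "original"


@dataclass(frozen=True)
class PipelineConfig:
    resize: ResizeConfig = field(default_factory=ResizeConfig)
    normalize: NormalizeConfig = field(default_factory=NormalizeConfig)
    od: ODConfig = field(default_factory=ODConfig)
    temporal: TemporalConfig = field(default_factory=TemporalConfig)
    roi: RoiConfig = field(default_factory=RoiConfig)
    macula: MaculaConfig = field(default_factory=MaculaConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)
    #: where the values came from: a file path or "defaults"
    source: str = "defaults"

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("source")
        return d

    def fingerprint(self) -> str:
        """Stable hash of the canonicalized configuration."""
        canon = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def with_roi(self, p: float | None = None, q: float | None = None,
                 r: float | None = None) -> "PipelineConfig":
        """Copy with ROI placement factors overridden (tuner support)."""
        roi = self.roi
        roi = replace(roi,
                      p=roi.p if p is None else p,
                      q=roi.q if q is None else q,
                      r=roi.r if r is None else r)
        return replace(self, roi=roi)


# key -> (validator, message); validators receive the final value
_RANGES: dict[str, tuple] = {
    "resize.height": (lambda v: v >= 1, "must be >= 1"),
    "normalize.theta_radius": (lambda v: v >= 1, "must be >= 1"),
    "normalize.sigma_radius": (lambda v: v >= 1, "must be >= 1"),
    "normalize.bg_filter": (lambda v: v >= 1 and v % 2 == 1, "must be odd and >= 1"),
    "od.candidate_threshold": (lambda v: 0 < v <= 1, "must be in (0, 1]"),
    "od.dd_divisor": (lambda v: v > 0, "must be > 0"),
    "macula.tau_factor": (lambda v: 0 < v <= 1, "must be in (0, 1]"),
    "evaluation.radius": (lambda v: v > 0, "must be > 0"),
    "evaluation.scale": (lambda v: v in ("original", "resized"),
                         "must be 'original' or 'resized'"),
}

_TUPLE_FIELDS = {"clahe_tiles", "open_se", "close_se", "p_grid", "q_grid", "r_grid"}


def _overlay_section(section_name: str, section_obj: Any,
                     updates: Mapping[str, Any]) -> Any:
    if not isinstance(updates, Mapping):
        raise ConfigError(f"section '{section_name}' must be a mapping")
    valid = {f for f in section_obj.__dataclass_fields__}
    kwargs = {}
    for key, value in updates.items():
        if key not in valid:
            raise ConfigError(f"unknown config key '{section_name}.{key}'")
        if key in _TUPLE_FIELDS:
            value = tuple(value)
        kwargs[key] = value
    return replace(section_obj, **kwargs)


def _validate(cfg: PipelineConfig) -> None:
    for dotted, (check, msg) in _RANGES.items():
        section, key = dotted.split(".")
        value = getattr(getattr(cfg, section), key)
        if not check(value):
            raise ConfigError(f"config key '{dotted}' = {value!r}: {msg}")


def load_config(path: str | None = None) -> PipelineConfig:
    """Load the pipeline configuration, overlaying a YAML file on defaults.

    Parameters
    ----------
    path:
        Optional YAML file.  Top-level keys are section names (``resize``,
        ``normalize``, ``od``, ``temporal``, ``roi``, ``macula``,
        ``evaluation``); each maps setting names to values.  Unknown keys
        raise :class:`~maculoc.errors.ConfigError`.
    """
    cfg = PipelineConfig()
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ConfigError("config file must contain a mapping at top level")
        sections = {}
        for name, updates in data.items():
            if not hasattr(cfg, name) or name == "source":
                raise ConfigError(f"unknown config section '{name}'")
            sections[name] = _overlay_section(name, getattr(cfg, name), updates)
        cfg = replace(cfg, source=str(path), **sections)
    _validate(cfg)
    return cfg
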