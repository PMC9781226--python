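"""Detection reports, JSON round-tripping, image I/O and overlay rendering.

A :class:`DetectionReport` is the structured outcome of the end-to-end
pipeline: either every landmark (disc center, DD, temporal direction,
macular center at both scales) or a failure attributed to the stage that
could not produce its output.  Reports serialize losslessly to JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
from skimage import draw

from .errors import InvalidInputError, ReportParseError

log = logging.getLogger(__name__)

__all__ = ["DetectionReport", "write_report", "read_report",
           "load_image", "save_image", "render_overlay"]

_RED = (220, 30, 30)
_YELLOW = (240, 220, 40)
_CYAN = (60, 200, 220)


@dataclass(frozen=True)
class DetectionReport:
    """Outcome of one end-to-end macular-center detection."""

    file: str
    status: str                      # "ok" or "failed:<stage>"
    od: dict | None = None           # {x, y, dd, v_prime}
    temporal: dict | None = None     # {direction, left_count, right_count}
    macula: dict | None = None       # {x, y, x_original, y_original, tau, blob_area}
    roi: dict | None = None          # {x0, y0, side} in resized coordinates
    scale_factor: float = 1.0
    stages: dict = field(default_factory=dict)   # stage -> "ok" | error message
    config_fingerprint: str = ""
    message: str = ""

    @property
    def ok(self) -> bool:
        return self.status == "ok"

    @property
    def failed_stage(self) -> str | None:
        if self.status.startswith("failed:"):
            return self.status.split(":", 1)[1]
        return None

    def to_dict(self) -> dict:
        return {
            "file": self.file, "status": self.status, "od": self.od,
            "temporal": self.temporal, "macula": self.macula, "roi": self.roi,
            "scale_factor": self.scale_factor, "stages": self.stages,
            "config_fingerprint": self.config_fingerprint,
            "message": self.message,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DetectionReport":
        missing = {"file", "status"} - set(d)
        if missing:
            raise ReportParseError(f"report missing fields: {sorted(missing)}")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ReportParseError(f"report has unknown fields: {sorted(unknown)}")
        return cls(**d)


def write_report(report: DetectionReport, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
        fh.write("\n")


def read_report(path: str) -> DetectionReport:
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ReportParseError(
                f"{path}: malformed JSON at line {exc.lineno}, col {exc.colno}"
            ) from exc
    if not isinstance(data, dict):
        raise ReportParseError(f"{path}: expected a JSON object")
    return DetectionReport.from_dict(data)


def load_image(path: str) -> np.ndarray:
    """Read a PNG/TIFF/JPEG as H×W×3 uint8 RGB."""
    px = iio.imread(path)
    if px.ndim == 2:
        px = np.stack([px] * 3, axis=-1)
    if px.shape[-1] == 4:
        px = px[..., :3]
    if px.ndim != 3 or px.shape[-1] != 3:
        raise InvalidInputError(f"{path}: not an RGB image (shape {px.shape})")
    return px.astype(np.uint8)


def save_image(path: str, pixels: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(pixels, dtype=np.uint8))


def _stamp(img, rr, cc, color):
    keep = (rr >= 0) & (rr < img.shape[0]) & (cc >= 0) & (cc < img.shape[1])
    img[rr[keep], cc[keep]] = color


def render_overlay(image: np.ndarray, report: DetectionReport) -> np.ndarray:
    """Draw the detection on a copy of the *original-scale* image.

    Successful reports get a red '+' at the macular center, a cyan circle
    of diameter DD at the disc center and a yellow ROI box.  Failed reports
    get a red banner strip across the top; the rest of the image is
    untouched.
    """
    out = np.asarray(image, dtype=np.uint8).copy()
    if out.ndim != 3:
        raise InvalidInputError("overlay expects an RGB image")
    if not report.ok:
        out[: max(4, out.shape[0] // 40), :] = _RED
        return out

    s = report.scale_factor or 1.0
    mx = int(round(report.macula["x_original"]))
    my = int(round(report.macula["y_original"]))
    arm = max(5, out.shape[0] // 40)
    for t in range(2):  # 2-px-thick cross
        _stamp(out, np.arange(my - arm, my + arm + 1),
               np.full(2 * arm + 1, mx + t), _RED)
        _stamp(out, np.full(2 * arm + 1, my + t),
               np.arange(mx - arm, mx + arm + 1), _RED)

    ox = int(round(report.od["x"] / s))
    oy = int(round(report.od["y"] / s))
    radius = max(2, int(round(report.od["dd"] / (2 * s))))
    rr, cc = draw.circle_perimeter(oy, ox, radius, shape=out.shape[:2])
    out[rr, cc] = _CYAN

    if report.roi is not None:
        x0 = int(round(report.roi["x0"] / s))
        y0 = int(round(report.roi["y0"] / s))
        side = int(round(report.roi["side"] / s))
        rr, cc = draw.rectangle_perimeter((y0, x0), extent=(side, side),
                                          shape=out.shape[:2])
        out[rr, cc] = _YELLOW
    return out
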