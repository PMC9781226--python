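"""Optic-disc localization and disc-diameter estimation.

The optic disc is the bright circular entry point of the optic nerve; it
anchors all downstream geometry.  Localization runs in two stages:

1. *Coarse candidate* — the illumination-normalized image ``Ic`` is
   binarized at 0.89 × max(Ic); the centroid of the largest connected
   component is the disc candidate.
2. *Refinement* — a (w'/4 × h'/4) region around the candidate is cropped
   from the red channel (disc bright, vessels faint there), enhanced with
   CLAHE, opened to suppress residual vessels, Otsu-binarized, then cleaned
   with a closing (radius 10) and an opening (radius 15); the centroid of
   the surviving largest blob is the disc center.

The disc diameter DD — the retinal distance unit — is taken as v'/12 where
v' is the width of the camera field of view, measured by Otsu-segmenting
the grayscale image against the dark surround.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from skimage import filters, morphology

from ._util import binary_closing, binary_opening, clahe, largest_blob
from .config import PipelineConfig
from .errors import InvalidInputError, ODNotFoundError
from .preprocess import NormalizedImage, ResizedImage, channel, normalize_illumination

log = logging.getLogger(__name__)

__all__ = ["ODResult", "locate_od_candidate", "crop_od_roi", "segment_od",
           "estimate_disc_diameter", "localize_od"]


@dataclass(frozen=True)
class ODResult:
    """Optic-disc localization outcome, in resized-image coordinates."""

    center: tuple[float, float]      # (x, y) disc center
    DD: float                        # disc-diameter unit, pixels
    v_prime: float                   # FOV width, pixels
    od_crop: np.ndarray              # red-channel crop of the disc bounding box
    roi_box: tuple[int, int, int, int]   # (x0, y0, w, h) of the coarse ROI
    candidate_center: tuple[float, float]
    od_box: tuple[int, int, int, int]    # (x0, y0, w, h) disc blob bounding box


def locate_od_candidate(norm: NormalizedImage) -> tuple[float, float]:
    """Coarse disc candidate: centroid of the largest bright blob of Ic.

    Binarizes at ``candidate_threshold × max(Ic)`` (the max pixel always
    passes, so the foreground is never empty).  Equal-area ties go to the
    blob with brighter mean Ic, then to scan order.
    """
    cfg = PipelineConfig()
    Ic = norm.Ic
    tau = cfg.od.candidate_threshold * float(Ic.max())
    mask = Ic >= tau
    picked = largest_blob(mask, intensity=Ic)
    if picked is None:  # defensive; cannot happen since max(Ic) >= tau
        raise ODNotFoundError("empty foreground at the candidate threshold")
    _, (cx, cy), _ = picked
    return cx, cy


def crop_od_roi(red: np.ndarray,
                candidate: tuple[float, float]) -> tuple[np.ndarray, tuple]:
    """Crop a (w'/4 × h'/4) region of the red channel around the candidate.

    Returns ``(crop, roi_box)`` with ``roi_box = (x0, y0, width, height)``
    in full-image coordinates; the box is clipped at the image borders.
    """
    h, w = red.shape
    cx, cy = candidate
    if not (0 <= cx < w and 0 <= cy < h):
        raise InvalidInputError(f"candidate {candidate} outside {w}×{h} image")
    cw, ch = max(1, round(w / 4)), max(1, round(h / 4))
    x0 = int(np.clip(round(cx - cw / 2), 0, w - 1))
    y0 = int(np.clip(round(cy - ch / 2), 0, h - 1))
    x1 = min(w, x0 + cw)
    y1 = min(h, y0 + ch)
    crop = red[y0:y1, x0:x1].copy()
    return crop, (x0, y0, x1 - x0, y1 - y0)


def segment_od(crop: np.ndarray, cfg: PipelineConfig | None = None):
    """Segment the disc inside its ROI crop.

    CLAHE → grayscale opening (vessel suppression) → Otsu → binary closing
    (radius 10) → binary opening (radius 15) → largest blob.

    Returns ``(mask, center_in_crop, od_crop)`` where ``od_crop`` is the
    crop restricted to the blob's bounding box.  Raises
    :class:`ODNotFoundError` when no blob survives (degenerate or
    disc-free crops).
    """
    cfg = cfg or PipelineConfig()
    crop = np.asarray(crop, dtype=np.float64)
    if crop.size == 0:
        raise InvalidInputError("empty OD crop")
    if np.ptp(crop) == 0:
        raise ODNotFoundError("constant OD crop: Otsu threshold degenerate")

    enh = clahe(crop, cfg.od.clahe_clip, cfg.od.clahe_tiles)
    opened = morphology.opening(enh, morphology.disk(cfg.od.vessel_open_radius))
    if np.ptp(opened) == 0:
        raise ODNotFoundError("OD crop flat after vessel removal")
    mask = opened > filters.threshold_otsu(opened)
    mask = binary_closing(mask, morphology.disk(cfg.od.close_radius))
    mask = binary_opening(mask, morphology.disk(cfg.od.open_radius))

    picked = largest_blob(mask, intensity=crop)
    if picked is None:
        raise ODNotFoundError("no disc blob survived morphology")
    blob, center, _ = picked
    ys, xs = np.nonzero(blob)
    od_crop = crop[ys.min():ys.max() + 1, xs.min():xs.max() + 1]
    return blob, center, od_crop


def estimate_disc_diameter(gray: np.ndarray,
                           cfg: PipelineConfig | None = None) -> tuple[float, float]:
    """Estimate the disc-diameter unit DD and the FOV width v'.

    The grayscale image is Otsu-thresholded to separate the illuminated
    retina from the dark surround; v' is the bounding-box width of the
    largest component and DD = v' / dd_divisor.  If the segmented FOV is
    implausibly small (< 10% of the image) the full image width is used.
    """
    cfg = cfg or PipelineConfig()
    gray = np.asarray(gray, dtype=np.float64)
    h, w = gray.shape
    v_prime = float(w)
    if np.ptp(gray) > 0:
        mask = gray > filters.threshold_otsu(gray)
        picked = largest_blob(mask)
        if picked is not None and picked[2] >= 0.10 * gray.size:
            _, xs = np.nonzero(picked[0])
            v_prime = float(xs.max() - xs.min() + 1)
        else:
            warnings.warn("FOV segmentation too small; falling back to image width")
    else:
        warnings.warn("flat grayscale image; falling back to image width for FOV")
    DD = v_prime / cfg.od.dd_divisor
    if DD <= 1.0:
        warnings.warn(f"implausibly small disc diameter DD={DD:.2f}")
    return DD, v_prime


def localize_od(resized: ResizedImage,
                cfg: PipelineConfig | None = None,
                norm: NormalizedImage | None = None) -> ODResult:
    """Full disc localization on a resized image.

    Composes candidate → red-channel crop → segmentation → DD estimate and
    reports the disc center in full resized-image coordinates.
    """
    cfg = cfg or PipelineConfig()
    if norm is None:
        norm = normalize_illumination(channel(resized, "green"), cfg)
    candidate = locate_od_candidate(norm)
    red = channel(resized, "red")
    crop, roi_box = crop_od_roi(red, candidate)
    blob, (cx, cy), _ = segment_od(crop, cfg)
    center = (roi_box[0] + cx, roi_box[1] + cy)

    ys, xs = np.nonzero(blob)
    od_box = (roi_box[0] + int(xs.min()), roi_box[1] + int(ys.min()),
              int(xs.max() - xs.min() + 1), int(ys.max() - ys.min() + 1))

    gray = channel(resized, "gray")
    DD, v_prime = estimate_disc_diameter(gray, cfg)
    if cfg.od.use_measured_dd:
        DD = float(od_box[2])

    x0, y0, bw, bh = od_box
    od_crop = np.asarray(red[y0:y0 + bh, x0:x0 + bw], dtype=np.float64)
    log.debug("OD at (%.1f, %.1f), DD=%.2f, v'=%.0f", *center, DD, v_prime)
    return ODResult(center=center, DD=DD, v_prime=v_prime, od_crop=od_crop,
                    roi_box=roi_box, candidate_center=candidate, od_box=od_box)
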