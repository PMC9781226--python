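"""Macular ROI placement, macular-center extraction, and the end-to-end
detection driver.

The macular center sits about 2.5 disc diameters temporal of the optic disc
and slightly below it.  The search region is therefore placed purely
geometrically:

    xM = xOD ± p·DD   (− for temporal LEFT, + for RIGHT)
    yM = yOD + q·DD
    ROI = square of side r·DD centered on (xM, yM)

with defaults p = 3.8, q = 0.25, r = 2.0 chosen by exhaustive grid tuning
over p ∈ {3.6, 3.8, 4.0}, q ∈ {0.25, 0.5}, r ∈ {2.0, 2.25, 2.5}.

Inside the ROI the macula is the darkest compact region.  The ROI grayscale
is CLAHE-enhanced and complemented so the macula becomes the *brightest*
structure (Im); thresholding at τ = 0.98 × max(Im), dilating and opening,
and taking the largest blob's centroid yields the macular center.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from skimage import morphology

from ._util import binary_opening, clahe, largest_blob
from .config import PipelineConfig
from .errors import (InvalidInputError, MaculocError, RoiOutOfBoundsError)
from .io import DetectionReport
from .od import ODResult, localize_od
from .preprocess import (FundusImage, ResizedImage, channel,
                         normalize_illumination, resize_to_standard)
from .temporal import (Direction, TemporalDecision, determine_temporal_direction,
                       extract_od_vessels, suppress_horizontal_vessels)

log = logging.getLogger(__name__)

__all__ = ["MacularROI", "MaculaResult", "TuneReport", "determine_macular_roi",
           "extract_macular_center", "detect", "tune_roi_parameters"]


@dataclass(frozen=True)
class MacularROI:
    center: tuple[float, float]          # (xM, yM), unrounded
    side: float                          # r × DD before clipping
    box: tuple[int, int, int, int]       # (x0, y0, w, h) clipped to the image
    params: tuple[float, float, float]   # (p, q, r)


@dataclass(frozen=True)
class MaculaResult:
    center_resized: tuple[float, float]
    center_original: tuple[float, float]
    tau: float
    blob_area: int
    Im: np.ndarray


@dataclass(frozen=True)
class TuneReport:
    """Exhaustive grid-tuning outcome: one row per (p, q, r) combination."""

    grid: list  # of (p, q, r, accuracy_percent, mean_distance)
    best: tuple[float, float, float]
    criterion: str = "accuracy, then mean distance, then smaller r"


def determine_macular_roi(direction: Direction, od_center: tuple[float, float],
                          DD: float, p: float, q: float, r: float,
                          image_dims: tuple[int, int]) -> MacularROI:
    """Place the macular search box geometrically from the disc.

    ``image_dims`` is (width, height).  The box is clipped to the image;
    a box with no overlap at all raises :class:`RoiOutOfBoundsError`,
    which signals an upstream disc/direction failure.
    """
    if DD <= 0:
        raise InvalidInputError(f"DD must be positive, got {DD}")
    w, h = image_dims
    xod, yod = od_center
    xm = xod - p * DD if direction is Direction.LEFT else xod + p * DD
    ym = yod + q * DD
    side = r * DD

    x0 = int(round(xm - side / 2))
    y0 = int(round(ym - side / 2))
    x1 = int(round(xm + side / 2))
    y1 = int(round(ym + side / 2))
    cx0, cy0 = max(0, x0), max(0, y0)
    cx1, cy1 = min(w, x1), min(h, y1)
    if cx1 <= cx0 or cy1 <= cy0:
        raise RoiOutOfBoundsError(
            f"macular ROI centered at ({xm:.0f}, {ym:.0f}) lies outside the "
            f"{w}×{h} image"
        )
    return MacularROI(center=(xm, ym), side=side,
                      box=(cx0, cy0, cx1 - cx0, cy1 - cy0), params=(p, q, r))


def extract_macular_center(roi_gray: np.ndarray,
                           cfg: PipelineConfig | None = None) -> "MaculaResult":
    """Find the macular center inside the ROI.

    The ROI grayscale is CLAHE-enhanced (clip 1, 8×8 tiles); Im is its
    complement, so the dark macula is Im's brightest structure.  Pixels at
    or above τ = tau_factor × max(Im) are kept, dilated and opened (disc
    radius 5 each), and the largest blob's centroid is returned.  If
    nothing survives the morphology, the location of max(Im) is used and a
    warning is issued.

    Coordinates are relative to the ROI; the caller offsets them.
    """
    cfg = cfg or PipelineConfig()
    roi = np.asarray(roi_gray, dtype=np.float64)
    if roi.size == 0:
        raise InvalidInputError("empty macular ROI")
    enh = clahe(roi, cfg.macula.clahe_clip, cfg.macula.clahe_tiles)
    Im = 255.0 - enh
    tau = cfg.macula.tau_factor * float(Im.max())
    mask = Im >= tau
    mask = morphology.dilation(mask, morphology.disk(cfg.macula.dilate_radius)) > 0
    mask = binary_opening(mask, morphology.disk(cfg.macula.open_radius))

    picked = largest_blob(mask, intensity=Im)
    if picked is None:
        warnings.warn("macular morphology left no blob; falling back to max(Im)")
        ry, rx = np.unravel_index(int(np.argmax(Im)), Im.shape)
        return MaculaResult(center_resized=(float(rx), float(ry)),
                            center_original=(float(rx), float(ry)),
                            tau=tau, blob_area=1, Im=Im)
    _, (cx, cy), area = picked
    return MaculaResult(center_resized=(cx, cy), center_original=(cx, cy),
                        tau=tau, blob_area=area, Im=Im)


# ---------------------------------------------------------------------------
# end-to-end driver


def _front_end(resized: ResizedImage, cfg: PipelineConfig):
    """Stages shared by detection and tuning: normalize → disc → temporal."""
    norm = normalize_illumination(channel(resized, "green"), cfg)
    odres = localize_od(resized, cfg, norm=norm)
    x0, y0, bw, bh = odres.od_box
    green = channel(resized, "green")
    od_green = green[y0:y0 + bh, x0:x0 + bw]
    vessels = extract_od_vessels(od_green, cfg)
    vertical = suppress_horizontal_vessels(vessels, cfg)
    decision = determine_temporal_direction(vertical)
    return norm, odres, decision


def _place_and_extract(resized: ResizedImage, odres: ODResult,
                       decision: TemporalDecision, cfg: PipelineConfig,
                       scale_factor: float):
    """ROI placement + macular extraction; returns (roi, result)."""
    roi = determine_macular_roi(decision.direction, odres.center, odres.DD,
                                cfg.roi.p, cfg.roi.q, cfg.roi.r,
                                (resized.width, resized.height))
    gray = channel(resized, "gray")
    x0, y0, w, h = roi.box
    res = extract_macular_center(gray[y0:y0 + h, x0:x0 + w], cfg)
    rx, ry = res.center_resized
    cx, cy = x0 + rx, y0 + ry
    ox, oy = cx / scale_factor, cy / scale_factor
    res = MaculaResult(center_resized=(cx, cy), center_original=(ox, oy),
                       tau=res.tau, blob_area=res.blob_area, Im=res.Im)
    return roi, res


_STAGES = ("preprocess", "od_localizer", "temporal_director", "macular_locator")


def detect(img: FundusImage, cfg: PipelineConfig | None = None) -> DetectionReport:
    """Run the full pipeline on one image.

    Never raises on a valid image: any stage failure yields a report with
    ``status = "failed:<stage>"`` and the per-stage log in ``stages``.
    """
    cfg = cfg or PipelineConfig()
    stages: dict[str, str] = {}
    fp = cfg.fingerprint()

    def fail(stage: str, exc: Exception) -> DetectionReport:
        stages[stage] = f"error: {exc}"
        log.info("%s: failed at %s: %s", img.path, stage, exc)
        return DetectionReport(file=img.path, status=f"failed:{stage}",
                               stages=stages, config_fingerprint=fp,
                               message=str(exc))

    try:
        resized = resize_to_standard(img, cfg)
        norm = normalize_illumination(channel(resized, "green"), cfg)
        stages["preprocess"] = "ok"
    except MaculocError as exc:
        return fail("preprocess", exc)

    try:
        odres = localize_od(resized, cfg, norm=norm)
        stages["od_localizer"] = "ok"
    except MaculocError as exc:
        return fail("od_localizer", exc)

    try:
        x0, y0, bw, bh = odres.od_box
        od_green = channel(resized, "green")[y0:y0 + bh, x0:x0 + bw]
        vertical = suppress_horizontal_vessels(extract_od_vessels(od_green, cfg), cfg)
        decision = determine_temporal_direction(vertical)
        stages["temporal_director"] = "ok"
    except MaculocError as exc:
        return fail("temporal_director", exc)

    try:
        roi, res = _place_and_extract(resized, odres, decision, cfg,
                                      resized.scale_factor)
        stages["macular_locator"] = "ok"
    except MaculocError as exc:
        return fail("macular_locator", exc)

    return DetectionReport(
        file=img.path, status="ok",
        od={"x": odres.center[0], "y": odres.center[1],
            "dd": odres.DD, "v_prime": odres.v_prime},
        temporal={"direction": decision.direction.value,
                  "left_count": decision.left_count,
                  "right_count": decision.right_count},
        macula={"x": res.center_resized[0], "y": res.center_resized[1],
                "x_original": res.center_original[0],
                "y_original": res.center_original[1],
                "tau": res.tau, "blob_area": res.blob_area},
        roi={"x0": roi.box[0], "y0": roi.box[1], "side": roi.box[2]},
        scale_factor=resized.scale_factor, stages=stages,
        config_fingerprint=fp,
    )


def tune_roi_parameters(images_with_gt, p_set=None, q_set=None, r_set=None,
                        cfg: PipelineConfig | None = None,
                        radius: float | None = None) -> TuneReport:
    """Exhaustive grid search of the ROI placement factors.

    ``images_with_gt`` is a sequence of ``(FundusImage, (x_gt, y_gt))``
    pairs with ground truth at original scale.  Every (p, q, r) in the
    Cartesian product is scored by detection accuracy under the
    correctness radius; ties break by lower mean distance, then smaller r.
    The expensive front-end stages (disc, temporal direction) run once per
    image and are reused across the grid.
    """
    cfg = cfg or PipelineConfig()
    p_set = tuple(p_set if p_set is not None else cfg.roi.p_grid)
    q_set = tuple(q_set if q_set is not None else cfg.roi.q_grid)
    r_set = tuple(r_set if r_set is not None else cfg.roi.r_grid)
    radius = radius if radius is not None else cfg.evaluation.radius
    images_with_gt = list(images_with_gt)
    if not images_with_gt:
        raise InvalidInputError("tuner needs at least one annotated image")

    fronts = []   # (resized, odres, decision, gt) or (None, exc) on failure
    for img, gt in images_with_gt:
        resized = resize_to_standard(img, cfg)
        try:
            _, odres, decision = _front_end(resized, cfg)
            fronts.append((resized, odres, decision, gt))
        except MaculocError as exc:
            log.info("tuner: front-end failure on %s: %s", img.path, exc)
            fronts.append(None)

    grid = []
    for p, q, r in itertools.product(p_set, q_set, r_set):
        combo_cfg = cfg.with_roi(p=p, q=q, r=r)
        distances = []
        n_correct = 0
        for front in fronts:
            if front is None:
                continue  # front-end failure counts as incorrect
            resized, odres, decision, gt = front
            try:
                _, res = _place_and_extract(resized, odres, decision,
                                            combo_cfg, resized.scale_factor)
            except MaculocError:
                continue
            d = float(np.hypot(res.center_original[0] - gt[0],
                               res.center_original[1] - gt[1]))
            distances.append(d)
            if d < radius:
                n_correct += 1
        accuracy = 100.0 * n_correct / len(images_with_gt)
        mean_d = float(np.mean(distances)) if distances else float("inf")
        grid.append((p, q, r, accuracy, mean_d))

    best = min(grid, key=lambda row: (-row[3], row[4], row[2]))
    return TuneReport(grid=grid, best=(best[0], best[1], best[2]))
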