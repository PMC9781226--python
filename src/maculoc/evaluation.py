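"""Scoring detections against ground truth.

A detection is correct when its Euclidean distance to the annotated macular
center is strictly below the correctness radius (50 px by default, applied
at original image scale).  Failed detections count as incorrect — dropping
them would inflate accuracy.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .errors import InvalidInputError
from .io import DetectionReport

log = logging.getLogger(__name__)

__all__ = ["GroundTruthRecord", "EvaluationSummary", "euclidean_distance",
           "classify_detection", "evaluate_dataset", "read_ground_truth"]


@dataclass(frozen=True)
class GroundTruthRecord:
    """One annotated image: macular center (original scale), optional disc."""

    file: str
    macula: tuple[float, float]
    od: tuple[float, float] | None = None


@dataclass(frozen=True)
class EvaluationSummary:
    accuracy: float                 # percent correct over all matched images
    mean_distance: float            # mean over successful detections, px
    n_total: int
    n_correct: int
    n_failed: int                   # detections with a failure status
    distances: dict = field(default_factory=dict)    # file -> distance
    scatter: list = field(default_factory=list)      # (file, dx, dy, distance, correct)
    unmatched: list = field(default_factory=list)    # files with no GT record

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "mean_distance": self.mean_distance,
            "n_total": self.n_total, "n_correct": self.n_correct,
            "n_failed": self.n_failed, "distances": self.distances,
            "scatter": [list(row) for row in self.scatter],
            "unmatched": self.unmatched,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationSummary":
        d = dict(d)
        d["scatter"] = [tuple(row) for row in d.get("scatter", [])]
        return cls(**d)

    @classmethod
    def from_json(cls, path: str) -> "EvaluationSummary":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def euclidean_distance(system: tuple[float, float],
                       gt: tuple[float, float]) -> float:
    """Straight-line pixel distance between detection and ground truth."""
    return math.hypot(system[0] - gt[0], system[1] - gt[1])


def classify_detection(distance: float, radius: float = 50.0) -> bool:
    """True when the detection is correct: distance strictly below radius."""
    if distance < 0:
        raise InvalidInputError("distance must be non-negative")
    return distance < radius


def read_ground_truth(path: str) -> list[GroundTruthRecord]:
    """Read a GT CSV with header ``file,x,y[,od_x,od_y]`` (UTF-8)."""
    df = pd.read_csv(path)
    required = {"file", "x", "y"}
    if not required.issubset(df.columns):
        raise InvalidInputError(
            f"{path}: ground-truth CSV needs columns {sorted(required)}")
    records = []
    has_od = {"od_x", "od_y"}.issubset(df.columns)
    for row in df.itertuples(index=False):
        od = (float(row.od_x), float(row.od_y)) if has_od else None
        records.append(GroundTruthRecord(file=str(row.file),
                                         macula=(float(row.x), float(row.y)),
                                         od=od))
    return records


def evaluate_dataset(reports: list[DetectionReport],
                     gt_records: list[GroundTruthRecord],
                     radius: float = 50.0,
                     scale: str = "original") -> EvaluationSummary:
    """Score a batch of detection reports against ground-truth records.

    Reports are matched to records by file id; unmatched reports are
    listed and excluded from the totals with a warning.  Failed detections
    are scored incorrect and excluded from the mean distance.
    """
    gt_by_file = {rec.file: rec for rec in gt_records}
    unmatched, distances, scatter = [], {}, []
    n_correct = n_failed = n_total = 0
    for rep in reports:
        rec = gt_by_file.get(rep.file)
        if rec is None:
            unmatched.append(rep.file)
            continue
        n_total += 1
        if not rep.ok:
            n_failed += 1
            continue
        if scale == "resized":
            sys_xy = (rep.macula["x"], rep.macula["y"])
            gt_xy = (rec.macula[0] * rep.scale_factor,
                     rec.macula[1] * rep.scale_factor)
        else:
            sys_xy = (rep.macula["x_original"], rep.macula["y_original"])
            gt_xy = rec.macula
        d = euclidean_distance(sys_xy, gt_xy)
        correct = classify_detection(d, radius)
        n_correct += int(correct)
        distances[rep.file] = d
        scatter.append((rep.file, sys_xy[0] - gt_xy[0], sys_xy[1] - gt_xy[1],
                        d, bool(correct)))
    if unmatched:
        warnings.warn(f"{len(unmatched)} report(s) had no ground truth and "
                      f"were excluded: {unmatched[:5]}")
    accuracy = 100.0 * n_correct / n_total if n_total else 0.0
    mean_d = (sum(distances.values()) / len(distances)) if distances else 0.0
    return EvaluationSummary(accuracy=accuracy, mean_distance=mean_d,
                             n_total=n_total, n_correct=n_correct,
                             n_failed=n_failed, distances=distances,
                             scatter=scatter, unmatched=unmatched)
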