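"""Macular ROI placement, center extraction, end-to-end detection, tuning."""

import numpy as np
import pytest

from maculoc import (Direction, FundusImage, InvalidInputError,
                     RoiOutOfBoundsError, detect, determine_macular_roi,
                     extract_macular_center, tune_roi_parameters)
from maculoc.synthetic import SyntheticSpec, generate_fundus


class TestRoiPlacement:
    def test_left_direction_worked_example(self):
        roi = determine_macular_roi(Direction.LEFT, (300.0, 200.0), 40.0,
                                    3.8, 0.25, 2.0, (600, 565))
        assert roi.center == (148.0, 210.0)
        assert roi.side == 80.0

    def test_right_direction_mirrors_abscissa(self):
        roi = determine_macular_roi(Direction.RIGHT, (100.0, 200.0), 40.0,
                                    3.8, 0.25, 2.0, (600, 565))
        assert roi.center == (252.0, 210.0)

    def test_zero_offsets_center_roi_on_disc(self):
        roi = determine_macular_roi(Direction.LEFT, (300.0, 200.0), 40.0,
                                    0.0, 0.0, 2.0, (600, 565))
        assert roi.center == (300.0, 200.0)

    def test_roi_fully_outside_image_raises(self):
        with pytest.raises(RoiOutOfBoundsError):
            determine_macular_roi(Direction.RIGHT, (580.0, 200.0), 40.0,
                                  3.8, 0.25, 2.0, (600, 565))

    @pytest.mark.parametrize("p,q,r", [(3.6, 0.25, 2.0), (3.8, 0.5, 2.25),
                                       (4.0, 0.25, 2.5), (1.0, 1.0, 2.0)])
    def test_center_distance_is_dd_times_hypot_pq(self, p, q, r):
        od = (400.0, 300.0)
        DD = 45.0
        roi = determine_macular_roi(Direction.LEFT, od, DD, p, q, r, (800, 600))
        d = np.hypot(roi.center[0] - od[0], roi.center[1] - od[1])
        assert d == pytest.approx(DD * np.hypot(p, q), rel=1e-12)


class TestExtraction:
    def test_single_dark_spot_found(self):
        rng = np.random.default_rng(0)
        yy, xx = np.mgrid[0:80, 0:90]
        roi = 120.0 - 50.0 * np.exp(-(np.hypot(xx - 40, yy - 37) / 12) ** 2)
        roi += rng.normal(0, 1.0, roi.shape)
        res = extract_macular_center(np.clip(roi, 0, 255))
        assert np.hypot(res.center_resized[0] - 40,
                        res.center_resized[1] - 37) <= 3

    def test_threshold_is_098_of_maximum(self):
        rng = np.random.default_rng(1)
        yy, xx = np.mgrid[0:80, 0:90]
        roi = 120.0 - 50.0 * np.exp(-(np.hypot(xx - 40, yy - 37) / 12) ** 2)
        roi += rng.normal(0, 1.0, roi.shape)
        res = extract_macular_center(np.clip(roi, 0, 255))
        assert res.tau == pytest.approx(0.98 * res.Im.max())

    def test_larger_of_two_dark_blobs_wins(self):
        roi = np.full((100, 160), 200.0)
        roi[20:30, 20:30] = 0.0     # area 100
        roi[60:90, 100:130] = 0.0   # area 900
        res = extract_macular_center(roi)
        assert abs(res.center_resized[0] - 114.5) <= 3
        assert abs(res.center_resized[1] - 74.5) <= 3

    def test_empty_roi_rejected(self):
        with pytest.raises(InvalidInputError):
            extract_macular_center(np.zeros((0, 5)))


class TestDetect:
    def test_nominal_fixture_within_criterion(self, nominal_fundus):
        _, image, truth = nominal_fundus
        rep = detect(FundusImage(image, "nominal"))
        assert rep.ok
        d = np.hypot(rep.macula["x_original"] - truth.macula[0],
                     rep.macula["y_original"] - truth.macula[1])
        assert d < 50

    def test_detect_is_deterministic(self, nominal_fundus):
        _, image, _ = nominal_fundus
        a = detect(FundusImage(image, "x"))
        b = detect(FundusImage(image, "x"))
        assert a.to_dict() == b.to_dict()

    def test_bright_artifact_failure_names_stage(self):
        # a washed-out disc with lesions brighter than it: the disc
        # localizer must report failure rather than silently mislocate
        spec = SyntheticSpec(laterality="right", od_brightness=20.0,
                             gradient=34.0, noise_sigma=10.0,
                             macula_depth=12.0, n_lesions=3, seed=2)
        image, _ = generate_fundus(spec)
        rep = detect(FundusImage(image, "artifact"))
        if not rep.ok:
            assert rep.failed_stage in ("od_localizer", "temporal_director",
                                        "macular_locator")
            assert rep.stages  # per-stage attribution present

    def test_reports_both_scales(self, nominal_fundus):
        _, image, _ = nominal_fundus
        rep = detect(FundusImage(image, "x"))
        s = rep.scale_factor
        assert rep.macula["x"] == pytest.approx(rep.macula["x_original"] * s)
        assert rep.macula["y"] == pytest.approx(rep.macula["y_original"] * s)


class TestTuner:
    def test_grid_covers_full_cartesian_product(self, clean_suite):
        pairs = [(FundusImage(img, f"t{i}"), truth.macula)
                 for i, (spec, img, truth) in enumerate(clean_suite[:2])]
        rep = tune_roi_parameters(pairs)
        assert len(rep.grid) == 18
        combos = {(p, q, r) for p, q, r, _, _ in rep.grid}
        assert len(combos) == 18

    def test_single_image_gives_binary_accuracy(self, clean_suite):
        spec, img, truth = clean_suite[0]
        rep = tune_roi_parameters([(FundusImage(img, "one"), truth.macula)])
        assert all(acc in (0.0, 100.0) for _, _, _, acc, _ in rep.grid)

    def test_no_images_rejected(self):
        with pytest.raises(InvalidInputError):
            tune_roi_parameters([])
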