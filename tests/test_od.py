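"""Optic-disc localization."""

import numpy as np
import pytest

from maculoc import (FundusImage, ODNotFoundError, crop_od_roi,
                     estimate_disc_diameter, localize_od, locate_od_candidate,
                     resize_to_standard, segment_od)
from maculoc.preprocess import NormalizedImage
from maculoc.synthetic import SyntheticSpec, generate_fundus


def _norm_from(Ic):
    z = np.zeros_like(Ic)
    return NormalizedImage(Ic=Ic, Ipre1=z, Ipre2=z, Ibt=z, Ibg=z, Iop=z)


class TestCandidate:
    def test_centroid_of_single_bright_disc(self):
        yy, xx = np.mgrid[0:200, 0:300]
        Ic = 40.0 + 200.0 * (np.hypot(xx - 120, yy - 90) < 20)
        cx, cy = locate_od_candidate(_norm_from(Ic))
        assert abs(cx - 120) <= 2 and abs(cy - 90) <= 2

    def test_larger_of_two_blobs_wins(self):
        Ic = np.zeros((100, 200))
        Ic[20:30, 20:30] = 255    # area 100
        Ic[60:80, 120:140] = 255  # area 400
        cx, cy = locate_od_candidate(_norm_from(Ic))
        assert abs(cx - 129.5) < 1 and abs(cy - 69.5) < 1


class TestCrop:
    def test_quarter_size_crop_centered_on_candidate(self):
        red = np.zeros((565, 743), dtype=np.uint8)
        crop, box = crop_od_roi(red, (370.0, 280.0))
        assert crop.shape == (141, 186)
        x0, y0, w, h = box
        assert x0 <= 370 < x0 + w and y0 <= 280 < y0 + h

    def test_corner_candidate_clips_to_image(self):
        red = np.zeros((565, 743), dtype=np.uint8)
        crop, box = crop_od_roi(red, (0.0, 0.0))
        assert box[:2] == (0, 0)
        assert crop.shape[0] <= 141 and crop.shape[1] <= 186

    def test_box_offsets_reconstruct_full_image_coordinates(self):
        red = np.arange(565 * 743, dtype=np.float64).reshape(565, 743)
        crop, (x0, y0, w, h) = crop_od_roi(red, (400.0, 300.0))
        assert np.array_equal(crop, red[y0:y0 + h, x0:x0 + w])


class TestSegment:
    def test_synthetic_disc_with_vessels_recovered(self):
        rng = np.random.default_rng(1)
        yy, xx = np.mgrid[0:141, 0:186]
        crop = 140.0 + 110.0 * np.exp(-(np.hypot(xx - 90, yy - 70) / 30) ** 4)
        crop[:, 95:98] -= 60.0   # vessel stroke through the disc
        crop += rng.normal(0, 4, crop.shape)
        mask, (cx, cy), od_crop = segment_od(np.clip(crop, 0, 255))
        assert abs(cx - 90) <= 3 and abs(cy - 70) <= 3
        true_area = np.pi * 30 ** 2
        assert 0.5 * true_area <= mask.sum() <= 2.0 * true_area

    def test_constant_crop_raises_od_not_found(self):
        with pytest.raises(ODNotFoundError):
            segment_od(np.full((100, 120), 90.0))


class TestDiscDiameter:
    def test_ratio_is_one_twelfth_of_fov_width(self):
        gray = np.zeros((565, 743))
        gray[:, 10:730] = 120.0    # bright band of width 720
        DD, v_prime = estimate_disc_diameter(gray)
        assert v_prime == 720
        assert DD == pytest.approx(60.0)

    def test_full_width_circular_fov(self, nominal_fundus, cfg):
        _, image, truth = nominal_fundus
        rz = resize_to_standard(FundusImage(image), cfg)
        from maculoc import channel
        DD, v_prime = estimate_disc_diameter(channel(rz, "gray"), cfg)
        expected = 2 * 0.48 * 584 * rz.scale_factor
        assert abs(v_prime - expected) <= 5

    def test_degenerate_flat_image_warns_and_falls_back(self):
        with pytest.warns(UserWarning):
            DD, v_prime = estimate_disc_diameter(np.zeros((50, 60)))
        assert v_prime == 60

    def test_dd_scales_linearly_with_fov_width(self, cfg):
        ratios = []
        for h in (560, 600, 640):
            spec = SyntheticSpec(height=h, width=round(1.31 * h),
                                 fov_radius=0.48 * h, seed=3)
            image, truth = generate_fundus(spec)
            rz = resize_to_standard(FundusImage(image), cfg)
            od = localize_od(rz, cfg)
            ratios.append(od.v_prime / od.DD)
        assert np.allclose(ratios, 12.0)


class TestLocalize:
    def test_nominal_fixture_within_five_pixels(self, nominal_fundus, cfg):
        _, image, truth = nominal_fundus
        rz = resize_to_standard(FundusImage(image), cfg)
        od = localize_od(rz, cfg)
        s = rz.scale_factor
        err = np.hypot(od.center[0] - truth.od[0] * s,
                       od.center[1] - truth.od[1] * s)
        assert err <= 5

    def test_mirrored_input_mirrors_disc_center(self, nominal_fundus, cfg):
        _, image, _ = nominal_fundus
        rz = resize_to_standard(FundusImage(image), cfg)
        od1 = localize_od(rz, cfg)
        rz2 = resize_to_standard(FundusImage(image[:, ::-1].copy()), cfg)
        od2 = localize_od(rz2, cfg)
        assert abs(od1.center[0] - (rz.width - 1 - od2.center[0])) <= 2
        assert abs(od1.center[1] - od2.center[1]) <= 2

    def test_deterministic(self, nominal_fundus, cfg):
        _, image, _ = nominal_fundus
        rz = resize_to_standard(FundusImage(image), cfg)
        a = localize_od(rz, cfg)
        b = localize_od(rz, cfg)
        assert a.center == b.center and a.DD == b.DD and a.od_box == b.od_box
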