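"""The synthetic fundus generator and its anatomical contract."""

import numpy as np
import pandas as pd
import pytest

from maculoc import InvalidSpecError
from maculoc.synthetic import (SyntheticSpec, generate_fundus, generate_suite)


class TestSingleImage:
    def test_same_spec_and_seed_bitwise_identical(self):
        spec = SyntheticSpec(seed=9, noise_sigma=5.0, gradient=10.0)
        a, _ = generate_fundus(spec)
        b, _ = generate_fundus(spec)
        assert np.array_equal(a, b)

    def test_lateralities_are_exact_mirrors(self):
        # a right-lateral image is pixel-identical to the flip of the
        # left-lateral render with the mirrored spec (same seed)
        right_spec = SyntheticSpec(seed=3, laterality="right").resolved()
        w = right_spec.width
        left_spec = SyntheticSpec(
            seed=3, laterality="left",
            fov_center=(w - 1 - right_spec.fov_center[0],
                        right_spec.fov_center[1]),
            fov_radius=right_spec.fov_radius,
            od_center=(w - 1 - right_spec.od_center[0],
                       right_spec.od_center[1]),
        )
        right, tr = generate_fundus(right_spec)
        left, tl = generate_fundus(left_spec)
        assert np.array_equal(left, right[:, ::-1])
        assert tl.macula[0] == pytest.approx(w - 1 - tr.macula[0])
        assert tl.macula[1] == pytest.approx(tr.macula[1])
        assert tl.od[0] == pytest.approx(w - 1 - tr.od[0])

    def test_default_lateralities_are_geometric_mirrors(self):
        _, tl = generate_fundus(SyntheticSpec(seed=3, laterality="left"))
        _, tr = generate_fundus(SyntheticSpec(seed=3, laterality="right"))
        w = SyntheticSpec().width
        assert abs(tl.od[0] - (w - 1 - tr.od[0])) <= 1.0
        assert abs(tl.macula[0] - (w - 1 - tr.macula[0])) <= 1.0
        assert tl.od[1] == pytest.approx(tr.od[1])

    def test_macula_sits_at_placement_rule_distance(self):
        spec = SyntheticSpec(seed=7)
        _, truth = generate_fundus(spec)
        d = np.hypot(truth.macula[0] - truth.od[0],
                     truth.macula[1] - truth.od[1])
        assert abs(d - 2.5 * truth.D_true) < 0.5

    def test_macula_outside_fov_rejected(self):
        # disc pushed far nasal: the 2.5-diameter temporal offset lands
        # the macula beyond the field of view
        spec = SyntheticSpec(laterality="left", od_center=(120.0, 292.0))
        with pytest.raises(InvalidSpecError, match="macula"):
            generate_fundus(spec)

    def test_disc_outside_fov_rejected(self):
        spec = SyntheticSpec(od_center=(700.0, 292.0))
        with pytest.raises(InvalidSpecError, match="disc"):
            generate_fundus(spec)

    def test_vessels_denser_on_nasal_half_of_disc(self):
        for lat, seed in (("left", 1), ("right", 2)):
            spec = SyntheticSpec(laterality=lat, seed=seed).resolved()
            image, truth = generate_fundus(spec)
            yy, xx = np.mgrid[0:image.shape[0], 0:image.shape[1]]
            in_disc = np.hypot(xx - truth.od[0], yy - truth.od[1]) <= truth.D_true / 2
            nasal_is_positive_x = lat == "left"
            nasal = truth.vessel_mask & in_disc & (
                (xx > truth.od[0]) if nasal_is_positive_x else (xx < truth.od[0]))
            temporal = truth.vessel_mask & in_disc & (
                (xx < truth.od[0]) if nasal_is_positive_x else (xx > truth.od[0]))
            assert nasal.sum() > temporal.sum()

    def test_truth_masks_consistent_with_image(self):
        spec = SyntheticSpec(seed=4)
        image, truth = generate_fundus(spec)
        # background excludes the dark macula and bright disc: its green
        # spread is narrow compared to the full image
        g = image[:, :, 1].astype(float)
        assert g[truth.background_mask].std() < g.std()


class TestSuite:
    def test_suite_contents_and_gt(self, tmp_path, clean_suite):
        out = tmp_path / "suite"
        suite = generate_suite(6, "clean", seed=5, out_dir=out)
        assert len(suite) == 6
        assert {s.laterality for s, _, _ in suite} == {"left", "right"}
        gt = pd.read_csv(out / "gt.csv")
        assert list(gt.columns) == ["file", "x", "y", "od_x", "od_y"]
        assert len(gt) == 6
        assert (out / "img_000.png").exists()
        assert (out / "img_000.spec.json").exists()

    def test_same_seed_reproduces_suite(self):
        a = generate_suite(4, "nominal", seed=8)
        b = generate_suite(4, "nominal", seed=8)
        for (_, ia, _), (_, ib, _) in zip(a, b):
            assert np.array_equal(ia, ib)

    def test_suite_is_prefix_extensible(self):
        short = generate_suite(3, "clean", seed=8)
        long = generate_suite(5, "clean", seed=8)
        for (_, ia, _), (_, ib, _) in zip(short, long):
            assert np.array_equal(ia, ib)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(InvalidSpecError):
            generate_suite(0, "clean", seed=1)
        with pytest.raises(InvalidSpecError):
            generate_suite(3, "impossible", seed=1)
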