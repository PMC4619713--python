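"""Tests of substrate classification: reference-curve building, the KS-based
probability of hardness, IDW interpolation, decision rules, and label mapping."""

import numpy as np
import pytest

from benthoscape.classify import (
    ARCurve,
    ReferenceARC,
    RuleThresholds,
    build_reference_arc,
    classify_phard,
    idw_interpolate,
    ks_phard,
    map_image_labels,
    rule_classify,
    site_class_proportions,
)


def curve(intensities, angles=None):
    intensities = np.asarray(intensities, dtype=float)
    if angles is None:
        angles = np.arange(1.0, len(intensities) + 1)
    return ARCurve(angles=angles, intensities=intensities)


class TestReferenceArc:
    def test_mean_of_identical_curves_is_identity(self):
        c = curve([-20, -21, -22, -23, -24])
        ref = build_reference_arc([c, c])
        assert np.allclose(ref.curve.intensities, c.intensities)
        assert ref.n_training == 2

    def test_mean_of_constant_curves(self):
        ref = build_reference_arc([curve([-20] * 6), curve([-30] * 6)])
        assert np.allclose(ref.curve.intensities, -25.0)

    def test_training_validation_split_bookkeeping(self):
        # a 100-curve training set from a 720-sample pool leaves 620 aside
        pool = 720
        training = [curve(np.full(5, -20.0 - i * 0.01)) for i in range(100)]
        ref = build_reference_arc(training)
        assert ref.n_training == 100
        assert pool - ref.n_training == 620

    def test_mismatched_grids_rejected(self):
        a = curve([-20] * 5)
        b = ARCurve(angles=np.arange(2.0, 7.0), intensities=np.full(5, -21.0))
        with pytest.raises(ValueError, match="angle grid"):
            build_reference_arc([a, b])

    def test_too_few_curves_rejected(self):
        with pytest.raises(ValueError):
            build_reference_arc([curve([-20] * 5)])


from oracles import brute_force_ks_phard


class TestKsPhard:
    def test_identical_curve_gives_one(self):
        c = curve([-20, -22, -24, -26, -28, -30])
        ref = ReferenceARC(curve=c, n_training=2)
        assert ks_phard(c, ref) == pytest.approx(1.0)

    def test_monotone_in_distance(self):
        base = np.array([-20.0, -21, -22, -23, -24, -25, -26, -27, -28, -29])
        ref = ReferenceARC(curve=curve(base), n_training=2)
        phs = []
        for bend in (0.0, 1.0, 2.0, 4.0, 8.0):
            tilted = base - bend * np.linspace(0, 1, 10)
            phs.append(ks_phard(curve(tilted), ref))
        assert all(a >= b - 1e-12 for a, b in zip(phs, phs[1:]))

    def test_matches_brute_force_on_fixed_curves(self):
        a = [-18.5, -19.0, -20.5, -22.0, -23.0, -24.5, -25.0, -26.5, -27.0, -28.0]
        b = [-20.0, -20.5, -21.0, -23.5, -25.0, -25.5, -27.0, -27.5, -28.5, -29.5]
        ref = ReferenceARC(curve=curve(b), n_training=2)
        assert ks_phard(curve(a), ref) == pytest.approx(brute_force_ks_phard(a, b), abs=1e-10)

    def test_flat_curve_rejected(self):
        flat = curve([-30.0] * 5)
        ref = ReferenceARC(curve=curve([-20, -21, -22, -23, -24]), n_training=2)
        with pytest.raises(ValueError, match="flat curve"):
            ks_phard(flat, ref)


class TestClassifyPhard:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.95, "hard"), (0.90, "mixed"), (0.10, "mixed"), (0.5, "mixed"), (0.05, "soft")],
    )
    def test_threshold_bins(self, p, expected):
        out = classify_phard(np.array([[p]]))
        assert out[0, 0] == expected

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            classify_phard(np.array([[0.5]]), lo=0.9, hi=0.1)

    def test_total_labelling(self, rng):
        vals = rng.random((20, 20))
        out = classify_phard(vals)
        assert set(np.unique(out)) <= {"hard", "mixed", "soft"}


class TestIdw:
    def test_exact_at_observation(self):
        obs = np.array([[0.0, 0.0, 0.2], [10.0, 0.0, 0.8]])
        tx, ty = np.meshgrid([0.0, 5.0, 10.0], [0.0])
        grid = idw_interpolate(obs, tx, ty)
        assert grid.values[0, 0] == pytest.approx(0.2)
        assert grid.values[0, 2] == pytest.approx(0.8)
        assert grid.provenance[0, 0] == "observed"
        assert grid.provenance[0, 1] == "interpolated"

    def test_midpoint_symmetry(self):
        obs = np.array([[0.0, 0.0, 0.2], [10.0, 0.0, 0.8]])
        tx, ty = np.meshgrid([5.0], [0.0])
        assert idw_interpolate(obs, tx, ty).values[0, 0] == pytest.approx(0.5)

    def test_bounded_by_observations(self, rng):
        for _ in range(30):
            n = int(rng.integers(1, 8))
            obs = np.column_stack(
                [rng.uniform(0, 100, n), rng.uniform(0, 100, n), rng.random(n)]
            )
            tx, ty = np.meshgrid(rng.uniform(0, 100, 15), rng.uniform(0, 100, 15))
            vals = idw_interpolate(obs, tx, ty).values
            assert vals.min() >= obs[:, 2].min() - 1e-12
            assert vals.max() <= obs[:, 2].max() + 1e-12

    def test_empty_observations_rejected(self):
        with pytest.raises(ValueError):
            idw_interpolate(np.empty((0, 3)), np.zeros((2, 2)), np.zeros((2, 2)))


class TestRuleClassify:
    def test_flat_soft_seabed(self):
        depth = np.full((30, 30), 80.0)
        slope = np.full((30, 30), 0.5)
        bs = np.full((30, 30), -27.0)
        out = rule_classify(depth, slope, bs, RuleThresholds(), cell_size=2.0)
        assert np.all(out == "soft")

    def test_raised_high_backscatter_component_is_hard(self):
        # 3 m raised feature, 10 deg flank gradient, -20 dB, ~150 m^2 (38 cells
        # at 2 m resolution) on a flat soft background
        depth = np.full((40, 40), 80.0)
        slope = np.full((40, 40), 0.5)
        bs = np.full((40, 40), -27.0)
        feat = (slice(18, 24), slice(17, 24))
        depth[feat] -= 3.0
        slope[feat] = 10.0
        bs[feat] = -20.0
        out = rule_classify(depth, slope, bs, RuleThresholds(), cell_size=2.0)
        assert np.all(out[feat] == "hard")
        assert out[0, 0] == "soft"

    def test_small_component_demoted_to_mixed(self):
        # qualifying cells but only ~48 m^2: below the 100 m^2 minimum area
        depth = np.full((40, 40), 80.0)
        slope = np.full((40, 40), 0.5)
        bs = np.full((40, 40), -27.0)
        feat = (slice(20, 23), slice(20, 24))  # 12 cells x 4 m^2 = 48 m^2
        depth[feat] -= 3.0
        slope[feat] = 10.0
        bs[feat] = -20.0
        out = rule_classify(depth, slope, bs, RuleThresholds(), cell_size=2.0)
        assert np.all(out[feat] == "mixed")

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rule_classify(np.zeros((3, 3)), np.zeros((3, 4)), np.zeros((3, 3)))

    def test_deterministic_and_total(self, small_truth):
        from benthoscape.pipeline import rule_thresholds_for

        t = rule_thresholds_for(small_truth.config)
        a = rule_classify(
            small_truth.depth_grid, small_truth.slope_grid,
            small_truth.backscatter_grid, t, cell_size=small_truth.config.cell_size,
        )
        b = rule_classify(
            small_truth.depth_grid, small_truth.slope_grid,
            small_truth.backscatter_grid, t, cell_size=small_truth.config.cell_size,
        )
        assert np.array_equal(a, b)
        assert set(np.unique(a)) <= {"hard", "mixed", "soft"}


class TestRecoveryOnSeparatedSeascape:
    def test_rule_classifier_recovers_interior_cells(self, separated_truth):
        from scipy import ndimage

        from benthoscape.pipeline import rule_thresholds_for

        truth = separated_truth
        t = rule_thresholds_for(truth.config)
        out = rule_classify(
            truth.depth_grid, truth.slope_grid, truth.backscatter_grid, t,
            cell_size=truth.config.cell_size,
        )
        ok = tot = 0
        for c in ("hard", "mixed", "soft"):
            interior = ndimage.binary_erosion(
                truth.true_class_grid == c, np.ones((3, 3), bool)
            )
            ok += (out[interior] == c).sum()
            tot += interior.sum()
        assert ok / tot >= 0.90


class TestSiteProportions:
    def test_all_soft_site(self):
        raster = np.full((10, 10), "soft", dtype="<U5")
        res = site_class_proportions(raster, np.ones((10, 10), bool))
        assert res["proportions"] == {"hard": 0.0, "mixed": 0.0, "soft": 1.0}
        assert res["areas_km2"]["soft"] == pytest.approx(0.04)

    def test_half_hard_rescaled(self):
        raster = np.full((2, 10), "soft", dtype="<U5")
        raster[0] = "hard"
        res = site_class_proportions(raster, np.ones((2, 10), bool))
        # observed swath area is irrelevant after rescaling to 0.04 km^2
        assert res["areas_km2"]["hard"] == pytest.approx(0.02)

    def test_conservation(self, rng):
        for _ in range(20):
            raster = rng.choice(["hard", "mixed", "soft"], size=(8, 8)).astype("<U5")
            res = site_class_proportions(raster, np.ones((8, 8), bool))
            assert abs(sum(res["areas_km2"].values()) - 0.04) < 1e-12
            assert abs(sum(res["proportions"].values()) - 1.0) < 1e-12

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            site_class_proportions(np.full((3, 3), "soft"), np.zeros((3, 3), bool))


class TestImageLabelMapping:
    @pytest.mark.parametrize(
        "dom,sub,expected",
        [
            ("sand", "sand", "soft"),
            ("rock", "rock", "hard"),
            ("sand", "rock", "mixed"),
            ("rock", "sand", "mixed"),
            ("mud", "none", "soft"),
            ("boulders", "none", "hard"),
        ],
    )
    def test_default_table(self, dom, sub, expected):
        assert map_image_labels(dom, sub) == expected

    def test_unknown_label_lists_vocabulary(self):
        with pytest.raises(ValueError, match="vocabulary"):
            map_image_labels("kelp", "sand")

    def test_override_rules(self):
        rules = {("sand", "rock"): "hard"}
        assert map_image_labels("sand", "rock", rules=rules) == "hard"
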