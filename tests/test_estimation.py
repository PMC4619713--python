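"""Tests of design-based estimation: Hájek percentages, the local
neighborhood variance estimator, two-phase probabilities, and image-based
biota covers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from benthoscape import catami
from benthoscape.estimation import (
    biota_total_area,
    ht_category_estimate,
    image_cover_scores,
    local_mean_variance,
    neighborhood_weights,
    site_mean_cover,
    two_phase_pi,
)


def site_table(y_hard, pi=None, rng=None):
    n = len(y_hard)
    rng = rng or np.random.default_rng(0)
    pi = np.full(n, 0.5) if pi is None else np.asarray(pi, float)
    y_hard = np.asarray(y_hard, float)
    return pd.DataFrame(
        {
            "site_id": np.arange(n),
            "x": rng.uniform(0, 1000, n),
            "y": rng.uniform(0, 1000, n),
            "pi": pi,
            "prop_hard": y_hard,
            "prop_mixed": (1 - y_hard) / 2,
            "prop_soft": (1 - y_hard) / 2,
        }
    )


class TestHtCategoryEstimate:
    def test_constant_field_exact(self):
        df = site_table(np.zeros(10))
        df["prop_mixed"] = 0.0
        df["prop_soft"] = 1.0
        est = ht_category_estimate(df)
        assert est["soft"].estimate == pytest.approx(100.0)
        assert est["hard"].estimate == 0.0
        assert est["soft"].std_error == 0.0
        assert (est["soft"].lcb95, est["soft"].ucb95) == (100.0, 100.0)

    def test_equal_pi_reduces_to_mean(self):
        df = site_table(np.array([0.2, 0.4, 0.6]), pi=np.full(3, 0.3))
        est = ht_category_estimate(df)
        assert est["hard"].estimate == pytest.approx(40.0)

    def test_estimates_sum_to_100(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 30))
            y = rng.random(n)
            df = site_table(y, pi=rng.uniform(0.05, 1.0, n), rng=rng)
            est = ht_category_estimate(df)
            total = sum(e.estimate for e in est.values())
            assert abs(total - 100.0) < 1e-9

    def test_ci_ordering_and_truncation(self, rng):
        df = site_table(rng.random(12), rng=rng)
        for e in ht_category_estimate(df).values():
            assert 0.0 <= e.lcb95 <= e.estimate <= e.ucb95 <= 100.0

    def test_invalid_pi_rejected(self):
        df = site_table(np.zeros(5), pi=np.array([0.5, 0.5, 0.5, 0.5, 1.5]))
        with pytest.raises(ValueError):
            ht_category_estimate(df)


class TestNeighborhoodWeights:
    def test_row_and_column_sums(self, rng):
        x, y = rng.uniform(0, 100, 25), rng.uniform(0, 100, 25)
        nw = neighborhood_weights(x, y)
        assert np.allclose(nw.weights.sum(axis=1), 1.0, atol=1e-12)
        assert np.abs(nw.weights.sum(axis=0) - 1.0).max() < 1e-5
        assert np.all(nw.weights >= 0)

    def test_neighborhoods_include_self(self, rng):
        x, y = rng.uniform(0, 100, 10), rng.uniform(0, 100, 10)
        nw = neighborhood_weights(x, y)
        for i, nbrs in enumerate(nw.neighborhoods):
            assert i in nbrs
            assert len(nbrs) >= 5  # self + 4 nearest (symmetrized unions grow)


class TestLocalMeanVariance:
    def test_constant_values_give_zero(self, rng):
        x, y = rng.uniform(0, 10, 8), rng.uniform(0, 10, 8)
        v = local_mean_variance(x, y, np.full(8, 0.5), np.zeros(8))
        assert v == 0.0

    def test_fallback_below_four_sites_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="benthoscape.estimation"):
            v = local_mean_variance(
                np.array([0.0, 1, 2]), np.array([0.0, 1, 0]),
                np.full(3, 0.5), np.array([0.1, -0.2, 0.1]),
            )
        assert v > 0
        assert any("falling back" in r.message for r in caplog.records)

    def test_close_to_srs_variance_for_random_values(self):
        # for spatially unstructured values with equal pi the local estimator
        # should track the SRS variance formula (median ratio within 20%)
        rng = np.random.default_rng(42)
        ratios = []
        for _ in range(300):
            n = 20
            x, y = rng.uniform(0, 100, n), rng.uniform(0, 100, n)
            pi = np.full(n, 0.1)
            z = rng.standard_normal(n)
            resid = z - z.mean()
            v_local = local_mean_variance(x, y, pi, resid)
            nhat = np.sum(1 / pi)
            v_srs = nhat**2 * np.var(resid, ddof=1) / n
            ratios.append(v_local / v_srs)
        assert 0.8 <= np.median(ratios) <= 1.2


class TestTwoPhasePi:
    def test_product(self):
        assert two_phase_pi(0.5, 0.5) == pytest.approx(0.25)

    def test_census_phase2_is_identity(self):
        assert two_phase_pi(0.37, 1.0) == pytest.approx(0.37)

    def test_bounded_by_min(self, rng):
        p1, p2 = rng.uniform(0.01, 1, 20), rng.uniform(0.01, 1, 20)
        out = two_phase_pi(p1, p2)
        assert np.all(out <= np.minimum(p1, p2) + 1e-15)

    def test_invalid(self):
        with pytest.raises(ValueError):
            two_phase_pi(0.0, 0.5)
        with pytest.raises(ValueError):
            two_phase_pi(0.5, 1.2)

    def test_phase2_census_reduces_to_single_phase_estimates(self, rng):
        df = site_table(rng.random(10), pi=rng.uniform(0.1, 0.9, 10), rng=rng)
        est1 = ht_category_estimate(df)
        df2 = df.copy()
        df2["pi"] = two_phase_pi(df["pi"].to_numpy(), np.ones(10))
        est2 = ht_category_estimate(df2)
        for c in est1:
            assert est1[c].estimate == est2[c].estimate  # bit identical
            assert est1[c].std_error == est2[c].std_error


def annotations_from_labels(labels_by_image):
    rows = []
    for (site, image), labels in labels_by_image.items():
        for k, lab in enumerate(labels):
            rows.append({"site_id": site, "image_id": image, "point_idx": k, "label": lab})
    return pd.DataFrame(rows)


class TestImageCoverScores:
    def test_all_bare_sand_gives_zero_biota(self):
        ann = annotations_from_labels({(1, "a"): ["substrate/unconsolidated/sand"] * 25})
        tab = image_cover_scores(ann, level=4)
        assert np.all(tab["cover"] == 0.0)
        assert set(tab["group"]) == set(catami.BIOTA_GROUPS)

    def test_five_sponge_points_give_20pct(self):
        labels = ["biota/sponges/massive/simple"] * 5 + ["substrate/unconsolidated/sand"] * 20
        tab = image_cover_scores(annotations_from_labels({(1, "a"): labels}), level=4)
        sponge = tab.loc[tab["group"] == "biota/sponges", "cover"].iloc[0]
        assert sponge == pytest.approx(0.20)

    def test_wrong_point_count_names_image(self):
        ann = annotations_from_labels({(3, "bad"): ["substrate/unconsolidated/sand"] * 24})
        with pytest.raises(ValueError, match="bad"):
            image_cover_scores(ann)

    def test_unknown_label_rejected(self):
        ann = annotations_from_labels({(1, "a"): ["biota/tunicates/x/y"] * 25})
        with pytest.raises(ValueError, match="unknown label"):
            image_cover_scores(ann)

    def test_level5_sums_to_level4(self, rng):
        vocab = catami.default_vocabulary()
        leaves = [l for l in vocab.leaves]
        imgs = {(s, f"i{k}"): list(rng.choice(leaves, 25)) for s in (1, 2) for k in range(3)}
        ann = annotations_from_labels(imgs)
        t4 = image_cover_scores(ann, level=4)
        t5 = image_cover_scores(ann, level=5)
        t5["parent"] = ["/".join(g.split("/")[:2]) for g in t5["group"]]
        rolled = t5.groupby(["site_id", "image_id", "parent"])["points_hit"].sum()
        for (sid, iid, parent), hits in rolled.items():
            ref = t4[(t4.site_id == sid) & (t4.image_id == iid) & (t4.group == parent)]
            assert int(ref["points_hit"].iloc[0]) == int(hits)

    def test_site_mean_over_images(self):
        labels_hit = ["biota/sponges/massive/simple"] * 25
        labels_none = ["substrate/unconsolidated/sand"] * 25
        ann = annotations_from_labels({(1, "a"): labels_hit, (1, "b"): labels_none})
        covers = site_mean_cover(image_cover_scores(ann, level=4))
        sponge = covers[(covers.site_id == 1) & (covers.group == "biota/sponges")]
        assert sponge["cover"].iloc[0] == pytest.approx(0.5)


class TestBiotaTotalArea:
    def sites(self, n=8, rng=None):
        rng = rng or np.random.default_rng(1)
        return pd.DataFrame(
            {
                "site_id": np.arange(n),
                "x": rng.uniform(0, 5000, n),
                "y": rng.uniform(0, 5000, n),
                "pi": np.full(n, 0.2),
            }
        )

    def test_zero_cover_gives_zero_with_degenerate_ci(self):
        sites = self.sites()
        covers = pd.DataFrame(
            {"site_id": sites["site_id"], "group": "biota/sponges", "cover": 0.0}
        )
        est = biota_total_area(covers, sites, frame_area_km2=774.0)
        e = est["biota/sponges"]
        assert (e.estimate, e.lcb95, e.ucb95) == (0.0, 0.0, 0.0)

    def test_uniform_cover_scales_frame_area(self):
        sites = self.sites()
        covers = pd.DataFrame(
            {"site_id": sites["site_id"], "group": "biota/bryozoa", "cover": 0.10}
        )
        est = biota_total_area(covers, sites, frame_area_km2=774.0)
        assert est["biota/bryozoa"].estimate == pytest.approx(77.4)
        assert est["biota/bryozoa"].std_error == 0.0

    def test_lower_bound_truncated_at_zero(self, rng):
        sites = self.sites(rng=rng)
        covers = pd.DataFrame(
            {
                "site_id": sites["site_id"],
                "group": "biota/ascidians",
                "cover": np.where(rng.random(len(sites)) < 0.2, 0.3, 0.0),
            }
        )
        est = biota_total_area(covers, sites, frame_area_km2=774.0)
        assert est["biota/ascidians"].lcb95 >= 0.0


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    y=st.lists(st.floats(0.0, 1.0), min_size=5, max_size=20),
    seed=st.integers(0, 2**16),
)
def test_hajek_percentages_always_sum_to_100(y, seed):
    rng = np.random.default_rng(seed)
    df = site_table(np.array(y), pi=rng.uniform(0.05, 1.0, len(y)), rng=rng)
    est = ht_category_estimate(df)
    assert abs(sum(e.estimate for e in est.values()) - 100.0) < 1e-9
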