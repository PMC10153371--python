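import itertools

import numpy as np
import pandas as pd
import pytest
from skimage.filters import threshold_otsu as sk_otsu

from glioprog import (DEFAULT_STAIN_MATRIX, classify_and_filter,
                      compare_score_groups, deconvolve_stains,
                      otsu_threshold, rgb_to_od, score_pdl1,
                      segment_channel, train_stain_classifier)
from glioprog.ihc_pipeline import od_to_rgb


def brute_force_otsu(x, n_bins=256):
    """Exhaustive search over histogram bin edges maximizing the
    between-class variance computed directly on the pixel partition."""
    x = np.asarray(x, float).ravel()
    edges = np.histogram_bin_edges(x, bins=n_bins, range=(x.min(), x.max()))
    # bin pixels exactly as the histogram does (right-closed last bin)
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0,
                  n_bins - 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    binned = centers[idx]
    best, best_sigma = None, -1.0
    for k in range(1, n_bins):
        t = edges[k]
        lo = binned[binned < t]
        hi = binned[binned >= t]
        if len(lo) == 0 or len(hi) == 0:
            continue
        w0, w1 = len(lo) / len(x), len(hi) / len(x)
        sigma = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if sigma > best_sigma + 1e-15:
            best_sigma, best = sigma, t
    return best


class TestOpticalDensity:
    def test_white_background_maps_to_zero(self):
        od = rgb_to_od(np.full((4, 4, 3), 255, np.uint8))
        np.testing.assert_allclose(od, 0.0)

    def test_closed_form_decade(self):
        intensity = 0.1 * 256.0 - 1.0   # (I+1)/(i0+1) = 0.1
        assert rgb_to_od(np.array(intensity)) == pytest.approx(1.0)

    def test_monotone_decreasing_in_intensity(self):
        vals = rgb_to_od(np.arange(256.0))
        assert np.all(np.diff(vals) < 0)

    def test_round_trip_within_quantization(self):
        rng = np.random.default_rng(0)
        tile = rng.integers(0, 256, (16, 16, 3)).astype(np.uint8)
        back = od_to_rgb(rgb_to_od(tile))
        assert np.abs(back - tile).max() < 0.5


class TestDeconvolution:
    def test_pure_stain_basis_vectors_recovered(self):
        od = np.zeros((1, 2, 3))
        od[0, 0] = DEFAULT_STAIN_MATRIX[:, 0]   # c = (1, 0)
        od[0, 1] = DEFAULT_STAIN_MATRIX[:, 1]   # c = (0, 1)
        pair = deconvolve_stains(od)
        assert pair.hematoxylin[0, 0] == pytest.approx(1.0, abs=1e-6)
        assert pair.dab[0, 0] == pytest.approx(0.0, abs=1e-6)
        assert pair.dab[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_white_pixel_has_zero_concentrations(self):
        pair = deconvolve_stains(np.zeros((2, 2, 3)))
        np.testing.assert_allclose(pair.hematoxylin, 0.0)
        np.testing.assert_allclose(pair.dab, 0.0)

    def test_synthesis_analysis_round_trip_noise_free(self):
        rng = np.random.default_rng(1)
        c = rng.uniform(0, 2, (8, 8, 2))
        od = np.einsum("ijk,lk->ijl", c, DEFAULT_STAIN_MATRIX.T.T)
        od = c[..., 0:1] * DEFAULT_STAIN_MATRIX[:, 0] \
            + c[..., 1:2] * DEFAULT_STAIN_MATRIX[:, 1]
        pair = deconvolve_stains(od)
        assert np.abs(pair.hematoxylin - c[..., 0]).max() < 1e-6
        assert np.abs(pair.dab - c[..., 1]).max() < 1e-6

    def test_matches_skimage_stain_vectors(self):
        from skimage.color import rgb_from_hed
        # rows of rgb_from_hed are the published H, E, DAB OD vectors
        h = rgb_from_hed[0] / np.linalg.norm(rgb_from_hed[0])
        d = rgb_from_hed[2] / np.linalg.norm(rgb_from_hed[2])
        np.testing.assert_allclose(DEFAULT_STAIN_MATRIX[:, 0], h, atol=5e-3)
        np.testing.assert_allclose(DEFAULT_STAIN_MATRIX[:, 1], d, atol=5e-3)

    def test_collinear_matrix_rejected(self):
        v = np.array([0.5, 0.6, 0.62])
        with pytest.raises(ValueError, match="collinear"):
            deconvolve_stains(np.zeros((2, 2, 3)),
                              np.column_stack([v, 2 * v]))

    def test_negative_concentrations_clipped_and_counted(self):
        od = -0.05 * np.ones((3, 3, 3))
        pair = deconvolve_stains(od)
        assert pair.clipped > 0
        assert pair.hematoxylin.min() >= 0 and pair.dab.min() >= 0


class TestOtsu:
    def test_bimodal_threshold_strictly_between_modes(self):
        x = np.r_[np.zeros(500), np.ones(500)]
        t = otsu_threshold(x)
        assert 0 < t < 1

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        img = np.r_[rng.normal(0.1, 0.05, 400),
                    rng.normal(0.8, 0.2, rng.integers(100, 800))]
        assert otsu_threshold(img) == pytest.approx(
            brute_force_otsu(img), abs=1e-12)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(3)
        img = rng.normal(0, 1, 1000) ** 2
        t0 = otsu_threshold(img)
        t5 = otsu_threshold(img + 5.0)
        assert t5 - t0 == pytest.approx(5.0, abs=1e-9)

    def test_close_to_skimage(self):
        rng = np.random.default_rng(4)
        img = np.r_[rng.normal(0.2, 0.05, 2000), rng.normal(1.0, 0.1, 500)]
        bin_width = np.ptp(img) / 256
        assert abs(otsu_threshold(img) - sk_otsu(img)) <= bin_width

    def test_constant_channel_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            otsu_threshold(np.ones((5, 5)))


class TestSegmentation:
    def test_empty_mask_gives_empty_table(self):
        segs = segment_channel(np.zeros((40, 40)), 0.5)
        assert len(segs) == 0

    def test_single_square_geometry(self):
        img = np.zeros((32, 32))
        img[10:15, 10:15] = 1.0
        segs = segment_channel(img, 0.5, min_area=1)
        assert len(segs) == 1
        row = segs.iloc[0]
        assert row["area"] == 25
        assert row["eccentricity"] == pytest.approx(0.0, abs=1e-9)
        assert row["mean_intensity"] == 1.0

    def test_diagonal_touch_merges_under_8_connectivity(self):
        img = np.zeros((40, 40))
        img[5:10, 5:10] = 1.0
        img[10:15, 10:15] = 1.0   # corner-adjacent
        segs = segment_channel(img, 0.5, min_area=1)
        assert len(segs) == 1
        img2 = np.zeros((40, 40))
        img2[5:10, 5:10] = 1.0
        img2[11:16, 11:16] = 1.0  # fully separated
        assert len(segment_channel(img2, 0.5, min_area=1)) == 2

    def test_min_area_filter(self):
        img = np.zeros((40, 40))
        img[1:3, 1:3] = 1.0       # area 4
        img[10:20, 10:20] = 1.0   # area 100
        segs = segment_channel(img, 0.5, min_area=20)
        assert segs["area"].tolist() == [100]


class TestStainClassifier:
    @staticmethod
    def _separable_table(n_per_class=12, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for k, cls in enumerate(("no", "low", "medium", "high")):
            for _ in range(n_per_class):
                rows.append({
                    "area": rng.integers(20, 200),
                    "mean_intensity": k + rng.uniform(0, 0.2),
                    "max_intensity": k + rng.uniform(0.2, 0.4),
                    "perimeter": rng.uniform(10, 60),
                    "eccentricity": rng.uniform(0, 1),
                    "solidity": rng.uniform(0.8, 1.0),
                    "stain_class": cls})
        return pd.DataFrame(rows)

    def test_separable_classes_learned_perfectly(self):
        table = self._separable_table()
        model = train_stain_classifier(table, seed=0)
        X = table[list(model.features)].to_numpy(float)
        assert (model.forest.predict(X) == table["stain_class"]).all()

    def test_permuted_labels_give_chance_oob(self):
        table = self._separable_table(n_per_class=50, seed=1)
        rng = np.random.default_rng(2)
        table["stain_class"] = rng.permutation(
            table["stain_class"].to_numpy())
        model = train_stain_classifier(table, seed=2)
        assert model.oob_accuracy == pytest.approx(0.25, abs=0.1)

    def test_deterministic_given_seed(self):
        table = self._separable_table(seed=3)
        held = self._separable_table(seed=4).drop(columns="stain_class")
        m1 = train_stain_classifier(table, seed=5)
        m2 = train_stain_classifier(table, seed=5)
        X = held[list(m1.features)].to_numpy(float)
        np.testing.assert_array_equal(m1.forest.predict(X),
                                      m2.forest.predict(X))

    def test_missing_class_rejected(self):
        table = self._separable_table()
        with pytest.raises(ValueError, match="high"):
            train_stain_classifier(table[table.stain_class != "high"])

    def test_filter_removes_no_stain_regions(self):
        table = self._separable_table(n_per_class=25, seed=6)
        model = train_stain_classifier(table, seed=6)
        segs = self._separable_table(n_per_class=10, seed=7)
        truth = segs["stain_class"].to_numpy()
        out = classify_and_filter(segs.drop(columns="stain_class"), model)
        assert (out["stain_class"] != "no").all()
        # near-perfectly separable: stained regions survive, artifacts go
        n_stained = int((truth != "no").sum())
        assert n_stained - 2 <= len(out) <= n_stained + 2

    def test_feature_mismatch_is_schema_error(self, stain_model):
        with pytest.raises(ValueError, match="features"):
            classify_and_filter(pd.DataFrame({"area": [10]}), stain_model)


class TestScoring:
    def test_empty_numerator_and_equality(self):
        hema = pd.DataFrame({"area": [300, 200]})
        assert score_pdl1(pd.DataFrame({"area": []}), hema).ratio == 0.0
        s = score_pdl1(pd.DataFrame({"area": [500]}),
                       pd.DataFrame({"area": [500]}))
        assert s.ratio == 1.0

    def test_zero_hematoxylin_flagged_undefined(self):
        s = score_pdl1(pd.DataFrame({"area": [10]}),
                       pd.DataFrame({"area": []}))
        assert s.undefined and np.isnan(s.ratio)


class TestGroupComparison:
    def test_identical_groups_p_one(self):
        stat, p = compare_score_groups([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert p == 1.0

    def test_exact_separated_triples(self):
        stat, p = compare_score_groups([1, 2, 3], [10, 11, 12])
        assert p == pytest.approx(0.1)

    def test_exact_matches_full_permutation_enumeration(self):
        a = np.array([0.3, 1.1, 2.9])
        b = np.array([0.7, 1.9, 3.5])
        _, p = compare_score_groups(a, b)
        pooled = np.concatenate([a, b])
        ranks = pooled.argsort().argsort() + 1
        obs = ranks[:3].sum()
        sums = [sum(ranks[list(c)]) for c in
                itertools.combinations(range(6), 3)]
        mean = np.mean(sums)
        p_exact = np.mean([abs(s - mean) >= abs(obs - mean) - 1e-12
                           for s in sums])
        assert p == pytest.approx(p_exact, abs=1e-12)

    def test_power_under_one_sd_shift(self):
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(200):
            a = rng.normal(0, 1, 50)
            b = rng.normal(1, 1, 50)
            _, p = compare_score_groups(a, b)
            hits += p < 0.05
        assert hits >= 180

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_score_groups([1, 2], [3, 4, 5])
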