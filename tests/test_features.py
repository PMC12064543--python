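"""Whole-ROI and per-pixel radiomics, ICC / mRMR / lasso filtering."""

import numpy as np
import pandas as pd
import pytest

from ithrad.containers import FeatureTable, ImageVolume, ROIMask
from ithrad.features import (
    EXTENDED_LOCAL_FEATURES,
    FeatureConfig,
    LocalFeatureConfig,
    extract_pixel_features,
    extract_whole_roi_features,
    icc_stability_filter,
    icc_two_way_random,
    lasso_select,
    mrmr_select,
)


class TestWholeRoi:
    def test_constant_roi_zero_variance_and_entropy(self, disk_mask_20):
        img = ImageVolume(np.full((20, 20), 3.0))
        f = extract_whole_roi_features(img, disk_mask_20)
        assert f["firstorder_variance"] == 0.0
        assert f["firstorder_entropy"] == 0.0

    def test_mean_is_arithmetic_mean(self, rng, disk_mask_20):
        img = ImageVolume(rng.normal(50, 10, (20, 20)))
        f = extract_whole_roi_features(img, disk_mask_20)
        assert f["firstorder_mean"] == pytest.approx(
            img.data[disk_mask_20.data].mean()
        )

    def test_glcm_matches_hand_enumeration(self):
        """2x2 image [[1,2],[3,4]], 4 bins, 0-degree offset.

        Discretized levels are 1,2,3,4.  Horizontal pairs: (1,2) and
        (3,4); after symmetrization each occurs twice, so the normalized
        GLCM has 0.25 at (1,2),(2,1),(3,4),(4,3) and contrast
        sum p*(i-j)^2 = 4 * 0.25 * 1 = 1.
        """
        from ithrad.features import _glcm_features, build_glcm

        img = np.array([[1.0, 2.0], [3.0, 4.0]])
        mask = np.ones((2, 2), dtype=bool)
        from ithrad.features import _discretize

        levels = _discretize(img, mask, 4)
        glcm = build_glcm(levels, mask, 4, (0, 1))
        expected = np.zeros((4, 4))
        expected[0, 1] = expected[1, 0] = 1
        expected[2, 3] = expected[3, 2] = 1
        assert np.array_equal(glcm, expected)
        feats = _glcm_features(glcm)
        assert feats["contrast"] == pytest.approx(1.0)
        assert feats["dissimilarity"] == pytest.approx(1.0)

    def test_invariant_to_mask_preserving_translation(self, rng):
        img = rng.normal(0, 1, (24, 24))
        mask = np.zeros((24, 24), dtype=bool)
        mask[4:12, 4:12] = True
        f1 = extract_whole_roi_features(ImageVolume(img), ROIMask(mask))
        shifted_img = np.roll(img, (6, 6), axis=(0, 1))
        shifted_mask = np.roll(mask, (6, 6), axis=(0, 1))
        f2 = extract_whole_roi_features(ImageVolume(shifted_img), ROIMask(shifted_mask))
        pd.testing.assert_series_equal(f1, f2)

    def test_single_pixel_roi_with_texture_errors(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        with pytest.raises(ValueError, match="single-pixel"):
            extract_whole_roi_features(ImageVolume(np.ones((5, 5))), ROIMask(mask))

    def test_first_order_only_single_pixel_ok(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        f = extract_whole_roi_features(
            ImageVolume(np.full((5, 5), 9.0)), ROIMask(mask),
            FeatureConfig(families=("firstorder",)),
        )
        assert f["firstorder_mean"] == 9.0

    def test_deterministic(self, rng, disk_mask_20):
        img = ImageVolume(rng.normal(0, 1, (20, 20)))
        a = extract_whole_roi_features(img, disk_mask_20)
        b = extract_whole_roi_features(img, disk_mask_20)
        pd.testing.assert_series_equal(a, b)


class TestPixelFeatures:
    def test_constant_image_zero_variance_and_contrast(self, disk_mask_20):
        img = ImageVolume(np.full((20, 20), 4.0))
        cfg = LocalFeatureConfig(features=EXTENDED_LOCAL_FEATURES)
        pfm = extract_pixel_features(img, disk_mask_20, cfg)
        for name in ("local_variance", "glcm_contrast", "local_skewness"):
            j = pfm.feature_names.index(name)
            assert np.allclose(pfm.values[:, j], 0.0)

    def test_one_row_per_in_mask_pixel(self, rng, disk_mask_20):
        img = ImageVolume(rng.normal(0, 1, (20, 20)))
        pfm = extract_pixel_features(img, disk_mask_20)
        assert pfm.n_pixels == disk_mask_20.n_pixels
        assert np.array_equal(pfm.coords, np.argwhere(disk_mask_20.data))

    def test_local_mean_separates_habitats(self):
        from scipy import ndimage as ndi

        from ithrad.synthetic import PhantomSpec, TextureParams, \
            generate_texture_phantom

        spec = PhantomSpec(
            grid_shape=(32, 32), n_habitats=2, habitat_fragments=(1, 1),
            area_fractions=(0.5, 0.5),
            texture_params=(TextureParams(0.0, 1.0, 0.0),
                            TextureParams(100.0, 1.0, 0.0)),
            radial_gradient=0.0, seed=3,
        )
        img, mask, tlm = generate_texture_phantom(spec)
        pfm = extract_pixel_features(img, mask, LocalFeatureConfig(radius=2))
        j = pfm.feature_names.index("local_mean")
        vals = pfm.values[:, j]
        # interior pixels: windows entirely inside one habitat
        interiors = {
            h: ndi.binary_erosion(tlm.labels == h, iterations=2)[mask.data]
            for h in (1, 2)
        }
        gap = abs(vals[interiors[1]].mean() - vals[interiors[2]].mean())
        within = max(vals[interiors[1]].std(), vals[interiors[2]].std())
        assert gap > 10 * within

    def test_out_of_mask_intensities_never_leak(self, rng, disk_mask_20):
        img = rng.normal(0, 1, (20, 20))
        cfg = LocalFeatureConfig(features=EXTENDED_LOCAL_FEATURES)
        base = extract_pixel_features(ImageVolume(img), disk_mask_20, cfg)
        for _ in range(5):
            tampered = img.copy()
            outside = ~disk_mask_20.data
            tampered[outside] = rng.normal(0, 100, outside.sum())
            out = extract_pixel_features(ImageVolume(tampered), disk_mask_20, cfg)
            assert np.array_equal(base.values, out.values)

    def test_isolated_pixel_gets_zero_texture_not_error(self, caplog):
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 4] = True   # no in-mask neighbors at all
        mask[0, 0] = True
        img = ImageVolume(np.arange(81, dtype=float).reshape(9, 9))
        cfg = LocalFeatureConfig(radius=1, features=EXTENDED_LOCAL_FEATURES)
        import logging

        with caplog.at_level(logging.WARNING, logger="ithrad.features"):
            pfm = extract_pixel_features(img, ROIMask(mask), cfg)
        j = pfm.feature_names.index("glcm_contrast")
        assert np.allclose(pfm.values[:, j], 0.0)
        assert any("neighbor" in r.message for r in caplog.records)

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError, match="empty"):
            extract_pixel_features(ImageVolume(np.ones((4, 4))),
                                   ROIMask(np.zeros((4, 4), dtype=bool)))


def _ft(arr, names=None):
    arr = np.asarray(arr, dtype=float)
    names = names or [f"f{j}" for j in range(arr.shape[1])]
    return FeatureTable(pd.DataFrame(
        arr, index=[f"s{i}" for i in range(arr.shape[0])], columns=names))


class TestICC:
    def test_identical_tables_keep_everything(self, rng):
        a = _ft(rng.standard_normal((30, 5)))
        kept = icc_stability_filter(a, a.copy(), threshold=0.9)
        assert kept == a.feature_names

    def test_hand_example_perfect_agreement(self):
        a = _ft([[1.0], [2.0], [3.0]])
        b = _ft([[1.0], [2.0], [3.0]])
        assert icc_two_way_random(a, b)["f0"] == pytest.approx(1.0)

    def test_independent_noise_is_dropped(self, rng):
        a = _ft(rng.standard_normal((100, 4)))
        b = _ft(rng.standard_normal((100, 4)))
        icc = icc_two_way_random(a, b)
        assert (icc.abs() < 0.3).all()
        assert icc_stability_filter(a, b) == []

    def test_matches_pingouin_reference(self, rng):
        pg = pytest.importorskip("pingouin")
        x = rng.standard_normal(40)
        y = 0.8 * x + 0.3 * rng.standard_normal(40) + 0.5
        a, b = _ft(x[:, None]), _ft(y[:, None])
        ours = icc_two_way_random(a, b)["f0"]
        long = pd.DataFrame({
            "subj": list(range(40)) * 2,
            "rater": ["A"] * 40 + ["B"] * 40,
            "y": np.concatenate([x, y]),
        })
        ref = pg.intraclass_corr(long, "subj", "rater", "y").set_index("Type")
        assert ours == pytest.approx(float(ref.loc["ICC(A,1)", "ICC"]), abs=1e-9)

    def test_too_few_subjects_errors(self, rng):
        a = _ft(rng.standard_normal((2, 3)))
        with pytest.raises(ValueError, match="3 subjects"):
            icc_two_way_random(a, a.copy())


class TestMrmr:
    def test_m_zero_returns_empty(self, rng):
        tab = _ft(rng.standard_normal((50, 4)))
        assert mrmr_select(tab, rng.integers(0, 2, 50), 0) == []

    def test_negative_m_errors(self, rng):
        tab = _ft(rng.standard_normal((50, 4)))
        with pytest.raises(ValueError):
            mrmr_select(tab, rng.integers(0, 2, 50), -1)

    def test_label_feature_ranked_first(self, rng):
        n = 200
        y = rng.integers(0, 2, n)
        tab = _ft(
            np.column_stack([rng.standard_normal(n),
                             y + 0.05 * rng.standard_normal(n),
                             rng.standard_normal(n)]),
            names=["noise_a", "signal", "noise_b"],
        )
        assert mrmr_select(tab, y, 1)[0] == "signal"

    def test_duplicate_feature_not_ranked_second(self, rng):
        n = 200
        y = rng.integers(0, 2, n)
        sig = y + 0.05 * rng.standard_normal(n)
        tab = _ft(
            np.column_stack([sig, sig.copy(), rng.standard_normal(n),
                             rng.standard_normal(n)]),
            names=["signal_a", "signal_b", "noise_a", "noise_b"],
        )
        ranked = mrmr_select(tab, y, 2)
        assert ranked[0] == "signal_a"          # lexical tie-break
        assert ranked[1] not in ("signal_b",)   # redundancy penalty

    def test_deterministic(self, rng):
        tab = _ft(rng.standard_normal((80, 6)))
        y = rng.integers(0, 2, 80)
        assert mrmr_select(tab, y, 4) == mrmr_select(tab, y, 4)


class TestLasso:
    def test_infinite_penalty_selects_nothing(self, rng):
        n = 100
        X = rng.standard_normal((n, 5))
        y = (X[:, 0] > 0).astype(int)
        sel, coefs = lasso_select(_ft(X), y, folds=4, seed=0,
                                  c_grid=np.array([1e-6]))
        assert sel == []
        assert len(coefs) == 0

    def test_recovers_signals_rejects_noise(self, rng):
        n = 400
        X = rng.standard_normal((n, 52))
        logit = 2.0 * X[:, 0] - 2.0 * X[:, 1]
        y = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(int)
        names = ["sig1", "sig2"] + [f"noise{j:02d}" for j in range(50)]
        sel, _ = lasso_select(_ft(X, names), y, folds=10, seed=0)
        assert "sig1" in sel and "sig2" in sel
        assert sum(1 for s in sel if s.startswith("noise")) <= 5

    def test_single_class_errors(self, rng):
        X = rng.standard_normal((20, 3))
        with pytest.raises(ValueError):
            lasso_select(_ft(X), np.ones(20, dtype=int))

    def test_same_seed_identical_selection(self, rng):
        n = 150
        X = rng.standard_normal((n, 10))
        y = (X[:, 0] + 0.5 * rng.standard_normal(n) > 0).astype(int)
        a = lasso_select(_ft(X), y, folds=5, seed=3)
        b = lasso_select(_ft(X), y, folds=5, seed=3)
        assert a[0] == b[0]
        pd.testing.assert_series_equal(a[1], b[1])
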