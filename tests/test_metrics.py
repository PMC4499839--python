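"""SNR/CNR metrics and the pooled t-test engine."""

import numpy as np
import pytest
from scipy import stats as sps

from vesselmorph.metrics import (ROI, cnr, noise_sd, roi_mean, roi_report,
                                 snr, ttest_from_summary, ttest_table,
                                 ttest_unpaired)


def box(z, y, x):
    return (slice(*z), slice(*y), slice(*x))


def moment_matched(mean, sd, n, rng):
    """Samples with exactly the requested mean and sample SD."""
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


@pytest.fixture()
def roi_volume():
    """Blocks with exact means and a background of exact unit SD."""
    vol = np.zeros((4, 10, 40))
    vol[:, :, 0:10] = 139.7     # wall
    vol[:, :, 10:20] = 120.1    # lumen
    vol[:, :, 20:30] = 134.2    # parenchyma
    # background with sample SD exactly 1: alternating +-sqrt((n-1)/n)
    n = 4 * 10 * 10
    a = np.sqrt((n - 1.0) / n)
    flat = np.where(np.arange(n) % 2 == 0, a, -a)
    vol[:, :, 30:40] = flat.reshape(4, 10, 10)
    return vol


ROIS = {
    "wall": ROI("wall", "wall", box=box((0, 4), (0, 10), (0, 10))),
    "lumen": ROI("lumen", "lumen", box=box((0, 4), (0, 10), (10, 20))),
    "parenchyma": ROI("parenchyma", "parenchyma",
                      box=box((0, 4), (0, 10), (20, 30))),
    "background": ROI("background", "background",
                      box=box((0, 4), (0, 10), (30, 40))),
}


class TestROIStats:
    def test_roi_mean_constant(self):
        vol = np.full((3, 3, 3), 7.0)
        assert roi_mean(vol, ROI("a", "wall",
                                 box=box((0, 3), (0, 3), (0, 3)))) == 7.0

    def test_roi_mean_two_voxels(self):
        vol = np.zeros((1, 1, 2))
        vol[0, 0] = [1.0, 3.0]
        assert roi_mean(vol, ROI("a", "wall",
                                 box=box((0, 1), (0, 1), (0, 2)))) == 2.0

    def test_noise_sd_hand_values(self):
        vol = np.zeros((1, 1, 2))
        vol[0, 0] = [0.0, 2.0]
        r = ROI("bg", "background", box=box((0, 1), (0, 1), (0, 2)))
        assert noise_sd(vol, r) == pytest.approx(np.sqrt(2.0))

    def test_noise_sd_constant_zero(self):
        vol = np.full((2, 2, 2), 4.0)
        r = ROI("bg", "background", box=box((0, 2), (0, 2), (0, 2)))
        assert noise_sd(vol, r) == 0.0

    def test_noise_sd_large_gaussian(self):
        rng = np.random.default_rng(0)
        vol = rng.normal(0, 1, (50, 50, 40))
        r = ROI("bg", "background", box=box((0, 50), (0, 50), (0, 40)))
        assert 0.99 < noise_sd(vol, r) < 1.01

    def test_published_snr_and_cnr_values(self, roi_volume):
        # SNR lumen 120.1 at N = 1; wall-parenchyma CNR 5.5
        assert snr(roi_volume, ROIS["lumen"], ROIS["background"]) == \
            pytest.approx(120.1)
        assert cnr(roi_volume, ROIS["wall"], ROIS["parenchyma"],
                   ROIS["background"]) == pytest.approx(5.5)

    def test_cnr_of_identical_rois_zero(self, roi_volume):
        assert cnr(roi_volume, ROIS["wall"], ROIS["wall"],
                   ROIS["background"]) == 0.0

    def test_cnr_equals_snr_difference(self, roi_volume):
        rep = roi_report(roi_volume, list(ROIS.values()))
        for (a, b), v in rep.cnr.items():
            assert v == pytest.approx(rep.snr[a] - rep.snr[b], abs=1e-12)

    def test_zero_noise_raises_with_guidance(self):
        vol = np.full((2, 2, 4), 1.0)
        bg = ROI("bg", "background", box=box((0, 2), (0, 2), (2, 4)))
        sig = ROI("w", "wall", box=box((0, 2), (0, 2), (0, 2)))
        with pytest.raises(ZeroDivisionError, match="background"):
            snr(vol, sig, bg)

    def test_empty_roi_rejected(self):
        vol = np.zeros((2, 2, 2))
        r = ROI("w", "wall", box=box((0, 0), (0, 2), (0, 2)))
        with pytest.raises(ValueError):
            roi_mean(vol, r)


class TestTTest:
    def test_identical_groups(self):
        res = ttest_unpaired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_shifted_groups_significant(self):
        res = ttest_unpaired([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert res.p < 1e-3
        assert res.t < 0

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 1.3, 25)
        mine = ttest_unpaired(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert mine.t == pytest.approx(ref.statistic, rel=1e-12)
        assert mine.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 3.0, 12)
        mine = ttest_unpaired(a, b, welch=True)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert mine.t == pytest.approx(ref.statistic, rel=1e-12)
        assert mine.p == pytest.approx(ref.pvalue, rel=1e-12)

    @pytest.mark.parametrize("row,expect_t", [
        # published distal side branches: 17.0+-3.6 vs 13.6+-3.3, n=100
        ((17.0, 3.6, 100, 13.6, 3.3, 100), 6.9629),
        # published mid main arteries: 23.5+-3.7 vs 20.8+-2.8
        ((23.5, 3.7, 100, 20.8, 2.8, 100), 5.8179),
    ])
    def test_summary_t_values(self, row, expect_t):
        res = ttest_from_summary(*row)
        assert res.t == pytest.approx(expect_t, abs=5e-3)
        assert res.p < 0.05
        assert res.df == row[2] + row[5] - 2

    def test_equal_means_any_sds(self):
        res = ttest_from_summary(5.0, 1.0, 10, 5.0, 3.0, 20)
        assert res.t == 0.0 and res.p == pytest.approx(1.0)

    def test_zero_variance_conventions(self):
        same = ttest_from_summary(2.0, 0.0, 5, 2.0, 0.0, 5)
        assert same.t == 0.0 and same.p == 1.0
        diff = ttest_from_summary(3.0, 0.0, 5, 2.0, 0.0, 5)
        assert np.isinf(diff.t) and diff.p == 0.0

    def test_moment_matched_equals_summary(self):
        rng = np.random.default_rng(3)
        a = moment_matched(17.0, 3.6, 100, rng)
        b = moment_matched(13.6, 3.3, 100, rng)
        raw = ttest_unpaired(a, b)
        summ = ttest_from_summary(17.0, 3.6, 100, 13.6, 3.3, 100)
        assert raw.t == pytest.approx(summ.t, rel=1e-10)
        assert raw.p == pytest.approx(summ.p, rel=1e-10)

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        a = rng.normal(10, 2, 40)
        b = rng.normal(11, 2, 35)
        t0 = ttest_unpaired(a, b).t
        t1 = ttest_unpaired(3.0 * a + 7.0, 3.0 * b + 7.0).t
        assert t0 == pytest.approx(t1, rel=1e-9)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            ttest_unpaired([1.0], [1.0, 2.0])


class TestTTestProperties:
    from hypothesis import given, settings, strategies as st

    @staticmethod
    @given(mean_a=st.floats(-50, 50), mean_b=st.floats(-50, 50),
           sd=st.floats(0.5, 10), n=st.integers(3, 200))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_antisymmetric_in_group_order(mean_a, mean_b, sd, n):
        ab = ttest_from_summary(mean_a, sd, n, mean_b, sd, n)
        ba = ttest_from_summary(mean_b, sd, n, mean_a, sd, n)
        assert ab.t == pytest.approx(-ba.t, rel=1e-12, abs=1e-12)
        assert ab.p == pytest.approx(ba.p, rel=1e-12, abs=1e-12)

    @staticmethod
    @given(shift=st.floats(-100, 100), scale=st.floats(0.01, 100))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_t_invariant_under_common_affine_map(shift, scale):
        rng = np.random.default_rng(9)
        a = rng.normal(10, 2, 25)
        b = rng.normal(12, 3, 30)
        t0 = ttest_unpaired(a, b).t
        t1 = ttest_unpaired(scale * a + shift, scale * b + shift).t
        assert t0 == pytest.approx(t1, rel=1e-6)


class TestTTestTable:
    def test_table_layout_and_significance(self):
        rows = [
            {"segment": "Distal side branches", "mean_a": 17.0, "sd_a": 3.6,
             "n_a": 100, "mean_b": 13.6, "sd_b": 3.3, "n_b": 100},
            {"segment": "Proximal main arteries", "mean_a": 36.7,
             "sd_a": 6.2, "n_a": 100, "mean_b": 37.4, "sd_b": 5.6,
             "n_b": 100},
        ]
        df = ttest_table(rows)
        assert list(df.columns) == ["segment", "group_a", "group_b", "t",
                                    "df", "p", "significant"]
        assert bool(df.loc[0, "significant"])
        assert not bool(df.loc[1, "significant"])

    def test_bonferroni_option_tightens(self):
        # plain p ~ 0.02: significant at 0.05 but not at 0.05/20
        rows = [{"segment": "s", "mean_a": 10.0, "sd_a": 3.0, "n_a": 10,
                 "mean_b": 6.6, "sd_b": 3.0, "n_b": 10}] * 20
        plain = ttest_table(rows)
        bonf = ttest_table(rows, bonferroni=True)
        assert bool(plain.loc[0, "significant"])
        assert not bool(bonf.loc[0, "significant"])
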