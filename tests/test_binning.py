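"""Box-Cox reference distributions, bin assignment, summary metrics."""

import numpy as np
import pytest
from scipy import stats as sps

from xegas.binning import (
    BinnedMap,
    BinningError,
    bin_map,
    boxcox_inverse,
    boxcox_lambda,
    boxcox_transform,
    build_reference,
    metrics,
)
from xegas.volume import VolumeImage


def _vol_mask(values):
    """Pack a 1D sample into a volume + mask for the binning API."""
    n = int(np.ceil(len(values) ** (1 / 3))) + 1
    data = np.zeros(n ** 3)
    data[: len(values)] = values
    mask = np.zeros(n ** 3, bool)
    mask[: len(values)] = True
    return VolumeImage(data.reshape(n, n, n)), mask.reshape(n, n, n)


class TestBoxcoxLambda:
    def test_gaussian_pool_gives_lambda_near_one(self, rng):
        x = rng.normal(10.0, 1.0, 100_000)
        assert 0.7 <= boxcox_lambda(x[x > 0]) <= 1.3

    def test_lognormal_pool_gives_lambda_near_zero(self, rng):
        x = np.exp(rng.normal(0.0, 0.5, 100_000))
        assert -0.15 <= boxcox_lambda(x) <= 0.15

    def test_lambda_one_transform_is_shift(self, rng):
        x = rng.random(100) + 0.5
        np.testing.assert_allclose(boxcox_transform(x, 1.0), x - 1.0, rtol=1e-12)

    def test_nonpositive_samples_rejected(self):
        with pytest.raises(BinningError, match="positive"):
            boxcox_lambda(np.array([1.0, 0.0, 2.0]))


class TestBuildReference:
    def test_forced_lambda_one_thresholds_are_mu_plus_k_sigma(self, rng):
        mu, sigma = 10.0, 1.5
        x = rng.normal(mu, sigma, 50_000)
        ref = build_reference([_vol_mask(x[x > 0])], "ventilation", lam=1.0)
        xx = x[x > 0]
        expected = xx.mean() + np.array([-2, -1, 0, 1, 2]) * xx.std(ddof=0)
        np.testing.assert_allclose(ref.thresholds, expected, rtol=1e-9)

    def test_lognormal_thresholds_match_closed_form(self, rng):
        """At lambda -> 0 the thresholds are exp(mu_ln + k*sigma_ln)."""
        mu_ln, sd_ln = 0.5, 0.4
        x = np.exp(rng.normal(mu_ln, sd_ln, 200_000))
        ref = build_reference([_vol_mask(x)], "ventilation")
        lx = np.log(x)
        expected = np.exp(lx.mean() + np.array([-2, -1, 0, 1, 2]) * lx.std())
        np.testing.assert_allclose(ref.thresholds, expected, rtol=0.02)

    def test_threshold_invertibility(self, rng):
        x = np.exp(rng.normal(0, 0.3, 20_000))
        ref = build_reference([_vol_mask(x)], "rbc")
        y = boxcox_transform(np.asarray(ref.thresholds), ref.lam)
        back = boxcox_inverse(y, ref.lam)
        np.testing.assert_allclose(back, ref.thresholds, rtol=1e-9)

    def test_reference_self_consistency(self, rng):
        """The pooled sample's transformed mean/SD equal mu_t/sigma_t."""
        x = rng.lognormal(0.0, 0.3, 30_000)
        ref = build_reference([_vol_mask(x)], "barrier")
        t = boxcox_transform(x, ref.lam)
        assert t.mean() == pytest.approx(ref.mu_t, abs=1e-9)
        assert t.std(ddof=0) == pytest.approx(ref.sigma_t, abs=1e-9)

    def test_barrier_uses_eight_bins_top_three_purple(self, rng):
        x = rng.lognormal(0, 0.3, 5000)
        ref = build_reference([_vol_mask(x)], "barrier")
        assert ref.n_bins == 8
        assert len(ref.thresholds) == 7
        assert ref.palette[5:] == ("purple", "purple", "purple")

    def test_small_pool_warns(self, rng):
        x = rng.lognormal(0, 0.3, 200)
        with pytest.warns(UserWarning, match="pooled"):
            build_reference([_vol_mask(x)], "rbc")

    def test_nonpositive_voxels_excluded_and_counted(self, rng):
        x = np.concatenate([rng.lognormal(0, 0.3, 5000), np.zeros(17)])
        ref = build_reference([_vol_mask(x)], "rbc")
        assert ref.n_excluded_nonpositive == 17
        assert ref.n_pooled == 5000


class TestBinMap:
    def _ref(self, rng):
        x = rng.lognormal(0.0, 0.3, 20_000)
        return build_reference([_vol_mask(x)], "ventilation"), x

    def test_all_below_first_threshold_is_all_bin_one(self, rng):
        ref, _ = self._ref(rng)
        vol, mask = _vol_mask(np.full(100, ref.thresholds[0] / 2))
        binned = bin_map(vol, mask, ref)
        assert binned.bin_pct(1) == pytest.approx(100.0)

    def test_value_at_threshold_goes_to_higher_bin(self, rng):
        ref, _ = self._ref(rng)
        vol, mask = _vol_mask(np.array([ref.thresholds[2]]))
        binned = bin_map(vol, mask, ref)
        assert binned.labels.data.ravel()[0] == 4

    def test_bin_label_monotone_in_value(self, rng):
        ref, _ = self._ref(rng)
        vals = np.sort(rng.lognormal(0, 0.5, 500))
        vol, mask = _vol_mask(vals)
        labels = bin_map(vol, mask, ref).labels.data.ravel()[:500]
        assert np.all(np.diff(labels) >= 0)

    def test_percentages_sum_to_100(self, rng):
        ref, x = self._ref(rng)
        vol, mask = _vol_mask(rng.lognormal(0, 0.4, 3000))
        binned = bin_map(vol, mask, ref)
        assert binned.percentages.sum() == pytest.approx(100.0, abs=1e-9)

    def test_reference_pool_bin1_matches_normal_theory(self, rng):
        """Binning the reference pool itself: bin 1 sits below mu_t-2sigma_t,
        i.e. ~Phi(-2) = 2.3% of voxels."""
        ref, x = self._ref(rng)
        vol, mask = _vol_mask(x)
        binned = bin_map(vol, mask, ref)
        assert binned.bin_pct(1) == pytest.approx(100 * sps.norm.cdf(-2), abs=0.5)

    def test_reference_pool_green_bins_match_normal_theory(self, rng):
        """Bins 3-4 cover (mu_t - sigma_t, mu_t + sigma_t): ~68%."""
        ref, x = self._ref(rng)
        vol, mask = _vol_mask(x)
        binned = bin_map(vol, mask, ref)
        green = binned.bin_pct(3) + binned.bin_pct(4)
        assert green == pytest.approx(68.3, abs=5.0)

    def test_undefined_voxels_in_mask_rejected(self, rng):
        ref, _ = self._ref(rng)
        vol, mask = _vol_mask(np.array([1.0, np.nan]))
        with pytest.raises(BinningError, match="non-finite"):
            bin_map(vol, mask, ref)

    def test_map_type_mismatch_rejected(self, rng):
        ref, _ = self._ref(rng)
        vol, mask = _vol_mask(np.ones(10))
        with pytest.raises(BinningError, match="reference"):
            bin_map(vol, mask, ref, map_type="barrier")


class TestMetrics:
    def _binned(self, pct, n_bins):
        labels = VolumeImage(np.zeros((2, 2, 2)))
        return BinnedMap(labels=labels, percentages=np.asarray(pct, float),
                         map_type="x", n_bins=n_bins)

    def test_metric_definitions(self):
        vent = self._binned([2, 14, 34, 34, 14, 2], 6)
        rbc = self._binned([5, 10, 35, 35, 10, 5], 6)
        barrier = self._binned([2, 13, 34, 34, 13, 2, 1, 1], 8)
        out = metrics({"ventilation": vent, "rbc": rbc, "barrier": barrier})
        assert out["vdp_pct"] == 2
        assert out["low_vent_pct"] == 14
        assert out["rbc_defect_pct"] == 5
        assert out["barrier_high_pct"] == 4  # bins 6+7+8
        assert "missing_maps" not in out

    def test_missing_map_flagged_not_fatal(self):
        out = metrics({"ventilation": self._binned([10, 10, 30, 30, 10, 10], 6)})
        assert out["vdp_pct"] == 10
        assert set(out["missing_maps"]) == {"rbc", "barrier"}


def test_reference_json_roundtrip(tmp_path, rng):
    from xegas.binning import ReferenceDistribution
    x = rng.lognormal(0, 0.3, 5000)
    ref = build_reference([_vol_mask(x)], "barrier")
    ref.to_json(tmp_path / "ref.json")
    back = ReferenceDistribution.from_json(tmp_path / "ref.json")
    assert back == ref
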