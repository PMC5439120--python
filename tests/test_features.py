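"""qLE map, feature extraction, centroid, and surprise tests."""

import numpy as np
import pytest

from mmrtf import features
from mmrtf.kde import ecdf


def gaussian_blob(freqs, times, f0, t0, sf=0.15, st=40.0, amp=1.0):
    lf = np.log2(freqs / f0)[:, None]
    dt = (times - t0)[None, :]
    return amp * np.exp(-0.5 * ((lf / sf) ** 2 + (dt / st) ** 2))


@pytest.fixture()
def axes():
    return np.geomspace(2, 48, 64), np.linspace(-100, 700, 161)


class TestMinimumBound:
    def test_single_condition_identity(self, rng):
        g = rng.random((4, 6))
        assert np.array_equal(features.minimum_bound([g]), g)

    def test_max_with_zero(self, rng):
        a = rng.random((4, 6))
        assert np.array_equal(features.minimum_bound([np.zeros_like(a), a]), a)

    def test_elementwise_max_brute_force(self, rng):
        mats = [rng.random((2, 2)) for _ in range(3)]
        b = features.minimum_bound(mats)
        for i in range(2):
            for j in range(2):
                assert b[i, j] == max(m[i, j] for m in mats)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            features.minimum_bound([np.zeros((2, 2)), np.zeros((3, 2))])


class TestQleMap:
    def test_range_and_monotonicity(self, rng):
        B = rng.random((20, 30))
        G1 = rng.random((20, 30))
        G2 = np.clip(G1 + 0.1, 0, None)
        q1, q2 = features.qle_map(G1, B), features.qle_map(G2, B)
        assert (q1 >= 0).all() and (q1 <= 1).all()
        assert (q2 >= q1 - 1e-12).all()

    def test_squared_ecdf_oracle(self, rng):
        B = rng.gamma(2.0, 1.0, size=(100, 100))
        G = rng.gamma(2.0, 1.0, size=(100, 100))
        q = features.qle_map(G, B, method="kde")
        oracle = ecdf(B.ravel(), G) ** 2
        assert np.max(np.abs(q - oracle)) < 0.02

    def test_degenerate_bound_warns_quarter(self):
        with pytest.warns(UserWarning, match="degenerate"):
            q = features.qle_map(np.random.rand(3, 3), np.ones((3, 3)))
        assert np.allclose(q, 0.25)


class TestExtractFeatures:
    def test_zero_threshold_single_feature(self, axes, rng):
        freqs, times = axes
        qle = rng.random((freqs.size, times.size)) * 0.5 + 0.25
        fs = features.extract_features(qle, freqs, times, threshold=0.0)
        # the 12 Hz band split may produce one feature per side
        assert 1 <= len(fs.features) <= 2
        assert fs.H.all()

    def test_two_disjoint_blobs_two_features(self, axes):
        freqs, times = axes
        qle = gaussian_blob(freqs, times, 5.0, 100.0) + gaussian_blob(freqs, times, 34.0, 50.0)
        fs = features.extract_features(qle, freqs, times, threshold=0.8)
        assert len(fs.features) == 2
        names = {f.name for f in fs.features}
        assert names == {"theta-1", "beta-gamma"}
        masks = [f.mask for f in fs.features]
        assert not (masks[0] & masks[1]).any()

    def test_threshold_above_max_empty(self, axes, rng):
        freqs, times = axes
        qle = rng.random((freqs.size, times.size)) * 0.5
        with pytest.warns(UserWarning, match="threshold"):
            fs = features.extract_features(qle, freqs, times, threshold=0.99)
        assert fs.features == []

    def test_region_spanning_band_boundary_split(self, axes):
        freqs, times = axes
        qle = gaussian_blob(freqs, times, 12.0, 100.0, sf=0.5, amp=1.0)
        fs = features.extract_features(qle, freqs, times, threshold=0.5)
        assert len(fs.features) >= 2
        for f in fs.features:
            rows = freqs[f.mask.any(axis=1)]
            assert (rows < 12.0).all() or (rows >= 12.0).all()

    def test_theta_features_ordered_by_latency(self, axes):
        freqs, times = axes
        qle = gaussian_blob(freqs, times, 5.0, 300.0) + gaussian_blob(freqs, times, 6.0, 50.0)
        fs = features.extract_features(qle, freqs, times, threshold=0.8)
        by_name = {f.name: f for f in fs.features}
        assert by_name["theta-1"].peak_latency_ms < by_name["theta-2"].peak_latency_ms


class TestFeatureDistributions:
    def test_single_point_mask_arithmetic(self):
        g = np.zeros((4, 6))
        g[2, 3] = 5.0
        h = np.zeros_like(g, dtype=bool)
        h[2, 3] = True
        y_t, y_f = features.feature_distributions(h, g)
        assert y_t[3] == pytest.approx(5.0 / 4)   # mean over K=4 scales
        assert y_f[2] == pytest.approx(5.0 / 6)   # mean over J=6 time points
        assert (np.delete(y_t, 3) == 0).all()

    def test_separable_blob_marginals_proportional(self):
        u, v = np.array([1.0, 3.0, 2.0]), np.array([0.5, 1.0, 0.25, 0.75])
        g = np.outer(u, v)
        h = np.ones_like(g, dtype=bool)
        y_t, y_f = features.feature_distributions(h, g)
        assert np.allclose(y_t / y_t.sum(), v / v.sum())
        assert np.allclose(y_f / y_f.sum(), u / u.sum())

    def test_empty_mask_zero_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            y_t, y_f = features.feature_distributions(np.zeros((3, 4), bool), np.ones((3, 4)))
        assert (y_t == 0).all() and (y_f == 0).all()


class TestFeatureCentroids:
    def centroid_for(self, qle, freqs, times, g=None, threshold=0.8):
        fs = features.extract_features(qle, freqs, times, threshold=threshold)
        assert fs.features
        feat = fs.features[0]
        y_t, y_f = features.feature_distributions(feat.mask, qle if g is None else g)
        return features.feature_centroids(
            y_t, y_f, feat.mask, qle if g is None else g, freqs, times, feature=feat.name
        )

    def test_single_blob_centroid_at_center(self, axes):
        freqs, times = axes
        qle = gaussian_blob(freqs, times, 17.0, 60.0)
        cents = self.centroid_for(qle, freqs, times)
        assert len(cents) == 1
        step = freqs[1] / freqs[0]
        assert abs(np.log(cents[0].freq_hz / 17.0)) <= np.log(step) * 1.5
        assert abs(cents[0].latency_ms - 60.0) <= (times[1] - times[0]) * 1.5

    def test_two_spectral_peaks_split_ordered_by_frequency(self, axes):
        # merged gamma+beta cloud: a single connected supra region whose
        # spectral distribution is bimodal must yield two centroids
        freqs, times = axes
        qle = (gaussian_blob(freqs, times, 34.0, 60.0, sf=0.25)
               + gaussian_blob(freqs, times, 18.0, 60.0, sf=0.25))
        fs = features.extract_features(qle, freqs, times, threshold=0.15)
        high = [f for f in fs.features if f.peak_freq_hz >= 12.0]
        cents = []
        for feat in high:
            y_t, y_f = features.feature_distributions(feat.mask, qle)
            cents += features.feature_centroids(y_t, y_f, feat.mask, qle, freqs, times)
        assert len(cents) >= 2
        freqs_found = sorted(c.freq_hz for c in cents)
        assert any(abs(fc - 18.0) < 3.0 for fc in freqs_found)
        assert any(abs(fc - 34.0) < 4.0 for fc in freqs_found)
        # composite features report gamma (higher frequency) first
        per_feature = features.centroid_table(fs, {"x": qle})
        high_rows = per_feature[per_feature.freq_hz >= 12.0]
        assert not high_rows.empty

    def test_temporal_onset_offset_split(self, axes):
        # one connected theta region with onset and offset temporal peaks
        freqs, times = axes
        qle = (gaussian_blob(freqs, times, 6.0, 220.0, st=90.0)
               + gaussian_blob(freqs, times, 6.0, 500.0, st=90.0))
        fs = features.extract_features(qle, freqs, times, threshold=0.25)
        theta = [f for f in fs.features if f.peak_freq_hz <= 8.0]
        cents = []
        for feat in theta:
            y_t, y_f = features.feature_distributions(feat.mask, qle)
            cents += features.feature_centroids(y_t, y_f, feat.mask, qle, freqs, times)
        lats = sorted(c.latency_ms for c in cents)
        assert len(cents) >= 2
        assert abs(lats[0] - 220.0) < 40.0 and abs(lats[-1] - 500.0) < 40.0

    def test_centroid_rp_bounded_by_mask_max(self, axes, rng):
        freqs, times = axes
        qle = gaussian_blob(freqs, times, 10.0, 300.0)
        g = rng.random(qle.shape)
        cents = self.centroid_for(qle, freqs, times, g=g)
        fs = features.extract_features(qle, freqs, times, threshold=0.8)
        mask = fs.features[0].mask
        for c in cents:
            assert c.rp <= g[mask].max() + 1e-12


class TestSurprise:
    def test_zero_when_balanced(self):
        si = features.SurpriseInput(dF=0.3, dT=0.3, c_cfc=1.0)
        assert features.surprise(si) == pytest.approx(0.0)

    def test_halving_df_adds_log_two(self):
        s1 = features.surprise(features.SurpriseInput(dF=0.4, dT=0.5))
        s2 = features.surprise(features.SurpriseInput(dF=0.2, dT=0.5))
        assert s2 - s1 == pytest.approx(np.log(2.0))

    def test_direct_value(self):
        s = features.surprise(features.SurpriseInput(dF=0.2, dT=0.5, c_cfc=1.0))
        assert s == pytest.approx(-np.log(0.4), abs=1e-12)

    def test_invalid_probabilities_raise(self):
        with pytest.raises(ValueError):
            features.SurpriseInput(dF=0.0, dT=0.5)
        with pytest.raises(ValueError):
            features.SurpriseInput(dF=0.5, dT=0.5, c_cfc=-1.0)

    def test_overlap_estimator_monotone_in_separation(self, axes):
        freqs, times = axes
        # growing spectral separation between theta components shrinks dF and
        # raises the surprise, as the statistic is meant to behave
        surprises = []
        for f2 in (5.5, 6.5, 8.0):
            y_f1 = np.exp(-0.5 * (np.log2(freqs / 5.0) / 0.2) ** 2)
            y_f2 = np.exp(-0.5 * (np.log2(freqs / f2) / 0.2) ** 2)
            y_t1 = np.exp(-0.5 * ((times - 70.0) / 60.0) ** 2)
            y_t2 = np.exp(-0.5 * ((times - 220.0) / 60.0) ** 2)
            si = features.estimate_surprise_inputs(y_f1, y_f2, y_t1, y_t2)
            surprises.append(features.surprise(si))
        assert surprises[0] < surprises[1] < surprises[2]
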