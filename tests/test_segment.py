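import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_force_gev, smoothing_cost_oracle, smoothing_icm_oracle
from microstates import EEGRecording
from microstates.cluster import MicrostateModel, compute_gfp
from microstates.segment import (
    Segmentation,
    SmoothingParams,
    backfit,
    compute_gev,
    compute_metrics,
    smooth_labels,
    spatial_correlation,
)
from microstates.synth import SimulationConfig, generate_templates, simulate_recording


def make_model(maps):
    K = maps.shape[0]
    return MicrostateModel(maps=maps, gev_total=np.nan, gev_per_class=np.full(K, np.nan))


class TestSpatialCorrelation:
    def test_self_negation_orthogonal(self, orthogonal_templates):
        a, b = orthogonal_templates[0], orthogonal_templates[1]
        assert spatial_correlation(a, a) == pytest.approx(1.0)
        assert spatial_correlation(a, -a) == pytest.approx(-1.0)
        assert abs(spatial_correlation(a, b)) < 1e-10

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            spatial_correlation(np.ones(5), np.arange(5.0))


class TestBackfit:
    def test_pure_map_recording(self, orthogonal_templates):
        model = make_model(orthogonal_templates)
        amps = np.array([2.0, -3.0, 0.5, -1.0, 4.0])
        data = (orthogonal_templates[2][:, None] * amps[None, :])
        seg = backfit(EEGRecording(data=data, fs=10.0), model)
        np.testing.assert_array_equal(seg.labels, 2)

    def test_matches_per_sample_scan(self, rng, orthogonal_templates):
        """Backfit equals an exhaustive per-sample argmax of |correlation|."""
        model = make_model(orthogonal_templates)
        data = rng.normal(size=(16, 100))
        rec = EEGRecording(data=data, fs=10.0)
        seg = backfit(rec, model)
        for t in range(100):
            corrs = [
                abs(spatial_correlation(data[:, t], m)) for m in orthogonal_templates
            ]
            assert seg.labels[t] == int(np.argmax(corrs))

    def test_channel_mismatch_rejected(self, orthogonal_templates, rng):
        model = make_model(orthogonal_templates)
        model.channel_labels = [f"X{i}" for i in range(16)]
        rec = EEGRecording(data=rng.normal(size=(16, 10)), fs=10.0)
        with pytest.raises(ValueError, match="channel sets"):
            backfit(rec, model)

    def test_noiseless_recovers_planted_labels(self):
        cfg = SimulationConfig(n_channels=24, duration_s=10.0, k_true=3, snr=None, seed=8)
        rec, gt = simulate_recording(cfg)
        seg = backfit(rec, make_model(gt.templates))
        np.testing.assert_array_equal(seg.labels, gt.labels)


class TestSmoothing:
    def test_lambda_zero_is_identity(self, preprocessed_sim, fitted_model):
        _, rec, _ = preprocessed_sim
        seg = backfit(rec, fitted_model)
        out = smooth_labels(seg, compute_gfp(rec), fitted_model, SmoothingParams(3, 0.0))
        np.testing.assert_array_equal(out.labels, seg.labels)

    def test_blip_absorbed_and_cost_matches_oracle(self):
        """A 1-sample blip with equal data terms is absorbed into the
        surrounding run, and the implementation's cost matrix equals the
        brute-force objective exactly."""
        C = 8
        maps = generate_templates(3, C, seed=0)
        # samples equal to the third map: zero correlation with maps 0 and 1
        data = np.tile(maps[2][:, None], (1, 21)) * 5.0
        rec = EEGRecording(data=data, fs=125.0)
        model = make_model(maps[:2])
        seg = backfit(rec, model)
        labels0 = np.zeros(21, dtype=int)
        labels0[10] = 1  # plant the blip
        seg = Segmentation(
            labels=labels0, fs=rec.fs, n_classes=2,
            corr_matrix=seg.corr_matrix, corr_trace=seg.corr_trace,
        )
        gfp = compute_gfp(rec)
        out, diag = smooth_labels(
            seg, gfp, model, SmoothingParams(3, 10.0), return_diagnostics=True
        )
        np.testing.assert_array_equal(out.labels, 0)
        oracle_cost = smoothing_cost_oracle(diag["d2"], out.labels, 3, 10.0, C)
        np.testing.assert_allclose(diag["final_cost"], oracle_cost, atol=1e-12)
        oracle_labels = smoothing_icm_oracle(diag["d2"], labels0, 3, 10.0, C)
        np.testing.assert_array_equal(out.labels, oracle_labels)

    def test_matches_independent_icm(self, preprocessed_sim, fitted_model):
        """Full smoothing run equals an independent ICM implementation."""
        _, rec, _ = preprocessed_sim
        short = rec.with_data(rec.data[:, :400])
        seg = backfit(short, fitted_model)
        gfp = compute_gfp(short)
        out, diag = smooth_labels(
            seg, gfp, fitted_model, SmoothingParams(3, 10.0), return_diagnostics=True
        )
        oracle = smoothing_icm_oracle(diag["d2"], seg.labels, 3, 10.0, short.n_channels)
        np.testing.assert_array_equal(out.labels, oracle)

    def test_duration_monotone_in_strength(self, preprocessed_sim, fitted_model):
        _, rec, _ = preprocessed_sim
        seg = backfit(rec, fitted_model)
        gfp = compute_gfp(rec)
        durs = []
        for lam in (0.0, 1.0, 5.0, 10.0):
            out = smooth_labels(seg, gfp, fitted_model, SmoothingParams(3, lam))
            durs.append(np.nanmean(compute_metrics(out).duration_ms))
        assert all(b >= a for a, b in zip(durs, durs[1:])), durs

    def test_preserves_shape_and_alphabet(self, preprocessed_sim, fitted_model):
        _, rec, _ = preprocessed_sim
        seg = backfit(rec, fitted_model)
        out = smooth_labels(seg, compute_gfp(rec), fitted_model)
        assert out.n_samples == seg.n_samples
        assert out.n_classes == seg.n_classes


class TestMetrics:
    def test_single_class_whole_recording(self):
        seg = Segmentation(labels=np.zeros(1250, dtype=int), fs=125.0, n_classes=1)
        m = compute_metrics(seg)
        assert m.coverage[0] == pytest.approx(1.0)
        assert m.occurrence_per_s[0] == pytest.approx(0.1)
        assert m.duration_ms[0] == pytest.approx(10_000.0)

    def test_alternating_classes(self):
        """Two classes alternating every 5 samples at 125 Hz."""
        labels = np.tile(np.repeat([0, 1], 5), 100)
        seg = Segmentation(labels=labels, fs=125.0, n_classes=2)
        m = compute_metrics(seg)
        np.testing.assert_allclose(m.coverage, 0.5)
        np.testing.assert_allclose(m.duration_ms, 40.0)
        np.testing.assert_allclose(m.occurrence_per_s, 12.5)

    def test_absent_class(self):
        seg = Segmentation(labels=np.zeros(100, dtype=int), fs=100.0, n_classes=3)
        m = compute_metrics(seg)
        assert np.isnan(m.duration_ms[1]) and np.isnan(m.duration_ms[2])
        assert m.occurrence_per_s[1] == 0.0 and m.coverage[2] == 0.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), k=st.integers(2, 5))
    def test_algebraic_identities(self, seed, k):
        """Coverage sums to 1; coverage = occurrence x duration / 1000 when
        durations include the edge segments."""
        r = np.random.default_rng(seed)
        labels = r.integers(0, k, size=500)
        seg = Segmentation(labels=labels, fs=125.0, n_classes=k)
        m = compute_metrics(seg, exclude_edge_segments_from_duration=False)
        assert m.coverage.sum() == pytest.approx(1.0, abs=1e-12)
        present = ~np.isnan(m.duration_ms)
        np.testing.assert_allclose(
            m.coverage[present],
            m.occurrence_per_s[present] * m.duration_ms[present] / 1000.0,
            atol=1e-12,
        )


class TestGEV:
    def test_perfect_fit(self, orthogonal_templates, rng):
        model = make_model(orthogonal_templates)
        labels = rng.integers(0, 4, size=50)
        amps = rng.uniform(0.5, 2.0, size=50)
        data = (orthogonal_templates[labels] * amps[:, None]).T
        rec = EEGRecording(data=data, fs=10.0)
        seg = Segmentation(labels=labels, fs=10.0, n_classes=4)
        per_class, total = compute_gev(rec, model, seg)
        assert total == pytest.approx(1.0, abs=1e-12)
        assert per_class.sum() == pytest.approx(total, abs=1e-12)

    def test_matches_brute_force(self, rng, orthogonal_templates):
        model = make_model(orthogonal_templates)
        data = rng.normal(size=(16, 80))
        rec = EEGRecording(data=data, fs=10.0)
        seg = backfit(rec, model)
        per_class, total = compute_gev(rec, model, seg)
        o_per, o_total = brute_force_gev(rec.data, model.maps, seg.labels)
        np.testing.assert_allclose(per_class, o_per, atol=1e-12)
        assert total == pytest.approx(o_total, abs=1e-12)
        assert np.all(per_class >= 0) and 0 <= total <= 1

    def test_zero_gfp_rejected(self, orthogonal_templates):
        model = make_model(orthogonal_templates)
        rec = EEGRecording(data=np.ones((16, 10)), fs=10.0)
        seg = Segmentation(labels=np.zeros(10, dtype=int), fs=10.0, n_classes=4)
        with pytest.raises(ValueError, match="zero total GFP"):
            compute_gev(rec, model, seg)


def test_polarity_invariance_end_to_end(preprocessed_sim, fitted_model):
    """Flipping the sign of the whole recording changes nothing downstream."""
    _, rec, _ = preprocessed_sim
    flipped = rec.with_data(-rec.data)
    gfp = compute_gfp(rec)
    seg1 = smooth_labels(backfit(rec, fitted_model), gfp, fitted_model)
    seg2 = smooth_labels(backfit(flipped, fitted_model), compute_gfp(flipped), fitted_model)
    np.testing.assert_array_equal(seg1.labels, seg2.labels)
    m1, m2 = compute_metrics(seg1), compute_metrics(seg2)
    np.testing.assert_allclose(m1.duration_ms, m2.duration_ms)
    np.testing.assert_allclose(m1.coverage, m2.coverage)
    g1 = compute_gev(rec, fitted_model, seg1)
    g2 = compute_gev(flipped, fitted_model, seg2)
    np.testing.assert_allclose(g1[0], g2[0], atol=1e-12)


def test_parameter_recovery_scaled():
    """Recovered duration/occurrence/coverage track planted truth within 15%
    on scaled-down synthetic data (48 ch, 60 s, snr 2, 3 seeds)."""
    from microstates.cluster import extract_peak_maps, modified_kmeans
    from microstates.preprocess import average_reference, bandpass_filter

    ratios = {"d": [], "o": [], "c": []}
    for seed in (1, 2, 3):
        cfg = SimulationConfig(n_channels=48, duration_s=60.0, k_true=4, snr=2.0, seed=seed)
        rec, gt = simulate_recording(cfg)
        r = average_reference(bandpass_filter(rec))
        maps, _ = extract_peak_maps(r)
        model = modified_kmeans(maps, 4, n_restarts=10, seed=seed)
        seg = smooth_labels(backfit(r, model), compute_gfp(r), model)
        m = compute_metrics(seg)
        match = np.abs(model.maps @ gt.templates.T).argmax(axis=1)
        inv = np.argsort(match)
        ratios["d"].append(m.duration_ms[inv] / gt.duration_ms)
        ratios["o"].append(m.occurrence_per_s[inv] / gt.occurrence_per_s)
        ratios["c"].append(m.coverage[inv] / gt.coverage)
    for v in ratios.values():
        assert np.abs(np.mean(v, axis=0) - 1.0).max() < 0.15
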