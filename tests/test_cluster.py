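import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_force_peaks
from microstates import EEGRecording
from microstates.cluster import (
    GFPSeries,
    compute_gfp,
    find_gfp_peaks,
    modified_kmeans,
    select_optimal_k,
    two_level_cluster,
)
from microstates.synth import SimulationConfig, generate_templates, simulate_recording


class TestGFP:
    def test_known_values(self):
        data = np.array([[1.0, 0.0, 3.0], [-1.0, 0.0, 3.0]])
        gfp = compute_gfp(EEGRecording(data=data, fs=10.0))
        # (+1,-1) -> 1; equal channels -> 0
        np.testing.assert_allclose(gfp.values, [1.0, 0.0, 0.0], atol=1e-12)

    def test_polarity_invariant(self, random_recording):
        flipped = random_recording.with_data(-random_recording.data)
        np.testing.assert_allclose(
            compute_gfp(flipped).values, compute_gfp(random_recording).values
        )


class TestPeaks:
    def test_monotone_series_has_none(self):
        gfp = GFPSeries(values=np.arange(10.0), fs=1.0)
        assert find_gfp_peaks(gfp).size == 0

    def test_simple_peak(self):
        gfp = GFPSeries(values=np.array([0.0, 1.0, 0.0]), fs=1.0)
        np.testing.assert_array_equal(find_gfp_peaks(gfp), [1])

    def test_plateau_first_index(self):
        gfp = GFPSeries(values=np.array([0.0, 2.0, 2.0, 2.0, 1.0, 3.0, 0.0]), fs=1.0)
        np.testing.assert_array_equal(find_gfp_peaks(gfp), [1, 5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), min_dist=st.integers(1, 7))
    def test_matches_brute_force(self, seed, min_dist):
        r = np.random.default_rng(seed)
        # mix continuous values and ties to exercise the plateau rule
        v = np.round(r.normal(size=200), 1)
        gfp = GFPSeries(values=np.abs(v), fs=1.0)
        expected = brute_force_peaks(np.abs(v), min_dist)
        np.testing.assert_array_equal(find_gfp_peaks(gfp, min_dist), expected)


class TestModifiedKmeans:
    def test_exact_recovery_orthogonal(self, orthogonal_templates):
        """K orthogonal maps repeated -> GEV 1 and perfect prototypes."""
        X = np.repeat(orthogonal_templates, 50, axis=0)
        model = modified_kmeans(X, 4, n_restarts=5, seed=0)
        assert model.gev_total == pytest.approx(1.0, abs=1e-12)
        corr = np.abs(model.maps @ orthogonal_templates.T)
        np.testing.assert_allclose(corr.max(axis=0), 1.0, atol=1e-10)
        # each template matched by exactly one prototype
        assert sorted(corr.argmax(axis=0)) == [0, 1, 2, 3]

    def test_polarity_invariance(self, rng):
        X = rng.normal(size=(60, 12))
        m1 = modified_kmeans(X, 3, n_restarts=5, seed=1)
        m2 = modified_kmeans(-X, 3, n_restarts=5, seed=1)
        assert m1.gev_total == pytest.approx(m2.gev_total, abs=1e-12)
        corr = np.abs(m1.maps @ m2.maps.T)
        np.testing.assert_allclose(np.sort(corr.max(axis=0)), 1.0, atol=1e-10)

    def test_channel_permutation_equivariance(self, rng):
        X = rng.normal(size=(60, 12))
        perm = rng.permutation(12)
        m1 = modified_kmeans(X, 3, n_restarts=5, seed=1)
        m2 = modified_kmeans(X[:, perm], 3, n_restarts=5, seed=1)
        np.testing.assert_allclose(np.abs(m1.maps[:, perm]), np.abs(m2.maps), atol=1e-8)

    def test_gev_trace_monotone_and_consistent(self, rng):
        """Within a restart GEV never decreases, and each iteration's GEV
        matches an independent evaluation of the definition."""
        X = rng.normal(size=(80, 10))
        model = modified_kmeans(X, 3, n_restarts=1, seed=4, record_history=True)
        trace = model.meta["gev_trace"]
        assert np.all(np.diff(trace) >= -1e-12)
        Xc = X - X.mean(axis=1, keepdims=True)
        w = (Xc**2).sum(axis=1)
        for snap in model.meta["history"]:
            A, labels = snap["maps"], snap["labels"]
            r = np.abs(
                (Xc / np.linalg.norm(Xc, axis=1, keepdims=True) @ A.T)[
                    np.arange(len(labels)), labels
                ]
            )
            gev = (w * r**2).sum() / w.sum()
            assert snap["gev"] == pytest.approx(gev, abs=1e-12)

    def test_more_classes_never_reduce_gev(self, rng):
        X = rng.normal(size=(100, 10))
        gevs = [
            modified_kmeans(X, k, n_restarts=10, seed=0).gev_total for k in range(2, 7)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(gevs, gevs[1:]))
        assert all(0.0 <= g <= 1.0 for g in gevs)

    def test_too_few_maps_rejected(self, rng):
        with pytest.raises(ValueError, match="K=5"):
            modified_kmeans(rng.normal(size=(4, 8)), 5)


class TestSelectOptimalK:
    def test_single_candidate(self, rng):
        X = rng.normal(size=(40, 10))
        report = select_optimal_k(X, [3], n_restarts=5, seed=0)
        assert report.selected_k == 3
        assert report.scores.shape == (1, 7)

    def test_normalization_contract(self, rng):
        X = rng.normal(size=(60, 10))
        report = select_optimal_k(X, range(2, 6), n_restarts=5, seed=0)
        for col in report.normalized.columns:
            v = report.normalized[col].dropna()
            assert v.min() == pytest.approx(0.0, abs=1e-12)
            assert v.max() == pytest.approx(1.0, abs=1e-12)

    def test_recovers_planted_k(self):
        """Peak maps from 4 well-separated templates at high SNR -> K* = 4
        in at least 9 of 10 seeds."""
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            templates = generate_templates(4, 32, seed=seed)
            labels = r.integers(0, 4, size=300)
            amps = r.uniform(0.5, 1.5, size=300)
            X = templates[labels] * amps[:, None]
            X += 0.05 * r.normal(size=X.shape)  # high SNR perturbation
            report = select_optimal_k(X, range(2, 8), n_restarts=10, seed=seed)
            hits += report.selected_k == 4
        assert hits >= 9


class TestTwoLevel:
    def test_single_subject_degenerate(self, preprocessed_sim):
        cfg, rec, gt = preprocessed_sim
        model, report, subject_models = two_level_cluster(
            [rec], k_range=range(2, 6), individual_k=4, n_restarts=8, seed=0
        )
        assert set(subject_models) == {"sim0"}
        assert model.K == report.selected_k

    def test_group_recovery_and_order_invariance(self):
        """Subjects sharing templates -> global maps match them; permuting
        subject order changes nothing (up to map order and sign)."""
        from microstates.preprocess import average_reference, bandpass_filter
        from microstates.synth import simulate_cohort

        cfg = SimulationConfig(n_channels=48, duration_s=40.0, k_true=4, snr=2.0, seed=21)
        recs, gts, templates = simulate_cohort(cfg, 5)
        recs = [average_reference(bandpass_filter(r)) for r in recs]
        model, _, _ = two_level_cluster(
            recs, k_range=range(2, 7), individual_k=4, n_restarts=10, seed=3
        )
        assert model.K == 4
        corr = np.abs(model.maps @ templates.T)
        assert corr.max(axis=0).min() >= 0.95
        model_p, _, _ = two_level_cluster(
            recs[::-1], k_range=range(2, 7), individual_k=4, n_restarts=10, seed=3
        )
        cross = np.abs(model.maps @ model_p.maps.T)
        np.testing.assert_allclose(cross.max(axis=0), 1.0, atol=1e-8)
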