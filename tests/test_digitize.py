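"""Movement compensation, cluster detection, and the full digitization pipeline."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from emtdig import (
    ClusterCountMismatchError,
    DigitizedPoint,
    NoiseModel,
    TrackingStream,
    compensate_reference,
    default_config,
    depth_compensate,
    detect_clusters,
    filter_error_index,
    fixture_head_truth,
    make_fixture,
    run_session,
    simulate_session_streams,
    sinusoidal_motion,
)

from conftest import random_rigid


def _stream(positions, rate=40.0, error_index=None, orientations=None):
    n = len(positions)
    return TrackingStream(
        np.arange(n) / rate,
        positions,
        rate=rate,
        error_index=error_index,
        orientations=orientations,
    )


class TestCompensateReference:
    def test_reference_at_origin_is_identity(self, rng):
        pos = rng.uniform(-50, 50, size=(100, 3))
        stylus = _stream(pos)
        reference = _stream(np.zeros((100, 3)))
        out = compensate_reference(stylus, reference)
        np.testing.assert_array_equal(out.positions, pos)

    def test_constant_reference_subtracts_offset(self, rng):
        pos = rng.uniform(-50, 50, size=(100, 3))
        stylus = _stream(pos)
        reference = _stream(np.tile([0.0, 0.0, 50.0], (100, 1)))
        out = compensate_reference(stylus, reference)
        np.testing.assert_allclose(out.positions, pos - [0, 0, 50], atol=1e-12)

    def test_rigid_comotion_gives_constant_output(self, head35):
        """A fixture rotating rigidly with the reference digitizes as if still."""
        cfg = default_config("aurora", seed=0)
        stylus, reference = simulate_session_streams(
            head35, cfg, noise=NoiseModel(sigma0=0.0), motion=sinusoidal_motion()
        )
        out = compensate_reference(stylus, reference)
        n_dwell = int(cfg.dwell_time * cfg.rate)
        for i in range(len(head35.points)):
            block = out.positions[i * n_dwell : (i + 1) * n_dwell]
            assert block.var(axis=0).max() < 1e-12

    def test_timestamp_mismatch_rejected(self, rng):
        stylus = _stream(rng.uniform(size=(10, 3)))
        reference = TrackingStream(
            np.arange(10) / 40.0 + 0.01, np.zeros((10, 3)), rate=40.0
        )
        with pytest.raises(ValueError, match="timestamp"):
            compensate_reference(stylus, reference)

    def test_sample_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="sample counts"):
            compensate_reference(
                _stream(rng.uniform(size=(10, 3))), _stream(np.zeros((9, 3)))
            )


class TestDetectClusters:
    def _planted(self, rng, centers, n_dwell=120, sigma=0.1, n_transit=15):
        """Dwells at each center joined by fast straight transits."""
        chunks = []
        prev = None
        for c in centers:
            c = np.asarray(c, dtype=float)
            if prev is not None and n_transit:
                frac = np.linspace(0, 1, n_transit + 2)[1:-1, None]
                chunks.append(prev + frac * (c - prev))
            chunks.append(c + rng.normal(0, sigma, size=(n_dwell, 3)))
            prev = c
        return _stream(np.vstack(chunks))

    def test_single_planted_cluster_recovered(self, rng):
        c = np.array([10.0, -5.0, 30.0])
        lead_in = np.linspace([60, 60, 60], c, 22)[:-1]
        stream = _stream(
            np.vstack([lead_in, c + rng.normal(0, 0.1, size=(120, 3))])
        )
        clusters = detect_clusters(stream, radius=1.0, min_count=100)
        assert len(clusters) == 1
        assert len(clusters[0]) >= 100
        assert np.linalg.norm(clusters[0].centroid - c) < 0.2

    def test_short_run_is_transit(self, rng):
        stream = self._planted(rng, [(0, 0, 0)], n_dwell=50)
        assert detect_clusters(stream, radius=1.0, min_count=100) == []

    def test_two_dwells_in_time_order(self, rng):
        a, b = np.zeros(3), np.array([50.0, 0.0, 0.0])
        clusters = detect_clusters(self._planted(rng, [a, b]), radius=1.0)
        assert len(clusters) == 2
        assert np.linalg.norm(clusters[0].centroid - a) < 0.2
        assert np.linalg.norm(clusters[1].centroid - b) < 0.2
        assert clusters[0].indices.max() < clusters[1].indices.min()

    def test_samples_belong_to_at_most_one_cluster(self, rng):
        stream = self._planted(rng, [(0, 0, 0), (50, 0, 0), (0, 50, 0)])
        clusters = detect_clusters(stream, radius=1.0)
        all_idx = np.concatenate([c.indices for c in clusters])
        assert len(all_idx) == len(set(all_idx))

    def test_pairwise_rule_matches_centroid_rule_on_clean_dwells(self, rng):
        stream = self._planted(rng, [(0, 0, 0), (50, 0, 0)], sigma=0.05)
        by_c = detect_clusters(stream, radius=1.0, rule="centroid")
        by_p = detect_clusters(stream, radius=1.0, rule="pairwise")
        assert len(by_c) == len(by_p) == 2
        for cc, cp in zip(by_c, by_p):
            np.testing.assert_allclose(cc.centroid, cp.centroid, atol=0.05)

    def test_centroid_unbiased_under_symmetric_noise(self, rng):
        """Mean centroid deviation over repeats < 3*sigma/sqrt(min_count)."""
        c = np.array([5.0, 5.0, 5.0])
        sigma, n_rep = 0.3, 100
        devs = np.empty((n_rep, 3))
        for i in range(n_rep):
            stream = _stream(c + rng.normal(0, sigma, size=(120, 3)))
            (cl,) = detect_clusters(stream, radius=3.0, min_count=100)
            devs[i] = cl.centroid - c
        assert np.linalg.norm(devs.mean(axis=0)) < 3 * sigma / np.sqrt(100)

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError):
            detect_clusters(_stream(np.empty((0, 3))))


class TestFilterErrorIndex:
    def test_max_one_keeps_everything(self, rng):
        ei = rng.uniform(0, 1, size=60)
        stream = _stream(rng.uniform(size=(60, 3)), error_index=ei)
        assert len(filter_error_index(stream, 1.0)) == 60

    def test_max_zero_drops_positive_indices(self, rng):
        stream = _stream(
            rng.uniform(size=(30, 3)), error_index=rng.uniform(0.1, 1.0, 30)
        )
        assert len(filter_error_index(stream, 0.0)) == 0

    def test_mixed_indices_direct_count(self, rng):
        ei = np.concatenate([np.full(60, 0.1), np.full(60, 0.9)])
        stream = _stream(rng.uniform(size=(120, 3)), error_index=ei)
        out = filter_error_index(stream, 0.5)
        assert len(out) == 60
        np.testing.assert_array_equal(out.error_index, 0.1)

    def test_stream_without_index_rejected(self, rng):
        with pytest.raises(ValueError, match="error index"):
            filter_error_index(_stream(rng.uniform(size=(10, 3))), 0.5)


class TestDepthCompensate:
    def test_hand_example(self):
        p = DigitizedPoint("a", "extra", (0, 0, 10.0))
        out = depth_compensate(p, (0, 0, 1.0), depth=2.0)
        np.testing.assert_allclose(out.position, [0, 0, 8.0])

    def test_zero_depth_is_identity(self):
        p = DigitizedPoint("a", "extra", (1.0, 2.0, 3.0))
        np.testing.assert_array_equal(
            depth_compensate(p, (0, 0, 1.0), depth=0.0).position, p.position
        )

    def test_inverse_pair(self):
        p = DigitizedPoint("a", "extra", (1.0, -2.0, 3.0))
        n = np.array([1.0, 1.0, 1.0]) / np.sqrt(3)
        back = depth_compensate(depth_compensate(p, n, 2.0), n, -2.0)
        np.testing.assert_allclose(back.position, p.position, atol=1e-12)

    def test_non_unit_normal_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            depth_compensate(DigitizedPoint("a", "extra", (0, 0, 0)), (0, 0, 2.0))


class TestRunSession:
    @pytest.mark.parametrize(
        "name", ["test_frame_9", "phantom_5", "head35", "eegcap32"]
    )
    def test_noiseless_end_to_end_identity(self, name):
        fx = make_fixture(name)
        cfg = default_config("fastrak_tx2", seed=0)
        stylus, reference = simulate_session_streams(
            fx, cfg, noise=NoiseModel(sigma0=0.0)
        )
        session = run_session(stylus, reference, list(zip(fx.labels, fx.kinds)))
        truth = fixture_head_truth(fx)
        for p in session.points:
            assert np.linalg.norm(p.position - truth[p.label]) < 1e-9
            assert p.frame == "head"

    def test_cardinals_satisfy_head_frame_invariants(self, head35):
        cfg = default_config("aurora", seed=3)
        stylus, reference = simulate_session_streams(head35, cfg)
        session = run_session(stylus, reference, list(zip(head35.labels, head35.kinds)))
        nas = session.point("nasion").position
        lpa = session.point("lpa").position
        rpa = session.point("rpa").position
        assert abs(nas[0]) < 1e-9 and abs(nas[2]) < 1e-9 and nas[1] > 0
        assert abs(lpa[1]) < 1e-9 and abs(lpa[2]) < 1e-9
        assert abs(rpa[1]) < 1e-9 and abs(rpa[2]) < 1e-9

    def test_low_noise_mean_error_below_tenth_mm(self, head35):
        cfg = default_config("aurora", seed=11)
        stylus, reference = simulate_session_streams(
            head35,
            cfg,
            noise=NoiseModel(sigma0=0.1, growth_exponent=0.0),
            fixture_offset=150.0,
        )
        session = run_session(stylus, reference, list(zip(head35.labels, head35.kinds)))
        truth = fixture_head_truth(head35)
        errs = [
            np.linalg.norm(p.position - truth[p.label]) for p in session.points
        ]
        assert np.mean(errs) < 0.1

    def test_label_permutation_only_relabels(self, head35):
        cfg = default_config("fastrak_tx2", seed=0)
        stylus, reference = simulate_session_streams(
            head35, cfg, noise=NoiseModel(sigma0=0.0)
        )
        labels = list(zip(head35.labels, head35.kinds))
        perm = labels[:3] + labels[3:][::-1]  # shuffle non-cardinals
        s1 = run_session(stylus, reference, labels)
        s2 = run_session(stylus, reference, perm)
        pos1 = sorted(map(tuple, np.round(s1.positions, 9)))
        pos2 = sorted(map(tuple, np.round(s2.positions, 9)))
        assert pos1 == pos2

    def test_global_frame_independence(self, head35, rng):
        """Head-frame output is invariant to a common global rigid motion."""
        cfg = default_config("aurora", seed=8)
        stylus, reference = simulate_session_streams(head35, cfg)
        G = random_rigid(rng)
        rot_ref = Rotation.from_matrix(G.rotation) * Rotation.from_quat(
            reference.orientations
        )
        stylus_g = TrackingStream(
            stylus.t, G.apply(stylus.positions), rate=cfg.rate,
            error_index=stylus.error_index,
        )
        reference_g = TrackingStream(
            reference.t, G.apply(reference.positions), rate=cfg.rate,
            orientations=rot_ref.as_quat(),
        )
        labels = list(zip(head35.labels, head35.kinds))
        s1 = run_session(stylus, reference, labels)
        s2 = run_session(stylus_g, reference_g, labels)
        np.testing.assert_allclose(s1.positions, s2.positions, atol=1e-8)

    def test_cluster_count_mismatch_reports_both_counts(self, head35):
        cfg = default_config("fastrak_tx2", seed=0)
        stylus, reference = simulate_session_streams(
            head35, cfg, noise=NoiseModel(sigma0=0.0)
        )
        labels = list(zip(head35.labels, head35.kinds))[:-1]  # 34 labels
        with pytest.raises(ClusterCountMismatchError) as exc:
            run_session(stylus, reference, labels)
        assert exc.value.n_clusters == 35
        assert exc.value.n_labels == 34

    def test_depth_compensation_applied(self):
        """Blunt-tip digitization of the excavated test frame is corrected."""
        fx = make_fixture("test_frame_9")
        cfg = default_config("aurora", seed=0)
        stylus, reference = simulate_session_streams(
            fx, cfg, noise=NoiseModel(sigma0=0.0)
        )
        # the simulated tip rests 2 mm out along each normal
        normals = {p.label: p.normal for p in fx.points}
        offsets = np.repeat(fx.normals, int(cfg.dwell_time * cfg.rate), axis=0)
        stylus_blunt = TrackingStream(
            stylus.t, stylus.positions + 2.0 * offsets, rate=cfg.rate,
            error_index=stylus.error_index,
        )
        labels = list(zip(fx.labels, fx.kinds))
        session = run_session(
            stylus_blunt, reference, labels, depth=2.0, normals=normals
        )
        truth = fixture_head_truth(fx)
        for p in session.points:
            assert np.linalg.norm(p.position - truth[p.label]) < 1e-9

    def test_error_index_filtering_improves_biased_session(self, head35):
        """Discarding high-error-index samples removes interference bias."""
        cfg = default_config("aurora", seed=2)
        stylus, reference = simulate_session_streams(
            head35, cfg, noise=NoiseModel(sigma0=0.05)
        )
        # corrupt the second half of every dwell and flag it
        n_dwell = int(cfg.dwell_time * cfg.rate)
        pos = stylus.positions.copy()
        ei = stylus.error_index.copy()
        for i in range(len(head35.points)):
            sl = slice(i * n_dwell + n_dwell // 2, (i + 1) * n_dwell)
            pos[sl] += np.array([0.8, 0, 0])
            ei[sl] = 0.9
        corrupted = TrackingStream(stylus.t, pos, rate=cfg.rate, error_index=ei)
        labels = list(zip(head35.labels, head35.kinds))
        truth = fixture_head_truth(head35)
        s_filt = run_session(
            corrupted, reference, labels, max_error_index=0.5, min_count=50
        )
        e_filt = np.mean(
            [np.linalg.norm(p.position - truth[p.label]) for p in s_filt.points]
        )
        assert e_filt < 0.2
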