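"""Pair kinematics: separation, completion, biphasic segmentation, MSD,
aligned population statistics, classification and histograms."""

import numpy as np
import pytest

from centrotrack import kinematics, simgen
from centrotrack.kinematics import SeparationSeries
from centrotrack.linker import Trajectory
from centrotrack.spots import SpotObservation


def traj(points, cid=0):
    obs = [SpotObservation(frame=f, center=np.asarray(p, dtype=float),
                           amplitude=1.0, sigma=np.ones(3), fit_residual=0.0,
                           source="propagated")
           for f, p in enumerate(points)]
    return Trajectory(centrosome_id=cid, observations=obs)


def series(d, dt=40.0, **kw):
    d = np.asarray(d, dtype=float)
    return SeparationSeries(kw.pop("pair_id", "p"), np.arange(d.size) * dt, d,
                            **kw)


def truth_series(truth, pair_id="p"):
    return SeparationSeries(pair_id, truth.time_s, truth.separation,
                            anaphase_onset_frame=truth.anaphase_onset_frame)


class TestSeparationSeries:
    def test_pythagorean_distance(self):
        a = traj([(0, 0, 0)] * 5)
        b = traj([(3, 4, 0)] * 5, cid=1)
        s = kinematics.separation_series(a, b, 40.0)
        assert np.allclose(s.d, 5.0)

    def test_identical_trajectories_zero(self):
        a = traj([(1, 2, 3)] * 4)
        s = kinematics.separation_series(a, a, 40.0)
        assert np.allclose(s.d, 0.0)

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        a = traj(rng.normal(size=(6, 3)))
        b = traj(rng.normal(size=(6, 3)), cid=1)
        sab = kinematics.separation_series(a, b, 40.0)
        sba = kinematics.separation_series(b, a, 40.0)
        assert np.array_equal(sab.d, sba.d)

    def test_too_few_common_frames_rejected(self):
        a = traj([(0, 0, 0)] * 2)
        with pytest.raises(ValueError):
            kinematics.separation_series(a, traj([(1, 0, 0)] * 2, 1), 40.0)


class TestDetectCompletion:
    def test_step_function_completes_at_drop(self):
        d = np.concatenate([np.full(10, 10.0), np.full(5, 1.5)])
        assert kinematics.detect_completion(series(d)) == 10

    def test_monotone_decrease_never_below_threshold(self):
        d = np.linspace(12.0, 5.0, 30)
        assert kinematics.detect_completion(series(d)) is None

    def test_truth_recovery_noiseless_pair(self, clustering_truth):
        """On a noiseless clustering pair the completion frame matches the
        generator truth exactly at a threshold inside the final descent step,
        and within one frame at the default threshold."""
        s = truth_series(clustering_truth)
        exact = kinematics.detect_completion(s, d_clustered=1.6)
        assert exact == clustering_truth.completion_frame
        default = kinematics.detect_completion(s)
        assert abs(default - clustering_truth.completion_frame) <= 1

    def test_short_series_warns_none(self):
        with pytest.warns(UserWarning):
            assert kinematics.detect_completion(series([1.0, 1.0])) is None

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        d = np.abs(np.concatenate([rng.normal(8, 2, 20),
                                   rng.normal(1.5, 0.1, 20)]))
        s = series(d)
        frames = [kinematics.detect_completion(s, d_clustered=thr)
                  for thr in (1.8, 2.0, 2.5, 3.0)]
        observed = [f for f in frames if f is not None]
        assert all(a >= b for a, b in zip(observed, observed[1:]))


class TestSegmentPhases:
    def test_noiseless_two_piece_exact(self):
        d = np.concatenate([np.full(20, 10.0), 10 - 9 / 23 * np.arange(1, 24)])
        seg = kinematics.segment_phases(series(d), 42)
        assert seg.motorized_onset_frame == 20
        assert seg.motorized_speed_um_s == pytest.approx(9 / (23 * 40))
        assert seg.onset_separation_um == pytest.approx(10.0 - 9 / 23)
        assert seg.search_interval == (0, 19)
        assert seg.motorized_interval == (20, 42)

    def test_pure_plateau_rejected(self):
        seg = kinematics.segment_phases(series(np.full(30, 5.0)), 29)
        assert seg.motorized_onset_frame is None

    def test_exhaustive_changepoint_vs_brute_force(self):
        """Noiseless two-piece series of every length up to 60 and every
        admissible change point: the fit recovers the change point exactly
        and agrees with an independent brute-force SSE minimization."""
        for n in range(6, 61, 6):
            for b in range(2, n - 2):
                d = np.where(np.arange(n) < b, 20.0,
                             20.0 - 0.3 * (np.arange(n) - b + 1))
                s = series(d)
                seg = kinematics.segment_phases(s, n - 1)
                assert seg.motorized_onset_frame == b, (n, b)
                assert seg.sse < 1e-18
                brute = _brute_force_changepoint(d)
                assert brute == b

    def test_ensemble_parameter_recovery(self):
        """Median motorized duration and onset separation recovered from a
        seeded clustering ensemble under the study conditions."""
        durs, onsets = [], []
        for i in range(50):
            p = simgen.MotionParams(mean_separation_search=8.0, sd_search=2.0,
                                    n_frames=120, cluster=True, seed=1000 + i)
            truth = simgen.simulate_pair(p)
            if truth.completion_frame is None:
                continue
            s = truth_series(truth, f"p{i}")
            c = kinematics.detect_completion(s)
            if c is None or c < 4:
                continue
            seg = kinematics.segment_phases(s, c)
            if seg.motorized_onset_frame is None:
                continue
            durs.append((c - seg.motorized_onset_frame + 1) * 40.0)
            onsets.append(seg.onset_separation_um)
        assert len(durs) >= 40
        assert abs(np.median(durs) - 900.0) <= 80.0
        assert abs(np.median(onsets) - 7.5) <= 1.0


def _brute_force_changepoint(d):
    """Independent oracle: enumerate knots, minimize the SSE of the
    plateau-plus-descent model numerically per knot, return the first
    descent frame of the best knot."""
    from scipy.optimize import minimize_scalar

    n = d.size
    N = n - 1

    def sse_of(k, m):
        model = np.array([d[N] + m * ((t if t >= k else k) - N)
                          for t in range(n)])
        return float(np.sum((d - model) ** 2))

    best = None
    for k in range(0, n - 2):
        res = minimize_scalar(lambda m: sse_of(k, m), bounds=(-5.0, 5.0),
                              method="bounded")
        if best is None or res.fun < best[0] - 1e-12:
            best = (res.fun, k + 1)
    return best[1]


class TestMsd:
    def test_constant_separation_msd_zero(self):
        curve = kinematics.msd([series(np.full(30, 7.0))])
        assert np.allclose(curve.msd, 0.0)
        assert curve.msd[0] == 0.0

    def test_linear_separation_quadratic_msd(self):
        c = 0.01
        t = np.arange(50) * 40.0
        curve = kinematics.msd([series(c * t)])
        assert np.allclose(curve.msd, (c * curve.lag_s) ** 2)

    def test_diffusive_limit(self):
        """Gaussian random-walk separation: MSD(k*dt) ~ sigma^2 * k within
        Monte-Carlo error over 200 walks."""
        rng = np.random.default_rng(3)
        sigma = 0.5
        walks = []
        for _ in range(200):
            d = 50.0 + np.cumsum(rng.normal(0, sigma, 60))
            walks.append(series(d))
        curve = kinematics.msd(walks, max_lag_s=10 * 40.0)
        k = curve.lag_s / 40.0
        expected = sigma ** 2 * k
        assert np.allclose(curve.msd[1:], expected[1:], rtol=0.1)

    def test_invariant_to_constant_shift(self):
        rng = np.random.default_rng(1)
        d = np.abs(rng.normal(10, 1, 40))
        a = kinematics.msd([series(d)])
        b = kinematics.msd([series(d + 5.0)])
        assert np.allclose(a.msd, b.msd)


class TestAlignPopulation:
    def test_two_constant_series(self):
        s1 = series(np.full(10, 10.0), anaphase_onset_frame=5)
        s2 = series(np.full(10, 12.0), pair_id="q", anaphase_onset_frame=5)
        stats = kinematics.align_population([s1, s2])
        assert np.allclose(stats.mean_d, 11.0)
        assert np.allclose(stats.sd_d, np.sqrt(2.0))

    def test_single_series_has_no_sd(self):
        s1 = series(np.full(8, 9.0), anaphase_onset_frame=4)
        stats = kinematics.align_population([s1])
        assert np.all(np.isnan(stats.sd_d))
        assert np.all(stats.n == 1)

    def test_missing_event_excluded_with_warning(self):
        s1 = series(np.full(8, 9.0), anaphase_onset_frame=4)
        s2 = series(np.full(8, 9.0), pair_id="q")
        with pytest.warns(UserWarning):
            stats = kinematics.align_population([s1, s2])
        assert np.all(stats.n == 1)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_recomputation(self, seed):
        rng = np.random.default_rng(seed)
        sers = [series(np.abs(rng.normal(10, 2, rng.integers(6, 15))),
                       pair_id=f"p{i}",
                       anaphase_onset_frame=int(rng.integers(2, 5)))
                for i in range(4)]
        stats = kinematics.align_population(sers)
        for j, t in enumerate(stats.aligned_time_s):
            rel = int(round(t / 40.0))
            vals = []
            for s in sers:
                idx = rel + s.anaphase_onset_frame
                if 0 <= idx < s.n:
                    vals.append(s.d[idx])
            assert stats.n[j] == len(vals)
            assert stats.mean_d[j] == pytest.approx(np.mean(vals))
            if len(vals) >= 2:
                assert stats.sd_d[j] == pytest.approx(np.std(vals, ddof=1))

    def test_sd_ratio_recovers_condition_difference(self):
        """Pooled cross-pair SD of non-clustering ensembles generated at
        search SD 1 vs 2 µm differs by a factor ~2 (the wild-type vs
        knockout contrast)."""
        def pooled(sd, seed0):
            sers = []
            for i in range(40):
                p = simgen.MotionParams(sd_search=sd, cluster=False,
                                        n_frames=90, seed=seed0 + i)
                sers.append(truth_series(simgen.simulate_pair(p), f"s{i}"))
            stats = kinematics.align_population(sers)
            ok = stats.n >= 30
            return np.nanmean(stats.sd_d[ok])

        ratio = pooled(2.0, 9000) / pooled(1.0, 5000)
        assert abs(ratio - 2.0) <= 0.5


class TestClassifyAndHistogram:
    def test_constant_low_all_clustered_at_zero(self):
        sers = [series(np.full(10, 1.0), pair_id=f"p{i}") for i in range(3)]
        labels, summary = kinematics.classify_pairs(sers)
        assert all(v == "clustered" for v in labels.values())
        assert all(c == 0 for c in summary["completions"].values())

    def test_constant_high_all_failed(self):
        sers = [series(np.full(10, 11.0), pair_id=f"p{i}") for i in range(3)]
        labels, _ = kinematics.classify_pairs(sers)
        assert all(v == "failed" for v in labels.values())

    def test_mixed_ensemble_confusion_zero(self):
        """30 clustering + 30 non-clustering generated pairs: classification
        against generator truth makes no errors."""
        sers, truth_labels = [], {}
        for i in range(30):
            p = simgen.MotionParams(mean_separation_search=8.0, sd_search=2.0,
                                    n_frames=150, cluster=True, seed=200 + i)
            t = simgen.simulate_pair(p)
            pid = f"c{i}"
            sers.append(truth_series(t, pid))
            truth_labels[pid] = ("clustered" if t.completion_frame is not None
                                 else "failed")
        for i in range(30):
            p = simgen.MotionParams(sd_search=2.0, cluster=False,
                                    n_frames=150, seed=500 + i)
            pid = f"f{i}"
            sers.append(truth_series(simgen.simulate_pair(p), pid))
            truth_labels[pid] = "failed"
        labels, _ = kinematics.classify_pairs(sers)
        assert labels == truth_labels

    def test_histogram_single_value_single_bin(self):
        sers = [series(np.full(20, 7.5))]
        edges, counts, median, sem = kinematics.phase_histogram(sers)
        assert (counts > 0).sum() == 1
        assert median == pytest.approx(7.5)
        assert counts.sum() == 20

    def test_histogram_counts_conserved(self):
        rng = np.random.default_rng(2)
        sers = [series(np.abs(rng.normal(9, 2, 25)), pair_id=f"p{i}")
                for i in range(4)]
        edges, counts, _, _ = kinematics.phase_histogram(sers)
        assert counts.sum() == 100

    def test_nonclustering_pooled_median_in_observed_band(self):
        """Non-clustering ensemble pools to a median separation of ~11-12 µm."""
        sers = []
        for i in range(40):
            p = simgen.MotionParams(cluster=False, n_frames=90, seed=3000 + i)
            sers.append(truth_series(simgen.simulate_pair(p), f"p{i}"))
        _, _, median, _ = kinematics.phase_histogram(sers)
        assert 11.0 <= median <= 12.0
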