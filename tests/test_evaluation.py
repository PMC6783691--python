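import itertools

import numpy as np
import pytest

from casitebench import evaluation as ev
from casitebench.clusters import ClusterSet, RyRCluster
from casitebench.detector import CRU, DetectionResult, ReleaseMap


PIX = 215.0


def make_clusters(specs):
    """specs: list of (u_px, l_px, v_nm, fire_time)."""
    cls = [
        RyRCluster(
            center=((u + 0.5) * PIX, v, (l + 0.5) * PIX),
            zdisk_index=0,
            fire_time=t,
        )
        for (u, l, v, t) in specs
    ]
    return ClusterSet(cls, "low", len(cls), None)


def make_detection(centroids, region_radius=1, slice_index=0, shape=(64, 64)):
    crus = []
    for r, c in centroids:
        cells = [
            (r + dr, c + dc)
            for dr in range(-region_radius, region_radius + 1)
            for dc in range(-region_radius, region_radius + 1)
            if 0 <= r + dr < shape[0] and 0 <= c + dc < shape[1]
        ]
        crus.append(
            CRU(
                centroid=(r + 0.5, c + 0.5),
                region=np.array(cells),
                integrated_amplitude=1.0,
            )
        )
    rmap = ReleaseMap(np.zeros(shape), np.zeros(shape), n_pairs=6)
    return DetectionResult(slice_index, rmap, crus)


class TestClassify:
    def test_no_detections_all_fn(self):
        cs = make_clusters([(10, 10, 0.0, 1.0)] * 1 + [(20, 12, 50.0, 2.0)] * 1)
        cs = make_clusters([(10 + i, 10, 0.0, 1.0) for i in range(5)])
        det = make_detection([])
        c = ev.classify(cs, det, slice_position=0.0, window=500, pixel_size=PIX)
        assert (c.tp_detected, c.fn, c.fp) == (0, 5, 0)

    def test_identity_holds_by_construction(self):
        rng = np.random.default_rng(0)
        cs = make_clusters(
            [(int(u), int(l), float(v), 1.0) for u, l, v in
             zip(rng.integers(2, 60, 12), rng.integers(2, 60, 12), rng.uniform(0, 800, 12))]
        )
        det = make_detection([(int(r), int(c)) for r, c in zip(rng.integers(2, 60, 8), rng.integers(2, 60, 8))])
        c = ev.classify(cs, det, 0.0, 600, PIX)
        assert c.tp_ground_truth == c.tp_detected + c.fn
        assert c.fp == len(det.crus) - c.tp_detected

    def test_toy_bipartite_case(self):
        """Truths at (10,10) and (30,10); CRUs at (10,10) and (50,50)."""
        cs = make_clusters([(10, 10, 0.0, 1.0), (30, 10, 0.0, 1.0)])
        det = make_detection([(10, 10), (50, 50)])
        c = ev.classify(cs, det, 0.0, 100, PIX)
        assert (c.tp_detected, c.fn, c.fp) == (1, 1, 1)

    def test_window_excludes_deep_clusters(self):
        cs = make_clusters([(10, 10, 100.0, 1.0), (20, 20, 900.0, 1.0)])
        det = make_detection([(10, 10), (20, 20)])
        c = ev.classify(cs, det, 0.0, 500, PIX)
        assert c.tp_ground_truth == 1
        assert (c.tp_detected, c.fp) == (1, 1)

    def test_silent_clusters_not_ground_truth(self):
        cs = make_clusters([(10, 10, 0.0, 45.0)])  # fires after the 30 ms window
        det = make_detection([(10, 10)])
        c = ev.classify(cs, det, 0.0, 500, PIX, duration=30.0)
        assert c.tp_ground_truth == 0
        assert c.fp == 1

    def test_matched_cru_removed_from_pool(self):
        """Two truths inside one region: only the nearer is matched."""
        cs = make_clusters([(10, 10, 0.0, 1.0), (11, 10, 0.0, 1.0)])
        det = make_detection([(10, 10)], region_radius=2)
        c = ev.classify(cs, det, 0.0, 500, PIX)
        assert (c.tp_detected, c.fn, c.fp) == (1, 1, 0)
        assert c.matches[0][0] == 0  # the nearer truth wins

    def test_greedy_close_to_optimal_on_toys(self):
        """Greedy matching count is never above, and within 1 of, the optimum."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            n_gt, n_det = rng.integers(2, 8), rng.integers(2, 8)
            gts = [(int(u), int(l), 0.0, 1.0) for u, l in rng.integers(3, 40, (n_gt, 2))]
            dets = [(int(r), int(c)) for r, c in rng.integers(3, 40, (n_det, 2))]
            cs = make_clusters(gts)
            det = make_detection(dets, region_radius=2)
            c = ev.classify(cs, det, 0.0, 500, PIX)
            # exhaustive optimal bipartite matching over admissible pairs
            admissible = []
            for gi, (u, l, _, _) in enumerate(gts):
                for di, (r, cc) in enumerate(dets):
                    if abs(u - r) <= 3 and abs(l - cc) <= 3:
                        admissible.append((gi, di))
            best = 0
            for k in range(min(n_gt, n_det), 0, -1):
                for combo in itertools.combinations(admissible, k):
                    g_used = {p[0] for p in combo}
                    d_used = {p[1] for p in combo}
                    if len(g_used) == k and len(d_used) == k:
                        best = k
                        break
                if best:
                    break
            assert best - 1 <= c.tp_detected <= best


class TestMetrics:
    def test_table_row_arithmetic(self):
        """recall 0.68 and precision 0.70 combine to f1 0.69."""
        assert round(ev.f1_score(0.68, 0.70), 2) == 0.69

    def test_perfect_detection(self):
        r, p, f = ev.metrics((10, 10, 0))
        assert (r, p, f) == (1.0, 1.0, 1.0)

    def test_zero_precision_annihilates_f1(self):
        assert ev.f1_score(0.5, 0.0) == 0.0

    def test_degenerate_conventions(self):
        r, p, f = ev.metrics((0, 0, 0))
        assert np.isnan(r) and p == 1.0 and np.isnan(f)
        r, p, f = ev.metrics((5, 0, 0))
        assert r == 0.0 and np.isnan(p)

    def test_f1_between_components(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            r, p = rng.uniform(0.01, 1.0, 2)
            f = ev.f1_score(r, p)
            assert min(r, p) <= f <= max(r, p)


def layered_scenario(seed=0, n_slices=3):
    """Clusters spread in depth + detections at the in-plane positions of the
    shallow ones, for window-sweep behavior tests."""
    rng = np.random.default_rng(seed)
    n = 30
    u = rng.integers(3, 60, n)
    l = rng.integers(3, 60, n)
    v = rng.uniform(0, 1200, n)
    cs = make_clusters([(int(a), int(b), float(c), 1.0) for a, b, c in zip(u, l, v)])
    slice_positions = np.array([0.0, 400.0, 800.0])[:n_slices]
    detections = []
    for si, pos in enumerate(slice_positions):
        cents = [
            (int(a), int(b))
            for a, b, c in zip(u, l, v)
            if abs(c - pos) < 450 and rng.random() < 0.8
        ]
        detections.append(make_detection(cents, slice_index=si))
    return cs, detections, slice_positions


class TestSweep:
    def test_tp_ground_truth_nondecreasing_in_window(self):
        cs, dets, pos = layered_scenario()
        curve = ev.sweep_windows(cs, dets, pos, np.arange(0, 1300, 50.0), PIX)
        tp_gt = curve.counts[:, :, 0]
        assert np.all(np.diff(tp_gt, axis=0) >= 0)

    def test_single_slice_single_window_reduces_to_metrics(self):
        cs, dets, pos = layered_scenario(n_slices=1)
        curve = ev.sweep_windows(cs, dets[:1], pos[:1], np.array([500.0]), PIX)
        c = ev.classify(cs, dets[0], pos[0], 500.0, PIX)
        r, p, f = ev.metrics(c)
        assert curve.mean_recall[0] == r
        assert curve.mean_precision[0] == p
        assert curve.f1[0] == f

    def test_fp_nonincreasing_in_window(self):
        cs, dets, pos = layered_scenario(seed=3)
        curve = ev.sweep_windows(cs, dets, pos, np.arange(0, 1300, 50.0), PIX)
        fp = curve.counts[:, :, 2].sum(axis=1)
        # wider windows admit more truths, so detections stop being FPs
        assert np.all(np.diff(fp) <= 1)  # non-increasing up to single-tie jitter
        assert fp[-1] < fp[0]


class TestBreakEven:
    def synthetic_curve(self):
        w = np.arange(0.0, 1001.0, 10.0)
        recall = 1.0 - w / 1000.0
        precision = w / 1000.0
        n_w = len(w)
        return ev.MetricsCurve(
            windows=w,
            recall=recall[:, None],
            precision=precision[:, None],
            counts=np.zeros((n_w, 1, 3), dtype=int),
        )

    def test_closed_form_crossing(self):
        wx, vx, flagged = ev.break_even(self.synthetic_curve())
        assert not flagged
        assert abs(wx - 500.0) < 1e-9
        assert abs(vx - 0.5) < 1e-9

    def test_argmin_property(self):
        curve = self.synthetic_curve()
        wx, _, _ = ev.break_even(curve)
        diffs = np.abs(curve.mean_recall - curve.mean_precision)
        i = int(np.argmin(np.abs(curve.windows - wx)))
        assert diffs[i] <= diffs.min() + 1e-9

    def test_no_crossing_flagged(self):
        w = np.arange(0.0, 101.0, 10.0)
        n_w = len(w)
        curve = ev.MetricsCurve(
            windows=w,
            recall=np.full((n_w, 1), 0.9),
            precision=np.full((n_w, 1), 0.5),
            counts=np.zeros((n_w, 1, 3), dtype=int),
        )
        _, _, flagged = ev.break_even(curve)
        assert flagged


class TestDifferentialRecall:
    def test_all_matched_gives_unity_bands(self):
        cs, _, _ = layered_scenario()
        # detections exactly at every truth, huge regions
        cents = [
            (int(c.center[0] / PIX), int(c.center[2] / PIX)) for c in cs.clusters
        ]
        dets = [make_detection(cents, region_radius=1)]
        dr = ev.differential_recall(cs, dets, np.array([0.0]), band_width=100.0, reference_window=1300.0)
        assert np.all(dr.raw == 1.0)

    def test_pooling_identity_exact(self):
        cs, dets, pos = layered_scenario(seed=5)
        bw = 50.0
        dr = ev.differential_recall(cs, dets, pos, band_width=bw, reference_window=1300.0)
        curve = ev.sweep_windows(cs, dets, pos, np.arange(0.0, 1300.0 + bw / 2, bw), PIX)
        pooled = curve.counts.sum(axis=1)
        for wi in (5, 10, 20):
            w = curve.windows[wi]
            tp_gt, tp_det = pooled[wi, 0], pooled[wi, 1]
            if tp_gt == 0:
                continue
            assert np.isclose(dr.cumulative_recall(w), tp_det / tp_gt)

    def test_band_fractions_in_unit_interval(self):
        cs, dets, pos = layered_scenario(seed=6)
        dr = ev.differential_recall(cs, dets, pos, band_width=20.0, reference_window=1300.0)
        assert np.all((dr.raw >= 0) & (dr.raw <= 1))


class TestSmoothAndFit:
    def test_constant_series_unchanged(self):
        centers = np.arange(30.0) * 10 + 5
        raw = np.full(30, 0.6)
        smoothed, fit, applied, _ = ev.smooth_and_fit(centers, raw)
        assert applied
        np.testing.assert_allclose(smoothed, 0.6, rtol=1e-9)

    def test_noiseless_gaussian_self_fit(self):
        """A pure Gaussian series (short enough to skip smoothing) is recovered
        to near machine precision by the single-term fit."""
        centers = np.arange(15.0) * 100 + 50
        raw = 0.9 * np.exp(-(centers**2) / (2 * 400.0**2))
        _, fit, applied, converged = ev.smooth_and_fit(centers, raw)
        assert converged and not applied
        a, sigma = fit
        assert abs(a / 0.9 - 1.0) < 1e-6
        assert abs(sigma / 400.0 - 1.0) < 1e-6

    def test_smoothed_gaussian_fit_close(self):
        """With the 21-point filter applied the fit stays within 0.1%."""
        centers = np.arange(100.0) * 10 + 5
        raw = 0.9 * np.exp(-(centers**2) / (2 * 400.0**2))
        _, fit, applied, converged = ev.smooth_and_fit(centers, raw)
        assert converged and applied
        assert abs(fit[0] / 0.9 - 1.0) < 1e-3
        assert abs(fit[1] / 400.0 - 1.0) < 1e-3

    def test_savgol_matches_windowed_polynomial_fit(self):
        rng = np.random.default_rng(2)
        centers = np.arange(60.0)
        raw = np.sin(centers / 10) + rng.normal(0, 0.05, 60)
        smoothed, _, applied, _ = ev.smooth_and_fit(centers, raw)
        assert applied
        i = 30
        window = raw[i - 10 : i + 11]
        coeffs = np.polyfit(np.arange(-10, 11), window, 3)
        assert np.isclose(smoothed[i], np.polyval(coeffs, 0.0), atol=1e-9)

    def test_short_series_passthrough(self):
        centers = np.arange(10.0)
        raw = np.linspace(1, 0, 10)
        smoothed, _, applied, _ = ev.smooth_and_fit(centers, raw)
        assert not applied
        np.testing.assert_array_equal(smoothed, raw)
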