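"""Classification of detected CRUs against ground truth and performance metrics.

For each imaging plane, ground-truth release sites within an *admissible
window* (a through-plane distance tolerance) are matched greedily against
segmented CRU regions: a site matches the nearest available CRU whose
1-pixel-dilated region contains the site's in-plane position; matched CRUs
leave the pool.  Unmatched sites are false negatives, unmatched CRUs false
positives, so TP(ground truth) = TP(detected) + FN holds by construction.

From the counts: recall = TP(det)/TP(gt), precision = TP(det)/(TP(det)+FP),
F1 = their harmonic mean.  Sweeping the admissible window yields recall and
precision curves (mean +/- std over slices) whose intersection is the
break-even point; binning matched status by through-plane distance into
10 nm bands yields the differential recall curve, which is Savitzky-Golay
smoothed (order 3, frame 21) and summarized by a single-term Gaussian fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

from casitebench.clusters import ClusterSet
from casitebench.detector import DetectionResult


@dataclass
class Classification:
    slice_index: int
    admissible_window: float  # nm
    tp_ground_truth: int
    tp_detected: int
    fn: int
    fp: int
    #: (cluster index into ClusterSet.clusters, CRU index, centroid distance px)
    matches: list[tuple[int, int, float]]
    #: indices (into ClusterSet.clusters) of the ground truths in the window
    gt_indices: np.ndarray = None
    #: through-plane distance (nm) per ground truth, aligned with gt_indices
    gt_distances: np.ndarray = None
    #: matched flag per ground truth, aligned with gt_indices
    gt_matched: np.ndarray = None

    def __post_init__(self):
        assert self.tp_ground_truth == self.tp_detected + self.fn, "Eq. TP(gt)=TP(det)+FN violated"
        assert min(self.tp_ground_truth, self.tp_detected, self.fn, self.fp) >= 0


def classify(
    cluster_set: ClusterSet,
    detection: DetectionResult,
    slice_position: float,
    window: float,
    pixel_size: float,
    duration: float = 30.0,
    pixel_tol: int = 1,
    count_silent_as_truth: bool = False,
) -> Classification:
    """Classify one slice's detections at one admissible window.

    Ground truths are the firing clusters whose through-plane distance
    |v - slice_position| is at most ``window``.  Matching is globally
    greedy on centroid distance over (ground truth, CRU) pairs where the
    CRU's ``pixel_tol``-dilated region contains the projected site.
    """
    # ground-truth selection
    gt_idx, gt_px, gt_dist = [], [], []
    for i, c in enumerate(cluster_set.clusters):
        if not count_silent_as_truth and c.fire_time >= duration:
            continue
        d = abs(c.center[1] - slice_position)
        if d <= window:
            gt_idx.append(i)
            gt_px.append((c.center[0] / pixel_size, c.center[2] / pixel_size))
            gt_dist.append(d)
    n_gt = len(gt_idx)
    crus = detection.crus
    n_det = len(crus)
    if n_gt == 0 or n_det == 0:
        return Classification(
            slice_index=detection.slice_index,
            admissible_window=window,
            tp_ground_truth=n_gt,
            tp_detected=0,
            fn=n_gt,
            fp=n_det,
            matches=[],
            gt_indices=np.asarray(gt_idx, dtype=int),
            gt_distances=np.asarray(gt_dist, dtype=float),
            gt_matched=np.zeros(n_gt, dtype=bool),
        )

    # region membership with pixel tolerance (Chebyshev dilation)
    region_sets = [
        {(r, c) for r, c in cru.region} for cru in crus
    ]
    pairs = []  # (distance, gt local index, cru index)
    for gi, (prow, pcol) in enumerate(gt_px):
        pr, pc = int(np.floor(prow)), int(np.floor(pcol))
        for ci, (cru, cells) in enumerate(zip(crus, region_sets)):
            hit = any(
                (pr + dr, pc + dc) in cells
                for dr in range(-pixel_tol, pixel_tol + 1)
                for dc in range(-pixel_tol, pixel_tol + 1)
            )
            if hit:
                dist = float(np.hypot(prow - cru.centroid[0], pcol - cru.centroid[1]))
                pairs.append((dist, gi, ci))
    pairs.sort()
    gt_matched = np.zeros(n_gt, dtype=bool)
    cru_used = np.zeros(n_det, dtype=bool)
    matches = []
    for dist, gi, ci in pairs:
        if not gt_matched[gi] and not cru_used[ci]:
            gt_matched[gi] = True
            cru_used[ci] = True
            matches.append((gt_idx[gi], ci, dist))
    tp = len(matches)
    return Classification(
        slice_index=detection.slice_index,
        admissible_window=window,
        tp_ground_truth=n_gt,
        tp_detected=tp,
        fn=n_gt - tp,
        fp=n_det - tp,
        matches=matches,
        gt_indices=np.asarray(gt_idx, dtype=int),
        gt_distances=np.asarray(gt_dist, dtype=float),
        gt_matched=gt_matched,
    )


def metrics(c) -> tuple[float, float, float]:
    """(recall, precision, f1) from a Classification or (tp_gt, tp_det, fp) counts.

    Degenerate conventions: recall is NaN when there are no ground truths;
    precision is 1.0 when there are neither detections nor ground truths,
    NaN when there are no detections but ground truths exist; F1 is 0 when
    either component is 0.
    """
    if isinstance(c, Classification):
        tp_gt, tp_det, fp = c.tp_ground_truth, c.tp_detected, c.fp
    else:
        tp_gt, tp_det, fp = c
    recall = tp_det / tp_gt if tp_gt > 0 else np.nan
    if tp_det + fp > 0:
        precision = tp_det / (tp_det + fp)
    else:
        precision = 1.0 if tp_gt == 0 else np.nan
    f1 = f1_score(recall, precision)
    return recall, precision, f1


def f1_score(recall: float, precision: float) -> float:
    """Harmonic mean of recall and precision (0 if either is 0, NaN propagates)."""
    if np.isnan(recall) or np.isnan(precision):
        return np.nan
    if recall == 0 or precision == 0:
        return 0.0
    return 2.0 / (1.0 / recall + 1.0 / precision)


@dataclass
class MetricsCurve:
    """Recall/precision/F1 as functions of the admissible window."""

    windows: np.ndarray  # nm
    recall: np.ndarray  # (n_windows, n_slices), NaN where undefined
    precision: np.ndarray
    counts: np.ndarray  # (n_windows, n_slices, 3) of (tp_gt, tp_det, fp)

    @staticmethod
    def _nanagg(func, arr):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows stay NaN
            return func(arr, axis=1)

    @property
    def mean_recall(self) -> np.ndarray:
        return self._nanagg(np.nanmean, self.recall)

    @property
    def mean_precision(self) -> np.ndarray:
        return self._nanagg(np.nanmean, self.precision)

    @property
    def std_recall(self) -> np.ndarray:
        return self._nanagg(np.nanstd, self.recall)

    @property
    def std_precision(self) -> np.ndarray:
        return self._nanagg(np.nanstd, self.precision)

    @property
    def f1(self) -> np.ndarray:
        """F1 computed from the mean recall and mean precision curves."""
        return np.array(
            [f1_score(r, p) for r, p in zip(self.mean_recall, self.mean_precision)]
        )

    def peak_f1(self) -> tuple[float, float]:
        """(value, window nm) of the maximum F1 over the sweep."""
        f1 = self.f1
        i = int(np.nanargmax(f1))
        return float(f1[i]), float(self.windows[i])

    def at_window(self, window: float) -> tuple[float, float, float]:
        """(mean recall, mean precision, f1) at the grid window nearest ``window``."""
        i = int(np.argmin(np.abs(self.windows - window)))
        return float(self.mean_recall[i]), float(self.mean_precision[i]), float(self.f1[i])

    def pooled_metrics(self, window: float) -> tuple[float, float, float]:
        """Metrics from counts pooled across slices at the nearest grid window."""
        i = int(np.argmin(np.abs(self.windows - window)))
        tp_gt, tp_det, fp = self.counts[i].sum(axis=0)
        return metrics((int(tp_gt), int(tp_det), int(fp)))


def sweep_windows(
    cluster_set: ClusterSet,
    detections: list[DetectionResult],
    slice_positions: np.ndarray,
    windows: np.ndarray | None = None,
    pixel_size: float = 215.0,
    duration: float = 30.0,
    pixel_tol: int = 1,
) -> MetricsCurve:
    """Classify every slice at every admissible window and aggregate."""
    if windows is None:
        windows = default_window_grid()
    n_w, n_s = len(windows), len(detections)
    recall = np.full((n_w, n_s), np.nan)
    precision = np.full((n_w, n_s), np.nan)
    counts = np.zeros((n_w, n_s, 3), dtype=int)
    for wi, w in enumerate(windows):
        for si, (det, pos) in enumerate(zip(detections, slice_positions)):
            c = classify(
                cluster_set, det, pos, w, pixel_size, duration=duration, pixel_tol=pixel_tol
            )
            r, p, _ = metrics(c)
            recall[wi, si] = r
            precision[wi, si] = p
            counts[wi, si] = (c.tp_ground_truth, c.tp_detected, c.fp)
    return MetricsCurve(np.asarray(windows, dtype=float), recall, precision, counts)


def default_window_grid(stop: float = 1500.0, step: float = 10.0) -> np.ndarray:
    return np.arange(0.0, stop + step / 2, step)


def break_even(curve: MetricsCurve) -> tuple[float, float, bool]:
    """Admissible window and common value where mean recall = mean precision.

    Linear interpolation between grid points at the sign change of
    (recall - precision).  If the curves never cross, the result at the grid
    point minimizing |recall - precision| is returned with ``flagged=True``.
    """
    r, p, w = curve.mean_recall, curve.mean_precision, curve.windows
    diff = r - p
    valid = ~np.isnan(diff)
    best = None
    for i in range(len(w) - 1):
        if not (valid[i] and valid[i + 1]):
            continue
        if diff[i] == 0:
            cand = (float(w[i]), float(r[i]))
            best = cand if best is None else best
        elif diff[i] * diff[i + 1] < 0:
            t = diff[i] / (diff[i] - diff[i + 1])
            wx = w[i] + t * (w[i + 1] - w[i])
            vx = r[i] + t * (r[i + 1] - r[i])
            best = (float(wx), float(vx))
            break
    if best is not None:
        return best[0], best[1], False
    i = int(np.nanargmin(np.abs(diff)))
    return float(w[i]), float((r[i] + p[i]) / 2.0), True


@dataclass
class DifferentialRecall:
    """Per-depth-band detection fraction and its smoothed/fitted summaries."""

    band_centers: np.ndarray  # nm
    raw: np.ndarray  # detected fraction per band
    counts: np.ndarray  # ground truths per band
    smoothed: np.ndarray | None
    fit_amplitude: float | None
    fit_sigma: float | None  # nm
    smoothing_applied: bool
    fit_converged: bool

    def cumulative_recall(self, window: float) -> float:
        """Count-weighted mean of band fractions for bands within ``window``.

        By the telescoping pooling identity this equals the pooled cumulative
        recall TP(det)/TP(gt) at that admissible window from the same
        per-window classifications.
        """
        sel = self.band_centers <= window
        n = self.counts[sel].sum()
        return float((self.raw[sel] * self.counts[sel]).sum() / n) if n else np.nan


def differential_recall(
    cluster_set: ClusterSet,
    detections: list[DetectionResult],
    slice_positions: np.ndarray,
    band_width: float = 10.0,
    reference_window: float = 1500.0,
    pixel_size: float = 215.0,
    duration: float = 30.0,
    curve: MetricsCurve | None = None,
) -> DifferentialRecall:
    """Detection fraction per through-plane distance band (10 nm bands).

    Implements the band recall as the discrete derivative
    ``d TP(detected) / d TP(ground truth)`` along the admissible-window
    sweep, with counts pooled over slices: the band ``[w, w + bw)`` receives
    the marginal matched fraction gained when the window grows from ``w`` to
    ``w + bw``.  Bands that gain no ground truths are omitted.

    A precomputed :class:`MetricsCurve` on the matching window grid is
    reused when provided.
    """
    windows = np.arange(0.0, reference_window + band_width / 2, band_width)
    if curve is None or len(curve.windows) != len(windows) or not np.allclose(
        curve.windows, windows
    ):
        curve = sweep_windows(
            cluster_set,
            detections,
            slice_positions,
            windows,
            pixel_size=pixel_size,
            duration=duration,
        )
    pooled = curve.counts.sum(axis=1)  # (n_windows, 3): tp_gt, tp_det, fp
    d_gt = np.diff(pooled[:, 0]).astype(float)
    # greedy matching can make the pooled matched count dip at ties; the
    # band fraction is clipped into [0, 1]
    d_det = np.clip(np.diff(pooled[:, 1]).astype(float), 0.0, np.maximum(d_gt, 0.0))
    occupied = d_gt > 0
    centers = (windows[:-1] + band_width / 2)[occupied]
    raw = d_det[occupied] / d_gt[occupied]
    counts = d_gt[occupied].astype(int)

    smoothed, fit, applied, converged = smooth_and_fit(centers, raw)
    return DifferentialRecall(
        band_centers=centers,
        raw=raw,
        counts=counts,
        smoothed=smoothed,
        fit_amplitude=fit[0] if fit else None,
        fit_sigma=fit[1] if fit else None,
        smoothing_applied=applied,
        fit_converged=converged,
    )


def smooth_and_fit(
    band_centers: np.ndarray, raw: np.ndarray
) -> tuple[np.ndarray, tuple[float, float] | None, bool, bool]:
    """Savitzky-Golay smoothing (order 3, frame 21) + single-term Gaussian fit.

    Series shorter than the filter frame pass through unsmoothed (flagged).
    Returns (smoothed, (amplitude, sigma) or None, smoothing_applied,
    fit_converged).
    """
    if len(raw) >= 21:
        smoothed = savgol_filter(raw, window_length=21, polyorder=3)
        applied = True
    else:
        smoothed = raw.copy()
        applied = False

    def gauss(z, a, sigma):
        return a * np.exp(-(z**2) / (2.0 * sigma**2))

    try:
        import warnings

        from scipy.optimize import OptimizeWarning

        sigma0 = max(band_centers[len(band_centers) // 2], 1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                gauss,
                band_centers,
                smoothed,
                p0=(max(float(np.max(smoothed)), 1e-3), sigma0),
                maxfev=10000,
            )
        fit = (float(popt[0]), float(abs(popt[1])))
        converged = True
    except RuntimeError:
        fit = None
        converged = False
    return smoothed, fit, applied, converged
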