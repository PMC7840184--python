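"""Contraction metrics from displacement fields and image stacks.

Flow strength ``s_i`` is the ROI mean of per-pixel displacement-vector
norms at frame i. Flow change ``c_i = s_i - s_{i-1}`` is the difference of
(moving-average-smoothed) flow strength between consecutive frames; post-
stimulus motion is quantified as the area under the curve within a fixed
window after onset. The windowed-MSE measure estimates per-pixel integer
motion between consecutive frames directly from intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from tubuliflow.core_io import DisplacementField, FlowSeries, Roi

__all__ = [
    "MotionResult",
    "ContractionEvent",
    "flow_strength",
    "moving_average",
    "flow_change",
    "make_flow_series",
    "auc",
    "windowed_auc_pair",
    "motion_auc",
    "windowed_mse_motion",
    "detect_contractions",
]

DEFAULT_AUC_WINDOW_S = 60.0
DEFAULT_SMOOTHING_WINDOW = 5


@dataclass
class MotionResult:
    """Flow series plus post-onset and basal AUC for one ROI."""

    flow: FlowSeries
    auc_post: float
    auc_basal: float
    window_s: float
    roi_label: str = ""
    rectified: bool = False

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be > 0")
        if not (np.isfinite(self.auc_post) and np.isfinite(self.auc_basal)):
            raise ValueError("AUC values must be finite")


@dataclass
class ContractionEvent:
    onset_s: float
    duration_s: float
    peak: float

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


def flow_strength(field: DisplacementField, roi: Roi | None = None) -> np.ndarray:
    """Per-frame ROI mean of displacement norms, in pixels.

    Pixels inside the field's flagged border margin are excluded.
    """
    norms = field.norms
    mask = field.valid_mask()
    if roi is not None:
        if roi.mask.shape != norms.shape[1:]:
            raise ValueError("ROI shape does not match field")
        mask = mask & roi.mask
    if not mask.any():
        raise ValueError("empty ROI after border exclusions")
    return norms[:, mask].mean(axis=1)


def moving_average(s: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; the window shrinks at the edges."""
    s = np.asarray(s, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window > len(s):
        raise ValueError(f"window {window} exceeds series length {len(s)}")
    if window == 1:
        return s.copy()
    h = window // 2
    csum = np.concatenate([[0.0], np.cumsum(s)])
    n = len(s)
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def flow_change(s: np.ndarray, smoothing_window: int = DEFAULT_SMOOTHING_WINDOW) -> np.ndarray:
    """Difference of smoothed flow strength between consecutive frames."""
    s = np.asarray(s, dtype=float)
    if len(s) < 2:
        raise ValueError("need at least 2 flow-strength samples")
    return np.diff(moving_average(s, smoothing_window))


def make_flow_series(s: np.ndarray, smoothing_window: int = DEFAULT_SMOOTHING_WINDOW) -> FlowSeries:
    s = np.asarray(s, dtype=float)
    smooth = moving_average(s, smoothing_window)
    return FlowSeries(
        s=s, s_smooth=smooth, c=np.diff(smooth), smoothing_window=smoothing_window
    )


def auc(
    series: np.ndarray,
    times: np.ndarray,
    onset_s: float,
    window_s: float = DEFAULT_AUC_WINDOW_S,
    rectified: bool = False,
) -> float:
    """Trapezoidal integral of the series over ``[onset, onset + window]``.

    Endpoint values are linearly interpolated; a window extending past the
    recording end is truncated (the caller is warned via the returned
    integral simply covering less time).
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    if onset_s < times[0] or onset_s > times[-1]:
        raise ValueError(f"onset {onset_s} s outside recording")
    hi = min(onset_s + window_s, times[-1])
    if rectified:
        series = np.abs(series)
    inner = (times > onset_s) & (times < hi)
    ts = np.concatenate([[onset_s], times[inner], [hi]])
    vs = np.concatenate(
        [[np.interp(onset_s, times, series)], series[inner], [np.interp(hi, times, series)]]
    )
    return float(np.trapezoid(vs, ts))


def windowed_auc_pair(
    series: np.ndarray,
    times: np.ndarray,
    onset_s: float,
    window_s: float = DEFAULT_AUC_WINDOW_S,
    rectified: bool = False,
) -> tuple[float, float]:
    """Post-onset AUC and the matched pre-onset (basal) AUC.

    Either window truncated by the recording bounds is rescaled to the
    nominal ``window_s`` length so the two integrals stay comparable.
    """
    times = np.asarray(times, dtype=float)
    post = auc(series, times, onset_s, window_s, rectified)
    post_len = min(onset_s + window_s, float(times[-1])) - onset_s
    if post_len <= 0:
        raise ValueError("no post-onset samples")
    if post_len < window_s:
        post *= window_s / post_len
    basal_lo = max(onset_s - window_s, float(times[0]))
    basal_len = onset_s - basal_lo
    if basal_len <= 0:
        raise ValueError("no pre-onset samples for the basal window")
    basal = auc(series, times, basal_lo, basal_len, rectified)
    if basal_len < window_s:
        basal *= window_s / basal_len
    return post, basal


def motion_auc(
    series: np.ndarray,
    times: np.ndarray,
    onset_s: float,
    window_s: float = DEFAULT_AUC_WINDOW_S,
    rectified: bool = False,
    smoothing_window: int = DEFAULT_SMOOTHING_WINDOW,
    roi_label: str = "",
) -> MotionResult:
    """Post-onset AUC with the matched equal-length basal (pre-onset) AUC.

    ``series`` is a flow-strength series; AUC is taken on the flow-change
    series derived from it (signed by default, rectified on request).
    """
    flow = make_flow_series(series, smoothing_window)
    post, basal = windowed_auc_pair(flow.c, times[1:], onset_s, window_s, rectified)
    return MotionResult(
        flow=flow,
        auc_post=post,
        auc_basal=basal,
        window_s=window_s,
        roi_label=roi_label,
        rectified=rectified,
    )


# ---------------------------------------------------------------------------
# Windowed-MSE motion
# ---------------------------------------------------------------------------

def _candidate_shifts(max_distance: int) -> list[tuple[int, int]]:
    """Integer shifts with sup-norm <= max_distance, in tie-break order:
    smallest Euclidean norm first, then lexicographic (dy, dx)."""
    cands = [
        (dy, dx)
        for dy in range(-max_distance, max_distance + 1)
        for dx in range(-max_distance, max_distance + 1)
    ]
    return sorted(cands, key=lambda d: (d[0] ** 2 + d[1] ** 2, d[0], d[1]))


def _shift_prev(prev: np.ndarray, dy: int, dx: int, md: int) -> np.ndarray:
    """``shifted[p] = prev[p - d]`` with symmetric (mirror) edge padding."""
    padded = np.pad(prev, md, mode="symmetric")
    H, W = prev.shape
    return padded[md - dy:md - dy + H, md - dx:md - dx + W]


def windowed_mse_motion(
    stack: np.ndarray,
    sigma: float = 1.0,
    max_distance: int = 3,
    roi: Roi | None = None,
    truncate: float = 4.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel integer-shift motion between consecutive frames.

    For each frame pair and pixel p the shift d (sup-norm at most
    ``max_distance``) minimizing the Gaussian-weighted local MSE between
    the current patch at p and the previous patch at ``p - d`` is found;
    per-pixel motion is the Euclidean norm of the winning shift. Ties are
    broken toward the smallest-norm shift (then lexicographic), so static
    input yields exactly zero motion.

    Returns ``(series, maps)``: the ROI-mean motion per frame pair
    (length T-1) and the per-pixel motion maps ``(T-1, H, W)``.
    """
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a (T, H, W) stack with >= 2 frames")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if max_distance < 1 or int(max_distance) != max_distance:
        raise ValueError("max_distance must be a positive integer")
    H, W = stack.shape[1:]
    if max_distance >= min(H, W) / 2:
        raise ValueError("max_distance too large for image size")
    md = int(max_distance)
    cands = _candidate_shifts(md)
    norms = np.array([np.hypot(dy, dx) for dy, dx in cands])

    T = stack.shape[0]
    maps = np.zeros((T - 1, H, W))
    series = np.zeros(T - 1)
    mask = roi.mask if roi is not None else np.ones((H, W), dtype=bool)
    for i in range(1, T):
        cur, prev = stack[i], stack[i - 1]
        best_mse = np.full((H, W), np.inf)
        best_norm = np.zeros((H, W))
        for (dy, dx), nrm in zip(cands, norms):
            diff2 = (cur - _shift_prev(prev, dy, dx, md)) ** 2
            mse = ndimage.gaussian_filter(diff2, sigma, mode="reflect", truncate=truncate)
            better = mse < best_mse
            best_mse[better] = mse[better]
            best_norm[better] = nrm
        maps[i - 1] = best_norm
        series[i - 1] = best_norm[mask].mean()
    return series, maps


# ---------------------------------------------------------------------------
# Event detection
# ---------------------------------------------------------------------------

def detect_contractions(
    series: np.ndarray,
    times: np.ndarray,
    k_sd: float = 3.0,
    min_frames: int = 2,
    merge_gap_frames: int = 2,
) -> list[ContractionEvent]:
    """Threshold-crossing contraction events on a motion series.

    The baseline is robust (median + k_sd * 1.4826 MAD); runs of at least
    ``min_frames`` supra-threshold samples become events and runs
    separated by fewer than ``merge_gap_frames`` frames are merged.
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(series) < 10:
        raise ValueError("need >= 10 samples for baseline estimation")
    med = np.median(series)
    mad = np.median(np.abs(series - med))
    thr = med + k_sd * 1.4826 * mad
    if mad == 0:
        thr = med + k_sd * max(series.std(), 1e-9)
    above = series > thr
    # raw runs
    runs: list[list[int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append([start, i - 1])
            start = None
    if start is not None:
        runs.append([start, len(above) - 1])
    # merge close runs
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 < merge_gap_frames:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    dt = float(np.median(np.diff(times))) if len(times) > 1 else 1.0
    events = []
    for lo, hi in merged:
        if hi - lo + 1 < min_frames:
            continue
        events.append(
            ContractionEvent(
                onset_s=float(times[lo]),
                duration_s=float(times[hi] - times[lo] + dt),
                peak=float(series[lo:hi + 1].max()),
            )
        )
    return events
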