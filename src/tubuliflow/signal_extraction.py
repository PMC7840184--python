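"""Per-ROI trace extraction from stabilized stacks.

Ratiometric traces are computed as the mean of per-pixel f340/f380 ratios
(not the ratio of ROI means). Single-wavelength traces are normalized to a
pre-stimulus baseline under either of two conventions, both recorded in
the trace metadata:

* ``"baseline"`` — conventional dF/F0, ``(F_i - F_b) / F_b``;
* ``"frame"``    — ``(F_i - F_b) / F_i``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from tubuliflow.core_io import Roi, SignalTrace, StimulusProtocol

__all__ = [
    "BaselineSpec",
    "extract_ratio_trace",
    "extract_dff_trace",
    "detrend_linear",
    "classify_responder",
]


@dataclass
class BaselineSpec:
    """Pre-stimulus window (seconds) and the statistic taken over it."""

    start_s: float
    end_s: float
    statistic: str = "mean"

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("baseline window must have positive length")
        if self.statistic not in ("mean", "median"):
            raise ValueError(f"unknown statistic {self.statistic!r}")

    def select(self, times: np.ndarray) -> np.ndarray:
        sel = (times >= self.start_s) & (times <= self.end_s)
        if sel.sum() < 3:
            raise ValueError("baseline window covers fewer than 3 samples")
        return sel

    def value(self, times: np.ndarray, series: np.ndarray) -> float:
        stat = np.mean if self.statistic == "mean" else np.median
        return float(stat(series[self.select(times)]))


def extract_ratio_trace(
    f340: np.ndarray,
    f380: np.ndarray,
    roi: Roi,
    dt: float,
    floor_frac: float = 0.01,
    method: str = "mean_of_ratios",
) -> SignalTrace:
    """Fura-2 ratio trace: per frame, the ROI statistic of f340/f380.

    Pixels whose f380 falls below ``floor_frac`` of the channel maximum
    are excluded (and counted in the metadata) to avoid ratio blow-up.
    ``method="ratio_of_means"`` is available for sensitivity analysis.
    """
    f340 = np.asarray(f340, dtype=np.float64)
    f380 = np.asarray(f380, dtype=np.float64)
    if f340.shape != f380.shape:
        raise ValueError("channel shape mismatch")
    floor = floor_frac * f380.max()
    values = np.empty(f340.shape[0])
    n_excluded = 0
    for i in range(f340.shape[0]):
        valid = roi.mask & (f380[i] > floor)
        n_excluded += int(roi.mask.sum() - valid.sum())
        if not valid.any():
            raise ValueError(f"all ROI pixels excluded at frame {i}")
        if method == "mean_of_ratios":
            values[i] = np.mean(f340[i][valid] / f380[i][valid])
        elif method == "ratio_of_means":
            values[i] = np.mean(f340[i][valid]) / np.mean(f380[i][valid])
        else:
            raise ValueError(f"unknown method {method!r}")
    return SignalTrace(
        times=np.arange(f340.shape[0]) * dt,
        values=values,
        kind="ratio",
        roi_label=roi.label,
        meta={"method": method, "n_excluded": n_excluded},
    )


def extract_dff_trace(
    stack: np.ndarray,
    roi: Roi,
    baseline: BaselineSpec,
    dt: float,
    convention: str = "baseline",
) -> SignalTrace:
    """Normalized intensity-change trace for a single-wavelength channel."""
    if convention not in ("baseline", "frame"):
        raise ValueError(f"unknown convention {convention!r}")
    stack = np.asarray(stack, dtype=np.float64)
    times = np.arange(stack.shape[0]) * dt
    f = np.array([stack[i][roi.mask].mean() for i in range(stack.shape[0])])
    f_b = baseline.value(times, f)
    if f_b <= 0:
        raise ValueError(f"non-positive baseline {f_b}")
    denom = f_b if convention == "baseline" else f
    values = (f - f_b) / denom
    return SignalTrace(
        times=times,
        values=values,
        kind="dff",
        roi_label=roi.label,
        meta={"convention": convention, "f_baseline": f_b},
    )


def detrend_linear(
    trace: SignalTrace,
    protected_windows: list[tuple[float, float]] | None = None,
) -> SignalTrace:
    """Subtract a least-squares line fitted outside protected windows.

    The mean of the unprotected samples is preserved, so only slope (and
    any offset of the protected region relative to it) is removed.
    """
    protected_windows = protected_windows or []
    t, v = trace.times, trace.values
    free = np.ones_like(t, dtype=bool)
    for lo, hi in protected_windows:
        free &= ~((t >= lo) & (t <= hi))
    if free.sum() < 2:
        raise ValueError("fewer than 2 samples outside protected windows")
    slope, intercept = np.polyfit(t[free], v[free], 1)
    corrected = v - (slope * t + intercept) + float(v[free].mean())
    return SignalTrace(
        times=t,
        values=corrected,
        kind=trace.kind if trace.kind != "ratio" else "raw",
        roi_label=trace.roi_label,
        meta={**trace.meta, "detrend_slope": float(slope)},
    )


def classify_responder(
    trace: SignalTrace,
    protocol: StimulusProtocol,
    k_sd: float = 3.0,
    min_frames: int = 2,
    baseline: BaselineSpec | None = None,
    response_window_s: float = 60.0,
    sd_floor: float = 1e-9,
) -> tuple[bool, float]:
    """Threshold-crossing responder call after the first stimulus onset.

    A trace responds if it exceeds ``baseline_mean + k_sd * baseline_sd``
    for at least ``min_frames`` consecutive samples within
    ``response_window_s`` after onset. Returns (flag, amplitude) with
    amplitude = peak-in-window minus baseline mean (floored at 0).
    """
    t, v = trace.times, trace.values
    onset = protocol.onsets[0]
    if baseline is None:
        pre = t < onset
        if pre.sum() < 3:
            raise ValueError("no baseline window before first onset")
        base_vals = v[pre]
    else:
        if baseline.end_s > onset:
            raise ValueError("baseline window must end before first onset")
        base_vals = v[baseline.select(t)]
    mu = float(base_vals.mean())
    sd = max(float(base_vals.std()), sd_floor)
    window = (t >= onset) & (t <= onset + response_window_s)
    above = (v > mu + k_sd * sd) & window
    # longest consecutive run above threshold inside the window
    run = best = 0
    for flag in above:
        run = run + 1 if flag else 0
        best = max(best, run)
    responder = best >= min_frames
    amplitude = max(float(v[window].max() - mu), 0.0) if window.any() else 0.0
    return responder, amplitude
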