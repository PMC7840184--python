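"""Correction chain for widefield/multiphoton recordings.

Frame-gain flicker removal by histogram matching to the first frame,
spatial + temporal Gaussian filtering, two-channel dye separation, and
isolation of transient signals from static background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.exposure import match_histograms

__all__ = [
    "FilterSpec",
    "correct_flicker",
    "gaussian_filter_stack",
    "separate_background",
    "isolate_transients",
    "RADIUS_TO_SIGMA",
]

# ImageJ-style blur "radius" to Gaussian sigma. The upstream tooling names
# a plugin, not a kernel; the constant is explicit and configurable.
RADIUS_TO_SIGMA = 0.5


@dataclass
class FilterSpec:
    """Spatial blur radius (px) and temporal Gaussian sigma (frames)."""

    spatial_radius: float = 5.0
    temporal_sigma: float = 5.0

    def __post_init__(self) -> None:
        if self.spatial_radius < 0 or self.temporal_sigma < 0:
            raise ValueError("filter parameters must be >= 0")


def correct_flicker(stack: np.ndarray) -> np.ndarray:
    """Map every frame's intensity histogram onto the first frame's.

    The monotone quantile-matching transform removes global per-frame gain
    changes (mains flicker, bleaching) while preserving the within-frame
    rank order of pixels exactly. Idempotent up to float tolerance.
    """
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a (T, H, W) stack with >= 2 frames")
    if np.ptp(stack[0]) == 0:
        raise ValueError("constant first frame: histogram matching undefined")
    out = np.empty_like(stack)
    out[0] = stack[0]
    for i in range(1, stack.shape[0]):
        out[i] = match_histograms(stack[i], stack[0])
    return out


def gaussian_filter_stack(stack: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Per-frame 2-D spatial Gaussian, then a purely temporal 1-D Gaussian.

    The spatial sigma is ``spec.spatial_radius * RADIUS_TO_SIGMA``. The
    temporal pass smooths along the frame axis only (no additional spatial
    blur). Either pass with parameter 0 is the identity; DC gain is 1.
    """
    stack = np.asarray(stack, dtype=np.float64)
    out = stack
    sigma_s = spec.spatial_radius * RADIUS_TO_SIGMA
    if sigma_s > 0:
        out = ndimage.gaussian_filter(out, sigma=(0.0, sigma_s, sigma_s), mode="nearest")
    if spec.temporal_sigma > 0:
        out = ndimage.gaussian_filter1d(out, sigma=spec.temporal_sigma, axis=0, mode="nearest")
    return out


def separate_background(
    target: np.ndarray,
    background: np.ndarray,
    baseline_frames: np.ndarray | list[int],
) -> tuple[np.ndarray, float]:
    """Remove spectral bleed of the background channel from the target.

    A single global bleed coefficient alpha is estimated by least-squares
    regression (with intercept) of target on background intensities over
    the baseline frames, where the target is assumed to carry no signal of
    its own. Returns ``clip(target - alpha * background, 0, None)`` and
    the estimated alpha.
    """
    target = np.asarray(target, dtype=np.float64)
    background = np.asarray(background, dtype=np.float64)
    if target.shape != background.shape:
        raise ValueError(f"shape mismatch {target.shape} vs {background.shape}")
    idx = np.asarray(baseline_frames, dtype=int)
    if idx.size == 0:
        raise ValueError("baseline_frames must be nonempty")
    t = target[idx].ravel()
    b = background[idx].ravel()
    var_b = b.var()
    if var_b <= 1e-15 * max(b.mean() ** 2, 1.0):
        warnings.warn("background channel is constant; alpha set to 0", stacklevel=2)
        return target.copy(), 0.0
    alpha = float(np.cov(t, b, bias=True)[0, 1] / var_b)
    corrected = np.clip(target - alpha * background, 0.0, None)
    return corrected, alpha


def isolate_transients(
    stack: np.ndarray,
    window_frames: int = 50,
    percentile: float = 10.0,
) -> np.ndarray:
    """Subtract a per-pixel running low-percentile temporal baseline.

    Static structures (whatever a pixel does most of the time) are
    suppressed toward zero while transient excursions above the rolling
    baseline survive with their amplitude intact.
    """
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 3:
        raise ValueError("need a (T, H, W) stack")
    if window_frames < 3:
        raise ValueError("window must be >= 3 frames")
    if window_frames > stack.shape[0]:
        raise ValueError(
            f"window {window_frames} exceeds stack length {stack.shape[0]}"
        )
    baseline = ndimage.percentile_filter(
        stack, percentile, size=(window_frames, 1, 1), mode="nearest"
    )
    return np.clip(stack - baseline, 0.0, None)
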