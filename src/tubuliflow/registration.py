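"""Dense displacement estimation, stack stabilization and drift removal.

The displacement estimator is intensity-based coarse-to-fine optical flow
(iterative Lucas-Kanade with Gaussian pyramids, via scikit-image). The
contract is accuracy, not a specific algorithm: rigid shifts up to 5 px are
recovered to < 0.25 px mean vector error on clean images and < 0.5 px at
SNR 10 (see the test suite). Conventions follow :mod:`tubuliflow.core_io`:
a vector v at pixel p of frame i means material at reference pixel p is
found at ``p + v`` in frame i.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import theilslopes
from skimage.registration import optical_flow_ilk, phase_cross_correlation

from tubuliflow.core_io import DisplacementField, TimeLapseRecording

__all__ = [
    "RegistrationConfig",
    "estimate_displacement",
    "register_ratiometric_pair",
    "apply_displacement",
    "correct_drift",
]


@dataclass
class RegistrationConfig:
    """Parameters of the dense flow estimator.

    ``radius`` is the local window radius of the Lucas-Kanade solver;
    ``num_warp`` the number of warping iterations per pyramid level;
    ``gaussian_sigma`` the prefilter smoothing. ``border_margin`` pixels
    next to the frame edge are flagged as unreliable for ROI statistics.
    """

    reference_mode: str = "to_t0"
    radius: int = 7
    num_warp: int = 10
    gaussian_sigma: float = 1.0
    border_margin: int = 5
    compose_consecutive: bool = False

    def __post_init__(self) -> None:
        if self.reference_mode not in ("to_t0", "consecutive"):
            raise ValueError(f"unknown reference_mode {self.reference_mode!r}")
        if self.radius < 1:
            raise ValueError("radius must be >= 1")


def _flow_pair(reference: np.ndarray, moving: np.ndarray, config: RegistrationConfig) -> np.ndarray:
    """(H, W, 2) flow such that ``moving(p + v(p)) ~= reference(p)``."""
    if np.ptp(reference) == 0 or np.ptp(moving) == 0:
        warnings.warn(
            "constant image: flow is undefined, returning zero field",
            stacklevel=3,
        )
        return np.zeros(reference.shape + (2,), dtype=np.float32)
    v, u = optical_flow_ilk(
        reference.astype(np.float32),
        moving.astype(np.float32),
        radius=config.radius,
        num_warp=config.num_warp,
        gaussian=False,
        prefilter=True,
    )
    return np.stack([v, u], axis=-1).astype(np.float32)


def estimate_displacement(
    stack: np.ndarray | TimeLapseRecording,
    config: RegistrationConfig | None = None,
    channel: str | None = None,
) -> DisplacementField:
    """Estimate a dense displacement field for every frame of a stack.

    For ``reference_mode="to_t0"`` the reference is the t0 frame; for
    ``"consecutive"`` each frame is referenced to its predecessor (frame 0
    gets a zero field). With ``compose_consecutive`` the to-t0 field is
    built by accumulating consecutive-frame flows, which is more robust to
    large deformations.
    """
    config = config or RegistrationConfig()
    if isinstance(stack, TimeLapseRecording):
        if channel is None:
            raise ValueError("channel must be given for a multi-channel recording")
        t0 = stack.t0_index
        stack = stack[channel]
    else:
        t0 = 0
        stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a (T, H, W) stack with >= 2 frames")
    T = stack.shape[0]
    fields = np.zeros(stack.shape + (2,), dtype=np.float32)
    if config.reference_mode == "consecutive":
        for i in range(1, T):
            fields[i] = _flow_pair(stack[i - 1], stack[i], config)
    elif config.compose_consecutive:
        # accumulate: v_0i(p) = v_0,i-1(p) + v_{i-1,i}(p + v_0,i-1(p))
        rows, cols = np.mgrid[0:stack.shape[1], 0:stack.shape[2]].astype(np.float32)
        acc = np.zeros(stack.shape[1:] + (2,), dtype=np.float32)
        for i in range(1, T):
            step = _flow_pair(stack[i - 1], stack[i], config)
            coords = [rows + acc[..., 0], cols + acc[..., 1]]
            warped = np.stack(
                [
                    ndimage.map_coordinates(step[..., k], coords, order=1, mode="nearest")
                    for k in (0, 1)
                ],
                axis=-1,
            )
            acc = acc + warped
            fields[i] = acc
    else:
        for i in range(T):
            if i == t0:
                continue
            fields[i] = _flow_pair(stack[t0], stack[i], config)
    return DisplacementField(
        vectors=fields,
        reference_mode=config.reference_mode,
        border_margin=config.border_margin,
    )


def apply_displacement(stack: np.ndarray, field: DisplacementField) -> np.ndarray:
    """Warp every frame onto the reference (t0) geometry.

    Each frame i is resampled at ``p + v_i(p)`` with bilinear
    interpolation, so the result at pixel p shows the material that sat at
    p in the reference frame. Out-of-frame samples take the edge value.
    Only meaningful for ``reference_mode="to_t0"`` fields.
    """
    stack = np.asarray(stack)
    if field.vectors.shape[:3] != stack.shape:
        raise ValueError(
            f"field shape {field.vectors.shape[:3]} != stack shape {stack.shape}"
        )
    if not np.all(np.isfinite(field.vectors)):
        raise ValueError("non-finite displacement vectors")
    rows, cols = np.mgrid[0:stack.shape[1], 0:stack.shape[2]].astype(np.float64)
    out = np.empty_like(stack, dtype=np.float64)
    for i in range(stack.shape[0]):
        coords = [rows + field.vectors[i, ..., 0], cols + field.vectors[i, ..., 1]]
        out[i] = ndimage.map_coordinates(
            stack[i].astype(np.float64), coords, order=1, mode="nearest"
        )
    return out


def register_ratiometric_pair(
    f340: np.ndarray,
    f380: np.ndarray,
    config: RegistrationConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, DisplacementField]:
    """Stabilize a ratiometric excitation pair with a single shared field.

    One displacement field is estimated on the pixelwise sum of the two
    channels, then applied identically to both, so the post-hoc ratio is
    free of differential motion artifacts.
    """
    f340 = np.asarray(f340, dtype=np.float64)
    f380 = np.asarray(f380, dtype=np.float64)
    if f340.shape != f380.shape:
        raise ValueError(f"shape mismatch: {f340.shape} vs {f380.shape}")
    config = config or RegistrationConfig()
    field = estimate_displacement(f340 + f380, config)
    return apply_displacement(f340, field), apply_displacement(f380, field), field


def global_shifts(stack: np.ndarray, upsample_factor: int = 50) -> np.ndarray:
    """Per-frame rigid translation vs the first frame, ``(T, 2)`` (drow, dcol).

    Positive values mean the frame content moved down/right relative to
    frame 0 (same sign convention as displacement fields).
    """
    stack = np.asarray(stack)
    shifts = np.zeros((stack.shape[0], 2))
    for i in range(1, stack.shape[0]):
        shift, _, _ = phase_cross_correlation(
            stack[0].astype(np.float64),
            stack[i].astype(np.float64),
            upsample_factor=upsample_factor,
            normalization=None,
        )
        # phase_cross_correlation returns the shift registering moving onto
        # reference, i.e. minus the content displacement.
        shifts[i] = -shift
    return shifts


def correct_drift(
    recording: TimeLapseRecording,
    reference_channel: str | None = None,
) -> tuple[TimeLapseRecording, np.ndarray]:
    """Remove slow constant-velocity translation, keeping fast motion.

    Per-frame global shifts against t0 are measured on ``reference_channel``
    (default: first channel) and a constant drift velocity is fitted with
    the robust Theil-Sen estimator, so transient contractions do not bias
    the fit. Only the fitted linear component is subtracted, from every
    channel. Returns the corrected recording and the (2,) drift velocity
    in px/frame (drow, dcol).
    """
    if recording.n_frames < 10:
        raise ValueError("drift correction needs >= 10 frames")
    ref = reference_channel or recording.channels[0]
    shifts = global_shifts(recording[ref])
    idx = np.arange(recording.n_frames)
    velocity = np.array(
        [theilslopes(shifts[:, k], idx)[0] for k in (0, 1)]
    )
    corrected = {}
    for ch, frames in recording.frames.items():
        out = np.empty_like(frames, dtype=np.float64)
        for i in range(recording.n_frames):
            # content moved by +velocity*i; shift it back
            out[i] = ndimage.shift(
                frames[i].astype(np.float64),
                -velocity * i,
                order=1,
                mode="nearest",
            )
        corrected[ch] = out
    return recording.with_frames(corrected), velocity
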