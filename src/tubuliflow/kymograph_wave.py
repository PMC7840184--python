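"""Tubule straightening, kymographs and wave-velocity regression.

A hand-drawn polyline is spline-smoothed and the image is resampled along
normals to the curve, yielding a straightened ``(T, width, arc_length)``
stack. Transverse averaging of a motion stack gives a space-time
kymograph; the propagation velocity is the slope of a least-squares
regression of arc-length position on per-bin half-max onset time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import make_interp_spline
from scipy.stats import linregress

__all__ = [
    "Kymograph",
    "WaveFit",
    "straighten_tubule",
    "build_kymograph",
    "estimate_wave_velocity",
]


@dataclass
class Kymograph:
    """Arc-length bins (µm) x time (s) matrix of mean transverse motion."""

    matrix: np.ndarray  # (n_bins, T)
    bin_size_um: float
    dt: float
    bin_centers_um: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.bin_size_um <= 0 or self.dt <= 0:
            raise ValueError("bin_size_um and dt must be > 0")
        if np.any(self.matrix < 0):
            raise ValueError("kymograph matrix must be non-negative")
        if self.bin_centers_um is None:
            self.bin_centers_um = (np.arange(self.matrix.shape[0]) + 0.5) * self.bin_size_um
        self.bin_centers_um = np.asarray(self.bin_centers_um, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.matrix.shape[1]) * self.dt


@dataclass
class WaveFit:
    velocity_um_s: float
    r_squared: float
    onset_times_s: np.ndarray
    positions_um: np.ndarray
    valid: bool

    def __post_init__(self) -> None:
        if self.valid and not np.isfinite(self.velocity_um_s):
            raise ValueError("valid fit requires finite velocity")
        if np.isfinite(self.r_squared) and not 0 <= self.r_squared <= 1 + 1e-9:
            raise ValueError("r_squared outside [0, 1]")


def _spline_centerline(polyline: np.ndarray, step_px: float = 1.0):
    """Arc-length-parameterized smooth centerline points and unit tangents."""
    poly = np.asarray(polyline, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 2:
        raise ValueError("polyline needs >= 2 vertices")
    seg = np.hypot(*np.diff(poly, axis=0).T)
    if np.any(seg == 0):
        raise ValueError("polyline has repeated vertices")
    u = np.concatenate([[0.0], np.cumsum(seg)])
    k = min(3, poly.shape[0] - 1)
    spl = make_interp_spline(u, poly, k=k)
    # resample at unit arc length (refine: chord length underestimates arc)
    dense = spl(np.linspace(0, u[-1], max(int(u[-1] * 4), 8)))
    arc = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(dense, axis=0).T))])
    total = arc[-1]
    n_out = max(int(round(total / step_px)) + 1, 2)
    targets = np.linspace(0, total, n_out)
    # map target arc lengths back to spline parameter
    params = np.interp(targets, arc, np.linspace(0, u[-1], len(dense)))
    pts = spl(params)
    tangents = spl(params, 1)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    return pts, tangents, total


def straighten_tubule(
    stack: np.ndarray,
    polyline: np.ndarray,
    width_px: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample a stack along normals to a spline-smoothed polyline.

    Returns ``(straightened, flagged)`` where ``straightened`` is
    ``(T, width_px, L)`` with L the rounded polyline arc length in pixels,
    and ``flagged`` marks columns whose local curvature radius is below
    ``width_px / 2`` (self-intersecting normals).
    """
    stack = np.asarray(stack, dtype=np.float64)
    single = stack.ndim == 2
    if single:
        stack = stack[None]
    if width_px < 3:
        raise ValueError("width_px must be >= 3")
    pts, tangents, total = _spline_centerline(polyline)
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])  # (x, y) rotated
    offsets = np.arange(width_px, dtype=float) - (width_px - 1) / 2.0
    # sample coordinates: (width, L) grids of x and y
    xs = pts[:, 0][None, :] + offsets[:, None] * normals[:, 0][None, :]
    ys = pts[:, 1][None, :] + offsets[:, None] * normals[:, 1][None, :]
    out = np.empty((stack.shape[0], width_px, pts.shape[0]))
    for i in range(stack.shape[0]):
        out[i] = ndimage.map_coordinates(stack[i], [ys, xs], order=1, mode="nearest")
    # curvature flag: |dT/ds| = 1/R; flag where R < width/2
    dT = np.gradient(tangents, axis=0)
    curvature = np.linalg.norm(dT, axis=1)  # per unit arc step (~1 px)
    flagged = curvature > 2.0 / width_px
    if single:
        out = out[0]
    return out, flagged


def build_kymograph(
    motion_stack: np.ndarray,
    bin_size_um: float,
    pixel_size: float = 1.0,
    dt: float = 1.0,
) -> Kymograph:
    """Average a straightened motion stack across the transverse axis and
    pool arc-length columns into bins."""
    motion_stack = np.asarray(motion_stack, dtype=float)
    if motion_stack.ndim != 3:
        raise ValueError("need a (T, width, L) straightened motion stack")
    if bin_size_um < pixel_size:
        raise ValueError("bin size must be at least one pixel")
    profile = motion_stack.mean(axis=1)  # (T, L)
    L = profile.shape[1]
    bin_px = bin_size_um / pixel_size
    n_bins = max(int(L / bin_px), 1)
    edges = (np.arange(n_bins + 1) * bin_px).round().astype(int)
    edges[-1] = L
    matrix = np.stack(
        [profile[:, a:b].mean(axis=1) for a, b in zip(edges[:-1], edges[1:])]
    )
    centers = (edges[:-1] + edges[1:]) / 2.0 * pixel_size
    return Kymograph(
        matrix=np.clip(matrix, 0, None),
        bin_size_um=bin_size_um,
        dt=dt,
        bin_centers_um=centers,
    )


def _onset_time(trace: np.ndarray, times: np.ndarray, threshold_frac: float) -> float | None:
    """First crossing of ``threshold_frac * max`` with linear interpolation."""
    peak = trace.max()
    if peak <= 0:
        return None
    thr = threshold_frac * peak
    above = trace >= thr
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(times[0])
    t0, t1 = times[i - 1], times[i]
    v0, v1 = trace[i - 1], trace[i]
    if v1 == v0:
        return float(t1)
    return float(t0 + (thr - v0) / (v1 - v0) * (t1 - t0))


def estimate_wave_velocity(
    kymo: Kymograph,
    threshold_frac: float = 0.5,
    min_bins: int = 5,
    min_r_squared: float = 0.5,
    min_activity_frac: float = 0.1,
) -> WaveFit:
    """Propagation velocity from a regression of position on onset time.

    Per spatial bin, the onset is the first time its trace crosses
    ``threshold_frac`` of its own maximum (bins whose peak is below
    ``min_activity_frac`` of the global peak are ignored). The slope of
    position (µm) on onset time (s) is the signed velocity. The fit is
    flagged invalid when onsets are synchronous (spread < 2 dt) or the
    regression explains less than ``min_r_squared`` of the variance.
    """
    global_peak = kymo.matrix.max()
    times = kymo.times
    onsets, positions = [], []
    for b in range(kymo.matrix.shape[0]):
        trace = kymo.matrix[b]
        if trace.max() < min_activity_frac * global_peak:
            continue
        t_on = _onset_time(trace, times, threshold_frac)
        if t_on is not None:
            onsets.append(t_on)
            positions.append(kymo.bin_centers_um[b])
    onsets = np.asarray(onsets)
    positions = np.asarray(positions)
    if len(onsets) < min_bins:
        raise ValueError(
            f"only {len(onsets)} bins with a threshold crossing (need {min_bins})"
        )
    spread = onsets.max() - onsets.min()
    if spread < 2 * kymo.dt:
        return WaveFit(
            velocity_um_s=np.nan,
            r_squared=np.nan,
            onset_times_s=onsets,
            positions_um=positions,
            valid=False,
        )
    fit = linregress(onsets, positions)
    r2 = float(fit.rvalue ** 2)
    return WaveFit(
        velocity_um_s=float(fit.slope),
        r_squared=r2,
        onset_times_s=onsets,
        positions_um=positions,
        valid=r2 >= min_r_squared,
    )
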