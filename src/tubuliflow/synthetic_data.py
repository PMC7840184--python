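"""Phantom time-lapse generators with exact ground truth.

Every generator renders movies through an analytic deformation of a static
template, so the true displacement of each pixel, the true Ca2+ trace, the
true wave velocity and the true transport profile are known by
construction. Rendering uses 1-px linear edge ramps (area-weighted
boundary pixels), which makes subpixel displacements detectable by the
registration stage.

All randomness flows from ``PhantomParams.seed`` through a single
``numpy.random.default_rng``; a fixed seed yields bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage

from tubuliflow.core_io import Roi, StimulusProtocol, TimeLapseRecording

__all__ = [
    "PhantomParams",
    "GroundTruth",
    "make_contracting_tubule",
    "make_wave_movie",
    "make_transport_movie",
    "make_dose_response",
    "corrupt",
    "transport_rois",
    "advection_profile",
]


@dataclass
class PhantomParams:
    """Knobs shared by all phantom generators. Units are physical (µm, s)."""

    shape: tuple[int, int] = (64, 64)
    n_frames: int = 40
    dt: float = 1.0
    pixel_size: float = 1.0

    # tubule geometry
    radius_um: float = 22.0
    wall_thickness_um: float = 8.0
    tubule_length_um: float = 500.0

    # contraction kinetics
    contraction_amplitude_um: float = 4.0
    onset_s: float = 10.0
    tau_rise_s: float = 2.0
    tau_decay_s: float = 8.0

    # Ca2+ signal
    ca_amplitude: float = 1.0
    coupling_delay_s: float = 0.0  # contraction onset minus Ca2+ onset

    # wave propagation (0 = synchronous)
    wave_velocity_um_s: float = 0.0

    # luminal transport
    n_particles: int = 40
    section_length_um: float = 40.0
    n_side_rois: int = 3
    advection_speed_um_s: float = 3.0
    advection_mode: str = "roi0_only"  # {"roi0_only", "ascending", "symmetric"}
    basal_jitter_px: float = 0.15
    transport_duration_s: float = 40.0

    # corruption
    noise_sigma: float = 0.0
    poisson_gain: float = 0.0
    flicker_amplitude: float = 0.0
    drift_px_per_frame: tuple[float, float] = (0.0, 0.0)
    bleed_alpha: float = 0.0

    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "dt", "pixel_size", "radius_um", "wall_thickness_um",
            "tubule_length_um", "tau_rise_s", "tau_decay_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in (
            "contraction_amplitude_um", "ca_amplitude", "noise_sigma",
            "poisson_gain", "flicker_amplitude", "section_length_um",
            "advection_speed_um_s", "basal_jitter_px",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """Exact quantities a phantom guarantees, for recovery tests."""

    displacement: np.ndarray | None = None      # (T, H, W, 2), to_t0 convention
    times: np.ndarray | None = None
    ca_trace: np.ndarray | None = None          # true dF/F over time
    contraction_px: np.ndarray | None = None    # radial amplitude per frame, px
    coupling_delay_s: float | None = None
    wave_velocity_um_s: float | None = None
    onset_by_position_s: np.ndarray | None = None
    advection_um_s: dict[int, float] | None = None
    expected_di_sign: int | None = None
    alpha: float | None = None
    flicker_gains: np.ndarray | None = None
    drift_px_per_frame: tuple[float, float] | None = None
    ec50: float | None = None
    hill_h: float | None = None
    rmax: float | None = None
    protocol: StimulusProtocol | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Kinetics and texture helpers
# ---------------------------------------------------------------------------

def alpha_kinetics(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Single-exponential rise/decay transient, normalized to peak 1 at t >= 0."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    if tau_rise <= 1e-12:
        out[pos] = np.exp(-t[pos] / tau_decay)
        return out
    t_peak = tau_rise * math.log1p(tau_decay / tau_rise)
    peak = (1 - math.exp(-t_peak / tau_rise)) * math.exp(-t_peak / tau_decay)
    out[pos] = (1 - np.exp(-t[pos] / tau_rise)) * np.exp(-t[pos] / tau_decay) / peak
    return out


def _smooth_noise(shape: tuple[int, int], rng: np.random.Generator, sigma: float = 2.0) -> np.ndarray:
    """Band-limited texture in [0, 1] for registration to latch onto."""
    tex = ndimage.gaussian_filter(rng.random(shape), sigma)
    lo, hi = tex.min(), tex.max()
    return (tex - lo) / max(hi - lo, 1e-12)


def _apply_noise(arr: np.ndarray, params: PhantomParams, rng: np.random.Generator) -> np.ndarray:
    out = arr.astype(np.float64)
    if params.poisson_gain > 0:
        out = rng.poisson(np.clip(out, 0, None) / params.poisson_gain) * params.poisson_gain
    if params.noise_sigma > 0:
        out = out + rng.normal(0.0, params.noise_sigma, out.shape)
    return out


# ---------------------------------------------------------------------------
# Contracting annular tubule
# ---------------------------------------------------------------------------

def make_contracting_tubule(
    params: PhantomParams,
    channels: tuple[str, ...] = ("brightfield", "gcamp"),
) -> tuple[TimeLapseRecording, GroundTruth]:
    """Annular tubule whose wall displaces radially inward on stimulation.

    The whole image is rendered through the radial deformation, so the
    ground-truth displacement field is valid at every pixel: material at
    radius r moves inward by ``a * min(r / R_in, 1)`` where ``a`` is the
    contraction amplitude at that frame. A peripheral-band fluorescence
    channel carries the coupled Ca2+ transient; the brightfield channel
    carries static texture for registration. Optional channels ``f340`` /
    ``f380`` render a ratiometric pair driven by the same Ca2+ trace.
    """
    ps = params.pixel_size
    amp_px = params.contraction_amplitude_um / ps
    r_out = params.radius_um / ps
    r_in = r_out - params.wall_thickness_um / ps
    if params.contraction_amplitude_um >= params.radius_um:
        raise ValueError("contraction amplitude must be smaller than the radius")
    if r_in <= amp_px + 1:
        raise ValueError("wall too thick / amplitude too large for the inner radius")

    H, W = params.shape
    rng = np.random.default_rng(params.seed)
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    rows, cols = np.mgrid[0:H, 0:W].astype(np.float64)
    dy, dx = rows - cy, cols - cx
    rho = np.hypot(dy, dx)
    with np.errstate(invalid="ignore", divide="ignore"):
        uy = np.where(rho > 0, dy / rho, 0.0)
        ux = np.where(rho > 0, dx / rho, 0.0)

    tex1 = _smooth_noise((H, W), rng, sigma=1.5)
    tex2 = _smooth_noise((H, W), rng, sigma=3.0)

    def wall_profile(r: np.ndarray) -> np.ndarray:
        return np.clip(np.minimum(r - r_in + 0.5, r_out - r + 0.5), 0.0, 1.0)

    def templates(r: np.ndarray, y: np.ndarray, x: np.ndarray, ca: float) -> dict[str, np.ndarray]:
        w = wall_profile(r)
        t1 = ndimage.map_coordinates(tex1, [y, x], order=1, mode="nearest")
        t2 = ndimage.map_coordinates(tex2, [y, x], order=1, mode="nearest")
        out: dict[str, np.ndarray] = {}
        if "brightfield" in channels:
            out["brightfield"] = 30.0 + 170.0 * w * (0.5 + 0.5 * t1) + 30.0 * t2
        if "gcamp" in channels:
            out["gcamp"] = 10.0 + 100.0 * w * (1.0 + ca)
        if "f340" in channels:
            out["f340"] = 10.0 + 100.0 * w * (1.0 + 0.8 * ca) * (0.6 + 0.4 * t1)
        if "f380" in channels:
            out["f380"] = 10.0 + 100.0 * w * (1.0 - 0.4 * ca) * (0.6 + 0.4 * t1)
        if "background" in channels:
            out["background"] = 20.0 + 60.0 * t2
        return out

    times = np.arange(params.n_frames) * params.dt
    ca_trace = params.ca_amplitude * alpha_kinetics(
        times - params.onset_s, params.tau_rise_s, params.tau_decay_s
    )
    a_series = amp_px * alpha_kinetics(
        times - params.onset_s - params.coupling_delay_s,
        params.tau_rise_s,
        params.tau_decay_s,
    )

    frames = {ch: np.empty((params.n_frames, H, W)) for ch in channels}
    truth_field = np.zeros((params.n_frames, H, W, 2), dtype=np.float32)
    for i, (a, ca) in enumerate(zip(a_series, ca_trace)):
        # inverse radial map: target radius rho -> source radius r
        scale = r_in / max(r_in - a, 1e-9)
        r_src = np.where(rho <= r_in - a, rho * scale, rho + a)
        y_src = cy + r_src * uy
        x_src = cx + r_src * ux
        for ch, img in templates(r_src, y_src, x_src, ca).items():
            frames[ch][i] = img
        # forward displacement of material at t0 pixel (radius rho here)
        disp = -a * np.minimum(rho / r_in, 1.0)
        truth_field[i, ..., 0] = disp * uy
        truth_field[i, ..., 1] = disp * ux

    frames = {ch: _apply_noise(arr, params, rng) for ch, arr in frames.items()}
    rec = TimeLapseRecording(frames=frames, dt=params.dt, pixel_size=ps)
    protocol = StimulusProtocol(onsets=[params.onset_s], duration=10.0)
    truth = GroundTruth(
        displacement=truth_field,
        times=times,
        ca_trace=ca_trace,
        contraction_px=a_series,
        coupling_delay_s=params.coupling_delay_s,
        protocol=protocol,
        extras={"center": (cy, cx), "r_in_px": r_in, "r_out_px": r_out},
    )
    return rec, truth


# ---------------------------------------------------------------------------
# Propagating contraction wave
# ---------------------------------------------------------------------------

def make_wave_movie(params: PhantomParams) -> tuple[TimeLapseRecording, GroundTruth]:
    """Horizontal tubule whose transverse contraction propagates along x.

    Contraction onset at longitudinal position x (px) is
    ``onset_s + x / v_px`` for positive wave velocity (propagation toward
    +x from the left end) and mirrored for negative velocity. The rendered
    band compresses vertically about its axis, so motion is detectable at
    and inside both walls.
    """
    if params.wave_velocity_um_s == 0:
        raise ValueError("wave velocity must be nonzero; use make_contracting_tubule for synchronous")
    if params.tubule_length_um < 10 * params.radius_um:
        raise ValueError("tubule length must be >= 10 x radius")
    ps = params.pixel_size
    v_px = params.wave_velocity_um_s / ps  # signed, px/s
    L_px = int(round(params.tubule_length_um / ps))
    spread_s = L_px / abs(v_px)
    if spread_s < 2 * params.dt:
        raise ValueError(
            f"wave unresolvable: onset spread {spread_s:.3g} s < 2 frames"
        )
    h0 = params.radius_um / ps
    amp_px = params.contraction_amplitude_um / ps
    if amp_px >= h0:
        raise ValueError("contraction amplitude must be smaller than the radius")

    H = int(round(2 * h0 + 12))
    W = L_px
    rng = np.random.default_rng(params.seed)
    yc = (H - 1) / 2.0
    tex = _smooth_noise((H, W), rng, sigma=1.5)
    template = (
        20.0
        + 200.0
        * np.clip(h0 - np.abs(np.arange(H) - yc) + 0.5, 0.0, 1.0)[:, None]
        * (0.5 + 0.5 * tex)
    )

    x_px = np.arange(W, dtype=float)
    if v_px > 0:
        onset_by_x = params.onset_s + x_px / v_px
    else:
        onset_by_x = params.onset_s + (W - 1 - x_px) / abs(v_px)

    times = np.arange(params.n_frames) * params.dt
    rows = np.arange(H, dtype=float)[:, None]
    cols = np.broadcast_to(np.arange(W, dtype=float), (H, W))
    bf = np.empty((params.n_frames, H, W))
    for i, t in enumerate(times):
        a_x = amp_px * alpha_kinetics(
            t - onset_by_x, params.tau_rise_s, params.tau_decay_s
        )
        h_x = h0 - a_x  # (W,)
        y_src = yc + (rows - yc) * (h0 / h_x)[None, :]
        bf[i] = ndimage.map_coordinates(template, [y_src, cols], order=1, mode="nearest")
    bf = _apply_noise(bf, params, rng)

    rec = TimeLapseRecording(
        frames={"brightfield": bf}, dt=params.dt, pixel_size=ps
    )
    truth = GroundTruth(
        times=times,
        wave_velocity_um_s=params.wave_velocity_um_s,
        onset_by_position_s=onset_by_x,
        contraction_px=np.full(params.n_frames, amp_px),
        extras={"yc": yc, "h0_px": h0},
    )
    return rec, truth


# ---------------------------------------------------------------------------
# Luminal transport
# ---------------------------------------------------------------------------

def advection_profile(params: PhantomParams) -> dict[int, float]:
    """Signed per-ROI advection speed (µm/s along +x) for each section index."""
    k = params.n_side_rois
    v0 = params.advection_speed_um_s
    prof: dict[int, float] = {}
    if params.advection_mode == "roi0_only":
        prof = {i: 0.0 for i in range(-k, k + 1)}
        prof[0] = v0
    elif params.advection_mode == "ascending":
        # strong flow toward ascending (+x) side, weak on descending side
        for i in range(-k, k + 1):
            decay = math.exp(-abs(i) / 2.0)
            prof[i] = v0 * decay if i >= 0 else 0.15 * v0 * decay
    elif params.advection_mode == "symmetric":
        # content spreads outward from the stimulated center, mirror-equal
        for i in range(-k, k + 1):
            decay = math.exp(-abs(i) / 2.0)
            prof[i] = math.copysign(v0 * decay, i) if i != 0 else 0.0
        prof[0] = 0.0
    else:
        raise ValueError(f"unknown advection_mode {params.advection_mode!r}")
    return prof


def _transport_geometry(params: PhantomParams) -> dict:
    ps = params.pixel_size
    L_px = params.section_length_um / ps
    k = params.n_side_rois
    margin = 6
    W = int(round((2 * k + 1) * L_px)) + 2 * margin
    h0 = params.radius_um / ps
    H = int(round(2 * h0 + 14))
    yc = (H - 1) / 2.0
    x0 = margin  # left edge of ROI -k
    return {"W": W, "H": H, "yc": yc, "h0": h0, "L_px": L_px, "x0": x0, "k": k}


def transport_rois(params: PhantomParams) -> list[Roi]:
    """Equidistant rectangular luminal ROIs ``"ROI -k" .. "ROI +k"``."""
    g = _transport_geometry(params)
    yc, h0, L, x0, k = g["yc"], g["h0"], g["L_px"], g["x0"], g["k"]
    y_top, y_bot = yc - h0 + 1, yc + h0 - 1
    rois = []
    for i in range(-k, k + 1):
        xl = x0 + (i + k) * L
        xr = xl + L
        # right edge inset by half a pixel so abutting sections share no centers
        poly = [[xl, y_top], [xr - 0.5, y_top], [xr - 0.5, y_bot], [xl, y_bot]]
        rois.append(Roi.from_polygon(f"ROI {i}", poly, (g["H"], g["W"])))
    return rois


def make_transport_movie(params: PhantomParams) -> tuple[TimeLapseRecording, GroundTruth]:
    """Luminal particles advected with a per-section speed profile.

    Particles jitter with a basal random walk throughout; within
    ``[onset_s, onset_s + transport_duration_s]`` each particle
    additionally advects along x at the speed of the section it currently
    occupies. The stimulated section is ROI 0; positive indices lie toward
    +x (the ascending-stage direction).
    """
    g = _transport_geometry(params)
    H, W, yc, h0, L, x0, k = (
        g["H"], g["W"], g["yc"], g["h0"], g["L_px"], g["x0"], g["k"]
    )
    ps = params.pixel_size
    prof = advection_profile(params)
    rng = np.random.default_rng(params.seed)

    n = params.n_particles
    px = rng.uniform(x0, x0 + (2 * k + 1) * L, n)
    py = rng.uniform(yc - 0.55 * h0, yc + 0.55 * h0, n)
    y_lo, y_hi = yc - 0.75 * h0, yc + 0.75 * h0

    # static wall template
    wall = np.clip(np.abs(np.arange(H) - yc) - h0 + 0.5, 0.0, 1.0)
    wall = np.clip(np.minimum(wall, h0 + 4 - np.abs(np.arange(H) - yc) + 0.5), 0, 1)
    tex = _smooth_noise((H, W), rng, sigma=1.5)
    base = 30.0 + 180.0 * wall[:, None] * (0.5 + 0.5 * tex)

    def roi_of(x: float) -> int:
        idx = int(math.floor((x - x0) / L)) - k
        return min(max(idx, -k), k)

    sigma_p = 1.6
    stamp_r = 5
    wy, wx = np.mgrid[-stamp_r:stamp_r + 1, -stamp_r:stamp_r + 1]

    times = np.arange(params.n_frames) * params.dt
    movie = np.empty((params.n_frames, H, W))
    active_lo = params.onset_s
    active_hi = params.onset_s + params.transport_duration_s
    for i, t in enumerate(times):
        if i > 0:
            px = px + rng.normal(0, params.basal_jitter_px, n)
            py = py + rng.normal(0, params.basal_jitter_px, n)
            if active_lo <= t < active_hi:
                for j in range(n):
                    px[j] += prof[roi_of(px[j])] / ps * params.dt
            px = np.clip(px, 1.0, W - 2.0)
            py = np.clip(py, y_lo, y_hi)
        img = base.copy()
        for j in range(n):
            cyj, cxj = int(round(py[j])), int(round(px[j]))
            blob = 150.0 * np.exp(
                -(((wy + cyj - py[j]) ** 2) + ((wx + cxj - px[j]) ** 2))
                / (2 * sigma_p ** 2)
            )
            ys = slice(max(cyj - stamp_r, 0), min(cyj + stamp_r + 1, H))
            xs = slice(max(cxj - stamp_r, 0), min(cxj + stamp_r + 1, W))
            by = slice(ys.start - (cyj - stamp_r), blob.shape[0] - ((cyj + stamp_r + 1) - ys.stop))
            bx = slice(xs.start - (cxj - stamp_r), blob.shape[1] - ((cxj + stamp_r + 1) - xs.stop))
            img[ys, xs] += blob[by, bx]
        movie[i] = img
    movie = _apply_noise(movie, params, rng)

    rec = TimeLapseRecording(frames={"brightfield": movie}, dt=params.dt, pixel_size=ps)
    if params.advection_mode == "ascending":
        di_sign = 1
    elif params.advection_mode == "symmetric":
        di_sign = 0
    else:
        di_sign = 0
    protocol = StimulusProtocol(onsets=[params.onset_s], duration=10.0)
    truth = GroundTruth(
        times=times,
        advection_um_s=prof,
        expected_di_sign=di_sign,
        protocol=protocol,
        extras={"geometry": g},
    )
    return rec, truth


# ---------------------------------------------------------------------------
# Dose-response and artifact corruption
# ---------------------------------------------------------------------------

def make_dose_response(
    ec50: float,
    h: float,
    rmax: float,
    concentrations: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Hill-equation responses ``rmax c^h / (ec50^h + c^h)`` plus noise."""
    c = np.asarray(concentrations, dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentrations must be > 0")
    resp = rmax * c ** h / (ec50 ** h + c ** h)
    if noise_sd > 0:
        resp = resp + np.random.default_rng(seed).normal(0, noise_sd, c.shape)
    truth = GroundTruth(ec50=ec50, hill_h=h, rmax=rmax)
    return resp, truth


def corrupt(
    recording: TimeLapseRecording,
    flicker_amplitude: float = 0.0,
    drift_px_per_frame: tuple[float, float] = (0.0, 0.0),
    bleed_alpha: float = 0.0,
    target_channel: str | None = None,
    background_channel: str = "background",
) -> tuple[TimeLapseRecording, GroundTruth]:
    """Apply acquisition artifacts: frame-gain flicker, drift, channel bleed.

    Flicker is a deterministic per-frame multiplicative gain
    ``1 + A sin(2 pi 0.317 i)`` (mains ripple aliased to frame rate);
    drift is a constant-velocity translation of all channels; bleed adds
    ``alpha * background`` into the target channel. With all parameters
    zero the recording passes through bit-identical.
    """
    T = recording.n_frames
    gains = 1.0 + flicker_amplitude * np.sin(2 * np.pi * 0.317 * np.arange(T) + 0.5)
    drift = np.asarray(drift_px_per_frame, dtype=float)
    out: dict[str, np.ndarray] = {ch: a.astype(np.float64).copy() for ch, a in recording.frames.items()}

    if bleed_alpha != 0:
        if target_channel is None or background_channel not in out:
            raise ValueError("bleed needs target_channel and a background channel")
        out[target_channel] = out[target_channel] + bleed_alpha * out[background_channel]

    if flicker_amplitude != 0:
        for ch in out:
            out[ch] = out[ch] * gains[:, None, None]

    if np.any(drift != 0):
        for ch in out:
            arr = out[ch]
            shifted = np.empty_like(arr)
            shifted[0] = arr[0]
            for i in range(1, T):
                shifted[i] = ndimage.shift(arr[i], drift * i, order=1, mode="nearest")
            out[ch] = shifted

    if flicker_amplitude == 0 and not np.any(drift != 0) and bleed_alpha == 0:
        out = {ch: recording[ch].copy() for ch in recording.frames}

    truth = GroundTruth(
        alpha=bleed_alpha,
        flicker_gains=gains,
        drift_px_per_frame=tuple(drift),
    )
    return recording.with_frames(out), truth
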