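"""Shared data model and file I/O.

Coordinate conventions
----------------------
* Images are ``(T, H, W)`` arrays indexed ``(frame, row, col)``, 0-based.
* Pixel ``(row, col)`` has its *center* at continuous coordinate
  ``(row, col)``.
* ROI polygons are ordered vertex lists in ``(x=col, y=row)`` order.
* Displacement vectors are stored ``(drow, dcol)`` on the last axis; a
  vector ``v`` at pixel ``p`` of frame ``i`` means material located at
  pixel ``p`` in the reference frame is found at ``p + v`` in frame ``i``.
* Times are ``frame_index * dt`` seconds with ``t = 0`` at the first
  frame; stimulus onsets are given in seconds on this clock.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "TimeLapseRecording",
    "Roi",
    "StimulusProtocol",
    "SignalTrace",
    "DisplacementField",
    "FlowSeries",
    "AcquisitionMetadata",
    "polygon_mask",
    "read_stack",
    "write_stack",
    "read_rois",
    "write_rois",
    "read_config",
    "write_config",
    "write_results",
    "read_results",
]

CHANNEL_NAMES = ("f340", "f380", "gcamp", "brightfield", "background")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class TimeLapseRecording:
    """Calibrated multi-channel time-lapse stack.

    Parameters
    ----------
    frames : mapping of channel label -> (T, H, W) float/int array
    dt : frame interval in seconds (> 0)
    pixel_size : micrometres per pixel (> 0)
    t0_index : index of the reference frame (default 0)
    """

    frames: dict[str, np.ndarray]
    dt: float
    pixel_size: float
    t0_index: int = 0

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("recording must contain at least one channel")
        shapes = {np.asarray(a).shape for a in self.frames.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels have mismatching shapes: {shapes}")
        shape = shapes.pop()
        if len(shape) != 3:
            raise ValueError(f"channel arrays must be (T, H, W), got {shape}")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if not 0 <= self.t0_index < shape[0]:
            raise ValueError(
                f"t0_index {self.t0_index} outside [0, {shape[0]})"
            )
        self.frames = {k: np.asarray(v) for k, v in self.frames.items()}

    @property
    def channels(self) -> list[str]:
        return list(self.frames)

    @property
    def n_frames(self) -> int:
        return next(iter(self.frames.values())).shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial shape (H, W)."""
        return next(iter(self.frames.values())).shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds, t=0 at the first frame."""
        return np.arange(self.n_frames) * self.dt

    def __getitem__(self, channel: str) -> np.ndarray:
        return self.frames[channel]

    def with_frames(self, frames: Mapping[str, np.ndarray]) -> "TimeLapseRecording":
        """Copy of this recording with replaced channel data."""
        return TimeLapseRecording(
            frames=dict(frames),
            dt=self.dt,
            pixel_size=self.pixel_size,
            t0_index=self.t0_index,
        )


_ROI_LABEL_RE = re.compile(r"^ROI\s*([+-]?\d+)$")


@dataclass
class Roi:
    """Polygonal region of interest with a derived raster mask."""

    label: str
    polygon: np.ndarray  # (N, 2) vertices, (x=col, y=row)
    mask: np.ndarray     # (H, W) bool

    @classmethod
    def from_polygon(
        cls, label: str, polygon: Sequence[Sequence[float]], shape: tuple[int, int]
    ) -> "Roi":
        poly = np.asarray(polygon, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
            raise ValueError(
                f"polygon needs >= 3 (x, y) vertices, got shape {poly.shape}"
            )
        H, W = shape
        if (
            poly[:, 0].min() < -0.5
            or poly[:, 0].max() > W - 0.5
            or poly[:, 1].min() < -0.5
            or poly[:, 1].max() > H - 0.5
        ):
            raise ValueError(f"polygon {label!r} extends outside image bounds {shape}")
        mask = polygon_mask(poly, shape)
        if not mask.any():
            raise ValueError(f"polygon {label!r} rasterizes to an empty mask")
        return cls(label=label, polygon=poly, mask=mask)

    @classmethod
    def from_mask(cls, label: str, mask: np.ndarray) -> "Roi":
        """ROI from a precomputed boolean mask (polygon left empty)."""
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError(f"mask for {label!r} is empty")
        return cls(label=label, polygon=np.empty((0, 2)), mask=mask)

    @property
    def index(self) -> int | None:
        """Signed index parsed from labels like ``"ROI -3"``, else None."""
        m = _ROI_LABEL_RE.match(self.label.strip())
        return int(m.group(1)) if m else None


@dataclass
class StimulusProtocol:
    """Stimulus timing: onsets (s), duration (s), agent, concentration (uM)."""

    onsets: list[float]
    duration: float
    agent: str = "ATP"
    concentration: float = 100.0

    def __post_init__(self) -> None:
        self.onsets = [float(t) for t in self.onsets]
        if any(b <= a for a, b in zip(self.onsets, self.onsets[1:])):
            raise ValueError("stimulus onsets must be strictly increasing")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")


@dataclass
class SignalTrace:
    """Time-stamped per-ROI signal (ratio, dF/F or raw intensity)."""

    times: np.ndarray
    values: np.ndarray
    kind: str  # {"ratio", "dff", "raw"}
    roi_label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.kind not in ("ratio", "dff", "raw"):
            raise ValueError(f"unknown trace kind {self.kind!r}")
        if self.kind == "ratio" and np.any(self.values <= 0):
            raise ValueError("ratio traces must be strictly positive")


@dataclass
class DisplacementField:
    """Per-frame dense shift vectors, ``(T, H, W, 2)`` with ``(drow, dcol)``.

    ``reference_mode="to_t0"``: ``vectors[i]`` maps the t0 frame onto frame
    ``i`` (material at t0 pixel p sits at ``p + vectors[i][p]`` in frame i).
    ``reference_mode="consecutive"``: the reference is frame ``i - 1``
    instead, and ``vectors[0]`` is zero.
    """

    vectors: np.ndarray
    reference_mode: str = "to_t0"
    border_margin: int = 0  # pixels near the border flagged unreliable

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float32)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 2:
            raise ValueError(
                f"vectors must be (T, H, W, 2), got {self.vectors.shape}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement vectors must be finite")
        if self.reference_mode not in ("to_t0", "consecutive"):
            raise ValueError(f"unknown reference_mode {self.reference_mode!r}")

    @property
    def norms(self) -> np.ndarray:
        """Euclidean vector norm per frame and pixel, ``(T, H, W)``."""
        return np.sqrt((self.vectors ** 2).sum(axis=-1))

    def valid_mask(self) -> np.ndarray:
        """(H, W) mask of pixels outside the flagged border margin."""
        T, H, W, _ = self.vectors.shape
        mask = np.zeros((H, W), dtype=bool)
        m = self.border_margin
        if m <= 0:
            mask[:] = True
        elif 2 * m < H and 2 * m < W:
            mask[m:-m, m:-m] = True
        return mask


@dataclass
class FlowSeries:
    """Flow strength s_i, its moving-average smoothing, and flow change c_i."""

    s: np.ndarray
    s_smooth: np.ndarray
    c: np.ndarray
    smoothing_window: int = 1

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.s_smooth = np.asarray(self.s_smooth, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if np.any(self.s < 0):
            raise ValueError("flow strength must be non-negative")
        if len(self.c) != len(self.s) - 1:
            raise ValueError("len(c) must equal len(s) - 1")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 1")


@dataclass
class AcquisitionMetadata:
    """Channel layout and calibration required to interpret a TIFF stack."""

    channels: list[str]
    dt: float
    pixel_size: float
    layout: str = "interleaved"  # or "blocks"
    t0_index: int = 0

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("at least one channel required")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.layout not in ("interleaved", "blocks"):
            raise ValueError(f"unknown layout {self.layout!r}")


# ---------------------------------------------------------------------------
# ROI rasterization
# ---------------------------------------------------------------------------

def polygon_mask(polygon: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon with the even-odd fill rule over pixel centers.

    Pixel centers lying exactly on a polygon edge count as inside, so an
    axis-aligned square with corners on pixel centers includes its boundary
    pixels.
    """
    poly = np.asarray(polygon, dtype=float)
    H, W = shape
    rows, cols = np.mgrid[0:H, 0:W]
    px = cols.ravel().astype(float)
    py = rows.ravel().astype(float)
    inside = np.zeros(px.size, dtype=bool)
    on_edge = np.zeros(px.size, dtype=bool)
    n = len(poly)
    eps = 1e-9
    for k in range(n):
        x1, y1 = poly[k]
        x2, y2 = poly[(k + 1) % n]
        # even-odd ray crossing (ray toward +x)
        crosses = (y1 > py) != (y2 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (px < x_at)
        # boundary inclusion: point within eps of the segment
        dx, dy = x2 - x1, y2 - y1
        seg2 = dx * dx + dy * dy
        if seg2 < eps:
            d2 = (px - x1) ** 2 + (py - y1) ** 2
            on_edge |= d2 <= eps
            continue
        t = ((px - x1) * dx + (py - y1) * dy) / seg2
        t = np.clip(t, 0.0, 1.0)
        d2 = (px - (x1 + t * dx)) ** 2 + (py - (y1 + t * dy)) ** 2
        on_edge |= d2 <= eps
    return (inside | on_edge).reshape(H, W)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_stack(path: str | Path, metadata: AcquisitionMetadata) -> TimeLapseRecording:
    """Read a multi-page TIFF into a calibrated recording.

    The page layout (channel order and interleaving) is taken from
    ``metadata`` and never guessed. Intensities are preserved bit-exact.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    n_ch = len(metadata.channels)
    if pages.shape[0] % n_ch:
        raise ValueError(
            f"{pages.shape[0]} pages not divisible by {n_ch} channels"
        )
    T = pages.shape[0] // n_ch
    frames: dict[str, np.ndarray] = {}
    if metadata.layout == "interleaved":
        for i, ch in enumerate(metadata.channels):
            frames[ch] = pages[i::n_ch]
    else:  # blocks
        for i, ch in enumerate(metadata.channels):
            frames[ch] = pages[i * T:(i + 1) * T]
    return TimeLapseRecording(
        frames=frames,
        dt=metadata.dt,
        pixel_size=metadata.pixel_size,
        t0_index=metadata.t0_index,
    )


def write_stack(
    recording: TimeLapseRecording,
    path: str | Path,
    layout: str = "interleaved",
) -> AcquisitionMetadata:
    """Write a recording to a multi-page TIFF; returns matching metadata."""
    chans = recording.channels
    arrays = [recording[ch] for ch in chans]
    T = recording.n_frames
    if layout == "interleaved":
        pages = np.stack(arrays, axis=1).reshape((-1,) + recording.shape)
    elif layout == "blocks":
        pages = np.concatenate(arrays, axis=0)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    tifffile.imwrite(Path(path), pages, photometric="minisblack")
    return AcquisitionMetadata(
        channels=chans,
        dt=recording.dt,
        pixel_size=recording.pixel_size,
        layout=layout,
        t0_index=recording.t0_index,
    )


def _roi_sort_key(roi: Roi) -> tuple[int, float, str]:
    idx = roi.index
    return (0, idx, roi.label) if idx is not None else (1, 0.0, roi.label)


def read_rois(path: str | Path, shape: tuple[int, int]) -> list[Roi]:
    """Read ROI polygons from JSON: ``{"rois": [{"label", "polygon"}]}``.

    ROIs labeled ``"ROI k"`` are returned ordered by signed index k;
    other labels follow alphabetically.
    """
    with open(path) as fh:
        data = json.load(fh)
    rois = [
        Roi.from_polygon(entry["label"], entry["polygon"], shape)
        for entry in data["rois"]
    ]
    return sorted(rois, key=_roi_sort_key)


def write_rois(rois: Sequence[Roi], path: str | Path) -> None:
    data = {
        "rois": [
            {"label": r.label, "polygon": np.asarray(r.polygon).tolist()}
            for r in rois
        ]
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


def read_config(path: str | Path) -> dict:
    """Read a YAML or JSON config file into a dict."""
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yml", ".yaml"):
            return yaml.safe_load(fh)
        return json.load(fh)


def write_config(config: dict, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix in (".yml", ".yaml"):
            yaml.safe_dump(config, fh)
        else:
            json.dump(config, fh, indent=1)


def flow_series_tables(flow: FlowSeries, dt: float) -> dict[str, pd.DataFrame]:
    """Long-format tables for a FlowSeries: per-frame s and per-step c."""
    n = len(flow.s)
    s_tab = pd.DataFrame(
        {
            "frame": np.arange(n),
            "time_s": np.arange(n) * dt,
            "s": flow.s,
            "s_smooth": flow.s_smooth,
        }
    )
    c_tab = pd.DataFrame(
        {
            "frame": np.arange(1, n),
            "time_s": np.arange(1, n) * dt,
            "c": flow.c,
        }
    )
    return {"flow_strength": s_tab, "flow_change": c_tab}


def trace_table(traces: Sequence[SignalTrace]) -> pd.DataFrame:
    """Long-format (roi, time_s, value, kind, convention) table."""
    rows = []
    for tr in traces:
        conv = tr.meta.get("convention", "")
        for t, v in zip(tr.times, tr.values):
            rows.append((tr.roi_label, t, v, tr.kind, conv))
    return pd.DataFrame(
        rows, columns=["roi", "time_s", "value", "kind", "convention"]
    )


def write_results(tables: Mapping[str, pd.DataFrame], path: str | Path) -> list[Path]:
    """Write result tables as headered CSV files, one per table name."""
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        out = outdir / f"{name}.csv"
        table.to_csv(out, index=False)
        written.append(out)
    return written


def read_results(path: str | Path) -> dict[str, pd.DataFrame]:
    """Read back every CSV in a results directory."""
    outdir = Path(path)
    return {p.stem: pd.read_csv(p) for p in sorted(outdir.glob("*.csv"))}
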