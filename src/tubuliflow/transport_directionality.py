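"""Whole-mount transport analysis around a focal stimulation zone.

A tubule centerline is partitioned into equidistant arc-length sections
(ROI 0 centered on the stimulation site, indices up to +-k), per-section
luminal motion is integrated before and after stimulus onset, and the
asymmetry of supra-basal motion between the ascending- and descending-
stage sides is summarized as a signed directionality index in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from tubuliflow.core_io import Roi, StimulusProtocol, TimeLapseRecording
from tubuliflow.motion_quantification import (
    DEFAULT_AUC_WINDOW_S,
    DEFAULT_SMOOTHING_WINDOW,
    flow_strength,
    motion_auc,
    moving_average,
    windowed_auc_pair,
)
from tubuliflow.registration import RegistrationConfig, estimate_displacement

__all__ = [
    "StagedTubule",
    "TransportProfile",
    "partition_rois",
    "transport_profile",
    "directionality_index",
]

STAGE_GROUPS = ("I", "II", "III")


@dataclass
class StagedTubule:
    """Centerline geometry plus stage annotation of a whole-mount tubule.

    ``stage_map`` lists contiguous ``(start_um, end_um, stage)`` arc-length
    intervals. ``ascending_toward_end`` orients the positive ROI direction:
    True means spermatogenic stages ascend with increasing arc length.
    """

    centerline: np.ndarray  # (N, 2) vertices, (x=col, y=row) px
    stim_center_um: float
    section_length_um: float
    stage_map: list[tuple[float, float, str]] = field(default_factory=list)
    ascending_toward_end: bool = True

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[0] < 2:
            raise ValueError("centerline needs >= 2 vertices")
        if self.section_length_um <= 0:
            raise ValueError("section_length_um must be > 0")
        for (a0, a1, st) in self.stage_map:
            if a1 <= a0:
                raise ValueError("stage intervals must have positive length")
            if st not in STAGE_GROUPS:
                raise ValueError(f"unknown stage group {st!r}")

    def stage_at(self, arc_um: float) -> str:
        for a0, a1, st in self.stage_map:
            if a0 <= arc_um <= a1:
                return st
        return ""


@dataclass
class TransportProfile:
    """Per-ROI transport AUC versus basal motion plus directionality index."""

    rows: pd.DataFrame  # columns: roi_index, stage, auc, basal
    di: float = np.nan

    def __post_init__(self) -> None:
        if 0 not in set(self.rows["roi_index"]):
            raise ValueError("profile must contain ROI 0")

    def auc_of(self, index: int) -> float:
        return float(self.rows.set_index("roi_index").loc[index, "auc"])

    def basal_of(self, index: int) -> float:
        return float(self.rows.set_index("roi_index").loc[index, "basal"])


def _resample_centerline(centerline: np.ndarray, pixel_size: float, step_px: float = 0.25):
    """Densely resampled points and their arc-length (µm) along the polyline."""
    pts = [centerline[0]]
    for a, b in zip(centerline[:-1], centerline[1:]):
        seg = np.hypot(*(b - a))
        n = max(int(np.ceil(seg / step_px)), 1)
        for j in range(1, n + 1):
            pts.append(a + (b - a) * j / n)
    pts = np.asarray(pts)
    d = np.hypot(*np.diff(pts, axis=0).T)
    arcs = np.concatenate([[0.0], np.cumsum(d)]) * pixel_size
    return pts, arcs


def partition_rois(
    tubule: StagedTubule,
    k: int = 6,
    width_px: float = 20.0,
    pixel_size: float = 1.0,
    shape: tuple[int, int] = (64, 64),
) -> list[Roi]:
    """Equidistant arc-length sections as centerline-buffered band masks.

    ROI 0 is centered on ``stim_center_um``; section i covers arc lengths
    ``stim + (i - 1/2) L .. stim + (i + 1/2) L``. Each image pixel within
    ``width_px / 2`` of the centerline is assigned to exactly one section
    (nearest centerline point), so the masks tile the band without overlap
    or gaps. Sections that would extend past either end of the centerline
    are dropped (fewer ROIs are returned). Positive indices run toward the
    ascending-stage direction.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pts, arcs = _resample_centerline(tubule.centerline, pixel_size)
    total = arcs[-1]
    L = tubule.section_length_um
    sign = 1 if tubule.ascending_toward_end else -1

    H, W = shape
    rows, cols = np.mgrid[0:H, 0:W]
    pix = np.column_stack([cols.ravel(), rows.ravel()]).astype(float)
    tree = cKDTree(pts)
    dist, nearest = tree.query(pix)
    in_band = dist <= width_px / 2.0
    pix_arc = arcs[nearest]

    rois: list[Roi] = []
    for i in range(-k, k + 1):
        lo = tubule.stim_center_um + (sign * i - 0.5) * L
        hi = lo + L
        if lo < -1e-9 or hi > total + 1e-9:
            continue  # insufficient centerline length on this side
        sel = in_band & (pix_arc >= lo) & (pix_arc < hi)
        mask = sel.reshape(H, W)
        if not mask.any():
            continue
        rois.append(Roi.from_mask(f"ROI {i}", mask))
    rois.sort(key=lambda r: r.index)
    return rois


def transport_profile(
    recording: TimeLapseRecording | np.ndarray,
    rois: list[Roi],
    protocol: StimulusProtocol,
    window_s: float = DEFAULT_AUC_WINDOW_S,
    smoothing_window: int = DEFAULT_SMOOTHING_WINDOW,
    series_mode: str = "increment",
    rectified: bool = True,
    channel: str = "brightfield",
    config: RegistrationConfig | None = None,
    tubule: StagedTubule | None = None,
) -> TransportProfile:
    """Per-ROI motion AUC after stimulus onset versus equal-length basal AUC.

    Motion is measured from dense registration of the brightfield channel
    with consecutive-frame reference, so the ROI-mean vector norm per
    frame is the incremental motion between successive images. With
    ``series_mode="increment"`` (default) that per-frame motion series is
    smoothed and integrated directly over ``window_s`` after onset and
    over the matching pre-onset window (a truncated basal window is
    rescaled to nominal length). ``series_mode="flow_change"`` instead
    integrates the (rectified) difference series of the smoothed motion,
    which emphasizes transitions rather than sustained transport.
    """
    if series_mode not in ("increment", "flow_change"):
        raise ValueError(f"unknown series_mode {series_mode!r}")
    if isinstance(recording, TimeLapseRecording):
        stack = recording[channel]
        dt = recording.dt
        pixel_size = recording.pixel_size
    else:
        stack = np.asarray(recording)
        dt = 1.0
        pixel_size = 1.0
    config = config or RegistrationConfig(reference_mode="consecutive")
    field_ = estimate_displacement(stack, config)
    times = np.arange(stack.shape[0]) * dt
    onset = protocol.onsets[0]

    records = []
    for roi in rois:
        s = flow_strength(field_, roi)
        if series_mode == "flow_change":
            res = motion_auc(
                s, times, onset, window_s, rectified, smoothing_window, roi.label
            )
            post, basal = res.auc_post, res.auc_basal
        else:
            smooth = moving_average(s, smoothing_window)
            post, basal = windowed_auc_pair(smooth, times, onset, window_s)
        idx = roi.index
        stage = ""
        if tubule is not None and idx is not None:
            # stage looked up at the section center
            arc = tubule.stim_center_um + (
                idx if tubule.ascending_toward_end else -idx
            ) * tubule.section_length_um
            stage = tubule.stage_at(arc)
        records.append(
            {"roi_index": idx, "stage": stage, "auc": post, "basal": basal}
        )
    rows = pd.DataFrame(records).sort_values("roi_index").reset_index(drop=True)
    profile = TransportProfile(rows=rows)
    profile.di = directionality_index(profile)
    return profile


def directionality_index(profile: TransportProfile) -> float:
    """Signed asymmetry of supra-basal transport between the two sides.

    ``DI = (A+ - A-) / (A+ + A-)`` with
    ``A+- = sum over i > 0 of max(AUC_{+-i} - basal_{+-i}, 0)``;
    0 when both sums vanish. Reversing the stage orientation (which
    negates all ROI indices) negates DI exactly.
    """
    rows = profile.rows
    pos = rows[rows["roi_index"] > 0]
    neg = rows[rows["roi_index"] < 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need at least one ROI on each side of ROI 0")
    a_pos = float(np.clip(pos["auc"] - pos["basal"], 0, None).sum())
    a_neg = float(np.clip(neg["auc"] - neg["basal"], 0, None).sum())
    if a_pos + a_neg == 0:
        return 0.0
    return (a_pos - a_neg) / (a_pos + a_neg)
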