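"""Trace-level statistics: Hill fits, activity episodes, event pairing.

The Hill fit normalizes responses to the response at a reference
concentration (default 100 µM) and fits
``r(c) = rmax c^h / (ec50^h + c^h)`` (bottom fixed at 0) by nonlinear
least squares with multi-start over log-spaced EC50 initializations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import pearsonr, spearmanr

__all__ = [
    "DoseResponseFit",
    "TimedEvent",
    "EventPairSet",
    "hill",
    "fit_hill",
    "find_activity_episodes",
    "Episode",
    "pair_events",
    "correlate_durations",
]


def hill(c: np.ndarray, ec50: float, h: float, rmax: float) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    return rmax * c ** h / (ec50 ** h + c ** h)


@dataclass
class DoseResponseFit:
    ec50: float
    hill_h: float
    rmax: float
    sse: float
    normalize_at: float | None = None
    constraints: dict = field(default_factory=lambda: {"bottom": 0.0})

    def __post_init__(self) -> None:
        if self.ec50 <= 0 or self.hill_h <= 0:
            raise ValueError("ec50 and hill coefficient must be > 0")

    def predict(self, c: np.ndarray) -> np.ndarray:
        return hill(c, self.ec50, self.hill_h, self.rmax)


def fit_hill(
    concentrations: np.ndarray,
    responses: np.ndarray,
    normalize_at: float | None = 100.0,
) -> DoseResponseFit:
    """Hill-equation fit of (possibly reference-normalized) responses.

    When ``normalize_at`` is given and present among the concentrations,
    responses are divided by the (mean) response at that concentration
    before fitting, so the fitted curve is ~1 at the reference.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if len(np.unique(c)) < 4:
        raise ValueError("need >= 4 distinct concentrations")
    if np.any(c <= 0):
        raise ValueError("concentrations must be > 0")
    if np.any(r < 0):
        raise ValueError("responses must be >= 0")
    if normalize_at is not None:
        ref = np.isclose(c, normalize_at)
        if ref.any():
            denom = r[ref].mean()
            if denom <= 0:
                raise ValueError("reference response is non-positive")
            r = r / denom

    def residuals(p: np.ndarray) -> np.ndarray:
        log_ec50, log_h, rmax = p
        return hill(c, np.exp(log_ec50), np.exp(log_h), rmax) - r

    rmax0 = max(r.max(), 1e-6)
    lo = [np.log(c.min() / 100), np.log(0.05), 0.0]
    hi = [np.log(c.max() * 100), np.log(20.0), 100 * rmax0]
    best = None
    for ec50_0 in np.geomspace(c.min() / 3, c.max() * 3, 7):
        for h0 in (0.5, 1.0, 2.0):
            try:
                sol = least_squares(
                    residuals,
                    x0=[np.log(ec50_0), np.log(h0), rmax0],
                    bounds=(lo, hi),
                    method="trf",
                    max_nfev=2000,
                )
            except Exception:
                continue
            sse = float(np.sum(sol.fun ** 2))
            if best is None or sse < best[0]:
                best = (sse, sol.x)
    if best is None:
        raise RuntimeError("Hill fit failed to converge from any start")
    sse, (log_ec50, log_h, rmax) = best
    return DoseResponseFit(
        ec50=float(np.exp(log_ec50)),
        hill_h=float(np.exp(log_h)),
        rmax=float(rmax),
        sse=sse,
        normalize_at=normalize_at,
    )


# ---------------------------------------------------------------------------
# Activity episodes
# ---------------------------------------------------------------------------

@dataclass
class Episode:
    start_s: float
    end_s: float
    n_events: int


def find_activity_episodes(
    onsets: np.ndarray,
    window_s: float = 90.0,
    min_events: int = 2,
    t_start: float | None = None,
    t_end: float | None = None,
) -> tuple[list[Episode], list[tuple[float, float]]]:
    """Enhanced-activity episodes: runs of events with inter-onset gaps
    within ``window_s`` containing at least ``min_events``.

    Maximal chains of consecutive onsets separated by at most ``window_s``
    form candidate episodes; chains shorter than ``min_events`` are
    dropped. Quiescent gaps are the complementary intervals between kept
    episodes (extended to ``t_start`` / ``t_end`` when given). The output
    is invariant to a global time shift of all onsets and bounds.
    """
    onsets = np.asarray(onsets, dtype=float)
    if np.any(np.diff(onsets) < 0):
        raise ValueError("onsets must be sorted")
    episodes: list[Episode] = []
    i = 0
    while i < len(onsets):
        j = i
        while j + 1 < len(onsets) and onsets[j + 1] - onsets[j] <= window_s:
            j += 1
        if j - i + 1 >= min_events:
            episodes.append(Episode(float(onsets[i]), float(onsets[j]), j - i + 1))
        i = j + 1
    gaps: list[tuple[float, float]] = []
    lo = t_start
    for ep in episodes:
        if lo is not None and ep.start_s > lo:
            gaps.append((lo, ep.start_s))
        lo = ep.end_s
    if t_end is not None:
        if lo is None:
            lo = t_start if t_start is not None else (
                float(onsets[0]) if len(onsets) else None
            )
        if lo is not None and t_end > lo:
            gaps.append((lo, t_end))
    return episodes, gaps


# ---------------------------------------------------------------------------
# Event pairing and duration correlation
# ---------------------------------------------------------------------------

@dataclass
class TimedEvent:
    onset_s: float
    duration_s: float
    label: str = ""

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class EventPairSet:
    pairs: list[tuple[TimedEvent, TimedEvent]]
    passive: list[TimedEvent]  # contractions without a Ca2+ partner
    silent: list[TimedEvent]   # Ca2+ events without a contraction partner


def _overlap(a: TimedEvent, b: TimedEvent) -> float:
    return min(a.end_s, b.end_s) - max(a.onset_s, b.onset_s)


def pair_events(
    ca_events: list[TimedEvent],
    contraction_events: list[TimedEvent],
) -> EventPairSet:
    """Greedy one-to-one matching by maximal temporal overlap.

    Candidate pairs with positive overlap are taken best-first; each event
    joins at most one pair. Unmatched contractions are flagged passive
    (no driving Ca2+ signal), unmatched Ca2+ events silent.
    """
    cands = []
    for ia, a in enumerate(ca_events):
        for ib, b in enumerate(contraction_events):
            ov = _overlap(a, b)
            if ov > 0:
                cands.append((ov, ia, ib))
    cands.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for ov, ia, ib in cands:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        pairs.append((ca_events[ia], contraction_events[ib]))
    passive = [b for i, b in enumerate(contraction_events) if i not in used_b]
    silent = [a for i, a in enumerate(ca_events) if i not in used_a]
    return EventPairSet(pairs=pairs, passive=passive, silent=silent)


def correlate_durations(pair_set: EventPairSet) -> dict:
    """Pearson (primary) and Spearman correlation of paired durations."""
    if len(pair_set.pairs) < 3:
        raise ValueError("need >= 3 pairs")
    d_ca = np.array([a.duration_s for a, _ in pair_set.pairs])
    d_con = np.array([b.duration_s for _, b in pair_set.pairs])
    if d_ca.std() == 0 or d_con.std() == 0:
        raise ValueError("zero variance in one duration vector")
    return {
        "pearson_r": float(pearsonr(d_ca, d_con).statistic),
        "spearman_r": float(spearmanr(d_ca, d_con).statistic),
        "n": len(d_ca),
    }
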