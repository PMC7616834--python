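"""Fluorescence-trace analytics for esophageal peristalsis.

Two regions of interest are recorded simultaneously: a *neurogenic* zone
(ROI1, anterior ring muscles driven directly by motor neurons) and a
*myogenic* zone (ROI2, posterior muscles that propagate contraction without
direct innervation). A calcium event in ROI1 is a *trigger*; a subsequent
ROI2 event within a pairing window marks that trigger as a *completed*
peristaltic wave. The completion rate is the percentage of triggers that
complete; cycle frequency is events per minute. Two-channel reporters
(photoconvertible calcium integrators, FRET cAMP sensors) are summarized as
per-cell intensity ratios averaged per animal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)


@dataclass
class TwoRoiTrace:
    """Paired neurogenic/myogenic fluorescence time series (arbitrary units)."""

    t: np.ndarray  # seconds, strictly increasing
    roi1: np.ndarray  # neurogenic zone
    roi2: np.ndarray  # myogenic zone
    sampling_rate: float  # Hz

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.roi1 = np.asarray(self.roi1, dtype=float)
        self.roi2 = np.asarray(self.roi2, dtype=float)
        if not (len(self.t) == len(self.roi1) == len(self.roi2)):
            raise ValueError("t, roi1, roi2 must have equal length")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("time must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) > 1 else 0.0


def read_trace(path: str | Path, sampling_rate: float | None = None) -> TwoRoiTrace:
    """Read a trace CSV with required header t, roi1, roi2. Sampling rate is
    inferred from the median time step unless given."""
    df = pd.read_csv(path)
    missing = {"t", "roi1", "roi2"} - set(df.columns)
    if missing:
        raise ValueError(f"trace {path}: missing columns {sorted(missing)}")
    if sampling_rate is None:
        dt = float(np.median(np.diff(df["t"].to_numpy())))
        sampling_rate = 1.0 / dt
    return TwoRoiTrace(df["t"].to_numpy(), df["roi1"].to_numpy(),
                       df["roi2"].to_numpy(), sampling_rate)


def write_trace(trace: TwoRoiTrace, path: str | Path) -> None:
    pd.DataFrame({"t": trace.t, "roi1": trace.roi1, "roi2": trace.roi2}
                 ).to_csv(path, index=False)


def detect_events(t: np.ndarray, x: np.ndarray, sampling_rate: float,
                  threshold_k: float = 3.0, min_interval: float = 1.0,
                  min_prominence: float = 0.1) -> np.ndarray:
    """Detect transient events as local maxima above an adaptive baseline.

    The signal is lightly Gaussian-smoothed (sigma 0.1 s) to suppress
    shot noise, then thresholded at the median plus ``threshold_k`` robust
    standard deviations (1.4826 x the median absolute deviation). Peaks must
    be separated by at least ``min_interval`` seconds and rise with a
    prominence of at least ``min_prominence`` times the smoothed signal
    range, measured within a +-``min_interval`` window. Every criterion is
    relative to the signal's own scale, so detection is invariant under
    affine rescaling of the fluorescence values. A flat signal (MAD = 0)
    yields no events with a warning. Returns peak times in seconds.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 samples for event detection")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    sigma = 0.1 * sampling_rate  # 100 ms smoothing kernel
    xs = gaussian_filter1d(x, sigma) if sigma >= 0.5 else x
    med = float(np.median(xs))
    mad = float(np.median(np.abs(xs - med)))
    if mad == 0.0:
        logger.warning("detect_events: MAD is zero (flat signal); no events")
        return np.empty(0)
    height = med + threshold_k * 1.4826 * mad
    rng = float(np.ptp(xs))
    distance = max(1, int(round(min_interval * sampling_rate)))
    peaks, _ = find_peaks(xs, height=height, distance=distance,
                          prominence=min_prominence * rng,
                          wlen=2 * distance + 1)
    # the smoothing delays the apparent maximum of sharp-onset transients;
    # refine each peak to the raw-signal argmax within the kernel's support
    w = max(1, int(np.ceil(3 * sigma)))
    refined = []
    for p in peaks:
        lo, hi = max(0, p - w), min(len(x), p + w + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    return t[sorted(set(refined))]


@dataclass
class EventPairing:
    """Trigger events (ROI1) with completion flags from ROI2 assignment.

    Each ROI2 event is assigned to the latest unconsumed trigger within the
    preceding ``window`` seconds; ROI2 events with no such trigger are
    *orphans* — they contradict the empirical rule that myogenic waves never
    arise without a neurogenic trigger, and are reported, not dropped.
    """

    trigger_times: np.ndarray
    completed_flags: np.ndarray  # bool per trigger
    orphan_roi2_events: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_triggers(self) -> int:
        return len(self.trigger_times)

    @property
    def n_completed(self) -> int:
        return int(self.completed_flags.sum())


def pair_events(roi1_events: np.ndarray, roi2_events: np.ndarray,
                window: float = 2.0) -> EventPairing:
    """Greedy earliest-match pairing of myogenic events to triggers.

    For each ROI2 event at time t2 (ascending), assign the latest trigger
    t1 with ``t2 - window <= t1 <= t2`` that is not yet consumed; mark it
    completed. Unassignable ROI2 events become orphans.
    """
    t1 = np.asarray(roi1_events, dtype=float)
    t2 = np.asarray(roi2_events, dtype=float)
    if np.any(np.diff(t1) < 0) or np.any(np.diff(t2) < 0):
        raise ValueError("event lists must be time-sorted")
    completed = np.zeros(len(t1), dtype=bool)
    orphans = []
    for t in t2:
        idx = np.searchsorted(t1, t, side="right") - 1
        assigned = False
        while idx >= 0 and t1[idx] >= t - window:
            if not completed[idx]:
                completed[idx] = True
                assigned = True
                break
            idx -= 1
        if not assigned:
            orphans.append(t)
    if orphans:
        logger.warning("pair_events: %d myogenic events without a prior "
                       "trigger in window (orphans)", len(orphans))
    return EventPairing(t1, completed, np.asarray(orphans))


def completion_rate(p: EventPairing) -> float:
    """Percentage of triggers that became complete peristaltic waves.
    NaN (logged) when there are no triggers."""
    if p.n_triggers == 0:
        logger.warning("completion_rate: zero triggers -> undefined")
        return float("nan")
    return 100.0 * p.n_completed / p.n_triggers


def cycle_frequency(events: np.ndarray, duration: float) -> float:
    """Events per minute over a recording of ``duration`` seconds."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return 60.0 * len(events) / duration


def per_animal_ratio(cells: pd.DataFrame) -> pd.DataFrame:
    """Unweighted per-animal mean of per-cell channel-intensity ratios.

    ``cells`` needs columns animal, cell, ch_num, ch_den (single-channel
    reporters use ch_den = 1). Cells with non-positive denominators are
    excluded with a warning.
    """
    required = {"animal", "cell", "ch_num", "ch_den"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"cell table missing columns {sorted(missing)}")
    df = cells.copy()
    bad = df["ch_den"] <= 0
    if bad.any():
        logger.warning("per_animal_ratio: excluding %d cells with "
                       "non-positive denominator: %s", int(bad.sum()),
                       df.loc[bad, "cell"].tolist())
        df = df[~bad]
    df["ratio"] = df["ch_num"] / df["ch_den"]
    out = (df.groupby("animal", sort=True)
           .agg(n_cells=("cell", "size"), mean_ratio=("ratio", "mean"))
           .reset_index())
    return out


def analyze_trace(trace: TwoRoiTrace, threshold_k: float = 3.0,
                  min_interval: float = 1.0, min_prominence: float = 0.1,
                  window: float = 2.0) -> dict:
    """End-to-end trace summary: detect events on both ROIs, pair them, and
    report cycle frequencies (both trigger-based and completed-wave-based —
    which of the two the field's 'cycle frequency' means is ambiguous, so
    both are emitted) plus the completion rate."""
    e1 = detect_events(trace.t, trace.roi1, trace.sampling_rate,
                       threshold_k, min_interval, min_prominence)
    e2 = detect_events(trace.t, trace.roi2, trace.sampling_rate,
                       threshold_k, min_interval, min_prominence)
    pairing = pair_events(e1, e2, window=window)
    dur = trace.duration
    return {
        "n_triggers": pairing.n_triggers,
        "n_completed": pairing.n_completed,
        "n_orphans": len(pairing.orphan_roi2_events),
        "completion_rate_percent": completion_rate(pairing) if pairing.n_triggers
        else None,
        "trigger_frequency_per_min": cycle_frequency(e1, dur) if dur > 0 else None,
        "completed_wave_frequency_per_min":
            cycle_frequency(pairing.trigger_times[pairing.completed_flags], dur)
            if dur > 0 else None,
        "trigger_times": e1.tolist(),
        "roi2_event_times": e2.tolist(),
    }
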