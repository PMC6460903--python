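"""Events-of-interest detection on band-limited signals.

Two detectors share the same run/merge/duration/peak logic and differ only
in the energy trace they threshold: a centered sliding-window RMS, or the
magnitude of the analytic signal (Hilbert envelope).  Thresholds are
``mean + n * SD`` of the trace over the whole epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .signal_model import EventList, EventMarker, Recording, SignalModelError

__all__ = [
    "RmsParams",
    "HilbertParams",
    "sliding_rms",
    "detect_rms",
    "detect_hilbert",
    "detect_recording",
]


class DetectError(SignalModelError):
    pass


@dataclass
class RmsParams:
    window_s: float = 0.003
    threshold_sd: float = 5.0
    min_duration_s: float = 0.006
    min_peaks: int = 6
    peak_threshold_sd: float = 3.0
    merge_gap_s: float = 0.010

    def __post_init__(self) -> None:
        if min(self.window_s, self.threshold_sd, self.min_duration_s,
               self.peak_threshold_sd, self.merge_gap_s) <= 0 or self.min_peaks < 1:
            raise DetectError("all detector parameters must be positive")


@dataclass
class HilbertParams:
    threshold_sd: float = 3.0
    min_duration_s: float = 0.010
    min_peaks: int = 6
    peak_threshold_sd: float = 3.0
    merge_gap_s: float = 0.010

    def __post_init__(self) -> None:
        if min(self.threshold_sd, self.min_duration_s,
               self.peak_threshold_sd, self.merge_gap_s) <= 0 or self.min_peaks < 1:
            raise DetectError("all detector parameters must be positive")


def sliding_rms(signal: np.ndarray, rate: float, window_s: float) -> np.ndarray:
    """Centered sliding-window RMS, same length as input.

    Edge windows are truncated to the available samples, so a constant
    signal maps to its absolute value everywhere.
    """
    x = np.asarray(signal, dtype=float)
    w = int(round(window_s * rate))
    if w < 1:
        w = 1
    if w > x.size:
        raise DetectError(f"window of {w} samples exceeds signal length {x.size}")
    sq = np.concatenate(([0.0], np.cumsum(x * x)))
    idx = np.arange(x.size)
    raw_lo = idx - w // 2
    lo = np.clip(raw_lo, 0, x.size)
    hi = np.clip(raw_lo + w, 0, x.size)
    counts = np.maximum(hi - lo, 1)
    return np.sqrt((sq[hi] - sq[lo]) / counts)


def _runs_above(trace: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    above = trace > threshold
    if not above.any():
        return []
    d = np.diff(above.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size)
    return list(zip(starts, ends))


def _merge_runs(runs: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    if not runs:
        return []
    merged = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        if s - pe < gap:
            merged[-1] = (ps, max(pe, e))
        else:
            merged.append((s, e))
    return merged


def _count_peaks(rect: np.ndarray, lo: int, hi: int, threshold: float) -> int:
    seg = rect[max(lo - 1, 0) : hi + 1]
    base = max(lo - 1, 0)
    interior = np.arange(1, seg.size - 1)
    if interior.size == 0:
        return 0
    is_peak = (seg[1:-1] > seg[:-2]) & (seg[1:-1] > seg[2:]) & (seg[1:-1] > threshold)
    peaks = interior[is_peak] + base
    return int(np.sum((peaks >= lo) & (peaks < hi)))


def _detect_on_trace(
    band_signal: np.ndarray,
    trace: np.ndarray,
    rate: float,
    threshold_sd: float,
    min_duration_s: float,
    min_peaks: int,
    peak_threshold_sd: float,
    merge_gap_s: float,
    channel: str,
    epoch_index: int,
    detector: str,
) -> EventList:
    sd = trace.std()
    if sd == 0:
        return EventList()
    threshold = trace.mean() + threshold_sd * sd
    runs = _runs_above(trace, threshold)
    runs = _merge_runs(runs, max(int(round(merge_gap_s * rate)), 1))
    min_len = min_duration_s * rate
    rect = np.abs(band_signal)
    rect_sd = rect.std()
    peak_thr = rect.mean() + peak_threshold_sd * rect_sd if rect_sd > 0 else np.inf
    markers = []
    for s, e in runs:
        if e - s < min_len:
            continue
        if _count_peaks(rect, s, e, peak_thr) < min_peaks:
            continue
        markers.append(
            EventMarker(
                channel=channel,
                onset=s / rate,
                duration=(e - s) / rate,
                label="EOI",
                epoch_index=epoch_index,
                properties={"detector": detector},
            )
        )
    return EventList(markers)


def detect_rms(
    band_signal: np.ndarray,
    rate: float,
    params: RmsParams | None = None,
    channel: str = "ch0",
    epoch_index: int = 0,
) -> EventList:
    """Staba-style RMS detector on an already band-passed signal."""
    params = params or RmsParams()
    x = np.asarray(band_signal, dtype=float)
    trace = sliding_rms(x, rate, params.window_s)
    return _detect_on_trace(
        x, trace, rate,
        params.threshold_sd, params.min_duration_s, params.min_peaks,
        params.peak_threshold_sd, params.merge_gap_s,
        channel, epoch_index, "rms",
    )


def detect_hilbert(
    band_signal: np.ndarray,
    rate: float,
    params: HilbertParams | None = None,
    channel: str = "ch0",
    epoch_index: int = 0,
) -> EventList:
    """Hilbert-envelope detector on an already band-passed signal."""
    params = params or HilbertParams()
    x = np.asarray(band_signal, dtype=float)
    envelope = np.abs(hilbert(x))
    return _detect_on_trace(
        x, envelope, rate,
        params.threshold_sd, params.min_duration_s, params.min_peaks,
        params.peak_threshold_sd, params.merge_gap_s,
        channel, epoch_index, "hilbert",
    )


def detect_recording(
    rec: Recording,
    detector: str = "rms",
    params: RmsParams | HilbertParams | None = None,
) -> EventList:
    """Run a detector over every channel of every epoch of a recording."""
    rec.validate()
    if detector not in ("rms", "hilbert"):
        raise DetectError(f"unknown detector {detector!r}")
    fn = detect_rms if detector == "rms" else detect_hilbert
    markers = []
    for k, ep in enumerate(rec.epochs):
        for ch in ep.channels:
            found = fn(ch.samples, ch.rate, params, channel=ch.name, epoch_index=k)
            markers.extend(found)
    return EventList(markers)
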