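"""Analytical EOI classification via the Stockwell (S-) transform.

The S-transform is computed in its FFT formulation: for frequency row
``n`` (DFT bins), ``S[n, :] = IFFT(X[m + n] * exp(-2 pi^2 m^2 / n^2))``
with ``X`` the signal DFT.  A column profile averaged around the time of
maximum absolute amplitude within the EOI is searched for an isolated
high-frequency peak: an HFO requires a peak/trough magnitude ratio of at
least ``peak_trough_ratio`` with the trough lying strictly between the
high-frequency peak and the closest lower-frequency local maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_model import EventList, EventMarker, Recording, SignalModelError

__all__ = [
    "StockwellParams",
    "stockwell_transform",
    "classify_eoi_stockwell",
    "classify_events_stockwell",
]


class StockwellError(SignalModelError):
    pass


@dataclass
class StockwellParams:
    f_min: float = 60.0
    f_max: float = 500.0
    ripple_boundary: float = 250.0
    peak_trough_ratio: float = 2.0
    context_s: float = 0.1
    profile_window_s: float = 0.010
    smooth_hz: float = 10.0

    def __post_init__(self) -> None:
        if not (self.f_min < self.ripple_boundary < self.f_max):
            raise StockwellError("need f_min < ripple_boundary < f_max")
        if self.peak_trough_ratio < 1:
            raise StockwellError("peak_trough_ratio must be >= 1")


def stockwell_transform(
    segment: np.ndarray,
    rate: float,
    f_lo: float,
    f_hi: float,
) -> tuple[np.ndarray, np.ndarray]:
    """S-transform magnitude for DFT-bin frequency rows in ``[f_lo, f_hi]``.

    Returns ``(S, freqs)`` with ``S`` of shape (n_freqs, n_samples); the
    zero-frequency row is always excluded.
    """
    x = np.asarray(segment, dtype=float)
    if x.size < 16:
        raise StockwellError("segment too short for S-transform (need >= 16)")
    if f_hi > rate / 2 + 1e-9:
        raise StockwellError(f"f_hi {f_hi} above Nyquist {rate / 2}")
    n = x.size
    spectrum = np.fft.fft(x)
    df = rate / n
    n_lo = max(int(np.ceil(f_lo / df)), 1)
    n_hi = int(np.floor(f_hi / df))
    if n_hi < n_lo:
        raise StockwellError(f"no frequency rows in [{f_lo}, {f_hi}] at df={df}")
    rows = np.arange(n_lo, n_hi + 1)
    # aliased frequency index m in -n/2 .. n/2
    m = ((np.arange(n) + n // 2) % n) - n // 2
    out = np.empty((rows.size, n))
    for i, k in enumerate(rows):
        gauss = np.exp(-2.0 * np.pi**2 * m.astype(float) ** 2 / k**2)
        shifted = np.roll(spectrum, -k)
        out[i] = np.abs(np.fft.ifft(shifted * gauss))
    return out, rows * df


def _local_max_mask(y: np.ndarray) -> np.ndarray:
    mask = np.zeros(y.size, dtype=bool)
    mask[1:-1] = (y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])
    return mask


def _local_min_mask(y: np.ndarray) -> np.ndarray:
    mask = np.zeros(y.size, dtype=bool)
    mask[1:-1] = (y[1:-1] < y[:-2]) & (y[1:-1] <= y[2:])
    return mask


def classify_eoi_stockwell(
    eoi: EventMarker,
    rec: Recording,
    params: StockwellParams | None = None,
) -> tuple[str, str]:
    """Label one EOI as R, F, or A; returns ``(label, reason)``.

    The transform runs on the (ideally unfiltered) recording over the EOI
    plus symmetric context, zero-padded to a whole number of seconds so
    frequency rows land on a grid of at most 1 Hz.
    """
    params = params or StockwellParams()
    epoch = rec.epoch(eoi.epoch_index)
    ch = epoch.channel(eoi.channel)
    rate = ch.rate
    start = max(eoi.onset - params.context_s, 0.0)
    end = min(eoi.onset + eoi.duration + params.context_s, epoch.duration)
    i0 = int(np.floor(start * rate))
    i1 = int(np.floor(end * rate))
    seg = ch.samples[i0:i1]
    if seg.size < 16:
        return "A", "segment_too_short"
    if not np.any(seg):
        return "A", "zero_signal"

    # zero-pad to k whole seconds -> integer-Hz frequency rows
    n_target = int(rate * max(int(np.ceil(seg.size / rate)), 1))
    padded = np.concatenate([seg, np.zeros(n_target - seg.size)])
    S, freqs = stockwell_transform(padded, rate, 1.0, params.f_max)

    # time of maximum |amplitude| inside the EOI, in segment coordinates
    e0 = int(np.floor(eoi.onset * rate)) - i0
    e1 = int(np.floor((eoi.onset + eoi.duration) * rate)) - i0
    e0, e1 = max(e0, 0), min(e1, seg.size)
    t_max = e0 + int(np.argmax(np.abs(seg[e0:e1])))
    half = max(int(round(params.profile_window_s / 2 * rate)), 1)
    c0, c1 = max(t_max - half, 0), min(t_max + half, seg.size)
    profile = S[:, c0:c1].mean(axis=1)
    if params.smooth_hz > 0:
        # suppress sub-resolution noise wiggles; genuine S-transform peaks
        # in the search band are far wider than this
        df = freqs[1] - freqs[0] if freqs.size > 1 else 1.0
        w = max(int(round(params.smooth_hz / df)), 1)
        profile = np.convolve(profile, np.ones(w) / w, mode="same")

    in_band = (freqs >= params.f_min) & (freqs <= params.f_max)
    peaks = _local_max_mask(profile)
    candidates = np.flatnonzero(peaks & in_band)
    if candidates.size == 0:
        return "A", "no_hf_peak"
    hf = candidates[np.argmax(profile[candidates])]

    # first local minimum below the HF peak = the trough
    mins = np.flatnonzero(_local_min_mask(profile)[:hf])
    if mins.size == 0:
        return "A", "no_trough"
    trough = mins[-1]

    # closest local maximum below the trough; the lowest row counts as a
    # peak when the profile keeps rising toward low frequencies
    maxima_below = np.flatnonzero(_local_max_mask(profile)[:trough])
    lf_exists = maxima_below.size > 0 or profile[0] > profile[trough]
    if not lf_exists:
        return "A", "no_lf_peak"

    if profile[trough] <= 0:
        ratio = np.inf
    else:
        ratio = profile[hf] / profile[trough]
    if ratio < params.peak_trough_ratio:
        return "A", "ratio_below_threshold"
    f_peak = freqs[hf]
    return ("R" if f_peak < params.ripple_boundary else "F"), f"peak_{f_peak:.0f}Hz"


def classify_events_stockwell(
    events: EventList,
    rec: Recording,
    params: StockwellParams | None = None,
) -> EventList:
    """Relabel every event; original labels kept in marker properties."""
    out = []
    for m in events:
        label, reason = classify_eoi_stockwell(m, rec, params)
        props = dict(m.properties)
        props.update({"stockwell_reason": reason, "previous_label": m.label})
        out.append(
            EventMarker(
                channel=m.channel,
                onset=m.onset,
                duration=m.duration,
                label=label,
                epoch_index=m.epoch_index,
                properties=props,
            )
        )
    return EventList(out)
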