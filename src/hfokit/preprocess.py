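"""Frequency-selective preprocessing.

Two routes are provided: a Blackman-windowed-sinc FIR filter (low-, high-
or band-pass, optionally self-convolved for a deeper stop band) applied by
FFT convolution with group-delay compensation, and empirical mode
decomposition with recomposition of a contiguous IMF subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import fftconvolve
from scipy.signal.windows import blackman

from .signal_model import Channel, Epoch, Recording, SignalModelError

__all__ = [
    "FirKernel",
    "ImfSet",
    "design_fir",
    "apply_fir",
    "apply_fir_signal",
    "emd",
    "emd_highpass",
    "kernel_response",
]

DEFAULT_TAPS = 513
DEFAULT_EPSILON = 0.2
MAX_SIFT_ITERATIONS = 200


class FilterError(SignalModelError):
    pass


@dataclass
class FirKernel:
    taps: np.ndarray
    rate: float
    low_hz: float | None = None
    high_hz: float | None = None
    self_convolved: bool = False

    def __post_init__(self) -> None:
        self.taps = np.asarray(self.taps, dtype=float)
        if self.taps.size % 2 != 1:
            raise FilterError("kernel length must be odd (linear phase)")

    @property
    def n_taps(self) -> int:
        return int(self.taps.size)

    @property
    def group_delay(self) -> int:
        return (self.n_taps - 1) // 2

    @property
    def transition_width_hz(self) -> float:
        """Standard windowed-sinc transition-width estimate."""
        base = self.n_taps if not self.self_convolved else (self.n_taps + 1) // 2
        return 4.0 * self.rate / base


def _lowpass_taps(cutoff_hz: float, rate: float, n_taps: int) -> np.ndarray:
    m = n_taps - 1
    n = np.arange(n_taps) - m / 2.0
    h = np.sinc(2.0 * cutoff_hz / rate * n) * blackman(n_taps)
    return h / h.sum()


def _highpass_taps(cutoff_hz: float, rate: float, n_taps: int) -> np.ndarray:
    h = -_lowpass_taps(cutoff_hz, rate, n_taps)
    h[(n_taps - 1) // 2] += 1.0
    return h


def design_fir(
    low_hz: float | None,
    high_hz: float | None,
    rate: float,
    n_taps: int = DEFAULT_TAPS,
    self_convolve: bool = False,
) -> FirKernel:
    """Design a Blackman-windowed sinc kernel.

    ``low_hz`` sets the high-pass edge, ``high_hz`` the low-pass edge; both
    together give a band-pass built as the composition (convolution) of the
    two kernels.  ``self_convolve=True`` convolves the resulting kernel
    with itself, squaring the frequency response and roughly doubling the
    stop-band attenuation in dB.
    """
    if low_hz is None and high_hz is None:
        raise FilterError("at least one cutoff must be given")
    nyquist = rate / 2.0
    for name, cutoff in (("low_hz", low_hz), ("high_hz", high_hz)):
        if cutoff is not None and not (0 < cutoff < nyquist):
            raise FilterError(f"{name}={cutoff} outside (0, {nyquist})")
    if low_hz is not None and high_hz is not None and low_hz >= high_hz:
        raise FilterError(f"low_hz {low_hz} must be < high_hz {high_hz}")
    if n_taps < 31 or n_taps % 2 == 0:
        raise FilterError("n_taps must be odd and >= 31")

    if low_hz is None:
        taps = _lowpass_taps(high_hz, rate, n_taps)
    elif high_hz is None:
        taps = _highpass_taps(low_hz, rate, n_taps)
    else:
        taps = np.convolve(
            _highpass_taps(low_hz, rate, n_taps),
            _lowpass_taps(high_hz, rate, n_taps),
        )
    if self_convolve:
        taps = np.convolve(taps, taps)
    return FirKernel(
        taps, rate, low_hz=low_hz, high_hz=high_hz, self_convolved=self_convolve
    )


def kernel_response(kernel: FirKernel, n_fft: int = 1 << 16) -> tuple[np.ndarray, np.ndarray]:
    """Zero-padded magnitude response; returns (freqs_hz, magnitude)."""
    mag = np.abs(np.fft.rfft(kernel.taps, n_fft))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / kernel.rate)
    return freqs, mag


def apply_fir_signal(x: np.ndarray, kernel: FirKernel) -> np.ndarray:
    """FFT linear convolution, delay-compensated, zero-padded edges."""
    full = fftconvolve(np.asarray(x, dtype=float), kernel.taps, mode="full")
    d = kernel.group_delay
    return full[d : d + len(x)]


def apply_fir(rec: Recording, kernel: FirKernel) -> Recording:
    rec.validate()
    out = []
    for ep in rec.epochs:
        channels = []
        for ch in ep.channels:
            if abs(ch.rate - kernel.rate) > 1e-9:
                raise FilterError(
                    f"channel {ch.name!r} rate {ch.rate} != kernel rate {kernel.rate}"
                )
            channels.append(
                Channel(ch.name, ch.rate, apply_fir_signal(ch.samples, kernel), ch.unit)
            )
        out.append(Epoch(channels, meta=dict(ep.meta)))
    return Recording(out, subject_id=rec.subject_id, start_time=rec.start_time)


# ---------------------------------------------------------------------------
# empirical mode decomposition


@dataclass
class ImfSet:
    """Result of an empirical mode decomposition.

    ``imfs[0]`` carries the highest-frequency content; the residual is
    whatever remains after subtracting every IMF, so the decomposition is
    complete by construction.
    """

    imfs: list[np.ndarray] = field(default_factory=list)
    residual: np.ndarray = field(default_factory=lambda: np.zeros(0))
    epsilon: float = DEFAULT_EPSILON

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out = out + imf
        return out


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Strict local maxima/minima; plateaus contribute their first sample."""
    # compress runs of equal consecutive values
    keep = np.concatenate(([True], np.diff(x) != 0))
    idx = np.flatnonzero(keep)
    y = x[idx]
    if y.size < 3:
        return np.array([], dtype=int), np.array([], dtype=int)
    interior = np.arange(1, y.size - 1)
    maxima = interior[(y[1:-1] > y[:-2]) & (y[1:-1] > y[2:])]
    minima = interior[(y[1:-1] < y[:-2]) & (y[1:-1] < y[2:])]
    return idx[maxima], idx[minima]


def _mirrored_envelope(x: np.ndarray, extrema: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through extrema, endpoints mirrored."""
    n = x.size
    t = extrema.astype(float)
    v = x[extrema]
    # mirror the two nearest extrema about each signal endpoint
    t_pre = (-t[:2][::-1])[: max(0, 2)]
    v_pre = v[:2][::-1]
    t_post = (2 * (n - 1) - t[-2:][::-1])
    v_post = v[-2:][::-1]
    tt = np.concatenate([t_pre, t, t_post])
    vv = np.concatenate([v_pre, v, v_post])
    order = np.argsort(tt)
    tt, vv = tt[order], vv[order]
    uniq = np.concatenate(([True], np.diff(tt) > 0))
    spline = CubicSpline(tt[uniq], vv[uniq])
    return spline(np.arange(n))


def _is_linear(x: np.ndarray, scale: float) -> bool:
    if x.size < 3:
        return True
    second = np.diff(x, n=2)
    return bool(np.max(np.abs(second)) <= 1e-10 * max(scale, 1e-30))


def emd(
    signal: np.ndarray,
    rate: float,
    max_imfs: int = 10,
    epsilon: float = DEFAULT_EPSILON,
) -> ImfSet:
    """Empirical mode decomposition by sifting.

    Envelopes are cubic splines through the local maxima/minima with
    mirrored endpoint extrema.  Sifting of one IMF stops when the
    normalized squared difference ``sum((s-d)^2 / s^2)`` drops to
    ``epsilon`` (a tiny floor guards zeros of ``s``), or after a hard
    iteration cap.  The outer loop stops at ``max_imfs`` or when the
    remainder is numerically linear / has fewer than two extrema of each
    kind.  Constant input yields zero IMFs and the input as residual.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 10:
        raise FilterError("signal too short for EMD (need >= 10 samples)")
    if epsilon <= 0:
        raise FilterError("epsilon must be > 0")
    scale = float(np.max(np.abs(x))) if x.size else 0.0
    floor = np.finfo(float).eps * max(scale, 1e-30) ** 2

    imfs: list[np.ndarray] = []
    residual = x.copy()
    while len(imfs) < max_imfs:
        maxima, minima = _local_extrema(residual)
        if maxima.size < 2 or minima.size < 2 or _is_linear(residual, scale):
            break
        s = residual.copy()
        for _ in range(MAX_SIFT_ITERATIONS):
            maxima, minima = _local_extrema(s)
            if maxima.size < 2 or minima.size < 2:
                break
            env_max = _mirrored_envelope(s, maxima)
            env_min = _mirrored_envelope(s, minima)
            m = 0.5 * (env_max + env_min)
            d = s - m
            criterion = float(np.sum(m**2 / (s**2 + floor)))
            s = d
            if criterion <= epsilon:
                break
        imfs.append(s)
        residual = residual - s
    return ImfSet(imfs=imfs, residual=residual, epsilon=epsilon)


def emd_highpass(
    rec: Recording,
    first_imf: int = 1,
    n_imfs: int = 1,
    epsilon: float = DEFAULT_EPSILON,
    max_imfs: int = 10,
) -> Recording:
    """Recompose IMFs ``first_imf .. first_imf + n_imfs - 1`` (1-based).

    Missing higher-order IMFs are treated as absent (contribute zero).
    """
    rec.validate()
    if first_imf < 1 or n_imfs < 1:
        raise FilterError("first_imf and n_imfs must be >= 1")
    out = []
    for ep in rec.epochs:
        channels = []
        for ch in ep.channels:
            if np.allclose(ch.samples, 0):
                channels.append(Channel(ch.name, ch.rate, np.zeros_like(ch.samples), ch.unit))
                continue
            imf_set = emd(ch.samples, ch.rate, max_imfs=max_imfs, epsilon=epsilon)
            acc = np.zeros_like(ch.samples)
            for k in range(first_imf - 1, first_imf - 1 + n_imfs):
                if k < imf_set.n_imfs:
                    acc += imf_set.imfs[k]
            channels.append(Channel(ch.name, ch.rate, acc, ch.unit))
        out.append(Epoch(channels, meta=dict(ep.meta)))
    return Recording(out, subject_id=rec.subject_id, start_time=rec.start_time)
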