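"""Synthetic EEG with known ground truth.

Pink (1/f) background plus injected tapered oscillatory bursts (ripples,
fast ripples), sharp biphasic spike transients, and exact event markers.
Everything is a pure function of the configuration and its seed (MT19937).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .signal_model import Channel, Epoch, EventList, EventMarker, Recording

__all__ = [
    "InjectionSpec",
    "StochasticEvents",
    "SimConfig",
    "generate_background",
    "inject",
    "generate_labeled_dataset",
    "ripple_label",
]

RIPPLE_BAND = (80.0, 250.0)
FAST_RIPPLE_BAND = (250.0, 500.0)
SPIKE_BASE_WIDTH_S = 0.005
SPIKE_TOTAL_WIDTH_S = 0.040


class SyntheticError(ValueError):
    pass


def ripple_label(f0: float) -> str:
    """R below 250 Hz, F at or above (ripple vs fast-ripple band)."""
    return "R" if f0 < FAST_RIPPLE_BAND[0] else "F"


@dataclass
class InjectionSpec:
    channel: str
    t0: float
    f0: float
    amplitude: float
    n_cycles: int = 8
    taper: float = 0.25
    kind: str = "hfo"  # "hfo" | "spike"

    def __post_init__(self) -> None:
        if self.kind not in ("hfo", "spike"):
            raise SyntheticError(f"unknown injection kind {self.kind!r}")
        if self.kind == "hfo":
            if not (RIPPLE_BAND[0] <= self.f0 <= FAST_RIPPLE_BAND[1]):
                raise SyntheticError(
                    f"hfo frequency {self.f0} Hz outside 80-500 Hz"
                )
            if self.n_cycles < 3:
                raise SyntheticError("n_cycles must be >= 3")
        if not (0 <= self.taper <= 0.5):
            raise SyntheticError("taper must be in [0, 0.5]")

    @property
    def duration(self) -> float:
        if self.kind == "spike":
            return SPIKE_TOTAL_WIDTH_S
        return self.n_cycles / self.f0

    @property
    def label(self) -> str:
        return "A" if self.kind == "spike" else ripple_label(self.f0)


@dataclass
class StochasticEvents:
    """Per-class expected event counts for random placement."""

    n_ripple: int = 0
    n_fast_ripple: int = 0
    n_spike: int = 0
    amplitude_sd: tuple[float, float] = (5.0, 10.0)  # in units of background scale
    n_cycles: tuple[int, int] = (6, 16)
    min_gap_s: float = 0.25


@dataclass
class SimConfig:
    n_channels: int = 1
    duration_s: float = 10.0
    rate: float = 2000.0
    background_scale: float = 10.0  # uV, standard deviation
    pink_exponent: float = -1.0
    events: list = field(default_factory=list)  # InjectionSpec or StochasticEvents
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SyntheticError("seed is mandatory")
        if self.rate <= 0 or self.duration_s <= 0 or self.n_channels < 1:
            raise SyntheticError("invalid simulation geometry")
        for spec in self.events:
            if isinstance(spec, InjectionSpec) and spec.kind == "hfo":
                if self.rate < 2 * spec.f0:
                    raise SyntheticError(
                        f"rate {self.rate} violates Nyquist for {spec.f0} Hz"
                    )

    def channel_names(self) -> list[str]:
        return [f"ch{i}" for i in range(self.n_channels)]

    def to_json(self, path) -> None:
        doc = asdict(self)
        doc["events"] = [
            {"type": type(e).__name__, **asdict(e)} for e in self.events
        ]
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            doc = json.load(fh)
        events = []
        for e in doc.get("events", []):
            kind = e.pop("type", "InjectionSpec")
            if kind == "StochasticEvents":
                e["amplitude_sd"] = tuple(e.get("amplitude_sd", (5.0, 10.0)))
                e["n_cycles"] = tuple(e.get("n_cycles", (6, 16)))
                events.append(StochasticEvents(**e))
            else:
                events.append(InjectionSpec(**e))
        doc["events"] = events
        return cls(**doc)


def _rng(seed: int) -> np.random.Generator:
    # Mersenne-Twister core, explicit seeding
    return np.random.Generator(np.random.MT19937(seed))


def _pink_noise(n: int, rate: float, exponent: float, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (exponent / 2.0)
    x = np.fft.irfft(spec * shaping, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_background(config: SimConfig) -> Recording:
    """Pink-noise background, one epoch, ``background_scale`` SD per channel."""
    rng = _rng(config.seed)
    n = int(round(config.duration_s * config.rate))
    channels = [
        Channel(
            name,
            config.rate,
            config.background_scale
            * _pink_noise(n, config.rate, config.pink_exponent, rng),
        )
        for name in config.channel_names()
    ]
    return Recording([Epoch(channels)], subject_id="synthetic")


def _hfo_wave(spec: InjectionSpec, rate: float) -> np.ndarray:
    n = int(round(spec.duration * rate))
    t = np.arange(n) / rate
    wave = spec.amplitude * np.sin(2 * np.pi * spec.f0 * t)
    if spec.taper > 0:
        from scipy.signal.windows import tukey

        wave *= tukey(n, alpha=min(2 * spec.taper, 1.0))
    return wave


def _spike_wave(spec: InjectionSpec, rate: float) -> np.ndarray:
    """Epileptiform transient: sharp apex riding a biphasic slow wave.

    The apex is a two-sided exponential with ~5 ms base width whose
    derivative discontinuity spreads energy across the whole spectrum
    (monotone ~1/f^2 decay, no isolated high-frequency bump) -- this is
    what rings after band-pass filtering.  The slow positive hump with a
    trailing negative lobe makes the transient biphasic at the spike-wave
    time scale and keeps its spectrum low-frequency dominated.
    """
    n = max(int(round(SPIKE_TOTAL_WIDTH_S * rate)), 9)
    t = np.arange(n) / rate - SPIKE_TOTAL_WIDTH_S / 2
    tau = SPIKE_BASE_WIDTH_S / 7.0
    sharp = np.exp(-np.abs(t) / tau)
    slow_sigma = SPIKE_TOTAL_WIDTH_S / 5.0
    slow = 1.5 * np.exp(-(t**2) / (2 * slow_sigma**2)) - 0.7 * np.exp(
        -((t - 0.012) ** 2) / (2 * (1.3 * slow_sigma) ** 2)
    )
    wave = sharp + slow
    return spec.amplitude * wave / np.abs(wave).max()


def inject(
    rec: Recording, spec: InjectionSpec, epoch_index: int = 0
) -> tuple[Recording, EventMarker]:
    """Add one burst/spike to a copy of ``rec``; return it with its marker."""
    rec.validate()
    epoch = rec.epoch(epoch_index)
    if not epoch.has_channel(spec.channel):
        raise SyntheticError(f"unknown channel {spec.channel!r}")
    ch = epoch.channel(spec.channel)
    if spec.t0 < 0 or spec.t0 + spec.duration > epoch.duration + 1e-12:
        raise SyntheticError(
            f"injection [{spec.t0}, {spec.t0 + spec.duration}) outside epoch "
            f"of {epoch.duration} s"
        )
    wave = _spike_wave(spec, ch.rate) if spec.kind == "spike" else _hfo_wave(spec, ch.rate)
    i0 = int(np.floor(spec.t0 * ch.rate))
    i1 = min(i0 + wave.size, ch.n_samples)

    new_epochs = []
    for k, ep in enumerate(rec.epochs):
        if k != epoch_index:
            new_epochs.append(ep)
            continue
        new_channels = []
        for c in ep.channels:
            if c.name == spec.channel:
                samples = c.samples.copy()
                samples[i0:i1] += wave[: i1 - i0]
                new_channels.append(Channel(c.name, c.rate, samples, c.unit))
            else:
                new_channels.append(c)
        new_epochs.append(Epoch(new_channels, meta=dict(ep.meta)))

    peak_freq = spec.f0 if spec.kind == "hfo" else 1.0 / (2 * SPIKE_BASE_WIDTH_S)
    marker = EventMarker(
        channel=spec.channel,
        onset=spec.t0,
        duration=spec.duration,
        label=spec.label,
        epoch_index=epoch_index,
        properties={"peak_frequency_hz": peak_freq, "kind": spec.kind},
    )
    return (
        Recording(new_epochs, subject_id=rec.subject_id, start_time=rec.start_time),
        marker,
    )


def _place_events(
    stoch: StochasticEvents,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[InjectionSpec]:
    entries = (
        [("R", None)] * stoch.n_ripple
        + [("F", None)] * stoch.n_fast_ripple
        + [("A", None)] * stoch.n_spike
    )
    specs: list[InjectionSpec] = []
    # feasibility: worst-case extent per event
    max_dur = max(stoch.n_cycles[1] / RIPPLE_BAND[0], SPIKE_BASE_WIDTH_S)
    per_channel = -(-len(entries) // config.n_channels)
    if per_channel * (max_dur + stoch.min_gap_s) > config.duration_s:
        raise SyntheticError(
            f"cannot place {len(entries)} events with gap {stoch.min_gap_s} s "
            f"in {config.duration_s} s x {config.n_channels} channels"
        )
    occupied: dict[str, list[tuple[float, float]]] = {
        name: [] for name in config.channel_names()
    }
    order = rng.permutation(len(entries))
    for idx in order:
        cls = entries[idx][0]
        for _attempt in range(1000):
            channel = config.channel_names()[rng.integers(config.n_channels)]
            if cls == "A":
                kind, f0, n_cycles = "spike", 0.0, 3
                dur = SPIKE_TOTAL_WIDTH_S
            else:
                band = RIPPLE_BAND if cls == "R" else FAST_RIPPLE_BAND
                # stay clear of the class boundary so labels are unambiguous
                f0 = float(rng.uniform(band[0] + 10, band[1] - 10))
                n_cycles = int(rng.integers(stoch.n_cycles[0], stoch.n_cycles[1] + 1))
                kind, dur = "hfo", n_cycles / f0
            t0 = float(rng.uniform(0.1, config.duration_s - dur - 0.1))
            window = (t0 - stoch.min_gap_s, t0 + dur + stoch.min_gap_s)
            if any(a < window[1] and window[0] < b for a, b in occupied[channel]):
                continue
            occupied[channel].append(window)
            amp = float(
                rng.uniform(*stoch.amplitude_sd) * config.background_scale
            )
            specs.append(
                InjectionSpec(
                    channel=channel,
                    t0=t0,
                    f0=f0 if kind == "hfo" else 300.0,
                    amplitude=amp,
                    n_cycles=n_cycles,
                    kind=kind,
                )
            )
            break
        else:
            raise SyntheticError("event placement failed: density too high")
    return specs


def generate_labeled_dataset(
    config: SimConfig, n_recordings: int = 1
) -> tuple[list[Recording], list[EventList]]:
    """Generate recordings with exact ground-truth markers.

    ``config.events`` may mix explicit :class:`InjectionSpec` entries and a
    :class:`StochasticEvents` description; recording ``i`` uses seed
    ``config.seed + i`` throughout.
    """
    recordings, truths = [], []
    for i in range(n_recordings):
        sub = SimConfig(
            n_channels=config.n_channels,
            duration_s=config.duration_s,
            rate=config.rate,
            background_scale=config.background_scale,
            pink_exponent=config.pink_exponent,
            events=config.events,
            seed=config.seed + i,
        )
        rec = generate_background(sub)
        rng = np.random.Generator(
            np.random.MT19937(np.random.SeedSequence([sub.seed, 0x9E3779B9]))
        )
        specs: list[InjectionSpec] = []
        for entry in sub.events:
            if isinstance(entry, StochasticEvents):
                specs.extend(_place_events(entry, sub, rng))
            else:
                specs.append(entry)
        markers = []
        for spec in specs:
            rec, marker = inject(rec, spec)
            markers.append(marker)
        recordings.append(rec)
        truths.append(EventList(markers))
    return recordings, truths
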