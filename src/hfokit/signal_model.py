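"""Core signal data model: recordings, epochs, channels, event markers.

Conventions used throughout the package:

* times are seconds (float), sample indices are 0-based;
* intervals are half-open ``[start, end)``;
* seconds -> samples conversion uses ``floor`` at both interval ends.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Channel",
    "Epoch",
    "Recording",
    "EventMarker",
    "EventList",
    "segment_by_time",
    "segment_by_events",
    "read_marker_csv",
    "write_marker_csv",
    "read_marker_json",
    "write_marker_json",
]


class SignalModelError(ValueError):
    """Raised on invalid recordings, markers, or segmentation requests."""


@dataclass
class Channel:
    """A single sampled signal.

    Parameters
    ----------
    name : str
        Channel identifier (e.g. an electrode contact label).
    rate : float
        Sampling rate in samples per second, strictly positive.
    samples : numpy.ndarray
        Amplitude values (microvolts by default).
    unit : str
        Physical unit of the samples.
    """

    name: str
    rate: float
    samples: np.ndarray
    unit: str = "uV"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise SignalModelError(f"channel {self.name!r}: rate must be > 0")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise SignalModelError(
                f"channel {self.name!r}: samples must be a non-empty 1-D array"
            )

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Channel duration in seconds."""
        return self.n_samples / self.rate


@dataclass
class Epoch:
    """An ordered set of channels covering the same span of time.

    Channels may have different sampling rates (and hence sample counts)
    but must agree on duration in seconds.
    """

    channels: list[Channel]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise SignalModelError("epoch must contain at least one channel")
        durations = [c.duration for c in self.channels]
        ref = durations[0]
        for c, d in zip(self.channels, durations):
            # one sample of slack per channel to tolerate rate rounding
            if abs(d - ref) > 1.0 / c.rate:
                raise SignalModelError(
                    "channels of an epoch must span the same duration "
                    f"({c.name!r}: {d} s vs {ref} s)"
                )

    @property
    def duration(self) -> float:
        return self.channels[0].duration

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def channel(self, name: str) -> Channel:
        for c in self.channels:
            if c.name == name:
                return c
        raise SignalModelError(f"no channel named {name!r}")

    def has_channel(self, name: str) -> bool:
        return any(c.name == name for c in self.channels)


@dataclass
class Recording:
    """A multichannel, optionally multi-epoch signal container.

    An empty epoch list is permitted only as the degenerate result of a
    selection that matched nothing; ``validate()`` enforces the regular
    at-least-one-epoch invariant.
    """

    epochs: list[Epoch]
    subject_id: str = ""
    start_time: str | None = None

    def validate(self) -> "Recording":
        if not self.epochs:
            raise SignalModelError("recording has no epochs")
        return self

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)

    def epoch(self, index: int) -> Epoch:
        try:
            return self.epochs[index]
        except IndexError:
            raise SignalModelError(f"no epoch with index {index}") from None


@dataclass
class EventMarker:
    """A labeled, time-bounded event on one channel of one epoch."""

    channel: str
    onset: float
    duration: float
    label: str
    epoch_index: int = 0
    properties: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise SignalModelError("marker onset must be >= 0")
        if self.duration <= 0:
            raise SignalModelError("marker duration must be > 0")
        if not self.label:
            raise SignalModelError("marker label must be non-empty")

    @property
    def offset(self) -> float:
        return self.onset + self.duration

    def sort_key(self) -> tuple:
        return (self.epoch_index, self.channel, self.onset, self.duration)


class EventList:
    """Ordered, validated sequence of :class:`EventMarker`.

    Markers are kept sorted by ``(epoch_index, channel, onset)``.
    """

    def __init__(self, markers: Iterable[EventMarker] = ()) -> None:
        self.markers: list[EventMarker] = sorted(markers, key=EventMarker.sort_key)

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self) -> Iterator[EventMarker]:
        return iter(self.markers)

    def __getitem__(self, i):
        return self.markers[i]

    def add(self, marker: EventMarker) -> None:
        self.markers.append(marker)
        self.markers.sort(key=EventMarker.sort_key)

    def filter(self, labels: Sequence[str]) -> "EventList":
        return EventList(m for m in self.markers if m.label in labels)

    def labels(self) -> list[str]:
        return [m.label for m in self.markers]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch_index": [m.epoch_index for m in self.markers],
                "channel": [m.channel for m in self.markers],
                "onset_s": [m.onset for m in self.markers],
                "duration_s": [m.duration for m in self.markers],
                "label": [m.label for m in self.markers],
            }
        )

    def is_sorted(self) -> bool:
        keys = [m.sort_key() for m in self.markers]
        return keys == sorted(keys)


# ---------------------------------------------------------------------------
# segmentation


def _slice_indices(start_s: float, end_s: float, rate: float) -> tuple[int, int]:
    return int(np.floor(start_s * rate)), int(np.floor(end_s * rate))


def segment_by_time(
    rec: Recording,
    windows: Sequence[tuple[float, float]],
    epoch_index: int = 0,
) -> Recording:
    """Extract time-based segments as a new Recording, one epoch per window.

    Windows are half-open ``[start, end)`` in seconds relative to the start
    of the selected epoch; sample indices are floored at both ends.
    """
    rec.validate()
    src = rec.epoch(epoch_index)
    out_epochs: list[Epoch] = []
    for start_s, end_s in windows:
        if not (0 <= start_s < end_s):
            raise SignalModelError(f"invalid window [{start_s}, {end_s})")
        if end_s > src.duration + 1e-12:
            raise SignalModelError(
                f"window [{start_s}, {end_s}) exceeds epoch duration {src.duration} s"
            )
        channels = []
        for ch in src.channels:
            i0, i1 = _slice_indices(start_s, end_s, ch.rate)
            i1 = min(i1, ch.n_samples)
            channels.append(Channel(ch.name, ch.rate, ch.samples[i0:i1], ch.unit))
        out_epochs.append(Epoch(channels, meta={"window": (start_s, end_s)}))
    return Recording(out_epochs, subject_id=rec.subject_id, start_time=rec.start_time)


def segment_by_events(
    rec: Recording,
    events: EventList,
    selected_labels: Sequence[str],
    pre_s: float,
    post_s: float,
) -> Recording:
    """Extract one epoch per event of a selected label.

    Each epoch spans ``[onset - pre_s, onset + post_s)`` clipped to the
    bounds of the source epoch; clipping is flagged in the epoch metadata.
    An empty Recording (no epochs) is returned when nothing matches.
    """
    rec.validate()
    if pre_s < 0 or post_s < 0:
        raise SignalModelError("pre_s and post_s must be >= 0")
    if not selected_labels:
        raise SignalModelError("selected_labels must be non-empty")
    matching = [m for m in events if m.label in selected_labels]
    out_epochs: list[Epoch] = []
    for m in matching:
        src = rec.epoch(m.epoch_index)
        start_s = m.onset - pre_s
        end_s = m.onset + post_s
        clipped = False
        if start_s < 0:
            start_s, clipped = 0.0, True
        if end_s > src.duration:
            end_s, clipped = src.duration, True
        channels = []
        for ch in src.channels:
            i0, i1 = _slice_indices(start_s, end_s, ch.rate)
            i1 = min(i1, ch.n_samples)
            channels.append(Channel(ch.name, ch.rate, ch.samples[i0:i1], ch.unit))
        out_epochs.append(
            Epoch(
                channels,
                meta={"event": m, "clipped": clipped, "window": (start_s, end_s)},
            )
        )
    return Recording(out_epochs, subject_id=rec.subject_id, start_time=rec.start_time)


# ---------------------------------------------------------------------------
# marker table I/O

_MARKER_COLUMNS = ["epoch_index", "channel", "onset_s", "duration_s", "label"]


def write_marker_csv(events: EventList, path) -> None:
    events.to_frame().to_csv(path, index=False)


def read_marker_csv(path) -> EventList:
    df = pd.read_csv(path)
    missing = [c for c in _MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise SignalModelError(f"marker CSV missing columns: {missing}")
    return EventList(
        EventMarker(
            channel=str(row.channel),
            onset=float(row.onset_s),
            duration=float(row.duration_s),
            label=str(row.label),
            epoch_index=int(row.epoch_index),
        )
        for row in df.itertuples()
    )


def write_marker_json(events: EventList, path) -> None:
    records = []
    for m in events:
        rec: dict = {
            "epoch_index": m.epoch_index,
            "channel": m.channel,
            "onset_s": m.onset,
            "duration_s": m.duration,
            "label": m.label,
        }
        if m.properties:
            rec["properties"] = {
                k: v for k, v in m.properties.items() if _json_scalar(v)
            }
        records.append(rec)
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)


def read_marker_json(path) -> EventList:
    with open(path) as fh:
        records = json.load(fh)
    return EventList(
        EventMarker(
            channel=str(r["channel"]),
            onset=float(r["onset_s"]),
            duration=float(r["duration_s"]),
            label=str(r["label"]),
            epoch_index=int(r.get("epoch_index", 0)),
            properties=dict(r.get("properties", {})),
        )
        for r in records
    )


def _json_scalar(v) -> bool:
    return isinstance(v, (int, float, str, bool)) or v is None
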