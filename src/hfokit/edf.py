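"""Minimal EDF/EDF+ reader and writer (16-bit samples, TAL annotations).

Only continuous files (plain EDF and EDF+C) are supported; the
discontinuous EDF+D dialect is rejected.  Reading concatenates all data
records into a single epoch; multi-epoch recordings are written by
concatenating their epochs, which requires identical channel layouts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .signal_model import (
    Channel,
    Epoch,
    EventList,
    EventMarker,
    Recording,
    SignalModelError,
)

__all__ = ["read_edf", "write_edf", "EdfError", "inspect_edf_header"]

_ANNOTATION_LABEL = "EDF Annotations"
_DIG_MIN, _DIG_MAX = -32768, 32767
DEFAULT_PHYSICAL_RANGE = (-3276.8, 3276.8)


class EdfError(SignalModelError):
    """Malformed or unsupported EDF content."""


def _field(raw: bytes, start: int, length: int) -> str:
    return raw[start : start + length].decode("ascii", errors="replace").strip()


def _pad(value: str, length: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > length:
        raise EdfError(f"header field too long: {value!r} (> {length} bytes)")
    return b.ljust(length)


def _num(value: str, length: int) -> bytes:
    # shortest exact ascii representation that fits the fixed-width field
    for fmt in ("%g", "%.8g", "%.6g", "%.4g", "%.2f", "%.1f"):
        s = fmt % value if isinstance(value, float) else str(value)
        if len(s) <= length:
            return _pad(s, length)
    raise EdfError(f"numeric value {value!r} does not fit in {length} bytes")


@dataclass
class _SignalHeader:
    label: str
    transducer: str
    phys_dim: str
    phys_min: float
    phys_max: float
    dig_min: int
    dig_max: int
    prefilter: str
    samples_per_record: int


@dataclass
class _EdfHeader:
    version: str
    patient_id: str
    recording_id: str
    startdate: str
    starttime: str
    reserved: str
    n_records: int
    record_duration: float
    signals: list[_SignalHeader]


def _parse_header(fh) -> _EdfHeader:
    raw = fh.read(256)
    if len(raw) < 256:
        raise EdfError("file too short for EDF header")
    version = _field(raw, 0, 8)
    if version != "0":
        raise EdfError(f"unsupported EDF version field {version!r}")
    reserved = _field(raw, 192, 44)
    if reserved.startswith("EDF+D"):
        raise EdfError("discontinuous EDF+D files are not supported")
    try:
        n_records = int(_field(raw, 236, 8))
        record_duration = float(_field(raw, 244, 8))
        ns = int(_field(raw, 252, 4))
    except ValueError as exc:
        raise EdfError(f"malformed numeric header field: {exc}") from None
    if ns < 1:
        raise EdfError("header declares no signals")
    sraw = fh.read(ns * 256)
    if len(sraw) < ns * 256:
        raise EdfError("file too short for signal headers")

    def col(offset: int, width: int, i: int) -> str:
        return sraw[offset * ns + i * width : offset * ns + (i + 1) * width].decode(
            "ascii", errors="replace"
        ).strip()

    signals = []
    for i in range(ns):
        try:
            signals.append(
                _SignalHeader(
                    label=col(0, 16, i),
                    transducer=col(16, 80, i),
                    phys_dim=col(96, 8, i),
                    phys_min=float(col(104, 8, i)),
                    phys_max=float(col(112, 8, i)),
                    dig_min=int(float(col(120, 8, i))),
                    dig_max=int(float(col(128, 8, i))),
                    prefilter=col(136, 80, i),
                    samples_per_record=int(col(216, 8, i)),
                )
            )
        except ValueError as exc:
            raise EdfError(f"malformed signal header {i}: {exc}") from None
    return _EdfHeader(
        version=version,
        patient_id=_field(raw, 8, 80),
        recording_id=_field(raw, 88, 80),
        startdate=_field(raw, 168, 8),
        starttime=_field(raw, 176, 8),
        reserved=reserved,
        n_records=n_records,
        record_duration=record_duration,
        signals=signals,
    )


def inspect_edf_header(path) -> dict:
    """Return raw header fields without reading sample data.

    Useful as an independent check of what a writer actually produced.
    """
    with open(path, "rb") as fh:
        hdr = _parse_header(fh)
    return {
        "n_records": hdr.n_records,
        "record_duration": hdr.record_duration,
        "reserved": hdr.reserved,
        "signals": [
            {
                "label": s.label,
                "phys_min": s.phys_min,
                "phys_max": s.phys_max,
                "samples_per_record": s.samples_per_record,
            }
            for s in hdr.signals
        ],
    }


def _parse_tals(payload: bytes, record_index: int) -> list[EventMarker]:
    markers = []
    for tal in payload.split(b"\x00"):
        if not tal:
            continue
        parts = tal.split(b"\x14")
        if len(parts) < 2:
            continue
        stamp = parts[0]
        if b"\x15" in stamp:
            onset_b, dur_b = stamp.split(b"\x15", 1)
        else:
            onset_b, dur_b = stamp, b""
        try:
            onset = float(onset_b)
        except ValueError:
            continue
        duration = float(dur_b) if dur_b else 0.0
        for text in parts[1:]:
            label = text.decode("utf-8", errors="replace").strip()
            if label:
                markers.append(
                    EventMarker(
                        channel="",
                        onset=max(onset, 0.0),
                        duration=duration if duration > 0 else 1e-6,
                        label=label,
                    )
                )
    return markers


def read_edf(path) -> tuple[Recording, EventList]:
    """Read a continuous EDF/EDF+ file.

    Returns one epoch per file (data records concatenated).  Annotation
    signals are excluded from the channel list and converted to event
    markers; annotation channel attribution is not encoded by EDF+, so
    markers carry an empty channel name unless the label embeds
    ``channel=NAME;`` as written by :func:`write_edf`.
    """
    with open(path, "rb") as fh:
        hdr = _parse_header(fh)
        if hdr.n_records <= 0:
            raise EdfError(f"header declares {hdr.n_records} data records")
        if hdr.record_duration <= 0:
            raise EdfError("non-positive data record duration")
        record_samples = sum(s.samples_per_record for s in hdr.signals)
        data = fh.read()
    expected = hdr.n_records * record_samples * 2
    if len(data) < expected:
        raise EdfError(
            f"truncated data section: expected {expected} bytes, got {len(data)}"
        )
    raw = np.frombuffer(data[:expected], dtype="<i2")
    raw = raw.reshape(hdr.n_records, record_samples)

    offsets = np.cumsum([0] + [s.samples_per_record for s in hdr.signals])
    channels: list[Channel] = []
    markers: list[EventMarker] = []
    for i, sig in enumerate(hdr.signals):
        chunk = raw[:, offsets[i] : offsets[i + 1]]
        if sig.label == _ANNOTATION_LABEL:
            for r in range(hdr.n_records):
                payload = chunk[r].astype("<i2").tobytes()
                markers.extend(_parse_tals(payload, r))
            continue
        if sig.dig_max == sig.dig_min:
            raise EdfError(f"signal {sig.label!r}: dig_min equals dig_max")
        gain = (sig.phys_max - sig.phys_min) / (sig.dig_max - sig.dig_min)
        phys = (chunk.astype(float) - sig.dig_min) * gain + sig.phys_min
        rate = sig.samples_per_record / hdr.record_duration
        channels.append(Channel(sig.label, rate, phys.reshape(-1), sig.phys_dim or "uV"))
    if not channels:
        raise EdfError("file contains no signal channels")

    cleaned = []
    for m in markers:
        channel = ""
        label = m.label
        if label.startswith("channel="):
            head, _, rest = label.partition(";")
            channel = head[len("channel="):]
            label = rest or label
        cleaned.append(
            EventMarker(
                channel=channel,
                onset=m.onset,
                duration=m.duration,
                label=label,
                epoch_index=0,
            )
        )
    rec = Recording(
        [Epoch(channels)],
        subject_id=hdr.patient_id,
        start_time=f"{hdr.startdate} {hdr.starttime}",
    )
    return rec, EventList(cleaned)


def _choose_record_layout(epoch: Epoch) -> tuple[float, int]:
    """Pick (record_duration, n_records) for one epoch.

    One-second records are used when every channel has an integer number
    of samples per second and the duration is a whole number of seconds;
    otherwise the whole epoch becomes a single record.
    """
    dur = epoch.duration
    integral = all(
        abs(c.rate - round(c.rate)) < 1e-9 for c in epoch.channels
    ) and abs(dur - round(dur)) < 1e-9
    if integral and round(dur) >= 1:
        return 1.0, int(round(dur))
    return dur, 1


def write_edf(
    rec: Recording,
    events: EventList | None,
    path,
    physical_range: tuple[float, float] = DEFAULT_PHYSICAL_RANGE,
) -> None:
    """Write a Recording (plus annotations) as an EDF+C file.

    All epochs must share channel names and rates; they are written as
    consecutive data records of a single continuous file.  Amplitudes
    outside ``physical_range`` raise instead of clipping.
    """
    rec.validate()
    events = events if events is not None else EventList()
    first = rec.epochs[0]
    names = first.channel_names
    rates = [c.rate for c in first.channels]
    for ep in rec.epochs[1:]:
        if ep.channel_names != names or [c.rate for c in ep.channels] != rates:
            raise EdfError("all epochs must share channel layout for EDF export")

    phys_min, phys_max = physical_range
    if phys_min >= phys_max:
        raise EdfError("invalid physical range")
    for ep in rec.epochs:
        for ch in ep.channels:
            lo, hi = ch.samples.min(), ch.samples.max()
            if lo < phys_min or hi > phys_max:
                raise EdfError(
                    f"channel {ch.name!r} amplitude [{lo:.3f}, {hi:.3f}] exceeds "
                    f"physical range [{phys_min}, {phys_max}]"
                )

    record_duration, records_per_epoch = _choose_record_layout(first)
    for ep in rec.epochs[1:]:
        if abs(ep.duration - first.duration) > 1e-9:
            raise EdfError("all epochs must have equal duration for EDF export")
    n_records = records_per_epoch * rec.n_epochs

    spr = []
    for ch in first.channels:
        n = ch.rate * record_duration
        if abs(n - round(n)) > 1e-6:
            raise EdfError(
                f"channel {ch.name!r}: rate {ch.rate} incompatible with record "
                f"duration {record_duration}"
            )
        spr.append(int(round(n)))

    # --- annotations -> per-record TAL payloads
    tal_records: list[bytes] = []
    epoch_offsets = [i * first.duration for i in range(rec.n_epochs)]
    for r in range(n_records):
        t0 = r * record_duration
        t1 = t0 + record_duration
        parts = [b"+%s\x14\x14\x00" % _fmt_time(t0).encode()]
        for m in events:
            onset = m.onset + epoch_offsets[m.epoch_index]
            if t0 <= onset < t1 or (r == n_records - 1 and onset >= t1):
                label = f"channel={m.channel};{m.label}" if m.channel else m.label
                parts.append(
                    b"+%s\x15%s\x14%s\x14\x00"
                    % (
                        _fmt_time(onset).encode(),
                        _fmt_time(m.duration).encode(),
                        label.encode("utf-8"),
                    )
                )
        tal_records.append(b"".join(parts))
    ann_bytes = max(len(p) for p in tal_records)
    ann_spr = math.ceil(ann_bytes / 2) + 1  # int16 samples, with slack

    signals = list(first.channels)
    ns = len(signals) + 1
    header_bytes = 256 * (1 + ns)

    gain = (_DIG_MAX - _DIG_MIN) / (phys_max - phys_min)

    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad(rec.subject_id or "X X X X", 80))
        fh.write(_pad("Startdate 01-JAN-2000 X X X", 80))
        fh.write(_pad("01.01.00", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_num(header_bytes, 8))
        fh.write(_pad("EDF+C", 44))
        fh.write(_num(n_records, 8))
        fh.write(_num(float(record_duration), 8))
        fh.write(_num(ns, 4))

        labels = [c.name for c in signals] + [_ANNOTATION_LABEL]
        for lab in labels:
            fh.write(_pad(lab, 16))
        for _ in labels:
            fh.write(_pad("", 80))
        for c in signals:
            fh.write(_pad(c.unit, 8))
        fh.write(_pad("", 8))  # annotation phys dim
        for _ in signals:
            fh.write(_num(phys_min, 8))
        fh.write(_num(-1, 8))
        for _ in signals:
            fh.write(_num(phys_max, 8))
        fh.write(_num(1, 8))
        for _ in labels:
            fh.write(_num(_DIG_MIN, 8))
        for _ in labels:
            fh.write(_num(_DIG_MAX, 8))
        for _ in labels:
            fh.write(_pad("", 80))
        for n in spr:
            fh.write(_num(n, 8))
        fh.write(_num(ann_spr, 8))
        for _ in labels:
            fh.write(_pad("", 32))

        for r in range(n_records):
            epoch = rec.epochs[r // records_per_epoch]
            local = r % records_per_epoch
            for ch, n in zip(epoch.channels, spr):
                seg = ch.samples[local * n : (local + 1) * n]
                dig = np.round((seg - phys_min) * gain) + _DIG_MIN
                fh.write(dig.astype("<i2").tobytes())
            payload = tal_records[r].ljust(ann_spr * 2, b"\x00")
            fh.write(payload)


def _fmt_time(t: float) -> str:
    s = f"{t:.6f}".rstrip("0").rstrip(".")
    return s if s else "0"
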