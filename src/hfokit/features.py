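"""Per-event feature extraction.

Twelve time-domain (morphological) features plus binned magnitude-spectrum
features (Tukey window, alpha = 0.5).  Results are collected in
:class:`FeatureTable`, which supports column-wise concatenation across
extraction stages and CSV/JSON serialization.

Conventions: a local extremum is a sample strictly greater (smaller) than
both neighbours, plateaus contributing their first sample; standard
deviations use the population form; degenerate cases (no extrema, single
interval) yield 0 rather than NaN.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal.windows import tukey

from .preprocess import _local_extrema
from .signal_model import EventList, EventMarker, Recording, SignalModelError

__all__ = [
    "FeatureTable",
    "TIME_FEATURE_NAMES",
    "time_features_of_segment",
    "extract_time_features",
    "extract_spectral_features",
    "concat_features",
]

TIME_FEATURE_NAMES = (
    "mAmp", "dAmp", "dtEx", "dur", "gdPos", "gdNeg",
    "rmaxA", "rminA", "linLen", "numEx", "sdAEx", "sdDtEx",
)


class FeatureError(SignalModelError):
    pass


@dataclass
class FeatureTable:
    """Events x features numeric table with named columns."""

    event_keys: list[EventMarker]
    feature_names: list[str]
    values: np.ndarray
    name: str = "feat"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FeatureError("values must be 2-D (events x features)")
        if self.values.shape != (len(self.event_keys), len(self.feature_names)):
            raise FeatureError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.event_keys)} events x {len(self.feature_names)} features"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise FeatureError("duplicate feature names")
        if not np.all(np.isfinite(self.values)):
            raise FeatureError("non-finite feature values")

    @property
    def n_events(self) -> int:
        return len(self.event_keys)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]

    def select(self, names: list[str]) -> "FeatureTable":
        missing = [n for n in names if n not in self.feature_names]
        if missing:
            raise FeatureError(f"unknown features: {missing}")
        cols = [self.feature_names.index(n) for n in names]
        return FeatureTable(self.event_keys, list(names), self.values[:, cols], self.name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"feature_names": self.feature_names, "values": self.values.tolist()},
                fh,
            )


def _consecutive_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All local extrema merged in time order; returns (indices, kinds).

    kind +1 for maxima, -1 for minima.
    """
    maxima, minima = _local_extrema(x)
    idx = np.concatenate([maxima, minima])
    kind = np.concatenate([np.ones(maxima.size), -np.ones(minima.size)])
    order = np.argsort(idx)
    return idx[order].astype(int), kind[order]


def time_features_of_segment(segment: np.ndarray, rate: float) -> dict[str, float]:
    """Compute all 12 time-domain features of one segment."""
    a = np.asarray(segment, dtype=float)
    if a.size < 2:
        raise FeatureError("segment must have at least 2 samples")
    mean = float(a.mean())
    out: dict[str, float] = {
        "mAmp": mean,
        "dAmp": float(a.max() - a.min()),
        "dur": a.size / rate,
        "rmaxA": float(a.max() - mean),
        "rminA": float(a.min() - mean),
        "linLen": float(np.sum(np.abs(np.diff(a)))),
    }
    ex_idx, ex_kind = _consecutive_extrema(a)
    out["numEx"] = float(ex_idx.size)
    if ex_idx.size >= 2:
        dts = np.diff(ex_idx) / rate
        out["dtEx"] = float(dts.mean())
        out["sdDtEx"] = float(dts.std())  # population SD; 0 for one interval
    else:
        out["dtEx"] = 0.0
        out["sdDtEx"] = 0.0
    if ex_idx.size >= 1:
        out["sdAEx"] = float(np.std(a[ex_idx] - mean))
    else:
        out["sdAEx"] = 0.0
    gd_pos = 0.0
    gd_neg = 0.0
    for i in range(ex_idx.size - 1):
        dt = (ex_idx[i + 1] - ex_idx[i]) / rate
        dv = a[ex_idx[i + 1]] - a[ex_idx[i]]
        if ex_kind[i] < 0 and ex_kind[i + 1] > 0:  # min -> max
            gd_pos = max(gd_pos, dv / dt)
        elif ex_kind[i] > 0 and ex_kind[i + 1] < 0:  # max -> min
            gd_neg = min(gd_neg, dv / dt)
    out["gdPos"] = gd_pos
    out["gdNeg"] = gd_neg
    return out


def _event_segment(marker: EventMarker, rec: Recording) -> tuple[np.ndarray, float]:
    epoch = rec.epoch(marker.epoch_index)
    ch = epoch.channel(marker.channel)
    i0 = int(np.floor(marker.onset * ch.rate))
    i1 = int(np.floor((marker.onset + marker.duration) * ch.rate))
    if i0 < 0 or i1 > ch.n_samples or i1 - i0 < 2:
        raise FeatureError(
            f"event {marker.label}@{marker.onset:.4f}s on {marker.channel!r} "
            f"out of bounds for epoch {marker.epoch_index}"
        )
    return ch.samples[i0:i1], ch.rate


def extract_time_features(
    events: EventList,
    rec: Recording,
    selection: tuple[str, ...] = TIME_FEATURE_NAMES,
    table_name: str = "time",
) -> FeatureTable:
    """One row per event with the selected time-domain features."""
    if not selection:
        raise FeatureError("selection must be non-empty")
    unknown = [n for n in selection if n not in TIME_FEATURE_NAMES]
    if unknown:
        raise FeatureError(f"unknown time features: {unknown}")
    rows = []
    for m in events:
        seg, rate = _event_segment(m, rec)
        feats = time_features_of_segment(seg, rate)
        rows.append([feats[n] for n in selection])
    values = np.asarray(rows, dtype=float).reshape(len(events), len(selection))
    return FeatureTable(list(events), list(selection), values, name=table_name)


def extract_spectral_features(
    events: EventList,
    rec: Recording,
    f_lo: float = 0.0,
    f_hi: float = 850.0,
    bin_hz: float = 10.0,
    normalize: bool = False,
    table_name: str = "spec",
) -> FeatureTable:
    """Binned magnitude-spectrum features with a Tukey (alpha=0.5) window.

    Magnitudes are summed into ``ceil((f_hi - f_lo) / bin_hz)`` half-open
    bins ``[f, f + bin_hz)``; a partial last bin is kept.  With
    ``normalize=True`` bins are divided by their maximum and that maximum
    is appended as feature ``specScale`` (0 for a zero-energy segment).
    """
    if bin_hz <= 0:
        raise FeatureError("bin_hz must be > 0")
    n_bins = math.ceil((f_hi - f_lo) / bin_hz)
    if n_bins < 1:
        raise FeatureError(f"empty band [{f_lo}, {f_hi})")
    rows = []
    for m in events:
        seg, rate = _event_segment(m, rec)
        if f_hi > rate / 2 + 1e-9:
            raise FeatureError(f"f_hi {f_hi} above Nyquist {rate / 2}")
        windowed = seg * tukey(seg.size, alpha=0.5)
        mags = np.abs(np.fft.rfft(windowed))
        freqs = np.fft.rfftfreq(seg.size, d=1.0 / rate)
        bins = np.zeros(n_bins)
        in_band = (freqs >= f_lo) & (freqs < f_hi)
        which = np.floor((freqs[in_band] - f_lo) / bin_hz).astype(int)
        np.add.at(bins, which, mags[in_band])
        if normalize:
            peak = bins.max()
            if peak > 0:
                bins = bins / peak
            row = np.concatenate([bins, [peak]])
        else:
            row = bins
        rows.append(row)
    names = [f"bin{int(f_lo + k * bin_hz)}" for k in range(n_bins)]
    if normalize:
        names.append("specScale")
    values = np.asarray(rows, dtype=float).reshape(len(events), len(names))
    return FeatureTable(list(events), names, values, name=table_name)


def concat_features(tables: list[FeatureTable]) -> FeatureTable:
    """Column-wise concatenation over identical event sets.

    With more than one table, names are prefixed by the source-table name
    to guarantee global uniqueness; a single table passes through as-is.
    """
    if not tables:
        raise FeatureError("no tables to concatenate")
    if len(tables) == 1:
        return tables[0]
    ref = tables[0].event_keys
    for t in tables[1:]:
        if len(t.event_keys) != len(ref) or any(
            a is not b and a.sort_key() != b.sort_key()
            for a, b in zip(ref, t.event_keys)
        ):
            raise FeatureError("event keys differ between tables")
    names = [f"{t.name}.{n}" for t in tables for n in t.feature_names]
    values = np.hstack([t.values for t in tables])
    return FeatureTable(list(ref), names, values, name="concat")
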