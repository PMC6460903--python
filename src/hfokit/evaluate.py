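"""Event matching, detection/classification statistics, and reports.

Matching is greedy one-to-one by descending temporal overlap (ties broken
by earlier onset), with overlap normalized by the shorter event so that
containment counts as full overlap.  Undefined 0/0 ratios are reported as
``None`` ("missing"), never silently as 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signal_model import EventList, EventMarker, Recording, SignalModelError

__all__ = [
    "MatchResult",
    "Counters",
    "match_events",
    "compute_metrics",
    "counters_from_match",
    "hfo_report",
    "correlation_report",
    "Report",
]


class EvaluateError(SignalModelError):
    pass


@dataclass
class MatchResult:
    pairs: list[tuple[EventMarker, EventMarker, float]]
    unmatched_reference: list[EventMarker]
    unmatched_test: list[EventMarker]

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


@dataclass
class Counters:
    """Per-class true-positive / false-positive / false-negative counters."""

    per_class: dict[str, dict[str, int]] = field(default_factory=dict)

    def add(self, label: str, kind: str, amount: int = 1) -> None:
        entry = self.per_class.setdefault(label, {"tp": 0, "fp": 0, "fn": 0})
        entry[kind] += amount

    def totals(self) -> dict[str, int]:
        out = {"tp": 0, "fp": 0, "fn": 0}
        for entry in self.per_class.values():
            for k in out:
                out[k] += entry[k]
        return out


def _overlap_fraction(a: EventMarker, b: EventMarker) -> float:
    lo = max(a.onset, b.onset)
    hi = min(a.offset, b.offset)
    if hi <= lo:
        return 0.0
    return (hi - lo) / min(a.duration, b.duration)


def match_events(
    reference: EventList,
    test: EventList,
    min_overlap_pct: float = 50.0,
) -> MatchResult:
    """Greedy one-to-one matching of test events against reference events.

    Candidate pairs require identical channel and epoch; pairs whose
    overlap (as a percentage of the shorter event) is below
    ``min_overlap_pct`` are discarded before matching.
    """
    if not (0 < min_overlap_pct <= 100):
        raise EvaluateError("min_overlap_pct must be in (0, 100]")
    candidates = []
    for i, r in enumerate(reference):
        for j, t in enumerate(test):
            if r.channel != t.channel or r.epoch_index != t.epoch_index:
                continue
            frac = _overlap_fraction(r, t)
            if frac * 100.0 >= min_overlap_pct:
                candidates.append((frac, r.onset, t.onset, i, j))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_r: set[int] = set()
    used_t: set[int] = set()
    pairs = []
    for frac, _, _, i, j in candidates:
        if i in used_r or j in used_t:
            continue
        used_r.add(i)
        used_t.add(j)
        pairs.append((reference[i], test[j], frac))
    unmatched_ref = [r for i, r in enumerate(reference) if i not in used_r]
    unmatched_test = [t for j, t in enumerate(test) if j not in used_t]
    return MatchResult(pairs, unmatched_ref, unmatched_test)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def compute_metrics(counters: Counters) -> dict:
    """Sensitivity, precision, FDR, FNR and F1 per class plus micro-average."""
    out: dict = {"per_class": {}, "micro": {}}

    def derive(tp: int, fp: int, fn: int) -> dict:
        sens = _ratio(tp, tp + fn)
        prec = _ratio(tp, tp + fp)
        fdr = _ratio(fp, tp + fp)
        fnr = None if sens is None else 1.0 - sens
        if sens is None or prec is None or (sens + prec) == 0:
            f1 = None
        else:
            f1 = 2 * prec * sens / (prec + sens)
        return {
            "tp": tp, "fp": fp, "fn": fn,
            "sensitivity": sens, "precision": prec,
            "fdr": fdr, "fnr": fnr, "f1": f1,
        }

    for label, entry in sorted(counters.per_class.items()):
        out["per_class"][label] = derive(entry["tp"], entry["fp"], entry["fn"])
    tot = counters.totals()
    out["micro"] = derive(tot["tp"], tot["fp"], tot["fn"])
    return out


def counters_from_match(match: MatchResult, label_aware: bool = False) -> Counters:
    """Build counters from a match result.

    With ``label_aware=True`` a matched pair only counts as a true
    positive when the labels agree; otherwise it increments the reference
    label's FN and the predicted label's FP (classification accounting).
    """
    counters = Counters()
    for r, t, _ in match.pairs:
        if not label_aware or r.label == t.label:
            counters.add(r.label, "tp")
        else:
            counters.add(r.label, "fn")
            counters.add(t.label, "fp")
    for r in match.unmatched_reference:
        counters.add(r.label, "fn")
    for t in match.unmatched_test:
        counters.add(t.label, "fp")
    return counters


@dataclass
class Report:
    """Generic nested report with text / JSON / CSV-ish rendering."""

    title: str
    sections: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"title": self.title, **self.sections}, indent=1, default=_jsonable)

    def to_text(self) -> str:
        lines = [self.title, "=" * len(self.title)]
        for name, content in self.sections.items():
            lines.append("")
            lines.append(f"[{name}]")
            if isinstance(content, pd.DataFrame):
                lines.append(content.to_string())
            else:
                lines.append(json.dumps(content, indent=1, default=_jsonable))
        return "\n".join(lines)


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return str(obj)


def hfo_report(
    events: EventList,
    rec: Recording,
    time_bin_s: float = 1.0,
) -> Report:
    """Per channel x label statistics plus a channel x time occurrence map.

    Inter-event interval is measured from previous offset to next onset and
    reported as missing (None) for channels with fewer than two events of a
    label.  Percentages are per channel and sum to 100.
    """
    rec.validate()
    rows = []
    groups: dict[tuple[str, str], list[EventMarker]] = {}
    channel_totals: dict[str, int] = {}
    for m in events:
        groups.setdefault((m.channel, m.label), []).append(m)
        channel_totals[m.channel] = channel_totals.get(m.channel, 0) + 1
    for (channel, label), markers in sorted(groups.items()):
        durations = [m.duration for m in markers]
        ieis = [
            markers[i + 1].onset - markers[i].offset
            for i in range(len(markers) - 1)
        ]
        rows.append(
            {
                "channel": channel,
                "label": label,
                "count": len(markers),
                "pct_of_channel": 100.0 * len(markers) / channel_totals[channel],
                "mean_duration_ms": 1000.0 * float(np.mean(durations)),
                "mean_iei_s": float(np.mean(ieis)) if ieis else None,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "channel", "label", "count", "pct_of_channel",
            "mean_duration_ms", "mean_iei_s",
        ],
    )

    duration = max((ep.duration for ep in rec.epochs), default=0.0)
    n_bins = max(int(np.ceil(duration / time_bin_s)), 1)
    channels = sorted({c.name for ep in rec.epochs for c in ep.channels})
    occurrence = np.zeros((len(channels), n_bins), dtype=int)
    for m in events:
        if m.channel in channels:
            b = min(int(m.onset / time_bin_s), n_bins - 1)
            occurrence[channels.index(m.channel), b] += 1
    occ = pd.DataFrame(
        occurrence,
        index=channels,
        columns=[f"t{k * time_bin_s:g}" for k in range(n_bins)],
    )
    return Report(
        "HFO activity report",
        {"per_channel": table, "occurrence_map": occ, "n_events": len(events)},
    )


def correlation_report(
    events: EventList,
    reference_labels: list[str],
    test_labels: list[str],
    min_overlap_pct: float = 50.0,
) -> Report:
    """Split one event list into reference/test subsets and correlate them."""
    overlap_labels = set(reference_labels) & set(test_labels)
    if overlap_labels:
        raise EvaluateError(f"label partitions overlap: {sorted(overlap_labels)}")
    if not reference_labels or not test_labels:
        raise EvaluateError("label partitions must be non-empty")
    reference = events.filter(reference_labels)
    test = events.filter(test_labels)
    match = match_events(reference, test, min_overlap_pct)
    counters = counters_from_match(match)
    metrics = compute_metrics(counters)

    def coverage(lst: EventList) -> dict:
        return {
            "n_events": len(lst),
            "channels": sorted({m.channel for m in lst}),
            "total_duration_s": float(sum(m.duration for m in lst)),
        }

    return Report(
        "Correlation assessment",
        {
            "reference_labels": list(reference_labels),
            "test_labels": list(test_labels),
            "matched": match.n_matched,
            "unmatched_reference": len(match.unmatched_reference),
            "unmatched_test": len(match.unmatched_test),
            "metrics": metrics,
            "reference_coverage": coverage(reference),
            "test_coverage": coverage(test),
        },
    )
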