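import numpy as np
import pytest

from hfokit.evaluate import (
    Counters,
    EvaluateError,
    compute_metrics,
    correlation_report,
    counters_from_match,
    hfo_report,
    match_events,
)
from hfokit.signal_model import Channel, Epoch, EventList, EventMarker, Recording


def ev(channel, onset, duration, label="R", epoch=0):
    return EventMarker(channel, onset, duration, label, epoch_index=epoch)


class TestMatchEvents:
    def test_identical_lists_fully_matched(self):
        events = EventList([ev("a", 0.1, 0.05), ev("a", 0.5, 0.05), ev("b", 0.2, 0.1)])
        m = match_events(events, EventList(events.markers), 50.0)
        assert m.n_matched == 3
        assert all(frac == pytest.approx(1.0) for _, _, frac in m.pairs)
        assert not m.unmatched_reference and not m.unmatched_test

    def test_half_overlap_boundary(self):
        ref = EventList([ev("a", 0.0, 0.1)])
        test = EventList([ev("a", 0.05, 0.1)])
        assert match_events(ref, test, 50.0).n_matched == 1
        assert match_events(ref, test, 51.0).n_matched == 0

    def test_different_channels_unmatched(self):
        ref = EventList([ev("a", 0.0, 0.1)])
        test = EventList([ev("b", 0.0, 0.1)])
        m = match_events(ref, test, 50.0)
        assert m.n_matched == 0

    def test_different_epochs_unmatched(self):
        ref = EventList([ev("a", 0.0, 0.1, epoch=0)])
        test = EventList([ev("a", 0.0, 0.1, epoch=1)])
        assert match_events(ref, test, 50.0).n_matched == 0

    def test_containment_counts_full(self):
        # overlap normalized by the shorter event
        ref = EventList([ev("a", 0.0, 1.0)])
        test = EventList([ev("a", 0.4, 0.1)])
        m = match_events(ref, test, 99.0)
        assert m.n_matched == 1
        assert m.pairs[0][2] == pytest.approx(1.0)

    def test_one_to_one(self):
        ref = EventList([ev("a", 0.0, 0.1)])
        test = EventList([ev("a", 0.0, 0.1), ev("a", 0.01, 0.1)])
        m = match_events(ref, test, 50.0)
        assert m.n_matched == 1
        assert len(m.unmatched_test) == 1

    def test_conservation(self):
        rng = np.random.default_rng(0)
        ref = EventList([ev("a", o, 0.05) for o in rng.uniform(0, 10, 12)])
        test = EventList([ev("a", o, 0.05) for o in rng.uniform(0, 10, 9)])
        m = match_events(ref, test, 30.0)
        assert m.n_matched + len(m.unmatched_reference) == 12
        assert m.n_matched + len(m.unmatched_test) == 9

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(1)
        ref = EventList([ev("a", o, 0.08) for o in rng.uniform(0, 20, 15)])
        test = EventList([ev("a", o + rng.normal(0, 0.02), 0.08)
                          for o in rng.uniform(0, 20, 15)])
        counts = [match_events(ref, test, pct).n_matched
                  for pct in (10, 30, 50, 70, 90)]
        assert counts == sorted(counts, reverse=True)

    def test_matches_brute_force(self):
        # oracle: O(n^2) matcher on a fixture without ambiguous overlaps
        rng = np.random.default_rng(2)
        onsets = np.cumsum(rng.uniform(0.3, 0.6, 30))
        ref = EventList([ev("a", o, 0.1) for o in onsets[::2]])
        test = EventList([ev("a", o + rng.uniform(-0.02, 0.02), 0.1)
                          for o in onsets[1::2]])
        m = match_events(ref, test, 40.0)
        brute = 0
        for r in ref:
            for t in test:
                lo, hi = max(r.onset, t.onset), min(r.offset, t.offset)
                if hi > lo and (hi - lo) / min(r.duration, t.duration) >= 0.40:
                    brute += 1
        assert m.n_matched == brute

    def test_bad_threshold(self):
        with pytest.raises(EvaluateError):
            match_events(EventList(), EventList(), 0.0)


class TestComputeMetrics:
    def test_worked_example(self):
        c = Counters()
        c.add("R", "tp", 8)
        c.add("R", "fn", 2)
        c.add("R", "fp", 4)
        m = compute_metrics(c)["per_class"]["R"]
        assert m["sensitivity"] == pytest.approx(0.800, abs=5e-4)
        assert m["precision"] == pytest.approx(0.667, abs=5e-4)
        assert m["fdr"] == pytest.approx(0.333, abs=5e-4)
        assert m["f1"] == pytest.approx(0.727, abs=5e-4)

    def test_all_zero_counters_missing(self):
        c = Counters()
        c.add("R", "tp", 0)
        m = compute_metrics(c)["per_class"]["R"]
        assert m["sensitivity"] is None
        assert m["precision"] is None
        assert m["fdr"] is None
        assert m["f1"] is None

    def test_precision_plus_fdr_is_one(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            c = Counters()
            c.add("R", "tp", int(rng.integers(0, 10)))
            c.add("R", "fp", int(rng.integers(0, 10)))
            c.add("R", "fn", int(rng.integers(0, 10)))
            m = compute_metrics(c)["per_class"]["R"]
            if m["precision"] is not None:
                assert m["precision"] + m["fdr"] == pytest.approx(1.0)

    def test_fnr_is_one_minus_sensitivity(self):
        c = Counters()
        c.add("R", "tp", 3)
        c.add("R", "fn", 1)
        m = compute_metrics(c)["per_class"]["R"]
        assert m["fnr"] == pytest.approx(1 - m["sensitivity"])

    def test_perfect_predictions(self):
        c = Counters()
        for label in ("R", "F", "A"):
            c.add(label, "tp", 5)
        metrics = compute_metrics(c)
        for label in ("R", "F", "A"):
            m = metrics["per_class"][label]
            assert m["sensitivity"] == 1.0
            assert m["precision"] == 1.0
            assert m["f1"] == 1.0
            assert m["fdr"] == 0.0


class TestHfoReport:
    def make_rec(self, duration=5.0, channels=("c0", "c1")):
        n = int(duration * 1000)
        return Recording([Epoch([Channel(c, 1000.0, np.zeros(n)) for c in channels])])

    def test_counts_and_iei(self):
        events = EventList([ev("c0", 0.0, 0.1), ev("c0", 1.0, 0.1), ev("c0", 2.0, 0.1)])
        rep = hfo_report(events, self.make_rec())
        row = rep.sections["per_channel"].iloc[0]
        assert row["count"] == 3
        assert row["mean_duration_ms"] == pytest.approx(100.0)
        assert row["mean_iei_s"] == pytest.approx(0.9)  # offset-to-onset

    def test_single_event_iei_missing(self):
        rep = hfo_report(EventList([ev("c0", 1.0, 0.1)]), self.make_rec())
        assert rep.sections["per_channel"].iloc[0]["mean_iei_s"] is None

    def test_percentages_sum_to_100(self):
        events = EventList([
            ev("c0", 0.5, 0.1, "R"), ev("c0", 1.5, 0.1, "F"),
            ev("c0", 2.5, 0.1, "R"), ev("c1", 1.0, 0.1, "A"),
        ])
        rep = hfo_report(events, self.make_rec())
        df = rep.sections["per_channel"]
        for channel, group in df.groupby("channel"):
            assert group["pct_of_channel"].sum() == pytest.approx(100.0, abs=0.01)

    def test_occurrence_map_shape_and_counts(self):
        events = EventList([ev("c0", 0.5, 0.1), ev("c0", 0.7, 0.1), ev("c1", 3.5, 0.1)])
        rep = hfo_report(events, self.make_rec(), time_bin_s=1.0)
        occ = rep.sections["occurrence_map"]
        assert occ.shape == (2, 5)
        assert occ.loc["c0"].sum() == 2
        assert occ.loc["c1", "t3"] == 1

    def test_renderings(self):
        rep = hfo_report(EventList([ev("c0", 1.0, 0.1)]), self.make_rec())
        assert "HFO activity report" in rep.to_text()
        assert '"n_events": 1' in rep.to_json()


class TestCorrelationReport:
    def test_identical_subsets(self):
        events = EventList([
            ev("a", 0.1, 0.05, "R"), ev("a", 0.1, 0.05, "visR"),
            ev("a", 0.9, 0.05, "R"), ev("a", 0.9, 0.05, "visR"),
        ])
        rep = correlation_report(events, ["visR"], ["R"], 50.0)
        micro = rep.sections["metrics"]["micro"]
        assert micro["sensitivity"] == 1.0
        assert micro["precision"] == 1.0

    def test_disjoint_events(self):
        events = EventList([
            ev("a", 0.1, 0.05, "visR"), ev("a", 5.0, 0.05, "R"),
        ])
        rep = correlation_report(events, ["visR"], ["R"], 50.0)
        micro = rep.sections["metrics"]["micro"]
        assert micro["sensitivity"] == 0.0
        assert micro["precision"] == 0.0

    def test_overlapping_partition_rejected(self):
        with pytest.raises(EvaluateError):
            correlation_report(EventList(), ["R"], ["R", "F"], 50.0)

    def test_symmetry_swaps_sensitivity_precision(self):
        rng = np.random.default_rng(5)
        markers = []
        for o in np.cumsum(rng.uniform(0.3, 0.5, 10)):
            markers.append(ev("a", o, 0.1, "visR"))
        for o in np.cumsum(rng.uniform(0.4, 0.7, 8)):
            markers.append(ev("a", o + 0.02, 0.1, "R"))
        events = EventList(markers)
        fwd = correlation_report(events, ["visR"], ["R"], 50.0)
        rev = correlation_report(events, ["R"], ["visR"], 50.0)
        f, r = fwd.sections["metrics"]["micro"], rev.sections["metrics"]["micro"]
        assert f["sensitivity"] == pytest.approx(r["precision"])
        assert f["precision"] == pytest.approx(r["sensitivity"])


class TestCountersFromMatch:
    def test_label_aware_accounting(self):
        ref = EventList([ev("a", 0.0, 0.1, "R"), ev("a", 1.0, 0.1, "F")])
        test = EventList([ev("a", 0.0, 0.1, "R"), ev("a", 1.0, 0.1, "R")])
        m = match_events(ref, test, 50.0)
        c = counters_from_match(m, label_aware=True)
        assert c.per_class["R"]["tp"] == 1
        assert c.per_class["F"]["fn"] == 1
        assert c.per_class["R"]["fp"] == 1
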