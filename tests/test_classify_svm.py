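import numpy as np
import pytest

from hfokit.classify_svm import (
    DEFAULT_C_GRID,
    DEFAULT_GAMMA_GRID,
    SelectionConfig,
    SvmError,
    anova_f,
    anova_rank,
    apply_scaler,
    classify_events,
    fit_scaler,
    greedy_forward_select,
    grid_optimize,
    load_model,
    n_outer_iterations,
    partition_rows,
    relabel_by_reference,
    save_model,
    select_feature_subset,
    train_model,
    validate_model,
)
from hfokit.features import FeatureTable
from hfokit.signal_model import EventList, EventMarker


def make_table(values, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"f{i}" for i in range(values.shape[1])]
    events = [EventMarker("c0", 0.001 * (i + 1), 0.001, "EOI")
              for i in range(values.shape[0])]
    return FeatureTable(events, names, values)


def gaussian_classes(seed, n_per=100, n_feat=20, sep=3.0):
    """3 classes, features 0 and 1 informative (mean separation sep*sigma)."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((3 * n_per, n_feat))
    y = np.repeat(["EOI", "R", "F"], n_per)
    means = [(0, 0), (sep, 0), (0, sep)]
    for i in range(3):
        X[i * n_per : (i + 1) * n_per, 0] += means[i][0]
        X[i * n_per : (i + 1) * n_per, 1] += means[i][1]
    return make_table(X), y


class TestScaler:
    def test_formula(self):
        table = make_table([[2.0], [3.0], [4.0]])
        scaler = fit_scaler(table, 0.0, 1.0)
        scaled = apply_scaler(scaler, table)
        np.testing.assert_allclose(scaled.values[:, 0], [0.0, 0.5, 1.0])

    def test_endpoints(self):
        table = make_table([[10.0, -5.0], [20.0, 5.0]])
        scaled = apply_scaler(fit_scaler(table, -1.0, 1.0), table)
        np.testing.assert_allclose(scaled.values[0], [-1.0, -1.0])
        np.testing.assert_allclose(scaled.values[1], [1.0, 1.0])

    def test_constant_feature_maps_to_m(self):
        table = make_table([[7.0], [7.0], [7.0]])
        scaled = apply_scaler(fit_scaler(table, 0.25, 1.0), table)
        np.testing.assert_allclose(scaled.values[:, 0], 0.25)

    def test_out_of_range_extrapolates(self):
        train = make_table([[0.0], [1.0]])
        scaler = fit_scaler(train, 0.0, 1.0)
        test = make_table([[2.0]])
        assert apply_scaler(scaler, test).values[0, 0] == pytest.approx(2.0)

    def test_idempotent_range(self):
        rng = np.random.default_rng(0)
        table = make_table(rng.uniform(-50, 50, (30, 4)))
        scaled = apply_scaler(fit_scaler(table, 0.0, 1.0), table)
        assert scaled.values.min() >= 0.0
        assert scaled.values.max() <= 1.0


class TestAnova:
    def test_discriminative_feature_ranks_first(self):
        rng = np.random.default_rng(1)
        n = 30
        a = np.concatenate([rng.normal(0, 1, n), rng.normal(5, 1, n),
                            rng.normal(10, 1, n)])
        b = rng.normal(0, 1, 3 * n)
        X = np.column_stack([b, a])
        y = np.repeat([0, 1, 2], n)
        assert list(anova_rank(X, y)) == [1, 0]

    def test_matches_sum_of_squares_oracle(self):
        # oracle: direct SSB/SSW evaluation on a 60 x 5 random table
        rng = np.random.default_rng(2)
        X = rng.standard_normal((60, 5))
        y = np.repeat([0, 1, 2], 20)
        got = anova_f(X, y)
        for j in range(5):
            col = X[:, j]
            grand = col.mean()
            ssb = sum((col[y == c].mean() - grand) ** 2 * (y == c).sum()
                      for c in (0, 1, 2))
            ssw = sum(((col[y == c] - col[y == c].mean()) ** 2).sum()
                      for c in (0, 1, 2))
            expected = (ssb / 2) / (ssw / 57)
            assert got[j] == pytest.approx(expected, abs=1e-10)

    def test_constant_feature_ranks_last(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([np.full(60, 4.0), rng.standard_normal(60)])
        y = np.repeat([0, 1, 2], 20)
        f = anova_f(X, y)
        assert f[0] == 0.0
        assert list(anova_rank(X, y)) == [1, 0]

    def test_single_class_rejected(self):
        with pytest.raises(SvmError):
            anova_f(np.zeros((10, 2)), np.zeros(10))

    def test_tiny_class_rejected(self):
        with pytest.raises(SvmError):
            anova_f(np.zeros((3, 2)), np.array([0, 0, 1]))


class TestGreedySelection:
    def test_perfect_feature_terminates_fast(self):
        # feature 0 alone separates classes perfectly
        rng = np.random.default_rng(4)
        n = 60
        f0 = np.concatenate([rng.uniform(0, 1, n), rng.uniform(10, 11, n)])
        noise = rng.standard_normal((2 * n, 3))
        X = np.column_stack([f0, noise])
        y = np.repeat([0, 1], n)
        train = np.arange(0, 2 * n, 2)
        val = np.arange(1, 2 * n, 2)
        subset, history = greedy_forward_select(
            [0, 1, 2, 3], X[train], y[train], X[val], y[val]
        )
        assert subset == [0]
        assert history == [1.0]

    def test_pure_noise_stays_at_baseline(self):
        # never grows beyond features that improve validation accuracy
        sizes = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((80, 5))
            y = np.repeat([0, 1], 40)
            train, val = np.arange(0, 80, 2), np.arange(1, 80, 2)
            subset, _ = greedy_forward_select(
                list(range(5)), X[train], y[train], X[val], y[val]
            )
            sizes.append(len(subset))
        # on pure noise the subset only ever grows by chance improvements
        assert np.mean(sizes) <= 2.0
        assert max(sizes) <= 3

    def test_single_candidate(self):
        rng = np.random.default_rng(6)
        n = 40
        f0 = np.concatenate([rng.normal(0, 1, n), rng.normal(6, 1, n)])[:, None]
        y = np.repeat([0, 1], n)
        subset, _ = greedy_forward_select([0], f0[::2], y[::2], f0[1::2], y[1::2])
        assert subset == [0]


class TestOuterLoop:
    def test_iteration_count_rule(self):
        assert n_outer_iterations(0.1) == 10
        assert n_outer_iterations(0.25) == 4
        assert n_outer_iterations(0.3) == 3

    def test_worked_example_split(self):
        rng = np.random.Generator(np.random.MT19937(0))
        train, val = partition_rows(11_434, 0.1, rng)
        assert val.size == 1_143
        assert train.size == 10_291

    def test_split_is_partition(self):
        rng = np.random.Generator(np.random.MT19937(1))
        train, val = partition_rows(100, 0.2, rng)
        assert sorted(np.concatenate([train, val]).tolist()) == list(range(100))

    def test_invalid_ratio_rejected(self):
        with pytest.raises(SvmError):
            SelectionConfig(ratio=0.8)
        with pytest.raises(SvmError):
            SelectionConfig(ratio=0.0)

    def test_recovers_planted_features(self):
        # parameter-recovery: 2 informative among 20, averaged over seeds
        recovered, noise_counts = 0, []
        for seed in range(3):
            table, y = gaussian_classes(seed)
            subset, hist = select_feature_subset(
                table, y, SelectionConfig(ratio=0.1, seed=seed)
            )
            recovered += int("f0" in subset and "f1" in subset)
            noise_counts.append(len([f for f in subset if f not in ("f0", "f1")]))
        assert recovered == 3
        assert np.mean(noise_counts) <= 2.0

    def test_determinism(self):
        table, y = gaussian_classes(9, n_per=40, n_feat=8)
        cfg = SelectionConfig(ratio=0.2, seed=5)
        s1, h1 = select_feature_subset(table, y, cfg)
        s2, h2 = select_feature_subset(table, y, cfg)
        assert s1 == s2 and h1 == h2

    def test_too_few_rows_rejected(self):
        table, y = gaussian_classes(0, n_per=5)
        with pytest.raises(SvmError):
            select_feature_subset(table, y, SelectionConfig(ratio=0.2, seed=0))


class TestGridOptimize:
    def test_single_cell(self):
        table, y = gaussian_classes(0, n_per=30, n_feat=3)
        C, gamma, acc = grid_optimize(table.values, y, [2.0], [0.5], folds=3)
        assert (C, gamma) == (2.0, 0.5)

    def test_matches_brute_force(self):
        # oracle: independent double loop with identical folds
        from sklearn.model_selection import StratifiedKFold
        from sklearn.svm import SVC

        table, y = gaussian_classes(1, n_per=50, n_feat=3)
        X, y = table.values, np.asarray(y)
        c_grid, g_grid = [0.5, 8.0], [0.01, 0.1, 1.0]
        got = grid_optimize(X, y, c_grid, g_grid, folds=3)
        best = (None, None, -1.0)
        for C in sorted(c_grid):
            for g in sorted(g_grid):
                accs = []
                for tr, te in StratifiedKFold(n_splits=3).split(X, y):
                    clf = SVC(C=C, gamma=g, kernel="rbf").fit(X[tr], y[tr])
                    accs.append(np.mean(clf.predict(X[te]) == y[te]))
                acc = float(np.mean(accs))
                if acc > best[2]:
                    best = (C, g, acc)
        assert got == best

    def test_tie_breaks_toward_smallest(self):
        # constant features: every cell ties; smallest C then gamma wins
        X = np.zeros((30, 2))
        y = np.repeat([0, 1, 2], 10)
        C, gamma, _ = grid_optimize(X, y, [4.0, 1.0], [0.3, 0.1], folds=3)
        assert (C, gamma) == (1.0, 0.1)

    def test_fold_starvation_rejected(self):
        X = np.zeros((6, 2))
        y = np.array([0, 0, 0, 0, 1, 1])
        with pytest.raises(SvmError, match="folds"):
            grid_optimize(X, y, [1.0], [0.1], folds=3)


@pytest.fixture(scope="module")
def trained():
    # construction guarantees separability (6 sigma between class means)
    table, y = gaussian_classes(3, n_per=60, n_feat=10, sep=6.0)
    cfg = SelectionConfig(ratio=0.2, seed=3, c_grid=(1.0, 8.0),
                          gamma_grid=(0.05, 0.5))
    return train_model(table, y, cfg), table, y


class TestTrainValidateClassify:

    def test_training_accuracy(self, trained):
        model, table, y = trained
        assert model.metadata["training_accuracy"] >= 0.95

    def test_save_load_identical_predictions(self, trained, tmp_path):
        model, table, y = trained
        path = tmp_path / "model.bin"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_array_equal(back.predict(table), model.predict(table))

    def test_single_class_rejected(self):
        table, _ = gaussian_classes(0, n_per=30, n_feat=4)
        with pytest.raises(SvmError):
            train_model(table, np.repeat("R", table.n_events))

    def test_fresh_sample_accuracy(self, trained):
        model, _, _ = trained
        fresh, fy = gaussian_classes(77, n_per=40, n_feat=10, sep=6.0)
        assert np.mean(model.predict(fresh) == fy) >= 0.9

    def test_validate_perfect(self, trained):
        model, table, y = trained
        predictions = model.predict(table)
        report = validate_model(model, table, predictions)  # truth := preds
        for m in report.sections["metrics"]["per_class"].values():
            assert m["sensitivity"] == 1.0
            assert m["precision"] == 1.0
            assert m["fdr"] == 0.0

    def test_validate_counters_hand_computed(self, trained):
        model, _, _ = trained
        # tiny fixture with known prediction pattern
        fresh, fy = gaussian_classes(88, n_per=20, n_feat=10, sep=6.0)
        report = validate_model(model, fresh, fy)
        per_class = report.sections["metrics"]["per_class"]
        preds = model.predict(fresh)
        for label in np.unique(fy):
            tp = int(np.sum((preds == label) & (fy == label)))
            fn = int(np.sum((preds != label) & (fy == label)))
            fp = int(np.sum((preds == label) & (fy != label)))
            assert per_class[str(label)]["tp"] == tp
            assert per_class[str(label)]["fn"] == fn
            assert per_class[str(label)]["fp"] == fp

    def test_classify_rewrites_labels(self, trained):
        model, table, y = trained
        out = classify_events(model, table)
        assert len(out) == table.n_events
        assert set(m.label for m in out) <= {"EOI", "R", "F"}

    def test_missing_features_listed(self, trained):
        model, table, _ = trained
        reduced = table.select([n for n in table.feature_names
                                if n not in model.feature_subset])
        with pytest.raises(SvmError, match=model.feature_subset[0]):
            model.predict(reduced)


class TestRelabel:
    def test_matched_takes_reference_label(self):
        detected = EventList([EventMarker("a", 0.0, 0.1, "EOI")])
        reference = EventList([EventMarker("a", 0.05, 0.1, "R")])
        out = relabel_by_reference(detected, reference, 50.0)
        assert out[0].label == "R"

    def test_unmatched_stays_eoi(self):
        detected = EventList([EventMarker("a", 0.0, 0.1, "EOI")])
        reference = EventList([EventMarker("a", 5.0, 0.1, "R")])
        out = relabel_by_reference(detected, reference, 50.0)
        assert out[0].label == "EOI"

    def test_count_conservation(self):
        rng = np.random.default_rng(12)
        detected = EventList([
            EventMarker("a", o, 0.1, "EOI")
            for o in np.cumsum(rng.uniform(0.3, 0.5, 30))
        ])
        reference = EventList([
            EventMarker("a", m.onset + 0.01, 0.1, "R" if i % 3 else "F")
            for i, m in enumerate(detected.markers[:15])
        ])
        out = relabel_by_reference(detected, reference, 50.0)
        counts = {lab: out.labels().count(lab) for lab in ("R", "F", "EOI")}
        assert sum(counts.values()) == 30
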