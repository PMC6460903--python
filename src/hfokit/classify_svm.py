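"""SVM classification stage.

Owns feature scaling, ANOVA feature ranking, wrapper (greedy-forward)
feature-subset selection with a resampled outer loop, exhaustive C/gamma
grid optimization with stratified cross-validation, and the three
operational modes (learning / validation / classification).  The quadratic
program itself is delegated to scikit-learn's libsvm binding.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .evaluate import Counters, Report, compute_metrics, match_events
from .features import FeatureTable
from .signal_model import EventList, EventMarker, SignalModelError

__all__ = [
    "Scaler",
    "SelectionConfig",
    "SVMModel",
    "fit_scaler",
    "apply_scaler",
    "anova_rank",
    "greedy_forward_select",
    "n_outer_iterations",
    "partition_rows",
    "select_feature_subset",
    "grid_optimize",
    "train_model",
    "relabel_by_reference",
    "validate_model",
    "classify_events",
    "save_model",
    "load_model",
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
]

# practical-guide style exponential grids
DEFAULT_C_GRID = tuple(2.0**k for k in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0**k for k in range(-15, 4, 2))

MODEL_FORMAT = "hfokit-svm-model"
MODEL_VERSION = 1


class SvmError(SignalModelError):
    pass


# ---------------------------------------------------------------------------
# scaling


@dataclass
class Scaler:
    """Per-feature linear map of ``[x_min, x_max]`` onto ``[m, M]``."""

    feature_names: list[str]
    x_min: np.ndarray
    x_max: np.ndarray
    m: float = 0.0
    M: float = 1.0


def fit_scaler(table: FeatureTable, m: float = 0.0, M: float = 1.0) -> Scaler:
    if table.n_events == 0:
        raise SvmError("cannot fit scaler on an empty table")
    return Scaler(
        list(table.feature_names),
        table.values.min(axis=0),
        table.values.max(axis=0),
        m,
        M,
    )


def apply_scaler(scaler: Scaler, table: FeatureTable) -> FeatureTable:
    """x' = m + (x - x_min)(M - m)/(x_max - x_min); out-of-range values
    extrapolate linearly, constant features collapse to ``m``."""
    if table.feature_names != scaler.feature_names:
        table = table.select(scaler.feature_names)
    span = scaler.x_max - scaler.x_min
    safe = np.where(span > 0, span, 1.0)
    scaled = scaler.m + (table.values - scaler.x_min) * (scaler.M - scaler.m) / safe
    scaled = np.where(span > 0, scaled, scaler.m)
    return FeatureTable(table.event_keys, table.feature_names, scaled, table.name)


# ---------------------------------------------------------------------------
# ANOVA ranking


def anova_f(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """One-way F statistic per column; constant columns get F = 0."""
    classes = np.unique(labels)
    if classes.size < 2:
        raise SvmError("ANOVA needs >= 2 classes")
    n = values.shape[0]
    grand = values.mean(axis=0)
    ssb = np.zeros(values.shape[1])
    ssw = np.zeros(values.shape[1])
    for c in classes:
        group = values[labels == c]
        if group.shape[0] < 2:
            raise SvmError(f"class {c!r} has fewer than 2 samples")
        ssb += group.shape[0] * (group.mean(axis=0) - grand) ** 2
        ssw += ((group - group.mean(axis=0)) ** 2).sum(axis=0)
    df_between = classes.size - 1
    df_within = n - classes.size
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df_between) / (ssw / df_within)
    f = np.where(ssw == 0, np.where(ssb == 0, 0.0, np.inf), f)
    f = np.where(ssb == 0, 0.0, f)
    return f


def anova_rank(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Column indices ordered by descending F; stable for ties."""
    f = anova_f(values, labels)
    return np.argsort(-f, kind="stable")


# ---------------------------------------------------------------------------
# greedy forward selection


def _majority_accuracy(y: np.ndarray) -> float:
    _, counts = np.unique(y, return_counts=True)
    return counts.max() / y.size


def _svc(C: float, gamma) -> SVC:
    return SVC(C=C, gamma=gamma, kernel="rbf")


def greedy_forward_select(
    ranked_features: list[int],
    train_X: np.ndarray,
    train_y: np.ndarray,
    val_X: np.ndarray,
    val_y: np.ndarray,
    C: float = 1.0,
    gamma="scale",
) -> tuple[list[int], list[float]]:
    """Hill-climbing wrapper selection on a fixed train/validation split.

    Starting from the empty set (baseline = majority-class validation
    accuracy), each round tries appending every remaining candidate in
    rank order, keeps the best strictly-improving one, and permanently
    drops candidates whose trial accuracy fell below ``mean - sd`` of that
    round's trial accuracies.  Returns (selected indices, accuracy after
    each accepted step).
    """
    selected: list[int] = []
    remaining = list(ranked_features)
    best = _majority_accuracy(val_y)
    history: list[float] = []
    while remaining:
        trials: dict[int, float] = {}
        for f in remaining:
            cols = selected + [f]
            clf = _svc(C, gamma).fit(train_X[:, cols], train_y)
            trials[f] = float(np.mean(clf.predict(val_X[:, cols]) == val_y))
        accs = np.array(list(trials.values()))
        best_f = max(remaining, key=lambda f: trials[f])  # rank order breaks ties
        cut = accs.mean() - accs.std()
        improved = trials[best_f] > best
        if improved:
            selected.append(best_f)
            best = trials[best_f]
            history.append(best)
        remaining = [
            f for f in remaining if f != best_f and trials[f] >= cut
        ]
        if not improved:
            break
    return selected, history


# ---------------------------------------------------------------------------
# outer resampling loop


@dataclass
class SelectionConfig:
    ratio: float = 0.1
    seed: int = 0
    min_occurrence: int = 2
    c_grid: tuple = DEFAULT_C_GRID
    gamma_grid: tuple = DEFAULT_GAMMA_GRID
    cv_folds: int = 3
    selection_C: float = 1.0
    selection_gamma: float | str = "scale"
    scale_m: float = 0.0
    scale_M: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.ratio <= 0.5):
            raise SvmError("ratio must be in (0, 0.5]")
        if n_outer_iterations(self.ratio) < 2:
            raise SvmError("ratio implies fewer than 2 outer iterations")


def n_outer_iterations(ratio: float) -> int:
    """Outer-loop iteration count: floor(1 / r)."""
    return int(np.floor(1.0 / ratio))


def partition_rows(
    n_rows: int, ratio: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Shuffle and split: validation gets ``floor(n_rows * ratio)`` rows."""
    n_val = int(np.floor(n_rows * ratio))
    if n_val < 1:
        raise SvmError(f"ratio {ratio} yields an empty validation subset")
    perm = rng.permutation(n_rows)
    return perm[n_val:], perm[:n_val]


def select_feature_subset(
    table: FeatureTable,
    labels: np.ndarray,
    config: SelectionConfig,
) -> tuple[list[str], dict[str, int]]:
    """Resampled wrapper feature-subset selection.

    Runs ``floor(1/ratio)`` outer iterations of shuffle/split, per-split
    scaling, ANOVA ranking, and greedy forward selection; aggregates the
    local subsets into an occurrence histogram and keeps features seen at
    least ``min_occurrence`` times.  Fully deterministic for a fixed seed.
    """
    labels = np.asarray(labels)
    n_classes = np.unique(labels).size
    if table.n_events < 10 * n_classes:
        raise SvmError(
            f"need at least {10 * n_classes} rows for {n_classes} classes"
        )
    rng = np.random.Generator(np.random.MT19937(config.seed))
    histogram: dict[str, int] = {name: 0 for name in table.feature_names}
    n = n_outer_iterations(config.ratio)
    for _ in range(n):
        train_idx, val_idx = partition_rows(table.n_events, config.ratio, rng)
        train_vals = table.values[train_idx]
        x_min, x_max = train_vals.min(axis=0), train_vals.max(axis=0)
        span = np.where(x_max > x_min, x_max - x_min, 1.0)
        scale = lambda v: config.scale_m + (v - x_min) * (
            config.scale_M - config.scale_m
        ) / span
        ranked = list(anova_rank(train_vals, labels[train_idx]))
        subset, _ = greedy_forward_select(
            ranked,
            scale(train_vals),
            labels[train_idx],
            scale(table.values[val_idx]),
            labels[val_idx],
            C=config.selection_C,
            gamma=config.selection_gamma,
        )
        for f in subset:
            histogram[table.feature_names[f]] += 1
    final = [
        name
        for name in table.feature_names
        if histogram[name] >= config.min_occurrence
    ]
    return final, histogram


# ---------------------------------------------------------------------------
# grid optimization


def grid_optimize(
    values: np.ndarray,
    labels: np.ndarray,
    c_grid=DEFAULT_C_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
    folds: int = 3,
) -> tuple[float, float, float]:
    """Exhaustive (C, gamma) grid search with stratified k-fold CV.

    Ties are broken toward the smallest C, then the smallest gamma.
    Returns ``(C, gamma, cv_accuracy)``.
    """
    if len(c_grid) == 0 or len(gamma_grid) == 0 or folds < 2:
        raise SvmError("grids must be non-empty and folds >= 2")
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < folds:
        raise SvmError(
            f"a class has only {counts.min()} samples; use fewer than "
            f"{folds} folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=False)
    splits = list(skf.split(values, labels))
    best = (None, None, -1.0)
    for C in sorted(c_grid):
        for gamma in sorted(gamma_grid):
            accs = []
            for train_idx, test_idx in splits:
                clf = _svc(C, gamma).fit(values[train_idx], labels[train_idx])
                accs.append(np.mean(clf.predict(values[test_idx]) == labels[test_idx]))
            acc = float(np.mean(accs))
            if acc > best[2]:
                best = (C, gamma, acc)
    return best


# ---------------------------------------------------------------------------
# model container and modes


@dataclass
class SVMModel:
    scaler: Scaler
    feature_subset: list[str]
    C: float
    gamma: float
    solver_state: SVC
    class_labels: list[str]
    metadata: dict = field(default_factory=dict)

    def predict(self, table: FeatureTable) -> np.ndarray:
        missing = [f for f in self.feature_subset if f not in table.feature_names]
        if missing:
            raise SvmError(f"table is missing model features: {missing}")
        sub = apply_scaler(self.scaler, table.select(self.feature_subset))
        return self.solver_state.predict(sub.values)


def train_model(
    table: FeatureTable,
    labels: np.ndarray,
    config: SelectionConfig | None = None,
) -> SVMModel:
    """Learning mode: subset selection, rescaling, grid search, final fit."""
    config = config or SelectionConfig()
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise SvmError("training requires at least 2 classes")
    subset, histogram = select_feature_subset(table, labels, config)
    if not subset:
        raise SvmError(
            "final feature subset is empty; lower min_occurrence or review data"
        )
    sub_table = table.select(subset)
    scaler = fit_scaler(sub_table, config.scale_m, config.scale_M)
    scaled = apply_scaler(scaler, sub_table)
    C, gamma, cv_acc = grid_optimize(
        scaled.values, labels, config.c_grid, config.gamma_grid, config.cv_folds
    )
    clf = _svc(C, gamma).fit(scaled.values, labels)
    train_acc = float(np.mean(clf.predict(scaled.values) == labels))
    return SVMModel(
        scaler=scaler,
        feature_subset=list(subset),
        C=C,
        gamma=gamma,
        solver_state=clf,
        class_labels=sorted(np.unique(labels).tolist()),
        metadata={
            "seed": config.seed,
            "ratio": config.ratio,
            "occurrence_histogram": histogram,
            "cv_accuracy": cv_acc,
            "training_accuracy": train_acc,
            "n_training_rows": table.n_events,
        },
    )


def save_model(model: SVMModel, path) -> None:
    payload = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "scaler": {
            "feature_names": model.scaler.feature_names,
            "x_min": model.scaler.x_min.tolist(),
            "x_max": model.scaler.x_max.tolist(),
            "m": model.scaler.m,
            "M": model.scaler.M,
        },
        "feature_subset": model.feature_subset,
        "C": model.C,
        "gamma": model.gamma,
        "class_labels": model.class_labels,
        "metadata": model.metadata,
        "solver_state": model.solver_state,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path) -> SVMModel:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format") != MODEL_FORMAT:
        raise SvmError(f"not a {MODEL_FORMAT} file")
    if payload.get("version") != MODEL_VERSION:
        raise SvmError(f"unsupported model version {payload.get('version')}")
    s = payload["scaler"]
    return SVMModel(
        scaler=Scaler(
            s["feature_names"],
            np.asarray(s["x_min"]),
            np.asarray(s["x_max"]),
            s["m"],
            s["M"],
        ),
        feature_subset=payload["feature_subset"],
        C=payload["C"],
        gamma=payload["gamma"],
        solver_state=payload["solver_state"],
        class_labels=payload["class_labels"],
        metadata=payload["metadata"],
    )


def relabel_by_reference(
    detected: EventList,
    reference: EventList,
    min_overlap_pct: float = 50.0,
) -> EventList:
    """Matched detections take the reference label; the rest stay EOI."""
    match = match_events(reference, detected, min_overlap_pct)
    relabeled = {id(t): r.label for r, t, _ in match.pairs}
    out = []
    for m in detected:
        label = relabeled.get(id(m), "EOI")
        out.append(
            EventMarker(
                channel=m.channel,
                onset=m.onset,
                duration=m.duration,
                label=label,
                epoch_index=m.epoch_index,
                properties=dict(m.properties),
            )
        )
    return EventList(out)


def validate_model(
    model: SVMModel, table: FeatureTable, labels: np.ndarray
) -> Report:
    """Validation mode: per-class counters and derived statistics."""
    labels = np.asarray(labels)
    predicted = model.predict(table)
    counters = Counters()
    for truth, pred in zip(labels, predicted):
        if truth == pred:
            counters.add(str(truth), "tp")
        else:
            counters.add(str(truth), "fn")
            counters.add(str(pred), "fp")
    metrics = compute_metrics(counters)
    accuracy = float(np.mean(predicted == labels))
    return Report(
        "SVM validation report",
        {
            "n_events": int(labels.size),
            "accuracy": accuracy,
            "metrics": metrics,
            "model": {
                "feature_subset": model.feature_subset,
                "C": model.C,
                "gamma": model.gamma,
            },
        },
    )


def classify_events(model: SVMModel, table: FeatureTable) -> EventList:
    """Classification mode: rewrite event labels from model predictions."""
    predicted = model.predict(table)
    out = []
    for m, label in zip(table.event_keys, predicted):
        out.append(
            EventMarker(
                channel=m.channel,
                onset=m.onset,
                duration=m.duration,
                label=str(label),
                epoch_index=m.epoch_index,
                properties={**m.properties, "previous_label": m.label},
            )
        )
    return EventList(out)
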