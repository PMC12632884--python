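"""State and abstract-operation decoders over synthetic sensor data.

Per-state binomial (L1-penalized logistic) classifiers are trained on
localizer runs and applied sample-by-sample to the reasoning run, yielding
time-resolved reactivation probability matrices.  Abstract operation
decoders (type, attribute, compound) generalize across held-out objects so
that above-chance accuracy can only come from object-invariant codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from sklearn.linear_model import LogisticRegression

from progreplay._cluster import cluster_mass_mask
from progreplay.simulate import SensorTimeseries
from progreplay.task import ATTRIBUTE_VALUES, ATTRIBUTES, TaskGraph

OBJECT_CHANCE = 1.0 / 12.0
BINARY_CHANCE = 0.5


@dataclass
class DecodingConfig:
    """Classifier and cross-validation knobs."""

    C: float = 1.0  # inverse L1 penalty strength
    time_grid_ms: tuple[float, ...] = tuple(float(t) for t in range(0, 501, 50))
    cv: str | int = "loo"  # "loo" or a fold count
    smoothing_sd_ms: float = 20.0
    max_iter: int = 200
    # augment binary/abstract training with late post-stimulus samples as
    # shared negatives; keeps paired classifiers (e.g. swap vs branch) from
    # being exact mirrors, which would make their probability series sum to
    # one and break downstream transition regressions
    null_negatives: bool = True
    null_time_ms: float | None = None  # default: last sample of each trial


@dataclass
class ClassifierWeights:
    state: str
    weights: np.ndarray
    intercept: float
    train_time_ms: float
    scheme: str


@dataclass
class DecoderSet:
    """One binomial classifier per state, taken at a single training time."""

    classifiers: dict[str, ClassifierWeights]
    fs: int
    scheme: str

    @property
    def states(self) -> tuple[str, ...]:
        return tuple(self.classifiers)

    def weight_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        W = np.stack([c.weights for c in self.classifiers.values()])
        b = np.array([c.intercept for c in self.classifiers.values()])
        return W, b


@dataclass
class DecodingCurve:
    """Cross-validated accuracy over candidate training times."""

    times_ms: np.ndarray
    accuracy: np.ndarray  # (n_times,)
    chance: float
    # per-time held-out predictions and the true labels, for nulls/confusion
    predictions: np.ndarray | None = None  # (n_test, n_times) label indices
    true_labels: np.ndarray | None = None  # (n_test,) label indices
    label_names: tuple[str, ...] | None = None
    cluster_mask: np.ndarray | None = None
    null_summary: dict = field(default_factory=dict)

    def smoothed(self, sd_ms: float, fs: int | None = None) -> np.ndarray:
        step = np.diff(self.times_ms).mean() if len(self.times_ms) > 1 else 1.0
        sd = max(sd_ms / step, 1e-9)
        return gaussian_filter1d(self.accuracy, sd)

    def peak_time_ms(self, sd_ms: float = 20.0) -> float:
        acc = self.smoothed(sd_ms)
        if np.allclose(acc, acc[0]):
            raise ValueError("flat accuracy curve: peak undefined")
        return float(self.times_ms[int(np.argmax(acc))])


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _features_at(data: np.ndarray, fs: int, t_ms: float) -> np.ndarray:
    """Per-trial sensor vector at one post-onset latency."""
    s = int(round(t_ms / 1000 * fs))
    s = min(max(s, 0), data.shape[2] - 1)
    return data[:, :, s]


def _fit_binary(X: np.ndarray, y: np.ndarray, cfg: DecodingConfig) -> tuple[np.ndarray, float]:
    """L1 logistic fit; falls back to an intercept-only model if one class."""
    if len(np.unique(y)) < 2:
        p = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
        return np.zeros(X.shape[1]), float(np.log(p / (1 - p)))
    clf = LogisticRegression(
        l1_ratio=1.0, C=cfg.C, solver="liblinear", max_iter=cfg.max_iter,
        random_state=0,
    )
    clf.fit(X, y)
    return clf.coef_[0].copy(), float(clf.intercept_[0])


def _null_features(
    data: np.ndarray, fs: int, cfg: DecodingConfig
) -> np.ndarray | None:
    """Late post-stimulus samples used as shared negative examples."""
    if not cfg.null_negatives:
        return None
    if cfg.null_time_ms is None:
        return data[:, :, -1]
    return _features_at(data, fs, cfg.null_time_ms)


def _fit_binary_with_null(
    X: np.ndarray, y: np.ndarray, cfg: DecodingConfig, X_null: np.ndarray | None
) -> tuple[np.ndarray, float]:
    if X_null is not None:
        X = np.vstack([X, X_null])
        y = np.concatenate([y, np.zeros(len(X_null), dtype=y.dtype)])
    return _fit_binary(X, y, cfg)


def _cv_folds(
    y: np.ndarray, cv: str | int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Class-stratified cross-validation folds.

    ``"loo"`` holds out one trial of every class per fold (so training sets
    stay class-balanced and each trial is tested exactly once); an integer
    gives that many stratified folds.
    """
    classes = np.unique(y)
    per_class = [rng.permutation(np.flatnonzero(y == c)) for c in classes]
    if cv == "loo":
        k = max(len(p) for p in per_class)
    else:
        k = int(cv)
    folds = [
        np.concatenate([p[i::k] for p in per_class if len(p[i::k])])
        for i in range(k)
    ]
    return [f for f in folds if len(f)]


# ---------------------------------------------------------------------------
# localizer state decoding
# ---------------------------------------------------------------------------


def train_state_decoders(
    localizer: SensorTimeseries,
    states: str,
    cfg: DecodingConfig | None = None,
    seed: int = 0,
) -> tuple[DecoderSet, DecodingCurve]:
    """Train per-state binomial classifiers with leave-one-out evaluation.

    ``states='objects'``: one-vs-rest classifiers over the 12 objects — for
    each object, all its trials but the held-out one are positives and every
    other object's trials are negatives; accuracy is the fraction of
    held-out trials whose argmax probability names the true object (chance
    1/12).  ``states='face_attributes'``: pairwise classifiers per binary
    attribute (one value's trials against the other's; chance 1/2).

    The returned :class:`DecoderSet` holds weights refit on all trials at
    the peak of the cross-validated accuracy curve.
    """
    cfg = cfg or DecodingConfig()
    rng = np.random.default_rng(seed)
    meta = localizer.trial_meta.reset_index(drop=True)
    if states == "objects":
        sel = np.flatnonzero(meta["kind"].isin(["object", "operation"]))
        if sel.size == 0:
            raise ValueError("localizer has no object trials")
        labels = meta.loc[sel, "state"].to_numpy()
        return _train_multiclass(localizer, sel, labels, cfg, rng, scheme="leave_one_out")
    if states == "face_attributes":
        sel = np.flatnonzero(meta["kind"] == "face")
        if sel.size == 0:
            raise ValueError("localizer has no face trials")
        return _train_face_attributes(localizer, sel, meta, cfg, rng)
    raise ValueError(f"unknown states {states!r}")


def _train_multiclass(
    localizer: SensorTimeseries,
    sel: np.ndarray,
    labels: np.ndarray,
    cfg: DecodingConfig,
    rng: np.random.Generator,
    scheme: str,
) -> tuple[DecoderSet, DecodingCurve]:
    data = localizer.stacked()[sel]
    names = tuple(sorted(set(labels)))
    y = np.array([names.index(l) for l in labels])
    n = len(y)
    folds = _cv_folds(y, cfg.cv, rng)
    times = np.asarray(cfg.time_grid_ms)
    preds = np.zeros((n, len(times)), dtype=int)
    for ti, t in enumerate(times):
        X = _features_at(data, localizer.fs, t)
        for test in folds:
            train = np.setdiff1d(np.arange(n), test)
            scores = np.zeros((len(test), len(names)))
            for si, _ in enumerate(names):
                w, b = _fit_binary(X[train], (y[train] == si).astype(int), cfg)
                scores[:, si] = X[test] @ w + b
            preds[test, ti] = np.argmax(scores, axis=1)
    acc = (preds == y[:, None]).mean(axis=0)
    curve = DecodingCurve(
        times_ms=times,
        accuracy=acc,
        chance=1.0 / len(names),
        predictions=preds,
        true_labels=y,
        label_names=names,
    )
    try:
        peak = curve.peak_time_ms(cfg.smoothing_sd_ms)
    except ValueError:
        peak = float(times[len(times) // 2])
    Xp = _features_at(data, localizer.fs, peak)
    classifiers = {}
    for si, name in enumerate(names):
        w, b = _fit_binary(Xp, (y == si).astype(int), cfg)
        classifiers[name] = ClassifierWeights(name, w, b, peak, scheme)
    return DecoderSet(classifiers, localizer.fs, scheme), curve


def _train_face_attributes(
    localizer: SensorTimeseries,
    sel: np.ndarray,
    meta: pd.DataFrame,
    cfg: DecodingConfig,
    rng: np.random.Generator,
) -> tuple[DecoderSet, DecodingCurve]:
    data = localizer.stacked()[sel]
    faces = meta.loc[sel, "state"].to_numpy()
    # value per attribute for each face trial
    values = {a: np.array([f.split("-")[i] for f in faces]) for i, a in enumerate(ATTRIBUTES)}
    n = len(faces)
    times = np.asarray(cfg.time_grid_ms)
    face_ids = np.unique(faces, return_inverse=True)[1]
    folds = _cv_folds(face_ids, cfg.cv, rng)
    X_null = _null_features(data, localizer.fs, cfg)
    correct = np.zeros((n, len(times)))
    for ti, t in enumerate(times):
        X = _features_at(data, localizer.fs, t)
        for test in folds:
            train = np.setdiff1d(np.arange(n), test)
            nul = X_null[train] if X_null is not None else None
            hits = np.zeros(len(test))
            for attr in ATTRIBUTES:
                v0, v1 = ATTRIBUTE_VALUES[attr]
                ybin = (values[attr] == v0).astype(int)
                w0, b0 = _fit_binary_with_null(X[train], ybin[train], cfg, nul)
                w1, b1 = _fit_binary_with_null(X[train], 1 - ybin[train], cfg, nul)
                pred = (X[test] @ w0 + b0 > X[test] @ w1 + b1).astype(int)
                hits += pred == ybin[test]
            correct[test, ti] = hits / len(ATTRIBUTES)
    acc = correct.mean(axis=0)
    curve = DecodingCurve(times_ms=times, accuracy=acc, chance=BINARY_CHANCE)
    try:
        peak = curve.peak_time_ms(cfg.smoothing_sd_ms)
    except ValueError:
        peak = float(times[len(times) // 2])
    Xp = _features_at(data, localizer.fs, peak)
    classifiers = {}
    for attr in ATTRIBUTES:
        v0, v1 = ATTRIBUTE_VALUES[attr]
        ybin = (values[attr] == v0).astype(int)
        w0, b0 = _fit_binary_with_null(Xp, ybin, cfg, X_null)
        w1, b1 = _fit_binary_with_null(Xp, 1 - ybin, cfg, X_null)
        classifiers[v0] = ClassifierWeights(v0, w0, b0, peak, "leave_one_out")
        classifiers[v1] = ClassifierWeights(v1, w1, b1, peak, "leave_one_out")
    return DecoderSet(classifiers, localizer.fs, "leave_one_out"), curve


# ---------------------------------------------------------------------------
# abstract operation decoding (held-out objects)
# ---------------------------------------------------------------------------


def _abstract_folds(graph: TaskGraph, dimension: str) -> list[dict]:
    """Enumerate train/test partitions; test objects never occur in training."""
    objs_of_op = {}
    for loc in graph.locations:
        objs_of_op.setdefault(graph.op_of[loc].name, []).append(loc)
    folds = []
    if dimension == "type":
        for held in ATTRIBUTES:
            test = [l for l in graph.locations if graph.op_of[l].attribute == held]
            train = [l for l in graph.locations if graph.op_of[l].attribute != held]
            folds.append({"train": train, "test": test, "held": held})
    elif dimension == "attribute":
        for train_type in ("swap", "branch"):
            train = [l for l in graph.locations if graph.op_of[l].op_type == train_type]
            test = [l for l in graph.locations if graph.op_of[l].op_type != train_type]
            folds.append({"train": train, "test": test, "held": train_type})
    elif dimension == "compound":
        for which in (0, 1):
            train = [objs[which] for objs in objs_of_op.values()]
            test = [objs[1 - which] for objs in objs_of_op.values()]
            folds.append({"train": train, "test": test, "held": which})
    else:
        raise ValueError(f"unknown dimension {dimension!r}")
    for f in folds:
        if set(f["train"]) & set(f["test"]):
            raise AssertionError("train/test object overlap")
    return folds


def _dimension_label(graph: TaskGraph, loc: str, dimension: str) -> str:
    op = graph.op_of[loc]
    return {"type": op.op_type, "attribute": op.attribute, "compound": op.name}[dimension]


def train_abstract_decoders(
    op_localizer: SensorTimeseries,
    graph: TaskGraph,
    dimension: str,
    cfg: DecodingConfig | None = None,
    seed: int = 0,
) -> tuple[dict, DecodingCurve]:
    """Held-out-object decoding of abstract operation codes.

    type
        swap-vs-branch classifiers trained on two attributes' objects and
        tested on the remaining attribute's objects (chance 1/2).
    attribute
        shape/limb/hat classifiers trained on one operation type's objects
        and tested on the other type's (chance 1/3).
    compound
        per-operation classifiers trained on one of the operation's two
        objects and tested on the other (6-way argmax; chance 1/6).

    Returns per-fold classifier weights (at the peak training time) and the
    cross-validated accuracy curve over the candidate time grid.
    """
    cfg = cfg or DecodingConfig()
    for op_name, objs in _objects_by_operation(graph).items():
        if len(objs) != 2:
            raise ValueError(f"operation {op_name} must have exactly 2 objects")
    meta = op_localizer.trial_meta.reset_index(drop=True)
    data = op_localizer.stacked()
    obj = meta["state"].to_numpy()
    dim_label = np.array([_dimension_label(graph, l, dimension) for l in obj])
    names = tuple(sorted(set(dim_label)))
    y = np.array([names.index(l) for l in dim_label])
    folds = _abstract_folds(graph, dimension)
    times = np.asarray(cfg.time_grid_ms)

    test_rows: list[np.ndarray] = []
    for f in folds:
        test_rows.append(np.flatnonzero(np.isin(obj, f["test"])))
    n_test = sum(len(r) for r in test_rows)
    preds = np.zeros((n_test, len(times)), dtype=int)
    truth = np.concatenate([y[r] for r in test_rows])

    X_null = _null_features(data, op_localizer.fs, cfg)
    for ti, t in enumerate(times):
        X = _features_at(data, op_localizer.fs, t)
        ofs = 0
        for f, rows in zip(folds, test_rows):
            tr = np.flatnonzero(np.isin(obj, f["train"]))
            nul = X_null[tr] if X_null is not None else None
            scores = np.zeros((len(rows), len(names)))
            for si, _ in enumerate(names):
                w, b = _fit_binary_with_null(X[tr], (y[tr] == si).astype(int), cfg, nul)
                scores[:, si] = X[rows] @ w + b
            preds[ofs : ofs + len(rows), ti] = np.argmax(scores, axis=1)
            ofs += len(rows)
    acc = (preds == truth[:, None]).mean(axis=0)
    curve = DecodingCurve(
        times_ms=times,
        accuracy=acc,
        chance=1.0 / len(names),
        predictions=preds,
        true_labels=truth,
        label_names=names,
    )
    try:
        peak = curve.peak_time_ms(cfg.smoothing_sd_ms)
    except ValueError:
        peak = float(times[len(times) // 2])
    Xp = _features_at(data, op_localizer.fs, peak)
    weights: dict = {}
    for f in folds:
        tr = np.flatnonzero(np.isin(obj, f["train"]))
        nul = X_null[tr] if X_null is not None else None
        fold_clf = {}
        for si, name in enumerate(names):
            w, b = _fit_binary_with_null(Xp[tr], (y[tr] == si).astype(int), cfg, nul)
            fold_clf[name] = ClassifierWeights(name, w, b, peak, "held_out_object")
        weights[f["held"]] = fold_clf
    return weights, curve


def _objects_by_operation(graph: TaskGraph) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for loc in graph.locations:
        out.setdefault(graph.op_of[loc].name, []).append(loc)
    return out


def compound_decoders_by_object(
    op_localizer: SensorTimeseries,
    graph: TaskGraph,
    cfg: DecodingConfig | None = None,
    train_time_ms: float | None = None,
) -> dict[str, ClassifierWeights]:
    """Per-object compound-operation classifiers for cross-object transfer.

    The classifier stored under object A is trained with A's trials as
    positives; when scoring a reasoning trial whose path contains A's
    operation partner B, A's weights are used — so operation reactivation
    probabilities never rely on the on-path object's own trials.
    """
    cfg = cfg or DecodingConfig()
    meta = op_localizer.trial_meta.reset_index(drop=True)
    data = op_localizer.stacked()
    obj = meta["state"].to_numpy()
    t = train_time_ms if train_time_ms is not None else float(np.median(cfg.time_grid_ms))
    X = _features_at(data, op_localizer.fs, t)
    X_null = _null_features(data, op_localizer.fs, cfg)
    out = {}
    for loc in graph.locations:
        ybin = (obj == loc).astype(int)
        w, b = _fit_binary_with_null(X, ybin, cfg, X_null)
        out[loc] = ClassifierWeights(graph.op_of[loc].name, w, b, t, "held_out_object_pairwise")
    return out


def exclusion_decoders(
    op_localizer: SensorTimeseries,
    graph: TaskGraph,
    dimension: str,
    exclude_objects: frozenset[str] | set[str],
    train_time_ms: float,
    cfg: DecodingConfig | None = None,
) -> DecoderSet:
    """Type/attribute classifiers trained with some objects held out.

    Used to decode operation codes during reasoning without contamination
    from the on-path objects' own visual patterns: every object on a
    trial's correct path is excluded from training, so the resulting series
    can only respond to object-invariant operation codes.
    """
    cfg = cfg or DecodingConfig()
    meta = op_localizer.trial_meta.reset_index(drop=True)
    data = op_localizer.stacked()
    obj = meta["state"].to_numpy()
    keep = ~np.isin(obj, list(exclude_objects))
    if not keep.any():
        raise ValueError("exclusion set covers every object")
    labels = np.array([_dimension_label(graph, l, dimension) for l in obj])
    names = tuple(sorted(set(labels)))
    X = _features_at(data, op_localizer.fs, train_time_ms)[keep]
    X_null = _null_features(data, op_localizer.fs, cfg)
    nul = X_null[keep] if X_null is not None else None
    y = labels[keep]
    classifiers = {}
    for name in names:
        w, b = _fit_binary_with_null(X, (y == name).astype(int), cfg, nul)
        classifiers[name] = ClassifierWeights(
            name, w, b, train_time_ms, "held_out_object"
        )
    return DecoderSet(classifiers, op_localizer.fs, "held_out_object")


def partner_object(graph: TaskGraph, location: str) -> str:
    """The other object sharing ``location``'s operation."""
    objs = _objects_by_operation(graph)[graph.op_of[location].name]
    return objs[0] if objs[1] == location else objs[1]


# ---------------------------------------------------------------------------
# applying decoders
# ---------------------------------------------------------------------------


@dataclass
class ReactivationMatrix:
    """Per-trial (samples x states) posterior reactivation probabilities."""

    trials: list[np.ndarray]
    states: tuple[str, ...]
    fs: int
    trial_ids: tuple[int, ...] | None = None

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, state: str) -> int:
        return self.states.index(state)

    def series(self, trial: int, state: str) -> np.ndarray:
        return self.trials[trial][:, self.state_index(state)]

    def subset(self, states: Sequence[str]) -> "ReactivationMatrix":
        cols = [self.state_index(s) for s in states]
        return ReactivationMatrix(
            [t[:, cols] for t in self.trials], tuple(states), self.fs, self.trial_ids
        )

    @staticmethod
    def concat(parts: Sequence["ReactivationMatrix"]) -> "ReactivationMatrix":
        states = tuple(s for p in parts for s in p.states)
        trials = [
            np.hstack([p.trials[i] for p in parts])
            for i in range(len(parts[0].trials))
        ]
        return ReactivationMatrix(trials, states, parts[0].fs, parts[0].trial_ids)


def apply_decoders(decoders: DecoderSet, run: SensorTimeseries) -> ReactivationMatrix:
    """Sigmoid of each classifier's linear score at every sample."""
    W, b = decoders.weight_matrix()
    if W.shape[1] != run.n_sensors:
        raise ValueError(
            f"decoder expects {W.shape[1]} sensors, run has {run.n_sensors}"
        )
    out = []
    for data in run.trials:
        out.append(_sigmoid(data.T @ W.T + b))
    ids = None
    for col in ("trial", "trial_id"):
        if col in run.trial_meta.columns:
            ids = tuple(int(v) for v in run.trial_meta[col])
            break
    return ReactivationMatrix(out, decoders.states, run.fs, ids)


# ---------------------------------------------------------------------------
# significance
# ---------------------------------------------------------------------------


def accuracy_null_curves(
    curve: DecodingCurve, n_shuffles: int, seed: int
) -> np.ndarray:
    """Label-shuffle null accuracy curves from stored held-out predictions."""
    if curve.predictions is None:
        raise ValueError("curve carries no per-trial predictions")
    rng = np.random.default_rng(seed)
    y = curve.true_labels
    null = np.zeros((n_shuffles, len(curve.times_ms)))
    for s in range(n_shuffles):
        ys = rng.permutation(y)
        null[s] = (curve.predictions == ys[:, None]).mean(axis=0)
    return null


def decoding_significance(
    curves: Sequence[DecodingCurve],
    n_shuffles: int = 1000,
    percentile: float = 97.5,
    seed: int = 0,
) -> np.ndarray:
    """Group-level mass-corrected cluster mask for above-chance decoding.

    Per participant, a label-shuffle null accuracy curve is built from the
    held-out predictions; shuffle curves are averaged across participants
    and clusters of the group-mean observed curve are thresholded at the
    requested percentile of the max-cluster-mass null.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    chance = curves[0].chance
    group = np.mean([c.accuracy for c in curves], axis=0)
    nulls = np.mean(
        [accuracy_null_curves(c, n_shuffles, seed + i) for i, c in enumerate(curves)],
        axis=0,
    )
    return cluster_mass_mask(group - chance, nulls - chance, percentile=percentile)


def confusion_at_peak(curve: DecodingCurve, sd_ms: float = 20.0) -> pd.DataFrame:
    """Row-normalized confusion matrix of held-out predictions at the peak."""
    if curve.predictions is None:
        raise ValueError("curve carries no per-trial predictions")
    peak_idx = int(np.argmax(curve.smoothed(sd_ms)))
    names = curve.label_names
    k = len(names)
    mat = np.zeros((k, k))
    for yt, yp in zip(curve.true_labels, curve.predictions[:, peak_idx]):
        mat[yt, yp] += 1
    rowsum = mat.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    return pd.DataFrame(mat / rowsum, index=list(names), columns=list(names))


def peak_latency_order(
    curves_per_participant: Sequence[Mapping[str, DecodingCurve]],
    order: Sequence[str] = ("location", "type", "attribute"),
    n_shuffles: int = 1000,
    sd_ms: float = 20.0,
    seed: int = 0,
) -> dict:
    """Proportion of participants whose peak latencies follow ``order``.

    The observed proportion is compared against the 97.5th percentile of a
    null in which the dimension labels of each participant's three peak
    latencies are shuffled (a random ordering is correct 1/6 of the time).
    """
    rng = np.random.default_rng(seed)
    lat = np.array(
        [
            [d[dim].peak_time_ms(sd_ms) for dim in order]
            for d in curves_per_participant
        ]
    )
    observed = float(np.mean(np.all(np.diff(lat, axis=1) > 0, axis=1)))
    null = np.zeros(n_shuffles)
    for s in range(n_shuffles):
        perm = np.stack([p[rng.permutation(len(order))] for p in lat])
        null[s] = np.mean(np.all(np.diff(perm, axis=1) > 0, axis=1))
    return {
        "proportion": observed,
        "null_975": float(np.percentile(null, 97.5)),
        "null_mean": float(null.mean()),
        "significant": observed > float(np.percentile(null, 97.5)),
    }
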