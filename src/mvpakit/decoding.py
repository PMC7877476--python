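"""Cross-validated linear-SVM decoding per searchlight.

The decoder follows a strict leave-one-run-out protocol.  In each outer fold
the training rows are z-scored per voxel, clipped to [-3, +3], the SVM cost
is selected by an inner leave-one-run-out grid search over the training runs
(ties go to the smallest cost), and a linear-kernel SVM (one-vs-one
multiclass) predicts the held-out run.  Test rows are scaled with the
training-fold parameters, never their own.  Accuracy is pooled correct /
total over all folds.

Chance level for imbalanced designs is the frequency-proportional guessing
rate sum(p_i^2): 0.25 for the 4 x 18 categories and 504/5184 = 9.72% for the
11 subcategories (ten of 6, one of 12).  Subcategory decoding uses per-class
misclassification cost weights proportional to inverse class frequency,
normalized to mean 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .searchlight import SphereSpec, iterate_centers, extract_features

__all__ = [
    "DecodingConfig",
    "DecodingResult",
    "AccuracyMap",
    "chance_level",
    "fit_scaler",
    "apply_scaler",
    "class_cost_weights",
    "select_cost",
    "cv_accuracy",
    "decode_whole_brain",
]


@dataclass(frozen=True)
class DecodingConfig:
    costs: tuple[float, ...] = (0.1, 1.0, 10.0)
    clip: tuple[float, float] = (-3.0, 3.0)
    class_weighted: bool = False  # on for subcategory decoding
    level: str = "category"  # category | subcategory

    def __post_init__(self):
        if any(c <= 0 for c in self.costs):
            raise ValueError("costs must be positive")
        lo, hi = self.clip
        if not (lo < 0 < hi):
            raise ValueError("clip bounds must straddle zero")

    @staticmethod
    def for_level(level: str, **kw) -> "DecodingConfig":
        return DecodingConfig(level=level,
                              class_weighted=(level == "subcategory"), **kw)


@dataclass
class DecodingResult:
    accuracy: float
    chance: float
    fold_accuracies: list[float]
    selected_costs: list[float]
    confusion: dict[tuple[str, str], int]  # (true, predicted) -> count


@dataclass
class AccuracyMap:
    data: np.ndarray  # 3-D, NaN outside mask
    mask: np.ndarray
    chance: float
    level: str
    subject_id: str = ""

    @property
    def values(self) -> np.ndarray:
        return self.data[self.mask]


def chance_level(class_counts) -> float:
    """Expected accuracy of frequency-proportional random guessing: sum p_i^2."""
    counts = np.asarray(list(class_counts), dtype=float)
    if counts.size == 0 or np.any(counts <= 0):
        raise ValueError("class counts must be positive and nonempty")
    p = counts / counts.sum()
    return float(np.sum(p ** 2))


@dataclass(frozen=True)
class Scaler:
    mean: np.ndarray
    sd: np.ndarray
    clip: tuple[float, float] = (-3.0, 3.0)


def fit_scaler(train: np.ndarray, clip=(-3.0, 3.0)) -> Scaler:
    """Per-voxel z-scoring parameters estimated on training rows only."""
    if train.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    return Scaler(mean=train.mean(axis=0), sd=train.std(axis=0, ddof=0),
                  clip=tuple(clip))


def apply_scaler(scaler: Scaler, X: np.ndarray) -> np.ndarray:
    """Z-score with the training parameters, then clip to the cutoff bounds.

    Zero-variance (constant) training voxels map to 0 everywhere.
    """
    sd = np.where(scaler.sd == 0, 1.0, scaler.sd)
    Z = (X - scaler.mean) / sd
    Z[:, scaler.sd == 0] = 0.0
    return np.clip(Z, scaler.clip[0], scaler.clip[1])


def class_cost_weights(labels) -> dict:
    """Per-class misclassification cost weights, inverse to class frequency,
    normalized so the weights average to 1."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to weight")
    w = 1.0 / counts
    w *= len(w) / w.sum()
    return dict(zip(classes.tolist(), w.tolist()))


def _make_svm(cost: float, config: DecodingConfig,
              train_labels: np.ndarray | None = None) -> SVC:
    cw = None
    if config.class_weighted:
        if train_labels is None:
            raise ValueError("class weighting requires training labels")
        cw = class_cost_weights(train_labels)
    return SVC(C=cost, kernel="linear", class_weight=cw)


def _fit_predict(train_X, train_y, test_X, cost, config) -> np.ndarray:
    clf = _make_svm(cost, config, train_y)
    clf.fit(train_X, train_y)
    return clf.predict(test_X)


def select_cost(train_X: np.ndarray, train_y: np.ndarray,
                train_runs: np.ndarray, config: DecodingConfig) -> float:
    """Inner leave-one-run-out grid search over the cost candidates.

    Returns the candidate with the highest inner accuracy; exact ties go to
    the smallest cost.  With a single candidate no inner CV is run.
    """
    if len(config.costs) == 1:
        return config.costs[0]
    inner_runs = np.unique(train_runs)
    if len(inner_runs) < 2:
        raise ValueError("nested cost selection needs >= 2 training runs")
    n_correct = {c: 0 for c in config.costs}
    for held in inner_runs:
        tr = train_runs != held
        te = ~tr
        scaler = fit_scaler(train_X[tr], config.clip)
        Xtr = apply_scaler(scaler, train_X[tr])
        Xte = apply_scaler(scaler, train_X[te])
        for cost in config.costs:
            pred = _fit_predict(Xtr, train_y[tr], Xte, cost, config)
            n_correct[cost] += int((pred == train_y[te]).sum())
    best = max(n_correct.values())
    return min(c for c in config.costs if n_correct[c] == best)


def cv_accuracy(X: np.ndarray, y, runs, config: DecodingConfig | None = None
                ) -> DecodingResult:
    """Leave-one-run-out cross-validated decoding accuracy.

    Per outer fold: fit the scaler on training rows, scale and clip both
    partitions, select the cost by nested CV, train the SVM, predict the
    held-out run.  Accuracy is pooled over folds.
    """
    config = config or DecodingConfig()
    y = np.asarray(y)
    runs = np.asarray(runs)
    run_ids = np.unique(runs)
    if len(run_ids) < 2:
        raise ValueError("need at least 2 runs for cross-validation")
    classes = np.unique(y)
    fold_acc, costs_used = [], []
    confusion: dict[tuple[str, str], int] = {}
    n_correct = 0
    for held in run_ids:
        te = runs == held
        tr = ~te
        missing = set(classes) - set(y[tr])
        if missing:
            raise ValueError(
                f"fold holding out run {held}: classes missing from "
                f"training partition: {sorted(missing)}")
        scaler = fit_scaler(X[tr], config.clip)
        Xtr = apply_scaler(scaler, X[tr])
        Xte = apply_scaler(scaler, X[te])
        cost = select_cost(X[tr], y[tr], runs[tr], config)
        pred = _fit_predict(Xtr, y[tr], Xte, cost, config)
        correct = int((pred == y[te]).sum())
        n_correct += correct
        fold_acc.append(correct / te.sum())
        costs_used.append(cost)
        for t, p in zip(y[te], pred):
            confusion[(t, p)] = confusion.get((t, p), 0) + 1
    counts = [int((y == c).sum()) for c in classes]
    return DecodingResult(
        accuracy=n_correct / len(y),
        chance=chance_level(counts),
        fold_accuracies=fold_acc,
        selected_costs=costs_used,
        confusion=confusion)


def decode_whole_brain(betas, spec: SphereSpec | None = None,
                       config: DecodingConfig | None = None,
                       subject_id: str = "") -> AccuracyMap:
    """Run cv_accuracy at every in-mask searchlight center.

    The result is independent of center evaluation order; per-center errors
    are re-raised with the offending center's coordinates.
    """
    import sklearn

    spec = spec or SphereSpec()
    config = config or DecodingConfig()
    labels = betas.labels(config.level)
    # integer label codes keep per-center sklearn overhead low
    _, y = np.unique(labels, return_inverse=True)
    runs = betas.run_labels
    out = np.full(betas.mask.shape, np.nan)
    chance = None
    with sklearn.config_context(assume_finite=True):
        for center in iterate_centers(betas.mask):
            X = extract_features(betas, center, spec)
            try:
                res = cv_accuracy(X, y, runs, config)
            except Exception as exc:
                raise RuntimeError(
                    f"decoding failed at center "
                    f"{tuple(int(c) for c in center)}: {exc}") from exc
            out[tuple(center)] = res.accuracy
            chance = res.chance
    return AccuracyMap(data=out, mask=betas.mask, chance=chance,
                       level=config.level, subject_id=subject_id)
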