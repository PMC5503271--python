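"""SVM classification and the repeated cross-validation evaluation protocol.

The classifier is a kernel SVM whose decision function is the usual
support-vector expansion f(x) = Σ y_i α_i K(x, x_i) + b, extended to the
four motion classes by one-vs-one voting. Features are standardized with
training-fold statistics only, and the RBF width defaults to the median
heuristic on pairwise training distances.

Evaluation follows the pooled multi-subject protocol: the 260 trials are
randomly shuffled, split into five stratified folds (each fold once the 20%
test set against the 80% train set), and the whole procedure is repeated
fifty times with fresh shuffles; the reported accuracy is the mean ± SD
over all 250 fold accuracies. Feature-set comparisons reuse identical fold
partitions across sets so the comparison is paired.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import (
    ConfigurationError,
    DegenerateDataError,
    ParameterError,
    StratificationError,
    ValidationError,
)
from .features import FEATURE_SETS, extract_features
from .types import Dataset, FeatureVector, feature_matrix

DEFAULT_C_GRID = tuple(2.0**k for k in range(-3, 10))


@dataclass
class ClassifierSpec:
    """Kernel SVM settings.

    ``gamma="median"`` sets the RBF width from the median pairwise distance
    of the standardized training features (γ = 1 / (2·median²)). ``epsilon``
    is the SVR tube radius, kept for completeness; the classifier never
    uses it.
    """

    kernel: str = "rbf"
    C: float = 1.0
    gamma: float | str = "median"
    degree: int = 3  # polynomial order p
    coef0: float = 1.0  # polynomial offset h
    epsilon: float = 0.1  # unused by classification
    multiclass_scheme: str = "one-vs-one"
    standardize: bool = True

    def __post_init__(self):
        if self.C <= 0:
            raise ParameterError(f"C must be positive, got {self.C}")
        if self.kernel not in ("rbf", "polynomial", "linear"):
            raise ParameterError(f"unknown kernel {self.kernel!r}")
        if self.multiclass_scheme != "one-vs-one":
            raise ParameterError("only one-vs-one multiclass is supported")


@dataclass
class GroupStatsResult:
    """Outcome of a group-comparison test (one-way ANOVA or paired t)."""

    statistic: float
    pvalue: float
    groups: tuple[str, ...]
    test: str

    def __post_init__(self):
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValidationError(f"p-value outside [0, 1]: {self.pvalue}")


class FittedModel:
    """A trained one-vs-one kernel SVM with its training-fold scaling."""

    def __init__(self, svc: SVC, mean: np.ndarray, scale: np.ndarray,
                 names: tuple[str, ...], classes: np.ndarray):
        self._svc = svc
        self._mean = mean
        self._scale = scale
        self.feature_names = names
        self.classes = classes

    @property
    def n_support(self) -> int:
        return int(self._svc.n_support_.sum())

    def _prepare(self, X) -> np.ndarray:
        if isinstance(X, (list, tuple, Dataset)) and len(X) and isinstance(X[0], FeatureVector):
            X, _, _ = feature_matrix(list(X), names=self.feature_names)
        X = np.asarray(X, dtype=float)
        return (X - self._mean) / self._scale

    def predict(self, X) -> np.ndarray:
        return self._svc.predict(self._prepare(X))

    def decision_function(self, X) -> np.ndarray:
        return self._svc.decision_function(self._prepare(X))

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


def _median_gamma(Xs: np.ndarray, max_rows: int = 500) -> float:
    rows = Xs if Xs.shape[0] <= max_rows else Xs[:: int(np.ceil(Xs.shape[0] / max_rows))]
    d = pdist(rows)
    m = float(np.median(d[d > 0])) if np.any(d > 0) else 0.0
    if m == 0.0:
        return 1.0 / max(Xs.shape[1], 1)
    return 1.0 / (2.0 * m * m)


def _fit_xy(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec,
            names: tuple[str, ...] = ()) -> FittedModel:
    classes = np.unique(y)
    if classes.size < 2:
        raise DegenerateDataError("training data contains a single class")
    if spec.standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
    else:
        mean = np.zeros(X.shape[1])
        scale = np.ones(X.shape[1])
    Xs = (X - mean) / scale
    gamma = spec.gamma
    if gamma == "median":
        gamma = _median_gamma(Xs)
    kernel = {"rbf": "rbf", "polynomial": "poly", "linear": "linear"}[spec.kernel]
    svc = SVC(kernel=kernel, C=spec.C, gamma=gamma, degree=spec.degree,
              coef0=spec.coef0, decision_function_shape="ovo")
    svc.fit(Xs, y)
    return FittedModel(svc, mean, scale, names, classes)


def fit_svm(train: Sequence[FeatureVector] | Dataset,
            spec: ClassifierSpec | None = None) -> FittedModel:
    """Train the one-vs-one kernel SVM on labelled feature vectors."""
    spec = spec or ClassifierSpec()
    X, y, names = feature_matrix(train)
    return _fit_xy(X, y, spec, names)


def select_C(
    train: Sequence[FeatureVector] | Dataset,
    spec: ClassifierSpec | None = None,
    grid: Sequence[float] = DEFAULT_C_GRID,
    seed: int = 0,
    n_folds: int = 5,
) -> float:
    """Pick the regularization constant by inner stratified 5-fold CV.

    Returns the grid member with the highest mean inner-CV accuracy; ties
    break toward the smallest C.
    """
    spec = spec or ClassifierSpec()
    grid = sorted(grid)
    if not grid:
        raise ParameterError("C grid must be non-empty")
    if any(c <= 0 for c in grid):
        raise ParameterError("C grid values must all be positive")
    X, y, _ = feature_matrix(train)
    _check_fold_feasible(y, n_folds)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=int(seed) % (2**31))
    splits = list(skf.split(X, y))
    best_c, best_acc = grid[0], -1.0
    for c in grid:
        cspec = ClassifierSpec(
            kernel=spec.kernel, C=c, gamma=spec.gamma, degree=spec.degree,
            coef0=spec.coef0, standardize=spec.standardize,
        )
        accs = []
        for tr, te in splits:
            model = _fit_xy(X[tr], y[tr], cspec)
            accs.append(np.mean(model.predict(X[te]) == y[te]))
        acc = float(np.mean(accs))
        if acc > best_acc:  # strict: ties keep the smaller C
            best_acc, best_c = acc, c
    return best_c


@dataclass
class CvReport:
    """Per-repeat, per-fold accuracies from repeated k-fold CV.

    ``fold_ids[r, i]`` is the fold index of sample ``i`` in repeat ``r``,
    so paired comparisons can verify identical partitions.
    """

    feature_set_name: str
    accuracies: np.ndarray  # shape (n_repeats, n_folds), fractions in [0, 1]
    fold_ids: np.ndarray  # shape (n_repeats, n_samples)
    n_repeats: int
    n_folds: int
    selected_C: float | None = None

    def __post_init__(self):
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        if self.accuracies.shape != (self.n_repeats, self.n_folds):
            raise ValidationError("accuracy matrix shape mismatch")
        if np.any((self.accuracies < 0) | (self.accuracies > 1)):
            raise ValidationError("accuracies must lie in [0, 1]")

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def std_accuracy(self) -> float:
        return float(self.accuracies.std(ddof=0))

    def summary(self) -> str:
        return (
            f"{self.feature_set_name}: "
            f"{100 * self.mean_accuracy:.2f}% ± {100 * self.std_accuracy:.2f}% "
            f"({self.n_repeats}×{self.n_folds}-fold CV)"
        )


def _check_fold_feasible(y: np.ndarray, n_folds: int) -> None:
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise StratificationError(
            f"smallest class has {counts.min()} members; need ≥ {n_folds} for "
            f"{n_folds}-fold stratified CV"
        )


def _repeat_seeds(seed: int, n_repeats: int) -> list[int]:
    root = np.random.SeedSequence(int(seed))
    return [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n_repeats)]


def repeated_cv(
    data: Sequence[FeatureVector] | Dataset,
    spec: ClassifierSpec | None = None,
    n_folds: int = 5,
    n_repeats: int = 50,
    seed: int = 0,
    feature_set_name: str = "features",
) -> CvReport:
    """Repeated stratified k-fold cross-validation of the SVM.

    Each repeat reshuffles with a seed derived from ``seed`` and the repeat
    index, partitions into ``n_folds`` stratified folds, and tests each
    fold against a model trained on the rest. Fully deterministic under
    ``seed``.
    """
    spec = spec or ClassifierSpec()
    X, y, _ = feature_matrix(data)
    _check_fold_feasible(y, n_folds)
    accuracies = np.zeros((n_repeats, n_folds))
    fold_ids = np.zeros((n_repeats, X.shape[0]), dtype=np.int32)
    for r, rs in enumerate(_repeat_seeds(seed, n_repeats)):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rs)
        for f, (tr, te) in enumerate(skf.split(X, y)):
            fold_ids[r, te] = f
            model = _fit_xy(X[tr], y[tr], spec)
            accuracies[r, f] = np.mean(model.predict(X[te]) == y[te])
    return CvReport(
        feature_set_name=feature_set_name,
        accuracies=accuracies,
        fold_ids=fold_ids,
        n_repeats=n_repeats,
        n_folds=n_folds,
        selected_C=spec.C,
    )


def compare_feature_sets(
    segments: Sequence | Dataset,
    fs: float = 1000.0,
    sets: Mapping[str, Sequence[str]] | Sequence[str] | None = None,
    spec: ClassifierSpec | None = None,
    seed: int = 0,
    n_folds: int = 5,
    n_repeats: int = 50,
    c_grid: Sequence[float] | None = None,
    svd_mode: str = "per-band",
) -> list[CvReport]:
    """Evaluate several feature-set configurations under identical folds.

    ``sets`` is either a list of registered set names (``time``, ``freq``,
    ``timefreq``, ``wtsvd``, ``all``) or a mapping of custom names to
    feature tuples. When ``c_grid`` is given, C is selected once per set by
    inner 5-fold CV before the repeated evaluation. Because every set sees
    the same labels in the same order and the same seed, fold partitions
    are identical across sets (a paired design).
    """
    spec = spec or ClassifierSpec()
    if sets is None:
        sets = list(FEATURE_SETS)
    if not isinstance(sets, Mapping):
        sets = {name: FEATURE_SETS[name] if name in FEATURE_SETS else None
                for name in sets}
        unknown = [k for k, v in sets.items() if v is None]
        if unknown:
            raise ConfigurationError(f"unknown feature set name(s): {unknown}")
    reports = []
    for name, feat_names in sets.items():
        vectors = extract_features(segments, feat_names, fs=fs, svd_mode=svd_mode)
        set_spec = spec
        if c_grid is not None:
            c = select_C(vectors, spec, grid=c_grid, seed=seed)
            set_spec = ClassifierSpec(
                kernel=spec.kernel, C=c, gamma=spec.gamma, degree=spec.degree,
                coef0=spec.coef0, standardize=spec.standardize,
            )
        reports.append(
            repeated_cv(vectors, set_spec, n_folds=n_folds, n_repeats=n_repeats,
                        seed=seed, feature_set_name=name)
        )
    return reports


def anova_by_motion(
    features: Sequence[FeatureVector], feature_name: str
) -> GroupStatsResult:
    """One-way ANOVA of one feature across the motion classes."""
    groups: dict[str, list[float]] = {}
    for v in features:
        if feature_name not in v.names:
            raise ConfigurationError(
                f"feature {feature_name!r} absent from vector with names {v.names}"
            )
        groups.setdefault(v.label, []).append(v.as_dict()[feature_name])
    arrays = {k: np.asarray(g) for k, g in groups.items() if len(g) >= 2}
    if len(arrays) < 2:
        raise DegenerateDataError("need ≥ 2 groups with ≥ 2 members each")
    if all(np.var(a) == 0 for a in arrays.values()):
        raise DegenerateDataError("zero within-group variance in every group")
    f, p = stats.f_oneway(*arrays.values())
    return GroupStatsResult(
        statistic=float(f), pvalue=float(p),
        groups=tuple(arrays), test="one-way-anova",
    )


def paired_ttest(a: Sequence[float], b: Sequence[float]) -> GroupStatsResult:
    """Two-sided paired t-test between two matched measurement sequences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 2:
        raise ValidationError("paired t-test needs at least two pairs")
    d = a - b
    if np.all(d == d[0]):
        if d[0] == 0:
            return GroupStatsResult(0.0, 1.0, ("a", "b"), "paired-t")
        raise DegenerateDataError("constant nonzero difference: variance is zero")
    t, p = stats.ttest_rel(a, b)
    return GroupStatsResult(float(t), float(p), ("a", "b"), "paired-t")
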