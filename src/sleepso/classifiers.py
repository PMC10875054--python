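"""Feature-based and sequence classification of candidate SO events.

Two routes from a candidate waveform to an SO / non-SO decision:

* a 17-value feature vector (durations, peak counts, amplitudes, moments,
  area, slope, crossings, energy) fed to a classical model — logistic
  regression, decision tree, random forest, SVM, or a small MLP — optionally
  after feature selection (univariate scoring, model-based importance,
  recursive feature elimination, or PCA);
* the raw waveform, either through DTW distances to a prototype set chosen
  by average-linkage hierarchical clustering (DTW feature construction), or
  end-to-end through the :class:`~sleepso.bilstm.BiLSTMClassifier`, or via
  budgeted DTW-1NN over the time-series index.

The published list of 17 features is not machine-readable, so the registry
here is a documented, pluggable stand-in with the same cardinality: it can
be swapped without touching anything downstream.

Evaluation follows repeated stratified 70/30 splits with balanced accuracy
as the metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import clone
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE, SelectKBest, f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import GridSearchCV, StratifiedShuffleSplit
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .bilstm import BiLSTMClassifier
from .dtw_tsi import TSIConfig, build_tsi, dtw_distance, tsi_classify
from .events import EventMorphology, count_positive_peaks
from .exceptions import DegenerateEventError, ParameterError, ValidationError

#: Names and order of the 17-feature registry (units in comments).
FEATURE_NAMES = (
    "d_total",             # s
    "d_to_negpeak",        # s
    "d_neg_to_pospeak",    # s
    "d_pospeak_to_end",    # s
    "n_pos_peaks",         # count
    "n_neg_peaks",         # count
    "neg_peak_uV",         # µV
    "pos_peak_uV",         # µV
    "p2p_amplitude_uV",    # µV
    "mean_uV",             # µV
    "sd_uV",               # µV
    "skewness",            # dimensionless
    "kurtosis",            # dimensionless (excess)
    "neg_halfwave_area",   # µV·s (magnitude)
    "slope_neg_to_pos",    # µV/s
    "n_zero_crossings",    # count (sign changes within the event)
    "energy",              # µV²·s
)

MODEL_KINDS = ("logreg", "dtree", "rf", "svm", "mlp", "bilstm", "dtw1nn")
SELECTION_METHODS = ("univariate", "importance", "rfe", "pca", "none")


def compute_features(morphology: EventMorphology, waveform) -> np.ndarray:
    """Deterministic 17-vector for one event.

    Durations and peak amplitudes come from the morphology; distributional
    and integral features are computed on the waveform using the effective
    sampling rate ``len(waveform) / d_total`` (so resampled waveforms remain
    consistent).
    """
    w = np.asarray(waveform, dtype=np.float64).ravel()
    if w.size < 3:
        raise DegenerateEventError("waveform too short for feature computation")
    m = morphology
    fs_eff = w.size / m.d_total
    neg_part = np.minimum(w, 0.0)
    sd = float(w.std())
    if sd > 0:
        skew = float(sstats.skew(w))
        kurt = float(sstats.kurtosis(w))
    else:
        skew = kurt = 0.0
    n_neg_peaks = count_positive_peaks(-w)
    slope = (
        m.p2p_amplitude_uV / m.d_neg_to_pospeak if m.d_neg_to_pospeak > 0 else 0.0
    )
    signs = np.sign(w)
    nz = signs != 0
    crossings = int(np.sum(np.abs(np.diff(signs[nz])) == 2))
    vec = np.array([
        m.d_total,
        m.d_to_negpeak,
        m.d_neg_to_pospeak,
        m.d_pospeak_to_end,
        float(m.n_pos_peaks),
        float(n_neg_peaks),
        m.neg_peak_uV,
        m.pos_peak_uV,
        m.p2p_amplitude_uV,
        float(w.mean()),
        sd,
        skew,
        kurt,
        float(np.abs(neg_part).sum() / fs_eff),
        slope,
        float(crossings),
        float(np.sum(w**2) / fs_eff),
    ])
    if not np.all(np.isfinite(vec)):
        raise ValidationError("non-finite feature value")
    return vec


def feature_matrix(morphologies, waveforms) -> np.ndarray:
    """Stack :func:`compute_features` over a corpus -> (n_events, 17)."""
    return np.vstack([
        compute_features(m, w) for m, w in zip(morphologies, waveforms)
    ])


# ---------------------------------------------------------------------------
# Feature selection
# ---------------------------------------------------------------------------

class _TopImportance:
    """Select the k features with the largest forest importances."""

    def __init__(self, k: int, seed: int):
        self.k, self.seed = k, seed

    def fit(self, X, y):
        forest = RandomForestClassifier(n_estimators=100, random_state=self.seed)
        forest.fit(X, y)
        order = np.argsort(-forest.feature_importances_, kind="stable")
        self.support_ = np.sort(order[:self.k])
        return self

    def transform(self, X):
        return np.asarray(X)[:, self.support_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)


class _Identity:
    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return np.asarray(X)

    def fit_transform(self, X, y=None):
        return np.asarray(X)


def select_features(X, y, method: str = "none", k: int | None = None, seed: int = 0):
    """Fit a feature-selection transformer on a training matrix.

    ``method`` is one of ``univariate`` (ANOVA F scoring), ``importance``
    (random-forest importances), ``rfe`` (recursive feature elimination with
    a random forest), ``pca``, or ``none``; ``k`` is the number of features
    or components kept (required unless ``none``).
    """
    X = np.asarray(X, dtype=np.float64)
    if method not in SELECTION_METHODS:
        raise ParameterError(f"unknown selection method {method!r}")
    if method == "none":
        return _Identity().fit(X, y)
    if k is None or not 1 <= k <= X.shape[1]:
        raise ParameterError(
            f"k must be in [1, {X.shape[1]}] for method {method!r}, got {k}"
        )
    if method == "univariate":
        sel = SelectKBest(f_classif, k=k)
    elif method == "importance":
        sel = _TopImportance(k=k, seed=seed)
    elif method == "rfe":
        sel = RFE(
            RandomForestClassifier(n_estimators=50, random_state=seed),
            n_features_to_select=k, step=1,
        )
    else:  # pca
        sel = Pipeline([
            ("scale", StandardScaler()),
            ("pca", PCA(n_components=k, random_state=seed)),
        ])
    sel.fit(X, y)
    return sel


# ---------------------------------------------------------------------------
# DTW feature construction
# ---------------------------------------------------------------------------

def dtw_prototypes(
    waveforms: list,
    n_prototypes: int = 500,
    window: int | None = None,
    linkage_method: str = "average",
) -> list[np.ndarray]:
    """Pick characteristic sequences by hierarchical clustering on DTW.

    The full pairwise DTW matrix is clustered (average linkage by default),
    the dendrogram is cut at ``n_prototypes`` clusters, and each cluster
    contributes its medoid (minimum summed within-cluster DTW distance).
    If the training set is not larger than ``n_prototypes``, every series is
    returned.
    """
    series = [np.asarray(w, dtype=np.float64).ravel() for w in waveforms]
    n = len(series)
    if n == 0:
        raise ParameterError("dtw_prototypes requires waveforms")
    if n <= n_prototypes:
        return [s.copy() for s in series]
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            w = window
            if w is not None:
                w = max(w, abs(series[i].size - series[j].size))
            dmat[i, j] = dmat[j, i] = dtw_distance(series[i], series[j], w)
    Z = linkage(squareform(dmat, checks=False), method=linkage_method)
    assignments = fcluster(Z, t=n_prototypes, criterion="maxclust")
    prototypes = []
    for cl in np.unique(assignments):
        members = np.flatnonzero(assignments == cl)
        sums = dmat[np.ix_(members, members)].sum(axis=1)
        prototypes.append(series[members[int(np.argmin(sums))]].copy())
    return prototypes


def dtw_feature_vector(waveform, prototypes: list, window: int | None = None) -> np.ndarray:
    """Vector of DTW distances from one waveform to every prototype."""
    if not prototypes:
        raise ParameterError("prototype set is empty")
    w = np.asarray(waveform, dtype=np.float64).ravel()
    out = np.empty(len(prototypes))
    for i, p in enumerate(prototypes):
        eff = window
        if eff is not None:
            eff = max(eff, abs(w.size - len(p)))
        out[i] = dtw_distance(w, p, eff)
    return out


def dtw_feature_matrix(waveforms, prototypes, window: int | None = None) -> np.ndarray:
    return np.vstack([dtw_feature_vector(w, prototypes, window) for w in waveforms])


# ---------------------------------------------------------------------------
# Model training
# ---------------------------------------------------------------------------

_DEFAULT_GRIDS = {
    "logreg": {"C": [0.1, 1.0, 10.0]},
    "dtree": {"max_depth": [3, 5, None]},
    "rf": {"n_estimators": [100], "max_depth": [None, 8]},
    "svm": {"C": [0.5, 5.0]},
    "mlp": {"alpha": [1e-4, 1e-2]},
}


def _base_estimator(model_kind: str, seed: int):
    if model_kind == "logreg":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if model_kind == "dtree":
        return DecisionTreeClassifier(random_state=seed)
    if model_kind == "rf":
        return RandomForestClassifier(random_state=seed)
    if model_kind == "svm":
        return SVC(random_state=seed)
    if model_kind == "mlp":
        return MLPClassifier(
            hidden_layer_sizes=(32,), max_iter=800, random_state=seed
        )
    raise ParameterError(f"unknown model kind {model_kind!r}")


@dataclass
class TrainedModel:
    """A fitted classifier plus the preprocessing it was trained with."""

    model_kind: str
    estimator: object
    selector: object | None = None
    scaler: object | None = None
    seed: int = 0
    metadata: dict = field(default_factory=dict)

    def _transform(self, X):
        X = np.asarray(X, dtype=np.float64)
        if self.scaler is not None:
            X = self.scaler.transform(X)
        if self.selector is not None:
            X = self.selector.transform(X)
        return X


def train_classifier(
    X,
    y,
    model_kind: str = "rf",
    hyper_grid: dict | None = None,
    seed: int = 0,
    selection: tuple[str, int] | None = None,
    cv: int = 3,
    bilstm_kwargs: dict | None = None,
) -> TrainedModel:
    """Fit one classifier, grid-searching its hyperparameters.

    For the classical kinds, ``X`` is a feature matrix; features are
    standardised, optionally reduced with ``selection=(method, k)``, and the
    model is grid-searched with stratified ``cv``-fold cross-validation on
    balanced accuracy.  For ``bilstm``, ``X`` is a list of waveforms and
    ``hyper_grid`` / ``selection`` are ignored.
    """
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValidationError("training labels contain a single class")
    if model_kind == "bilstm":
        clf = BiLSTMClassifier(seed=seed, **(bilstm_kwargs or {}))
        clf.fit(X, y)
        return TrainedModel(model_kind, clf, seed=seed,
                            metadata={"n_train": len(X)})
    if model_kind == "dtw1nn":
        raise ParameterError("use build_tsi/tsi_classify (or crossvalidate) for dtw1nn")
    X = np.asarray(X, dtype=np.float64)
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    selector = None
    if selection is not None:
        method, k = selection
        selector = select_features(Xs, y, method=method, k=k, seed=seed)
        Xs = selector.transform(Xs)
    grid = hyper_grid if hyper_grid is not None else _DEFAULT_GRIDS[model_kind]
    base = _base_estimator(model_kind, seed)
    if grid:
        search = GridSearchCV(base, grid, cv=cv, scoring="balanced_accuracy")
        search.fit(Xs, y)
        est = search.best_estimator_
        meta = {"best_params": search.best_params_}
    else:
        est = clone(base).fit(Xs, y)
        meta = {}
    meta.update(n_train=len(y), seed=seed)
    return TrainedModel(model_kind, est, selector=selector, scaler=scaler,
                        seed=seed, metadata=meta)


def predict(model: TrainedModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Labels and positive-class scores for new events.

    For probabilistic models the score is the probability of the
    lexicographically larger class; scores are in [0, 1].
    """
    if model.model_kind == "bilstm":
        clf = model.estimator
        return clf.predict(X), clf.predict_proba(X)
    Xt = model._transform(X)
    est = model.estimator
    labels = est.predict(Xt)
    if hasattr(est, "predict_proba"):
        scores = est.predict_proba(Xt)[:, -1]
    else:
        # margin-based models (SVM): squash the decision function to [0, 1]
        raw = est.decision_function(Xt)
        scores = 1.0 / (1.0 + np.exp(-raw))
    return labels, scores


# ---------------------------------------------------------------------------
# Repeated-split evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineSpec:
    """What to train and on which representation.

    ``model_kind`` selects the classifier; classical kinds consume the
    17-feature matrix (or DTW features when ``dtw_features`` is set),
    ``bilstm`` and ``dtw1nn`` consume raw waveforms.
    """

    model_kind: str = "rf"
    selection: tuple[str, int] | None = None
    hyper_grid: dict | None = None
    dtw_features: bool = False
    n_prototypes: int = 30
    dtw_window: int | None = None
    tsi_config: TSIConfig | None = None
    tsi_budget: int | None = None
    bilstm_kwargs: dict | None = None

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ParameterError(f"unknown model kind {self.model_kind!r}")


def _fit_predict_split(
    spec: PipelineSpec, X, waveforms, y, train_idx, test_idx, seed: int
) -> np.ndarray:
    y_train = y[train_idx]
    if spec.model_kind == "bilstm":
        model = train_classifier(
            [waveforms[i] for i in train_idx], y_train, "bilstm", seed=seed,
            bilstm_kwargs=spec.bilstm_kwargs,
        )
        labels, _ = predict(model, [waveforms[i] for i in test_idx])
        return labels
    if spec.model_kind == "dtw1nn":
        cfg = spec.tsi_config or TSIConfig(seed=seed)
        tree = build_tsi([waveforms[i] for i in train_idx], y_train, cfg)
        budget = spec.tsi_budget or cfg.budget
        return np.array([
            tsi_classify(tree, waveforms[i], budget)[0] for i in test_idx
        ])
    if spec.dtw_features:
        protos = dtw_prototypes(
            [waveforms[i] for i in train_idx], spec.n_prototypes, spec.dtw_window
        )
        X_train = dtw_feature_matrix(
            [waveforms[i] for i in train_idx], protos, spec.dtw_window
        )
        X_test = dtw_feature_matrix(
            [waveforms[i] for i in test_idx], protos, spec.dtw_window
        )
    else:
        X = np.asarray(X, dtype=np.float64)
        X_train, X_test = X[train_idx], X[test_idx]
    model = train_classifier(
        X_train, y_train, spec.model_kind, hyper_grid=spec.hyper_grid,
        seed=seed, selection=spec.selection,
    )
    labels, _ = predict(model, X_test)
    return labels


def crossvalidate(
    X,
    waveforms,
    labels,
    spec: PipelineSpec,
    n_repeats: int = 10,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[float, float, list[float]]:
    """Repeated stratified shuffle-split evaluation.

    Each repeat draws a fresh stratified ``train_fraction`` split, trains the
    pipeline from scratch, and scores balanced accuracy on the held-out part.
    Returns ``(mean, sd, per-repeat scores)``.
    """
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValidationError("need both classes present")
    n = len(y)
    if n < 10:
        raise ValidationError("too few events to split")
    splitter = StratifiedShuffleSplit(
        n_splits=n_repeats, train_size=train_fraction, random_state=seed
    )
    scores = []
    for rep, (train_idx, test_idx) in enumerate(splitter.split(np.zeros(n), y)):
        pred = _fit_predict_split(spec, X, waveforms, y, train_idx, test_idx,
                                  seed=seed + rep)
        scores.append(float(balanced_accuracy_score(y[test_idx], pred)))
    arr = np.asarray(scores)
    return float(arr.mean()), float(arr.std()), scores


def learning_curve(
    X,
    waveforms,
    labels,
    spec: PipelineSpec,
    sizes: list[int],
    seed: int = 0,
    n_repeats: int = 3,
    test_fraction: float = 0.3,
) -> pd.DataFrame:
    """Held-out balanced accuracy as a function of training-set size.

    For each requested size, ``n_repeats`` stratified splits hold out
    ``test_fraction`` of the data, the training pool is subsampled to the
    size, and the pipeline is trained and scored from scratch.
    """
    y = np.asarray(labels)
    n = len(y)
    rows = []
    for size in sizes:
        if size > int(n * (1 - test_fraction)):
            raise ParameterError(f"size {size} exceeds the available training pool")
        splitter = StratifiedShuffleSplit(
            n_splits=n_repeats, test_size=test_fraction, random_state=seed
        )
        reps = []
        for rep, (train_idx, test_idx) in enumerate(
            splitter.split(np.zeros(n), y)
        ):
            rng = np.random.default_rng(seed + 1000 * rep + size)
            # stratified subsample of the training pool
            keep = []
            for cls in np.unique(y):
                cls_idx = train_idx[y[train_idx] == cls]
                want = max(1, int(round(size * cls_idx.size / train_idx.size)))
                keep.extend(rng.choice(cls_idx, size=min(want, cls_idx.size),
                                       replace=False))
            keep = np.sort(np.asarray(keep))
            pred = _fit_predict_split(spec, X, waveforms, y, keep, test_idx,
                                      seed=seed + rep)
            reps.append(float(balanced_accuracy_score(y[test_idx], pred)))
        rows.append({
            "n_train": size,
            "mean_balanced_accuracy": float(np.mean(reps)),
            "sd_balanced_accuracy": float(np.std(reps)),
        })
    return pd.DataFrame(rows)
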