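"""Classification of T1-T2 molecular fingerprints.

The workflow mirrors a point-of-care decision pipeline: spectrum maps are
featurized deterministically (log-intensity grid thumbnail or R/S/T peak
descriptors), embedded into two dimensions for visual inspection
(MDS/t-SNE/Isomap), hierarchically clustered for staging, and classified
by standard supervised models (logistic regression, kNN, a small neural
network, Gaussian naive Bayes) under stratified k-fold or leave-one-out
cross-validation.  The reported metric suite is the usual confusion-table
family: classification accuracy, sensitivity, specificity, precision,
F1 (harmonic mean of precision and sensitivity) and AUC computed from the
pooled out-of-fold decision scores via the rank-sum (Mann-Whitney)
identity with midranks for ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.linear_model import LogisticRegression
from sklearn.manifold import MDS, TSNE, Isomap
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier

from .laplace_inversion import SpectrumMap
from .peak_analysis import classify_peaks_rst, detect_peaks

__all__ = [
    "FeatureVector",
    "ClassificationResult",
    "featurize",
    "feature_matrix",
    "reduce_dimension",
    "cluster_and_heatmap",
    "separation_test",
    "metrics_from_confusion",
    "train_evaluate",
    "MODEL_NAMES",
]

MODEL_NAMES = ("logistic_regression", "knn", "neural_network", "naive_bayes")


@dataclass(frozen=True)
class FeatureVector:
    subject_id: str
    values: np.ndarray
    featurizer: str
    params: tuple = ()


@dataclass(frozen=True)
class ClassificationResult:
    model: str
    protocol: str
    seed: int | None
    tp: int
    tn: int
    fp: int
    fn: int
    metrics: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


# ---------------------------------------------------------------------------
# Featurization
# ---------------------------------------------------------------------------

def _grid_features(spectrum: SpectrumMap, size: int) -> np.ndarray:
    F = spectrum.intensity
    peak = float(F.max())
    if peak <= 0:
        return np.zeros(size * size)
    # log intensity above the dynamic-range floor (empty cells -> 0), so
    # the feature carries map structure rather than a constant background
    eps = 1e-6 * peak
    logF = np.log10(F + eps) - np.log10(eps)
    # block-average down to size x size (blocks of near-equal extent)
    blocks = [np.array_split(row_block, size, axis=1)
              for row_block in np.array_split(logF, size, axis=0)]
    thumb = np.array([[b.mean() for b in row] for row in blocks])
    v = thumb.ravel()
    return v / np.linalg.norm(v)


def _peak_features(spectrum: SpectrumMap) -> np.ndarray:
    report = detect_peaks(spectrum)
    values = []
    if report.peaks:
        labelled = classify_peaks_rst(report)
        for label in ("R", "S", "T"):
            p = labelled.by_label(label)
            if p is None:
                values.extend([0.0, 0.0, 0.0, 0.0])
            else:
                values.extend([np.log10(p.t1_ms), np.log10(p.t2_ms),
                               p.a_ratio, p.volume])
    else:
        values.extend([0.0] * 12)
    values.append(report.tail_extent_decades)
    return np.asarray(values, dtype=float)


def featurize(spectrum: SpectrumMap, method: str = "grid",
              subject_id: str = "", size: int = 32,
              embedding=None) -> FeatureVector:
    """Convert a spectrum map into a fixed-length feature vector.

    ``"grid"``: log-intensity map block-averaged to ``size x size``,
    flattened and L2-normalized.  ``"peaks"``: raw (log T1, log T2,
    A-ratio, volume) descriptors for the R/S/T slots plus the tail
    extent.  ``"embedding"``: delegates to a user-supplied callable
    (e.g. a CNN image embedding) mapping the intensity matrix to a
    vector.
    """
    if method == "grid":
        values = _grid_features(spectrum, size)
        params = ("size", size)
    elif method == "peaks":
        values = _peak_features(spectrum)
        params = ()
    elif method == "embedding":
        if embedding is None:
            raise ValueError("method 'embedding' needs an embedding callable")
        values = np.asarray(embedding(spectrum.intensity), dtype=float)
        params = (getattr(embedding, "__name__", "embedding"),)
    else:
        raise ValueError(f"unknown featurizer {method!r}")
    return FeatureVector(subject_id=subject_id, values=values,
                         featurizer=method, params=params)


def feature_matrix(features: list[FeatureVector]) -> np.ndarray:
    """Stack feature vectors, enforcing shared provenance and length."""
    if not features:
        raise ValueError("empty feature list")
    ref = (features[0].featurizer, features[0].params,
           len(features[0].values))
    for f in features[1:]:
        if (f.featurizer, f.params, len(f.values)) != ref:
            raise ValueError(
                "feature vectors mix featurizers or lengths: "
                f"{ref} vs {(f.featurizer, f.params, len(f.values))}"
            )
    return np.vstack([f.values for f in features])


# ---------------------------------------------------------------------------
# Unsupervised: embedding, clustering, group separation
# ---------------------------------------------------------------------------

def _classical_mds(D: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Torgersen's classical scaling from a distance matrix."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    w, V = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:n_components]
    w = np.clip(w[idx], 0.0, None)
    return V[:, idx] * np.sqrt(w)


def reduce_dimension(features: list[FeatureVector] | np.ndarray,
                     method: str = "mds", seed: int | None = 0,
                     max_iter: int = 300) -> np.ndarray:
    """Embed subjects into 2D for visual classification.

    MDS (default) starts from the classical Torgersen solution (PCA of
    the double-centered distance matrix) and refines it by stress
    majorization capped at ``max_iter`` iterations; t-SNE and Isomap are
    available behind the same interface.
    """
    X = feature_matrix(features) if isinstance(features, list) else features
    if X.shape[0] < 3:
        raise ValueError("dimension reduction needs at least 3 subjects")
    if method == "mds":
        D = squareform(pdist(X))
        init = _classical_mds(D)
        model = MDS(n_components=2, metric="precomputed",
                    metric_mds=True, n_init=1, max_iter=max_iter,
                    init="classical_mds",  # overridden by explicit init
                    normalized_stress=False, random_state=seed)
        return model.fit_transform(D, init=init)
    if method == "tsne":
        perplexity = min(30.0, (X.shape[0] - 1) / 3)
        model = TSNE(n_components=2, random_state=seed,
                     perplexity=perplexity, init="pca")
        return model.fit_transform(X)
    if method == "isomap":
        n_neighbors = min(5, X.shape[0] - 1)
        return Isomap(n_components=2,
                      n_neighbors=n_neighbors).fit_transform(X)
    raise ValueError(f"unknown reduction method {method!r}")


def cluster_and_heatmap(features: list[FeatureVector] | np.ndarray,
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average-linkage hierarchical clustering with a leaf-ordered heat map.

    Returns ``(linkage_matrix, leaf_order, ordered_distance_matrix)``.
    The ordered matrix is ready for heat-map rendering (large = distant).
    A single subject yields an empty linkage and a trivial ordering.
    """
    X = feature_matrix(features) if isinstance(features, list) else features
    n = X.shape[0]
    if n < 1:
        raise ValueError("need at least one subject")
    if n == 1:
        return (np.empty((0, 4)), np.array([0]), np.zeros((1, 1)))
    condensed = pdist(X)
    Z = hierarchy.linkage(condensed, method="average")
    order = hierarchy.leaves_list(Z)
    D = squareform(condensed)
    return Z, order, D[np.ix_(order, order)]


def separation_test(values: np.ndarray, labels: list | np.ndarray,
                    equal_var: bool = False) -> tuple[float, float]:
    """Two-tailed two-sample t test of group separation.

    ``values`` is a 1D statistic per subject (typically the first reduced
    coordinate); ``labels`` must contain exactly two groups with at least
    two subjects each.  Welch's variant by default; ``equal_var=True``
    switches to the classic pooled-variance form.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = sorted(set(labels.tolist()))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(groups)}")
    a = values[labels == groups[0]]
    b = values[labels == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Supervised evaluation
# ---------------------------------------------------------------------------

def metrics_from_confusion(tp: int, tn: int, fp: int, fn: int,
                           ) -> dict[str, float | None]:
    """Confusion-table metric suite; undefined ratios report as None."""
    n = tp + tn + fp + fn

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    ca = ratio(tp + tn, n)
    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    prec = ratio(tp, tp + fp)
    if prec is None or sens is None or (prec + sens) == 0:
        f1 = None
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return {"ca": ca, "sensitivity": sens, "specificity": spec,
            "precision": prec, "f1": f1}


def rank_auc(scores: np.ndarray, y_true: np.ndarray) -> float | None:
    """AUC by the Mann-Whitney rank-sum identity (midranks for ties)."""
    pos = y_true == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        return None
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def _make_model(name: str, seed: int | None):
    if name == "logistic_regression":
        return LogisticRegression(C=1.0, max_iter=1000)
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=3)
    if name == "neural_network":
        return MLPClassifier(hidden_layer_sizes=(32,), activation="logistic",
                             alpha=1e-3, max_iter=500, random_state=seed)
    if name == "naive_bayes":
        return GaussianNB()
    raise ValueError(
        f"unknown model {name!r}; valid: {', '.join(MODEL_NAMES)}"
    )


def train_evaluate(features: list[FeatureVector] | np.ndarray,
                   labels: list | np.ndarray,
                   model: str = "neural_network",
                   protocol: str | int = "loo",
                   seed: int | None = 0,
                   positive_label: str = "disease") -> ClassificationResult:
    """Cross-validated binary classification with pooled-fold metrics.

    ``protocol`` is ``"loo"`` (leave-one-out, k = N) or an integer k for
    stratified k-fold with seeded shuffling.  Out-of-fold predictions are
    pooled into one confusion table; AUC comes from the pooled decision
    scores for the positive class.
    """
    X = feature_matrix(features) if isinstance(features, list) else np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValueError(
            f"binary classification needs exactly 2 classes, got {classes}"
        )
    if positive_label not in classes:
        positive_label = classes[-1]
    y = (labels == positive_label).astype(int)
    n = len(y)
    if protocol == "loo":
        splitter = LeaveOneOut()
        protocol_name = "loo"
    else:
        k = int(protocol)
        if not 2 <= k <= n:
            raise ValueError(f"k must be in [2, {n}]")
        splitter = StratifiedKFold(n_splits=k, shuffle=True,
                                   random_state=seed)
        protocol_name = f"k={k}"
    y_pred = np.empty(n, dtype=int)
    y_score = np.empty(n, dtype=float)
    for train_idx, test_idx in splitter.split(X, y):
        clf = _make_model(model, seed)
        with warnings.catch_warnings():
            # the epoch cap on the small network is a deliberate setting
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(X[train_idx], y[train_idx])
        y_pred[test_idx] = clf.predict(X[test_idx])
        if hasattr(clf, "predict_proba"):
            proba = clf.predict_proba(X[test_idx])
            pos_col = list(clf.classes_).index(1) if 1 in clf.classes_ else None
            y_score[test_idx] = proba[:, pos_col] if pos_col is not None else 0.0
        else:
            y_score[test_idx] = clf.decision_function(X[test_idx])
    tp = int(np.sum((y_pred == 1) & (y == 1)))
    tn = int(np.sum((y_pred == 0) & (y == 0)))
    fp = int(np.sum((y_pred == 1) & (y == 0)))
    fn = int(np.sum((y_pred == 0) & (y == 1)))
    metrics = metrics_from_confusion(tp, tn, fp, fn)
    metrics["auc"] = rank_auc(y_score, y)
    return ClassificationResult(model=model, protocol=protocol_name,
                                seed=seed, tp=tp, tn=tn, fp=fp, fn=fn,
                                metrics=metrics)
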