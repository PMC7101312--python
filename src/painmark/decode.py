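"""Window-sweep decoding of the three stimulation conditions.

Implements the classification study: five classical classifiers (KNN, SVM,
Gaussian naive Bayes, LDA, QDA) scored with balanced accuracy under
stratified 10-fold cross-validation in each 100 ms post-stimulus window; a
final held-out test with PCA(2) + grid-searched SVM on a stratified 80/20
split of the augmented trials; and greedy sequential forward channel
selection.  Classifier fitting is delegated to scikit-learn; the study logic
(sweep, grid, selection, leakage discipline) lives here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .features import TimeWindow, max_amplitude_features, window_grid
from .preprocess import Epochs

__all__ = [
    "CLASS_ORDER",
    "DecodeConfig",
    "WindowSweepResult",
    "FinalTestResult",
    "balanced_accuracy",
    "confusion_matrix",
    "stratified_split",
    "pca_project",
    "make_classifier",
    "fit_predict",
    "cross_validate",
    "grid_search_svm",
    "sequential_forward_selection",
    "sweep_windows",
    "final_test",
]

CLASS_ORDER: tuple[str, ...] = ("INNO", "MOD", "NOX")
CLASSIFIER_NAMES: tuple[str, ...] = ("KNN", "SVM", "NB", "LDA", "QLDA")


def default_svm_grid() -> list[dict]:
    """Linear and RBF kernels crossed with regularisation / kernel width."""
    grid: list[dict] = []
    for c in (0.1, 1.0, 10.0, 100.0):
        grid.append({"kernel": "linear", "C": c})
    for c in (0.1, 1.0, 10.0, 100.0):
        for gamma in ("scale", 0.01, 0.1, 1.0):
            grid.append({"kernel": "rbf", "C": c, "gamma": gamma})
    return grid


@dataclass
class DecodeConfig:
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES
    k_folds: int = 10
    test_fraction: float = 0.2
    pca_components: int = 2
    svm_grid: list[dict] = field(default_factory=default_svm_grid)
    n_select: int = 5
    knn_k: int = 5
    selection_classifier: str = "LDA"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if not (0 < self.test_fraction < 1):
            raise ValueError("test_fraction must lie in (0, 1)")
        unknown = [c for c in self.classifiers if c not in CLASSIFIER_NAMES]
        if unknown:
            raise ValueError(f"unknown classifiers {unknown}")


def balanced_accuracy(y_true, y_pred, classes=None) -> float:
    """Mean over classes of per-class recall (chance = 1/k on k classes)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("inputs must be non-empty and of equal length")
    if classes is None:
        classes = np.unique(y_true)
    recalls = []
    for c in classes:
        mask = y_true == c
        if not mask.any():
            raise ValueError(f"class {c!r} absent from y_true")
        recalls.append(np.mean(y_pred[mask] == c))
    return float(np.mean(recalls))


def confusion_matrix(y_true, y_pred, class_order=CLASS_ORDER) -> np.ndarray:
    """Counts with rows = true class, columns = predicted class."""
    index = {c: i for i, c in enumerate(class_order)}
    out = np.zeros((len(class_order), len(class_order)), dtype=int)
    for t, p in zip(np.asarray(y_true), np.asarray(y_pred), strict=True):
        if t not in index or p not in index:
            raise ValueError(f"label {t!r}/{p!r} not in class order {class_order}")
        out[index[t], index[p]] += 1
    return out


def stratified_split(
    labels, test_fraction: float = 0.2, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test indices with per-class proportions
    preserved to within one trial (seeded shuffle)."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if np.any(counts * test_fraction < 1):
        raise ValueError("a class is too small for the requested test fraction")
    idx = np.arange(len(labels))
    train, test = train_test_split(
        idx, test_size=test_fraction, stratify=labels, random_state=seed, shuffle=True
    )
    return np.sort(train), np.sort(test)


def pca_project(
    train_features: np.ndarray, apply_features: np.ndarray, n_components: int = 2
) -> tuple[np.ndarray, np.ndarray, PCA]:
    """Fit PCA on training rows only; project both sets.

    Returns (train_scores, apply_scores, fitted_pca).  Raises on degenerate
    (zero-variance) training features, where directions are undefined.
    """
    train_features = np.asarray(train_features, dtype=float)
    if n_components > min(train_features.shape):
        raise ValueError("n_components exceeds the training matrix rank bound")
    if np.allclose(train_features.var(axis=0), 0):
        raise ValueError("training features are constant; PCA is undefined")
    pca = PCA(n_components=n_components, svd_solver="full")
    train_scores = pca.fit_transform(train_features)
    apply_scores = pca.transform(np.asarray(apply_features, dtype=float))
    return train_scores, apply_scores, pca


class RidgeQDA(BaseEstimator, ClassifierMixin):
    """Quadratic discriminant analysis with a covariance ridge.

    Gaussian class-conditional model with per-class mean and covariance;
    each covariance carries a relative ridge ``reg_param * mean(diag)`` so
    the discriminant stays defined when a class has fewer samples than
    features (the singular case is reported with a warning).
    """

    def __init__(self, reg_param: float = 1e-3):
        self.reg_param = reg_param

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        n, p = X.shape
        self.means_, self.precisions_, self.log_dets_, self.priors_ = [], [], [], []
        singular = False
        for c in self.classes_:
            Xc = X[y == c]
            mu = Xc.mean(axis=0)
            cov = np.cov(Xc, rowvar=False, ddof=1) if len(Xc) > 1 else np.zeros((p, p))
            cov = np.atleast_2d(cov)
            if len(Xc) <= p:
                singular = True
            ridge = self.reg_param * max(np.trace(cov) / p, 1e-12)
            cov = cov + ridge * np.eye(p)
            sign, logdet = np.linalg.slogdet(cov)
            self.means_.append(mu)
            self.precisions_.append(np.linalg.inv(cov))
            self.log_dets_.append(logdet)
            self.priors_.append(len(Xc) / n)
        if singular:
            warnings.warn(
                "singular class covariance; ridge regularisation applied",
                stacklevel=2,
            )
        return self

    def _scores(self, X):
        X = np.asarray(X, dtype=float)
        out = np.empty((X.shape[0], len(self.classes_)))
        for j, (mu, prec, ld, pr) in enumerate(
            zip(self.means_, self.precisions_, self.log_dets_, self.priors_)
        ):
            d = X - mu
            maha = np.einsum("ij,jk,ik->i", d, prec, d)
            out[:, j] = -0.5 * (ld + maha) + np.log(pr)
        return out

    def predict(self, X):
        return self.classes_[np.argmax(self._scores(X), axis=1)]


def make_classifier(name: str, hyper: dict | None = None, knn_k: int = 5):
    """Instantiate one of the five study classifiers.

    LDA uses the SVD solver (robust to singular pooled covariance); QDA
    carries a small covariance ridge (``reg_param``) as the documented
    fallback for singular per-class covariances.
    """
    hyper = dict(hyper or {})
    if name == "KNN":
        return KNeighborsClassifier(n_neighbors=hyper.get("k", knn_k))
    if name == "SVM":
        return SVC(
            kernel=hyper.get("kernel", "rbf"),
            C=hyper.get("C", 1.0),
            gamma=hyper.get("gamma", "scale"),
        )
    if name == "NB":
        return GaussianNB()
    if name == "LDA":
        return LinearDiscriminantAnalysis(solver="svd")
    if name == "QLDA":
        return RidgeQDA(reg_param=hyper.get("reg_param", 1e-3))
    raise ValueError(f"unknown classifier {name!r}")


def fit_predict(
    classifier_name: str,
    X_train,
    y_train,
    X_test,
    hyper: dict | None = None,
    knn_k: int = 5,
) -> np.ndarray:
    """Fit the named classifier and predict test labels (deterministic)."""
    clf = make_classifier(classifier_name, hyper, knn_k=knn_k)
    clf.fit(np.asarray(X_train, dtype=float), np.asarray(y_train))
    return clf.predict(np.asarray(X_test, dtype=float))


def cross_validate(
    classifier_name: str,
    X,
    y,
    k: int = 10,
    seed: int = 0,
    hyper: dict | None = None,
    knn_k: int = 5,
) -> np.ndarray:
    """Per-fold balanced accuracies under stratified k-fold CV."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class ({counts.min()}) is below the fold count {k}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = []
    for train_idx, val_idx in skf.split(X, y):
        pred = fit_predict(
            classifier_name, X[train_idx], y[train_idx], X[val_idx], hyper, knn_k
        )
        scores.append(balanced_accuracy(y[val_idx], pred, classes=classes))
    return np.array(scores)


def grid_search_svm(
    X, y, grid: list[dict] | None = None, k: int = 10, seed: int = 0
) -> tuple[dict, float, list[tuple[dict, float]]]:
    """Exhaustive SVM hyperparameter search by mean CV balanced accuracy.

    Returns (best_params, best_score, full_table); ties are broken by grid
    order (first maximiser wins).
    """
    if grid is None:
        grid = default_svm_grid()
    if not grid:
        raise ValueError("empty grid")
    table: list[tuple[dict, float]] = []
    best: tuple[dict, float] | None = None
    for params in grid:
        score = float(np.mean(cross_validate("SVM", X, y, k=k, seed=seed, hyper=params)))
        table.append((params, score))
        if best is None or score > best[1]:
            best = (params, score)
    return best[0], best[1], table


class _FastLDAScorer:
    """Mean CV balanced accuracy of a pooled-covariance Gaussian discriminant,
    vectorised over all folds at once.

    Numerically equivalent to scoring sklearn's LDA per fold, but the greedy
    channel selection evaluates thousands of small candidate sets and the
    per-fit estimator overhead would dominate; here class means, pooled
    covariances (with a tiny invertibility ridge) and discriminants are
    batched across folds with one einsum each.
    """

    def __init__(self, X, y, k: int, seed: int, n_repeats: int):
        self.X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes = np.unique(y)
        codes = np.searchsorted(self.classes, y)
        n, C = len(y), len(self.classes)
        folds = [
            fold
            for r in range(n_repeats)
            for fold in StratifiedKFold(
                n_splits=k, shuffle=True, random_state=seed + r
            ).split(self.X, y)
        ]
        F = len(folds)
        vmax = max(len(va) for _, va in folds)
        # validation rows gathered per fold, zero-weight padded to equal size
        self.val_idx = np.zeros((F, vmax), dtype=int)
        self.val_w = np.zeros((F, vmax))
        for f, (_, va) in enumerate(folds):
            self.val_idx[f, : len(va)] = va
            self.val_w[f, : len(va)] = 1.0
        y1hot = np.eye(C)[codes]  # (n, C)
        self.yv1hot = y1hot[self.val_idx] * self.val_w[:, :, None]  # (F,vmax,C)
        self.val_codes = codes[self.val_idx]  # (F, vmax)
        self.counts_total = y1hot.sum(axis=0)  # (C,)
        self.counts_val = self.yv1hot.sum(axis=1)  # (F, C)
        self.counts_train = self.counts_total[None, :] - self.counts_val
        self.n_train = self.counts_train.sum(axis=1)
        self.log_priors = np.log(self.counts_train / self.n_train[:, None])
        self.y1hot = y1hot
        self.C = C

    def score(self, cols) -> float:
        Xc = self.X[:, cols]  # (n, k)
        p = Xc.shape[1]
        Xv = Xc[self.val_idx]  # (F, vmax, k)
        # training moments = totals minus validation moments
        sums_total = self.y1hot.T @ Xc  # (C, k)
        sums_val = np.einsum("fvc,fvk->fck", self.yv1hot, Xv)
        means = (sums_total[None] - sums_val) / self.counts_train[:, :, None]
        S_total = Xc.T @ Xc  # (k, k)
        S_val = np.einsum("fv,fvk,fvl->fkl", self.val_w, Xv, Xv)
        cov = S_total[None] - S_val - np.einsum(
            "fc,fck,fcl->fkl", self.counts_train, means, means
        )
        cov /= (self.n_train - self.C)[:, None, None]
        tr = np.einsum("fkk->f", cov)
        cov = cov + (1e-8 * tr / p)[:, None, None] * np.eye(p)
        prec = np.linalg.inv(cov)  # batched over folds
        lin = np.einsum("fvk,fkl,fcl->fvc", Xv, prec, means)
        quad = 0.5 * np.einsum("fck,fkl,fcl->fc", means, prec, means)
        disc = lin - quad[:, None, :] + self.log_priors[:, None, :]
        pred = np.argmax(disc, axis=2)  # (F, vmax)
        correct = (pred == self.val_codes) * self.val_w
        hits = np.einsum("fvc,fv->fc", self.yv1hot, correct)
        recalls = hits / self.counts_val
        return float(recalls.mean())


def sequential_forward_selection(
    X,
    y,
    n_select: int = 5,
    k: int = 10,
    seed: int = 0,
    classifier: str = "LDA",
    channel_labels=None,
    n_repeats: int = 5,
) -> list:
    """Greedy forward channel selection by mean CV balanced accuracy.

    At each step the channel whose addition maximises the CV score of the
    augmented set is appended; score ties are broken by lower channel index.
    The score averages ``n_repeats`` stratified k-fold repetitions (seeds
    ``seed .. seed + n_repeats - 1``) so that the argmax over ~64 candidate
    channels tracks real gains rather than a single fold split's noise.
    Returns channels in selection order (labels if given, else indices).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n_channels = X.shape[1]
    if n_select > n_channels:
        raise ValueError("n_select exceeds the channel count")

    if classifier == "LDA":
        scorer = _FastLDAScorer(X, y, k=k, seed=seed, n_repeats=n_repeats)
        score_cols = scorer.score
    else:

        def score_cols(cols: list[int]) -> float:
            return float(
                np.mean(
                    [
                        np.mean(
                            cross_validate(classifier, X[:, cols], y, k=k,
                                           seed=seed + r)
                        )
                        for r in range(n_repeats)
                    ]
                )
            )

    selected: list[int] = []
    remaining = list(range(n_channels))
    for _ in range(n_select):
        best_ch, best_score = None, -np.inf
        for ch in remaining:
            score = score_cols(selected + [ch])
            if score > best_score:  # strict: ties keep the lower index
                best_ch, best_score = ch, score
        selected.append(best_ch)
        remaining.remove(best_ch)
    if channel_labels is not None:
        return [channel_labels[i] for i in selected]
    return selected


@dataclass
class WindowSweepResult:
    """Per-window, per-classifier fold scores and the winning window."""

    windows: list[TimeWindow]
    #: fold_baccs[window_index][classifier_name] -> np.ndarray of fold scores
    fold_baccs: list[dict[str, np.ndarray]]
    best_window: TimeWindow
    best_window_index: int

    def mean_table(self) -> list[dict[str, float]]:
        return [
            {name: float(np.mean(scores)) for name, scores in row.items()}
            for row in self.fold_baccs
        ]

    def window_means(self) -> np.ndarray:
        """Mean balanced accuracy per window, pooled over classifiers."""
        return np.array(
            [np.mean([np.mean(s) for s in row.values()]) for row in self.fold_baccs]
        )


def sweep_windows(
    epochs: Epochs,
    config: DecodeConfig | None = None,
    windows: list[TimeWindow] | None = None,
) -> WindowSweepResult:
    """Score every classifier in every 100 ms window on all 64 channels.

    The sweep uses the original (non-augmented) trials and no PCA; the best
    window is the argmax of the classifier-pooled mean balanced accuracy,
    earlier windows winning ties.
    """
    config = config or DecodeConfig()
    windows = windows if windows is not None else window_grid()
    y = np.asarray(epochs.kept().labels)
    rows: list[dict[str, np.ndarray]] = []
    for w in windows:
        feats = max_amplitude_features(epochs, w)
        row = {
            name: cross_validate(
                name, feats.values, y, k=config.k_folds, seed=config.seed,
                knn_k=config.knn_k,
            )
            for name in config.classifiers
        }
        rows.append(row)
    means = [np.mean([np.mean(s) for s in row.values()]) for row in rows]
    best = int(np.argmax(means))  # np.argmax returns the first maximiser
    return WindowSweepResult(
        windows=list(windows),
        fold_baccs=rows,
        best_window=windows[best],
        best_window_index=best,
    )


@dataclass
class FinalTestResult:
    window: TimeWindow
    best_params: dict
    validation_bacc_mean: float
    validation_bacc_sd: float
    test_bacc: float
    confusion: np.ndarray
    n_train: int
    n_test: int


def final_test(
    augmented_epochs: Epochs,
    window: TimeWindow,
    config: DecodeConfig | None = None,
) -> FinalTestResult:
    """Held-out evaluation of the full pipeline in one window.

    Features -> stratified 80/20 split -> PCA(2) fitted on the training rows
    -> SVM hyperparameters grid-searched by 10-fold CV on the training scores
    -> balanced accuracy and confusion matrix on the untouched 20 %.
    All fitting uses training rows only.
    """
    config = config or DecodeConfig()
    feats = max_amplitude_features(augmented_epochs, window)
    y = np.asarray(feats.labels)
    train_idx, test_idx = stratified_split(y, config.test_fraction, seed=config.seed)
    X_train, X_test = feats.values[train_idx], feats.values[test_idx]
    y_train, y_test = y[train_idx], y[test_idx]
    train_scores, test_scores, _ = pca_project(
        X_train, X_test, n_components=config.pca_components
    )
    best_params, _, table = grid_search_svm(
        train_scores, y_train, config.svm_grid, k=config.k_folds, seed=config.seed
    )
    val_folds = cross_validate(
        "SVM", train_scores, y_train, k=config.k_folds, seed=config.seed,
        hyper=best_params,
    )
    pred = fit_predict("SVM", train_scores, y_train, test_scores, hyper=best_params)
    classes = np.unique(y)
    order = [c for c in CLASS_ORDER if c in classes] or list(classes)
    return FinalTestResult(
        window=window,
        best_params=best_params,
        validation_bacc_mean=float(np.mean(val_folds)),
        validation_bacc_sd=float(np.std(val_folds)),
        test_bacc=balanced_accuracy(y_test, pred, classes=classes),
        confusion=confusion_matrix(y_test, pred, class_order=order),
        n_train=len(train_idx),
        n_test=len(test_idx),
    )
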