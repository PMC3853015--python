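"""Log-variance features, SVM training, and leak-free cross-validation.

Feature extraction takes, per trial, the log of the output variance of the
top-k spatial filters from every class bank (``n_classes * k`` columns).
Cross-validation is stratified tenfold; spatial filters are always fit on
the training trials of each fold only, and the filter count k (and, for the
regularized variant, the penalty weights alpha/beta) are selected by an
inner cross-validation nested inside each training fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.multiclass import OneVsRestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from micsp import csp
from micsp.io_preprocess import Epochs, ValidationError

#: the 10-point regularization grid searched for alpha and beta
DEFAULT_REG_GRID: tuple[float, ...] = (0.0,) + tuple(2.0**-e for e in range(8, -1, -1))


@dataclass(frozen=True)
class SVMSpec:
    """Support-vector-machine settings.

    Linear kernel with unit cost by default; `scheme` selects one-vs-one
    voting ('ovo', the LIBSVM-style default) or one-vs-rest ('ovr').
    """

    kernel: str = "linear"
    cost: float = 1.0
    scheme: str = "ovo"

    def __post_init__(self) -> None:
        if self.cost <= 0:
            raise ValidationError("SVM cost must be positive")
        if self.scheme not in ("ovo", "ovr"):
            raise ValidationError(f"unknown multiclass scheme {self.scheme!r}")


@dataclass
class CVResult:
    """Outcome of one cross-validated evaluation."""

    method: str
    fold_accuracies: np.ndarray  # percent, one per fold
    selections: list[dict]  # per fold: {"k": int, "alpha": float|None, "beta": float|None}
    folds: np.ndarray  # fold index per trial
    seed: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "mean_accuracy": self.mean_accuracy,
            "selections": self.selections,
            "seed": self.seed,
        }


# -- features ----------------------------------------------------------------


def _raw_covariances(epochs: Epochs) -> np.ndarray:
    """Unnormalized per-trial covariance ``X X' / T`` (keeps amplitude scale)."""
    d = epochs.data.astype(float)
    return np.einsum("tcs,tds->tcd", d, d) / epochs.n_samples


def _bank_feature_matrix(fb: csp.FilterBank, raw_covs: np.ndarray, k: int) -> np.ndarray:
    """(n_trials, n_classes * k) log-variances of the top-k filters per bank."""
    n = raw_covs.shape[1]
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} outside [1, {n}]")
    W = np.vstack([fb.filters[c][:k] for c in fb.classes])
    var = np.einsum("fc,tcd,fd->tf", W, raw_covs, W)
    var = np.maximum(var, np.finfo(float).tiny)
    return np.log(var)


def log_variance_features(epochs: Epochs, fb: csp.FilterBank, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial log-variance features under a filter bank.

    Returns ``(X, y)`` with ``X`` of shape ``(n_trials, n_classes * k)``.
    Scaling a trial by c shifts each of its features by ``2 ln c``.
    """
    return _bank_feature_matrix(fb, _raw_covariances(epochs), k), epochs.labels.copy()


# -- folds and SVM -----------------------------------------------------------


def make_folds(labels: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Stratified fold assignment (fold index per trial), deterministic in seed.

    With 80 trials per class and 10 folds every fold holds exactly 8 trials
    of each class.
    """
    labels = np.asarray(labels)
    counts = np.unique(labels, return_counts=True)[1]
    if n_folds > counts.min():
        raise ValidationError(
            f"n_folds={n_folds} exceeds the smallest class count {counts.min()}"
        )
    rng = np.random.default_rng(seed)
    folds = np.empty(len(labels), dtype=int)
    for label in np.unique(labels):
        idx = np.flatnonzero(labels == label)
        idx = rng.permutation(idx)
        for f, chunk in enumerate(np.array_split(idx, n_folds)):
            folds[chunk] = f
    return folds


def _build_svm(spec: SVMSpec):
    svc = SVC(kernel=spec.kernel, C=spec.cost, random_state=0)
    if spec.scheme == "ovr":
        clf = OneVsRestClassifier(svc)
    else:
        clf = svc
    return Pipeline([("scale", StandardScaler()), ("svm", clf)])


def train_svm(features: np.ndarray, labels: np.ndarray, spec: SVMSpec = SVMSpec()):
    """Fit a multi-class SVM; the training accuracy is attached as
    ``model.train_accuracy_`` (percent)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValidationError("training requires at least two classes")
    model = _build_svm(spec)
    model.fit(features, labels)
    model.train_accuracy_ = 100.0 * float(np.mean(model.predict(features) == labels))
    return model


# -- cross-validation --------------------------------------------------------


def _fit_bank(
    norm_covs: np.ndarray,
    labels: np.ndarray,
    method: str,
    alpha: float | None,
    beta: float | None,
    shrinkage: float,
    penalties: dict[int, np.ndarray] | None = None,
) -> csp.FilterBank:
    cs = csp.covariances_from_trials(norm_covs, labels, shrinkage=shrinkage)
    if method == "multi_csp":
        return csp.multi_csp(cs)
    if method == "gecsp":
        return csp.gecsp(cs)
    if method == "strcsp":
        return csp.strcsp(cs, alpha=alpha, beta=beta, penalties=penalties)
    raise ValidationError(f"unknown method {method!r}")


def _penalties_for(norm_covs: np.ndarray, labels: np.ndarray, shrinkage: float) -> dict[int, np.ndarray]:
    cs = csp.covariances_from_trials(norm_covs, labels, shrinkage=shrinkage)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {c: csp.stationarity_penalty(cs, c) for c in cs.classes}


def _select_hyperparams(
    norm_covs: np.ndarray,
    raw_covs: np.ndarray,
    labels: np.ndarray,
    method: str,
    k_grid: list[int],
    candidates: list[tuple[float | None, float | None]],
    spec: SVMSpec,
    n_folds: int,
    seed: int,
    shrinkage: float,
) -> tuple[int, float | None, float | None]:
    """Pick (k, alpha, beta) by stratified CV on the given trials.

    Tie-break: smallest k first, then smallest alpha + beta.
    """
    folds = make_folds(labels, n_folds, seed)
    scores: dict[tuple, list[float]] = {(k, a, b): [] for k in k_grid for (a, b) in candidates}
    need_penalty = method == "strcsp" and any(a and a > 0 for a, _ in candidates)
    for f in range(n_folds):
        fit = folds != f
        val = ~fit
        penalties = _penalties_for(norm_covs[fit], labels[fit], shrinkage) if need_penalty else None
        for a, b in candidates:
            bank = _fit_bank(norm_covs[fit], labels[fit], method, a, b, shrinkage, penalties)
            feats_fit = _bank_feature_matrix(bank, raw_covs[fit], max(k_grid))
            feats_val = _bank_feature_matrix(bank, raw_covs[val], max(k_grid))
            n_classes = len(bank.classes)
            for k in k_grid:
                cols = _topk_columns(n_classes, max(k_grid), k)
                model = train_svm(feats_fit[:, cols], labels[fit], spec)
                acc = float(np.mean(model.predict(feats_val[:, cols]) == labels[val]))
                scores[(k, a, b)].append(acc)
    z = lambda v: 0.0 if v is None else v
    best = max(
        scores,
        key=lambda key: (np.mean(scores[key]), -key[0], -(z(key[1]) + z(key[2]))),
    )
    return best


def _topk_columns(n_classes: int, k_max: int, k: int) -> np.ndarray:
    """Columns of the first k filters of each bank inside a k_max layout."""
    return np.concatenate([np.arange(c * k_max, c * k_max + k) for c in range(n_classes)])


def cross_validate(
    epochs: Epochs,
    method: str,
    k_grid: list[int] | tuple[int, ...] = (1, 2, 3, 4, 5, 6),
    alpha_grid: list[float] | tuple[float, ...] | None = None,
    beta_grid: list[float] | tuple[float, ...] | None = None,
    spec: SVMSpec = SVMSpec(),
    n_folds: int = 10,
    seed: int = 0,
    nested: bool = True,
    inner_folds: int | None = None,
    shrinkage: float = 1e-6,
) -> CVResult:
    """Stratified n-fold cross-validation of one CSP method.

    For every outer fold the filter bank is fit on the training trials only.
    When more than one hyperparameter candidate exists, selection runs as an
    inner cross-validation on the training fold (``nested=True``, unbiased)
    or once on the full dataset (``nested=False``, the optimistic reading of
    a single-level protocol). `alpha_grid`/`beta_grid` apply to the
    'strcsp' method only and default to :data:`DEFAULT_REG_GRID`.
    """
    k_grid = sorted(set(int(k) for k in k_grid))
    if method == "strcsp":
        alphas = list(DEFAULT_REG_GRID) if alpha_grid is None else list(alpha_grid)
        betas = list(DEFAULT_REG_GRID) if beta_grid is None else list(beta_grid)
        candidates = list(product(alphas, betas))
    else:
        candidates = [(None, None)]
    inner_folds = n_folds if inner_folds is None else inner_folds

    raw_covs = _raw_covariances(epochs)
    traces = np.trace(raw_covs, axis1=1, axis2=2)
    norm_covs = raw_covs / traces[:, None, None]
    labels = epochs.labels
    folds = make_folds(labels, n_folds, seed)

    fixed_selection = None
    if len(k_grid) == 1 and len(candidates) == 1:
        fixed_selection = (k_grid[0], candidates[0][0], candidates[0][1])
    elif not nested:
        fixed_selection = _select_hyperparams(
            norm_covs, raw_covs, labels, method, k_grid, candidates, spec, inner_folds, seed + 7919, shrinkage
        )

    fold_accs = np.empty(n_folds)
    selections: list[dict] = []
    need_penalty = method == "strcsp" and any(a and a > 0 for a, _ in candidates)
    for f in range(n_folds):
        train = folds != f
        test = ~train
        if fixed_selection is not None:
            k_sel, a_sel, b_sel = fixed_selection
        else:
            k_sel, a_sel, b_sel = _select_hyperparams(
                norm_covs[train], raw_covs[train], labels[train], method, k_grid,
                candidates, spec, inner_folds, seed + 104729 + f, shrinkage,
            )
        penalties = _penalties_for(norm_covs[train], labels[train], shrinkage) if need_penalty else None
        bank = _fit_bank(norm_covs[train], labels[train], method, a_sel, b_sel, shrinkage, penalties)
        feats_train = _bank_feature_matrix(bank, raw_covs[train], k_sel)
        feats_test = _bank_feature_matrix(bank, raw_covs[test], k_sel)
        model = train_svm(feats_train, labels[train], spec)
        fold_accs[f] = 100.0 * float(np.mean(model.predict(feats_test) == labels[test]))
        selections.append({"k": int(k_sel), "alpha": a_sel, "beta": b_sel})
    return CVResult(method=method, fold_accuracies=fold_accs, selections=selections, folds=folds, seed=seed)


def compare_methods(
    datasets: list[Epochs],
    methods: list[str],
    dataset_names: list[str] | None = None,
    seed: int = 0,
    **cv_kwargs,
) -> tuple[pd.DataFrame, dict[tuple[str, str], dict]]:
    """Cross-validate each method on each dataset and compare by paired t-test.

    Returns a (methods x datasets) accuracy table with a trailing 'mean'
    column, plus two-sided paired t-tests between every method pair across
    datasets (skipped with a warning when only one dataset is given).
    """
    if len(methods) < 2:
        raise ValidationError("need at least two methods to compare")
    names = dataset_names or [f"S{i + 1}" for i in range(len(datasets))]
    table = pd.DataFrame(index=methods, columns=names, dtype=float)
    for j, e in enumerate(datasets):
        for m in methods:
            table.loc[m, names[j]] = cross_validate(e, m, seed=seed, **cv_kwargs).mean_accuracy
    table["mean"] = table[names].mean(axis=1)
    tests: dict[tuple[str, str], dict] = {}
    if len(datasets) < 2:
        warnings.warn("single dataset: paired t-tests skipped", stacklevel=2)
        return table, tests
    for i, m1 in enumerate(methods):
        for m2 in methods[i + 1 :]:
            a = table.loc[m1, names].to_numpy(dtype=float)
            b = table.loc[m2, names].to_numpy(dtype=float)
            if np.allclose(a, b):
                tests[(m1, m2)] = {"t": 0.0, "p": 1.0}
            else:
                t, p = stats.ttest_rel(a, b)
                tests[(m1, m2)] = {"t": float(t), "p": float(p)}
    return table, tests
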