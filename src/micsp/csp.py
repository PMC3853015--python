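"""One-vs-rest multiclass common spatial patterns and regularized variants.

Three filter-bank constructions over a shared covariance model:

``multi_csp``
    Whiten the composite covariance ``S = sum_i S_i``, then eigendecompose
    each whitened class covariance. Class and rest-of-classes share
    eigenvectors; their eigenvalues are complementary (sum to 1).
``gecsp``
    Solve the generalized eigenproblem ``S_i w = lambda S w`` directly
    (maximizing the Rayleigh quotient ``w' S_i w / w' S w``). Algebraically
    equivalent to ``multi_csp`` up to row scaling.
``strcsp``
    Generalized eigenproblem with a regularized denominator
    ``S + alpha * penalty_i + beta * I``, where ``penalty_i`` is a
    stationarity penalty built from per-trial covariance deviations and the
    identity term is a Tikhonov (filter-norm) penalty. Reduces exactly to
    ``gecsp`` at ``alpha = beta = 0``.

Trial covariances are trace-normalized, so every construction is invariant
to global amplitude scaling. Filter rows have their largest-magnitude entry
forced positive for reproducible output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from micsp.io_preprocess import Epochs, ValidationError


@dataclass
class CovarianceSet:
    """Per-class mean covariances, retained trial covariances, composite sum.

    `class_means` maps label -> (N, N) mean covariance (shrunk toward a
    scaled identity so the composite is positive definite even after CAR).
    `trial_covs` maps label -> (n_trials_i, N, N) stack of trace-normalized
    single-trial covariances.
    """

    class_means: dict[int, np.ndarray]
    trial_covs: dict[int, np.ndarray]
    channels: list[str] | None = None

    @property
    def classes(self) -> list[int]:
        return sorted(self.class_means)

    @property
    def n_channels(self) -> int:
        return next(iter(self.class_means.values())).shape[0]

    @property
    def composite(self) -> np.ndarray:
        """Sum over classes of the class-mean covariances."""
        return np.sum([self.class_means[c] for c in self.classes], axis=0)


@dataclass
class WhiteningResult:
    """Whitening matrix for the composite covariance: ``P S P' = I``."""

    P: np.ndarray
    U0: np.ndarray
    eigvals: np.ndarray


@dataclass
class FilterBank:
    """Per-class spatial filter matrices (filters as rows) with eigenvalues.

    `filters[i]` is the full (N, N) projection matrix for class i with rows
    sorted by descending eigenvalue; truncation to the top-k rows happens at
    feature-extraction time. `patterns[i]` holds the companion spatial
    patterns as columns (inverse of the filter matrix), filled lazily by
    :func:`spatial_patterns`.
    """

    method: str
    filters: dict[int, np.ndarray]
    eigvals: dict[int, np.ndarray]
    alpha: float | None = None
    beta: float | None = None
    channels: list[str] | None = None
    patterns: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def classes(self) -> list[int]:
        return sorted(self.filters)

    def __post_init__(self) -> None:
        for c, w in self.filters.items():
            if np.any(np.all(w == 0, axis=1)):
                raise ValidationError(f"class {c} has an all-zero filter row")
            ev = self.eigvals[c]
            if np.any(np.diff(ev) > 1e-8):
                raise ValidationError(f"class {c} eigenvalues not sorted descending")


def _fix_signs(W: np.ndarray) -> np.ndarray:
    """Force the largest-magnitude entry of each filter row to be positive."""
    idx = np.argmax(np.abs(W), axis=1)
    signs = np.sign(W[np.arange(W.shape[0]), idx])
    signs[signs == 0] = 1.0
    return W * signs[:, None]


def _symmetrize(A: np.ndarray) -> np.ndarray:
    return 0.5 * (A + A.T)


# -- covariance estimation ---------------------------------------------------


def trial_covariance(trial: np.ndarray) -> np.ndarray:
    """Trace-normalized spatial covariance ``X X' / tr(X X')`` of one trial."""
    X = np.asarray(trial, dtype=float)
    if X.ndim != 2:
        raise ValidationError("trial must be a (channels, samples) matrix")
    if X.shape[1] <= X.shape[0]:
        warnings.warn(
            f"trial has {X.shape[1]} samples for {X.shape[0]} channels; covariance may be poorly conditioned",
            stacklevel=2,
        )
    S = X @ X.T
    tr = np.trace(S)
    if tr <= 0 or not np.isfinite(tr):
        raise ValidationError("trial has zero (or non-finite) energy")
    return _symmetrize(S / tr)


def class_covariances(
    epochs: Epochs,
    shrinkage: float = 1e-6,
    expected_classes: list[int] | None = None,
) -> CovarianceSet:
    """Per-class mean of trial covariances, shrunk toward a scaled identity.

    Shrinkage ``S_i <- (1 - g) S_i + g (tr(S_i)/N) I`` guarantees a positive
    definite composite even when CAR has made single-trial covariances
    rank-deficient by one.
    """
    present = sorted(np.unique(epochs.labels).tolist())
    if expected_classes is not None:
        missing = sorted(set(expected_classes) - set(present))
        if missing:
            raise ValidationError(f"classes without trials: {missing}")
    if len(present) < 2:
        raise ValidationError("need at least two classes")
    if not 0 <= shrinkage < 1:
        raise ValidationError("shrinkage must be in [0, 1)")
    n = epochs.n_channels
    class_means: dict[int, np.ndarray] = {}
    trial_covs: dict[int, np.ndarray] = {}
    for label in present:
        covs = np.stack([trial_covariance(x) for x in epochs.class_trials(label)])
        trial_covs[label] = covs
        mean = covs.mean(axis=0)
        class_means[label] = (1 - shrinkage) * mean + shrinkage * (np.trace(mean) / n) * np.eye(n)
    return CovarianceSet(class_means=class_means, trial_covs=trial_covs, channels=list(epochs.channels))


def covariances_from_trials(
    trial_covs_all: np.ndarray,
    labels: np.ndarray,
    shrinkage: float = 1e-6,
) -> CovarianceSet:
    """Build a :class:`CovarianceSet` from precomputed trial covariances.

    Lets cross-validation cache the per-trial covariances once and rebuild
    class means cheaply for every training subset.
    """
    labels = np.asarray(labels)
    n = trial_covs_all.shape[1]
    class_means: dict[int, np.ndarray] = {}
    trial_covs: dict[int, np.ndarray] = {}
    for label in sorted(np.unique(labels).tolist()):
        covs = trial_covs_all[labels == label]
        trial_covs[label] = covs
        mean = covs.mean(axis=0)
        class_means[label] = (1 - shrinkage) * mean + shrinkage * (np.trace(mean) / n) * np.eye(n)
    return CovarianceSet(class_means=class_means, trial_covs=trial_covs)


# -- whitening and filter banks ----------------------------------------------


def whitening(cs: CovarianceSet, tol: float = 1e-10) -> WhiteningResult:
    """Whitening matrix ``P = L^(-1/2) U0'`` of the composite covariance."""
    S = _symmetrize(cs.composite)
    vals, vecs = linalg.eigh(S)
    order = np.argsort(-vals, kind='stable')
    vals, vecs = vals[order], vecs[:, order]
    if vals[-1] <= tol * vals[0]:
        raise ValidationError(
            "composite covariance is rank deficient; increase the shrinkage "
            "parameter of class_covariances"
        )
    P = (vecs / np.sqrt(vals)).T
    return WhiteningResult(P=P, U0=vecs, eigvals=vals)


def multi_csp(cs: CovarianceSet) -> FilterBank:
    """One-vs-rest CSP by whitening + per-class eigendecomposition.

    For each class i the whitened class covariance ``Y_i = P S_i P'`` and
    its rest-complement ``Y_i' = P (S - S_i) P' = I - Y_i`` share
    eigenvectors; the projection matrix is ``W_i = U_i' P`` with rows sorted
    by descending eigenvalue of ``Y_i``.
    """
    wr = whitening(cs)
    filters: dict[int, np.ndarray] = {}
    eigvals: dict[int, np.ndarray] = {}
    for label in cs.classes:
        Y = _symmetrize(wr.P @ cs.class_means[label] @ wr.P.T)
        vals, vecs = linalg.eigh(Y)
        order = np.argsort(-vals, kind='stable')
        vals, vecs = vals[order], vecs[:, order]
        filters[label] = _fix_signs(vecs.T @ wr.P)
        eigvals[label] = vals
    return FilterBank(method="multi_csp", filters=filters, eigvals=eigvals, channels=cs.channels)


def gecsp(cs: CovarianceSet) -> FilterBank:
    """One-vs-rest CSP by the generalized eigenproblem ``S_i w = lambda S w``."""
    S = _symmetrize(cs.composite)
    vals0 = linalg.eigvalsh(S)
    if vals0[0] <= 0:
        raise ValidationError("composite covariance is not positive definite")
    filters: dict[int, np.ndarray] = {}
    eigvals: dict[int, np.ndarray] = {}
    for label in cs.classes:
        vals, vecs = linalg.eigh(_symmetrize(cs.class_means[label]), S)
        order = np.argsort(-vals, kind='stable')
        vals, vecs = vals[order], vecs[:, order]
        filters[label] = _fix_signs(vecs.T)
        eigvals[label] = vals
    return FilterBank(method="gecsp", filters=filters, eigvals=eigvals, channels=cs.channels)


def _matrix_abs(A: np.ndarray) -> np.ndarray:
    """Matrix absolute value: flip negative eigenvalues positive."""
    vals, vecs = linalg.eigh(_symmetrize(A))
    return _symmetrize((vecs * np.abs(vals)) @ vecs.T)


def stationarity_penalty(cs: CovarianceSet, class_id: int) -> np.ndarray:
    """Symmetric PSD penalty from per-trial covariance deviations.

    ``penalty = sum_k abs_m(S_ik - S_i)`` where ``abs_m`` is the matrix
    absolute value. The quadratic form ``w' penalty w`` upper-bounds the
    summed absolute variance deviations ``sum_k |w'(S_ik - S_i)w|``, so
    filters with nonstationary output variance are penalized.
    """
    if class_id not in cs.trial_covs:
        raise ValidationError(f"no trial covariances for class {class_id}")
    covs = cs.trial_covs[class_id]
    n = covs.shape[1]
    if covs.shape[0] < 2:
        warnings.warn(f"class {class_id} has a single trial; stationarity penalty is zero", stacklevel=2)
        return np.zeros((n, n))
    mean = covs.mean(axis=0)
    penalty = np.zeros((n, n))
    for S_k in covs:
        penalty += _matrix_abs(S_k - mean)
    return _symmetrize(penalty)


def strcsp(
    cs: CovarianceSet,
    alpha: float,
    beta: float,
    penalties: dict[int, np.ndarray] | None = None,
) -> FilterBank:
    """Stationary Tikhonov-regularized one-vs-rest CSP.

    Maximizes, per class i, ``w' S_i w / (w' (S + alpha * penalty_i +
    beta * I) w)`` via a generalized eigenproblem. `penalties` may supply
    precomputed stationarity penalties (otherwise they are computed from the
    stored trial covariances). At ``alpha = beta = 0`` this is exactly
    :func:`gecsp`.
    """
    if alpha < 0 or beta < 0:
        raise ValidationError("regularization weights must be non-negative")
    S = _symmetrize(cs.composite)
    n = cs.n_channels
    filters: dict[int, np.ndarray] = {}
    eigvals: dict[int, np.ndarray] = {}
    for label in cs.classes:
        pen = np.zeros((n, n))
        if alpha > 0:
            pen = penalties[label] if penalties is not None else stationarity_penalty(cs, label)
        B = _symmetrize(S + alpha * pen + beta * np.eye(n))
        vals, vecs = linalg.eigh(_symmetrize(cs.class_means[label]), B)
        order = np.argsort(-vals, kind='stable')
        vals, vecs = vals[order], vecs[:, order]
        filters[label] = _fix_signs(vecs.T)
        eigvals[label] = vals
    return FilterBank(
        method="strcsp", filters=filters, eigvals=eigvals, alpha=alpha, beta=beta, channels=cs.channels
    )


def spatial_patterns(fb: FilterBank) -> dict[int, np.ndarray]:
    """Spatial patterns per class: columns of the inverse filter matrix.

    Pattern j (column j of the returned matrix) is the scalp projection of
    the source extracted by filter row j; falls back to the pseudo-inverse
    with a warning if a filter matrix is singular. Results are cached on
    ``fb.patterns``.
    """
    out: dict[int, np.ndarray] = {}
    for label in fb.classes:
        W = fb.filters[label]
        try:
            A = linalg.inv(W)
        except linalg.LinAlgError:
            warnings.warn(f"singular filter matrix for class {label}; using pseudo-inverse", stacklevel=2)
            A = linalg.pinv(W)
        out[label] = A
    fb.patterns = out
    return out
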