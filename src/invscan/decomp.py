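"""PCA on the feature matrix, and supervised separability of inversion genotypes.

PCA (whitened scores) is the workhorse that concentrates the correlated
inversion-linked SNP signal onto the leading components. The separability
check is an evaluation device, not a genotype caller: a logistic-loss
linear classifier is trained on the first two PC coordinates to predict
known inversion genotypes, and held-out accuracy is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.linear_model import SGDClassifier
from sklearn.metrics import accuracy_score
from sklearn.model_selection import train_test_split

from .errors import InputError, ParameterError
from .featurize import FeatureMatrix

#: above this many matrix columns PCA switches to the randomized solver
RANDOMIZED_SOLVER_THRESHOLD = 20_000


@dataclass
class PCScores:
    """Whitened sample coordinates on the top principal components."""

    coords: np.ndarray
    explained_variance_ratio: np.ndarray
    c: int
    sample_ids: Sequence[str]


@dataclass(frozen=True)
class SeparabilityResult:
    accuracy: float
    n_train: int
    n_test: int
    seed: int


def fit_pca(matrix: FeatureMatrix, n_components: int = 10, seed: int = 0) -> PCScores:
    """Whitened PCA scores of the samples.

    Deterministic: the exact (full SVD) solver is used at ordinary scale,
    the seeded randomized solver above :data:`RANDOMIZED_SOLVER_THRESHOLD`
    columns. A zero-variance (all-rows-identical) matrix is degenerate but
    legal: scores and explained variance come back as zeros.
    """
    X = matrix.values
    n, k = X.shape
    if not 1 <= n_components <= min(n, k):
        raise ParameterError(
            f"n_components must lie in [1, min(n, k)] = [1, {min(n, k)}], got {n_components}"
        )
    if not np.isfinite(X).all():
        raise InputError("feature matrix contains non-finite entries")
    if np.allclose(X, X[0]):
        zeros = np.zeros((n, n_components))
        return PCScores(zeros, np.zeros(n_components), n_components, matrix.sample_ids)
    solver = "randomized" if k > RANDOMIZED_SOLVER_THRESHOLD else "full"
    pca = PCA(n_components=n_components, whiten=True, svd_solver=solver, random_state=seed)
    coords = pca.fit_transform(X)
    # whitening rescales every component to unit variance, which would blow
    # numerically-zero directions of a rank-deficient matrix up into noise;
    # zero them instead
    negligible = pca.explained_variance_ < 1e-12 * pca.explained_variance_.max()
    coords[:, negligible] = 0.0
    evr = pca.explained_variance_ratio_.copy()
    evr[negligible] = 0.0
    return PCScores(coords, evr, n_components, matrix.sample_ids)


def genotype_separability(
    scores: PCScores,
    labels: Sequence,
    seed: int = 0,
    test_fraction: float = 0.25,
) -> SeparabilityResult:
    """Held-out accuracy of a logistic-loss classifier on the first two PCs.

    The split is stratified by inversion genotype (default 25% test). Every
    class must have at least two members to be stratifiable.
    """
    y = np.asarray(labels)
    if scores.coords.shape[0] != y.shape[0]:
        raise InputError(
            f"{scores.coords.shape[0]} score rows but {y.shape[0]} labels"
        )
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise InputError("separability needs at least two inversion genotype classes")
    if counts.min() < 2:
        bad = classes[counts.argmin()]
        raise InputError(
            f"class {bad!r} has a single member; stratified splitting is impossible"
        )
    X = scores.coords[:, :2]
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_fraction, stratify=y, random_state=seed
    )
    # Stochastic-gradient logistic regression, configured to actually reach
    # the separating solution on 2-D inputs: a constant step with iterate
    # averaging (the default decaying schedule stalls early), balanced class
    # weights so the homozygous-inverted class — tiny under Hardy-Weinberg
    # at moderate inversion frequency — is not absorbed by one-vs-rest, and
    # near-zero L2 (two features need no shrinkage, and shrinkage biases
    # the minority-class boundary).
    clf = SGDClassifier(
        loss="log_loss",
        learning_rate="constant",
        eta0=0.1,
        alpha=1e-6,
        average=True,
        max_iter=5000,
        tol=1e-5,
        class_weight="balanced",
        random_state=seed,
    )
    clf.fit(X_tr, y_tr)
    acc = float(accuracy_score(y_te, clf.predict(X_te)))
    return SeparabilityResult(acc, len(y_tr), len(y_te), seed)
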