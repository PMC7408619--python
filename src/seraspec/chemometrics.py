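"""Chemometric models: PCA, PLS-DA, random forest, linear SVM, samplers.

All classifiers are binary and expose a real-valued score whose threshold
reproduces the hard prediction exactly: PLS-DA predicts a 0/1 response
(positive iff score >= 0.5), the random forest scores with the fraction
of trees voting positive (threshold 0.5), and the linear SVM with its
signed decision value (threshold 0). Class-imbalance samplers (up-, down-
sampling and SMOTE) operate on feature-matrix rows and never touch the
feature dimension.

Model fitting is delegated to scikit-learn estimators (PCA,
PLSRegression with ``scale=False``, RandomForestClassifier, linear SVC);
this module fixes the conventions around them (labels, thresholds,
seeding, importances).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Sequence

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .spectra_io import SpectralDataset

__all__ = [
    "FeatureMatrix",
    "PCAResult",
    "ClassifierModel",
    "pca_fit",
    "pca_transform",
    "plsda_fit",
    "rf_fit",
    "svm_fit",
    "fit_classifier",
    "balance_classes",
    "cohen_kappa",
]


@dataclass
class FeatureMatrix:
    """Per-spectrum feature rows for one binary task.

    ``labels`` holds the class name of each row; ``y01`` encodes the
    positive class as 1. Patient ids are carried so that grouped
    cross-validation and per-patient voting remain well defined even
    after row resampling (synthetic/duplicated rows inherit the patient
    id of the row they derive from).
    """

    X: np.ndarray
    wavenumbers: np.ndarray
    spectrum_ids: list[str]
    patient_ids: list[str]
    labels: np.ndarray
    positive_class: str
    negative_class: str

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        n = self.X.shape[0]
        if not (len(self.spectrum_ids) == len(self.patient_ids) == len(self.labels) == n):
            raise ValueError("row metadata length mismatch")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")
        extra = set(self.labels) - {self.positive_class, self.negative_class}
        if extra:
            raise ValueError(f"rows with labels outside the task: {sorted(extra)}")

    @property
    def y01(self) -> np.ndarray:
        return (self.labels == self.positive_class).astype(int)

    @classmethod
    def from_dataset(
        cls, dataset: SpectralDataset, positive_class: str, negative_class: str
    ) -> "FeatureMatrix":
        spectra = [s for s in dataset.spectra if s.label in (positive_class, negative_class)]
        if not spectra:
            raise ValueError(
                f"no spectra labelled {positive_class!r} or {negative_class!r}"
            )
        return cls(
            X=np.stack([s.absorbances for s in spectra]),
            wavenumbers=spectra[0].wavenumbers.copy(),
            spectrum_ids=[s.spectrum_id for s in spectra],
            patient_ids=[s.patient_id for s in spectra],
            labels=np.array([s.label for s in spectra], dtype=object),
            positive_class=positive_class,
            negative_class=negative_class,
        )

    def take(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = np.asarray(indices, dtype=int)
        return FeatureMatrix(
            X=self.X[idx],
            wavenumbers=self.wavenumbers,
            spectrum_ids=[self.spectrum_ids[i] for i in idx],
            patient_ids=[self.patient_ids[i] for i in idx],
            labels=self.labels[idx],
            positive_class=self.positive_class,
            negative_class=self.negative_class,
        )

    def __len__(self) -> int:
        return self.X.shape[0]


# --- PCA ---------------------------------------------------------------------


@dataclass
class PCAResult:
    scores: np.ndarray             # (n, ncomp)
    loadings: np.ndarray           # (ncomp, p), orthonormal rows
    explained_fraction: np.ndarray # (ncomp,)
    mean: np.ndarray               # stored centring, for out-of-sample projection


def pca_fit(X: np.ndarray | FeatureMatrix, ncomp: int) -> PCAResult:
    """Column-mean-centred SVD; scores, orthonormal loadings, variance fractions."""
    if isinstance(X, FeatureMatrix):
        X = X.X
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 rows")
    if ncomp > min(X.shape[0] - 1, X.shape[1]):
        raise ValueError(f"ncomp {ncomp} exceeds min(rows-1, columns)")
    model = PCA(n_components=ncomp, svd_solver="full")
    scores = model.fit_transform(X)
    return PCAResult(
        scores=scores,
        loadings=model.components_,
        explained_fraction=model.explained_variance_ratio_,
        mean=model.mean_,
    )


def pca_transform(result: PCAResult, X: np.ndarray) -> np.ndarray:
    """Project new rows using the stored centring (no refitting)."""
    return (np.asarray(X, dtype=float) - result.mean) @ result.loadings.T


# --- classifiers -------------------------------------------------------------


@dataclass
class ClassifierModel:
    """A fitted binary discriminator with a thresholded score.

    ``threshold`` is 0.5 for PLS-DA (predicted response) and the random
    forest (vote fraction), 0.0 for the SVM decision value.
    """

    kind: str
    hyperparams: dict
    estimator: object
    threshold: float
    feature_importance: np.ndarray | None = None

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.kind == "plsda":
            return self.estimator.predict(X).ravel()
        if self.kind == "rf":
            proba = self.estimator.predict_proba(X)
            return proba[:, list(self.estimator.classes_).index(1)]
        if self.kind == "svm_linear":
            return self.estimator.decision_function(X)
        raise ValueError(f"unknown classifier kind {self.kind!r}")

    def predict(self, X: np.ndarray) -> np.ndarray:
        """1 for the positive class wherever score >= threshold."""
        return (self.score(X) >= self.threshold).astype(int)


def _check_two_classes(y01: np.ndarray) -> None:
    if len(np.unique(y01)) < 2:
        raise ValueError("training data contains a single class")


def plsda_fit(fm: FeatureMatrix, ncomp: int) -> ClassifierModel:
    """PLS-DA: PLS regression of the 0/1 response on centred features.

    The score is the raw predicted response; the positive class is called
    at 0.5. Importance is the first-component x-loading profile.
    """
    y = fm.y01
    _check_two_classes(y)
    if not 1 <= ncomp <= min(fm.X.shape):
        raise ValueError(f"ncomp {ncomp} out of range for X {fm.X.shape}")
    est = PLSRegression(n_components=ncomp, scale=False)
    est.fit(fm.X, y.astype(float))
    return ClassifierModel(
        kind="plsda",
        hyperparams={"ncomp": ncomp},
        estimator=est,
        threshold=0.5,
        feature_importance=np.abs(est.x_loadings_[:, 0]),
    )


def rf_fit(
    fm: FeatureMatrix,
    n_trees: int = 500,
    mtry: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> ClassifierModel:
    """Random forest of Gini-split trees grown to purity.

    ``mtry`` (features tried per split) defaults to ⌊√p⌋. The score is
    the fraction of trees voting positive — with pure leaves,
    scikit-learn's averaged leaf probabilities coincide with the vote
    fraction. Importance is the mean decrease in Gini impurity.
    """
    y = fm.y01
    _check_two_classes(y)
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if mtry is None:
        mtry = max(1, int(np.sqrt(fm.X.shape[1])))
    rng = np.random.default_rng(rng)
    seed = int(rng.integers(2**31))
    est = RandomForestClassifier(
        n_estimators=n_trees, max_features=mtry, random_state=seed, n_jobs=1
    )
    est.fit(fm.X, y)
    return ClassifierModel(
        kind="rf",
        hyperparams={"n_trees": n_trees, "mtry": mtry, "seed": seed},
        estimator=est,
        threshold=0.5,
        feature_importance=est.feature_importances_,
    )


def svm_fit(fm: FeatureMatrix, C: float = 1.0) -> ClassifierModel:
    """Soft-margin linear SVM; the score is the signed decision value."""
    y = fm.y01
    _check_two_classes(y)
    est = SVC(kernel="linear", C=C)
    est.fit(fm.X, y)
    importance = np.abs(est.coef_.ravel())
    return ClassifierModel(
        kind="svm_linear",
        hyperparams={"C": C},
        estimator=est,
        threshold=0.0,
        feature_importance=importance,
    )


def fit_classifier(
    fm: FeatureMatrix,
    kind: str,
    hyper,
    rng: np.random.Generator | int | None = None,
) -> ClassifierModel:
    """Dispatch on kind with the tuned hyperparameter (ncomp / n_trees / C)."""
    if kind == "plsda":
        return plsda_fit(fm, int(hyper))
    if kind == "rf":
        return rf_fit(fm, n_trees=int(hyper), rng=rng)
    if kind == "svm_linear":
        return svm_fit(fm, C=float(hyper))
    raise ValueError(f"unknown classifier kind {kind!r}")


# --- class balancing ---------------------------------------------------------


def balance_classes(
    fm: FeatureMatrix,
    method: str = "none",
    k: int = 5,
    rng: np.random.Generator | int | None = None,
) -> FeatureMatrix:
    """Equalise class counts by row resampling.

    ``up``: minority rows re-drawn with replacement until counts match
    (all original rows retained). ``down``: majority subsampled without
    replacement. ``smote``: synthetic minority rows x + λ(x_nn − x) with
    λ ~ U(0,1) and x_nn one of the k nearest minority neighbours
    (Euclidean); requires more minority rows than k. Synthetic and
    duplicated rows inherit the patient id of their seed row.
    """
    if method == "none":
        return fm
    rng = np.random.default_rng(rng)
    y = fm.y01
    _check_two_classes(y)
    idx_pos = np.where(y == 1)[0]
    idx_neg = np.where(y == 0)[0]
    minority, majority = (idx_pos, idx_neg) if len(idx_pos) < len(idx_neg) else (idx_neg, idx_pos)
    deficit = len(majority) - len(minority)
    if deficit == 0 and method in ("up", "down", "smote"):
        return fm

    if method == "up":
        extra = rng.choice(minority, size=deficit, replace=True)
        order = np.concatenate([np.arange(len(fm)), extra])
        return fm.take(order)
    if method == "down":
        keep_majority = rng.choice(majority, size=len(minority), replace=False)
        keep = np.sort(np.concatenate([minority, keep_majority]))
        return fm.take(keep)
    if method == "smote":
        if len(minority) <= k:
            raise ValueError(f"SMOTE needs > k={k} minority rows, got {len(minority)}")
        Xmin = fm.X[minority]
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xmin)
        _, neigh = nn.kneighbors(Xmin)  # column 0 is the point itself
        rows, sids, pids, labs = [], [], [], []
        for j in range(deficit):
            i = int(rng.integers(len(minority)))
            m = int(neigh[i, 1 + rng.integers(k)])
            lam = float(rng.uniform())
            rows.append(Xmin[i] + lam * (Xmin[m] - Xmin[i]))
            src = minority[i]
            sids.append(f"smote_{j}_{fm.spectrum_ids[src]}")
            pids.append(fm.patient_ids[src])
            labs.append(fm.labels[src])
        return FeatureMatrix(
            X=np.vstack([fm.X, np.stack(rows)]),
            wavenumbers=fm.wavenumbers,
            spectrum_ids=fm.spectrum_ids + sids,
            patient_ids=fm.patient_ids + pids,
            labels=np.concatenate([fm.labels, np.array(labs, dtype=object)]),
            positive_class=fm.positive_class,
            negative_class=fm.negative_class,
        )
    raise ValueError(f"unknown balancing method {method!r}")


# --- agreement statistic -----------------------------------------------------


def cohen_kappa(y_true: Sequence, y_pred: Sequence) -> float:
    """Cohen's κ = (p_o − p_e)/(1 − p_e) from the two label sequences.

    When chance agreement p_e is 1 (both marginals degenerate on one
    class), κ is defined as 1.0 for perfect agreement and 0.0 otherwise.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred) or len(y_true) == 0:
        raise ValueError("label sequences must have equal length >= 1")
    n = len(y_true)
    classes = np.unique(np.concatenate([y_true, y_pred]))
    p_o = float(np.mean(y_true == y_pred))
    p_e = sum(
        float(np.mean(y_true == c)) * float(np.mean(y_pred == c)) for c in classes
    )
    if abs(1.0 - p_e) < 1e-15:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)
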