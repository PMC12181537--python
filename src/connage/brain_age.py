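"""Brain-age prediction.

Assembles multimodal feature vectors (structural connectivity, functional
connectivity, nodal temporal variability, regional GM/WM/CSF densities) and
runs a two-round tenfold cross-validated Lasso protocol:

1. feature screening — per fold, a Lasso with internal regularization-path
   selection is fit on the training portion; features with non-zero
   coefficients are pooled across folds;
2. prediction — a second tenfold CV restricted to the pooled features
   produces out-of-fold age predictions, MAE/RMSE, and the per-subject
   brain-age gap (predicted minus chronological age).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from .connectivity import ConnectivityMatrix
from .synthetic import SubjectRecord

__all__ = [
    "FeatureMatrix",
    "BrainAgeResult",
    "assemble_features",
    "assemble_feature_matrix",
    "feature_names",
    "select_features_cv",
    "fit_predict_cv",
    "brain_age_gap",
]


@dataclass
class FeatureMatrix:
    """n_subjects x p feature matrix with deterministic column naming:
    ``sc:i-j``, ``fc:i-j`` (upper-triangle pairs), ``tv:k``, ``gm:k``,
    ``wm:k``, ``csf:k``."""

    values: np.ndarray
    feature_names: list[str]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if v.shape != (len(self.subject_ids), len(self.feature_names)):
            raise ValueError("shape inconsistent with names/ids")
        if not np.isfinite(v).all():
            raise ValueError("feature matrix contains non-finite values")
        self.values = v

    def restrict(self, names: set[str] | list[str]) -> "FeatureMatrix":
        keep = [i for i, n in enumerate(self.feature_names) if n in set(names)]
        return FeatureMatrix(
            values=self.values[:, keep],
            feature_names=[self.feature_names[i] for i in keep],
            subject_ids=self.subject_ids,
        )


@dataclass
class BrainAgeResult:
    """Cross-validated brain-age predictions and accuracy metrics."""

    subject_ids: list[str]
    chronological_age: np.ndarray
    predicted_age: np.ndarray
    gap: np.ndarray  # predicted - chronological, years
    mae: float
    rmse: float
    alpha: float  # regularization of the final all-data refit
    selected_features: set[str]
    fold_assignments: np.ndarray
    seed: int


def feature_names(n_regions: int, dynamic: str = "tv") -> list[str]:
    """Deterministic column names for R regions.

    ``dynamic="tv"`` uses the R temporal-variability columns; ``"sl"``
    replaces them with synchronization-likelihood pair columns.
    """
    iu, ju = np.triu_indices(n_regions, k=1)
    names = [f"sc:{i}-{j}" for i, j in zip(iu, ju)]
    names += [f"fc:{i}-{j}" for i, j in zip(iu, ju)]
    if dynamic == "tv":
        names += [f"tv:{k}" for k in range(n_regions)]
    elif dynamic == "sl":
        names += [f"sl:{i}-{j}" for i, j in zip(iu, ju)]
    else:
        raise ValueError(f"unknown dynamic feature kind {dynamic!r}")
    for mod in ("gm", "wm", "csf"):
        names += [f"{mod}:{k}" for k in range(n_regions)]
    return names


def assemble_features(
    subject: SubjectRecord,
    fc: ConnectivityMatrix,
    sc: ConnectivityMatrix,
    dynamic_values: np.ndarray,
    dynamic: str = "tv",
) -> tuple[np.ndarray, list[str]]:
    """One subject's feature row: SC upper triangle, FC upper triangle, the
    dynamic block (R temporal-variability values, or the SL upper triangle),
    then GM, WM, CSF densities (R each)."""
    R = subject.n_regions
    for name, mat in (("fc", fc), ("sc", sc)):
        if mat.n_regions != R:
            raise ValueError(
                f"{name} matrix has {mat.n_regions} regions, subject has {R}"
            )
    dynamic_values = np.asarray(dynamic_values, dtype=float)
    iu, ju = np.triu_indices(R, k=1)
    if dynamic == "tv":
        if dynamic_values.shape != (R,):
            raise ValueError("tv block must have one value per region")
        dyn = dynamic_values
    elif dynamic == "sl":
        if dynamic_values.shape != (R, R):
            raise ValueError("sl block must be an R x R matrix")
        dyn = dynamic_values[iu, ju]
    else:
        raise ValueError(f"unknown dynamic feature kind {dynamic!r}")
    if subject.tissue_density.shape != (3, R):
        raise ValueError("tissue density must be 3 x R")
    row = np.concatenate(
        [
            sc.values[iu, ju],
            fc.values[iu, ju],
            dyn,
            subject.tissue_density[0],
            subject.tissue_density[1],
            subject.tissue_density[2],
        ]
    )
    return row, feature_names(R, dynamic=dynamic)


def assemble_feature_matrix(
    rows: list[np.ndarray], names: list[str], subject_ids: list[str]
) -> FeatureMatrix:
    return FeatureMatrix(
        values=np.vstack(rows), feature_names=names, subject_ids=subject_ids
    )


def _fold_standardize(train: np.ndarray, test: np.ndarray):
    """Z-score columns on training statistics; constant columns map to 0."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def _screening_coef(Xtr: np.ndarray, ytr: np.ndarray, seed: int) -> np.ndarray:
    """Lasso coefficients at the screening regularization.

    The regularization path is tuned by 5-fold CV; the reported coefficients
    use the one-standard-error rule (largest alpha whose CV error is within
    one SE of the minimum), which keeps the screening conservative: on pure
    noise it selects (almost) nothing, while genuinely predictive features
    survive.
    """
    model = LassoCV(cv=5, random_state=seed, alphas=60, max_iter=5000, tol=1e-3)
    model.fit(Xtr, ytr)
    mse = model.mse_path_.mean(axis=1)
    se = model.mse_path_.std(axis=1) / np.sqrt(model.mse_path_.shape[1])
    i_min = int(np.argmin(mse))
    # alphas_ is descending; the first index within one SE is the sparsest.
    i_1se = int(np.flatnonzero(mse <= mse[i_min] + se[i_min])[0])
    if i_1se == i_min:
        return model.coef_
    refit = Lasso(alpha=model.alphas_[i_1se], max_iter=5000, tol=1e-3)
    return refit.fit(Xtr, ytr).coef_


def _prediction_lasso_cv(
    Xtr: np.ndarray, ytr: np.ndarray, seed: int, extensions: int = 3
) -> LassoCV:
    """CV-tuned Lasso at the error-minimizing regularization.

    When the CV error indicates an (almost) noiseless linear target, the fit
    is refined with a tighter convergence tolerance and the regularization
    path extended below its usual floor, so exact linear relationships are
    recovered to fine precision instead of stopping at the path bottom.
    """
    model = LassoCV(
        cv=5, random_state=seed, alphas=100, max_iter=10000, tol=1e-4
    ).fit(Xtr, ytr)
    y_var = float(np.var(ytr))
    if y_var > 0 and model.mse_path_.mean(axis=1).min() < 1e-4 * y_var:
        model = LassoCV(
            cv=5, random_state=seed, alphas=100, max_iter=100000, tol=1e-8
        ).fit(Xtr, ytr)
        for _ in range(extensions):
            a_min = model.alphas_.min()
            if model.alpha_ > a_min * (1 + 1e-10):
                break
            alphas = np.geomspace(a_min, a_min * 1e-4, 40)
            model = LassoCV(
                cv=5, random_state=seed, alphas=alphas, max_iter=100000, tol=1e-8
            ).fit(Xtr, ytr)
    return model


def select_features_cv(
    X: FeatureMatrix, y: np.ndarray, k: int = 10, seed: int = 42
) -> set[str]:
    """Round-1 feature screening: union across folds of Lasso-selected
    (non-zero coefficient) features, each fold tuning its own regularization
    on the training portion."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2 * k:
        raise ValueError(f"need n >= 2k subjects (n={n}, k={k})")
    if np.ptp(y) == 0:
        raise ValueError("target is constant")
    selected: set[str] = set()
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for train_idx, _ in kf.split(X.values):
            Xtr, _ = _fold_standardize(X.values[train_idx], X.values[train_idx])
            coef = _screening_coef(Xtr, y[train_idx], seed)
            selected.update(X.feature_names[i] for i in np.flatnonzero(coef))
    return selected


def fit_predict_cv(
    X: FeatureMatrix, y: np.ndarray, k: int = 10, seed: int = 42
) -> BrainAgeResult:
    """Round-2 prediction on the selected-feature matrix: out-of-fold
    predictions aggregated over all folds, MAE/RMSE, per-subject gap, and
    the regularization strength of the final all-data refit."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X.values.shape[1] == 0:
        raise ValueError(
            "empty feature selection; re-run with the full feature set"
        )
    if n < 2 * k:
        raise ValueError(f"need n >= 2k subjects (n={n}, k={k})")
    preds = np.empty(n)
    folds = np.empty(n, dtype=int)
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for fold_id, (train_idx, test_idx) in enumerate(kf.split(X.values)):
            Xtr, Xte = _fold_standardize(X.values[train_idx], X.values[test_idx])
            model = _prediction_lasso_cv(Xtr, y[train_idx], seed)
            preds[test_idx] = model.predict(Xte)
            folds[test_idx] = fold_id
        Xall, _ = _fold_standardize(X.values, X.values)
        final = _prediction_lasso_cv(Xall, y, seed)
    gap = brain_age_gap(preds, y)
    mae = float(np.mean(np.abs(gap)))
    rmse = float(np.sqrt(np.mean(gap**2)))
    return BrainAgeResult(
        subject_ids=list(X.subject_ids),
        chronological_age=y,
        predicted_age=preds,
        gap=gap,
        mae=mae,
        rmse=rmse,
        alpha=float(final.alpha_),
        selected_features=set(X.feature_names),
        fold_assignments=folds,
        seed=seed,
    )


def brain_age_gap(predicted: np.ndarray, chronological: np.ndarray) -> np.ndarray:
    """Elementwise predicted minus chronological age, in years."""
    predicted = np.asarray(predicted, dtype=float)
    chronological = np.asarray(chronological, dtype=float)
    if predicted.shape != chronological.shape:
        raise ValueError(
            f"length mismatch: {predicted.shape} vs {chronological.shape}"
        )
    return predicted - chronological
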