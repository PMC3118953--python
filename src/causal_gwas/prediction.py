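"""Genotype encoding and kernel ridge regression signatures.

Selected SNPs are encoded as 0/1/2 minor-allele dosages, missing calls are
imputed with the training-set per-SNP mode, and each column is centered and
scaled by training-set statistics (sample s.d., ddof=1; constant columns
get scale 1). Kernel ridge regression with the radial basis kernel
K(x, y) = exp(−γ‖x−y‖²) solves the dual system (K + λI)c = y on 0/1 labels
and scores a new subject z as Σᵢ cᵢ·K(z, xᵢ); the continuous score ranks
subjects for ROC analysis. λ and γ are selected by stratified 10-fold
cross-validation maximizing mean fold AUC; ties prefer the smaller γ, then
the larger λ (stronger regularization). The default λ grid is
{10⁻¹⁰, 10⁻⁸, …, 1}; the default γ grid scales inversely with the number of
SNPs in the model, γ ∈ {2⁻³/n, …, 2³/n}.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import linalg
from sklearn.metrics import roc_auc_score
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.model_selection import StratifiedKFold

from .gwas_io import MISSING, GenotypeDataset


@dataclass
class EncodingParams:
    snp_ids: list[str]
    modes: np.ndarray   # per-SNP imputation value
    means: np.ndarray
    scales: np.ndarray


@dataclass
class KRRModel:
    X_train: np.ndarray
    dual_coef: np.ndarray
    gamma: float
    lam: float
    encoding: Optional[EncodingParams] = None

    @property
    def snp_ids(self) -> Optional[list[str]]:
        return None if self.encoding is None else self.encoding.snp_ids


def default_lambda_grid() -> np.ndarray:
    """λ ∈ {10⁻¹⁰, 10⁻⁸, 10⁻⁶, 10⁻⁴, 10⁻², 1}."""
    return 10.0 ** np.arange(-10, 1, 2)


def default_gamma_grid(n_snps: int) -> np.ndarray:
    """γ ∈ {2ᵏ/n : k = −3 … 3} for a model over n SNPs."""
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    return 2.0 ** np.arange(-3, 4) / n_snps


def encode(
    ds: GenotypeDataset,
    snps: Sequence[str],
    fit_params: Optional[EncodingParams] = None,
) -> tuple[np.ndarray, EncodingParams]:
    """Encode selected SNP columns to a standardized numeric matrix.

    With ``fit_params`` given (a training-set fit), its imputation modes and
    center/scale statistics are reused — the test-set contract.
    """
    missing_ids = [s for s in snps if s not in set(ds.snp_ids)]
    if missing_ids:
        raise KeyError(f"SNP(s) not genotyped in dataset: {', '.join(missing_ids)}")
    cols = np.stack([ds.column(s) for s in snps], axis=1).astype(float)
    cols[cols == MISSING] = np.nan

    if fit_params is None:
        modes = np.empty(cols.shape[1])
        for j in range(cols.shape[1]):
            col = cols[:, j]
            obs = col[~np.isnan(col)].astype(int)
            if len(obs) == 0:
                modes[j] = 0.0
            else:
                modes[j] = float(np.argmax(np.bincount(obs, minlength=3)))
        filled = np.where(np.isnan(cols), modes, cols)
        means = filled.mean(axis=0)
        scales = filled.std(axis=0, ddof=1) if len(filled) > 1 else np.ones(cols.shape[1])
        scales = np.where(scales > 0, scales, 1.0)
        params = EncodingParams(list(snps), modes, means, scales)
    else:
        if list(snps) != fit_params.snp_ids:
            raise ValueError("snps do not match the fitted encoding parameters")
        params = fit_params
        filled = np.where(np.isnan(cols), params.modes, cols)
    X = (filled - params.means) / params.scales
    return X, params


def krr_fit(X: np.ndarray, y: np.ndarray, lam: float, gamma: float) -> KRRModel:
    """Fit dual coefficients of RBF kernel ridge regression: (K + λI)c = y."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if lam < 0 or gamma <= 0:
        raise ValueError("require lam >= 0 and gamma > 0")
    if len(X) < 2:
        raise ValueError("need at least 2 training subjects")
    K = rbf_kernel(X, X, gamma=gamma)
    A = K + lam * np.eye(len(X))
    try:
        c = linalg.solve(A, y, assume_a="sym")
    except linalg.LinAlgError:
        c = None
    bad = c is None or not np.all(np.isfinite(c)) or (
        np.max(np.abs(A @ c - y)) > 1e-6 * max(1.0, float(np.max(np.abs(y))))
    )
    if bad:
        if lam == 0:
            raise np.linalg.LinAlgError(
                "kernel system singular (duplicate rows at λ=0?); use λ > 0"
            )
        # λ > 0: mathematically non-singular but numerically ill-conditioned
        # (e.g. duplicate rows at tiny λ); min-norm solution is well defined
        c, *_ = np.linalg.lstsq(A, y, rcond=None)
    return KRRModel(X, c, gamma, lam)


def krr_predict(model: KRRModel, X: np.ndarray) -> np.ndarray:
    """Continuous prediction scores Σᵢ cᵢ·K(z, xᵢ)."""
    K = rbf_kernel(np.asarray(X, dtype=float), model.X_train, gamma=model.gamma)
    return K @ model.dual_coef


def tune_krr(
    X: np.ndarray,
    y: np.ndarray,
    lambda_grid: Optional[Sequence[float]] = None,
    gamma_grid: Optional[Sequence[float]] = None,
    folds: int = 10,
    seed: int = 0,
) -> tuple[float, float, list[dict]]:
    """Select (λ, γ) by stratified k-fold CV maximizing mean fold AUC."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    lams = np.asarray(
        lambda_grid if lambda_grid is not None else default_lambda_grid(), dtype=float
    )
    gams = np.asarray(
        gamma_grid if gamma_grid is not None else default_gamma_grid(X.shape[1]),
        dtype=float,
    )
    if len(lams) == 0 or len(gams) == 0:
        raise ValueError("parameter grids must be non-empty")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    n_min = int(min(np.sum(y == 0), np.sum(y == 1)))
    if n_min < folds:
        raise ValueError(
            f"a class has only {n_min} subjects: a fold would hold one class; "
            f"use at most {n_min} folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))

    table: list[dict] = []
    best: tuple[float, float, float] | None = None  # (mean_auc, lam, gamma)
    # ascending gamma, descending lambda: first strict maximum realises the
    # tie-break (smaller gamma, then larger lambda)
    for gamma in sorted(gams):
        for lam in sorted(lams, reverse=True):
            aucs = []
            for tr, te in splits:
                model = krr_fit(X[tr], y[tr], lam, gamma)
                scores = krr_predict(model, X[te])
                aucs.append(roc_auc_score(y[te], scores))
            mean_auc = float(np.mean(aucs))
            table.append({"lambda": float(lam), "gamma": float(gamma), "cv_auc": mean_auc})
            if best is None or mean_auc > best[0]:
                best = (mean_auc, float(lam), float(gamma))
    assert best is not None
    return best[1], best[2], table


def fit_signature(
    ds: GenotypeDataset,
    snps: Sequence[str],
    lambda_grid: Optional[Sequence[float]] = None,
    gamma_grid: Optional[Sequence[float]] = None,
    folds: int = 10,
    seed: int = 0,
) -> KRRModel:
    """Encode a training dataset over ``snps``, tune and fit one KRR model."""
    if ds.phenotype is None:
        raise ValueError("training dataset needs a phenotype")
    X, params = encode(ds, snps)
    lam, gamma, _ = tune_krr(
        X, ds.phenotype, lambda_grid, gamma_grid, folds=folds, seed=seed
    )
    model = krr_fit(X, ds.phenotype.astype(float), lam, gamma)
    model.encoding = params
    return model


def predict_signature(model: KRRModel, ds: GenotypeDataset) -> np.ndarray:
    """Score a dataset with a fitted signature (training encoding reused)."""
    if model.encoding is None:
        raise ValueError("model has no stored encoding parameters")
    X, _ = encode(ds, model.encoding.snp_ids, fit_params=model.encoding)
    return krr_predict(model, X)
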