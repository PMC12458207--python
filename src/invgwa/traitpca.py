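"""Trait-space PCA with regularized iterative imputation of missing values.

Missing line x trait cells are imputed by iterating a low-rank SVD
reconstruction whose singular values are shrunk by a noise-variance estimate
(regularized PCA imputation): observed cells are never modified, imputed cells
converge to a fixed point of the reconstruction. The completed matrix is then
column-standardized and decomposed by SVD; inverted vs standard arrangement
groups are compared on the component scores with a Welch two-sample t-test
(the unequal-variance form — arrangement groups are small and imbalanced, and
their score variances genuinely differ).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import INV, STD, DataValidationError, InversionTable

__all__ = ["TraitPCAResult", "impute_regularized_pca", "trait_pca", "pc_group_test"]


def impute_regularized_pca(
    trait_matrix: pd.DataFrame | np.ndarray,
    ncp: int = 2,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int | None = None,
) -> tuple[pd.DataFrame | np.ndarray, bool]:
    """Complete a lines x traits matrix by regularized iterative PCA.

    Missing cells start at trait means; each iteration standardizes with the
    current column statistics, reconstructs at rank ``ncp`` with singular
    values shrunk by the trailing-component noise variance, and overwrites
    only the missing cells. Returns ``(completed, converged)``.
    """
    is_df = isinstance(trait_matrix, pd.DataFrame)
    X = np.asarray(trait_matrix, dtype=float).copy()
    n, p = X.shape
    mask = np.isnan(X)
    if (np.sum(~mask, axis=0) < 2).any():
        raise DataValidationError("every trait needs >= 2 observed values")
    if (np.sum(~mask, axis=1) < 1).any():
        raise DataValidationError("every line needs >= 1 observed value")
    if ncp >= min(n, p):
        raise DataValidationError(f"ncp={ncp} must be below min(n, p)={min(n, p)}")
    if not mask.any():
        return trait_matrix, True

    col_mean = np.nanmean(X, axis=0)
    X[mask] = np.broadcast_to(col_mean, X.shape)[mask]

    converged = False
    for _ in range(max_iter):
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        sd = np.where(sd == 0, 1.0, sd)
        Z = (X - mu) / sd
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        lam = s**2 / (n - 1)
        sigma2 = float(lam[ncp:].mean()) if len(lam) > ncp else 0.0
        shrink = np.zeros_like(s)
        lead = lam[:ncp]
        with np.errstate(divide="ignore", invalid="ignore"):
            shrink[:ncp] = np.where(lead > 0, np.maximum(lead - sigma2, 0.0) / lead, 0.0)
        Z_hat = (U[:, :ncp] * (s[:ncp] * shrink[:ncp])) @ Vt[:ncp]
        X_new = Z_hat * sd + mu
        delta = np.max(np.abs(X_new[mask] - X[mask])) / (np.std(X) + 1e-12)
        X[mask] = X_new[mask]
        if delta < tol:
            converged = True
            break

    if is_df:
        out = trait_matrix.copy()
        out.iloc[:, :] = X
        return out, converged
    return X, converged


@dataclass
class TraitPCAResult:
    scores: pd.DataFrame  # lines x components
    loadings: pd.DataFrame  # traits x components
    variance_explained: np.ndarray
    n_components_retained: int


def trait_pca(complete: pd.DataFrame, scale: bool = True) -> TraitPCAResult:
    """Column-standardized PCA via SVD of a complete lines x traits matrix."""
    if complete.isna().to_numpy().any():
        raise DataValidationError("trait_pca requires a complete matrix (impute first)")
    X = complete.to_numpy(dtype=float)
    n, p = X.shape
    Z = X - X.mean(axis=0)
    if scale:
        sd = Z.std(axis=0, ddof=1)
        sd = np.where(sd == 0, 1.0, sd)
        Z = Z / sd
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    k = int((s > s[0] * 1e-12).sum()) if len(s) else 0
    var_exp = s**2 / (s**2).sum()
    comp = [f"PC{i + 1}" for i in range(len(s))]
    scores = pd.DataFrame(Z @ Vt.T, index=complete.index, columns=comp)
    loadings = pd.DataFrame(Vt.T, index=complete.columns, columns=comp)
    return TraitPCAResult(
        scores=scores,
        loadings=loadings,
        variance_explained=var_exp,
        n_components_retained=k,
    )


def pc_group_test(
    scores: pd.DataFrame,
    inversions: InversionTable,
    inversion: str,
    component: str = "PC1",
) -> tuple[float, float, float]:
    """Welch t-test of PC scores between INV and STD homozygous lines.

    Returns ``(t, df, p)`` with Satterthwaite fractional degrees of freedom.
    """
    lines = scores.index.to_numpy(dtype=object)
    g = inversions.genotype(inversion, lines)
    a = scores.loc[g == INV, component].to_numpy(dtype=float)
    b = scores.loc[g == STD, component].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DataValidationError("both arrangement groups need >= 2 lines")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
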