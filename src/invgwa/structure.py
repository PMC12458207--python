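"""Variant selection strategies and genomic PCA.

Implements the three polymorphism-selection strategies (Full, LD-thinned,
leave-one-chromosome-out), standardized-genotype PCA over the selected set,
and the permutation test for how much principal-component variance an
inversion explains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    INV,
    STD,
    DataValidationError,
    GenotypeMatrix,
    InversionTable,
    SelectionStrategy,
)

__all__ = [
    "filter_variants",
    "pairwise_r2",
    "ld_prune",
    "GenomicPCAResult",
    "select_variants",
    "genomic_pca",
    "pc_inversion_r2",
]


def filter_variants(
    genotypes: GenotypeMatrix, maf_min: float = 0.05, miss_max: float = 0.20
) -> np.ndarray:
    """Indices with MAF strictly above ``maf_min`` and missing fraction
    strictly below ``miss_max``."""
    return np.flatnonzero(
        (genotypes.maf > maf_min) & (genotypes.missing_fraction < miss_max)
    )


def pairwise_r2(a: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of dosage vector ``a`` with each column of
    ``B`` over pairwise-complete lines (composite LD on dosages)."""
    B = np.atleast_2d(B.T).T
    valid = np.isfinite(a)[:, None] & np.isfinite(B)
    a0 = np.where(valid, a[:, None], 0.0)
    b0 = np.where(valid, B, 0.0)
    n = valid.sum(axis=0).astype(float)
    n[n == 0] = np.nan
    sa, sb = a0.sum(0), b0.sum(0)
    saa, sbb, sab = (a0 * a0).sum(0), (b0 * b0).sum(0), (a0 * b0).sum(0)
    cov = sab - sa * sb / n
    va = saa - sa * sa / n
    vb = sbb - sb * sb / n
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = cov * cov / (va * vb)
    return np.where((va > 0) & (vb > 0), r2, 0.0)


def ld_prune(
    genotypes: GenotypeMatrix,
    candidates: np.ndarray,
    r2_max: float = 0.2,
    min_spacing_bp: int = 5000,
    window: int = 50,
) -> np.ndarray:
    """Greedy left-to-right LD pruning per arm.

    A candidate is kept iff it lies at least ``min_spacing_bp`` beyond the
    last kept variant on its arm and its dosage r² with each of the last
    ``window`` kept variants is strictly below ``r2_max``. Deterministic in
    the position ordering, and idempotent.
    """
    candidates = np.asarray(candidates, dtype=int)
    if candidates.size == 0:
        return candidates
    arms = genotypes.variants["arm"].to_numpy()
    pos = genotypes.variants["pos"].to_numpy()
    dos = genotypes.dosages
    kept_all: list[int] = []
    for arm in pd.unique(arms[candidates]):
        cand = candidates[arms[candidates] == arm]
        cand = cand[np.argsort(pos[cand], kind="stable")]
        kept: list[int] = []
        kept_cols: list[np.ndarray] = []
        last_pos = -np.inf
        for j in cand:
            if pos[j] - last_pos < min_spacing_bp:
                continue
            if kept_cols:
                B = np.column_stack(kept_cols[-window:])
                if np.nanmax(pairwise_r2(dos[:, j], B)) >= r2_max:
                    continue
            kept.append(int(j))
            kept_cols.append(dos[:, j])
            last_pos = pos[j]
        kept_all.extend(kept)
    return np.array(sorted(kept_all), dtype=int)


def select_variants(genotypes: GenotypeMatrix, strategy: SelectionStrategy) -> np.ndarray:
    """Variant index set under a selection strategy."""
    if strategy.name == "full":
        return filter_variants(genotypes, strategy.maf_min, strategy.miss_max)
    idx = filter_variants(genotypes, strategy.maf_min, strategy.miss_max)
    if strategy.name == "loco":
        arms = genotypes.variants["arm"].to_numpy()
        if not (arms != strategy.excluded_arm).any():
            raise DataValidationError(
                f"LOCO({strategy.excluded_arm}): no variants left on other arms"
            )
        idx = idx[arms[idx] != strategy.excluded_arm]
    return ld_prune(genotypes, idx, strategy.r2_max, strategy.min_spacing_bp)


@dataclass
class GenomicPCAResult:
    scores: pd.DataFrame  # lines x components
    eigenvalues: np.ndarray
    strategy: SelectionStrategy
    variants_used: np.ndarray


def genomic_pca(
    genotypes: GenotypeMatrix,
    strategy: SelectionStrategy,
    n_components: int = 10,
) -> GenomicPCAResult:
    """Standardized-genotype PCA: each variant is scaled to
    ``(x - 2p) / sqrt(2p(1-p))`` with missing entries zeroed after centring,
    then the line x line covariance is eigendecomposed. Scores are the leading
    eigenvectors scaled by the singular values."""
    idx = select_variants(genotypes, strategy)
    if idx.size == 0:
        raise DataValidationError("selection produced an empty variant set")
    dos = genotypes.dosages[:, idx]
    p = np.nanmean(dos, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    idx, dos, p = idx[poly], dos[:, poly], p[poly]
    Z = (dos - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    Z = np.where(np.isfinite(Z), Z, 0.0)
    m = Z.shape[1]
    C = Z @ Z.T / m
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    vals = np.maximum(vals[order], 0.0)
    vecs = vecs[:, order]
    k = min(n_components, len(vals))
    comp = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(
        vecs[:, :k] * np.sqrt(vals[:k]), index=list(genotypes.line_ids), columns=comp
    )
    return GenomicPCAResult(
        scores=scores, eigenvalues=vals, strategy=strategy, variants_used=idx
    )


def pc_inversion_r2(
    pca: GenomicPCAResult,
    inversions: InversionTable,
    inversion: str,
    component: str = "PC1",
    n_perm: int = 100,
    seed: int = 0,
) -> tuple[float, np.ndarray, bool]:
    """R² of a PC score on inversion genotype (homozygotes only) against a
    label-shuffling permutation null.

    Returns ``(r_squared, permuted r² values, exceeds_q95)``.
    """
    lines = pca.scores.index.to_numpy(dtype=object)
    g = inversions.genotype(inversion, lines)
    keep = np.isin(g, (INV, STD))
    y = pca.scores.loc[keep, component].to_numpy(dtype=float)
    x = (g[keep] == INV).astype(float)

    def _r2(xv: np.ndarray) -> float:
        xc = xv - xv.mean()
        yc = y - y.mean()
        sxx, syy = float(xc @ xc), float(yc @ yc)
        if sxx == 0 or syy == 0:
            return np.nan
        return float((xc @ yc) ** 2 / (sxx * syy))

    obs = _r2(x)
    rng = np.random.default_rng(seed)
    perm = np.array([_r2(rng.permutation(x)) for _ in range(n_perm)])
    q95 = np.nanpercentile(perm, 95, method="linear")
    return obs, perm, bool(obs > q95)
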