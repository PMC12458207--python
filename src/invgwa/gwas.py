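"""The four genome-wide association strategies and their trait permutations.

Strategies differ only in the relatedness correction and the treatment of
inversions:

``full``
    VanRaden GRM from the full filtered genome; raw trait.
``ld``
    GCTA GRM from the LD-pruned genome; raw trait.
``loco``
    Per-arm scoring: variants on an arm are tested against the sub-GRM built
    without that arm, so the arm's own LD block is never part of the
    correction.
``factored``
    The trait is first residualized on the panel's inversion dosages, then
    scored with the Full GRM (the standard reference-panel webtool approach).

Permutations shuffle trait values across lines with genotypes, covariates and
the relatedness kernel held fixed; permutation seeds derive from the master
seed and the permutation index so any single permutation is reproducible in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    GRM,
    CovariateTable,
    DataValidationError,
    GenotypeMatrix,
    GWAResult,
    InversionTable,
)
from .lmm import MixedLMM

__all__ = ["GRMBundle", "ScanCache", "factor_out_inversions", "run_gwa", "permute_gwa"]


@dataclass
class GRMBundle:
    """The relatedness matrices a study needs: Full, LD, and per-arm LOCO."""

    full: GRM | None = None
    ld: GRM | None = None
    loco: dict[str, GRM] = field(default_factory=dict)

    def for_method(self, method: str) -> GRM | dict[str, GRM]:
        if method in ("full", "factored"):
            if self.full is None:
                raise DataValidationError(f"method {method!r} needs the Full GRM")
            return self.full
        if method == "ld":
            if self.ld is None:
                raise DataValidationError("method 'ld' needs the LD GRM")
            return self.ld
        if method == "loco":
            if not self.loco:
                raise DataValidationError("method 'loco' needs per-arm sub-GRMs")
            return self.loco
        raise DataValidationError(f"unknown GWA method {method!r}")


class ScanCache:
    """Caches per-(GRM, line-set) eigendecompositions and rotated genotype
    blocks so permutation scans cost O(n m) per fit instead of O(n^2 m)."""

    def __init__(self) -> None:
        self._grm: dict = {}
        self._rot: dict = {}
        self._geno: dict = {}
        self._filter: dict = {}
        self._rows: dict = {}
        self._meta: dict = {}

    def variant_meta(self, genotypes: GenotypeMatrix) -> tuple:
        key = id(genotypes)
        if key not in self._meta:
            v = genotypes.variants
            self._meta[key] = (
                v["id"].to_numpy(dtype=object),
                v["arm"].to_numpy(dtype=object),
                v["pos"].to_numpy(),
            )
        return self._meta[key]

    def line_rows(self, genotypes: GenotypeMatrix, line_key: tuple) -> np.ndarray:
        key = (id(genotypes), line_key)
        if key not in self._rows:
            self._rows[key] = genotypes.line_index(line_key)
        return self._rows[key]

    def variant_filter(
        self, genotypes: GenotypeMatrix, line_key: tuple, line_rows: np.ndarray,
        maf_min: float, miss_max: float,
    ) -> np.ndarray:
        key = (id(genotypes), line_key, maf_min, miss_max)
        if key not in self._filter:
            self._filter[key] = _variant_filter(genotypes, line_rows, maf_min, miss_max)
        return self._filter[key]

    def subset_grm(self, grm: GRM, line_key: tuple, line_ids) -> GRM:
        key = (id(grm), line_key)
        if key not in self._grm:
            self._grm[key] = grm.subset(line_ids)
        return self._grm[key]

    def genotype_block(
        self, genotypes: GenotypeMatrix, line_key: tuple, line_rows: np.ndarray,
        variant_idx: np.ndarray,
    ) -> np.ndarray:
        key = (id(genotypes), line_key, variant_idx.tobytes())
        if key not in self._geno:
            dos = genotypes.dosages[np.ix_(line_rows, variant_idx)]
            mu = np.nanmean(dos, axis=0)
            dos = np.where(np.isnan(dos), mu, dos)
            self._geno[key] = dos
        return self._geno[key]

    def rotated(self, sub_grm: GRM, block_key: tuple, G: np.ndarray) -> np.ndarray:
        key = (id(sub_grm), block_key)
        if key not in self._rot:
            _, U = sub_grm.eigendecomposition()
            self._rot[key] = U.T @ G
        return self._rot[key]


def factor_out_inversions(
    y: pd.Series,
    inversions: InversionTable,
    inversion_names: list[str] | None = None,
) -> pd.Series:
    """Residualize a trait on additive inversion dosages (STD=0, HET=1, INV=2).

    Lines with missing trait values are dropped; constant dosage columns
    (monomorphic inversions in the analysis set) are removed automatically.
    """
    y = y.dropna()
    lines = y.index.to_numpy(dtype=object)
    names = inversion_names or inversions.inversions
    cols = [inversions.dosage(nm, lines) for nm in names]
    X = np.column_stack([np.ones(len(y))] + cols) if cols else np.ones((len(y), 1))
    keep = [0] + [j for j in range(1, X.shape[1]) if np.nanstd(X[:, j]) > 0]
    X = X[:, keep]
    X = np.where(np.isnan(X), 0.0, X)
    beta, *_ = np.linalg.lstsq(X, y.to_numpy(dtype=float), rcond=None)
    resid = y.to_numpy(dtype=float) - X @ beta
    return pd.Series(resid, index=y.index)


def _analysis_lines(
    y: pd.Series, genotypes: GenotypeMatrix, covariates: CovariateTable | None
) -> pd.Series:
    keep = y.dropna()
    geno_lines = set(genotypes.line_ids)
    cov_lines = set(covariates.line_ids) if covariates is not None else None
    idx = [
        l for l in keep.index
        if l in geno_lines and (cov_lines is None or l in cov_lines)
    ]
    return keep.loc[idx]


def _design(lines: np.ndarray, covariates: CovariateTable | None) -> tuple[np.ndarray, list[str]]:
    if covariates is None:
        return np.ones((len(lines), 1)), ["intercept"]
    sym = covariates.symbiont(lines)
    if np.nanstd(sym) == 0:
        return np.ones((len(lines), 1)), ["intercept"]
    return np.column_stack([np.ones(len(lines)), sym]), ["intercept", "symbiont"]


def _variant_filter(
    genotypes: GenotypeMatrix, line_rows: np.ndarray, maf_min: float, miss_max: float
) -> np.ndarray:
    dos = genotypes.dosages[line_rows]
    with np.errstate(invalid="ignore"):
        p = np.nanmean(dos, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    miss = np.isnan(dos).mean(axis=0)
    with np.errstate(invalid="ignore"):
        ok = (maf > maf_min) & (miss < miss_max)
    return np.flatnonzero(np.where(np.isnan(maf), False, ok))


def _score_one(
    yv: np.ndarray,
    X: np.ndarray,
    names: list[str],
    sub_grm: GRM,
    G: np.ndarray,
    G_rot: np.ndarray,
) -> pd.DataFrame:
    fit = MixedLMM(yv, X, sub_grm, exog_names=names).fit()
    return fit.score_tests(G, G_rot=G_rot)


def run_gwa(
    trait: pd.Series,
    genotypes: GenotypeMatrix,
    inversions: InversionTable,
    covariates: CovariateTable | None,
    grms: GRMBundle,
    method: str,
    maf_min: float = 0.05,
    miss_max: float = 0.15,
    trait_id: str | None = None,
    permutation_index: int = 0,
    cache: ScanCache | None = None,
    factor_inversions: list[str] | None = None,
) -> GWAResult:
    """Score every filtered variant for one trait under one strategy.

    ``trait`` is a line-indexed Series; lines with missing values, without
    genotypes, or without covariates are dropped. Returns a
    :class:`~invgwa.datatypes.GWAResult` in genomic order.
    """
    cache = cache or ScanCache()
    trait_id = trait_id or str(trait.name or "trait")
    if method == "factored":
        trait = factor_out_inversions(trait, inversions, factor_inversions)
    y = _analysis_lines(trait, genotypes, covariates)
    if len(y) < 10:
        raise DataValidationError(f"only {len(y)} usable lines for {trait_id}")
    lines = y.index.to_numpy(dtype=object)
    line_key = tuple(lines)
    line_rows = cache.line_rows(genotypes, line_key)
    X, names = _design(lines, covariates)
    vidx = cache.variant_filter(genotypes, line_key, line_rows, maf_min, miss_max)
    yv = y.to_numpy(dtype=float)

    grm_for = grms.for_method(method)
    pieces: list[tuple[np.ndarray, pd.DataFrame]] = []
    if method == "loco":
        arms = genotypes.variants["arm"].to_numpy()
        for arm in pd.unique(arms[vidx]):
            if arm not in grm_for:
                raise DataValidationError(f"no LOCO sub-GRM for arm {arm!r}")
            sub = cache.subset_grm(grm_for[arm], line_key, lines)
            aidx = vidx[arms[vidx] == arm]
            G = cache.genotype_block(genotypes, line_key, line_rows, aidx)
            G_rot = cache.rotated(sub, (line_key, aidx.tobytes()), G)
            pieces.append((aidx, _score_one(yv, X, names, sub, G, G_rot)))
    else:
        sub = cache.subset_grm(grm_for, line_key, lines)
        G = cache.genotype_block(genotypes, line_key, line_rows, vidx)
        G_rot = cache.rotated(sub, (line_key, vidx.tobytes()), G)
        pieces.append((vidx, _score_one(yv, X, names, sub, G, G_rot)))

    idx = np.concatenate([a for a, _ in pieces])
    order = np.argsort(idx, kind="stable")
    cols = {
        c: np.concatenate([t[c].to_numpy() for _, t in pieces])[order]
        for c in ("score", "variance", "chi2", "p", "beta", "se", "skipped")
    }
    idx = idx[order]
    keep = ~cols.pop("skipped").astype(bool)
    n_skipped = int((~keep).sum())
    idx = idx[keep]
    ids, arms_all, pos_all = cache.variant_meta(genotypes)
    out = pd.DataFrame(
        {"id": ids[idx], "arm": arms_all[idx], "pos": pos_all[idx], "variant_idx": idx}
        | {c: v[keep] for c, v in cols.items()}
    )
    return GWAResult(
        trait_id=trait_id,
        method=method,
        table=out,
        permutation_index=permutation_index,
        maf_min=maf_min,
        miss_max=miss_max,
        n_lines_used=len(y),
        n_skipped=n_skipped,
    )


def permutation_seed(seed: int, perm_index: int) -> np.random.Generator:
    """Deterministic per-permutation generator: stream (seed, perm_index)."""
    return np.random.default_rng([seed & 0x7FFFFFFF, perm_index])


def permute_gwa(
    trait: pd.Series,
    genotypes: GenotypeMatrix,
    inversions: InversionTable,
    covariates: CovariateTable | None,
    grms: GRMBundle,
    method: str,
    n_perm: int = 100,
    seed: int = 0,
    cache: ScanCache | None = None,
    **kwargs,
) -> list[GWAResult]:
    """Observed run plus ``n_perm`` trait-shuffling permutation replicates.

    Element 0 is the observed scan; element k >= 1 shuffles the raw trait
    values across the measured lines with generator stream (seed, k). The
    factored strategy residualizes after shuffling.
    """
    cache = cache or ScanCache()
    results = [
        run_gwa(
            trait, genotypes, inversions, covariates, grms, method,
            permutation_index=0, cache=cache, **kwargs,
        )
    ]
    observed = trait.dropna()
    for k in range(1, n_perm + 1):
        rng = permutation_seed(seed, k)
        shuffled = pd.Series(
            rng.permutation(observed.to_numpy(dtype=float)),
            index=observed.index, name=trait.name,
        )
        results.append(
            run_gwa(
                shuffled, genotypes, inversions, covariates, grms, method,
                permutation_index=k, cache=cache, **kwargs,
            )
        )
    return results
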