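"""Genetic relatedness matrices: VanRaden, GCTA, and leave-one-chromosome-out.

The Full GRM uses the VanRaden estimator on the full filtered variant set
(missing dosages imputed to the variant mean ``2p``); the LD and LOCO GRMs use
the GCTA estimator on LD-pruned sets, averaging each pair's contribution over
the variants where both lines are genotyped. LOCO builds one sub-GRM per
excluded chromosome arm so a scored arm's own LD block (e.g. an inversion)
cannot be absorbed into the relatedness correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    GRM,
    HET,
    INV,
    STD,
    DataValidationError,
    GenotypeMatrix,
    InversionTable,
    SelectionStrategy,
)
from .structure import select_variants

__all__ = ["grm_vanraden", "grm_gcta", "grm_loco", "full_grm", "ld_grm", "loco_grms", "relatedness_by_genotype"]


def grm_vanraden(
    genotypes: GenotypeMatrix,
    variant_idx: np.ndarray | None = None,
    strategy: SelectionStrategy | None = None,
) -> GRM:
    """VanRaden GRM: ``Z Z' / (2 sum p(1-p))`` with ``Z`` the mean-centred
    dosage matrix and missing dosages imputed to the column mean."""
    idx = np.arange(genotypes.n_variants) if variant_idx is None else np.asarray(variant_idx)
    dos = genotypes.dosages[:, idx]
    p = np.nanmean(dos, axis=0) / 2.0
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom == 0:
        raise DataValidationError("all selected variants are monomorphic")
    Z = np.where(np.isnan(dos), 0.0, dos - 2.0 * p)
    K = Z @ Z.T / denom
    K = (K + K.T) / 2.0
    return GRM(
        matrix=K,
        line_ids=genotypes.line_ids,
        method="vanraden",
        strategy=strategy,
        n_variants_used=len(idx),
    )


def grm_gcta(
    genotypes: GenotypeMatrix,
    variant_idx: np.ndarray | None = None,
    strategy: SelectionStrategy | None = None,
) -> GRM:
    """GCTA GRM: per-variant standardized cross-products averaged over the
    pairwise non-missing variant count. Monomorphic variants are dropped."""
    idx = np.arange(genotypes.n_variants) if variant_idx is None else np.asarray(variant_idx)
    dos = genotypes.dosages[:, idx]
    p = np.nanmean(dos, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise DataValidationError("all selected variants are monomorphic")
    dos, p = dos[:, poly], p[poly]
    W = (dos - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    obs = np.isfinite(W)
    W0 = np.where(obs, W, 0.0)
    num = W0 @ W0.T
    cnt = obs.astype(float) @ obs.astype(float).T
    if (cnt == 0).any():
        raise DataValidationError("a line pair shares no genotyped variants")
    K = num / cnt
    K = (K + K.T) / 2.0
    return GRM(
        matrix=K,
        line_ids=genotypes.line_ids,
        method="gcta",
        strategy=strategy,
        n_variants_used=int(poly.sum()),
    )


def full_grm(genotypes: GenotypeMatrix, strategy: SelectionStrategy | None = None) -> GRM:
    """The Full-genome VanRaden GRM on the Full selection."""
    strategy = strategy or SelectionStrategy.full()
    return grm_vanraden(genotypes, select_variants(genotypes, strategy), strategy)


def ld_grm(genotypes: GenotypeMatrix, strategy: SelectionStrategy | None = None) -> GRM:
    """The LD-thinned GCTA GRM."""
    strategy = strategy or SelectionStrategy.ld()
    return grm_gcta(genotypes, select_variants(genotypes, strategy), strategy)


def grm_loco(genotypes: GenotypeMatrix, arm: str, **ld_kwargs) -> GRM:
    """GCTA GRM from the LD-pruned complement of one chromosome arm."""
    strategy = SelectionStrategy.loco(arm, **ld_kwargs)
    idx = select_variants(genotypes, strategy)
    if idx.size == 0:
        raise DataValidationError(f"LOCO({arm}): empty variant complement")
    return grm_gcta(genotypes, idx, strategy)


def loco_grms(genotypes: GenotypeMatrix, **ld_kwargs) -> dict[str, GRM]:
    """One LOCO sub-GRM per arm present in the panel."""
    arms = pd.unique(genotypes.variants["arm"])
    if len(arms) < 2:
        raise DataValidationError("LOCO needs at least two chromosome arms")
    return {arm: grm_loco(genotypes, arm, **ld_kwargs) for arm in arms}


def relatedness_by_genotype(
    grm: GRM, inversions: InversionTable, inversion: str
) -> dict[str, dict]:
    """Off-diagonal relatedness partitioned by the unordered genotype pair of
    the two lines: INV-INV, STD-STD, INV-STD, and pairs involving a HET line.

    Returns per-group ``{"mean", "median", "values"}``.
    """
    g = inversions.genotype(inversion, grm.line_ids)
    n = len(g)
    iu = np.triu_indices(n, k=1)
    vals = grm.matrix[iu]
    g1, g2 = g[iu[0]], g[iu[1]]
    groups = {
        "INV-INV": (g1 == INV) & (g2 == INV),
        "STD-STD": (g1 == STD) & (g2 == STD),
        "INV-STD": ((g1 == INV) & (g2 == STD)) | ((g1 == STD) & (g2 == INV)),
        "HET-any": (g1 == HET) | (g2 == HET),
    }
    out = {}
    for name, mask in groups.items():
        v = vals[mask]
        out[name] = {
            "n_pairs": int(mask.sum()),
            "mean": float(v.mean()) if v.size else np.nan,
            "median": float(np.median(v)) if v.size else np.nan,
            "values": v,
        }
    return out
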