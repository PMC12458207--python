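"""Enrichment of top association hits for externally flagged outlier variants.

The outlier set stands in for variants flagged by an external population-
differentiation or environmental-association scan; enrichment is a Fisher
exact test on the 2x2 classification {top hit, not} x {outlier, not} over the
GWA-filtered variant universe, and its odds ratio is ranked against odds
ratios built identically from permuted scans.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _cmle_odds_ratio

from .datatypes import DataValidationError, GWAResult, OutlierSet
from .summaries import exceedance

__all__ = ["top_hits", "EnrichmentResult", "outlier_enrichment", "enrichment_vs_permutation"]


def top_hits(result: GWAResult, k: int = 500) -> np.ndarray:
    """Variant indices of the k smallest p-values.

    Ties at the boundary are broken deterministically by (arm, position).
    Returns all variants when k exceeds the table size.
    """
    tab = result.table
    order = np.lexsort(
        (tab["pos"].to_numpy(), tab["arm"].to_numpy(), tab["p"].to_numpy())
    )
    chosen = order[: min(k, len(tab))]
    return np.sort(tab["variant_idx"].to_numpy()[chosen])


@dataclass
class EnrichmentResult:
    table: np.ndarray  # 2x2: rows {hit, not-hit}, cols {outlier, not-outlier}
    odds_ratio: float  # sample (cross-product) odds ratio
    odds_ratio_cmle: float  # conditional-MLE odds ratio
    odds_ratio_haldane: float  # 0.5-corrected, finite even for empty cells
    p_value: float


def outlier_enrichment(
    hits: np.ndarray | Sequence[int],
    outliers: OutlierSet | np.ndarray,
    universe: np.ndarray | Sequence[int],
) -> EnrichmentResult:
    """Fisher exact test of hit/outlier co-occurrence over a variant universe."""
    hits = np.unique(np.asarray(hits, dtype=int))
    out = outliers.indices if isinstance(outliers, OutlierSet) else np.asarray(outliers, dtype=int)
    out = np.unique(out)
    universe = np.unique(np.asarray(universe, dtype=int))
    uni = set(universe.tolist())
    if not set(hits.tolist()) <= uni:
        raise DataValidationError("hits must be a subset of the universe")
    if not set(out.tolist()) <= uni:
        raise DataValidationError("outliers must be a subset of the universe")
    a = len(np.intersect1d(hits, out, assume_unique=True))
    b = len(hits) - a
    c = len(out) - a
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    orr, p = stats.fisher_exact(table, alternative="two-sided")
    cmle = float(_cmle_odds_ratio(table).statistic)
    hald = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    return EnrichmentResult(
        table=table,
        odds_ratio=float(orr),
        odds_ratio_cmle=cmle,
        odds_ratio_haldane=float(hald),
        p_value=float(p),
    )


def enrichment_vs_permutation(
    observed: EnrichmentResult,
    permuted: Sequence[EnrichmentResult],
    q: float = 95.0,
) -> tuple[bool, float]:
    """Observed enrichment odds ratio against the permutation distribution.

    Infinite sample odds ratios are ranked through their Haldane-Anscombe
    companion values so an all-hits-are-outliers table still orders sensibly.
    Returns ``(exceeds_q95, q95)`` on the Haldane scale.
    """
    obs = observed.odds_ratio_haldane
    perm = [r.odds_ratio_haldane for r in permuted]
    return exceedance(obs, perm, q=q)


def enrichment_summary(
    flags: pd.DataFrame, group_col: str = "inversion_associated"
) -> pd.DataFrame:
    """Proportion of traits whose enrichment exceeds permutations, stratified
    by inversion-association status, with Clopper-Pearson intervals."""
    rows = []
    for key, sub in flags.groupby(group_col):
        k, n = int(sub["exceeds"].sum()), len(sub)
        ci = stats.binomtest(k, n).proportion_ci(method="exact") if n else None
        rows.append(
            {
                group_col: key,
                "n_traits": n,
                "exceed_proportion": k / n if n else np.nan,
                "ci_low": float(ci.low) if ci else np.nan,
                "ci_high": float(ci.high) if ci else np.nan,
            }
        )
    return pd.DataFrame(rows)
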