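"""Inversion-trait linear models with a frequency-matched empirical null.

Each trait is regressed on a single inversion over lines homozygous for the
inverted or standard arrangement (heterozygous lines are excluded — their
arrangement dosage is not interpretable for inbred line means). Significance is
calibrated against the same model fitted to random variants matched to the
inversion's allele frequency on the same arm, away from the breakpoints: a
trait counts as inversion-associated only when it beats both the parametric
p-value and the 95% quantile of that matched null, and when inverted
homozygotes make up a non-trivial share of the lines used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    INV,
    STD,
    CovariateTable,
    DataValidationError,
    GenotypeMatrix,
    InversionSpan,
    InversionTable,
    PhenotypeTable,
)

__all__ = [
    "InversionModelFit",
    "MatchedNull",
    "fit_inversion_model",
    "eligible_matched_variants",
    "build_matched_null",
    "classify_inversion_associated",
    "ancestry_model_comparison",
]


@dataclass
class InversionModelFit:
    trait_id: str
    inversion_name: str
    n_lines_used: int
    F_statistic: float
    p_value: float
    r_squared: float
    effect_direction: int
    n_inv_hom: int = 0
    status: str = "ok"  # "ok" | "degenerate"

    @property
    def inv_hom_fraction(self) -> float:
        return self.n_inv_hom / self.n_lines_used if self.n_lines_used else 0.0


def _two_group_fit(y: np.ndarray, x: np.ndarray) -> tuple[float, float, float, int]:
    """OLS of y on a 0/1 indicator; returns (F, p, r2, sign). Closed form."""
    n = len(y)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0 or syy == 0 or n < 3:
        return np.nan, np.nan, np.nan, 0
    b = float(xc @ yc) / sxx
    r2 = b * b * sxx / syy
    F = r2 / (1.0 - r2) * (n - 2) if r2 < 1.0 else np.inf
    p = float(stats.f.sf(F, 1, n - 2)) if np.isfinite(F) else 0.0
    return F, p, r2, int(np.sign(b))


def fit_inversion_model(
    trait_id: str,
    inversion: str,
    phenotypes: PhenotypeTable,
    inversions: InversionTable,
    min_group: int = 3,
) -> InversionModelFit:
    """OLS of a trait on the inversion indicator over INV/STD homozygotes.

    F and p come from comparing against the intercept-only model (equivalent
    to the one-way ANOVA of the two arrangement groups). Degenerate designs
    (a group below ``min_group``, constant trait) return ``status='degenerate'``
    with NaN statistics rather than propagating NaNs downstream.
    """
    y_all = phenotypes.trait(trait_id)
    lines = y_all.index.to_numpy(dtype=object)
    g = inversions.genotype(inversion, lines)
    keep = np.isin(g, (INV, STD)) & y_all.notna().to_numpy()
    y = y_all.to_numpy(dtype=float)[keep]
    x = (g[keep] == INV).astype(float)
    n_inv = int(x.sum())
    n_std = int(len(x) - n_inv)
    F, p, r2, sign = _two_group_fit(y, x) if len(y) else (np.nan, np.nan, np.nan, 0)
    status = "ok"
    if n_inv < min_group or n_std < min_group or not np.isfinite(r2):
        status = "degenerate"
    return InversionModelFit(
        trait_id=trait_id,
        inversion_name=inversion,
        n_lines_used=len(y),
        F_statistic=F,
        p_value=p,
        r_squared=r2,
        effect_direction=sign,
        n_inv_hom=n_inv,
        status=status,
    )


@dataclass
class MatchedNull:
    inversion_name: str
    matched_variant_ids: list[str]
    fits: pd.DataFrame  # per-variant F, p, r2, n
    r2_q95: float
    freq_tol: float
    min_dist_bp: int


def eligible_matched_variants(
    genotypes: GenotypeMatrix,
    inversions: InversionTable,
    span: InversionSpan,
    freq_tol: float = 0.01,
    min_dist_bp: int = 2_000_000,
) -> np.ndarray:
    """Indices of variants eligible as frequency-matched null draws.

    Same arm as the inversion, alternate-allele frequency within ``freq_tol``
    of the inverted-arrangement allele frequency, outside the span, and at
    least ``min_dist_bp`` from both breakpoints.
    """
    inv_freq = inversions.allele_frequency(span.name)
    arm = genotypes.variants["arm"].to_numpy()
    pos = genotypes.variants["pos"].to_numpy()
    af = genotypes.allele_freq
    same_arm = arm == span.arm
    freq_ok = np.abs(af - inv_freq) <= freq_tol
    outside = (pos < span.start) | (pos > span.end)
    far = (np.abs(pos - span.start) >= min_dist_bp) & (np.abs(pos - span.end) >= min_dist_bp)
    return np.flatnonzero(same_arm & freq_ok & outside & far)


def build_matched_null(
    trait_id: str,
    span: InversionSpan,
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    inversions: InversionTable,
    n_draws: int = 100,
    freq_tol: float = 0.01,
    min_dist_bp: int = 2_000_000,
    seed: int = 0,
) -> MatchedNull:
    """Fit the inversion-style model to frequency-matched random variants.

    Each drawn variant is modelled through its homozygous dosage classes only
    (0 vs 2), mirroring the heterozygote exclusion of the inversion model.
    Raises when fewer than ``n_draws`` variants are eligible; the caller may
    relax ``freq_tol`` explicitly.
    """
    eligible = eligible_matched_variants(genotypes, inversions, span, freq_tol, min_dist_bp)
    if len(eligible) < n_draws:
        raise DataValidationError(
            f"only {len(eligible)} variants eligible for the matched null of "
            f"{span.name} (need {n_draws}); relax freq_tol or min_dist_bp explicitly"
        )
    rng = np.random.default_rng(seed)
    draw = np.sort(rng.choice(eligible, size=n_draws, replace=False))

    y_all = phenotypes.trait(trait_id).reindex(list(genotypes.line_ids))
    y = y_all.to_numpy(dtype=float)
    rows = []
    for j in draw:
        d = genotypes.dosages[:, j]
        keep = np.isfinite(y) & np.isin(d, (0.0, 2.0))
        F, p, r2, sign = _two_group_fit(y[keep], (d[keep] == 2.0).astype(float))
        rows.append(
            {
                "variant_id": genotypes.variants["id"].iloc[j],
                "variant_idx": int(j),
                "n": int(keep.sum()),
                "F": F,
                "p": p,
                "r2": r2,
            }
        )
    fits = pd.DataFrame(rows)
    r2_q95 = float(np.nanpercentile(fits["r2"].to_numpy(), 95, method="linear"))
    return MatchedNull(
        inversion_name=span.name,
        matched_variant_ids=list(fits["variant_id"]),
        fits=fits,
        r2_q95=r2_q95,
        freq_tol=freq_tol,
        min_dist_bp=min_dist_bp,
    )


def classify_inversion_associated(
    fit: InversionModelFit,
    null: MatchedNull,
    min_hom_frac: float = 0.05,
    alpha: float = 0.05,
) -> bool:
    """A trait is inversion-associated iff the model is significant, its R²
    beats the matched-null 95% quantile, and inverted homozygotes are at least
    ``min_hom_frac`` of the lines used."""
    if fit.status != "ok":
        return False
    return (
        fit.p_value < alpha
        and fit.r_squared > null.r2_q95
        and fit.inv_hom_fraction >= min_hom_frac
    )


def _ols_rss(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rank = np.linalg.matrix_rank(X)
    return float(resid @ resid), rank


def _model_vs_null(y: np.ndarray, X: np.ndarray) -> tuple[float, float, float]:
    n = len(y)
    rss0 = float(((y - y.mean()) ** 2).sum())
    rss, rank = _ols_rss(y, X)
    df1 = rank - 1
    df2 = n - rank
    if df1 <= 0 or df2 <= 0 or rss0 == 0:
        return np.nan, np.nan, np.nan
    r2 = 1.0 - rss / rss0
    F = (rss0 - rss) / df1 / (rss / df2)
    return F, float(stats.f.sf(F, df1, df2)), r2


def _nested_f(y: np.ndarray, X_red: np.ndarray, X_full: np.ndarray) -> tuple[float, float]:
    n = len(y)
    rss_r, rank_r = _ols_rss(y, X_red)
    rss_f, rank_f = _ols_rss(y, X_full)
    df1 = rank_f - rank_r
    df2 = n - rank_f
    if df1 <= 0 or df2 <= 0:
        return np.nan, np.nan
    F = (rss_r - rss_f) / df1 / (rss_f / df2)
    return F, float(stats.f.sf(F, df1, df2))


def ancestry_model_comparison(
    trait_id: str,
    inversion: str,
    phenotypes: PhenotypeTable,
    inversions: InversionTable,
    covariates: CovariateTable,
    n_perm: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Contrast Ancestry-only, Inversion-only and Full OLS models of one trait.

    Each model is tested against the intercept-only null, the Full model is
    tested against each single-term model, and a permutation reference (trait
    line means shuffled) records how often each comparison is significant by
    chance. Returns a flat record dict; skips with a notice when the ancestry
    covariate is absent.
    """
    if not covariates.has_ancestry:
        return {"trait_id": trait_id, "inversion": inversion, "status": "no_ancestry"}
    y_all = phenotypes.trait(trait_id)
    lines = [
        l
        for l in y_all.index
        if l in set(covariates.line_ids) and l in set(inversions.line_ids)
    ]
    y_s = y_all.loc[lines]
    g = inversions.genotype(inversion, lines)
    keep = np.isin(g, (INV, STD)) & y_s.notna().to_numpy()
    y = y_s.to_numpy(dtype=float)[keep]
    inv_x = (g[keep] == INV).astype(float)
    anc = covariates.ancestry(np.asarray(lines, dtype=object)[keep])
    n = len(y)
    ones = np.ones(n)
    X_anc = np.column_stack([ones, anc])
    X_inv = np.column_stack([ones, inv_x])
    X_full = np.column_stack([ones, anc, inv_x])

    rec: dict = {"trait_id": trait_id, "inversion": inversion, "n_lines_used": n, "status": "ok"}
    if anc.std() == 0:
        rec["status"] = "ancestry_constant"
    for name, X in (("ancestry", X_anc), ("inversion", X_inv), ("full", X_full)):
        F, p, r2 = _model_vs_null(y, X)
        rec[f"F_{name}"], rec[f"p_{name}"], rec[f"r2_{name}"] = F, p, r2
    rec["F_full_vs_ancestry"], rec["p_full_vs_ancestry"] = _nested_f(y, X_anc, X_full)
    rec["F_full_vs_inversion"], rec["p_full_vs_inversion"] = _nested_f(y, X_inv, X_full)

    rng = np.random.default_rng(seed)
    perm_sig = {k: 0 for k in ("ancestry", "inversion", "full")}
    for _ in range(n_perm):
        yp = rng.permutation(y)
        for name, X in (("ancestry", X_anc), ("inversion", X_inv), ("full", X_full)):
            _, p, _ = _model_vs_null(yp, X)
            if np.isfinite(p) and p < alpha:
                perm_sig[name] += 1
    for name, c in perm_sig.items():
        rec[f"perm_sig_frac_{name}"] = c / n_perm if n_perm else np.nan
    return rec


def inversion_association_table(
    phenotypes: PhenotypeTable,
    inversions: InversionTable,
    genotypes: GenotypeMatrix,
    spans: list[InversionSpan],
    n_draws: int = 100,
    freq_tol: float = 0.01,
    min_dist_bp: int = 2_000_000,
    min_hom_frac: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Per trait x inversion association screen used by the CLI and pipeline."""
    span_by_name = {s.name: s for s in spans}
    rows = []
    for k, inv in enumerate(inversions.inversions):
        span = span_by_name[inv]
        nulls: dict[str, MatchedNull] = {}
        for t_i, trait in enumerate(phenotypes.trait_ids):
            fit = fit_inversion_model(trait, inv, phenotypes, inversions)
            null = build_matched_null(
                trait, span, genotypes, phenotypes, inversions,
                n_draws=n_draws, freq_tol=freq_tol, min_dist_bp=min_dist_bp,
                seed=seed + 1000 * k + t_i,
            )
            rows.append(
                {
                    "trait_id": trait,
                    "inversion": inv,
                    "n_lines_used": fit.n_lines_used,
                    "F": fit.F_statistic,
                    "p": fit.p_value,
                    "r2": fit.r_squared,
                    "r2_q95": null.r2_q95,
                    "status": fit.status,
                    "associated": classify_inversion_associated(fit, null, min_hom_frac),
                }
            )
    return pd.DataFrame(rows)
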