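"""Bin-level GWA summaries: hit proportions, genomic inflation, permutation
exceedance, and method/region contrasts.

Variants are partitioned per arm into inside-inversion and outside-inversion
bins (1-based inclusive span coordinates, overlapping spans unioned). For each
bin the hit proportion (p < alpha, strict) and the genomic inflation factor
(median chi-square over the chi-square_1 median, 0.4549...) are compared with
the trait's permutation distribution: a statistic "exceeds" when it is above
the permutations' 95th percentile (linear interpolation between closest
ranks). Method pairs are contrasted with two-sided Fisher exact tests on the
per-trait exceedance counts, with Clopper-Pearson intervals on proportions.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import DataValidationError, GWAResult, InversionSpan

__all__ = [
    "CHI2_1_MEDIAN",
    "bin_variants",
    "hit_proportion",
    "gif",
    "exceedance",
    "bin_summary",
    "method_region_contrast",
]

#: median of the chi-square distribution with 1 degree of freedom
CHI2_1_MEDIAN = 0.4549364231195728


def bin_variants(variants: pd.DataFrame, spans: Sequence[InversionSpan]) -> pd.Series:
    """Label each variant ``{arm}:inside`` or ``{arm}:outside``.

    A variant is inside iff ``start <= pos <= end`` for any span on its arm;
    overlapping spans on one arm are implicitly unioned.
    """
    arm = variants["arm"].to_numpy()
    pos = variants["pos"].to_numpy()
    inside = np.zeros(len(variants), dtype=bool)
    for sp in spans:
        inside |= (arm == sp.arm) & (pos >= sp.start) & (pos <= sp.end)
    labels = np.where(inside, ":inside", ":outside")
    return pd.Series(
        np.char.add(arm.astype(str), labels.astype(str)), index=variants.index
    )


def hit_proportion(result: GWAResult, bin_label: str | None = None, alpha: float = 1e-5) -> float:
    """Fraction of the bin's variants with p strictly below ``alpha``."""
    tab = result.table
    if bin_label is not None:
        tab = tab.loc[tab["bin"] == bin_label]
    if len(tab) == 0:
        return np.nan
    return float((tab["p"].to_numpy() < alpha).mean())


def gif(result: GWAResult, bin_label: str | None = None) -> float:
    """Genomic inflation factor: median score-test chi-square in the bin over
    the chi-square_1 median. NaN (flagged) for an empty bin."""
    tab = result.table
    if bin_label is not None:
        tab = tab.loc[tab["bin"] == bin_label]
    if len(tab) == 0:
        return np.nan
    return float(np.median(tab["chi2"].to_numpy()) / CHI2_1_MEDIAN)


def exceedance(observed: float, permuted: Iterable[float], q: float = 95.0) -> tuple[bool, float]:
    """observed > q-th percentile of the permuted values (linear interpolation
    between closest ranks). Returns ``(flag, percentile)``."""
    perm = np.asarray(list(permuted), dtype=float)
    if perm.size == 0:
        raise DataValidationError("exceedance needs at least one permuted value")
    q_val = float(np.nanpercentile(perm, q, method="linear"))
    if not np.isfinite(observed):
        return False, q_val
    return bool(observed > q_val), q_val


def annotate_bins(result: GWAResult, spans: Sequence[InversionSpan]) -> GWAResult:
    result.table = result.table.copy()
    result.table["bin"] = bin_variants(result.table, spans).to_numpy()
    return result


def bin_summary(
    runs: Sequence[GWAResult],
    spans: Sequence[InversionSpan],
    alpha: float = 1e-5,
) -> pd.DataFrame:
    """Per-bin summary of an observed run against its permutations.

    ``runs[0]`` must be the observed scan (permutation_index 0). Returns one
    row per bin with the observed hit proportion and GIF, the permutation 95th
    percentiles, and the exceedance flags.
    """
    if not runs or runs[0].permutation_index != 0:
        raise DataValidationError("runs[0] must be the observed scan")
    obs = annotate_bins(runs[0], spans)
    perms = runs[1:]
    bins = obs.table["bin"].to_numpy()
    vidx = obs.table["variant_idx"].to_numpy()
    rows = []
    for b in sorted(pd.unique(bins)):
        mask = bins == b
        h_obs = hit_proportion(obs, b, alpha)
        g_obs = gif(obs, b)
        # permutation runs share the observed run's variant set and order
        h_perm, g_perm = [], []
        for r in perms:
            p = r.table["p"].to_numpy()
            chi2 = r.table["chi2"].to_numpy()
            if len(p) != len(bins) or not np.array_equal(
                r.table["variant_idx"].to_numpy(), vidx
            ):  # pragma: no cover - defensive
                raise DataValidationError("permutation scan not aligned to observed")
            h_perm.append(float((p[mask] < alpha).mean()))
            g_perm.append(float(np.median(chi2[mask]) / CHI2_1_MEDIAN))
        if perms:
            ex_h, q_h = exceedance(h_obs, h_perm)
            ex_g, q_g = exceedance(g_obs, g_perm)
        else:
            ex_h = ex_g = False
            q_h = q_g = np.nan
        rows.append(
            {
                "trait_id": obs.trait_id,
                "method": obs.method,
                "bin": b,
                "n_variants": int((obs.table["bin"] == b).sum()),
                "hit_proportion": h_obs,
                "gif": g_obs,
                "permutation_q95_hit": q_h,
                "permutation_q95_gif": q_g,
                "exceeds_hit": ex_h,
                "exceeds_gif": ex_g,
            }
        )
    return pd.DataFrame(rows)


def _clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    if n == 0:
        return np.nan, np.nan
    res = stats.binomtest(k, n).proportion_ci(confidence_level=conf, method="exact")
    return float(res.low), float(res.high)


def method_region_contrast(
    flags: pd.DataFrame,
    stat_col: str = "exceeds_hit",
) -> pd.DataFrame:
    """Contrast exceedance frequencies between methods within each bin and
    between regions within each method.

    ``flags`` needs columns ``trait_id``, ``method``, ``bin`` and the boolean
    ``stat_col``. Method pairs within a bin and region pairs (inside vs
    outside on one arm) within a method are tested with two-sided Fisher exact
    tests; proportions carry Clopper-Pearson 95% intervals.
    """
    need = {"trait_id", "method", "bin", stat_col}
    if not need <= set(flags.columns):
        raise DataValidationError(f"flags table needs columns {sorted(need)}")
    rows = []
    methods = sorted(flags["method"].unique())
    for b in sorted(flags["bin"].unique()):
        sub = flags.loc[flags["bin"] == b]
        counts = {
            m: (
                int(sub.loc[sub["method"] == m, stat_col].sum()),
                int((sub["method"] == m).sum()),
            )
            for m in methods
        }
        for i, m1 in enumerate(methods):
            for m2 in methods[i + 1:]:
                k1, n1 = counts[m1]
                k2, n2 = counts[m2]
                table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
                orr, p = stats.fisher_exact(table, alternative="two-sided")
                lo1, hi1 = _clopper_pearson(k1, n1)
                lo2, hi2 = _clopper_pearson(k2, n2)
                rows.append(
                    {
                        "contrast": "method", "bin": b, "a": m1, "b": m2,
                        "prop_a": k1 / n1 if n1 else np.nan,
                        "ci_a": (lo1, hi1),
                        "prop_b": k2 / n2 if n2 else np.nan,
                        "ci_b": (lo2, hi2),
                        "odds_ratio": orr, "fisher_p": p,
                    }
                )
    # inside vs outside within a method, per arm
    arms = sorted({b.split(":")[0] for b in flags["bin"].unique()})
    for m in methods:
        sub = flags.loc[flags["method"] == m]
        for arm in arms:
            bi, bo = f"{arm}:inside", f"{arm}:outside"
            if bi not in set(sub["bin"]) or bo not in set(sub["bin"]):
                continue
            ki = int(sub.loc[sub["bin"] == bi, stat_col].sum())
            ni = int((sub["bin"] == bi).sum())
            ko = int(sub.loc[sub["bin"] == bo, stat_col].sum())
            no = int((sub["bin"] == bo).sum())
            orr, p = stats.fisher_exact(
                np.array([[ki, ni - ki], [ko, no - ko]]), alternative="two-sided"
            )
            rows.append(
                {
                    "contrast": "region", "bin": f"{arm}", "a": f"{m}:inside",
                    "b": f"{m}:outside",
                    "prop_a": ki / ni if ni else np.nan,
                    "ci_a": _clopper_pearson(ki, ni),
                    "prop_b": ko / no if no else np.nan,
                    "ci_b": _clopper_pearson(ko, no),
                    "odds_ratio": orr, "fisher_p": p,
                }
            )
    return pd.DataFrame(rows)
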