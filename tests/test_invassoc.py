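"""Inversion-trait models: oracle equivalences, matched-null constraints and
classification gates."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from invgwa.datatypes import DataValidationError, InversionTable, PhenotypeTable
from invgwa.invassoc import (
    InversionModelFit,
    MatchedNull,
    ancestry_model_comparison,
    build_matched_null,
    classify_inversion_associated,
    eligible_matched_variants,
    fit_inversion_model,
)


def _pheno(values, lines, trait="t1"):
    df = pd.DataFrame({trait: values}, index=lines)
    return PhenotypeTable(values=df, categories=pd.Series(["Behavior"], index=[trait]))


def _inv_table(genos, lines, name="Inv"):
    return InversionTable(pd.DataFrame({name: genos}, index=lines))


def test_perfect_separation():
    lines = [f"l{i}" for i in range(20)]
    genos = ["INV"] * 10 + ["STD"] * 10
    y = [1.0] * 10 + [0.0] * 10
    fit = fit_inversion_model("t1", "Inv", _pheno(y, lines), _inv_table(genos, lines))
    assert fit.r_squared == pytest.approx(1.0)
    assert fit.p_value < 1e-20
    assert fit.effect_direction == 1


def test_het_lines_and_missing_trait_excluded():
    lines = [f"l{i}" for i in range(12)]
    genos = ["INV"] * 5 + ["HET"] * 2 + ["STD"] * 5
    y = [1.0] * 5 + [99.0] * 2 + [0.0] * 4 + [np.nan]
    fit = fit_inversion_model("t1", "Inv", _pheno(y, lines), _inv_table(genos, lines))
    assert fit.n_lines_used == 9
    assert fit.n_inv_hom == 5


def test_degenerate_fit_marker_not_nan_propagation():
    lines = [f"l{i}" for i in range(6)]
    fit = fit_inversion_model(
        "t1", "Inv",
        _pheno([1.0] * 6, lines),
        _inv_table(["INV"] * 3 + ["STD"] * 3, lines),
    )
    assert fit.status == "degenerate"
    null = MatchedNull("Inv", [], pd.DataFrame(), r2_q95=0.0, freq_tol=0.01, min_dist_bp=0)
    assert classify_inversion_associated(fit, null) is False


def test_f_equals_squared_pooled_t(rng):
    lines = [f"l{i}" for i in range(40)]
    genos = ["INV"] * 15 + ["STD"] * 25
    y = rng.standard_normal(40) + np.r_[np.ones(15), np.zeros(25)]
    fit = fit_inversion_model("t1", "Inv", _pheno(y, lines), _inv_table(genos, lines))
    t = stats.ttest_ind(y[:15], y[15:], equal_var=True)
    assert fit.F_statistic == pytest.approx(t.statistic**2, rel=1e-10)
    assert fit.p_value == pytest.approx(t.pvalue, rel=1e-10)


def test_r2_matches_rss_ratio_brute_force(rng):
    lines = [f"l{i}" for i in range(50)]
    genos = list(rng.choice(["INV", "STD"], size=50, p=[0.4, 0.6]))
    y = rng.standard_normal(50)
    fit = fit_inversion_model("t1", "Inv", _pheno(y, lines), _inv_table(genos, lines))
    x = (np.array(genos) == "INV").astype(float)
    X = np.column_stack([np.ones(50), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = ((y - X @ beta) ** 2).sum()
    rss0 = ((y - y.mean()) ** 2).sum()
    assert abs(fit.r_squared - (1 - rss / rss0)) < 1e-10


def test_null_trait_pvalues_uniform(inv_panel, rng):
    gm, inv, _ = inv_panel
    lines = list(gm.line_ids)
    pvals = []
    for _ in range(1000):
        y = rng.standard_normal(len(lines))
        fit = fit_inversion_model("t1", "In(2L)t", _pheno(y, lines), inv)
        pvals.append(fit.p_value)
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


# ---------------------------------------------------------------- matched null


def test_matched_null_constraints_hold_exhaustively(inv_panel, trait_panel):
    gm, inv, spans = inv_panel
    ph, _ = trait_panel
    span = spans[0]
    null = build_matched_null(
        "trait_001", span, gm, ph, inv, n_draws=60, freq_tol=0.05, seed=3
    )
    inv_freq = inv.allele_frequency(span.name)
    for _, row in null.fits.iterrows():
        j = int(row["variant_idx"])
        v = gm.variants.iloc[j]
        assert v["arm"] == span.arm
        assert abs(gm.allele_freq[j] - inv_freq) <= 0.05
        assert abs(v["pos"] - span.start) >= 2_000_000
        assert abs(v["pos"] - span.end) >= 2_000_000
        assert v["pos"] < span.start or v["pos"] > span.end


def test_near_breakpoint_variants_never_eligible(inv_panel):
    gm, inv, spans = inv_panel
    span = spans[0]
    idx = eligible_matched_variants(gm, inv, span, freq_tol=1.0, min_dist_bp=2_000_000)
    pos = gm.variants["pos"].to_numpy()[idx]
    # a variant 1.9 Mb from a breakpoint is excluded even with no freq filter
    assert not np.any((np.abs(pos - span.start) < 2_000_000) | (np.abs(pos - span.end) < 2_000_000))


def test_exact_eligible_set_is_used_whole(inv_panel, trait_panel):
    gm, inv, spans = inv_panel
    ph, _ = trait_panel
    span = spans[0]
    idx = eligible_matched_variants(gm, inv, span, freq_tol=0.05)
    n = len(idx)
    a = build_matched_null("trait_001", span, gm, ph, inv, n_draws=n, freq_tol=0.05, seed=1)
    b = build_matched_null("trait_001", span, gm, ph, inv, n_draws=n, freq_tol=0.05, seed=99)
    assert sorted(a.matched_variant_ids) == sorted(b.matched_variant_ids)


def test_shortfall_raises(inv_panel, trait_panel):
    gm, inv, spans = inv_panel
    ph, _ = trait_panel
    with pytest.raises(DataValidationError, match="eligible"):
        build_matched_null("trait_001", spans[0], gm, ph, inv, n_draws=10_000)


# ---------------------------------------------------------------- classify


def _fit(p, r2, hom_frac, n=100):
    return InversionModelFit(
        trait_id="t", inversion_name="Inv", n_lines_used=n,
        F_statistic=1.0, p_value=p, r_squared=r2, effect_direction=1,
        n_inv_hom=int(round(hom_frac * n)),
    )


def _null(q95=0.2):
    return MatchedNull("Inv", [], pd.DataFrame(), r2_q95=q95, freq_tol=0.01, min_dist_bp=2_000_000)


@pytest.mark.parametrize(
    "p,r2,hom,expected",
    [
        (0.04, 0.3, 0.10, True),
        (0.04, 0.3, 0.03, False),  # homozygote floor
        (0.2, 0.9, 0.10, False),  # p gate
        (0.04, 0.1, 0.10, False),  # below matched-null q95
    ],
)
def test_classification_gates(p, r2, hom, expected):
    assert classify_inversion_associated(_fit(p, r2, hom), _null()) is expected


def test_classification_monotone_in_r2():
    flags = [
        classify_inversion_associated(_fit(0.01, r2, 0.2), _null(0.2))
        for r2 in np.linspace(0, 1, 21)
    ]
    assert flags == sorted(flags)  # never flips True -> False as r2 grows


# ---------------------------------------------------------------- ancestry


def test_ancestry_only_architecture_detected(inv_panel, covariates, rng):
    gm, inv, _ = inv_panel
    lines = list(gm.line_ids)
    anc = covariates.ancestry(gm.line_ids)
    hits_inv, miss_anc = 0, 0
    n_rep = 60
    for _ in range(n_rep):
        y = np.sqrt(0.2) * (anc - anc.mean()) / anc.std() + np.sqrt(0.8) * rng.standard_normal(len(lines))
        rec = ancestry_model_comparison(
            "t1", "In(2L)t", _pheno(y, lines), inv, covariates, n_perm=0
        )
        hits_inv += rec["p_full_vs_inversion"] < 0.05
        miss_anc += rec["p_full_vs_ancestry"] >= 0.05
    assert hits_inv >= 0.9 * n_rep
    assert miss_anc >= 0.9 * n_rep


def test_ancestry_permutation_calibration(inv_panel, covariates, rng):
    gm, inv, _ = inv_panel
    lines = list(gm.line_ids)
    y = rng.standard_normal(len(lines))
    rec = ancestry_model_comparison(
        "t1", "In(2L)t", _pheno(y, lines), inv, covariates, n_perm=200, seed=8
    )
    for name in ("ancestry", "inversion", "full"):
        assert rec[f"perm_sig_frac_{name}"] < 0.12


def test_missing_ancestry_skips(inv_panel, trait_panel):
    gm, inv, _ = inv_panel
    ph, _ = trait_panel
    from invgwa.datatypes import CovariateTable

    cov = CovariateTable(pd.DataFrame({"symbiont": 1}, index=list(gm.line_ids)))
    rec = ancestry_model_comparison("trait_001", "In(2L)t", ph, inv, cov)
    assert rec["status"] == "no_ancestry"
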