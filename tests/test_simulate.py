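"""Generator properties: inbreeding structure, inversion LD, trait variance
architecture, and outlier-set construction."""

import numpy as np
import pytest

from invgwa import (
    ArmSpec,
    InversionSpec,
    PanelConfig,
    TraitConfig,
    simulate_outlier_flags,
    simulate_panel,
    simulate_traits,
)
from invgwa.datatypes import ConfigurationError


def _mini_cfg(**kw):
    base = dict(
        n_lines=100,
        arms=[ArmSpec("2L", 5_000_000, 400), ArmSpec("2R", 5_000_000, 300)],
        inversions=[InversionSpec("2L", 1_000_000, 3_000_000, 0.5, 0.8, name="Inv")],
        residual_het_rate=0.0,
        genotype_missing_rate=0.0,
        seed=5,
    )
    base.update(kw)
    return PanelConfig(**base)


def _inv_r2(gm, inv, spans):
    """Brute-force r^2 of every variant with the inversion dosage."""
    d = inv.dosage("Inv", gm.line_ids)
    dos = gm.dosages
    mu = np.nanmean(dos, axis=0)
    x = np.where(np.isnan(dos), mu, dos)
    xc = x - x.mean(axis=0)
    dc = d - d.mean()
    denom = (xc**2).sum(0) * (dc**2).sum()
    with np.errstate(invalid="ignore"):
        r2 = (xc.T @ dc) ** 2 / denom
    pos = gm.variants["pos"].to_numpy()
    on_arm = gm.variants["arm"].to_numpy() == "2L"
    inside = on_arm & (pos >= spans[0].start) & (pos <= spans[0].end)
    return r2, inside


def test_fully_inbred_dosages_are_homozygous():
    gm, _, _ = simulate_panel(_mini_cfg())
    assert set(np.unique(gm.dosages)) <= {0.0, 2.0}


def test_perfect_divergence_gives_r2_one_in_span():
    cfg = _mini_cfg(
        inversions=[InversionSpec("2L", 1_000_000, 3_000_000, 0.5, 1.0, name="Inv")]
    )
    gm, inv, spans = simulate_panel(cfg)
    r2, inside = _inv_r2(gm, inv, spans)
    assert np.allclose(r2[inside], 1.0)


def test_divergent_span_elevates_ld_against_brute_force():
    cfg = _mini_cfg(n_lines=200, arms=[ArmSpec("2L", 5_000_000, 700)],
                    inversions=[InversionSpec("2L", 500_000, 4_000_000, 0.5, 0.8, name="Inv")])
    gm, inv, spans = simulate_panel(cfg)
    r2, inside = _inv_r2(gm, inv, spans)
    assert inside.sum() >= 400
    assert np.nanmean(r2[inside]) > 5 * np.nanmean(r2[~inside])


def test_ld_monotone_in_divergence():
    means = []
    for d in (0.2, 0.5, 0.8):
        cfg = _mini_cfg(
            n_lines=300,
            inversions=[InversionSpec("2L", 1_000_000, 3_000_000, 0.5, d, name="Inv")],
        )
        gm, inv, spans = simulate_panel(cfg)
        r2, inside = _inv_r2(gm, inv, spans)
        means.append(np.nanmean(r2[inside]))
    assert means[0] < means[1] < means[2]


def test_background_allele_frequencies_recovered():
    cfg = _mini_cfg(n_lines=400, inversions=[])
    gm, _, _ = simulate_panel(cfg)
    # realized frequency of 2n sampled alleles vs binomial error: ~95% of
    # variants should fall inside a 95% binomial band around the realized freq
    p_hat = gm.allele_freq
    n_alleles = 2 * gm.n_lines
    se = np.sqrt(p_hat * (1 - p_hat) / n_alleles)
    # self-consistency band: realized dosage mean vs per-line Bernoulli draws
    k = (gm.dosages == 2).sum(axis=0)
    p_line = k / gm.n_lines
    assert np.allclose(p_line, p_hat)  # inbred: allele freq == line freq
    assert (se > 0).all()


def test_missingness_and_het_rates():
    cfg = _mini_cfg(residual_het_rate=0.05, genotype_missing_rate=0.1)
    gm, _, _ = simulate_panel(cfg)
    miss = np.isnan(gm.dosages).mean()
    het = (gm.dosages == 1.0).mean()
    assert abs(miss - 0.1) < 0.01
    assert 0.02 < het < 0.08  # het sites can be masked by missingness


def test_seed_determinism():
    g1, i1, s1 = simulate_panel(_mini_cfg())
    g2, i2, s2 = simulate_panel(_mini_cfg())
    assert np.array_equal(g1.dosages, g2.dosages, equal_nan=True)
    assert i1.genotypes.equals(i2.genotypes)
    assert s1 == s2


@pytest.mark.parametrize(
    "kw",
    [
        {"inversions": [InversionSpec("2L", 1, 9_999_999, 0.5, 0.8)]},  # exceeds arm
        {"arms": [ArmSpec("2L", 5_000_000, 1)]},  # too few variants
        {"residual_het_rate": 1.5},
        {"inversions": [InversionSpec("2L", 10, 20, 1.0, 0.8)]},  # freq boundary
    ],
)
def test_config_errors(kw):
    with pytest.raises(ConfigurationError):
        simulate_panel(_mini_cfg(**kw))


# ------------------------------------------------------------------ traits


def _panel_for_traits(seed=7):
    return simulate_panel(
        _mini_cfg(
            n_lines=200,
            seed=seed,
            inversions=[InversionSpec("2L", 1_000_000, 3_000_000, 0.3, 0.8, name="Inv")],
        )
    )


def _trait_inv_r2(y, d):
    keep = np.isfinite(y)
    yc = y[keep] - y[keep].mean()
    dc = d[keep] - d[keep].mean()
    return float((yc @ dc) ** 2 / ((yc @ yc) * (dc @ dc)))


def test_pure_noise_traits_have_no_inversion_signal():
    gm, inv, spans = _panel_for_traits()
    cfg = TraitConfig(
        n_traits=60, inversion_effect_r2=0.0, polygenic_h2=0.0,
        n_causal_background=0, covariate_effect=0.0,
        phenotype_missing_rate=0.0, seed=3,
    )
    ph, truth = simulate_traits(gm, inv, None, cfg, spans=spans)
    d = inv.dosage("Inv", gm.line_ids)
    r2 = [_trait_inv_r2(ph.values[t].to_numpy(), d) for t in ph.trait_ids]
    assert np.mean(np.array(r2) < 0.05) >= 0.9


def test_inversion_effect_r2_calibrated():
    gm, inv, spans = _panel_for_traits()
    cfg = TraitConfig(
        n_traits=500, inversion_effect_r2=0.10, polygenic_h2=0.0,
        n_causal_background=0, covariate_effect=0.0,
        phenotype_missing_rate=0.0, seed=4,
    )
    ph, _ = simulate_traits(gm, inv, None, cfg, spans=spans)
    d = inv.dosage("Inv", gm.line_ids)
    r2 = np.array([_trait_inv_r2(ph.values[t].to_numpy(), d) for t in ph.trait_ids])
    assert abs(r2.mean() - 0.10) < 0.02


def test_phenotype_missing_rate():
    gm, inv, spans = _panel_for_traits()
    cfg = TraitConfig(n_traits=100, phenotype_missing_rate=0.2, seed=5)
    ph, _ = simulate_traits(gm, inv, None, cfg, spans=spans)
    frac = ph.values.isna().to_numpy().mean()
    assert abs(frac - 0.2) < 0.01


def test_causal_placement_respects_span_flag():
    gm, inv, spans = _panel_for_traits()
    pos = gm.variants["pos"].to_numpy()
    on_arm = gm.variants["arm"].to_numpy() == "2L"
    inside = on_arm & (pos >= spans[0].start) & (pos <= spans[0].end)
    for flag in (False, True):
        cfg = TraitConfig(n_traits=5, causal_inside_spans=flag, seed=6)
        _, truth = simulate_traits(gm, inv, None, cfg, spans=spans)
        for idx in truth["causal_idx"]:
            assert all(inside[j] == flag for j in idx)


def test_constant_covariate_warns():
    gm, inv, spans = _panel_for_traits()
    cfg = TraitConfig(n_traits=2, covariate_effect=0.5, seed=8)
    with pytest.warns(UserWarning, match="unidentifiable"):
        simulate_traits(gm, inv, np.zeros(gm.n_lines), cfg, spans=spans)


# ------------------------------------------------------------------ outliers


def test_outlier_overlap_extremes_and_exact_count():
    gm, _, _ = _panel_for_traits()
    causal = list(range(0, 400, 2))  # 200 causal indices
    o0 = simulate_outlier_flags(gm, causal, overlap=0.0, n_outliers=100, seed=1)
    assert len(np.intersect1d(o0.indices, causal)) == 0
    o1 = simulate_outlier_flags(gm, causal, overlap=1.0, n_outliers=100, seed=1)
    assert set(o1.indices) <= set(causal)
    oh = simulate_outlier_flags(gm, causal, overlap=0.5, n_outliers=100, seed=1)
    assert len(np.intersect1d(oh.indices, causal)) == 50
    assert len(oh.indices) == len(set(oh.indices)) == 100


def test_outlier_proxies_when_causal_set_small():
    gm, _, _ = _panel_for_traits()
    out = simulate_outlier_flags(gm, [3, 4], overlap=1.0, n_outliers=10, seed=2)
    assert {3, 4} <= set(out.indices)
    assert len(out.indices) == 10
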