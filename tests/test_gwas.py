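"""GWA strategies: filtering, LOCO identity, factoring, and permutations."""

import numpy as np
import pandas as pd
import pytest

from invgwa import factor_out_inversions, permute_gwa, run_gwa
from invgwa.datatypes import InversionTable
from invgwa.grm import full_grm, ld_grm, loco_grms
from invgwa.gwas import GRMBundle, ScanCache
from invgwa.summaries import CHI2_1_MEDIAN, gif


@pytest.fixture(scope="module")
def bundle(inv_panel):
    gm, _, _ = inv_panel
    return GRMBundle(full=full_grm(gm), ld=ld_grm(gm), loco=loco_grms(gm))


def test_factor_out_exact_inversion_trait(inv_panel):
    gm, inv, _ = inv_panel
    d = inv.dosage("In(2L)t", gm.line_ids)
    y = pd.Series(3.0 + 2.0 * d, index=gm.line_ids)
    resid = factor_out_inversions(y, inv)
    assert np.max(np.abs(resid.to_numpy())) < 1e-10


def test_factor_out_residuals_orthogonal(inv_panel, trait_panel):
    gm, inv, _ = inv_panel
    ph, _ = trait_panel
    y = ph.trait("trait_001")
    resid = factor_out_inversions(y, inv)
    d = inv.dosage("In(2L)t", resid.index.to_numpy(dtype=object))
    r = resid.to_numpy()
    assert abs(r @ (d - d.mean())) / (np.linalg.norm(r) * np.linalg.norm(d - d.mean())) < 1e-8


def test_factor_out_drops_constant_columns(inv_panel):
    gm, inv, _ = inv_panel
    mono = InversionTable(
        pd.DataFrame(
            {"In(2L)t": inv.genotypes["In(2L)t"], "fixed": "STD"},
            index=inv.genotypes.index,
        )
    )
    y = pd.Series(np.linspace(0, 1, gm.n_lines), index=gm.line_ids)
    resid = factor_out_inversions(y, mono)
    # oracle: pseudo-inverse fit on the full (rank-deficient) design
    d = inv.dosage("In(2L)t", gm.line_ids)
    X = np.column_stack([np.ones(gm.n_lines), d, np.zeros(gm.n_lines)])
    oracle = y.to_numpy() - X @ np.linalg.pinv(X) @ y.to_numpy()
    assert np.allclose(resid.to_numpy(), oracle, atol=1e-10)


def test_low_maf_variants_filtered(inv_panel, trait_panel, covariates, bundle):
    gm, inv, _ = inv_panel
    ph, _ = trait_panel
    res = run_gwa(ph.trait("trait_001"), gm, inv, covariates, bundle, "full")
    lines = res.table
    used = gm.line_index(
        ph.trait("trait_001").dropna().index.intersection(pd.Index(gm.line_ids))
    )
    dos = gm.dosages[used][:, lines["variant_idx"]]
    p = np.nanmean(dos, axis=0) / 2
    maf = np.minimum(p, 1 - p)
    assert (maf > 0.05).all()
    assert (np.isnan(dos).mean(axis=0) < 0.15).all()


def test_loco_equals_full_with_loco_grm(inv_panel, trait_panel, covariates, bundle):
    gm, inv, _ = inv_panel
    ph, _ = trait_panel
    y = ph.trait("trait_002")
    loco = run_gwa(y, gm, inv, covariates, bundle, "loco")
    alt_bundle = GRMBundle(full=bundle.loco["2L"])
    full_alt = run_gwa(y, gm, inv, covariates, alt_bundle, "full")
    a = loco.table[loco.table["arm"] == "2L"].reset_index(drop=True)
    b = full_alt.table[full_alt.table["arm"] == "2L"].reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b)


def test_permutation_zero_is_observed(inv_panel, trait_panel, covariates, bundle):
    gm, inv, _ = inv_panel
    ph, _ = trait_panel
    runs = permute_gwa(
        ph.trait("trait_001"), gm, inv, covariates, bundle, "full", n_perm=2, seed=5
    )
    solo = run_gwa(ph.trait("trait_001"), gm, inv, covariates, bundle, "full")
    pd.testing.assert_frame_equal(runs[0].table, solo.table)
    assert [r.permutation_index for r in runs] == [0, 1, 2]


def test_permutation_sequence_deterministic(inv_panel, trait_panel, covariates, bundle):
    gm, inv, _ = inv_panel
    ph, _ = trait_panel
    a = permute_gwa(ph.trait("trait_003"), gm, inv, covariates, bundle, "full", n_perm=3, seed=9)
    b = permute_gwa(ph.trait("trait_003"), gm, inv, covariates, bundle, "full", n_perm=3, seed=9)
    for ra, rb in zip(a, b):
        pd.testing.assert_frame_equal(ra.table, rb.table)


def test_factored_removes_pure_inversion_signal(inv_panel, covariates, bundle):
    """A trait that is exactly inversion dosage + noise loses its within-span
    signal under the factored strategy."""
    gm, inv, spans = inv_panel
    rng = np.random.default_rng(31)
    d = inv.dosage("In(2L)t", gm.line_ids)
    y = pd.Series(d + 0.1 * rng.standard_normal(gm.n_lines), index=gm.line_ids, name="y")
    fac = run_gwa(y, gm, inv, covariates, bundle, "factored")
    pos = fac.table["pos"].to_numpy()
    inside = (fac.table["arm"] == "2L").to_numpy() & (pos >= spans[0].start) & (pos <= spans[0].end)
    chi2_in = fac.table.loc[inside, "chi2"].to_numpy()
    # signal removed: median within-span chi2 consistent with the null median
    assert np.median(chi2_in) < 3 * CHI2_1_MEDIAN
    loco = run_gwa(y, gm, inv, covariates, bundle, "loco")
    chi2_loco = loco.table.loc[inside.nonzero()[0], "chi2"].to_numpy()
    assert np.median(chi2_loco) > 10 * np.median(chi2_in)


def test_median_permutation_gif_near_one(rng):
    """On a structure-free panel, permuted traits should give median GIF ~ 1."""
    from invgwa import ArmSpec, PanelConfig, simulate_panel
    from invgwa.datatypes import CovariateTable

    cfg = PanelConfig(
        n_lines=120,
        arms=[ArmSpec("2L", 10_000_000, 700), ArmSpec("2R", 10_000_000, 700)],
        inversions=[],
        residual_het_rate=0.0,
        genotype_missing_rate=0.0,
        seed=21,
    )
    gm, inv, spans = simulate_panel(cfg)
    bundle = GRMBundle(full=full_grm(gm))
    y = pd.Series(rng.standard_normal(gm.n_lines), index=gm.line_ids, name="noise")
    runs = permute_gwa(y, gm, inv, None, bundle, "full", n_perm=20, seed=2)
    gifs = [gif(r) for r in runs[1:]]
    assert abs(np.median(gifs) - 1.0) < 0.1


def test_cache_reuse_matches_fresh_runs(inv_panel, trait_panel, covariates, bundle):
    gm, inv, _ = inv_panel
    ph, _ = trait_panel
    cache = ScanCache()
    a = run_gwa(ph.trait("trait_002"), gm, inv, covariates, bundle, "ld", cache=cache)
    b = run_gwa(ph.trait("trait_002"), gm, inv, covariates, bundle, "ld", cache=cache)
    c = run_gwa(ph.trait("trait_002"), gm, inv, covariates, bundle, "ld")
    pd.testing.assert_frame_equal(a.table, b.table)
    pd.testing.assert_frame_equal(a.table, c.table)
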