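"""Relatedness estimators against brute-force oracles and their invariances."""

import numpy as np
import pandas as pd
import pytest

from invgwa.datatypes import DataValidationError, GenotypeMatrix, InversionTable, GRM
from invgwa.grm import (
    grm_gcta,
    grm_loco,
    grm_vanraden,
    full_grm,
    loco_grms,
    relatedness_by_genotype,
)


def _gm(dosages, arm="2L", pos=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    pos = pos if pos is not None else np.arange(1, m + 1) * 100_000
    variants = pd.DataFrame(
        {"id": [f"{arm}_{j}" for j in range(m)], "arm": arm, "pos": pos, "is_indel": False}
    )
    return GenotypeMatrix(np.array([f"l{i}" for i in range(n)], dtype=object), variants, dosages)


@pytest.fixture(scope="module")
def small_panel(rng):
    dosages = rng.binomial(1, rng.uniform(0.2, 0.8, 20), size=(10, 20)).astype(float) * 2
    dosages[rng.random((10, 20)) < 0.05] = np.nan
    return _gm(dosages)


def _vanraden_oracle(dos):
    n, m = dos.shape
    p = np.nanmean(dos, axis=0) / 2
    K = np.zeros((n, n))
    denom = 2 * np.sum(p * (1 - p))
    for j in range(n):
        for k in range(n):
            acc = 0.0
            for i in range(m):
                zj = 0.0 if np.isnan(dos[j, i]) else dos[j, i] - 2 * p[i]
                zk = 0.0 if np.isnan(dos[k, i]) else dos[k, i] - 2 * p[i]
                acc += zj * zk
            K[j, k] = acc / denom
    return K


def _gcta_oracle(dos):
    n, m = dos.shape
    p = np.nanmean(dos, axis=0) / 2
    K = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            acc, cnt = 0.0, 0
            for i in range(m):
                if np.isnan(dos[j, i]) or np.isnan(dos[k, i]):
                    continue
                w = 2 * p[i] * (1 - p[i])
                acc += (dos[j, i] - 2 * p[i]) * (dos[k, i] - 2 * p[i]) / w
                cnt += 1
            K[j, k] = acc / cnt
    return K


def test_vanraden_matches_double_loop_oracle(small_panel):
    K = grm_vanraden(small_panel).matrix
    assert np.max(np.abs(K - _vanraden_oracle(small_panel.dosages))) < 1e-10


def test_gcta_matches_double_loop_oracle(small_panel):
    K = grm_gcta(small_panel).matrix
    assert np.max(np.abs(K - _gcta_oracle(small_panel.dosages))) < 1e-10


def test_identical_lines_offdiag_equals_diag(rng):
    row = rng.binomial(1, 0.5, 30).astype(float) * 2
    other = rng.binomial(1, 0.5, (4, 30)).astype(float) * 2
    gm = _gm(np.vstack([row, row, other]))
    for K in (grm_vanraden(gm).matrix, grm_gcta(gm).matrix):
        assert K[0, 1] == pytest.approx(K[0, 0], rel=1e-12)


def test_single_variant_gcta_closed_form():
    # dosages {0,2} at p=0.5: standardized products are +/-2 exactly
    gm = _gm(np.array([[0.0], [0.0], [2.0], [2.0]]))
    K = grm_gcta(gm).matrix
    expected = np.array(
        [[2.0, 2.0, -2.0, -2.0],
         [2.0, 2.0, -2.0, -2.0],
         [-2.0, -2.0, 2.0, 2.0],
         [-2.0, -2.0, 2.0, 2.0]]
    )
    assert np.allclose(K, expected)
    assert np.allclose(K, _gcta_oracle(gm.dosages))


def test_estimators_agree_on_uniform_frequencies(rng):
    p = np.full(400, 0.5)
    dos = (rng.random((40, 400)) < p).astype(float) * 2
    gm = _gm(dos)
    a = grm_vanraden(gm).matrix
    b = grm_gcta(gm).matrix
    iu = np.triu_indices(40, 1)
    assert np.corrcoef(a[iu], b[iu])[0, 1] > 0.99


def test_monomorphic_panel_errors():
    gm = _gm(np.zeros((5, 4)))
    with pytest.raises(DataValidationError):
        grm_vanraden(gm)
    with pytest.raises(DataValidationError):
        grm_gcta(gm)


def test_duplication_invariance(small_panel):
    dos = small_panel.dosages
    gm2 = _gm(np.hstack([dos, dos]))  # every variant duplicated
    for build in (grm_vanraden, grm_gcta):
        K1 = build(small_panel).matrix
        K2 = build(gm2).matrix
        assert np.allclose(K1, K2, atol=1e-12)


def test_psd_up_to_tolerance(small_panel, rng):
    # VanRaden (mean-imputed) is PSD by construction even with missing data;
    # pairwise-complete GCTA is exactly PSD on complete data.
    ev = np.linalg.eigvalsh(grm_vanraden(small_panel).matrix)
    assert ev.min() > -1e-8 * max(ev.max(), 1.0)
    complete = _gm(rng.binomial(1, rng.uniform(0.2, 0.8, 50), (12, 50)).astype(float) * 2)
    for build in (grm_vanraden, grm_gcta):
        ev = np.linalg.eigvalsh(build(complete).matrix)
        assert ev.min() > -1e-8 * max(ev.max(), 1.0)


def test_gcta_near_psd_at_panel_scale(inv_panel):
    # with realistic (low) missingness and many variants the pairwise-complete
    # denominators perturb the spectrum only marginally
    gm, _, _ = inv_panel
    from invgwa.grm import ld_grm

    K = ld_grm(gm).matrix
    ev = np.linalg.eigvalsh(K)
    assert ev.min() > -0.02 * ev.max()


def test_inbred_diagonal_near_two(inv_panel):
    gm, _, _ = inv_panel
    K = full_grm(gm).matrix
    assert abs(np.diag(K).mean() - 2.0) < 0.2


def test_loco_single_arm_errors():
    gm = _gm(np.tile([0.0, 2.0], (6, 5)))
    with pytest.raises(DataValidationError):
        loco_grms(gm)


def test_loco_uses_zero_variants_from_excluded_arm(inv_panel):
    gm, _, _ = inv_panel
    g = grm_loco(gm, "2L")
    assert g.strategy.excluded_arm == "2L"
    from invgwa.structure import select_variants

    idx = select_variants(gm, g.strategy)
    assert (gm.variants["arm"].iloc[idx] != "2L").all()
    assert g.n_variants_used == len(idx)


def test_loco_collapses_inverted_relatedness(inv_panel):
    gm, inv, _ = inv_panel
    rf = relatedness_by_genotype(full_grm(gm), inv, "In(2L)t")
    rl = relatedness_by_genotype(grm_loco(gm, "2L"), inv, "In(2L)t")
    assert rf["INV-INV"]["mean"] > rf["STD-STD"]["mean"]
    assert rl["INV-INV"]["mean"] < rf["INV-INV"]["mean"]
    assert abs(rl["INV-INV"]["mean"]) < 0.1


def test_relatedness_partition(inv_panel):
    gm, inv, _ = inv_panel
    groups = relatedness_by_genotype(full_grm(gm), inv, "In(2L)t")
    n = gm.n_lines
    assert sum(g["n_pairs"] for g in groups.values()) == n * (n - 1) // 2


def test_identity_grm_zero_group_means(inv_panel):
    gm, inv, _ = inv_panel
    ident = GRM(np.eye(gm.n_lines), gm.line_ids, method="identity")
    groups = relatedness_by_genotype(ident, inv, "In(2L)t")
    for g in groups.values():
        if g["n_pairs"]:
            assert g["mean"] == 0.0
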