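"""End-to-end orchestration of a simulated inversion-GWAS study.

``run_study`` executes the stages in dependency order — simulate panel and
traits, inversion-trait screen, trait PCA, genomic PCA, GRMs, multi-method
GWA with permutations, bin summaries and contrasts, outlier enrichment, and
PC1/PC2 colocalization — writing every artifact as TSV plus a JSON manifest
of parameters, seeds and file hashes. Re-running with the same configuration
reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as iomod
from .coloc import coloc_table, sliding_coloc
from .datatypes import SelectionStrategy
from .enrichment import enrichment_vs_permutation, outlier_enrichment, top_hits
from .grm import full_grm, ld_grm, loco_grms
from .gwas import GRMBundle, ScanCache, permute_gwa
from .invassoc import inversion_association_table
from .simulate import (
    ArmSpec,
    InversionSpec,
    PanelConfig,
    TraitConfig,
    simulate_covariates,
    simulate_outlier_flags,
    simulate_panel,
    simulate_traits,
)
from .structure import genomic_pca, pc_inversion_r2
from .summaries import bin_summary, method_region_contrast
from .traitpca import impute_regularized_pca, trait_pca

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "panel": {
        "n_lines": 120,
        "arms": [["2L", 23_000_000, 2000], ["2R", 21_000_000, 2000]],
        "inversions": [["2L", 2_200_000, 8_200_000, 0.30, 0.80]],
        "residual_het_rate": 0.002,
        "genotype_missing_rate": 0.01,
    },
    "traits": {
        "n_traits": 8,
        "n_null_traits": 4,
        "inversion_effect_r2": 0.10,
        "n_causal_background": 5,
        "polygenic_h2": 0.20,
        "covariate_effect": 0.25,
        "phenotype_missing_rate": 0.10,
    },
    "inv_assoc": {"n_draws": 50, "freq_tol": 0.05, "min_dist_bp": 2_000_000},
    "gwa": {"methods": ["loco", "factored"], "n_perm": 25, "hit_alpha": 1e-5},
    "enrichment": {"n_outliers": 60, "overlap": 0.5, "top_k": 100},
    "coloc": {"window_bp": 10_000, "step_bp": 5_000, "min_variants": 2},
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(source: str | Path | dict | None) -> dict:
    if source is None:
        cfg = {}
    elif isinstance(source, dict):
        cfg = source
    else:
        cfg = yaml.safe_load(Path(source).read_text()) or {}
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in cfg.items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


def run_study(config: str | Path | dict | None, out_dir: str | Path) -> dict:
    """Run the full study; returns (and writes) the manifest."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {"config": cfg, "stages": {}}

    def record(stage: str, files: dict[str, Path], **params) -> None:
        manifest["stages"][stage] = {
            "params": params,
            "files": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in files.items()},
        }

    # ---- stage 1: simulate panel, covariates, traits
    pc = cfg["panel"]
    panel_cfg = PanelConfig(
        n_lines=pc["n_lines"],
        arms=[ArmSpec(*a) for a in pc["arms"]],
        inversions=[InversionSpec(*i) for i in pc["inversions"]],
        residual_het_rate=pc["residual_het_rate"],
        genotype_missing_rate=pc["genotype_missing_rate"],
        seed=seed,
    )
    gm, inv_table, spans = simulate_panel(panel_cfg)
    cov = simulate_covariates(gm.line_ids, seed=seed + 1)
    tc = cfg["traits"]
    trait_cfg = TraitConfig(seed=seed + 2, **tc)
    phenos, truth = simulate_traits(
        gm, inv_table, cov.symbiont(gm.line_ids), trait_cfg, spans=spans
    )
    files = {
        "dosages": out / "genotypes.tsv",
        "vcf": out / "genotypes.vcf",
        "inversions": out / "inversions.tsv",
        "spans": out / "spans.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "covariates": out / "covariates.tsv",
        "truth": out / "truth.tsv",
    }
    iomod.write_dosage_tsv(gm, files["dosages"])
    iomod.write_vcf(gm, files["vcf"])
    iomod.write_inversions(inv_table, spans, files["inversions"], files["spans"])
    iomod.write_phenotypes(phenos, files["phenotypes"])
    iomod.write_covariates(cov, files["covariates"])
    truth.map(lambda v: json.dumps(v) if isinstance(v, list) else v).to_csv(
        files["truth"], sep="\t"
    )
    record("simulate", files, panel=asdict(panel_cfg), traits=asdict(trait_cfg))

    # ---- stage 2: inversion-trait screen
    ia = cfg["inv_assoc"]
    assoc = inversion_association_table(
        phenos, inv_table, gm, spans,
        n_draws=ia["n_draws"], freq_tol=ia["freq_tol"],
        min_dist_bp=ia["min_dist_bp"], seed=seed + 3,
    )
    f = {"inv_assoc": out / "inversion_association.tsv"}
    assoc.to_csv(f["inv_assoc"], sep="\t", index=False)
    record("inversion_assoc", f, **ia)

    # ---- stage 3: trait PCA on the associated set (fall back to all traits)
    assoc_traits = sorted(assoc.loc[assoc["associated"], "trait_id"].unique())
    pca_traits = assoc_traits if len(assoc_traits) >= 3 else phenos.trait_ids
    mat = phenos.values[pca_traits]
    complete, converged = impute_regularized_pca(mat, ncp=2, seed=seed + 4)
    tp = trait_pca(complete)
    f = {
        "trait_scores": out / "trait_pca_scores.tsv",
        "trait_loadings": out / "trait_pca_loadings.tsv",
        "scree": out / "trait_pca_scree.tsv",
    }
    tp.scores.to_csv(f["trait_scores"], sep="\t")
    tp.loadings.to_csv(f["trait_loadings"], sep="\t")
    pd.DataFrame(
        {"component": tp.scores.columns[: len(tp.variance_explained)],
         "variance_explained": tp.variance_explained}
    ).to_csv(f["scree"], sep="\t", index=False)
    record("trait_pca", f, traits=pca_traits, imputation_converged=bool(converged))

    # ---- stage 4: genomic PCA under the three strategies
    rows = []
    strategies = [SelectionStrategy.full(), SelectionStrategy.ld()] + [
        SelectionStrategy.loco(sp.arm) for sp in spans
    ]
    for strat in strategies:
        g_pca = genomic_pca(gm, strat, n_components=4)
        for sp in spans:
            for comp in ("PC1", "PC2"):
                r2, perm, flag = pc_inversion_r2(
                    g_pca, inv_table, sp.name, comp, n_perm=100, seed=seed + 5
                )
                rows.append(
                    {
                        "strategy": strat.name,
                        "excluded_arm": strat.excluded_arm,
                        "inversion": sp.name,
                        "component": comp,
                        "r2": r2,
                        "perm_q95": float(np.nanpercentile(perm, 95)),
                        "exceeds": flag,
                    }
                )
    f = {"genomic_pca": out / "genomic_pca_inversion_r2.tsv"}
    pd.DataFrame(rows).to_csv(f["genomic_pca"], sep="\t", index=False)
    record("genomic_pca", f)

    # ---- stage 5: GRMs
    bundle = GRMBundle(full=full_grm(gm), ld=ld_grm(gm), loco=loco_grms(gm))
    f = {"grm_full": out / "grm_full.tsv", "grm_ld": out / "grm_ld.tsv"}
    iomod.write_grm(bundle.full, f["grm_full"])
    iomod.write_grm(bundle.ld, f["grm_ld"])
    for arm, g in bundle.loco.items():
        f[f"grm_loco_{arm}"] = out / f"grm_loco_{arm}.tsv"
        iomod.write_grm(g, f[f"grm_loco_{arm}"])
    record("grm", f)

    # ---- stage 6-8: GWA with permutations, summaries, enrichment
    gw = cfg["gwa"]
    en = cfg["enrichment"]
    cache = ScanCache()
    causal_all = sorted({int(j) for idx in truth["causal_idx"] for j in idx})
    outliers = simulate_outlier_flags(
        gm, causal_all or [0], overlap=en["overlap"],
        n_outliers=en["n_outliers"], seed=seed + 6,
    )
    iomod.write_outliers(outliers, gm, out / "outliers.tsv")
    summaries = []
    enrich_rows = []
    for trait_id in phenos.trait_ids:
        for method in gw["methods"]:
            runs = permute_gwa(
                phenos.trait(trait_id), gm, inv_table, cov, bundle, method,
                n_perm=gw["n_perm"], seed=seed + 7, cache=cache, trait_id=trait_id,
            )
            summaries.append(bin_summary(runs, spans, alpha=gw["hit_alpha"]))
            uni = runs[0].table["variant_idx"].to_numpy()
            uni_set = set(uni.tolist())
            out_in_uni = np.array(
                [j for j in outliers.indices if j in uni_set], dtype=int
            )
            if len(out_in_uni) >= 5:
                obs_e = outlier_enrichment(top_hits(runs[0], en["top_k"]), out_in_uni, uni)
                perm_e = [
                    outlier_enrichment(top_hits(r, en["top_k"]), out_in_uni, uni)
                    for r in runs[1:]
                ]
                flag, q95 = enrichment_vs_permutation(obs_e, perm_e)
                enrich_rows.append(
                    {
                        "trait_id": trait_id,
                        "method": method,
                        "odds_ratio": obs_e.odds_ratio,
                        "p": obs_e.p_value,
                        "perm_q95": q95,
                        "exceeds": flag,
                        "inversion_associated": trait_id in set(assoc_traits),
                    }
                )
    summary_df = pd.concat(summaries, ignore_index=True)
    contrast_hit = method_region_contrast(summary_df, "exceeds_hit")
    contrast_gif = method_region_contrast(summary_df, "exceeds_gif")
    f = {
        "bin_summaries": out / "bin_summaries.tsv",
        "contrast_hits": out / "contrast_hits.tsv",
        "contrast_gif": out / "contrast_gif.tsv",
        "enrichment": out / "enrichment.tsv",
        "outliers": out / "outliers.tsv",
    }
    summary_df.to_csv(f["bin_summaries"], sep="\t", index=False)
    contrast_hit.to_csv(f["contrast_hits"], sep="\t", index=False)
    contrast_gif.to_csv(f["contrast_gif"], sep="\t", index=False)
    pd.DataFrame(enrich_rows).to_csv(f["enrichment"], sep="\t", index=False)
    record("gwa_summaries", f, **gw, **en)

    # ---- stage 9: colocalization of trait-space PC1 vs PC2 profiles
    cl = cfg["coloc"]
    arm_lengths = {a[0]: a[1] for a in pc["arms"]}
    coloc_files = {}
    for method in gw["methods"]:
        prof = {}
        for comp in ("PC1", "PC2"):
            y = tp.scores[comp]
            y.name = comp
            prof[comp] = permute_gwa(
                y, gm, inv_table, cov, bundle, method,
                n_perm=0, seed=seed + 8, cache=cache, trait_id=comp,
            )[0]
        wins = sliding_coloc(
            prof["PC1"], prof["PC2"],
            window_bp=cl["window_bp"], step_bp=cl["step_bp"],
            min_variants=cl["min_variants"], arm_lengths=arm_lengths,
        )
        path = out / f"coloc_{method}.tsv"
        coloc_table(wins).to_csv(path, sep="\t", index=False)
        coloc_files[f"coloc_{method}"] = path
    record("coloc", coloc_files, **cl)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
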