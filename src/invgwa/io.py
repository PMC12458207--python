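"""Readers and writers for every external table the pipeline touches.

Formats: GT-only VCF 4.2 (diploid, biallelic), plain dosage TSV, inversion
genotype TSV (long), inversion span TSV (1-based inclusive), long-format
phenotype TSV, covariate TSV, outlier TSV, and square GRM TSV. Every reader is
total on the corresponding writer's output (round-trip property).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    GRM,
    CovariateTable,
    DataValidationError,
    GenotypeMatrix,
    InversionSpan,
    InversionTable,
    OutlierSet,
    PhenotypeTable,
)

log = logging.getLogger("invgwa")

_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
_DOSAGE = {"0/0": 0.0, "0/1": 1.0, "1/0": 1.0, "1/1": 2.0, "./.": np.nan}


# ---------------------------------------------------------------- genotypes

def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal diploid GT-only VCF. Indels get a 2-bp REF to survive
    the round trip; SNPs are written as A>T."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for arm, sub in gm.variants.groupby("arm", sort=False):
            fh.write(f"##contig=<ID={arm},length={int(sub['pos'].max()) + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, gm.line_ids))
            + "\n"
        )
        dos = gm.dosages
        for j, row in gm.variants.iterrows():
            ref, alt = ("AT", "A") if row["is_indel"] else ("A", "T")
            calls = "\t".join(
                _GT.get(dos[i, j], "./.") if not np.isnan(dos[i, j]) else "./."
                for i in range(gm.n_lines)
            )
            fh.write(
                f"{row['arm']}\t{row['pos']}\t{row['id']}\t{ref}\t{alt}\t.\t.\t.\tGT\t{calls}\n"
            )


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    line_ids = np.array(vcf.samples, dtype=object)
    rows, cols = [], []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_skipped += 1
            continue
        # gts012: 0/1/2 dosage, 3 = missing
        d = v.gt_types.astype(float)
        d[d == 3] = np.nan
        if np.all(np.isnan(d)):
            n_skipped += 1
            continue
        rows.append(
            {
                "id": v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}",
                "arm": v.CHROM,
                "pos": v.POS,
                "is_indel": len(v.REF) != len(v.ALT[0]),
            }
        )
        cols.append(d)
    if n_skipped:
        log.info("read_genotypes: skipped %d records (non-biallelic or all-missing)", n_skipped)
    if not rows:
        raise DataValidationError(f"{path}: no usable variant records")
    return GenotypeMatrix(
        line_ids=line_ids,
        variants=pd.DataFrame(rows),
        dosages=np.column_stack(cols),
    )


def write_dosage_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    df = gm.variants.copy()
    dos = pd.DataFrame(gm.dosages.T, columns=list(gm.line_ids))
    pd.concat([df, dos], axis=1).to_csv(path, sep="\t", index=False, na_rep="NA")


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    meta_cols = ["id", "arm", "pos", "is_indel"]
    for c in meta_cols:
        if c not in df.columns:
            raise DataValidationError(f"{path}: missing column {c!r}")
    line_cols = [c for c in df.columns if c not in meta_cols]
    variants = df[meta_cols].copy()
    variants["arm"] = variants["arm"].astype(str)
    dos = df[line_cols].to_numpy(dtype=float).T
    all_missing = np.all(np.isnan(dos), axis=0)
    if all_missing.any():
        log.info("read_genotypes: dropped %d all-missing sites", int(all_missing.sum()))
        keep = ~all_missing
        variants = variants.loc[keep].reset_index(drop=True)
        dos = dos[:, keep]
    return GenotypeMatrix(
        line_ids=np.array(line_cols, dtype=object), variants=variants, dosages=dos
    )


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from VCF or dosage TSV (auto-detected by suffix)."""
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in (".vcf", ".gz") or path.name.endswith(".vcf.gz") else "dosage-tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage-tsv":
        return _read_dosage_tsv(path)
    raise DataValidationError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------- inversions

def write_inversions(
    table: InversionTable, spans: Sequence[InversionSpan], geno_path: str | Path, span_path: str | Path
) -> None:
    long = (
        table.genotypes.reset_index(names="line_id")
        .melt(id_vars="line_id", var_name="inversion_name", value_name="genotype")
    )
    long.to_csv(geno_path, sep="\t", index=False)
    pd.DataFrame(
        [{"arm": s.arm, "start": s.start, "end": s.end, "name": s.name} for s in spans]
    ).to_csv(span_path, sep="\t", index=False)


def read_inversions(
    geno_path: str | Path, span_path: str | Path
) -> tuple[InversionTable, list[InversionSpan]]:
    long = pd.read_csv(geno_path, sep="\t")
    if long.duplicated(["line_id", "inversion_name"]).any():
        raise DataValidationError("duplicate (line, inversion) rows")
    wide = long.pivot(index="line_id", columns="inversion_name", values="genotype")
    wide.columns.name = None
    sp = pd.read_csv(span_path, sep="\t")
    spans = [
        InversionSpan(name=r["name"], arm=str(r["arm"]), start=int(r["start"]), end=int(r["end"]))
        for _, r in sp.iterrows()
    ]
    return InversionTable(wide), spans


# ---------------------------------------------------------------- phenotypes

def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    long = (
        table.values.reset_index(names="line_id")
        .melt(id_vars="line_id", var_name="trait_id", value_name="value")
    )
    long["category"] = table.categories.reindex(long["trait_id"]).to_numpy()
    long.dropna(subset=["value"]).to_csv(path, sep="\t", index=False)


def read_phenotypes(
    path: str | Path,
    genotype_lines: Sequence[str] | None = None,
    min_lines: int = 75,
) -> PhenotypeTable:
    """Read a long-format phenotype TSV.

    Lines absent from ``genotype_lines`` (when given) are logged and dropped;
    traits measured in fewer than ``min_lines`` lines are flagged via
    ``PhenotypeTable.low_n_traits``. Empty input is an error.
    """
    long = pd.read_csv(path, sep="\t")
    if long.empty:
        raise DataValidationError(f"{path}: empty phenotype file")
    need = {"line_id", "trait_id", "value"}
    if not need <= set(long.columns):
        raise DataValidationError(f"{path}: phenotype TSV needs columns {sorted(need)}")
    if long.duplicated(["line_id", "trait_id"]).any():
        raise DataValidationError("duplicate (line, trait) rows")
    if genotype_lines is not None:
        known = set(genotype_lines)
        unknown = ~long["line_id"].isin(known)
        if unknown.any():
            log.info(
                "read_phenotypes: dropped %d rows for %d lines absent from genotypes",
                int(unknown.sum()),
                long.loc[unknown, "line_id"].nunique(),
            )
            long = long.loc[~unknown]
    wide = long.pivot(index="line_id", columns="trait_id", values="value")
    wide.columns.name = None
    if "category" in long.columns:
        cats = long.drop_duplicates("trait_id").set_index("trait_id")["category"]
    else:
        cats = pd.Series("Physiology", index=wide.columns)
    table = PhenotypeTable(values=wide, categories=cats.reindex(wide.columns))
    low = table.low_n_traits(min_lines)
    if low:
        log.info("read_phenotypes: %d traits measured in < %d lines", len(low), min_lines)
    return table


# ---------------------------------------------------------------- covariates

def write_covariates(cov: CovariateTable, path: str | Path) -> None:
    cov.table.reset_index(names="line_id").to_csv(path, sep="\t", index=False)


def read_covariates(path: str | Path) -> CovariateTable:
    df = pd.read_csv(path, sep="\t").set_index("line_id")
    return CovariateTable(df)


# ---------------------------------------------------------------- outliers

def write_outliers(out: OutlierSet, gm: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame({"variant_id": gm.variants["id"].iloc[out.indices].to_numpy()})
    df["score"] = out.score if out.score is not None else np.nan
    df["empirical_p"] = out.empirical_p if out.empirical_p is not None else np.nan
    df.to_csv(path, sep="\t", index=False)


def read_outliers(path: str | Path, gm: GenotypeMatrix) -> OutlierSet:
    df = pd.read_csv(path, sep="\t")
    lookup = pd.Series(np.arange(gm.n_variants), index=gm.variants["id"])
    missing = ~df["variant_id"].isin(lookup.index)
    if missing.any():
        raise DataValidationError("outlier variant ids absent from genotype matrix")
    out = OutlierSet(
        indices=lookup.loc[df["variant_id"]].to_numpy(),
        score=df["score"].to_numpy() if df["score"].notna().any() else None,
        empirical_p=df["empirical_p"].to_numpy() if df["empirical_p"].notna().any() else None,
    )
    out.validate_against(gm)
    return out


# ---------------------------------------------------------------- GRM

def write_grm(grm: GRM, path: str | Path) -> None:
    pd.DataFrame(grm.matrix, index=list(grm.line_ids), columns=list(grm.line_ids)).to_csv(
        path, sep="\t"
    )


def read_grm(path: str | Path, method: str = "vanraden") -> GRM:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GRM(
        matrix=df.to_numpy(dtype=float),
        line_ids=df.index.to_numpy(dtype=object),
        method=method,
    )
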