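"""Synthetic inbred-line panels with inversion-style high-LD blocks.

The generator emulates a reference panel of ~200 near-homozygous lines: each
line is a pair of identical haplotypes (dosage 0/2) except at residual
heterozygous sites (dosage 1). One or more chromosome arms carry an inversion
segregating as two diverged haplotype classes, so variants inside the span are
in strong LD with arrangement status; background variants are in approximate
linkage equilibrium with frequencies from a truncated Beta(0.5, 0.5).

Traits are line means built from an inversion-arrangement effect, a sparse set
of causal variants, a binary covariate effect, and Gaussian noise, with
components scaled to prescribed variance fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    HET,
    INV,
    STD,
    ConfigurationError,
    CovariateTable,
    GenotypeMatrix,
    InversionSpan,
    InversionTable,
    OutlierSet,
    PhenotypeTable,
    TRAIT_CATEGORIES,
)

__all__ = [
    "ArmSpec",
    "InversionSpec",
    "PanelConfig",
    "TraitConfig",
    "simulate_panel",
    "simulate_covariates",
    "simulate_traits",
    "simulate_outlier_flags",
]


@dataclass(frozen=True)
class ArmSpec:
    name: str
    length_bp: int
    n_variants: int


@dataclass(frozen=True)
class InversionSpec:
    """One simulated inversion: arm span, inverted-arrangement frequency and
    haplotype-class allele-frequency divergence ``d = |p_inv - p_std|``."""

    arm: str
    start: int
    end: int
    frequency: float
    divergence: float
    name: str | None = None


@dataclass
class PanelConfig:
    n_lines: int = 200
    arms: Sequence[ArmSpec] = (
        ArmSpec("2L", 23_000_000, 1000),
        ArmSpec("2R", 21_000_000, 1000),
    )
    inversions: Sequence[InversionSpec] = (
        InversionSpec("2L", 2_200_000, 13_200_000, 0.30, 0.80),
    )
    residual_het_rate: float = 0.0
    genotype_missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for r, nm in (
            (self.residual_het_rate, "residual_het_rate"),
            (self.genotype_missing_rate, "genotype_missing_rate"),
        ):
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError(f"{nm} must lie in [0, 1], got {r}")
        arm_len = {a.name: a.length_bp for a in self.arms}
        for a in self.arms:
            if a.n_variants < 2:
                raise ConfigurationError(f"arm {a.name}: need >= 2 variants")
            if a.n_variants > a.length_bp:
                raise ConfigurationError(f"arm {a.name}: more variants than positions")
        for inv in self.inversions:
            if inv.arm not in arm_len:
                raise ConfigurationError(f"inversion on unknown arm {inv.arm!r}")
            if not (1 <= inv.start < inv.end <= arm_len[inv.arm]):
                raise ConfigurationError(
                    f"inversion span [{inv.start}, {inv.end}] exceeds arm {inv.arm}"
                )
            if not 0.0 < inv.frequency < 1.0:
                raise ConfigurationError("inverted-haplotype frequency must be in (0,1)")
            if not 0.0 <= inv.divergence <= 1.0:
                raise ConfigurationError("divergence d must lie in [0, 1]")


def _inversion_name(spec: InversionSpec, k: int) -> str:
    return spec.name if spec.name is not None else f"In({spec.arm})s{k + 1}"


def _truncated_beta(rng: np.random.Generator, size: int, lo: float = 0.05, hi: float = 0.95):
    """Beta(0.5, 0.5) truncated to [lo, hi] via inverse-CDF sampling."""
    dist = stats.beta(0.5, 0.5)
    u = rng.uniform(dist.cdf(lo), dist.cdf(hi), size=size)
    return dist.ppf(u)


def simulate_panel(
    config: PanelConfig,
) -> tuple[GenotypeMatrix, InversionTable, list[InversionSpan]]:
    """Draw a genotype panel, its inversion genotypes, and the span list.

    Within each inversion span a line's alleles are drawn from haplotype-class
    frequencies separated by ``divergence``; outside spans alleles are i.i.d.
    per line at a background frequency. Identical seeds give identical panels.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_lines
    line_ids = np.array([f"line_{i + 1:03d}" for i in range(n)], dtype=object)

    spans: list[InversionSpan] = []
    inv_geno: dict[str, np.ndarray] = {}
    # per-inversion line state: 2 haplotype classes per line (0=std, 1=inv)
    hap_classes: dict[str, np.ndarray] = {}
    for k, spec in enumerate(config.inversions):
        name = _inversion_name(spec, k)
        if name in inv_geno:
            raise ConfigurationError(f"duplicate inversion name {name!r}")
        spans.append(InversionSpan(name=name, arm=spec.arm, start=spec.start, end=spec.end))
        cls = rng.random(n) < spec.frequency
        het = rng.random(n) < config.residual_het_rate
        h = np.stack([cls, cls], axis=1).astype(int)
        h[het, 1] = 1 - h[het, 0]
        hap_classes[name] = h
        geno = np.where(het, HET, np.where(cls, INV, STD))
        inv_geno[name] = geno.astype(object)

    var_frames = []
    dosage_blocks = []
    for arm in config.arms:
        pos = np.sort(rng.choice(arm.length_bp, size=arm.n_variants, replace=False)) + 1
        is_indel = rng.random(arm.n_variants) < 0.15
        p_bg = _truncated_beta(rng, arm.n_variants)
        dos = np.empty((n, arm.n_variants))

        covered = np.zeros(arm.n_variants, dtype=bool)
        for (spec, span) in zip(config.inversions, spans):
            if span.arm != arm.name:
                continue
            in_span = (pos >= span.start) & (pos <= span.end) & ~covered
            m = int(in_span.sum())
            if m == 0:
                continue
            covered |= in_span
            d = spec.divergence
            centre = rng.uniform(d / 2.0, 1.0 - d / 2.0, size=m)
            sign = rng.choice([-1.0, 1.0], size=m)
            p_inv = centre + sign * d / 2.0
            p_std = centre - sign * d / 2.0
            h = hap_classes[span.name]  # (n, 2) haplotype classes
            freqs = np.stack([p_std, p_inv], axis=0)  # (2, m)
            a1 = rng.random((n, m)) < freqs[h[:, 0]]
            # second haplotype identical unless the line is inversion-HET
            same = h[:, 0] == h[:, 1]
            a2 = np.where(same[:, None], a1, rng.random((n, m)) < freqs[h[:, 1]])
            dos[:, in_span] = a1.astype(float) + a2.astype(float)

        bg = ~covered
        alle = rng.random((n, int(bg.sum()))) < p_bg[bg]
        dos[:, bg] = 2.0 * alle

        # residual heterozygosity at background + homozygous in-span sites
        het_mask = rng.random((n, arm.n_variants)) < config.residual_het_rate
        dos[het_mask] = 1.0
        miss = rng.random((n, arm.n_variants)) < config.genotype_missing_rate
        dos[miss] = np.nan

        var_frames.append(
            pd.DataFrame(
                {
                    "id": [f"{arm.name}_{p}" for p in pos],
                    "arm": arm.name,
                    "pos": pos.astype(int),
                    "is_indel": is_indel,
                }
            )
        )
        dosage_blocks.append(dos)

    gm = GenotypeMatrix(
        line_ids=line_ids,
        variants=pd.concat(var_frames, ignore_index=True),
        dosages=np.concatenate(dosage_blocks, axis=1),
    )
    inv_table = InversionTable(pd.DataFrame(inv_geno, index=line_ids))
    return gm, inv_table, spans


def simulate_covariates(
    line_ids: Sequence[str], infection_rate: float = 0.5, seed: int = 0
) -> CovariateTable:
    """Binary symbiont infection status plus a Beta-distributed ancestry proportion."""
    rng = np.random.default_rng(seed)
    n = len(line_ids)
    return CovariateTable(
        pd.DataFrame(
            {
                "symbiont": (rng.random(n) < infection_rate).astype(int),
                "ancestry": rng.beta(8.0, 2.0, size=n),
            },
            index=list(line_ids),
        )
    )


@dataclass
class TraitConfig:
    """Architecture of the simulated trait panel.

    ``inversion_effect_r2`` is the trait-variance fraction contributed by the
    inversion-arrangement dosage; ``polygenic_h2`` the fraction contributed by
    the ``n_causal_background`` causal variants. The last ``n_null_traits``
    traits carry no genetic signal at all (pure noise + covariate).
    """

    n_traits: int = 20
    inversion_effect_r2: float = 0.10
    n_causal_background: int = 5
    polygenic_h2: float = 0.20
    covariate_effect: float = 0.25
    phenotype_missing_rate: float = 0.10
    trait_categories: Sequence[str] = TRAIT_CATEGORIES
    seed: int = 0
    n_null_traits: int = 0
    causal_inside_spans: bool = False
    inversion: str | None = None  # defaults to the panel's first inversion

    def __post_init__(self) -> None:
        for f, nm in ((self.inversion_effect_r2, "inversion_effect_r2"),
                      (self.polygenic_h2, "polygenic_h2")):
            if not 0.0 <= f < 1.0:
                raise ConfigurationError(f"{nm} must lie in [0, 1)")
        if self.inversion_effect_r2 + self.polygenic_h2 >= 1.0:
            raise ConfigurationError("variance fractions must sum below 1")
        if not 0.0 <= self.phenotype_missing_rate <= 1.0:
            raise ConfigurationError("phenotype_missing_rate must lie in [0, 1]")
        if self.n_null_traits > self.n_traits:
            raise ConfigurationError("n_null_traits exceeds n_traits")


def _scaled(component: np.ndarray, target_var: float) -> np.ndarray:
    sd = component.std()
    if sd == 0:
        return np.zeros_like(component)
    return component * (np.sqrt(target_var) / sd)


def simulate_traits(
    genotypes: GenotypeMatrix,
    inversions: InversionTable,
    covariate: np.ndarray | None,
    config: TraitConfig,
    spans: Sequence[InversionSpan] = (),
) -> tuple[PhenotypeTable, pd.DataFrame]:
    """Simulate line-mean traits; returns the table and a causal truth record.

    Truth columns: ``trait_id``, ``is_null``, ``causal_idx`` (list of variant
    indices), ``beta`` (list of matched effects), ``beta_inv``.
    """
    rng = np.random.default_rng(config.seed)
    n = genotypes.n_lines
    inv_name = config.inversion or (inversions.inversions[0] if inversions.inversions else None)
    inv_dos = (
        inversions.dosage(inv_name, genotypes.line_ids)
        if inv_name is not None
        else np.zeros(n)
    )
    if covariate is None:
        cov = np.zeros(n)
    else:
        cov = np.asarray(covariate, dtype=float)
        if cov.std() == 0 and config.covariate_effect != 0:
            warnings.warn("covariate constant across lines: effect unidentifiable")

    in_span = np.zeros(genotypes.n_variants, dtype=bool)
    for sp in spans:
        on_arm = genotypes.variants["arm"].to_numpy() == sp.arm
        pos = genotypes.variants["pos"].to_numpy()
        in_span |= on_arm & (pos >= sp.start) & (pos <= sp.end)
    eligible = genotypes.maf >= 0.05
    eligible &= in_span if config.causal_inside_spans else ~in_span
    eligible_idx = np.flatnonzero(eligible)

    # mean-imputed dosages for trait construction
    dos = genotypes.dosages.copy()
    col_mean = np.nanmean(dos, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(dos))
    dos[nan_r, nan_c] = col_mean[nan_c]

    values = np.empty((n, config.n_traits))
    truth_rows = []
    cats = [
        config.trait_categories[i % len(config.trait_categories)]
        for i in range(config.n_traits)
    ]
    for t in range(config.n_traits):
        is_null = t >= config.n_traits - config.n_null_traits
        eps_var = 1.0
        genetic = np.zeros(n)
        causal_idx: list[int] = []
        betas: list[float] = []
        beta_inv = 0.0
        if not is_null:
            if config.inversion_effect_r2 > 0 and inv_dos.std() > 0:
                genetic += _scaled(inv_dos - inv_dos.mean(), config.inversion_effect_r2)
                beta_inv = np.sqrt(config.inversion_effect_r2) / inv_dos.std()
                eps_var -= config.inversion_effect_r2
            if config.polygenic_h2 > 0 and config.n_causal_background > 0:
                k = min(config.n_causal_background, len(eligible_idx))
                if k == 0:
                    raise ConfigurationError("no eligible causal variants")
                causal_idx = [int(j) for j in rng.choice(eligible_idx, size=k, replace=False)]
                raw_beta = rng.standard_normal(k)
                comp = dos[:, causal_idx] @ raw_beta
                scale = (
                    np.sqrt(config.polygenic_h2) / comp.std() if comp.std() > 0 else 0.0
                )
                genetic += comp * scale
                betas = [float(b) for b in raw_beta * scale]
                eps_var -= config.polygenic_h2
        eps = rng.standard_normal(n)
        values[:, t] = (
            config.covariate_effect * cov + genetic + np.sqrt(eps_var) * eps
        )
        truth_rows.append(
            {
                "trait_id": f"trait_{t + 1:03d}",
                "is_null": is_null,
                "causal_idx": causal_idx,
                "beta": betas,
                "beta_inv": beta_inv,
                "category": cats[t],
            }
        )

    trait_ids = [r["trait_id"] for r in truth_rows]
    miss = rng.random(values.shape) < config.phenotype_missing_rate
    values = np.where(miss, np.nan, values)
    table = PhenotypeTable(
        values=pd.DataFrame(values, index=genotypes.line_ids, columns=trait_ids),
        categories=pd.Series(cats, index=trait_ids),
    )
    return table, pd.DataFrame(truth_rows).set_index("trait_id")


def simulate_outlier_flags(
    genotypes: GenotypeMatrix,
    causal_indices: Sequence[int],
    overlap: float,
    n_outliers: int,
    seed: int = 0,
) -> OutlierSet:
    """Outlier variant set with a controlled overlap with the causal set.

    ``round(overlap * n_outliers)`` members come from ``causal_indices`` (or
    their highest-LD proxies when the causal set is smaller); the remainder is
    uniform over non-causal variants. Sampling is without replacement.
    """
    if not 0.0 <= overlap <= 1.0:
        raise ConfigurationError("overlap must lie in [0, 1]")
    if n_outliers > genotypes.n_variants:
        raise ConfigurationError("more outliers requested than variants")
    rng = np.random.default_rng(seed)
    causal = np.unique(np.asarray(causal_indices, dtype=int))
    n_causal_part = int(round(overlap * n_outliers))
    chosen: list[int] = []
    if n_causal_part <= len(causal):
        chosen.extend(rng.choice(causal, size=n_causal_part, replace=False))
    else:
        chosen.extend(causal)
        extra = n_causal_part - len(causal)
        # fill with the non-causal variants in highest LD with any causal variant
        dos = genotypes.dosages
        col_mean = np.nanmean(dos, axis=0)
        z = np.where(np.isnan(dos), col_mean, dos)
        z = z - z.mean(axis=0)
        sd = z.std(axis=0)
        sd[sd == 0] = np.inf
        zc = z[:, causal] / sd[causal]
        zall = z / sd
        r2 = (zall.T @ zc / len(zall)) ** 2  # (n_variants, n_causal)
        best = r2.max(axis=1)
        best[causal] = -np.inf
        proxies = np.argsort(-best, kind="stable")[:extra]
        chosen.extend(proxies)
    non_causal = np.setdiff1d(np.arange(genotypes.n_variants), np.array(chosen + list(causal)))
    n_rest = n_outliers - len(chosen)
    if n_rest > 0:
        chosen.extend(rng.choice(non_causal, size=n_rest, replace=False))
    idx = np.array(sorted(chosen), dtype=int)
    out = OutlierSet(indices=idx)
    out.validate_against(genotypes)
    return out
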