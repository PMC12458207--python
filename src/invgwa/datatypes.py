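"""Core in-memory containers shared by every pipeline stage.

All genomic coordinates are 1-based and inclusive (VCF convention): a variant
at position ``p`` lies inside a span ``[start, end]`` iff ``start <= p <= end``.
Dosages are additive alternate-allele counts in {0, 1, 2}; missing entries are
``NaN``. Inbred lines are expected (not required) to sit at {0, 2}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

INV, STD, HET = "INV", "STD", "HET"
#: additive dosage coding of an inversion genotype (number of inverted arrangements)
INVERSION_DOSAGE = {STD: 0.0, HET: 1.0, INV: 2.0}


class ConfigurationError(ValueError):
    """A simulation or run configuration violates its invariants."""


class DataValidationError(ValueError):
    """An input table violates the format contract."""


@dataclass(frozen=True)
class InversionSpan:
    """Genomic extent of one inversion (1-based, inclusive)."""

    name: str
    arm: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise DataValidationError(
                f"span {self.name}: start ({self.start}) must be < end ({self.end})"
            )

    def contains(self, arm: str, pos: int | np.ndarray) -> bool | np.ndarray:
        inside = (np.asarray(pos) >= self.start) & (np.asarray(pos) <= self.end)
        return inside & (arm == self.arm)


@dataclass
class GenotypeMatrix:
    """Lines x variants dosage matrix with per-variant metadata.

    ``variants`` has columns ``id``, ``arm``, ``pos``, ``is_indel``; positions
    must be strictly increasing within each arm and variant ids unique.
    """

    line_ids: np.ndarray
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.line_ids), len(self.variants)):
            raise DataValidationError(
                f"dosage shape {self.dosages.shape} != "
                f"({len(self.line_ids)}, {len(self.variants)})"
            )
        if self.variants["id"].duplicated().any():
            dup = self.variants["id"][self.variants["id"].duplicated()].iloc[0]
            raise DataValidationError(f"duplicate variant id {dup!r}")
        if len(np.unique(self.line_ids)) != len(self.line_ids):
            raise DataValidationError("duplicate line ids")
        for arm, sub in self.variants.groupby("arm", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise DataValidationError(f"positions not strictly increasing on {arm}")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise DataValidationError("dosages must be in {0,1,2} or NaN")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per variant over non-missing entries."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    @property
    def maf(self) -> np.ndarray:
        p = self.allele_freq
        return np.minimum(p, 1.0 - p)

    @property
    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def line_index(self, line_ids: Sequence[str]) -> np.ndarray:
        lookup = {lid: i for i, lid in enumerate(self.line_ids)}
        try:
            return np.array([lookup[l] for l in line_ids], dtype=int)
        except KeyError as e:  # pragma: no cover - defensive
            raise DataValidationError(f"unknown line id {e.args[0]!r}") from None

    def subset(
        self,
        lines: Sequence[str] | np.ndarray | None = None,
        variant_idx: np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        li = slice(None) if lines is None else self.line_index(lines)
        vi = slice(None) if variant_idx is None else np.asarray(variant_idx, dtype=int)
        return GenotypeMatrix(
            line_ids=self.line_ids[li],
            variants=self.variants.iloc[vi].reset_index(drop=True),
            dosages=self.dosages[li][:, vi] if lines is not None else self.dosages[:, vi],
        )


@dataclass
class InversionTable:
    """Per-line inversion genotypes, ``INV`` / ``STD`` / ``HET``.

    Backed by a DataFrame indexed by line id with one column per inversion.
    """

    genotypes: pd.DataFrame

    def __post_init__(self) -> None:
        bad = ~self.genotypes.isin([INV, STD, HET]) & self.genotypes.notna()
        if bad.to_numpy().any():
            raise DataValidationError("inversion genotypes must be INV/STD/HET")
        if self.genotypes.columns.duplicated().any():
            raise DataValidationError("inversion names must be unique")

    @property
    def inversions(self) -> list[str]:
        return list(self.genotypes.columns)

    @property
    def line_ids(self) -> np.ndarray:
        return self.genotypes.index.to_numpy(dtype=object)

    def genotype(self, inversion: str, line_ids: Sequence[str]) -> np.ndarray:
        return self.genotypes.loc[list(line_ids), inversion].to_numpy(dtype=object)

    def dosage(self, inversion: str, line_ids: Sequence[str]) -> np.ndarray:
        """Additive inverted-arrangement dosage: STD=0, HET=1, INV=2."""
        g = self.genotype(inversion, line_ids)
        return np.array([INVERSION_DOSAGE.get(x, np.nan) for x in g], dtype=float)

    def homozygous_mask(self, inversion: str, line_ids: Sequence[str]) -> np.ndarray:
        g = self.genotype(inversion, line_ids)
        return np.isin(g, (INV, STD))

    def allele_frequency(self, inversion: str) -> float:
        """Inverted-arrangement allele frequency, HET counted as one allele."""
        g = self.genotypes[inversion].dropna()
        if len(g) == 0:
            raise DataValidationError(f"no genotypes for {inversion}")
        return float((2 * (g == INV).sum() + (g == HET).sum()) / (2 * len(g)))


TRAIT_CATEGORIES = (
    "Behavior",
    "Life-History",
    "Morphology",
    "Physiology",
    "Stress-resistance",
)


@dataclass
class PhenotypeTable:
    """Per-line trait means (wide: lines x traits, NaN = not measured)."""

    values: pd.DataFrame
    categories: pd.Series

    def __post_init__(self) -> None:
        missing_cat = [t for t in self.values.columns if t not in self.categories.index]
        if missing_cat:
            raise DataValidationError(f"traits without category: {missing_cat[:5]}")

    @property
    def trait_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def line_ids(self) -> np.ndarray:
        return self.values.index.to_numpy(dtype=object)

    @property
    def n_lines_measured(self) -> pd.Series:
        return self.values.notna().sum(axis=0)

    def trait(self, trait_id: str) -> pd.Series:
        return self.values[trait_id]

    def low_n_traits(self, min_lines: int = 75) -> list[str]:
        """Traits measured in fewer than ``min_lines`` lines (study filter)."""
        n = self.n_lines_measured
        return list(n.index[n < min_lines])


@dataclass
class CovariateTable:
    """Per-line fixed-effect covariates (symbiont infection, optional ancestry)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "symbiont" not in self.table.columns:
            raise DataValidationError("covariate table needs a 'symbiont' column")
        sym = self.table["symbiont"]
        if not sym.dropna().isin([0, 1]).all():
            raise DataValidationError("symbiont status must be 0/1 (absent/present)")
        if "ancestry" in self.table.columns:
            anc = self.table["ancestry"].dropna()
            if ((anc < 0) | (anc > 1)).any():
                raise DataValidationError("ancestry proportions must lie in [0, 1]")

    @property
    def line_ids(self) -> np.ndarray:
        return self.table.index.to_numpy(dtype=object)

    def symbiont(self, line_ids: Sequence[str]) -> np.ndarray:
        return self.table.loc[list(line_ids), "symbiont"].to_numpy(dtype=float)

    @property
    def has_ancestry(self) -> bool:
        return "ancestry" in self.table.columns

    def ancestry(self, line_ids: Sequence[str]) -> np.ndarray:
        return self.table.loc[list(line_ids), "ancestry"].to_numpy(dtype=float)


@dataclass
class OutlierSet:
    """Variant indices flagged by an external differentiation/association scan."""

    indices: np.ndarray
    score: np.ndarray | None = None
    empirical_p: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if len(np.unique(self.indices)) != len(self.indices):
            raise DataValidationError("outlier indices must be unique")

    def validate_against(self, genotypes: GenotypeMatrix) -> None:
        if self.indices.size and (
            self.indices.min() < 0 or self.indices.max() >= genotypes.n_variants
        ):
            raise DataValidationError("outlier indices outside genotype matrix")


@dataclass(frozen=True)
class SelectionStrategy:
    """Variant selection policy feeding PCA and GRM construction.

    ``full`` keeps every variant passing MAF/missingness filters; ``ld`` adds
    greedy LD pruning; ``loco`` is ``ld`` restricted to the complement of one
    chromosome arm.
    """

    name: str
    maf_min: float = 0.05
    miss_max: float = 0.20
    r2_max: float | None = None
    min_spacing_bp: int | None = None
    excluded_arm: str | None = None

    def __post_init__(self) -> None:
        if self.name not in ("full", "ld", "loco"):
            raise ConfigurationError(f"unknown strategy {self.name!r}")
        if self.name == "full" and (self.r2_max is not None or self.min_spacing_bp is not None):
            raise ConfigurationError("Full strategy takes no LD parameters")
        if self.name in ("ld", "loco") and (self.r2_max is None or self.min_spacing_bp is None):
            raise ConfigurationError(f"{self.name} strategy needs r2_max and min_spacing_bp")
        if (self.name == "loco") != (self.excluded_arm is not None):
            raise ConfigurationError("exactly the LOCO strategy names an excluded arm")

    @classmethod
    def full(cls, maf_min: float = 0.05, miss_max: float = 0.20) -> "SelectionStrategy":
        return cls("full", maf_min=maf_min, miss_max=miss_max)

    @classmethod
    def ld(
        cls,
        maf_min: float = 0.05,
        miss_max: float = 0.15,
        r2_max: float = 0.2,
        min_spacing_bp: int = 5000,
    ) -> "SelectionStrategy":
        return cls("ld", maf_min, miss_max, r2_max, min_spacing_bp)

    @classmethod
    def loco(
        cls,
        excluded_arm: str,
        maf_min: float = 0.05,
        miss_max: float = 0.15,
        r2_max: float = 0.2,
        min_spacing_bp: int = 5000,
    ) -> "SelectionStrategy":
        return cls("loco", maf_min, miss_max, r2_max, min_spacing_bp, excluded_arm)


@dataclass
class GRM:
    """Line x line genetic relatedness matrix.

    ``method`` records the estimator (``vanraden`` or ``gcta``); ``strategy``
    the variant selection that produced it. The eigendecomposition is computed
    lazily and cached (it is reused across every trait fitted against this GRM).
    """

    matrix: np.ndarray
    line_ids: np.ndarray
    method: str
    strategy: SelectionStrategy | None = None
    n_variants_used: int = 0
    _eig: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        n = len(self.line_ids)
        if self.matrix.shape != (n, n):
            raise DataValidationError("GRM must be square over line_ids")
        asym = np.max(np.abs(self.matrix - self.matrix.T)) if n else 0.0
        if asym > 1e-12:
            raise DataValidationError(f"GRM asymmetric (max |K-K'| = {asym:.2e})")
        if self.method not in ("vanraden", "gcta", "identity"):
            raise DataValidationError(f"unknown GRM method {self.method!r}")

    @property
    def excluded_arm(self) -> str | None:
        return self.strategy.excluded_arm if self.strategy is not None else None

    def eigendecomposition(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues (ascending) and eigenvectors of the relatedness matrix."""
        if self._eig is None:
            d, U = np.linalg.eigh(self.matrix)
            self._eig = (d, U)
        return self._eig

    def subset(self, line_ids: Sequence[str]) -> "GRM":
        lookup = {lid: i for i, lid in enumerate(self.line_ids)}
        idx = np.array([lookup[l] for l in line_ids], dtype=int)
        return GRM(
            matrix=self.matrix[np.ix_(idx, idx)],
            line_ids=np.asarray(line_ids, dtype=object),
            method=self.method,
            strategy=self.strategy,
            n_variants_used=self.n_variants_used,
        )


@dataclass
class GWAResult:
    """Per-variant score-test results for one trait x method run.

    ``table`` columns: ``id``, ``arm``, ``pos``, ``score``, ``variance``,
    ``chi2``, ``p``, ``beta``, ``se`` plus the ``bin`` label once assigned.
    ``permutation_index`` 0 is the observed run; >0 are trait permutations.
    """

    trait_id: str
    method: str
    table: pd.DataFrame
    permutation_index: int = 0
    maf_min: float = 0.05
    miss_max: float = 0.15
    n_lines_used: int = 0
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("full", "ld", "loco", "factored"):
            raise DataValidationError(f"unknown GWA method {self.method!r}")
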