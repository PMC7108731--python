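"""Shared data model for two-cohort rare-variant association analyses.

The central objects are :class:`CohortDataset` (samples × variants dosage
matrix with per-variant allele statistics), :class:`VariantMask` (the set of
variants in a gene or gene-set that qualify under an annotation rule) and
:class:`TraitPanel` (samples × metabolite matrix with covariates and
supergroup labels). Genotype dosages are stored as float arrays with ``nan``
for missing calls; storage is lossless — imputation happens only inside the
association engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd


class ConsequenceClass(str, Enum):
    LOF = "LoF"
    MISSENSE = "missense"
    OTHER = "other"


class MaskRule(str, Enum):
    """Variant-grouping rules.

    ``LoF``: high-confidence loss-of-function variants at any allele
    frequency. ``MCAP_LoF``: the same LoF variants plus rare (MAF < 1%)
    missense variants with an M-CAP deleteriousness score > 0.025.
    """

    LOF = "LoF"
    MCAP_LOF = "MCAP_LoF"


#: strict M-CAP deleteriousness cutoff for missense variants
MCAP_THRESHOLD = 0.025
#: missense variants must be rare to enter the combined mask
MISSENSE_MAF_MAX = 0.01


@dataclass
class VariantRecord:
    """One biallelic variant with its annotation and allele statistics."""

    variant_id: str  # chrom:pos:ref:alt
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str = ""
    consequence_class: ConsequenceClass = ConsequenceClass.OTHER
    lof_high_confidence: bool = False
    mcap_score: Optional[float] = None
    maf: float = 0.0
    ac: int = 0
    an: int = 0

    def __post_init__(self) -> None:
        if self.an > 0:
            expected = min(self.ac, self.an - self.ac) / self.an
            if abs(self.maf - expected) > 1e-12:
                self.maf = expected
        if self.mcap_score is not None and not (0.0 <= self.mcap_score <= 1.0):
            raise ValueError(
                f"mcap_score out of [0,1] for {self.variant_id}: {self.mcap_score}"
            )


def allele_stats(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-variant (ac, an, maf) from a samples × variants dosage matrix.

    Missing genotypes (nan) are excluded from ``an``. ``maf`` is the minor
    allele frequency, i.e. ``min(ac, an-ac)/an`` (0 when ``an`` is 0).
    """
    d = np.asarray(dosages, dtype=float)
    called = ~np.isnan(d)
    ac = np.nansum(d, axis=0).astype(int)
    an = 2 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(an > 0, np.minimum(ac, an - ac) / np.maximum(an, 1), 0.0)
    return ac, an, maf


@dataclass
class CohortDataset:
    """Genotypes for one sequencing cohort.

    ``dosages`` is samples × variants with entries in {0, 1, 2, nan}.
    """

    cohort_id: str
    sample_ids: list[str]
    variants: list[VariantRecord]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError(f"duplicate sample ids in cohort {self.cohort_id}")
        vids = [v.variant_id for v in self.variants]
        if len(set(vids)) != len(vids):
            raise ValueError(f"duplicate variant ids in cohort {self.cohort_id}")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} != "
                f"({len(self.sample_ids)}, {len(self.variants)})"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def variant_index(self) -> dict[str, int]:
        return {v.variant_id: j for j, v in enumerate(self.variants)}

    def recompute_allele_stats(self) -> None:
        ac, an, maf = allele_stats(self.dosages)
        for j, v in enumerate(self.variants):
            v.ac, v.an, v.maf = int(ac[j]), int(an[j]), float(maf[j])

    def subset_variants(self, variant_ids: list[str]) -> "CohortDataset":
        idx = self.variant_index()
        cols = [idx[v] for v in variant_ids]
        return CohortDataset(
            cohort_id=self.cohort_id,
            sample_ids=list(self.sample_ids),
            variants=[replace(self.variants[c]) for c in cols],
            dosages=self.dosages[:, cols].copy(),
        )


@dataclass
class VariantMask:
    """Variants of one testable unit (gene or gene-set) under a mask rule."""

    unit_id: str
    rule: MaskRule
    variant_ids: list[str]

    def __len__(self) -> int:
        return len(self.variant_ids)


@dataclass
class GeneSetCollection:
    """Named gene sets (flat gene-symbol lists)."""

    sets: dict[str, list[str]]
    source: str = ""

    def filtered(self, min_genes: int = 4) -> "GeneSetCollection":
        """Drop sets with fewer than ``min_genes`` genes (default keeps >3)."""
        kept = {k: v for k, v in self.sets.items() if len(v) >= min_genes}
        return GeneSetCollection(sets=kept, source=self.source)


@dataclass
class TraitPanel:
    """Per-sample metabolite measurements plus covariates.

    ``values`` is a DataFrame indexed by sample id with one column per trait
    (nan = missing). ``covariates`` shares the index. ``supergroup`` maps each
    trait to its biomarker family, used to forbid within-family covariate
    traits.
    """

    values: pd.DataFrame
    covariates: pd.DataFrame
    supergroup: dict[str, str] = field(default_factory=dict)
    is_residualised: bool = False
    cohort_id: str = ""

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.covariates.index):
            raise ValueError("values and covariates must share a sample index")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "TraitPanel":
        return TraitPanel(
            values=self.values.copy(),
            covariates=self.covariates.copy(),
            supergroup=dict(self.supergroup),
            is_residualised=self.is_residualised,
            cohort_id=self.cohort_id,
        )


@dataclass
class GeneticCorrTable:
    """Symmetric lookup of genetic correlation (rg) and its p-value.

    Consumed as data (e.g. LD-score estimates from external summary
    statistics); missing pairs are treated as lacking evidence of *no*
    correlation, i.e. they fail the covariate-eligibility criterion.
    """

    table: pd.DataFrame  # columns: trait_a, trait_b, rg, p

    def __post_init__(self) -> None:
        required = {"trait_a", "trait_b", "rg", "p"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"genetic-correlation table needs columns {sorted(required)}")
        self._lookup: dict[tuple[str, str], tuple[float, float]] = {}
        for row in self.table.itertuples(index=False):
            key = (str(row.trait_a), str(row.trait_b))
            val = (float(row.rg), float(row.p))
            self._lookup[key] = val
            self._lookup[(key[1], key[0])] = val

    def rg_p(self, trait_a: str, trait_b: str) -> Optional[float]:
        hit = self._lookup.get((trait_a, trait_b))
        return None if hit is None else hit[1]

    def rg(self, trait_a: str, trait_b: str) -> Optional[float]:
        hit = self._lookup.get((trait_a, trait_b))
        return None if hit is None else hit[0]


@dataclass
class AggTestResult:
    """Result of one gene/set × trait × rule aggregation test."""

    unit_id: str
    trait: str
    rule: str
    p: float
    rho_opt: float = float("nan")
    n_variants: int = 0
    ac_total: int = 0
    q_stat: float = float("nan")
    cohort: str = ""
    notes: str = ""

    @property
    def untestable(self) -> bool:
        return np.isnan(self.p)
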