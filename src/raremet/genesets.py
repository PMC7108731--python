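"""Gene-set level tests and GWAS-proximal set construction.

Gene-set tests pool the qualifying variants of all member genes into one
mask and apply SKAT-O, per cohort and meta-analysed, with a p < 0.01
discovery gate. Sensitivity analyses drop the variants of named genes and
re-test. GWAS-proximal sets collect the unambiguously reported genes near
genome-wide-significant loci for the four traditional lipid traits, tested
on the pooled two-cohort dataset.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .assoc import (
    DEFAULT_RHO_GRID,
    NullModel,
    ScoreSummary,
    beta_maf_weights,
    run_test,
    score_summary,
)
from .datamodel import AggTestResult, CohortDataset, GeneSetCollection, MaskRule
from .io import AnnotationTable
from .masks import build_masks, pooled_mask
from .meta import meta_aggregate

logger = logging.getLogger(__name__)

DEFAULT_LIPID_TRAITS = ("HDL-C", "LDL-C", "TC", "TG")
DEFAULT_EXCLUSION_PATTERNS = ("NR", "intergenic", "APO(APOE) cluster", "HLA-area")


def _mask_summary(
    set_name: str,
    genes: Sequence[str],
    dataset: CohortDataset,
    null: NullModel,
    annotations: AnnotationTable,
    rule: MaskRule,
    exclude_genes: Sequence[str] = (),
) -> Optional[ScoreSummary]:
    mask = pooled_mask(set_name, list(genes), dataset, annotations, rule)
    member = set(mask.variant_ids)
    if exclude_genes:
        drop = pooled_mask("_drop", list(exclude_genes), dataset, annotations, rule)
        member -= set(drop.variant_ids)
    order = dataset.variant_index()
    vids = sorted(member, key=lambda v: order[v])
    if not vids:
        return None
    sub = dataset.subset_variants(vids)
    maf = np.array([v.maf for v in sub.variants])
    return score_summary(
        null,
        sub.dosages,
        beta_maf_weights(maf),
        vids,
        unit_id=set_name,
        rule=rule.value,
        cohort=dataset.cohort_id,
        ac_total=int(sum(v.ac for v in sub.variants)),
    )


def geneset_test(
    set_name: str,
    genes: Sequence[str],
    cohorts: Sequence[tuple[CohortDataset, NullModel]],
    annotations: AnnotationTable,
    rule: MaskRule = MaskRule.LOF,
    test: str = "skato",
    rho_grid: Sequence[float] = DEFAULT_RHO_GRID,
    exclude_genes: Sequence[str] = (),
) -> AggTestResult:
    """SKAT-O on the pooled mask of a gene-set, meta-analysed over cohorts."""
    summaries = []
    trait = cohorts[0][1].trait if cohorts else ""
    for dataset, null in cohorts:
        s = _mask_summary(set_name, genes, dataset, null, annotations, rule, exclude_genes)
        if s is not None:
            summaries.append(s)
    if not summaries:
        return AggTestResult(
            unit_id=set_name,
            trait=trait,
            rule=rule.value,
            p=float("nan"),
            notes="untestable: empty pooled mask",
        )
    if len(summaries) == 1:
        return run_test(summaries[0], test, rho_grid)
    return meta_aggregate(summaries, test, rho_grid)


def remove_genes_sensitivity(
    set_name: str,
    genes: Sequence[str],
    remove: Sequence[str],
    cohorts: Sequence[tuple[CohortDataset, NullModel]],
    annotations: AnnotationTable,
    rule: MaskRule = MaskRule.LOF,
    test: str = "skato",
    residual_alpha: float = 0.05,
) -> tuple[AggTestResult, bool]:
    """Re-test the set after removing the variants of named genes.

    Returns the residual-test result and whether residual evidence of
    association remains (p < ``residual_alpha``).
    """
    kept = [g for g in genes if g not in set(remove)]
    res = geneset_test(
        f"{set_name}-minus-{len(remove)}",
        kept,
        cohorts,
        annotations,
        rule,
        test,
        exclude_genes=list(remove),
    )
    residual = (not np.isnan(res.p)) and res.p < residual_alpha
    return res, residual


def build_gwas_genesets(
    catalog: pd.DataFrame,
    traits: Sequence[str] = DEFAULT_LIPID_TRAITS,
    p_threshold: float = 5e-8,
    exclusion_patterns: Sequence[str] = DEFAULT_EXCLUSION_PATTERNS,
) -> GeneSetCollection:
    """One gene-set per lipid trait from a GWAS-catalog-style table.

    Keeps loci at genome-wide significance whose reported-gene field names
    exactly one gene not matching an exclusion pattern. Output gene lists
    are unique and sorted, so construction is idempotent and
    order-independent.
    """
    excl = set(exclusion_patterns)
    sets: dict[str, list[str]] = {}
    for trait in traits:
        rows = catalog[
            (catalog["DISEASE/TRAIT"].astype(str) == trait)
            & (pd.to_numeric(catalog["P-VALUE"], errors="coerce") < p_threshold)
        ]
        genes: set[str] = set()
        for raw in rows["REPORTED GENE(S)"].astype(str):
            parts = [g.strip() for g in raw.split(",") if g.strip()]
            if len(parts) != 1:  # ambiguous reporting
                continue
            gene = parts[0]
            if gene in excl:
                continue
            genes.add(gene)
        if not genes:
            warnings.warn(f"no reported genes survive filtering for trait {trait!r}")
        sets[f"{trait}_reported"] = sorted(genes)
    return GeneSetCollection(sets=sets, source="gwas_catalog")


def pooled_cohort(datasets: Sequence[CohortDataset], cohort_id: str = "POOLED") -> CohortDataset:
    """Union of samples across cohorts with variants aligned by id.

    Dosages are missing where a variant is absent from a sample's cohort, so
    allele counts at shared variants add across cohorts exactly.
    """
    all_samples: list[str] = []
    for ds in datasets:
        overlap = set(all_samples) & set(ds.sample_ids)
        if overlap:
            raise ValueError(f"overlapping sample ids across cohorts: {sorted(overlap)[:5]}")
        all_samples.extend(ds.sample_ids)
    union: dict[str, int] = {}
    variants = []
    for ds in datasets:
        for v in ds.variants:
            if v.variant_id not in union:
                union[v.variant_id] = len(union)
                variants.append(replace(v))
    n, m = len(all_samples), len(variants)
    dosages = np.full((n, m), np.nan)
    row0 = 0
    for ds in datasets:
        cols = np.array([union[v] for v in ds.variant_ids], dtype=int)
        if cols.size:
            dosages[row0 : row0 + ds.n_samples][:, cols] = ds.dosages
        row0 += ds.n_samples
    out = CohortDataset(cohort_id, all_samples, variants, dosages)
    out.recompute_allele_stats()
    return out
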