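"""Variant mask construction.

Two nested grouping rules per gene: high-confidence LoF variants at any
allele frequency, and the same LoF variants plus rare (within-cohort
MAF < 1%) missense variants with M-CAP score > 0.025. MAF filtering uses the
within-cohort MAF of the dataset being masked.
"""

from __future__ import annotations

from .datamodel import (
    MCAP_THRESHOLD,
    MISSENSE_MAF_MAX,
    CohortDataset,
    MaskRule,
    VariantMask,
)
from .io import AnnotationTable


def variant_qualifies(
    rule: MaskRule,
    consequence_class: str,
    lof_hc: bool,
    mcap_score: float | None,
    maf: float,
) -> bool:
    """Single-variant eligibility under a mask rule.

    An absent M-CAP score is treated as non-deleterious. LoF variants are not
    MAF-filtered; missense variants must satisfy both the M-CAP and the MAF
    cutoff (strict inequalities on both).
    """
    if lof_hc:
        return True
    if rule is MaskRule.LOF:
        return False
    if consequence_class != "missense" or mcap_score is None:
        return False
    return mcap_score > MCAP_THRESHOLD and maf < MISSENSE_MAF_MAX


def build_masks(
    dataset: CohortDataset, annotations: AnnotationTable, rule: MaskRule
) -> list[VariantMask]:
    """One mask per gene with ≥1 qualifying variant present in the dataset.

    Genes with no qualifying variant are simply absent. A variant annotated
    against several genes may appear in each gene's mask; within one gene it
    is counted once.
    """
    maf_by_id = {v.variant_id: v.maf for v in dataset.variants}
    masks: list[VariantMask] = []
    for gene in annotations.genes():
        rows = annotations.rows_for_gene(gene)
        member_ids: list[str] = []
        seen: set[str] = set()
        for row in rows.itertuples(index=False):
            vid = str(row.variant_id)
            if vid in seen or vid not in maf_by_id:
                continue
            mcap = None if row.mcap_score is None or row.mcap_score != row.mcap_score else float(row.mcap_score)
            if variant_qualifies(
                rule,
                str(row.consequence_class),
                bool(row.lof_hc),
                mcap,
                maf_by_id[vid],
            ):
                member_ids.append(vid)
                seen.add(vid)
        if member_ids:
            # deterministic: dataset (file) order
            order = dataset.variant_index()
            member_ids.sort(key=lambda v: order[v])
            masks.append(VariantMask(unit_id=gene, rule=rule, variant_ids=member_ids))
    return masks


def pooled_mask(
    unit_id: str,
    genes: list[str],
    dataset: CohortDataset,
    annotations: AnnotationTable,
    rule: MaskRule,
) -> VariantMask:
    """Union of qualifying variants across member genes (for gene-set tests)."""
    gene_masks = {m.unit_id: m for m in build_masks(dataset, annotations, rule)}
    order = dataset.variant_index()
    members: set[str] = set()
    for g in genes:
        if g in gene_masks:
            members.update(gene_masks[g].variant_ids)
    return VariantMask(
        unit_id=unit_id,
        rule=rule,
        variant_ids=sorted(members, key=lambda v: order[v]),
    )
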