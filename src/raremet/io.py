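"""Readers and writers for the pipeline's file formats.

Genotypes come in as VCF 4.x (biallelic, GT fields) via cyvcf2. Variant
annotations, phenotypes, covariates, supergroups and genetic correlations are
TSV with a header; gene sets are GMT. Writers emit exactly the text formats
the readers consume, so a simulated study can round-trip through disk.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .datamodel import (
    CohortDataset,
    ConsequenceClass,
    GeneSetCollection,
    GeneticCorrTable,
    TraitPanel,
    VariantRecord,
    allele_stats,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, cohort_id: str) -> CohortDataset:
    """Read a biallelic VCF into a :class:`CohortDataset`.

    Variant order follows file order; multiallelic records are rejected with
    an error naming the offending variant. Missing genotypes become nan and
    are excluded from the called allele number.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise ValueError(f"malformed VCF {path}: {exc}") from exc

    sample_ids = list(vcf.samples)
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multiallelic record not supported: {rec.CHROM}:{rec.POS} "
                f"ALT={','.join(rec.ALT) or '.'} (split upstream)"
            )
        # gts012: 0/1/2 = dosage of ALT, 3 = unknown
        g = rec.gt_types.astype(float)
        g[g == 3] = np.nan
        columns.append(g)
        variants.append(
            VariantRecord(
                variant_id=f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}",
                chrom=str(rec.CHROM),
                pos=int(rec.POS),
                ref=str(rec.REF),
                alt=str(rec.ALT[0]),
            )
        )
    dosages = (
        np.column_stack(columns) if columns else np.empty((len(sample_ids), 0))
    )
    ds = CohortDataset(cohort_id, sample_ids, variants, dosages)
    ds.recompute_allele_stats()
    return ds


def write_vcf(dataset: CohortDataset, path: str | Path) -> None:
    """Write the dataset as a minimal GT-only VCF 4.2 text file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        contigs = []
        for v in dataset.variants:
            if v.chrom not in contigs:
                contigs.append(v.chrom)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dataset.sample_ids)
            + "\n"
        )
        gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, v in enumerate(dataset.variants):
            col = dataset.dosages[:, j]
            gts = ["./." if np.isnan(x) else gt_codes[float(x)] for x in col]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

class AnnotationTable:
    """Per-(variant, gene) consequence annotations.

    A variant annotated against several genes appears once per gene and may
    enter the masks of each. Variants absent from the table are implicitly
    ``other`` and enter no mask.
    """

    COLUMNS = ["variant_id", "gene", "consequence_class", "lof_hc", "mcap_score"]

    def __init__(self, table: pd.DataFrame):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"annotation table missing columns {sorted(missing)}")
        dup = table.duplicated(subset=["variant_id", "gene"], keep=False)
        if dup.any():
            conflicted = table.loc[dup]
            groups = conflicted.groupby(["variant_id", "gene"])
            for (vid, gene), grp in groups:
                if grp["consequence_class"].nunique() > 1:
                    raise ValueError(
                        f"conflicting consequence classes for ({vid}, {gene})"
                    )
            table = table.drop_duplicates(subset=["variant_id", "gene"])
        self.table = table.reset_index(drop=True)

    def genes(self) -> list[str]:
        return sorted(self.table["gene"].unique())

    def rows_for_gene(self, gene: str) -> pd.DataFrame:
        return self.table[self.table["gene"] == gene]

    def lookup(self, variant_id: str) -> pd.DataFrame:
        return self.table[self.table["variant_id"] == variant_id]


def merge_annotations(*tables: AnnotationTable) -> AnnotationTable:
    return AnnotationTable(
        pd.concat([t.table for t in tables], ignore_index=True)
    )


def read_annotations(path: str | Path) -> AnnotationTable:
    """Read the variant annotation TSV.

    Columns: variant_id, gene, consequence_class (LoF/missense/other),
    lof_hc (bool-ish), mcap_score (float or NA).
    """
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "gene": str})
    if "lof_hc" in df.columns:
        df["lof_hc"] = (
            df["lof_hc"].astype(str).str.strip().str.lower().isin({"true", "1", "hc", "yes"})
        )
    if "mcap_score" in df.columns:
        df["mcap_score"] = pd.to_numeric(df["mcap_score"], errors="coerce")
    return AnnotationTable(df)


def write_annotations(ann: AnnotationTable, path: str | Path) -> None:
    df = ann.table.copy()
    df["lof_hc"] = df["lof_hc"].map({True: "true", False: "false"})
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def annotation_frame(
    records: list[tuple[str, str, str, bool, Optional[float]]]
) -> AnnotationTable:
    """Build an AnnotationTable from (variant_id, gene, class, lof_hc, mcap) rows."""
    df = pd.DataFrame(records, columns=AnnotationTable.COLUMNS)
    df["consequence_class"] = df["consequence_class"].map(
        lambda c: c.value if isinstance(c, ConsequenceClass) else str(c)
    )
    return AnnotationTable(df)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, min_genes: int = 4) -> GeneSetCollection:
    """Read a GMT file, dropping sets with fewer than ``min_genes`` genes.

    Duplicate set names are deterministically renamed with a numeric suffix
    and a warning is emitted.
    """
    sets: dict[str, list[str]] = {}
    n_dropped = 0
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"empty GMT file: {path}")
    for ln in lines:
        parts = ln.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need name, description, genes): {ln!r}")
        name, _desc, *genes = parts
        genes = [g for g in genes if g]
        if len(genes) < min_genes:
            n_dropped += 1
            continue
        if name in sets:
            k = 2
            while f"{name}_{k}" in sets:
                k += 1
            warnings.warn(f"duplicate gene-set name {name!r} renamed to {name}_{k}")
            name = f"{name}_{k}"
        sets[name] = genes
    if n_dropped:
        logger.info("read_gmt: dropped %d sets with <%d genes", n_dropped, min_genes)
    return GeneSetCollection(sets=sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, collection.source or "na", *genes]) + "\n")


# ---------------------------------------------------------------------------
# Phenotypes / covariates / supergroups / genetic correlations
# ---------------------------------------------------------------------------

def read_trait_panel(
    pheno_path: str | Path,
    covar_path: str | Path,
    supergroup_path: Optional[str | Path] = None,
    cohort_id: str = "",
) -> TraitPanel:
    values = pd.read_csv(pheno_path, sep="\t", index_col="sample_id", na_values=["NA", ""])
    covar = pd.read_csv(covar_path, sep="\t", index_col="sample_id", na_values=["NA", ""])
    covar = covar.loc[values.index]
    supergroup: dict[str, str] = {}
    if supergroup_path is not None:
        sg = pd.read_csv(supergroup_path, sep="\t")
        supergroup = dict(zip(sg["trait"].astype(str), sg["supergroup"].astype(str)))
    return TraitPanel(values=values, covariates=covar, supergroup=supergroup, cohort_id=cohort_id)


def write_trait_panel(
    panel: TraitPanel,
    pheno_path: str | Path,
    covar_path: str | Path,
    supergroup_path: Optional[str | Path] = None,
) -> None:
    panel.values.to_csv(pheno_path, sep="\t", index_label="sample_id", na_rep="NA")
    panel.covariates.to_csv(covar_path, sep="\t", index_label="sample_id", na_rep="NA")
    if supergroup_path is not None:
        pd.DataFrame(
            {"trait": list(panel.supergroup), "supergroup": list(panel.supergroup.values())}
        ).to_csv(supergroup_path, sep="\t", index=False)


def read_genetic_corr(path: str | Path) -> GeneticCorrTable:
    return GeneticCorrTable(pd.read_csv(path, sep="\t"))


def write_genetic_corr(gc: GeneticCorrTable, path: str | Path) -> None:
    gc.table.to_csv(path, sep="\t", index=False)


def read_gwas_catalog(path: str | Path) -> pd.DataFrame:
    """Read a GWAS-catalog-style TSV (DISEASE/TRAIT, REPORTED GENE(S), P-VALUE)."""
    df = pd.read_csv(path, sep="\t")
    required = {"DISEASE/TRAIT", "REPORTED GENE(S)", "P-VALUE"}
    if not required.issubset(df.columns):
        raise ValueError(f"GWAS catalog table needs columns {sorted(required)}")
    return df
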