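"""End-to-end orchestration of the two-cohort analysis.

Stages run in dependency order: phenotype preparation → discovery tests →
forwarding gate → correlated-trait covariate selection → validation tests →
score meta-analysis → replication verdicts; plus gene-set, GWAS-proximal,
tails-enrichment and single-variant arms, each toggleable. Every output TSV
carries a commented header with the seed and a config hash so reruns are
verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import phenotypes
from .assoc import (
    NullModel,
    beta_maf_weights,
    fit_null,
    leave_one_out,
    run_test,
    score_summary,
    single_variant_scan,
)
from .datamodel import CohortDataset, GeneSetCollection, GeneticCorrTable, MaskRule, TraitPanel
from .design import effective_tests, replication_verdict, select_covariates, thresholds
from .genesets import build_gwas_genesets, geneset_test, pooled_cohort
from .io import AnnotationTable
from .masks import build_masks, pooled_mask
from .meta import meta_aggregate, two_stage_gate
from .simulate import SimulatedStudy, SynthConfig, generate
from .tails import (
    TailsResult,
    count_deleterious_alleles,
    define_tails,
    permutation_p,
    prune_overlapping_traits,
    stream_rng,
    tails_meta_and_verdict,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    stages: dict = field(
        default_factory=lambda: {
            "gene_based": True,
            "gene_set": True,
            "gwas_proximal": False,
            "tails": True,
            "single_variant": False,
        }
    )
    synth: Optional[SynthConfig] = None
    gene_sets: Optional[GeneSetCollection] = None
    tail_gene_sets: Optional[GeneSetCollection] = None
    gwas_catalog: Optional[pd.DataFrame] = None
    n_genes_genome: int = 20000
    discovery_gate_gene: float = 5e-3
    discovery_gate_set: float = 0.01
    tails_k: int = 10
    tails_n_perm: int = 2000
    rho_grid: Optional[Sequence[float]] = None

    def config_hash(self) -> str:
        payload = {
            "seed": self.seed,
            "stages": self.stages,
            "synth": asdict(self.synth) if self.synth else None,
            "n_genes_genome": self.n_genes_genome,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, header: dict) -> None:
    with open(path, "w") as fh:
        for k, v in header.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def _fit_nulls(panel: TraitPanel, extra: Optional[dict[str, np.ndarray]] = None) -> dict[str, NullModel]:
    nulls = {}
    for trait in panel.trait_names:
        y = panel.values[trait].to_numpy(dtype=float)
        obs = ~np.isnan(y)
        X = None
        if extra and trait in extra:
            X = extra[trait][obs]
        nulls[trait] = fit_null(
            y[obs],
            X,
            trait=trait,
            sample_ids=[s for s, o in zip(panel.sample_ids, obs) if o],
        )
    return nulls


def _gene_summary(dataset: CohortDataset, null: NullModel, mask, rule: MaskRule):
    idx = dataset.variant_index()
    sample_rows = None
    if null.sample_ids is not None and null.sample_ids != dataset.sample_ids:
        pos = {s: i for i, s in enumerate(dataset.sample_ids)}
        sample_rows = [pos[s] for s in null.sample_ids]
    cols = [idx[v] for v in mask.variant_ids]
    G = dataset.dosages[:, cols]
    if sample_rows is not None:
        G = G[sample_rows]
    maf = np.array([dataset.variants[c].maf for c in cols])
    ac = int(sum(dataset.variants[c].ac for c in cols))
    return score_summary(
        null,
        G,
        beta_maf_weights(maf),
        mask.variant_ids,
        unit_id=mask.unit_id,
        rule=mask.rule.value if isinstance(mask.rule, MaskRule) else str(mask.rule),
        cohort=dataset.cohort_id,
        ac_total=ac,
    )


def run(config: RunConfig, study: Optional[SimulatedStudy] = None) -> Path:
    """Execute the configured stages; returns the results directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if study is None:
        synth = config.synth or SynthConfig(seed=config.seed)
        study = generate(synth)
    header = {"seed": config.seed, "config_hash": config.config_hash()}

    # --- phenotype preparation, per cohort ---------------------------------
    prepared = [phenotypes.prepare_panel(p) for p in study.panels]
    disc_panel, valid_panel = prepared[0], prepared[1]
    disc_ds, valid_ds = study.cohorts[0], study.cohorts[1]
    nulls_disc = _fit_nulls(disc_panel)
    nulls_valid = _fit_nulls(valid_panel)

    neff = effective_tests(disc_panel.values.dropna())
    thr = thresholds(neff=neff, n_genes=config.n_genes_genome)
    with open(outdir / "thresholds.txt", "w") as fh:
        for k, v in header.items():
            fh.write(f"# {k}={v}\n")
        for k, v in asdict(thr).items():
            fh.write(f"{k}\t{v}\n")

    pheno_corr = phenotypes.phenotypic_correlation(disc_panel)
    rho_grid = list(config.rho_grid) if config.rho_grid else None

    counts_log: dict[str, int] = {}

    # --- gene-based two-stage analysis -------------------------------------
    if config.stages.get("gene_based", True):
        rows = []
        for rule, test in ((MaskRule.LOF, "burden"), (MaskRule.MCAP_LOF, "skato")):
            masks_d = {m.unit_id: m for m in build_masks(disc_ds, study.annotations, rule)}
            masks_v = {m.unit_id: m for m in build_masks(valid_ds, study.annotations, rule)}
            for trait in disc_panel.trait_names:
                null_d = nulls_disc[trait]
                for gene, mask in masks_d.items():
                    s_d = _gene_summary(disc_ds, null_d, mask, rule)
                    kwargs = {"rho_grid": rho_grid} if rho_grid else {}
                    res_d = run_test(s_d, test, **kwargs)
                    if np.isnan(res_d.p) or not two_stage_gate(res_d.p, config.discovery_gate_gene):
                        continue
                    covs = select_covariates(
                        trait, pheno_corr, study.genetic_corr, disc_panel.supergroup
                    )
                    # validation: unadjusted for the verdict, adjusted for meta
                    summaries = [s_d]
                    p_valid_unadj = np.nan
                    if gene in masks_v:
                        s_v_unadj = _gene_summary(valid_ds, nulls_valid[trait], masks_v[gene], rule)
                        p_valid_unadj = run_test(s_v_unadj, test, **kwargs).p
                        null_v = nulls_valid[trait]
                        if covs:
                            yv = valid_panel.values[trait].to_numpy(dtype=float)
                            obs = ~np.isnan(yv)
                            Xc = valid_panel.values[covs].to_numpy(dtype=float)[obs]
                            Xc = np.where(np.isnan(Xc), 0.0, Xc)
                            null_v = fit_null(
                                yv[obs],
                                Xc,
                                trait=trait,
                                sample_ids=[
                                    s for s, o in zip(valid_panel.sample_ids, obs) if o
                                ],
                            )
                        summaries.append(_gene_summary(valid_ds, null_v, masks_v[gene], rule))
                    res_m = meta_aggregate(summaries, test, **kwargs) if len(summaries) > 1 else res_d
                    n_union = len(set().union(*[set(s.variant_ids) for s in summaries]))
                    replicated = replication_verdict(
                        res_m.p, thr.gene_level_multitrait, n_union, p_valid_unadj
                    ) if not np.isnan(p_valid_unadj) else False
                    rows.append(
                        {
                            "unit_id": gene,
                            "trait": trait,
                            "rule": rule.value,
                            "test": test,
                            "n_variants": n_union,
                            "ac": res_m.ac_total,
                            "rho_opt": res_m.rho_opt,
                            "p_discovery": res_d.p,
                            "p_validation_unadjusted": p_valid_unadj,
                            "p_meta": res_m.p,
                            "n_covariates": len(covs),
                            "replicated": replicated,
                            "notes": res_m.notes,
                        }
                    )
        df = pd.DataFrame(rows)
        counts_log["gene_based_forwarded"] = len(df)
        counts_log["gene_based_replicated"] = int(df["replicated"].sum()) if len(df) else 0
        _write_tsv(df, outdir / "gene_based.tsv", header)

    # --- gene-set analysis ---------------------------------------------------
    if config.stages.get("gene_set", True) and config.gene_sets is not None:
        rows = []
        for name, genes in config.gene_sets.filtered().sets.items():
            for trait in disc_panel.trait_names:
                res_d = geneset_test(
                    name, genes, [(disc_ds, nulls_disc[trait])], study.annotations
                )
                if np.isnan(res_d.p) or not two_stage_gate(res_d.p, config.discovery_gate_set):
                    continue
                res_m = geneset_test(
                    name,
                    genes,
                    [(disc_ds, nulls_disc[trait]), (valid_ds, nulls_valid[trait])],
                    study.annotations,
                )
                rows.append(
                    {
                        "unit_id": name,
                        "trait": trait,
                        "rule": "LoF",
                        "p_discovery": res_d.p,
                        "p_meta": res_m.p,
                        "significant": bool(res_m.p < thr.geneset_level),
                        "n_variants": res_m.n_variants,
                    }
                )
        df = pd.DataFrame(rows)
        counts_log["gene_set_forwarded"] = len(df)
        _write_tsv(df, outdir / "gene_set.tsv", header)

    # --- GWAS-proximal gene-sets on the pooled cohort -----------------------
    if config.stages.get("gwas_proximal", False) and config.gwas_catalog is not None:
        pooled = pooled_cohort([disc_ds, valid_ds])
        pooled_values = pd.concat([disc_panel.values, valid_panel.values])
        collection = build_gwas_genesets(config.gwas_catalog)
        rows = []
        for name, genes in collection.sets.items():
            if not genes:
                continue
            for trait in disc_panel.trait_names:
                y = pooled_values[trait].to_numpy(dtype=float)
                obs = ~np.isnan(y)
                null = fit_null(
                    y[obs],
                    trait=trait,
                    sample_ids=[s for s, o in zip(pooled_values.index, obs) if o],
                )
                for rule in (MaskRule.LOF, MaskRule.MCAP_LOF):
                    res = geneset_test(
                        name, genes, [(pooled, null)], study.annotations, rule=rule
                    )
                    if np.isnan(res.p):
                        continue
                    rows.append(
                        {
                            "unit_id": name,
                            "trait": trait,
                            "rule": rule.value,
                            "p": res.p,
                            "significant": bool(res.p < thr.gwas_proximal_level),
                            "n_variants": res.n_variants,
                        }
                    )
        _write_tsv(pd.DataFrame(rows), outdir / "gwas_proximal.tsv", header)

    # --- tails enrichment ----------------------------------------------------
    if config.stages.get("tails", True) and config.tail_gene_sets is not None:
        rows = []
        tail_specs = {}
        for trait in disc_panel.trait_names:
            tail_specs[trait] = {
                side: define_tails(disc_panel, trait, side, k=config.tails_k)
                for side in ("upper", "lower")
            }
        retained = prune_overlapping_traits(tail_specs)
        counts_log["tails_traits_retained"] = len(retained)
        for trait in retained:
            for side in ("upper", "lower"):
                for set_name, genes in config.tail_gene_sets.sets.items():
                    per_cohort = []
                    for panel, ds, label in (
                        (disc_panel, disc_ds, "WES"),
                        (valid_panel, valid_ds, "WGS"),
                    ):
                        spec = define_tails(panel, trait, side, k=config.tails_k)
                        obs = count_deleterious_alleles(
                            spec.member_samples, genes, ds, study.annotations
                        )
                        eligible = list(panel.values[trait].dropna().index.astype(str))
                        p = permutation_p(
                            obs,
                            eligible,
                            genes,
                            ds,
                            study.annotations,
                            k=config.tails_k,
                            n_perm=config.tails_n_perm,
                            rng=stream_rng(config.seed, trait, side, set_name, label),
                        )
                        per_cohort.append(TailsResult(trait, side, set_name, obs, p, label))
                    verdict = tails_meta_and_verdict(
                        per_cohort[0], per_cohort[1], thr.tails_level
                    )
                    rows.append(
                        {
                            "trait": trait,
                            "side": side,
                            "gene_set": set_name,
                            "wes_observed": per_cohort[0].observed_alleles,
                            "wes_p": per_cohort[0].perm_p,
                            "wgs_p": per_cohort[1].perm_p,
                            "meta_p": verdict.meta_p if verdict.meta_p is not None else np.nan,
                            "enriched": verdict.enriched,
                        }
                    )
        _write_tsv(pd.DataFrame(rows), outdir / "tails.tsv", header)

    # --- single-variant scan -------------------------------------------------
    if config.stages.get("single_variant", False):
        rows = []
        for trait in disc_panel.trait_names:
            for r in single_variant_scan(nulls_disc[trait], disc_ds):
                rows.append(
                    {
                        "trait": trait,
                        "variant_id": r.variant_id,
                        "p": r.p,
                        "beta": r.beta,
                        "se": r.se,
                        "flag": r.flag,
                    }
                )
        _write_tsv(pd.DataFrame(rows), outdir / "single_variant.tsv", header)

    with open(outdir / "run.log", "w") as fh:
        for k, v in {**header, **counts_log}.items():
            fh.write(f"{k}={v}\n")
    return outdir
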