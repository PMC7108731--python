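"""Two-cohort synthetic study generator with known ground truth.

Emulates the discovery/validation design (a larger exome-sequenced cohort
and a smaller genome-sequenced one, at reduced sample sizes): a rare-variant
site-frequency spectrum (log-uniform MAF), partially overlapping variant
sets between cohorts, LoF/missense annotations with M-CAP-like scores, and
a correlated multi-metabolite panel organised into supergroups via a latent
factor model. Gene-level genetic effects with configurable architecture
(uniform-burden / single-driver / heterogeneous) and planted tail signals
provide recoverable ground truth for every pipeline stage.

Sites are drawn independently (no linkage disequilibrium): rare variants are
near-independent and the aggregation tests operate at the mask level, so
this is a documented simplification, not a fidelity goal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    CohortDataset,
    GeneticCorrTable,
    MaskRule,
    TraitPanel,
    VariantRecord,
)
from .io import AnnotationTable
from .masks import variant_qualifies


@dataclass
class EffectSpec:
    """A planned gene → trait genetic effect.

    ``architecture``: 'uniform-burden' gives every mask-qualifying variant
    the same per-allele effect ``beta``; 'single-driver' puts the whole
    effect on one qualifying variant; 'heterogeneous' draws per-variant
    effects N(0, beta^2) with mixed signs.
    """

    gene: str
    trait: str
    architecture: str = "uniform-burden"
    beta: float = 0.5
    #: when set, beta is calibrated so the total-design non-centrality of the
    #: injected signal (summed over cohorts, unit residual variance) hits this
    target_ncp: Optional[float] = None


@dataclass
class SynthConfig:
    seed: int = 0
    n_samples: tuple[int, int] = (800, 700)
    n_genes: int = 30
    mean_variants_per_gene: float = 8.0
    maf_min: Optional[float] = None  # default 1/(2 * min cohort size)
    maf_max: float = 0.05
    lof_fraction: float = 0.3
    mcap_beta_params: tuple[float, float] = (0.5, 2.0)
    overlap_fraction: float = 0.5
    genotype_missing_rate: float = 0.01
    n_traits: int = 12
    n_supergroups: int = 4
    factor_loading: float = 0.6
    #: loading on a single factor shared by every trait (cross-supergroup
    #: correlation, e.g. for covariate-boosting designs); 0 disables it
    global_loading: float = 0.0
    noise_sd: float = 0.8
    covariate_effect: float = 0.2
    effects: list[EffectSpec] = field(default_factory=list)


@dataclass
class GroundTruthEffect:
    gene: str
    trait: str
    architecture: str
    betas: dict[str, float]  # variant id -> per-allele effect
    driver: Optional[str] = None


@dataclass
class GroundTruth:
    effects: list[GroundTruthEffect] = field(default_factory=list)
    planted_tails: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.effects:
            for vid, b in e.betas.items():
                rows.append(
                    {
                        "gene": e.gene,
                        "trait": e.trait,
                        "architecture": e.architecture,
                        "variant_id": vid,
                        "beta": b,
                        "is_driver": vid == e.driver,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class SimulatedStudy:
    cohorts: list[CohortDataset]
    annotations: AnnotationTable
    panels: list[TraitPanel]
    genetic_corr: GeneticCorrTable
    truth: GroundTruth
    config: SynthConfig


def _draw_variant_table(cfg: SynthConfig, rng: np.random.Generator):
    """Global (union) variant table: ids, genes, annotations, MAFs, cohort
    membership."""
    maf_min = cfg.maf_min or 1.0 / (2 * min(cfg.n_samples))
    rows = []
    pos = 0
    for g in range(cfg.n_genes):
        gene = f"G{g:03d}"
        n_var = 1 + rng.poisson(max(cfg.mean_variants_per_gene - 1, 0))
        for _ in range(n_var):
            pos += 97  # arbitrary spacing
            maf = float(np.exp(rng.uniform(np.log(maf_min), np.log(cfg.maf_max))))
            is_lof = rng.random() < cfg.lof_fraction
            mcap = None if is_lof else float(rng.beta(*cfg.mcap_beta_params))
            u = rng.random()
            if u < cfg.overlap_fraction:
                membership = (True, True)
            elif u < cfg.overlap_fraction + (1 - cfg.overlap_fraction) / 2:
                membership = (True, False)
            else:
                membership = (False, True)
            rows.append(
                {
                    "variant_id": f"1:{pos}:A:C",
                    "pos": pos,
                    "gene": gene,
                    "maf": maf,
                    "lof": is_lof,
                    "mcap": mcap,
                    "in_c1": membership[0],
                    "in_c2": membership[1],
                }
            )
    return pd.DataFrame(rows)


def _qualifying(table: pd.DataFrame, gene: str, rule: MaskRule = MaskRule.MCAP_LOF) -> pd.DataFrame:
    sub = table[table["gene"] == gene]
    keep = [
        variant_qualifies(
            rule,
            "LoF" if r.lof else "missense",
            bool(r.lof),
            r.mcap,
            float(r.maf),
        )
        for r in sub.itertuples(index=False)
    ]
    return sub[np.asarray(keep, dtype=bool)]


def generate(config: SynthConfig) -> SimulatedStudy:
    """Generate the full two-cohort study; byte-identical under equal seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    table = _draw_variant_table(cfg, rng)

    maf_min = cfg.maf_min or 1.0 / (2 * min(cfg.n_samples))
    if maf_min * 2 * min(cfg.n_samples) < 0.5:
        raise ValueError("configured minimum MAF infeasible for the cohort sizes")

    cohorts: list[CohortDataset] = []
    panels: list[TraitPanel] = []
    truth = GroundTruth()

    # realised per-variant betas on the global table (shared across cohorts)
    effect_entries: list[GroundTruthEffect] = []
    for spec in cfg.effects:
        qual = _qualifying(table, spec.gene)
        if qual.empty:
            raise ValueError(f"effect gene {spec.gene} has no mask-qualifying variants")
        vids = list(qual["variant_id"])

        def _info(sub_vids) -> float:
            # total score information: sum over cohorts of n * genotype var
            info = 0.0
            sub = qual[qual["variant_id"].isin(sub_vids)]
            for c, n in enumerate(cfg.n_samples):
                member = sub["in_c1"] if c == 0 else sub["in_c2"]
                mafs = sub["maf"].to_numpy()[member.to_numpy()]
                info += n * float(np.sum(2.0 * mafs * (1.0 - mafs)))
            return info

        if spec.architecture == "uniform-burden":
            beta = spec.beta
            if spec.target_ncp is not None:
                beta = float(np.sqrt(spec.target_ncp / max(_info(vids), 1e-12)))
            betas = {v: beta for v in vids}
            driver = None
        elif spec.architecture == "single-driver":
            driver = vids[int(np.argmax(qual["maf"].to_numpy()))]
            beta = spec.beta
            if spec.target_ncp is not None:
                beta = float(np.sqrt(spec.target_ncp / max(_info([driver]), 1e-12)))
            betas = {driver: beta}
        elif spec.architecture == "heterogeneous":
            draws = rng.normal(0.0, spec.beta, size=len(vids))
            betas = dict(zip(vids, draws.tolist()))
            driver = None
        else:
            raise ValueError(f"unknown architecture {spec.architecture!r}")
        effect_entries.append(
            GroundTruthEffect(spec.gene, spec.trait, spec.architecture, betas, driver)
        )
    truth.effects = effect_entries

    trait_names = [f"MET{t:03d}" for t in range(cfg.n_traits)]
    supergroup = {t: f"SG{idx % cfg.n_supergroups}" for idx, t in enumerate(trait_names)}

    for c, n in enumerate(cfg.n_samples):
        member_col = "in_c1" if c == 0 else "in_c2"
        sub = table[table[member_col]].reset_index(drop=True)
        m = len(sub)
        maf = sub["maf"].to_numpy()
        dosages = rng.binomial(2, maf[None, :], size=(n, m)).astype(float)
        if cfg.genotype_missing_rate > 0:
            miss = rng.random(dosages.shape) < cfg.genotype_missing_rate
            dosages[miss] = np.nan
        sample_ids = [f"C{c+1}S{i:05d}" for i in range(n)]
        variants = [
            VariantRecord(
                variant_id=r.variant_id,
                chrom="1",
                pos=int(r.pos),
                ref="A",
                alt="C",
                gene=r.gene,
            )
            for r in sub.itertuples(index=False)
        ]
        ds = CohortDataset(f"COHORT{c+1}", sample_ids, variants, dosages)
        ds.recompute_allele_stats()
        cohorts.append(ds)

        # covariates and supergroup-structured factor traits
        age = rng.normal(50.0, 10.0, size=n)
        sex = rng.integers(0, 2, size=n).astype(float)
        factors = rng.normal(size=(n, cfg.n_supergroups))
        global_factor = rng.normal(size=n)
        vindex = {v: j for j, v in enumerate(sub["variant_id"])}
        values = {}
        for idx, t in enumerate(trait_names):
            sg = idx % cfg.n_supergroups
            y = (
                cfg.factor_loading * factors[:, sg]
                + cfg.global_loading * global_factor
                + cfg.covariate_effect * (age - 50.0) / 10.0
                + 0.5 * cfg.covariate_effect * sex
                + cfg.noise_sd * rng.normal(size=n)
            )
            for entry in effect_entries:
                if entry.trait != t:
                    continue
                for vid, b in entry.betas.items():
                    j = vindex.get(vid)
                    if j is not None:
                        g = dosages[:, j]
                        y = y + b * np.where(np.isnan(g), 2 * maf[j], g)
            values[t] = y
        panel = TraitPanel(
            values=pd.DataFrame(values, index=sample_ids),
            covariates=pd.DataFrame({"age": age, "sex": sex}, index=sample_ids),
            supergroup=dict(supergroup),
            cohort_id=ds.cohort_id,
        )
        panels.append(panel)

    ann_rows = [
        (
            r.variant_id,
            r.gene,
            "LoF" if r.lof else "missense",
            bool(r.lof),
            r.mcap,
        )
        for r in table.itertuples(index=False)
    ]
    annotations = AnnotationTable(
        pd.DataFrame(
            ann_rows,
            columns=["variant_id", "gene", "consequence_class", "lof_hc", "mcap_score"],
        )
    )

    # genetic-correlation table from the known sharing structure: pairs that
    # share a causal gene show strong evidence of genetic correlation
    genes_by_trait: dict[str, set[str]] = {}
    for e in effect_entries:
        genes_by_trait.setdefault(e.trait, set()).add(e.gene)
    gc_rows = []
    for i, a in enumerate(trait_names):
        for b in trait_names[i + 1 :]:
            shared = genes_by_trait.get(a, set()) & genes_by_trait.get(b, set())
            if shared:
                gc_rows.append({"trait_a": a, "trait_b": b, "rg": 0.5, "p": 1e-4})
            else:
                gc_rows.append({"trait_a": a, "trait_b": b, "rg": 0.0, "p": 0.8})
    genetic_corr = GeneticCorrTable(pd.DataFrame(gc_rows))

    return SimulatedStudy(cohorts, annotations, panels, genetic_corr, truth, cfg)


def plant_tail_signal(
    dataset: CohortDataset,
    panel: TraitPanel,
    gene_set: Sequence[str],
    trait: str,
    side: str,
    n_carriers: int = 10,
    n_alleles: Optional[int] = None,
    alleles_per_carrier: int = 1,
    max_ac: int = 10,
) -> tuple[CohortDataset, AnnotationTable, dict]:
    """Plant rare deleterious alleles in the most extreme samples of a trait.

    Creates new high-confidence LoF singleton-style variants assigned to the
    genes of ``gene_set`` (cycled), carried by the ``n_carriers`` most
    extreme samples on the chosen side; each planted variant accumulates at
    most ``max_ac - 1`` alleles so its cohort allele count stays below the
    counting cutoff. Returns the mutated dataset, an annotation table for
    the new variants, and a ground-truth record.
    """
    if max_ac < 2:
        raise ValueError("max_ac must allow at least one allele per variant")
    total = n_alleles if n_alleles is not None else n_carriers * alleles_per_carrier
    if total == 0:
        return dataset, AnnotationTable(
            pd.DataFrame(columns=AnnotationTable.COLUMNS)
        ), {"trait": trait, "side": side, "carriers": [], "variants": []}
    series = panel.values[trait].dropna()
    if len(series) < n_carriers:
        raise ValueError("not enough extreme samples to plant the signal")
    order = series.sort_values(ascending=(side == "lower"))
    carriers = [str(s) for s in order.index[:n_carriers]]
    pos_of = {s: i for i, s in enumerate(dataset.sample_ids)}

    per_variant = max_ac - 1
    genes = list(gene_set)
    new_variants: list[VariantRecord] = []
    new_cols: list[np.ndarray] = []
    ann_rows = []
    allele = 0
    vnum = 0
    while allele < total:
        take = min(per_variant, total - allele)
        col = np.zeros(dataset.n_samples)
        for j in range(take):
            col[pos_of[carriers[(allele + j) % n_carriers]]] += 1.0
        if col.max() > 2:
            raise ValueError("allele budget exceeds diploid dosage for a carrier")
        gene = genes[vnum % len(genes)]
        vid = f"PT:{900000 + vnum}:A:C"
        new_variants.append(
            VariantRecord(
                variant_id=vid, chrom="PT", pos=900000 + vnum, ref="A", alt="C", gene=gene
            )
        )
        ann_rows.append((vid, gene, "LoF", True, None))
        new_cols.append(col)
        allele += take
        vnum += 1

    mutated = CohortDataset(
        cohort_id=dataset.cohort_id,
        sample_ids=list(dataset.sample_ids),
        variants=[replace(v) for v in dataset.variants] + new_variants,
        dosages=np.column_stack([dataset.dosages, *new_cols]),
    )
    mutated.recompute_allele_stats()
    for v in mutated.variants[-len(new_variants):]:
        if v.ac >= max_ac:
            raise ValueError("planted variant reached the allele-count cutoff")
    ann = AnnotationTable(
        pd.DataFrame(ann_rows, columns=AnnotationTable.COLUMNS)
    )
    entry = {
        "trait": trait,
        "side": side,
        "carriers": carriers,
        "variants": [v.variant_id for v in new_variants],
        "n_alleles": total,
    }
    return mutated, ann, entry
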