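"""Permutation enrichment of deleterious rare alleles in phenotype tails.

For each trait the k most extreme participants per side define a tail
(k = 10 by default, with 0.5%/1% percentile modes for sensitivity). Traits
whose tails share too many participants are greedily pruned. Within a tail,
deleterious alleles (combined LoF + M-CAP mask members with cohort allele
count < 10) are summed, and an empirical p comes from re-drawing k random
participants 10,000 times. Discovery-significant results are meta-analysed
across cohorts with Stouffer's method.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import CohortDataset, MaskRule, TraitPanel
from .io import AnnotationTable
from .masks import pooled_mask
from .meta import stouffer

logger = logging.getLogger(__name__)

DEFAULT_TAIL_K = 10
DEFAULT_MAX_AC = 10
DEFAULT_N_PERM = 10_000


@dataclass
class TailSpec:
    trait: str
    side: str  # "upper" | "lower"
    mode: str  # "count" | "percentile"
    k: int
    member_samples: list[str] = field(default_factory=list)
    percentile: Optional[float] = None

    def __post_init__(self) -> None:
        self.member_samples = sorted(self.member_samples)


@dataclass
class TailsResult:
    trait: str
    side: str
    gene_set: str
    observed_alleles: int
    perm_p: float
    cohort: str = ""


@dataclass
class TailsVerdict:
    trait: str
    side: str
    gene_set: str
    wes_p: float
    wgs_p: Optional[float]
    meta_p: Optional[float]
    enriched: bool
    gated: bool  # False when discovery p >= 0.05 (not meta-analysed)


def stream_rng(master_seed: int, *keys: str) -> np.random.Generator:
    """Independent, order-invariant RNG stream per (trait, side, set) key."""
    digest = hashlib.sha256("|".join(keys).encode()).digest()
    child = int.from_bytes(digest[:4], "big") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([master_seed % (2**31), child]))


def define_tails(
    panel: TraitPanel,
    trait: str,
    side: str,
    mode: str = "count",
    k: int = DEFAULT_TAIL_K,
    percentile: Optional[float] = None,
) -> TailSpec:
    """The k most extreme samples on one side of a trait distribution.

    In percentile mode, k = round(percentile * n non-missing). Boundary ties
    are broken deterministically by sample id order.
    """
    series = panel.values[trait].dropna()
    if mode == "percentile":
        if percentile is None:
            raise ValueError("percentile mode needs a percentile")
        k = max(1, int(round(percentile * len(series))))
    if len(series) < 2 * k:
        raise ValueError(f"too few non-missing values for trait {trait!r}: {len(series)} < {2*k}")
    ascending = side == "lower"
    df = pd.DataFrame(
        {"value": series.to_numpy(dtype=float), "sample": series.index.astype(str)}
    ).sort_values(["value", "sample"], ascending=[ascending, True], kind="mergesort")
    members = list(df["sample"].head(k))
    return TailSpec(
        trait=trait,
        side=side,
        mode=mode,
        k=k,
        member_samples=members,
        percentile=percentile,
    )


def prune_overlapping_traits(
    tails: dict[str, dict[str, TailSpec]], max_shared: int = 8
) -> list[str]:
    """Greedy keep-first pruning of traits with heavily overlapping tails.

    Scanning traits in input order, a trait is dropped if its upper or lower
    tail shares at least ``max_shared`` participants with the corresponding
    tail of any previously retained trait.
    """
    retained: list[str] = []
    for trait, pair in tails.items():
        clash = False
        for kept in retained:
            for side in ("upper", "lower"):
                if side in pair and side in tails[kept]:
                    shared = set(pair[side].member_samples) & set(
                        tails[kept][side].member_samples
                    )
                    if len(shared) >= max_shared:
                        clash = True
                        break
            if clash:
                break
        if clash:
            logger.info("prune_overlapping_traits: dropped %s", trait)
        else:
            retained.append(trait)
    return retained


def _qualifying_counts(
    gene_set: Sequence[str],
    dataset: CohortDataset,
    annotations: AnnotationTable,
    rule: MaskRule,
    max_ac: int,
) -> np.ndarray:
    """Per-sample deleterious-allele count over the set's qualifying variants
    (mask members with cohort allele count < max_ac); missing dosages count 0."""
    mask = pooled_mask("_tails", list(gene_set), dataset, annotations, rule)
    ac_by_id = {v.variant_id: v.ac for v in dataset.variants}
    vids = [v for v in mask.variant_ids if ac_by_id[v] < max_ac]
    if not vids:
        return np.zeros(dataset.n_samples)
    idx = dataset.variant_index()
    cols = [idx[v] for v in vids]
    return np.nansum(dataset.dosages[:, cols], axis=1)


def count_deleterious_alleles(
    samples: Sequence[str],
    gene_set: Sequence[str],
    dataset: CohortDataset,
    annotations: AnnotationTable,
    rule: MaskRule = MaskRule.MCAP_LOF,
    max_ac: int = DEFAULT_MAX_AC,
) -> int:
    """Total deleterious alleles carried by ``samples`` (dosage sum)."""
    counts = _qualifying_counts(gene_set, dataset, annotations, rule, max_ac)
    pos = {s: i for i, s in enumerate(dataset.sample_ids)}
    rows = [pos[s] for s in samples]
    return int(round(float(np.sum(counts[rows]))))


def permutation_p(
    observed: int,
    eligible_samples: Sequence[str],
    gene_set: Sequence[str],
    dataset: CohortDataset,
    annotations: AnnotationTable,
    k: int = DEFAULT_TAIL_K,
    n_perm: int = DEFAULT_N_PERM,
    rng: Optional[np.random.Generator] = None,
    rule: MaskRule = MaskRule.MCAP_LOF,
    max_ac: int = DEFAULT_MAX_AC,
) -> float:
    """Empirical p: fraction of random k-subsets with allele count >= observed.

    Subsets are drawn uniformly without replacement from the trait's
    non-missing samples; p uses the add-one convention (r+1)/(n_perm+1) so it
    is never exactly zero.
    """
    eligible = list(eligible_samples)
    if k > len(eligible):
        raise ValueError(f"k={k} exceeds {len(eligible)} eligible samples")
    if rng is None:
        rng = np.random.default_rng()
    counts = _qualifying_counts(gene_set, dataset, annotations, rule, max_ac)
    pos = {s: i for i, s in enumerate(dataset.sample_ids)}
    c = counts[[pos[s] for s in eligible]]
    n = len(eligible)
    # vectorised k-subsets: top-k of random keys per permutation
    draws = np.empty(n_perm)
    chunk = max(1, min(n_perm, int(2e6 / max(n, 1))))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        keys = rng.random((b, n))
        top = np.argpartition(keys, k - 1, axis=1)[:, :k]
        draws[done : done + b] = c[top].sum(axis=1)
        done += b
    r = int(np.sum(draws >= observed))
    return (r + 1) / (n_perm + 1)


def tails_meta_and_verdict(
    wes: TailsResult,
    wgs: TailsResult,
    threshold: float,
    discovery_alpha: float = 0.05,
) -> TailsVerdict:
    """Gate on discovery p < 0.05, Stouffer-combine, declare enrichment.

    Enrichment requires the meta p to reach the corrected threshold and
    nominal significance in the validation cohort.
    """
    if (wes.trait, wes.side, wes.gene_set) != (wgs.trait, wgs.side, wgs.gene_set):
        raise ValueError("cohort results refer to different trait/side/set")
    if not wes.perm_p < discovery_alpha:
        return TailsVerdict(
            wes.trait, wes.side, wes.gene_set, wes.perm_p, wgs.perm_p, None, False, False
        )
    meta_p = stouffer([wes.perm_p, wgs.perm_p])
    enriched = meta_p <= threshold and wgs.perm_p < discovery_alpha
    return TailsVerdict(
        wes.trait, wes.side, wes.gene_set, wes.perm_p, wgs.perm_p, meta_p, bool(enriched), True
    )
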