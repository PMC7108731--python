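"""Study-design layer: covariate selection, multiplicity, power.

Correlated-metabolite covariate boosting: at the validation stage only, a
candidate trait may be added as a covariate for an outcome if it shows no
evidence of genetic correlation with it (rg p > 0.05 in an external table),
is phenotypically correlated in-sample (|r| > 0.10) and belongs to a
different biomarker supergroup. Multiplicity is relaxed through the
effective number of tests — the number of principal components explaining
more than 95% of trait (or gene-set) variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import GeneticCorrTable


@dataclass
class ThresholdSet:
    """Significance thresholds, each an exact Bonferroni quotient."""

    neff_traits: int
    gene_level: float
    gene_level_multitrait: float
    geneset_level: float
    tails_level: float
    gwas_proximal_level: float


def select_covariates(
    outcome: str,
    pheno_corr: pd.DataFrame,
    gc: GeneticCorrTable,
    supergroups: dict[str, str],
    r_threshold: float = 0.10,
    rg_p_threshold: float = 0.05,
) -> list[str]:
    """Traits eligible as covariates for ``outcome`` (may be empty).

    All three criteria must hold: (i) no evidence of genetic correlation
    (rg p > 0.05; a missing entry fails), (ii) in-sample phenotypic
    correlation |r| > 0.10, (iii) different supergroup. Candidates with a
    missing phenotypic correlation are skipped.
    """
    if outcome not in pheno_corr.columns:
        raise ValueError(f"outcome {outcome!r} absent from the phenotypic correlation matrix")
    selected = []
    for cand in pheno_corr.columns:
        if cand == outcome:
            continue
        r = pheno_corr.loc[outcome, cand]
        if pd.isna(r) or abs(r) <= r_threshold:
            continue
        rg_p = gc.rg_p(outcome, cand)
        if rg_p is None or rg_p <= rg_p_threshold:
            continue
        if supergroups.get(cand) == supergroups.get(outcome) and supergroups.get(outcome) is not None:
            continue
        selected.append(cand)
    return selected


def _pairwise_correlation_psd(values: np.ndarray | pd.DataFrame) -> np.ndarray:
    df = pd.DataFrame(values)
    corr = df.corr(min_periods=2).to_numpy()
    corr = np.where(np.isnan(corr), 0.0, corr)
    np.fill_diagonal(corr, 1.0)
    corr = (corr + corr.T) / 2.0
    # pairwise-complete correlation need not be PSD; clip negative eigenvalues
    w, v = np.linalg.eigh(corr)
    if w.min() < -1e-10:
        w = np.clip(w, 0.0, None)
        corr = (v * w) @ v.T
    return corr


def effective_tests(values: np.ndarray | pd.DataFrame, variance_threshold: float = 0.95) -> int:
    """Smallest number of principal components of the trait correlation
    matrix whose cumulative explained variance exceeds ``variance_threshold``."""
    arr = np.asarray(pd.DataFrame(values), dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("need at least two samples")
    if arr.shape[1] < 2:
        raise ValueError("need at least two traits")
    corr = _pairwise_correlation_psd(arr)
    eig = np.sort(np.linalg.eigvalsh(corr))[::-1]
    eig = np.clip(eig, 0.0, None)
    frac = np.cumsum(eig) / eig.sum()
    k = int(np.searchsorted(frac, variance_threshold, side="right") + 1)
    return min(k, len(eig))


def thresholds(
    neff: int,
    n_genes: int = 20000,
    neff_genesets: int = 1094,
    neff_tail_traits: int = 9,
    n_tail_pathways: int = 15,
    neff_lipid_traits: int = 10,
    alpha: float = 0.05,
) -> ThresholdSet:
    """Bonferroni quotients for every analysis arm.

    With the defaults (19 effective traits supplied as ``neff``): gene-level
    0.05/20000 = 2.5e-6, multi-trait gene-level 1.32e-7, gene-set level
    0.05/(1094*19) = 2.41e-6, tails 0.05/(9*15) = 0.00037, GWAS-proximal
    0.05/10 = 0.005.
    """
    gene_level = alpha / n_genes
    return ThresholdSet(
        neff_traits=neff,
        gene_level=gene_level,
        gene_level_multitrait=gene_level / neff,
        geneset_level=alpha / (neff_genesets * neff),
        tails_level=alpha / (neff_tail_traits * n_tail_pathways),
        gwas_proximal_level=alpha / neff_lipid_traits,
    )


def replication_verdict(
    meta_p: float,
    threshold: float,
    n_variants_tested: int,
    wgs_unadjusted_p: float,
) -> bool:
    """A signal replicates iff it meets the corrected threshold, more than
    two variants were tested, and the unadjusted validation test is
    nominally significant."""
    return bool(meta_p < threshold and n_variants_tested > 2 and wgs_unadjusted_p < 0.05)


def analytic_power(n: int, maf: float, beta_sd: float, alpha: float) -> float:
    """Two-sided 1-df chi-square power of a single-variant test.

    Non-centrality n * 2 maf (1-maf) * beta^2 with the effect in trait-SD
    units per allele.
    """
    if not 0.0 < maf <= 0.5:
        raise ValueError("maf must lie in (0, 0.5]")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    ncp = n * 2.0 * maf * (1.0 - maf) * beta_sd**2
    z_alpha = stats.norm.isf(alpha / 2.0)
    root = np.sqrt(ncp)
    return float(stats.norm.cdf(root - z_alpha) + stats.norm.cdf(-root - z_alpha))
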