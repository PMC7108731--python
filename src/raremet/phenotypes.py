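"""Phenotype QC and transformation.

The preparation chain applied per cohort: drop samples with excessive trait
missingness, rank-based inverse-normalise every trait, then replace each
trait by its residuals from an ordinary least-squares fit on the covariates.
Downstream association tests consume the residualised panel.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import TraitPanel

logger = logging.getLogger(__name__)

#: Blom offset for the inverse-normal transform
RANK_OFFSET = 3.0 / 8.0


def filter_missing_samples(panel: TraitPanel, max_missing: float = 0.30) -> TraitPanel:
    """Remove samples whose trait missingness exceeds ``max_missing``.

    The inequality is strict: a sample missing exactly the threshold fraction
    is retained.
    """
    frac = panel.values.isna().mean(axis=1)
    keep = frac <= max_missing
    if not keep.any():
        raise ValueError("all samples exceed the missingness threshold")
    removed = list(panel.values.index[~keep])
    if removed:
        logger.info("filter_missing_samples: removed %d samples: %s", len(removed), removed)
    return TraitPanel(
        values=panel.values.loc[keep].copy(),
        covariates=panel.covariates.loc[keep].copy(),
        supergroup=dict(panel.supergroup),
        is_residualised=panel.is_residualised,
        cohort_id=panel.cohort_id,
    )


def rank_inverse_normal(x: np.ndarray | pd.Series, offset: float = RANK_OFFSET) -> np.ndarray:
    """Rank-based inverse-normal transform with Blom offset.

    Non-missing entries map to ``Phi^{-1}((rank - offset) / (n + 1 - 2*offset))``
    with average ranks for ties; missing entries stay missing.
    """
    arr = np.asarray(x, dtype=float)
    out = np.full(arr.shape, np.nan)
    obs = ~np.isnan(arr)
    vals = arr[obs]
    n = vals.size
    if n < 2:
        raise ValueError("need at least two non-missing values")
    if np.all(vals == vals[0]):
        raise ValueError("constant vector: ranks undefined")
    ranks = stats.rankdata(vals, method="average")
    out[obs] = stats.norm.ppf((ranks - offset) / (n + 1.0 - 2.0 * offset))
    return out


def _design_matrix(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Intercept + covariates; constant columns dropped, rank checked."""
    cols = []
    names = []
    for c in covariates.columns:
        col = covariates[c].to_numpy(dtype=float)
        if np.nanstd(col) > 0:
            cols.append(col)
            names.append(c)
    X = np.column_stack([np.ones(len(covariates)), *cols])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify collinear columns by incremental rank
        bad = []
        acc = X[:, :1]
        for j in range(1, X.shape[1]):
            cand = np.column_stack([acc, X[:, j]])
            if np.linalg.matrix_rank(cand) == acc.shape[1]:
                bad.append(names[j - 1])
            else:
                acc = cand
        raise ValueError(f"rank-deficient covariates; collinear columns: {bad}")
    return X, names


def residualize(panel: TraitPanel, inverse_normalise: bool = True) -> TraitPanel:
    """Inverse-normalise (optional) then residualise every trait on covariates.

    Residuals are from per-trait OLS on intercept + covariates, using the
    samples with a non-missing trait value; missing values stay missing.
    """
    X_full, _ = _design_matrix(panel.covariates)
    out = panel.values.copy()
    for trait in panel.values.columns:
        y = panel.values[trait].to_numpy(dtype=float)
        if inverse_normalise:
            y = rank_inverse_normal(y)
        obs = ~np.isnan(y)
        X = X_full[obs]
        beta, *_ = np.linalg.lstsq(X, y[obs], rcond=None)
        resid = np.full(y.shape, np.nan)
        resid[obs] = y[obs] - X @ beta
        out[trait] = resid
    return TraitPanel(
        values=out,
        covariates=panel.covariates.copy(),
        supergroup=dict(panel.supergroup),
        is_residualised=True,
        cohort_id=panel.cohort_id,
    )


def phenotypic_correlation(panel: TraitPanel, min_pairs: int = 3) -> pd.DataFrame:
    """Pearson correlation between traits on pairwise-complete observations.

    Pairs with fewer than ``min_pairs`` complete observations are recorded as
    missing. The diagonal is exactly 1.
    """
    corr = panel.values.corr(method="pearson", min_periods=min_pairs)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def prepare_panel(panel: TraitPanel, max_missing: float = 0.30) -> TraitPanel:
    """Full preparation chain: missingness filter → inverse-normal → residuals."""
    return residualize(filter_missing_samples(panel, max_missing))
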