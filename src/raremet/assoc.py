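"""Score-based rare-variant aggregation tests.

The engine works in the score-test formulation: a null model regresses the
trait on covariates; per-variant weighted scores U and their null covariance
V are then sufficient for the burden test (rho=1), the variance-component
SKAT test (rho=0) and the optimal unified SKAT-O omnibus. Because (U, V) are
additive over independent cohorts, the same machinery drives the exact
two-cohort meta-analysis.

Conventions: with null residuals r, residual variance s2 and projected,
weighted genotypes G~W, the summary is U = W G~' r / s2 and
V = W G~' G~ W / s2, so that Var(U) = V under the null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .datamodel import AggTestResult, CohortDataset
from .quadform import liu_quantile, pvalue_quadform, quadform_pvalue_info

DEFAULT_RHO_GRID = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)


def beta_maf_weights(maf: np.ndarray, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """Conventional Beta(1,25)-density MAF weights (flat option: a=b=1)."""
    maf = np.clip(np.asarray(maf, dtype=float), 1e-12, 1 - 1e-12)
    return stats.beta.pdf(maf, a, b)


def flat_weights(maf: np.ndarray) -> np.ndarray:
    return np.ones(np.asarray(maf).shape)


@dataclass
class NullModel:
    """OLS null fit of a trait on covariates (intercept always included)."""

    trait: str
    residuals: np.ndarray
    design: np.ndarray
    q_basis: np.ndarray  # orthonormal basis of the design column space
    sigma2: float
    sample_ids: Optional[list[str]] = None

    @property
    def n(self) -> int:
        return self.design.shape[0]

    @property
    def k(self) -> int:
        return self.design.shape[1]

    def project(self, m: np.ndarray) -> np.ndarray:
        """Apply I - X (X'X)^{-1} X' to columns of ``m``."""
        return m - self.q_basis @ (self.q_basis.T @ m)


def fit_null(
    y: np.ndarray,
    X: Optional[np.ndarray] = None,
    trait: str = "",
    sample_ids: Optional[list[str]] = None,
    add_intercept: bool = True,
) -> NullModel:
    """Fit the null OLS model; sigma2 = RSS / (n - k).

    ``X`` are covariate columns without intercept (None = intercept only).
    Missing values must have been removed/aligned by the caller.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if np.isnan(y).any():
        raise ValueError("missing trait values must be removed before fit_null")
    if X is None:
        X = np.empty((n, 0))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if add_intercept:
        X = np.column_stack([np.ones(n), X])
    if n <= X.shape[1]:
        raise ValueError(f"n={n} <= number of design columns {X.shape[1]}")
    q, r = np.linalg.qr(X)
    if np.abs(np.diag(r)).min() < 1e-10 * max(np.abs(np.diag(r)).max(), 1.0):
        raise ValueError("design matrix is rank deficient")
    resid = y - q @ (q.T @ y)
    sigma2 = float(resid @ resid) / (n - X.shape[1])
    return NullModel(
        trait=trait,
        residuals=resid,
        design=X,
        q_basis=q,
        sigma2=sigma2,
        sample_ids=sample_ids,
    )


@dataclass
class ScoreSummary:
    """Per-variant weighted scores and their null covariance for one
    cohort × trait × mask — the currency of the meta-analysis."""

    unit_id: str
    trait: str
    rule: str
    variant_ids: list[str]
    U: np.ndarray
    V: np.ndarray
    n_samples: int
    ac_total: int = 0
    cohort: str = ""

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float).ravel()
        self.V = np.asarray(self.V, dtype=float)
        m = len(self.variant_ids)
        if self.U.size != m or self.V.shape != (m, m):
            raise ValueError("U/V dimensions must match variant_ids")
        if not np.allclose(self.V, self.V.T, atol=1e-8):
            raise ValueError("V must be symmetric")


def impute_missing(G: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages (2 x MAF within the analysed samples)."""
    G = np.asarray(G, dtype=float)
    if not np.isnan(G).any():
        return G
    G = G.copy()
    col_mean = np.nanmean(np.where(np.isnan(G), np.nan, G), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    idx = np.where(np.isnan(G))
    G[idx] = col_mean[idx[1]]
    return G


def score_summary(
    null: NullModel,
    G: np.ndarray,
    weights: np.ndarray,
    variant_ids: Sequence[str],
    unit_id: str = "",
    rule: str = "",
    cohort: str = "",
    ac_total: Optional[int] = None,
) -> ScoreSummary:
    """Weighted score vector and null covariance for a mask's genotypes."""
    if null.sigma2 <= 0:
        raise ValueError("null model has non-positive residual variance")
    G = impute_missing(G)
    if G.shape[0] != null.n:
        raise ValueError("genotype rows must match null model samples")
    w = np.asarray(weights, dtype=float).ravel()
    Gt = null.project(G)
    U = w * (Gt.T @ null.residuals) / null.sigma2
    V = (w[:, None] * w[None, :]) * (Gt.T @ Gt) / null.sigma2
    if ac_total is None:
        ac_total = int(np.nansum(G))
    return ScoreSummary(
        unit_id=unit_id,
        trait=null.trait,
        rule=rule,
        variant_ids=list(variant_ids),
        U=U,
        V=V,
        n_samples=null.n,
        ac_total=ac_total,
        cohort=cohort,
    )


def _untestable(s: ScoreSummary, note: str) -> AggTestResult:
    return AggTestResult(
        unit_id=s.unit_id,
        trait=s.trait,
        rule=s.rule,
        p=float("nan"),
        n_variants=len(s.variant_ids),
        ac_total=s.ac_total,
        cohort=s.cohort,
        notes=note,
    )


def burden_test(s: ScoreSummary) -> AggTestResult:
    """Weighted burden (rho = 1): Q = (1'U)^2 / (1'V1) ~ chi2_1 under null."""
    denom = float(np.sum(s.V))
    if denom <= 1e-12:
        return _untestable(s, "untestable: zero burden variance (monomorphic)")
    q = float(np.sum(s.U)) ** 2 / denom
    return AggTestResult(
        unit_id=s.unit_id,
        trait=s.trait,
        rule=s.rule,
        p=float(stats.chi2.sf(q, df=1)),
        rho_opt=1.0,
        n_variants=len(s.variant_ids),
        ac_total=s.ac_total,
        q_stat=q,
        cohort=s.cohort,
        notes="burden",
    )


def skat_test(s: ScoreSummary) -> AggTestResult:
    """Variance-component test (rho = 0): Q = U'U ~ sum lambda_i chi2_1."""
    lam = np.linalg.eigvalsh(s.V)
    lam = lam[lam > 1e-10 * max(lam.max(initial=0.0), 1e-300)]
    if lam.size == 0:
        return _untestable(s, "untestable: null covariance has no positive eigenvalues")
    q = float(s.U @ s.U)
    p, method = quadform_pvalue_info(q, lam)
    return AggTestResult(
        unit_id=s.unit_id,
        trait=s.trait,
        rule=s.rule,
        p=p,
        rho_opt=0.0,
        n_variants=len(s.variant_ids),
        ac_total=s.ac_total,
        q_stat=q,
        cohort=s.cohort,
        notes=f"skat:{method}",
    )


def _rho_lambdas(V_sqrt: np.ndarray, rho: float) -> np.ndarray:
    """Eigenvalues of the mixture defining Q_rho = U' R_rho U."""
    m = V_sqrt.shape[0]
    R = (1.0 - rho) * np.eye(m) + rho * np.ones((m, m))
    lam = np.linalg.eigvalsh(V_sqrt @ R @ V_sqrt)
    return lam[lam > 1e-10 * max(lam.max(initial=0.0), 1e-300)]


def _exact_quantile(p: float, lam: np.ndarray, accuracy: float = 1e-4) -> float:
    """q with P(Q > q) = p, by bracketing + Brent on the quadform tail."""
    guess = max(liu_quantile(p, lam), 1e-8)
    lo, hi = 0.0, guess
    while pvalue_quadform(hi, lam, accuracy) > p:
        lo = hi
        hi *= 2.0
        if hi > 1e12:
            break
    return float(
        optimize.brentq(
            lambda q: pvalue_quadform(q, lam, accuracy) - p, lo, hi, xtol=1e-10, rtol=1e-12
        )
    )


def skato_test(
    s: ScoreSummary,
    rho_grid: Sequence[float] = DEFAULT_RHO_GRID,
    accuracy: float = 1e-6,
) -> AggTestResult:
    """Optimal unified test: omnibus over the burden/SKAT mixing grid.

    Per-rho statistics Q_rho = (1-rho) U'U + rho (1'U)^2 are each referred to
    their exact mixture null; the omnibus p of the minimum per-rho p is
    computed by the one-dimensional mixing-variable integration of the
    optimal unified construction (rho values of 1 are handled at 0.999 inside
    the decomposition, as in the reference formulation). A length-one grid
    collapses exactly to the corresponding single test.
    """
    rho_grid = list(rho_grid)
    if len(rho_grid) == 0:
        raise ValueError("empty rho grid")
    if len(s.variant_ids) == 1:
        res = burden_test(s)
        if not np.isnan(res.p):
            res.notes = "skato: single variant, all rho equivalent"
        return res
    if len(rho_grid) == 1:
        if rho_grid[0] == 1.0:
            return burden_test(s)
        if rho_grid[0] == 0.0:
            return skat_test(s)

    m = len(s.variant_ids)
    d, E = np.linalg.eigh(s.V)
    d = np.clip(d, 0.0, None)
    V_sqrt = (E * np.sqrt(d)) @ E.T

    rho_adj = np.minimum(np.asarray(rho_grid, dtype=float), 0.999)
    uu = float(s.U @ s.U)
    u1sq = float(np.sum(s.U)) ** 2
    q_obs = (1.0 - rho_adj) * uu + rho_adj * u1sq

    p_rho = np.empty(len(rho_adj))
    lam_rho = []
    for i, rho in enumerate(rho_adj):
        lam = _rho_lambdas(V_sqrt, rho)
        if lam.size == 0:
            return _untestable(s, "untestable: degenerate covariance")
        lam_rho.append(lam)
        p_rho[i] = pvalue_quadform(q_obs[i], lam, accuracy)

    i_min = int(np.argmin(p_rho))
    pmin = float(p_rho[i_min])
    rho_opt = float(rho_grid[i_min])

    # omnibus parameters, all expressible through V
    vb = s.V @ np.ones(m)
    s11 = float(vb.sum())  # 1'V1
    note_method = "integration"
    if s11 <= 1e-12 * max(np.abs(s.V).max(), 1e-300):
        p_omni = pmin  # burden direction degenerate: components coincide
        note_method = "degenerate-burden"
    else:
        V2 = s.V - np.outer(vb, vb) / s11
        lam2 = np.linalg.eigvalsh(V2)
        lam2 = lam2[lam2 > 1e-10 * max(lam2.max(initial=0.0), 1e-300)]
        if lam2.size == 0:
            # V is rank one along the burden direction: all Q_rho perfectly
            # correlated, the omnibus equals the minimum p
            p_omni = pmin
            note_method = "rank-one"
        else:
            mu_q = float(lam2.sum())
            var_zeta = 4.0 * float(vb @ V2 @ vb) / s11
            var_q = 2.0 * float(np.sum(lam2**2)) + var_zeta
            tau = rho_adj * s11 + (1.0 - rho_adj) * float(vb @ vb) / s11
            try:
                q_min = np.array([_exact_quantile(pmin, lam) for lam in lam_rho])
                scale = np.sqrt(max(var_q - var_zeta, 0.0) / var_q) if var_q > 0 else 1.0

                def cond_cdf(x: float) -> float:
                    qm = np.min((q_min - tau * x) / (1.0 - rho_adj))
                    if qm <= 0.0:
                        return 0.0
                    q_adj = (qm - mu_q) * scale + mu_q
                    if q_adj <= 0.0:
                        return 0.0
                    return 1.0 - pvalue_quadform(q_adj, lam2, accuracy=1e-4)

                # integrate F(.)*chi2_1 density over the mixing variable; the
                # substitution x = t^2 absorbs the density's 1/sqrt(x)
                # singularity, leaving a smooth integrand for a Gauss rule
                with np.errstate(divide="ignore"):
                    x_max = float(np.min(np.where(tau > 0, q_min / np.where(tau > 0, tau, 1.0), np.inf)))
                t_max = float(np.sqrt(min(max(x_max, 0.0), 40.0)))
                if t_max <= 0.0:
                    p_omni = 1.0
                else:
                    nodes, wts = np.polynomial.legendre.leggauss(48)
                    t = 0.5 * t_max * (nodes + 1.0)
                    vals = np.array([cond_cdf(ti * ti) for ti in t])
                    dens = np.sqrt(2.0 / np.pi) * np.exp(-0.5 * t * t)
                    val = 0.5 * t_max * float(np.sum(wts * vals * dens))
                    p_omni = 1.0 - val
            except Exception:
                p_omni = min(pmin * len(rho_grid), 1.0)
                note_method = "bonferroni-fallback"

    # the omnibus min-p statistic can never be more significant than the
    # smallest per-rho p, nor less significant than its Bonferroni bound
    p_omni = float(np.clip(p_omni, pmin, min(pmin * len(rho_grid), 1.0)))
    return AggTestResult(
        unit_id=s.unit_id,
        trait=s.trait,
        rule=s.rule,
        p=p_omni,
        rho_opt=rho_opt,
        n_variants=m,
        ac_total=s.ac_total,
        q_stat=float(q_obs[i_min]),
        cohort=s.cohort,
        notes=f"skato:{note_method}",
    )


def run_test(s: ScoreSummary, test: str, rho_grid: Sequence[float] = DEFAULT_RHO_GRID) -> AggTestResult:
    if test == "burden":
        return burden_test(s)
    if test == "skat":
        return skat_test(s)
    if test == "skato":
        return skato_test(s, rho_grid)
    raise ValueError(f"unknown test {test!r}")


@dataclass
class SingleVariantResult:
    variant_id: str
    p: float
    beta: float
    se: float
    flag: str = ""


def single_variant_scan(
    null: NullModel, dataset: CohortDataset
) -> list[SingleVariantResult]:
    """Per-variant asymptotic score test with univariate effect estimates.

    Monomorphic variants are skipped (p = nan, flagged); variants collinear
    with the null design get p = 1 (no residual information), flagged.
    """
    out: list[SingleVariantResult] = []
    G = dataset.dosages
    for j, v in enumerate(dataset.variants):
        g = G[:, j]
        obs = ~np.isnan(g)
        if np.nanstd(g) == 0:
            out.append(SingleVariantResult(v.variant_id, float("nan"), float("nan"), float("nan"), "monomorphic"))
            continue
        gi = impute_missing(g[:, None]).ravel()
        gt = null.project(gi[:, None]).ravel()
        denom = float(gt @ gt)
        if denom <= 1e-10 * float(gi @ gi):
            out.append(SingleVariantResult(v.variant_id, 1.0, 0.0, float("inf"), "collinear-with-design"))
            continue
        score = float(gt @ null.residuals)
        z2 = score**2 / (denom * null.sigma2)
        beta = score / denom
        se = float(np.sqrt(null.sigma2 / denom))
        out.append(
            SingleVariantResult(v.variant_id, float(stats.chi2.sf(z2, df=1)), beta, se)
        )
    return out


@dataclass
class LeaveOneOutResult:
    driven_by_single: bool
    driver_id: Optional[str]
    removal_ps: dict[str, float] = field(default_factory=dict)
    degenerate: bool = False
    full_p: float = float("nan")


def leave_one_out(
    null: NullModel,
    G: np.ndarray,
    weights: np.ndarray,
    variant_ids: Sequence[str],
    test: str = "burden",
    alpha: float = 0.05,
    rho_grid: Sequence[float] = DEFAULT_RHO_GRID,
) -> LeaveOneOutResult:
    """Single-variant driver analysis by leave-one-out re-testing.

    The association is "driven by a single variant" if removing some variant
    lifts the re-test p above ``alpha``; the driver is the removal giving the
    largest p (ties: lower variant index). A one-variant mask is trivially
    driven and flagged degenerate.
    """
    variant_ids = list(variant_ids)
    m = len(variant_ids)
    full = run_test(
        score_summary(null, G, weights, variant_ids), test, rho_grid
    )
    if m < 2:
        return LeaveOneOutResult(
            driven_by_single=True,
            driver_id=variant_ids[0] if variant_ids else None,
            degenerate=True,
            full_p=full.p,
        )
    removal_ps: dict[str, float] = {}
    w = np.asarray(weights, dtype=float).ravel()
    best_p = -np.inf
    driver = None
    for j, vid in enumerate(variant_ids):
        keep = [i for i in range(m) if i != j]
        res = run_test(
            score_summary(null, G[:, keep], w[keep], [variant_ids[i] for i in keep]),
            test,
            rho_grid,
        )
        pj = res.p if not np.isnan(res.p) else 1.0
        removal_ps[vid] = pj
        if pj > best_p:  # strict: ties keep the lower-index variant
            best_p = pj
            driver = vid
    driven = best_p > alpha
    return LeaveOneOutResult(
        driven_by_single=bool(driven),
        driver_id=driver if driven else driver,
        removal_ps=removal_ps,
        full_p=full.p,
    )


def conditional_test(
    y: np.ndarray,
    X: Optional[np.ndarray],
    G_mask: np.ndarray,
    weights: np.ndarray,
    variant_ids: Sequence[str],
    conditioning_G: Optional[np.ndarray] = None,
    test: str = "skato",
    trait: str = "",
    unit_id: str = "",
    rule: str = "",
    rho_grid: Sequence[float] = DEFAULT_RHO_GRID,
) -> AggTestResult:
    """Aggregation test conditioning on extra genotype columns.

    Conditioning dosages are appended to the covariate design before the null
    fit; columns collinear with the existing design are dropped with a
    warning. An empty conditioning set reproduces the unconditional test.
    """
    import warnings

    n = np.asarray(y).size
    base = np.empty((n, 0)) if X is None else np.asarray(X, dtype=float)
    if base.ndim == 1:
        base = base[:, None]
    design = np.column_stack([np.ones(n), base])
    if conditioning_G is not None and np.asarray(conditioning_G).size:
        C = impute_missing(np.asarray(conditioning_G, dtype=float))
        if C.ndim == 1:
            C = C[:, None]
        for j in range(C.shape[1]):
            cand = np.column_stack([design, C[:, j]])
            if np.linalg.matrix_rank(cand) == design.shape[1]:
                warnings.warn(
                    f"conditioning column {j} collinear with design; dropped"
                )
                continue
            design = cand
    null = fit_null(y, design[:, 1:], trait=trait, add_intercept=True)
    s = score_summary(null, G_mask, weights, variant_ids, unit_id=unit_id, rule=rule)
    return run_test(s, test, rho_grid)
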