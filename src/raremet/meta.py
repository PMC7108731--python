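"""Cross-cohort evidence combination.

Aggregation tests are meta-analysed in the score domain under a homogeneous
(shared-effect) model: per-cohort score vectors and covariances are embedded
on the union variant list and summed, after which any of the single-cohort
tests applies unchanged. Cohorts in which a variant is absent contribute
zero score and zero variance at that position, so masks with zero variant
overlap between cohorts remain meta-analysable. Permutation p-values are
combined with Stouffer's one-sided z method.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .assoc import DEFAULT_RHO_GRID, ScoreSummary, run_test
from .datamodel import AggTestResult


def union_variant_ids(summaries: Sequence[ScoreSummary]) -> list[str]:
    """Union of cohort variant lists, ordered by first appearance."""
    seen: dict[str, None] = {}
    for s in summaries:
        for v in s.variant_ids:
            seen.setdefault(v, None)
    return list(seen)


def combine_summaries(summaries: Sequence[ScoreSummary]) -> ScoreSummary:
    if not summaries:
        raise ValueError("need at least one cohort summary")
    first = summaries[0]
    for s in summaries[1:]:
        if (s.unit_id, s.trait, s.rule) != (first.unit_id, first.trait, first.rule):
            raise ValueError(
                "inconsistent unit/trait/rule across cohort summaries: "
                f"{(s.unit_id, s.trait, s.rule)} vs {(first.unit_id, first.trait, first.rule)}"
            )
    union = union_variant_ids(summaries)
    pos = {v: i for i, v in enumerate(union)}
    m = len(union)
    U = np.zeros(m)
    V = np.zeros((m, m))
    for s in summaries:
        idx = np.array([pos[v] for v in s.variant_ids], dtype=int)
        U[idx] += s.U
        V[np.ix_(idx, idx)] += s.V
    return ScoreSummary(
        unit_id=first.unit_id,
        trait=first.trait,
        rule=first.rule,
        variant_ids=union,
        U=U,
        V=V,
        n_samples=sum(s.n_samples for s in summaries),
        ac_total=sum(s.ac_total for s in summaries),
        cohort="META",
    )


def meta_aggregate(
    summaries: Sequence[ScoreSummary],
    test: str = "skato",
    rho_grid: Sequence[float] = DEFAULT_RHO_GRID,
) -> AggTestResult:
    """Homogeneous score meta-analysis followed by the chosen test."""
    return run_test(combine_summaries(summaries), test, rho_grid)


def stouffer(p_values: Sequence[float], weights: Optional[Sequence[float]] = None) -> float:
    """One-sided Stouffer combination: z_i = Phi^{-1}(1 - p_i).

    Unweighted by default. p-values of exactly 0 or 1 are rejected — clamp
    permutation p-values with the (r+1)/(n+1) convention before combining.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("p-values must lie strictly in (0, 1)")
    w = np.ones(p.size) if weights is None else np.asarray(weights, dtype=float)
    z = stats.norm.isf(p)
    return float(stats.norm.sf(np.sum(w * z) / np.sqrt(np.sum(w**2))))


def two_stage_gate(discovery_p: float, threshold: float = 5e-3) -> bool:
    """Forward a hypothesis to validation iff its discovery p is strictly
    below the gating threshold."""
    return bool(discovery_p < threshold)
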