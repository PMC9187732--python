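"""Standalone statistics: 2x2 cross-model enrichment and the power simulation.

``overlap_enrichment`` compares the fraction of shared differentially
expressed genes between two model systems (e.g. donor organoids vs isogenic
neural stem cells vs induced neurons) as a 2x2 odds ratio with an exact test.

``simulate_setd_power`` estimates the power of a small two-group comparison
(second-hit analysis: 14 resilient vs 9 affected replicates) to detect a
fold-change effect at a Bonferroni family-wise threshold, under a normal
model with a large common standard deviation (18.5, the observed mean
expression).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import group_ols_pvalues

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    table: np.ndarray  # [[k_a, n_a - k_a], [k_b, n_b - k_b]]
    odds_ratio: float  # sample (cross-product) odds ratio
    ci_95: tuple[float, float]
    p_value: float  # two-sided Fisher exact
    ci_method: str  # "exact-conditional" or "woolf"


def overlap_enrichment(k_a: int, n_a: int, k_b: int, n_b: int) -> EnrichmentResult:
    """Odds ratio for hit rates k_a/n_a vs k_b/n_b with exact two-sided p.

    The point estimate is the sample odds ratio (a·d)/(b·c). The 95% CI uses
    the exact conditional (noncentral hypergeometric) method where defined,
    falling back to the Woolf log-normal interval; the method used is
    recorded. A zero margin leaves the estimate undefined.
    """
    for k, n in ((k_a, n_a), (k_b, n_b)):
        if not (0 <= k <= n):
            raise ValueError("need 0 <= k <= n for both conditions")
    a, b = k_a, n_a - k_a
    c, d = k_b, n_b - k_b
    table = np.array([[a, b], [c, d]], dtype=int)
    if a + c == 0 or b + d == 0 or a + b == 0 or c + d == 0:
        logger.warning("a margin of the 2x2 table is zero; estimate undefined")
        return EnrichmentResult(table, float("nan"), (float("nan"), float("nan")), float("nan"), "undefined")
    if b * c == 0:
        sample_or = float("inf") if a * d > 0 else float("nan")
    else:
        sample_or = (a * d) / (b * c)
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    try:
        res = stats.contingency.odds_ratio(table, kind="conditional")
        ci = res.confidence_interval(confidence_level=0.95)
        ci_95 = (float(ci.low), float(ci.high))
        method = "exact-conditional"
    except Exception:  # pragma: no cover - scipy failure path
        ci_95 = _woolf_ci(a, b, c, d)
        method = "woolf"
    if 0 in (a, b, c, d) and method != "exact-conditional":
        method = "exact-only-unavailable"
    return EnrichmentResult(table, float(sample_or), ci_95, p, method)


def _woolf_ci(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    log_or = np.log((a * d) / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (float(np.exp(log_or - 1.959964 * se)), float(np.exp(log_or + 1.959964 * se)))


@dataclass
class PowerGrid:
    """Estimated power per (base mean, fold change) cell."""

    power: pd.DataFrame  # index: base means; columns: fold changes
    n_sim: int
    n_case_reps: int
    n_ctrl_reps: int
    sd: float
    fwer_alpha: float  # per-test threshold after Bonferroni


DEFAULT_MEAN_GRID = (2.0, 3.0, 4.0, 5.0)
DEFAULT_FC_GRID = (1.2, 1.5, 2.0, 2.5, 3.0, 3.5)


def simulate_setd_power(
    n_case: int = 9,
    n_ctrl: int = 14,
    mean_grid: Sequence[float] = DEFAULT_MEAN_GRID,
    fc_grid: Sequence[float] = DEFAULT_FC_GRID,
    sd: float = 18.5,
    n_sim: int = 1000,
    n_genes_for_fwer: int = 9978,
    seed: int | None = None,
) -> PowerGrid:
    """Monte-Carlo power of the two-group regression test at FWER 0.05.

    Per grid cell, ``n_sim`` replicates each draw n_ctrl control values from
    Normal(mean, sd) and n_case case values from Normal(mean*fc, sd) (negative
    draws are kept; the model is the plain normal), and test the group
    difference with the pipeline's OLS group test (no covariates; equivalent
    to a pooled two-sample t-test). Power is the fraction of replicates with
    p <= 0.05 / n_genes_for_fwer.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    rng = np.random.default_rng(seed)
    alpha = 0.05 / n_genes_for_fwer
    group = np.concatenate([np.ones(n_case), np.zeros(n_ctrl)])
    grid = pd.DataFrame(index=list(mean_grid), columns=list(fc_grid), dtype=float)
    for mean in mean_grid:
        for fc in fc_grid:
            case = rng.normal(mean * fc, sd, size=(n_sim, n_case))
            ctrl = rng.normal(mean, sd, size=(n_sim, n_ctrl))
            Y = np.concatenate([case, ctrl], axis=1)  # replicates as "genes"
            _, p = group_ols_pvalues(Y, group)
            grid.loc[mean, fc] = float(np.mean(p <= alpha))
    return PowerGrid(
        power=grid,
        n_sim=n_sim,
        n_case_reps=n_case,
        n_ctrl_reps=n_ctrl,
        sd=sd,
        fwer_alpha=alpha,
    )
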