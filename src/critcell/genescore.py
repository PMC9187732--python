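"""Candidate driver-gene prioritization within a CNV locus.

Each locus gene x is scored by how strongly its co-expression partners are
differentially expressed. Connectivity is the squared Pearson correlation
r²(x, y) between gene profiles in a large reference brain compendium; the
differential-expression weights come from the case/control cohort:

    GeneScore(x) = (1 / log10 λ) · Σ_y (-log10 P_y) · r²(x, y) / Num_y

where Num_y counts the reference genes entering the sum and λ is the
genomic-control inflation factor of the run's full p-value vector (median
observed 1-df chi-square statistic over its null median). Because observed
and permuted runs contrast different pseudo-case/pseudo-control splits, each
run is normalized by its own λ. Cell-type-specific scores restrict the sum
to a cluster's specific ∪ non-specific genes. Significance uses the same
pseudo-case permutation scheme as the cluster scores; FDR thresholds are the
5th/10th percentile of the pooled per-cluster p-values for the locus.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import ExpressionMatrix, SampleSheet
from .cellscore import ClusterPartition, permutation_case_matrix, iter_permutation_pvalues
from .diffexpr import compute_pca, group_ols_pvalues

logger = logging.getLogger(__name__)

_LAMBDA_EPS = 1e-9
_CHI2_NULL_MEDIAN = stats.chi2.ppf(0.5, df=1)


@dataclass
class ConnectivityTable:
    """Squared Pearson correlations of locus genes against a reference compendium."""

    r_squared: pd.DataFrame  # locus genes x reference genes; NaN where undefined
    num_available: pd.Series  # locus gene -> count of defined correlations
    dropped_locus_genes: list[str]

    @property
    def locus_genes(self) -> list[str]:
        return list(self.r_squared.index)

    @property
    def reference_genes(self) -> list[str]:
        return list(self.r_squared.columns)


@dataclass
class GeneScoreValue:
    score: float
    lam: float
    normalized: bool  # False when λ <= 1 and the 1/log10 λ prefactor is undefined


def compute_connectivity(
    locus_genes: Sequence[str], compendium: ExpressionMatrix
) -> ConnectivityTable:
    """r² of each locus gene's compendium profile against every other gene.

    Self-correlations are excluded; locus genes absent from the compendium are
    dropped (logged); zero-variance reference genes yield undefined entries
    that do not count toward ``num_available``.
    """
    if compendium.shape[1] < 3:
        raise ValueError("compendium needs >= 3 samples")
    present = [g for g in locus_genes if g in compendium.data.index]
    dropped = [g for g in locus_genes if g not in compendium.data.index]
    if dropped:
        logger.warning("locus genes absent from compendium: %s", dropped)
    if not present:
        raise ValueError("no locus gene found in the compendium")
    X = compendium.data.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc**2).sum(axis=1))
    zero_var = norms == 0
    if zero_var.any():
        logger.warning("%d zero-variance compendium genes excluded", int(zero_var.sum()))
    loc = {g: i for i, g in enumerate(compendium.data.index)}
    locus_idx = [loc[g] for g in present]
    with np.errstate(divide="ignore", invalid="ignore"):
        num = Xc[locus_idx] @ Xc.T
        denom = norms[locus_idx][:, None] * norms[None, :]
        r = num / denom
    r2 = np.clip(r**2, 0.0, 1.0)
    r2[:, zero_var] = np.nan
    r2[norms[locus_idx] == 0, :] = np.nan
    for row, gi in enumerate(locus_idx):
        r2[row, gi] = np.nan  # exclude self
    table = pd.DataFrame(r2, index=present, columns=compendium.data.index)
    return ConnectivityTable(
        r_squared=table,
        num_available=table.notna().sum(axis=1),
        dropped_locus_genes=dropped,
    )


def genomic_control_lambda(p_values) -> float:
    """Genomic-control inflation factor λ from a p-value vector.

    p-values map to 1-df chi-square statistics through the upper tail; λ is
    the ratio of their median to the null median (≈0.4549). λ = 1 indicates a
    well-calibrated run, λ > 1 global inflation.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need >= 1 p-value")
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    observed = stats.chi2.isf(p, df=1)
    return float(np.median(observed) / _CHI2_NULL_MEDIAN)


def compute_genescore(
    x: str,
    conn: ConnectivityTable,
    p_values: pd.Series,
    gene_subset: Sequence[str] | None = None,
    lam: float | None = None,
) -> GeneScoreValue:
    """Connectivity-weighted DE score for locus gene ``x``.

    ``p_values`` is the per-gene DE p-value series of the run being scored;
    λ defaults to the genomic control of that full vector (never of the
    subset). ``gene_subset`` restricts the reference genes (cell-type scope).
    When λ <= 1 the 1/log10 λ prefactor is undefined; the unnormalized sum is
    returned flagged (normalized=False) rather than a sign-flipped score.
    """
    if x not in conn.r_squared.index:
        raise KeyError(f"locus gene {x!r} not in connectivity table")
    if lam is None:
        lam = genomic_control_lambda(p_values.to_numpy())
    weights = conn.r_squared.loc[x]
    common = weights.dropna().index.intersection(p_values.index)
    if gene_subset is not None:
        common = common.intersection(pd.Index(gene_subset))
    if len(common) == 0:
        logger.warning("gene %s: no reference gene enters the score", x)
        return GeneScoreValue(float("nan"), lam, False)
    contrib = (-np.log10(p_values.loc[common])) * weights.loc[common]
    unnormalized = float(contrib.sum() / len(common))
    if lam <= 1.0 + _LAMBDA_EPS:
        logger.warning(
            "gene %s: λ = %.4f <= 1, prefactor undefined; emitting unnormalized score",
            x,
            lam,
        )
        return GeneScoreValue(unnormalized, lam, False)
    return GeneScoreValue(unnormalized / math.log10(lam), lam, True)


def _batch_scores(
    pvals: np.ndarray,
    gene_index: pd.Index,
    conn: ConnectivityTable,
    scopes: dict[str, Sequence[str] | None],
) -> dict[str, np.ndarray]:
    """GeneScores for a (batch, genes) p-value matrix, per scope.

    Returns scope -> (batch, locus genes) array. Each batch row is normalized
    by its own λ (computed on the full p vector); rows with λ <= 1 fall back
    to the unnormalized score, mirroring :func:`compute_genescore`.
    """
    neglogp = -np.log10(pvals)
    lam = np.array([genomic_control_lambda(row) for row in pvals])
    with np.errstate(divide="ignore"):
        prefactor = np.where(lam > 1.0 + _LAMBDA_EPS, 1.0 / np.log10(lam), 1.0)
    out: dict[str, np.ndarray] = {}
    for scope, subset in scopes.items():
        cols = conn.r_squared.columns.intersection(gene_index)
        if subset is not None:
            cols = cols.intersection(pd.Index(subset))
        if len(cols) == 0:
            out[scope] = np.full((pvals.shape[0], len(conn.locus_genes)), np.nan)
            continue
        W = conn.r_squared[cols].to_numpy(dtype=float)  # locus x refs (NaN allowed)
        mask = np.isfinite(W)
        W0 = np.where(mask, W, 0.0)
        col_pos = [gene_index.get_loc(c) for c in cols]
        nl = neglogp[:, col_pos]  # batch x refs
        sums = nl @ W0.T  # batch x locus
        counts = mask.sum(axis=1)  # per locus gene
        with np.errstate(divide="ignore", invalid="ignore"):
            scores = sums / counts[None, :]
        scores[:, counts == 0] = np.nan
        out[scope] = scores * prefactor[:, None]
    out["__lambda__"] = lam
    return out


def genescore_permutation_pvalues(
    m: ExpressionMatrix,
    sheet: SampleSheet,
    conn: ConnectivityTable,
    clusters: Sequence[ClusterPartition] | None = None,
    n_perm: int = 100_000,
    seed: int | None = None,
    enumerate_when_possible: bool = True,
) -> pd.DataFrame:
    """Observed and permutation-tested GeneScores per locus gene and scope.

    Scopes are "all" (every reference gene) plus one per supplied cluster
    partition (the cluster's specific ∪ non-specific genes). Each permutation
    refits the per-gene regressions (PC1 covariate, computed once), recomputes
    its own λ, then scores. Returns a table indexed by (gene, scope) with the
    observed score, λ of the observed run, one-sided empirical p and floor
    flag.
    """
    pc1 = compute_pca(m, n_components=1).pc1[:, None]
    group = sheet.group_indicator(m.col_ids)
    Y = m.data.to_numpy(dtype=float)
    _, p_obs = group_ols_pvalues(Y, group, pc1)

    scopes: dict[str, Sequence[str] | None] = {"all": None}
    if clusters is not None:
        for part in clusters:
            scopes[part.cluster_id] = part.all_genes

    obs = _batch_scores(p_obs[None, :], m.data.index, conn, scopes)
    lam_obs = float(obs.pop("__lambda__")[0])

    case_mat, enumerated = permutation_case_matrix(
        sheet, m.col_ids, n_perm, seed, enumerate_when_possible
    )
    P = case_mat.shape[0]
    exceed = {s: np.zeros(len(conn.locus_genes)) for s in scopes}
    for start, pvals in iter_permutation_pvalues(Y, case_mat, pc1):
        null = _batch_scores(pvals, m.data.index, conn, scopes)
        null.pop("__lambda__")
        for s in scopes:
            with np.errstate(invalid="ignore"):
                exceed[s] += np.nansum(null[s] >= obs[s][0][None, :], axis=0)

    rows = []
    for s in scopes:
        for j, g in enumerate(conn.locus_genes):
            score = float(obs[s][0][j])
            if np.isnan(score):
                rows.append((g, s, score, lam_obs, float("nan"), False, P))
                continue
            count = int(exceed[s][j])
            at_floor = count == 0
            p = (1.0 / P) if at_floor else count / P
            rows.append((g, s, score, lam_obs, p, at_floor, P))
    table = pd.DataFrame(
        rows,
        columns=["gene", "scope", "score", "lambda", "p_empirical", "at_floor", "n_permutations"],
    ).set_index(["gene", "scope"])
    table.attrs["enumerated"] = enumerated
    return table


def percentile_fdr_thresholds(
    pooled_p, percentiles: Sequence[float] = (5, 10)
) -> dict[float, float]:
    """Nearest-rank (lower) percentile p thresholds over pooled cluster p-values.

    The q-th percentile of n sorted p-values is the ceil(n·q/100)-th smallest;
    it is undefined (NaN) when n·q/100 < 1 (too few values to resolve the
    tail). Genes with p at or below the q-th percentile threshold are called
    at FDR q/100.
    """
    p = np.sort(np.asarray(pooled_p, dtype=float))
    out: dict[float, float] = {}
    for q in percentiles:
        k = math.ceil(len(p) * q / 100.0)
        if len(p) * q / 100.0 < 1:
            logger.warning("%d pooled values too few for the %gth percentile", len(p), q)
            out[q / 100.0] = float("nan")
        else:
            out[q / 100.0] = float(p[k - 1])
    return out
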