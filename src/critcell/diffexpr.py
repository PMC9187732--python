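"""Per-gene differential expression by ordinary least squares.

Expression (inverse-normal transformed) is regressed on a case/control
indicator plus covariates — by default the first principal component of the
normalized matrix, which acts as a surrogate for shared technical factors.
All replicates are treated as independent samples. The group coefficient's
two-sided t-test p-value weights every downstream cluster and driver score,
so the OLS is implemented in closed form and vectorized over genes and over
permuted label vectors; a permutation null re-uses the same code path with a
stack of group indicators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .dataio import ExpressionMatrix, SampleSheet

logger = logging.getLogger(__name__)

_ZERO_RESID_TOL = 1e-12


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    variance_fractions: np.ndarray

    @property
    def pc1(self) -> np.ndarray:
        return self.scores.iloc[:, 0].to_numpy()


def compute_pca(m: ExpressionMatrix, n_components: int | None = None) -> PCAResult:
    """PCA with samples as observations and genes as (centered) features.

    PC1 is oriented so the sum of its gene loadings is non-negative; the same
    convention is applied to every returned component so scores are
    reproducible across platforms.
    """
    X = m.data.to_numpy(dtype=float).T  # samples x genes
    n_samples, n_genes = X.shape
    if n_samples < 2:
        raise ValueError("PCA requires >= 2 samples")
    max_comp = min(n_samples - 1, n_genes)
    k = max_comp if n_components is None else min(n_components, max_comp)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    flip = np.where(pca.components_.sum(axis=1) < 0, -1.0, 1.0)
    scores = scores * flip
    cols = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=m.data.columns, columns=cols),
        variance_fractions=pca.explained_variance_ratio_.copy(),
    )


def group_ols_pvalues(
    Y: np.ndarray,
    groups: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form OLS t-test of the group coefficient, batched.

    Parameters
    ----------
    Y : (n_genes, n_samples) response matrix.
    groups : (n_samples,) or (n_batch, n_samples) 0/1 case indicator(s).
    covariates : optional (n_samples, n_cov) design columns shared by all
        batches (an intercept is always included).

    Returns
    -------
    betas, pvalues : arrays of shape (n_batch, n_genes); the batch axis is
    squeezed away when ``groups`` was one-dimensional.
    """
    Y = np.asarray(Y, dtype=float)
    groups = np.asarray(groups, dtype=float)
    squeeze = groups.ndim == 1
    if squeeze:
        groups = groups[None, :]
    P, n = groups.shape
    G = Y.shape[0]
    cov = np.empty((n, 0)) if covariates is None else np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    k = 2 + cov.shape[1]
    if n <= k:
        raise ValueError(f"need more samples ({n}) than design columns ({k})")

    ones = np.ones(n)
    X = np.empty((P, n, k))
    X[:, :, 0] = ones
    X[:, :, 1] = groups
    X[:, :, 2:] = cov[None, :, :]

    XtX = np.einsum("pni,pnj->pij", X, X)
    if np.linalg.matrix_rank(X[0]) < k or np.any(np.linalg.cond(XtX) > 1e12):
        raise ValueError(_collinearity_message(X[0]))
    XtX_inv = np.linalg.inv(XtX)

    XtY = np.einsum("pnk,gn->pkg", X, Y)  # (P, k, G)
    B = np.einsum("pij,pjg->pgi", XtX_inv, XtY)  # (P, G, k)
    yy = np.einsum("gn,gn->g", Y, Y)
    quad = np.einsum("pgi,pij,pgj->pg", B, XtX, B)
    rss = np.maximum(yy[None, :] - quad, 0.0)
    dof = n - k
    sigma2 = rss / dof
    var_beta = sigma2 * XtX_inv[:, 1, 1][:, None]
    beta = B[:, :, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / np.sqrt(var_beta)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)
    scale = np.maximum(yy[None, :] / max(n, 1), 1.0)
    degenerate = sigma2 <= _ZERO_RESID_TOL * scale
    if degenerate.any():
        logger.warning("%d gene fits had ~zero residual variance; p set to 1", int(degenerate.sum()))
        pvals = np.where(degenerate, 1.0, pvals)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    if squeeze:
        return beta[0], pvals[0]
    return beta, pvals


def _collinearity_message(X: np.ndarray) -> str:
    """Name the design columns whose removal restores full rank."""
    k = X.shape[1]
    names = ["intercept", "group"] + [f"covariate_{j}" for j in range(k - 2)]
    culprits = [
        names[j]
        for j in range(k)
        if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == min(X.shape[0], k - 1)
        and np.linalg.cond(np.delete(X, j, axis=1).T @ np.delete(X, j, axis=1)) < 1e12
    ]
    return f"design matrix is collinear; offending columns: {culprits or names}"


def adjust_bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compute_fold_changes(raw: ExpressionMatrix, sheet: SampleSheet) -> pd.Series:
    """Per-gene case-mean / control-mean fold change on raw (pre-normalization) FPKM."""
    cases = [s for s in sheet.case_samples if s in raw.data.columns]
    controls = [s for s in sheet.control_samples if s in raw.data.columns]
    if not cases or not controls:
        raise ValueError("both groups must be non-empty")
    case_mean = raw.data[cases].mean(axis=1)
    ctrl_mean = raw.data[controls].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = case_mean / ctrl_mean
    undefined = ctrl_mean == 0
    if undefined.any():
        logger.warning("%d genes have zero control mean; fold change undefined", int(undefined.sum()))
        fc[undefined] = np.nan
    return fc


def fit_differential_expression(
    m: ExpressionMatrix,
    sheet: SampleSheet,
    covariates: np.ndarray | None = None,
    raw: ExpressionMatrix | None = None,
) -> pd.DataFrame:
    """Per-gene OLS differential expression table.

    ``m`` should be the normalized matrix; ``covariates`` is an
    (n_samples, n_cov) array aligned to the matrix columns (typically PC1).
    When ``raw`` is given, dosage-scale fold changes (case mean FPKM / control
    mean FPKM) are attached; they are deliberately computed on raw FPKM, not
    normalized values.
    """
    group = sheet.group_indicator(m.col_ids)
    if group.sum() == 0 or group.sum() == len(group):
        raise ValueError("need both case and control samples")
    beta, p = group_ols_pvalues(m.data.to_numpy(dtype=float), group, covariates)
    table = pd.DataFrame(
        {
            "beta": beta,
            "p_value": p,
            "q_value": adjust_bh_fdr(p),
            "n_case": int(group.sum()),
            "n_control": int(len(group) - group.sum()),
        },
        index=m.data.index,
    )
    if raw is not None:
        table["fold_change"] = compute_fold_changes(raw, sheet).reindex(table.index)
    else:
        table["fold_change"] = np.nan
    return table
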