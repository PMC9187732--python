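"""Critical-cell-type scoring from bulk differential expression.

For each single-cell cluster gene set, CellScore contrasts the mean
-log10(DE p-value) over the cluster's cell-type-specific genes (genes found
in that cluster only) against the same mean over its non-specific genes
(genes shared with other clusters):

    CellScore = mean_{specific y}(-log10 P_y) - mean_{non-specific y}(-log10 P_y)

Significance comes from a pseudo-case permutation null: permuted "cases" are
drawn without replacement from the true controls only, the true cases joining
the remaining controls as pseudo-controls, so every null cohort is free of
the real case signal while keeping the observed design size. Per permutation
the per-gene regressions are refit (with PC1 as covariate; PC1 is computed
once — relabeling does not change expression, hence not its principal
components) and the cluster scores recomputed. The empirical p is the
one-sided proportion of null scores at or above the observed score, reported
as the bound 1/N when no null score reaches it. Cluster significance uses
Bonferroni family-wise thresholds (e.g. 0.05/10 clusters = 0.005).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .dataio import ExpressionMatrix, GeneSetCollection, SampleSheet
from .diffexpr import compute_pca, group_ols_pvalues

logger = logging.getLogger(__name__)

_PERM_CHUNK = 256


# ---------------------------------------------------------------------------
# Cluster gene partition
# ---------------------------------------------------------------------------


@dataclass
class ClusterPartition:
    """A cluster's genes split into cell-type-specific vs shared."""

    cluster_id: str
    specific_genes: list[str]
    nonspecific_genes: list[str]

    @property
    def all_genes(self) -> list[str]:
        return self.specific_genes + self.nonspecific_genes


def partition_cluster_genes(clusters: GeneSetCollection) -> list[ClusterPartition]:
    """Split each cluster into specific (unique to it) and non-specific genes.

    Genes absent from the expression universe are retained here; they drop out
    at scoring time when intersected with the DE table (with the denominators
    adjusted accordingly).
    """
    if len(clusters) == 0:
        raise ValueError("need >= 1 cluster")
    membership: dict[str, int] = {}
    for _, genes in clusters.items():
        for g in set(genes):
            membership[g] = membership.get(g, 0) + 1
    out = []
    for name, genes in clusters.items():
        specific = [g for g in genes if membership[g] == 1]
        nonspecific = [g for g in genes if membership[g] > 1]
        out.append(ClusterPartition(name, specific, nonspecific))
    return out


# ---------------------------------------------------------------------------
# Score
# ---------------------------------------------------------------------------


def compute_cellscore(p_values: pd.Series, part: ClusterPartition) -> float:
    """CellScore from per-gene DE p-values for one cluster partition.

    Only genes present in ``p_values`` enter each mean; if either side has no
    gene in the table the score is undefined (NaN, warned).
    """
    spec = p_values.reindex(part.specific_genes).dropna()
    nonspec = p_values.reindex(part.nonspecific_genes).dropna()
    if len(spec) < len(part.specific_genes) or len(nonspec) < len(part.nonspecific_genes):
        logger.info(
            "cluster %s: %d/%d specific and %d/%d non-specific genes in DE table",
            part.cluster_id,
            len(spec),
            len(part.specific_genes),
            len(nonspec),
            len(part.nonspecific_genes),
        )
    if len(spec) == 0 or len(nonspec) == 0:
        logger.warning("cluster %s: empty specific or non-specific side; score undefined", part.cluster_id)
        return float("nan")
    return float((-np.log10(spec)).mean() - (-np.log10(nonspec)).mean())


def _scores_from_pmatrix(
    neglogp: np.ndarray, gene_index: pd.Index, parts: Sequence[ClusterPartition]
) -> np.ndarray:
    """Cluster scores for a (batch, genes) matrix of -log10 p. Returns (batch, clusters)."""
    loc = {g: i for i, g in enumerate(gene_index)}
    out = np.full((neglogp.shape[0], len(parts)), np.nan)
    for j, part in enumerate(parts):
        si = [loc[g] for g in part.specific_genes if g in loc]
        ni = [loc[g] for g in part.nonspecific_genes if g in loc]
        if not si or not ni:
            continue
        out[:, j] = neglogp[:, si].mean(axis=1) - neglogp[:, ni].mean(axis=1)
    return out


# ---------------------------------------------------------------------------
# Pseudo-case permutations
# ---------------------------------------------------------------------------


@dataclass
class PermutationNull:
    """A cluster's null score multiset under the pseudo-case scheme."""

    unit_id: str
    null_scores: np.ndarray
    n_permutations: int
    n_pseudo_cases: int
    control_pool: list[str]
    seed: int | None
    enumerated: bool = False


def draw_permutation(sheet: SampleSheet, rng: np.random.Generator) -> pd.Series:
    """One pseudo-case relabeling: n_case samples drawn from the controls.

    Returns a sample_id -> {case, control} series with the observed label
    counts; all true cases become pseudo-controls.
    """
    cases = sheet.case_samples
    controls = sheet.control_samples
    if len(controls) < len(cases):
        raise ValueError(
            "pseudo-case scheme inapplicable: fewer controls "
            f"({len(controls)}) than cases ({len(cases)})"
        )
    pseudo_cases = set(rng.choice(controls, size=len(cases), replace=False))
    labels = {
        s: ("case" if s in pseudo_cases else "control") for s in sheet.sample_ids
    }
    return pd.Series(labels, name="group")


def permutation_case_matrix(
    sheet: SampleSheet,
    sample_order: Sequence[str],
    n_perm: int,
    seed: int | None,
    enumerate_when_possible: bool = True,
) -> tuple[np.ndarray, bool]:
    """Stack of pseudo-case indicators aligned to ``sample_order``.

    When the number of distinct pseudo-case assignments C(n_controls, n_cases)
    does not exceed ``n_perm``, the full set is enumerated exactly once each;
    otherwise assignments are sampled uniformly without replacement within
    each draw. Returns (matrix of shape (P, n_samples), enumerated flag).
    """
    cases = sheet.case_samples
    controls = sheet.control_samples
    if len(controls) < len(cases):
        raise ValueError(
            "pseudo-case scheme inapplicable: fewer controls "
            f"({len(controls)}) than cases ({len(cases)})"
        )
    pos = {s: i for i, s in enumerate(sample_order)}
    ctrl_idx = [pos[s] for s in controls]
    n_case = len(cases)
    total = math.comb(len(controls), n_case)
    if enumerate_when_possible and total <= n_perm:
        combos = itertools.combinations(ctrl_idx, n_case)
        mat = np.zeros((total, len(sample_order)))
        for r, combo in enumerate(combos):
            mat[r, list(combo)] = 1.0
        return mat, True
    rng = np.random.default_rng(seed)
    # vectorized without-replacement draws: first n_case of a random ordering
    order = np.argsort(rng.random((n_perm, len(ctrl_idx))), axis=1)[:, :n_case]
    chosen = np.asarray(ctrl_idx)[order]
    mat = np.zeros((n_perm, len(sample_order)))
    np.put_along_axis(mat, chosen, 1.0, axis=1)
    return mat, False


def iter_permutation_pvalues(
    Y: np.ndarray,
    case_matrix: np.ndarray,
    covariates: np.ndarray | None,
    chunk: int = _PERM_CHUNK,
) -> Iterable[tuple[int, np.ndarray]]:
    """Yield (offset, p-value block) for chunks of permuted label vectors."""
    for start in range(0, case_matrix.shape[0], chunk):
        block = case_matrix[start : start + chunk]
        _, pvals = group_ols_pvalues(Y, block, covariates)
        yield start, pvals


def build_null_distributions(
    m: ExpressionMatrix,
    sheet: SampleSheet,
    parts: Sequence[ClusterPartition],
    n_perm: int,
    seed: int | None = None,
    enumerate_when_possible: bool = True,
    covariates: np.ndarray | None = None,
) -> dict[str, PermutationNull]:
    """Null CellScore multisets for all clusters from one shared label stream.

    All clusters see the same permuted label draws (cross-cluster
    comparability). ``covariates`` defaults to PC1 of ``m``, computed once and
    reused across permutations.
    """
    if covariates is None:
        covariates = compute_pca(m, n_components=1).pc1[:, None]
    case_mat, enumerated = permutation_case_matrix(
        sheet, m.col_ids, n_perm, seed, enumerate_when_possible
    )
    Y = m.data.to_numpy(dtype=float)
    P = case_mat.shape[0]
    scores = np.empty((P, len(parts)))
    for start, pvals in iter_permutation_pvalues(Y, case_mat, covariates):
        neglogp = -np.log10(pvals)
        scores[start : start + pvals.shape[0]] = _scores_from_pmatrix(
            neglogp, m.data.index, parts
        )
    controls = sheet.control_samples
    return {
        part.cluster_id: PermutationNull(
            unit_id=part.cluster_id,
            null_scores=scores[:, j].copy(),
            n_permutations=P,
            n_pseudo_cases=len(sheet.case_samples),
            control_pool=controls,
            seed=seed,
            enumerated=enumerated,
        )
        for j, part in enumerate(parts)
    }


def build_null_distribution(
    m: ExpressionMatrix,
    sheet: SampleSheet,
    part: ClusterPartition,
    n_perm: int,
    seed: int | None = None,
    **kwargs,
) -> PermutationNull:
    """Single-cluster convenience wrapper around :func:`build_null_distributions`."""
    return build_null_distributions(m, sheet, [part], n_perm, seed, **kwargs)[part.cluster_id]


# ---------------------------------------------------------------------------
# Empirical p, FWER, cross-dataset combination
# ---------------------------------------------------------------------------


@dataclass
class ScoreResult:
    """Observed score with its permutation p-value and threshold flags."""

    unit_id: str
    score: float
    p_empirical: float
    at_floor: bool
    n_permutations: int
    fwer_flags: dict[float, bool] = field(default_factory=dict)

    def to_record(self) -> dict[str, object]:
        rec: dict[str, object] = {
            "unit_id": self.unit_id,
            "score": self.score,
            "p_empirical": self.p_empirical,
            "at_floor": self.at_floor,
            "n_permutations": self.n_permutations,
        }
        for level, flag in sorted(self.fwer_flags.items()):
            rec[f"fwer_{level:g}"] = flag
        return rec


def empirical_pvalue(observed: float, null: PermutationNull) -> tuple[float, bool]:
    """One-sided empirical p: proportion of null scores >= observed.

    Larger scores indicate perturbation. When no null score reaches the
    observed value the p-value is at the permutation floor and is reported as
    the bound 1/N (at_floor=True, to be rendered as "<1/N").
    """
    if null.n_permutations == 0:
        raise ValueError("empty null distribution")
    count = int(np.sum(null.null_scores >= observed))
    if count == 0:
        return 1.0 / null.n_permutations, True
    return count / null.n_permutations, False


def fwer_threshold(n_tests: int, level: float) -> float:
    """Bonferroni per-test p threshold controlling FWER at ``level``."""
    if n_tests < 1 or not (0 < level < 1):
        raise ValueError("need n_tests >= 1 and level in (0, 1)")
    return level / n_tests


class CombinedP(NamedTuple):
    neg_log10_p: float
    p: float  # convenience back-transform, 10**(-neg_log10_p)


def combine_dataset_pvalues(
    score_a: float, p_a: float, score_b: float, p_b: float
) -> CombinedP:
    """Score-weighted average of two datasets' -log10 p for one cluster.

    Weights are |score_a| and |score_b| normalized to sum to one, applied to
    -log10 p_a and -log10 p_b (e.g. organoid and post-mortem cohorts). Both
    scales are returned; the -log10 value is primary.
    """
    if not (0 < p_a <= 1 and 0 < p_b <= 1):
        raise ValueError("p-values must lie in (0, 1]")
    wa, wb = abs(score_a), abs(score_b)
    if wa + wb == 0:
        logger.warning("both scores zero; combined p undefined")
        return CombinedP(float("nan"), float("nan"))
    wa, wb = wa / (wa + wb), wb / (wa + wb)
    value = wa * (-math.log10(p_a)) + wb * (-math.log10(p_b))
    return CombinedP(value, 10.0 ** (-value))


# ---------------------------------------------------------------------------
# Cluster de-duplication and atlas fine-mapping
# ---------------------------------------------------------------------------


def pairwise_overlap_matrix(sets: GeneSetCollection) -> pd.DataFrame:
    """Directional overlap percentages: entry (A, B) = 100 * |A ∩ B| / |A|."""
    if len(sets) < 2:
        raise ValueError("need >= 2 sets")
    names = sets.names
    members = {n: set(sets.genes(n)) for n in names}
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for a in names:
        if not members[a]:
            logger.warning("set %s is empty; overlap row undefined", a)
            continue
        for b in names:
            out.loc[a, b] = 100.0 * len(members[a] & members[b]) / len(members[a])
    return out


def deduplicate_clusters(overlaps: pd.DataFrame, threshold: float = 50.0) -> list[list[str]]:
    """Group clusters whose overlap (either direction) reaches ``threshold``.

    Groups are connected components of the overlap graph, so chains of
    pairwise-redundant clusters merge transitively into one unique cluster.
    """
    if not (0 < threshold <= 100):
        raise ValueError("threshold must lie in (0, 100]")
    names = list(overlaps.index)
    g = nx.Graph()
    g.add_nodes_from(names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ab, ba = overlaps.loc[a, b], overlaps.loc[b, a]
            if (np.isfinite(ab) and ab >= threshold) or (np.isfinite(ba) and ba >= threshold):
                g.add_edge(a, b)
    components = [sorted(c, key=names.index) for c in nx.connected_components(g)]
    components.sort(key=lambda c: names.index(c[0]))
    return components


def merge_cluster_groups(
    sets: GeneSetCollection, groups: list[list[str]]
) -> GeneSetCollection:
    """Union the gene sets of each de-duplicated cluster group."""
    merged: dict[str, tuple[str, list[str]]] = {}
    for members in groups:
        union: list[str] = []
        seen: set[str] = set()
        for name in members:
            for gene in sets.genes(name):
                if gene not in seen:
                    union.append(gene)
                    seen.add(gene)
        merged["+".join(members)] = (f"union of {len(members)} clusters", union)
    return GeneSetCollection(merged)


def atlas_overlap_profile(
    cluster_genes: Sequence[str], atlas: GeneSetCollection
) -> pd.Series:
    """Mean directional overlap of one cluster against each atlas cell type."""
    if len(atlas) == 0:
        raise ValueError("atlas is empty")
    cluster = set(cluster_genes)
    out = {}
    for name, genes in atlas.items():
        ref = set(genes)
        if not cluster or not ref:
            out[name] = float("nan")
            continue
        fwd = 100.0 * len(cluster & ref) / len(cluster)
        rev = 100.0 * len(cluster & ref) / len(ref)
        out[name] = 0.5 * (fwd + rev)
    return pd.Series(out)


def profile_correlation(profile_a: pd.Series, profile_b: pd.Series) -> tuple[float, float]:
    """Pearson r (and two-sided p) between two atlas overlap profiles."""
    if not profile_a.index.equals(profile_b.index):
        raise ValueError("profiles must share the identical atlas")
    if len(profile_a) < 3:
        raise ValueError("need profiles of length >= 3")
    a = profile_a.to_numpy(dtype=float)
    b = profile_b.to_numpy(dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        logger.warning("zero-variance profile; correlation undefined")
        return float("nan"), float("nan")
    r = stats.pearsonr(a, b)
    return float(r.statistic), float(r.pvalue)


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------


def score_clusters(
    m: ExpressionMatrix,
    sheet: SampleSheet,
    clusters: GeneSetCollection,
    n_perm: int = 100_000,
    seed: int | None = None,
    fwer_levels: Sequence[float] = (0.05, 0.1),
    enumerate_when_possible: bool = True,
) -> list[ScoreResult]:
    """Observed CellScores, permutation p-values and FWER flags per cluster.

    ``m`` must be the QC'd, inverse-normal-transformed matrix. The FWER flags
    compare each cluster's empirical p against Bonferroni thresholds over the
    number of scored clusters.
    """
    parts = partition_cluster_genes(clusters)
    pc1 = compute_pca(m, n_components=1).pc1[:, None]
    group = sheet.group_indicator(m.col_ids)
    _, p_obs = group_ols_pvalues(m.data.to_numpy(dtype=float), group, pc1)
    observed = _scores_from_pmatrix(
        -np.log10(p_obs)[None, :], m.data.index, parts
    )[0]
    nulls = build_null_distributions(
        m, sheet, parts, n_perm, seed, enumerate_when_possible, covariates=pc1
    )
    thresholds = {lvl: fwer_threshold(len(parts), lvl) for lvl in fwer_levels}
    results = []
    for j, part in enumerate(parts):
        score = observed[j]
        if np.isnan(score):
            results.append(
                ScoreResult(part.cluster_id, score, float("nan"), False, n_perm, {})
            )
            continue
        null = nulls[part.cluster_id]
        p, at_floor = empirical_pvalue(score, null)
        flags = {lvl: bool(p <= thr) for lvl, thr in thresholds.items()}
        results.append(
            ScoreResult(part.cluster_id, float(score), p, at_floor, null.n_permutations, flags)
        )
    return results
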