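"""Synthetic cohorts, cluster gene sets and reference compendia.

All generators plant recorded ground truth (locus dosage fold changes,
cluster-specific case perturbations, correlated reference blocks, donor
effects), so every pipeline stage can be tested against known expected
outcomes without external data. Default shapes mirror the study cohort this
framework was built for: 12 control donors versus 9 case donors with 1-3
replicates each, ~10k genes, a 22-gene CNV locus with a hemizygous-deletion
dosage fold change of 0.5, and 10 single-cell clusters.

Expression follows a log-normal model: log2 FPKM = gene baseline + donor
random effect + low-rank hidden sample factors + replicate noise,
exponentiated to the FPKM scale. Additive donor effects on the log scale
produce the intra-donor > inter-donor replicate-correlation structure seen
in real organoid cohorts; the hidden factors emulate the dominant-component
plus residual-component sample structure of real bulk data. Because case
and control replicate-noise distributions are identical, the expected
FPKM-scale group fold change of a locus gene equals the planted dosage
factor exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cellscore import ClusterPartition
from .dataio import ExpressionMatrix, GeneSetCollection, SampleSheet

logger = logging.getLogger(__name__)


@dataclass
class TruthRecord:
    """Planted ground truth sufficient to recompute expected outcomes."""

    seed: int
    locus_genes: list[str] = field(default_factory=list)
    dosage_fc: float = 1.0
    perturbed_genes: list[str] = field(default_factory=list)
    perturbed_effect: float = 0.0  # additive log2 shift in case samples
    perturbed_cluster: str | None = None
    driver_gene: str | None = None
    driver_block: list[str] = field(default_factory=list)
    donor_sd: float = 0.4
    noise_sd: float = 0.25
    factor_sds: tuple[float, ...] = (1.0, 0.35, 0.35)

    def to_dict(self) -> dict[str, object]:
        return {
            "seed": self.seed,
            "locus_genes": self.locus_genes,
            "dosage_fc": self.dosage_fc,
            "perturbed_genes": self.perturbed_genes,
            "perturbed_effect": self.perturbed_effect,
            "perturbed_cluster": self.perturbed_cluster,
            "driver_gene": self.driver_gene,
            "driver_block": self.driver_block,
            "donor_sd": self.donor_sd,
            "noise_sd": self.noise_sd,
            "factor_sds": list(self.factor_sds),
        }


def gene_names(n: int, locus_size: int = 0) -> list[str]:
    """Gene namespace: LOC genes (the CNV locus) first, then background genes."""
    locus = [f"LOC{i:03d}" for i in range(locus_size)]
    rest = [f"G{i:05d}" for i in range(n - locus_size)]
    return locus + rest


def generate_cohort(
    n_case_donors: int = 9,
    n_ctrl_donors: int = 12,
    reps_per_donor: int | tuple[int, int] = (1, 3),
    n_genes: int = 9978,
    locus_size: int = 22,
    dosage_fc: float = 0.5,
    perturbed_genes: list[str] | None = None,
    perturbed_effect: float = 0.0,
    perturbed_cluster: str | None = None,
    donor_sd: float = 0.4,
    noise_sd: float = 0.25,
    baseline_mean: float = 2.5,
    baseline_sd: float = 1.5,
    factor_sds: tuple[float, ...] = (1.0, 0.35, 0.35),
    seed: int = 0,
) -> tuple[ExpressionMatrix, SampleSheet, TruthRecord]:
    """Simulate a case/control organoid cohort with planted locus dosage.

    Locus genes (the first ``locus_size`` rows, named LOC###) are multiplied
    by ``dosage_fc`` in case donors (0.5 emulates a hemizygous deletion, 1.5 a
    duplication). ``perturbed_genes`` receive an additive ``perturbed_effect``
    log2 shift in case samples (a cluster-specific transcriptomic response).
    ``reps_per_donor`` may be a fixed count or an inclusive (lo, hi) range.

    ``factor_sds`` adds group-independent low-rank sample structure: each
    hidden factor contributes loading_gene x factor_sample to log2 expression,
    with per-sample factor values of the given SDs. The default emulates real
    bulk cohorts, where one dominant component (absorbed by the PC1 covariate
    downstream) plus weaker residual components drive shared variation; the
    residual components keep each contrast's genomic-control inflation away
    from the degenerate λ = 1 regime, as in real data.
    """
    if locus_size > n_genes:
        raise ValueError("locus_size cannot exceed n_genes")
    if dosage_fc <= 0:
        raise ValueError("dosage_fc must be positive")
    if min(n_case_donors, n_ctrl_donors) < 1:
        raise ValueError("need >= 1 donor per group")
    rng = np.random.default_rng(seed)
    genes = gene_names(n_genes, locus_size)
    locus = genes[:locus_size]
    perturbed = list(perturbed_genes or [])
    missing = [g for g in perturbed if g not in genes]
    if missing:
        raise ValueError(f"perturbed genes not in the gene namespace: {missing[:5]}")

    donors = [f"CASE{i:02d}" for i in range(n_case_donors)] + [
        f"CTRL{i:02d}" for i in range(n_ctrl_donors)
    ]
    groups = ["case"] * n_case_donors + ["control"] * n_ctrl_donors
    if isinstance(reps_per_donor, tuple):
        lo, hi = reps_per_donor
        reps = rng.integers(lo, hi + 1, size=len(donors))
    else:
        reps = np.full(len(donors), int(reps_per_donor))

    baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    donor_effects = rng.normal(0.0, donor_sd, size=(len(donors), n_genes))
    n_factors = len(factor_sds)
    # bounded loadings: coherent PC-like gene programs without the heavy
    # multiplicative tails unbounded loadings would put on FPKM-scale means
    loadings = rng.uniform(-1.0, 1.0, size=(n_genes, n_factors))

    gene_pos = {g: i for i, g in enumerate(genes)}
    locus_idx = np.array([gene_pos[g] for g in locus], dtype=int)
    pert_idx = np.array([gene_pos[g] for g in perturbed], dtype=int)

    columns: dict[str, np.ndarray] = {}
    records = []
    for di, (donor, group) in enumerate(zip(donors, groups)):
        shift = np.zeros(n_genes)
        if group == "case":
            if locus_size:
                shift[locus_idx] += np.log2(dosage_fc)
            if len(pert_idx):
                shift[pert_idx] += perturbed_effect
        for r in range(int(reps[di])):
            noise = rng.normal(0.0, noise_sd, size=n_genes)
            factors = rng.normal(0.0, np.asarray(factor_sds)) if n_factors else np.zeros(0)
            log2fpkm = baseline + donor_effects[di] + shift + noise + loadings @ factors
            sample_id = f"{donor}_r{r + 1}"
            columns[sample_id] = np.exp2(log2fpkm)
            records.append(
                {
                    "sample_id": sample_id,
                    "donor_id": donor,
                    "replicate_index": r + 1,
                    "group": group,
                }
            )
    matrix = ExpressionMatrix(pd.DataFrame(columns, index=genes))
    sheet = SampleSheet(pd.DataFrame(records))
    truth = TruthRecord(
        seed=seed,
        locus_genes=locus,
        dosage_fc=dosage_fc,
        perturbed_genes=perturbed,
        perturbed_effect=perturbed_effect,
        perturbed_cluster=perturbed_cluster,
        donor_sd=donor_sd,
        noise_sd=noise_sd,
        factor_sds=tuple(factor_sds),
    )
    return matrix, sheet, truth


def generate_cluster_sets(
    n_clusters: int = 10,
    specific_per_cluster: int | tuple[int, int] = (47, 266),
    shared_pool: int = 150,
    shared_per_gene: tuple[int, int] = (2, 3),
    gene_pool: list[str] | None = None,
    seed: int = 0,
) -> tuple[GeneSetCollection, list[ClusterPartition]]:
    """Cluster gene sets with known specific/non-specific structure.

    Each cluster receives its own unique specific genes (count drawn from
    ``specific_per_cluster`` when a range); every shared-pool gene is assigned
    to 2-3 distinct clusters by construction, so the expected partition is
    known exactly and is returned alongside the collection. When ``gene_pool``
    is given, all set members are drawn (disjointly) from it — use the cohort
    gene namespace so cluster genes exist in the expression matrix.
    """
    if n_clusters < 1:
        raise ValueError("need >= 1 cluster")
    rng = np.random.default_rng(seed)
    if isinstance(specific_per_cluster, tuple):
        lo, hi = specific_per_cluster
        spec_counts = rng.integers(lo, hi + 1, size=n_clusters)
    else:
        spec_counts = np.full(n_clusters, int(specific_per_cluster))
    total_needed = int(spec_counts.sum()) + shared_pool
    if gene_pool is not None:
        if len(gene_pool) < total_needed:
            raise ValueError(
                f"gene pool exhausted: need {total_needed}, have {len(gene_pool)}"
            )
        chosen = list(rng.choice(gene_pool, size=total_needed, replace=False))
    else:
        chosen = [f"CLG{i:05d}" for i in range(total_needed)]

    names = [f"c{i + 1}" for i in range(n_clusters)]
    cursor = 0
    specific: dict[str, list[str]] = {}
    for name, count in zip(names, spec_counts):
        specific[name] = chosen[cursor : cursor + int(count)]
        cursor += int(count)
    shared_genes = chosen[cursor:]

    shared: dict[str, list[str]] = {name: [] for name in names}
    assignment: dict[str, list[str]] = {}
    for g in shared_genes:
        k = int(rng.integers(shared_per_gene[0], min(shared_per_gene[1], n_clusters) + 1))
        if n_clusters < 2:
            raise ValueError("shared genes require >= 2 clusters")
        targets = rng.choice(names, size=max(k, 2), replace=False)
        assignment[g] = list(targets)
        for t in targets:
            shared[t].append(g)

    sets = {
        name: (f"synthetic cluster {name}", specific[name] + shared[name])
        for name in names
    }
    parts = [
        ClusterPartition(name, list(specific[name]), list(shared[name]))
        for name in names
    ]
    return GeneSetCollection(sets), parts


def generate_reference_compendium(
    gene_ids: list[str],
    n_samples: int = 200,
    blocks: list[tuple[list[str], float]] | None = None,
    log2_mean: float = 3.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, dict[str, object]]:
    """Reference co-expression compendium with planted correlated blocks.

    Each block is a factor model on the log scale: member genes share a
    common factor with loading sqrt(rho), giving pairwise log-scale
    correlation rho within the block; remaining genes are independent.
    Values are exponentiated to an FPKM-like positive scale (which attenuates
    the realized correlation mildly). Returns the matrix and a truth fragment
    listing the block memberships and target correlations.
    """
    rng = np.random.default_rng(seed)
    blocks = blocks or []
    pos = {g: i for i, g in enumerate(gene_ids)}
    in_block: set[str] = set()
    for members, rho in blocks:
        if not (0 <= rho < 1):
            raise ValueError("block correlation must lie in [0, 1)")
        overlap = in_block.intersection(members)
        if overlap:
            raise ValueError(
                f"genes assigned to multiple blocks (correlation model "
                f"ill-defined): {sorted(overlap)[:5]}"
            )
        missing = [g for g in members if g not in pos]
        if missing:
            raise ValueError(f"block genes not in gene_ids: {missing[:5]}")
        in_block.update(members)

    Z = rng.normal(0.0, 1.0, size=(len(gene_ids), n_samples))
    for members, rho in blocks:
        factor = rng.normal(0.0, 1.0, size=n_samples)
        idx = [pos[g] for g in members]
        Z[idx] = np.sqrt(rho) * factor[None, :] + np.sqrt(1.0 - rho) * Z[idx]
    values = np.exp2(log2_mean + Z)
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=[f"BR{j:04d}" for j in range(n_samples)])
    )
    truth = {
        "seed": seed,
        "n_samples": n_samples,
        "blocks": [{"genes": list(m), "rho": r} for m, r in blocks],
    }
    return matrix, truth


def planted_mean_matrix(
    n_rows: int,
    n_high: int,
    threshold: float = 2.0,
    n_samples: int = 6,
    seed: int = 0,
) -> ExpressionMatrix:
    """Matrix with exactly ``n_high`` rows whose mean is >= ``threshold``.

    Row values are a planted mean times positive weights renormalized to
    average exactly one, so realized row means equal the planted means — a
    sharp fixture for the mean-expression filter.
    """
    if n_high > n_rows:
        raise ValueError("n_high cannot exceed n_rows")
    rng = np.random.default_rng(seed)
    high = threshold + rng.exponential(3.0, size=n_high)
    low = threshold * rng.uniform(0.0, 0.999, size=n_rows - n_high)
    means = np.concatenate([high, low])
    rng.shuffle(means)
    weights = rng.lognormal(0.0, 0.3, size=(n_rows, n_samples))
    weights /= weights.mean(axis=1, keepdims=True)
    values = means[:, None] * weights
    genes = [f"G{i:05d}" for i in range(n_rows)]
    samples = [f"S{j}" for j in range(n_samples)]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))
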