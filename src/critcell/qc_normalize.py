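"""Quality control and normalization of the transcript-level FPKM matrix.

The funnel is order-fixed: representative-transcript selection, mean-FPKM
expression filter, variability flagging on control samples, then rank-based
inverse normal transformation. Means for the expression filter use all
samples; standard deviations for variability use control samples only — the
asymmetry is deliberate (cases may carry true dosage effects that must not be
filtered away as "variability").
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import ExpressionMatrix, SampleSheet

logger = logging.getLogger(__name__)


@dataclass
class VariabilityReport:
    """Per-gene variability diagnostics on control samples.

    ``intra_sd_per_donor`` holds, for every control donor with >= 2
    replicates, the SD of that donor's replicate values per gene. The flags
    z-score the per-gene max intra-donor SD (any donor) and the SD across
    control-donor means across genes, and compare against the configured
    z cutoffs (defaults 2 and 1.5).
    """

    intra_sd_per_donor: pd.DataFrame  # genes x control donors (NaN if < 2 reps)
    max_intra_sd: pd.Series
    inter_sd: pd.Series
    intra_z: pd.Series
    inter_z: pd.Series
    intra_flag: pd.Series
    inter_flag: pd.Series

    @property
    def flagged_genes(self) -> list[str]:
        mask = self.intra_flag | self.inter_flag
        return list(mask.index[mask])


def select_representative_transcripts(tx: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse transcripts to one representative per gene.

    The representative is the transcript with the highest mean FPKM across all
    samples (cases and controls); ties break to the lexicographically smallest
    transcript id (logged).
    """
    if tx.gene_of_transcript is None:
        raise ValueError("transcript-to-gene mapping required")
    unmapped = [t for t in tx.row_ids if t not in tx.gene_of_transcript]
    if unmapped:
        raise ValueError(f"transcripts without gene mapping: {unmapped[:10]}")
    means = tx.data.mean(axis=1)
    frame = pd.DataFrame(
        {
            "transcript": tx.data.index,
            "gene": [tx.gene_of_transcript[t] for t in tx.data.index],
            "mean": means.to_numpy(),
        }
    )
    chosen: dict[str, str] = {}
    for gene, grp in frame.groupby("gene", sort=False):
        best = grp["mean"].max()
        candidates = sorted(grp.loc[grp["mean"] == best, "transcript"])
        if len(candidates) > 1:
            logger.warning(
                "gene %s: tie among transcripts %s; keeping %s",
                gene,
                candidates,
                candidates[0],
            )
        chosen[gene] = candidates[0]
    out = tx.data.loc[list(chosen.values())].copy()
    out.index = list(chosen.keys())
    return ExpressionMatrix(out)


def filter_expressed(m: ExpressionMatrix, threshold: float = 2.0) -> ExpressionMatrix:
    """Drop genes whose mean FPKM across all samples is strictly below threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    means = m.data.mean(axis=1)
    keep = means >= threshold
    if not keep.any():
        logger.warning("no gene passed the mean-FPKM >= %g filter", threshold)
    return ExpressionMatrix(m.data.loc[keep].copy(), gene_of_transcript=m.gene_of_transcript)


def flag_variable_genes(
    m: ExpressionMatrix,
    sheet: SampleSheet,
    intra_z: float = 2.0,
    inter_z: float = 1.5,
) -> VariabilityReport:
    """Flag genes with outlying intra- or inter-individual variability.

    Computed on control samples only. A gene's intra statistic is the maximum,
    over control donors with >= 2 replicates, of the SD across that donor's
    replicates; the inter statistic is the SD across control-donor mean
    expressions. Both statistics are z-scored across genes and flagged above
    the respective cutoff.
    """
    ctrl = sheet.table[sheet.table["group"] == "control"]
    donors = ctrl["donor_id"].unique()
    if len(donors) < 2:
        raise ValueError("need >= 2 control donors for variability flags")
    present = [s for s in ctrl["sample_id"] if s in m.data.columns]
    ctrl = ctrl[ctrl["sample_id"].isin(present)]

    intra_cols = {}
    donor_means = {}
    for donor, grp in ctrl.groupby("donor_id"):
        cols = list(grp["sample_id"])
        vals = m.data[cols]
        donor_means[donor] = vals.mean(axis=1)
        if len(cols) >= 2:
            intra_cols[donor] = vals.std(axis=1, ddof=1)
        else:
            logger.info("donor %s has a single replicate; no intra SD", donor)
    intra_sd = pd.DataFrame(intra_cols, index=m.data.index, dtype=float)
    if intra_sd.shape[1] == 0:
        logger.warning("all control donors have a single replicate; intra flags all false")
        max_intra = pd.Series(np.nan, index=m.data.index)
        intra_zscores = pd.Series(np.nan, index=m.data.index)
        intra_flag = pd.Series(False, index=m.data.index)
    else:
        max_intra = intra_sd.max(axis=1)
        intra_zscores = _zscore(max_intra)
        intra_flag = intra_zscores > intra_z

    means_frame = pd.DataFrame(donor_means)
    inter_sd = means_frame.std(axis=1, ddof=1)
    inter_zscores = _zscore(inter_sd)
    inter_flag = inter_zscores > inter_z

    return VariabilityReport(
        intra_sd_per_donor=intra_sd,
        max_intra_sd=max_intra,
        inter_sd=inter_sd,
        intra_z=intra_zscores,
        inter_z=inter_zscores,
        intra_flag=intra_flag.fillna(False).astype(bool),
        inter_flag=inter_flag.fillna(False).astype(bool),
    )


def _zscore(s: pd.Series) -> pd.Series:
    sd = s.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return pd.Series(0.0, index=s.index)
    return (s - s.mean()) / sd


def remove_flagged_genes(m: ExpressionMatrix, report: VariabilityReport) -> ExpressionMatrix:
    keep = [g for g in m.row_ids if g not in set(report.flagged_genes)]
    return ExpressionMatrix(m.data.loc[keep].copy(), gene_of_transcript=m.gene_of_transcript)


def inverse_normal_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Rank-based inverse normal transform per gene across samples.

    Ties get averaged ranks; ranks map through the standard normal quantile of
    (rank - 3/8) / (n + 1/4) (Blom offset). A constant gene maps to an
    all-zero row (logged), and every transformed row has mean ~ 0.
    """
    values = m.data.to_numpy(dtype=float)
    n = values.shape[1]
    if n < 2:
        raise ValueError("need >= 2 samples to rank-normalize")
    ranks = stats.rankdata(values, axis=1, method="average")
    transformed = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    constant = np.ptp(values, axis=1) == 0
    if constant.any():
        logger.info("%d constant gene rows transformed to zeros", int(constant.sum()))
    out = pd.DataFrame(transformed, index=m.data.index, columns=m.data.columns)
    return ExpressionMatrix(out, gene_of_transcript=m.gene_of_transcript)


@dataclass
class ReplicateCorrelations:
    """Pairwise squared Pearson correlations between samples, split by donor."""

    intra_r2: pd.DataFrame  # columns: sample_a, sample_b, donor, r2
    inter_r2: pd.DataFrame  # columns: sample_a, sample_b, r2
    mean_intra: float
    mean_inter: float
    ranksum_p: float  # two-sided rank-sum p comparing intra vs inter r2


def replicate_correlations(m: ExpressionMatrix, sheet: SampleSheet) -> ReplicateCorrelations:
    """All pairwise sample r^2, partitioned into intra- vs inter-individual."""
    cols = [s for s in sheet.sample_ids if s in m.data.columns]
    donor = sheet.donor_of()
    corr = np.corrcoef(m.data[cols].to_numpy(dtype=float).T)
    intra_rows, inter_rows = [], []
    for i, j in itertools.combinations(range(len(cols)), 2):
        r2 = corr[i, j] ** 2
        if donor[cols[i]] == donor[cols[j]]:
            intra_rows.append((cols[i], cols[j], donor[cols[i]], r2))
        else:
            inter_rows.append((cols[i], cols[j], r2))
    intra = pd.DataFrame(intra_rows, columns=["sample_a", "sample_b", "donor", "r2"])
    inter = pd.DataFrame(inter_rows, columns=["sample_a", "sample_b", "r2"])
    mean_intra = float(intra["r2"].mean()) if len(intra) else float("nan")
    mean_inter = float(inter["r2"].mean()) if len(inter) else float("nan")
    if len(intra) and len(inter):
        p = float(stats.mannwhitneyu(intra["r2"], inter["r2"], alternative="two-sided").pvalue)
    else:
        logger.warning("intra/inter partition empty; rank-sum comparison skipped")
        p = float("nan")
    return ReplicateCorrelations(intra, inter, mean_intra, mean_inter, p)


def check_panel_absence(
    m: ExpressionMatrix, panel: list[str], threshold: float = 2.0
) -> tuple[bool, pd.DataFrame]:
    """Check that no panel gene (e.g. viral-induction markers) is expressed.

    Returns (clean, report): clean is true iff no panel gene reaches mean
    expression >= threshold; the report lists each panel gene's mean and
    whether it was detected in the matrix at all.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    rows = []
    for g in panel:
        present = g in m.data.index
        mean = float(m.data.loc[g].mean()) if present else float("nan")
        expressed = present and mean >= threshold
        rows.append({"gene": g, "detected": present, "mean": mean, "expressed": expressed})
    report = pd.DataFrame(rows, columns=["gene", "detected", "mean", "expressed"])
    clean = not bool(report["expressed"].any())
    return clean, report
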