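# Methods

## Pipeline model

The package analyzes a gene (or transcript) × sample matrix of non-negative
FPKM-scale values with a sample sheet assigning each sample to a donor,
replicate index and case/control group. Donors belong to exactly one group;
replicates are treated as independent samples throughout (the cohorts this
targets are small, and inter-individual replicate correlations are close to
intra-individual ones after QC, so a donor-level mixed model would cost more
permutation resolution than it buys).

### QC funnel (order-fixed)

1. **Representative transcripts.** One transcript per gene, the one with the
   highest mean FPKM across *all* samples; ties break to the
   lexicographically smallest transcript id (logged).
2. **Expression filter.** Genes with mean FPKM across all samples strictly
   below 2 are removed; a mean exactly at the threshold is retained.
3. **Variability flags.** Computed on control samples only, so true
   case/control biology is never filtered as "variability": per gene, the
   maximum over control donors (≥ 2 replicates) of the replicate SD (intra),
   and the SD across control-donor means (inter). "More than 2 SD intra /
   1.5 SD inter" is operationalized as a z-score of these statistics across
   genes, compared to cutoffs 2 and 1.5 — the only reading that makes the
   cutoffs population-level; raw-SD units would make them FPKM-scale
   dependent. Both cutoffs are configuration-exposed. Donors with a single
   replicate contribute no intra SD (logged).
4. **Inverse normal transform.** Per gene across samples: averaged-tie
   ranks mapped through Φ⁻¹((rank − 3/8)/(n + 1/4)) (Blom offset, the
   standard convention; the choice is logged and only affects extreme-rank
   spacing). Constant genes map to zero rows. Downstream regression and PCA
   use the transformed values; **fold changes are always computed on raw
   FPKM** (case mean / control mean), because dosage-scale readouts
   (≈0.5 for hemizygous deletions, ≈1.5 for duplications) are meaningless
   on rank-normalized values.

### Differential expression

Per gene, ordinary least squares of normalized expression on the case
indicator plus covariates; by default the only covariate is PC1 of the
normalized matrix (samples as observations, genes as centered features, PC1
oriented so its loading sum is non-negative). PC1 acts as a surrogate for
shared technical/biological factors; further covariates are accepted.
Two-sided p-values come from the group coefficient's t-statistic; genes with
(numerically) zero residual variance get p = 1 rather than being dropped, so
gene universes stay aligned across stages. BH step-up FDR adjusts the
p-vector. The OLS is closed-form and vectorized over genes and over stacks
of permuted label vectors (cross-checked against statsmodels per-gene fits
in the tests); this is what makes permutation nulls affordable.

### CellScore

Clusters are partitioned into specific genes (present in exactly one
cluster of the collection) and non-specific genes (present in ≥ 2).
CellScore is the mean −log10 p over specific genes present in the DE table
minus the same mean over non-specific genes present; denominators count only
genes actually entering each mean (logged when smaller than the input
lists), and a cluster with an empty side is undefined (NaN) rather than
silently scored.

**Pseudo-case permutation null.** Each permutation draws n_case samples
uniformly without replacement from the true controls as pseudo-cases; all
true cases plus remaining controls form the pseudo-controls, preserving the
observed design size. PC1 is computed once on the observed matrix and reused
— only labels permute, expression (and hence its principal components) does
not change. All clusters share one label stream per run, preserving
cross-cluster comparability. When C(n_controls, n_cases) ≤ n_perm the full
assignment set is enumerated exactly once each instead of sampled.

The empirical p is the one-sided proportion of null scores ≥ observed
(larger score = perturbation; a two-sided reading is not meaningful for a
difference of means of −log10 p). The raw proportion is used, with an
explicit "< 1/N" floor when no null score reaches the observed value — this
reporting convention (rather than (k+1)/(N+1)) is what produces bounds like
"< 1e-06" at 10⁶ permutations. FWER flags compare p against level/n_clusters
(Bonferroni). Two datasets' results for the same cluster combine as
|score|-weighted averages of −log10 p, returned on both the −log10 and the
p scale (labeled).

### Cluster de-duplication and atlas fine-mapping

Directional overlap of sets A→B is 100·|A∩B|/|A| (the denominator is the
first set — the definition is configuration-exposed since either convention
is defensible); "mean overlap" averages the two directions. Redundant
clusters (either direction ≥ 50%) merge as connected components, so chains
merge transitively; each merged group's gene set is the union of its
members. A cluster's atlas profile is its mean overlap against each atlas
cell type, and profiles over the identical atlas are compared by Pearson
correlation.

### GeneScore

Connectivity is the squared Pearson correlation of each locus gene's
compendium profile with every other compendium gene (self excluded,
zero-variance reference genes undefined, locus genes absent from the
compendium dropped with a logged list). The genomic-control factor λ maps
p-values to 1-df chi-square statistics (upper tail) and takes the ratio of
their median to the null median (≈0.4549). GeneScore(x) is the mean over
reference genes of (−log10 P_y)·r²(x,y), times 1/log10 λ. λ is always
computed from the run's **full** DE p-vector, never the cell-type subset,
and each run — observed or permuted — uses its own λ, because different
pseudo-case assignments carry different global inflation (true cases sit in
every permutation's pseudo-control arm, so null runs genuinely contain
diluted case signal; per-run λ is what absorbs it). `Num_y` counts the genes
actually entering the sum (reference ∩ DE table ∩ subset, with defined r²).

**λ ≤ 1 guard.** The 1/log10 λ prefactor is undefined at λ = 1 and
sign-flipping below it; a negative prefactor would invert the ranking, which
cannot be intended. When λ ≤ 1 the unnormalized score is emitted with an
explicit flag. This regime is rare when the data carry real shared
structure (see the generator notes) but is handled deterministically.

Empirical p-values per (locus gene, scope) use the same pseudo-case scheme
and floor reporting as CellScore. FDR thresholds are the nearest-rank
(lower) 5th and 10th percentiles of the pooled per-cluster p-values for the
locus — the ceil(n·q/100)-th smallest value, undefined when n·q/100 < 1;
nearest-rank is reproducible and conservative where an interpolation scheme
would be arbitrary.

### Enrichment and power

The 2×2 overlap enrichment reports the sample odds ratio (a·d)/(b·c), a
two-sided Fisher exact p, and a 95% CI by the exact conditional
(noncentral hypergeometric) method with a Woolf log-normal fallback; the
method used is recorded. The power simulation draws n_ctrl = 14 control
values from Normal(mean, 18.5) and n_case = 9 case values from
Normal(mean·fc, 18.5) per replicate — negative draws are kept, as the model
is the plain normal — and tests each replicate with the pipeline's OLS group
test without covariates (equivalent to a pooled two-sample t-test; the
simulated data have no PC structure to adjust for). Power is the fraction of
1000 replicates with p ≤ 0.05/n_genes; the default Bonferroni denominator is
the post-QC universe of 9,978 genes and is configuration-exposed. Across
base means 2–5 and fold changes 1.2–3.5 every cell's power is far below
80%, which is the design's headline limitation for second-hit analyses.

## Synthetic data

`generate_cohort` draws log2 FPKM = gene baseline (N(2.5, 1.5²)) + donor
random effect (SD 0.4) + low-rank hidden sample factors + replicate noise
(SD 0.25), exponentiated to the FPKM scale. Defaults mirror the cohort
shape this framework was built for: 12 control vs 9 case donors, 1–3
replicates each, ~10⁴ genes, a 22-gene locus at dosage fold change 0.5.
Case donors' locus genes are multiplied by the dosage factor; designated
"perturbed" genes receive an additive log2 shift in case samples. Because
replicate-noise distributions are identical across groups, the expected
FPKM-scale group fold change of a locus gene equals the planted dosage
exactly; donor effects produce the intra- > inter-individual replicate
correlation ordering of real organoid cohorts.

The hidden factors (per-gene loadings Uniform(−1, 1); per-sample factor
values with SDs 1.0, 0.35, 0.35) emulate the sample structure of real bulk
data: one dominant component — absorbed downstream by the PC1 covariate —
plus weaker residual components. The residual components matter
statistically: they keep each contrast's genomic-control λ away from the
degenerate λ → 1 regime in which the 1/log10 λ normalization is
unstable, which is also where real data sit (real contrasts are never
perfectly calibrated). Loadings are bounded because unbounded ones put heavy
multiplicative tails on FPKM-scale group means and would swamp the planted
dosage signal. `generate_cluster_sets` assigns every shared-pool gene to
2–3 clusters by construction, so the expected specific/non-specific
partition is recorded exactly; `generate_reference_compendium` builds
correlated blocks by a log-scale factor model (within-block correlation ρ,
attenuated mildly by exponentiation) and places a designated driver gene
inside a block overlapping the perturbed genes.

What the generator does **not** emulate: count noise (FPKM values are
log-normal, not mean–variance-coupled), realistic gene-length or GC biases,
batch structure correlated with group, cell-type composition drift across
replicates, and single-cell count matrices. Passing tests therefore
demonstrate the statistical machinery — calibration, recovery, bookkeeping —
under a faithful-but-idealized noise model, not robustness to every
real-data artifact.

## Numerical choices and degenerate inputs

- OLS designs are rejected as collinear above condition number 1e12, naming
  the removable column; zero-residual fits get p = 1 with a warning.
- Empirical p-values are never 0: the floor is 1/N with an `at_floor` flag,
  rendered as "<1/N".
- Ties in transcript selection, ranks and percentiles are resolved by
  documented deterministic rules (lexicographic id, averaged ranks,
  nearest-rank-lower).
- Same seed ⇒ identical output everywhere; permutation label streams derive
  from one `numpy` Generator per run.

## Problem sizes used in the shipped tests

The statistical suites run at reduced scale chosen as the package's own
test design: null-calibration uniformity uses 200 independent cohorts
(150 genes, 3 + 4 donors × 2 replicates) × 1000 permutations;
planted-cluster recovery 50 seeds (400 genes, 4 clusters, 400 permutations);
planted-driver recovery 50 seeds (600 genes, 40-gene block at ρ = 0.8,
150-sample compendium, 150 permutations); the enumeration oracle uses the
C(4,2) design. The power grid runs at its published design (1000 simulated
replicates per cell). Full-scale runs (10⁴ genes, 10⁵–10⁶ permutations) use
the identical code paths via the CLI.

## Known limitations

- Replicates as independent samples overstate effective n when donor
  effects are strong; the permutation null shares this convention, which
  keeps the empirical p calibrated, but the OLS p-values feeding the scores
  are anti-conservative in absolute terms.
- The pseudo-case null contains diluted true-case signal by construction
  (true cases are pseudo-controls); λ normalization absorbs the global part
  of this for GeneScore, but CellScore nulls retain it, making cluster
  p-values conservative when the case signal is strong and broad.
- GeneScore's λ normalization is unstable near λ = 1; the guard emits
  unnormalized flagged scores rather than extrapolating.
- Percentile FDR is a relative criterion across clusters for one locus; it
  does not control FDR in the frequentist sense a BH procedure would.
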