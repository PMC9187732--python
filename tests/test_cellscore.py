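"""Cluster partitioning, CellScore, permutation null, FWER and fine-mapping."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from critcell.dataio import GeneSetCollection
from critcell.cellscore import (
    ClusterPartition,
    PermutationNull,
    atlas_overlap_profile,
    build_null_distributions,
    combine_dataset_pvalues,
    compute_cellscore,
    deduplicate_clusters,
    draw_permutation,
    empirical_pvalue,
    fwer_threshold,
    merge_cluster_groups,
    pairwise_overlap_matrix,
    partition_cluster_genes,
    permutation_case_matrix,
    profile_correlation,
    score_clusters,
)
from critcell.qc_normalize import inverse_normal_transform
from critcell.synthetic import generate_cluster_sets, generate_cohort

from conftest import make_sheet


def collection(**sets):
    return GeneSetCollection({k: (k, list(v)) for k, v in sets.items()})


class TestPartition:
    def test_disjoint_clusters_all_specific(self):
        parts = partition_cluster_genes(collection(a=["x", "y"], b=["z"]))
        assert parts[0].specific_genes == ["x", "y"] and parts[0].nonspecific_genes == []
        assert parts[1].specific_genes == ["z"]

    def test_shared_gene_nonspecific_in_both(self):
        parts = partition_cluster_genes(collection(A=["g", "a"], B=["g", "b"]))
        for p in parts:
            assert "g" in p.nonspecific_genes and "g" not in p.specific_genes

    def test_generator_planted_design_recovered(self):
        sets, expected = generate_cluster_sets(
            n_clusters=10, specific_per_cluster=(47, 266), shared_pool=120, seed=7
        )
        parts = partition_cluster_genes(sets)
        for got, exp in zip(parts, expected):
            assert sorted(got.specific_genes) == sorted(exp.specific_genes)
            assert sorted(got.nonspecific_genes) == sorted(exp.nonspecific_genes)

    def test_membership_bookkeeping(self):
        sets, _ = generate_cluster_sets(n_clusters=6, specific_per_cluster=20,
                                        shared_pool=40, seed=3)
        parts = partition_cluster_genes(sets)
        total_membership = sum(len(genes) for _, genes in sets.items())
        assert sum(len(p.specific_genes) + len(p.nonspecific_genes) for p in parts) == total_membership


class TestCellScore:
    def test_hand_arithmetic(self):
        p = pd.Series({"s1": 1e-3, "s2": 1e-1, "n1": 1e-2})
        part = ClusterPartition("c", ["s1", "s2"], ["n1"])
        assert compute_cellscore(p, part) == pytest.approx(0.0, abs=1e-12)

    def test_constant_case(self):
        p = pd.Series({"s1": 0.01, "s2": 0.01, "n1": 1.0, "n2": 1.0})
        part = ClusterPartition("c", ["s1", "s2"], ["n1", "n2"])
        assert compute_cellscore(p, part) == pytest.approx(2.0, abs=1e-12)

    def test_exchangeable_pvalues_center_score_at_zero(self, rng):
        part = ClusterPartition("c", [f"s{i}" for i in range(20)], [f"n{i}" for i in range(20)])
        scores = []
        for _ in range(1000):
            p = pd.Series(rng.uniform(1e-12, 1, size=40),
                          index=part.specific_genes + part.nonspecific_genes)
            scores.append(compute_cellscore(p, part))
        se = np.std(scores, ddof=1) / np.sqrt(len(scores))
        assert abs(np.mean(scores)) < 3 * se

    def test_absent_genes_shrink_denominator(self):
        p = pd.Series({"s1": 0.01, "n1": 1.0})
        part = ClusterPartition("c", ["s1", "missing"], ["n1"])
        assert compute_cellscore(p, part) == pytest.approx(2.0)

    def test_empty_side_undefined(self, caplog):
        p = pd.Series({"s1": 0.01})
        part = ClusterPartition("c", ["s1"], ["absent"])
        with caplog.at_level("WARNING"):
            assert math.isnan(compute_cellscore(p, part))


class TestPermutationScheme:
    def test_pseudo_cases_drawn_from_controls_only(self, rng):
        sheet = make_sheet(23, 36, reps=1)
        labels = draw_permutation(sheet, rng)
        pseudo_cases = set(labels[labels == "case"].index)
        assert len(pseudo_cases) == 23
        assert pseudo_cases <= set(sheet.control_samples)
        # all true cases are pseudo-controls
        assert all(labels[s] == "control" for s in sheet.case_samples)

    def test_smaller_case_arm(self, rng):
        sheet = make_sheet(12, 36, reps=1)
        labels = draw_permutation(sheet, rng)
        assert (labels == "case").sum() == 12

    def test_more_cases_than_controls_rejected(self, rng):
        sheet = make_sheet(5, 4, reps=1)
        with pytest.raises(ValueError, match="inapplicable"):
            draw_permutation(sheet, rng)

    def test_enumeration_covers_all_assignments_once(self):
        sheet = make_sheet(2, 4, reps=1)
        mat, enumerated = permutation_case_matrix(sheet, sheet.sample_ids, 10, seed=0)
        assert enumerated and mat.shape[0] == 6
        rows = {tuple(r) for r in mat}
        assert len(rows) == 6
        case_cols = [sheet.sample_ids.index(s) for s in sheet.case_samples]
        assert all(mat[:, c].sum() == 0 for c in case_cols)
        assert (mat.sum(axis=1) == 2).all()

    def test_sampling_mode_counts(self):
        sheet = make_sheet(3, 8, reps=1)
        mat, enumerated = permutation_case_matrix(
            sheet, sheet.sample_ids, 50, seed=1, enumerate_when_possible=False
        )
        assert not enumerated and mat.shape == (50, 11)
        assert (mat.sum(axis=1) == 3).all()


@pytest.fixture(scope="module")
def cohort():
    m, sheet, _ = generate_cohort(
        n_case_donors=3, n_ctrl_donors=4, reps_per_donor=2, n_genes=150,
        locus_size=0, dosage_fc=1.0, seed=21,
    )
    sets, _ = generate_cluster_sets(
        n_clusters=3, specific_per_cluster=15, shared_pool=15,
        gene_pool=m.row_ids, seed=22,
    )
    return inverse_normal_transform(m), sheet, partition_cluster_genes(sets)


class TestNullDistribution:
    def test_same_seed_identical_null(self, cohort):
        norm, sheet, parts = cohort
        n1 = build_null_distributions(norm, sheet, parts, n_perm=100, seed=5,
                                      enumerate_when_possible=False)
        n2 = build_null_distributions(norm, sheet, parts, n_perm=100, seed=5,
                                      enumerate_when_possible=False)
        for cid in n1:
            np.testing.assert_array_equal(n1[cid].null_scores, n2[cid].null_scores)

    def test_null_mean_near_zero_over_exchangeable_cohorts(self):
        # within one cohort the null mean is dataset-specific; exchangeability
        # centers it at zero only across independently generated cohorts
        means = []
        for seed in range(25):
            m, sheet, _ = generate_cohort(
                n_case_donors=3, n_ctrl_donors=4, reps_per_donor=2, n_genes=120,
                locus_size=0, dosage_fc=1.0, seed=100 + seed,
            )
            sets, _ = generate_cluster_sets(
                n_clusters=2, specific_per_cluster=15, shared_pool=10,
                gene_pool=m.row_ids, seed=200 + seed,
            )
            parts = partition_cluster_genes(sets)
            nulls = build_null_distributions(
                inverse_normal_transform(m), sheet, parts, n_perm=200,
                seed=seed, enumerate_when_possible=False,
            )
            means.append(nulls[parts[0].cluster_id].null_scores.mean())
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means)) < 3 * se


class TestEmpiricalP:
    def test_direct_count(self):
        null = PermutationNull("c", np.array([1.0, 2.0, 3.0, 4.0]), 4, 2, [], None)
        p, at_floor = empirical_pvalue(2.5, null)
        assert p == 0.5 and not at_floor

    def test_observed_below_null_minimum(self):
        null = PermutationNull("c", np.array([1.0, 2.0]), 2, 1, [], None)
        assert empirical_pvalue(0.0, null) == (1.0, False)

    def test_floor_reported_as_bound(self):
        null = PermutationNull("c", np.zeros(1_000_000), 1_000_000, 1, [], None)
        p, at_floor = empirical_pvalue(1.0, null)
        assert at_floor and p == pytest.approx(1e-6)

    @given(obs=st.floats(-5, 5), n=st.integers(1, 50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_p_always_in_unit_interval(self, obs, n):
        scores = np.linspace(-1, 1, n)
        null = PermutationNull("c", scores, n, 1, [], None)
        p, _ = empirical_pvalue(obs, null)
        assert 0 < p <= 1


class TestFWER:
    @pytest.mark.parametrize(
        "n,level,expected", [(10, 0.05, 0.005), (10, 0.1, 0.01), (1, 0.05, 0.05)]
    )
    def test_bonferroni_threshold(self, n, level, expected):
        assert fwer_threshold(n, level) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fwer_threshold(0, 0.05)
        with pytest.raises(ValueError):
            fwer_threshold(10, 1.5)


class TestCombineDatasets:
    def test_symmetric_case(self):
        assert combine_dataset_pvalues(1.0, 0.01, 1.0, 0.01).neg_log10_p == pytest.approx(2.0)

    def test_degenerate_weight(self):
        out = combine_dataset_pvalues(2.0, 1e-4, 0.0, 0.5)
        assert out.neg_log10_p == pytest.approx(4.0)

    def test_hand_weighted_average(self):
        out = combine_dataset_pvalues(3.0, 1e-4, 1.0, 1e-2)
        assert out.neg_log10_p == pytest.approx(3.5)
        assert out.p == pytest.approx(10**-3.5)

    def test_both_scores_zero_undefined(self):
        assert math.isnan(combine_dataset_pvalues(0.0, 0.5, 0.0, 0.5).neg_log10_p)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            combine_dataset_pvalues(1.0, 0.0, 1.0, 0.5)


class TestOverlapAndDedup:
    def test_identical_sets_full_overlap(self):
        m = pairwise_overlap_matrix(collection(a=["x", "y"], b=["x", "y"]))
        assert m.loc["a", "b"] == 100 and m.loc["b", "a"] == 100
        assert m.loc["a", "a"] == 100

    def test_directional_denominator(self):
        m = pairwise_overlap_matrix(collection(A=["a", "b", "c", "d"], B=["a", "b"]))
        assert m.loc["A", "B"] == 50 and m.loc["B", "A"] == 100

    def test_disjoint_sets_zero(self):
        m = pairwise_overlap_matrix(collection(a=["x"], b=["y"]))
        assert m.loc["a", "b"] == 0

    def test_no_edges_all_singletons(self):
        m = pairwise_overlap_matrix(collection(a=["1", "2", "3"], b=["4", "5"], c=["6"]))
        assert deduplicate_clusters(m, 50) == [["a"], ["b"], ["c"]]

    def test_transitive_chain_merges(self):
        sets = collection(A=["1", "2"], B=["2", "3"], C=["3", "4"])
        groups = deduplicate_clusters(pairwise_overlap_matrix(sets), 50)
        assert groups == [["A", "B", "C"]]
        merged = merge_cluster_groups(sets, groups)
        assert merged.genes("A+B+C") == ["1", "2", "3", "4"]

    def test_templates_plus_copies_recover_template_count(self, rng):
        # 24 clusters built from 11 templates; copies share >=50% of genes
        genes = [f"t{i}_{j}" for i in range(11) for j in range(20)]
        templates = {f"T{i}": genes[i * 20 : (i + 1) * 20] for i in range(11)}
        sets = {}
        for i, (name, members) in enumerate(templates.items()):
            sets[name] = (name, members)
        for k in range(13):
            src = f"T{k % 11}"
            copy = list(templates[src][:12]) + [f"extra{k}_{j}" for j in range(6)]
            sets[f"copy{k}"] = (f"copy{k}", copy)
        groups = deduplicate_clusters(pairwise_overlap_matrix(GeneSetCollection(sets)), 50)
        assert len(groups) == 11


class TestAtlasFinemap:
    def test_subset_cluster_profile(self):
        atlas = collection(RG=["a", "b", "c", "d"], IPC=["x", "y"])
        profile = atlas_overlap_profile(["a", "b"], atlas)
        assert profile["RG"] == pytest.approx(0.5 * (100 + 50))
        assert profile["IPC"] == 0

    def test_disjoint_cluster_all_zero(self):
        atlas = collection(A=["a"], B=["b"])
        assert (atlas_overlap_profile(["z"], atlas) == 0).all()

    def test_profile_length_matches_atlas(self):
        atlas = collection(**{f"t{i}": [f"g{i}"] for i in range(6)})
        assert len(atlas_overlap_profile(["g0"], atlas)) == 6

    def test_profile_correlation_identity_and_reflection(self):
        a = pd.Series([1.0, 2.0, 3.0], index=["x", "y", "z"])
        r, _ = profile_correlation(a, a * 2)
        assert r == pytest.approx(1.0)
        r, _ = profile_correlation(a, -a + 10)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_profile_undefined(self):
        a = pd.Series([1.0, 2.0, 3.0], index=["x", "y", "z"])
        b = pd.Series([5.0, 5.0, 5.0], index=["x", "y", "z"])
        r, p = profile_correlation(a, b)
        assert math.isnan(r) and math.isnan(p)


class TestScoreClustersEndToEnd:
    def test_planted_cluster_identified(self):
        sets, parts = generate_cluster_sets(
            n_clusters=4, specific_per_cluster=25, shared_pool=30,
            gene_pool=[f"G{i:05d}" for i in range(400)], seed=31,
        )
        target = parts[1]
        m, sheet, _ = generate_cohort(
            n_case_donors=5, n_ctrl_donors=7, reps_per_donor=2, n_genes=400,
            locus_size=0, dosage_fc=1.0, perturbed_genes=target.specific_genes,
            perturbed_effect=1.2, seed=32,
        )
        results = score_clusters(
            inverse_normal_transform(m), sheet, sets, n_perm=400, seed=33,
            enumerate_when_possible=False,
        )
        by_p = sorted(results, key=lambda r: r.p_empirical)
        assert by_p[0].unit_id == target.cluster_id
        assert by_p[0].fwer_flags[0.05]
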