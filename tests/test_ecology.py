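import io as _io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode
from skbio.diversity import beta_diversity

from phfkit.ecology import (
    DistanceMatrix,
    bray_curtis,
    compare_metrics_matched,
    correlate_phf_host,
    distance_matrix,
    partition_distances,
    prune_to_families,
    stability_series,
    unifrac,
)
from phfkit.io import AbundanceTable
from phfkit.taxonomy import NamespaceMap, Rank

from conftest import random_abundance_table
from oracles import random_tree, unifrac_oracle


def _tree(newick: str) -> TreeNode:
    return TreeNode.read(_io.StringIO(newick))


class TestBrayCurtis:
    def test_identity(self):
        assert bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0

    def test_disjoint_supports(self):
        assert bray_curtis([1, 0], [0, 3]) == 1.0

    def test_hand_computed(self):
        assert bray_curtis([2, 2], [1, 3]) == pytest.approx(0.25)

    def test_two_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])


class TestUnifrac:
    def test_self_distance_zero(self):
        tree = _tree("((A:1,B:2):0.5,(C:1,D:1):0.7);")
        x = pd.Series({"A": 3.0, "B": 0.0, "C": 1.0, "D": 2.0})
        assert unifrac(tree, x, x, weighted=False) == 0.0
        assert unifrac(tree, x, x, weighted=True) == 0.0

    def test_star_tree_unweighted_is_jaccard_distance(self, rng):
        """With equal branch lengths on a star tree, shared/unique branch
        lengths reduce to set counts, so unweighted UniFrac equals the
        Jaccard distance on presence sets."""
        tips = [f"t{i}" for i in range(8)]
        tree = _tree("(" + ",".join(f"{t}:1" for t in tips) + ");")
        for _ in range(20):
            x = pd.Series(rng.integers(0, 2, 8).astype(float), index=tips)
            y = pd.Series(rng.integers(0, 2, 8).astype(float), index=tips)
            if (x + y).sum() == 0:
                continue
            sx, sy = set(x[x > 0].index), set(y[y > 0].index)
            union = len(sx | sy)
            jaccard = (union - len(sx & sy)) / union if union else 0.0
            assert unifrac(tree, x, y, weighted=False) == pytest.approx(jaccard)

    def test_matches_branch_enumeration_oracle(self, rng):
        for _ in range(200):
            n_tips = int(rng.integers(2, 7))
            tree = random_tree(rng, n_tips)
            tips = [t.name for t in tree.tips()]
            x = pd.Series(rng.integers(0, 10, n_tips).astype(float), index=tips)
            y = pd.Series(rng.integers(0, 10, n_tips).astype(float), index=tips)
            if x.sum() == 0 or y.sum() == 0:
                continue
            for weighted in (False, True):
                ours = unifrac(tree, x, y, weighted)
                ref = unifrac_oracle(tree, x.to_dict(), y.to_dict(), weighted)
                assert ours == pytest.approx(ref, abs=1e-10)

    def test_matches_scikit_bio(self, rng):
        """Independent cross-check against scikit-bio's implementations."""
        for seed in range(5):
            tree = random_tree(np.random.default_rng(seed), 6)
            tips = [t.name for t in tree.tips()]
            counts = rng.integers(0, 20, size=(3, 6))
            counts[counts.sum(axis=1) == 0, 0] = 1
            values = pd.DataFrame(counts.T.astype(float), index=tips,
                                  columns=["s0", "s1", "s2"])
            t = AbundanceTable(values)
            ours_w = distance_matrix(t, "unifrac_weighted", tree)
            ref_w = beta_diversity(
                "weighted_unifrac", counts, ids=["s0", "s1", "s2"],
                taxa=tips, tree=tree, normalized=True,
            )
            assert np.allclose(ours_w.data, ref_w.data, atol=1e-10)
            ours_u = distance_matrix(t, "unifrac_unweighted", tree)
            ref_u = beta_diversity(
                "unweighted_unifrac", counts, ids=["s0", "s1", "s2"],
                taxa=tips, tree=tree,
            )
            assert np.allclose(ours_u.data, ref_u.data, atol=1e-10)

    def test_weighted_bounded_and_maximal_for_disjoint_subtrees(self):
        tree = _tree("((A:1,B:2):0.5,(C:1,D:1):0.7);")
        x = pd.Series({"A": 2.0, "B": 1.0, "C": 0.0, "D": 0.0})
        y = pd.Series({"A": 0.0, "B": 0.0, "C": 1.0, "D": 3.0})
        assert unifrac(tree, x, y, weighted=True) == pytest.approx(1.0)

    def test_feature_without_tip_is_an_error(self):
        tree = _tree("(A:1,B:1);")
        with pytest.raises(ValueError, match="nosuchtip"):
            unifrac(tree, pd.Series({"A": 1.0, "nosuchtip": 1.0}),
                    pd.Series({"B": 1.0}), weighted=False)


class TestDistanceMatrixProperties:
    def test_metric_axioms_on_random_tables(self, rng):
        tree = random_tree(rng, 10)
        tips = [t.name for t in tree.tips()]
        values = pd.DataFrame(
            rng.integers(1, 30, size=(10, 6)).astype(float), index=tips,
            columns=[f"s{i}" for i in range(6)],
        )
        t = AbundanceTable(values)
        for metric in ("bray_curtis", "unifrac_unweighted", "unifrac_weighted"):
            d = distance_matrix(t, metric, tree)
            assert np.allclose(np.diag(d.data), 0)
            assert np.allclose(d.data, d.data.T)
            assert (d.data >= 0).all()
            if metric != "unifrac_unweighted":
                assert (d.data <= 1 + 1e-12).all()

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(("a", "b"), np.array([[0.0, 0.4], [0.2, 0.0]]), "bray_curtis")


class TestPartition:
    def test_two_by_two_counts(self, rng):
        t = random_abundance_table(rng, n_samples=4, n_individuals=2)
        d = distance_matrix(t, "bray_curtis")
        part = partition_distances(d, t.sample_meta)
        assert len(part["intra"]) == 2
        assert len(part["inter"]) == 4

    def test_single_individual_has_no_inter(self, rng):
        t = random_abundance_table(rng, n_samples=5, n_individuals=1)
        d = distance_matrix(t, "bray_curtis")
        part = partition_distances(d, t.sample_meta)
        assert len(part["inter"]) == 0
        assert len(part["intra"]) == 10

    def test_conservation(self, rng):
        t = random_abundance_table(rng, n_samples=8, n_individuals=3)
        d = distance_matrix(t, "bray_curtis")
        part = partition_distances(d, t.sample_meta)
        assert len(part["intra"]) + len(part["inter"]) == 8 * 7 // 2


class TestStability:
    def _meta(self, times, individual="i1"):
        return pd.DataFrame(
            {"individual_id": individual, "time_index": times},
            index=[f"s{t}" for t in times],
        )

    def test_identical_consecutive_samples_give_one(self):
        values = pd.DataFrame(
            {"s0": [1.0, 2.0], "s1": [1.0, 2.0]}, index=["f1", "f2"]
        )
        t = AbundanceTable(values, None, self._meta([0, 1]))
        d = distance_matrix(t, "bray_curtis")
        ss = stability_series(d, t.sample_meta)
        assert ss.values.tolist() == [1.0]

    def test_one_minus_distance(self):
        ids = ("s0", "s1")
        d = DistanceMatrix(ids, np.array([[0.0, 0.25], [0.25, 0.0]]),
                           "bray_curtis")
        ss = stability_series(d, self._meta([0, 1]))
        assert ss.values.tolist() == [0.75]

    def test_collection_order_not_calendar(self):
        """Samples at times 1, 2, 4 pair as (1,2) and (2,4): consecutive in
        collection order even across the gap."""
        ids = ("s1", "s2", "s4")
        data = np.array([[0.0, 0.1, 0.5], [0.1, 0.0, 0.3], [0.5, 0.3, 0.0]])
        ss = stability_series(DistanceMatrix(ids, data, "bray_curtis"),
                              self._meta([1, 2, 4]))
        pairs = list(zip(ss.records["time_from"], ss.records["time_to"]))
        assert pairs == [(1, 2), (2, 4)]
        assert ss.values.tolist() == [0.9, 0.7]

    def test_duplicate_time_index_rejected(self):
        ids = ("a", "b")
        d = DistanceMatrix(ids, np.zeros((2, 2)), "bray_curtis")
        meta = pd.DataFrame(
            {"individual_id": ["i1", "i1"], "time_index": [1, 1]},
            index=["a", "b"],
        )
        with pytest.raises(ValueError, match="duplicate time_index"):
            stability_series(d, meta)

    def test_singleton_individuals_contribute_nothing(self):
        ids = ("a", "b")
        d = DistanceMatrix(ids, np.zeros((2, 2)), "bray_curtis")
        meta = pd.DataFrame(
            {"individual_id": ["i1", "i2"], "time_index": [0, 0]},
            index=["a", "b"],
        )
        assert len(stability_series(d, meta).records) == 0

    def test_bray_curtis_stability_in_unit_interval(self, rng):
        t = random_abundance_table(rng, n_samples=8, n_individuals=2)
        d = distance_matrix(t, "bray_curtis")
        ss = stability_series(d, t.sample_meta)
        assert ((ss.values >= 0) & (ss.values <= 1)).all()


class TestMatchedComparison:
    def test_identical_groups_are_null(self):
        v = [0.3, 0.5, 0.7, 0.2]
        rep = compare_metrics_matched({"a": v, "b": v, "c": v})
        assert rep.friedman_statistic == 0.0
        assert rep.friedman_p == 1.0
        assert (rep.pairwise["p_adjusted"] == 1.0).all()

    def test_strictly_ordered_groups_are_significant(self, rng):
        """a_i < b_i < c_i for all 20 blocks: every pairwise signed-rank test
        survives Bonferroni."""
        a = rng.uniform(0, 1, 20)
        b = a + rng.uniform(0.05, 0.2, 20)
        c = b + rng.uniform(0.05, 0.2, 20)
        rep = compare_metrics_matched({"a": a, "b": b, "c": c})
        assert rep.friedman_p < 0.001
        assert (rep.pairwise["p_adjusted"] < 0.05).all()
        # effect direction: medians increase a -> b -> c
        ab = rep.pairwise.set_index(["group_a", "group_b"])
        assert ab.loc[("a", "b"), "median_diff"] < 0
        assert ab.loc[("a", "c"), "median_diff"] < 0

    def test_adjusted_p_capped_at_one(self, rng):
        x = rng.normal(size=15)
        rep = compare_metrics_matched(
            {"a": x, "b": x + rng.normal(0, 1e-3, 15),
             "c": x + rng.normal(0, 1e-3, 15)}
        )
        assert (rep.pairwise["p_adjusted"] <= 1.0).all()

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_metrics_matched({"a": [1.0], "b": [2.0]})


class TestPhfHostCorrelation:
    def _tables(self, x, y):
        samples = [f"s{i}" for i in range(len(x))]
        phf = AbundanceTable(
            pd.DataFrame([x], index=["FamA"], columns=samples, dtype=float)
        )
        host = AbundanceTable(
            pd.DataFrame([y], index=["FamilyA_ncbi"], columns=samples,
                         dtype=float)
        )
        nsmap = NamespaceMap.from_records([("FamA", "FamilyA_ncbi", 0.9)])
        return phf, host, nsmap

    def test_perfectly_monotone_pair(self):
        phf, host, nsmap = self._tables([1, 2, 3, 4], [10, 20, 30, 40])
        out = correlate_phf_host(phf, host, nsmap)
        assert out["rho"].iloc[0] == pytest.approx(1.0)

    def test_constant_profile_is_excluded(self):
        phf, host, nsmap = self._tables([1, 1, 1, 1], [10, 20, 30, 40])
        out = correlate_phf_host(phf, host, nsmap)
        assert bool(out["excluded"].iloc[0])
        assert np.isnan(out["p_adjusted"].iloc[0])

    def test_unmapped_family_is_skipped(self):
        phf, host, _ = self._tables([1, 2, 3, 4], [10, 20, 30, 40])
        nsmap = NamespaceMap.from_records([("FamA", "FamilyA_ncbi", 0.4)])
        out = correlate_phf_host(phf, host, nsmap)
        assert len(out) == 0

    @pytest.mark.parametrize("rho_true", [0.1, 0.6, 0.9])
    def test_correlation_recovery(self, rho_true):
        rng = np.random.default_rng(1000 + int(rho_true * 100))
        xy = rng.multivariate_normal(
            [0, 0], [[1, rho_true], [rho_true, 1]], size=500
        )
        phf, host, nsmap = self._tables(
            np.exp(xy[:, 0]), np.exp(xy[:, 1])
        )
        out = correlate_phf_host(phf, host, nsmap)
        assert out["rho"].iloc[0] == pytest.approx(rho_true, abs=0.1)


class TestPruneToFamilies:
    def test_first_preorder_tip_represents_family(self):
        tree = _tree("((A:1,B:2):0.5,(C:1,D:1):0.7);")
        pruned = prune_to_families(
            tree, {"A": "FamX", "B": "FamX", "C": "FamY", "D": "FamY"}
        )
        assert sorted(t.name for t in pruned.tips()) == ["FamX", "FamY"]

    def test_unannotated_tree_rejected(self):
        tree = _tree("(A:1,B:1);")
        with pytest.raises(ValueError):
            prune_to_families(tree, {"Z": "FamX"})
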