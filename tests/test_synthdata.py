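import numpy as np
import pandas as pd
import pytest

from phfkit.concordance import ComparisonMode, concordance_report
from phfkit.ecology import distance_matrix, partition_distances
from phfkit.io import write_abundance, write_linkage_table, write_prediction_table
from phfkit.pipeline import agglomerate, prevalence, prevalent_features, to_relative_abundance
from phfkit.synthdata import (
    CohortConfig,
    generate_cohort,
    generate_host_tables,
    plant_prevalence,
    sample_depths,
)
from phfkit.taxonomy import CONCORDANCE_RANKS, Rank, names_match_at

SMALL = dict(
    n_individuals=3, samples_per_individual=4, n_families=16,
    votus_per_family_per_individual=3,
)


class TestConfigValidation:
    def test_shared_pool_needs_two_individuals(self):
        cfg = CohortConfig(n_individuals=1, shared_votu_fraction=0.2)
        with pytest.raises(ValueError, match="two individuals"):
            cfg.validate()

    def test_error_rates_must_grow_with_depth(self):
        cfg = CohortConfig(prediction_error={
            Rank.PHYLUM: 0.5, Rank.CLASS: 0.1, Rank.ORDER: 0.1,
            Rank.FAMILY: 0.1, Rank.GENUS: 0.1,
        })
        with pytest.raises(ValueError, match="non-decreasing"):
            cfg.validate()

    def test_proportions_in_range(self):
        with pytest.raises(ValueError):
            CohortConfig(p_predicted=1.5).validate()


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = CohortConfig(seed=42, **SMALL)
        outs = []
        for run in ("a", "b"):
            cohort = generate_cohort(CohortConfig(seed=42, **SMALL))
            d = tmp_path / run
            d.mkdir()
            write_prediction_table(cohort.predictions, d / "p.tsv")
            write_linkage_table(cohort.linkages, d / "l.tsv")
            write_abundance(cohort.abundance, d / "m.tsv", d / "f.tsv", d / "s.tsv")
            outs.append(d)
        for name in ("p.tsv", "l.tsv", "m.tsv", "f.tsv", "s.tsv"):
            assert (outs[0] / name).read_bytes() == (outs[1] / name).read_bytes()

    def test_different_seed_differs(self):
        a = generate_cohort(CohortConfig(seed=1, **SMALL))
        b = generate_cohort(CohortConfig(seed=2, **SMALL))
        assert not a.abundance.values.equals(b.abundance.values)


class TestGroundTruthStructure:
    def test_lineages_are_internally_consistent(self):
        """Matching at a rank implies matching at every shallower rank, both
        for truths and for corrupted predictions."""
        cfg = CohortConfig(seed=3, **SMALL)
        cohort = generate_cohort(cfg)
        lineages = list(cohort.truth.lineages.values())
        lineages += [l for l in cohort.predictions.rows["lineage"]]
        by_key = {}
        for l in lineages[:500]:
            for shallow, deep in zip(CONCORDANCE_RANKS, CONCORDANCE_RANKS[1:]):
                key = l.name_at(deep)
                if key:
                    by_key.setdefault((deep, key), set()).add(l.name_at(shallow))
        for (deep, key), parents in by_key.items():
            assert len(parents) == 1, f"{deep}:{key} has parents {parents}"

    def test_noiseless_config_recovers_100_percent(self):
        cfg = CohortConfig(
            seed=4, p_predicted=1.0, multi_prediction_rate=0.0,
            hic_multi_host_rate=0.0,
            prediction_error={r: 0.0 for r in CONCORDANCE_RANKS},
            **SMALL,
        )
        pred, link, _ = generate_host_tables(cfg, 200)
        rep = concordance_report(pred, link)
        assert (rep.table["percent"] == 100.0).all()

    def test_marginal_error_rates_converge(self):
        """Law of large numbers: empirical per-rank error of the primary
        prediction is within 2% of the configured rate at n = 5,000."""
        cfg = CohortConfig(
            seed=5, p_predicted=1.0, multi_prediction_rate=0.0,
            hic_multi_host_rate=0.0,
        )
        pred, link, truth = generate_host_tables(cfg, 5_000)
        best = {c: lins[0][0] for c, lins in pred.grouped().items()}
        for rank in CONCORDANCE_RANKS:
            err = np.mean([
                not names_match_at(best[c], truth.lineages[c], rank)
                for c in best
            ])
            assert err == pytest.approx(
                cfg.prediction_error[rank], abs=0.02
            ), str(rank)

    def test_confidence_ranks_primary_first(self):
        cfg = CohortConfig(seed=6, p_predicted=1.0, multi_prediction_rate=1.0)
        pred, _, truth = generate_host_tables(cfg, 300)
        counts = pred.rows.groupby("contig_id").size()
        assert (counts > 1).any()


class TestCohortEcology:
    def test_ar1_autocorrelation_recovered(self):
        """Lag-1 autocorrelation of log relative abundance tracks the
        configured persistence (long series, near-noiseless counts)."""
        cfg = CohortConfig(
            seed=7, n_individuals=1, samples_per_individual=200, n_families=4,
            votus_per_family_per_individual=5, shared_votu_fraction=0.0,
            ar_persistence=0.8, mean_depth=1e6, depth_dispersion=0.01,
            prediction_error={r: 0.0 for r in CONCORDANCE_RANKS},
            hic_multi_host_rate=0.0, multi_prediction_rate=0.0,
        )
        cohort = generate_cohort(cfg)
        rel = cohort.abundance.values.div(
            cohort.abundance.values.sum(axis=0), axis=1
        )
        logs = np.log(rel + 1e-12)
        acs = []
        for f in rel.index:
            x = logs.loc[f].to_numpy()
            x = x - x.mean()
            denom = (x * x).sum()
            if denom > 0:
                acs.append((x[:-1] * x[1:]).sum() / denom)
        assert np.mean(acs) == pytest.approx(0.8, abs=0.1)

    def test_private_votus_shared_families(self):
        """Contig-level communities are individual-specific while family
        profiles are shared: interindividual Bray-Curtis is much higher at
        the vOTU level than at the PHF level."""
        cohort = generate_cohort(CohortConfig(seed=8, shared_votu_fraction=0.05))
        rel = to_relative_abundance(cohort.abundance)
        d_votu = distance_matrix(rel, "bray_curtis")
        agg = agglomerate(rel, labels=cohort.abundance.feature_meta["true_family"])
        d_phf = distance_matrix(agg, "bray_curtis")
        meta = cohort.abundance.sample_meta
        inter_votu = partition_distances(d_votu, meta)["inter"].mean()
        inter_phf = partition_distances(d_phf, meta)["inter"].mean()
        assert inter_votu - inter_phf > 0.1

    def test_tree_covers_all_families(self):
        cohort = generate_cohort(CohortConfig(seed=9, **SMALL))
        tips = {t.name for t in cohort.tree.tips()}
        assert tips == set(cohort.truth.family_profiles.columns)
        for node in cohort.tree.traverse(include_self=False):
            assert node.length > 0


class TestPlantedPrevalence:
    @pytest.mark.parametrize("k", [0, 18, 74])
    def test_exactly_k_features_flagged(self, k):
        cfg = CohortConfig(seed=10, n_families=74, n_individuals=20,
                           samples_per_individual=3)
        table, planted = plant_prevalence(cfg, k)
        prev = prevalence(table)
        flagged = sorted(prevalent_features(prev))
        assert flagged == sorted(planted)
        assert len(flagged) == k

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            plant_prevalence(CohortConfig(n_families=10), 11)


class TestDepthModel:
    def test_calibrated_tail_mass(self):
        rng = np.random.default_rng(11)
        d = sample_depths(20_000, rng, below_fraction=0.315, threshold=1_500)
        assert (d < 1_500).mean() == pytest.approx(0.315, abs=0.02)
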