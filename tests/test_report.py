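"""eGene summaries, contribution profiles, combination trees, replication."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import grscan as gs
from grscan.report import percent_half_up, significant_records, tree_to_nested_dict
from conftest import make_cohort, make_weights


def records_from(rows):
    """rows: (combination, gene, es, p[, q])"""
    df = pd.DataFrame(rows, columns=["combination", "gene_id", "es", "p"])
    df["se"] = 0.1
    df["n_low"] = df["n_high"] = 10
    df["q"] = df["p"]
    return df


class TestSummarizeEgenes:
    def test_toy_filtering_and_strongest(self):
        rows = [
            ("a", "A", 1.0, 1e-9),
            ("a+b", "A", -2.0, 1e-8),
            ("a+b+c", "A", 1.5, 1e-8),
            ("a", "B", 0.5, 1e-9),
            ("b", "B", 0.4, 1e-9),
            ("c", "B", 0.4, 0.5),  # not significant
        ]
        out = gs.summarize_egenes(records_from(rows), 1e-5, stat="p", min_combinations=3)
        assert list(out["gene_id"]) == ["A"]
        row = out.iloc[0]
        assert row["n_significant_combinations"] == 3
        assert row["min_combination_size"] == 1
        assert row["max_combination_size"] == 3
        assert row["strongest_combination"] == "a+b"  # max |es|
        assert row["strongest_es"] == -2.0
        assert row["single_variant_sufficient"]

    def test_empty_and_too_strict(self):
        assert gs.summarize_egenes(records_from([]), 0.05, stat="p").empty
        rows = [("a", "A", 1.0, 0.5)]
        assert gs.summarize_egenes(records_from(rows), 1e-10, stat="p").empty

    def test_threshold_monotonicity(self, rng):
        rows = [
            (f"v{i}", f"G{i % 7}", rng.normal(), 10 ** -rng.uniform(0, 8))
            for i in range(60)
        ]
        recs = records_from(rows)
        loose = set(gs.summarize_egenes(recs, 1e-2, stat="p")["gene_id"])
        strict = set(gs.summarize_egenes(recs, 1e-5, stat="p")["gene_id"])
        assert strict <= loose


class TestContributionProfile:
    def test_printed_percent_resolution(self):
        assert percent_half_up(40366, 40903) == 98.7
        assert percent_half_up(36873, 40903) == 90.1
        assert percent_half_up(182, 192) == 94.8
        assert percent_half_up(5, 5) == 100.0

    def test_counts_and_fractions(self):
        rows = [
            ("a+b", "A", 1.0, 1e-9),
            ("a+c", "A", 1.0, 1e-9),
            ("a+b+c", "A", 1.0, 1e-9),
            ("b+c", "A", 1.0, 0.9),  # not significant
        ]
        prof = gs.contribution_profile(records_from(rows), 1e-5, stat="p")
        assert prof.attrs["n_significant_combinations"] == 3
        got = dict(zip(prof["variant_id"], prof["n_combinations"]))
        assert got == {"a": 3, "b": 2, "c": 2}
        assert prof.loc[prof["variant_id"] == "a", "percent"].item() == 100.0

    def test_partition_reconstructs_total(self, rng):
        """Combinations containing v plus those not containing v must sum to
        the gene's significant-combination count."""
        pool = ["a", "b", "c", "d"]
        combos = [
            "+".join(c) for k in (1, 2, 3) for c in combinations(pool, k)
        ]
        rows = [(c, "G", 1.0, 1e-8) for c in combos]
        recs = records_from(rows)
        prof = gs.contribution_profile(recs, 1e-5, stat="p")
        total = prof.attrs["n_significant_combinations"]
        n_with_a = prof.loc[prof["variant_id"] == "a", "n_combinations"].item()
        n_without_a = sum(1 for c in combos if "a" not in c.split("+"))
        assert n_with_a + n_without_a == total

    def test_no_significant_is_an_error(self):
        recs = records_from([("a", "A", 1.0, 0.9)])
        with pytest.raises(ValueError, match="no significant"):
            gs.contribution_profile(recs, 1e-5, stat="p")


class TestCombinationTree:
    def test_lattice_example(self):
        rows = [
            ("a", "G", 1.0, 1e-9),
            ("a+b", "G", 1.1, 1e-9),
            ("a+c", "G", 1.2, 0.5),
            ("a+b+c", "G", 1.3, 1e-9),
        ]
        tree = gs.build_combination_tree(records_from(rows), "G", ("a",), 1e-5, "p")
        assert set(tree.nodes) == {"a", "a+b", "a+c", "a+b+c"}
        assert sorted(tree.edges) == [
            ("a", "a+b"),
            ("a", "a+c"),
            ("a+b", "a+b+c"),
            ("a+c", "a+b+c"),
        ]
        assert tree.nodes["a+c"]["significant"] is False
        nested = tree_to_nested_dict(tree)
        assert nested["combination"] == "a"
        assert {c["combination"] for c in nested["children"]} == {"a+b", "a+c"}

    def test_root_is_full_set_or_isolated(self):
        rows = [("a+b+c", "G", 1.0, 1e-9), ("a", "G", 1.0, 1e-9)]
        recs = records_from(rows)
        t1 = gs.build_combination_tree(recs, "G", ("a", "b", "c"))
        assert len(t1.nodes) == 1 and t1.edges == []
        # no tested superset adds exactly one variant to {a}
        t2 = gs.build_combination_tree(recs, "G", ("a",))
        assert len(t2.nodes) == 1

    def test_missing_root_raises(self):
        recs = records_from([("a", "G", 1.0, 1e-9)])
        with pytest.raises(KeyError):
            gs.build_combination_tree(recs, "G", ("b",))

    def test_edges_match_bruteforce_covering_relations(self, rng):
        """Edges equal the covering relations of the subset lattice
        restricted to tested combinations reachable from the root."""
        pool = ["a", "b", "c", "d", "e"]
        tested = set()
        for k in range(1, 6):
            for c in combinations(pool, k):
                if rng.random() < 0.6:
                    tested.add(c)
        tested.add(("a",))
        rows = [("+".join(c), "G", 1.0, 1e-9) for c in tested]
        tree = gs.build_combination_tree(records_from(rows), "G", ("a",))
        # brute-force: reachable closure under +1-variant tested supersets
        reach = {frozenset(["a"])}
        grew = True
        while grew:
            grew = False
            for t in tested:
                ft = frozenset(t)
                for r in list(reach):
                    if len(ft) == len(r) + 1 and r < ft and ft not in reach:
                        reach.add(ft)
                        grew = True
        expected_edges = {
            ("+".join(sorted(p)), "+".join(sorted(c)))
            for p in reach
            for c in reach
            if len(c) == len(p) + 1 and p < c
        }
        assert set(tree.edges) == expected_edges


class TestCrossDataset:
    def test_overlap_cases(self):
        shared, counts = gs.cross_dataset_overlap({"g1", "g2", "g3"}, {"g2", "g3", "g4"})
        assert shared == {"g2", "g3"} and counts == (3, 3, 2)
        assert gs.cross_dataset_overlap({"a"}, {"b"})[0] == set()
        assert gs.cross_dataset_overlap({"a", "b"}, {"a", "b"})[1] == (2, 2, 2)


class TestReplication:
    def _cohort_and_records(self, rng, n=60):
        dosage = rng.binomial(2, 0.4, size=(n, 3))
        y = rng.normal(size=(2, n))
        y[0] += 0.8 * dosage.sum(axis=1)
        cohort = make_cohort(dosage, y)
        wt = make_weights(["v1", "v2", "v3"], [1.3, 1.5, 1.7])
        records, _ = gs.run_series(cohort, wt, config=gs.ScanConfig(q_fraction=0.3))
        return cohort, wt, records

    def test_self_replication_reproduces_es(self, rng):
        cohort, wt, records = self._cohort_and_records(rng)
        table = gs.replicate_top_combinations(
            records, cohort, wt, top_k=3, threshold=0.05, stat="q"
        )
        tested = table[table["testable"]]
        assert len(tested) > 0
        np.testing.assert_allclose(tested["es_b"], tested["es_a"], rtol=1e-10)
        assert tested["same_sign"].all()

    def test_fewer_than_top_k_and_untestable(self, rng):
        cohort, wt, records = self._cohort_and_records(rng)
        sig = significant_records(records, 0.05, "q")
        gene = sig["gene_id"].iloc[0]
        n_avail = sig[sig["gene_id"] == gene]["combination"].nunique()
        table = gs.replicate_top_combinations(
            records, cohort, wt, top_k=n_avail + 50, threshold=0.05, stat="q"
        )
        assert len(table[table["gene_id"] == gene]) == n_avail
        # drop a variant from cohort_b: rows flagged untestable, kept
        small = cohort.genotypes
        keep = [v for v in small.variant_ids if v != "v1"]
        gm2 = gs.GenotypeMatrix(
            sample_ids=small.sample_ids,
            variant_ids=np.array(keep, dtype=object),
            dosage=small.dosage_for(keep),
            variant_meta=small.variant_meta.loc[keep],
        )
        cohort_b = gs.Cohort(
            genotypes=gm2, expression=cohort.expression, covariates=cohort.covariates
        )
        table2 = gs.replicate_top_combinations(
            records, cohort_b, wt, top_k=5, threshold=0.05, stat="q"
        )
        has_v1 = table2["combination"].str.split("+").map(lambda c: "v1" in c)
        assert (~table2.loc[has_v1, "testable"]).all()
        assert len(table2) == len(
            gs.replicate_top_combinations(records, cohort, wt, 5, 0.05, "q")
        )

    def test_sign_concordance_on_independent_draws(self):
        """Planted effects keep their sign when the strongest combinations
        are re-tested in an independent cohort from the same recipe."""
        concordant = total = 0
        for seed in range(10):
            cfg = gs.demo_config(seed)
            cohort_a, wt, truth = gs.simulate_cohort(cfg)
            rec_a, _ = gs.run_series(cohort_a, wt)
            cohort_b, _, _ = gs.simulate_cohort(
                gs.demo_config(seed + 1000)
            )
            sig = rec_a[rec_a["significant"] & rec_a["gene_id"].isin(truth["gene_id"])]
            if sig.empty:
                continue
            table = gs.replicate_top_combinations(
                sig.assign(q=sig["q"]), cohort_b, wt, top_k=5,
                threshold=0.05, stat="q",
            )
            tested = table[table["testable"]]
            concordant += int(tested["same_sign"].sum())
            total += len(tested)
        assert total > 0
        assert concordant / total > 0.9
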