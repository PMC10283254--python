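from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from scsnf.characterize import (
    GeneSetCollection,
    differential_expression,
    enrichment_overlap,
    map_mirna_targets,
    ora_hypergeometric,
    read_gmt,
    read_mirna_targets,
)


def enumeration_p(N, K, m, k):
    """Exhaustive enumeration of all C(N, m) query draws: the fraction with
    overlap >= k against a fixed K-subset of the universe."""
    universe = list(range(N))
    pathway = set(range(K))
    hits = total = 0
    for draw in combinations(universe, m):
        total += 1
        hits += len(pathway & set(draw)) >= k
    return hits / total


def make_collection(sets, universe=None):
    return GeneSetCollection({k: set(v) for k, v in sets.items()},
                             set(universe) if universe else set())


class TestDifferentialExpression:
    def test_null_type_one_error(self, block_factory):
        rng = np.random.default_rng(1)
        block = block_factory(rng.normal(size=(200, 500)))
        labels = pd.Series([1, 2] * 100, index=block.subject_ids)
        de = differential_expression(block, labels)
        rate = (de["p"] < 0.05).mean()
        assert abs(rate - 0.05) < 0.03
        assert (de["q"] < 0.05).sum() <= 2

    def test_separable_feature_detected_up(self, block_factory):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(60, 20))
        labels = pd.Series([1, 2] * 30, index=[f"S{i:03d}" for i in range(60)])
        vals[:, 0] = (labels.values == 1) + rng.normal(0, 0.01, 60)
        block = block_factory(vals, subjects=list(labels.index))
        de = differential_expression(block, labels).set_index("feature")
        top = de.loc[block.feature_ids[0]]
        assert top["q"] < 1e-6
        assert top["direction"] == "up"

    def test_covariate_invariance_on_independent_data(self, block_factory):
        rng = np.random.default_rng(3)
        block = block_factory(rng.normal(size=(120, 50)))
        labels = pd.Series([1, 2] * 60, index=block.subject_ids)
        cov = pd.DataFrame({"cpi": rng.normal(50, 10, 120)}, index=block.subject_ids)
        plain = differential_expression(block, labels).set_index("feature")["estimate"]
        adj = differential_expression(block, labels, covariates=cov).set_index("feature")["estimate"]
        assert np.abs(plain - adj).max() < 0.5

    def test_bh_monotone_in_p(self, block_factory):
        rng = np.random.default_rng(4)
        block = block_factory(rng.normal(size=(30, 40)))
        labels = pd.Series([1, 2] * 15, index=block.subject_ids)
        de = differential_expression(block, labels)
        by_p = de.sort_values("p")["feature"].tolist()
        by_q = de.sort_values(["q", "p"])["feature"].tolist()
        assert by_p == by_q

    def test_singleton_subtype_errors(self, block_factory):
        block = block_factory(np.random.default_rng(0).normal(size=(5, 3)))
        labels = pd.Series([1, 2, 2, 2, 2], index=block.subject_ids)
        with pytest.raises(ValueError, match="3 subjects"):
            differential_expression(block, labels)

    def test_direction_partition(self, small_study):
        from scsnf.io import standardize_features

        block = standardize_features(small_study.blocks["protein"])
        de = differential_expression(block, small_study.true_labels)
        up = set(de.loc[de["direction"] == "up", "feature"])
        down = set(de.loc[de["direction"] == "down", "feature"])
        assert not (up & down)
        assert up or down  # planted signal must surface


class TestMirnaTargets:
    def de_frame(self, rows):
        return pd.DataFrame(rows, columns=["feature", "modality", "estimate", "p", "q", "direction"])

    def test_union_semantics(self):
        de = self.de_frame([
            ("m1", "mirna", 1.0, 0.001, 0.01, "up"),
            ("m2", "mirna", 0.8, 0.002, 0.01, "up"),
        ])
        out = map_mirna_targets(de, {"m1": {"A", "B"}, "m2": {"B", "C"}})
        assert out["up"] == {"A", "B", "C"}
        assert out["down"] == set()

    def test_no_significant_mirnas(self):
        de = self.de_frame([("m1", "mirna", 0.1, 0.5, 0.9, "")])
        out = map_mirna_targets(de, {"m1": {"A"}})
        assert out == {"up": set(), "down": set()}

    def test_missing_mirna_skipped(self, caplog):
        de = self.de_frame([
            ("m1", "mirna", 1.0, 0.001, 0.01, "up"),
            ("m9", "mirna", -1.0, 0.001, 0.01, "down"),
        ])
        out = map_mirna_targets(de, {"m1": {"A"}})
        assert out["up"] == {"A"} and out["down"] == set()

    def test_empty_map_errors(self):
        with pytest.raises(ValueError, match="empty"):
            map_mirna_targets(self.de_frame([]), {})

    def test_read_target_map(self, tmp_path):
        path = tmp_path / "targets.tsv"
        path.write_text("mirna_id\tgene_symbol\nm1\tA\nm1\tB\nm2\tC\n")
        assert read_mirna_targets(path) == {"m1": {"A", "B"}, "m2": {"C"}}


class TestORA:
    def test_worked_example_252_over_15504(self):
        universe = {f"g{i}" for i in range(20)}
        pathway = {f"g{i}" for i in range(10)}
        query = {f"g{i}" for i in range(5)}  # all 5 inside the pathway
        coll = make_collection({"P": pathway}, universe)
        res = ora_hypergeometric(query, coll)
        assert res.loc[0, "p"] == pytest.approx(252 / 15504, abs=1e-12)

    def test_zero_overlap_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        coll = make_collection({"P": {f"g{i}" for i in range(10)}}, universe)
        res = ora_hypergeometric({f"g{i}" for i in range(15, 20)}, coll)
        assert res.loc[0, "p"] == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "N,K,m,k", [(10, 4, 3, 2), (12, 6, 5, 3), (15, 5, 6, 1), (20, 10, 5, 5), (25, 8, 6, 4)]
    )
    def test_matches_exhaustive_enumeration(self, N, K, m, k):
        universe = {f"g{i}" for i in range(N)}
        pathway = {f"g{i}" for i in range(K)}
        # query drawing exactly k pathway genes and m-k outside genes
        query = {f"g{i}" for i in range(k)} | {f"g{i}" for i in range(K, K + m - k)}
        coll = make_collection({"P": pathway}, universe)
        res = ora_hypergeometric(query, coll)
        assert res.loc[0, "p"] == pytest.approx(enumeration_p(N, K, m, k), abs=1e-12)

    def test_query_equals_universe(self):
        # with the whole universe drawn, every pathway overlap is certain
        universe = {f"g{i}" for i in range(12)}
        coll = make_collection({"P": {f"g{i}" for i in range(5)}}, universe)
        res = ora_hypergeometric(set(universe), coll)
        assert res.loc[0, "p"] == pytest.approx(enumeration_p(12, 5, 12, 5), abs=1e-12)

    def test_empty_query_empty_result(self):
        coll = make_collection({"P": {"a", "b"}})
        assert ora_hypergeometric(set(), coll).empty

    def test_empty_collection_errors(self):
        with pytest.raises(ValueError):
            ora_hypergeometric({"a"}, GeneSetCollection({}, {"a"}))

    def test_nested_query_monotone_in_overlap(self):
        # adding a pathway gene to the query never increases that pathway's p
        universe = {f"g{i}" for i in range(18)}
        pathway = {f"g{i}" for i in range(7)}
        coll = make_collection({"P": pathway}, universe)
        query = {f"g{i}" for i in range(10, 14)}
        last = ora_hypergeometric(query, coll).loc[0, "p"]
        for i in range(4):
            query = query | {f"g{i}"}
            p = ora_hypergeometric(query, coll).loc[0, "p"]
            assert p <= last + 1e-12
            last = p

    def test_read_gmt(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("P1\tdesc\tA\tB\nP2\tdesc\tB\tC\tD\n")
        coll = read_gmt(path)
        assert coll.sets == {"P1": {"A", "B"}, "P2": {"B", "C", "D"}}
        assert coll.universe == {"A", "B", "C", "D"}


class TestEnrichmentOverlap:
    def test_triple_intersection(self):
        table = enrichment_overlap({"x": {"A", "B"}, "y": {"B", "C"}, "z": {"B"}})
        triple = table.set_index("region").loc["x & y & z"]
        assert triple["count"] == 1 and triple["members"] == "B"

    def test_disjoint_sets(self):
        table = enrichment_overlap({"x": {"A"}, "y": {"B"}})
        assert table.set_index("region").loc["x & y", "count"] == 0

    def test_identical_sets_all_in_full_region(self):
        table = enrichment_overlap({"x": {"A", "B"}, "y": {"A", "B"}, "z": {"A", "B"}})
        by_region = table.set_index("region")["count"]
        assert by_region["x & y & z"] == 2
        assert by_region.drop("x & y & z").sum() == 0

    def test_duplicate_names_error(self):
        with pytest.raises(ValueError):
            enrichment_overlap({"x": {"A"}})
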