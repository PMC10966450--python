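"""Pair curation, fold planning, and the synthetic fixture generator."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from voxelppi.dataset import (DatasetError, FoldPlan, PairRecord,
                              curate_pairs, expand_training_items,
                              greedy_cluster, make_folds, pair_key,
                              read_cluster_map, read_pair_table)
from voxelppi.preprocess import compute_interface, remove_disordered
from voxelppi.structure_io import parse_structure
from voxelppi.synthetic import (FixtureError, FixtureSpec,
                                build_fixture_complex,
                                generate_fixture_complex)


def table(rows):
    return pd.DataFrame(rows, columns=["id_a", "id_b", "label"])


class TestCuratePairs:
    def test_conflict_removed_from_negatives(self):
        pos = table([("P", "Q", 1), ("R", "S", 1)])
        neg = table([("Q", "P", 0), ("R", "Q", 0), ("S", "P", 0)])
        records = curate_pairs(pos, neg)
        neg_keys = {r.key for r in records if r.label == 0}
        assert pair_key("P", "Q") not in neg_keys
        assert {r.key for r in records if r.label == 1} == {
            ("P", "Q"), ("R", "S")}

    def test_self_interactions_dropped(self):
        pos = table([("P", "P", 1), ("P", "Q", 1)])
        neg = table([("Q", "R", 0)])
        records = curate_pairs(pos, neg)
        assert all(r.id_a != r.id_b for r in records)
        assert len(records) == 2

    def test_duplicates_collapse_and_sum_evidence(self):
        pos = pd.DataFrame({"id_a": ["P", "Q"], "id_b": ["Q", "P"],
                            "label": [1, 1], "evidence_count": [2, 3]})
        neg = table([("P", "R", 0)])
        records = curate_pairs(pos, neg)
        rec = next(r for r in records if r.label == 1)
        assert rec.evidence_count == 5

    def test_redundant_pair_with_fewer_interactions_dropped(self):
        # P and P' are 95% identical; P' has more recorded interactions
        pos = table([("P", "Q", 1), ("Pp", "Q", 1), ("Pp", "R", 1)])
        neg = table([("Q", "S", 0)])

        def similarity(a, b):
            return 0.95 if {a, b} == {"P", "Pp"} else (1.0 if a == b else 0.1)

        records = curate_pairs(pos, neg, similarity=similarity)
        keys = {r.key for r in records}
        assert pair_key("P", "Q") not in keys
        assert pair_key("Pp", "Q") in keys

    def test_idempotent(self):
        pos = table([("P", "Q", 1), ("Q", "R", 1), ("P", "P", 1)])
        neg = table([("P", "Q", 0), ("R", "S", 0), ("S", "P", 0)])
        first = curate_pairs(pos, neg)
        pos2 = table([(r.id_a, r.id_b, 1) for r in first if r.label == 1])
        neg2 = table([(r.id_a, r.id_b, 0) for r in first if r.label == 0])
        second = curate_pairs(pos2, neg2)
        assert [(r.key, r.label) for r in first] == \
            [(r.key, r.label) for r in second]

    def test_empty_result_rejected(self):
        with pytest.raises(DatasetError):
            curate_pairs(table([("P", "P", 1)]), table([("Q", "Q", 0)]))

    def test_balance_warning(self, caplog):
        pos = table([("P", "Q", 1)])
        neg = table([("P", "R", 0)])
        with caplog.at_level("WARNING"):
            curate_pairs(pos, neg)
        assert "balance" in caplog.text


class TestFolds:
    def ten_pairs(self):
        return [PairRecord(f"P{i}", f"Q{i}", i % 2) for i in range(10)]

    def test_singleton_clusters_balance(self):
        pairs = self.ten_pairs()
        cmap = {p: p for r in pairs for p in r.key}
        plan = make_folds(pairs, cmap, k=5, seed=0)
        sizes = [len(plan.pairs_in_fold(f)) for f in range(5)]
        assert sizes == [2, 2, 2, 2, 2]
        plan.validate()

    def test_shared_cluster_stays_together(self):
        pairs = self.ten_pairs()
        cmap = {p: p for r in pairs for p in r.key}
        cmap["P0"] = cmap["P1"] = "clusterX"  # links pairs 0 and 1
        plan = make_folds(pairs, cmap, k=5, seed=0)
        assert plan.assignment[pair_key("P0", "Q0")] == \
            plan.assignment[pair_key("P1", "Q1")]
        plan.validate()

    def test_deterministic_given_seed(self):
        pairs = self.ten_pairs()
        cmap = {p: p for r in pairs for p in r.key}
        p1 = make_folds(pairs, cmap, k=5, seed=3)
        p2 = make_folds(pairs, cmap, k=5, seed=3)
        assert p1.assignment == p2.assignment

    def test_missing_protein_rejected(self):
        pairs = self.ten_pairs()
        cmap = {p: p for r in pairs for p in r.key}
        del cmap["P3"]
        with pytest.raises(DatasetError, match="P3"):
            make_folds(pairs, cmap, k=5, seed=0)

    def test_oversized_cluster_rejected(self):
        pairs = self.ten_pairs()
        cmap = {p: "mega" if p.startswith("P") else p
                for r in pairs for p in r.key}
        with pytest.raises(DatasetError, match="40%"):
            make_folds(pairs, cmap, k=5, seed=0)

    def test_plan_json_roundtrip(self):
        pairs = self.ten_pairs()
        cmap = {p: p for r in pairs for p in r.key}
        plan = make_folds(pairs, cmap, k=5, seed=0)
        plan2 = FoldPlan.from_json(plan.to_json())
        assert plan2.assignment == plan.assignment
        assert plan2.k == plan.k


class TestExpand:
    def test_model_arithmetic(self):
        pairs = [PairRecord(f"P{i}", f"Q{i}", i % 2) for i in range(10)]
        cmap = {p: p for r in pairs for p in r.key}
        plan = make_folds(pairs, cmap, k=5, seed=0)
        fold = 0
        train, test = expand_training_items(plan, fold, pairs)
        assert len(test) == 2
        assert len(train) == 40  # 8 pairs x 5 models
        assert all(m == 1 for _, m, _ in test)
        train_keys = {k for k, _, _ in train}
        test_keys = {k for k, _, _ in test}
        assert not train_keys & test_keys

    def test_partial_models_warn(self, caplog):
        pairs = [PairRecord("P0", "Q0", 1,
                            model_paths={1: "a", 2: "b", 3: "c"})]
        pairs += [PairRecord(f"P{i}", f"Q{i}", i % 2) for i in range(1, 5)]
        cmap = {p: p for r in pairs for p in r.key}
        plan = make_folds(pairs, cmap, k=5, seed=0)
        fold = plan.assignment[pair_key("P1", "Q1")]
        with caplog.at_level("WARNING"):
            train, _ = expand_training_items(plan, fold, pairs)
        assert sum(1 for k, _, _ in train
                   if k == pair_key("P0", "Q0")) == 3
        assert "3 models" in caplog.text

    def test_missing_model1_rejected(self):
        pairs = [PairRecord("P0", "Q0", 1, model_paths={2: "b"})]
        pairs += [PairRecord(f"P{i}", f"Q{i}", i % 2) for i in range(1, 5)]
        cmap = {p: p for r in pairs for p in r.key}
        plan = make_folds(pairs, cmap, k=5, seed=0)
        fold = plan.assignment[pair_key("P0", "Q0")]
        with pytest.raises(DatasetError, match="model 1"):
            expand_training_items(plan, fold, pairs)

    def test_bad_fold_index(self):
        pairs = [PairRecord(f"P{i}", f"Q{i}", i % 2) for i in range(5)]
        cmap = {p: p for r in pairs for p in r.key}
        plan = make_folds(pairs, cmap, k=5, seed=0)
        with pytest.raises(DatasetError):
            expand_training_items(plan, 7, pairs)


class TestTables:
    def test_pair_table_roundtrip(self):
        text = "id_a\tid_b\tlabel\nP\tQ\t1\nR\tS\t0\n"
        df = read_pair_table(io.StringIO(text))
        assert list(df.columns[:3]) == ["id_a", "id_b", "label"]
        assert "evidence_count" in df.columns

    def test_cluster_map_easy_cluster_dialect(self):
        text = "rep1\trep1\nrep1\tmemberA\nrep2\trep2\n"
        cmap = read_cluster_map(io.StringIO(text))
        assert cmap["memberA"] == "rep1"
        assert cmap["rep2"] == "rep2"

    def test_greedy_cluster_single_linkage(self):
        sim = lambda a, b: 1.0 if a == b else \
            (0.6 if {a, b} <= {"P", "Q", "R"} else 0.0)
        cmap = greedy_cluster(["P", "Q", "R", "S"], sim, threshold=0.4)
        assert cmap["P"] == cmap["Q"] == cmap["R"]
        assert cmap["S"] != cmap["P"]


class TestFixtureGenerator:
    def test_gap_is_respected(self):
        s = build_fixture_complex(FixtureSpec(n_res_a=40, n_res_b=40,
                                              gap=5.0, seed=2))
        d, _ = cKDTree(s.chains[0].coords).query(s.chains[1].coords)
        assert d.min() == pytest.approx(5.0, abs=1e-3)

    def test_interface_found_at_default_threshold(self):
        pdb = generate_fixture_complex(FixtureSpec(n_res_a=40, n_res_b=40,
                                                   gap=5.0, seed=3))
        s = parse_structure(pdb)
        res = compute_interface(s)
        assert res.threshold_used == 12.0
        assert res.residues_a and res.residues_b

    def test_tail_ground_truth(self):
        spec = FixtureSpec(n_res_a=40, n_res_b=40, gap=5.0,
                           disordered_tail_len=20,
                           plddt_profile={"core": 90.0, "tail": 30.0},
                           seed=4)
        s = parse_structure(generate_fixture_complex(spec))
        pruned, report = remove_disordered(s)
        assert len(report.removed_segments) == 1
        _, start, end, mean = report.removed_segments[0]
        assert (start, end) == (41, 60)
        assert mean == pytest.approx(30.0)
        assert set(pruned.chains[0].residue_index) == set(range(1, 41))

    def test_byte_identical_given_seed(self):
        spec = FixtureSpec(n_res_a=30, n_res_b=30, gap=4.0, seed=9)
        assert generate_fixture_complex(spec) == \
            generate_fixture_complex(spec)

    def test_seeds_differ(self):
        a = generate_fixture_complex(FixtureSpec(seed=1, n_res_a=30,
                                                 n_res_b=30))
        b = generate_fixture_complex(FixtureSpec(seed=2, n_res_a=30,
                                                 n_res_b=30))
        assert a != b

    def test_heavy_atom_density_realistic(self):
        s = build_fixture_complex(FixtureSpec(n_res_a=150, n_res_b=150,
                                              gap=5.0, seed=5))
        for chain in s.chains:
            coords = chain.coords
            centroid = coords.mean(axis=0)
            radii = np.linalg.norm(coords - centroid, axis=1)
            envelope = 4.0 / 3.0 * np.pi * np.quantile(radii, 0.95) ** 3
            density = 0.95 * len(coords) / envelope
            assert 0.04 < density < 0.12

    def test_four_atoms_per_residue_elements(self):
        s = build_fixture_complex(FixtureSpec(n_res_a=30, n_res_b=30,
                                              gap=5.0, seed=6))
        for chain in s.chains:
            assert len(chain) == 4 * 30
            assert set(chain.element) <= {"C", "N", "O", "S"}
            assert chain.is_ca.sum() == 30

    def test_impossible_packing_rejected(self):
        with pytest.raises(FixtureError):
            build_fixture_complex(FixtureSpec(n_res_a=200, n_res_b=10,
                                              gap=5.0, density=0.8, seed=0))

    def test_invalid_spec_rejected(self):
        with pytest.raises(FixtureError):
            FixtureSpec(n_res_a=0)
        with pytest.raises(FixtureError):
            FixtureSpec(gap=-1.0)
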