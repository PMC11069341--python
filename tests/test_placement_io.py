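"""jplace parsing, best-hit classification, quality filtering, grouping."""

import json

import numpy as np
import pandas as pd
import pytest

from guildquant import placement_io as pio
from guildquant import synthetic_data as syn
from guildquant import tree_annotation as ta
from guildquant._trees import leaf_ids_under, node_id
from conftest import disjoint_clades

MINIMAL = {
    "tree": "((A:0.2{0},B:0.1{1})n1:0.3{2},(C:0.1{3},D:0.4{4})n2:0.2{5})root;",
    "placements": [{"p": [[0, -100.0, 1.0]], "n": ["q1"]}],
    "fields": ["edge_num", "likelihood", "like_weight_ratio"],
    "version": 3,
    "metadata": {},
}


def write_minimal(tmp_path, doc=None):
    path = tmp_path / "x.jplace"
    path.write_text(json.dumps(doc if doc is not None else MINIMAL))
    return path


@pytest.fixture
def sim():
    tree = syn.simulate_tree(40, seed=9)
    c1, c2, c3 = disjoint_clades(tree, 4, 10, 3)
    return syn.simulate_placements(
        tree,
        {"cIa": (c1, 1.0), "cIb": (c2, 1.0), "u0": (c3, 0.0)},
        n_queries=120,
        seed=14,
    )


class TestJplaceIO:
    def test_minimal_file_parses(self, tmp_path):
        ps = pio.read_jplace(write_minimal(tmp_path))
        assert len(ps.placements) == 1
        assert ps.placements[0]["name"] == "q1"
        assert ps.placements[0]["p"][0][2] == 1.0

    def test_missing_fields_key_errors_by_name(self, tmp_path):
        doc = {k: v for k, v in MINIMAL.items() if k != "fields"}
        with pytest.raises(ValueError, match="fields"):
            pio.read_jplace(write_minimal(tmp_path, doc))

    def test_unknown_field_warned_not_fatal(self, tmp_path):
        doc = dict(MINIMAL)
        doc["fields"] = ["edge_num", "likelihood", "like_weight_ratio", "wobble"]
        doc["placements"] = [{"p": [[0, -100.0, 1.0, 9.9]], "n": ["q1"]}]
        with pytest.warns(UserWarning, match="wobble"):
            pio.read_jplace(write_minimal(tmp_path, doc))

    def test_lwr_above_one_rejected(self, tmp_path):
        doc = dict(MINIMAL)
        doc["placements"] = [{"p": [[0, -1.0, 0.8], [1, -1.0, 0.5]], "n": ["q1"]}]
        with pytest.raises(ValueError, match="like_weight_ratio"):
            pio.read_jplace(write_minimal(tmp_path, doc))

    def test_unknown_edge_rejected(self, tmp_path):
        doc = dict(MINIMAL)
        doc["placements"] = [{"p": [[99, -1.0, 1.0]], "n": ["q1"]}]
        with pytest.raises(ValueError, match="unknown edges"):
            pio.read_jplace(write_minimal(tmp_path, doc))

    def test_round_trip_is_idempotent(self, tmp_path, sim):
        p1 = tmp_path / "a.jplace"
        p2 = tmp_path / "b.jplace"
        pio.write_jplace(sim.placement_set, p1)
        ps1 = pio.read_jplace(p1)
        pio.write_jplace(ps1, p2)
        assert p1.read_text() == p2.read_text()
        ps2 = pio.read_jplace(p2)
        norm = lambda ps: sorted(
            (q["name"], sorted(map(tuple, q["p"]))) for q in ps.placements
        )
        assert norm(ps1) == norm(ps2)

    def test_edge_tokens_map_to_the_right_nodes(self):
        tree, edge_map = pio.parse_jplace_tree(MINIMAL["tree"])
        leaves_of = {num: leaf_ids_under(nd) for num, nd in edge_map.items()}
        assert leaves_of[0] == frozenset({"A"})
        assert leaves_of[2] == frozenset({"A", "B"})
        assert leaves_of[5] == frozenset({"C", "D"})


class TestConsensusTaxonomy:
    def tree(self):
        import dendropy

        return dendropy.Tree.get(
            data="((A:1,B:1)p:1,(C:1,D:1)q:1)r;", schema="newick",
            preserve_underscores=True,
        )

    def test_longest_common_prefix(self):
        tax = pio.consensus_taxonomy(
            self.tree(),
            {"A": "Bacteria;Proteo;Alpha", "B": "Bacteria;Proteo;Gamma",
             "C": "Bacteria;Firm;Bacilli", "D": "Bacteria;Firm;Bacilli"},
        )
        assert tax["p"] == "Bacteria;Proteo"
        assert tax["q"] == "Bacteria;Firm;Bacilli"
        assert tax["r"] == "Bacteria"

    def test_disjoint_domains_give_empty_root(self):
        tax = pio.consensus_taxonomy(
            self.tree(),
            {"A": "Bacteria;X", "B": "Bacteria;X", "C": "Archaea;Y", "D": "Archaea;Y"},
        )
        assert tax["r"] == ""

    def test_missing_or_malformed_path_errors(self):
        with pytest.raises(KeyError, match="D"):
            pio.consensus_taxonomy(self.tree(), {"A": "x", "B": "x", "C": "x"})
        with pytest.raises(ValueError, match="B"):
            pio.consensus_taxonomy(
                self.tree(), {"A": "x", "B": "x;;y", "C": "x", "D": "x"}
            )


class TestAssignQueries:
    def test_best_hit_recovers_planted_clusters(self, sim):
        asg = pio.assign_queries(sim.placement_set, sim.annotated_tree)
        truth = dict(zip(sim.truth_assignments["query"], sim.truth_assignments["cluster"]))
        assert all(truth[q] == c for q, c in zip(asg["query"], asg["cluster"]))

    def test_argmax_on_split_mass(self, sim):
        ps = sim.placement_set
        tree, edge_map = pio.parse_jplace_tree(ps.tree_text)
        atree = sim.annotated_tree
        # craft a query with 0.6 in one cluster, 0.4 in another
        by_cluster = {}
        for num in edge_map:
            lab = atree.cluster_of(_edge_child_id(tree, edge_map, num))[0]
            by_cluster.setdefault(lab, []).append(num)
        e1 = by_cluster["cIa"][0]
        e2 = by_cluster["cIb"][0]
        crafted = pio.PlacementSet(
            tree_text=ps.tree_text,
            fields=ps.fields,
            placements=[{"name": "qx", "p": [[e1, -1.0, 0.6], [e2, -1.0, 0.4]]}],
        )
        asg = pio.assign_queries(crafted, atree)
        assert asg.loc[0, "cluster"] == "cIa"
        assert asg.loc[0, "confidence"] == pytest.approx(0.6)

    def test_u0_cluster_flagged_nonfunctional(self, sim):
        asg = pio.assign_queries(sim.placement_set, sim.annotated_tree)
        u0 = asg[asg["cluster"] == "u0"]
        assert len(u0) > 0
        assert (u0["u"] == 0.0).all()

    def test_lwr_scaling_does_not_change_the_winner(self, sim):
        ps = sim.placement_set
        scaled = pio.PlacementSet(
            tree_text=ps.tree_text,
            fields=ps.fields,
            placements=[
                {"name": q["name"], "p": [[r[0], r[1], r[2] * 0.5] for r in q["p"]]}
                for q in ps.placements
            ],
        )
        a1 = pio.assign_queries(ps, sim.annotated_tree)
        a2 = pio.assign_queries(scaled, sim.annotated_tree)
        assert (a1["cluster"] == a2["cluster"]).all()

    def test_edge_count_mismatch_rejected(self, sim):
        other = syn.simulate_tree(10, seed=1)
        atree = ta.AnnotatedTree(other)
        with pytest.raises(ValueError, match="edge count"):
            pio.assign_queries(sim.placement_set, atree)


def _edge_child_id(tree, edge_map, num):
    return node_id(edge_map[num])


class TestFilterAndGroups:
    def test_threshold_splits_and_reports(self):
        asg = pd.DataFrame(
            {"query": ["a", "b"], "cluster": ["c", "c"], "u": [1.0, 1.0],
             "taxonomy": ["t", "t"], "confidence": [0.9, 0.3],
             "best_edge": [0, 1], "n_placements": [1, 1]}
        )
        kept, disc, rep = pio.filter_low_quality(asg, 0.5)
        assert len(kept) == 1 and len(disc) == 1
        assert rep["pct_discarded"] == pytest.approx(50.0)
        assert rep["mean_confidence_kept"] == pytest.approx(0.9)
        kept0, _, rep0 = pio.filter_low_quality(asg, 0.0)
        assert len(kept0) == 2

    def test_discard_fraction_matches_confidence_cdf(self):
        rng = np.random.default_rng(3)
        conf = rng.beta(5, 1, size=2000)
        asg = pd.DataFrame(
            {"query": [f"q{i}" for i in range(2000)], "cluster": "c", "u": 1.0,
             "taxonomy": "t", "confidence": conf, "best_edge": 0, "n_placements": 1}
        )
        thr = 0.7
        _, disc, rep = pio.filter_low_quality(asg, thr)
        assert rep["pct_discarded"] / 100 == pytest.approx((conf < thr).mean(), abs=1e-9)

    def test_grouping_sums_tpm_and_counts_distinct_queries(self):
        asg = pd.DataFrame(
            {"query": ["a", "b", "c"], "cluster": ["cI"] * 3, "u": [1.0] * 3,
             "taxonomy": ["Bacteria;X"] * 3, "confidence": [1.0] * 3,
             "best_edge": [0] * 3, "n_placements": [1] * 3}
        )
        ab = pd.DataFrame(
            {"query_id": ["a", "b", "c"], "context": ["epi"] * 3, "tpm": [5.0, 5.0, 10.0]}
        )
        groups = pio.build_groups(asg, ab)
        assert len(groups) == 1
        assert groups.loc[0, "abundance_tpm"] == pytest.approx(20.0)
        assert groups.loc[0, "d_obs"] == 3

    def test_contexts_do_not_cross_talk(self):
        asg = pd.DataFrame(
            {"query": ["a", "b"], "cluster": ["cI"] * 2, "u": [1.0] * 2,
             "taxonomy": ["Bacteria;X"] * 2, "confidence": [1.0] * 2,
             "best_edge": [0] * 2, "n_placements": [1] * 2}
        )
        ab = pd.DataFrame(
            {"query_id": ["a", "b", "a", "b"], "context": ["epi", "epi", "meso", "meso"],
             "tpm": [1.0, 2.0, 3.0, 4.0]}
        )
        groups = pio.build_groups(asg, ab)
        g = groups.set_index("context")
        assert g.loc["epi", "abundance_tpm"] == pytest.approx(3.0)
        assert g.loc["meso", "abundance_tpm"] == pytest.approx(7.0)

    def test_tpm_conservation_end_to_end(self, sim):
        asg = pio.assign_queries(sim.placement_set, sim.annotated_tree)
        kept, disc, _ = pio.filter_low_quality(asg, 0.5)
        groups = pio.build_groups(kept, sim.abundance)
        kept_tpm = groups["abundance_tpm"].sum()
        disc_tpm = sim.abundance[sim.abundance["query_id"].isin(disc["query"])]["tpm"].sum()
        assert kept_tpm + disc_tpm == pytest.approx(sim.abundance["tpm"].sum())

    def test_duplicate_abundance_rows_rejected(self):
        asg = pd.DataFrame(
            {"query": ["a"], "cluster": ["cI"], "u": [1.0], "taxonomy": ["x"],
             "confidence": [1.0], "best_edge": [0], "n_placements": [1]}
        )
        ab = pd.DataFrame(
            {"query_id": ["a", "a"], "context": ["epi", "epi"], "tpm": [1.0, 2.0]}
        )
        with pytest.raises(ValueError, match="duplicated"):
            pio.build_groups(asg, ab)

    def test_unplaced_abundance_query_warns(self):
        asg = pd.DataFrame(
            {"query": ["a"], "cluster": ["cI"], "u": [1.0], "taxonomy": ["x"],
             "confidence": [1.0], "best_edge": [0], "n_placements": [1]}
        )
        ab = pd.DataFrame(
            {"query_id": ["a", "ghost"], "context": ["epi", "epi"], "tpm": [1.0, 2.0]}
        )
        with pytest.warns(UserWarning, match="never placed"):
            pio.build_groups(asg, ab)

    def test_placed_query_without_abundance_errors_by_default(self):
        asg = pd.DataFrame(
            {"query": ["a", "b"], "cluster": ["cI"] * 2, "u": [1.0] * 2,
             "taxonomy": ["x"] * 2, "confidence": [1.0] * 2,
             "best_edge": [0] * 2, "n_placements": [1] * 2}
        )
        ab = pd.DataFrame({"query_id": ["a"], "context": ["epi"], "tpm": [1.0]})
        with pytest.raises(ValueError, match="lack abundance"):
            pio.build_groups(asg, ab)
        with pytest.warns(UserWarning, match="dropping"):
            groups = pio.build_groups(asg, ab, on_missing_abundance="drop")
        assert groups["d_obs"].sum() == 1
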