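import itertools

import networkx as nx
import numpy as np
import pytest

from panbin.align import AlignmentHit
from panbin.orthology import (
    OrthologTable,
    bbh_pairs,
    best_hits,
    build_graph,
    flag_multicopy,
    infer_orthologs,
    mcl_cluster,
)


def _hit(q, s, score, ident, qc=1.0, sc=1.0):
    return AlignmentHit(q, s, score, ident, min(ident + 5, 100.0), qc, sc, 100)


class TestBestHits:
    def test_single_hit_per_query(self):
        bh = best_hits([_hit("a", "x", 100, 90)])
        assert bh["a"].subject_id == "x"

    def test_equal_score_tie_breaks_on_identity(self):
        bh = best_hits([_hit("a", "x", 100, 80), _hit("a", "y", 100, 90)])
        assert bh["a"].subject_id == "y"

    def test_full_tie_breaks_on_smaller_subject_id(self):
        bh = best_hits([_hit("a", "y", 100, 90), _hit("a", "x", 100, 90)])
        assert bh["a"].subject_id == "x"

    def test_random_table_matches_bruteforce_scan(self):
        rng = np.random.default_rng(0)
        hits = []
        for q in range(10):
            for s in rng.choice(20, size=rng.integers(1, 8), replace=False):
                hits.append(_hit(f"q{q}", f"s{s}", float(rng.integers(50, 200)),
                                 float(rng.integers(30, 100))))
        bh = best_hits(hits)
        for q in {h.query_id for h in hits}:
            mine = [h for h in hits if h.query_id == q]
            top = max((h.score, h.pct_identity) for h in mine)
            expected = min(
                (h for h in mine if (h.score, h.pct_identity) == top),
                key=lambda h: h.subject_id,
            )
            assert bh[q] is expected


class TestBBHPairs:
    def _reciprocal(self, pairs):
        """Build both best-hit maps from (a, b, score, identity, qcov, scov)."""
        ab = {p[0]: _hit(p[0], p[1], p[2], p[3], p[4], p[5]) for p in pairs}
        ba = {p[1]: _hit(p[1], p[0], p[2], p[3], p[5], p[4]) for p in pairs}
        return ab, ba

    def test_stray_low_identity_pair_removed_by_aai_window(self):
        # 20 pairs near 90% identity (sd ~2), one stray at 35%
        rng = np.random.default_rng(1)
        pairs = [(f"a{i}", f"b{i}", 200.0, float(90 + rng.normal(0, 2)), 1.0, 1.0)
                 for i in range(20)]
        pairs.append(("a_stray", "b_stray", 150.0, 35.0, 1.0, 1.0))
        ab, ba = self._reciprocal(pairs)
        accepted, aai = bbh_pairs(ab, ba, "A", "B")
        assert ("a_stray", "b_stray") not in accepted
        assert len(accepted) == 20
        assert aai.n_pairs == 21  # AAI computed on the provisional set

    def test_zero_sd_retains_everything(self):
        pairs = [(f"a{i}", f"b{i}", 100.0, 75.0, 1.0, 1.0) for i in range(5)]
        ab, ba = self._reciprocal(pairs)
        accepted, aai = bbh_pairs(ab, ba, "A", "B")
        assert len(accepted) == 5
        assert aai.sd_identity == 0.0

    def test_low_coverage_excluded_regardless_of_identity(self):
        pairs = [("a0", "b0", 300.0, 99.0, 0.65, 1.0),
                 ("a1", "b1", 100.0, 90.0, 1.0, 1.0),
                 ("a2", "b2", 100.0, 90.0, 1.0, 1.0)]
        ab, ba = self._reciprocal(pairs)
        accepted, _ = bbh_pairs(ab, ba, "A", "B", min_cov=0.70)
        assert ("a0", "b0") not in accepted
        # laxer query-only mode admits it
        accepted_q, _ = bbh_pairs(ab, ba, "A", "B", min_cov=0.60, cov_mode="query")
        assert ("a0", "b0") in accepted_q

    def test_no_provisional_pairs_flags_undefined_aai(self):
        ab = {"a": _hit("a", "b", 100, 90, qc=0.3, sc=0.3)}
        ba = {"b": _hit("b", "a", 100, 90, qc=0.3, sc=0.3)}
        accepted, aai = bbh_pairs(ab, ba, "A", "B")
        assert accepted == {}
        assert not aai.defined

    def test_widening_window_never_removes_pairs(self):
        rng = np.random.default_rng(2)
        pairs = [(f"a{i}", f"b{i}", 100.0, float(rng.uniform(40, 99)), 1.0, 1.0)
                 for i in range(30)]
        ab, ba = self._reciprocal(pairs)
        prev = set()
        for w in (0.5, 1.0, 2.0, 4.0):
            acc, _ = bbh_pairs(ab, ba, "A", "B", aai_window=w)
            assert prev <= set(acc)
            prev = set(acc)

    def test_symmetry_of_acceptance(self):
        rng = np.random.default_rng(3)
        pairs = [(f"a{i}", f"b{i}", 100.0, float(rng.uniform(60, 99)), 1.0, 1.0)
                 for i in range(15)]
        ab, ba = self._reciprocal(pairs)
        acc_fwd, _ = bbh_pairs(ab, ba, "A", "B")
        acc_rev, _ = bbh_pairs(ba, ab, "B", "A")
        assert {(a, b) for a, b in acc_fwd} == {(a, b) for b, a in acc_rev}


def _clique_graph(groups, weight=0.9):
    G = nx.Graph()
    for grp in groups:
        G.add_nodes_from(grp)
        for u, v in itertools.combinations(grp, 2):
            G.add_edge(u, v, weight=weight)
    return G


class TestMCL:
    def test_two_disjoint_triangles_stay_separate(self):
        G = _clique_graph([[("A", f"t{i}") for i in range(3)],
                           [("B", f"u{i}") for i in range(3)]])
        table = mcl_cluster(G)
        assert len(table.families) == 2
        assert sorted(len(m) for m in table.families.values()) == [3, 3]

    def test_single_node_is_a_singleton(self):
        G = nx.Graph()
        G.add_node(("A", "only"))
        table = mcl_cluster(G)
        assert table.families == {}
        assert table.singletons == {("A", "only")}

    def test_barbell_splits_at_weak_bridge(self):
        # expected partition computed with an independent dense-matrix MCL
        # run (expansion/inflation 2.0, self-loops = max incident weight):
        # the two 4-cliques separate, the 0.1 bridge does not hold
        left = [("A", f"l{i}") for i in range(4)]
        right = [("B", f"r{i}") for i in range(4)]
        G = _clique_graph([left, right], weight=0.9)
        G.add_edge(left[3], right[0], weight=0.1)
        table = mcl_cluster(G, inflation=2.0)
        members = sorted(sorted(m) for m in table.families.values())
        assert members == [sorted(left), sorted(right)]

    def test_disconnected_components_never_merge(self):
        rng = np.random.default_rng(4)
        for trial in range(10):
            sizes = rng.integers(2, 7, size=3)
            groups, labels = [], {}
            for c, size in enumerate(sizes):
                grp = [("G", f"c{c}n{i}") for i in range(size)]
                # random connected graph: a path plus random extra edges
                groups.append(grp)
                for node in grp:
                    labels[node] = c
            G = nx.Graph()
            for grp in groups:
                nx.add_path(G, grp)
                for u, v in itertools.combinations(grp, 2):
                    if rng.random() < 0.4:
                        G.add_edge(u, v)
                for u, v in G.subgraph(grp).edges:
                    G[u][v]["weight"] = float(rng.uniform(0.3, 1.0))
            table = mcl_cluster(G)
            for members in table.families.values():
                assert len({labels[m] for m in members}) == 1

    def test_idempotence_on_clusters_as_cliques(self):
        G = _clique_graph([[("A", f"x{i}") for i in range(4)],
                           [("B", f"y{i}") for i in range(5)]], weight=1.0)
        t1 = mcl_cluster(G)
        G2 = _clique_graph([sorted(m) for m in t1.families.values()], weight=1.0)
        t2 = mcl_cluster(G2)
        assert sorted(map(sorted, t1.families.values())) == sorted(map(sorted, t2.families.values()))

    def test_inflation_must_exceed_one(self):
        with pytest.raises(ValueError):
            mcl_cluster(nx.Graph(), inflation=1.0)


class TestOrthologTable:
    def test_partition_conservation(self, small_set, small_hits):
        proteomes, _ = small_set
        table, _ = infer_orthologs(proteomes, hits_by_pair=small_hits)
        assert table.n_genes == sum(p.n_genes for p in proteomes)

    def test_family_ids_are_deterministic(self, small_set, small_hits):
        proteomes, _ = small_set
        t1, _ = infer_orthologs(proteomes, hits_by_pair=small_hits)
        t2, _ = infer_orthologs(proteomes, hits_by_pair=small_hits)
        assert {f: sorted(m) for f, m in t1.families.items()} == \
               {f: sorted(m) for f, m in t2.families.items()}

    def test_multicopy_flags(self):
        table = OrthologTable(
            families={
                "F1": {("G1", "a"), ("G1", "b"), ("G2", "c")},
                "F2": {("G1", "d"), ("G2", "e")},
            },
            singletons={("G3", "z")},
        )
        assert flag_multicopy(table) == [("F1", "G1", 2)]

    def test_families_require_two_members(self):
        with pytest.raises(ValueError):
            OrthologTable(families={"F1": {("G1", "a")}}, singletons=set())


def test_build_graph_components_match_planted_families(small_set, small_hits):
    proteomes, truth = small_set
    table, _ = infer_orthologs(proteomes, hits_by_pair=small_hits)
    fam = truth.gene_to_family
    pure = sum(
        1 for members in table.families.values()
        if len({fam[g] for _, g in members}) == 1
    )
    assert pure / len(table.families) >= 0.99
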