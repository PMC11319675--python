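"""BGC filtering, Dice graph, Louvain grouping, consensus and counts."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phylosym.bgc import (
    BGCError,
    BGCRecord,
    assign_consensus_class,
    bgc_count_table,
    build_similarity_graph,
    dice_similarity,
    filter_bgcs,
    group_presence_matrix,
    louvain_partition,
    make_groups,
    modularity,
    read_bgc_gff3,
    read_bgc_table,
    retain_annotated_groups,
)


def mk(bgc_id="b1", genome="g1", start=1001, end=11000, edge=False,
       cls="terpene", domains=("PF00001", "PF00002"), source="sanntis"):
    return BGCRecord(
        bgc_id=bgc_id, genome_id=genome, contig_id=f"{genome}_c",
        start=start, end=end, strand="+", predicted_class=cls,
        domains=frozenset(domains), source=source, contig_edge=edge,
    )


class TestFilter:
    def test_short_interior_removed(self):
        r = mk(start=1001, end=1001 + 2999 - 1)  # 2999 bp
        assert filter_bgcs([r]) == []

    def test_exactly_3000_retained(self):
        r = mk(start=1001, end=1001 + 3000 - 1)  # 3000 bp
        assert filter_bgcs([r]) == [r]

    def test_contig_edge_removed_even_if_long(self):
        r = mk(start=1, end=10000, edge=True)
        assert filter_bgcs([r]) == []

    def test_edge_inferred_from_contig_length(self):
        interior = mk(bgc_id="a", start=1001, end=11000, edge=None)
        at_end = mk(bgc_id="b", start=5001, end=20000, edge=None)
        lengths = {"g1_c": 20000}
        assert filter_bgcs([interior, at_end], contig_lengths=lengths) == [interior]

    def test_missing_edge_info_rejected(self):
        r = mk(edge=None)
        with pytest.raises(BGCError, match="contig"):
            filter_bgcs([r])


class TestDice:
    def test_identical_sets(self):
        assert dice_similarity({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint_sets(self):
        assert dice_similarity({"a"}, {"b"}) == 0.0

    def test_hand_count(self):
        got = dice_similarity({"PF00001", "PF00002", "PF00003"},
                              {"PF00002", "PF00003", "PF00004"})
        assert got == pytest.approx(2 * 2 / 6)

    def test_empty_set_rejected(self):
        with pytest.raises(BGCError):
            dice_similarity(set(), {"a"})

    @given(st.sets(st.integers(0, 30), min_size=1, max_size=12),
           st.sets(st.integers(0, 30), min_size=1, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_symmetric_bounded_identity(self, a, b):
        d = dice_similarity(a, b)
        assert d == dice_similarity(b, a)
        assert 0.0 <= d <= 1.0
        assert (d == 1.0) == (a == b)


class TestSimilarityGraph:
    def test_all_distinct_threshold_one_gives_edgeless(self):
        recs = [mk(bgc_id=f"b{i}", domains=(f"PF{i:05d}",)) for i in range(4)]
        g = build_similarity_graph(recs, edge_threshold=1.0)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 4

    def test_identical_records_single_edge_weight_one(self):
        recs = [mk(bgc_id="b1"), mk(bgc_id="b2")]
        g = build_similarity_graph(recs, edge_threshold=0.5)
        assert g.number_of_edges() == 1
        assert g["b1"]["b2"]["weight"] == pytest.approx(1.0)

    def test_threshold_selects_single_pair(self):
        # pairwise dice: (b1,b2)=0.8, (b1,b3)=(b2,b3) below 0.5
        r1 = mk(bgc_id="b1", domains=("d1", "d2", "d3", "d4", "d5"))
        r2 = mk(bgc_id="b2", domains=("d1", "d2", "d3", "d4", "d6"))
        r3 = mk(bgc_id="b3", domains=("d1", "x2", "x3", "x4", "x5"))
        g = build_similarity_graph([r1, r2, r3], edge_threshold=0.5)
        assert g.number_of_edges() == 1
        assert g.has_edge("b1", "b2")

    def test_matches_pairwise_dice_oracle(self):
        rng = np.random.default_rng(1)
        recs = []
        for i in range(25):
            doms = rng.choice(40, size=rng.integers(2, 9), replace=False)
            recs.append(mk(bgc_id=f"b{i}", domains=tuple(f"PF{d:05d}" for d in doms)))
        g = build_similarity_graph(recs, edge_threshold=0.3)
        for a, b in itertools.combinations(recs, 2):
            d = dice_similarity(a.domains, b.domains)
            assert g.has_edge(a.bgc_id, b.bgc_id) == (d >= 0.3)
            if d >= 0.3:
                assert g[a.bgc_id][b.bgc_id]["weight"] == pytest.approx(d)

    def test_empty_domains_rejected(self):
        with pytest.raises(BGCError, match="empty domain"):
            build_similarity_graph([mk(domains=())])

    def test_bad_threshold(self):
        with pytest.raises(BGCError):
            build_similarity_graph([mk()], edge_threshold=0.0)


def partitions(nodes):
    """All set partitions (Bell number; fine for <= 8 nodes)."""
    nodes = list(nodes)
    if not nodes:
        yield []
        return
    first, rest = nodes[0], nodes[1:]
    for part in partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] | {first}] + part[i + 1:]
        yield part + [{first}]


class TestLouvain:
    def test_two_disjoint_triangles(self):
        g = nx.Graph()
        for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            g.add_edge(a, b, weight=1.0)
        part, q = louvain_partition(g, seed=0)
        assert sorted(sorted(c) for c in part) == [[0, 1, 2], [3, 4, 5]]
        assert q == pytest.approx(0.5, abs=1e-12)

    def test_single_edge_one_community(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=1.0)
        part, q = louvain_partition(g, seed=0)
        assert part == [{"a", "b"}]
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_complete_graph_one_community(self):
        g = nx.complete_graph(4)
        for u, v in g.edges:
            g[u][v]["weight"] = 1.0
        part, _ = louvain_partition(g, seed=0)
        assert part == [{0, 1, 2, 3}]

    def test_empty_graph(self):
        assert louvain_partition(nx.Graph(), seed=0) == ([], 0.0)

    def test_q_matches_networkx_modularity(self):
        rng = np.random.default_rng(3)
        g = nx.gnp_random_graph(20, 0.25, seed=3)
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(0.2, 1.0))
        part, q = louvain_partition(g, seed=1)
        assert q == pytest.approx(
            nx.community.modularity(g, part, weight="weight"), abs=1e-12
        )

    @pytest.mark.parametrize("n_per_block", [2, 3, 4])
    def test_attains_exhaustive_maximum_on_planted_blocks(self, n_per_block):
        """Two dense blocks with weak cross-weight (<= 0.1 x intra)."""
        g = nx.Graph()
        blocks = [list(range(n_per_block)),
                  list(range(n_per_block, 2 * n_per_block))]
        for block in blocks:
            for u, v in itertools.combinations(block, 2):
                g.add_edge(u, v, weight=1.0)
        g.add_edge(blocks[0][0], blocks[1][0], weight=0.1)
        part, q = louvain_partition(g, seed=0)
        best = max(modularity(g, p) for p in partitions(g.nodes))
        assert q >= best - 1e-9

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        g = nx.gnp_random_graph(30, 0.2, seed=7)
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(0.2, 1.0))
        assert louvain_partition(g, seed=11) == louvain_partition(g, seed=11)


class TestGroups:
    def test_consensus_majority(self):
        recs = [mk(bgc_id="a", cls="terpene"), mk(bgc_id="b", cls="terpene"),
                mk(bgc_id="c", cls="RiPP")]
        assert assign_consensus_class(recs) == "terpene"

    def test_consensus_tie_lexicographic(self):
        recs = [mk(bgc_id="a", cls="NRP"), mk(bgc_id="b", cls="terpene")]
        assert assign_consensus_class(recs) == "NRP"

    def test_consensus_singleton(self):
        assert assign_consensus_class([mk(cls="alkaloid")]) == "alkaloid"

    def test_hybrid_counts_as_full_label(self):
        recs = [mk(bgc_id="a", cls="NRP+polyketide"),
                mk(bgc_id="b", cls="NRP+polyketide"), mk(bgc_id="c", cls="NRP")]
        assert assign_consensus_class(recs) == "NRP+polyketide"

    def test_retention_rule(self):
        recs = [mk(bgc_id="a", source="sanntis"),
                mk(bgc_id="b", source="antismash"),
                mk(bgc_id="c", source="sanntis")]
        groups = make_groups(recs, [{"a", "b"}, {"c"}])
        kept, dropped = retain_annotated_groups(groups)
        assert [g.group_id for g in kept] == [1]
        assert dropped == 1
        assert retain_annotated_groups([]) == ([], 0)

    def test_partition_conservation(self):
        rng = np.random.default_rng(2)
        recs = []
        for i in range(30):
            doms = rng.choice(30, size=rng.integers(2, 7), replace=False)
            recs.append(mk(bgc_id=f"b{i}", domains=tuple(map(str, doms))))
        g = build_similarity_graph(recs, edge_threshold=0.5)
        part, _ = louvain_partition(g, seed=0)
        groups = make_groups(recs, part)
        assert sum(len(grp) for grp in groups) == len(recs)

    def test_presence_matrix(self):
        recs = [mk(bgc_id="a", genome="g1"), mk(bgc_id="b", genome="g1"),
                mk(bgc_id="c", genome="g2")]
        groups = make_groups(recs, [{"a", "b", "c"}])
        tm = group_presence_matrix(groups, ["g1", "g2", "g3"])
        assert tm.loc["g1", "group_1"] == 1  # presence, not count
        assert tm.loc["g2", "group_1"] == 1
        assert tm.loc["g3", "group_1"] == 0
        with pytest.raises(BGCError, match="not in genome list"):
            group_presence_matrix(groups, ["g1"])

    def test_count_table_conservation(self):
        recs = [mk(bgc_id="a", genome="g1", cls="terpene"),
                mk(bgc_id="b", genome="g1", cls="terpene"),
                mk(bgc_id="c", genome="g1", cls="NRP")]
        counts = bgc_count_table(recs, ["g1", "g2"])
        assert counts.loc["g1", "total"] == 3
        assert counts.loc["g1", "terpene"] == 2
        assert counts.loc["g1", "NRP"] == 1
        assert counts.loc["g2"].sum() == 0
        per_class = counts.drop(columns="total").sum(axis=1)
        assert (per_class == counts["total"]).all()

    def test_empty_records_all_zero(self):
        counts = bgc_count_table([], ["g1"])
        assert counts.loc["g1", "total"] == 0


class TestReaders:
    def test_tsv_roundtrip(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text(
            "bgc_id\tgenome_id\tcontig_id\tstart\tend\tstrand\t"
            "predicted_class\tdomains\tsource\tcontig_edge\n"
            "b1\tg1\tc1\t100\t5000\t+\tterpene\tPF00001;PF00002\tsanntis\tfalse\n"
        )
        (r,) = read_bgc_table(p)
        assert r.domains == frozenset({"PF00001", "PF00002"})
        assert r.length == 4901
        assert r.contig_edge is False

    def test_gff3_dialect(self, tmp_path):
        p = tmp_path / "b.gff3"
        p.write_text(
            "##gff-version 3\n"
            "c1\tsanntis\tBGC\t100\t5000\t.\t+\t.\t"
            "ID=b1;genome=g1;class=terpene;domains=PF00001,PF00002;"
            "source=sanntis;contig_edge=false\n"
            "c1\tprokka\tgene\t1\t10\t.\t+\t.\tID=x\n"
        )
        (r,) = read_bgc_gff3(p)
        assert r.bgc_id == "b1"
        assert r.predicted_class == "terpene"
        assert r.domains == frozenset({"PF00001", "PF00002"})

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(BGCError):
            mk(start=100, end=50)
        with pytest.raises(BGCError):
            mk(start=0, end=50)
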