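"""Prior knowledge network: SIF I/O, preprocessing, centrality, reachability."""

import logging

import networkx as nx
import numpy as np
import pytest

from combilogic.pkn import (PriorKnowledgeNetwork, SifParseError,
                            closeness_centrality, preprocess_identifiability,
                            reachable, read_sif, write_sif)
from conftest import random_digraph_edges, transitive_closure_oracle


class TestReadSif:
    def test_two_line_file(self, tmp_path):
        path = tmp_path / "net.sif"
        path.write_text("S\t1\tA\nA\t-1\tM\n")
        pkn = read_sif(path)
        assert set(pkn.nodes) == {"S", "A", "M"}
        assert [(i.source, i.sign, i.target) for i in pkn.interactions] == [
            ("S", 1, "A"), ("A", -1, "M")]

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.sif"
        path.write_text("")
        pkn = read_sif(path)
        assert not pkn.nodes and not pkn.interactions

    def test_duplicate_line_deduplicated_with_warning(self, tmp_path, caplog):
        path = tmp_path / "dup.sif"
        path.write_text("S\t1\tA\nS\t1\tA\n")
        with caplog.at_level(logging.WARNING):
            pkn = read_sif(path)
        assert len(pkn.interactions) == 1
        assert any("duplicate" in r.message for r in caplog.records)

    def test_contradictory_signs_kept_as_parallel_edges(self, tmp_path):
        path = tmp_path / "dual.sif"
        path.write_text("S\t1\tA\nS\t-1\tA\n")
        assert len(read_sif(path).interactions) == 2

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.sif"
        path.write_text("S\t1\tA\nonly two\tfields\n")
        with pytest.raises(SifParseError, match=":2:"):
            read_sif(path)

    def test_unknown_relation_token_named(self, tmp_path):
        path = tmp_path / "tok.sif"
        path.write_text("S\tactivates\tA\n")
        with pytest.raises(SifParseError, match="activates"):
            read_sif(path)

    def test_roundtrip(self, tmp_path, chain_pkn):
        path = tmp_path / "out.sif"
        write_sif(chain_pkn, path)
        again = read_sif(path)
        assert again.interactions == chain_pkn.interactions


class TestPreprocess:
    def test_chain_compressed_with_sign_product(self, chain_pkn):
        out = preprocess_identifiability(chain_pkn, {"S"}, {"M"})
        assert set(out.nodes) == {"S", "M"}
        assert len(out.interactions) == 1
        edge = out.interactions[0]
        # +1 * +1 * -1 chain collapses to a single inhibition
        assert (edge.source, edge.target, edge.sign) == ("S", "M", -1)

    def test_dangling_node_removed(self, chain_pkn):
        chain_pkn.add_node("D")
        out = preprocess_identifiability(chain_pkn, {"S"}, {"M"})
        assert "D" not in out.nodes

    def test_unreachable_readout_flagged_not_removed(self):
        pkn = PriorKnowledgeNetwork()
        pkn.add_node("S", role="stimulus")
        pkn.add_node("M", role="readout")
        pkn.add_node("M2", role="readout")
        pkn.add_interaction("S", "M", 1)
        with pytest.warns(UserWarning, match="M2"):
            out = preprocess_identifiability(pkn, {"S"}, {"M", "M2"})
        assert "M2" in out.nodes and "M2" in out.flagged_readouts

    @pytest.mark.parametrize("seed", range(6))
    def test_idempotent_and_counts_never_increase(self, seed):
        pkn = _random_pkn_with_roles(seed)
        stimuli, readouts = pkn.stimuli, pkn.readouts
        once = preprocess_identifiability(pkn, stimuli, readouts)
        assert len(once.nodes) <= len(pkn.nodes)
        assert len(once.interactions) <= len(pkn.interactions)
        twice = preprocess_identifiability(once, stimuli, readouts)
        assert set(twice.nodes) == set(once.nodes)
        assert sorted(map(tuple, map(
            lambda i: (i.source, i.target, i.sign), twice.interactions))) == \
            sorted(map(lambda i: (i.source, i.target, i.sign),
                       once.interactions))

    @pytest.mark.parametrize("seed", range(6))
    def test_compression_preserves_stimulus_readout_reachability(self, seed):
        pkn = _random_pkn_with_roles(seed)
        stimuli, readouts = pkn.stimuli, pkn.readouts
        out = preprocess_identifiability(pkn, stimuli, readouts)
        for s in stimuli:
            for m in readouts:
                before = reachable(pkn.interactions, s, m)
                after = reachable(out.interactions, s, m)
                assert before == after, (s, m)


def _random_pkn_with_roles(seed: int) -> PriorKnowledgeNetwork:
    rng = np.random.default_rng(seed)
    pkn = PriorKnowledgeNetwork()
    stimuli = [f"S{i}" for i in range(3)]
    readouts = [f"M{i}" for i in range(3)]
    inner = [f"X{i}" for i in range(6)]
    for s in stimuli:
        pkn.add_node(s, role="stimulus")
    for m in readouts:
        pkn.add_node(m, role="readout")
    order = stimuli + inner + readouts
    for _ in range(14):
        i, j = sorted(rng.choice(len(order), size=2, replace=False))
        src, tgt = order[i], order[j]
        if tgt in stimuli:
            continue
        sign = 1 if rng.random() < 0.8 else -1
        if not any(x.source == src and x.target == tgt and x.sign == sign
                   for x in pkn.interactions):
            pkn.add_interaction(src, tgt, sign)
    return pkn


class TestCloseness:
    def test_star_center_is_maximal(self):
        pkn = PriorKnowledgeNetwork()
        for leaf in "abcd":
            pkn.add_interaction("hub", leaf, 1)
        table = closeness_centrality(pkn).set_index("node")
        center = table.loc["hub", "closeness"]
        assert all(center > table.loc[leaf, "closeness"] for leaf in "abcd")

    def test_single_node_scores_zero(self):
        pkn = PriorKnowledgeNetwork()
        pkn.add_node("solo")
        table = closeness_centrality(pkn)
        assert table["closeness"].tolist() == [0.0]

    def test_path_graph_matches_bfs_oracle(self):
        pkn = PriorKnowledgeNetwork()
        for a, b in [("a", "b"), ("b", "c"), ("c", "d")]:
            pkn.add_interaction(a, b, 1)
        table = closeness_centrality(pkn).set_index("node")["closeness"]
        g = nx.DiGraph([(i.source, i.target) for i in pkn.interactions])
        for v in "abcd":
            lengths = nx.single_source_shortest_path_length(g, v)
            expected = sum(1 / d for u, d in lengths.items() if u != v) / 3
            assert table[v] == pytest.approx(expected)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            closeness_centrality(PriorKnowledgeNetwork())


class TestReachable:
    def test_chain_and_disconnected(self):
        assert reachable([("S", "A"), ("A", "M")], "S", "M")
        assert not reachable([("S", "A"), ("B", "M")], "S", "M")

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_transitive_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nodes, edges = random_digraph_edges(
            n_nodes=int(rng.integers(3, 9)), p=0.25, rng=rng)
        idx, closure = transitive_closure_oracle(nodes, edges)
        for a in nodes:
            for b in nodes:
                assert reachable(edges, a, b) == bool(closure[idx[a], idx[b]])
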