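import numpy as np
import pytest

import stemloop as sl
from stemloop.structure_features import (
    CANONICAL_PAIRS,
    MIN_LOOP,
    NETWORK_FEATURE_NAMES,
    network_block,
)

from graph_oracle import modularity_of, reference_block


def max_pairs_oracle(seq: str) -> int:
    """Exhaustive maximum over all nested structures with loop >= MIN_LOOP."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if j - i <= MIN_LOOP:
            return 0
        out = best(i + 1, j)
        for k in range(i + MIN_LOOP + 1, j + 1):
            if (seq[i], seq[k]) in CANONICAL_PAIRS:
                out = max(out, 1 + best(i + 1, k - 1) + best(k + 1, j))
        return out

    return best(0, len(seq) - 1)


def structure_is_valid(seq: str, db: sl.DotBracket) -> bool:
    for i, j in db.pairs():
        if (seq[i], seq[j]) not in CANONICAL_PAIRS or j - i <= MIN_LOOP:
            return False
    return True


class TestFoldFallback:
    def test_triple_stem_is_maximal(self):
        rec = sl.RnaRecord("x", "GGGAAAACCC")
        db = sl.fold_fallback(rec)
        assert db.structure == "(((....)))"
        assert len(db.pairs()) == max_pairs_oracle(rec.sequence)

    def test_short_homopolymer_stays_unpaired(self):
        assert sl.fold_fallback(sl.RnaRecord("x", "AAAA")).structure == "...."

    @pytest.mark.parametrize("seed", range(6))
    def test_fold_is_valid_and_maximal_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGU"), size=14))
        rec = sl.RnaRecord(f"r{seed}", seq)
        db = sl.fold_fallback(rec)
        assert structure_is_valid(seq, db)
        assert len(db.pairs()) == max_pairs_oracle(seq)


class TestBuildGraph:
    def test_hairpin_graph_counts(self):
        g = sl.build_graph(sl.RnaRecord("x", "GCAAACG"), sl.DotBracket("((...))"))
        assert g.vcount() == 7 and g.ecount() == 8
        assert set(e.tuple for e in g.es) >= {(0, 6), (1, 5)}

    def test_unpaired_sequence_gives_path_graph(self):
        g = sl.build_graph(sl.RnaRecord("x", "ACGU"), sl.DotBracket("...."))
        assert g.vcount() == 4 and g.ecount() == 3

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            sl.build_graph(sl.RnaRecord("x", "ACGUA"), sl.DotBracket("...."))

    def test_graph_is_simple(self):
        g = sl.build_graph(
            sl.RnaRecord("x", "GGGAAAACCC"), sl.fold_fallback(sl.RnaRecord("x", "GGGAAAACCC"))
        )
        assert g.is_simple()


FIXTURE_STRUCTURES = [
    ("GCAAACG", "((...))"),
    ("ACGU", "...."),
    ("ACGUA", "....."),
    ("GGGAAAACCC", "(((....)))"),
    ("GGAAAACCAAGG", "((....))...."),
]


class TestNetworkBlock:
    def test_hairpin_spot_values(self):
        g = sl.build_graph(sl.RnaRecord("x", "GCAAACG"), sl.DotBracket("((...))"))
        block = dict(zip(NETWORK_FEATURE_NAMES, network_block(g)))
        assert block["net.A-degree"] == pytest.approx(16 / 7)
        assert block["net.Densith"] == pytest.approx(8 / 21)
        assert block["net.N-articulation"] == 0
        assert block["net.girth"] == 4

    def test_path_graph_closed_forms(self):
        g = sl.build_graph(sl.RnaRecord("x", "ACGUA"), sl.DotBracket("....."))
        block = dict(zip(NETWORK_FEATURE_NAMES, network_block(g)))
        assert block["net.Densith"] == pytest.approx(0.4)
        assert block["net.diameter"] == 4
        assert block["net.N-articulation"] == 3
        assert block["net.girth"] == 0  # acyclic encoded as 0
        assert block["net.transitivity"] == 0

    @pytest.mark.parametrize("seq,db", FIXTURE_STRUCTURES)
    def test_descriptors_match_brute_force_oracle(self, seq, db):
        g = sl.build_graph(sl.RnaRecord("x", seq), sl.DotBracket(db))
        block = dict(zip(NETWORK_FEATURE_NAMES, network_block(g)))
        edges = [e.tuple for e in g.es]
        expected = reference_block(g.vcount(), edges)
        for name, ref in expected.items():
            assert block[name] == pytest.approx(ref, abs=1e-9), name

    def test_modularity_on_two_cliques_matches_hand_value(self):
        # two triangles joined by one edge: greedy finds the triangles and
        # Q = 2 * (3/7 - (7/14)^2) = 5/14
        g_edges = [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)]
        import igraph as ig

        g = ig.Graph(n=6, edges=g_edges)
        block = dict(zip(NETWORK_FEATURE_NAMES, network_block(g)))
        assert block["net.Modularity"] == pytest.approx(
            modularity_of(6, g_edges, [0, 0, 0, 1, 1, 1])
        )
        assert block["net.Modularity"] == pytest.approx(5 / 14)

    def test_modularity_is_deterministic(self):
        rec = sl.RnaRecord("x", "GGGAAAACCC")
        g = sl.build_graph(rec, sl.fold_fallback(rec))
        runs = {tuple(network_block(g)) for _ in range(3)}
        assert len(runs) == 1

    @pytest.mark.parametrize("seq,db", FIXTURE_STRUCTURES)
    def test_handshake_and_density_identities(self, seq, db):
        g = sl.build_graph(sl.RnaRecord("x", seq), sl.DotBracket(db))
        block = dict(zip(NETWORK_FEATURE_NAMES, network_block(g)))
        n, m = g.vcount(), g.ecount()
        assert block["net.A-degree"] * n == pytest.approx(2 * m)
        assert block["net.Densith"] == pytest.approx(m / (n * (n - 1) / 2))

    def test_adding_a_pair_edge_increases_mean_degree_and_density(self):
        rec = sl.RnaRecord("x", "GGAAAACCAAGG")
        sparse = sl.build_graph(rec, sl.DotBracket("((....))...."))
        dense = sl.build_graph(rec, sl.DotBracket("((.(...))).."))
        names = NETWORK_FEATURE_NAMES
        b0 = dict(zip(names, network_block(sparse)))
        b1 = dict(zip(names, network_block(dense)))
        assert b1["net.A-degree"] >= b0["net.A-degree"]
        assert b1["net.Densith"] >= b0["net.Densith"]

    def test_disconnected_graph_rejected(self):
        import igraph as ig

        g = ig.Graph(n=4, edges=[(0, 1), (2, 3)])
        with pytest.raises(ValueError, match="connected"):
            network_block(g)
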