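"""Graph construction, walk enumeration, and k-mer complexity."""
from collections import Counter, defaultdict

import pytest

import seqrex as sx
from seqrex import (build_graph, enumerate_language, enumerate_walks,
                    expand_pattern, kmer_complexity, random_regex,
                    to_postfix, topo_order, validate_for_k)
from helpers import compiled, count_k_paths, random_dna


def graph_for(pattern, k, variant="Gk"):
    return build_graph(to_postfix(expand_pattern(pattern)), k, variant)


class TestBuildGraph:
    def test_star_pattern_unrolled_inventory(self):
        """TCG*A at k=3: the star operand is duplicated behind two split
        nodes and one join, giving 5 character nodes and 10 nodes total."""
        g = graph_for("TCG*A", 3)
        kinds = Counter(n.kind for n in g.nodes)
        assert kinds == {"character": 5, "split": 2, "join": 1,
                         "entry": 1, "exit": 1}
        assert sorted(n.char for n in g.nodes if n.kind == "character") == \
            ["A", "C", "G", "G", "T"]
        words = {w.word for w in enumerate_walks(g)}
        assert words == {"TCA", "TCGA", "TCGGA"}

    def test_literal_chain_has_no_auxiliary_nodes(self):
        g = graph_for("ACG", 3)
        kinds = Counter(n.kind for n in g.nodes)
        assert kinds == {"character": 3, "entry": 1, "exit": 1}
        assert g.topo == [g.s] + [n.id for n in g.nodes
                                  if n.kind == "character"] + [g.t]

    def test_unrolled_walks_spell_the_bounded_repetition_words(self):
        g = graph_for("CG(A|TT)*GC", 3)
        words = {w.word for w in enumerate_walks(g)}
        assert words == {"CGGC", "CGAGC", "CGTTGC", "CGAAGC", "CGATTGC",
                         "CGTTAGC", "CGTTTTGC"}

    def test_plus_requires_at_least_one_traversal(self):
        g = graph_for("A(T)+A", 3)
        assert {w.word for w in enumerate_walks(g)} == {"ATA", "ATTA"}

    def test_malformed_postfix_raises(self):
        with pytest.raises(sx.PostfixError):
            build_graph(["A", sx.CONCAT], 3)


class TestTopoOrder:
    def test_partial_order_property_on_random_graphs(self, rng):
        for _ in range(60):
            r = random_regex(rng, max_depth=4)
            try:
                validate_for_k(r, 3)
            except sx.SeqrexError:
                continue
            g = build_graph(to_postfix(r), 3, "Gk")
            pos = {n: i for i, n in enumerate(g.topo)}
            assert g.topo[0] == g.s and g.topo[-1] == g.t
            assert all(pos[a] < pos[b] for a, b in g.arcs)

    def test_back_arc_raises_cycle_error(self):
        g = graph_for("ACG", 3)
        chars = g.character_nodes()
        g.adj[chars[-1]].append(chars[0])
        with pytest.raises(sx.CycleError):
            topo_order(g)


class TestEnumerateWalks:
    def test_repetition_levels_of_the_two_branch_star(self):
        """The cyclic graph for CG(A|TT)*GC spells 1/2/4 distinct walks at
        star repetition levels 0/1/2, with the expected ordered 3-mers."""
        g = graph_for("CG(A|TT)*GC", 3, "G")
        (loop, kind), = g.loops
        assert kind == "star"
        by_level = defaultdict(set)
        for w in enumerate_walks(g, max_repeat=2, max_walks=1000):
            by_level[w.nodes.count(loop) - 1].add(w.kmers)
        assert by_level[0] == {("CGG", "GGC")}
        assert by_level[1] == {("CGA", "GAG", "AGC"),
                               ("CGT", "GTT", "TTG", "TGC")}
        assert by_level[2] == {
            ("CGA", "GAA", "AAG", "AGC"),
            ("CGA", "GAT", "ATT", "TTG", "TGC"),
            ("CGT", "GTT", "TTA", "TAG", "AGC"),
            ("CGT", "GTT", "TTT", "TTT", "TTG", "TGC")}

    def test_single_chain_walk(self):
        g = graph_for("ACG", 3)
        (w,) = enumerate_walks(g)
        assert w.word == "ACG" and w.kmers == ("ACG",)

    def test_budget_exceeded(self):
        g = graph_for("(A|T)(A|T)(A|T)", 3)
        with pytest.raises(sx.WalkBudgetExceeded):
            enumerate_walks(g, max_walks=7)

    def test_unrolled_walks_spell_words_of_the_language(self, rng):
        for _ in range(40):
            r = random_regex(rng, max_depth=3)
            try:
                validate_for_k(r, 3)
            except sx.SeqrexError:
                continue
            g = build_graph(to_postfix(r), 3, "Gk")
            try:
                walks = enumerate_walks(g, max_walks=3000)
            except sx.WalkBudgetExceeded:
                continue
            pat = compiled(r)
            assert all(pat.fullmatch(w.word) for w in walks)

    def test_cyclic_walks_cover_the_bounded_language(self, rng):
        """Every word of L(R) up to length k+4 is spelled by some walk of
        the cyclic graph when the repeat budget is generous."""
        k = 3
        for _ in range(30):
            r = random_regex(rng, max_depth=3)
            try:
                validate_for_k(r, k)
            except sx.SeqrexError:
                continue
            g = build_graph(to_postfix(r), k, "G")
            try:
                words = {w.word for w in enumerate_walks(g, max_repeat=k + 4,
                                                         max_walks=20000)}
            except sx.WalkBudgetExceeded:
                continue
            target = {w for w in enumerate_language(r, k + 4)}
            assert target <= words


class TestRepeatCoverage:
    def test_longer_repeats_of_word_operands_are_covered(self, rng):
        """For repeats whose operand is a single word, any cyclic walk with
        up to k+2 traversals has an unrolled walk whose k-mers it covers."""
        k = 3
        for _ in range(40):
            word = random_dna(rng, int(rng.integers(1, 4)))
            prefix = random_dna(rng, int(rng.integers(1, 4)))
            suffix = random_dna(rng, int(rng.integers(1, 4)))
            op = "*" if rng.random() < 0.5 else "+"
            r = expand_pattern(f"{prefix}({word}){op}{suffix}")
            try:
                validate_for_k(r, k)
            except sx.MinLengthError:
                continue
            g = build_graph(to_postfix(r), k, "G")
            gk = build_graph(to_postfix(r), k, "Gk")
            kmer_sets = [set(w.kmers) for w in enumerate_walks(gk, max_walks=5000)]
            for w in enumerate_walks(g, max_repeat=k + 2, max_walks=5000):
                assert any(ks <= set(w.kmers) for ks in kmer_sets), w.word

    def test_mixed_alternative_repeats_escape_the_unrolling(self):
        """Known limitation: a walk mixing repeat alternatives >= k times can
        carry a k-mer set that no unrolled walk is contained in (its boundary
        k-mers differ from every homogeneous exit/entry combination)."""
        g = graph_for("CG(A|TT)*GC", 3, "G")
        gk = graph_for("CG(A|TT)*GC", 3)
        kmer_sets = [set(w.kmers) for w in enumerate_walks(gk)]
        walk3 = next(w for w in enumerate_walks(g, max_repeat=3, max_walks=5000)
                     if w.word == "CGATTAGC")
        assert not any(ks <= set(walk3.kmers) for ks in kmer_sets)


class TestKmerComplexity:
    def test_literal_chain_window_count(self):
        g = graph_for("ACGTACG", 3)
        res = kmer_complexity(g)
        assert res.c_k == 5  # L - k + 1
        assert res.v == (0, 0, 1, 1, 1, 1, 1)

    def test_concatenated_classes_follow_window_products(self):
        # [AC][AG][AT][CG] at k=2: windows 2*2 + 2*2 + 2*2 = 12
        g = graph_for("[AC][AG][AT][CG]", 2)
        assert kmer_complexity(g).c_k == 12

    def test_matches_exhaustive_path_counting(self, rng):
        checked = 0
        while checked < 60:
            r = random_regex(rng, max_depth=3)
            try:
                validate_for_k(r, 3)
            except sx.SeqrexError:
                continue
            g = build_graph(to_postfix(r), 3, "Gk")
            if len(g.nodes) > 30:
                continue
            res = kmer_complexity(g)
            oracle = count_k_paths(g)
            assert dict(zip(res.char_order, res.v)) == \
                {n: oracle.get(n, 0) for n in res.char_order}
            assert res.c_k == sum(oracle.values())
            checked += 1

    def test_requires_acyclic_variant(self):
        with pytest.raises(ValueError):
            kmer_complexity(graph_for("ACG", 3, "G"))


def test_dot_export_lists_every_node_and_arc():
    g = graph_for("A(T|G)C", 2)
    dot = g.to_dot()
    assert dot.count("->") == len(g.arcs)
    assert all(f"n{n.id}" in dot for n in g.nodes)
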