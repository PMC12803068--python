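"""Sampling, locus masking, sketch-distance trees and Fitch parsimony."""

import itertools

import numpy as np
import pytest
from skbio.tree import TreeNode

from fusescan.kmer_screen import (extract_query_kmers,
                                  find_matches_in_contig, measure_locus)
from fusescan.locus_ancestry import (RootedStateTree, build_rooted_tree,
                                     extract_and_mask, fitch_mrca,
                                     mash_distance, sample_by_cluster,
                                     sketch_genome)
from conftest import random_dna


class TestSampling:
    def test_even_split(self):
        members = {0: [f"a{i}" for i in range(500)],
                   1: [f"b{i}" for i in range(500)]}
        s = sample_by_cluster(members, 300, seed=1)
        assert len(s) == 300
        assert sum(g.startswith("a") for g in s) == 150
        assert sum(g.startswith("b") for g in s) == 150

    def test_shortfall_redistributed(self):
        members = {0: [f"a{i}" for i in range(40)],
                   1: [f"b{i}" for i in range(5000)]}
        s = sample_by_cluster(members, 300, seed=1)
        assert sum(g.startswith("a") for g in s) == 40
        assert sum(g.startswith("b") for g in s) == 260

    def test_deterministic_and_seed_sensitive(self):
        members = {0: [f"g{i}" for i in range(1000)]}
        a = sample_by_cluster(members, 300, seed=7)
        b = sample_by_cluster(members, 300, seed=7)
        c = sample_by_cluster(members, 300, seed=8)
        assert a == b
        overlap = len(set(a) & set(c))
        # hypergeometric expectation: 300*300/1000 = 90, sd ~ 6.6
        assert 50 <= overlap <= 130
        assert a != c

    def test_too_few_genomes_errors(self):
        with pytest.raises(ValueError):
            sample_by_cluster({0: ["only"]}, 10, seed=0)


class TestExtractMask:
    def make_measurement(self, contig, query):
        ms = find_matches_in_contig(contig, query, "G", "c")
        return measure_locus(ms, query, "G")

    def test_intact_locus_length(self, rng):
        gene = random_dna(rng, 900)
        q = extract_query_kmers("g", gene)
        contig = random_dna(rng, 100) + gene + random_dna(rng, 100)
        m = self.make_measurement(contig, q)
        ext = extract_and_mask([("c", contig)], m, q)
        assert len(ext.locus_seq) == q.expected_span
        assert ext.locus_seq == gene[4:-4]

    def test_insertion_contains_cargo_verbatim(self, rng):
        gene = random_dna(rng, 900)
        cargo = random_dna(rng, 5000)
        q = extract_query_kmers("g", gene)
        contig = (random_dna(rng, 100) + gene[:450] + cargo + gene[450:]
                  + random_dna(rng, 100))
        m = self.make_measurement(contig, q)
        ext = extract_and_mask([("c", contig)], m, q)
        assert len(ext.locus_seq) == q.expected_span + 5000
        assert cargo in ext.locus_seq

    def test_reverse_orientation_yields_gene_orientation(self, rng):
        from fusescan.kmer_screen import reverse_complement
        gene = random_dna(rng, 900)
        q = extract_query_kmers("g", gene)
        contig = reverse_complement(
            random_dna(rng, 80) + gene + random_dna(rng, 80))
        m = self.make_measurement(contig, q)
        ext = extract_and_mask([("c", contig)], m, q)
        assert ext.locus_seq == gene[4:-4]

    def test_masked_genome_rescreens_missing(self, rng):
        gene = random_dna(rng, 900)
        q = extract_query_kmers("g", gene)
        contig = random_dna(rng, 100) + gene + random_dna(rng, 100)
        m = self.make_measurement(contig, q)
        ext = extract_and_mask([("c", contig)], m, q)
        (cid, masked_seq), = ext.masked_genome
        assert len(masked_seq) == len(contig)
        m2 = self.make_measurement(masked_seq, q)
        assert m2.status == "missing"


class TestSketchTree:
    def test_self_distance_zero(self, rng):
        contigs = [("c", random_dna(rng, 20000))]
        s = sketch_genome(contigs)
        assert mash_distance(s, s) == 0.0

    def test_nj_recovers_known_split(self, rng):
        anc = np.array(list(random_dna(rng, 30000)))

        def mutate(seq, n):
            seq = seq.copy()
            pos = rng.choice(len(seq), n, replace=False)
            repl = np.array(list("ACGT"))[rng.integers(0, 4, n)]
            seq[pos] = repl
            return seq

        p1 = mutate(anc, 600)
        p2 = mutate(anc, 600)
        genomes = {"A": p1, "B": mutate(p1, 150), "C": p2,
                   "D": mutate(p2, 150)}
        ogs = {"o1": mutate(anc, 2500), "o2": mutate(anc, 4000)}
        tree = build_rooted_tree(
            {g: [("c", "".join(s))] for g, s in genomes.items()},
            {g: [("c", "".join(s))] for g, s in ogs.items()},
            {g: 0 for g in genomes})
        t = tree.topology
        ab = t.lca(["A", "B"])
        assert {x.name for x in ab.tips()} == {"A", "B"}
        cd = t.lca(["C", "D"])
        assert {x.name for x in cd.tips()} == {"C", "D"}

    def test_more_distant_outgroup_chosen(self, rng):
        for rep in range(20):
            r = np.random.default_rng(rep)
            anc = np.array(list("ACGT"))[r.integers(0, 4, 20000)]

            def mutate(seq, n):
                seq = seq.copy()
                pos = r.choice(len(seq), n, replace=False)
                seq[pos] = np.array(list("ACGT"))[r.integers(0, 4, n)]
                return seq

            genomes = {f"g{i}": mutate(anc, 200) for i in range(4)}
            near, far = mutate(anc, 1000), mutate(anc, 5000)
            tree = build_rooted_tree(
                {g: [("c", "".join(s))] for g, s in genomes.items()},
                {"near": [("c", "".join(near))],
                 "far": [("c", "".join(far))]},
                {g: 0 for g in genomes})
            assert tree.rooted_on == "far"

    def test_identical_genomes_raise_star_error(self, rng):
        seq = random_dna(rng, 20000)
        with pytest.raises(ValueError):
            build_rooted_tree({g: [("c", seq)] for g in "ABC"},
                              {"o1": [("c", seq)], "o2": [("c", seq)]},
                              {g: 0 for g in "ABC"})


def brute_force_fitch(tree: TreeNode, leaf_states: dict[str, int],
                      states: list[int]):
    """Exhaustive minimum over all internal labelings; returns
    (min score, set of root states achieving it)."""
    internal = [n for n in tree.postorder() if not n.is_tip()]
    best = None
    root_states = set()
    for labels in itertools.product(states, repeat=len(internal)):
        lab = dict(zip(map(id, internal), labels))

        def state_of(n):
            return leaf_states[n.name] if n.is_tip() else lab[id(n)]

        score = sum(state_of(c) != state_of(n)
                    for n in internal for c in n.children)
        if best is None or score < best:
            best = score
            root_states = {lab[id(internal[-1])]}
        elif score == best:
            root_states.add(lab[id(internal[-1])])
    return best, root_states


def random_binary_tree(r, n_leaves):
    nodes = [TreeNode(name=f"L{i}") for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(r.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(children=[a, b])
        nodes.append(parent)
    return nodes[0]


class TestFitch:
    def wrap(self, ingroup: TreeNode, leaf_states):
        """Attach two stateless outgroups above the ingroup root."""
        og2 = TreeNode(name="og2")
        inner = TreeNode(children=[og2, ingroup])
        og1 = TreeNode(name="og1")
        root = TreeNode(children=[og1, inner])
        return RootedStateTree(root, leaf_states, ("og1", "og2"), "og1")

    def test_uniform_labels_score_zero_not_split(self):
        t = TreeNode.read(["((A,B),(C,D));"])
        tree = self.wrap(t, {n: 1 for n in "ABCD"})
        call = fitch_mrca(tree, "g", zero_cluster_id=0,
                          positive_cluster_ids=[1])
        assert call.parsimony_score == 0
        assert call.mrca_state_set == frozenset([1])
        assert call.classification == "ambiguous"  # no intact descendant

    def test_derived_zero_clade_gives_split_ancestor(self):
        t = TreeNode.read(["(((A,B),(C,D)),(E,F));"])
        states = {"A": 0, "B": 0, "C": 1, "D": 1, "E": 1, "F": 1}
        call = fitch_mrca(self.wrap(t, states), "g", 0, [1])
        assert call.classification == "split_ancestor"
        assert call.parsimony_score == 1

    def test_derived_positive_clade_gives_intact_ancestor(self):
        t = TreeNode.read(["(((A,B),(C,D)),(E,F));"])
        states = {"A": 1, "B": 1, "C": 0, "D": 0, "E": 0, "F": 0}
        call = fitch_mrca(self.wrap(t, states), "g", 0, [1])
        assert call.classification == "intact_ancestor"

    def test_unlabeled_leaf_errors(self):
        t = TreeNode.read(["((A,B),(C,D));"])
        with pytest.raises(ValueError):
            fitch_mrca(self.wrap(t, {"A": 0, "B": 0, "C": 1}), "g", 0, [1])

    @pytest.mark.parametrize("seed", range(40))
    def test_score_and_mrca_match_exhaustive_enumeration(self, seed):
        r = np.random.default_rng(seed)
        n_leaves = int(r.integers(3, 9))
        n_states = int(r.integers(2, 5))
        t = random_binary_tree(r, n_leaves)
        states = {f"L{i}": int(r.integers(0, n_states))
                  for i in range(n_leaves)}
        call = fitch_mrca(self.wrap(t.copy(), states), "g", 0,
                          list(range(1, n_states)))
        score, root_states = brute_force_fitch(t, states,
                                               list(range(n_states)))
        assert call.parsimony_score == score
        assert call.mrca_state_set == frozenset(root_states)

    @pytest.mark.parametrize("seed", range(10))
    def test_score_upper_bound(self, seed):
        r = np.random.default_rng(100 + seed)
        n_leaves = int(r.integers(3, 9))
        t = random_binary_tree(r, n_leaves)
        states = {f"L{i}": int(r.integers(0, 3)) for i in range(n_leaves)}
        call = fitch_mrca(self.wrap(t, states), "g", 0, [1, 2])
        freq = max(list(states.values()).count(s) for s in set(
            states.values()))
        assert call.parsimony_score <= n_leaves - freq
        if len(set(states.values())) == 1:
            assert call.parsimony_score == 0
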