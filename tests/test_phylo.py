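"""Distances, neighbor joining, rooting, transfer counting, rate contrast."""

import itertools
import math

import numpy as np
import pytest

from orgkit.phylo import (CopyAlignment, Node, bootstrap_support, build_tree,
                          count_transfer_events, distance_matrix, from_newick,
                          neighbor_joining, pairwise_distance,
                          rate_acceleration, root_with_outgroup)
from orgkit.simulate import generate_transfer_scenario


def path_distances(tree: Node) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths computed independently of NJ internals."""
    paths: dict[str, list[Node]] = {}

    def walk(node, acc):
        acc = acc + [node]
        if node.is_leaf:
            paths[node.name] = acc
        for c in node.children:
            walk(c, acc)

    walk(tree, [])
    out = {}
    for a, b in itertools.combinations(sorted(paths), 2):
        pa, pb = paths[a], paths[b]
        k = 0
        while k < min(len(pa), len(pb)) and pa[k] is pb[k]:
            k += 1
        out[(a, b)] = sum(n.length for n in pa[k:]) + sum(n.length for n in pb[k:])
    return out


class TestDistances:
    def test_identical_sequences_have_zero_distance(self):
        assert pairwise_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_jc_formula_at_ten_percent_difference(self):
        # p = 0.10 -> d = -0.75 ln(1 - 0.4/3); counting oracle via 10% sites
        a = "A" * 100
        b = "C" * 10 + "A" * 90
        expected = -0.75 * math.log(1 - 0.4 / 3)
        assert pairwise_distance(a, b, "jc") == pytest.approx(expected, abs=1e-12)

    def test_k2p_separates_transitions_and_transversions(self):
        a = "A" * 100
        ts = "G" * 10 + "A" * 90  # A->G transitions
        tv = "C" * 10 + "A" * 90  # A->C transversions
        d_ts = pairwise_distance(a, ts, "k2p")
        d_tv = pairwise_distance(a, tv, "k2p")
        P, Q = 0.1, 0.1
        assert d_ts == pytest.approx(-0.5 * math.log((1 - 2 * P) * math.sqrt(1)), abs=1e-12)
        assert d_tv == pytest.approx(
            -0.5 * math.log((1 - Q) * math.sqrt(1 - 2 * Q)), abs=1e-12
        )

    def test_gap_columns_pairwise_deleted(self):
        assert pairwise_distance("AC-T", "ACGT") == 0.0

    def test_all_gap_overlap_is_an_error(self):
        with pytest.raises(ValueError):
            pairwise_distance("----", "ACGT")

    def test_saturation_flagged_as_infinite(self):
        assert pairwise_distance("A" * 10, "C" * 10, "jc") == math.inf

    def test_matrix_agrees_with_scalar_routine(self):
        aln = CopyAlignment(
            labels=["a|mt", "b|mt", "c|nuc"],
            seqs=["ACGTAC-TAA", "ACTTACGTAA", "GCGTANGTCA"],
        )
        for model in ("jc", "k2p"):
            D = distance_matrix(aln, model)
            for i in range(3):
                for j in range(3):
                    expected = (0.0 if i == j else
                                pairwise_distance(aln.seqs[i], aln.seqs[j], model))
                    assert D[i, j] == pytest.approx(expected, abs=1e-12)


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovered_exactly(self):
        true = from_newick("((A:0.1,B:0.2):0.06,C:0.3,D:0.15);")
        pd_true = path_distances(true)
        labels = sorted({x for pair in pd_true for x in pair})
        D = np.zeros((4, 4))
        for (a, b), d in pd_true.items():
            i, j = labels.index(a), labels.index(b)
            D[i, j] = D[j, i] = d
        nj = neighbor_joining(D, labels)
        assert path_distances(nj) == pytest.approx(pd_true)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_additive_trees_up_to_12_leaves(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        # random ladder topology with random positive branch lengths
        nodes = [Node(name=f"L{i}", length=float(rng.uniform(0.05, 0.4)))
                 for i in range(n)]
        while len(nodes) > 3:
            a = nodes.pop(int(rng.integers(len(nodes))))
            b = nodes.pop(int(rng.integers(len(nodes))))
            nodes.append(Node(length=float(rng.uniform(0.05, 0.3)),
                              children=[a, b]))
        true = Node(children=nodes)
        pd_true = path_distances(true)
        labels = sorted({x for pair in pd_true for x in pair})
        D = np.zeros((n, n))
        for (a, b), d in pd_true.items():
            i, j = labels.index(a), labels.index(b)
            D[i, j] = D[j, i] = d
        nj = neighbor_joining(D, labels)
        got = path_distances(nj)
        for pair, d in pd_true.items():
            assert got[pair] == pytest.approx(d, abs=1e-9)

    def test_agrees_with_independent_nj_implementation(self):
        skbio = pytest.importorskip("skbio")
        aln, _ = generate_transfer_scenario(k=2, seed=4, n_sites=600)
        D = distance_matrix(aln, "jc")
        mine = neighbor_joining(D, aln.labels)
        theirs = skbio.tree.nj(
            skbio.DistanceMatrix(D, ids=aln.labels)
        )
        mine_d = path_distances(mine)
        for (a, b), d in mine_d.items():
            assert theirs.find(a).distance(theirs.find(b)) == pytest.approx(d, abs=1e-6)

    def test_three_taxa_star_resolution(self):
        D = np.array([[0, 2.0, 3.0], [2.0, 0, 4.0], [3.0, 4.0, 0]])
        tree = neighbor_joining(D, ["a", "b", "c"])
        assert sorted(tree.leaf_names()) == ["a", "b", "c"]
        assert path_distances(tree)[("a", "b")] == pytest.approx(2.0)

    def test_equal_distance_ties_are_deterministic(self):
        D = np.full((5, 5), 1.0)
        np.fill_diagonal(D, 0.0)
        labels = ["e", "d", "c", "b", "a"]
        t1 = neighbor_joining(D.copy(), labels)
        t2 = neighbor_joining(D.copy(), list(reversed(labels)))
        assert t1.to_newick() == t2.to_newick()

    def test_non_finite_matrix_rejected(self):
        D = np.array([[0.0, math.inf], [math.inf, 0.0]])
        with pytest.raises(ValueError):
            neighbor_joining(D, ["a", "b"])


class TestTransferCounting:
    def test_monophyletic_nuclear_copies_one_event(self):
        tree = from_newick(
            "((o1|mt:1,o2|mt:1):1,((a|nuc:1,b|nuc:1):1,(a|mt:1,b|mt:1):1):1);"
        )
        k, clades = count_transfer_events(tree)
        assert k == 1
        assert sorted(clades[0]) == ["a|nuc", "b|nuc"]

    def test_two_separate_nuclear_placements(self):
        tree = from_newick(
            "((o|mt:1,(a|nuc:1,b|nuc:1):1):1,((c|nuc:1,d|nuc:1):1,(c|mt:1,d|mt:1):1):1);"
        )
        k, _ = count_transfer_events(tree)
        assert k == 2

    def test_invariant_to_leaf_order_permutation(self):
        aln, truth = generate_transfer_scenario(k=2, seed=6)
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(aln.labels))
        shuffled = CopyAlignment(
            labels=[aln.labels[i] for i in perm],
            seqs=[aln.seqs[i] for i in perm],
        )
        for a in (aln, shuffled):
            tree = root_with_outgroup(build_tree(a), ["OUT1|mt", "OUT2|mt"])
            assert count_transfer_events(tree)[0] == truth.k

    def test_missing_outgroup_rejected(self):
        aln, _ = generate_transfer_scenario(k=1, seed=7, n_sites=300)
        tree = build_tree(aln)
        with pytest.raises(ValueError):
            root_with_outgroup(tree, ["nope|mt"])


class TestRates:
    def test_equal_rates_give_ratio_near_one(self):
        aln, _ = generate_transfer_scenario(k=1, rate_multiplier=1.0, seed=8,
                                            n_sites=2000)
        rc = rate_acceleration(aln, ["OUT1|mt", "OUT2|mt"], n_boot=100, seed=0)
        assert rc.ci_low <= 1.25 and rc.ratio == pytest.approx(1.0, abs=0.4)

    def test_fivefold_scenario_recovered(self):
        aln, _ = generate_transfer_scenario(
            k=1, rate_multiplier=5.0, seed=9, n_sites=1000,
            transfer_clades=(("A", "B", "C", "D", "E", "F", "G", "H"),),
        )
        rc = rate_acceleration(aln, ["OUT1|mt", "OUT2|mt"], n_boot=100, seed=0)
        assert 3.0 <= rc.ratio <= 7.0

    def test_single_nuclear_leaf_flagged(self):
        aln, _ = generate_transfer_scenario(k=1, seed=10,
                                            transfer_clades=(("A",),))
        rc = rate_acceleration(aln, ["OUT1|mt", "OUT2|mt"], n_boot=20, seed=0)
        assert rc.flagged is not None and rc.ratio > 0


class TestBootstrap:
    def test_identical_seed_reproduces_identical_supports(self):
        aln, _ = generate_transfer_scenario(k=2, seed=11, n_sites=400)
        t1 = bootstrap_support(aln, n_boot=30, seed=5)
        t2 = bootstrap_support(aln, n_boot=30, seed=5)
        assert t1.to_newick() == t2.to_newick()

    def test_clear_clades_get_high_support(self):
        aln, _ = generate_transfer_scenario(k=1, seed=12, n_sites=2000)
        tree = bootstrap_support(aln, n_boot=50, seed=3)
        supports = [n.support for n in tree.walk()
                    if n.support is not None]
        assert supports and max(supports) == 100.0
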