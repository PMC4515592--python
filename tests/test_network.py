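"""Reduced-median network construction and tree extraction."""

import warnings

import numpy as np
import pytest

from mtphylo.network import (
    BinaryMatrix,
    NetworkError,
    annotate_clades,
    build_reduced_median,
    extract_tree,
    to_newick,
)
from mtphylo.sequence_io import Haplotype, Variant
from mtphylo.synthetic import SimConfig, simulate_panmictic

from conftest import sub


def _hap(sid, variants):
    return Haplotype(sid, "pop", "other", frozenset(variants))


V1 = sub(100, "A", "G")
V2 = sub(200, "C", "T", )
V3 = sub(300, "G", "A")


class TestBuildReducedMedian:
    def test_empty_input_errors(self):
        with pytest.raises(NetworkError):
            BinaryMatrix.from_haplotypes([])

    def test_single_haplotype_gives_single_node_no_edges(self):
        net = build_reduced_median(BinaryMatrix.from_haplotypes([_hap("a", [V1])]))
        assert len(net.nodes) == 1 and len(net.edges) == 0

    def test_compatible_characters_give_perfect_phylogeny(self):
        # chain 000 -> 100 -> 110 -> 111: all internal states observed
        haps = [_hap("a", []), _hap("b", [V1]), _hap("c", [V1, V2]), _hap("d", [V1, V2, V3])]
        net = build_reduced_median(BinaryMatrix.from_haplotypes(haps))
        assert len(net.edges) == 3
        assert net.n_median_vectors == 0
        assert len(net.nodes) == 4

    def test_latent_intermediates_are_not_median_vectors(self):
        # star data: 100, 010, 001 need the unobserved 000 centre
        haps = [_hap("a", [V1]), _hap("b", [V2]), _hap("c", [V3])]
        net = build_reduced_median(BinaryMatrix.from_haplotypes(haps))
        assert len(net.edges) == 3
        assert net.n_median_vectors == 0
        assert net.n_latent == 1

    def test_four_gamete_conflict_keeps_cycle_at_equal_weights(self):
        haps = [_hap("a", []), _hap("b", [V1]), _hap("c", [V2]), _hap("d", [V1, V2])]
        net = build_reduced_median(BinaryMatrix.from_haplotypes(haps))
        assert len(net.nodes) == 4
        assert len(net.edges) == 4  # the classic 4-cycle retained

    def test_dominated_conflict_is_resolved(self):
        # V1 on 6/8 rows (weight 1), V2 on 2/8 (weight 4): ratio >= 2
        haps = (
            [_hap(f"a{i}", [V1]) for i in range(5)]
            + [_hap("b", [V2]), _hap("c", [V1, V2]), _hap("d", [])]
        )
        net = build_reduced_median(BinaryMatrix.from_haplotypes(haps), reduction_threshold=2.0)
        assert len(net.edges) == len(net.nodes) - 1  # cycle broken to a tree
        rare_edges = [e for e in net.edges if net.columns[e[2]].position == 200]
        assert len(rare_edges) == 1  # rare character appears once

    def test_simulated_infinite_sites_data_are_conflict_free(self):
        res = simulate_panmictic(SimConfig(seed=7, n_samples=12))
        mat = BinaryMatrix.from_haplotypes(res.haplotypes)
        net = build_reduced_median(mat)
        assert net.n_median_vectors == 0
        assert len(net.edges) == len(mat.columns)
        assert len(net.edges) == len(net.nodes) - 1


class TestExtractTree:
    def test_root_must_be_in_network(self):
        net = build_reduced_median(BinaryMatrix.from_haplotypes([_hap("a", [V1]), _hap("b", [])]))
        with pytest.raises(NetworkError):
            extract_tree(net, (1, 1))

    def test_tree_network_is_returned_rooted_unchanged(self):
        haps = [_hap("a", []), _hap("b", [V1]), _hap("c", [V1, V2])]
        net = build_reduced_median(BinaryMatrix.from_haplotypes(haps))
        tree = extract_tree(net, (0, 0))
        tips = {t.tip_samples[0] for t in tree.iter_tips() if t.tip_samples}
        assert tips == {"a", "b", "c"}
        # spanning tree: edges = nodes - 1 in the network
        n_edges = sum(len(n.children) for n in tree.iter_nodes() if n.node_id.endswith(".s") is False)
        assert len(net.edges) == len(net.nodes) - 1

    def test_spanning_tree_property_on_conflict_network(self):
        haps = [_hap("a", []), _hap("b", [V1]), _hap("c", [V2]), _hap("d", [V1, V2])]
        net = build_reduced_median(BinaryMatrix.from_haplotypes(haps))
        tree = extract_tree(net, (0, 0))
        # every observed haplotype reachable
        tips = {t.tip_samples[0] for t in tree.iter_tips() if t.tip_samples}
        assert tips == {"a", "b", "c", "d"}
        # spanning tree of the 4-cycle uses 3 of the 4 edges
        n_mut_edges = sum(len(n.edge_variants) for n in tree.iter_nodes())
        assert n_mut_edges == 3

    def test_higher_frequency_character_is_basal_and_recurrent(self):
        # V1 on 4/6 rows (frequent), V2 on 2/6; conflict within threshold
        haps = (
            [_hap("a", []), _hap("b", [V1]), _hap("b2", [V1]), _hap("b3", [V1])]
            + [_hap("c", [V2]), _hap("d", [V1, V2])]
        )
        net = build_reduced_median(BinaryMatrix.from_haplotypes(haps))
        assert len(net.edges) == 4  # cycle retained (ratio 3/2 < 2)
        tree = extract_tree(net, (0, 0))
        by_pos = {}
        for n in tree.iter_nodes():
            for v in n.edge_variants:
                by_pos.setdefault(v.position, []).append(n)
        # the frequent character recurs; the rare one appears once
        assert len(by_pos[100]) == 2
        assert len(by_pos[200]) == 1
        root_positions = {v.position for c in tree.children for v in c.edge_variants}
        assert 100 in root_positions
        assert tree.recurrent_positions() == {100}

    def test_tie_breaks_are_deterministic(self):
        haps = [_hap("a", []), _hap("b", [V1]), _hap("c", [V2]), _hap("d", [V1, V2])]
        net = build_reduced_median(BinaryMatrix.from_haplotypes(haps))
        t1 = to_newick(extract_tree(net, (0, 0)))
        t2 = to_newick(extract_tree(net, (0, 0)))
        assert t1 == t2
        # equal weights: the lowest-position character wins the tie
        tree = extract_tree(net, (0, 0))
        dup = [p for p, k in _position_counts(tree).items() if k == 2]
        assert dup == [100]

    def test_planted_topology_recovered_from_simulated_data(self):
        for seed in (1, 2, 3):
            res = simulate_panmictic(SimConfig(seed=seed, n_samples=10))
            mat = BinaryMatrix.from_haplotypes(res.haplotypes)
            zero = tuple([0] * mat.rows.shape[1])
            tree = extract_tree(build_reduced_median(mat, root_state=zero), zero)
            assert _mutation_clades(tree) == _mutation_clades(res.true_tree)


def _position_counts(tree):
    counts = {}
    for n in tree.iter_nodes():
        for v in n.edge_variants:
            counts[v.position] = counts.get(v.position, 0) + 1
    return counts


def _mutation_clades(tree):
    """Sample bipartitions below every mutation-bearing edge (dedup'd)."""
    clades = set()
    for n in tree.iter_nodes():
        if n.edge_variants:
            below = frozenset(s for t in n.iter_tips() for s in t.tip_samples)
            if below:
                clades.add(below)
    return clades


class TestAnnotateClades:
    def test_single_variant_label_marks_subtree_root(self):
        haps = [_hap("a", []), _hap("b", [V1]), _hap("c", [V1, V2])]
        net = build_reduced_median(BinaryMatrix.from_haplotypes(haps))
        tree = extract_tree(net, (0, 0))
        annotate_clades(tree, {"HgX": [str(V1)]})
        node = tree.find_clade("HgX")
        assert node is not None
        tips = {s for t in node.iter_tips() for s in t.tip_samples}
        assert tips == {"b", "c"}

    def test_nested_definitions_child_more_specific(self):
        haps = [_hap("a", []), _hap("b", [V1]), _hap("c", [V1, V2])]
        net = build_reduced_median(BinaryMatrix.from_haplotypes(haps))
        tree = extract_tree(net, (0, 0))
        annotate_clades(tree, {"Hg": [str(V1)], "Hg1": [str(V1), str(V2)]})
        assert tree.find_clade("Hg") is not None
        assert tree.find_clade("Hg1") is not None
        assert tree.find_clade("Hg1") in list(tree.find_clade("Hg").iter_nodes())

    def test_unmatched_definition_warns_not_errors(self):
        haps = [_hap("a", []), _hap("b", [V1])]
        tree = extract_tree(build_reduced_median(BinaryMatrix.from_haplotypes(haps)), (0,))
        with pytest.warns(UserWarning, match="Nowhere"):
            annotate_clades(tree, {"Nowhere": ["C9999T"]})


class TestNewick:
    def test_newick_parses_and_has_all_samples(self):
        import dendropy

        res = simulate_panmictic(SimConfig(seed=5, n_samples=8))
        mat = BinaryMatrix.from_haplotypes(res.haplotypes)
        zero = tuple([0] * mat.rows.shape[1])
        tree = extract_tree(build_reduced_median(mat, root_state=zero), zero)
        nwk = to_newick(tree)
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        labels = {l.taxon.label for l in parsed.leaf_node_iter() if l.taxon}
        samples = {s for t in tree.iter_tips() for s in t.tip_samples}
        # dedup'd tips carry joined labels
        joined = set()
        for lab in labels:
            joined.update(lab.split("|"))
        assert samples <= joined
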