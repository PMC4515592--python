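"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from mtphylo.network import PhyloNode
from mtphylo.sequence_io import Variant


def sub(position: int, ref: str = "A", derived: str = "G", syn: str = "not_coding") -> Variant:
    return Variant(position, ref, derived, "substitution", synonymous=syn)


def star_tree(n_tips: int, muts_per_tip: int = 1, syn: str = "not_coding") -> PhyloNode:
    """Star phylogeny: every tip hangs off the root with private substitutions."""
    root = PhyloNode("root")
    pos = 100
    for i in range(n_tips):
        vs = []
        for _ in range(muts_per_tip):
            vs.append(sub(pos, syn=syn))
            pos += 1
        root.add_child(PhyloNode(f"tip{i}", edge_variants=vs, tip_samples=[f"tip{i}"]))
    return root


def three_tip_example() -> PhyloNode:
    """Shared edge with 2 mutations above 2 tips with 1 private each, plus a
    bare third tip: rho from the root is (3 + 3 + 0) / 3 = 2."""
    root = PhyloNode("root")
    inner = root.add_child(PhyloNode("inner", edge_variants=[sub(100), sub(101)]))
    inner.add_child(PhyloNode("a", edge_variants=[sub(102)], tip_samples=["a"]))
    inner.add_child(PhyloNode("b", edge_variants=[sub(103)], tip_samples=["b"]))
    root.add_child(PhyloNode("c", edge_variants=[], tip_samples=["c"]))
    return root


def random_mutation_tree(rng: np.random.Generator, n_tips: int, mean_muts: float = 1.5) -> PhyloNode:
    """Random rooted topology with Poisson mutation counts on edges."""
    nodes = [PhyloNode(f"t{i}", tip_samples=[f"t{i}"]) for i in range(n_tips)]
    # occasionally give a tip extra sample multiplicity
    for n in nodes:
        if rng.random() < 0.2:
            n.tip_samples.append(n.tip_samples[0] + "_dup")
    counter = 0
    pos = 1
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = PhyloNode(f"i{counter}")
        counter += 1
        for child in (a, b):
            k = rng.poisson(mean_muts)
            child.edge_variants = []
            for _ in range(k):
                child.edge_variants.append(sub(pos, syn="yes" if rng.random() < 0.4 else "no"))
                pos = pos % 16000 + 1
            parent.add_child(child)
        nodes = [n for k2, n in enumerate(nodes) if k2 not in (i, j)] + [parent]
    return nodes[0]


# ---------------------------------------------------------------------------
# independent rho / sigma oracles (path enumeration, tip-by-tip)
# ---------------------------------------------------------------------------

def rho_path_oracle(node: PhyloNode, count=lambda v: v.var_class == "substitution") -> float:
    """Rho by brute-force enumeration of root-to-tip paths."""
    total = 0.0
    n = 0
    for tip in node.iter_tips():
        w = max(len(tip.tip_samples), 1)
        m = 0
        cur = tip
        while cur is not node:
            m += sum(1 for v in cur.edge_variants if count(v))
            cur = cur.parent
        total += w * m
        n += w
    return total / n


def sigma_enumeration_oracle(node: PhyloNode, count=lambda v: v.var_class == "substitution") -> float:
    """Saillard sigma by explicit enumeration of every edge below the node."""
    tips = list(node.iter_tips())
    n = sum(max(len(t.tip_samples), 1) for t in tips)
    acc = 0.0
    stack = list(node.children)
    while stack:
        child = stack.pop()
        m_e = sum(1 for v in child.edge_variants if count(v))
        n_e = sum(max(len(t.tip_samples), 1) for t in child.iter_tips())
        acc += (n_e / n) ** 2 * m_e
        stack.extend(child.children)
    return acc**0.5


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
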