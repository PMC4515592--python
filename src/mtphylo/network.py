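"""Reduced-median networks and frequency-guided tree extraction.

Haplotypes are binary-encoded against the reference state (0 = rCRS allele,
1 = derived).  For character data compatible with a perfect phylogeny rooted
in the reference, the network *is* the unique perfect phylogeny.  For
conflicting characters (the four-gamete situation created by recurrent
mutation), median vectors are added and alternative resolutions are kept as
cycles unless one character is sufficiently rarer than the other
(reduction threshold), mirroring reduced-median practice where frequent,
likely-homoplasic mutations are the ones allowed to recur.

``extract_tree`` collapses the network to a single rooted mutation-labelled
tree: cycles are resolved so that the higher-frequency (lower-weight)
mutation sits deeper in the tree and is the one duplicated, with a fixed
lexicographic tie-break for determinism.
"""

from __future__ import annotations

import heapq
import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_io import Haplotype, Variant


class NetworkError(ValueError):
    pass


# ---------------------------------------------------------------------------
# binary encoding
# ---------------------------------------------------------------------------

@dataclass
class BinaryMatrix:
    """Deduplicated binary haplotype matrix with per-character weights.

    ``columns`` are the Variant objects defining each character; ``weights``
    are inverse relative mutation frequencies binned to integers 1-99 (a
    frequent mutation gets a low weight, i.e. it is cheap to reuse).
    """

    columns: list[Variant]
    rows: np.ndarray  # (n_distinct_haplotypes, n_characters), uint8
    row_samples: list[list[str]]
    weights: np.ndarray  # int, per column

    @classmethod
    def from_haplotypes(
        cls, haplotypes: Sequence[Haplotype], include_indels: bool = False
    ) -> "BinaryMatrix":
        if not haplotypes:
            raise NetworkError("empty haplotype list")
        variants: dict[Variant, int] = {}
        for h in haplotypes:
            for v in h.variants:
                if not include_indels and v.var_class != "substitution":
                    continue
                variants.setdefault(v, 0)
                variants[v] += 1
        cols = sorted(variants)
        n = len(haplotypes)
        mat = np.zeros((n, len(cols)), dtype=np.uint8)
        col_index = {v: j for j, v in enumerate(cols)}
        for i, h in enumerate(haplotypes):
            for v in h.variants:
                j = col_index.get(v)
                if j is not None:
                    mat[i, j] = 1
        # drop invariant columns (all-0 impossible here; all-1 possible)
        counts = mat.sum(axis=0)
        keep = [j for j in range(len(cols)) if 0 < counts[j] < n]
        cols = [cols[j] for j in keep]
        mat = mat[:, keep]
        counts = counts[keep]
        # weights: inverse relative frequency, binned to 1..99
        weights = np.clip(np.rint(n / np.maximum(counts, 1)), 1, 99).astype(int)
        # deduplicate rows, keeping sample multiplicity
        seen: dict[tuple, int] = {}
        row_samples: list[list[str]] = []
        dedup: list[tuple] = []
        for i, h in enumerate(haplotypes):
            key = tuple(int(x) for x in mat[i])
            if key in seen:
                row_samples[seen[key]].append(h.sample_id)
            else:
                seen[key] = len(dedup)
                dedup.append(key)
                row_samples.append([h.sample_id])
        return cls(
            columns=cols,
            rows=np.array(dedup, dtype=np.uint8).reshape(len(dedup), len(cols)),
            row_samples=row_samples,
            weights=weights,
        )


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

@dataclass
class HaploNetwork:
    """Nodes are haplotype state vectors; each edge flips one character."""

    columns: list[Variant]
    weights: np.ndarray
    nodes: dict[tuple, str]  # vector -> kind: observed | median | latent
    node_samples: dict[tuple, list[str]]
    edges: set[tuple[tuple, tuple, int]]  # (u, v, char index), u < v lexicographically

    @property
    def n_median_vectors(self) -> int:
        return sum(1 for k in self.nodes.values() if k == "median")

    @property
    def n_latent(self) -> int:
        return sum(1 for k in self.nodes.values() if k == "latent")

    def neighbors(self, u: tuple) -> list[tuple[tuple, int]]:
        out = []
        for a, b, c in self.edges:
            if a == u:
                out.append((b, c))
            elif b == u:
                out.append((a, c))
        return out

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for a, b, c in sorted(self.edges):
            rows.append(
                {
                    "from": "".join(map(str, a)),
                    "to": "".join(map(str, b)),
                    "variant": str(self.columns[c]),
                    "weight": int(self.weights[c]),
                }
            )
        return pd.DataFrame(rows, columns=["from", "to", "variant", "weight"])


def _edge(u: tuple, v: tuple, c: int) -> tuple:
    return (u, v, c) if u <= v else (v, u, c)


def _conflicting_pairs(rows: np.ndarray) -> list[tuple[int, int]]:
    """Character pairs violating rooted (three-gamete) compatibility.

    With the ancestral state known to be all-zero, characters i and j are
    incompatible iff the patterns (1,1), (1,0) and (0,1) all occur.
    """
    m = rows.shape[1]
    out = []
    for i, j in itertools.combinations(range(m), 2):
        a = rows[:, i].astype(bool)
        b = rows[:, j].astype(bool)
        if (a & b).any() and (a & ~b).any() and (~a & b).any():
            out.append((i, j))
    return out


def _perfect_phylogeny(matrix: BinaryMatrix, root_state: tuple) -> HaploNetwork:
    """Unique perfect phylogeny for rooted-compatible characters.

    Characters with identical taxon sets share an edge path (a chain of
    latent intermediates); the laminar containment order of taxon sets gives
    the tree.  Exactly one edge per character, no median vectors.
    """
    rows = matrix.rows
    m = rows.shape[1]
    sets = [frozenset(np.flatnonzero(rows[:, j]).tolist()) for j in range(m)]
    groups: dict[frozenset, list[int]] = {}
    for j, s in enumerate(sets):
        groups.setdefault(s, []).append(j)
    ordered = sorted(groups, key=lambda s: (-len(s), min(groups[s])))

    nodes: dict[tuple, str] = {root_state: "latent"}
    node_samples: dict[tuple, list[str]] = {}
    edges: set = set()
    end_vec: dict[frozenset, tuple] = {}

    for s in ordered:
        parent_sets = [t for t in ordered if len(t) > len(s) and s < t]
        if parent_sets:
            parent = min(parent_sets, key=len)
            cur = end_vec[parent]
        else:
            cur = root_state
        for j in sorted(groups[s], key=lambda j: (matrix.columns[j].position, j)):
            nxt = list(cur)
            nxt[j] ^= 1
            nxt = tuple(nxt)
            nodes.setdefault(nxt, "latent")
            edges.add(_edge(cur, nxt, j))
            cur = nxt
        end_vec[s] = cur

    row_keys = [tuple(int(x) for x in r) for r in rows]
    for key, samples in zip(row_keys, matrix.row_samples):
        nodes[key] = "observed"
        node_samples[key] = list(samples)
    return HaploNetwork(matrix.columns, matrix.weights, nodes, node_samples, edges)


def _median_closure(node_set: set[tuple], max_nodes: int = 2000) -> set[tuple]:
    """Add componentwise-majority medians of node triples until closure."""
    nodes = set(node_set)
    added = True
    while added:
        added = False
        for u, v, w in itertools.combinations(sorted(nodes), 3):
            a = np.array([u, v, w], dtype=np.uint8)
            med = tuple(int(x) for x in (a.sum(axis=0) >= 2).astype(np.uint8))
            if med not in nodes:
                nodes.add(med)
                added = True
                if len(nodes) > max_nodes:
                    raise NetworkError("median closure exceeded node budget")
    return nodes


def build_reduced_median(
    matrix: BinaryMatrix,
    reduction_threshold: float = 2.0,
    root_state: tuple | None = None,
) -> HaploNetwork:
    """Build a reduced-median network from a binary haplotype matrix.

    Pairwise-compatible data yield the unique perfect phylogeny (a tree with
    one edge per character and no median vectors).  Conflicting character
    pairs produce median vectors and reticulations; a conflict whose weight
    ratio reaches ``reduction_threshold`` is resolved by deleting one edge of
    the rarer character in each conflict cycle, so the frequent character is
    the one that recurs.

    ``root_state`` may force a node for the ancestral (reference) haplotype,
    e.g. the all-zero vector.
    """
    if matrix.rows.size == 0 and len(matrix.row_samples) == 0:
        raise NetworkError("empty matrix")
    m = matrix.rows.shape[1]
    if root_state is None and m > 0:
        pass
    if m == 0:
        # all haplotypes identical: a single node
        key = ()
        nodes = {key: "observed"}
        samples = {key: [s for group in matrix.row_samples for s in group]}
        return HaploNetwork(matrix.columns, matrix.weights, nodes, samples, set())

    zero = tuple([0] * m)
    conflicts = _conflicting_pairs(matrix.rows)
    if not conflicts:
        net = _perfect_phylogeny(matrix, root_state if root_state is not None else zero)
        if root_state is not None and root_state not in net.nodes:
            raise NetworkError("root state unreachable in perfect phylogeny")
        return net

    observed = {tuple(int(x) for x in r) for r in matrix.rows}
    seed = set(observed)
    if root_state is not None:
        seed.add(root_state)
    closed = _median_closure(seed)

    nodes: dict[tuple, str] = {}
    for v in closed:
        if v in observed:
            nodes[v] = "observed"
        elif root_state is not None and v == root_state:
            nodes[v] = "latent"
        else:
            nodes[v] = "median"
    node_samples = {
        tuple(int(x) for x in r): list(s)
        for r, s in zip(matrix.rows, matrix.row_samples)
    }

    # distance-1 adjacency
    edges: set = set()
    node_list = sorted(nodes)
    for u, v in itertools.combinations(node_list, 2):
        diff = [j for j in range(m) if u[j] != v[j]]
        if len(diff) == 1:
            edges.add(_edge(u, v, diff[0]))

    _prune_dead_ends(nodes, edges)
    _connect_components(matrix, nodes, edges)
    _reduce_conflicts(matrix, nodes, edges, conflicts, reduction_threshold)
    _prune_dead_ends(nodes, edges)
    return HaploNetwork(matrix.columns, matrix.weights, nodes, node_samples, edges)


def _degree(edges: set, u: tuple) -> int:
    return sum(1 for a, b, _ in edges if a == u or b == u)


def _prune_dead_ends(nodes: dict, edges: set) -> None:
    """Iteratively drop unobserved nodes of degree <= 1 (never parsimony-useful)."""
    changed = True
    while changed:
        changed = False
        for u in [v for v, k in list(nodes.items()) if k != "observed"]:
            deg = _degree(edges, u)
            if deg <= 1 and len(nodes) > 1:
                for e in [e for e in edges if u in (e[0], e[1])]:
                    edges.discard(e)
                del nodes[u]
                changed = True


def _components(nodes: dict, edges: set) -> list[set]:
    adj: dict[tuple, set] = {u: set() for u in nodes}
    for a, b, _ in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen: set = set()
    comps = []
    for u in sorted(nodes):
        if u in seen:
            continue
        comp = {u}
        stack = [u]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y not in comp:
                    comp.add(y)
                    stack.append(y)
        seen |= comp
        comps.append(comp)
    return comps


def _connect_components(matrix: BinaryMatrix, nodes: dict, edges: set) -> None:
    """Join disconnected components with minimal latent single-step chains."""
    while True:
        comps = _components(nodes, edges)
        if len(comps) <= 1:
            return
        best = None
        for ia, ib in itertools.combinations(range(len(comps)), 2):
            for u in sorted(comps[ia]):
                for v in sorted(comps[ib]):
                    d = sum(1 for x, y in zip(u, v) if x != y)
                    key = (d, min(u, v), max(u, v))
                    if best is None or key < best[0]:
                        best = (key, u, v)
        _, u, v = best
        if u > v:
            u, v = v, u
        diff = [j for j in range(len(u)) if u[j] != v[j]]
        diff.sort(key=lambda j: (matrix.weights[j], matrix.columns[j].position, j))
        cur = u
        for j in diff:
            nxt = list(cur)
            nxt[j] ^= 1
            nxt = tuple(nxt)
            if nxt not in nodes:
                nodes[nxt] = "latent"
            edges.add(_edge(cur, nxt, j))
            cur = nxt


def _reduce_conflicts(
    matrix: BinaryMatrix,
    nodes: dict,
    edges: set,
    conflicts: list[tuple[int, int]],
    threshold: float,
) -> None:
    """Resolve dominated conflicts: delete one rare-character edge per cycle."""
    for i, j in conflicts:
        wi, wj = float(matrix.weights[i]), float(matrix.weights[j])
        if wi == wj:
            continue
        hi, lo = (i, j) if wi > wj else (j, i)
        if max(wi, wj) < threshold * min(wi, wj):
            continue
        # locate 4-cycles x, x+e_lo, x+e_hi, x+e_lo+e_hi
        for x in sorted(nodes):
            if x[hi] != 0 or x[lo] != 0:
                continue
            a = list(x); a[hi] = 1; a = tuple(a)          # x + hi
            b = list(x); b[lo] = 1; b = tuple(b)          # x + lo
            c = list(a); c[lo] = 1; c = tuple(c)          # x + hi + lo
            cycle = (
                _edge(x, a, hi) in edges
                and _edge(x, b, lo) in edges
                and _edge(a, c, lo) in edges
                and _edge(b, c, hi) in edges
            )
            if not cycle:
                continue
            # two rare-char (hi) edges: (x,a) and (b,c); delete the one with
            # less observed support, tie-broken lexicographically
            def support(p, q):
                return sum(1 for t in (p, q) if nodes.get(t) == "observed")

            e1, e2 = _edge(x, a, hi), _edge(b, c, hi)
            drop = min((support(x, a), e1), (support(b, c), e2))[1]
            edges.discard(drop)


# ---------------------------------------------------------------------------
# rooted mutation-labelled tree
# ---------------------------------------------------------------------------

class PhyloNode:
    """Rooted mutation-labelled tree node.

    ``edge_variants`` are the variants on the edge to the parent (empty at
    the root); tips carry ``tip_samples``.  ``branch_years`` is set on
    simulated genealogies.
    """

    __slots__ = (
        "node_id",
        "edge_variants",
        "children",
        "tip_samples",
        "clade_label",
        "parent",
        "branch_years",
    )

    def __init__(
        self,
        node_id: str,
        edge_variants: list[Variant] | None = None,
        tip_samples: list[str] | None = None,
        clade_label: str | None = None,
        branch_years: float | None = None,
    ):
        self.node_id = node_id
        self.edge_variants = list(edge_variants or [])
        self.children: list[PhyloNode] = []
        self.tip_samples = list(tip_samples or [])
        self.clade_label = clade_label
        self.parent: PhyloNode | None = None
        self.branch_years = branch_years

    def add_child(self, child: "PhyloNode") -> "PhyloNode":
        child.parent = self
        self.children.append(child)
        return child

    def iter_nodes(self):
        yield self
        for c in self.children:
            yield from c.iter_nodes()

    def iter_tips(self):
        if not self.children:
            yield self
        else:
            for c in self.children:
                yield from c.iter_tips()

    def find(self, node_id: str) -> "PhyloNode | None":
        for n in self.iter_nodes():
            if n.node_id == node_id:
                return n
        return None

    def find_clade(self, label: str) -> "PhyloNode | None":
        for n in self.iter_nodes():
            if n.clade_label == label:
                return n
        return None

    @property
    def n_samples_below(self) -> int:
        return sum(len(t.tip_samples) for t in self.iter_tips())

    def variants_from_root(self) -> list[Variant]:
        path = []
        node = self
        while node is not None:
            path.extend(node.edge_variants)
            node = node.parent
        return path

    def recurrent_positions(self) -> set[int]:
        """Positions struck on more than one edge of the tree.

        Any such position violates the infinite-sites assumption, whether as
        a parallel mutation on separate lineages or a back mutation on one
        root-to-tip path; dating counts every occurrence.
        """
        counts: dict[int, int] = {}
        for node in self.iter_nodes():
            for v in node.edge_variants:
                counts[v.position] = counts.get(v.position, 0) + 1
        return {p for p, k in counts.items() if k > 1}

    def __repr__(self):
        return f"PhyloNode({self.node_id!r}, tips={self.n_samples_below})"


def extract_tree(
    network: HaploNetwork, root_haplotype: tuple
) -> PhyloNode:
    """Extract a single rooted spanning tree from the network.

    Shortest-path (Dijkstra) spanning tree from the root with edge cost =
    character weight, so low-weight (high-frequency) mutations are placed as
    deep as possible; among equal-cost parents the edge with the smaller
    (weight, position, derived base, parent state) wins.  Deterministic.
    """
    if root_haplotype not in network.nodes:
        raise NetworkError("root haplotype not in network")
    cols = network.columns
    weights = network.weights

    dist: dict[tuple, float] = {root_haplotype: 0.0}
    heap = [(0.0, root_haplotype)]
    adj: dict[tuple, list[tuple[tuple, int]]] = {u: [] for u in network.nodes}
    for a, b, c in network.edges:
        adj[a].append((b, c))
        adj[b].append((a, c))
    visited: set = set()
    while heap:
        d, u = heapq.heappop(heap)
        if u in visited:
            continue
        visited.add(u)
        for v, c in adj[u]:
            nd = d + float(weights[c])
            if nd < dist.get(v, np.inf):
                dist[v] = nd
                heapq.heappush(heap, (nd, v))

    if len(visited) != len(network.nodes):
        raise NetworkError("network is not connected")

    # deterministic parent choice among optimal predecessors
    parent: dict[tuple, tuple[tuple, int]] = {}
    for v in network.nodes:
        if v == root_haplotype:
            continue
        cands = []
        for u, c in adj[v]:
            if abs(dist[u] + float(weights[c]) - dist[v]) < 1e-9:
                cands.append(
                    (
                        float(weights[c]),
                        cols[c].position,
                        cols[c].derived_base,
                        u,
                        c,
                    )
                )
        if not cands:
            raise NetworkError("disconnected node in extraction")
        best = min(cands)
        parent[v] = (best[3], best[4])

    children: dict[tuple, list[tuple[tuple, int]]] = {u: [] for u in network.nodes}
    for v, (u, c) in parent.items():
        children[u].append((v, c))

    counter = itertools.count()
    root = PhyloNode(f"n{next(counter)}")

    def attach_samples(node: PhyloNode, state: tuple):
        samples = network.node_samples.get(state, [])
        if not samples:
            return
        if children[state]:
            tip = PhyloNode(f"{node.node_id}.s", tip_samples=samples)
            node.add_child(tip)
        else:
            node.tip_samples = list(samples)

    def build(state: tuple, node: PhyloNode):
        kids = sorted(
            children[state],
            key=lambda vc: (cols[vc[1]].position, cols[vc[1]].derived_base, vc[0]),
        )
        attach_samples(node, state)
        for v, c in kids:
            child = PhyloNode(f"n{next(counter)}", edge_variants=[cols[c]])
            node.add_child(child)
            build(v, child)

    build(root_haplotype, root)
    return root


def annotate_clades(
    tree: PhyloNode, clade_definitions: Mapping[str, Iterable[Variant | str]]
) -> PhyloNode:
    """Label nodes whose root-to-node mutation set contains a definition.

    Definitions map labels to defining variant sets (Variant objects or
    PhyloTree-style strings).  The most specific (largest) matching
    definition wins at each node; definitions matching no node raise a
    warning, not an error.  Modifies and returns the tree.
    """
    defs = {
        label: {str(v) for v in vs} for label, vs in clade_definitions.items()
    }
    matched: set[str] = set()
    for node in tree.iter_nodes():
        acc = {str(v) for v in node.variants_from_root()}
        best = None
        for label, vs in sorted(defs.items()):
            if vs <= acc:
                if best is None or len(vs) > len(defs[best]):
                    best = label
        if best is not None:
            # label only the basal node of each clade: parent must not match
            if node.parent is not None:
                pacc = {str(v) for v in node.parent.variants_from_root()}
                if defs[best] <= pacc:
                    continue
            node.clade_label = best
            matched.add(best)
    for label in set(defs) - matched:
        warnings.warn(f"clade definition {label!r} matched no node", stacklevel=2)
    return tree


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def to_newick(tree: PhyloNode, include_variants: bool = True) -> str:
    """Newick serialization; edge variant lists ride in [&...] comments."""
    import dendropy

    dtree = dendropy.Tree()

    def convert(node: PhyloNode, dnode):
        dnode.label = node.node_id
        if node.tip_samples:
            dnode.label = "|".join(node.tip_samples)
        dnode.edge.length = len(node.edge_variants)
        if include_variants and node.edge_variants:
            dnode.annotations.add_new(
                "variants", "/".join(str(v) for v in sorted(node.edge_variants))
            )
        if node.clade_label:
            dnode.annotations.add_new("clade", node.clade_label)
        for c in node.children:
            convert(c, dnode.new_child())

    convert(tree, dtree.seed_node)
    return dtree.as_string(
        schema="newick",
        suppress_annotations=not include_variants,
        suppress_rooting=True,
        suppress_leaf_node_labels=False,
    ).strip()


def write_newick(tree: PhyloNode, path, include_variants: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree, include_variants=include_variants) + "\n")
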