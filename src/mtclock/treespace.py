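"""Exhaustive enumeration of small unrooted binary tree topologies.

With n <= ~10 taxa the number of unrooted binary topologies, (2n-5)!!, is
small enough to enumerate outright, which lets downstream analyses assign a
weight to *every* possible tree rather than to a heuristically searched
subset.  Enumeration is by stepwise addition: each new taxon is attached to
every edge of every partial tree, which constructs each topology exactly
once.

Internally an unrooted topology is held in the classic rooted-at-a-leaf
form: the alphabetically first taxon is the reference leaf and the rest of
the tree is a rooted binary structure of nested pairs.  Edges of the
unrooted tree correspond one-to-one to nodes of that structure, and a
min-lexicographic rewrite of the nesting gives a canonical string key that
is identical for isomorphic trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import dendropy

Nested = "str | tuple"  # leaf label, or a pair of Nested

MAX_ENUM_TAXA = 10


def _canonical(node) -> str:
    if isinstance(node, str):
        return node
    a, b = (_canonical(node[0]), _canonical(node[1]))
    if b < a:
        a, b = b, a
    return f"({a},{b})"


def _leafset(node) -> frozenset:
    if isinstance(node, str):
        return frozenset([node])
    return _leafset(node[0]) | _leafset(node[1])


def _subtree_leafsets(node, out: list) -> frozenset:
    ls = (
        frozenset([node])
        if isinstance(node, str)
        else _subtree_leafsets(node[0], out) | _subtree_leafsets(node[1], out)
    )
    out.append(ls)
    return ls


@dataclass(frozen=True)
class Topology:
    """Unrooted binary tree shape over a fixed label set (no branch lengths)."""

    ref: str
    rest: object  # Nested over the remaining labels

    @cached_property
    def taxa(self) -> frozenset:
        return frozenset([self.ref]) | _leafset(self.rest)

    @cached_property
    def canonical_form(self) -> str:
        return f"[{self.ref}]{_canonical(self.rest)}"

    def __eq__(self, other) -> bool:
        return isinstance(other, Topology) and self.canonical_form == other.canonical_form

    def __hash__(self) -> int:
        return hash(self.canonical_form)

    @cached_property
    def bipartitions(self) -> frozenset:
        """All non-trivial splits, each as the side not containing the ref leaf."""
        sets: list = []
        _subtree_leafsets(self.rest, sets)
        n = len(self.taxa)
        return frozenset(s for s in sets if 2 <= len(s) <= n - 2)

    def has_clade(self, clade) -> bool:
        """True if the label set forms one side of a bipartition.

        Trivial clades (singletons, the full taxon set, or n-1 of n taxa)
        are present in every binary tree.
        """
        clade = frozenset(clade)
        if not clade or not clade <= self.taxa:
            raise ValueError("clade must be a non-empty subset of the taxa")
        n = len(self.taxa)
        if len(clade) in (1, n - 1, n):
            return True
        return clade in self.bipartitions or (self.taxa - clade) in self.bipartitions

    def newick(self) -> str:
        def w(node):
            if isinstance(node, str):
                return node
            return f"({w(node[0])},{w(node[1])})"

        if isinstance(self.rest, str):  # n == 2 degenerate
            return f"({self.ref},{self.rest});"
        return f"({self.ref},{w(self.rest[0])},{w(self.rest[1])});"

    @classmethod
    def from_newick(cls, newick: str) -> "Topology":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        adj, labels = _dendropy_to_adjacency(tree)
        return cls.from_adjacency(adj, labels)

    @classmethod
    def from_adjacency(cls, adj: dict, labels: dict) -> "Topology":
        leaves = sorted(labels.values())
        ref_id = next(i for i, lab in labels.items() if lab == leaves[0])

        def build(node, parent):
            nbrs = [x for x in adj[node] if x != parent]
            if not nbrs:
                return labels[node]
            if len(nbrs) != 2:
                raise ValueError("tree is not binary (after rooting at the reference leaf)")
            return (build(nbrs[0], node), build(nbrs[1], node))

        (start,) = adj[ref_id]
        return cls(ref=leaves[0], rest=build(start, ref_id))


def _dendropy_to_adjacency(tree: dendropy.Tree):
    """Collapse a dendropy tree to an unrooted adjacency map, suppressing
    any degree-2 root node."""
    adj: dict = {}
    labels: dict = {}
    for node in tree.preorder_node_iter():
        adj.setdefault(id(node), [])
        if node.is_leaf():
            labels[id(node)] = node.taxon.label if node.taxon else node.label
        for child in node.child_nodes():
            adj.setdefault(id(child), [])
            adj[id(node)].append(id(child))
            adj[id(child)].append(id(node))
    # suppress degree-2 nodes (rooted newick roots)
    for nid in [n for n, nb in adj.items() if len(nb) == 2 and n not in labels]:
        a, b = adj.pop(nid)
        adj[a] = [x for x in adj[a] if x != nid] + [b]
        adj[b] = [x for x in adj[b] if x != nid] + [a]
    return adj, labels


def canonicalize(topology: Topology) -> str:
    """Stable string key; equal iff the unrooted labelled shapes are equal."""
    return topology.canonical_form


def _insertions(node, leaf):
    """All trees from attaching `leaf` onto the edge above each node."""
    yield (node, leaf)
    if isinstance(node, tuple):
        left, right = node
        for new_left in _insertions(left, leaf):
            yield (new_left, right)
        for new_right in _insertions(right, leaf):
            yield (left, new_right)


def enumerate_topologies(taxa, constraint=None) -> list[Topology]:
    """All unrooted binary topologies over `taxa`, by stepwise addition.

    Parameters
    ----------
    taxa:
        Iterable of 3..10 unique labels.
    constraint:
        Optional label set that must form a bipartition (clade) in every
        returned topology; non-conforming topologies are filtered out.

    Returns (2n-5)!! topologies when unconstrained, sorted by canonical key.
    """
    labels = sorted(set(taxa))
    n = len(labels)
    if n != len(list(taxa)):
        raise ValueError("taxon labels must be unique")
    if not 3 <= n <= MAX_ENUM_TAXA:
        raise ValueError(f"enumeration supports 3..{MAX_ENUM_TAXA} taxa, got {n}")
    if constraint is not None:
        constraint = frozenset(constraint)
        if not constraint <= set(labels):
            raise ValueError("constraint labels must be a subset of the taxa")

    ref = labels[0]
    rests = [(labels[1], labels[2])] if n >= 3 else []
    for leaf in labels[3:]:
        rests = [new for rest in rests for new in _insertions(rest, leaf)]
    topologies = [Topology(ref=ref, rest=rest) for rest in rests]
    if constraint is not None:
        topologies = [t for t in topologies if t.has_clade(constraint)]
    return sorted(topologies, key=lambda t: t.canonical_form)


def _topology_adjacency(topology: Topology):
    """Unrooted adjacency map (node id -> neighbour ids) and leaf labels."""
    adj: dict = {}
    labels: dict = {}
    counter = [0]

    def new_id():
        counter[0] += 1
        return counter[0]

    def build(node):
        nid = new_id()
        adj[nid] = []
        if isinstance(node, str):
            labels[nid] = node
        else:
            for child in node:
                cid = build(child)
                adj[nid].append(cid)
                adj[cid].append(nid)
        return nid

    rest_root = build(topology.rest)
    ref_id = new_id()
    adj[ref_id] = [rest_root]
    labels[ref_id] = topology.ref
    adj[rest_root].append(ref_id)
    return adj, labels


def root_with_outgroup(topology: Topology, outgroup) -> tuple:
    """Root on the edge separating the outgroup from the ingroup.

    Returns a nested-pair rooted tree (outgroup_subtree, ingroup_subtree).
    Raises if the outgroup is not monophyletic in this topology.
    """
    outgroup = frozenset(outgroup)
    if not outgroup or not outgroup < topology.taxa:
        raise ValueError("outgroup must be a proper non-empty subset of the taxa")
    if not topology.has_clade(outgroup):
        raise ValueError(
            f"outgroup {sorted(outgroup)} is not monophyletic in this topology"
        )
    adj, labels = _topology_adjacency(topology)

    def side_leafset(node, parent):
        if node in labels:
            return frozenset([labels[node]])
        out = frozenset()
        for nbr in adj[node]:
            if nbr != parent:
                out |= side_leafset(nbr, node)
        return out

    def build(node, parent):
        if node in labels:
            return labels[node]
        children = [build(n, node) for n in adj[node] if n != parent]
        if len(children) != 2:
            raise AssertionError("non-binary node while rooting")
        return tuple(children)

    for u in adj:
        for v in adj[u]:
            if side_leafset(v, u) == outgroup:
                return (build(v, u), build(u, v))
    raise AssertionError("outgroup edge not found despite monophyly check")


def rooted_newick(nested) -> str:
    def w(node):
        if isinstance(node, str):
            return node
        return f"({w(node[0])},{w(node[1])})"

    return w(nested) + ";"


def rooted_leafsets(nested) -> list[frozenset]:
    out: list = []
    _subtree_leafsets(nested, out)
    return out


def write_topologies(topologies, path) -> None:
    """One Newick string per line, with the canonical key as a comment."""
    with open(path, "w") as fh:
        for t in topologies:
            fh.write(f"{t.newick()}\n")
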