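"""Unrooted maximum-parsimony trees over binary methylation characters.

Leaves are phased methylation patterns (strings over {C, T}, one character
per CpG site); the tree length is the minimum number of methylation-state
changes needed on a topology (Fitch's algorithm, counted per site and
summed).  Topology search is exhaustive over all (2n-5)!! unrooted binary
trees up to 9 leaves and stepwise addition followed by
nearest-neighbor-interchange refinement above that; both are deterministic
for a given leaf order, with ties broken by enumeration order.  Branch
lengths in the emitted Newick are per-edge change counts from one (of
possibly many) most-parsimonious ancestral assignment and are not to scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ParsimonyResult",
    "fitch_length",
    "parsimony_tree",
    "bootstrap_support",
    "EXHAUSTIVE_MAX_LEAVES",
]

EXHAUSTIVE_MAX_LEAVES = 9

_STATE = {"C": 1, "T": 2}


def _encode(patterns: list[str]) -> np.ndarray:
    """Leaf state bitmasks, shape (n_leaves, n_sites); C=1, T=2."""
    if len({len(p) for p in patterns}) > 1:
        raise ValueError("patterns must have equal length")
    try:
        return np.array([[_STATE[ch] for ch in p] for p in patterns], dtype=np.uint8)
    except KeyError as e:
        raise ValueError(f"patterns must be over {{C,T}}, got {e}") from None


def _adjacency(edges) -> dict[int, list[int]]:
    adj: dict[int, list[int]] = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    return adj


def _postorder(adj: dict[int, list[int]], root: int) -> list[tuple[int, int]]:
    """(node, parent) pairs, children before parents."""
    order = []
    stack = [(root, -1)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        for nb in adj[node]:
            if nb != parent:
                stack.append((nb, node))
    return order[::-1]


def fitch_length(edges, leaf_states: np.ndarray) -> int:
    """Minimum total state changes on an unrooted tree (Fitch, all sites)."""
    n_leaves, n_sites = leaf_states.shape
    if n_leaves == 1 or n_sites == 0:
        return 0
    adj = _adjacency(edges)
    sets: dict[int, np.ndarray] = {}
    changes = 0
    for node, parent in _postorder(adj, root=0):
        if node < n_leaves:
            sets[node] = leaf_states[node]
            continue
        acc = None
        for nb in adj[node]:
            if nb == parent:
                continue
            child = sets[nb]
            if acc is None:
                acc = child
            else:
                inter = acc & child
                empty = inter == 0
                changes += int(empty.sum())
                acc = np.where(empty, acc | child, inter)
        sets[node] = acc
    # fold the root leaf itself in
    root_child = sets[adj[0][0]]
    inter = leaf_states[0] & root_child
    changes += int((inter == 0).sum())
    return changes


def _insertions(edges, new_leaf: int, new_internal: int):
    """All trees obtained by attaching new_leaf onto each edge, in order."""
    for i, (a, b) in enumerate(edges):
        rest = edges[:i] + edges[i + 1 :]
        yield rest + [(a, new_internal), (new_internal, b), (new_internal, new_leaf)]


def _enumerate_topologies(n_leaves: int):
    """All unrooted binary topologies, deterministically ordered.

    Leaves 0..n-1, internal nodes n_leaves..2*n_leaves-3, built by
    recursive edge insertion.
    """
    if n_leaves == 2:
        yield [(0, 1)]
        return
    base = [(n_leaves, 0), (n_leaves, 1), (n_leaves, 2)]
    stack = [(base, 3)]
    while stack:
        edges, k = stack.pop()
        if k == n_leaves:
            yield edges
            continue
        for tree in reversed(list(_insertions(edges, k, n_leaves + k - 2))):
            stack.append((tree, k + 1))


def _exhaustive_search(leaf_states: np.ndarray) -> tuple[list, int]:
    best_edges, best_len = None, None
    for edges in _enumerate_topologies(leaf_states.shape[0]):
        length = fitch_length(edges, leaf_states)
        if best_len is None or length < best_len:
            best_edges, best_len = edges, length
    return best_edges, best_len


def _stepwise_addition(
    leaf_states: np.ndarray, beam: int = 8
) -> list[tuple[list, int]]:
    """Beam-search stepwise addition: the ``beam`` best trees at each step.

    Leaves are added in input order; partial trees are ranked by Fitch
    length with ties broken by edge-list order, keeping the search
    deterministic.
    """
    n = leaf_states.shape[0]
    frontier = [[(n, 0), (n, 1), (n, 2)]]
    for k in range(3, n):
        scored = []
        seen = set()
        for edges in frontier:
            for tree in _insertions(edges, k, n + k - 2):
                key = frozenset(tuple(sorted(e)) for e in tree)
                if key in seen:
                    continue
                seen.add(key)
                scored.append((fitch_length(tree, leaf_states[: k + 1]), tree))
        scored.sort(key=lambda x: (x[0], x[1]))
        frontier = [tree for _, tree in scored[:beam]]
    return [(edges, fitch_length(edges, leaf_states)) for edges in frontier]


def _spr_neighbours(edges):
    """Trees one subtree-prune-regraft move away, in deterministic order.

    For every directed edge (s, t) with t internal, the subtree on the s
    side is pruned (t's two remaining neighbours are spliced together) and
    regrafted, via t, onto every edge of the remaining tree.  The SPR
    neighbourhood contains all nearest-neighbor interchanges.
    """
    adj = _adjacency(edges)
    edge_set = {tuple(sorted(e)) for e in edges}
    for s, t in sorted((a, b) for a, b in edge_set for a, b in ((a, b), (b, a))):
        if len(adj[t]) != 3:
            continue
        # leaves/nodes on s's side of the pruned edge
        side = set()
        stack = [(s, t)]
        while stack:
            node, parent = stack.pop()
            side.add(node)
            for nb in adj[node]:
                if nb != parent:
                    stack.append((nb, node))
        x, y = [nb for nb in adj[t] if nb != s]
        spliced = tuple(sorted((x, y)))
        remaining = {
            e for e in edge_set if e[0] not in side and e[1] not in side and t not in e
        }
        remaining.add(spliced)
        subtree_edges = {e for e in edge_set if e[0] in side and e[1] in side}
        for a, b in sorted(remaining):
            if (a, b) == spliced:
                continue  # recreates the original tree
            new = (remaining - {(a, b)}) | subtree_edges
            new |= {
                tuple(sorted((a, t))),
                tuple(sorted((t, b))),
                tuple(sorted((t, s))),
            }
            yield sorted(new)


def _spr_refine(edges, length, leaf_states: np.ndarray) -> tuple[list, int]:
    improved = True
    while improved:
        improved = False
        for cand in _spr_neighbours(edges):
            cand_len = fitch_length(cand, leaf_states)
            if cand_len < length:
                edges, length = cand, cand_len
                improved = True
                break
    return edges, length


def _heuristic_search(leaf_states: np.ndarray) -> tuple[list, int]:
    """Beam stepwise addition, then SPR refinement of every beam entry."""
    best_edges, best_len = None, None
    for edges, length in _stepwise_addition(leaf_states):
        edges, length = _spr_refine(edges, length, leaf_states)
        if best_len is None or length < best_len:
            best_edges, best_len = edges, length
    return best_edges, best_len


def _bipartitions(edges, n_leaves: int) -> set[frozenset]:
    """Non-trivial leaf bipartitions, canonicalised as the side without leaf 0."""
    adj = _adjacency(edges)
    out = set()
    for a, b in edges:
        # leaves on b's side of edge (a, b)
        side = set()
        stack = [(b, a)]
        while stack:
            node, parent = stack.pop()
            if node < n_leaves:
                side.add(node)
            for nb in adj[node]:
                if nb != parent:
                    stack.append((nb, node))
        if 0 in side:
            side = set(range(n_leaves)) - side
        if 2 <= len(side) <= n_leaves - 2:
            out.add(frozenset(side))
    return out


def _edge_changes(edges, leaf_states: np.ndarray) -> dict[tuple[int, int], int]:
    """Per-edge change counts from one most-parsimonious assignment."""
    n_leaves, n_sites = leaf_states.shape
    adj = _adjacency(edges)
    sets: dict[int, np.ndarray] = {}
    for node, parent in _postorder(adj, root=0):
        if node < n_leaves:
            sets[node] = leaf_states[node]
            continue
        acc = None
        for nb in adj[node]:
            if nb == parent:
                continue
            child = sets[nb]
            if acc is None:
                acc = child
            else:
                inter = acc & child
                acc = np.where(inter == 0, acc | child, inter)
        sets[node] = acc
    # up-pass: assign states top-down, preferring the parent's state
    assign: dict[int, np.ndarray] = {0: leaf_states[0]}
    counts: dict[tuple[int, int], int] = {}
    stack = [(adj[0][0], 0)]
    while stack:
        node, parent = stack.pop()
        s = sets[node]
        p_state = assign[parent]
        in_set = (s & p_state) != 0
        # lowest set bit when the parent's state is unavailable
        fallback = np.where(s & 1 != 0, 1, 2).astype(np.uint8)
        assign[node] = np.where(in_set, p_state, fallback).astype(np.uint8)
        counts[tuple(sorted((parent, node)))] = int((assign[node] != p_state).sum())
        for nb in adj[node]:
            if nb != parent:
                stack.append((nb, node))
    return counts


@dataclass
class ParsimonyResult:
    leaf_names: list[str]
    edges: list[tuple[int, int]]
    tree_length: int
    newick: str = ""
    bootstrap_support: dict[frozenset, float] = field(default_factory=dict)
    leaf_weights: dict[str, float] = field(default_factory=dict)
    method: str = "exhaustive"

    def bipartitions(self) -> set[frozenset]:
        return _bipartitions(self.edges, len(self.leaf_names))


def _to_newick(
    edges,
    leaf_names: list[str],
    edge_lengths: dict[tuple[int, int], int] | None = None,
    support: dict[frozenset, float] | None = None,
) -> str:
    n = len(leaf_names)
    if n == 1:
        return f"{leaf_names[0]};"
    if n == 2:
        ln = edge_lengths.get((0, 1), 0) if edge_lengths else 0
        return f"({leaf_names[0]}:{ln},{leaf_names[1]}:0);"
    adj = _adjacency(edges)
    root = adj[0][0]  # internal node next to leaf 0: basal multifurcation

    def subtree(node: int, parent: int) -> str:
        length = (edge_lengths or {}).get(tuple(sorted((parent, node))), 0)
        if node < n:
            return f"{leaf_names[node]}:{length}"
        children = [subtree(nb, node) for nb in adj[node] if nb != parent]
        label = ""
        if support is not None:
            side = set()
            stack = [(node, parent)]
            while stack:
                x, p = stack.pop()
                if x < n:
                    side.add(x)
                for nb in adj[x]:
                    if nb != p:
                        stack.append((nb, x))
            if 0 in side:
                side = set(range(n)) - side
            key = frozenset(side)
            if key in support:
                label = f"{support[key]:.3f}"
        return f"({','.join(children)}){label}:{length}"

    parts = [subtree(nb, root) for nb in adj[root]]
    return f"({','.join(parts)});"


def parsimony_tree(hepitypes, method: str = "auto", _leaf_order=None) -> ParsimonyResult:
    """Most-parsimonious unrooted tree over hepitype patterns.

    ``hepitypes`` are objects with ``pattern``/``frequency`` (or bare
    pattern strings).  Patterns must be unique: aggregate identical reads
    into hepitypes first.  Leaves are added in order of descending
    frequency, ties lexicographic by pattern, which fixes the search (and
    its tie-breaking) deterministically.
    """
    items = [
        (h, getattr(h, "pattern", h), float(getattr(h, "frequency", 0.0)))
        for h in hepitypes
    ]
    patterns = [p for _, p, _ in items]
    if len(set(patterns)) != len(patterns):
        raise ValueError("duplicate patterns: aggregate into hepitypes first")
    order = _leaf_order or sorted(range(len(items)), key=lambda i: (-items[i][2], items[i][1]))
    leaf_names = [items[i][1] for i in order]
    weights = {items[i][1]: items[i][2] for i in order}
    n = len(leaf_names)
    if n == 0:
        raise ValueError("no hepitypes supplied")
    states = _encode(leaf_names)
    if n == 1:
        res = ParsimonyResult(leaf_names, [], 0, method="degenerate")
    elif n == 2:
        length = int((states[0] != states[1]).sum())
        res = ParsimonyResult(
            leaf_names, [(0, 1)], length, method="degenerate"
        )
    else:
        if method == "auto":
            method = "exhaustive" if n <= EXHAUSTIVE_MAX_LEAVES else "heuristic"
        search = _exhaustive_search if method == "exhaustive" else _heuristic_search
        edges, length = search(states)
        res = ParsimonyResult(leaf_names, edges, length, method=method)
    res.leaf_weights = weights
    lengths = (
        _edge_changes(res.edges, states) if n >= 2 else {}
    )
    res.newick = _to_newick(res.edges, leaf_names, lengths)
    return res


def bootstrap_support(
    hepitypes, replicates: int = 1000, seed: int = 0, method: str = "auto"
) -> ParsimonyResult:
    """Site-resampling bootstrap supports for the maximum-parsimony tree.

    CpG columns are resampled with replacement, a tree is rebuilt per
    replicate with the same search settings, and each internal edge of the
    original tree is annotated with the fraction of replicates containing
    its leaf bipartition.  Bit-identical for a fixed seed.
    """
    base = parsimony_tree(hepitypes, method=method)
    n = len(base.leaf_names)
    if n < 4:
        base.bootstrap_support = {}
        return base
    states = _encode(base.leaf_names)
    n_sites = states.shape[1]
    rng = np.random.default_rng(seed)
    target = base.bipartitions()
    hits = {bp: 0 for bp in target}
    if method == "auto":
        method = "exhaustive" if n <= EXHAUSTIVE_MAX_LEAVES else "heuristic"
    search = _exhaustive_search if method == "exhaustive" else _heuristic_search
    for _ in range(replicates):
        cols = rng.integers(0, n_sites, size=n_sites)
        edges, _length = search(states[:, cols])
        reps = _bipartitions(edges, n)
        for bp in target:
            if bp in reps:
                hits[bp] += 1
    base.bootstrap_support = {bp: hits[bp] / replicates for bp in target}
    lengths = _edge_changes(base.edges, states)
    base.newick = _to_newick(base.edges, base.leaf_names, lengths, base.bootstrap_support)
    return base
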