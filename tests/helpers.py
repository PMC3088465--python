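"""Independent oracles and fixture builders for the test suite.

Everything here deliberately avoids the package's bitmask split machinery:
trees are enumerated as explicit adjacency maps, quartet resolutions are
read off label sets, and rank statistics are computed by brute force, so
these functions can serve as independent checks of the library code paths.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import dendropy

import roguenet as rn


# ---------------------------------------------------------------------------
# Sample construction
# ---------------------------------------------------------------------------

def make_sample(newicks, run_ids=None, labels=None):
    """TreeSample from newick strings over a shared namespace."""
    tns = dendropy.TaxonNamespace(labels) if labels else dendropy.TaxonNamespace()
    trees = []
    for s in newicks:
        t = dendropy.Tree.get(data=s if s.rstrip().endswith(";") else s + ";",
                              schema="newick", taxon_namespace=tns,
                              preserve_underscores=True)
        rn.treeio.deroot(t)
        trees.append(t)
    if run_ids is None:
        run_ids = ["run1"] * len(trees)
    gens = []
    seen = Counter()
    for r in run_ids:
        gens.append(seen[r])
        seen[r] += 1
    return rn.TreeSample(trees, tns, list(run_ids), gens)


FIG2_TREE_A = "((((A,B),x),(C,D)),((E,F),(G,H)));"
FIG2_TREE_B = "(((A,B),(C,D)),(((G,H),x),(E,F)));"
FIG2_LABELS = ("A", "B", "x", "C", "D", "E", "F", "G", "H")


def fig2_sample():
    """Two trees identical but for the placement of the single taxon x."""
    return make_sample([FIG2_TREE_A, FIG2_TREE_B], labels=FIG2_LABELS)


# ---------------------------------------------------------------------------
# Exhaustive enumeration of unrooted binary trees
# ---------------------------------------------------------------------------

def _all_adjacencies(n_leaves):
    """All (2n-5)!! unrooted binary topologies on leaves 0..n-1."""
    base = {0: [-1], 1: [-1], 2: [-1], -1: [0, 1, 2]}
    trees = [base]
    for leaf in range(3, n_leaves):
        nxt = []
        for adj in trees:
            edges = sorted((u, v) for u, nb in adj.items() for v in nb if u < v)
            for (u, v) in edges:
                new = {k: list(vs) for k, vs in adj.items()}
                w = min(x for x in new if x < 0) - 1
                new[u].remove(v)
                new[v].remove(u)
                new[u].append(w)
                new[v].append(w)
                new[w] = [u, v, leaf]
                new[leaf] = [w]
                nxt.append(new)
        trees = nxt
    return trees


def _component_leaves(adj, block_u, block_v):
    """Leaves reachable from block_v without crossing edge (block_u, block_v)."""
    out = set()
    stack = [(block_u, block_v)]
    while stack:
        parent, node = stack.pop()
        if node >= 0:
            out.add(node)
        for nbr in adj[node]:
            if nbr != parent:
                stack.append((node, nbr))
    return frozenset(out)


def enumerate_tree_split_systems(n_leaves):
    """Nontrivial splits (as frozensets of leaf indices, the side excluding
    leaf 0) of every unrooted binary tree on n leaves."""
    systems = []
    for adj in _all_adjacencies(n_leaves):
        splits = set()
        for u, nb in adj.items():
            for v in nb:
                if not u < v:
                    continue
                side = _component_leaves(adj, u, v)
                if 0 in side:
                    side = frozenset(range(n_leaves)) - side
                if 2 <= len(side) <= n_leaves - 2:
                    splits.add(side)
        systems.append(frozenset(splits))
    return systems


def displayable_together(side1, side2, systems, n_leaves):
    """Oracle: is there a binary tree displaying both splits?

    Sides are frozensets of leaf indices (any orientation); trivial splits
    are displayed by every tree.
    """
    def norm(side):
        side = frozenset(side)
        if 0 in side:
            side = frozenset(range(n_leaves)) - side
        return side

    s1, s2 = norm(side1), norm(side2)
    need = {s for s in (s1, s2) if 2 <= len(s) <= n_leaves - 2}
    return any(need <= system for system in systems)


# ---------------------------------------------------------------------------
# Quartet / stability oracle
# ---------------------------------------------------------------------------

def quartet_resolution(tree, index, quartet):
    """Which pairing a tree displays for 4 taxon labels, or None.

    Works on label sets straight off the dendropy nodes.
    """
    a, b, c, d = quartet
    qset = set(quartet)
    all_labels = {t.label for t in tree.taxon_namespace}
    for node in tree.postorder_node_iter():
        if node.parent_node is None:
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        inside = qset & below
        if len(inside) != 2:
            continue
        if inside in ({a, b}, {c, d}):
            return frozenset([frozenset([a, b]), frozenset([c, d])])
        if inside in ({a, c}, {b, d}):
            return frozenset([frozenset([a, c]), frozenset([b, d])])
        if inside in ({a, d}, {b, c}):
            return frozenset([frozenset([a, d]), frozenset([b, c])])
    return None


def exhaustive_leaf_stability(sample, taxon):
    """Independent recomputation of the stability index over ALL quartets
    containing the taxon."""
    labels = sample.labels
    others = [lab for lab in labels if lab != taxon]
    terms = []
    for trio in itertools.combinations(others, 3):
        quartet = (taxon,) + trio
        counts = Counter()
        for tree in sample.trees:
            res = quartet_resolution(tree, None, quartet)
            if res is not None:
                counts[res] += 1
        if not counts:
            continue
        freqs = sorted(counts.values(), reverse=True) + [0, 0]
        f1, f2 = freqs[0], freqs[1]
        terms.append((f1 - f2) / (f1 + f2))
    return sum(terms) / len(terms) if terms else float("nan")


# ---------------------------------------------------------------------------
# Rank-test oracle
# ---------------------------------------------------------------------------

def brute_force_u(xs, ys):
    """Mann-Whitney U statistic of xs versus ys by direct pair counting."""
    u = 0.0
    for x in xs:
        for y in ys:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u
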