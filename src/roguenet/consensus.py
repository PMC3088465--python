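"""Majority-rule consensus, post-analysis pruning, and support comparison.

The majority-rule consensus of a tree sample is the (possibly
multifurcating) tree assembled from every nontrivial split occurring in
strictly more than half of the trees; each retained split is annotated with
its sample frequency, the split's posterior probability in a Bayesian
sample.  Strict majority guarantees the retained splits are pairwise
compatible, so the assembly never needs tie-breaking.

Pruning removes rogue leaves from every tree of the sample *after*
inference — the rogues inform the analysis but no longer dilute the split
frequencies — and the consensus is recomputed on the reduced namespace.
``compare_support`` quantifies the effect: a one-sided Mann-Whitney U test
on the two support lists (they are legitimately of different lengths, since
pruning changes the node count), plus a paired Wilcoxon signed-rank test on
the splits identifiable in both consensuses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
from scipy import stats

from .splits import Split, SplitFrequencyTable, restrict_split, split_frequencies
from .treeio import TreeSample, deroot

__all__ = [
    "ConsensusTree",
    "SupportComparison",
    "SupportSummary",
    "compare_support",
    "majority_consensus",
    "prune_taxa",
    "support_summary",
]


@dataclass
class ConsensusTree:
    """A majority-rule consensus: topology plus per-split supports.

    ``supports`` maps every retained nontrivial split to its frequency in
    (cutoff, 1].  The dendropy tree mirrors the supports as internal-node
    labels for serialization.
    """

    tree: dendropy.Tree
    supports: dict[Split, float]
    cutoff: float
    labels: tuple[str, ...]

    def support_values(self) -> list[float]:
        return sorted(self.supports.values(), reverse=True)

    def newick(self) -> str:
        return self.tree.as_string(schema="newick",
                                   unquoted_underscores=True).strip()


def _assemble(majority: dict[Split, float],
              labels: tuple[str, ...],
              taxon_namespace: dendropy.TaxonNamespace) -> dendropy.Tree:
    """Build a tree from pairwise-compatible splits.

    Anchored at taxon 0: each canonical side (which excludes taxon 0) is a
    clade, and compatibility makes the set of sides laminar, so nesting by
    containment is well defined.
    """
    n = len(labels)
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    tree.is_rooted = False
    root = tree.seed_node

    # clade nodes, largest first so each parent exists before its children
    clades = sorted(majority.items(), key=lambda kv: (-kv[0].size,
                                                      kv[0].indicator()))
    nodes: list[tuple[int, dendropy.Node]] = []  # (mask, node), insertion order
    for s, freq in clades:
        parent = root
        for mask, nd in nodes:
            if s.bits & mask == s.bits:  # contained; laminar => deepest-so-far
                parent = nd
        node = dendropy.Node()
        node.label = repr(freq)  # full precision: round-trips exactly
        parent.add_child(node)
        nodes.append((s.bits, node))

    for i, lab in enumerate(labels):
        parent = root
        bit = 1 << i
        for mask, nd in nodes:
            if mask & bit:
                parent = nd
        leaf = dendropy.Node(taxon=taxon_namespace.get_taxon(lab))
        parent.add_child(leaf)
    return tree


def majority_consensus(sample: TreeSample, cutoff: float = 0.5) -> ConsensusTree:
    """Consensus of all nontrivial splits with frequency strictly above
    ``cutoff`` (cutoff >= 0.5 keeps them pairwise compatible)."""
    if len(sample.trees) == 0:
        raise ValueError("cannot build a consensus of an empty sample")
    if not 0.5 <= cutoff < 1.0:
        raise ValueError(f"majority cutoff must be in [0.5, 1), got {cutoff}")
    table = split_frequencies(sample)
    majority = {s: f for s, f in table.frequencies().items()
                if not s.is_trivial and f > cutoff}
    tree = _assemble(majority, sample.labels, sample.taxon_namespace)
    return ConsensusTree(tree, majority, cutoff, sample.labels)


def prune_taxa(sample: TreeSample, taxa: Iterable[str]) -> TreeSample:
    """Remove the given leaves from every tree, suppressing the resulting
    degree-2 nodes, and re-home the sample on a reduced namespace."""
    drop = set(taxa)
    known = set(sample.labels)
    unknown = sorted(drop - known)
    if unknown:
        raise ValueError(f"cannot prune unknown taxa: {', '.join(unknown)}")
    kept = [lab for lab in sample.labels if lab not in drop]
    if len(kept) < 4:
        raise ValueError(
            f"pruning {len(drop)} taxa would leave {len(kept)} < 4 taxa")
    if not drop:
        return sample.subset(range(len(sample.trees)))

    new_tns = dendropy.TaxonNamespace(kept)
    drop_taxa = [t for t in sample.taxon_namespace if t.label in drop]
    new_trees = []
    for tree in sample.trees:
        pruned = tree.extract_tree_without_taxa(
            taxa=drop_taxa, suppress_unifurcations=True)
        pruned.migrate_taxon_namespace(new_tns)
        deroot(pruned)
        new_trees.append(pruned)
    prov = dict(sample.provenance)
    prov["pruned_taxa"] = sorted(drop)
    return TreeSample(new_trees, new_tns, list(sample.run_ids),
                      list(sample.generation_index), prov)


@dataclass
class SupportSummary:
    n_nodes: int
    frac_well_supported: float
    well_supported_cutoff: float


def support_summary(tree: ConsensusTree,
                    well_supported_cutoff: float = 0.90) -> SupportSummary:
    """Fraction of internal consensus edges with support >= cutoff.

    Counts every internal edge of the unrooted consensus, i.e. every
    retained nontrivial split.
    """
    vals = list(tree.supports.values())
    n = len(vals)
    frac = (sum(v >= well_supported_cutoff for v in vals) / n) if n else 0.0
    return SupportSummary(n, frac, well_supported_cutoff)


@dataclass
class SupportComparison:
    """Pre- vs post-pruning node supports with summary statistics.

    The headline test is a one-sided Mann-Whitney U (alternative: post
    supports stochastically larger); the paired Wilcoxon signed-rank runs
    on splits present in both consensuses, matching each post split to the
    restriction of pre splits onto the reduced taxon set.
    """

    pre_supports: list[float]
    post_supports: list[float]
    frac_well_supported_pre: float
    frac_well_supported_post: float
    well_supported_cutoff: float
    test_name: str
    statistic: float
    p_value: float
    paired_test_name: str
    paired_statistic: float
    paired_p_value: float
    n_pairs: int

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("quantity\tvalue\n")
            fh.write(f"n_nodes_pre\t{len(self.pre_supports)}\n")
            fh.write(f"n_nodes_post\t{len(self.post_supports)}\n")
            fh.write(f"mean_support_pre\t{np.mean(self.pre_supports):.6g}\n")
            fh.write(f"mean_support_post\t{np.mean(self.post_supports):.6g}\n")
            fh.write(f"well_supported_cutoff\t{self.well_supported_cutoff}\n")
            fh.write(f"frac_well_supported_pre\t{self.frac_well_supported_pre:.6g}\n")
            fh.write(f"frac_well_supported_post\t{self.frac_well_supported_post:.6g}\n")
            fh.write(f"test\t{self.test_name}\n")
            fh.write(f"statistic\t{self.statistic:.6g}\n")
            fh.write(f"p_value\t{self.p_value:.6g}\n")
            fh.write(f"paired_test\t{self.paired_test_name}\n")
            fh.write(f"paired_statistic\t{self.paired_statistic:.6g}\n")
            fh.write(f"paired_p_value\t{self.paired_p_value:.6g}\n")
            fh.write(f"n_pairs\t{self.n_pairs}\n")

    def summary(self) -> str:
        return (f"support {np.mean(self.pre_supports):.3f} -> "
                f"{np.mean(self.post_supports):.3f}; well-supported "
                f"{self.frac_well_supported_pre:.1%} -> "
                f"{self.frac_well_supported_post:.1%}; "
                f"{self.test_name} p = {self.p_value:.4g}")


def _matched_pairs(pre: ConsensusTree,
                   post: ConsensusTree) -> tuple[list[float], list[float]]:
    keep = [i for i, lab in enumerate(pre.labels) if lab in set(post.labels)]
    kept_labels = tuple(pre.labels[i] for i in keep)
    if kept_labels != post.labels:
        raise ValueError("post-consensus taxa are not an ordered subset of "
                         "the pre-consensus taxa")
    restricted: dict[Split, float] = {}
    for s, f in pre.supports.items():
        r = restrict_split(s, keep)
        if r is not None:
            # several pre splits may collapse onto one reduced split; keep
            # the best-supported pre-image as the matched value
            restricted[r] = max(restricted.get(r, 0.0), f)
    xs, ys = [], []
    for s, f_post in post.supports.items():
        if s in restricted:
            xs.append(restricted[s])
            ys.append(f_post)
    return xs, ys


def compare_support(pre: ConsensusTree, post: ConsensusTree,
                    well_supported_cutoff: float = 0.90) -> SupportComparison:
    """Test whether pruning increased consensus node support."""
    if pre.cutoff != post.cutoff:
        raise ValueError("consensus trees were built at different cutoffs")
    pre_vals = list(pre.supports.values())
    post_vals = list(post.supports.values())
    if not pre_vals or not post_vals:
        raise ValueError("support comparison needs internal nodes on both "
                         "consensus trees")

    if np.ptp(pre_vals + post_vals) == 0:
        u_stat = len(pre_vals) * len(post_vals) / 2.0
        p = 1.0
    else:
        u_stat, p = stats.mannwhitneyu(post_vals, pre_vals,
                                       alternative="greater")
        u_stat, p = float(u_stat), float(p)

    xs, ys = _matched_pairs(pre, post)
    diffs = np.array(ys) - np.array(xs)
    if len(diffs) == 0 or np.all(diffs == 0):
        w_stat, w_p = 0.0, 1.0
    else:
        w_stat, w_p = stats.wilcoxon(ys, xs, alternative="greater",
                                     zero_method="wilcox")
        w_stat, w_p = float(w_stat), float(w_p)

    pre_sum = support_summary(pre, well_supported_cutoff)
    post_sum = support_summary(post, well_supported_cutoff)
    return SupportComparison(
        pre_supports=pre_vals,
        post_supports=post_vals,
        frac_well_supported_pre=pre_sum.frac_well_supported,
        frac_well_supported_post=post_sum.frac_well_supported,
        well_supported_cutoff=well_supported_cutoff,
        test_name="mann-whitney-u-one-sided",
        statistic=u_stat,
        p_value=p,
        paired_test_name="wilcoxon-signed-rank-one-sided",
        paired_statistic=w_stat,
        paired_p_value=w_p,
        n_pairs=len(xs),
    )
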