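"""Posterior-like tree samples with known ground truth.

The generator emulates the tree distribution a converged Bayesian MCMC run
produces for a data set containing a few unstable leaves: a single fixed,
fully resolved *core* topology stands in for the dominant signal; light
topological noise (one random NNI applied to a configurable fraction of
draws) stands in for residual MCMC wobble; and each planted *rogue* leaf is
re-grafted independently in every tree at an edge drawn from its attachment
distribution (uniform over all core edges by default, or a small fixed edge
set with given probabilities).  Every stochastic choice flows from one seed,
so identical configurations give byte-identical samples.

Defaults mirror a 59-taxon study: a 55-leaf core, 4 rogues, 1000 trees —
the size of a thinned posterior window — with one NNI on 20% of draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .splits import Split, restrict_split, split_frequencies
from .treeio import TreeSample

__all__ = [
    "DetectionMetrics",
    "GroundTruth",
    "SimulationConfig",
    "core_split_recall",
    "evaluate_detection",
    "random_resolved_newick",
    "rogue_recovery_experiment",
    "simulate_sample",
]

AttachmentSpec = str | Mapping[str, Sequence[tuple[frozenset[str], float]]]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic posterior sample.

    ``rogue_taxa`` are extra leaves on top of ``n_taxa - len(rogue_taxa)``
    core taxa.  ``core_perturb_rate`` is the per-tree probability of
    applying one uniformly random NNI to the core before the rogues are
    attached.  ``rogue_attachment`` is ``"uniform"`` or a mapping from
    rogue label to a list of ``(core-leaf-set, probability)`` pairs, each
    leaf set naming a core edge by the split it induces.
    """

    n_taxa: int = 59
    n_trees: int = 1000
    rogue_taxa: tuple[str, ...] = ("r1", "r2", "r3", "r4")
    core_perturb_rate: float = 0.2
    rogue_attachment: AttachmentSpec = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 8:
            raise ValueError(f"need n_taxa >= 8, got {self.n_taxa}")
        if self.n_trees < 1:
            raise ValueError("need at least one tree")
        if len(set(self.rogue_taxa)) != len(self.rogue_taxa):
            raise ValueError("duplicate rogue labels")
        if self.n_core < 4:
            raise ValueError("need at least 4 core (non-rogue) taxa")
        if not 0.0 <= self.core_perturb_rate <= 1.0:
            raise ValueError("core_perturb_rate must be in [0, 1]")
        if isinstance(self.rogue_attachment, str):
            if self.rogue_attachment != "uniform":
                raise ValueError(
                    f"unknown attachment mode {self.rogue_attachment!r}")
        else:
            core = set(self.core_labels)
            for rogue, dist in self.rogue_attachment.items():
                if rogue not in self.rogue_taxa:
                    raise ValueError(f"attachment given for non-rogue {rogue!r}")
                probs = [p for _, p in dist]
                if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                    raise ValueError(
                        f"attachment probabilities for {rogue!r} must be "
                        f"non-negative and sum to 1")
                for side, _ in dist:
                    if not set(side) <= core:
                        raise ValueError(
                            f"attachment edge for {rogue!r} names non-core taxa")

    @property
    def n_core(self) -> int:
        return self.n_taxa - len(self.rogue_taxa)

    @property
    def core_labels(self) -> tuple[str, ...]:
        width = len(str(self.n_core))
        return tuple(f"t{i + 1:0{width}d}" for i in range(self.n_core))

    @property
    def labels(self) -> tuple[str, ...]:
        return self.core_labels + tuple(self.rogue_taxa)


@dataclass
class GroundTruth:
    """What the generator actually did, for scoring detection against."""

    core_tree: dendropy.Tree
    core_splits: frozenset[Split]
    planted_rogues: frozenset[str]
    attachments: list[dict[str, Split]]  # per tree: rogue -> core-edge split
    newicks: list[str]                   # the emitted trees, verbatim


# ---------------------------------------------------------------------------
# Core topology machinery (unrooted trees as adjacency maps)
# ---------------------------------------------------------------------------

def _random_core_adjacency(n_leaves: int, rng: np.random.Generator):
    """Random resolved unrooted topology by sequential random attachment."""
    adj: dict[int, list[int]] = {0: [-1], 1: [-1], 2: [-1], -1: [0, 1, 2]}
    edges = [(0, -1), (1, -1), (2, -1)]
    next_internal = -2
    for leaf in range(3, n_leaves):
        u, v = edges[int(rng.integers(len(edges)))]
        w = next_internal
        next_internal -= 1
        adj[u].remove(v)
        adj[v].remove(u)
        adj[u].append(w)
        adj[v].append(w)
        adj[w] = [u, v, leaf]
        adj[leaf] = [w]
        edges.remove((u, v))
        edges.extend([(u, w), (v, w), (leaf, w)])
    return adj


def _edge_list(adj) -> list[tuple[int, int]]:
    edges = []
    for u, nbrs in adj.items():
        for v in nbrs:
            if u < v:
                edges.append((u, v))
    edges.sort()
    return edges


def _apply_random_nni(adj, rng: np.random.Generator) -> None:
    internal = [(u, v) for u, v in _edge_list(adj) if u < 0 and v < 0]
    if not internal:
        return
    u, v = internal[int(rng.integers(len(internal)))]
    u_side = [x for x in adj[u] if x != v]
    v_side = [x for x in adj[v] if x != u]
    a = u_side[int(rng.integers(len(u_side)))]
    c = v_side[int(rng.integers(len(v_side)))]
    adj[u][adj[u].index(a)] = c
    adj[v][adj[v].index(c)] = a
    adj[a][adj[a].index(u)] = v
    adj[c][adj[c].index(v)] = u


def _side_mask(adj, u: int, v: int) -> int:
    """Bitmask of leaf indices reachable from v without crossing edge (u, v)."""
    mask = 0
    stack = [(u, v)]
    while stack:
        parent, node = stack.pop()
        if node >= 0:
            mask |= 1 << node
        for nbr in adj[node]:
            if nbr != parent:
                stack.append((node, nbr))
    return mask


def _edge_splits(adj, n_leaves: int) -> dict[tuple[int, int], Split]:
    return {(u, v): Split.from_bits(_side_mask(adj, u, v), n_leaves)
            for u, v in _edge_list(adj)}


def _to_newick(adj, labels: Sequence[str]) -> str:
    def render(parent: int, node: int) -> str:
        if node >= 0:
            return labels[node]
        parts = [render(node, nbr) for nbr in adj[node] if nbr != parent]
        return "(" + ",".join(parts) + ")"

    root = -1
    parts = [render(root, nbr) for nbr in adj[root]]
    return "(" + ",".join(parts) + ");"


def random_resolved_newick(labels: Sequence[str], seed: int) -> str:
    """A uniform-attachment random binary unrooted tree, as Newick."""
    if len(labels) < 3:
        raise ValueError("need at least 3 labels")
    rng = np.random.default_rng(seed)
    adj = _random_core_adjacency(len(labels), rng)
    return _to_newick(adj, list(labels))


# ---------------------------------------------------------------------------
# Sample generation
# ---------------------------------------------------------------------------

def simulate_sample(config: SimulationConfig) -> tuple[TreeSample, GroundTruth]:
    """Draw a posterior-like sample plus its generating ground truth."""
    rng = np.random.default_rng(config.seed)
    k = config.n_core
    core_labels = config.core_labels
    all_labels = config.labels

    core_adj = _random_core_adjacency(k, rng)
    core_newick = _to_newick(core_adj, core_labels)

    newicks: list[str] = []
    attachments: list[dict[str, Split]] = []
    for _ in range(config.n_trees):
        adj = {node: list(nbrs) for node, nbrs in core_adj.items()}
        if config.core_perturb_rate > 0 and rng.random() < config.core_perturb_rate:
            _apply_random_nni(adj, rng)
        edges = _edge_list(adj)

        chosen: dict[str, tuple[int, int]] = {}
        record: dict[str, Split] = {}
        edge_by_split: dict[Split, tuple[int, int]] | None = None
        for rogue in config.rogue_taxa:
            if isinstance(config.rogue_attachment, str):
                e = edges[int(rng.integers(len(edges)))]
            else:
                dist = config.rogue_attachment.get(rogue)
                if dist is None:
                    e = edges[int(rng.integers(len(edges)))]
                else:
                    if edge_by_split is None:
                        edge_by_split = {s: uv for uv, s
                                         in _edge_splits(adj, k).items()}
                    sides = [s for s, _ in dist]
                    probs = [p for _, p in dist]
                    pick = int(rng.choice(len(sides), p=probs))
                    want = Split.from_side(
                        (core_labels.index(lab) for lab in sides[pick]), k)
                    e = edge_by_split.get(want)
                    if e is None:  # edge lost to an NNI; fall back to uniform
                        e = edges[int(rng.integers(len(edges)))]
            chosen[rogue] = e
            record[rogue] = Split.from_bits(_side_mask(adj, e[0], e[1]), k)

        next_node = min(x for x in adj if x < 0) - 1
        segments: dict[tuple[int, int], tuple[int, int]] = {}
        for ri, rogue in enumerate(config.rogue_taxa):
            u, v = segments.get(chosen[rogue], chosen[rogue])
            w = next_node
            next_node -= 1
            leaf = k + ri
            adj[u].remove(v)
            adj[v].remove(u)
            adj[u].append(w)
            adj[v].append(w)
            adj[w] = [u, v, leaf]
            adj[leaf] = [w]
            segments[chosen[rogue]] = (u, w)

        newicks.append(_to_newick(adj, all_labels))
        attachments.append(record)

    tns = dendropy.TaxonNamespace(all_labels)
    tree_list = dendropy.TreeList.get(
        data="\n".join(newicks) + "\n", schema="newick",
        preserve_underscores=True, taxon_namespace=tns)
    sample = TreeSample(
        trees=list(tree_list),
        taxon_namespace=tns,
        run_ids=["sim"] * config.n_trees,
        generation_index=list(range(config.n_trees)),
        provenance={"simulated": True, "seed": config.seed,
                    "n_taxa": config.n_taxa, "n_trees": config.n_trees,
                    "rogue_taxa": list(config.rogue_taxa),
                    "core_perturb_rate": config.core_perturb_rate},
    )

    core_tns = dendropy.TaxonNamespace(core_labels)
    core_tree = dendropy.Tree.get(data=core_newick, schema="newick",
                                  preserve_underscores=True,
                                  taxon_namespace=core_tns)
    core_splits = frozenset(s for s in _edge_splits(core_adj, k).values()
                            if not s.is_trivial)
    truth = GroundTruth(core_tree, core_splits,
                        frozenset(config.rogue_taxa), attachments, newicks)
    return sample, truth


# ---------------------------------------------------------------------------
# Scoring against ground truth
# ---------------------------------------------------------------------------

@dataclass
class DetectionMetrics:
    precision: float | None
    recall: float | None


def evaluate_detection(report, truth: GroundTruth) -> DetectionMetrics:
    """Precision/recall of the flagged set against the planted rogues
    (``None`` where the ratio is undefined)."""
    flagged = set(report.flagged)
    planted = set(truth.planted_rogues)
    tp = len(flagged & planted)
    precision = tp / len(flagged) if flagged else None
    recall = tp / len(planted) if planted else None
    return DetectionMetrics(precision, recall)


def core_split_recall(consensus_tree, truth: GroundTruth) -> float:
    """Fraction of the core's nontrivial splits recovered by a consensus.

    The consensus may live on the full namespace (rogues included); its
    splits are restricted onto the core taxa before matching.
    """
    if not truth.core_splits:
        return 1.0
    core_labels = tuple(t.label for t in truth.core_tree.taxon_namespace)
    labels = consensus_tree.labels
    keep = [i for i, lab in enumerate(labels) if lab in set(core_labels)]
    found = set()
    for s in consensus_tree.supports:
        r = restrict_split(s, keep)
        if r is not None:
            found.add(r)
    return len(truth.core_splits & found) / len(truth.core_splits)


# ---------------------------------------------------------------------------
# The recovery experiment (detection + pruning + support comparison)
# ---------------------------------------------------------------------------

def rogue_recovery_experiment(n_replicates: int = 20, base_seed: int = 0,
                              config: SimulationConfig | None = None,
                              **config_overrides) -> pd.DataFrame:
    """Replicated end-to-end study: simulate, detect, prune, compare.

    Each replicate re-seeds the generator with ``base_seed + i``, flags
    rogues with the default rule, prunes the flagged set, and compares the
    pre- and post-pruning majority-rule consensuses.  Returns one row per
    replicate with detection precision/recall, well-supported node
    fractions, core-split recall, and the Mann-Whitney p-value.
    """
    from .consensus import compare_support, majority_consensus, prune_taxa
    from .instability import detect_rogues

    base = config or SimulationConfig()
    rows = []
    for i in range(n_replicates):
        cfg_kwargs = dict(
            n_taxa=base.n_taxa, n_trees=base.n_trees,
            rogue_taxa=base.rogue_taxa,
            core_perturb_rate=base.core_perturb_rate,
            rogue_attachment=base.rogue_attachment,
        )
        cfg_kwargs.update(config_overrides)
        cfg = SimulationConfig(seed=(base_seed + i) % (2 ** 31), **cfg_kwargs)
        sample, truth = simulate_sample(cfg)
        report = detect_rogues(sample, seed=cfg.seed)
        metrics = evaluate_detection(report, truth)
        pre = majority_consensus(sample)
        flagged = report.flagged
        if flagged and len(sample.labels) - len(flagged) >= 4:
            pruned = prune_taxa(sample, flagged)
        else:
            pruned = sample
        post = majority_consensus(pruned)
        cmp = compare_support(pre, post)
        rows.append({
            "seed": cfg.seed,
            "precision": metrics.precision,
            "recall": metrics.recall,
            "n_flagged": len(flagged),
            "frac_well_supported_pre": cmp.frac_well_supported_pre,
            "frac_well_supported_post": cmp.frac_well_supported_post,
            "support_increased": cmp.frac_well_supported_post
                                 > cmp.frac_well_supported_pre,
            "mean_support_pre": float(np.mean(cmp.pre_supports)),
            "mean_support_post": float(np.mean(cmp.post_supports)),
            "mwu_p_value": cmp.p_value,
            "core_recall_pre": core_split_recall(pre, truth),
            "core_recall_post": core_split_recall(post, truth),
        })
    return pd.DataFrame(rows)
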