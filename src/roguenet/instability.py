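"""Per-taxon instability scoring and rogue-taxon detection.

A rogue taxon is a leaf whose attachment point wanders across the trees of
a posterior sample.  In a consensus network (the split system containing
every split above a frequency threshold) such a leaf shows up as
reticulation: pairs of retained splits that are mutually incompatible and
that differ essentially only in where that leaf sits.  This module turns
that visual criterion into three per-taxon statistics:

* **conflict resolution score** — the number of incompatible split pairs in
  the network that become compatible (or collapse to triviality) once the
  taxon is deleted from both splits.  A taxon whose removal dissolves the
  reticulation is the reticulation's cause.
* **attachment positions / entropy** — for each tree, the taxon is pruned
  and the edge of the reduced tree it was attached to is identified by that
  edge's split; the Shannon entropy (natural log) of the resulting
  frequency distribution measures how widely the attachment wanders.
* **leaf stability** — the classic quartet-based index: over sampled
  quartets containing the taxon, the mean of (f1 - f2)/(f1 + f2) where
  f1 >= f2 are the two most frequent of the quartet's three resolutions
  across the sample.  1 means perfectly consistent placement.

The default flagging rule combines the first two: a taxon is flagged as
rogue when its conflict resolution score is positive, not negligible
relative to the best-scoring taxon (score >= 0.1 * max score), and its
attachment entropy reaches 0.5 nats.  The relative gate is what makes the
rule robust: bystander taxa adjacent to a reticulation can dissolve a
handful of conflicts, but only the wandering leaf itself dissolves a large
share of them, and rogues inflate every other taxon's raw attachment
entropy by hopping from one side of its attachment edge to the other.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field, asdict
from typing import Iterator

import numpy as np
import pandas as pd

from .splits import (Split, SplitFrequencyTable, is_compatible, restrict_mask,
                     restrict_split, sample_split_masks, split_frequencies)

__all__ = [
    "ConflictNetwork",
    "FlagRule",
    "RogueReport",
    "TaxonInstability",
    "attachment_positions",
    "build_conflict_network",
    "conflict_resolution_score",
    "conflict_resolution_scores",
    "detect_rogues",
    "leaf_stability",
]

_ENTROPY_TOL = 1e-9


# ---------------------------------------------------------------------------
# Conflict networks
# ---------------------------------------------------------------------------

@dataclass
class ConflictNetwork:
    """All nontrivial splits at or above a frequency threshold, plus every
    incompatible pair among them.

    With threshold 0 every observed split is retained, so the network's
    conflict pairs are exactly the reticulations a splits graph of the full
    sample would draw.
    """

    splits: list[Split]
    frequencies: np.ndarray
    threshold: float
    labels: tuple[str, ...]
    pair_index: np.ndarray  # (P, 2) indices into ``splits``
    n_trees: int

    @property
    def n_conflict_pairs(self) -> int:
        return len(self.pair_index)

    def conflict_pairs(self) -> Iterator[tuple[Split, Split]]:
        for i, j in self.pair_index:
            yield self.splits[int(i)], self.splits[int(j)]

    def to_splitstree_nexus(self, path) -> None:
        n = len(self.labels)
        order = sorted(range(len(self.splits)),
                       key=lambda i: (-self.frequencies[i],
                                      self.splits[i].indicator()))
        with open(path, "w") as fh:
            fh.write("#NEXUS\n\nBEGIN TAXA;\n")
            fh.write(f"DIMENSIONS ntax={n};\nTAXLABELS\n")
            for lab in self.labels:
                fh.write(f"    '{lab}'\n")
            fh.write(";\nEND;\n\nBEGIN SPLITS;\n")
            fh.write(f"DIMENSIONS ntax={n} nsplits={len(self.splits)};\n")
            fh.write("FORMAT labels=no weights=yes;\nMATRIX\n")
            for row, i in enumerate(order, start=1):
                members = " ".join(str(j + 1) for j in sorted(self.splits[i].side))
                fh.write(f"[{row}] {self.frequencies[i]:.6g} {members},\n")
            fh.write(";\nEND;\n")


def _popcount(x: np.ndarray) -> np.ndarray:
    return np.bitwise_count(x)


def build_conflict_network(table: SplitFrequencyTable,
                           threshold: float = 0.0) -> ConflictNetwork:
    """Filter the frequency table at ``threshold`` and enumerate every
    incompatible pair among the retained nontrivial splits."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"network threshold must be in [0, 1], got {threshold}")
    n = len(table.labels)
    retained = [(s, c / table.n_trees) for s, c in table.counts.items()
                if not s.is_trivial and c / table.n_trees >= threshold]
    retained.sort(key=lambda sf: (-sf[1], sf[0].indicator()))
    splits = [s for s, _ in retained]
    freqs = np.array([f for _, f in retained], dtype=float)
    m = len(splits)

    pi: list[np.ndarray] = []
    pj: list[np.ndarray] = []
    if m > 1 and n <= 64:
        full = np.uint64((1 << n) - 1)
        masks = np.array([s.bits for s in splits], dtype=np.uint64)
        comp = masks ^ full
        for i in range(m - 1):
            a, b = masks[i], comp[i]
            cs, ds = masks[i + 1:], comp[i + 1:]
            compat = ((a & cs) == 0) | ((a & ds) == 0) | \
                     ((b & cs) == 0) | ((b & ds) == 0)
            j = np.nonzero(~compat)[0]
            if len(j):
                pi.append(np.full(len(j), i, dtype=np.int64))
                pj.append(j + i + 1)
    elif m > 1:
        ii, jj = [], []
        for i in range(m - 1):
            for j in range(i + 1, m):
                if not is_compatible(splits[i], splits[j]):
                    ii.append(i)
                    jj.append(j)
        if ii:
            pi.append(np.array(ii, dtype=np.int64))
            pj.append(np.array(jj, dtype=np.int64))
    if pi:
        pair_index = np.stack([np.concatenate(pi), np.concatenate(pj)], axis=1)
    else:
        pair_index = np.empty((0, 2), dtype=np.int64)
    return ConflictNetwork(splits, freqs, threshold, tuple(table.labels),
                           pair_index, table.n_trees)


def _taxon_index(labels: tuple[str, ...], taxon: str) -> int:
    try:
        return labels.index(taxon)
    except ValueError:
        raise KeyError(f"unknown taxon: {taxon!r}") from None


def conflict_resolution_scores(network: ConflictNetwork) -> dict[str, int]:
    """Conflict resolution score for every taxon at once.

    A conflict pair counts toward taxon ``t`` when deleting ``t`` from both
    splits leaves them compatible, or reduces either one to a trivial or
    empty split (``restrict_split`` returning null).
    """
    labels = network.labels
    n = len(labels)
    if network.n_conflict_pairs == 0:
        return {lab: 0 for lab in labels}
    if n <= 64:
        full = np.uint64((1 << n) - 1)
        masks = np.array([s.bits for s in network.splits], dtype=np.uint64)
        A = masks[network.pair_index[:, 0]]
        B = masks[network.pair_index[:, 1]]
        nA = masks ^ full
        notA = nA[network.pair_index[:, 0]]
        notB = nA[network.pair_index[:, 1]]
        out: dict[str, int] = {}
        for t, lab in enumerate(labels):
            keep = full ^ np.uint64(1 << t)
            at, ac = A & keep, notA & keep
            bt, bc = B & keep, notB & keep
            null_a = (_popcount(at) <= 1) | (_popcount(ac) <= 1)
            null_b = (_popcount(bt) <= 1) | (_popcount(bc) <= 1)
            compat = ((at & bt) == 0) | ((at & bc) == 0) | \
                     ((ac & bt) == 0) | ((ac & bc) == 0)
            out[lab] = int(np.count_nonzero(null_a | null_b | compat))
        return out
    out = {}
    all_idx = set(range(n))
    for t, lab in enumerate(labels):
        keep = all_idx - {t}
        score = 0
        for s1, s2 in network.conflict_pairs():
            r1 = restrict_split(s1, keep)
            r2 = restrict_split(s2, keep)
            if r1 is None or r2 is None or is_compatible(r1, r2):
                score += 1
        out[lab] = score
    return out


def conflict_resolution_score(network: ConflictNetwork, taxon: str) -> int:
    """Number of network conflicts dissolved by deleting one taxon."""
    _taxon_index(network.labels, taxon)  # raises on unknown taxon
    return conflict_resolution_scores(network)[taxon]


# ---------------------------------------------------------------------------
# Attachment positions
# ---------------------------------------------------------------------------

def _attachment_caches(sample) -> list[tuple[dict[int, object], dict[object, int],
                                             dict[object, object]]]:
    """Per tree: leaf-index -> node, node -> below-mask, node -> parent."""
    cached = getattr(sample, "_attach_cache", None)
    if cached is not None:
        return cached
    index = sample.label_index
    out = []
    for tree in sample.trees:
        leaf_of: dict[int, object] = {}
        below: dict[object, int] = {}
        parent: dict[object, object] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                i = index[node.taxon.label]
                below[node] = 1 << i
                leaf_of[i] = node
            else:
                m = 0
                for ch in node.child_nodes():
                    m |= below[ch]
                below[node] = m
            parent[node] = node.parent_node
        out.append((leaf_of, below, parent))
    setattr(sample, "_attach_cache", out)
    return out


def _attachment_key(leaf_of, below, parent, t: int, n: int) -> frozenset[int]:
    """Canonical reduced-namespace masks of the edges the taxon hung from.

    For a binary attachment (parent of degree three in the unrooted sense)
    the two surviving incident edges merge into the single attachment edge
    of the reduced tree and the key is a singleton; at a polytomy the key is
    the node's full edge signature.
    """
    x = leaf_of[t]
    p = parent[x]
    bit = 1 << t
    masks = []
    for ch in p.child_nodes():
        if ch is not x:
            masks.append(below[ch])
    if parent[p] is not None:
        masks.append(below[p])
    full_r = (1 << (n - 1)) - 1
    key = set()
    for m in masks:
        r = restrict_mask(m & ~bit, t)
        if r == 0 or r == full_r:
            continue
        if r & 1:
            r ^= full_r
        key.add(r)
    return frozenset(key)


def attachment_positions(sample, taxon: str):
    """Frequency distribution of the taxon's attachment position.

    Keys are :class:`Split` objects over the reduced (taxon-removed)
    namespace — trivial splits retained, since attaching next to a single
    leaf is a perfectly good position — or frozensets of splits for
    attachments at a polytomy.
    """
    labels = sample.labels
    t = _taxon_index(labels, taxon)
    n = len(labels)
    caches = _attachment_caches(sample)
    counter: Counter[frozenset[int]] = Counter()
    for leaf_of, below, parent in caches:
        counter[_attachment_key(leaf_of, below, parent, t, n)] += 1
    total = len(sample.trees)
    out = {}
    for key, c in counter.items():
        splits = frozenset(Split(m, n - 1) for m in key)
        pretty = next(iter(splits)) if len(splits) == 1 else splits
        out[pretty] = c / total
    return out


def attachment_profile(sample, taxon: str) -> tuple[int, float]:
    """(number of distinct attachment positions, Shannon entropy in nats)."""
    dist = attachment_positions(sample, taxon)
    freqs = np.array(list(dist.values()))
    entropy = float(-(freqs * np.log(freqs)).sum()) + 0.0  # normalize -0.0
    return len(dist), max(entropy, 0.0)


# ---------------------------------------------------------------------------
# Leaf stability
# ---------------------------------------------------------------------------

def _unrank_combination(rank: int, pool: int, k: int) -> tuple[int, ...]:
    """Lexicographic unranking of a k-combination of range(pool)."""
    combo = []
    x = 0
    for i in range(k, 0, -1):
        while math.comb(pool - x - 1, i - 1) <= rank:
            rank -= math.comb(pool - x - 1, i - 1)
            x += 1
        combo.append(x)
        x += 1
    return tuple(combo)


def _stability_arrays(sample):
    """Distinct nontrivial split masks (as a taxon-membership bool matrix)
    plus bit-packed per-tree membership of each distinct split."""
    cached = getattr(sample, "_stability_cache", None)
    if cached is not None:
        return cached
    per_tree = sample_split_masks(sample)
    n_trees = len(per_tree)
    n = len(sample.labels)
    order: dict[int, int] = {}
    for masks in per_tree:
        for m in masks:
            order.setdefault(m, len(order))
    m_distinct = len(order)
    words = (n_trees + 63) // 64
    packed = np.zeros((m_distinct, words), dtype=np.uint64)
    for j, masks in enumerate(per_tree):
        w, b = divmod(j, 64)
        bit = np.uint64(1 << b)
        for m in masks:
            packed[order[m], w] |= bit
    bits_at = np.empty((m_distinct, n), dtype=bool)
    for row, mm in enumerate(order):
        for col in range(n):
            bits_at[row, col] = (mm >> col) & 1
    cached = (bits_at, packed, n_trees)
    setattr(sample, "_stability_cache", cached)
    return cached


def leaf_stability(sample, taxon: str, n_quartets: int = 1000,
                   seed: int | None = None) -> float:
    """Quartet-based stability index in [0, 1].

    Quartets containing the taxon are sampled uniformly without replacement
    (exhaustively when there are at most ``n_quartets`` of them).  For each
    quartet the three possible resolutions are tallied across the sample
    (trees not resolving the quartet are skipped for it); with f1 >= f2 the
    top two tallies, the quartet contributes (f1 - f2)/(f1 + f2).  Quartets
    never resolved contribute nothing; if no sampled quartet is ever
    resolved the index is NaN.
    """
    labels = sample.labels
    t = _taxon_index(labels, taxon)
    n = len(labels)
    if n < 4:
        raise ValueError("leaf stability needs at least 4 taxa")
    others = [i for i in range(n) if i != t]
    total = math.comb(len(others), 3)
    if total <= n_quartets:
        triples = list(itertools.combinations(range(len(others)), 3))
    else:
        rng = np.random.default_rng(seed)
        ranks = rng.choice(total, size=n_quartets, replace=False)
        triples = [_unrank_combination(int(r), len(others), 3)
                   for r in sorted(ranks)]

    bits_at, packed, _ = _stability_arrays(sample)
    if len(bits_at) == 0:
        return float("nan")

    terms = []
    for trip in triples:
        q = (t, others[trip[0]], others[trip[1]], others[trip[2]])
        sub = bits_at[:, q]
        sums = sub.sum(axis=1)
        valid = sums == 2
        if not valid.any():
            continue
        same = sub[:, 1:] == sub[:, :1]
        cls = same.argmax(axis=1)
        counts = []
        for r in range(3):
            rows = valid & (cls == r)
            if rows.any():
                orred = np.bitwise_or.reduce(packed[rows], axis=0)
                counts.append(int(_popcount(orred).sum()))
            else:
                counts.append(0)
        counts.sort(reverse=True)
        f1, f2 = counts[0], counts[1]
        if f1 == 0:
            continue
        terms.append((f1 - f2) / (f1 + f2))
    if not terms:
        return float("nan")
    return float(np.mean(terms))


# ---------------------------------------------------------------------------
# Rogue detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlagRule:
    """Parameters of the rogue-flagging decision.

    A taxon is flagged when its conflict resolution score is positive, at
    least ``min_relative_score`` of the best score among all taxa, and its
    attachment entropy is at least ``min_entropy`` nats.
    """

    min_entropy: float = 0.5
    min_relative_score: float = 0.1


@dataclass
class TaxonInstability:
    taxon: str
    conflict_resolution_score: int
    attachment_position_count: int
    attachment_entropy: float
    leaf_stability: float
    flagged: bool


@dataclass
class RogueReport:
    """All per-taxon instability scores, the flagged rogue set, and the
    parameters that produced them (so alternative flag rules can be replayed
    from the recorded scores)."""

    records: list[TaxonInstability]
    flagged: frozenset[str]
    parameters: dict

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records])

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False,
                                   float_format="%.6g")

    def summary(self) -> str:
        lines = [f"{len(self.records)} taxa scored; "
                 f"{len(self.flagged)} flagged as rogue"]
        for r in sorted(self.records,
                        key=lambda r: -r.conflict_resolution_score):
            mark = " *ROGUE*" if r.flagged else ""
            lines.append(
                f"  {r.taxon}: conflicts_resolved={r.conflict_resolution_score}"
                f" positions={r.attachment_position_count}"
                f" entropy={r.attachment_entropy:.3f}"
                f" stability={r.leaf_stability:.3f}{mark}")
        return "\n".join(lines)


def detect_rogues(sample, threshold: float = 0.0,
                  rule: FlagRule | None = None, *,
                  n_quartets: int = 1000, seed: int = 0,
                  network: ConflictNetwork | None = None) -> RogueReport:
    """Score every taxon and flag the rogues.

    Runs the full instability battery: conflict network at ``threshold``
    (default 0, keeping every observed split), conflict resolution scores,
    attachment profiles, and seeded quartet leaf stability.
    """
    if len(sample.trees) == 0:
        raise ValueError("cannot detect rogues in an empty sample")
    rule = rule or FlagRule()
    if network is None:
        table = split_frequencies(sample)
        network = build_conflict_network(table, threshold)
    scores = conflict_resolution_scores(network)
    max_score = max(scores.values()) if scores else 0
    records = []
    flagged = set()
    for i, lab in enumerate(sample.labels):
        n_pos, entropy = attachment_profile(sample, lab)
        stab = leaf_stability(sample, lab, n_quartets=n_quartets,
                              seed=(seed + 1000003 * i) % (2 ** 31))
        score = scores[lab]
        is_rogue = (score > 0
                    and score >= rule.min_relative_score * max_score
                    and entropy >= rule.min_entropy - _ENTROPY_TOL)
        if is_rogue:
            flagged.add(lab)
        records.append(TaxonInstability(lab, score, n_pos, entropy, stab,
                                        is_rogue))
    params = {
        "threshold": threshold,
        "min_entropy": rule.min_entropy,
        "min_relative_score": rule.min_relative_score,
        "n_quartets": n_quartets,
        "seed": seed,
        "n_trees": len(sample.trees),
        "n_taxa": len(sample.labels),
        "n_conflict_pairs": network.n_conflict_pairs,
    }
    return RogueReport(records, frozenset(flagged), params)
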