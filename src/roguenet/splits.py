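"""Canonical bipartition (split) algebra.

A split is the two-way partition of the taxon set induced by deleting one
edge of an unrooted leaf-labelled tree.  Splits are the atomic unit of all
conflict analysis in this package: consensus trees are built from
high-frequency splits, consensus networks from *all* observed splits, and
rogue taxa are the leaves whose removal reconciles incompatible splits.

Splits are stored as integer bitmasks over a fixed, ordered taxon label
list.  The canonical side of a split is the side *not* containing taxon
index 0, which makes the representation a unique hashable key: a split and
its complement canonicalize identically.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Iterator

if TYPE_CHECKING:  # pragma: no cover
    import dendropy

__all__ = [
    "Split",
    "SplitFrequencyTable",
    "UniverseMismatchError",
    "extract_splits",
    "is_compatible",
    "restrict_split",
    "split_frequencies",
    "tree_split_masks",
]


class UniverseMismatchError(ValueError):
    """Raised when two splits over different taxon universes are combined."""


def _canonical(bits: int, n: int) -> int:
    """Return the side of the bipartition that excludes taxon index 0."""
    if bits & 1:
        bits ^= (1 << n) - 1
    return bits


@dataclass(frozen=True, slots=True)
class Split:
    """A bipartition of the taxa ``0..n-1``, stored canonically.

    ``bits`` holds the canonical side (the one excluding taxon 0) as a
    bitmask; ``n`` is the universe size.  Use :meth:`from_side` or
    :meth:`from_bits` rather than the raw constructor, which requires an
    already-canonical mask.
    """

    bits: int
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"split universe must have >= 2 taxa, got {self.n}")
        full = (1 << self.n) - 1
        if not 0 < self.bits < full:
            raise ValueError("split side must be a proper non-empty subset")
        if self.bits & 1:
            raise ValueError("non-canonical split mask (side contains taxon 0); "
                             "use Split.from_bits")

    @classmethod
    def from_bits(cls, bits: int, n: int) -> "Split":
        return cls(_canonical(bits, n), n)

    @classmethod
    def from_side(cls, indices: Iterable[int], n: int) -> "Split":
        bits = 0
        for i in indices:
            if not 0 <= i < n:
                raise ValueError(f"taxon index {i} outside universe of size {n}")
            bits |= 1 << i
        return cls.from_bits(bits, n)

    @property
    def size(self) -> int:
        return self.bits.bit_count()

    @property
    def side(self) -> frozenset[int]:
        """Indices on the canonical side."""
        return frozenset(i for i in range(self.n) if self.bits >> i & 1)

    @property
    def complement_side(self) -> frozenset[int]:
        return frozenset(i for i in range(self.n) if not self.bits >> i & 1)

    @property
    def is_trivial(self) -> bool:
        """True for leaf splits (one taxon separated from all others)."""
        k = self.size
        return k == 1 or k == self.n - 1

    def side_labels(self, labels: Iterable[str]) -> frozenset[str]:
        labels = tuple(labels)
        return frozenset(labels[i] for i in self.side)

    def indicator(self) -> str:
        """``01`` string, one character per taxon, 1 = canonical side."""
        return "".join("1" if self.bits >> i & 1 else "0" for i in range(self.n))

    def __repr__(self) -> str:  # compact: indices of canonical side
        return f"Split({sorted(self.side)}|n={self.n})"


def is_compatible(s1: Split, s2: Split) -> bool:
    """Four-point rule: splits A|B and C|D are jointly displayable on one
    tree iff at least one of A∩C, A∩D, B∩C, B∩D is empty."""
    if s1.n != s2.n:
        raise UniverseMismatchError(
            f"splits over different universes ({s1.n} vs {s2.n} taxa)")
    full = (1 << s1.n) - 1
    a, c = s1.bits, s2.bits
    b, d = a ^ full, c ^ full
    return (a & c == 0) or (a & d == 0) or (b & c == 0) or (b & d == 0)


def restrict_split(s: Split, keep: Iterable[int], *,
                   nontrivial_only: bool = True) -> Split | None:
    """Restrict a split to the sub-universe ``keep``.

    Both sides are intersected with ``keep`` and re-indexed over the reduced
    namespace (kept indices in ascending order).  Returns ``None`` when a
    side empties, or — unless ``nontrivial_only=False`` — when the result is
    a trivial split.
    """
    kept = sorted(set(keep))
    if any(i < 0 or i >= s.n for i in kept):
        raise ValueError("keep set is not a subset of the universe")
    m = len(kept)
    if m < 2:
        return None
    bits = 0
    for new_i, old_i in enumerate(kept):
        if s.bits >> old_i & 1:
            bits |= 1 << new_i
    full = (1 << m) - 1
    if bits == 0 or bits == full:
        return None
    r = Split.from_bits(bits, m)
    if nontrivial_only and r.is_trivial:
        return None
    return r


def restrict_mask(bits: int, drop_index: int) -> int:
    """Delete one bit position from a mask, shifting higher bits down.

    Low-level companion of :func:`restrict_split` for single-taxon removal;
    the caller is responsible for canonicalization over the reduced universe.
    """
    low = bits & ((1 << drop_index) - 1)
    high = (bits >> (drop_index + 1)) << drop_index
    return low | high


# ---------------------------------------------------------------------------
# Split extraction from trees
# ---------------------------------------------------------------------------

def _label_index(tree: "dendropy.Tree") -> dict[str, int]:
    return {t.label: i for i, t in enumerate(tree.taxon_namespace)}


def tree_split_masks(tree: "dendropy.Tree", index: dict[str, int] | None = None,
                     *, include_trivial: bool = False) -> set[int]:
    """Canonical split masks of every edge of the unrooted topology.

    The tree may be stored rooted; a bifurcating seed node contributes the
    same split through both of its child edges, which deduplication absorbs.
    """
    if index is None:
        index = _label_index(tree)
    n = len(index)
    full = (1 << n) - 1
    masks: set[int] = set()
    below: dict[object, int] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            mask = 1 << index[node.taxon.label]
        else:
            mask = 0
            for ch in node.child_nodes():
                mask |= below[ch]
        below[node] = mask
        if node.parent_node is None:
            continue
        if mask == 0 or mask == full:
            continue
        c = _canonical(mask, n)
        k = c.bit_count()
        if include_trivial or 2 <= k <= n - 2:
            masks.add(c)
    return masks


def extract_splits(tree: "dendropy.Tree", index: dict[str, int] | None = None,
                   *, include_trivial: bool = False) -> frozenset[Split]:
    """One :class:`Split` per internal edge of the unrooted topology (plus
    leaf splits when ``include_trivial``)."""
    if index is None:
        index = _label_index(tree)
    n = len(index)
    return frozenset(Split(m, n) for m in
                     tree_split_masks(tree, index, include_trivial=include_trivial))


# ---------------------------------------------------------------------------
# Frequency accounting
# ---------------------------------------------------------------------------

@dataclass
class SplitFrequencyTable:
    """Per-tree-deduplicated split occurrence counts across a tree sample."""

    counts: dict[Split, int]
    n_trees: int
    labels: tuple[str, ...]

    def frequency(self, s: Split) -> float:
        return self.counts.get(s, 0) / self.n_trees

    def frequencies(self) -> dict[Split, float]:
        return {s: c / self.n_trees for s, c in self.counts.items()}

    def __len__(self) -> int:
        return len(self.counts)

    def __iter__(self) -> Iterator[Split]:
        return iter(self.counts)

    def nontrivial(self) -> "SplitFrequencyTable":
        return SplitFrequencyTable(
            {s: c for s, c in self.counts.items() if not s.is_trivial},
            self.n_trees, self.labels)

    def to_tsv(self, path) -> None:
        """Columns: split indicator string, count, frequency."""
        rows = sorted(self.counts.items(),
                      key=lambda kv: (-kv[1], kv[0].indicator()))
        with open(path, "w") as fh:
            fh.write("split\tcount\tfrequency\n")
            for s, c in rows:
                fh.write(f"{s.indicator()}\t{c}\t{c / self.n_trees:.6g}\n")

    def to_splitstree_nexus(self, path) -> None:
        """SplitsTree-readable NEXUS with TAXA and SPLITS blocks; split
        weights are the sample frequencies."""
        rows = sorted(self.counts.items(),
                      key=lambda kv: (-kv[1], kv[0].indicator()))
        with open(path, "w") as fh:
            fh.write("#NEXUS\n\nBEGIN TAXA;\n")
            fh.write(f"DIMENSIONS ntax={len(self.labels)};\nTAXLABELS\n")
            for lab in self.labels:
                fh.write(f"    '{lab}'\n")
            fh.write(";\nEND;\n\nBEGIN SPLITS;\n")
            fh.write(f"DIMENSIONS ntax={len(self.labels)} nsplits={len(rows)};\n")
            fh.write("FORMAT labels=no weights=yes;\nMATRIX\n")
            for i, (s, c) in enumerate(rows, start=1):
                members = " ".join(str(j + 1) for j in sorted(s.side))
                fh.write(f"[{i}] {c / self.n_trees:.6g} {members},\n")
            fh.write(";\nEND;\n")


def _sample_index(sample) -> dict[str, int]:
    return {lab: i for i, lab in enumerate(sample.labels)}


def sample_split_masks(sample, *, include_trivial: bool = False) -> list[set[int]]:
    """Per-tree canonical split mask sets, cached on the sample object."""
    key = "_split_masks_trivial" if include_trivial else "_split_masks"
    cached = getattr(sample, key, None)
    if cached is not None:
        return cached
    index = _sample_index(sample)
    masks = [tree_split_masks(t, index, include_trivial=include_trivial)
             for t in sample.trees]
    try:
        object.__setattr__(sample, key, masks)
    except AttributeError:
        setattr(sample, key, masks)
    return masks


def split_frequencies(sample, *, include_trivial: bool = False) -> SplitFrequencyTable:
    """Tally canonical splits across a tree sample (one count per tree per
    split, regardless of how many edges of a tree induce it)."""
    if len(sample.trees) == 0:
        raise ValueError("cannot tabulate split frequencies of an empty sample")
    n = len(sample.labels)
    counter: Counter[int] = Counter()
    for masks in sample_split_masks(sample, include_trivial=include_trivial):
        counter.update(masks)
    counts = {Split(m, n): c for m, c in counter.items()}
    return SplitFrequencyTable(counts, len(sample.trees), tuple(sample.labels))
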