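"""Reading and writing tree samples; burn-in and thinning.

Input is one or more files of trees over a common taxon set: NEXUS trees
blocks (including the MrBayes ``.t`` dialect with ``translate`` tables and
``[&U]``/``[&R]`` rooting comments) or plain Newick, one tree per line.
Each file is treated as one MCMC run.  Parsing is delegated to dendropy;
this module adds the sample container, cross-file namespace checking, and
the burn-in / thinning arithmetic applied per run.

All downstream conflict analysis is rooting-invariant; trees are derooted
(basal bifurcations collapsed) on ingestion so that every internal edge
corresponds to exactly one bipartition.  Edge lengths are read and carried
but ignored by every topological computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy

__all__ = [
    "NamespaceConflictError",
    "TreeSample",
    "apply_burnin",
    "read_tree_sample",
    "read_tree",
    "thin_sample",
    "write_tree",
]


class NamespaceConflictError(ValueError):
    """Taxon sets disagree across input files."""


def _strip_quotes(label: str) -> str:
    if len(label) >= 2 and label[0] == label[-1] and label[0] in "'\"":
        return label[1:-1]
    return label


def deroot(tree: dendropy.Tree) -> dendropy.Tree:
    """Collapse a bifurcating seed node in place; no-op otherwise."""
    seed = tree.seed_node
    if len(seed.child_nodes()) == 2:
        tree.deroot()
    tree.is_rooted = False
    return tree


@dataclass
class TreeSample:
    """An ordered collection of leaf-labelled trees over one taxon namespace.

    ``run_ids`` and ``generation_index`` record, per tree, which run (input
    file) it came from and its position within that run.  ``provenance``
    accumulates the burn-in fraction and thinning step already applied.
    """

    trees: list[dendropy.Tree]
    taxon_namespace: dendropy.TaxonNamespace
    run_ids: list[str]
    generation_index: list[int]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.trees) == len(self.run_ids) == len(self.generation_index)):
            raise ValueError("trees, run_ids and generation_index must be parallel")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(t.label for t in self.taxon_namespace)

    @property
    def label_index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.labels)}

    @property
    def runs(self) -> tuple[str, ...]:
        """Distinct run ids in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.run_ids:
            seen.setdefault(r)
        return tuple(seen)

    def __len__(self) -> int:
        return len(self.trees)

    def subset(self, indices: Sequence[int], provenance: dict | None = None) -> "TreeSample":
        return TreeSample(
            trees=[self.trees[i] for i in indices],
            taxon_namespace=self.taxon_namespace,
            run_ids=[self.run_ids[i] for i in indices],
            generation_index=[self.generation_index[i] for i in indices],
            provenance=dict(provenance if provenance is not None else self.provenance),
        )

    def by_run(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for i, r in enumerate(self.run_ids):
            out.setdefault(r, []).append(i)
        return out


def _sniff_schema(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "nexus" if line.strip().upper().startswith("#NEXUS") else "newick"
    raise ValueError(f"{path}: file contains no trees")


def read_tree_sample(paths: Iterable[str | Path], format_hint: str = "auto",
                     run_ids: Sequence[str] | None = None) -> TreeSample:
    """Read one or more tree files into a single sample.

    Every file must cover exactly the same taxon set (labels compared by
    exact string match after surrounding-quote stripping; ``translate``
    tables are resolved by dendropy).  Each file becomes one run, labelled
    ``run1``, ``run2``, ... unless ``run_ids`` is given.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no input paths given")
    if format_hint not in ("auto", "nexus", "newick"):
        raise ValueError(f"unknown format hint: {format_hint!r}")
    if run_ids is not None and len(run_ids) != len(paths):
        raise ValueError("run_ids must match the number of paths")

    per_file: list[dendropy.TreeList] = []
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(p)
        schema = format_hint if format_hint != "auto" else _sniff_schema(p)
        tl = dendropy.TreeList.get(
            path=str(p), schema=schema, preserve_underscores=True,
            taxon_namespace=dendropy.TaxonNamespace())
        if len(tl) == 0:
            raise ValueError(f"{p}: file contains no trees")
        per_file.append(tl)

    ref_labels = {_strip_quotes(t.label) for t in per_file[0].taxon_namespace}
    for p, tl in zip(paths[1:], per_file[1:]):
        labels = {_strip_quotes(t.label) for t in tl.taxon_namespace}
        if labels != ref_labels:
            offending = sorted(labels.symmetric_difference(ref_labels))
            raise NamespaceConflictError(
                f"taxon sets differ between {paths[0]} and {p}; "
                f"offending labels: {', '.join(offending)}")

    common = per_file[0].taxon_namespace
    trees: list[dendropy.Tree] = []
    ids: list[str] = []
    gens: list[int] = []
    for fi, tl in enumerate(per_file):
        rid = run_ids[fi] if run_ids is not None else f"run{fi + 1}"
        if tl.taxon_namespace is not common:
            for t in tl:
                t.migrate_taxon_namespace(common)
        for gi, t in enumerate(tl):
            deroot(t)
            trees.append(t)
            ids.append(rid)
            gens.append(gi)
    return TreeSample(trees, common, ids, gens,
                      provenance={"sources": [str(p) for p in paths]})


def apply_burnin(sample: TreeSample, fraction: float) -> TreeSample:
    """Discard the first ``ceil(fraction * run_size)`` trees of each run.

    The ceiling convention is conservative: no tree inside the nominal
    burn-in window is ever retained.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"burn-in fraction must be in [0, 1), got {fraction}")
    keep: list[int] = []
    for run, idx in sample.by_run().items():
        drop = math.ceil(fraction * len(idx))
        keep.extend(idx[drop:])
    keep.sort()
    prov = dict(sample.provenance)
    prov["burnin_fraction"] = fraction
    return sample.subset(keep, prov)


def thin_sample(sample: TreeSample, step: int) -> TreeSample:
    """Retain every ``step``-th tree of each run (indices step-1, 2*step-1, ...)."""
    if not isinstance(step, int) or step < 1:
        raise ValueError(f"thinning step must be a positive integer, got {step}")
    keep: list[int] = []
    for run, idx in sample.by_run().items():
        keep.extend(idx[step - 1::step])
    keep.sort()
    prov = dict(sample.provenance)
    prov["thin_step"] = step
    return sample.subset(keep, prov)


def write_tree(tree: dendropy.Tree, path: str | Path, format: str = "newick") -> None:
    """Write a (possibly support-annotated) tree.

    Node supports are serialized as internal-node labels; they must parse
    as reals in [0, 1].  NEXUS output carries a translate-free trees block.
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"unknown tree format: {format!r}")
    for node in tree.preorder_internal_node_iter():
        if node.label is not None:
            try:
                v = float(node.label)
            except ValueError:
                continue
            if not 0.0 <= v <= 1.0:
                raise ValueError(
                    f"internal-node support {node.label} outside [0, 1]")
    tree.write(path=str(path), schema=format, unquoted_underscores=True,
               suppress_rooting=False)


def read_tree(path: str | Path, format: str = "auto") -> dendropy.Tree:
    """Read a single (annotated) tree; internal-node labels are preserved."""
    p = Path(path)
    schema = format if format != "auto" else _sniff_schema(p)
    return dendropy.Tree.get(
        path=str(p), schema=schema, preserve_underscores=True,
        suppress_internal_node_taxa=True)
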