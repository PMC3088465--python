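# Methods

## Split algebra

All conflict analysis is purely topological and rooting-invariant.  Trees
are derooted on ingestion (a bifurcating seed node is collapsed) and edge
lengths, while read and carried, are ignored.  A split is stored as the
bitmask of the side *not* containing the first taxon of the namespace,
which makes a split and its complement one hashable object.  Compatibility
is the four-point rule: `A|B` and `C|D` are jointly displayable iff at
least one of `A∩C, A∩D, B∩C, B∩D` is empty.  Split frequencies are tallied
once per tree (a sample containing the same topology twice counts it
twice — posterior frequencies are per draw, not per topology), and
multifurcating trees contribute only the splits of edges actually present.

## Burn-in and thinning

Burn-in discards the first `ceil(fraction × run_size)` trees of each run —
ceiling, so that no tree inside the nominal burn-in window is ever kept.
Thinning keeps every `step`-th tree of each run starting with the
`step`-th; the phase is irrelevant to all downstream statistics (they are
exchangeable over trees) and is fixed only for reproducibility.  Both
operations act per run, never across run boundaries.

## The conflict network and the instability scores

The consensus network at threshold `t` is the set of nontrivial splits
with sample frequency ≥ `t`, together with every incompatible pair among
them.  The default threshold is 0: every observed conflicting split is
kept.  (At any threshold > 0.5 the network provably contains no conflicts,
since strict-majority splits are pairwise compatible.)  Trivial splits are
excluded — they are compatible with everything.

Per-taxon statistics:

- **Conflict resolution score**: the number of conflict pairs `(s1, s2)`
  such that restricting both splits to the taxon-removed namespace leaves
  them compatible, or reduces either to an empty/trivial split.  This
  encodes "removing this taxon dissolves the reticulation".  For taxon
  sets of ≤ 64 taxa the computation is vectorized over pairs with uint64
  bitmasks; larger namespaces fall back to an equivalent per-pair path.
- **Attachment positions**: for each tree, the taxon is pruned and the
  edge of the reduced tree it hung from is identified by that edge's
  split in the reduced namespace.  Trivial splits are retained here —
  attaching beside a single leaf is a position like any other.  When the
  taxon hangs off a polytomy there is no single merged edge; the position
  is then keyed by the polytomy's full edge signature (the set of its
  incident splits).  The attachment entropy is the Shannon entropy (nats)
  of the position frequencies; the position count is the number of
  distinct keys.
- **Leaf stability**: quartets containing the taxon are drawn uniformly
  without replacement (exhaustively when there are at most `n_quartets`
  of them, 1000 by default; sampling is seeded and reproducible, with
  cost bounded by O(n_quartets × distinct splits)).  For each quartet the
  three resolutions are tallied over the sample — a tree that does not
  resolve the quartet is skipped for it — and the quartet contributes
  `(f1 − f2)/(f1 + f2)` for the top two tallies `f1 ≥ f2` (1 when only
  one resolution is ever seen, per the convention `f2 = 0`).  The index
  is the mean over quartets resolved at least once, bounded in [0, 1] and
  insensitive to unresolved quartets.

## The flag rule

A taxon is flagged as rogue when all three hold:

1. conflict resolution score > 0;
2. score ≥ `min_relative_score` × (best score among all taxa), default 0.1;
3. attachment entropy ≥ `min_entropy`, default 0.5 nats.

Why a *relative* score gate: in a sample containing genuine rogues, every
statistic of every taxon is contaminated by them.  A rogue hopping across
the tree lands on one or the other side of any given taxon's attachment
edge, so even perfectly stable taxa acquire inflated attachment entropy;
and a taxon that sits immediately above a clade dissolves the occasional
conflict between that clade's decorated split variants, so bystanders
routinely have small positive scores.  No fixed absolute cutoff on either
statistic separates cause from casualty.  What does separate them is the
share of the conflict structure a taxon explains: a genuine rogue
dissolves the large majority of the pairs it is involved in, typically
one to two orders of magnitude more than the best bystander.  The entropy
gate (absolute, and deliberately low at 0.5 nats ≈ the entropy of an even
two-way alternation) exists to suppress flags in near-conflict-free
samples, where the relative gate alone would promote whichever taxon owns
the largest handful of conflicts.

The rule's separation margin grows with taxon count and sample size; on
very small problems (≲ 15 taxa or only tens of trees) the relative gap
between rogues and bystanders narrows and the reported raw scores should
be inspected rather than trusted to the default thresholds.  Every score
is recorded in the report so any alternative rule is reproducible without
recomputation.

Detection defaults to the pooled sample across runs (the full posterior
is what the consensus summarizes); per-run detection with a union of
flags is available, as are thinning/windowing options for emulating
subsampled network analyses.  Detection is single-pass by default;
iterative re-detection after pruning is possible by rerunning on the
pruned sample.

## Consensus, pruning, and the support comparison

The majority-rule consensus keeps nontrivial splits with frequency
strictly > cutoff (default 0.5; ties at exactly 0.5 are excluded, which
guarantees pairwise compatibility without tie-breaking) and annotates
each with its exact frequency.  Assembly anchors at the first taxon: the
canonical sides form a laminar family and nest directly into a tree; no
greedy extension beyond the majority splits is performed.  A node is
"well-supported" when its posterior probability is ≥ 0.90; the summary
counts every internal edge of the unrooted consensus.

Pruning removes the given leaves from every tree, suppresses the
resulting degree-2 nodes, and re-homes the sample on the reduced
namespace; pruning commutes with split restriction, so restricted split
frequencies can only aggregate upward (several pre-image splits may merge
onto one reduced split).

The headline significance test is a one-sided Mann-Whitney U on the two
support lists (post > pre); the lists legitimately differ in length since
pruning changes the node count, and support distributions are bounded and
non-normal, which rules out the t-test.  A paired Wilcoxon signed-rank
test is reported alongside, on splits identifiable in both consensuses:
each post split is matched to the restriction of pre splits onto the
reduced taxon set, taking the best-supported pre-image when several
collapse together.  Degenerate cases (all supports tied, or no nonzero
paired differences) report p = 1 — no evidence of change — rather than a
tie-broken statistic.

## The synthetic posterior

The generator emulates the tree sample a converged Bayesian analysis
yields for data with a few unstable leaves, using purely topological
noise — the detection method sees only topologies, so sequence simulation
plus MCMC would add cost without exercising anything further:

- a single random resolved core topology per seed (uniform sequential
  random attachment);
- per tree, one uniformly random NNI applied with probability
  `core_perturb_rate` (default 0.2), standing in for residual MCMC wobble
  around a dominant topology;
- each rogue re-attached independently in every tree by grafting its
  pendant edge onto a core edge (pendant edges included) drawn from its
  attachment distribution — uniform by default, or a fixed small edge set
  with given probabilities (a named edge lost to that tree's NNI falls
  back to a uniform draw);
- full ground truth: the core tree and splits, plus each rogue's chosen
  attachment edge in every tree.

Identical configurations give byte-identical output; all draws flow from
one `numpy` generator in a fixed order.

Defaults mirror a moderate-sized empirical study: 59 taxa = 55-taxon core
plus 4 rogues, 1000 trees (the size of a thinned posterior window), NNI
rate 0.2.  What the generator does *not* emulate: MCMC autocorrelation,
among-run heterogeneity, correlated rogue behaviour (rogues wandering as
a block), and rate/branch-length information.  Passing tests therefore
demonstrate that the statistics recover *independently re-attached*
leaves under light topological noise — not that the flag rule is optimal
for every empirical pathology (e.g. two taxa that are stable relative to
each other but wander jointly would each be flagged only by their shared
conflicts).

## The recovery experiment

`rogue_recovery_experiment` replicates the full pipeline end to end
(simulate → detect → prune flagged → consensus pre/post → compare) over
20 seeds at the default scale, reporting per-replicate detection
precision/recall, well-supported node fractions, mean supports, core
split recall, and the Mann-Whitney p-value.  With uniform rogues the
pre-pruning consensus loses most deep splits entirely (every core split's
frequency is split across its rogue-decorated variants), so the
well-supported fraction rises from roughly a third to ~100% after
pruning — the same direction, more pronounced, as the effect the method
targets on real data.  Problem sizes throughout (20 replicates × 1000
trees; test fixtures of 9-40 taxa) were chosen to exercise every code
path at the default study scale while keeping the whole suite a
few-minute run on a single CPU.

## Numerical conventions

- Entropy uses natural logarithms; `-0.0` is normalized to `0.0`.
- The entropy gate is applied with a 1e-9 tolerance so that an exact
  two-way alternation (entropy ln 2) compares cleanly against cutoffs.
- Consensus support labels are serialized at full `repr` precision and
  round-trip exactly through Newick and NEXUS.
- Quartet subsampling uses lexicographic unranking of combination indices
  drawn without replacement, so a given seed defines the quartet set
  independently of iteration order.
- Seeds are kept below 2^31 throughout; per-taxon stability seeds are
  derived from the report seed by a fixed affine map.
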