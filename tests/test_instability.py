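"""Instability scoring: conflict networks, attachment, stability, flagging."""

import itertools
import math

import numpy as np
import pytest

import roguenet as rn
from roguenet.instability import attachment_profile
from conftest import random_sample
from helpers import exhaustive_leaf_stability, make_sample


def table_from_splits(splits, n_trees, labels):
    return rn.SplitFrequencyTable({s: n_trees for s in splits}, n_trees,
                                  tuple(labels))


class TestConflictNetwork:
    def test_identical_trees_have_no_conflicts(self, identical_sample):
        net = rn.build_conflict_network(
            rn.split_frequencies(identical_sample), 0.0)
        assert net.n_conflict_pairs == 0
        assert rn.conflict_resolution_scores(net) == \
            {lab: 0 for lab in identical_sample.labels}

    def test_fig2_conflicts_straddle_x_placements(self, fig2):
        net = rn.build_conflict_network(rn.split_frequencies(fig2), 0.0)
        assert net.n_conflict_pairs > 0
        labels = fig2.labels
        x = labels.index("x")
        for s1, s2 in net.conflict_pairs():
            # every conflict opposes a split from tree A to one from tree B
            # whose disagreement is x's side-membership
            assert not rn.is_compatible(s1, s2)
            keep = [i for i in range(len(labels)) if i != x]
            r1, r2 = (rn.restrict_split(s, keep) for s in (s1, s2))
            assert r1 is None or r2 is None or rn.is_compatible(r1, r2)

    def test_majority_threshold_leaves_no_conflicts(self):
        for seed in range(3):
            sample = random_sample(seed=seed, n_taxa=9, n_trees=30,
                                   perturb=0.8, rogues=("r1",))
            net = rn.build_conflict_network(
                rn.split_frequencies(sample), 0.51)
            assert net.n_conflict_pairs == 0

    def test_threshold_zero_keeps_every_observed_split(self, fig2):
        table = rn.split_frequencies(fig2)
        net = rn.build_conflict_network(table, 0.0)
        assert len(net.splits) == len(table.nontrivial())

    def test_splitstree_export(self, tmp_path, fig2):
        net = rn.build_conflict_network(rn.split_frequencies(fig2), 0.0)
        path = tmp_path / "net.nex"
        net.to_splitstree_nexus(path)
        assert "BEGIN SPLITS;" in path.read_text()


class TestConflictResolutionScore:
    def test_hand_computed_five_taxon_example(self):
        # universe {A,B,C,D,X}: {A,B}|{C,D,X} vs {A,X}|{B,C,D} clash, and
        # only deleting X reconciles them
        labels = tuple("ABCDX")
        s1 = rn.Split.from_side([0, 1], 5)
        s2 = rn.Split.from_side([0, 4], 5)
        assert not rn.is_compatible(s1, s2)
        net = rn.build_conflict_network(table_from_splits([s1, s2], 2, labels))
        assert net.n_conflict_pairs == 1
        assert rn.conflict_resolution_score(net, "X") == 1
        assert rn.conflict_resolution_score(net, "C") == 0

    def test_unknown_taxon_rejected(self, fig2):
        net = rn.build_conflict_network(rn.split_frequencies(fig2))
        with pytest.raises(KeyError):
            rn.conflict_resolution_score(net, "nope")

    def test_vectorized_scores_match_restriction_definition(self):
        sample = random_sample(seed=2, n_taxa=9, n_trees=15, perturb=0.8,
                               rogues=("r1",))
        net = rn.build_conflict_network(rn.split_frequencies(sample))
        scores = rn.conflict_resolution_scores(net)
        n = len(sample.labels)
        for t, lab in enumerate(sample.labels):
            keep = [i for i in range(n) if i != t]
            expected = 0
            for s1, s2 in net.conflict_pairs():
                r1 = rn.restrict_split(s1, keep)
                r2 = rn.restrict_split(s2, keep)
                if r1 is None or r2 is None or rn.is_compatible(r1, r2):
                    expected += 1
            assert scores[lab] == expected

    def test_planted_rogue_attains_maximum_score(self):
        hits = 0
        for seed in range(10):
            cfg = rn.SimulationConfig(n_taxa=20, n_trees=200,
                                      rogue_taxa=("r1",),
                                      core_perturb_rate=0.2, seed=seed)
            sample, _ = rn.simulate_sample(cfg)
            net = rn.build_conflict_network(rn.split_frequencies(sample))
            scores = rn.conflict_resolution_scores(net)
            if max(scores, key=scores.get) == "r1":
                hits += 1
        assert hits >= 9

    def test_scores_equivariant_under_relabeling(self):
        nwks = ["((((A,B),x),(C,D)),(E,F));", "(((A,B),(C,D)),((E,x),F));"]
        labels = ("A", "B", "x", "C", "D", "E", "F")
        perm = {"A": "p1", "B": "p2", "x": "p3", "C": "p4", "D": "p5",
                "E": "p6", "F": "p7"}
        renamed = [nwk.translate(str.maketrans(perm)) for nwk in nwks]
        s1 = make_sample(nwks, labels=labels)
        s2 = make_sample(renamed, labels=tuple(perm[lab] for lab in labels))
        sc1 = rn.conflict_resolution_scores(
            rn.build_conflict_network(rn.split_frequencies(s1)))
        sc2 = rn.conflict_resolution_scores(
            rn.build_conflict_network(rn.split_frequencies(s2)))
        assert {perm[k]: v for k, v in sc1.items()} == sc2


class TestAttachmentPositions:
    def test_identical_trees_single_position_zero_entropy(self, identical_sample):
        for lab in identical_sample.labels:
            dist = rn.attachment_positions(identical_sample, lab)
            assert len(dist) == 1
            count, entropy = attachment_profile(identical_sample, lab)
            assert count == 1 and entropy == 0.0

    def test_fig2_x_has_two_equal_positions(self, fig2):
        dist = rn.attachment_positions(fig2, "x")
        assert sorted(dist.values()) == [0.5, 0.5]
        _, entropy = attachment_profile(fig2, "x")
        assert entropy == pytest.approx(math.log(2))

    def test_fig2_other_taxa_are_stable(self, fig2):
        for lab in fig2.labels:
            if lab == "x":
                continue
            assert attachment_profile(fig2, lab) == (1, 0.0)

    def test_uniform_rogue_entropy_approaches_log_edge_count(self):
        cfg = rn.SimulationConfig(n_taxa=9, n_trees=1000, rogue_taxa=("r1",),
                                  core_perturb_rate=0.0, seed=21)
        sample, _ = rn.simulate_sample(cfg)
        n_edges = 2 * 8 - 3  # unrooted binary core on 8 leaves
        count, entropy = attachment_profile(sample, "r1")
        assert count == n_edges
        assert entropy == pytest.approx(math.log(n_edges), abs=0.05)

    def test_unknown_taxon_rejected(self, fig2):
        with pytest.raises(KeyError):
            rn.attachment_positions(fig2, "nope")


class TestLeafStability:
    def test_identical_binary_trees_give_stability_one(self, identical_sample):
        for lab in identical_sample.labels:
            assert rn.leaf_stability(identical_sample, lab, 50, seed=1) == 1.0

    def test_even_conflict_zeroes_the_affected_quartets(self):
        sample = make_sample(["((A,B),(C,D));", "((A,C),(B,D));"],
                             labels=list("ABCD"))
        # the single quartet flips between two resolutions: f1 == f2
        assert rn.leaf_stability(sample, "A", 10, seed=0) == 0.0

    @pytest.mark.parametrize("taxon", ["t1", "t4", "r1"])
    def test_agrees_with_exhaustive_oracle(self, taxon):
        cfg = rn.SimulationConfig(n_taxa=8, n_trees=12, rogue_taxa=("r1",),
                                  core_perturb_rate=0.5, seed=3)
        sample, _ = rn.simulate_sample(cfg)
        got = rn.leaf_stability(sample, taxon, n_quartets=10 ** 6, seed=0)
        want = exhaustive_leaf_stability(sample, taxon)
        assert got == pytest.approx(want, abs=1e-12)

    def test_seeded_subsampling_is_deterministic(self):
        sample = random_sample(seed=4, n_taxa=12, n_trees=20, perturb=0.5,
                               rogues=("r1",))
        a = rn.leaf_stability(sample, "t01", n_quartets=30, seed=99)
        b = rn.leaf_stability(sample, "t01", n_quartets=30, seed=99)
        c = rn.leaf_stability(sample, "t01", n_quartets=30, seed=100)
        assert a == b
        assert isinstance(c, float)  # different seed still valid


class TestDetectRogues:
    def test_identical_trees_flag_nothing(self, identical_sample):
        report = rn.detect_rogues(identical_sample, seed=0)
        assert report.flagged == frozenset()
        assert all(r.conflict_resolution_score == 0 for r in report.records)

    def test_fig2_flags_exactly_x(self, fig2):
        report = rn.detect_rogues(fig2, seed=0)
        assert report.flagged == frozenset({"x"})

    def test_all_scores_recorded_for_reproducibility(self, fig2):
        report = rn.detect_rogues(fig2, seed=0)
        df = report.to_dataframe()
        assert set(df.columns) >= {"taxon", "conflict_resolution_score",
                                   "attachment_position_count",
                                   "attachment_entropy", "leaf_stability",
                                   "flagged"}
        assert len(df) == len(fig2.labels)
        assert report.parameters["n_trees"] == 2

    def test_report_tsv_roundtrip(self, tmp_path, fig2):
        report = rn.detect_rogues(fig2, seed=0)
        path = tmp_path / "report.tsv"
        report.to_tsv(path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == len(fig2.labels) + 1

    def test_empty_sample_rejected(self, identical_sample):
        with pytest.raises(ValueError):
            rn.detect_rogues(identical_sample.subset([]), seed=0)
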