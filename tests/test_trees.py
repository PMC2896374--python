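"""Tree structure, Newick/Nexus I/O, rooting, pruning, covariance, consensus."""

import numpy as np
import pytest

import edphylo as e
from edphylo.trees import TreeValidationError


def leaf_set(tree):
    return set(tree.leaf_labels)


def pairwise_distance(tree, a, b):
    C = e.vcv_matrix(tree)
    i, j = C.labels.index(a), C.labels.index(b)
    return C.values[i, i] + C.values[j, j] - 2 * C.values[i, j]


# ---------------------------------------------------------------------------
# parse / write
# ---------------------------------------------------------------------------


class TestNewickIO:
    def test_smallest_tree(self):
        t = e.parse_newick("(A:1,B:1);")
        assert leaf_set(t) == {"A", "B"}
        assert t.leaf_depths() == {"A": 1.0, "B": 1.0}
        assert e.write_newick(t) == "(A:1,B:1);"

    def test_structure_read_off(self, three_leaf):
        C = three_leaf.vcv(["A", "B", "C"])
        assert C.values[0, 1] == 1.0  # A-B MRCA at depth 1

    def test_canonical_child_order(self):
        assert e.write_newick(e.parse_newick("(B:1,A:1);")) == "(A:1,B:1);"

    @pytest.mark.parametrize(
        "text",
        [
            "(A:1,(B:0.5,C:0.5):0.5);",
            "((A:1,B:1):1,C:2);",
            "(A:1e-3,(B:2.5E2,C:0.5):0.5);",
            "('sp one':1,'sp two':1);",
            "(A,B,(C,D));",  # no branch lengths at all
        ],
    )
    def test_round_trip_identity(self, text):
        once = e.write_newick(e.parse_newick(text))
        assert e.write_newick(e.parse_newick(once)) == once

    def test_round_trip_on_simulated_trees(self):
        for seed in range(20):
            t = e.simulate_yule_tree(12, 1.0, seed)
            s = e.write_newick(t)
            assert e.write_newick(e.parse_newick(s)) == s

    def test_missing_lengths_stay_absent(self):
        t = e.parse_newick("(A,B);")
        assert e.write_newick(t) == "(A,B);"
        with pytest.raises(TreeValidationError, match="missing branch length"):
            t.leaf_depths()

    def test_malformed_input_raises(self):
        with pytest.raises(e.NewickParseError):
            e.parse_newick("((A:1,B:1;")

    def test_duplicate_leaf_label_raises(self):
        with pytest.raises(TreeValidationError, match="duplicate"):
            e.parse_newick("(A:1,(A:1,B:1):1);")

    def test_support_written_as_internal_label(self):
        sample = e.TreeSample(
            [
                e.parse_newick("((A:1,B:1):1,(C:1,D:1):1);"),
                e.parse_newick("((A:1,B:1):1,(C:1,D:1):1);"),
                e.parse_newick("((A:1,C:1):1,(B:1,D:1):1);"),
            ]
        )
        text = e.write_newick(e.majority_rule_consensus(sample))
        assert "0.667" in text

    def test_percentage_supports_divided_by_100(self):
        t = e.parse_newick("((A:1,B:1)95:1,C:2);")
        text = e.write_newick(t)
        assert "0.95" in text

    def test_nexus_trees_block_with_translate(self, tmp_path):
        nexus = """#NEXUS
begin taxa; dimensions ntax=3; taxlabels A B C; end;
begin trees;
  translate 1 A, 2 B, 3 C;
  tree one = ((1:1,2:1):1,3:2);
  tree two = ((1:2,2:2):1,3:2);
end;
"""
        p = tmp_path / "sample.nex"
        p.write_text(nexus)
        sample = e.read_tree_sample(str(p))
        assert len(sample) == 2
        assert sample.leaf_labels == {"A", "B", "C"}
        assert sample[0].leaf_depths()["A"] == 2.0


# ---------------------------------------------------------------------------
# rooting
# ---------------------------------------------------------------------------


class TestRooting:
    def test_idempotent_when_already_rooted(self, three_leaf):
        r = e.root_on_outgroup(three_leaf, "C")
        assert e.write_newick(r) == e.write_newick(three_leaf)

    def test_trifurcation_rooting(self):
        t = e.parse_newick("(A:1,B:1,C:4);")
        r = e.root_on_outgroup(t, "C")
        kids = r.root.children
        assert len(kids) == 2
        assert {c.label for c in kids if c.is_leaf} == {"C"}
        # midpoint split of the outgroup branch
        assert r.leaf_depths()["C"] == 2.0

    def test_missing_outgroup_raises(self, three_leaf):
        with pytest.raises(KeyError):
            e.root_on_outgroup(three_leaf, "X")

    def test_rerooting_preserves_leaf_to_leaf_distances(self):
        for seed in (1, 2, 3):
            t = e.simulate_yule_tree(8, 1.0, seed)
            labels = t.leaf_labels
            og = labels[3]
            r = e.root_on_outgroup(t, og)
            for other in labels:
                if other == og:
                    continue
                assert pairwise_distance(t, og, other) == pytest.approx(
                    pairwise_distance(r, og, other), abs=1e-12
                )


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------


class TestPrune:
    def test_keep_all_is_identity(self, balanced_four):
        p = e.prune(balanced_four, ["A", "B", "C", "D"])
        assert e.write_newick(p) == e.write_newick(balanced_four)

    def test_stem_above_retained_root_discarded(self):
        t = e.parse_newick("((A:1,B:1):1,C:3);")
        assert e.write_newick(e.prune(t, ["A", "B"])) == "(A:1,B:1);"

    def test_degree_two_suppression_sums_lengths(self):
        t = e.parse_newick("((A:1,B:1):1,C:3);")
        assert e.write_newick(e.prune(t, ["A", "C"])) == "(A:2,C:3);"

    def test_unknown_label_raises(self, three_leaf):
        with pytest.raises(KeyError):
            e.prune(three_leaf, ["A", "X"])

    def test_fewer_than_two_labels_raises(self, three_leaf):
        with pytest.raises(TreeValidationError):
            e.prune(three_leaf, ["A"])

    def test_prune_then_vcv_equals_vcv_submatrix(self):
        # with the original root position retained, pruning commutes with
        # submatrix selection of the covariance
        for seed in range(10):
            t = e.simulate_yule_tree(10, 1.0, seed)
            keep = list(t.leaf_labels[2:8])
            sub = e.vcv_matrix(e.prune(t, keep, keep_stem=True), keep)
            full = e.vcv_matrix(t).submatrix(keep)
            np.testing.assert_allclose(sub.values, full.values, atol=1e-12)

    def test_default_prune_rebases_depths_on_kept_mrca(self):
        # default (comparative convention): the kept MRCA becomes the root,
        # so covariances shift down by the discarded stem depth
        t = e.parse_newick("(((A:1,B:1):2,C:3):1,D:4);")
        C = e.vcv_matrix(e.prune(t, ["A", "B"]), ["A", "B"]).values
        np.testing.assert_array_equal(C, np.eye(2))


# ---------------------------------------------------------------------------
# covariance
# ---------------------------------------------------------------------------


class TestVcv:
    def test_cherry_has_no_shared_branches(self, cherry):
        np.testing.assert_array_equal(cherry.vcv(["A", "B"]).values, np.eye(2))

    def test_three_leaf_shared_paths(self, three_leaf):
        C = three_leaf.vcv(["A", "B", "C"]).values
        np.testing.assert_array_equal(
            C, [[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]]
        )

    def test_symmetric_psd_on_random_trees(self):
        rng = np.random.default_rng(7)
        for seed in range(1000):
            t = e.simulate_yule_tree(int(rng.integers(3, 9)), 1.0, seed)
            C = e.vcv_matrix(t).values
            np.testing.assert_allclose(C, C.T, atol=0)
            assert np.linalg.eigvalsh(C)[0] >= -1e-9

    def test_ultrametric_trees_have_equal_diagonal(self):
        for seed in range(50):
            t = e.simulate_yule_tree(10, 1.0, seed)
            d = np.diag(e.vcv_matrix(t).values)
            assert np.ptp(d) <= 1e-9 * max(d.max(), 1.0)

    def test_missing_length_raises(self):
        t = e.parse_newick("((A:1,B),C:2);")
        with pytest.raises(TreeValidationError, match="missing branch length"):
            e.vcv_matrix(t)


# ---------------------------------------------------------------------------
# consensus and burn-in
# ---------------------------------------------------------------------------


def clade_frequencies(sample):
    """Brute-force oracle: count non-trivial rooted clades by enumeration."""
    counts = {}

    def collect(node, acc):
        if node.is_leaf:
            return frozenset([node.label])
        s = frozenset()
        for c in node.children:
            s = s | collect(c, acc)
        acc.append(s)
        return s

    for t in sample:
        acc = []
        full = collect(t.root, acc)
        for s in acc:
            if s != full and len(s) > 1:
                counts[s] = counts.get(s, 0) + 1
    return {s: c / len(sample) for s, c in counts.items()}


class TestConsensus:
    def test_identical_trees_reproduce_topology_with_full_support(self):
        base = e.parse_newick("((A:1,B:1):1,((C:1,D:1):1,E:2):1);")
        sample = e.simulate_tree_sample(base, 10, 0.0, 0)
        cons = e.majority_rule_consensus(sample)
        assert cons.clades() == base.clades()
        assert e.write_newick(cons) == e.write_newick(base).replace("):", ")1:")

    def test_two_thirds_split_retained_with_that_support(self):
        sample = e.TreeSample(
            [
                e.parse_newick("((A:1,B:1):1,(C:1,D:1):1);"),
                e.parse_newick("((A:1,B:1):1,(C:1,D:1):1);"),
                e.parse_newick("((A:1,C:1):1,(B:1,D:1):1);"),
            ]
        )
        cons = e.majority_rule_consensus(sample)
        assert frozenset({"A", "B"}) in cons.clades()
        ab = next(
            n for n in cons.root.children
            if not n.is_leaf and {c.label for c in n.children} == {"A", "B"}
        )
        assert ab.support == pytest.approx(2 / 3)

    def test_exact_half_ties_excluded_gives_polytomy(self):
        sample = e.TreeSample(
            [
                e.parse_newick("((A:1,B:1):1,C:2);"),
                e.parse_newick("((A:1,C:1):1,B:2);"),
            ]
        )
        cons = e.majority_rule_consensus(sample, threshold=0.5)
        assert cons.clades() == set()  # star: every split at frequency 1/2
        assert len(cons.root.children) == 3

    def test_agreement_with_bruteforce_oracle_on_small_samples(self):
        for seed in range(15):
            base = e.simulate_yule_tree(8, 1.0, seed)
            sample = e.simulate_tree_sample(base, 20, 0.3, seed + 100)
            freqs = clade_frequencies(sample)
            cons = e.majority_rule_consensus(sample)
            expected = {s for s, f in freqs.items() if f > 0.5}
            assert cons.clades() == expected

            def supports(node, acc):
                if node.is_leaf:
                    return frozenset([node.label])
                s = frozenset()
                for c in node.children:
                    s = s | supports(c, acc)
                if node.support is not None:
                    acc[s] = node.support
                return s

            acc = {}
            supports(cons.root, acc)
            for s, sup in acc.items():
                assert sup == pytest.approx(freqs[s])
                assert sup > 0.5

    def test_mismatched_leaf_sets_rejected(self):
        with pytest.raises(TreeValidationError):
            e.TreeSample(
                [e.parse_newick("(A:1,B:1);"), e.parse_newick("(A:1,C:1);")]
            )

    def test_invalid_threshold_rejected(self, balanced_four):
        sample = e.simulate_tree_sample(balanced_four, 3, 0.0, 0)
        with pytest.raises(TreeValidationError):
            e.majority_rule_consensus(sample, threshold=0.4)


class TestBurnin:
    @pytest.mark.parametrize(
        "n, fraction, remaining",
        [(100, 0.25, 75), (100, 0.0, 100), (4, 0.5, 2)],
    )
    def test_burnin_arithmetic(self, n, fraction, remaining, balanced_four):
        sample = e.simulate_tree_sample(balanced_four, n, 0.0, 0)
        sample.generation_index = list(range(1, n + 1))
        out = e.discard_burnin(sample, fraction)
        assert len(out) == remaining
        assert out.generation_index[0] == n - remaining + 1
        assert out.generation_index[-1] == n

    def test_burnin_cannot_empty_sample(self, balanced_four):
        sample = e.simulate_tree_sample(balanced_four, 1, 0.0, 0)
        with pytest.raises(TreeValidationError):
            e.discard_burnin(sample, 0.99)
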