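"""Split extraction, compatibility scoring and SPR perturbation."""

import dendropy
import numpy as np
import pytest

from hnsdiv.simulate import random_tree, simulate_gene_trees
from hnsdiv.treecompat import (
    compatibility_score,
    minimal_compatibility,
    nni_perturb,
    pooled_compatibility,
    run_compat_experiment,
    splits_compatible,
    spr_perturb,
    tree_splits,
)


def newick(s):
    return dendropy.Tree.get(data=s, schema="newick")


def named_splits(tree):
    """Splits as frozensets of labels (the smaller-side convention does
    not matter for comparison)."""
    ss = tree_splits(tree)
    out = set()
    for m in ss.masks:
        side = frozenset(t for i, t in enumerate(ss.taxa) if m >> i & 1)
        other = frozenset(ss.taxa) - side
        out.add(min(side, other, key=sorted))
    return out


class TestSplits:
    def test_quartet_single_split(self):
        assert named_splits(newick("((A,B),(C,D));")) == {frozenset("AB")}

    def test_star_tree_has_no_splits(self):
        assert named_splits(newick("(A,B,C,D,E);")) == set()

    def test_caterpillar(self):
        got = named_splits(newick("((((A,B),C),D),E);"))
        # AB|CDE and ABC|DE (the helper reports the lexicographically
        # smaller side)
        assert got == {frozenset("AB"), frozenset("ABC")}

    def test_duplicate_leaf_errors(self):
        t = newick("((A,A2),(C,D));")
        for leaf in t.leaf_node_iter():
            if leaf.taxon.label == "A2":
                leaf.taxon.label = "A"
        with pytest.raises(ValueError):
            tree_splits(t)


class TestCompatibility:
    def mask(self, tree):
        ss = tree_splits(tree)
        return ss, next(iter(ss.masks))

    def test_identical_splits_compatible(self):
        ss, m = self.mask(newick("((A,B),(C,D));"))
        assert splits_compatible(m, m, ss.full_mask)

    def test_conflicting_quartet_splits(self):
        s1, m1 = self.mask(newick("((A,B),(C,D));"))
        s2, m2 = self.mask(newick("((A,C),(B,D));"))
        assert not splits_compatible(m1, m2, s1.full_mask)

    def test_nested_splits_compatible(self):
        t = newick("((((A,B),C),D),E);")
        masks = sorted(tree_splits(t).masks)
        assert splits_compatible(masks[0], masks[1], tree_splits(t).full_mask)

    def test_score_self_is_one(self):
        t = newick("((((A,B),C),D),E);")
        assert compatibility_score(t, t) == 1.0

    def test_score_conflicting_quartets_is_zero(self):
        assert compatibility_score(newick("((A,B),(C,D));"),
                                   newick("((A,C),(B,D));")) == 0.0

    def test_half_compatible_five_leaf_case(self):
        t = newick("((((A,B),C),D),E);")      # AB|CDE, ABC|DE
        ref = newick("((((A,B),D),C),E);")    # AB|CDE, ABD|CE
        assert compatibility_score(t, ref) == 0.5

    def test_shared_leaf_restriction(self):
        t = newick("((((A,B),C),D),E);")
        ref = newick("(((A,B),C),(D,F));")
        score = compatibility_score(t, ref)  # shared leaves A,B,C,D
        assert 0.0 <= score <= 1.0
        with pytest.raises(ValueError):
            compatibility_score(newick("((A,B),(C,X));"),
                                newick("((A,B),(Y,Z));"))

    def test_minimal_is_lower_bound(self):
        rng_trees = [random_tree(8, s) for s in range(5)]
        t = random_tree(8, 99)
        m = minimal_compatibility(t, rng_trees)
        assert all(m <= compatibility_score(t, r) + 1e-12 for r in rng_trees)

    def test_minimal_with_self_reference(self):
        t = newick("((((A,B),C),D),E);")
        assert minimal_compatibility(t, [t]) == 1.0
        conflicting = newick("((((A,C),B),E),D);")
        assert minimal_compatibility(t, [t, conflicting]) < 1.0

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError):
            minimal_compatibility(newick("((A,B),(C,D));"), [])

    def test_subset_splits_score_one(self):
        partial = newick("((A,B),C,(D,E));")   # one split of the caterpillar
        fullt = newick("((((A,B),C),D),E);")
        assert compatibility_score(partial, fullt) == 1.0

    def test_pooled_variant_bounds_minimal(self):
        refs = [random_tree(8, s) for s in range(5)]
        t = random_tree(8, 50)
        assert pooled_compatibility(t, refs) <= minimal_compatibility(t, refs) + 1e-12


class TestSPR:
    def test_leaf_set_preserved(self):
        t = random_tree(10, 1)
        labels = sorted(l.taxon.label for l in t.leaf_node_iter())
        for seed in range(10):
            p = spr_perturb(t, seed, rounds=2)
            assert sorted(l.taxon.label for l in p.leaf_node_iter()) == labels

    def test_quartet_never_reconstructs_original(self):
        base = "((A:1,B:1):1,(C:1,D:1):1);"
        orig = named_splits(newick(base))
        seen = set()
        for seed in range(60):
            got = named_splits(spr_perturb(newick(base), seed, 1))
            assert got != orig
            seen |= got
        assert seen == {frozenset("AC"), frozenset("AD")}  # both alternatives

    def test_seed_contract(self):
        t = random_tree(12, 3)
        a = spr_perturb(t, 7, 1)
        b = spr_perturb(t, 7, 1)
        assert named_splits(a) == named_splits(b)

    def test_one_round_changes_topology(self):
        t = random_tree(15, 5)
        for seed in range(10):
            assert named_splits(spr_perturb(t, seed, 1)) != named_splits(t)

    def test_too_few_leaves_errors(self):
        with pytest.raises(ValueError):
            spr_perturb(newick("(A,(B,C));"), 0, 1)
        with pytest.raises(ValueError):
            spr_perturb(random_tree(8, 0), 0, rounds=0)


class TestExperiment:
    def test_dataset_shapes_and_sampling(self):
        sp = random_tree(10, 2)
        unbound = simulate_gene_trees(sp, 20, seed=1)
        bound = simulate_gene_trees(sp, 8, seed=2)
        exp = run_compat_experiment(bound, unbound, seed=3)
        assert len(exp.scores["C"]) == len(exp.scores["B"]) == 8
        assert len(exp.scores["D"]) == len(exp.scores["E"]) == 8
        # C is a without-replacement subsample of A's scores
        assert len(set(exp.sampled_indices)) == 8
        assert np.isin(exp.scores["C"], exp.scores["A"]).all()
        assert set(exp.ks_results) == {"B", "D", "E"}

    def test_size_violation_errors(self):
        sp = random_tree(10, 2)
        trees = simulate_gene_trees(sp, 5, seed=1)
        with pytest.raises(ValueError):
            run_compat_experiment(trees, trees[:3], seed=0)

    def test_perturbation_orders_score_means(self):
        """Two SPR rounds degrade compatibility at least as much as one,
        which degrades it relative to unperturbed trees (mean over seeds)."""
        sp = random_tree(12, 4)
        means = {"B": [], "D": [], "E": []}
        for seed in range(6):
            unbound = simulate_gene_trees(sp, 30, seed=100 + seed)
            bound = simulate_gene_trees(sp, 15, seed=200 + seed)
            exp = run_compat_experiment(bound, unbound, seed=seed)
            for k in means:
                means[k].append(exp.scores[k].mean())
        assert np.mean(means["E"]) < np.mean(means["D"]) < np.mean(means["B"])


def test_nni_keeps_leaves_and_changes_topology():
    t = random_tree(10, 6)
    labels = sorted(l.taxon.label for l in t.leaf_node_iter())
    changed = 0
    for seed in range(10):
        p = nni_perturb(t, seed, rounds=1)
        assert sorted(l.taxon.label for l in p.leaf_node_iter()) == labels
        changed += named_splits(p) != named_splits(t)
    assert changed >= 5
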