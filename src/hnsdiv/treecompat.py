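"""Gene-tree split compatibility and prune-regraft perturbation tests.

Each unrooted gene tree is reduced to its set of nontrivial bipartitions
(splits).  Two splits are compatible iff at least one of the four pairwise
side intersections is empty.  Three scores against a reference tree set
are provided: the per-tree minimal compatibility (fraction of the tree's
splits compatible with every split of one reference, minimised over the
set), a strict pooled variant, and the pooled split-frequency score (per
split, the fraction of reference split occurrences it is compatible with,
minimised over the tree's splits) — the last is the experiment default
because its near-continuous null distribution keeps KS comparisons
calibrated at desk-scale set sizes.  Random
subtree-prune-regraft (SPR) moves emulate single horizontal-transfer or
recombination events; the experiment driver builds the five canonical
datasets (A: reference trees, B: focal trees, C: size-matched downsample
of A, D/E: B after one/two SPR rounds), scores B-E against A and compares
the score distributions with two-sided Kolmogorov-Smirnov tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np

from .stats import TestResult, ks_two_sample

__all__ = [
    "SplitSet",
    "tree_splits",
    "splits_compatible",
    "compatibility_score",
    "minimal_compatibility",
    "min_split_frequency",
    "pooled_compatibility",
    "spr_perturb",
    "nni_perturb",
    "run_compat_experiment",
]


@dataclass(frozen=True)
class SplitSet:
    """Nontrivial bipartitions of a leaf set, as canonical bitmasks.

    ``taxa`` fixes the bit order; each split is stored as the
    lexicographically smaller side, i.e. min(mask, ~mask & full)."""

    taxa: Tuple[str, ...]
    masks: frozenset

    @property
    def full_mask(self) -> int:
        return (1 << len(self.taxa)) - 1


def _canonical(mask: int, full: int) -> int:
    return min(mask, full & ~mask)


def _leaf_masks(tree: dendropy.Tree, index: Mapping[str, int]) -> Dict[int, int]:
    """Postorder bitmask of leaf labels below each node (by id)."""
    masks: Dict[int, int] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            masks[id(node)] = 1 << index[node.taxon.label]
        else:
            m = 0
            for ch in node.child_nodes():
                m |= masks[id(ch)]
            masks[id(node)] = m
    return masks


def tree_splits(tree: dendropy.Tree,
                taxa: Optional[Sequence[str]] = None) -> SplitSet:
    """Nontrivial splits of an (un)rooted tree, one per internal edge."""
    labels = [l.taxon.label for l in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate leaf labels")
    order = tuple(taxa) if taxa is not None else tuple(sorted(labels))
    index = {t: i for i, t in enumerate(order)}
    full = (1 << len(order)) - 1
    masks = _leaf_masks(tree, index)
    out: Set[int] = set()
    n = len(labels)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        m = masks[id(node)]
        size = bin(m).count("1")
        if size < 2 or n - size < 2:
            continue
        out.add(_canonical(m, full))
    return SplitSet(order, frozenset(out))


def splits_compatible(s1: int, s2: int, full: int) -> bool:
    """Four-intersection rule on bitmask splits over the same leaf set."""
    c1, c2 = full & ~s1, full & ~s2
    return (s1 & s2 == 0) or (s1 & c2 == 0) or (c1 & s2 == 0) or (c1 & c2 == 0)


def _restrict(split_set: SplitSet, shared: Sequence[str]) -> Set[int]:
    """Project splits onto a leaf subset, dropping trivial results."""
    proj_bits = [split_set.taxa.index(t) for t in shared]
    k = len(shared)
    full = (1 << k) - 1
    out: Set[int] = set()
    for m in split_set.masks:
        pm = 0
        for j, bit in enumerate(proj_bits):
            if m >> bit & 1:
                pm |= 1 << j
        size = bin(pm).count("1")
        if 2 <= size <= k - 2:
            out.add(_canonical(pm, full))
    return out


def _score_masks(t_masks: Iterable[int], ref_masks: Iterable[int], full: int) -> float:
    t_masks = list(t_masks)
    if not t_masks:
        return 1.0
    ok = 0
    for m in t_masks:
        if all(splits_compatible(m, r, full) for r in ref_masks):
            ok += 1
    return ok / len(t_masks)


def compatibility_score(t: dendropy.Tree | SplitSet,
                        ref: dendropy.Tree | SplitSet) -> float:
    """Fraction of ``t``'s nontrivial splits compatible with every split
    of ``ref``; comparisons restrict to the shared leaf set, and a tree
    left without nontrivial splits scores 1 by convention."""
    st = t if isinstance(t, SplitSet) else tree_splits(t)
    sr = ref if isinstance(ref, SplitSet) else tree_splits(ref)
    if st.taxa == sr.taxa:
        return _score_masks(st.masks, sr.masks, st.full_mask)
    shared = sorted(set(st.taxa) & set(sr.taxa))
    if len(shared) < 4:
        raise ValueError(f"fewer than 4 shared leaves ({len(shared)})")
    full = (1 << len(shared)) - 1
    return _score_masks(_restrict(st, shared), _restrict(sr, shared), full)


def minimal_compatibility(t: dendropy.Tree | SplitSet,
                          refs: Sequence[dendropy.Tree | SplitSet]) -> float:
    """Minimum compatibility score over a non-empty reference set."""
    if not refs:
        raise ValueError("empty reference set")
    best = 1.0
    for r in refs:
        best = min(best, compatibility_score(t, r))
        if best == 0.0:
            break
    return best


def pooled_compatibility(t: dendropy.Tree | SplitSet,
                         refs: Sequence[dendropy.Tree | SplitSet]) -> float:
    """Strict variant scoring against the pooled split set of the
    references (a split must be compatible with every pooled split)."""
    if not refs:
        raise ValueError("empty reference set")
    st = t if isinstance(t, SplitSet) else tree_splits(t)
    pooled: Set[int] = set()
    for r in refs:
        sr = r if isinstance(r, SplitSet) else tree_splits(r)
        if sr.taxa != st.taxa:
            raise ValueError("pooled scoring requires identical leaf sets")
        pooled |= sr.masks
    return _score_masks(st.masks, pooled, st.full_mask)


def _split_pool(refs: Sequence[SplitSet]) -> Tuple[List[int], np.ndarray, float]:
    """Occurrence-weighted pool of reference splits."""
    counts: Dict[int, int] = {}
    for r in refs:
        for m in r.masks:
            counts[m] = counts.get(m, 0) + 1
    masks = list(counts)
    weights = np.array([counts[m] for m in masks], dtype=float)
    return masks, weights, float(weights.sum())


def min_split_frequency(t: dendropy.Tree | SplitSet,
                        refs: Sequence[dendropy.Tree | SplitSet]) -> float:
    """Minimal split compatibility against the pooled reference splits.

    For each nontrivial split of ``t``, the fraction of reference split
    occurrences it is compatible with; the tree's score is the minimum
    over its splits (1 for a tree with no nontrivial splits).  Compared
    with the min-over-trees score this is nearly continuous, which keeps
    null KS comparisons between score distributions correctly calibrated
    at desk-scale set sizes.
    """
    if not refs:
        raise ValueError("empty reference set")
    st = t if isinstance(t, SplitSet) else tree_splits(t)
    sref = [r if isinstance(r, SplitSet) else tree_splits(r) for r in refs]
    if any(r.taxa != st.taxa for r in sref):
        raise ValueError("pooled scoring requires identical leaf sets")
    masks, weights, total = _split_pool(sref)
    return _min_split_frequency_masks(st, masks, weights, total)


def _min_split_frequency_masks(st: SplitSet, masks: List[int],
                               weights: np.ndarray, total: float) -> float:
    if not st.masks or total == 0:
        return 1.0
    full = st.full_mask
    best = 1.0
    for m in st.masks:
        ok = sum(w for ref_mask, w in zip(masks, weights)
                 if splits_compatible(m, ref_mask, full))
        best = min(best, ok / total)
    return best


# ---------------------------------------------------------------------------
# topology surgery

def _collapse_unifurcations(tree: dendropy.Tree) -> List[dendropy.Node]:
    """Collapse degree-two nodes left by pruning, returning the nodes whose
    (merged) edges mark the old attachment point."""
    merged: List[dendropy.Node] = []
    changed = True
    while changed:
        changed = False
        for node in list(tree.preorder_node_iter()):
            children = node.child_nodes()
            if len(children) != 1:
                continue
            child = children[0]
            if node is tree.seed_node:
                node.remove_child(child)
                tree.seed_node = child
                merged.append(child)
            else:
                parent = node.parent_node
                length = (node.edge.length or 0.0) + (child.edge.length or 0.0)
                node.remove_child(child)
                parent.remove_child(node)
                parent.add_child(child)
                child.edge.length = length
                merged.append(child)
            changed = True
            break
    return merged


def _forbidden_attachment_ids(tree: dendropy.Tree,
                              merged: Sequence[dendropy.Node]) -> Set[int]:
    """Edges adjacent to the original attachment of a pruned subtree.

    A merged internal edge is forbidden directly.  When the collapse
    promoted a new seed node, the old attachment sat on the unrooted edge
    spanning that (degree-two-as-root) node, which the rooted
    representation stores as its two child edges."""
    out: Set[int] = set()
    for node in merged:
        if node is tree.seed_node:
            out.update(id(c) for c in node.child_nodes())
        else:
            out.add(id(node))
    return out


def spr_perturb(tree: dendropy.Tree, seed: int, rounds: int = 1) -> dendropy.Tree:
    """Random subtree-prune-regraft moves on a copy of ``tree``.

    Each round prunes a uniformly chosen eligible edge and regrafts it on
    a uniformly chosen edge that is not adjacent to the original
    attachment point, so the move always changes the unrooted topology.
    The leaf set is unchanged.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    if sum(1 for _ in tree.leaf_node_iter()) < 4:
        raise ValueError("SPR needs at least 4 leaves")
    rng = random.Random(seed)
    out = tree.clone(depth=1)
    for _ in range(rounds):
        out = _one_spr(out, rng)
    return out


def _one_spr(tree: dendropy.Tree, rng: random.Random) -> dendropy.Tree:
    if len(tree.seed_node.child_nodes()) == 2:
        # trifurcating-root representation: one rooted edge per unrooted edge
        tree.deroot()
    candidates = [i for i, n in enumerate(tree.preorder_node_iter())
                  if n is not tree.seed_node]
    rng.shuffle(candidates)
    for cand in candidates:
        work = tree.clone(depth=1)
        copy_nodes = list(work.preorder_node_iter())
        pn = copy_nodes[cand]
        parent = pn.parent_node
        parent.remove_child(pn)
        merged = _collapse_unifurcations(work)
        forbidden = _forbidden_attachment_ids(work, merged)
        if len(work.seed_node.child_nodes()) == 2:
            # a two-child root spans a single unrooted edge, the one the
            # pruned subtree came off: both halves are adjacent to it
            forbidden.update(id(c) for c in work.seed_node.child_nodes())
        attach = [n for n in work.preorder_node_iter()
                  if n is not work.seed_node and id(n) not in forbidden]
        if not attach:
            continue
        target = rng.choice(attach)
        tparent = target.parent_node
        new_node = dendropy.Node()
        tlen = target.edge.length or 0.0
        u = rng.random()
        tparent.remove_child(target)
        tparent.add_child(new_node)
        new_node.edge.length = tlen * u
        new_node.add_child(target)
        target.edge.length = tlen * (1.0 - u)
        new_node.add_child(pn)
        return work
    raise ValueError("no eligible prune/regraft move found")


def nni_perturb(tree: dendropy.Tree, seed: int, rounds: int = 1) -> dendropy.Tree:
    """Random nearest-neighbour interchanges on a copy of ``tree`` (small
    topology jitter, e.g. gene-tree estimation noise)."""
    rng = random.Random(seed)
    out = tree.clone(depth=1)
    for _ in range(rounds):
        cands = [n for n in out.preorder_node_iter()
                 if n.parent_node is not None and not n.is_leaf()]
        if not cands:
            break
        n = rng.choice(cands)
        p = n.parent_node
        sibs = [s for s in p.child_nodes() if s is not n]
        if not sibs or not n.child_nodes():
            continue
        s = rng.choice(sibs)
        c = rng.choice(n.child_nodes())
        p.remove_child(s)
        n.remove_child(c)
        p.add_child(c)
        n.add_child(s)
    return out


@dataclass
class CompatExperiment:
    scores: Dict[str, np.ndarray]
    ks_results: Dict[str, TestResult]
    sampled_indices: np.ndarray


SCORERS = ("pooled_frequency", "min_over_trees", "pooled_strict")


def run_compat_experiment(bound: Sequence[dendropy.Tree],
                          unbound: Sequence[dendropy.Tree],
                          seed: int, *, scorer: str = "pooled_frequency",
                          ) -> CompatExperiment:
    """Score the five datasets and compare their distributions.

    A = ``unbound`` (reference), B = ``bound``, C = |B| trees sampled from
    A without replacement, D = B after one SPR round per tree, E = after
    two rounds.  Every tree in B-E is scored against A — by default with
    the pooled split-frequency score (see `min_split_frequency`; the
    min-over-trees and strict pooled variants are selectable) — and KS
    compares B, D and E against the downsampled null C.
    """
    if scorer not in SCORERS:
        raise ValueError(f"unknown scorer {scorer!r}; choose from {SCORERS}")
    if len(bound) < 2 or len(unbound) < len(bound):
        raise ValueError("need |unbound| >= |bound| >= 2")
    rng = np.random.default_rng(seed)
    taxa = tuple(sorted(l.taxon.label for l in unbound[0].leaf_node_iter()))
    refs = [tree_splits(t, taxa) for t in unbound]
    if scorer == "pooled_frequency":
        masks, weights, total = _split_pool(refs)

        def score(s: SplitSet) -> float:
            return _min_split_frequency_masks(s, masks, weights, total)
    elif scorer == "min_over_trees":
        def score(s: SplitSet) -> float:
            return minimal_compatibility(s, refs)
    else:
        def score(s: SplitSet) -> float:
            return pooled_compatibility(s, refs)

    def score_set(trees: Sequence[dendropy.Tree | SplitSet]) -> np.ndarray:
        return np.asarray([score(t if isinstance(t, SplitSet)
                                 else tree_splits(t, taxa)) for t in trees])

    a_scores = score_set(refs)
    idx = rng.choice(len(unbound), size=len(bound), replace=False)
    scores = {
        "A": a_scores,
        "B": score_set(bound),
        "C": a_scores[idx],
    }
    spr_seeds = rng.integers(0, 2 ** 31 - 1, size=2 * len(bound))
    d_trees = [spr_perturb(t, int(spr_seeds[i]), rounds=1)
               for i, t in enumerate(bound)]
    e_trees = [spr_perturb(t, int(spr_seeds[len(bound) + i]), rounds=2)
               for i, t in enumerate(bound)]
    scores["D"] = score_set(d_trees)
    scores["E"] = score_set(e_trees)
    ks = {name: ks_two_sample(scores[name], scores["C"])
          for name in ("B", "D", "E")}
    return CompatExperiment(scores=scores, ks_results=ks, sampled_indices=idx)
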