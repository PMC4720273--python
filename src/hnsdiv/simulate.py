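"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates the study conditions end to end so every stage is
testable without external downloads:

* paired pulldown/control coverage tracks: the control (WCE) is Poisson
  around a configurable mean depth (default 300x, the scale implied by
  5-11 million 36-bp reads extended to 200 bp on a ~4.6-5 Mb chromosome);
  each pulldown replicate multiplies the expected depth by a lognormal
  intensity field 10^eps with eps a stationary Gaussian field of marginal
  sd ``noise_sigma`` (default 0.2, the sigma of the log10 ratio noise
  component) and ~300 bp correlation length (per-nucleotide coverage built
  from 200-bp extended reads is strongly locally correlated), and
  additionally by ``signal_fold`` inside planted bound regions;
* codon alignments evolved on a tree by nucleotide proposals with
  stop-codon rejection and omega-scaled acceptance of nonsynonymous
  changes (a simplified Goldman-Yang-like scheme, not any named published
  model);
* intergenic nucleotide alignments under a single-parameter (Jukes-Cantor
  type) process;
* random Yule trees, gene trees with NNI estimation noise, and syntenic
  gene/intergenic annotations with planted class labels.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import dataclasses
import itertools
import random
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .binding import CoverageTrack, RegionSet
from .diversity import AlignmentCluster, _AA, _NTS, _STOPS
from .treecompat import nni_perturb

__all__ = [
    "SimConfig",
    "TruthBundle",
    "simulate_binding_tracks",
    "random_tree",
    "scale_to_mean_pairwise",
    "simulate_codon_alignment",
    "simulate_intergenic_cluster",
    "simulate_gene_trees",
    "simulate_annotation",
    "simulate_intergenic_dataset",
]

_SENSE = [c for c in ("".join(t) for t in itertools.product(_NTS, repeat=3))
          if c not in _STOPS]


@dataclass
class SimConfig:
    """Study conditions for the synthetic generators.

    Binding-track parameters: ``genome_length`` bp, ``n_regions`` planted
    bound regions with lengths uniform in ``region_length_range`` (default
    300-3000 bp; called bound regions in the study average ~1.4-1.6 kb),
    ``signal_fold`` linear pulldown enrichment inside regions,
    ``noise_sigma`` marginal sd of the log10 ratio noise, ``noise_corr_bp``
    correlation length of the noise field, ``read_depth`` mean control
    coverage.  Sequence parameters: ``n_taxa`` leaves (default 44, the
    strain panel size of the ortholog analysis), ``omega`` dN/dS used in
    codon simulation, ``ts_tv`` transition/transversion ratio (default 1,
    matching the one-parameter distance estimators), ``site_rate``
    substitution proposals per site per unit branch length.  Annotation
    parameters: ``n_genes`` per strain, ``gene_length_range``,
    ``intergenic_gap_range`` (default 5-400 bp so both sides of the
    10-300 bp acceptance window occur), ``htg_fraction``,
    ``bound_fraction``, ``strains``.
    """

    genome_length: int = 1_000_000
    n_regions: int = 50
    region_length_range: Tuple[int, int] = (300, 3000)
    signal_fold: float = 20.0
    noise_sigma: float = 0.2
    noise_corr_bp: int = 300
    read_depth: float = 300.0
    circular: bool = False
    n_taxa: int = 44
    omega: float = 0.05
    ts_tv: float = 1.0
    site_rate: float = 1.0
    n_genes: int = 60
    gene_length_range: Tuple[int, int] = (300, 1500)
    intergenic_gap_range: Tuple[int, int] = (5, 400)
    htg_fraction: float = 0.2
    bound_fraction: float = 0.2
    strains: Tuple[str, ...] = ("SE11", "SE15", "K12")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        lo, hi = self.region_length_range
        if not (1 <= lo <= hi <= self.genome_length):
            raise ValueError("invalid region_length_range")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be positive")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)


@dataclass
class TruthBundle:
    """Planted ground truth accompanying a simulated dataset."""

    planted_regions: Optional[Dict[str, RegionSet]] = None
    gene_labels: Optional[pd.DataFrame] = None
    intergenic_labels: Optional[pd.DataFrame] = None
    true_rates: Dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# binding tracks

def _smooth_unit_noise(n: int, corr: int, rng: np.random.Generator,
                       circular: bool) -> np.ndarray:
    """Stationary Gaussian field with exactly unit marginal variance and a
    Gaussian autocorrelation of scale ``corr`` bp."""
    z = rng.standard_normal(n)
    mode = "wrap" if circular else "reflect"
    f = gaussian_filter1d(z, sigma=corr, mode=mode)
    # variance of a Gaussian-kernel average of white noise = sum of squared
    # weights; use the discrete kernel actually applied
    radius = int(4 * corr + 0.5)
    x = np.arange(-radius, radius + 1)
    w = np.exp(-0.5 * (x / corr) ** 2)
    w /= w.sum()
    return f / np.sqrt((w ** 2).sum())


def _place_regions(cfg: SimConfig, rng: np.random.Generator,
                   min_gap: int = 500, max_tries: int = 100_000) -> np.ndarray:
    lo, hi = cfg.region_length_range
    placed: List[Tuple[int, int]] = []
    tries = 0
    while len(placed) < cfg.n_regions:
        tries += 1
        if tries > max_tries:
            raise ValueError("could not place non-overlapping regions; "
                             "reduce n_regions or region lengths")
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, cfg.genome_length - length + 1))
        cand = (start, start + length)
        if all(cand[1] + min_gap <= s or e + min_gap <= cand[0]
               for s, e in placed):
            placed.append(cand)
    return np.array(sorted(placed), dtype=np.int64).reshape(-1, 2)


def simulate_binding_tracks(cfg: SimConfig
                            ) -> Tuple[CoverageTrack, CoverageTrack,
                                       CoverageTrack, TruthBundle]:
    """Two pulldown replicates, one control track, and the planted truth.

    Replicates share the planted regions but draw independent noise
    fields, so the per-replicate log10 ratio carries one lognormal noise
    component of sd ``noise_sigma`` (plus Poisson counting noise).
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_place, rng_wce, rng_c1, rng_c2 = map(np.random.default_rng, ss.spawn(4))
    regions = (_place_regions(cfg, rng_place) if cfg.n_regions
               else np.empty((0, 2), dtype=np.int64))
    mask = np.zeros(cfg.genome_length, dtype=bool)
    for s, e in regions:
        mask[s:e] = True

    wce = rng_wce.poisson(cfg.read_depth, cfg.genome_length).astype(float)

    def chap(rng: np.random.Generator) -> CoverageTrack:
        eps = cfg.noise_sigma * _smooth_unit_noise(
            cfg.genome_length, cfg.noise_corr_bp, rng, cfg.circular)
        mean = cfg.read_depth * 10.0 ** eps
        mean[mask] *= cfg.signal_fold
        return CoverageTrack("chr", rng.poisson(mean).astype(float))

    truth = TruthBundle(
        planted_regions={"chr": RegionSet("chr", regions,
                                          np.full(len(regions), np.log10(cfg.signal_fold)))},
        true_rates={"signal_fold": cfg.signal_fold})
    return chap(rng_c1), chap(rng_c2), CoverageTrack("chr", wce), truth


# ---------------------------------------------------------------------------
# trees

def random_tree(n_taxa: int, seed: int, mean_branch: float = 0.1) -> dendropy.Tree:
    """Unrooted-style binary Yule topology with exponential branch lengths
    and leaves labelled t1..tn."""
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    from dendropy.simulate import treesim

    rng = random.Random(seed)
    tree = treesim.birth_death_tree(birth_rate=1.0, death_rate=0.0,
                                    num_extant_tips=n_taxa, rng=rng)
    nprng = np.random.default_rng(np.random.SeedSequence((seed, 0xB0)))
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"t{i + 1}"
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            edge.length = None
            continue
        edge.length = float(nprng.exponential(mean_branch))
        if edge.length <= 0:
            edge.length = 1e-9
    tree.is_rooted = False
    return tree


def _pairwise_path_lengths(tree: dendropy.Tree) -> np.ndarray:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = [l.taxon for l in tree.leaf_node_iter()]
    out = []
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            out.append(pdm.distance(taxa[i], taxa[j]))
    return np.asarray(out, dtype=float)


def scale_to_mean_pairwise(tree: dendropy.Tree, target: float) -> dendropy.Tree:
    """Rescale branch lengths so the mean pairwise leaf distance equals
    ``target`` (in substitutions per site)."""
    mean = float(np.mean(_pairwise_path_lengths(tree)))
    if mean <= 0:
        raise ValueError("tree has zero total depth")
    f = target / mean
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= f
    return tree


def two_taxon_tree(distance: float) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=f"(t1:{distance / 2},t2:{distance / 2});",
                             schema="newick")
    return tree


# ---------------------------------------------------------------------------
# sequence evolution

def _propose(nt: int, kappa: float, rng: np.random.Generator) -> int:
    # A<->G and C<->T are transitions; index order ACGT
    transition = {0: 2, 1: 3, 2: 0, 3: 1}
    w = np.ones(4)
    w[nt] = 0.0
    w[transition[nt]] = kappa
    w /= w.sum()
    return int(rng.choice(4, p=w))


def _evolve_codon_branch(seq: np.ndarray, t: float, omega: float, kappa: float,
                         site_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Propose-accept nucleotide substitutions along one branch.

    Proposal intensity is ``site_rate`` per nucleotide site per unit
    branch length; proposals creating stop codons are rejected, and
    nonsynonymous proposals are accepted with relative probability omega
    versus synonymous ones (omega > 1 instead penalises synonymous ones).
    """
    seq = seq.copy()
    n_prop = rng.poisson(max(t, 0.0) * site_rate * seq.size)
    acc_nonsyn = min(1.0, omega)
    acc_syn = 1.0 if omega <= 1.0 else 1.0 / omega
    for _ in range(n_prop):
        pos = int(rng.integers(seq.size))
        new_nt = _propose(int(seq[pos]), kappa, rng)
        c0 = pos - pos % 3
        old_codon = "".join(_NTS[i] for i in seq[c0:c0 + 3])
        trial = seq[c0:c0 + 3].copy()
        trial[pos - c0] = new_nt
        new_codon = "".join(_NTS[i] for i in trial)
        if new_codon in _STOPS:
            continue
        syn = _AA[old_codon] == _AA[new_codon]
        p_acc = acc_syn if syn else acc_nonsyn
        if p_acc >= 1.0 or rng.random() < p_acc:
            seq[pos] = new_nt
    return seq


def simulate_codon_alignment(tree: dendropy.Tree, omega: float, ts_tv: float,
                             n_codons: int, seed: int,
                             site_rate: float = 1.0) -> AlignmentCluster:
    """Gap-free codon alignment, one sequence per leaf, no stop codons."""
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    leaves = list(tree.leaf_node_iter())
    if len(leaves) < 2:
        raise ValueError("tree needs at least 2 leaves")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    root_codons = rng.choice(len(_SENSE), size=n_codons)
    root = np.concatenate([
        np.array([_NTS.index(c) for c in _SENSE[i]], dtype=np.int8)
        for i in root_codons])
    seqs: Dict[str, str] = {}

    def descend(node, state):
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            child_state = _evolve_codon_branch(state, t, omega, ts_tv,
                                               site_rate, rng)
            if child.is_leaf():
                seqs[child.taxon.label] = "".join(_NTS[i] for i in child_state)
            else:
                descend(child, child_state)

    descend(tree.seed_node, root)
    return AlignmentCluster("sim_codon", seqs, mode="codon")


def simulate_intergenic_cluster(tree: dendropy.Tree, rate: float, length: int,
                                seed: int) -> AlignmentCluster:
    """Gap-free nucleotide alignment under a Jukes-Cantor-type process
    with ``rate`` substitutions per site per unit branch length."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    root = rng.integers(0, 4, size=length).astype(np.int8)
    seqs: Dict[str, str] = {}

    def evolve(state: np.ndarray, t: float) -> np.ndarray:
        state = state.copy()
        n_events = rng.poisson(max(t, 0.0) * rate * length)
        for _ in range(n_events):
            pos = int(rng.integers(length))
            state[pos] = (state[pos] + 1 + rng.integers(3)) % 4
        return state

    def descend(node, state):
        for child in node.child_nodes():
            child_state = evolve(state, child.edge.length or 0.0)
            if child.is_leaf():
                seqs[child.taxon.label] = "".join(_NTS[i] for i in child_state)
            else:
                descend(child, child_state)

    descend(tree.seed_node, root)
    return AlignmentCluster("sim_intergenic", seqs, mode="nucleotide")


def simulate_gene_trees(species_tree: dendropy.Tree, n_trees: int, seed: int,
                        nni_mean: float = 2.0) -> List[dendropy.Tree]:
    """Gene trees as the species topology plus Poisson(nni_mean) random
    NNI moves each (topological estimation noise)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = []
    for i in range(n_trees):
        k = int(rng.poisson(nni_mean))
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        out.append(nni_perturb(species_tree, sub_seed, rounds=k) if k
                   else species_tree.clone(depth=1))
    return out


# ---------------------------------------------------------------------------
# annotations

def simulate_annotation(cfg: SimConfig
                        ) -> Tuple[pd.DataFrame, pd.DataFrame,
                                   pd.DataFrame, TruthBundle]:
    """Syntenic per-strain gene tables, truth-labelled intergenic gaps,
    HTG prediction lists, and called-region truth.

    Genes keep one order and orientation across strains (a small fraction
    get a strand flip in one strain to exercise synteny rejection); gap
    lengths are drawn per cluster and re-drawn per strain with probability
    0.3 so the 10-300 bp all-strain acceptance window has both accepted
    and rejected cases.
    """
    ss = np.random.SeedSequence((cfg.seed, 0xA11))
    rng = np.random.default_rng(ss)
    n = cfg.n_genes
    glo, ghi = cfg.gene_length_range
    ilo, ihi = cfg.intergenic_gap_range

    lengths = rng.integers(glo, ghi + 1, size=n)
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    base_gaps = rng.integers(ilo, ihi + 1, size=n - 1)
    htg = rng.random(n) < cfg.htg_fraction
    bound = rng.random(n) < cfg.bound_fraction
    inverted = rng.random(n) < 0.05  # strand flip in one strain
    worst_case = 100 + int(lengths.sum()) + (n - 1) * ihi
    if worst_case > cfg.genome_length:
        raise ValueError("genes cannot be packed into the genome")

    gene_rows = []
    region_by_strain: Dict[str, List[Tuple[int, int]]] = {s: [] for s in cfg.strains}
    gap_records: Dict[str, List[Tuple[int, int, int]]] = {s: [] for s in cfg.strains}
    for s_idx, strain in enumerate(cfg.strains):
        pos = 100
        for i in range(n):
            start, end = pos, pos + int(lengths[i])
            strand = strands[i]
            if inverted[i] and s_idx == len(cfg.strains) - 1:
                strand = "+" if strand == "-" else "-"
            gene_rows.append({
                "gene_id": f"{strain}_g{i:04d}", "strain": strain,
                "chrom": f"{strain}_chr", "start": start, "end": end,
                "strand": strand, "ortholog_cluster_id": f"og{i:04d}"})
            if bound[i] and s_idx == 0:
                mid = (start + end) // 2
                half = max(10, (end - start) // 4)
                region_by_strain[strain].append((mid - half, mid + half))
            pos = end
            if i < n - 1:
                gap = int(base_gaps[i])
                if rng.random() < 0.3:
                    gap = int(rng.integers(ilo, ihi + 1))
                gap_records[strain].append((i, pos, pos + gap))
                pos += gap

    genes = pd.DataFrame(gene_rows)
    regions = {s: (RegionSet(f"{s}_chr", np.array(v), np.ones(len(v)))
                   if v else RegionSet.empty(f"{s}_chr"))
               for s, v in region_by_strain.items()}

    ig_rows = []
    for i in range(n - 1):
        gaps = {s: gap_records[s][i][2] - gap_records[s][i][1] for s in cfg.strains}
        conserved = (all(10 <= g <= 300 for g in gaps.values())
                     and not inverted[i] and not inverted[i + 1])
        ig_rows.append({"left_cluster": f"og{i:04d}", "right_cluster": f"og{i + 1:04d}",
                        "conserved": conserved,
                        **{f"{s}_gap": gaps[s] for s in cfg.strains}})
    intergenics = pd.DataFrame(ig_rows)

    htg_ids = [f"og{i:04d}" for i in range(n) if htg[i]]
    list_rows = []
    for cid in htg_ids:
        which = rng.integers(3)  # 0: list1, 1: list2, 2: both
        if which in (0, 2):
            list_rows.append({"list_name": "pred1", "cluster_id": cid})
        if which in (1, 2):
            list_rows.append({"list_name": "pred2", "cluster_id": cid})
    htg_lists = pd.DataFrame(list_rows, columns=["list_name", "cluster_id"])

    truth = TruthBundle(
        planted_regions=regions,
        gene_labels=pd.DataFrame({
            "ortholog_cluster_id": [f"og{i:04d}" for i in range(n)],
            "htg": htg, "hns_bound": bound}),
        intergenic_labels=intergenics)
    return genes, intergenics, htg_lists, truth


# ---------------------------------------------------------------------------
# end-to-end intergenic diversity dataset

def simulate_intergenic_dataset(tree: dendropy.Tree, n_bound: int, n_unbound: int,
                                length: int, base_rate: float,
                                bound_rate_mult: float, seed: int
                                ) -> Tuple[List[AlignmentCluster], pd.DataFrame]:
    """Class II intergenic clusters with a planted bound-class rate effect.

    Bound clusters evolve at ``bound_rate_mult`` times the unbound rate on
    a shared tree; returns the clusters plus a label frame.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    clusters: List[AlignmentCluster] = []
    labels = []
    for k in range(n_bound + n_unbound):
        is_bound = k < n_bound
        rate = base_rate * (bound_rate_mult if is_bound else 1.0)
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        c = simulate_intergenic_cluster(tree, rate, length, sub_seed)
        c = AlignmentCluster(f"ig{k:04d}", c.sequences, "nucleotide")
        clusters.append(c)
        labels.append({"cluster_id": c.cluster_id, "hns_bound": is_bound,
                       "orientation_class": "II_tail_to_head"})
    return clusters, pd.DataFrame(labels)
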