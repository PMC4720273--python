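"""Reproduction experiments: the package's headline quantities.

Each function recomputes one quantity from scratch at the study's
desk-scale conditions — threshold arithmetic, the published three-strain
bound-proportion percentages (recomputed from the published totals, which
are inputs), planted-region recovery, omega recovery, contrast power and
calibration, and the gene-tree perturbation experiment.  Both the
acceptance test suite and ``scripts/acceptance.py`` call these.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .binding import (
    IntensityTrack,
    binding_intensity,
    call_regions,
    fit_noise_model,
    intersect_replicates,
    normalize_track,
)
from .diversity import cluster_diversity, pairwise_dnds
from .segments import BlockTable, bound_proportions, classify_segments
from .simulate import (
    SimConfig,
    random_tree,
    scale_to_mean_pairwise,
    simulate_binding_tracks,
    simulate_codon_alignment,
    simulate_gene_trees,
    simulate_intergenic_dataset,
    two_taxon_tree,
)
from .stats import ks_two_sample, wilcoxon_rank_sum
from .treecompat import min_split_frequency, run_compat_experiment, tree_splits

# Published totals of the three-strain comparison (inputs, bp).
GENOME_BP = {"SE11": 4_887_515, "SE15": 4_717_338, "K12": 4_646_332}
COMMON_BP = {"SE11": 3_886_369, "SE15": 3_886_157, "K12": 3_886_242}
BOUND_TOTAL_BP = {"SE11": 802_561, "SE15": 642_859, "K12": 697_762}
BOUND_COMMON_BP = {"SE11": 451_643, "SE15": 383_226, "K12": 427_731}
STRAINS = ("SE11", "SE15", "K12")


def _derive(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence((seed, tag)).generate_state(1)[0] % (2 ** 31))


def noise_threshold(seed: int, n: int = 10 ** 6) -> Dict[str, float]:
    """Fit the noise model to a pure Normal(0, 0.2) intensity sample and
    report the mode and the threshold offset (3 sigma)."""
    rng = np.random.default_rng(_derive(seed, 1))
    track = IntensityTrack("chr", rng.normal(0.0, 0.2, size=n))
    model = fit_noise_model(track, sigma=0.2)
    return {"mode": model.mode, "threshold": model.threshold,
            "offset": model.threshold - model.mode}


def published_bound_percentages() -> Dict[str, float]:
    """Whole-genome and common-segment bound percentages from the
    published totals, computed through the segment-accounting pipeline."""
    from .binding import RegionSet

    rows, regions = [], {}
    for s in STRAINS:
        rows.append({"block_id": "common", "strain": s, "chrom": f"{s}_chr",
                     "start": 0, "end": COMMON_BP[s], "strand": "+"})
        rows.append({"block_id": f"rest_{s}", "strain": s, "chrom": f"{s}_chr",
                     "start": COMMON_BP[s], "end": GENOME_BP[s], "strand": "+"})
        rest_bound = BOUND_TOTAL_BP[s] - BOUND_COMMON_BP[s]
        ivals = np.array([[0, BOUND_COMMON_BP[s]],
                          [COMMON_BP[s], COMMON_BP[s] + rest_bound]])
        regions[s] = RegionSet(f"{s}_chr", ivals, np.zeros(2))
    blocks = BlockTable(STRAINS, pd.DataFrame(rows))
    out = bound_proportions(classify_segments(blocks), regions)
    out = out.set_index(["strain", "class"])["proportion_pct"]
    result = {}
    for s in STRAINS:
        result[f"{s}_genome_pct"] = round(float(out[(s, "genome")]), 1)
        result[f"{s}_common_pct"] = round(float(out[(s, "common")]), 1)
    return result


def planted_recovery(seed: int) -> Dict[str, float]:
    """Recall and precision of the calling pipeline on planted signal:
    1 Mb genome, 50 regions of 300-3000 bp, 20-fold enrichment, sigma 0.2.

    A planted region counts as recovered when the union of intersected
    replicate calls covers >= 90% of it; precision is the fraction of
    called bases outside any planted region.
    """
    cfg = SimConfig(genome_length=10 ** 6, n_regions=50,
                    region_length_range=(300, 3000), signal_fold=20.0,
                    noise_sigma=0.2, seed=_derive(seed, 2))
    chap1, chap2, wce, truth = simulate_binding_tracks(cfg)
    wn = normalize_track(wce)
    calls = []
    for chap in (chap1, chap2):
        track = binding_intensity(normalize_track(chap), wn)
        model = fit_noise_model(track, sigma=cfg.noise_sigma)
        calls.append(call_regions(track, model))
    merged = intersect_replicates(calls[0], calls[1])
    planted = truth.planted_regions["chr"]
    pm = planted.coverage_mask(cfg.genome_length)
    cm = merged.coverage_mask(cfg.genome_length)
    recovered = 0
    for s, e in planted.intervals:
        if cm[s:e].sum() >= 0.9 * (e - s):
            recovered += 1
    called_bp = int(cm.sum())
    outside = float((cm & ~pm).sum() / called_bp * 100) if called_bp else 0.0
    return {"recall_pct": 100.0 * recovered / len(planted),
            "outside_truth_pct": outside,
            "n_planted": len(planted), "called_bp": called_bp}


def omega_recovery(seed: int, omega: float, n_codons: int = 2000,
                   n_seeds: int = 20, distance: float = 0.1) -> float:
    """Mean estimated dN/dS over replicate two-taxon simulations."""
    tree = two_taxon_tree(distance)
    rng = np.random.default_rng(_derive(seed, 3))
    ests = []
    for _ in range(n_seeds):
        sub = int(rng.integers(0, 2 ** 31 - 1))
        c = simulate_codon_alignment(tree, omega, 1.0, n_codons, sub)
        dn, ds = pairwise_dnds(c.sequences["t1"], c.sequences["t2"])
        if ds > 0:
            ests.append(dn / ds)
    return float(np.mean(ests))


def _contrast_p(tree, seed: int, mult: float) -> float:
    clusters, labels = simulate_intergenic_dataset(
        tree, n_bound=50, n_unbound=400, length=100, base_rate=0.005,
        bound_rate_mult=mult, seed=seed)
    pis = np.array([cluster_diversity(c).pi for c in clusters])
    bound = labels["hns_bound"].to_numpy()
    return wilcoxon_rank_sum(pis[bound], pis[~bound]).p_value


def contrast_power(seed: int, n_reps: int = 20) -> float:
    """Fraction (%) of replicates in which the planted 1.5x bound-class
    rate in class II intergenics is detected at p < 0.05."""
    tree = scale_to_mean_pairwise(random_tree(44, _derive(seed, 4)), 1.0)
    rng = np.random.default_rng(_derive(seed, 5))
    hits = sum(_contrast_p(tree, int(rng.integers(0, 2 ** 31 - 1)), 1.5) < 0.05
               for _ in range(n_reps))
    return 100.0 * hits / n_reps


def contrast_null_fpr(seed: int, n_reps: int = 200) -> float:
    """False-positive percentage of the same contrast with no effect."""
    tree = scale_to_mean_pairwise(random_tree(44, _derive(seed, 4)), 1.0)
    rng = np.random.default_rng(_derive(seed, 6))
    hits = sum(_contrast_p(tree, int(rng.integers(0, 2 ** 31 - 1)), 1.0) < 0.05
               for _ in range(n_reps))
    return 100.0 * hits / n_reps


def spr_rejection_rate(seed: int, n_seeds: int = 20, n_trees: int = 100,
                       n_leaves: int = 20) -> float:
    """Percentage of experiment replicates in which one SPR round per
    tree is rejected against the downsampled null at p < 0.001 (KS)."""
    species = random_tree(n_leaves, _derive(seed, 7))
    rng = np.random.default_rng(_derive(seed, 8))
    hits = 0
    for _ in range(n_seeds):
        s1, s2, s3 = (int(rng.integers(0, 2 ** 31 - 1)) for _ in range(3))
        unbound = simulate_gene_trees(species, n_trees, seed=s1)
        bound = simulate_gene_trees(species, n_trees, seed=s2)
        exp = run_compat_experiment(bound, unbound, seed=s3)
        hits += exp.ks_results["D"].p_value < 1e-3
    return 100.0 * hits / n_seeds


def ks_null_calibration(seed: int, n_seeds: int = 100, n_trees: int = 100,
                        n_leaves: int = 20) -> float:
    """Percentage of null replicates (no perturbation, bound trees drawn
    from the same law as the reference set) with KS p < 0.05."""
    species = random_tree(n_leaves, _derive(seed, 7))
    rng = np.random.default_rng(_derive(seed, 9))
    taxa = tuple(f"t{i + 1}" for i in range(n_leaves))
    hits = 0
    for _ in range(n_seeds):
        s1, s2 = (int(rng.integers(0, 2 ** 31 - 1)) for _ in range(2))
        unbound = simulate_gene_trees(species, n_trees, seed=s1)
        bound = simulate_gene_trees(species, n_trees, seed=s2)
        refs = [tree_splits(t, taxa) for t in unbound]
        a = np.array([min_split_frequency(s, refs) for s in refs])
        b = np.array([min_split_frequency(tree_splits(t, taxa), refs)
                      for t in bound])
        c = a[rng.choice(n_trees, n_trees, replace=False)]
        hits += ks_two_sample(b, c).p_value < 0.05
    return 100.0 * hits / n_seeds
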