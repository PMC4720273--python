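"""Gene/intergenic classification policies and conservation profiles."""

import numpy as np
import pandas as pd
import pytest

from hnsdiv.annotation import (
    annotate_bound_genes,
    annotate_bound_intergenics,
    classify_intergenic_lineage,
    classify_lineage,
    classify_orientation,
    conservation_profile,
    extract_conserved_intergenics,
)
from hnsdiv.simulate import SimConfig, simulate_annotation
from conftest import make_regions


def gene_row(gene_id, start, end, strand="+", strain="K12", cluster=None):
    return {"gene_id": gene_id, "strain": strain, "chrom": f"{strain}_chr",
            "start": start, "end": end, "strand": strand,
            "ortholog_cluster_id": cluster or gene_id}


class TestBoundGenes:
    def test_any_overlap(self):
        genes = pd.DataFrame([gene_row("g1", 1000, 2000)])
        regions = {"K12": make_regions([[1500, 2500]], chrom="K12_chr")}
        out = annotate_bound_genes(genes, regions, "any_overlap")
        assert out["hns_bound"].iloc[0]

    def test_three_prime_tail_demotion(self):
        genes = pd.DataFrame([gene_row("g1", 0, 1000, strand="+")])
        regions = {"K12": make_regions([[990, 1100]], chrom="K12_chr")}
        assert annotate_bound_genes(genes, regions, "any_overlap")["hns_bound"].iloc[0]
        assert not annotate_bound_genes(
            genes, regions, "exclude_3prime_10pct")["hns_bound"].iloc[0]
        # same geometry on the minus strand: the 3' end is the start
        genes_m = pd.DataFrame([gene_row("g1", 0, 1000, strand="-")])
        regions_m = {"K12": make_regions([[0, 10]], chrom="K12_chr")}
        assert not annotate_bound_genes(
            genes_m, regions_m, "exclude_3prime_10pct")["hns_bound"].iloc[0]

    def test_large_or_internal_overlap_stays_bound(self):
        genes = pd.DataFrame([gene_row("g1", 0, 1000)])
        internal = {"K12": make_regions([[400, 450]], chrom="K12_chr")}
        out = annotate_bound_genes(genes, internal, "exclude_3prime_10pct")
        assert out["hns_bound"].iloc[0]  # 5% but not at the 3' terminus
        big = {"K12": make_regions([[700, 1000]], chrom="K12_chr")}
        out = annotate_bound_genes(genes, big, "exclude_3prime_10pct")
        assert out["hns_bound"].iloc[0]  # touches 3' end but 30% > 10%

    def test_no_overlap_unbound(self):
        genes = pd.DataFrame([gene_row("g1", 0, 1000)])
        out = annotate_bound_genes(genes, {}, "any_overlap")
        assert not out["hns_bound"].iloc[0]

    def test_bound_in_one_strain_suffices(self):
        genes = pd.DataFrame([gene_row("g1", 0, 1000, strain="K12", cluster="og1"),
                              gene_row("g1b", 0, 1000, strain="SE11", cluster="og1")])
        regions = {"SE11": make_regions([[100, 400]], chrom="SE11_chr")}
        out = annotate_bound_genes(genes, regions, "any_overlap")
        assert out["hns_bound"].all()

    def test_policy_monotonicity(self):
        rng = np.random.default_rng(4)
        genes = pd.DataFrame([gene_row(f"g{i}", i * 2000, i * 2000 + 1000)
                              for i in range(30)])
        tu = pd.DataFrame({"gene_id": [f"g{i}" for i in range(30)],
                           "tu_id": [f"tu{i // 3}" for i in range(30)]})
        ivals = sorted((int(s), int(s) + 120)
                       for s in rng.choice(30, 8, replace=False) * 2000 + 880)
        regions = {"K12": make_regions(ivals, chrom="K12_chr")}
        strict = annotate_bound_genes(genes, regions, "exclude_3prime_10pct")
        base = annotate_bound_genes(genes, regions, "any_overlap")
        loose = annotate_bound_genes(genes, regions, "transcription_unit", tu_table=tu)
        s = set(strict.loc[strict.hns_bound, "gene_id"])
        b = set(base.loc[base.hns_bound, "gene_id"])
        l = set(loose.loc[loose.hns_bound, "gene_id"])
        assert s <= b <= l

    def test_insertion_dependent_forcing(self):
        genes = pd.DataFrame([gene_row("g1", 0, 1000, cluster="og1")])
        regions = {"K12": make_regions([[100, 900]], chrom="K12_chr")}
        out = annotate_bound_genes(genes, regions, "any_overlap",
                                   insertion_dependent=["og1"])
        assert not out["hns_bound"].iloc[0]
        out = annotate_bound_genes(genes, regions, "any_overlap",
                                   insertion_dependent=["og1"],
                                   include_insertion_dependent=True)
        assert out["hns_bound"].iloc[0]

    def test_unknown_policy_errors(self):
        with pytest.raises(ValueError):
            annotate_bound_genes(pd.DataFrame([gene_row("g", 0, 10)]), {}, "bogus")


class TestLineage:
    def test_at_least_one_list(self):
        genes = pd.DataFrame([gene_row("g1", 0, 10), gene_row("g2", 20, 30)])
        out = classify_lineage(genes, [{"g1"}, set(), set()])
        assert out.set_index("gene_id")["lineage"].to_dict() == \
            {"g1": "HTG", "g2": "Core"}

    def test_empty_lists_all_core(self):
        genes = pd.DataFrame([gene_row("g1", 0, 10)])
        assert (classify_lineage(genes, [])["lineage"] == "Core").all()


class TestOrientation:
    @pytest.mark.parametrize("left,right,expect", [
        ("+", "-", "I"),
        ("-", "+", "II_head_to_head"),
        ("+", "+", "II_tail_to_head"),
        ("-", "-", "II_tail_to_head"),
    ])
    def test_classes(self, left, right, expect):
        assert classify_orientation(left, right) == expect

    def test_missing_strand(self):
        with pytest.raises(ValueError):
            classify_orientation("+", ".")


class TestIntergenicLineage:
    def make(self, left, right):
        return pd.DataFrame([{"cluster_id": "ig0", "left_cluster": "a",
                              "right_cluster": "b", "left_strand": "+",
                              "right_strand": "+"}]), {"a": left, "b": right}

    @pytest.mark.parametrize("left,right,expect", [
        ("HTG", "HTG", "HTG_intergenic"),
        ("Core", "Core", "Core_intergenic"),
        ("HTG", "Core", "mixed"),
    ])
    def test_rules(self, left, right, expect):
        df, mapping = self.make(left, right)
        assert classify_intergenic_lineage(df, mapping)["lineage"].iloc[0] == expect


def three_strain_genes(gaps, strands=("+", "+", "+"), invert_in=None):
    """Three syntenic genes per strain with given inter-gene gaps; one
    gene's strand optionally inverted in the last strain."""
    rows = []
    for strain in ("SE11", "SE15", "K12"):
        pos = 0
        for i, (length, strand) in enumerate(zip((500, 600, 700), strands)):
            s = strand
            if invert_in == i and strain == "K12":
                s = "+" if s == "-" else "-"
            rows.append(gene_row(f"{strain}_g{i}", pos, pos + length, strand=s,
                                 strain=strain, cluster=f"og{i}"))
            pos += length + (gaps[strain][i] if i < 2 else 0)
    return pd.DataFrame(rows)


class TestConservedIntergenics:
    def test_accepts_gap_in_window(self):
        gaps = {s: [50, 120] for s in ("SE11", "SE15", "K12")}
        out = extract_conserved_intergenics(three_strain_genes(gaps))
        assert len(out) == 2
        assert (out["SE11_length"] == [50, 120]).all()

    def test_rejects_short_gap_in_one_strain(self):
        gaps = {"SE11": [50, 120], "SE15": [5, 120], "K12": [50, 120]}
        out = extract_conserved_intergenics(three_strain_genes(gaps))
        assert len(out) == 1 and out["SE11_length"].iloc[0] == 120

    def test_rejects_gap_above_window(self):
        gaps = {"SE11": [50, 350], "SE15": [50, 120], "K12": [50, 120]}
        out = extract_conserved_intergenics(three_strain_genes(gaps))
        assert len(out) == 1

    def test_rejects_inverted_neighbour(self):
        gaps = {s: [50, 120] for s in ("SE11", "SE15", "K12")}
        out = extract_conserved_intergenics(three_strain_genes(gaps, invert_in=1))
        assert len(out) == 0  # both pairs touch the inverted gene

    def test_orientation_from_flanks(self):
        gaps = {s: [50, 120] for s in ("SE11", "SE15", "K12")}
        out = extract_conserved_intergenics(
            three_strain_genes(gaps, strands=("+", "-", "+")))
        by_pair = out.set_index("left_cluster")["orientation_class"]
        assert by_pair["og0"] == "I"
        assert by_pair["og1"] == "II_head_to_head"

    def test_matches_simulated_truth_exactly(self):
        cfg = SimConfig(n_genes=40, seed=5)
        genes, intergenics, htg_lists, truth = simulate_annotation(cfg)
        out = extract_conserved_intergenics(genes)
        got = set(zip(out["left_cluster"], out["right_cluster"]))
        expect = {(r.left_cluster, r.right_cluster)
                  for r in truth.intergenic_labels.itertuples() if r.conserved}
        assert got == expect

    def test_bound_flag_from_regions(self):
        gaps = {s: [50, 120] for s in ("SE11", "SE15", "K12")}
        genes = three_strain_genes(gaps)
        out = extract_conserved_intergenics(genes)
        regions = {"SE15": make_regions([[510, 540]], chrom="SE15_chr")}
        out = annotate_bound_intergenics(out, regions)
        flagged = out.set_index("left_cluster")["hns_bound"]
        assert flagged["og0"] and not flagged["og1"]


class TestConservationProfile:
    def test_hand_computed_group_stats(self):
        presence = pd.DataFrame(
            {"g1": [True, True], "g2": [True, False],
             "g3": [False, True], "g4": [True, False], "g5": [True, True]},
            index=["genomeA", "genomeB"]).T
        classes = {f"g{i}": "bound" for i in range(1, 6)}
        groups = {"genomeA": "family", "genomeB": "family"}
        out = conservation_profile(presence, classes, groups)
        # rates: A = 4/5 = 0.8, B = 3/5 = 0.6
        assert out["mean_conservation"].iloc[0] == pytest.approx(0.7)
        assert out["sd_conservation"].iloc[0] == pytest.approx(np.std([0.8, 0.6], ddof=1))

    def test_fixed_rates_mean_and_sd(self):
        presence = pd.DataFrame(
            [[True, True], [False, True], [True, False], [False, False],
             [True, True]],
            index=[f"gene{i}" for i in range(5)],
            columns=["gA", "gB"])
        classes = {f"gene{i}": "c" for i in range(5)}
        out = conservation_profile(presence, classes, {"gA": "grp", "gB": "grp"})
        rates = [presence["gA"].mean(), presence["gB"].mean()]
        assert out["mean_conservation"].iloc[0] == pytest.approx(np.mean(rates))

    def test_all_present_and_all_absent(self):
        presence = pd.DataFrame([[True, True], [False, False]],
                                index=["gene_up", "gene_down"],
                                columns=["gA", "gB"])
        classes = {"gene_up": "up", "gene_down": "down"}
        out = conservation_profile(presence, classes, {"gA": "g", "gB": "g"})
        means = out.set_index("gene_class")["mean_conservation"]
        assert means["up"] == 1.0 and means["down"] == 0.0
        sds = out.set_index("gene_class")["sd_conservation"]
        assert (sds == 0.0).all()

    def test_empty_class_errors(self):
        presence = pd.DataFrame([[True]], index=["g1"], columns=["gA"])
        with pytest.raises(ValueError):
            conservation_profile(presence, {"g_missing": "c"}, {"gA": "g"})


def test_simulated_gene_truth_recovered():
    """On the synthetic annotation bundle, bound and HTG labels recomputed
    by the pipeline match the planted truth exactly."""
    cfg = SimConfig(n_genes=50, seed=9)
    genes, _, htg_lists, truth = simulate_annotation(cfg)
    out = annotate_bound_genes(genes, truth.planted_regions, "any_overlap")
    got_bound = (out.groupby("ortholog_cluster_id")["hns_bound"].first())
    expect = truth.gene_labels.set_index("ortholog_cluster_id")
    assert got_bound.sort_index().tolist() == expect["hns_bound"].sort_index().tolist()

    by_list = [set(sub["cluster_id"]) for _, sub in htg_lists.groupby("list_name")]
    tmp = genes.rename(columns={"gene_id": "orig_gene_id",
                                "ortholog_cluster_id": "gene_id"})
    lineage = classify_lineage(tmp, by_list)
    got_htg = lineage.groupby("gene_id")["htg"].first()
    assert got_htg.sort_index().tolist() == expect["htg"].sort_index().tolist()
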