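"""Gene and intergenic-region classification for the diversity contrasts.

Genes are flagged H-NS-bound when their coding span overlaps a called
binding region in at least one strain (policy ``any_overlap``), with two
stricter variants: ``exclude_3prime_10pct`` demotes genes whose only
overlap is a single block touching the 3' terminus and covering at most
10% of the gene, and ``transcription_unit`` promotes every gene whose
transcription unit contains a bound member.  Genes whose binding depends
on a neighbouring strain-specific insertion (supplied as an exclusion
list) are forced unbound under the default reading.

Lineage labels follow the at-least-one-prediction rule: a gene named in
any horizontal-transfer prediction list is an HTG, everything else Core.

Conserved intergenic regions are the gaps between two neighbouring
orthologous genes that appear in the same order and orientation in every
strain with a per-strain length of 10-300 bp.  Their orientation class
follows the flanking strands: convergent (tail-to-tail) regions are
class I (non-regulatory); divergent (head-to-head) and co-oriented
(tail-to-head) regions are class II (regulatory).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .binding import RegionSet

__all__ = [
    "POLICIES",
    "annotate_bound_genes",
    "classify_lineage",
    "extract_conserved_intergenics",
    "annotate_bound_intergenics",
    "classify_orientation",
    "classify_intergenic_lineage",
    "conservation_profile",
]

POLICIES = ("any_overlap", "exclude_3prime_10pct", "exclude_3prime_10pct_window",
            "transcription_unit")

GENE_COLUMNS = ("gene_id", "strain", "chrom", "start", "end", "strand",
                "ortholog_cluster_id")


def _overlap_segments(start: int, end: int, regions: RegionSet) -> List[Tuple[int, int]]:
    out = []
    for s, e in regions.intervals:
        lo, hi = max(start, s), min(end, e)
        if lo < hi:
            out.append((lo, hi))
    return out


def _counts_as_bound(row, segs: List[Tuple[int, int]], policy: str) -> bool:
    if not segs:
        return False
    if policy in ("any_overlap", "transcription_unit"):
        return True
    glen = row.end - row.start
    total = sum(e - s for s, e in segs)
    if total > 0.10 * glen:
        return True
    if policy == "exclude_3prime_10pct_window":
        # demote iff every overlapped base lies in the 3'-terminal 10%
        if row.strand == "+":
            window_start = row.end - glen * 0.10
            confined = all(s >= window_start for s, e in segs)
        else:
            window_end = row.start + glen * 0.10
            confined = all(e <= window_end for s, e in segs)
        return not confined
    # default reading: the merged overlap must be one contiguous block that
    # touches the 3' terminus
    segs = sorted(segs)
    merged = [list(segs[0])]
    for s, e in segs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    if len(merged) > 1:
        return True
    s, e = merged[0]
    touches = (e == row.end) if row.strand == "+" else (s == row.start)
    return not touches


def annotate_bound_genes(genes: pd.DataFrame, regions: Mapping[str, RegionSet],
                         policy: str = "any_overlap",
                         tu_table: Optional[pd.DataFrame] = None,
                         insertion_dependent: Optional[Iterable[str]] = None,
                         include_insertion_dependent: bool = False,
                         ) -> pd.DataFrame:
    """Flag genes as H-NS bound.

    ``genes`` is a long frame over strains with the GENE_COLUMNS layout;
    binding is decided per ortholog cluster: bound iff the gene overlaps a
    region in at least one strain under the chosen policy.  The
    ``insertion_dependent`` cluster ids (binding driven by a neighbouring
    strain-specific insertion) are forced unbound by default, or forced
    bound when ``include_insertion_dependent`` is set.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {POLICIES}")
    if policy == "transcription_unit" and tu_table is None:
        raise ValueError("transcription_unit policy requires a TU table")
    df = genes.copy()
    flags = []
    for row in df.itertuples():
        reg = regions.get(row.strain)
        segs = _overlap_segments(row.start, row.end, reg) if reg is not None else []
        flags.append(_counts_as_bound(row, segs, policy))
    df["_self_bound"] = flags
    bound_by_cluster = df.groupby("ortholog_cluster_id")["_self_bound"].transform("any")
    df["hns_bound"] = bound_by_cluster

    if policy == "transcription_unit":
        tu = tu_table.set_index("gene_id")["tu_id"]
        df["_tu"] = df["gene_id"].map(tu)
        tu_bound = df.groupby("_tu")["hns_bound"].transform("any")
        df.loc[df["_tu"].notna(), "hns_bound"] = tu_bound[df["_tu"].notna()]
        df = df.drop(columns="_tu")

    ins = set(insertion_dependent or ())
    df["insertion_dependent_bound"] = df["ortholog_cluster_id"].isin(ins)
    if ins:
        value = bool(include_insertion_dependent)
        df.loc[df["insertion_dependent_bound"], "hns_bound"] = value
    return df.drop(columns="_self_bound")


def classify_lineage(genes: pd.DataFrame,
                     htg_lists: Sequence[Iterable[str]]) -> pd.DataFrame:
    """HTG iff the gene id appears in at least one prediction list."""
    union: Set[str] = set()
    for lst in htg_lists:
        union.update(lst)
    df = genes.copy()
    df["htg"] = df["gene_id"].isin(union)
    df["lineage"] = np.where(df["htg"], "HTG", "Core")
    return df


def classify_orientation(left_strand: str, right_strand: str) -> str:
    """Orientation class from the flanking strands (left/right by genome
    coordinate): converging tails -> I; diverging heads -> II_head_to_head;
    co-oriented -> II_tail_to_head."""
    if left_strand not in "+-" or right_strand not in "+-":
        raise ValueError("missing or invalid strand")
    if (left_strand, right_strand) == ("+", "-"):
        return "I"
    if (left_strand, right_strand) == ("-", "+"):
        return "II_head_to_head"
    return "II_tail_to_head"


def _pair_signature(cl: str, sl: str, cr: str, sr: str) -> Tuple:
    """Canonical form of an adjacent ortholog pair, invariant to whole-
    locus inversion (mirror flips order and both strands)."""
    fwd = (cl, sl, cr, sr)
    flip = {"+": "-", "-": "+"}
    rev = (cr, flip[sr], cl, flip[sl])
    return min(fwd, rev)


def extract_conserved_intergenics(genes: pd.DataFrame,
                                  min_len: int = 10, max_len: int = 300,
                                  ) -> pd.DataFrame:
    """Conserved intergenic clusters from per-strain gene tables.

    A cluster is emitted for every pair of neighbouring orthologous genes
    that is adjacent, in the same order and orientation (up to whole-locus
    inversion), in every strain, with a gap length within
    [``min_len``, ``max_len``] in every strain.  Rows carry per-strain gap
    coordinates for downstream binding overlap.
    """
    strains = sorted(genes["strain"].unique())
    per_strain: Dict[str, Dict[Tuple, Dict]] = {}
    for strain in strains:
        sub = genes[genes["strain"] == strain].sort_values("start")
        pairs: Dict[Tuple, Dict] = {}
        rows = list(sub.itertuples())
        for a, b in zip(rows, rows[1:]):
            sig = _pair_signature(a.ortholog_cluster_id, a.strand,
                                  b.ortholog_cluster_id, b.strand)
            gap = b.start - a.end
            pairs[sig] = {"gap": gap, "start": a.end, "end": b.start,
                          "chrom": a.chrom,
                          "left_cluster": a.ortholog_cluster_id,
                          "right_cluster": b.ortholog_cluster_id,
                          "left_strand": a.strand, "right_strand": b.strand,
                          "left_gene": a.gene_id, "right_gene": b.gene_id}
        per_strain[strain] = pairs

    common_sigs = set.intersection(*(set(p) for p in per_strain.values())) \
        if per_strain else set()
    records = []
    for idx, sig in enumerate(sorted(common_sigs)):
        entries = {s: per_strain[s][sig] for s in strains}
        if not all(min_len <= e["gap"] <= max_len for e in entries.values()):
            continue
        first = entries[strains[0]]
        rec = {"cluster_id": f"ig{idx:04d}",
               "left_cluster": first["left_cluster"],
               "right_cluster": first["right_cluster"],
               "left_strand": first["left_strand"],
               "right_strand": first["right_strand"],
               "orientation_class": classify_orientation(first["left_strand"],
                                                         first["right_strand"])}
        for s in strains:
            rec[f"{s}_chrom"] = entries[s]["chrom"]
            rec[f"{s}_start"] = entries[s]["start"]
            rec[f"{s}_end"] = entries[s]["end"]
            rec[f"{s}_length"] = entries[s]["gap"]
        records.append(rec)
    return pd.DataFrame(records)


def annotate_bound_intergenics(intergenics: pd.DataFrame,
                               regions: Mapping[str, RegionSet]) -> pd.DataFrame:
    """Bound iff the gap overlaps a called region in at least one strain."""
    df = intergenics.copy()
    flags = []
    for row in df.itertuples():
        bound = False
        for strain, reg in regions.items():
            start = getattr(row, f"{strain}_start", None)
            end = getattr(row, f"{strain}_end", None)
            if start is None or reg is None:
                continue
            if _overlap_segments(int(start), int(end), reg):
                bound = True
                break
        flags.append(bound)
    df["hns_bound"] = flags
    return df


def classify_intergenic_lineage(intergenics: pd.DataFrame,
                                gene_lineage: Mapping[str, str]) -> pd.DataFrame:
    """HTG_intergenic iff both flanking genes are HTG, Core_intergenic iff
    both Core, otherwise mixed (excluded from the HTG/Core contrast).

    ``gene_lineage`` maps ortholog cluster id -> "HTG"/"Core".
    """
    df = intergenics.copy()
    out = []
    for row in df.itertuples():
        left = gene_lineage.get(row.left_cluster)
        right = gene_lineage.get(row.right_cluster)
        if left == "HTG" and right == "HTG":
            out.append("HTG_intergenic")
        elif left == "Core" and right == "Core":
            out.append("Core_intergenic")
        else:
            out.append("mixed")
    df["lineage"] = out
    return df


def conservation_profile(presence: pd.DataFrame, gene_classes: Mapping[str, str],
                         genome_groups: Mapping[str, str], ddof: int = 1,
                         ) -> pd.DataFrame:
    """Mean and sd of per-genome conservation rates by gene class and
    taxon group.

    ``presence`` is a genes x genomes boolean frame; the conservation rate
    of a class in one genome is the fraction of that class's genes present
    there.  Rates are then averaged over the genomes of each taxon group;
    sd uses ``ddof`` (sample sd by default).
    """
    classes = pd.Series(gene_classes)
    groups = pd.Series(genome_groups)
    missing = set(presence.columns) - set(groups.index)
    if missing:
        raise ValueError(f"genomes without a taxon group: {sorted(missing)}")
    rows = []
    for cls_name in sorted(classes.unique()):
        members = classes.index[classes == cls_name]
        members = [g for g in members if g in presence.index]
        if not members:
            raise ValueError(f"gene class {cls_name!r} has no genes in the matrix")
        rates = presence.loc[members].mean(axis=0)  # per genome
        for grp in sorted(groups.unique()):
            genomes = [g for g in groups.index[groups == grp] if g in rates.index]
            if not genomes:
                continue
            vals = rates[genomes].to_numpy(dtype=float)
            sd = float(np.std(vals, ddof=ddof)) if vals.size > ddof else 0.0
            rows.append({"gene_class": cls_name, "taxon_group": grp,
                         "mean_conservation": float(vals.mean()),
                         "sd_conservation": sd, "n_genomes": vals.size})
    return pd.DataFrame(rows)
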