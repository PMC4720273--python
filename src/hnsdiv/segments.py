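"""Common/shared/specific genome-segment accounting.

Multi-genome alignment blocks (consumed as a block coordinate table, one
row per block with per-strain coordinates) are classified by their
presence pattern: present in every strain ("common"), in a proper subset
of at least two ("shared"), or in exactly one ("specific").  The module
then computes, per strain and class, the proportion of base pairs covered
by called binding regions, and projects binding regions between strains
through block-relative coordinates to count how many strains share each
bound base (the conserved / shared-by-two / unique accounting).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .binding import RegionSet

__all__ = [
    "BlockTable",
    "SegmentClassification",
    "classify_segments",
    "bound_proportions",
    "conserved_overlap",
]


@dataclass
class BlockTable:
    """Alignment blocks with per-strain coordinates.

    ``table`` is a long-format frame with columns
    block_id, strain, chrom, start, end, strand ('+'/'-');
    a block absent from a strain simply has no row for it.
    """

    strains: Tuple[str, ...]
    table: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"block_id", "strain", "chrom", "start", "end", "strand"}
        missing = need - set(self.table.columns)
        if missing:
            raise ValueError(f"block table missing columns {sorted(missing)}")
        if (self.table["end"] <= self.table["start"]).any():
            raise ValueError("block end must exceed start")
        bad = set(self.table["strain"]) - set(self.strains)
        if bad:
            raise ValueError(f"unknown strains in block table: {sorted(bad)}")
        for strain, sub in self.table.groupby("strain"):
            sub = sub.sort_values("start")
            if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping blocks in strain {strain}")

    def presence(self) -> pd.DataFrame:
        """blocks x strains boolean presence matrix."""
        p = (self.table.assign(present=True)
             .pivot_table(index="block_id", columns="strain", values="present",
                          aggfunc="any", fill_value=False))
        for s in self.strains:
            if s not in p.columns:
                p[s] = False
        return p[list(self.strains)].astype(bool)

    @classmethod
    def from_backbone_tsv(cls, path, strains: Sequence[str]) -> "BlockTable":
        """Read the wide backbone-style TSV (block_id plus, per strain,
        {s}_chrom, {s}_start, {s}_end, {s}_strand; start==end==0 when the
        block is absent from that strain)."""
        wide = pd.read_csv(path, sep="\t")
        rows = []
        for _, r in wide.iterrows():
            for s in strains:
                start, end = int(r[f"{s}_start"]), int(r[f"{s}_end"])
                if start == 0 and end == 0:
                    continue
                rows.append({"block_id": r["block_id"], "strain": s,
                             "chrom": r[f"{s}_chrom"], "start": start,
                             "end": end, "strand": r[f"{s}_strand"]})
        return cls(tuple(strains), pd.DataFrame(rows))

    def to_backbone_tsv(self, path) -> None:
        recs = {}
        for _, r in self.table.iterrows():
            rec = recs.setdefault(r["block_id"], {"block_id": r["block_id"]})
            rec.update({f"{r['strain']}_chrom": r["chrom"],
                        f"{r['strain']}_start": r["start"],
                        f"{r['strain']}_end": r["end"],
                        f"{r['strain']}_strand": r["strand"]})
        wide = pd.DataFrame(list(recs.values()))
        for s in self.strains:
            for col, fill in ((f"{s}_chrom", "."), (f"{s}_start", 0),
                              (f"{s}_end", 0), (f"{s}_strand", "+")):
                if col not in wide.columns:
                    wide[col] = fill
                wide[col] = wide[col].fillna(fill)
        wide.to_csv(path, sep="\t", index=False)


@dataclass
class SegmentClassification:
    """Per-block class labels and per-strain per-class bp totals."""

    strains: Tuple[str, ...]
    labels: pd.DataFrame  # block_id, label, present_in (tuple)
    class_bp: pd.DataFrame  # strain, label, bp
    blocks: BlockTable


def _label(present: Sequence[str], all_strains: Sequence[str]) -> str:
    if len(present) == 0:
        raise ValueError("block present in no strain")
    if len(present) == len(all_strains):
        return "common"
    if len(present) == 1:
        return f"specific:{present[0]}"
    return "shared:" + "+".join(present)


def classify_segments(blocks: BlockTable) -> SegmentClassification:
    """Label every block by its presence pattern and total the per-strain
    base pairs per class."""
    pres = blocks.presence()
    if (~pres).all(axis=1).any():
        raise ValueError("block present in zero strains")
    order = list(blocks.strains)
    labels = []
    for block_id, row in pres.iterrows():
        present = tuple(s for s in order if row[s])
        labels.append({"block_id": block_id, "label": _label(present, order),
                       "present_in": present})
    lab = pd.DataFrame(labels)
    merged = blocks.table.merge(lab[["block_id", "label"]], on="block_id")
    merged["bp"] = merged["end"] - merged["start"]
    class_bp = (merged.groupby(["strain", "label"], as_index=False)["bp"].sum())
    return SegmentClassification(blocks.strains, lab, class_bp, blocks)


def _intersect_bp(regions: np.ndarray, blocks: np.ndarray) -> int:
    """Total overlap bp between two sorted interval arrays."""
    total = 0
    i = j = 0
    while i < len(regions) and j < len(blocks):
        s = max(regions[i][0], blocks[j][0])
        e = min(regions[i][1], blocks[j][1])
        if s < e:
            total += e - s
        if regions[i][1] <= blocks[j][1]:
            i += 1
        else:
            j += 1
    return int(total)


def bound_proportions(cls: SegmentClassification,
                      regions: Mapping[str, RegionSet],
                      genome_lengths: Optional[Mapping[str, int]] = None,
                      ) -> pd.DataFrame:
    """Per strain and segment class: bound bp, class bp and the bound
    percentage, plus a whole-genome row per strain.

    The whole-genome denominator is ``genome_lengths`` when given,
    otherwise the sum of class bp (blocks tiling the chromosome).
    """
    merged = cls.blocks.table.merge(cls.labels[["block_id", "label"]], on="block_id")
    rows = []
    for strain in cls.strains:
        reg = regions.get(strain)
        reg_iv = reg.intervals if reg is not None and len(reg) else np.empty((0, 2), int)
        sub = merged[merged["strain"] == strain]
        genome = (genome_lengths[strain] if genome_lengths
                  else int((sub["end"] - sub["start"]).sum()))
        if len(reg_iv) and int(reg_iv[:, 1].max()) > genome:
            raise ValueError(f"region beyond genome bounds for strain {strain}")
        total_bound = int((reg_iv[:, 1] - reg_iv[:, 0]).sum()) if len(reg_iv) else 0
        for label, lsub in sub.groupby("label"):
            blk = lsub.sort_values("start")[["start", "end"]].to_numpy()
            class_bp = int((blk[:, 1] - blk[:, 0]).sum())
            bound_bp = _intersect_bp(reg_iv, blk)
            rows.append({"strain": strain, "class": label, "bound_bp": bound_bp,
                         "class_bp": class_bp,
                         "proportion_pct": 100.0 * bound_bp / class_bp if class_bp else 0.0})
        rows.append({"strain": strain, "class": "genome", "bound_bp": total_bound,
                     "class_bp": genome,
                     "proportion_pct": 100.0 * total_bound / genome if genome else 0.0})
    return pd.DataFrame(rows)


def conserved_overlap(regions: Mapping[str, RegionSet], blocks: BlockTable,
                      classes: Sequence[str] = ("common",),
                      classification: Optional[SegmentClassification] = None,
                      ) -> pd.DataFrame:
    """Cross-strain sharing of bound base pairs inside multi-strain blocks.

    Each strain's regions are projected into block-relative coordinates
    (linear offset; reflected on '-' strand blocks) and, per strain, bound
    bp are partitioned by how many other strains' regions cover the same
    block-relative base: conserved (all others), shared, or unique.
    Returns per strain the bp and percentage at each sharing level.
    """
    cls = classification or classify_segments(blocks)
    lab = cls.labels.set_index("block_id")
    masks: Dict[str, Dict[object, np.ndarray]] = {s: {} for s in blocks.strains}
    block_strains: Dict[object, List[str]] = {}

    for block_id, row in lab.iterrows():
        kind = row["label"].split(":")[0]
        if kind not in {c.split(":")[0] for c in classes} and row["label"] not in classes:
            continue
        sub = blocks.table[blocks.table["block_id"] == block_id]
        if len(sub) < 2:
            continue
        length = int((sub["end"] - sub["start"]).min())
        block_strains[block_id] = list(sub["strain"])
        for _, b in sub.iterrows():
            strain = b["strain"]
            reg = regions.get(strain)
            mask = np.zeros(length, dtype=bool)
            if reg is not None and len(reg):
                for s, e in reg.intervals:
                    lo, hi = max(s, b["start"]), min(e, b["end"])
                    if lo >= hi:
                        continue
                    r0, r1 = lo - b["start"], hi - b["start"]
                    if b["strand"] == "-":
                        blen = b["end"] - b["start"]
                        r0, r1 = blen - r1, blen - r0
                    r0, r1 = max(0, min(r0, length)), max(0, min(r1, length))
                    mask[r0:r1] = True
            masks[strain][block_id] = mask

    counts: Dict[str, Dict[int, int]] = {s: {0: 0, 1: 0, 2: 0} for s in blocks.strains}
    for block_id, strains_here in block_strains.items():
        for s in strains_here:
            own = masks[s][block_id]
            if not own.any():
                continue
            others = [masks[o][block_id] for o in strains_here if o != s]
            n_other = (np.sum(others, axis=0) if others
                       else np.zeros(own.size, dtype=int))
            for level in range(len(blocks.strains)):
                bp = int(np.sum(own & (n_other == level)))
                if bp:
                    counts[s][level] = counts[s].get(level, 0) + bp

    rows = []
    max_others = len(blocks.strains) - 1
    for s in blocks.strains:
        total = sum(counts[s].values())
        row: Dict[str, object] = {"strain": s, "total_bound_bp": total}
        for level in range(max_others + 1):
            bp = counts[s].get(level, 0)
            name = ("unique" if level == 0
                    else "conserved" if level == max_others
                    else f"shared_by_{level + 1}")
            row[f"{name}_bp"] = bp
            row[f"{name}_pct"] = 100.0 * bp / total if total else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
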