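"""Readers and writers for the plain-text interchange formats.

All coordinates are 0-based half-open internally.  bedGraph rows are
run-length compressed on write and expanded to per-nucleotide arrays on
read; BED6 scores clamp 1000x the mean log-intensity to [0, 1000].
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .binding import CoverageTrack, IntensityTrack, RegionSet
from .diversity import AlignmentCluster

__all__ = [
    "read_bedgraph", "write_bedgraph", "write_bed", "read_bed",
    "write_region_summary", "read_gff3", "write_gff3",
    "read_fasta_cluster", "write_fasta_cluster", "write_config_yaml",
]


def read_bedgraph(path, length: Optional[int] = None) -> CoverageTrack:
    """Expand a 4-column bedGraph into a per-nucleotide coverage track."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["chrom", "start", "end", "value"])
    df = df[df["chrom"].astype(str).str.lower() != "track"]
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError(f"expected one chromosome, found {list(chroms)}")
    n = length or int(df["end"].max())
    values = np.zeros(n, dtype=float)
    for row in df.itertuples():
        values[int(row.start):int(row.end)] = float(row.value)
    return CoverageTrack(str(chroms[0]), values)


def write_bedgraph(track: CoverageTrack, path) -> None:
    v = track.values
    breaks = np.flatnonzero(np.diff(v)) + 1
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks, [v.size]])
    with open(path, "w", newline="\n") as fh:
        for s, e in zip(starts, ends):
            fh.write(f"{track.chrom}\t{s}\t{e}\t{v[s]:g}\n")


def write_bed(regions: RegionSet, path) -> None:
    """BED6: name = region index, score = 1000*mean log-intensity clamped
    to [0, 1000]."""
    with open(path, "w", newline="\n") as fh:
        for i, ((s, e), m) in enumerate(zip(regions.intervals,
                                            regions.mean_intensity)):
            score = int(np.clip(1000.0 * m, 0, 1000))
            fh.write(f"{regions.chrom}\t{s}\t{e}\tregion_{i}\t{score}\t.\n")


def read_bed(path) -> RegionSet:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None)
    except pd.errors.EmptyDataError:
        return RegionSet.empty("")
    chrom = str(df.iloc[0, 0])
    ivals = df.iloc[:, 1:3].to_numpy(dtype=np.int64)
    means = (df.iloc[:, 4].to_numpy(dtype=float) / 1000.0
             if df.shape[1] >= 5 else np.zeros(len(df)))
    order = np.argsort(ivals[:, 0])
    return RegionSet(chrom, ivals[order], means[order])


def write_region_summary(regions: RegionSet, genome_length: int, path) -> None:
    pd.DataFrame([{
        "chrom": regions.chrom, "n_regions": len(regions),
        "total_bp": regions.total_bp,
        "fraction_of_genome": regions.total_bp / genome_length,
    }]).to_csv(path, sep="\t", index=False)


_GFF_COLS = ["seqid", "source", "type", "start", "end", "score", "strand",
             "phase", "attributes"]


def read_gff3(path) -> pd.DataFrame:
    """GFF3 gene rows to the internal gene-table layout (0-based
    half-open).  Attributes must carry ID= and may carry ortholog_cluster=."""
    df = pd.read_csv(path, sep="\t", comment="#", names=_GFF_COLS)
    df = df[df["type"] == "gene"].copy()

    def attr(s: str, key: str) -> Optional[str]:
        for part in s.split(";"):
            if part.startswith(key + "="):
                return part.split("=", 1)[1]
        return None

    out = pd.DataFrame({
        "gene_id": df["attributes"].map(lambda s: attr(s, "ID")),
        "chrom": df["seqid"],
        "start": df["start"].astype(int) - 1,
        "end": df["end"].astype(int),
        "strand": df["strand"],
        "ortholog_cluster_id": df["attributes"].map(
            lambda s: attr(s, "ortholog_cluster")),
    })
    return out.reset_index(drop=True)


def write_gff3(genes: pd.DataFrame, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples():
            attrs = f"ID={row.gene_id};ortholog_cluster={row.ortholog_cluster_id}"
            fh.write(f"{row.chrom}\thnsdiv\tgene\t{row.start + 1}\t{row.end}\t."
                     f"\t{row.strand}\t.\t{attrs}\n")


def read_fasta_cluster(path, cluster_id: str, mode: str) -> AlignmentCluster:
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    return AlignmentCluster(cluster_id, seqs, mode)


def write_fasta_cluster(cluster: AlignmentCluster, path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sorted(cluster.sequences.items())]
    SeqIO.write(records, str(path), "fasta")


def write_config_yaml(cfg_dict: Mapping, path) -> None:
    with open(path, "w", newline="\n") as fh:
        yaml.safe_dump(dict(cfg_dict), fh, sort_keys=True)
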