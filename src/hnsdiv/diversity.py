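"""Per-cluster sequence diversity as the mean of all pairwise distances.

For codon-aligned ortholog clusters the module estimates nonsynonymous (dN)
and synonymous (dS) substitutions per site with a Nei–Gojobori-style
counting method: synonymous/nonsynonymous site counts are averaged over the
two sequences, per-codon differences are averaged over all minimal
mutational pathways (pathways passing through stop codons are dropped and
the remainder renormalised), and proportions are converted to distances
with the one-parameter multiple-hit correction

    d = -(3/4) * ln(1 - (4/3) p).

For nucleotide (intergenic) clusters the same correction is applied to the
p-distance.  Cluster diversity is the arithmetic mean over all unordered
sequence pairs, with the exclusion rules used for conserved-intergenic
screening: broken codons (frameshifted length or internal stop), ungapped
length differences >= 10% of the aligned length, saturation (p >= 3/4) and
any pairwise distance > 1.0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "AlignmentCluster",
    "DiversityRecord",
    "SaturationError",
    "check_broken_codons",
    "filter_cluster",
    "pairwise_dnds",
    "pairwise_nt_distance",
    "cluster_diversity",
    "jukes_cantor",
]

_TABLE = unambiguous_dna_by_id[11]  # bacterial code; stops TAA/TAG/TGA
_NTS = "ACGT"
_STOPS = frozenset(_TABLE.stop_codons)
_AA = dict(_TABLE.forward_table)


class SaturationError(ValueError):
    """Raised when a proportion of differences reaches the 3/4 ceiling of
    the one-parameter correction."""


@dataclass
class AlignmentCluster:
    """Gap-aligned homologous sequences keyed by strain/taxon.

    mode is "codon" (aligned length divisible by 3, in-frame) or
    "nucleotide" (conserved intergenic regions).
    """

    cluster_id: str
    sequences: Dict[str, str]
    mode: str = "codon"

    def __post_init__(self) -> None:
        if self.mode not in ("codon", "nucleotide"):
            raise ValueError(f"unknown mode {self.mode!r}")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError("aligned sequences must have equal length")
        if self.mode == "codon" and lengths and next(iter(lengths)) % 3:
            raise ValueError("codon alignment length not divisible by 3")

    @property
    def aligned_length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    def ungapped_lengths(self) -> Dict[str, int]:
        return {k: len(s) - s.count("-") for k, s in self.sequences.items()}


@dataclass
class DiversityRecord:
    cluster_id: str
    dn: Optional[float] = None
    ds: Optional[float] = None
    pi: Optional[float] = None
    n_seqs: int = 0
    excluded: bool = False
    reason: Optional[str] = None  # distance_gt_1 | length_diff_ge_10pct | saturation | broken_codon


# ---------------------------------------------------------------------------
# codon bookkeeping, precomputed once at import

def _codon_index(codon: str) -> int:
    return (_NTS.index(codon[0]) << 4) | (_NTS.index(codon[1]) << 2) | _NTS.index(codon[2])


def _syn_sites() -> Dict[str, float]:
    """Synonymous site count per sense codon (changes to stops count as
    nonsynonymous, the original counting convention)."""
    out = {}
    for codon in map("".join, itertools.product(_NTS, repeat=3)):
        if codon in _STOPS:
            continue
        s = 0.0
        for pos in range(3):
            for nt in _NTS:
                if nt == codon[pos]:
                    continue
                alt = codon[:pos] + nt + codon[pos + 1:]
                if alt not in _STOPS and _AA[alt] == _AA[codon]:
                    s += 1.0 / 3.0
        out[codon] = s
    return out


_SYN_SITES = _syn_sites()


def _pathway_counts(a: str, b: str) -> Tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons,
    averaged over minimal mutational pathways.  Pathways visiting a stop
    codon are dropped and the rest renormalised; if every pathway passes
    through a stop, all pathways are used."""
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    paths: List[Tuple[float, float]] = []
    clean: List[Tuple[float, float]] = []
    for order in itertools.permutations(diff):
        cur = a
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if nxt in _STOPS:
                through_stop = True
                sd += 0.0  # counted below as nonsyn; aa comparison vs stop undefined
                nd += 1.0
            else:
                if cur in _STOPS or _AA.get(cur) != _AA.get(nxt):
                    nd += 1.0
                else:
                    sd += 1.0
            cur = nxt
        paths.append((sd, nd))
        if not through_stop:
            clean.append((sd, nd))
    use = clean if clean else paths
    sd = sum(p[0] for p in use) / len(use)
    nd = sum(p[1] for p in use) / len(use)
    return sd, nd


_PAIR_COUNTS: Dict[Tuple[str, str], Tuple[float, float]] = {}


def _pair_counts(a: str, b: str) -> Tuple[float, float]:
    key = (a, b)
    hit = _PAIR_COUNTS.get(key)
    if hit is None:
        hit = _pathway_counts(a, b)
        _PAIR_COUNTS[key] = hit
        _PAIR_COUNTS[(b, a)] = hit
    return hit


# ---------------------------------------------------------------------------

def jukes_cantor(p: float) -> float:
    """One-parameter multiple-hit correction d = -(3/4) ln(1 - (4/3) p)."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.4f} >= 3/4")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def check_broken_codons(seq: str) -> bool:
    """True iff ``seq`` (ungapped coding sequence) is a clean ORF: length a
    multiple of three and no internal in-frame stop codon.  A terminal stop
    is allowed."""
    seq = seq.upper()
    if any(c not in _NTS for c in seq):
        raise ValueError("non-nucleotide characters in coding sequence")
    if len(seq) % 3:
        return False
    for i in range(0, len(seq) - 3, 3):
        if seq[i:i + 3] in _STOPS:
            return False
    return True


def filter_cluster(cluster: AlignmentCluster, *, compare_to: str = "aligned") -> Optional[str]:
    """Screening applied before distance estimation.

    Returns None if the cluster passes, else the exclusion reason.
    ``compare_to`` selects the denominator of the intergenic length rule:
    "aligned" (default: max pairwise ungapped-length difference measured
    against the aligned length) or "pairwise" (against the shorter of the
    two ungapped lengths).
    """
    if cluster.mode == "codon":
        for seq in cluster.sequences.values():
            if not check_broken_codons(seq.replace("-", "")):
                return "broken_codon"
        return None
    lengths = list(cluster.ungapped_lengths().values())
    if len(lengths) < 2:
        return None
    spread = max(lengths) - min(lengths)
    denom = cluster.aligned_length if compare_to == "aligned" else min(lengths)
    if denom and spread >= 0.10 * denom:
        return "length_diff_ge_10pct"
    return None


def _strip_pairwise_gaps(a: str, b: str, codon: bool) -> Tuple[str, str]:
    if codon:
        ka, kb = [], []
        for i in range(0, len(a), 3):
            ca, cb = a[i:i + 3], b[i:i + 3]
            if "-" in ca or "-" in cb:
                continue
            ka.append(ca)
            kb.append(cb)
        return "".join(ka), "".join(kb)
    keep = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    if not keep:
        return "", ""
    xs, ys = zip(*keep)
    return "".join(xs), "".join(ys)


def pairwise_dnds(a: str, b: str) -> Tuple[float, float]:
    """Counting-method (dN, dS) for two equal-length in-frame sequences.

    Gap codon columns are removed pairwise.  Raises SaturationError when
    either proportion reaches 3/4.
    """
    if len(a) != len(b):
        raise ValueError("sequences differ in aligned length")
    if len(a) % 3:
        raise ValueError("aligned length not divisible by 3")
    a, b = _strip_pairwise_gaps(a.upper(), b.upper(), codon=True)
    if not a:
        raise ValueError("no comparable codon columns")
    S = N = sd = nd = 0.0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if ca in _STOPS or cb in _STOPS:
            raise ValueError(f"stop codon in aligned sequence at column {i}")
        S += 0.5 * (_SYN_SITES[ca] + _SYN_SITES[cb])
        dsd, dnd = _pair_counts(ca, cb)
        sd += dsd
        nd += dnd
    N = len(a) - S
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    if S == 0 and sd > 0:
        raise SaturationError("synonymous differences with zero synonymous sites")
    if N == 0 and nd > 0:
        raise SaturationError("nonsynonymous differences with zero nonsynonymous sites")
    return jukes_cantor(pn), jukes_cantor(ps)


def pairwise_nt_distance(a: str, b: str) -> float:
    """Corrected nucleotide distance after pairwise gap removal."""
    if len(a) != len(b):
        raise ValueError("sequences differ in aligned length")
    a, b = _strip_pairwise_gaps(a.upper(), b.upper(), codon=False)
    if not a:
        raise ValueError("no comparable columns")
    p = sum(x != y for x, y in zip(a, b)) / len(a)
    return jukes_cantor(p)


def cluster_diversity(cluster: AlignmentCluster, *, prefilter: bool = True,
                      compare_to: str = "aligned") -> DiversityRecord:
    """Mean of all pairwise distances for one cluster, with exclusions.

    Codon mode fills dn/ds; nucleotide mode fills pi.  A record is excluded
    (with reason) if the cluster fails `filter_cluster`, any pairwise
    proportion saturates, or any pairwise distance exceeds 1.0.
    """
    names = sorted(cluster.sequences)
    if len(names) < 2:
        raise ValueError("cluster needs at least two sequences")
    rec = DiversityRecord(cluster_id=cluster.cluster_id, n_seqs=len(names))
    if prefilter:
        reason = filter_cluster(cluster, compare_to=compare_to)
        if reason is not None:
            rec.excluded, rec.reason = True, reason
            return rec
    if cluster.mode == "nucleotide" and not any(
            "-" in s for s in cluster.sequences.values()):
        return _gapfree_nt_diversity(cluster, names, rec)
    dns, dss, pis = [], [], []
    try:
        for x, y in itertools.combinations(names, 2):
            if cluster.mode == "codon":
                dn, ds = pairwise_dnds(cluster.sequences[x], cluster.sequences[y])
                if dn > 1.0 or ds > 1.0:
                    rec.excluded, rec.reason = True, "distance_gt_1"
                    return rec
                dns.append(dn)
                dss.append(ds)
            else:
                d = pairwise_nt_distance(cluster.sequences[x], cluster.sequences[y])
                if d > 1.0:
                    rec.excluded, rec.reason = True, "distance_gt_1"
                    return rec
                pis.append(d)
    except SaturationError:
        rec.excluded, rec.reason = True, "saturation"
        return rec
    if cluster.mode == "codon":
        rec.dn = float(np.mean(dns))
        rec.ds = float(np.mean(dss))
    else:
        rec.pi = float(np.mean(pis))
    return rec


def _gapfree_nt_diversity(cluster: AlignmentCluster, names: List[str],
                          rec: DiversityRecord) -> DiversityRecord:
    """Vectorised all-pairs path for gap-free nucleotide clusters;
    semantics identical to the pairwise loop."""
    mat = np.frombuffer("".join(cluster.sequences[n] for n in names).encode(),
                        dtype=np.uint8).reshape(len(names), -1)
    L = mat.shape[1]
    diffs = (mat[:, None, :] != mat[None, :, :]).sum(axis=2)
    iu = np.triu_indices(len(names), k=1)
    p = diffs[iu] / L
    if (p >= 0.75).any():
        rec.excluded, rec.reason = True, "saturation"
        return rec
    d = -0.75 * np.log1p(-4.0 * p / 3.0)
    if (d > 1.0).any():
        rec.excluded, rec.reason = True, "distance_gt_1"
        return rec
    rec.pi = float(d.mean())
    return rec


def complete_deletion(cluster: AlignmentCluster) -> AlignmentCluster:
    """Cluster-wide removal of every column (codon column in codon mode)
    containing a gap in any sequence — the gap-free sensitivity mode."""
    names = sorted(cluster.sequences)
    seqs = [cluster.sequences[n] for n in names]
    L = cluster.aligned_length
    step = 3 if cluster.mode == "codon" else 1
    kept = []
    for i in range(0, L, step):
        cols = [s[i:i + step] for s in seqs]
        if any("-" in c for c in cols):
            continue
        kept.append(cols)
    new = {n: "".join(k[j] for k in kept) for j, n in enumerate(names)}
    return AlignmentCluster(cluster.cluster_id, new, cluster.mode)
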