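"""Independent enumeration oracles for the counting-method dN/dS.

Written directly from the definition (no lookup tables, no shared code
with the implementation).
"""

import itertools
import math

from Bio.Seq import Seq

NTS = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# oracle: straight from the counting-method definition, no lookup tables

def _aa(codon):
    return str(Seq(codon).translate(table=11))


def oracle_sites(codon):
    """Synonymous sites: per position, the fraction of the three possible
    changes that preserve the amino acid (changes to stops count as
    nonsynonymous)."""
    s = 0.0
    for pos in range(3):
        for nt in NTS:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if alt not in STOPS and _aa(alt) == _aa(codon):
                s += 1 / 3
    return s


def oracle_diffs(a, b):
    """Average (syn, nonsyn) difference counts over all minimal pathways,
    dropping pathways through stop codons (all pathways if none survive)."""
    positions = [i for i in range(3) if a[i] != b[i]]
    if not positions:
        return 0.0, 0.0
    all_paths, clean_paths = [], []
    for order in itertools.permutations(positions):
        cur, sd, nd, hit_stop = a, 0.0, 0.0, False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if nxt in STOPS:
                hit_stop = True
                nd += 1
            elif cur in STOPS or _aa(cur) != _aa(nxt):
                nd += 1
            else:
                sd += 1
            cur = nxt
        all_paths.append((sd, nd))
        if not hit_stop:
            clean_paths.append((sd, nd))
    use = clean_paths or all_paths
    return (sum(p[0] for p in use) / len(use),
            sum(p[1] for p in use) / len(use))


def oracle_dnds(a, b):
    S = sd = nd = 0.0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        S += 0.5 * (oracle_sites(ca) + oracle_sites(cb))
        d = oracle_diffs(ca, cb)
        sd += d[0]
        nd += d[1]
    N = len(a) - S
    pn, ps = nd / N, sd / S if S else 0.0
    return (-0.75 * math.log(1 - 4 * pn / 3),
            -0.75 * math.log(1 - 4 * ps / 3))


def random_codon_pair(rng):
    """A random sense-codon pair (all 0-3 positional differences occur)."""
    sense = [c for c in map("".join, itertools.product(NTS, repeat=3))
             if c not in STOPS]
    while True:
        a = sense[rng.integers(len(sense))]
        b = sense[rng.integers(len(sense))]
        return a, b


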