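# Methods

`hnsdiv` links the genome-wide binding of the bacterial nucleoid protein
H-NS to sequence diversification in *Escherichia coli*-like comparative
data.  The pipeline has five analysis stages — binding-region calling,
genome-segment accounting, feature classification, per-cluster diversity
estimation, and statistical contrasts (including a gene-tree congruence
experiment) — plus a synthetic-data generator that produces every input
the stages consume, so the whole pipeline is testable without external
data.  This note records the models, the parameters that matter, the
numerical choices, and what the synthetic data do and do not emulate.

## Binding-region calling

Inputs are per-nucleotide coverage tracks from an affinity pulldown
(ChAP) and a whole-cell-extract control (WCE).  Each track is divided by
its genome-wide median; the binding intensity is log10(ChAP/WCE) per
position.  Positions with zero coverage in either track have no usable
ratio: they are stored as a NO_SIGNAL sentinel (NaN), excluded from the
noise fit and never callable.  This resolves the ambiguity of assigning
such positions an intensity of "zero", which would collide with the
perfectly informative ratio of 1.

The intensity histogram is bimodal: a noise component around 0 and a
signal component extending upward.  The noise component is summarised as
a normal distribution whose mean is the density mode — located with a
binned Gaussian KDE (Silverman's bandwidth, argmax on a 512-point grid,
mirroring the defaults of standard density routines) — and whose sigma
defaults to the reference value 0.2.  The calling threshold is
mode + 3·sigma = mode + 0.6; sigma is deliberately *not* re-estimated
per track, matching the practice of carrying the reference threshold
into tracks where noise and signal overlap.  Bound regions are maximal
runs of positions strictly above the threshold and strictly longer than
200 bp ("greater than" in both cases, as printed); replicate calls are
intersected base-by-base with no post-intersection length filter.
Multiplying both raw tracks by a positive constant leaves calls
unchanged (the median normalisation cancels it).

Windowed track comparison (200-bp windows, 100-bp steps, Pearson
correlation of window means, NO_SIGNAL dropped) is provided for
replicate-quality assessment.

## Genome segments

Multi-genome alignment blocks are consumed as a coordinate table (one
block per row, per-strain chrom/start/end/strand; computing the
alignment itself is out of scope).  A block present in all strains is
"common", in a proper subset of at least two "shared", in one
"specific".  Per strain and class the pipeline reports the percentage of
base pairs covered by called regions; given the published per-class and
bound totals as inputs, this accounting reproduces the published
percentages exactly to one decimal.  Cross-strain sharing of bound bases
is computed by projecting regions into block-relative coordinates
(linear offset within a block, coordinate reflection on '-' strand
blocks, clipped to the shortest strain's block length); micro-indels
inside blocks are ignored, which is adequate at region (hundreds of bp)
granularity.

## Feature classification

A gene (ortholog cluster) is H-NS-bound when its coding span overlaps a
called region in at least one strain.  Two stricter policies are
implemented: `exclude_3prime_10pct` demotes genes whose merged overlap
is a single block that touches the 3' terminus and covers ≤10% of the
gene length (a windowed sub-policy instead requires every overlapped
base to lie in the 3'-terminal 10%); `transcription_unit` promotes every
gene whose transcription unit (user-supplied table) contains a bound
member.  Genes whose binding depends on a neighbouring strain-specific
insertion cannot be recomputed without the real genomes; they are
consumed as an exclusion list and forced unbound by default (or bound,
for the sensitivity variant).  The bound sets are monotone:
exclude ⊆ any-overlap ⊆ transcription-unit.

Lineage: a gene named in at least one horizontal-transfer prediction
list is an HTG; all others are Core.  Intergenic regions between two
convergent genes (tail-to-tail) are class I (non-regulatory); divergent
(head-to-head) and co-oriented (tail-to-head) regions are class II
(regulatory).  An intergenic region is HTG-intergenic only if both
flanks are HTGs, Core-intergenic only if both are Core, otherwise mixed
and excluded from the lineage contrast.

Conserved intergenic regions are gaps between neighbouring orthologous
genes that appear in the same order and orientation (up to whole-locus
inversion) in every strain, 10–300 bp long in every strain.  Taxonomic
conservation profiles average, per genome, the fraction of a gene class
present, then report mean and standard deviation (sample sd, n−1;
switchable) across the genomes of each taxon group.

## Diversity estimation

Per-cluster diversity is the arithmetic mean of all pairwise distances.

For codon clusters the pairwise estimator is a Nei–Gojobori-style
counting method: synonymous site counts per codon use the fraction of
single-nucleotide changes that preserve the amino acid (changes creating
stop codons count as nonsynonymous); per-codon differences are averaged
over all minimal mutational pathways with equal weights, dropping
pathways that pass through a stop codon and renormalising (all pathways
are used in the rare case that none survives); proportions on both site
classes are corrected with the one-parameter transform
d = −(3/4)·ln(1 − (4/3)p).  This is a deliberate substitution for the
ML codon-model estimation (codeml-style) that full-scale analyses of
this kind use — re-implementing ML codon models is out of scope — so
absolute values are not comparable to ML-based medians; the
reproduction checks therefore target estimator
self-consistency (agreement with a brute-force pathway-enumeration
oracle to 1e-10) and parameter recovery (simulated dN/dS recovered
within 25%), and the scientific claims rest on class *contrasts*, which
the counting method preserves.  Intergenic clusters use the p-distance
with the same correction.

Filters, applied in this order: codon clusters are excluded when any
member has a broken codon (length not a multiple of 3, or an internal
in-frame stop); intergenic clusters when the spread of ungapped lengths
reaches 10% of the aligned length (the alternative reading — spread
relative to the shorter sequence — is a flag); any pairwise proportion
≥ 3/4 excludes for saturation; any pairwise distance > 1.0 excludes the
cluster.  Gap columns are removed pairwise by default; a cluster-wide
complete-deletion mode supports the gap-free sensitivity analysis.
The >1.0 rule is applied in both modes, although at desk scales it can
only fire for intergenic clusters.

## Statistical layer

Unpaired two-sample comparisons: Wilcoxon rank-sum (exact enumeration
when the pooled sample has ≤12 tie-free values, otherwise the normal
approximation with tie and continuity corrections), classic
mean-centered Levene (Brown–Forsythe by flag), two-sided
Kolmogorov–Smirnov (asymptotic p), and Fisher's exact test for 2×2
tables.  Box summaries use linear-interpolation quartiles and whiskers
at the most extreme data points within 1.5 IQR of the box; with heavy
point masses the interpolated quartile can exceed the upper whisker — the
whisker is reported as observed, not clamped to the box.  Raw p-values
are reported to match the original analysis; Benjamini–Hochberg
adjustment is available but off by default.  `grouped_contrast` emits
the rank-sum and Levene results and box summaries per stratum.

## Gene-tree congruence experiment

Each gene tree is reduced to its nontrivial splits (bitmask
representation; two splits are compatible iff one of the four side
intersections is empty; trees with unequal leaf sets are compared on the
shared leaves, skipping comparisons with fewer than four).  The
experiment builds five sets: A (reference trees), B (focal trees),
C (|B| trees sampled from A without replacement), and D/E (B after
one/two random SPR moves per tree — prune edge uniform among eligible
edges, regraft uniform among edges not adjacent to the original
attachment, so a move always changes the unrooted topology).  Score
distributions of B, D and E are compared against C with the two-sided KS
test.

Three scores are implemented.  The per-tree minimal compatibility
(fraction of a tree's splits compatible with every split of one
reference, minimised over the reference set) and a strict pooled variant
follow the two literal readings of "minimal split compatibility against
a set"; both, however, take only a handful of distinct values at
desk-scale set sizes (~100 trees, 20 leaves), which makes null KS
p-values pile near 1 and ruins calibration.  The default experiment
scorer is therefore the pooled split-frequency score: for each split of
the tree, the occurrence-weighted fraction of reference splits it is
compatible with, minimised over the tree's splits.  Its null
distribution is nearly continuous; measured over 80 null replicates the
fraction of KS comparisons below 0.05 is 0.050 with near-uniform
p-values, while a single SPR move per tree is rejected at p < 0.001
essentially always.  All three scorers are selectable.

## Synthetic data

The generator's defaults are the study conditions.

Binding tracks: WCE coverage is Poisson with mean 300 (the scale implied
by 5–11 million 36-bp reads extended to 200 bp on a ~4.6–5 Mb
chromosome; the real depth distribution is not stated, so Poisson is the
minimal choice and the mean is config-exposed).  Each pulldown replicate
multiplies the expected depth by 10^ε, where ε is a stationary Gaussian
field with marginal sd `noise_sigma` = 0.2 — the sigma of the log-ratio
noise component that the 0.6 threshold is calibrated against — and a
~300 bp correlation length, and additionally by `signal_fold` (default
20) inside planted regions.  The correlation length matters: coverage
built from 200-bp extended fragments is strongly locally correlated, and
independent per-base noise would make 200-bp above-threshold runs
essentially impossible (0.9934²⁰⁰ ≈ 0.26) for any realistic enrichment.
Planted regions default to 50 non-overlapping intervals of 300–3000 bp
(called bound regions in real data average ~1.4–1.6 kb), at least 500 bp
apart.  What is *not* emulated: read-level artefacts (mappability,
duplicates, GC bias trends), chromosome circularity across the origin
(flag available), and strain-to-strain signal differences — so passing
recovery tests demonstrates the calling logic, not robustness to
mapping artefacts.

Sequence evolution: codon alignments evolve by per-branch nucleotide
proposals (Poisson count at `site_rate` per site per unit branch length,
K80-style kernel with `ts_tv`) with stop-codon rejection and acceptance
of nonsynonymous changes at relative probability ω (synonymous changes
are penalised instead when ω > 1).  This is a simplified
Goldman–Yang-like scheme, adequate for parameter-recovery testing but
not matching any named published model; the default `ts_tv` is 1.0 so
that the generator's substitution process matches the assumptions of the
one-parameter distance corrections used downstream (κ is exposed for
sensitivity work).  Intergenic alignments evolve under a Jukes–Cantor
process scaled by a per-cluster rate.  Trees are Yule topologies with
exponential branch lengths, leaves t1..tn; the default leaf count is 44
(the strain-panel size of the ortholog analysis).  Gene-tree sets for
the congruence experiment add Poisson(2) random NNI moves per tree as
topological estimation noise — enough to give compatibility scores a
spread-out null, little enough that one SPR move stands out.

Annotations: syntenic gene tables across three strains with per-cluster
strands, gap lengths drawn from 5–400 bp (covering both rejection sides
of the 10–300 bp window, re-drawn per strain with probability 0.3), a
5% strand-flip rate in one strain to exercise synteny rejection, HTG
labels at a 20% rate split across two overlapping prediction lists, and
bound-gene truth at 20% (519/2702 ≈ 19% in the real data) realised as
planted regions inside gene bodies.

The intergenic contrast experiment plants a 1.5× rate effect in 50
bound vs 400 unbound class II clusters of 100 bp at base diversity
0.005 on a shared 44-taxon tree normalised to unit mean pairwise
distance; all clusters share the tree, as real intergenics share the
strain phylogeny.

## Reproduction experiment sizes

The quantities recomputed by `scripts/acceptance.py` use: 1 Mb genomes
with 50 planted regions for recovery; 10,000 random codon pairs for the
oracle-equivalence check; 20 two-taxon replicates of 2,000 codons at
pairwise distance 0.1 for ω recovery; 20 effect and 200 null replicates
for the intergenic contrast; 20 experiment replicates and 100 null
seeds (100 gene trees of 20 leaves each) for the congruence experiment.
These sizes give stable desk-scale estimates: recovery and power sit
well inside their acceptance margins, and binomial noise on the
calibration fractions is 1–2 percentage points.

## Known limitations

* The counting-method dN/dS is biased relative to ML codon models at
  high divergence or strong codon bias; only contrasts and orderings
  should be compared with ML-based results.
* Cross-strain projection ignores micro-indels within alignment blocks.
* The KS test on compatibility scores remains slightly conservative for
  the two discrete scorer variants; the calibrated default should be
  used for inference.
* The synthetic noise field is stationary; real tracks have
  non-stationary coverage (replication-origin gradients, rRNA masking)
  that the caller has not been tested against.
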