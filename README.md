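# hnsdiv

Comparative-genomics toolkit linking the binding of the bacterial
nucleoid-structuring protein **H-NS** to sequence diversification.
H-NS silences AT-rich, horizontally transferred DNA (xenogeneic
silencing); comparing where H-NS binds across related *Escherichia
coli* strains with how fast those sequences evolve asks whether
H-NS-mediated repression frees bound regions — especially regulatory
regions upstream of genes — to accumulate substitutions.

The package implements that analysis end to end, for researchers who
have pulldown/control coverage tracks, genome-alignment block tables,
ortholog clusters and gene trees — or who want to study the pipeline's
behaviour on simulated data:

* **`hnsdiv.binding`** — region calling from paired ChAP/WCE coverage:
  median normalisation, per-nucleotide log₁₀(ChAP/WCE), a normal noise
  model fitted by kernel density estimation with calling threshold
  *mode + 3σ* (σ = 0.2 ⇒ offset 0.6), maximal runs > 200 bp, replicate
  intersection.
* **`hnsdiv.segments`** — common / shared / specific genome-segment
  classification from alignment blocks, per-class bound proportions,
  and cross-strain conservation of bound bases.
* **`hnsdiv.annotation`** — H-NS-bound gene policies, HTG vs Core
  lineage ("in ≥ 1 prediction list"), conserved intergenic extraction
  (10–300 bp, syntenic in all strains), class I / class II orientation,
  taxonomic conservation profiles.
* **`hnsdiv.diversity`** — per-cluster diversity as the mean of all
  pairwise distances: counting-method dN/dS (sites averaged over the
  two sequences, differences averaged over stop-free minimal mutational
  pathways, correction d = −(3/4)·ln(1 − (4/3)p)) and corrected
  nucleotide distances, with broken-codon, length-spread, saturation
  and > 1.0 exclusions.
* **`hnsdiv.stats`** — Wilcoxon rank-sum (exact for small tie-free
  samples), Levene, two-sided KS, Fisher's exact, box summaries, and
  stratified group contrasts.
* **`hnsdiv.treecompat`** — gene-tree split compatibility against a
  reference tree set, random SPR perturbations emulating horizontal
  transfer events, and the five-dataset KS experiment.
* **`hnsdiv.simulate`** — generators for every input above, with
  planted ground truth.

## Worked example

Simulate a 1 Mb chromosome with 50 planted H-NS-bound regions at
20-fold enrichment, call regions, and check recovery:

```python
from hnsdiv.simulate import SimConfig, simulate_binding_tracks
from hnsdiv.binding import (normalize_track, binding_intensity,
                            fit_noise_model, call_regions,
                            intersect_replicates)

cfg = SimConfig(genome_length=10**6, n_regions=50, signal_fold=20, seed=11)
chap1, chap2, wce, truth = simulate_binding_tracks(cfg)

wce_n = normalize_track(wce)
calls = []
for chap in (chap1, chap2):
    track = binding_intensity(normalize_track(chap), wce_n)
    model = fit_noise_model(track, sigma=0.2)
    print(f"mode={model.mode:+.4f}  threshold={model.threshold:.4f}")
    calls.append(call_regions(track, model, min_len=200))
merged = intersect_replicates(*calls)
print(f"{len(merged)} regions called, {merged.total_bp} bp "
      f"(planted: {truth.planted_regions['chr'].total_bp} bp)")
```

Output:

```
mode=-0.0319  threshold=0.5681
mode=-0.0124  threshold=0.5876
51 regions called, 89178 bp (planted: 89351 bp)
```

The fitted noise mode sits near 0 so the threshold is ≈ 0.6, and the
intersected replicate calls recover the planted ~89 kb of bound
sequence almost exactly — one planted region is split in two by a
noise dip, hence 51 calls for 50 planted regions.

The same pipeline is available from the shell:

```
hnsdiv simulate --out sim/ --seed 11
hnsdiv call --chap sim/chap_rep1.bedgraph --chap2 sim/chap_rep2.bedgraph \
            --wce sim/wce.bedgraph --out calls/
hnsdiv annotate --gff SE11=sim/genes_SE11.gff3 ... --out ann/
```

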