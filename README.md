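# tfea

Transcription-factor enrichment analysis for nascent-transcription (and
related) genomics data: infer consensus regions of interest (ROIs) from
multi-sample interval calls, rank them by differential signal, and test
each TF motif for positionally weighted enrichment along that ranking.

## Who this is for

Labs analyzing PRO-seq/GRO-seq (or ATAC/ChIP) experiments across
conditions who want to know *which transcription factors changed
activity*. The input is per-sample BED region calls plus a differential
table (e.g. DESeq2 output), genome FASTA and a motif database in MEME
minimal format; the output is one enrichment score and adjusted p-value
per motif.

## The two core methods

**Consensus ROI inference.** Each sample region, summarized by midpoint
μ_k and half-width σ_k, is modelled as a Gaussian density
φ((x − μ_k)/(ρσ_k)) for the position of the underlying locus (width ratio
ρ = 1 by default). Within a condition, replicate densities are
multiplied; across conditions the products are summed:

    P_joint(x) = Σ_i Π_j ( Σ_k p_ij^(k)(x) )

with samples lacking a region in a group contributing a uniform 1/Δ
factor. Local maxima of P_joint (top M+1, M the median region count per
sample) become ROI centers μ̂; widths are inverse-distance weighted means
of the contributing σ_k, and overlapping ROIs are shrunk symmetrically
until disjoint.

**Positionally weighted motif enrichment.** For each motif, the 3 kb
window around each ranked ROI center is scanned on both strands with a
log-odds PWM (pseudo-count 0.1, zero-order background averaged over all
ROIs, match threshold p < 1e-6 computed exactly by dynamic programming).
The distance d_i from the ROI center to its best hit (null if none within
1.5 kb) becomes a weight w_i = exp(−d_i/d̄), with the decay length d̄
calibrated on the interquartile-ranked ROIs. The enrichment score is
twice the integrated difference between the normalized running sum of
weights and the uniform background line,

    E = (2/N) Σ_i ( e(i) − (i+1)/N ),   E ∈ [−1, 1],

positive when hit-proximal ROIs concentrate at the top of the ranking.
Significance comes from 1000 random rank permutations (Z-score against
the fitted normal null, two-sided p, Bonferroni across motifs), after an
optional across-motif GC-content regression correction. Motif
displacement (MD/MDD) scores are included as rank-free baselines.

## Worked example

Fully synthetic, no downloads: simulate ranked 3 kb sequences with a
p53-like consensus embedded near the centers of the top-ranked 10% (sd
150 bp) and uniformly in 10% of the rest, then run the enrichment over a
20-motif panel:

```python
from tfea.simulate import embedding_benchmark

results, embedded = embedding_benchmark(seed=1)
print(results.head(3)[["motif", "e", "z", "p_adj", "n_hits", "d_bar"]])
```

```
                      motif         e          z         p_adj  n_hits       d_bar
0  TP53_consensus_synthetic  0.566660  19.827312  3.460883e-86     412  737.833333
1                     SYN12 -0.352923  -1.960493  9.987638e-01      14  807.375000
2                     SYN10  0.307695   1.891057  1.000000e+00      14  812.000000
```

The embedded motif has 412 of 2000 windows with a passing hit, a strongly
positive E-score (0.57) and an adjusted p-value ~1e-86; the 19 decoy
motifs only reach chance-level hit counts (~14 of 2000) and stay at
p_adj ≈ 1.

The same machinery runs from the shell on real files:

```bash
tfea run --design design.tsv --deseq results.tsv \
         --fasta genome.fa --motifs hocomoco.meme --out out/ --seed 1
```

writing `rois.bed`, `ranked.tsv`, `hits.tsv`, `enrichment.tsv` and run
metadata. `mumerge`, `tfea rank`, `tfea scan`, `tfea mdscore` and
`tfea simulate` expose the individual stages.

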