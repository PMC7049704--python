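# leakyscan

Start-codon context and leaky-scanning analysis for compact fungal genomes.

Many fungal transcripts carry AUG triplets in their transcript leader (TL, the
region 5' of the annotated start codon). Under the scanning model of
translation initiation, a pre-initiation complex walks the leader 5'→3' and
initiates at each start codon it meets with a probability that depends on the
codon's sequence (Kozak) context. Weak-context starts are "leaked" past,
routing ribosomes to upstream ORFs (which repress the main ORF and trigger
nonsense-mediated decay, NMD) or to downstream AUGs (which produce
N-terminally truncated isoforms, e.g. cytoplasmic versions of mitochondrial
proteins). `leakyscan` packages the genome-wide analysis that quantifies this:

- **Transcript-end annotation** from 5'-end (TSS-seq) and 3'-end (polyA-site)
  sequencing: replicate consensus, spike-in normalization, single-linkage
  clustering with a 50-nt maximum gap, the decap-ratio filter
  `R = (w_i/Σw) / (w_i^nodecap/Σw^nodecap) > 1` against a no-decap control,
  prominence filtering (≥10% of a gene's signal in ≥1 condition) and
  most-distal selection (`clustering`, `annotation`, `pipeline`).
- **Read-level filters**: TSS-seq tag/adapter trimming, polyA trimming and the
  internal-priming rule (keep a read iff it aligns after polyA trimming but
  not before) with a toy exact-match aligner (`preprocess`).
- **Kozak model**: position frequency matrix over −12..+14 built from the
  most highly translated genes (top 5%, capped at 400 above 8000 genes);
  scores over the wide (−10..−1) or narrow (−4..−1) window,
  `score = Σ f(pos, base) / Σ max_b f(pos, b)` ∈ (0, 1]; per-position Shannon
  information content and logo export (`kozak`).
- **Start-codon enumeration**: uAUGs (out-of-frame, or in-frame with an
  intervening stop), the annotated AUG, downstream AUGs (d1AUG), TSS-proximity
  classes (within/beyond 20 nt), near-cognate codons in strong context, and
  dual-localization candidates (d1AUG score > aAUG score + 0.1 in abundant
  mRNAs) (`scan`).
- **Translation quantification**: TPM, translation efficiency
  (TE = footprint/RNA TPM), A-site occupancy in the 10 codons downstream of a
  start, regression of relative occupancy on the Kozak-score difference,
  footprint 5'-end frame composition and periodicity QC (`quantify`).
- **Group statistics**: median-of-ratios normalization, wild-type vs
  NMD-deficient (upf1Δ) log2 fold changes, and one-sided two-sample
  Kolmogorov–Smirnov tests by uAUG count / proximity / score bin (`stats`).
- **A synthetic-data generator** (`simulate`) that emulates the whole study
  with known ground truth — planted TSS/PAS positions, uAUGs of controlled
  Kozak score, a logistic leaky-scanning initiation model
  `p(s) = 1/(1+exp(−slope·(s−midpoint)))`, 3-nt footprint periodicity, NMD
  fold changes — so every pipeline stage can be tested as a recovery problem
  (`evaluate`).

The package is a library: import it from Python, or start from the narrative
scripts in `examples/`.

## Worked example

`examples/04_leaky_scanning_fit.py` simulates 1500 genes, measures footprint
density in 10-codon windows downstream of each single-uAUG gene's u1AUG and
annotated AUG, and fits the initiation curve:

```
genes analysed (single uAUG, top 50% RNA abundance): 196
footprint log2-ratio ~ score-difference: slope 9.21, R^2 0.70, p 6.2e-53
RNA control:                             slope 0.15 +- 0.32 (z = 0.48)
recovered initiation curve: slope 7.35 (true 8.0), midpoint 0.613 (true 0.6)
```

The footprint ratio rises steeply with the uAUG−aAUG score difference while
the RNA-coverage control stays flat: ribosome allocation between competing
start codons tracks sequence context, and the fitted logistic recovers the
planted leak parameters within ~10%. The other examples cover transcript-end
annotation (`01`), the Kozak matrix and scoring (`02`), uAUG/dAUG enumeration
and dual-localization calls (`03`), TE/NMD group statistics (`05`) and read
preprocessing (`06`).

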