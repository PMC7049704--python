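"""Recover the leaky-scanning initiation curve from ribosome footprints.

Under sequential scanning, a pre-initiation complex initiates at each AUG
with probability p(s) = 1/(1 + exp(-slope*(s - midpoint))) of its Kozak
score s. The footprint density ratio between a gene's first uORF and its
main ORF is then p(u) / ((1-p(u)) p(a)); regressing observed log ratios on
the scores recovers the curve. RNA-seq coverage is the negative control:
uniform coverage carries no score signal.
"""

from leakyscan import SimConfig, evaluate, generate_expression, generate_genome

config = SimConfig(n_genes=1500, seed=42)
genome, genes, truth = generate_genome(config)
expr = generate_expression(truth, config)

result = evaluate.leak_recovery(truth, expr, config)
ribo, rna = result["ribo_fit"], result["rna_fit"]

print(f"genes analysed (single uAUG, top 50% RNA abundance): {result['n_genes']}")
print(f"footprint log2-ratio ~ score-difference: slope {ribo.slope:.2f}, "
      f"R^2 {ribo.r2:.2f}, p {ribo.pvalue:.1e}")
print(f"RNA control:                             slope {rna.slope:.2f} "
      f"+- {rna.stderr:.2f} (z = {result['rna_slope_z']:.2f})")
print(f"recovered initiation curve: slope {result['slope']:.2f} "
      f"(true {config.leak_slope}), midpoint {result['midpoint']:.3f} "
      f"(true {config.leak_midpoint})")
# A positive footprint slope with a flat RNA control shows ribosome
# allocation between the competing start codons tracks their sequence
# context, the footprint-level signature of leaky scanning.
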