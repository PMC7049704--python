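"""Read-level filters for 5'-end and polyA-site libraries.

TSS-seq reads must carry both the 5' tag (11 arbitrary nt + CGCCGCG + 3 nt)
and the 3' adapter; both are stripped. PolyA-site reads are trimmed of their
terminal A run and realigned: a read that already aligned *before* trimming
copied a genomic A stretch (internal priming) and is discarded.
"""

from leakyscan import SimConfig, generate_end_reads, generate_genome
from leakyscan.preprocess import (
    DEFAULT_ADAPTER,
    TaggedRead,
    filter_trim_tss,
    preprocess_pas_reads,
    trim_polya,
)

tagged = TaggedRead("r1", "ACGTACGTACG" + "CGCCGCG" + "TTT" + "GGCCAATTGGCC" + DEFAULT_ADAPTER)
untagged = TaggedRead("r2", "GGCCAATTGGCC" + DEFAULT_ADAPTER)
print(f"tagged read    -> insert {filter_trim_tss(tagged)!r}")
print(f"tag-less read  -> {filter_trim_tss(untagged)!r} (rejected)")

for seq in ("ACGTAAAAA", "ACGTA"):
    trimmed, n = trim_polya(seq)
    print(f"trim_polya({seq!r}) -> ({trimmed!r}, removed {n})")

# on a simulated polyA-site library with planted internal-priming artifacts
config = SimConfig(n_genes=80, seed=3)
genome, genes, truth = generate_genome(config)
reads = generate_end_reads(truth, genes, genome, config)
kept, tally = preprocess_pas_reads(reads.pas_reads, genome)
print(f"\npolyA-site library: {len(reads.pas_reads)} reads -> {tally}")
print(f"planted artifacts: {len(truth.pas_artifacts)}; "
      f"all rejected: {not any(r.id in truth.pas_artifacts for r, _ in kept)}")
# The rejected count equals the planted artifact count: with error-free
# reads the before/after-trimming alignment rule is an exact classifier.
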