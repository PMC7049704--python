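"""Read-level filters for 5'-end (TSS-seq) and 3'-end (polyA-site) libraries.

TSS-seq reads must carry both the library 5' tag (11 arbitrary nt, the
literal CGCCGCG, then 3 arbitrary nt) and the 3' sequencing adapter; both are
removed and reads lacking either are rejected. PolyA-site reads are trimmed
of their terminal A run, and reads whose untrimmed sequence already aligns to
the genome are discarded as internal-priming artifacts (their "tail" is
genomic, not added at polyadenylation).

Alignment here is a toy exact-substring mapper sufficient for synthetic
genomes; real data goes through a dedicated aligner upstream of this package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

#: the TSS-seq 3' adapter (oligo) and 5' tag pattern used by the library protocol
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAAC"
DEFAULT_TAG = "11NCGCCGCGNNN"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TaggedRead:
    id: str
    sequence: str
    qualities: str | None = None


def tag_pattern_to_regex(tag: str) -> re.Pattern:
    """Expand a tag spec like '11NCGCCGCGNNN' into an anchored regex.

    A digit run repeats the following character; N matches any base. The
    default expands to 11 wildcards + literal CGCCGCG + 3 wildcards.
    """
    if not tag:
        raise ValueError("empty tag pattern")
    out = []
    i = 0
    while i < len(tag):
        m = re.match(r"\d+", tag[i:])
        if m:
            count = int(m.group())
            i += m.end()
            if i >= len(tag):
                raise ValueError(f"tag pattern {tag!r} ends with a bare count")
            char = tag[i]
            i += 1
        else:
            count, char = 1, tag[i]
            i += 1
        if char.upper() == "N":
            out.append(f".{{{count}}}" if count > 1 else ".")
        elif char.upper() in "ACGT":
            out.append(char.upper() * count)
        else:
            raise ValueError(f"invalid character {char!r} in tag pattern")
    return re.compile("^" + "".join(out))


def _find_adapter(seq: str, adapter: str, min_overlap: int = 10) -> int | None:
    """Start of the adapter (full match anywhere, or a >=min_overlap prefix at the
    read 3' end); None if absent."""
    if min_overlap > len(adapter):
        raise ValueError("min_overlap exceeds adapter length")
    pos = seq.find(adapter)
    if pos != -1:
        return pos
    for k in range(len(adapter) - 1, min_overlap - 1, -1):
        if seq.endswith(adapter[:k]):
            return len(seq) - k
    return None


def filter_trim_tss(
    read: TaggedRead,
    adapter: str = DEFAULT_ADAPTER,
    tag_pattern: str = DEFAULT_TAG,
    min_adapter_overlap: int = 10,
) -> str | None:
    """Trim the 5' tag and 3' adapter from a TSS-seq read.

    Returns the insert sequence, or None if the read lacks either the tag at
    its 5' end or the adapter (rejection is a value, not an exception). No
    mismatches are tolerated in the tag literal or the adapter.
    """
    if not adapter:
        raise ValueError("empty adapter")
    pattern = tag_pattern_to_regex(tag_pattern)
    seq = read.sequence.upper()
    m = pattern.match(seq)
    if m is None:
        return None
    rest = seq[m.end():]
    apos = _find_adapter(rest, adapter.upper(), min_adapter_overlap)
    if apos is None:
        return None
    return rest[:apos]


def trim_polya(seq: str, min_run: int = 5) -> tuple[str, int]:
    """Remove the maximal terminal run of A when it is at least ``min_run`` long.

    Returns (trimmed sequence, number of bases removed); shorter runs leave
    the read unchanged. Idempotent only up to re-exposed upstream A runs,
    which is why the internal-priming filter realigns rather than re-trims.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    seq_u = seq.upper()
    n = len(seq_u) - len(seq_u.rstrip("A"))
    if n >= min_run:
        return seq[: len(seq) - n], n
    return seq, 0


@dataclass
class AlignResult:
    status: str  # unique | ambiguous | unmapped
    chrom: str | None = None
    start: int | None = None  # 0-based, half-open interval start on + strand
    strand: str | None = None


def _find_all(haystack: str, needle: str, limit: int = 2) -> list[int]:
    hits = []
    start = 0
    while len(hits) < limit:
        pos = haystack.find(needle, start)
        if pos == -1:
            break
        hits.append(pos)
        start = pos + 1
    return hits


def toy_align(seq: str, genome: dict[str, str]) -> AlignResult:
    """Exact-substring alignment against both strands of a genome.

    A unique hit returns its forward-strand interval start and the strand the
    read matches; multiple hits are 'ambiguous', none 'unmapped'. Minus-strand
    hits report coordinates of the forward-strand interval covered.
    """
    if not seq:
        return AlignResult("unmapped")
    seq = seq.upper()
    rc = revcomp(seq)
    hits: list[tuple[str, int, str]] = []
    for chrom, chrom_seq in genome.items():
        for pos in _find_all(chrom_seq, seq):
            hits.append((chrom, pos, "+"))
        if rc != seq:
            for pos in _find_all(chrom_seq, rc):
                hits.append((chrom, pos, "-"))
        else:  # palindromic read matches both strands at the same locus
            for pos in _find_all(chrom_seq, seq, limit=1):
                hits.append((chrom, pos, "-"))
        if len(hits) > 1:
            return AlignResult("ambiguous")
    if not hits:
        return AlignResult("unmapped")
    chrom, pos, strand = hits[0]
    return AlignResult("unique", chrom, pos, strand)


def internal_priming_filter(aligned_before_trim: bool, aligned_after_trim: bool) -> bool:
    """Keep a polyA-site read iff it aligns after polyA trimming but not before.

    Reads genomic before trimming carry a templated A stretch (internal
    priming on an A-rich region) rather than a true polyA tail.
    """
    return aligned_after_trim and not aligned_before_trim


def preprocess_pas_reads(
    reads: list[TaggedRead],
    genome: dict[str, str],
    min_run: int = 5,
) -> tuple[list[tuple[TaggedRead, AlignResult]], dict[str, int]]:
    """Trim and filter a batch of polyA-site reads against a genome.

    Returns kept (read, alignment-after-trimming) pairs plus a tally of
    rejection reasons.
    """
    kept = []
    tally = {"kept": 0, "internal_priming": 0, "unaligned": 0, "no_tail": 0}
    for read in reads:
        before = toy_align(read.sequence, genome).status == "unique"
        trimmed, n = trim_polya(read.sequence, min_run)
        if n == 0:
            tally["no_tail"] += 1
            continue
        aln = toy_align(trimmed, genome)
        after = aln.status == "unique"
        if not internal_priming_filter(before, after):
            tally["internal_priming" if before else "unaligned"] += 1
            continue
        kept.append((TaggedRead(read.id, trimmed, None), aln))
        tally["kept"] += 1
    return kept, tally
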