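"""Gene models, GFF3 round-tripping, transcript-end updates and sequence extraction.

A GeneModel is one representative transcript per gene: a transcript interval
[tx_start, tx_end), a CDS interval, optional intron(s) in the leader, and a
strand, all 0-based half-open on the genome. The transcript leader (TL) is
the spliced region 5' of the CDS; the 3'UTR the region 3' of it. GFF3 is
1-based inclusive at the I/O boundary only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    #: intron intervals (genomic, half-open), all within the transcript
    introns: tuple[tuple[int, int], ...] = ()
    provenance: str = "annotated"  # annotated | updated | retained | curation-flagged

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not (self.tx_start <= self.cds_start < self.cds_end <= self.tx_end):
            raise ValueError(f"{self.gene_id}: CDS not contained in transcript")

    @property
    def tss(self) -> int:
        """Genomic coordinate of the first transcribed base."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def pas(self) -> int:
        """Genomic coordinate of the last transcribed base (polyA site)."""
        return self.tx_end - 1 if self.strand == "+" else self.tx_start

    @property
    def exons(self) -> list[tuple[int, int]]:
        """Exon intervals in genomic order."""
        pieces = []
        pos = self.tx_start
        for istart, iend in sorted(self.introns):
            pieces.append((pos, istart))
            pos = iend
        pieces.append((pos, self.tx_end))
        return [(s, e) for s, e in pieces if e > s]

    def _spliced(self, genome: dict[str, str], lo: int, hi: int) -> str:
        seq = "".join(
            genome[self.chrom][max(s, lo):min(e, hi)]
            for s, e in self.exons
            if min(e, hi) > max(s, lo)
        )
        return _revcomp(seq) if self.strand == "-" else seq

    def tl_seq(self, genome: dict[str, str]) -> str:
        """Spliced transcript-leader sequence, 5'->3'."""
        if self.strand == "+":
            return self._spliced(genome, self.tx_start, self.cds_start)
        return self._spliced(genome, self.cds_end, self.tx_end)

    def cds_seq(self, genome: dict[str, str]) -> str:
        return self._spliced(genome, self.cds_start, self.cds_end)

    def utr3_seq(self, genome: dict[str, str]) -> str:
        if self.strand == "+":
            return self._spliced(genome, self.cds_end, self.tx_end)
        return self._spliced(genome, self.tx_start, self.cds_start)

    def transcript_seq(self, genome: dict[str, str]) -> str:
        return self._spliced(genome, self.tx_start, self.tx_end)

    @property
    def tl_len(self) -> int:
        raw = (self.cds_start - self.tx_start) if self.strand == "+" else (
            self.tx_end - self.cds_end
        )
        lo, hi = ((self.tx_start, self.cds_start) if self.strand == "+"
                  else (self.cds_end, self.tx_end))
        intronic = sum(
            max(0, min(e, hi) - max(s, lo)) for s, e in self.introns
        )
        return raw - intronic

    @property
    def cds_len(self) -> int:
        intronic = sum(
            max(0, min(e, self.cds_end) - max(s, self.cds_start))
            for s, e in self.introns
        )
        return self.cds_end - self.cds_start - intronic

    @property
    def utr3_len(self) -> int:
        return (self.tx_end - self.cds_end) if self.strand == "+" else (
            self.cds_start - self.tx_start
        )

    @property
    def gene_len(self) -> int:
        return self.tx_end - self.tx_start


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def genes_to_frame(genes: list[GeneModel]) -> pd.DataFrame:
    """Flat coordinate table (one row per gene) used by the clustering module."""
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "tx_start": [g.tx_start for g in genes],
            "tx_end": [g.tx_end for g in genes],
            "cds_start": [g.cds_start for g in genes],
            "cds_end": [g.cds_end for g in genes],
            "tss": [g.tss for g in genes],
            "pas": [g.pas for g in genes],
        }
    )


# ---------------------------------------------------------------------------
# FASTA / GFF3 I/O


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def write_gff3(genes: list[GeneModel], path) -> None:
    """Write gene/mRNA/exon/CDS/UTR features, 1-based inclusive coordinates."""
    def line(g, ftype, start, end, feature_id, parent=None):
        attrs = f"ID={feature_id}"
        if parent:
            attrs += f";Parent={parent}"
        if ftype == "gene":
            attrs += f";provenance={g.provenance}"
        return (
            f"{g.chrom}\tleakyscan\t{ftype}\t{start + 1}\t{end}\t.\t{g.strand}\t.\t{attrs}"
        )

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.tx_start)):
            gid = g.gene_id
            mrna = f"{gid}.t1"
            fh.write(line(g, "gene", g.tx_start, g.tx_end, gid) + "\n")
            fh.write(line(g, "mRNA", g.tx_start, g.tx_end, mrna, gid) + "\n")
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(line(g, "exon", s, e, f"{mrna}.exon{i}", mrna) + "\n")
            for i, (s, e) in enumerate(_clip_segments(g.exons, g.cds_start, g.cds_end), 1):
                fh.write(line(g, "CDS", s, e, f"{mrna}.cds{i}", mrna) + "\n")
            if g.strand == "+":
                utr5 = _clip_segments(g.exons, g.tx_start, g.cds_start)
                utr3 = _clip_segments(g.exons, g.cds_end, g.tx_end)
            else:
                utr5 = _clip_segments(g.exons, g.cds_end, g.tx_end)
                utr3 = _clip_segments(g.exons, g.tx_start, g.cds_start)
            for i, (s, e) in enumerate(utr5, 1):
                fh.write(line(g, "five_prime_UTR", s, e, f"{mrna}.utr5.{i}", mrna) + "\n")
            for i, (s, e) in enumerate(utr3, 1):
                fh.write(line(g, "three_prime_UTR", s, e, f"{mrna}.utr3.{i}", mrna) + "\n")


def _clip_segments(segments, lo, hi):
    return [(max(s, lo), min(e, hi)) for s, e in segments if min(e, hi) > max(s, lo)]


def read_gff3(path) -> list[GeneModel]:
    """Reconstruct GeneModels from a GFF3 file (inverse of write_gff3)."""
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            raise ValueError(f"gene {gene.id} has no mRNA feature")
        # representative transcript: longest CDS, ties by id
        def cds_span(m):
            return sum(c.end - c.start + 1 for c in db.children(m, featuretype="CDS"))
        mrna = sorted(mrnas, key=lambda m: (-cds_span(m), m.id))[0]
        exons = sorted(
            (e.start - 1, e.end) for e in db.children(mrna, featuretype="exon")
        )
        cds = sorted(
            (c.start - 1, c.end) for c in db.children(mrna, featuretype="CDS")
        )
        if not exons:
            exons = [(gene.start - 1, gene.end)]
        if not cds:
            raise ValueError(f"gene {gene.id} has no CDS")
        introns = tuple(
            (exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)
        )
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                tx_start=exons[0][0],
                tx_end=exons[-1][1],
                cds_start=cds[0][0],
                cds_end=cds[-1][1],
                introns=introns,
                provenance=gene.attributes.get("provenance", ["annotated"])[0],
            )
        )
    return genes


# ---------------------------------------------------------------------------
# End updates and statistics


def update_ends(
    genes: list[GeneModel],
    distal_tss: pd.Series | dict,
    distal_pas: pd.Series | dict,
    curation_threshold: int = 100,
) -> tuple[list[GeneModel], pd.DataFrame]:
    """Replace transcript ends with distal cluster peaks.

    Genes without a cluster keep their previous annotation ('retained').
    Changes larger than ``curation_threshold`` bp are applied but listed for
    manual curation. A proposed TSS (or PAS) inside the CDS flags the gene and
    leaves it unchanged.
    """
    distal_tss = dict(distal_tss)
    distal_pas = dict(distal_pas)
    updated: list[GeneModel] = []
    curation_rows = []
    for g in genes:
        new_tss = distal_tss.get(g.gene_id)
        new_pas = distal_pas.get(g.gene_id)
        if new_tss is None and new_pas is None:
            updated.append(replace(g, provenance="retained"))
            continue
        tss = g.tss if new_tss is None else new_tss
        pas = g.pas if new_pas is None else new_pas
        if g.strand == "+":
            tx_start, tx_end = tss, pas + 1
        else:
            tx_start, tx_end = pas, tss + 1
        bad_tss = not (
            (g.strand == "+" and tx_start < g.cds_start)
            or (g.strand == "-" and tx_end > g.cds_end)
        )
        bad_pas = not (
            (g.strand == "+" and tx_end > g.cds_end)
            or (g.strand == "-" and tx_start < g.cds_start)
        )
        if bad_tss or bad_pas:
            logger.warning("%s: proposed end inside CDS, gene flagged", g.gene_id)
            updated.append(replace(g, provenance="curation-flagged"))
            curation_rows.append((g.gene_id, "end-inside-CDS", 0, 0))
            continue
        tss_change = abs(tss - g.tss)
        pas_change = abs(pas - g.pas)
        introns = tuple(i for i in g.introns if tx_start <= i[0] and i[1] <= tx_end)
        new = replace(g, tx_start=tx_start, tx_end=tx_end, introns=introns,
                      provenance="updated")
        updated.append(new)
        if max(tss_change, pas_change) > curation_threshold:
            curation_rows.append((g.gene_id, "large-change", tss_change, pas_change))
    curation = pd.DataFrame(
        curation_rows, columns=["gene_id", "reason", "tss_change", "pas_change"]
    )
    return updated, curation


def transcript_stats(genes: list[GeneModel]) -> tuple[pd.DataFrame, dict]:
    """Per-gene TL/3'UTR/gene lengths and intron counts, plus medians and means."""
    per_gene = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "tl_len": [g.tl_len for g in genes],
            "utr3_len": [g.utr3_len for g in genes],
            "gene_len": [g.gene_len for g in genes],
            "n_introns": [len(g.introns) for g in genes],
            "intron_len_total": [sum(e - s for s, e in g.introns) for g in genes],
        }
    )
    summary = {}
    for col in ("tl_len", "utr3_len", "gene_len", "n_introns"):
        summary[f"median_{col}"] = float(per_gene[col].median())
        summary[f"mean_{col}"] = float(per_gene[col].mean())
    return per_gene, summary


def extract_sequences(genes: list[GeneModel], genome: dict[str, str]) -> pd.DataFrame:
    """Strand- and splice-aware TL/CDS/transcript sequences for every gene.

    Warns (not errors) about CDSs that do not look like complete ORFs, since
    updated ends never alter the CDS itself.
    """
    rows = []
    for g in genes:
        if g.chrom not in genome or g.tx_end > len(genome[g.chrom]) or g.tx_start < 0:
            raise ValueError(f"{g.gene_id}: coordinates outside chromosome bounds")
        cds = g.cds_seq(genome)
        if len(cds) % 3 != 0:
            logger.warning("%s: CDS length not a multiple of 3", g.gene_id)
        elif not cds.startswith("ATG") or cds[-3:] not in STOPS:
            logger.warning("%s: CDS lacks start and/or stop codon", g.gene_id)
        rows.append(
            {
                "gene_id": g.gene_id,
                "tl_seq": g.tl_seq(genome),
                "cds_seq": cds,
                "utr3_seq": g.utr3_seq(genome),
            }
        )
    return pd.DataFrame(rows)
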