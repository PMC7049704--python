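"""Plain-text writers/readers for the pipeline's tabular interchange formats.

bedGraph for per-position end counts (one file per strand/sample), FASTQ for
polyA-site reads, TSV for count tables, clusters and ground truth. FASTA and
GFF3 live in the annotation module.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .preprocess import TaggedRead


def write_bedgraph(positions: pd.DataFrame, path, strand: str | None = None) -> None:
    """Write chrom/pos/count rows as bedGraph (0-based half-open intervals)."""
    df = positions if strand is None else positions[positions["strand"] == strand]
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["pos"],
            "end": df["pos"] + 1,
            "count": df["count"] if "count" in df else df["weight"],
        }
    ).sort_values(["chrom", "start"])
    out.to_csv(path, sep="\t", header=False, index=False)


def read_site_tsv(path) -> pd.DataFrame:
    """Read a site-count TSV with columns chrom, pos, strand, count [, ...]."""
    return pd.read_csv(path, sep="\t")


def write_site_tsv(positions: pd.DataFrame, path) -> None:
    positions.to_csv(path, sep="\t", index=False)


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    """Long-form count table: gene_id, sample, count."""
    counts.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fastq(reads: list[TaggedRead], path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual = read.qualities or "I" * len(read.sequence)
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")


def read_fastq(path) -> list[TaggedRead]:
    reads = []
    with open(path) as fh:
        while True:
            header = fh.readline().strip()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            reads.append(TaggedRead(header.lstrip("@"), seq, qual))
    return reads


def write_clusters_bed(clusters: pd.DataFrame, path) -> None:
    """Clusters as BED6+: chrom start end name weight strand peak [R]."""
    df = clusters.copy()
    cols = {
        "chrom": df["chrom"],
        "start": df["start"],
        "end": df["end"],
        "name": df.get("gene_id", pd.Series(["."] * len(df))).fillna("."),
        "score": df["weight"].round(3),
        "strand": df["strand"],
        "peak": df["peak"],
    }
    if "R" in df:
        cols["R"] = df["R"].round(4)
    pd.DataFrame(cols).sort_values(["chrom", "start"]).to_csv(
        path, sep="\t", header=False, index=False
    )


def write_truth(truth, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    truth.sites.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    if truth.false_tss is not None:
        truth.false_tss.to_csv(outdir / "truth_false_tss.tsv", sep="\t", index=False)
    if truth.pas_artifacts:
        pd.Series(sorted(truth.pas_artifacts), name="read_id").to_csv(
            outdir / "truth_pas_artifacts.tsv", sep="\t", index=False
        )
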