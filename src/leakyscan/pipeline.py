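"""End-to-end orchestration: end-seq counts -> clusters -> updated annotation,
and annotation + expression -> start-site tables, occupancy windows and fits.

These wrappers chain the module-level operations in the order the analysis
uses them; every step is also callable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import clustering, kozak, quantify, scan
from .annotation import GeneModel, extract_sequences, genes_to_frame, update_ends


@dataclass
class EndAnnotationResult:
    genes: list[GeneModel]
    curation: pd.DataFrame
    tss_clusters: pd.DataFrame   # after decap + prominence, with gene_id
    pas_clusters: pd.DataFrame
    tss_clusters_all: pd.DataFrame  # consensus-level clusters with decap R


def _normalize_counts(df: pd.DataFrame, spike: pd.DataFrame, spike_reference: float):
    """Scale each (condition, replicate) sample by its spike-in factor."""
    spike_map = spike.set_index(["condition", "replicate"])["spike_count"]
    out = df.copy()
    key = pd.MultiIndex.from_frame(out[["condition", "replicate"]])
    factors = spike_reference / spike_map.loc[key].to_numpy()
    out["count"] = out["count"] * factors
    return out


def consensus_by_condition(
    counts: pd.DataFrame,
    n_replicates: int,
    spike: pd.DataFrame | None = None,
    spike_reference: float | None = None,
) -> pd.DataFrame:
    """Spike-normalize, then keep positions present in all replicates per condition.

    Returns one row per (chrom, pos, strand) with a weight column per
    condition (weight_<condition>) and their total in 'weight'.
    """
    df = counts
    if spike is not None:
        df = _normalize_counts(df, spike, spike_reference)
    pieces = []
    for cond, sub in df.groupby("condition"):
        cons = clustering.replicate_consensus(
            sub.rename(columns={})[["chrom", "pos", "strand", "replicate", "count"]],
            n_replicates,
        )
        pieces.append(cons.rename(columns={"weight": f"weight_{cond}"}))
    merged = pieces[0]
    for piece in pieces[1:]:
        merged = merged.merge(piece, on=["chrom", "pos", "strand"], how="outer")
    weight_cols = [c for c in merged.columns if c.startswith("weight_")]
    merged[weight_cols] = merged[weight_cols].fillna(0.0)
    merged["weight"] = merged[weight_cols].sum(axis=1)
    return merged


def recover_transcript_ends(
    genes: list[GeneModel],
    tss_counts: pd.DataFrame,
    nodecap_counts: pd.DataFrame,
    pas_counts: pd.DataFrame,
    n_replicates: int,
    spike: pd.DataFrame | None = None,
    spike_reference: float | None = None,
    max_gap: int = 50,
    prominence: float = 0.10,
    window: int = 1000,
) -> EndAnnotationResult:
    """The transcript-end annotation pipeline.

    TSS side: replicate consensus and spike normalization per condition,
    50-nt clustering, decap-ratio filter against the no-decap control,
    gene assignment, prominence filter, distal selection. PAS side is the
    same without the decap filter. Ends are then rewritten onto the gene
    models, flagging large changes for curation.
    """
    gene_table = genes_to_frame(genes)

    tss_positions = consensus_by_condition(tss_counts, n_replicates, spike, spike_reference)
    weight_cols = tuple(c for c in tss_positions.columns if c.startswith("weight_"))
    tss_clusters, _ = clustering.cluster_sites(
        tss_positions, max_gap, weight_cols=("weight", *weight_cols)
    )
    nd = nodecap_counts.copy()
    nd_clusters, _ = clustering.cluster_sites(nd.rename(columns={"count": "weight"}), max_gap)
    tss_clusters = clustering.decap_filter(tss_clusters, nd_clusters)
    kept = tss_clusters[tss_clusters["kept"]]
    kept = clustering.assign_to_genes(kept, gene_table, "tss", window)
    kept = clustering.prominence_filter(kept, prominence, weight_cols or ("weight",))
    distal_tss = clustering.select_distal(kept, gene_table, "tss")

    pas_positions = consensus_by_condition(pas_counts, n_replicates, spike, spike_reference)
    pas_weight_cols = tuple(c for c in pas_positions.columns if c.startswith("weight_"))
    pas_clusters, _ = clustering.cluster_sites(
        pas_positions, max_gap, weight_cols=("weight", *pas_weight_cols)
    )
    pas_assigned = clustering.assign_to_genes(pas_clusters, gene_table, "pas", window)
    pas_kept = clustering.prominence_filter(
        pas_assigned, prominence, pas_weight_cols or ("weight",)
    )
    distal_pas = clustering.select_distal(pas_kept, gene_table, "pas")

    updated, curation = update_ends(genes, distal_tss, distal_pas)
    return EndAnnotationResult(updated, curation, kept, pas_kept, tss_clusters)


def scan_annotation(
    genes: list[GeneModel],
    genome: dict[str, str],
    model: kozak.KozakModel | None = None,
) -> pd.DataFrame:
    """Kozak-scored start-site table (uAUG/aAUG/dAUG) for every gene."""
    seqs = extract_sequences(genes, genome)
    all_sites = []
    for row in seqs.itertuples():
        all_sites.extend(scan.scan_gene(row.tl_seq, row.cds_seq, row.gene_id, model))
    return scan.sites_to_frame(all_sites)


def gene_site_summary(sites: pd.DataFrame, proximity_threshold: int = 20) -> pd.DataFrame:
    """Per-gene uAUG count, TSS-proximity class and u1AUG score."""
    rows = []
    for gene_id, sub in sites.groupby("gene_id"):
        u = sub[sub["cls"] == "uAUG"].sort_values("transcript_pos")
        rows.append(
            dict(
                gene_id=gene_id,
                n_uaug=len(u),
                proximity_class=scan.classify_tss_proximity(
                    u["dist_from_tss"], proximity_threshold
                ),
                u1_score=(u["wide_score"].iloc[0] if len(u) else np.nan),
                u1_pos=(int(u["transcript_pos"].iloc[0]) if len(u) else -1),
            )
        )
    return pd.DataFrame(rows)


def occupancy_windows(
    sites: pd.DataFrame,
    ribo_sites: pd.DataFrame,
    rna_sites: pd.DataFrame,
    transcript_lengths: pd.Series,
    anchors: tuple[str, str] = ("u1", "a"),
    n_codons: int = 10,
    asite_offset: int = quantify.DEFAULT_ASITE_OFFSET,
) -> pd.DataFrame:
    """Per-gene A-site window counts around two anchor start codons.

    ``anchors`` picks the two site ranks compared (("u1", "a") for the
    uORF-vs-main contrast, ("d1", "a") for downstream starts). Returns one
    row per gene having both anchors, with summed footprint and RNA 5'-end
    window counts and the wide-score difference dscore = score(first) -
    score(second).
    """
    first, second = anchors
    pivot = sites[sites["rank"].isin([first, second])].pivot_table(
        index="gene_id", columns="rank", values=["transcript_pos", "wide_score"],
        aggfunc="first",
    )
    pivot = pivot.dropna()
    ribo_by_gene = dict(tuple(ribo_sites.groupby("gene_id")))
    rna_by_gene = dict(tuple(rna_sites.groupby("gene_id")))
    rows = []
    for gene_id, row in pivot.iterrows():
        tx_len = int(transcript_lengths.get(gene_id, 0))
        if tx_len == 0:
            continue
        pos_f = int(row[("transcript_pos", first)])
        pos_s = int(row[("transcript_pos", second)])
        ribo = ribo_by_gene.get(gene_id)
        rna = rna_by_gene.get(gene_id)
        ribo_prof = (
            quantify.asite_profile(ribo, tx_len, default_offset=asite_offset)
            if ribo is not None else np.zeros(tx_len)
        )
        rna_prof = (
            quantify.asite_profile(rna, tx_len, default_offset=0)
            if rna is not None else np.zeros(tx_len)
        )
        span = 3 * n_codons
        rows.append(
            dict(
                gene_id=gene_id,
                dscore=row[("wide_score", first)] - row[("wide_score", second)],
                score_first=row[("wide_score", first)],
                score_second=row[("wide_score", second)],
                ribo_u=quantify.window_density(ribo_prof, pos_f, n_codons) * span,
                ribo_a=quantify.window_density(ribo_prof, pos_s, n_codons) * span,
                rna_u=quantify.window_density(rna_prof, pos_f, n_codons) * span,
                rna_a=quantify.window_density(rna_prof, pos_s, n_codons) * span,
            )
        )
    return pd.DataFrame(rows)


def expression_table(counts: pd.DataFrame, lengths: pd.Series,
                     ribo_prefix: str = "ribo_wt", rna_prefix: str = "rna_wt",
                     min_rna_tpm: float = 1.0) -> pd.DataFrame:
    """Per-gene footprint/RNA TPM (replicate-summed counts) and TE."""
    wide = counts.pivot_table(index="gene_id", columns="sample", values="count",
                              aggfunc="sum")
    ribo = wide[[c for c in wide.columns if c.startswith(ribo_prefix)]].sum(axis=1)
    rna = wide[[c for c in wide.columns if c.startswith(rna_prefix)]].sum(axis=1)
    lens = lengths.loc[wide.index]
    records = pd.DataFrame(
        {
            "gene_id": wide.index,
            "ribo_tpm": quantify.tpm(ribo.to_numpy(), lens.to_numpy()),
            "rna_tpm": quantify.tpm(rna.to_numpy(), lens.to_numpy()),
        }
    ).reset_index(drop=True)
    return quantify.translation_efficiency(records, min_rna_tpm)
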