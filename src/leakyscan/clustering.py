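"""Transcript-end site clustering and filtering.

Per-position 5' (TSS) or 3' (polyA) end counts are reduced to clusters in
four steps: replicate consensus (a position must be seen in every replicate),
spike-in normalization across samples, single-linkage clustering with a
maximum intra-cluster gap (50 nt), and — for TSS data — the decap-ratio
filter against a no-decap control library:

    R = (w_i / sum w) / (w_nodecap_i / sum w_nodecap) > 1

keeps cluster i only when its share of the decapping-treated library strictly
exceeds its share of the control, the signature of a genuine capped 5' end.
Prominent clusters (>= 10% of a gene's normalized count in at least one
condition) are then reduced to the most distal one per gene, whose peak
becomes the annotated transcript end.

Coordinates are 0-based; cluster spans are half-open [start, end).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

POSITION_COLS = ["chrom", "pos", "strand"]


def replicate_consensus(
    positions: pd.DataFrame, n_replicates: int | None = None
) -> pd.DataFrame:
    """Keep positions observed (count > 0) in all replicates; sum their counts.

    ``positions`` is long-form with columns chrom, pos, strand, replicate,
    count. Returns chrom, pos, strand, weight. With one replicate this is an
    identity filter (zero-count rows aside).
    """
    df = positions[positions["count"] > 0]
    if n_replicates is None:
        n_replicates = df["replicate"].nunique()
    grouped = df.groupby(POSITION_COLS, sort=True).agg(
        n_reps=("replicate", "nunique"), weight=("count", "sum")
    )
    out = grouped[grouped["n_reps"] >= n_replicates].drop(columns="n_reps")
    return out.reset_index()


def spike_normalize(weights, spike_counts_sample: float, spike_counts_reference: float):
    """Scale a sample's weights by (reference spike total / sample spike total).

    Equal true spike input across samples makes this a depth correction: a
    sample sequenced twice as deep has twice the spike count and its weights
    are halved.
    """
    if spike_counts_sample <= 0 or spike_counts_reference <= 0:
        raise ValueError("spike totals must be positive")
    return weights * (spike_counts_reference / spike_counts_sample)


def cluster_sites(
    positions: pd.DataFrame,
    max_gap: int = 50,
    weight_cols: tuple[str, ...] = ("weight",),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-linkage chain positions into clusters per (chrom, strand).

    A new cluster starts when the gap between consecutive positions exceeds
    ``max_gap`` (a gap of exactly ``max_gap`` still joins). Returns
    (clusters, positions-with-cluster_id). Cluster weight columns are sums
    over members; the peak is the member position of maximal total weight
    (5'-most on ties, deterministically).
    """
    df = positions.sort_values(POSITION_COLS, kind="mergesort").reset_index(drop=True)
    if df.empty:
        clusters = pd.DataFrame(
            columns=["cluster_id", "chrom", "strand", "start", "end", "n_positions",
                     "peak", *weight_cols]
        )
        return clusters, df.assign(cluster_id=pd.Series(dtype=int))
    new_group = (
        (df["chrom"] != df["chrom"].shift())
        | (df["strand"] != df["strand"].shift())
        | ((df["pos"] - df["pos"].shift()) > max_gap)
    )
    df["cluster_id"] = new_group.cumsum() - 1

    total = df[list(weight_cols)].sum(axis=1)
    peak_idx = total.groupby(df["cluster_id"]).idxmax()
    agg = {col: (col, "sum") for col in weight_cols}
    clusters = df.groupby("cluster_id").agg(
        chrom=("chrom", "first"),
        strand=("strand", "first"),
        start=("pos", "min"),
        end=("pos", "max"),
        n_positions=("pos", "size"),
        **agg,
    )
    clusters["end"] += 1  # half-open span
    clusters["peak"] = df.loc[peak_idx, "pos"].to_numpy()
    return clusters.reset_index(), df


def _overlap_weights(clusters: pd.DataFrame, other: pd.DataFrame,
                     weight_col: str = "weight") -> np.ndarray:
    """Sum of ``other`` cluster weights span-overlapping each row of ``clusters``
    on the same chrom and strand."""
    out = np.zeros(len(clusters))
    for key, sub in other.groupby(["chrom", "strand"]):
        mask = (clusters["chrom"] == key[0]) & (clusters["strand"] == key[1])
        if not mask.any():
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        weights = sub[weight_col].to_numpy()
        for i in clusters.index[mask]:
            s, e = clusters.at[i, "start"], clusters.at[i, "end"]
            hit = (starts < e) & (ends > s)
            out[clusters.index.get_loc(i)] = weights[hit].sum()
    return out


def decap_filter(
    clusters: pd.DataFrame,
    nodecap_clusters: pd.DataFrame,
    weight_col: str = "weight",
) -> pd.DataFrame:
    """Annotate TSS clusters with the decap ratio R and keep those with R > 1.

    Each cluster is matched to no-decap clusters by span overlap on the same
    strand (multiple overlaps summed). Clusters absent from the no-decap
    library are kept with R = inf: there is no evidence they are artifacts.
    Returns the input with columns R and kept.
    """
    clusters = clusters.copy()
    if nodecap_clusters.empty:
        logger.warning("empty no-decap cluster set: keeping all %d clusters", len(clusters))
        clusters["R"] = np.inf
        clusters["kept"] = True
        return clusters
    total = clusters[weight_col].sum()
    nd_total = nodecap_clusters[weight_col].sum()
    if total <= 0 or nd_total <= 0:
        raise ValueError("cluster weight totals must be positive")
    nd_weight = _overlap_weights(clusters, nodecap_clusters, weight_col)
    frac = clusters[weight_col].to_numpy() / total
    with np.errstate(divide="ignore"):
        clusters["R"] = np.where(nd_weight > 0, frac / (nd_weight / nd_total), np.inf)
    clusters["kept"] = clusters["R"] > 1
    return clusters


def assign_to_genes(
    clusters: pd.DataFrame,
    genes: pd.DataFrame,
    kind: str,
    window: int = 1000,
) -> pd.DataFrame:
    """Assign clusters to genes by peak position.

    A TSS cluster belongs to a gene when its peak lies in the window upstream
    of the CDS start (or in the annotated transcript leader); PAS clusters
    symmetrically downstream of the CDS end / in the 3'UTR. Peaks eligible for
    several genes go to the one with the nearest CDS start (resp. end).

    ``genes`` needs columns gene_id, chrom, strand, cds_start, cds_end,
    tx_start, tx_end (0-based, half-open).
    """
    if kind not in ("tss", "pas"):
        raise ValueError("kind must be 'tss' or 'pas'")
    clusters = clusters.copy()
    clusters["gene_id"] = None
    clusters["anchor_dist"] = np.inf
    for _, g in genes.iterrows():
        plus = g["strand"] == "+"
        # genomic window of eligible peaks: upstream of the CDS (or anywhere in
        # the annotated TL) for TSS, mirrored downstream / 3'UTR for PAS
        if (kind == "tss") == plus:
            anchor = g["cds_start"]
            lo = min(g["cds_start"] - window, g["tx_start"])
            hi = g["cds_start"]  # exclusive
        else:
            anchor = g["cds_end"]
            lo = g["cds_end"]
            hi = max(g["cds_end"] + window, g["tx_end"])
        mask = (
            (clusters["chrom"] == g["chrom"])
            & (clusters["strand"] == g["strand"])
            & (clusters["peak"] >= lo)
            & (clusters["peak"] < hi)
        )
        if not mask.any():
            continue
        dist = (clusters.loc[mask, "peak"] - anchor).abs()
        better = dist < clusters.loc[mask, "anchor_dist"]
        idx = dist.index[better]
        clusters.loc[idx, "gene_id"] = g["gene_id"]
        clusters.loc[idx, "anchor_dist"] = dist[better]
    return clusters.drop(columns="anchor_dist")


def prominence_filter(
    clusters: pd.DataFrame,
    threshold: float = 0.10,
    condition_cols: tuple[str, ...] = ("weight",),
) -> pd.DataFrame:
    """Keep clusters carrying >= ``threshold`` of their gene's weight in >= 1 condition.

    Clusters without a gene assignment are dropped; a gene whose total weight
    is zero in every condition keeps no clusters.
    """
    df = clusters[clusters["gene_id"].notna()].copy()
    if df.empty:
        return df
    keep = np.zeros(len(df), dtype=bool)
    for col in condition_cols:
        gene_total = df.groupby("gene_id")[col].transform("sum")
        with np.errstate(invalid="ignore"):
            frac = np.where(gene_total > 0, df[col] / gene_total, 0.0)
        keep |= frac >= threshold
    return df[keep]


def select_distal(clusters: pd.DataFrame, genes: pd.DataFrame, kind: str) -> pd.Series:
    """Per-gene transcript end: peak of the most distal prominent cluster.

    Distal means 5'-most relative to the gene's strand for TSS clusters and
    3'-most for PAS clusters. Returns a Series gene_id -> peak position.
    """
    if kind not in ("tss", "pas"):
        raise ValueError("kind must be 'tss' or 'pas'")
    strand = genes.set_index("gene_id")["strand"]
    out = {}
    for gene_id, sub in clusters[clusters["gene_id"].notna()].groupby("gene_id"):
        plus = strand.get(gene_id) == "+"
        upstream_most = (kind == "tss") == plus
        peak = sub["peak"].min() if upstream_most else sub["peak"].max()
        out[gene_id] = int(peak)
    return pd.Series(out, name="peak", dtype="int64")
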