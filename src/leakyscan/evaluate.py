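"""Recovery metrics against simulation ground truth.

Shared by the test suite and the acceptance script: how well the pipeline
recovers planted transcript ends, start sites, the Kozak matrix, the
leaky-scanning parameters and the footprint frame bias.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import kozak, pipeline, quantify, scan, stats
from .annotation import extract_sequences
from .simulate import GroundTruth, SimConfig, sample_context


def cluster_recovery(kept_clusters: pd.DataFrame, truth: GroundTruth,
                     tolerance: float) -> dict:
    """Precision/recall of recovered prominent TSS clusters against planted TSSs.

    A cluster is a true positive when its peak lies within ``tolerance`` nt of
    a planted TSS on the same chrom/strand; a planted TSS is recovered when
    some kept cluster peaks within tolerance of it.
    """
    g = truth.genes
    tp = 0
    for row in kept_clusters.itertuples():
        near = (
            (g["chrom"] == row.chrom)
            & (g["strand"] == row.strand)
            & ((g["tss"] - row.peak).abs() <= tolerance)
        )
        tp += int(near.any())
    recovered = 0
    for row in g.itertuples():
        near = (
            (kept_clusters["chrom"] == row.chrom)
            & (kept_clusters["strand"] == row.strand)
            & ((kept_clusters["peak"] - row.tss).abs() <= tolerance)
        )
        recovered += int(near.any())
    return {
        "precision": tp / max(1, len(kept_clusters)),
        "recall": recovered / len(g),
        "n_clusters": len(kept_clusters),
        "n_genes": len(g),
    }


def decap_effectiveness(all_clusters: pd.DataFrame, truth: GroundTruth,
                        tolerance: float) -> dict:
    """Among consensus-level clusters, how the decap-ratio filter treats the
    labelled false clusters versus the planted true ones."""
    def survey(centers: pd.DataFrame, pos_col: str, tol: float):
        reached = kept = 0
        for row in centers.itertuples():
            near = (
                (all_clusters["chrom"] == row.chrom)
                & (all_clusters["strand"] == row.strand)
                & ((all_clusters["peak"] - getattr(row, pos_col)).abs() <= tol)
            )
            if near.any():
                reached += 1
                kept += int(all_clusters.loc[near, "kept"].any())
        return reached, kept

    f_reached, f_kept = survey(truth.false_tss, "center", 12)
    t_reached, t_kept = survey(truth.genes, "tss", tolerance)
    return {
        "false_reaching_filter": f_reached,
        "false_removed_fraction": 1 - f_kept / max(1, f_reached),
        "true_reaching_filter": t_reached,
        "true_retained_fraction": t_kept / max(1, t_reached),
    }


def enumeration_discrepancies(genes, genome, truth: GroundTruth) -> int:
    """Genes whose scanned uAUG/dAUG sets differ from the planted ground truth."""
    seqs = extract_sequences(genes, genome)
    t = truth.sites
    bad = 0
    for row in seqs.itertuples():
        sub = t[t["gene_id"] == row.gene_id]
        u = [s.transcript_pos for s in scan.find_uaugs(row.tl_seq, row.cds_seq)]
        d = [s.transcript_pos
             for s in scan.find_daugs(row.cds_seq, tl_len=len(row.tl_seq))]
        if u != sub[sub["cls"] == "uAUG"]["transcript_pos"].tolist():
            bad += 1
        elif d != sub[sub["cls"] == "dAUG"]["transcript_pos"].tolist():
            bad += 1
    return bad


def pwm_recovery(truth_model: kozak.KozakModel, n_contexts: int,
                 rng: np.random.Generator) -> dict:
    """Estimation error of the frequency matrix rebuilt from sampled contexts."""
    contexts = [sample_context(truth_model, rng) for _ in range(n_contexts)]
    est = kozak.build_pwm(contexts)
    err = np.abs(est.freq - truth_model.freq)
    return {
        "mean_abs_error": float(err.mean()),
        "q95_abs_error": float(np.quantile(err, 0.95)),
        "max_abs_error": float(err.max()),
        "model": est,
    }


def leak_windows(truth: GroundTruth, expr) -> pd.DataFrame:
    """Occupancy windows for the u1AUG-vs-aAUG contrast, restricted as the
    analysis prescribes: single-uAUG genes in the top half by RNA abundance."""
    g = truth.genes.set_index("gene_id")
    tx_len = g["tx_end"] - g["tx_start"]
    n_uaug = truth.sites[truth.sites["cls"] == "uAUG"].groupby("gene_id").size()
    single = n_uaug[n_uaug == 1].index
    abundant = g.index[g["abundance"] >= g["abundance"].median()]
    eligible = single.intersection(abundant)
    sites = truth.sites[truth.sites["gene_id"].isin(eligible)]
    return pipeline.occupancy_windows(sites, expr.ribo_sites, expr.rna_sites, tx_len)


def leak_recovery(truth: GroundTruth, expr, config: SimConfig) -> dict:
    """Fit the leaky-scanning parameters from simulated relative occupancy."""
    windows = leak_windows(truth, expr)
    table, fit_ribo, fit_rna = quantify.relative_occupancy(windows)
    slope, midpoint = quantify.fit_leak_model(
        table["score_first"], table["score_second"], table["log2_ribo_ratio"]
    )
    return {
        "n_genes": len(table),
        "slope": slope,
        "midpoint": midpoint,
        "slope_rel_error": abs(slope - config.leak_slope) / config.leak_slope,
        "midpoint_rel_error": abs(midpoint - config.leak_midpoint) / config.leak_midpoint,
        "ribo_fit": fit_ribo,
        "rna_fit": fit_rna,
        "rna_slope_z": fit_rna.slope / fit_rna.stderr,
    }


def frame_recovery(truth: GroundTruth, expr, max_genes: int = 1000) -> dict:
    """Footprint 5'-end frame composition over unambiguous main-ORF regions.

    Uses genes without uAUGs, over the CDS region upstream of the first
    downstream AUG (capped at 16 codons), so every footprint in the region
    comes from ribosomes decoding frame 0 of the annotated ORF.
    """
    g = truth.genes.set_index("gene_id")
    sites = truth.sites
    aaug = sites[sites["cls"] == "aAUG"].set_index("gene_id")["transcript_pos"]
    d1 = sites[sites["rank"] == "d1"].set_index("gene_id")["transcript_pos"]
    clean = g.index[g["uorf_flux"] == 0]
    by_gene = dict(tuple(expr.ribo_sites.groupby("gene_id")))
    counts = np.zeros(3)
    for gene_id in clean[:max_genes]:
        reads = by_gene.get(gene_id)
        if reads is None:
            continue
        a = int(aaug[gene_id])
        lo = a + 3
        hi = min(a + 3 + 48, int(d1.get(gene_id, np.inf)))
        asite = reads["pos"] + quantify.DEFAULT_ASITE_OFFSET
        inside = reads[(asite >= lo) & (asite < hi)]
        if inside.empty:
            continue
        fracs, totals = quantify.frame_composition(
            inside["pos"].to_numpy(), a - quantify.DEFAULT_ASITE_OFFSET,
            inside["count"].to_numpy(),
        )
        counts += totals
    fractions = counts / counts.sum()
    return {"fractions": fractions, "counts": counts, "n_reads": int(counts.sum())}


def ks_type1_error(n_sims: int = 2000, sample_size: int = 40, alpha: float = 0.01,
                   seed: int = 0) -> dict:
    """Rejection rate of the one-sided KS test on null (identical) populations."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        pooled = rng.normal(size=2 * sample_size)
        _, p = stats.ks_one_sided(pooled[:sample_size], pooled[sample_size:],
                                  "y_greater", method="asymptotic")
        rejections += p < alpha
    return {"rate": rejections / n_sims, "n_sims": n_sims, "alpha": alpha}
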