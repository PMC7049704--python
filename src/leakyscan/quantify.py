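"""Translation quantification: TPM, translation efficiency, A-site occupancy
windows, relative occupancy vs Kozak-score difference, and footprint frame
composition.

Footprint 5' ends are assigned to ribosomal A-sites with a fixed offset
(default 15 nt for all read lengths, overridable per length). Occupancy
around a candidate start codon is measured over the 10 codons immediately
downstream of the codon, and the uAUG/aAUG (or d1AUG/aAUG) comparison is the
log ratio of those window densities — a within-transcript contrast that
cancels abundance and cap-recruitment differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

DEFAULT_ASITE_OFFSET = 15
DEFAULT_LENGTH_RANGE = (26, 34)


def tpm(counts, lengths) -> np.ndarray:
    """Transcripts per million: length-normalized rates scaled to sum 10^6."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("lengths must be positive")
    if counts.sum() == 0:
        raise ValueError("all counts are zero")
    rate = counts / lengths
    return 1e6 * rate / rate.sum()


def translation_efficiency(
    records: pd.DataFrame, min_rna_tpm: float = 1.0
) -> pd.DataFrame:
    """TE = footprint TPM / RNA TPM per gene; genes under the RNA floor get NaN.

    ``records`` needs columns gene_id, ribo_tpm, rna_tpm.
    """
    out = records.copy()
    ok = out["rna_tpm"] >= min_rna_tpm
    out["te"] = np.where(ok, out["ribo_tpm"] / out["rna_tpm"].where(ok), np.nan)
    return out


def asite_profile(
    reads: pd.DataFrame,
    transcript_len: int,
    offsets: dict[int, int] | None = None,
    default_offset: int | None = DEFAULT_ASITE_OFFSET,
) -> np.ndarray:
    """Per-nucleotide A-site density of footprint 5' ends on one transcript.

    ``reads`` has columns pos (5' end, transcript coords), length, count.
    Each read contributes its count at pos + offset(length); lengths missing
    from ``offsets`` fall back to ``default_offset`` or are dropped (logged).
    """
    profile = np.zeros(transcript_len)
    if reads.empty:
        return profile
    offsets = offsets or {}
    offs = reads["length"].map(offsets)
    if default_offset is not None:
        offs = offs.fillna(default_offset)
    dropped = int(reads.loc[offs.isna(), "count"].sum())
    if dropped:
        logger.info("dropped %d reads with unknown length offset", dropped)
    ok = offs.notna()
    asite = (reads.loc[ok, "pos"] + offs[ok]).to_numpy(dtype=int)
    counts = reads.loc[ok, "count"].to_numpy(dtype=float)
    inside = (asite >= 0) & (asite < transcript_len)
    np.add.at(profile, asite[inside], counts[inside])
    return profile


def window_density(
    profile: np.ndarray, anchor: int, n_codons: int = 10
) -> float:
    """Mean density over the ``n_codons`` codons after the anchor codon.

    The window starts at the codon following the anchor AUG (anchor + 3) and
    spans 3 * n_codons nt, clipped at the transcript end.
    """
    start = anchor + 3
    end = min(start + 3 * n_codons, len(profile))
    if end <= start:
        return 0.0
    return float(profile[start:end].sum()) / (end - start)


@dataclass
class FitResult:
    slope: float
    intercept: float
    r2: float
    pvalue: float
    stderr: float
    n: int


def relative_occupancy(
    windows: pd.DataFrame, pseudocount: float = 0.5
) -> tuple[pd.DataFrame, FitResult, FitResult]:
    """Regress relative start-codon occupancy on the Kozak-score difference.

    ``windows`` has per-gene columns dscore (score(u1) - score(a), or
    d1 - a), ribo_u, ribo_a, rna_u, rna_a: summed window counts for the two
    anchors. Returns the augmented table and least-squares fits of the
    footprint and RNA log2 ratios on dscore (slope, R^2 and the two-sided
    t-test p of the slope). The RNA fit is the negative control: uniform
    coverage is score-independent.
    """
    df = windows.copy()
    if len(df) < 3:
        raise ValueError("need at least 3 genes to fit")
    if np.isclose(df["dscore"].std(ddof=0), 0):
        raise ValueError("degenerate design: score difference is constant")
    for kind in ("ribo", "rna"):
        df[f"log2_{kind}_ratio"] = np.log2(
            (df[f"{kind}_u"] + pseudocount) / (df[f"{kind}_a"] + pseudocount)
        )

    def fit(col):
        res = stats.linregress(df["dscore"], df[col])
        return FitResult(res.slope, res.intercept, res.rvalue**2, res.pvalue,
                         res.stderr, len(df))

    return df, fit("log2_ribo_ratio"), fit("log2_rna_ratio")


def fit_leak_model(
    score_u: np.ndarray,
    score_a: np.ndarray,
    log2_ratio: np.ndarray,
    p0: tuple[float, float] = (5.0, 0.5),
) -> tuple[float, float]:
    """Recover leaky-scanning parameters from relative occupancy.

    Under sequential scanning with initiation probability
    p(s) = 1 / (1 + exp(-slope * (s - midpoint))), the expected footprint
    ratio between a transcript's first uORF window and its main-ORF window is
    p(s_u) / ((1 - p(s_u)) * p(s_a)). Least-squares on log2 of that ratio
    against the observed log2 window ratios estimates (slope, midpoint).
    """
    score_u = np.asarray(score_u, float)
    score_a = np.asarray(score_a, float)

    def model(X, slope, mid):
        su, sa = X
        pu = 1.0 / (1.0 + np.exp(-slope * (su - mid)))
        pa = 1.0 / (1.0 + np.exp(-slope * (sa - mid)))
        ratio = pu / np.clip((1.0 - pu) * pa, 1e-12, None)
        return np.log2(ratio)

    popt, _ = optimize.curve_fit(
        model,
        (score_u, score_a),
        np.asarray(log2_ratio, float),
        p0=p0,
        bounds=([0.1, 0.0], [100.0, 1.5]),
        maxfev=10000,
    )
    return float(popt[0]), float(popt[1])


def frame_composition(
    positions, anchor: int, counts=None
) -> tuple[np.ndarray, np.ndarray]:
    """Fractions of footprint 5' ends in frames 0/+1/+2 relative to an anchor.

    ``anchor`` is any frame-0 transcript position (e.g. where a 5' end of a
    frame-0-decoding footprint would fall). Returns (fractions, counts).
    """
    positions = np.asarray(positions, dtype=int)
    if positions.size == 0:
        raise ValueError("no footprint 5' ends in region")
    counts = (np.ones(positions.size) if counts is None
              else np.asarray(counts, dtype=float))
    frames = (positions - anchor) % 3
    totals = np.array([counts[frames == f].sum() for f in range(3)])
    return totals / totals.sum(), totals


def periodicity_qc(
    reads: pd.DataFrame,
    anchor: int = 0,
    min_modal_frame_fraction: float = 0.5,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
) -> dict:
    """Sample-level 3-nt periodicity and read-length QC.

    ``reads`` has columns pos, length, count with positions in a frame-0
    anchored coordinate system (e.g. CDS-relative, pooled over ORFs).
    Flags the sample when the modal frame holds < 50% of reads or the modal
    read length falls outside the expected range.
    """
    fractions, totals = frame_composition(
        reads["pos"].to_numpy(), anchor, reads["count"].to_numpy()
    )
    length_hist = reads.groupby("length")["count"].sum().sort_index()
    modal_length = int(length_hist.idxmax())
    modal_frame_fraction = float(fractions.max())
    return {
        "frame_fractions": fractions,
        "frame_counts": totals,
        "length_hist": length_hist,
        "modal_length": modal_length,
        "modal_frame_fraction": modal_frame_fraction,
        "length_in_range": length_range[0] <= modal_length <= length_range[1],
        "pass": (
            modal_frame_fraction >= min_modal_frame_fraction
            and length_range[0] <= modal_length <= length_range[1]
        ),
    }
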