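"""Start-codon candidate enumeration and classification.

Enumerates AUGs in the transcript leader (uAUGs), the annotated AUG (aAUG)
and downstream AUGs within the CDS (dAUGs, d1 = first), classifies genes by
uAUG proximity to the TSS, scans for strong-context near-cognate codons, and
calls dual-localization candidates from aAUG/d1AUG score differences.

A transcript-leader AUG counts as a uAUG only if it cannot extend the main
protein: it must be out of frame with the annotated start, or in frame with
an intervening stop codon. In-frame stop-free AUGs are N-terminal extensions
and are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import kozak

STOPS = {"TAA", "TAG", "TGA"}
#: the nine codons one substitution away from ATG
NEAR_COGNATES = {
    "TTG", "CTG", "GTG",  # first position
    "AAG", "ACG", "AGG",  # second position
    "ATA", "ATC", "ATT",  # third position
}
_VALID = set("ACGTN")


@dataclass
class StartSite:
    """One candidate start codon on a transcript."""

    gene_id: str
    transcript_pos: int          # 0-based offset of the first base of the codon
    codon: str
    cls: str                     # uAUG | aAUG | dAUG | near-cognate
    frame_rel_aaug: int          # 0, 1 or 2
    dist_from_tss: int
    in_frame_stop_before_aaug: bool | None = None  # uAUG only
    stop_transcript_pos: int | None = None         # first in-frame stop (ORF end)
    wide_score: float | None = None
    narrow_score: float | None = None
    rank: str = ""               # u1, u2, ... / d1, d2, ...


def _check_alphabet(seq: str, what: str) -> None:
    bad = set(seq.upper()) - _VALID
    if bad:
        raise ValueError(f"{what} contains non-ACGTN characters: {sorted(bad)}")


def first_inframe_stop(seq: str, start: int) -> int | None:
    """Position of the first stop codon in frame with ``start``, or None."""
    for j in range(start, len(seq) - 2, 3):
        if seq[j:j + 3] in STOPS:
            return j
    return None


def find_uaugs(tl_seq: str, cds_seq: str, gene_id: str = "") -> list[StartSite]:
    """Enumerate uAUGs in a transcript leader.

    ``tl_seq`` must be immediately 5'-adjacent to ``cds_seq`` in spliced
    transcript coordinates. Out-of-frame uORFs without a leader stop extend
    into the CDS and are retained, with their stop position recorded (possibly
    None if no stop before the transcript runs out).
    """
    _check_alphabet(tl_seq, "tl_seq")
    _check_alphabet(cds_seq, "cds_seq")
    tl_seq = tl_seq.upper()
    transcript = tl_seq + cds_seq.upper()
    tl_len = len(tl_seq)
    sites: list[StartSite] = []
    for i in range(tl_len - 2 + 1):
        if tl_seq[i:i + 3] != "ATG":
            # AUGs overlapping the TL/CDS junction cannot exist upstream of
            # the aAUG: the CDS starts with ATG, so only full-TL triplets count
            continue
        dist = tl_len - i
        frame = (i - tl_len) % 3
        if frame == 0:
            stop_in_tl = first_inframe_stop(tl_seq[:tl_len], i + 3)
            if stop_in_tl is None:
                continue  # in-frame N-terminal extension, not a uAUG
            stop_pos = stop_in_tl
            has_stop = True
        else:
            stop_pos = first_inframe_stop(transcript, i + 3)
            has_stop = None  # frame-based inclusion; flag is for in-frame only
        sites.append(
            StartSite(
                gene_id=gene_id,
                transcript_pos=i,
                codon="ATG",
                cls="uAUG",
                frame_rel_aaug=frame,
                dist_from_tss=i,
                in_frame_stop_before_aaug=has_stop if frame == 0 else False,
                stop_transcript_pos=stop_pos,
            )
        )
    for rank, site in enumerate(sites, start=1):
        site.rank = f"u{rank}"
    return sites


def find_daugs(cds_seq: str, gene_id: str = "", tl_len: int = 0) -> list[StartSite]:
    """Enumerate AUGs strictly downstream of the annotated start, within the CDS.

    The first one (smallest offset) is the d1AUG. Frame is the offset mod 3
    relative to the annotated reading frame.
    """
    _check_alphabet(cds_seq, "cds_seq")
    cds_seq = cds_seq.upper()
    sites = []
    for j in range(1, len(cds_seq) - 2):
        if cds_seq[j:j + 3] == "ATG":
            sites.append(
                StartSite(
                    gene_id=gene_id,
                    transcript_pos=tl_len + j,
                    codon="ATG",
                    cls="dAUG",
                    frame_rel_aaug=j % 3,
                    dist_from_tss=tl_len + j,
                    stop_transcript_pos=(
                        s + tl_len
                        if (s := first_inframe_stop(cds_seq, j + 3)) is not None
                        else None
                    ),
                )
            )
    for rank, site in enumerate(sites, start=1):
        site.rank = f"d{rank}"
    return sites


def annotated_site(tl_seq: str, cds_seq: str, gene_id: str = "") -> StartSite:
    """The annotated start codon as a StartSite (frame 0, at the TL/CDS junction)."""
    return StartSite(
        gene_id=gene_id,
        transcript_pos=len(tl_seq),
        codon=cds_seq[:3].upper(),
        cls="aAUG",
        frame_rel_aaug=0,
        dist_from_tss=len(tl_seq),
        rank="a",
    )


def scan_gene(tl_seq: str, cds_seq: str, gene_id: str = "",
              model: kozak.KozakModel | None = None) -> list[StartSite]:
    """All uAUGs, the aAUG and all dAUGs of one gene, optionally Kozak-scored."""
    sites = (
        find_uaugs(tl_seq, cds_seq, gene_id)
        + [annotated_site(tl_seq, cds_seq, gene_id)]
        + find_daugs(cds_seq, gene_id, tl_len=len(tl_seq))
    )
    if model is not None:
        transcript = (tl_seq + cds_seq).upper()
        for site in sites:
            site.wide_score = kozak.score_at(transcript, site.transcript_pos, model, "wide")
            site.narrow_score = kozak.score_at(transcript, site.transcript_pos, model, "narrow")
    return sites


def sites_to_frame(sites: list[StartSite]) -> pd.DataFrame:
    df = pd.DataFrame([vars(s) for s in sites])
    if df.empty:
        df = pd.DataFrame(
            columns=["gene_id", "transcript_pos", "codon", "cls", "frame_rel_aaug",
                     "dist_from_tss", "in_frame_stop_before_aaug",
                     "stop_transcript_pos", "wide_score", "narrow_score", "rank"]
        )
    return df


def classify_tss_proximity(uaug_distances, threshold: int = 20) -> str:
    """Per-gene uAUG proximity class.

    'none' without uAUGs; '1+ far' if at least one uAUG lies more than
    ``threshold`` nt from the TSS; '1+ close' if all uAUGs are within it.
    Distances are TSS to the A of the codon.
    """
    distances = list(uaug_distances)
    if not distances:
        return "none"
    if any(d > threshold for d in distances):
        return "1+ far"
    return "1+ close"


def near_cognate_scan(
    seq: str,
    model: kozak.KozakModel,
    min_wide_score: float = 0.9,
    gene_id: str = "",
    tl_len: int | None = None,
) -> list[StartSite]:
    """Find near-cognate codons (one substitution from ATG) in strong context.

    ``seq`` is the transcript region to scan (typically TL plus the CDS 5'
    region). The wide score is computed on the same -10..-1 window as for
    AUGs; the anchor codon itself is outside the window and ignored.
    """
    _check_alphabet(seq, "seq")
    seq = seq.upper()
    aaug_pos = tl_len if tl_len is not None else len(seq)
    hits = []
    for i in range(len(seq) - 2):
        codon = seq[i:i + 3]
        if codon not in NEAR_COGNATES:
            continue
        score = kozak.score_at(seq, i, model, "wide")
        if score >= min_wide_score:
            hits.append(
                StartSite(
                    gene_id=gene_id,
                    transcript_pos=i,
                    codon=codon,
                    cls="near-cognate",
                    frame_rel_aaug=(i - aaug_pos) % 3,
                    dist_from_tss=i,
                    wide_score=score,
                )
            )
    return hits


def dual_localization_candidates(
    sites: pd.DataFrame,
    expression: pd.DataFrame,
    mts_table: pd.DataFrame | None = None,
    score_margin: float = 0.1,
    abundance_quantile: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genes whose first downstream AUG outscores the annotated start.

    Restricted to the top ``abundance_quantile`` of genes by RNA abundance,
    a gene is a candidate when wide(d1AUG) > wide(aAUG) + ``score_margin`` —
    the signature of leaky initiation producing an alternative, often
    N-terminally truncated, isoform. Candidates are labelled in-frame /
    out-of-frame and, when an MTS prediction table (gene_id, mts) for the
    inter-AUG peptide is supplied, MTS+/MTS-.

    Returns (candidate table, summary counts by frame [x MTS]).
    """
    aaug = sites[sites["cls"] == "aAUG"].set_index("gene_id")
    d1 = sites[(sites["cls"] == "dAUG") & (sites["rank"] == "d1")].set_index("gene_id")
    expr = expression.set_index("gene_id")
    cutoff = expr["rna_tpm"].quantile(1 - abundance_quantile)
    abundant = expr.index[expr["rna_tpm"] >= cutoff]

    shared = d1.index.intersection(aaug.index).intersection(abundant)
    table = pd.DataFrame(
        {
            "gene_id": shared,
            "aaug_score": aaug.loc[shared, "wide_score"].to_numpy(),
            "d1aug_score": d1.loc[shared, "wide_score"].to_numpy(),
            "inter_aug_nt": (
                d1.loc[shared, "transcript_pos"] - aaug.loc[shared, "transcript_pos"]
            ).to_numpy(),
            "in_frame": (d1.loc[shared, "frame_rel_aaug"] == 0).to_numpy(),
        }
    )
    table = table[table["d1aug_score"] > table["aaug_score"] + score_margin]
    table = table.reset_index(drop=True)
    group_cols = ["in_frame"]
    if mts_table is not None:
        mts = mts_table.set_index("gene_id")["mts"]
        table["mts"] = table["gene_id"].map(mts).fillna(False).astype(bool)
        group_cols.append("mts")
    summary = (
        table.groupby(group_cols, as_index=False).size().rename(columns={"size": "n"})
    )
    return table, summary
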