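"""Kozak-context position frequency matrix: construction, scoring, information content.

The model is a base x position frequency matrix anchored at the A of the start
codon, spanning positions -12..+14 in transcript coordinates (27 columns).
Scoring uses only the upstream window: "wide" = -10..-1, "narrow" = -4..-1;
the AUG itself is fixed and the downstream context carries too little signal
to be informative, so neither contributes to the score.

A context's score is the sum of its per-position frequencies divided by the
sum of the per-position column maxima, which maps the column-consensus
sequence to exactly 1 and every other sequence into (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: positions covered by the matrix, relative to the A of AUG
OFFSETS = np.arange(-12, 15)
N_COLUMNS = 27
ANCHOR = 12  # column index of the A of AUG

#: column slices of the two scoring windows
WINDOWS = {
    "wide": slice(2, 12),    # -10..-1
    "narrow": slice(8, 12),  # -4..-1
}


@dataclass
class KozakModel:
    """Position frequency matrix over -12..+14 anchored at the A of AUG."""

    freq: np.ndarray  # shape (4, 27), columns sum to 1
    pseudocount: float = 1.0
    n_sequences: int = 0
    source: str = ""

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.shape != (4, N_COLUMNS):
            raise ValueError(f"freq must be 4x{N_COLUMNS}, got {self.freq.shape}")
        if not np.allclose(self.freq.sum(axis=0), 1.0, atol=1e-8):
            raise ValueError("matrix columns must sum to 1")
        if np.any(self.freq <= 0):
            raise ValueError("frequencies must be positive (use a pseudocount)")

    @property
    def consensus(self) -> str:
        """Column-consensus sequence over the full -12..+14 span."""
        return "".join(BASES[i] for i in self.freq.argmax(axis=0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.freq, index=list(BASES), columns=OFFSETS)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="base")

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "KozakModel":
        df = pd.read_csv(path, sep="\t", index_col="base")
        return cls(df.loc[list(BASES)].to_numpy(), **kwargs)


def _window_slice(window: str) -> slice:
    try:
        return WINDOWS[window]
    except KeyError:
        raise ValueError(f"unknown window {window!r}; expected one of {sorted(WINDOWS)}")


def select_hitrans(
    expression: pd.DataFrame,
    fraction: float = 0.05,
    cap: int = 400,
    cap_threshold: int = 8000,
    tpm_col: str = "ribo_tpm",
) -> list[str]:
    """Pick the most highly translated genes used to build the consensus matrix.

    Top ``fraction`` of genes by footprint TPM; genomes with more than
    ``cap_threshold`` annotated genes instead contribute their top ``cap``
    genes. Ties at the cutoff break by gene_id so the set is deterministic.
    """
    n = len(expression)
    if n == 0:
        raise ValueError("empty expression table")
    k = cap if n > cap_threshold else max(1, int(n * fraction))
    ordered = expression.sort_values(
        [tpm_col, "gene_id"], ascending=[False, True], kind="mergesort"
    )
    return ordered["gene_id"].head(k).tolist()


def build_pwm(contexts, pseudocount: float = 1.0, source: str = "") -> KozakModel:
    """Build the frequency matrix from AUG-aligned context sequences.

    All contexts must be 27 nt, aligned at the AUG (columns -12..+14).
    N bases are excluded from their column's counts; Laplace smoothing with
    ``pseudocount`` keeps every frequency positive.
    """
    contexts = list(contexts)
    if not contexts:
        raise ValueError("no context sequences supplied")
    counts = np.zeros((4, N_COLUMNS))
    for seq in contexts:
        if len(seq) != N_COLUMNS:
            raise ValueError(f"context length {len(seq)} != {N_COLUMNS}")
        for j, base in enumerate(seq.upper()):
            i = _BASE_INDEX.get(base)
            if i is not None:
                counts[i, j] += 1
    counts += pseudocount
    freq = counts / counts.sum(axis=0, keepdims=True)
    return KozakModel(freq, pseudocount=pseudocount, n_sequences=len(contexts), source=source)


def kozak_score(context: str, model: KozakModel, window: str = "wide") -> float:
    """Similarity of a context to the matrix over the chosen upstream window.

    score = sum_pos f(pos, base) / sum_pos max_b f(pos, b), so the consensus
    scores exactly 1.  N positions (transcript edge padding) contribute the
    column mean to both numerator and denominator, making them uninformative.
    """
    if len(context) != N_COLUMNS:
        raise ValueError(f"context must be the full {N_COLUMNS} nt window")
    sl = _window_slice(window)
    cols = range(sl.start, sl.stop)
    freq = model.freq
    colmax = freq.max(axis=0)
    colmean = freq.mean(axis=0)
    num = 0.0
    den = 0.0
    for j in cols:
        base = context[j].upper()
        i = _BASE_INDEX.get(base)
        if i is None:
            num += colmean[j]
            den += colmean[j]
        else:
            num += freq[i, j]
            den += colmax[j]
    return num / den


def kozak_score_logodds(context: str, model: KozakModel, window: str = "wide") -> float:
    """Alternative log-odds score (vs uniform background), for sensitivity checks.

    Not bounded in [0, 1]; N positions contribute 0.
    """
    if len(context) != N_COLUMNS:
        raise ValueError(f"context must be the full {N_COLUMNS} nt window")
    sl = _window_slice(window)
    total = 0.0
    for j in range(sl.start, sl.stop):
        i = _BASE_INDEX.get(context[j].upper())
        if i is not None:
            total += np.log2(model.freq[i, j] / 0.25)
    return total


def context_window(transcript: str, pos: int) -> str:
    """27-nt context for a codon whose first base sits at ``pos`` (transcript coords).

    Positions outside the transcript are padded with N; scoring treats N
    columns as uninformative.
    """
    left = pos - ANCHOR
    right = pos + (N_COLUMNS - ANCHOR)
    pre = "N" * max(0, -left)
    post = "N" * max(0, right - len(transcript))
    return pre + transcript[max(0, left):min(len(transcript), right)] + post


def score_at(transcript: str, pos: int, model: KozakModel, window: str = "wide") -> float:
    """Score the start-codon context at transcript position ``pos``."""
    return kozak_score(context_window(transcript, pos), model, window)


def information_content(model: KozakModel) -> np.ndarray:
    """Shannon information content per position, in bits: IC = 2 + sum_b f log2 f."""
    f = model.freq
    return 2.0 + (f * np.log2(f)).sum(axis=0)


def bits_per_base(model: KozakModel, window: str = "wide") -> float:
    """Mean information content (bits per base) over a scoring window."""
    sl = _window_slice(window)
    return float(information_content(model)[sl].mean())


def logo_matrix(model: KozakModel) -> pd.DataFrame:
    """IC-scaled letter heights: height(b, pos) = f(b, pos) * IC(pos).

    Heights at a position sum to that position's information content, the
    standard sequence-logo scaling.
    """
    ic = information_content(model)
    heights = model.freq * ic[np.newaxis, :]
    return pd.DataFrame(heights, index=list(BASES), columns=OFFSETS)
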