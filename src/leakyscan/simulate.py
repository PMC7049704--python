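"""Synthetic genomes, end-sequencing reads and expression counts with ground truth.

The generator emulates the statistical structure the analysis assumes, for a
compact fungal genome:

* single-exon genes with lognormal transcript-leader (TL), CDS and 3'UTR
  lengths (TL/3'UTR medians default to 105 and 127 nt);
* TLs carrying planted uAUGs — out of frame with the annotated start, or in
  frame with an intervening stop — whose sequence contexts are sampled from a
  ground-truth Kozak matrix at controlled score levels, with no other AUG
  anywhere in the leader;
* 5'-end (TSS-seq) reads clustered around each gene's true TSS in every
  replicate, a no-decap control library that captures true 5' ends only
  weakly, and false clusters (degradation products) enriched in the control
  and present in random replicate subsets;
* polyA-site reads with non-templated polyA tails, plus internal-priming
  artifacts whose "tails" copy a genomic A stretch;
* footprint and RNA counts following a sequential leaky-scanning model: a
  scanning pre-initiation complex initiates at each AUG it meets with
  probability p(s) = 1 / (1 + exp(-slope * (s - midpoint))) of its Kozak
  score s, so downstream starts receive only the flux that leaked past
  upstream ones. Footprint 5' ends carry a configurable 3-nt frame bias, and
  an upf1-null RNA sample inflates genes by an NMD fold-change that grows
  with their uORF initiation flux.

Everything is deterministic given (config, seed), and every planted feature
is recorded in a GroundTruth object for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kozak
from .annotation import GeneModel
from .preprocess import TaggedRead

SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
STOPS = {"TAA", "TAG", "TGA"}

# uORF block layout (see _build_tl): 12 nt upstream context, ATG, 12 nt
# downstream context (4 sense codons of the uORF), 6 more sense codons, then
# its TAA stop: a 10-codon uORF, long enough to fill an occupancy window
_UBLOCK = 48
_UORF_CODONS = [c for c in SENSE_CODONS if c != "ATG"]
_READ_LENGTHS = np.array([26, 27, 28, 29, 30])
_READ_LENGTH_P = np.array([0.08, 0.18, 0.44, 0.20, 0.10])


def default_kozak_truth() -> kozak.KozakModel:
    """A Cryptococcus-like ground-truth context matrix.

    A purine-rich -3..-1 with C enrichment at -1/-2/-5, a weaker C bias out
    to -10, an invariant AUG anchor and an uninformative downstream context.
    """
    freq = np.full((4, kozak.N_COLUMNS), 0.25)
    biased = {  # offset -> {base: freq}; leftovers split evenly
        -10: {"C": 0.35}, -9: {"C": 0.35}, -8: {"C": 0.40}, -7: {"C": 0.35},
        -6: {"C": 0.40}, -5: {"C": 0.50}, -4: {"A": 0.55},
        -3: {"A": 0.65, "G": 0.15}, -2: {"A": 0.45, "C": 0.30},
        -1: {"C": 0.50, "A": 0.30},
        0: {"A": 0.997}, 1: {"T": 0.997}, 2: {"G": 0.997},
    }
    for offset, spec in biased.items():
        col = offset + kozak.ANCHOR
        rest = (1.0 - sum(spec.values())) / (4 - len(spec))
        for i, base in enumerate(kozak.BASES):
            freq[i, col] = spec.get(base, rest)
    return kozak.KozakModel(freq, pseudocount=0.0 + 1e-9, n_sequences=0, source="truth")


@dataclass
class SimConfig:
    """Study conditions for the synthetic data. All rates are per nucleotide
    or per gene as noted; lognormal parameters are (median, sigma of log)."""

    n_genes: int = 200
    tl_length_params: tuple[float, float] = (105.0, 1.0)     # nt
    utr3_length_params: tuple[float, float] = (127.0, 0.85)  # nt
    cds_length_params: tuple[float, float] = (470.0, 0.45)   # codons
    uaug_rate: float = 0.0086            # expected uAUGs per TL nt
    kozak_truth: kozak.KozakModel | None = None
    leak_slope: float = 8.0
    leak_midpoint: float = 0.6
    rna_abundance_params: tuple[float, float] = (10.0, 1.0)  # TPM-scale
    frame_weights: tuple[float, float, float] = (0.77, 0.10, 0.13)
    tss_cluster_sd: float = 3.0          # nt
    false_tss_rate: float = 0.5          # false clusters per gene
    polyA_artifact_rate: float = 0.1     # fraction of PAS reads
    n_replicates: int = 3
    n_conditions: int = 1
    spike_fractions: tuple[float, ...] | None = None  # per replicate depth factors
    tl_intron_fraction: float = 0.0
    ncc_rate: float = 0.0                # near-cognate plant rate per TL nt
    overdispersion: float = 0.0
    te_scale: float = 1.0
    nmd_strength: float = 2.0
    tss_reads_per_gene: float = 50.0     # decap library, per replicate
    nodecap_capture: float = 0.1         # true-signal fraction in the control
    false_tss_weight: float = 10.0       # reads per false cluster per replicate
    false_tss_rep_prob: float = 0.7      # replicate inclusion of a false cluster
    nodecap_false_enrichment: float = 3.0  # false-cluster weight gain in the control
    pas_reads_per_gene: float = 20.0
    ribo_site_depth: float = 1.0         # footprint reads per codon at flux 1
    rna_site_depth: float = 0.5
    reads_per_gene: float = 60.0         # mean count-table depth
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kozak_truth is None:
            self.kozak_truth = default_kozak_truth()
        self.validate()

    def validate(self) -> None:
        nonneg = [
            self.uaug_rate, self.false_tss_rate, self.polyA_artifact_rate,
            self.tss_cluster_sd, self.ncc_rate, self.overdispersion,
            self.tl_intron_fraction, self.nmd_strength,
        ]
        if any(v < 0 for v in nonneg):
            raise ValueError("rates and spreads must be >= 0")
        if not np.isclose(sum(self.frame_weights), 1.0):
            raise ValueError("frame_weights must sum to 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        # each planted uORF needs ~(_UBLOCK + spacing) nt of leader
        if self.uaug_rate * _UBLOCK > 0.9:
            raise ValueError(
                f"uaug_rate {self.uaug_rate} too high: mean TL cannot host "
                f"{_UBLOCK}-nt uORF blocks at that density"
            )


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery tests."""

    genes: pd.DataFrame          # per-gene coordinates, abundance, fluxes, NMD fc
    sites: pd.DataFrame          # planted/realized start sites with true scores
    config: SimConfig
    false_tss: pd.DataFrame | None = None     # labelled false 5'-end clusters
    pas_artifacts: set[str] = field(default_factory=set)  # internal-priming read ids


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _lognormal_len(rng, params, size, minimum):
    median, sigma = params
    draw = rng.lognormal(np.log(median), sigma, size)
    return np.maximum(minimum, np.round(draw)).astype(int)


def logistic_p(score, slope: float, midpoint: float):
    """Initiation probability of a scanning PIC at a start of given score."""
    return 1.0 / (1.0 + np.exp(-slope * (np.asarray(score, float) - midpoint)))


def sample_context(model: kozak.KozakModel, rng) -> str:
    """Draw a 27-nt context column-wise from the matrix, anchor forced to ATG."""
    cum = model.freq.cumsum(axis=0)
    u = rng.random(kozak.N_COLUMNS)
    idx = (u[np.newaxis, :] > cum).sum(axis=0)
    chars = [kozak.BASES[i] for i in idx]
    chars[kozak.ANCHOR:kozak.ANCHOR + 3] = "ATG"
    return "".join(chars)


def sample_context_with_score(
    model: kozak.KozakModel,
    target: float,
    rng,
    window: str = "wide",
    tol: float = 0.01,
    max_iter: int = 300,
) -> str:
    """Hill-climb a sampled context toward a target wide score.

    Used to plant uAUGs across the whole score range rather than only at the
    high scores that straight sampling produces.
    """
    ctx = list(sample_context(model, rng))
    sl = kozak.WINDOWS[window]
    cur = kozak.kozak_score("".join(ctx), model, window)
    for _ in range(max_iter):
        if abs(cur - target) <= tol:
            break
        j = int(rng.integers(sl.start, sl.stop))
        old = ctx[j]
        ctx[j] = kozak.BASES[int(rng.integers(4))]
        new = kozak.kozak_score("".join(ctx), model, window)
        if abs(new - target) < abs(cur - target):
            cur = new
        else:
            ctx[j] = old
    return "".join(ctx)


def _destroy_atg(seq: list[str], protected: set[int]) -> None:
    """Mutate the T of every ATG whose A position is not protected."""
    changed = True
    while changed:
        changed = False
        for i in range(len(seq) - 2):
            if seq[i] == "A" and seq[i + 1] == "T" and seq[i + 2] == "G":
                if i in protected:
                    continue
                seq[i + 1] = "C"
                changed = True


def _random_seq(rng, n: int) -> list[str]:
    return [kozak.BASES[i] for i in rng.integers(0, 4, n)]


def _sample_uorf_context(model, target, rng) -> str:
    """A planted-uORF context: no AUG outside the anchor, no stop in the
    first four uORF codons (the planted TAA must terminate the uORF)."""
    for _ in range(200):
        ctx = sample_context_with_score(model, target, rng)
        if "ATG" in ctx[:12] or "ATG" in ctx[13:]:
            continue
        codons = [ctx[k:k + 3] for k in range(15, 27, 3)]
        if any(c in STOPS for c in codons):
            continue
        return ctx
    raise RuntimeError("could not sample a valid uORF context")


def _sample_aaug_context(model, rng) -> str:
    """Annotated-start context: AUG-free upstream 12 nt, stop-free first codons."""
    for _ in range(200):
        ctx = sample_context(model, rng)
        if "ATG" in ctx[:12]:
            continue
        codons = [ctx[k:k + 3] for k in range(15, 27, 3)]
        if any(c in STOPS for c in codons):
            continue
        return ctx
    raise RuntimeError("could not sample a valid aAUG context")


def _build_tl(tl_target: int, aaug_up12: str, rng, config: SimConfig):
    """Assemble one transcript leader, right to left.

    Returns (tl string, list of (uaug_offset_from_tl_end, context)). Planted
    uORF blocks are 12 nt context + ATG + 4 codons + TAA; micro-padding
    between blocks sets each uAUG out of frame with the annotated start
    (2/3 of plants) or in frame with its planted intervening stop (1/3).
    """
    n_u = rng.poisson(config.uaug_rate * tl_target)
    capacity = max(0, (tl_target - 12) // (_UBLOCK + 3))
    n_u = min(n_u, capacity)
    budget = max(0, tl_target - 12 - _UBLOCK * n_u)
    gaps = rng.multinomial(budget, np.ones(n_u + 1) / (n_u + 1)) if n_u else [budget]

    suffix: list[str] = list(aaug_up12)
    planted: list[tuple[int, str]] = []  # (distance of A from TL 3' end, context)
    for k in range(n_u):
        gap = int(gaps[n_u - k])
        suffix = _random_seq(rng, gap) + suffix
        # distance from the A of this block's ATG to the TL 3' end
        dist = (_UBLOCK - 12) + len(suffix)
        want_inframe = rng.random() < (1.0 / 3.0)
        pad = (-dist) % 3 if want_inframe else 0
        if not want_inframe and dist % 3 == 0:
            pad = 1 + int(rng.integers(2))
        suffix = _random_seq(rng, pad) + suffix
        dist += pad
        target = float(rng.uniform(0.30, 0.98))
        ctx = _sample_uorf_context(config.kozak_truth, target, rng)
        tail = "".join(rng.choice(_UORF_CODONS, 6))
        block = list(ctx[:27] + tail + "TAA")  # up12+ATG+(10 codons)+stop
        suffix = block + suffix
        planted.append((dist, ctx))
    suffix = _random_seq(rng, int(gaps[0])) + suffix
    tl_len = len(suffix)
    protected = set()
    for dist, _ in planted:
        a = tl_len - dist
        protected.add(a)
    _destroy_atg(suffix, protected)
    return "".join(suffix), planted


def _scan_tl_uaugs(tl: str, cds: str):
    """Generator-side uAUG scan (definition check for planted leaders)."""
    out = []
    tx = tl + cds
    for i in range(len(tl) - 2):
        if tl[i:i + 3] != "ATG":
            continue
        dist = len(tl) - i
        if dist % 3 == 0:
            stops = [
                j for j in range(i + 3, len(tl) - 2, 3) if tl[j:j + 3] in STOPS
            ]
            if not stops:
                continue
            stop = stops[0]
        else:
            stop = next(
                (j for j in range(i + 3, len(tx) - 2, 3) if tx[j:j + 3] in STOPS),
                None,
            )
        out.append((i, stop))
    return out


def generate_genome(config: SimConfig):
    """Build the synthetic genome, gene models and ground truth.

    Returns (genome: dict chrom -> sequence, genes: list[GeneModel], truth).
    """
    rng = _rng(config, 1)
    model = config.kozak_truth
    n = config.n_genes
    tl_targets = _lognormal_len(rng, config.tl_length_params, n, 15)
    utr3_lens = _lognormal_len(rng, config.utr3_length_params, n, 30)
    cds_codons = _lognormal_len(rng, config.cds_length_params, n, 60)
    abundance = rng.lognormal(np.log(config.rna_abundance_params[0]),
                              config.rna_abundance_params[1], n)

    chrom_parts: dict[str, list[str]] = {}
    chrom_pos: dict[str, int] = {}
    genes: list[GeneModel] = []
    gene_rows = []
    site_rows = []
    chrom_idx = 1

    for g in range(n):
        gene_id = f"gene{g + 1:05d}"
        chrom = f"chr{chrom_idx}"
        if chrom not in chrom_parts:
            spacer = _random_seq(rng, 100 + int(rng.integers(0, 100)))
            spacer[0] = spacer[-1] = "C"
            chrom_parts[chrom] = ["".join(spacer)]
            chrom_pos[chrom] = len(spacer)

        # --- transcript assembly (5'->3') -------------------------------
        ctx_a = _sample_aaug_context(model, rng)
        tl, planted = _build_tl(int(tl_targets[g]), ctx_a[:12], rng, config)
        n_body = int(cds_codons[g]) - 6
        body = "".join(rng.choice(SENSE_CODONS, n_body))
        cds = "ATG" + ctx_a[15:27] + body + "TAA"
        utr3 = _random_seq(rng, int(utr3_lens[g]))
        utr3[-1] = "CGT"[int(rng.integers(3))]
        # plant one genomic A stretch per gene for internal-priming artifacts
        arun_pos = None
        if config.polyA_artifact_rate > 0 and len(utr3) >= 60:
            arun_pos = int(rng.integers(35, len(utr3) - 15))
            utr3[arun_pos:arun_pos + 8] = list("A" * 8)
        utr3 = "".join(utr3)
        transcript = tl + cds + utr3
        tl_len, cds_len = len(tl), len(cds)

        # --- placement on the genome ------------------------------------
        strand = "+" if rng.random() < 0.5 else "-"
        offset = chrom_pos[chrom]
        seg = transcript if strand == "+" else _revcomp(transcript)
        chrom_parts[chrom].append(seg)
        spacer = _random_seq(rng, 100 + int(rng.integers(0, 150)))
        spacer[0] = spacer[-1] = "C"
        chrom_parts[chrom].append("".join(spacer))
        tx_start, tx_end = offset, offset + len(transcript)
        chrom_pos[chrom] = tx_end + len(spacer)
        if chrom_pos[chrom] > 400_000:
            chrom_idx += 1
        if strand == "+":
            cds_start = tx_start + tl_len
            cds_end = cds_start + cds_len
        else:
            cds_end = tx_end - tl_len
            cds_start = cds_end - cds_len
        genes.append(
            GeneModel(gene_id, chrom, strand, tx_start, tx_end, cds_start, cds_end)
        )

        # --- ground truth: sites, scores, scanning fluxes ----------------
        found = _scan_tl_uaugs(tl, cds)
        planted_pos = sorted(tl_len - dist for dist, _ in planted)
        if [p for p, _ in found] != planted_pos:
            raise AssertionError(
                f"{gene_id}: leader scan {found} disagrees with planted {planted_pos}"
            )
        inflow = 1.0
        gene_sites = []
        for rank, (pos, stop) in enumerate(found, start=1):
            wide = kozak.score_at(transcript, pos, model, "wide")
            narrow = kozak.score_at(transcript, pos, model, "narrow")
            p = float(logistic_p(wide, config.leak_slope, config.leak_midpoint))
            gene_sites.append(
                dict(gene_id=gene_id, cls="uAUG", rank=f"u{rank}",
                     transcript_pos=pos, dist_from_tss=pos,
                     frame_rel_aaug=(pos - tl_len) % 3,
                     in_frame_stop_before_aaug=(pos - tl_len) % 3 == 0,
                     stop_transcript_pos=stop, wide_score=wide,
                     narrow_score=narrow, p_init=p, flux=inflow * p)
            )
            inflow *= 1.0 - p
        wide_a = kozak.score_at(transcript, tl_len, model, "wide")
        narrow_a = kozak.score_at(transcript, tl_len, model, "narrow")
        p_a = float(logistic_p(wide_a, config.leak_slope, config.leak_midpoint))
        flux_a = inflow * p_a
        gene_sites.append(
            dict(gene_id=gene_id, cls="aAUG", rank="a", transcript_pos=tl_len,
                 dist_from_tss=tl_len, frame_rel_aaug=0,
                 in_frame_stop_before_aaug=None,
                 stop_transcript_pos=tl_len + cds_len - 3, wide_score=wide_a,
                 narrow_score=narrow_a, p_init=p_a, flux=flux_a)
        )
        leftover = inflow * (1.0 - p_a)
        d_rank = 0
        for j in range(1, cds_len - 2):
            if cds[j:j + 3] != "ATG":
                continue
            d_rank += 1
            pos = tl_len + j
            wide_d = kozak.score_at(transcript, pos, model, "wide")
            stop = next(
                (tl_len + k for k in range(j + 3, cds_len - 2, 3)
                 if cds[k:k + 3] in STOPS),
                None,
            )
            p_d = float(logistic_p(wide_d, config.leak_slope, config.leak_midpoint))
            flux_d = leftover * p_d if d_rank == 1 else 0.0
            if d_rank == 1:
                leftover *= 1.0 - p_d
            gene_sites.append(
                dict(gene_id=gene_id, cls="dAUG", rank=f"d{d_rank}",
                     transcript_pos=pos, dist_from_tss=pos,
                     frame_rel_aaug=j % 3, in_frame_stop_before_aaug=None,
                     stop_transcript_pos=stop, wide_score=wide_d,
                     narrow_score=kozak.score_at(transcript, pos, model, "narrow"),
                     p_init=p_d, flux=flux_d)
            )
        uorf_flux = sum(r["flux"] for r in gene_sites if r["cls"] == "uAUG")
        site_rows.extend(gene_sites)
        gene_rows.append(
            dict(gene_id=gene_id, chrom=chrom, strand=strand,
                 tx_start=tx_start, tx_end=tx_end, cds_start=cds_start,
                 cds_end=cds_end, tss=genes[-1].tss, pas=genes[-1].pas,
                 tl_len=tl_len, cds_len=cds_len, utr3_len=len(utr3),
                 abundance=abundance[g], flux_a=flux_a, uorf_flux=uorf_flux,
                 leak_through=leftover,
                 te_true=config.te_scale * flux_a,
                 nmd_fc=1.0 + config.nmd_strength * uorf_flux,
                 arun_utr3_pos=arun_pos if arun_pos is not None else -1)
        )

    genome = {chrom: "".join(parts) for chrom, parts in chrom_parts.items()}
    truth = GroundTruth(
        genes=pd.DataFrame(gene_rows),
        sites=pd.DataFrame(site_rows),
        config=config,
    )
    truth.genes["rna_tpm_true"] = 1e6 * truth.genes["abundance"] / truth.genes["abundance"].sum()
    return genome, genes, truth


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# End-sequencing reads


@dataclass
class EndReads:
    tss: pd.DataFrame        # chrom,pos,strand,condition,replicate,count
    nodecap: pd.DataFrame    # chrom,pos,strand,count
    pas_positions: pd.DataFrame
    pas_reads: list[TaggedRead]
    spike: pd.DataFrame      # condition,replicate,spike_count
    spike_reference: float


def _aggregate(df: pd.DataFrame) -> pd.DataFrame:
    keys = [c for c in df.columns if c != "count"]
    return df.groupby(keys, as_index=False)["count"].sum()


def generate_end_reads(truth: GroundTruth, genes, genome, config: SimConfig) -> EndReads:
    """Simulate 5'-end and 3'-end libraries; labels false clusters and
    internal-priming reads in the GroundTruth."""
    rng = _rng(config, 2)
    gtab = truth.genes
    n = len(gtab)
    sd = config.tss_cluster_sd

    depth = (
        np.asarray(config.spike_fractions, float)
        if config.spike_fractions is not None
        else rng.uniform(0.6, 1.4, config.n_conditions * config.n_replicates)
    )
    if depth.size != config.n_conditions * config.n_replicates:
        raise ValueError("spike_fractions must have one entry per sample")
    spike_base = 10000.0
    spike_rows = []

    # --- false TSS cluster centers -------------------------------------
    n_false = rng.poisson(config.false_tss_rate * n)
    false_rows = []
    if n_false:
        idx = rng.integers(0, n, n_false)
        for fi, gi in enumerate(idx):
            g = gtab.iloc[gi]
            # a planted false cluster is a *distinct* cluster: keep it beyond
            # the 50-nt chaining reach of the true TSS cluster, else the two
            # would merge and the label would be meaningless
            for _ in range(50):
                off = int(rng.integers(10, 800))
                center = (g["cds_start"] - off) if g["strand"] == "+" else (
                    g["cds_end"] + off
                )
                if abs(center - g["tss"]) >= max(80, 10 * sd):
                    break
            false_rows.append(
                dict(false_id=f"false{fi + 1}", chrom=g["chrom"],
                     strand=g["strand"], center=int(center), gene_id=g["gene_id"])
            )
    false_tss = pd.DataFrame(
        false_rows, columns=["false_id", "chrom", "strand", "center", "gene_id"]
    )
    truth.false_tss = false_tss
    rep_present = (
        rng.random((len(false_tss), config.n_conditions * config.n_replicates))
        < config.false_tss_rep_prob
    )

    # --- decap (TSS) libraries -----------------------------------------
    tss_frames = []
    sample_i = 0
    for cond in range(1, config.n_conditions + 1):
        for rep in range(1, config.n_replicates + 1):
            d = depth[sample_i]
            counts = rng.poisson(config.tss_reads_per_gene * d, n)
            gene_idx = np.repeat(np.arange(n), counts)
            # truncated at 3 sd: every true-library position stays within
            # the cluster-recovery tolerance of its planted TSS
            noise = np.clip(np.round(rng.normal(0, sd, gene_idx.size)),
                            -3 * sd, 3 * sd).astype(int)
            pos = gtab["tss"].to_numpy()[gene_idx] + noise
            frames = [pd.DataFrame({
                "chrom": gtab["chrom"].to_numpy()[gene_idx],
                "pos": pos,
                "strand": gtab["strand"].to_numpy()[gene_idx],
                "count": 1,
            })]
            for fi, f in false_tss.iterrows():
                if not rep_present[fi, sample_i]:
                    continue
                m = rng.poisson(config.false_tss_weight * d)
                if m == 0:
                    continue
                fpos = f["center"] + np.round(rng.normal(0, 2.0, m)).astype(int)
                frames.append(pd.DataFrame({
                    "chrom": f["chrom"], "pos": fpos, "strand": f["strand"],
                    "count": 1,
                }))
            lib = _aggregate(pd.concat(frames, ignore_index=True))
            lib["condition"] = f"cond{cond}"
            lib["replicate"] = rep
            tss_frames.append(lib)
            spike_rows.append(dict(condition=f"cond{cond}", replicate=rep,
                                   spike_count=float(np.round(spike_base * d))))
            sample_i += 1
    tss = pd.concat(tss_frames, ignore_index=True)

    # --- no-decap control ----------------------------------------------
    counts = rng.poisson(config.tss_reads_per_gene * config.nodecap_capture, n)
    gene_idx = np.repeat(np.arange(n), counts)
    nd_noise = np.clip(np.round(rng.normal(0, sd, gene_idx.size)),
                       -3 * sd, 3 * sd).astype(int)
    nd_frames = [pd.DataFrame({
        "chrom": gtab["chrom"].to_numpy()[gene_idx],
        "pos": gtab["tss"].to_numpy()[gene_idx] + nd_noise,
        "strand": gtab["strand"].to_numpy()[gene_idx],
        "count": 1,
    })]
    for fi, f in false_tss.iterrows():
        # the control is dominated by non-capped species: artifact clusters
        # are enriched relative to the weak true-TSS carry-over
        m = rng.poisson(config.false_tss_weight * config.nodecap_false_enrichment)
        if m == 0:
            continue
        nd_frames.append(pd.DataFrame({
            "chrom": f["chrom"],
            "pos": f["center"] + np.round(rng.normal(0, 2.0, m)).astype(int),
            "strand": f["strand"], "count": 1,
        }))
    nodecap = _aggregate(pd.concat(nd_frames, ignore_index=True))

    # --- PAS per-position counts ----------------------------------------
    pas_frames = []
    sample_i = 0
    for cond in range(1, config.n_conditions + 1):
        for rep in range(1, config.n_replicates + 1):
            d = depth[sample_i]
            counts = rng.poisson(config.pas_reads_per_gene * d, n)
            gene_idx = np.repeat(np.arange(n), counts)
            lib = _aggregate(pd.DataFrame({
                "chrom": gtab["chrom"].to_numpy()[gene_idx],
                "pos": gtab["pas"].to_numpy()[gene_idx]
                + np.round(rng.normal(0, 2.0, gene_idx.size)).astype(int),
                "strand": gtab["strand"].to_numpy()[gene_idx],
                "count": 1,
            }))
            lib["condition"] = f"cond{cond}"
            lib["replicate"] = rep
            pas_frames.append(lib)
            sample_i += 1
    pas_positions = pd.concat(pas_frames, ignore_index=True)

    # --- PAS reads (FASTQ-level, for the read filters) -------------------
    reads: list[TaggedRead] = []
    artifacts: set[str] = set()
    gene_models = {g.gene_id: g for g in genes}
    body_len = 30
    for _, row in gtab.iterrows():
        gm = gene_models[row["gene_id"]]
        transcript = gm.transcript_seq(genome)
        m = rng.poisson(config.pas_reads_per_gene)
        arun = int(row["arun_utr3_pos"])
        arun_tx = row["tl_len"] + row["cds_len"] + arun if arun >= 0 else -1
        for k in range(m):
            rid = f"{row['gene_id']}.pas{k + 1}"
            if arun >= 0 and rng.random() < config.polyA_artifact_rate:
                end = arun_tx + 6 + int(rng.integers(0, 3))  # ends inside the A run
                body = transcript[max(0, end - body_len):end]
                reads.append(TaggedRead(rid, body, "I" * len(body)))
                artifacts.add(rid)
            else:
                tail = "A" * int(rng.integers(8, 15))
                body = transcript[-body_len:]
                reads.append(TaggedRead(rid, body + tail, "I" * (len(body) + len(tail))))
    truth.pas_artifacts = artifacts

    return EndReads(
        tss=tss,
        nodecap=nodecap,
        pas_positions=pas_positions,
        pas_reads=reads,
        spike=pd.DataFrame(spike_rows),
        spike_reference=spike_base,
    )


# ---------------------------------------------------------------------------
# Expression


@dataclass
class Expression:
    counts: pd.DataFrame      # gene_id, sample, count (long form)
    ribo_sites: pd.DataFrame  # gene_id, pos, length, count (transcript coords)
    rna_sites: pd.DataFrame   # gene_id, pos, length, count


def _poisson_counts(rng, mu, overdispersion):
    if overdispersion > 0:
        shape = 1.0 / overdispersion
        mu = rng.gamma(shape, mu * overdispersion)
    return rng.poisson(mu)


def generate_expression(truth: GroundTruth, config: SimConfig) -> Expression:
    """Simulate footprint/RNA count tables and per-position footprint 5' ends.

    Footprint density on every ORF is proportional to its initiation flux
    under the scanning recursion; RNA coverage is uniform; the upf1-null RNA
    sample is inflated by each gene's NMD fold-change.
    """
    rng = _rng(config, 3)
    g = truth.genes
    n = len(g)
    a = g["abundance"].to_numpy()
    tx_len = (g["tx_end"] - g["tx_start"]).to_numpy()
    cds_len = g["cds_len"].to_numpy()
    flux_a = g["flux_a"].to_numpy()
    fc = g["nmd_fc"].to_numpy()

    def scaled(weights):
        return config.reads_per_gene * n * weights / weights.sum()

    rna_mu = scaled(a * tx_len)
    ribo_mu = scaled(a * flux_a * cds_len)
    upf1_mu = scaled(a * fc * tx_len)

    rows = []
    for rep in range(1, config.n_replicates + 1):
        d = rng.uniform(0.8, 1.2)
        for sample, mu in (
            (f"ribo_wt_rep{rep}", ribo_mu),
            (f"rna_wt_rep{rep}", rna_mu),
            (f"rna_upf1_rep{rep}", upf1_mu),
        ):
            counts = _poisson_counts(rng, mu * d, config.overdispersion)
            rows.append(pd.DataFrame({
                "gene_id": g["gene_id"], "sample": sample, "count": counts,
            }))
    counts = pd.concat(rows, ignore_index=True)

    # --- per-position footprint 5' ends (one representative sample) -----
    frame_w = np.asarray(config.frame_weights)
    a_rel = a / a.mean()
    sites = truth.sites
    ribo_frames = []
    by_gene = dict(tuple(sites.groupby("gene_id", sort=False)))
    for i in range(n):
        row = g.iloc[i]
        gid = row["gene_id"]
        gsites = by_gene[gid]
        orfs = []  # (start_pos, n_codons, flux)
        for _, s in gsites.iterrows():
            if s["flux"] <= 0:
                continue
            stop = s["stop_transcript_pos"]
            end = int(stop) if pd.notna(stop) else int(tx_len[i]) - 2
            n_codons = max(1, (end - int(s["transcript_pos"])) // 3)
            orfs.append((int(s["transcript_pos"]), n_codons, float(s["flux"])))
        for start, n_codons, flux in orfs:
            m = rng.poisson(config.ribo_site_depth * a_rel[i] * flux * n_codons)
            if m == 0:
                continue
            codon = rng.integers(0, n_codons, m)
            frame = rng.choice(3, m, p=frame_w)
            length = rng.choice(_READ_LENGTHS, m, p=_READ_LENGTH_P)
            pos5 = start + 3 * codon + frame - 15
            ok = pos5 >= 0
            if not ok.any():
                continue
            ribo_frames.append(pd.DataFrame({
                "gene_id": gid, "pos": pos5[ok], "length": length[ok], "count": 1,
            }))
    ribo_sites = (
        _aggregate(pd.concat(ribo_frames, ignore_index=True))
        if ribo_frames else pd.DataFrame(columns=["gene_id", "pos", "length", "count"])
    )

    # --- RNA 5' ends: uniform coverage ----------------------------------
    rna_frames = []
    for i in range(n):
        m = rng.poisson(config.rna_site_depth * a_rel[i] * tx_len[i] / 3.0)
        if m == 0:
            continue
        pos = rng.integers(0, max(1, tx_len[i] - 50), m)
        rna_frames.append(pd.DataFrame({
            "gene_id": g["gene_id"].iloc[i], "pos": pos, "length": 50, "count": 1,
        }))
    rna_sites = (
        _aggregate(pd.concat(rna_frames, ignore_index=True))
        if rna_frames else pd.DataFrame(columns=["gene_id", "pos", "length", "count"])
    )
    return Expression(counts=counts, ribo_sites=ribo_sites, rna_sites=rna_sites)
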