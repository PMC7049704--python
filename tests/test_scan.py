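"""Start-codon enumeration: uAUG/dAUG definitions, proximity classes,
near-cognate scan, dual-localization candidates, and a brute-force oracle."""

import re

import numpy as np
import pandas as pd
import pytest

from leakyscan import scan
from leakyscan.annotation import extract_sequences
from leakyscan.simulate import default_kozak_truth

CDS = "ATG" + "GCT" * 20 + "TAA"


class TestFindUaugs:
    def test_out_of_frame_atg_is_uaug(self):
        sites = scan.find_uaugs("GATGAA", CDS)
        assert len(sites) == 1
        s = sites[0]
        assert (s.transcript_pos, s.dist_from_tss) == (1, 1)
        assert s.frame_rel_aaug != 0

    def test_in_frame_atg_without_stop_excluded(self):
        # an N-terminal extension, not an upstream ORF
        assert scan.find_uaugs("ATGAAA", CDS) == []

    def test_in_frame_atg_with_intervening_stop_included(self):
        sites = scan.find_uaugs("ATGTGAAAA", CDS)
        assert len(sites) == 1
        assert sites[0].frame_rel_aaug == 0
        assert sites[0].in_frame_stop_before_aaug
        assert sites[0].stop_transcript_pos == 3

    def test_out_of_frame_uorf_extends_into_cds(self):
        tl = "CCATGCC"  # ATG at 2, distance 5, no stop in the 5-nt remainder
        sites = scan.find_uaugs(tl, "ATGCTAACCTAA")  # uORF-frame TAA inside CDS
        assert len(sites) == 1
        stop = sites[0].stop_transcript_pos
        assert stop is not None and stop >= len(tl)

    def test_non_nucleotide_characters_error(self):
        with pytest.raises(ValueError):
            scan.find_uaugs("AXG", CDS)

    def test_ranks_run_five_prime_to_three_prime(self):
        tl = "ATGTAACCATGCC"  # in-frame-with-stop at 0, out-of-frame at 8
        sites = scan.find_uaugs(tl, CDS)
        assert [s.rank for s in sites] == ["u1", "u2"]
        assert [s.transcript_pos for s in sites] == [0, 8]


class TestFindDaugs:
    def test_first_downstream_aug_in_frame(self):
        sites = scan.find_daugs("ATGGCTATGTAA")
        assert sites[0].rank == "d1"
        assert sites[0].transcript_pos == 6
        assert sites[0].frame_rel_aaug == 0

    def test_first_downstream_aug_out_of_frame(self):
        sites = scan.find_daugs("ATGGCATGGTAA")
        assert sites[0].transcript_pos == 5
        assert sites[0].frame_rel_aaug == 2

    def test_cds_without_internal_aug_yields_nothing(self):
        assert scan.find_daugs("ATG" + "GGG" * 10 + "TAA") == []


class TestProximityClasses:
    @pytest.mark.parametrize(
        "distances, expected",
        [([5, 30], "1+ far"), ([5, 18], "1+ close"), ([], "none"),
         ([20], "1+ close"), ([21], "1+ far")],
    )
    def test_rule(self, distances, expected):
        assert scan.classify_tss_proximity(distances) == expected


class TestBruteForceOracle:
    @staticmethod
    def oracle_uaugs(tl, cds):
        """Regex-and-loop reimplementation of the uAUG definition."""
        out = []
        tx = tl + cds
        for m in re.finditer(r"(?=ATG)", tl):
            i = m.start()
            if i + 3 > len(tl):
                continue
            dist = len(tl) - i
            if dist % 3 != 0:
                out.append(i)
            else:
                between = tl[i + 3:len(tl)]
                codons = [between[k:k + 3] for k in range(0, len(between) - 2, 3)]
                if any(c in ("TAA", "TAG", "TGA") for c in codons):
                    out.append(i)
        return out

    @staticmethod
    def oracle_daugs(cds):
        return [m.start() for m in re.finditer(r"(?=ATG)", cds)
                if 0 < m.start() < len(cds) - 2]

    def test_agreement_on_random_transcripts(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            tl = "".join(rng.choice(list("ACGT"), int(rng.integers(0, 120))))
            cds = "ATG" + "".join(
                rng.choice(list("ACGT"), 3 * int(rng.integers(3, 30)))
            ) + "TAA"
            assert [s.transcript_pos for s in scan.find_uaugs(tl, cds)] == \
                self.oracle_uaugs(tl, cds)
            assert [s.transcript_pos - len(tl)
                    for s in scan.find_daugs(cds, tl_len=len(tl))] == \
                self.oracle_daugs(cds)

    def test_every_tl_atg_is_uaug_or_inframe_extension(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            tl = "".join(rng.choice(list("ACGT"), 90))
            uaugs = {s.transcript_pos for s in scan.find_uaugs(tl, CDS)}
            for m in re.finditer(r"(?=ATG)", tl[:-2] if len(tl) > 2 else ""):
                i = m.start()
                if i in uaugs:
                    continue
                # excluded ATGs must be in-frame with no intervening stop
                dist = len(tl) - i
                assert dist % 3 == 0
                codons = [tl[k:k + 3] for k in range(i + 3, len(tl) - 2, 3)]
                assert not any(c in ("TAA", "TAG", "TGA") for c in codons)


class TestNearCognates:
    def test_strong_context_near_cognate_reported(self, truth_model):
        cons = truth_model.consensus
        seq = "G" * 20 + cons[:12] + "ATT" + cons[15:] + "G" * 20
        hits = scan.near_cognate_scan(seq, truth_model, min_wide_score=0.95)
        assert any(h.codon == "ATT" and h.transcript_pos == 32 for h in hits)

    def test_sequence_without_near_cognates_empty(self, truth_model):
        assert scan.near_cognate_scan("CCCCCCCCCC", truth_model) == []

    def test_threshold_above_one_always_empty(self, truth_model):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), 300))
        assert scan.near_cognate_scan(seq, truth_model, min_wide_score=1.01) == []


class TestDualLocalization:
    @staticmethod
    def tables(aaug, d1, rna_tpm, in_frame=True):
        sites = pd.DataFrame([
            dict(gene_id="g1", cls="aAUG", rank="a", transcript_pos=100,
                 frame_rel_aaug=0, wide_score=aaug),
            dict(gene_id="g1", cls="dAUG", rank="d1", transcript_pos=169,
                 frame_rel_aaug=0 if in_frame else 1, wide_score=d1),
        ])
        expr = pd.DataFrame({"gene_id": ["g1", "g2"], "rna_tpm": [rna_tpm, 1.0]})
        return sites, expr

    def test_margin_exceeded_is_candidate(self):
        sites, expr = self.tables(0.70, 0.85, rna_tpm=100.0)
        cand, summary = scan.dual_localization_candidates(sites, expr)
        assert cand["gene_id"].tolist() == ["g1"]
        assert cand.loc[0, "inter_aug_nt"] == 69
        assert summary.set_index("in_frame").loc[True, "n"] == 1

    def test_margin_not_met_is_not_candidate(self):
        sites, expr = self.tables(0.70, 0.75, rna_tpm=100.0)
        cand, _ = scan.dual_localization_candidates(sites, expr)
        assert cand.empty

    def test_low_abundance_gene_excluded(self):
        sites, expr = self.tables(0.70, 0.85, rna_tpm=0.1)
        cand, _ = scan.dual_localization_candidates(sites, expr)
        assert cand.empty

    def test_mts_labels_join_when_table_given(self):
        sites, expr = self.tables(0.70, 0.85, rna_tpm=100.0)
        mts = pd.DataFrame({"gene_id": ["g1"], "mts": [True]})
        cand, summary = scan.dual_localization_candidates(sites, expr, mts)
        assert bool(cand.loc[0, "mts"])
        assert set(summary.columns) == {"in_frame", "mts", "n"}


class TestAgainstGroundTruth:
    def test_enumeration_matches_planted_sites_exactly(self, small_sim):
        _, genome, genes, truth = small_sim
        seqs = extract_sequences(genes, genome)
        for row in seqs.itertuples():
            t = truth.sites[truth.sites["gene_id"] == row.gene_id]
            u = scan.find_uaugs(row.tl_seq, row.cds_seq, row.gene_id)
            d = scan.find_daugs(row.cds_seq, row.gene_id, tl_len=len(row.tl_seq))
            assert [s.transcript_pos for s in u] == \
                t[t["cls"] == "uAUG"]["transcript_pos"].tolist()
            assert [s.transcript_pos for s in d] == \
                t[t["cls"] == "dAUG"]["transcript_pos"].tolist()
            assert [s.stop_transcript_pos for s in u] == [
                None if pd.isna(x) else int(x)
                for x in t[t["cls"] == "uAUG"]["stop_transcript_pos"]
            ]
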