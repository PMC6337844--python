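import re

import numpy as np
import pytest

from intronkit.annotate import (
    SplicedAlignParams,
    at_content_scan,
    find_splice_signals,
    gene_model_from_spliced,
    spliced_align,
)
from intronkit.seqio import NucleotideSequence, ProteinSequence, reverse_complement
from intronkit.synthetic_data import generate_family, random_family_config

from .oracles import blosum_dict, enumerate_spliced_score, random_spliced_instance

B = blosum_dict()


class TestSpliceSignals:
    def test_gtag_positions(self):
        donors, acceptors = find_splice_signals(NucleotideSequence("x", "GTAG"))
        assert donors == [0]
        assert acceptors == [2]

    def test_no_signals(self):
        assert find_splice_signals(NucleotideSequence("x", "CCCC")) == ([], [])

    def test_counts_match_regex_scan_oracle(self):
        rng = np.random.default_rng(3)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
        donors, acceptors = find_splice_signals(NucleotideSequence("x", seq))
        assert donors == [m.start() for m in re.finditer("(?=GT)", seq)]
        assert acceptors == [m.start() for m in re.finditer("(?=AG)", seq)]


SMALL = SplicedAlignParams(
    min_intron_len=20, max_intron_len=100, intron_open_penalty=4.0
)


class TestSplicedAlign:
    def test_exact_backtranslation_single_block(self):
        sa = spliced_align(
            ProteinSequence("p", "MKF"), NucleotideSequence("g", "ATGAAATTT"), "+"
        )
        assert sa.score == B[("M", "M")] + B[("K", "K")] + B[("F", "F")]
        assert sa.blocks == (((0, 3), (0, 9)),)
        assert sa.introns == ()

    def test_phase2_intron_inside_codon(self):
        genomic = NucleotideSequence("g", "ATGAA" + "GT" + "C" * 20 + "AG" + "ATTT")
        sa = spliced_align(ProteinSequence("p", "MKF"), genomic, "+", SMALL)
        assert len(sa.introns) == 1
        intron = sa.introns[0]
        assert (intron.donor, intron.acceptor, intron.phase) == ("GT", "AG", 2)
        assert (intron.start, intron.end) == (5, 29)
        gm = gene_model_from_spliced(sa, genomic)
        assert gm.protein.residues == "MKF"
        assert gm.exons == ((0, 5), (29, 33))
        # the score matches single-intron placement enumeration
        expected = enumerate_spliced_score("MKF", genomic.residues, B, 4.0, 20, 100)
        assert sa.score == pytest.approx(expected)

    def test_minus_strand_equivalent(self):
        genomic = NucleotideSequence("g", "ATGAA" + "GT" + "C" * 20 + "AG" + "ATTT")
        flipped = reverse_complement(genomic)
        sa = spliced_align(ProteinSequence("p", "MKF"), flipped, None, SMALL)
        assert sa.strand == "-"
        gm = gene_model_from_spliced(sa, flipped)
        gm.validate_against(flipped)
        assert gm.protein.residues == "MKF"

    def test_no_positive_alignment_is_empty_result(self):
        sa = spliced_align(
            ProteinSequence("p", "WWWW"), NucleotideSequence("g", "CCCCCCCCC"), "+"
        )
        assert sa.is_empty
        assert sa.score <= 0

    def test_matches_enumeration_oracle_on_random_instances(self):
        rng = np.random.default_rng(20)
        for _ in range(25):
            inst = random_spliced_instance(rng)
            params = SplicedAlignParams(
                intron_open_penalty=inst["intron_penalty"],
                min_intron_len=inst["min_intron"],
                max_intron_len=inst["max_intron"],
            )
            got = spliced_align(
                ProteinSequence("p", inst["protein"]),
                NucleotideSequence("g", inst["genomic"]),
                "+",
                params,
            ).score
            want = enumerate_spliced_score(
                inst["protein"],
                inst["genomic"],
                B,
                inst["intron_penalty"],
                inst["min_intron"],
                inst["max_intron"],
            )
            assert got == pytest.approx(want)

    def test_intron_penalty_monotonicity(self):
        fam = generate_family(random_family_config(seed=5))
        tgt, ref = fam.taxa[0], fam.taxa[1]
        counts = []
        for pen in (10.0, 40.0, 80.0, 200.0):
            params = SplicedAlignParams(intron_open_penalty=pen)
            sa = spliced_align(ref.protein, tgt.genomic, "+", params)
            counts.append(len(sa.introns))
        assert counts == sorted(counts, reverse=True)

    def test_synthetic_truth_recovered_at_zero_divergence(self):
        cfg = random_family_config(seed=9, subst_prob=0.0)
        fam = generate_family(cfg)
        tgt = fam.taxa[0]
        sa = spliced_align(fam.taxa[1].protein, tgt.genomic, None)
        gm = gene_model_from_spliced(sa, tgt.genomic)
        assert gm.exons == tgt.model.exons
        assert gm.intron_phases == tgt.model.intron_phases
        assert gm.protein.residues == tgt.protein.residues


class TestGeneModelFromSpliced:
    def test_internal_stop_raises_with_codon_position(self):
        # gene with an in-frame TAA inside: MK*F back-translated
        genomic = NucleotideSequence("g", "ATGAAATAATTT")
        sa = spliced_align(ProteinSequence("p", "MKXF"), genomic, "+")
        with pytest.raises(ValueError, match="codon 2"):
            gene_model_from_spliced(sa, genomic)
        gm = gene_model_from_spliced(sa, genomic, permit_internal_stop=True)
        assert gm.protein.residues == "MKXF"

    def test_empty_alignment_rejected(self):
        from intronkit.annotate import empty_alignment

        with pytest.raises(ValueError):
            gene_model_from_spliced(
                empty_alignment("p", "g"), NucleotideSequence("g", "ACGTACA")
            )


class TestAtContent:
    @pytest.mark.parametrize(
        "seq,expected", [("ATAT", 1.0), ("GCGC", 0.0), ("ATGC", 0.5)]
    )
    def test_whole_window(self, seq, expected):
        assert at_content_scan(NucleotideSequence("x", seq), 4) == [(0, expected)]

    def test_window_larger_than_sequence_collapses(self):
        assert at_content_scan(NucleotideSequence("x", "ATG"), 100) == [
            (0, pytest.approx(2 / 3))
        ]

    def test_matches_counting_oracle_and_excludes_n(self):
        rng = np.random.default_rng(8)
        seq = "".join("ACGTN"[i] for i in rng.integers(0, 5, 500))
        nt = NucleotideSequence("x", seq)
        for start, frac in at_content_scan(nt, window=50, step=10):
            win = seq[start : start + 50]
            denom = sum(1 for c in win if c != "N")
            want = (win.count("A") + win.count("T")) / denom if denom else 0.0
            assert frac == pytest.approx(want)
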