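import pytest

from intronkit.align import MultipleAlignment
from intronkit.intron_map import (
    ColumnMark,
    IntronMark,
    classify_conservation,
    format_alignment_with_marks,
    introns_to_protein_coords,
    map_marks_to_columns,
    neighbor_column_tolerance,
)
from intronkit.seqio import GeneModel, NucleotideSequence, ProteinSequence


def _model(exons, phases, protein, strand="+", gene_id="g"):
    return GeneModel("ctg", strand, exons, phases, ProteinSequence(gene_id, protein), gene_id)


class TestMarks:
    def test_single_exon_model_has_no_marks(self):
        gm = _model(((0, 9),), (), "MKF")
        assert introns_to_protein_coords(gm) == []

    def test_phase2_intron_after_five_coding_nt(self):
        # 5 coding nt before the intron: residue 1, phase 2
        gm = _model(((0, 5), (29, 33)), (2,), "MKF")
        assert introns_to_protein_coords(gm) == [IntronMark("g", 1, 2)]

    def test_minus_strand_uses_transcription_order(self):
        # minus strand: transcription starts at the rightmost exon
        genomic = NucleotideSequence("g", "CC" + "TTT" + "CTGGAC" + "CAT" + "CC")
        gm = GeneModel(
            "g", "-", ((2, 5), (11, 14)), (0,), ProteinSequence("p", "MK"), "p"
        )
        assert introns_to_protein_coords(gm) == [IntronMark("p", 1, 0)]

    def test_synthetic_truth_marks_match_generator(self, demo_family):
        for taxon in demo_family.taxa:
            assert (
                tuple(introns_to_protein_coords(taxon.model)) == taxon.intron_marks
            )


class TestColumnMapping:
    def test_ungapped_msa_column_equals_residue(self):
        msa = MultipleAlignment((("a", "MKFW"), ("b", "MKFW")))
        marks = {"a": [IntronMark("a", 2, 0)]}
        assert map_marks_to_columns(msa, marks) == [ColumnMark("a", 2, 0, 2)]

    def test_leading_gap_shifts_column(self):
        msa = MultipleAlignment((("a", "-----MKFW"), ("b", "QRSTVMKFW")))
        marks = {"a": [IntronMark("a", 2, 1)]}
        assert map_marks_to_columns(msa, marks) == [ColumnMark("a", 7, 1, 2)]

    def test_gapped_msa_matches_column_walk_oracle(self, demo_family):
        msa = demo_family.true_alignment
        marks = {t.name: list(t.intron_marks) for t in demo_family.taxa}
        got = map_marks_to_columns(msa, marks)
        for cm in got:
            row = msa.row(cm.gene_id)
            # walk the row counting residues
            seen = -1
            for col, ch in enumerate(row):
                if ch != "-":
                    seen += 1
                    if seen == cm.residue_index:
                        assert col == cm.column
                        break

    def test_mark_outside_row_rejected(self):
        msa = MultipleAlignment((("a", "MKFW"), ("b", "MKFW")))
        with pytest.raises(ValueError):
            map_marks_to_columns(msa, {"a": [IntronMark("a", 10, 0)]})


class TestClassification:
    def test_identical_models_all_shared(self):
        marks = [
            ColumnMark("a", 5, 0, 5),
            ColumnMark("b", 5, 0, 5),
            ColumnMark("a", 9, 2, 9),
            ColumnMark("b", 9, 2, 9),
        ]
        rep = classify_conservation(marks, ["a", "b"])
        assert rep.summary()["shared_by_all"] == 2
        assert rep.count_triplet() == (2, 0, 0)

    def test_demo_family_counts(self, demo_family):
        marks = {t.name: list(t.intron_marks) for t in demo_family.taxa}
        cmarks = map_marks_to_columns(demo_family.true_alignment, marks)
        rep = classify_conservation(cmarks, [t.name for t in demo_family.taxa])
        assert rep.count_triplet() == (2, 3, 2)
        assert rep.n_marks == sum(len(m) for m in marks.values())

    def test_phase_scramble_breaks_sharing(self):
        marks = [ColumnMark("a", 5, 0, 5), ColumnMark("b", 5, 1, 5)]
        strict = classify_conservation(marks, ["a", "b"], phase_strict=True)
        assert strict.summary()["shared_by_all"] == 0
        loose = classify_conservation(marks, ["a", "b"], phase_strict=False)
        assert loose.summary()["shared_by_all"] == 1

    def test_invariant_under_row_reordering(self, demo_family):
        msa = demo_family.true_alignment
        reordered = MultipleAlignment(tuple(reversed(msa.rows)))
        marks = {t.name: list(t.intron_marks) for t in demo_family.taxa}
        a = classify_conservation(
            map_marks_to_columns(msa, marks), [t.name for t in demo_family.taxa]
        )
        b = classify_conservation(
            map_marks_to_columns(reordered, marks),
            [t.name for t in demo_family.taxa],
        )
        assert a.count_triplet() == b.count_triplet()

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError):
            classify_conservation([], ["only"])


class TestTolerance:
    def test_tol_zero_is_identity(self, demo_family):
        marks = {t.name: list(t.intron_marks) for t in demo_family.taxa}
        rep = classify_conservation(
            map_marks_to_columns(demo_family.true_alignment, marks),
            [t.name for t in demo_family.taxa],
        )
        assert neighbor_column_tolerance(rep, 0) is rep

    def test_adjacent_columns_merge_at_tol_one(self):
        marks = [ColumnMark("a", 5, 0, 5), ColumnMark("b", 6, 0, 6)]
        rep = classify_conservation(marks, ["a", "b"])
        assert rep.summary()["shared_by_all"] == 0
        merged = neighbor_column_tolerance(rep, 1)
        assert merged.summary()["shared_by_all"] == 1
        assert merged.n_marks == 2

    def test_jittered_marks_recover_truth_at_tol_one(self, demo_family):
        marks = {t.name: list(t.intron_marks) for t in demo_family.taxa}
        cmarks = map_marks_to_columns(demo_family.true_alignment, marks)
        # jitter: push every taxonB mark one column right
        jittered = [
            ColumnMark(m.gene_id, m.column + (1 if m.gene_id == "taxonB" else 0),
                       m.phase, m.residue_index)
            for m in cmarks
        ]
        names = [t.name for t in demo_family.taxa]
        rep = classify_conservation(jittered, names)
        assert rep.count_triplet() != (2, 3, 2)
        merged = neighbor_column_tolerance(rep, 1)
        assert merged.count_triplet() == (2, 3, 2)

    def test_mark_count_conserved(self, demo_family):
        marks = {t.name: list(t.intron_marks) for t in demo_family.taxa}
        cmarks = map_marks_to_columns(demo_family.true_alignment, marks)
        names = [t.name for t in demo_family.taxa]
        for tol in (0, 1, 3):
            rep = neighbor_column_tolerance(
                classify_conservation(cmarks, names), tol
            )
            assert rep.n_marks == len(cmarks)


def test_marked_alignment_rendering():
    msa = MultipleAlignment((("geneA", "MK-FW"), ("geneB", "MKRFW")))
    text = format_alignment_with_marks(
        msa, [ColumnMark("geneA", 3, 1, 2)], width=60
    )
    lines = text.splitlines()
    assert lines[0].endswith("MK-FW")
    assert lines[1].endswith("MKRFW")
    # arrow line marks column 3 with the phase digit
    arrow = lines[2]
    assert arrow[len("geneA  ") + 3] == "1"
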