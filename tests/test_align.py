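import numpy as np
import pytest

from intronkit.align import (
    MultipleAlignment,
    PairwiseAlignment,
    dotplot,
    global_align,
    local_search,
    percent_identity,
    progressive_msa,
    project_interval,
)
from intronkit.seqio import ProteinSequence
from intronkit.synthetic_data import generate_family, random_family_config

from .oracles import blosum_dict, enumerate_global_score

B = blosum_dict()
_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _random_peptide(rng, lo, hi):
    return "".join(_AA20[int(k)] for k in rng.integers(0, 20, int(rng.integers(lo, hi + 1))))


class TestGlobalAlign:
    def test_identical_sequences_score_diagonal_sum(self):
        s = "MKLVNPQRST"
        aln = global_align(ProteinSequence("a", s), ProteinSequence("b", s))
        assert "-" not in aln.aligned_a + aln.aligned_b
        assert aln.score == sum(B[(c, c)] for c in s)

    def test_single_gap_column(self):
        aln = global_align(ProteinSequence("a", "MK"), ProteinSequence("b", "MRK"))
        assert aln.ncols == 3
        assert (aln.aligned_a.count("-"), aln.aligned_b.count("-")) == (1, 0)

    def test_score_symmetric(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            a = ProteinSequence("a", _random_peptide(rng, 5, 12))
            b = ProteinSequence("b", _random_peptide(rng, 5, 12))
            assert global_align(a, b).score == global_align(b, a).score

    def test_matches_path_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            a = _random_peptide(rng, 2, 7)
            b = _random_peptide(rng, 2, 7)
            got = global_align(ProteinSequence("a", a), ProteinSequence("b", b)).score
            want = enumerate_global_score(a, b, B, 11.0, 1.0)
            assert got == pytest.approx(want)

    def test_round_trip_degapping(self):
        aln = global_align(
            ProteinSequence("a", "MKWVNPF"), ProteinSequence("b", "MKVNPFY")
        )
        assert aln.sequence_a() == "MKWVNPF"
        assert aln.sequence_b() == "MKVNPFY"


class TestLocalSearch:
    def test_verbatim_query_ranks_first(self):
        rng = np.random.default_rng(5)
        query = ProteinSequence("q", "MKWVNPQRSTWYACDEFGHI")
        decoys = [
            ProteinSequence(f"d{i}", _random_peptide(rng, 15, 25)) for i in range(20)
        ]
        collection = decoys[:10] + [ProteinSequence("hit", query.residues)] + decoys[10:]
        hits = local_search(query, collection)
        assert hits[0][0].id == "hit"
        assert hits[0][1] == sum(B[(c, c)] for c in query.residues)

    def test_min_score_filters_everything_dissimilar(self):
        query = ProteinSequence("q", "WWWWWWWW")
        hits = local_search(
            query, [ProteinSequence("d", "GGGGGGGG")], min_score=1.0
        )
        assert hits == []

    def test_planted_homolog_found_among_decoys(self):
        fam = generate_family(random_family_config(seed=31, n_taxa=2))
        query, homolog = fam.taxa[0].protein, fam.taxa[1].protein
        rng = np.random.default_rng(32)
        decoys = [
            ProteinSequence(f"d{i}", _random_peptide(rng, 200, 300))
            for i in range(50)
        ]
        collection = decoys[:25] + [homolog] + decoys[25:]
        hits = local_search(query, collection, min_score=50.0)
        assert hits[0][0].id == homolog.id


class TestProgressiveMsa:
    def test_two_sequences_equal_pairwise(self):
        a, b = ProteinSequence("a", "MKWVNP"), ProteinSequence("b", "MKVNPF")
        msa = progressive_msa([a, b])
        pw = global_align(a, b)
        assert msa.rows == ((pw.id_a, pw.aligned_a), (pw.id_b, pw.aligned_b))

    def test_identical_triplet_gap_free(self):
        seqs = [ProteinSequence(f"s{i}", "MKLVNPQRSTWY") for i in range(3)]
        msa = progressive_msa(seqs)
        assert all(row == "MKLVNPQRSTWY" for _, row in msa.rows)

    def test_duplicate_ids_rejected(self):
        seqs = [ProteinSequence("x", "MKLV"), ProteinSequence("x", "MKIV")]
        with pytest.raises(ValueError):
            progressive_msa(seqs)

    def test_row_order_is_input_order(self, demo_family):
        seqs = [t.protein for t in demo_family.taxa]
        msa = progressive_msa(seqs)
        assert msa.ids == [s.id for s in seqs]

    def test_recovers_true_homology_columns(self):
        """At moderate divergence, >=90% of true residue pairings are in
        the computed alignment."""
        fam = generate_family(random_family_config(seed=13, subst_prob=0.1))
        msa = progressive_msa([t.protein for t in fam.taxa])
        total = agree = 0
        for ta, tb in [(0, 1), (0, 2), (1, 2)]:
            a, b = fam.taxa[ta], fam.taxa[tb]
            true_pairs = set()
            col_to_b = {c: i for i, c in enumerate(b.column_map)}
            for ia, c in enumerate(a.column_map):
                if c in col_to_b:
                    true_pairs.add((ia, col_to_b[c]))
            got_pairs = set()
            cm_a = {c: i for i, c in enumerate(msa.column_map(a.name))}
            cm_b = {c: i for i, c in enumerate(msa.column_map(b.name))}
            for col in range(msa.ncols):
                if col in cm_a and col in cm_b:
                    got_pairs.add((cm_a[col], cm_b[col]))
            total += len(true_pairs)
            agree += len(true_pairs & got_pairs)
        assert agree / total >= 0.90


class TestIdentityAndProjection:
    def test_identical_sequences_full_identity(self):
        aln = global_align(ProteinSequence("a", "MKWVNP"), ProteinSequence("b", "MKWVNP"))
        assert percent_identity(aln) == 100.0

    def test_gap_columns_excluded_from_denominator(self):
        aln = PairwiseAlignment("a", "b", "MK--F", "MKRAF", 0.0)
        assert percent_identity(aln) == 100.0

    def test_identity_symmetric(self):
        a, b = ProteinSequence("a", "MKWVNPDE"), ProteinSequence("b", "MKVNPFDE")
        assert percent_identity(global_align(a, b)) == pytest.approx(
            percent_identity(global_align(b, a))
        )

    def test_empty_region_rejected(self):
        aln = PairwiseAlignment("a", "b", "MK--", "--RF", 0.0)
        with pytest.raises(ValueError):
            percent_identity(aln, region=(2, 2))

    def test_projection_identity_on_ungapped(self):
        aln = PairwiseAlignment("a", "b", "MKWVF", "MKWVF", 0.0)
        assert project_interval(aln, (2, 5)) == (2, 5)

    def test_projection_onto_gaps_is_empty(self):
        aln = PairwiseAlignment("a", "b", "MKWV", "MK--", 0.0)
        assert project_interval(aln, (2, 4)) is None

    def test_projection_matches_column_walk_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            a = ProteinSequence("a", _random_peptide(rng, 8, 15))
            b = ProteinSequence("b", _random_peptide(rng, 8, 15))
            aln = global_align(a, b)
            lo = int(rng.integers(0, len(a)))
            hi = int(rng.integers(lo, len(a))) + 1
            got = project_interval(aln, (lo, hi))
            # oracle: walk columns, record b-residues under a's interval
            bi = -1
            ai = -1
            touched = []
            for ca, cb in zip(aln.aligned_a, aln.aligned_b):
                if cb != "-":
                    bi += 1
                if ca != "-":
                    ai += 1
                    if lo <= ai < hi and cb != "-":
                        touched.append(bi)
            want = (min(touched), max(touched) + 1) if touched else None
            assert got == want


class TestDotplot:
    def test_self_comparison_has_full_diagonal(self):
        p = ProteinSequence("a", "MKWVNPQRSTWYACDEF")
        dp = dotplot(p, p, word_size=3, min_identity_per_word=3)
        assert all((i, i) in dp.hits for i in range(len(p) - 2))

    def test_disjoint_alphabets_empty(self):
        dp = dotplot(
            ProteinSequence("a", "AAAAAA"),
            ProteinSequence("b", "CCCCCC"),
            word_size=3,
            min_identity_per_word=1,
        )
        assert dp.hits == frozenset()

    def test_internal_repeat_gives_offset_line(self):
        unit = "MKWVNPQR"
        p = ProteinSequence("a", unit * 3)
        dp = dotplot(p, p, word_size=4, min_identity_per_word=4)
        period = len(unit)
        assert all(
            (i, i + period) in dp.hits for i in range(len(p) - period - 3)
        )

    def test_word_size_exceeding_length_rejected(self):
        with pytest.raises(ValueError):
            dotplot(ProteinSequence("a", "MK"), ProteinSequence("b", "MK"), 3, 1)
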