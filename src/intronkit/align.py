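"""Pairwise and progressive protein alignment, identity, projection,
dotplots and local search over user-provided sequence collections.

Pairwise alignment is standard affine-gap global/local alignment
(BLOSUM62, open 11, extend 1 by default; a gap of length L costs
``open + (L-1)*extend``), delegated to :class:`Bio.Align.PairwiseAligner`.
The progressive multiple aligner is a deterministic UPGMA-guided
profile-profile aligner: the guide tree comes from average-linkage
clustering of 3-mer cosine distances, ties broken by input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .seqio import ProteinSequence

__all__ = [
    "PairwiseAlignment",
    "MultipleAlignment",
    "DomainInterval",
    "DotplotMatrix",
    "global_align",
    "local_search",
    "progressive_msa",
    "percent_identity",
    "project_interval",
    "dotplot",
]

DOMAIN_NAMES = {
    "NT", "CT", "GBD", "CBD", "SBD", "LIM", "PET", "RRM", "SPOC",
    "RID", "RBP-ID", "CID", "other",
}


def _column_maps(aligned: str) -> list[int]:
    """Residue index -> alignment column for one gapped row."""
    return [col for col, ch in enumerate(aligned) if ch != "-"]


@dataclass(frozen=True)
class PairwiseAlignment:
    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")
        if any(
            a == "-" and b == "-" for a, b in zip(self.aligned_a, self.aligned_b)
        ):
            raise ValueError("column with gap in both rows")

    @property
    def ncols(self) -> int:
        return len(self.aligned_a)

    @property
    def column_map_a(self) -> list[int]:
        return _column_maps(self.aligned_a)

    @property
    def column_map_b(self) -> list[int]:
        return _column_maps(self.aligned_b)

    def sequence_a(self) -> str:
        return self.aligned_a.replace("-", "")

    def sequence_b(self) -> str:
        return self.aligned_b.replace("-", "")


@dataclass(frozen=True)
class MultipleAlignment:
    rows: tuple[tuple[str, str], ...]  # (id, gapped string), input order

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty alignment")
        ncols = len(self.rows[0][1])
        if any(len(r) != ncols for _, r in self.rows):
            raise ValueError("alignment rows differ in length")
        for col in range(ncols):
            if all(r[col] == "-" for _, r in self.rows):
                raise ValueError(f"all-gap column {col}")

    @property
    def ncols(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.rows]

    def row(self, seq_id: str) -> str:
        for i, r in self.rows:
            if i == seq_id:
                return r
        raise KeyError(seq_id)

    def column_map(self, seq_id: str) -> list[int]:
        return _column_maps(self.row(seq_id))


@dataclass(frozen=True)
class DomainInterval:
    """A named protein region, e.g. the PET or a LIM domain."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.name not in DOMAIN_NAMES:
            raise ValueError(f"unknown domain name {self.name!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid domain interval [{self.start}, {self.end})")


def _make_aligner(
    matrix: str, gap_open: float, gap_extend: float, mode: str
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    aligner.mode = mode
    return aligner


def global_align(
    a: ProteinSequence,
    b: ProteinSequence,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> PairwiseAlignment:
    """Optimal global alignment with affine gaps; deterministic traceback
    (the aligner's first-reported optimum)."""
    aligner = _make_aligner(matrix, gap_open, gap_extend, "global")
    try:
        alns = aligner.align(a.residues, b.residues)
    except ValueError as exc:
        raise ValueError(f"cannot align '{a.id}' vs '{b.id}': {exc}") from exc
    best = alns[0]
    return PairwiseAlignment(a.id, b.id, str(best[0]), str(best[1]), float(best.score))


def local_search(
    query: ProteinSequence,
    collection: Sequence[ProteinSequence],
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    min_score: float = 0.0,
) -> list[tuple[ProteinSequence, float]]:
    """Rank a sequence collection by local-alignment score to the query.

    A network-free stand-in for a translated database search: hits are
    sorted by score descending, ties by collection order, scores below
    ``min_score`` dropped.
    """
    if not collection:
        raise ValueError("empty collection")
    aligner = _make_aligner(matrix, gap_open, gap_extend, "local")
    scored = []
    for idx, subject in enumerate(collection):
        score = float(aligner.score(query.residues, subject.residues))
        if score >= min_score:
            scored.append((idx, subject, score))
    scored.sort(key=lambda t: (-t[2], t[0]))
    return [(subject, score) for _, subject, score in scored]


# ---------------------------------------------------------------------------
# progressive MSA

_NEG = -1.0e18


def _kmer_cosine_distances(seqs: Sequence[str], k: int = 3) -> np.ndarray:
    vecs = []
    vocab: dict[str, int] = {}
    counts_list = []
    for s in seqs:
        c: dict[int, int] = {}
        for i in range(max(len(s) - k + 1, 1)):
            w = s[i : i + k]
            j = vocab.setdefault(w, len(vocab))
            c[j] = c.get(j, 0) + 1
        counts_list.append(c)
    dim = max(len(vocab), 1)
    for c in counts_list:
        v = np.zeros(dim)
        for j, n in c.items():
            v[j] = n
        vecs.append(v)
    m = len(seqs)
    dist = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            na, nb = np.linalg.norm(vecs[i]), np.linalg.norm(vecs[j])
            cos = vecs[i] @ vecs[j] / (na * nb) if na and nb else 0.0
            dist[i, j] = dist[j, i] = 1.0 - cos
    return dist


def _profile_align(
    pa: np.ndarray, pb: np.ndarray, bmat: np.ndarray, go: float, ge: float
) -> tuple[np.ndarray, np.ndarray]:
    """Global affine profile-profile alignment.

    Profiles are integer arrays (n_seqs x ncols) of matrix-alphabet
    residue indices, -1 for gaps.  Column pair score is the mean
    substitution score over non-gap residue pairs.  Returns the two
    profiles with gap columns (-1) inserted.
    """
    nalpha = bmat.shape[0]

    def col_counts(prof: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        L = prof.shape[1]
        counts = np.zeros((L, nalpha))
        for r in prof:
            ok = r >= 0
            np.add.at(counts, np.nonzero(ok)[0], np.eye(nalpha)[r[ok]])
        return counts, counts.sum(axis=1)

    ca, na = col_counts(pa)
    cb, nb = col_counts(pb)
    denom = np.outer(na, nb)
    denom[denom == 0] = 1.0
    S = (ca @ bmat @ cb.T) / denom
    La, Lb = pa.shape[1], pb.shape[1]
    M = np.full((La + 1, Lb + 1), _NEG)
    E = np.full((La + 1, Lb + 1), _NEG)  # gap in A (consume B column)
    F = np.full((La + 1, Lb + 1), _NEG)  # gap in B (consume A column)
    M[0, 0] = 0.0
    for j in range(1, Lb + 1):
        E[0, j] = -go - (j - 1) * ge
    for i in range(1, La + 1):
        F[i, 0] = -go - (i - 1) * ge
        Mi, Ei, Fi = M[i], E[i], F[i]
        prevM, prevE, prevF = M[i - 1], E[i - 1], F[i - 1]
        Fi[1:] = np.maximum(
            np.maximum(prevM[1:], prevE[1:]) - go, prevF[1:] - ge
        )
        # within-row recurrences need a scalar loop (E depends on j-1)
        for j in range(1, Lb + 1):
            best_prev = max(prevM[j - 1], prevE[j - 1], prevF[j - 1])
            Mi[j] = best_prev + S[i - 1, j - 1]
            Ei[j] = max(max(Mi[j - 1], Fi[j - 1]) - go, Ei[j - 1] - ge)
    # traceback, deterministic preference M > F > E
    i, j = La, Lb
    state = max(
        (("M", M[i, j]), ("F", F[i, j]), ("E", E[i, j])), key=lambda t: t[1]
    )[0]
    cols: list[tuple[int, int]] = []  # (col of A or -1, col of B or -1)
    while i > 0 or j > 0:
        if state == "M":
            cols.append((i - 1, j - 1))
            prev = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            for st, arr in (("M", M), ("F", F), ("E", E)):
                if abs(arr[i, j] - prev) < 1e-9:
                    state = st
                    break
        elif state == "F":
            cols.append((i - 1, -1))
            v = F[i, j]
            if abs(F[i - 1, j] - ge - v) < 1e-9 and i > 1:
                state = "F"
            elif abs(M[i - 1, j] - go - v) < 1e-9:
                state = "M"
            elif abs(E[i - 1, j] - go - v) < 1e-9:
                state = "E"
            else:
                state = "F"
            i -= 1
        else:  # E
            cols.append((-1, j - 1))
            v = E[i, j]
            if abs(E[i, j - 1] - ge - v) < 1e-9 and j > 1:
                state = "E"
            elif abs(M[i, j - 1] - go - v) < 1e-9:
                state = "M"
            elif abs(F[i, j - 1] - go - v) < 1e-9:
                state = "F"
            else:
                state = "E"
            j -= 1
        if i == 0 and j > 0:
            state = "E"
        elif j == 0 and i > 0:
            state = "F"
    cols.reverse()
    L = len(cols)
    out_a = np.full((pa.shape[0], L), -1, dtype=np.int64)
    out_b = np.full((pb.shape[0], L), -1, dtype=np.int64)
    for c, (ia, ib) in enumerate(cols):
        if ia >= 0:
            out_a[:, c] = pa[:, ia]
        if ib >= 0:
            out_b[:, c] = pb[:, ib]
    return out_a, out_b


def progressive_msa(
    seqs: Sequence[ProteinSequence],
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> MultipleAlignment:
    """Deterministic UPGMA-guided progressive multiple alignment.

    Row order equals input order.  Two input sequences reduce to a plain
    pairwise global alignment.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids in MSA input")
    mat = substitution_matrices.load(matrix)
    alphabet = str(mat.alphabet)
    bmat = np.asarray(mat, dtype=float)
    aa_idx = {aa: i for i, aa in enumerate(alphabet)}

    def encode(s: str) -> np.ndarray:
        return np.array([[aa_idx[c] for c in s]], dtype=np.int64)

    if len(seqs) == 2:
        pw = global_align(seqs[0], seqs[1], matrix, gap_open, gap_extend)
        return MultipleAlignment(
            ((pw.id_a, pw.aligned_a), (pw.id_b, pw.aligned_b))
        )

    dist = _kmer_cosine_distances([s.residues for s in seqs])
    Z = linkage(squareform(dist, checks=False), method="average")
    profiles: dict[int, tuple[np.ndarray, list[int]]] = {
        i: (encode(s.residues), [i]) for i, s in enumerate(seqs)
    }
    nleaf = len(seqs)
    for step, (left, right, _, _) in enumerate(Z):
        pa, members_a = profiles.pop(int(left))
        pb, members_b = profiles.pop(int(right))
        oa, ob = _profile_align(pa, pb, bmat, gap_open, gap_extend)
        profiles[nleaf + step] = (
            np.vstack([oa, ob]),
            members_a + members_b,
        )
    prof, members = profiles.popitem()[1]
    # drop all-gap columns (possible after nested merges)
    keep = (prof >= 0).any(axis=0)
    prof = prof[:, keep]
    order = np.argsort(members)
    rows = []
    for leaf_rank in order:
        row = prof[leaf_rank]
        gapped = "".join("-" if x < 0 else alphabet[x] for x in row)
        rows.append((ids[members[leaf_rank]], gapped))
    return MultipleAlignment(tuple(rows))


# ---------------------------------------------------------------------------
# identity / projection / dotplot


def percent_identity(
    aln: PairwiseAlignment, region: tuple[int, int] | None = None
) -> float:
    """Percent identical positions over columns where both rows bear a
    residue (gap-excluded denominator), optionally restricted to an
    alignment-column interval."""
    lo, hi = region if region is not None else (0, aln.ncols)
    if not 0 <= lo <= hi <= aln.ncols:
        raise ValueError(f"region [{lo}, {hi}) outside alignment columns")
    both = ident = 0
    for a, b in zip(aln.aligned_a[lo:hi], aln.aligned_b[lo:hi]):
        if a != "-" and b != "-":
            both += 1
            if a == b:
                ident += 1
    if both == 0:
        raise ValueError("region has no co-aligned columns")
    return 100.0 * ident / both


def project_interval(
    aln: PairwiseAlignment, interval: tuple[int, int]
) -> tuple[int, int] | None:
    """Project a residue interval of sequence a onto sequence b.

    Returns the smallest b-interval covering every b residue co-aligned
    with the a-interval, or None if the region aligns only to gaps.
    """
    lo, hi = interval
    if not 0 <= lo <= hi <= len(aln.sequence_a()):
        raise ValueError(f"interval [{lo}, {hi}) outside sequence '{aln.id_a}'")
    cmap_a = aln.column_map_a
    b_residues = []
    # walk columns once, tracking b residue indices
    b_at_col = {}
    bi = 0
    for col, ch in enumerate(aln.aligned_b):
        if ch != "-":
            b_at_col[col] = bi
            bi += 1
    for r in range(lo, hi):
        col = cmap_a[r]
        if col in b_at_col:
            b_residues.append(b_at_col[col])
    if not b_residues:
        return None
    return (min(b_residues), max(b_residues) + 1)


@dataclass(frozen=True)
class DotplotMatrix:
    word_size: int
    min_identity_per_word: int
    shape: tuple[int, int]
    hits: frozenset[tuple[int, int]]


def dotplot(
    a: ProteinSequence,
    b: ProteinSequence,
    word_size: int = 10,
    min_identity_per_word: int = 5,
) -> DotplotMatrix:
    """Word-based dotplot: a hit at (i, j) iff the ``word_size`` windows
    starting there share at least ``min_identity_per_word`` identities."""
    if word_size < 1:
        raise ValueError("word_size must be >= 1")
    if word_size > min(len(a), len(b)):
        raise ValueError("word_size exceeds sequence length")
    ra = np.frombuffer(a.residues.encode(), dtype=np.uint8)
    rb = np.frombuffer(b.residues.encode(), dtype=np.uint8)
    eq = (ra[:, None] == rb[None, :]).astype(np.int32)
    na, nb = len(ra) - word_size + 1, len(rb) - word_size + 1
    counts = np.zeros((na, nb), dtype=np.int32)
    for k in range(word_size):
        counts += eq[k : k + na, k : k + nb]
    ii, jj = np.nonzero(counts >= min_identity_per_word)
    return DotplotMatrix(
        word_size=word_size,
        min_identity_per_word=min_identity_per_word,
        shape=(na, nb),
        hits=frozenset(zip(ii.tolist(), jj.tolist())),
    )
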