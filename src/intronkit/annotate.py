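"""Homology-guided gene annotation over GT..AG introns.

The annotation procedure is a dynamic program that aligns a reference
protein to genomic DNA codon by codon.  Introns may open only at a GT
dinucleotide and close at an AG, may interrupt a codon at phase 0, 1 or
2, cost a flat ``intron_open_penalty`` within the configured length
bounds, and must preserve the reading frame across the junction.  The
optimum is a local (Smith-Waterman-style) chain of codon-aligned exon
blocks: the maximum-score gene structure under the model, computed
exactly.

Scoring units are those of the protein substitution matrix (BLOSUM62 by
default).  Genomic-side gaps (unaligned codons that remain coding) are
charged ``gap_open`` plus ``gap_extend`` per nucleotide beyond the first
codon, so that skipping a plausible intron as a long gap is always more
expensive than opening the intron itself; protein-side gaps are charged
per residue as usual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from Bio.Align import substitution_matrices

from .seqio import (
    GeneModel,
    NucleotideSequence,
    ProteinSequence,
    reverse_complement,
    translate_cds,
)

__all__ = [
    "SplicedAlignParams",
    "Intron",
    "SplicedAlignment",
    "find_splice_signals",
    "spliced_align",
    "gene_model_from_spliced",
    "at_content_scan",
]

_NEG = -1.0e18
_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_BASES = "ACGTN"


def _load_matrix(name: str) -> tuple[np.ndarray, dict[str, int]]:
    mat = substitution_matrices.load(name)
    alphabet = str(mat.alphabet)
    arr = np.asarray(mat, dtype=float)
    return arr, {aa: i for i, aa in enumerate(alphabet)}


@dataclass(frozen=True)
class SplicedAlignParams:
    """Parameters of the spliced protein-to-genome aligner.

    ``max_intron_len`` defaults to 25 kb to accommodate genes whose
    interaction motifs sit >20 kb downstream of the upstream exon, as
    observed in myriapod Notch-repressor loci.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    intron_open_penalty: float = 40.0
    min_intron_len: int = 40
    max_intron_len: int = 25_000

    def __post_init__(self) -> None:
        if self.min_intron_len < 4:
            raise ValueError("min_intron_len must be >= 4 (room for GT..AG)")
        if self.max_intron_len < self.min_intron_len:
            raise ValueError("max_intron_len must be >= min_intron_len")


@dataclass(frozen=True)
class Intron:
    start: int  # forward-strand [start, end)
    end: int
    donor: str
    acceptor: str
    phase: int


@dataclass(frozen=True)
class SplicedAlignment:
    """A scored chain of codon-aligned exon blocks separated by introns.

    ``blocks`` are maximal ungapped runs, each pairing a protein interval
    [p0, p1) with a genomic interval [g0, g1) of exactly three times its
    length.  Split codons at intron junctions and gap segments lie
    between blocks; ``exons`` are the full coding genomic intervals.
    Intervals are forward-strand; ``blocks``, ``introns`` and ``exons``
    are listed in transcription order (descending coordinates on '-').
    """

    protein_id: str
    genomic_id: str
    strand: Literal["+", "-"]
    score: float
    blocks: tuple[tuple[tuple[int, int], tuple[int, int]], ...]
    introns: tuple[Intron, ...]
    exons: tuple[tuple[int, int], ...]
    protein_interval: tuple[int, int]

    @property
    def is_empty(self) -> bool:
        return not self.blocks

    def __post_init__(self) -> None:
        for intr in self.introns:
            if (intr.donor, intr.acceptor) != ("GT", "AG"):
                raise ValueError("introns must use the GT..AG rule")
            if intr.phase not in (0, 1, 2):
                raise ValueError("intron phase must be 0, 1 or 2")


def empty_alignment(
    protein_id: str, genomic_id: str, strand: Literal["+", "-"] = "+"
) -> SplicedAlignment:
    """Explicit no-alignment result (score 0, no blocks)."""
    return SplicedAlignment(protein_id, genomic_id, strand, 0.0, (), (), (), (0, 0))


def find_splice_signals(nt: NucleotideSequence) -> tuple[list[int], list[int]]:
    """All GT donor and AG acceptor dinucleotide start positions."""
    s = nt.residues
    donors = [i for i in range(len(s) - 1) if s[i : i + 2] == "GT"]
    acceptors = [i for i in range(len(s) - 1) if s[i : i + 2] == "AG"]
    return donors, acceptors


# ---------------------------------------------------------------------------
# DP internals


class _Scorer:
    """Precomputed lookup tables for one (params, genomic) combination."""

    def __init__(self, g: str, params: SplicedAlignParams):
        self.params = params
        self.mat, self.aa_idx = _load_matrix(params.matrix)
        self.g = g
        n = len(g)
        self.n = n
        gi = np.fromiter((_BASE_IDX[c] for c in g), dtype=np.int64, count=n)
        self.gi = gi
        # aa index of the codon *ending* at j (j >= 3), X for any N
        codon_aa = np.full(n + 1, -1, dtype=np.int64)
        if n >= 3:
            lut = self._codon_lut()
            ids = gi[:-2] * 25 + gi[1:-1] * 5 + gi[2:]
            codon_aa[3:] = lut[ids]
        self.codon_aa = codon_aa
        # donors / acceptor-end positions
        self.donors = np.array(
            [i for i in range(n - 1) if g[i : i + 2] == "GT"], dtype=np.int64
        )
        self.acc_end = np.array(
            [e for e in range(2, n + 1) if g[e - 2 : e] == "AG"], dtype=np.int64
        )
        self._build_intron_tables()

    def _codon_lut(self) -> np.ndarray:
        lut = np.empty(125, dtype=np.int64)
        x = self.aa_idx["X"]
        for i0, b0 in enumerate(_BASES):
            for i1, b1 in enumerate(_BASES):
                for i2, b2 in enumerate(_BASES):
                    codon = b0 + b1 + b2
                    aa = "X" if "N" in codon else translate_cds(codon)
                    lut[i0 * 25 + i1 * 5 + i2] = self.aa_idx.get(aa, x)
        return lut

    def _build_intron_tables(self) -> None:
        """Group donors by the pending nucleotides of a split codon.

        For an intron of phase p the p nucleotides preceding the donor
        complete a codon with the 3-p nucleotides following the
        acceptor; donors are bucketed by those pending nucleotides so
        the exit codon score is a single matrix lookup per class.
        """
        p_ = self.params
        g, n = self.g, self.n
        acc = self.acc_end
        self.intron_classes: dict[int, list[tuple[np.ndarray, np.ndarray, np.ndarray]]] = {}
        for phase in (0, 1, 2):
            classes = []
            if len(self.donors) and len(acc):
                dsel = self.donors[self.donors - phase >= 0]
                keys = {}
                for d in dsel:
                    pending = g[d - phase : d]
                    keys.setdefault(pending, []).append(int(d))
                for pending, dlist in sorted(keys.items()):
                    dl = np.asarray(dlist, dtype=np.int64)
                    # eligibility: min <= e - d <= max  (intron = [d, e))
                    span = acc[:, None] - dl[None, :]
                    mask = (span >= p_.min_intron_len) & (span <= p_.max_intron_len)
                    if not mask.any():
                        continue
                    # aa of the completed codon per acceptor-end e
                    width = 3 - phase
                    aa = np.full(len(acc), -1, dtype=np.int64)
                    ok = acc + width <= n
                    for k in np.nonzero(ok)[0]:
                        e = int(acc[k])
                        codon = pending + g[e : e + width]
                        aa[k] = (
                            self.aa_idx["X"]
                            if "N" in codon
                            else self.aa_idx.get(translate_cds(codon), self.aa_idx["X"])
                        )
                    classes.append((dl, mask, aa))
            self.intron_classes[phase] = classes

    def protein_row(self, aa: str) -> int:
        try:
            return self.aa_idx[aa]
        except KeyError:
            raise ValueError(f"residue {aa!r} not in matrix alphabet") from None


def _forward_dp(
    p: str, sc: _Scorer
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fill the three state matrices M (match), Gp (genomic gap), Gg
    (protein gap); local alignments may start at score 0 before any
    matched codon."""
    prm = sc.params
    m, n = len(p), sc.n
    go, ge, pen = prm.gap_open, prm.gap_extend, prm.intron_open_penalty
    M = np.full((m + 1, n + 1), _NEG)
    Gp = np.full((m + 1, n + 1), _NEG)
    Gg = np.full((m + 1, n + 1), _NEG)
    acc = sc.acc_end
    valid_codon = sc.codon_aa >= 0
    for i in range(1, m + 1):
        ai = sc.protein_row(p[i - 1])
        prevH = np.maximum(np.maximum(M[i - 1], Gp[i - 1]), Gg[i - 1])
        base_prev = np.maximum(prevH, 0.0)
        Mi = np.full(n + 1, _NEG)
        if n >= 3:
            S = np.where(valid_codon, sc.mat[ai, np.maximum(sc.codon_aa, 0)], _NEG)
            Mi[3:] = S[3:] + base_prev[: n - 2]
        for phase in (0, 1, 2):
            width = 3 - phase
            for dl, mask, aa_exit in sc.intron_classes[phase]:
                vals = np.maximum(prevH[dl - phase], 0.0)
                W = np.where(mask, vals[None, :], _NEG).max(axis=1)
                sel = (aa_exit >= 0) & (W > _NEG / 2)
                if not sel.any():
                    continue
                jpos = acc[sel] + width
                cand = W[sel] - pen + sc.mat[ai, aa_exit[sel]]
                np.maximum.at(Mi, jpos, cand)
        # protein-side gap (residue aligned to nothing): per-residue affine
        Gg[i] = np.maximum(
            np.maximum(M[i - 1], Gp[i - 1]) - go, Gg[i - 1] - ge
        )
        # genomic-side gap (unaligned coding codons): within-row scan,
        # extension charged per nucleotide (3*ge per codon past the first)
        base = np.maximum(Mi, Gg[i]) - go
        Gpi = np.full(n + 1, _NEG)
        step = 3.0 * ge
        for r in range(3):
            idx = np.arange(r, n + 1, 3)
            if len(idx) >= 2:
                b = base[idx]
                ks = np.arange(len(idx), dtype=float)
                run = np.maximum.accumulate(b + step * ks)
                Gpi[idx[1:]] = run[:-1] - step * (ks[1:] - 1.0)
        M[i], Gp[i] = Mi, Gpi
    return M, Gp, Gg


def _isclose(a: float, b: float) -> bool:
    return math.isclose(a, b, rel_tol=0.0, abs_tol=1e-6)


def _traceback(
    p: str, sc: _Scorer, M: np.ndarray, Gp: np.ndarray, Gg: np.ndarray
) -> tuple[float, list[tuple]]:
    prm = sc.params
    best = float(M.max())
    if best <= 0.0:
        return best, []
    flat = int(np.argmax(M))
    i, j = divmod(flat, M.shape[1])
    events: list[tuple] = []
    state = "M"

    def pick_prev_state(i_, j_, value) -> str:
        # preference order: match, genomic gap, protein gap
        for st, arr in (("M", M), ("Gp", Gp), ("Gg", Gg)):
            if _isclose(arr[i_, j_], value):
                return st
        raise AssertionError("traceback: predecessor state not found")

    def resolve_start(i_, j_) -> str | None:
        """Return predecessor state at (i_, j_) or None for a fresh start."""
        prev = max(M[i_, j_], Gp[i_, j_], Gg[i_, j_])
        if prev <= 0.0 or prev < _NEG / 2:
            return None
        return pick_prev_state(i_, j_, prev)

    go, ge, pen = prm.gap_open, prm.gap_extend, prm.intron_open_penalty
    while True:
        if state == "M":
            v = M[i, j]
            moved = False
            if j >= 3 and sc.codon_aa[j] >= 0:
                ai = sc.protein_row(p[i - 1])
                s = sc.mat[ai, sc.codon_aa[j]]
                prev = max(M[i - 1, j - 3], Gp[i - 1, j - 3], Gg[i - 1, j - 3])
                if _isclose(v, s + max(prev, 0.0)):
                    events.append(("match", i - 1, j - 3, j))
                    nxt = resolve_start(i - 1, j - 3)
                    if (
                        nxt is None
                        or not _isclose(v, s + prev)
                    ):
                        if _isclose(v, s):  # fresh start
                            return best, events[::-1]
                    if nxt is None:
                        return best, events[::-1]
                    i, j, state = i - 1, j - 3, nxt
                    moved = True
            if not moved:
                # an intron exit produced this cell; prefer low phase and
                # the leftmost eligible donor (deterministic tie-break)
                found = False
                ai = sc.protein_row(p[i - 1])
                for phase in (0, 1, 2):
                    width = 3 - phase
                    e = j - width
                    if e < 2 or sc.g[e - 2 : e] != "AG":
                        continue
                    suffix = sc.g[e : e + width]
                    for d in sorted(
                        int(x)
                        for x in sc.donors
                        if prm.min_intron_len <= e - x <= prm.max_intron_len
                        and x - phase >= 0
                    ):
                        pending = sc.g[d - phase : d]
                        codon = pending + suffix
                        aa = "X" if "N" in codon else translate_cds(codon)
                        s = sc.mat[ai, sc.aa_idx.get(aa, sc.aa_idx["X"])]
                        prev = max(
                            M[i - 1, d - phase],
                            Gp[i - 1, d - phase],
                            Gg[i - 1, d - phase],
                        )
                        if _isclose(v, max(prev, 0.0) - pen + s):
                            events.append(
                                ("smatch", i - 1, d - phase, d, e, j, phase)
                            )
                            if prev <= 0.0 or not _isclose(v, prev - pen + s):
                                return best, events[::-1]
                            i, j = i - 1, d - phase
                            state = pick_prev_state(i, j, prev)
                            found = True
                            break
                    if found:
                        break
                if not found:
                    raise AssertionError("traceback failed in match state")
        elif state == "Gp":
            v = Gp[i, j]
            if _isclose(v, Gp[i, j - 3] - 3.0 * ge):
                events.append(("gins", j - 3, j))
                j -= 3
            else:
                prev = max(M[i, j - 3], Gg[i, j - 3])
                assert _isclose(v, prev - go), "traceback failed in Gp state"
                events.append(("gins", j - 3, j))
                j -= 3
                state = "M" if _isclose(M[i, j], prev) else "Gg"
        else:  # Gg
            v = Gg[i, j]
            if _isclose(v, Gg[i - 1, j] - ge):
                events.append(("pdel", i - 1))
                i -= 1
            else:
                prev = max(M[i - 1, j], Gp[i - 1, j])
                assert _isclose(v, prev - go), "traceback failed in Gg state"
                events.append(("pdel", i - 1))
                i -= 1
                state = "M" if _isclose(M[i, j], prev) else "Gp"


def _events_to_alignment(
    events: list[tuple],
    score: float,
    protein_id: str,
    genomic_id: str,
    strand: Literal["+", "-"],
    n: int,
) -> SplicedAlignment:
    """Assemble blocks/introns/exons from forward-order DP events.

    Events use the DP-strand coordinate system; for '-' alignments they
    are mapped back to the forward strand (x -> n - x).
    """
    blocks: list[tuple[tuple[int, int], tuple[int, int]]] = []
    introns: list[Intron] = []
    coding: list[tuple[int, int]] = []  # DP-strand coding intervals

    def add_coding(s: int, e: int, new_exon: bool = False) -> None:
        if coding and not new_exon and coding[-1][1] == s:
            coding[-1] = (coding[-1][0], e)
        else:
            coding.append((s, e))

    cur_block: list[int] | None = None  # [p0, p1, g0, g1]
    p_lo, p_hi = None, None
    for ev in events:
        kind = ev[0]
        if kind == "match":
            _, pi, gs, geend = ev
            p_lo = pi if p_lo is None else p_lo
            p_hi = pi + 1
            add_coding(gs, geend)
            if cur_block and cur_block[1] == pi and cur_block[3] == gs:
                cur_block[1], cur_block[3] = pi + 1, geend
            else:
                if cur_block:
                    blocks.append(
                        ((cur_block[0], cur_block[1]), (cur_block[2], cur_block[3]))
                    )
                cur_block = [pi, pi + 1, gs, geend]
        elif kind == "smatch":
            _, pi, gs, d, e, geend, phase = ev
            p_lo = pi if p_lo is None else p_lo
            p_hi = pi + 1
            if phase > 0:
                add_coding(gs, d)
            introns.append(Intron(d, e, "GT", "AG", phase))
            add_coding(e, geend, new_exon=True)
            if cur_block:
                blocks.append(
                    ((cur_block[0], cur_block[1]), (cur_block[2], cur_block[3]))
                )
                cur_block = None
        elif kind == "gins":
            _, gs, geend = ev
            add_coding(gs, geend)
            if cur_block:
                blocks.append(
                    ((cur_block[0], cur_block[1]), (cur_block[2], cur_block[3]))
                )
                cur_block = None
        elif kind == "pdel":
            _, pi = ev
            p_lo = pi if p_lo is None else p_lo
            p_hi = pi + 1
            if cur_block:
                blocks.append(
                    ((cur_block[0], cur_block[1]), (cur_block[2], cur_block[3]))
                )
                cur_block = None
    if cur_block:
        blocks.append(((cur_block[0], cur_block[1]), (cur_block[2], cur_block[3])))

    if strand == "-":
        blocks = [((p0, p1), (n - g1, n - g0)) for (p0, p1), (g0, g1) in blocks]
        introns = [
            Intron(n - it.end, n - it.start, it.donor, it.acceptor, it.phase)
            for it in introns
        ]
        coding = [(n - e, n - s) for s, e in coding]
    return SplicedAlignment(
        protein_id=protein_id,
        genomic_id=genomic_id,
        strand=strand,
        score=score,
        blocks=tuple(blocks),
        introns=tuple(introns),
        exons=tuple(coding),
        protein_interval=(p_lo if p_lo is not None else 0, p_hi if p_hi is not None else 0),
    )


def _align_one_strand(
    protein: ProteinSequence,
    genomic: NucleotideSequence,
    strand: Literal["+", "-"],
    params: SplicedAlignParams,
) -> SplicedAlignment:
    g = (
        genomic.residues
        if strand == "+"
        else reverse_complement(genomic).residues
    )
    sc = _Scorer(g, params)
    M, Gp, Gg = _forward_dp(protein.residues, sc)
    score, events = _traceback(protein.residues, sc, M, Gp, Gg)
    if not events:
        return empty_alignment(protein.id, genomic.id, strand)
    return _events_to_alignment(
        events, score, protein.id, genomic.id, strand, len(g)
    )


def spliced_align(
    protein: ProteinSequence,
    genomic: NucleotideSequence,
    strand: Literal["+", "-", None] = None,
    params: SplicedAlignParams | None = None,
) -> SplicedAlignment:
    """Optimal spliced alignment of ``protein`` against ``genomic``.

    With ``strand=None`` both strands are searched and the better score
    wins (ties go to '+').  A best score <= 0 yields an explicit empty
    alignment rather than an exception.
    """
    params = params or SplicedAlignParams()
    if len(genomic) < 3:
        raise ValueError("genomic sequence shorter than one codon")
    if strand in ("+", "-"):
        return _align_one_strand(protein, genomic, strand, params)
    fwd = _align_one_strand(protein, genomic, "+", params)
    rev = _align_one_strand(protein, genomic, "-", params)
    return fwd if fwd.score >= rev.score else rev


def gene_model_from_spliced(
    sa: SplicedAlignment,
    genomic: NucleotideSequence,
    permit_internal_stop: bool = False,
) -> GeneModel:
    """Turn a spliced alignment into a gene model.

    An in-frame stop codon in the spliced CDS raises (naming the codon)
    unless ``permit_internal_stop`` is set, in which case the codon
    translates to X; the permissive mode supports loci where read-through
    beyond an annotated stop is biologically plausible.
    """
    if sa.is_empty:
        raise ValueError("cannot build a gene model from an empty alignment")
    exons = tuple(sorted(sa.exons))
    phases = tuple(it.phase for it in sa.introns)
    parts = "".join(genomic.residues[s:e] for s, e in exons)
    if sa.strand == "-":
        parts = str(reverse_complement(NucleotideSequence("tmp", parts)).residues)
    aa = translate_cds(parts)
    if "*" in aa:
        pos = aa.index("*")
        if not permit_internal_stop:
            raise ValueError(
                f"internal stop codon at spliced codon {pos} "
                f"(protein '{sa.protein_id}' on '{sa.genomic_id}'); "
                "pass permit_internal_stop=True to translate it as X"
            )
        aa = aa.replace("*", "X")
    protein = ProteinSequence(f"{sa.genomic_id}|{sa.protein_id}", aa)
    return GeneModel(
        seq_id=sa.genomic_id,
        strand=sa.strand,
        exons=exons,
        intron_phases=phases,
        protein=protein,
        gene_id=f"{sa.genomic_id}.{sa.protein_id}",
    )


def at_content_scan(
    nt: NucleotideSequence, window: int, step: int = 0
) -> list[tuple[int, float]]:
    """Sliding-window AT fraction, the heuristic used to spot AT-rich
    untranslated trailer sequence downstream of a coding region.

    N residues are excluded from numerator and denominator; a window of
    only Ns reports 0.0.  A window larger than the sequence collapses to
    a single whole-sequence window.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    step = step or window
    if step < 1:
        raise ValueError("step must be >= 1")
    s = nt.residues
    if window > len(s):
        window = len(s)
        starts = [0]
    else:
        starts = list(range(0, len(s) - window + 1, step))
    out = []
    for st in starts:
        win = s[st : st + window]
        at = win.count("A") + win.count("T")
        denom = len(win) - win.count("N")
        out.append((st, at / denom if denom else 0.0))
    return out
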