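"""Independent reference implementations used to cross-check the
library: plain enumeration and dictionary lookups, no shared code with
the algorithms under test."""

from __future__ import annotations

import math

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_AA = dict(_TABLE.forward_table)
CODON_AA.update({c: "*" for c in _TABLE.stop_codons})


def codon_lookup_translate(seq: str, offset: int = 0) -> str:
    """Direct per-codon dictionary translation (stops retained, N -> X)."""
    out = []
    s = seq[offset:]
    for k in range(0, len(s) - len(s) % 3, 3):
        codon = s[k : k + 3]
        out.append("X" if "N" in codon else CODON_AA[codon])
    return "".join(out)


def blosum_dict(name: str = "BLOSUM62") -> dict[tuple[str, str], float]:
    mat = substitution_matrices.load(name)
    alpha = str(mat.alphabet)
    return {
        (a, b): float(mat[i, j])
        for i, a in enumerate(alpha)
        for j, b in enumerate(alpha)
    }


def enumerate_global_score(
    a: str, b: str, B: dict, go: float, ge: float
) -> float:
    """Best global affine-gap score by exhaustive path enumeration.

    A gap of length L costs go + (L-1)*ge; end gaps are charged.
    Exponential — only for peptides of length <= ~8.
    """
    best = -math.inf

    def rec(i: int, j: int, score: float, prev: str | None) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + B[(a[i], b[j])], "M")
        if i < len(a):
            rec(i + 1, j, score - (ge if prev == "F" else go), "F")
        if j < len(b):
            rec(i, j + 1, score - (ge if prev == "E" else go), "E")

    rec(0, 0, 0.0, None)
    return best


def enumerate_spliced_score(
    protein: str,
    genomic: str,
    B: dict,
    intron_penalty: float,
    min_intron: int,
    max_intron: int,
) -> float:
    """Best score of an ungapped local placement (any protein substring,
    any genomic start) with at most one GT..AG intron, by explicit
    enumeration of every (protein start, genomic start, exon split,
    donor, acceptor, extension) candidate.  Alignments start and end on
    a matched codon; an intron may interrupt a codon at phase 0, 1 or 2
    and costs ``intron_penalty`` within the length bounds."""
    m, n = len(protein), len(genomic)

    def aa_of(codon: str) -> str:
        return "X" if "N" in codon else CODON_AA[codon]

    # codon score of residue k against the codon starting at g
    S = [
        [B[(protein[k], aa_of(genomic[g : g + 3]))] for g in range(n - 2)]
        for k in range(m)
    ]
    acceptor_ends = [e for e in range(2, n + 1) if genomic[e - 2 : e] == "AG"]
    best = 0.0
    for k0 in range(m):
        for g0 in range(n - 2):
            # intron-free runs: every extension is a candidate alignment
            score = 0.0
            k, g = k0, g0
            while k < m and g <= n - 3:
                score += S[k][g]
                best = max(best, score)
                k += 1
                g += 3
            # runs with one intron after c full prefix codons and p
            # pending nucleotides of the interrupted codon
            prefix = 0.0
            for c in range(0, m - k0 + 1):
                if c > 0:
                    g_prev = g0 + 3 * (c - 1)
                    if g_prev > n - 3:
                        break
                    prefix += S[k0 + c - 1][g_prev]
                for p in (0, 1, 2):
                    ksplit = k0 + c
                    if p > 0 and ksplit >= m:
                        continue
                    d = g0 + 3 * c + p
                    if d + 2 > n or genomic[d : d + 2] != "GT":
                        continue
                    for e in acceptor_ends:
                        if not min_intron <= e - d <= max_intron:
                            continue
                        score = prefix - intron_penalty
                        if p:
                            if e + 3 - p > n:
                                continue
                            codon = genomic[d - p : d] + genomic[e : e + 3 - p]
                            score += B[(protein[ksplit], aa_of(codon))]
                            best = max(best, score)  # split codon may end it
                            k, g = ksplit + 1, e + 3 - p
                        else:
                            k, g = ksplit, e
                        while k < m and g <= n - 3:
                            score += S[k][g]
                            best = max(best, score)
                            k += 1
                            g += 3
    return best


# --- instance generators for the oracle sweeps -----------------------------

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_CODONS_OF = {}
for codon, aa in CODON_AA.items():
    if aa != "*":
        _CODONS_OF.setdefault(aa, []).append(codon)
for aa in _CODONS_OF:
    _CODONS_OF[aa].sort()


def random_spliced_instance(rng: np.random.Generator) -> dict:
    """A small protein/genomic pair for the enumeration sweep: a 7-10
    residue peptide back-translated exactly, usually with one 45-70 nt
    intron planted three or more codons from either end, plus 0-2
    substitutions away from the splice site and short random flanks.
    Gap moves cost more than any mismatch they could rescue on these
    instances, so the ungapped <=1-intron enumeration is exhaustive."""
    m = int(rng.integers(7, 11))
    protein = "".join(_AA20[int(k)] for k in rng.integers(0, 20, m))
    cds = "".join(
        _CODONS_OF[aa][int(rng.integers(0, len(_CODONS_OF[aa])))] for aa in protein
    )
    with_intron = bool(rng.random() < 0.75)
    if with_intron:
        t = int(rng.integers(9, 3 * m - 8))  # >= 3 codons from each end
        ilen = int(rng.integers(45, 71))
        interior = "".join("ACGT"[int(x)] for x in rng.integers(0, 4, ilen - 4))
        # keep the acceptor unambiguous
        interior = interior[:-10] + interior[-10:].replace("AG", "CC").replace(
            "A", "T"
        )
        genomic = cds[:t] + "GT" + interior + "AG" + cds[t:]
        split_codon = t // 3
    else:
        genomic = cds
        split_codon = None
    # 0-2 substitutions away from termini and the splice codon
    n_sub = int(rng.integers(0, 3))
    mutable = [
        k
        for k in range(2, m - 2)
        if split_codon is None or abs(k - split_codon) >= 4
    ]
    protein = list(protein)
    for k in rng.permutation(mutable)[:n_sub]:
        protein[k] = _AA20[int(rng.integers(0, 20))]
    flank5 = "".join("ACGT"[int(x)] for x in rng.integers(0, 4, int(rng.integers(0, 10))))
    flank3 = "".join("ACGT"[int(x)] for x in rng.integers(0, 4, int(rng.integers(0, 10))))
    return {
        "protein": "".join(protein),
        "genomic": flank5 + genomic + flank3,
        "intron_penalty": 11.0,
        "min_intron": 40,
        "max_intron": 80,
    }
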