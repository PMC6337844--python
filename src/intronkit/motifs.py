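"""Short-motif and charge characterization of candidate proteins.

Three scanners cover the characterization layer applied to every
Notch-repressor candidate: the CSL-interaction tetra-peptide pattern
(hydrophobic, W, hydrophobic, P — written ΦWΦP), runs of basic residues
that may act as nuclear localization signals, and the isoelectric point
computed by Henderson-Hasselbalch summation with bisection.

Two tetra-peptide presets are provided.  The strict pattern takes
Φ = {A,V,L,I,M,F,W,Y,C} and requires W at position 2 and P at position
4; the relaxed preset widens position 1 to Φ ∪ {T,S} and position 2 to
{W,M,F}, accommodating the naturally occurring variants TWVP, LWVP,
TMVP and TFVP while keeping VWWP a strict match.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import ProteinSequence

__all__ = [
    "HYDROPHOBIC",
    "MotifPattern",
    "MotifHit",
    "BasicStretch",
    "IsoelectricResult",
    "strict_pattern",
    "relaxed_pattern",
    "scan_tetrapeptide",
    "net_charge",
    "isoelectric_point",
    "find_basic_stretches",
    "characterize_protein",
]

HYDROPHOBIC = frozenset("AVLIMFWYC")

# Side-chain and terminal pKa values.  EMBOSS is the default set; the
# Bjellqvist set is selectable because the reported pI of a protein
# shifts by a few tenths of a pH unit between sets.
PKA_SETS: dict[str, dict[str, float]] = {
    "emboss": {
        "Nterm": 8.6, "Cterm": 3.6,
        "K": 10.8, "R": 12.5, "H": 6.5,
        "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
    },
    "bjellqvist": {
        "Nterm": 7.5, "Cterm": 3.55,
        "K": 10.0, "R": 12.0, "H": 5.98,
        "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
    },
}
_POSITIVE = ("K", "R", "H")
_NEGATIVE = ("D", "E", "C", "Y")


@dataclass(frozen=True)
class MotifPattern:
    """Per-position allowed residue sets for a tetra-peptide."""

    name: str
    positions: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if len(self.positions) != 4 or any(not p for p in self.positions):
            raise ValueError("pattern needs 4 non-empty position sets")

    def score(self, tetrapeptide: str) -> int:
        return sum(
            1 for ch, allowed in zip(tetrapeptide, self.positions) if ch in allowed
        )


def strict_pattern() -> MotifPattern:
    return MotifPattern(
        "strict_PhiWPhiP",
        (HYDROPHOBIC, frozenset("W"), HYDROPHOBIC, frozenset("P")),
    )


def relaxed_pattern() -> MotifPattern:
    return MotifPattern(
        "relaxed",
        (
            HYDROPHOBIC | frozenset("TS"),
            frozenset("WMF"),
            HYDROPHOBIC,
            frozenset("P"),
        ),
    )


@dataclass(frozen=True)
class MotifHit:
    protein_id: str
    start: int  # 0-based
    tetrapeptide: str
    match_score: int  # positions matching the pattern used in the scan

    def __post_init__(self) -> None:
        if len(self.tetrapeptide) != 4:
            raise ValueError("tetrapeptide must have length 4")
        if not 0 <= self.match_score <= 4:
            raise ValueError("match_score must be in 0..4")


def scan_tetrapeptide(
    p: ProteinSequence,
    pattern: MotifPattern | None = None,
    min_score: int = 4,
) -> list[MotifHit]:
    """Score every 4-residue window against the pattern and return the
    windows reaching ``min_score``, in position order."""
    pattern = pattern or strict_pattern()
    if len(p) < 4:
        raise ValueError(f"protein '{p.id}' shorter than 4 residues")
    hits = []
    s = p.residues
    for i in range(len(s) - 3):
        tetra = s[i : i + 4]
        score = pattern.score(tetra)
        if score >= min_score:
            hits.append(MotifHit(p.id, i, tetra, score))
    return hits


def net_charge(p: ProteinSequence, pH: float, pKa_set: str = "emboss") -> float:
    """Net charge at the given pH by Henderson-Hasselbalch summation over
    D, E, C, Y, H, K, R side chains and the two termini.  Strictly
    decreasing in pH."""
    if not 0.0 <= pH <= 14.0:
        raise ValueError("pH must be in [0, 14]")
    try:
        pka = PKA_SETS[pKa_set]
    except KeyError:
        raise ValueError(
            f"unknown pKa_set {pKa_set!r}; available: {sorted(PKA_SETS)}"
        ) from None
    s = p.residues
    charge = 1.0 / (1.0 + 10.0 ** (pH - pka["Nterm"]))
    charge -= 1.0 / (1.0 + 10.0 ** (pka["Cterm"] - pH))
    for aa in _POSITIVE:
        charge += s.count(aa) / (1.0 + 10.0 ** (pH - pka[aa]))
    for aa in _NEGATIVE:
        charge -= s.count(aa) / (1.0 + 10.0 ** (pka[aa] - pH))
    return charge


@dataclass(frozen=True)
class IsoelectricResult:
    pI: float
    pKa_set: str
    net_charge_at_pI: float


def isoelectric_point(
    p: ProteinSequence, pKa_set: str = "emboss", tol: float = 1e-4
) -> IsoelectricResult:
    """Isoelectric point by bisection of :func:`net_charge` on [0, 14].

    The charge function is strictly decreasing, positive at pH 0 and
    negative at pH 14 (the termini alone guarantee a sign change), so
    bisection converges to the unique root.
    """
    lo, hi = 0.0, 14.0
    while hi - lo > 1e-8:
        mid = 0.5 * (lo + hi)
        if net_charge(p, mid, pKa_set) > 0:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    result = IsoelectricResult(mid, pKa_set, net_charge(p, mid, pKa_set))
    assert abs(result.net_charge_at_pI) < tol
    return result


@dataclass(frozen=True)
class BasicStretch:
    start: int
    end: int
    basic_count: int  # K + R within [start, end)


def find_basic_stretches(
    p: ProteinSequence, window: int = 7, min_basic: int = 4
) -> list[BasicStretch]:
    """Candidate nuclear localization signals: merge every sliding window
    holding at least ``min_basic`` K/R residues into maximal stretches."""
    if not 1 <= min_basic <= window:
        raise ValueError("need window >= min_basic >= 1")
    s = p.residues
    if len(s) < window:
        return []
    is_basic = [c in "KR" for c in s]
    count = sum(is_basic[:window])
    qualifying = []
    for start in range(len(s) - window + 1):
        if start:
            count += is_basic[start + window - 1] - is_basic[start - 1]
        if count >= min_basic:
            qualifying.append(start)
    stretches = []
    for start in qualifying:
        if stretches and start < stretches[-1][1]:
            stretches[-1][1] = start + window
        else:
            stretches.append([start, start + window])
    return [
        BasicStretch(a, b, sum(is_basic[a:b])) for a, b in stretches
    ]


def characterize_protein(
    p: ProteinSequence,
    pKa_set: str = "emboss",
    nls_window: int = 7,
    nls_min_basic: int = 4,
) -> dict:
    """One-row characterization: length, pI, basic stretches and
    tetra-peptide motif hits under both presets."""
    pi = isoelectric_point(p, pKa_set)
    stretches = find_basic_stretches(p, nls_window, nls_min_basic)
    strict_hits = scan_tetrapeptide(p, strict_pattern(), 4) if len(p) >= 4 else []
    relaxed_hits = scan_tetrapeptide(p, relaxed_pattern(), 4) if len(p) >= 4 else []
    return {
        "id": p.id,
        "length": len(p),
        "pI": round(pi.pI, 2),
        "n_basic_stretches": len(stretches),
        "basic_stretches": ";".join(f"{s.start + 1}-{s.end}" for s in stretches),
        "strict_motif_hits": ";".join(
            f"{h.tetrapeptide}@{h.start + 1}" for h in strict_hits
        ),
        "relaxed_motif_hits": ";".join(
            f"{h.tetrapeptide}@{h.start + 1}" for h in relaxed_hits
        ),
    }
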