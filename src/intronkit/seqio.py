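"""Sequence containers, FASTA/GFF3 I/O and genetic-code translation.

Conventions used throughout the library:

* all coordinates are 0-based, half-open intervals on the forward strand;
  GFF3 export converts to the 1-based closed convention of that format;
* minus-strand gene models store their exons on the forward strand in
  ascending order and are assembled in reverse (reverse-complemented)
  order for translation;
* codons containing ``N`` translate to ``X`` rather than raising, because
  whole-genome-shotgun contigs routinely contain gap characters.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "NucleotideSequence",
    "ProteinSequence",
    "GeneModel",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "translate",
    "translate_cds",
    "six_frame_translation",
    "write_gff3",
    "read_gff3",
]

_DNA_ALPHABET = frozenset("ACGTN")
_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" + "X*")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Standard genetic code (NCBI table 1); any codon containing N maps to X.
_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
_CODON_TO_AA.update({c: "*" for c in _STANDARD_TABLE.stop_codons})

StopPolicy = Literal["truncate", "retain", "readthrough"]
Frame = Literal[1, 2, 3, -1, -2, -3]
FRAMES: tuple[Frame, ...] = (1, 2, 3, -1, -2, -3)


def _validate_residues(residues: str, alphabet: frozenset, what: str, seq_id: str) -> None:
    bad = set(residues) - alphabet
    if bad:
        raise ValueError(
            f"{what} '{seq_id}' contains invalid residue(s): {sorted(bad)!r}"
        )


@dataclass(frozen=True)
class NucleotideSequence:
    """A DNA sequence restricted to the residues A, C, G, T and N."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise ValueError(f"nucleotide sequence '{self.id}' is empty")
        _validate_residues(self.residues, _DNA_ALPHABET, "nucleotide sequence", self.id)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid sequence over the 20 standard residues plus X and '*'.

    ``*`` marks a stop and should only appear in products of
    :func:`translate` with ``stop_policy='retain'``.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise ValueError(f"protein sequence '{self.id}' is empty")
        _validate_residues(self.residues, _AA_ALPHABET, "protein sequence", self.id)

    def __len__(self) -> int:
        return len(self.residues)


def reverse_complement(nt: NucleotideSequence) -> NucleotideSequence:
    """Reverse complement; an involution, with N mapping to N."""
    return NucleotideSequence(nt.id, nt.residues.translate(_COMPLEMENT)[::-1])


def translate_cds(cds: str) -> str:
    """Translate a coding sequence codon by codon, retaining '*' for stops.

    Trailing nucleotides that do not fill a codon are ignored; codons
    containing N yield X.
    """
    out = []
    for k in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[k : k + 3]
        out.append("X" if "N" in codon else _CODON_TO_AA[codon])
    return "".join(out)


def translate(
    nt: NucleotideSequence,
    frame: Frame = 1,
    stop_policy: StopPolicy = "retain",
) -> ProteinSequence:
    """Translate ``nt`` in one of the six reading frames.

    Frames +1..+3 read the forward strand with offsets 0..2; frames
    -1..-3 read the reverse complement with offsets 0..2.  ``stop_policy``
    controls stop codons: ``truncate`` cuts at the first stop, ``retain``
    keeps ``*`` characters, ``readthrough`` replaces internal stops with
    ``X`` and continues (a terminal stop is kept).
    """
    if frame not in FRAMES:
        raise ValueError(f"frame must be one of {FRAMES}, got {frame!r}")
    seq = nt.residues if frame > 0 else reverse_complement(nt).residues
    offset = abs(frame) - 1
    if len(seq) - offset < 3:
        raise ValueError(
            f"sequence '{nt.id}' too short to translate in frame {frame:+d}"
        )
    aa = translate_cds(seq[offset:])
    if stop_policy == "truncate":
        stop = aa.find("*")
        if stop == 0:
            raise ValueError(
                f"translation of '{nt.id}' frame {frame:+d} starts with a stop codon"
            )
        if stop != -1:
            aa = aa[:stop]
    elif stop_policy == "readthrough":
        body, last = aa[:-1], aa[-1]
        aa = body.replace("*", "X") + last
    elif stop_policy != "retain":
        raise ValueError(f"unknown stop_policy {stop_policy!r}")
    return ProteinSequence(f"{nt.id}|frame{frame:+d}", aa)


def six_frame_translation(
    nt: NucleotideSequence, stop_policy: StopPolicy = "retain"
) -> dict[Frame, ProteinSequence]:
    """Translate in all six frames; keys are +1,+2,+3,-1,-2,-3."""
    return {frame: translate(nt, frame, stop_policy) for frame in FRAMES}


@dataclass(frozen=True)
class GeneModel:
    """Exon structure of a protein-coding gene on a genomic sequence.

    ``exons`` are forward-strand [start, end) intervals in ascending
    order regardless of strand.  ``intron_phases`` lists, in
    transcription order, the number of nucleotides of the interrupted
    codon lying 5' of each intron (0, 1 or 2).  ``protein`` is the exact
    translation of the spliced, strand-aware coding sequence.
    """

    seq_id: str
    strand: Literal["+", "-"]
    exons: tuple[tuple[int, int], ...]
    intron_phases: tuple[int, ...]
    protein: ProteinSequence
    gene_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        object.__setattr__(self, "intron_phases", tuple(self.intron_phases))
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError("gene model needs at least one exon")
        for s, e in self.exons:
            if not 0 <= s < e:
                raise ValueError(f"invalid exon interval [{s}, {e})")
        for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise ValueError("exons overlap or are unsorted")
        if len(self.intron_phases) != len(self.exons) - 1:
            raise ValueError("need exactly one intron phase per intron")
        if any(p not in (0, 1, 2) for p in self.intron_phases):
            raise ValueError("intron phases must be 0, 1 or 2")
        # phases must telescope: phase_i == (coding nt before intron i) mod 3
        lens = [e - s for s, e in self.transcription_order_exons()]
        cum = 0
        for k, phase in enumerate(self.intron_phases):
            cum += lens[k]
            if cum % 3 != phase:
                raise ValueError(
                    f"intron {k} phase {phase} inconsistent with cumulative "
                    f"coding length {cum}"
                )

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    def transcription_order_exons(self) -> tuple[tuple[int, int], ...]:
        return self.exons if self.strand == "+" else self.exons[::-1]

    def introns(self) -> tuple[tuple[int, int], ...]:
        """Forward-strand intron intervals, in transcription order."""
        gaps = [
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
        ]
        return tuple(gaps if self.strand == "+" else gaps[::-1])

    def coding_sequence(self, genomic: NucleotideSequence) -> str:
        """Spliced CDS read in transcription order."""
        if self.exons[-1][1] > len(genomic):
            raise ValueError(
                f"gene model exceeds genomic sequence '{genomic.id}' bounds"
            )
        parts = [genomic.residues[s:e] for s, e in self.exons]
        cds = "".join(parts)
        if self.strand == "-":
            cds = cds.translate(_COMPLEMENT)[::-1]
        return cds

    def validate_against(self, genomic: NucleotideSequence) -> None:
        """Check the translation invariant against the genomic sequence."""
        cds = self.coding_sequence(genomic)
        if len(cds) % 3:
            raise ValueError("total exon length is not divisible by 3")
        if translate_cds(cds) != self.protein.residues:
            raise ValueError(
                f"translation of spliced exons does not match protein "
                f"'{self.protein.id}'"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(
    path: str | Path, kind: Literal["auto", "dna", "protein"] = "auto"
) -> list[NucleotideSequence | ProteinSequence]:
    """Read a FASTA file into typed sequence records.

    With ``kind='auto'`` a record whose residues are all in {A,C,G,T,N}
    is classified as DNA, anything else as protein; pass ``kind``
    explicitly for short peptides over the DNA-letter subset.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"FASTA file '{path}' contains no records")
    seen: set[str] = set()
    out: list[NucleotideSequence | ProteinSequence] = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id '{rec.id}' in '{path}'")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        if kind == "dna":
            out.append(NucleotideSequence(rec.id, residues))
        elif kind == "protein":
            out.append(ProteinSequence(rec.id, residues))
        else:
            if residues and set(residues) <= _DNA_ALPHABET:
                out.append(NucleotideSequence(rec.id, residues))
            else:
                out.append(ProteinSequence(rec.id, residues))
    return out


def write_fasta(
    records: Iterable[NucleotideSequence | ProteinSequence],
    path: str | Path,
    line_width: int = 60,
) -> None:
    """Write records as multi-FASTA, wrapping bodies at ``line_width``."""
    records = list(records)
    if not records:
        raise ValueError("refusing to write an empty FASTA file")
    if line_width < 1:
        raise ValueError("line_width must be positive")
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for k in range(0, len(rec.residues), line_width):
                fh.write(rec.residues[k : k + line_width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def _gff3_cds_phases(model: GeneModel) -> list[int]:
    """GFF3 phase column per CDS segment (transcription order)."""
    phases = []
    cum = 0
    for s, e in model.transcription_order_exons():
        phases.append((3 - cum % 3) % 3)
        cum += e - s
    return phases


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    """Export gene models as GFF3 gene/mRNA/exon/CDS features.

    Coordinates are converted to the 1-based closed GFF3 convention; the
    CDS phase column is derived from the cumulative coding length.
    """
    models = list(models)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for k, gm in enumerate(models):
            gid = gm.gene_id or f"{gm.protein.id}"
            lo = gm.exons[0][0] + 1
            hi = gm.exons[-1][1]
            attrs = f"ID=gene:{gid}"
            fh.write(
                f"{gm.seq_id}\tintronkit\tgene\t{lo}\t{hi}\t.\t{gm.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{gm.seq_id}\tintronkit\tmRNA\t{lo}\t{hi}\t.\t{gm.strand}\t.\t"
                f"ID=mRNA:{gid};Parent=gene:{gid}\n"
            )
            tx_exons = gm.transcription_order_exons()
            tx_phases = _gff3_cds_phases(gm)
            for j, ((s, e), ph) in enumerate(zip(tx_exons, tx_phases)):
                fh.write(
                    f"{gm.seq_id}\tintronkit\texon\t{s + 1}\t{e}\t.\t{gm.strand}\t.\t"
                    f"ID=exon:{gid}.{j};Parent=mRNA:{gid}\n"
                )
                fh.write(
                    f"{gm.seq_id}\tintronkit\tCDS\t{s + 1}\t{e}\t.\t{gm.strand}\t{ph}\t"
                    f"ID=cds:{gid};Parent=mRNA:{gid}\n"
                )


def read_gff3(
    path: str | Path, genomes: Iterable[NucleotideSequence]
) -> list[GeneModel]:
    """Reconstruct gene models from GFF3 CDS features.

    ``genomes`` must provide every referenced seqid; the protein field is
    recomputed by translating the spliced CDS (stops retained would
    violate the model invariant, so internal stops raise).
    """
    import gffutils

    by_id = {g.id: g for g in genomes}
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for mrna in db.features_of_type("mRNA"):
        cds = sorted(db.children(mrna, featuretype="CDS"), key=lambda f: f.start)
        if not cds:
            continue
        exons = tuple((f.start - 1, f.end) for f in cds)
        strand = mrna.strand if mrna.strand in "+-" else "+"
        if mrna.seqid not in by_id:
            raise ValueError(f"no genomic sequence provided for seqid '{mrna.seqid}'")
        genomic = by_id[mrna.seqid]
        gid = mrna.id.split(":", 1)[-1]
        # phases from cumulative coding length in transcription order
        tx = exons if strand == "+" else exons[::-1]
        cum, phases = 0, []
        for s, e in tx[:-1]:
            cum += e - s
            phases.append(cum % 3)
        parts = "".join(genomic.residues[s:e] for s, e in exons)
        if strand == "-":
            parts = parts.translate(_COMPLEMENT)[::-1]
        protein = ProteinSequence(gid, translate_cds(parts).rstrip("*") or "X")
        gm = GeneModel(mrna.seqid, strand, exons, tuple(phases), protein, gene_id=gid)
        models.append(gm)
    if not models:
        raise ValueError(f"no mRNA/CDS features found in '{path}'")
    return models
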