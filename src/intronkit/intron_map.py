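"""Intron positions in protein coordinates and their conservation across
a gene family.

An intron is anchored to the codon it interrupts: ``residue_index`` is
the 0-based index of that codon's residue (for phase 1/2) or of the
residue immediately following the intron (phase 0); ``phase`` is the
number of nucleotides of the codon lying 5' of the intron.  Marks are
projected through a multiple alignment and grouped into equivalence
classes; by default two marks are "the same position" only when they
share both alignment column and phase, since a phase mismatch cannot
descend from a single ancestral intron.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .align import MultipleAlignment
from .seqio import GeneModel

__all__ = [
    "IntronMark",
    "ColumnMark",
    "ConservationClass",
    "IntronConservationReport",
    "introns_to_protein_coords",
    "map_marks_to_columns",
    "classify_conservation",
    "neighbor_column_tolerance",
    "format_alignment_with_marks",
]


@dataclass(frozen=True, order=True)
class IntronMark:
    gene_id: str
    residue_index: int
    phase: int

    def __post_init__(self) -> None:
        if self.phase not in (0, 1, 2):
            raise ValueError("phase must be 0, 1 or 2")
        if self.residue_index < 0:
            raise ValueError("residue_index must be >= 0")


@dataclass(frozen=True, order=True)
class ColumnMark:
    gene_id: str
    column: int
    phase: int
    residue_index: int


@dataclass(frozen=True)
class ConservationClass:
    column: int  # smallest member column
    phase: int | None  # None when phases were not enforced
    genes: frozenset[str]
    marks: tuple[ColumnMark, ...]


@dataclass(frozen=True)
class IntronConservationReport:
    gene_ids: tuple[str, ...]
    phase_strict: bool
    classes: tuple[ConservationClass, ...]

    @property
    def n_marks(self) -> int:
        return sum(len(c.marks) for c in self.classes)

    def summary(self) -> dict:
        """Counts of classes shared by all genes, by exact pairs, by
        larger sub-groups, and specific to single genes."""
        all_genes = set(self.gene_ids)
        shared_by_all = 0
        shared_by_pair: dict[str, int] = defaultdict(int)
        specific: dict[str, int] = defaultdict(int)
        shared_by_subset = 0
        for cls in self.classes:
            if cls.genes == all_genes:
                shared_by_all += 1
            elif len(cls.genes) == 1:
                specific[next(iter(cls.genes))] += 1
            elif len(cls.genes) == 2:
                shared_by_pair["|".join(sorted(cls.genes))] += 1
            else:
                shared_by_subset += 1
        return {
            "shared_by_all": shared_by_all,
            "shared_by_pair": dict(shared_by_pair),
            "shared_by_subset": shared_by_subset,
            "specific": dict(specific),
        }

    def count_triplet(self) -> tuple[int, int, int]:
        """(shared by all, shared by >=2 but not all, single-gene) class
        counts — the shape of the family-wide comparison."""
        s = self.summary()
        pairs = sum(s["shared_by_pair"].values()) + s["shared_by_subset"]
        return (s["shared_by_all"], pairs, sum(s["specific"].values()))

    def to_rows(self) -> list[dict]:
        rows = []
        for cls in sorted(self.classes, key=lambda c: (c.column, c.phase or 0)):
            label = (
                "shared_by_all"
                if cls.genes == set(self.gene_ids)
                else "specific"
                if len(cls.genes) == 1
                else "shared"
            )
            rows.append(
                {
                    "class": label,
                    "column": cls.column,
                    "phase": cls.phase,
                    "genes": ",".join(sorted(cls.genes)),
                    "n_marks": len(cls.marks),
                }
            )
        return rows


def introns_to_protein_coords(gm: GeneModel) -> list[IntronMark]:
    """One mark per intron: residue floor(c/3), phase c mod 3 where c is
    the coding length preceding the intron in transcription order."""
    marks = []
    lens = [e - s for s, e in gm.transcription_order_exons()]
    gid = gm.gene_id or gm.protein.id
    cum = 0
    for k in range(gm.n_introns):
        cum += lens[k]
        marks.append(IntronMark(gid, cum // 3, cum % 3))
    return marks


def map_marks_to_columns(
    msa: MultipleAlignment, marks: Mapping[str, Sequence[IntronMark]]
) -> list[ColumnMark]:
    """Assign each mark the alignment column of its anchor residue."""
    out = []
    for gene_id, gene_marks in marks.items():
        cmap = msa.column_map(gene_id)
        for mk in gene_marks:
            if mk.residue_index >= len(cmap):
                raise ValueError(
                    f"mark at residue {mk.residue_index} outside row "
                    f"'{gene_id}' ({len(cmap)} residues)"
                )
            out.append(
                ColumnMark(gene_id, cmap[mk.residue_index], mk.phase, mk.residue_index)
            )
    return sorted(out)


def classify_conservation(
    column_marks: Iterable[ColumnMark],
    gene_ids: Sequence[str],
    phase_strict: bool = True,
) -> IntronConservationReport:
    """Group marks at identical alignment positions.

    With ``phase_strict`` (default) a class is keyed by (column, phase);
    otherwise by column alone.  Every input mark lands in exactly one
    class.
    """
    if len(gene_ids) < 2:
        raise ValueError("need at least 2 genes to classify conservation")
    groups: dict[tuple, list[ColumnMark]] = defaultdict(list)
    for mk in sorted(column_marks):
        key = (mk.column, mk.phase) if phase_strict else (mk.column,)
        groups[key].append(mk)
    classes = []
    for key in sorted(groups):
        ms = groups[key]
        classes.append(
            ConservationClass(
                column=key[0],
                phase=key[1] if phase_strict else None,
                genes=frozenset(m.gene_id for m in ms),
                marks=tuple(ms),
            )
        )
    return IntronConservationReport(
        gene_ids=tuple(gene_ids), phase_strict=phase_strict, classes=tuple(classes)
    )


def neighbor_column_tolerance(
    report: IntronConservationReport, tol: int = 0
) -> IntronConservationReport:
    """Merge classes whose columns lie within ``tol`` of one another.

    Robustness knob for alignment jitter near gaps: marks of equal phase
    (when the report is phase-strict) within ``tol`` columns are merged
    by transitive closure; ``tol=0`` returns an equivalent report.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    if tol == 0:
        return report
    marks = sorted(
        (m for cls in report.classes for m in cls.marks),
        key=lambda m: (m.column, m.phase, m.gene_id, m.residue_index),
    )
    # union-find over marks (sorted by column so the window scan can break)
    parent = list(range(len(marks)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for i, mi in enumerate(marks):
        for j in range(i + 1, len(marks)):
            mj = marks[j]
            if mj.column - mi.column > tol:
                break
            if report.phase_strict and mi.phase != mj.phase:
                continue
            union(i, j)
    groups: dict[int, list[ColumnMark]] = defaultdict(list)
    for i, mk in enumerate(marks):
        groups[find(i)].append(mk)
    classes = []
    for root in sorted(groups):
        ms = groups[root]
        col = min(m.column for m in ms)
        phase = ms[0].phase if report.phase_strict else None
        classes.append(
            ConservationClass(
                column=col,
                phase=phase,
                genes=frozenset(m.gene_id for m in ms),
                marks=tuple(sorted(ms)),
            )
        )
    return IntronConservationReport(
        gene_ids=report.gene_ids,
        phase_strict=report.phase_strict,
        classes=tuple(classes),
    )


def format_alignment_with_marks(
    msa: MultipleAlignment,
    column_marks: Iterable[ColumnMark],
    width: int = 60,
) -> str:
    """Render the alignment in blocks with an arrow line marking intron
    columns (the glyph is the intron phase digit)."""
    marks_by_col: dict[int, set[int]] = defaultdict(set)
    for mk in column_marks:
        marks_by_col[mk.column].add(mk.phase)
    label_w = max(len(i) for i in msa.ids) + 2
    lines = []
    for start in range(0, msa.ncols, width):
        stop = min(start + width, msa.ncols)
        for seq_id, row in msa.rows:
            lines.append(f"{seq_id:<{label_w}}{row[start:stop]}")
        arrow = []
        for col in range(start, stop):
            if col in marks_by_col:
                arrow.append(str(min(marks_by_col[col])))
            else:
                arrow.append(" ")
        lines.append(" " * label_w + "".join(arrow).rstrip())
        lines.append("")
    return "\n".join(lines).rstrip() + "\n"
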