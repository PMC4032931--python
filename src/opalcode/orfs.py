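"""Simplified six-frame ORF prediction with optional stop-codon readthrough.

Candidate-phyla genomes that recode a stop codon cannot be gene-called with
the standard table: every recoded codon truncates the ORF.  This module
scans all six frames for ORFs running from a bacterial start codon (ATG,
GTG, TTG) to the first downstream STOP of the supplied genetic code, where a
designated ``readthrough_codon`` is *not* treated as a stop.  Readthrough
positions are recorded in protein coordinates so downstream stages can
substitute any hypothesised meaning there.

Only stop-terminated ORFs are reported (no partial genes at contig edges),
and within a frame each stop keeps its longest ORF (most upstream start).
Coordinates are 0-based half-open on the forward strand, with the terminal
stop codon inside the interval.
"""

from __future__ import annotations

from dataclasses import dataclass

from .codes import STOP, GeneticCode, NucleotideSequence, reverse_complement

START_CODONS = ("ATG", "GTG", "TTG")


@dataclass(frozen=True)
class OpenReadingFrame:
    contig_id: str
    start: int  # 0-based, forward strand
    end: int  # half-open, forward strand; includes the terminal stop codon
    strand: str  # "+" or "-"
    codons: tuple[str, ...]  # in translation order (reverse-complemented for "-")
    translation: str  # readthrough codons that are STOP under the calling code appear as X
    readthrough_positions: tuple[int, ...]  # protein coordinates

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF interval length must be a multiple of 3")
        if any(p >= len(self.translation) for p in self.readthrough_positions):
            raise ValueError("readthrough position beyond translation")

    @property
    def id(self) -> str:
        return f"{self.contig_id}:{self.start}-{self.end}:{self.strand}"

    def codon_at(self, protein_pos: int) -> str:
        """The codon encoding residue ``protein_pos`` (strand-aware)."""
        if not 0 <= protein_pos < len(self.translation):
            raise IndexError(f"protein position {protein_pos} out of range")
        return self.codons[protein_pos]


def _scan_frame(
    residues: str,
    frame: int,
    code: GeneticCode,
    min_aa: int,
    readthrough_codon: str | None,
) -> list[tuple[int, int, tuple[str, ...]]]:
    """Yield (start_offset, end_offset, codons) in the coordinate system of ``residues``."""
    n = len(residues)
    out = []
    start_idx: int | None = None  # codon index of most upstream start since last stop
    codon_offsets = range(frame, n - 2, 3)
    codons = [residues[i : i + 3] for i in codon_offsets]
    for ci, codon in enumerate(codons):
        is_stop = (
            "N" not in codon
            and code.table[codon] == STOP
            and codon != readthrough_codon
        )
        if is_stop:
            if start_idx is not None and ci - start_idx >= min_aa:
                s = frame + 3 * start_idx
                e = frame + 3 * (ci + 1)
                out.append((s, e, tuple(codons[start_idx : ci + 1])))
            start_idx = None
        elif start_idx is None and codon in START_CODONS:
            start_idx = ci
    return out


def find_orfs(
    contig: NucleotideSequence,
    code: GeneticCode,
    min_aa: int = 30,
    readthrough_codon: str | None = None,
) -> list[OpenReadingFrame]:
    """Six-frame ORF scan under ``code`` with optional readthrough of one codon.

    An ORF runs from a start codon to the first downstream STOP; ORFs with
    fewer than ``min_aa`` translated residues are dropped.  Minus-strand ORFs
    are reported in forward-strand coordinates.  Readthrough codons that the
    code maps to STOP translate as X, with their protein positions recorded.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    if readthrough_codon is not None:
        readthrough_codon = readthrough_codon.upper()
    fwd = contig.residues
    rev = reverse_complement(fwd)
    L = len(fwd)
    orfs: list[OpenReadingFrame] = []
    for strand, residues in (("+", fwd), ("-", rev)):
        for frame in (0, 1, 2):
            for s, e, codons in _scan_frame(residues, frame, code, min_aa, readthrough_codon):
                protein = []
                rt = []
                for i, codon in enumerate(codons[:-1]):  # last codon is the stop
                    if "N" in codon:
                        protein.append("X")
                    elif codon == readthrough_codon and code.table[codon] == STOP:
                        protein.append("X")
                        rt.append(i)
                    else:
                        protein.append(code.table[codon])
                if strand == "+":
                    start, end = s, e
                else:
                    start, end = L - e, L - s
                orfs.append(
                    OpenReadingFrame(
                        contig_id=contig.id,
                        start=start,
                        end=end,
                        strand=strand,
                        codons=codons[:-1],
                        translation="".join(protein),
                        readthrough_positions=tuple(rt),
                    )
                )
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


def orfs_to_protein_records(orfs: list[OpenReadingFrame]) -> list[tuple[str, str]]:
    """(id, protein) pairs suitable for FASTA export."""
    return [(o.id, o.translation) for o in orfs]


def orfs_to_bed(orfs: list[OpenReadingFrame]) -> str:
    """BED-like 6-column table: contig, start, end, name, length_aa, strand."""
    lines = [
        f"{o.contig_id}\t{o.start}\t{o.end}\t{o.id}\t{len(o.translation)}\t{o.strand}"
        for o in orfs
    ]
    return "\n".join(lines) + ("\n" if lines else "")
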