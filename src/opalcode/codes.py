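"""Genetic-code tables, code variants, translation, and the GC-null codon model.

A genome bin suspected of stop-codon reassignment (e.g. the opal codon TGA
recoded to glycine) is analysed under *code hypotheses*: complete 64-codon
tables that differ from the standard bacterial code only at declared,
reassigned codons.  The null model for codon frequency assumes independent
nucleotide positions with P(G) = P(C) = GC/2 and P(A) = P(T) = (1-GC)/2 —
the simplest model in which a codon's expected occurrence is predicted from
the genomic GC percentage alone.

DNA alphabet throughout: the opal codon "UGA" is written TGA.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
STOP = "*"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class NucleotideSequence:
    """A contig or gene sequence over {A, C, G, T, N}."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        bad = set(self.residues) - set("ACGTN")
        if bad:
            raise ValueError(f"invalid nucleotide symbols in {self.id!r}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneticCode:
    """A complete 64-codon -> amino-acid-or-STOP mapping.

    ``reassigned`` records (codon, meaning) pairs at which this code differs
    from the standard code, e.g. ``[("TGA", "G")]`` for opal-to-glycine.
    """

    name: str
    table: dict[str, str]
    reassigned: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if set(self.table) != set(CODONS):
            raise ValueError("genetic code must map exactly the 64 DNA codons")
        bad = {v for v in self.table.values() if v != STOP and v not in AMINO_ACIDS}
        if bad:
            raise ValueError(f"invalid translation symbols: {sorted(bad)}")

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(c for c in CODONS if self.table[c] == STOP)

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in CODONS if self.table[c] != STOP)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneticCode):
            return NotImplemented
        return self.table == other.table

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.table.items())))

    def to_text(self) -> str:
        """Serialize as one ``codon<TAB>symbol`` line per codon."""
        return "\n".join(f"{c}\t{self.table[c]}" for c in CODONS) + "\n"

    @classmethod
    def from_text(cls, text: str, name: str = "from_text") -> "GeneticCode":
        table: dict[str, str] = {}
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                codon, symbol = line.split()
            except ValueError as exc:
                raise ValueError(f"malformed code line {lineno}: {line!r}") from exc
            table[codon.upper()] = symbol
        std = standard_code()
        reassigned = tuple(
            (c, table[c]) for c in CODONS if c in table and table[c] != std.table[c]
        )
        return cls(name=name, table=table, reassigned=reassigned)


def standard_code() -> GeneticCode:
    """The canonical standard code (NCBI translation table 1)."""
    ncbi = CodonTable.unambiguous_dna_by_id[1]
    table = dict(ncbi.forward_table)
    for codon in ncbi.stop_codons:
        table[codon] = STOP
    return GeneticCode(name="standard", table=table)


def make_variant_code(base: GeneticCode, codon: str, meaning: str) -> GeneticCode:
    """Return ``base`` with ``codon`` reassigned to ``meaning`` (an amino acid or STOP)."""
    codon = codon.upper()
    if len(codon) != 3 or any(n not in NUCLEOTIDES for n in codon):
        raise ValueError(f"invalid DNA codon: {codon!r}")
    if meaning != STOP and meaning not in AMINO_ACIDS:
        raise ValueError(f"invalid meaning {meaning!r}: must be one of the 20 amino acids or {STOP!r}")
    table = dict(base.table)
    table[codon] = meaning
    if meaning == base.table[codon]:
        reassigned = base.reassigned
    else:
        reassigned = base.reassigned + ((codon, meaning),)
    name = f"{base.name}|{codon}={'STOP' if meaning == STOP else meaning}"
    return GeneticCode(name=name, table=table, reassigned=reassigned)


def all_variant_codes(base: GeneticCode, codon: str) -> list[GeneticCode]:
    """All 21 code hypotheses for ``codon``: each amino acid plus STOP."""
    return [make_variant_code(base, codon, m) for m in STOP + AMINO_ACIDS]


@dataclass(frozen=True)
class GcNullModel:
    """Independent-position nucleotide model parameterised by GC fraction."""

    gc_fraction: float
    nucleotide_probs: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        gc = self.gc_fraction
        if not 0.0 <= gc <= 1.0:
            raise ValueError(f"gc_fraction must be in [0, 1], got {gc}")
        object.__setattr__(
            self,
            "nucleotide_probs",
            {"G": gc / 2, "C": gc / 2, "A": (1 - gc) / 2, "T": (1 - gc) / 2},
        )


def expected_codon_frequency(model: GcNullModel, codon: str) -> float:
    """Probability of ``codon`` under the GC null: product of positional probabilities.

    Summing over the 64 codons gives exactly 1 for any GC fraction.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(n not in NUCLEOTIDES for n in codon):
        raise ValueError(f"codon must be 3 unambiguous DNA bases, got {codon!r}")
    p = 1.0
    for n in codon:
        p *= model.nucleotide_probs[n]
    return p


def translate(
    seq: NucleotideSequence | str,
    code: GeneticCode,
    internal_stop_policy: str = "terminate",
) -> tuple[str, list[int]]:
    """Translate an in-frame sequence under ``code``.

    Returns ``(protein, stop_positions)`` where ``stop_positions`` are codon
    indices at which a STOP-mapped codon occurred.  A trailing STOP is never
    included in the protein; codons containing N translate to X.  Internal
    STOPs are handled per ``internal_stop_policy``:

    - ``terminate``: translation ends at the first STOP codon;
    - ``readthrough_as_X``: internal STOPs become X and translation continues;
    - ``error``: an internal STOP raises ValueError.

    A trailing partial codon (length not a multiple of 3) is ignored.
    """
    if internal_stop_policy not in ("terminate", "readthrough_as_X", "error"):
        raise ValueError(f"unknown internal_stop_policy {internal_stop_policy!r}")
    residues = seq.residues if isinstance(seq, NucleotideSequence) else seq.upper()
    if not residues:
        raise ValueError("cannot translate an empty sequence")
    n_codons = len(residues) // 3
    if n_codons == 0:
        raise ValueError("sequence shorter than one codon")
    protein: list[str] = []
    stops: list[int] = []
    for i in range(n_codons):
        codon = residues[3 * i : 3 * i + 3]
        if "N" in codon:
            protein.append("X")
            continue
        aa = code.table[codon]
        if aa != STOP:
            protein.append(aa)
            continue
        stops.append(i)
        terminal = i == n_codons - 1
        if terminal or internal_stop_policy == "terminate":
            break
        if internal_stop_policy == "error":
            raise ValueError(f"internal stop codon {codon} at codon index {i}")
        protein.append("X")
    return "".join(protein), stops
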