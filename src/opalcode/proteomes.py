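"""Code-variant proteome databases with decoys and contaminants.

To arbitrate between code hypotheses for a target codon, the bin's ORFs
(called with readthrough of that codon) are translated once per hypothesis:
STOP truncates each protein at its first readthrough position, while every
amino-acid hypothesis substitutes its symbol there.  The classic 3-way
database is {STOP, Trp, Gly}; the exhaustive one is all 21 meanings.  For
search-style FDR bookkeeping the target proteins plus common contaminants
are mirrored by reversed-sequence decoys.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .codes import AMINO_ACIDS, STOP
from .orfs import OpenReadingFrame

DECOY_PREFIX = "DECOY_"


@dataclass
class ProteomeVariant:
    """The bin's proteins translated under one hypothesis for the target codon."""

    variant_id: str  # one of the 20 amino-acid letters, or "STOP"
    target_codon: str
    proteins: list[tuple[str, str]]  # (orf_id, protein string)

    def __post_init__(self) -> None:
        for pid, seq in self.proteins:
            if STOP in seq:
                raise ValueError(f"protein {pid!r} in variant {self.variant_id} contains a stop symbol")


def _variant_label(meaning: str) -> str:
    return "STOP" if meaning == STOP else meaning


def build_variant_proteomes(
    orfs: list[OpenReadingFrame],
    target_codon: str = "TGA",
    meanings: list[str] | None = None,
) -> list[ProteomeVariant]:
    """One ProteomeVariant per hypothesised meaning of ``target_codon``.

    ``meanings`` defaults to all 21 hypotheses (STOP plus the 20 amino
    acids).  ORFs must have been called with readthrough of the target codon
    so sequence downstream of candidate stops is present; proteins without
    readthrough positions are identical across variants.  Empty truncations
    (a readthrough at position 0 under the STOP hypothesis) are dropped.
    """
    if meanings is None:
        meanings = [STOP] + list(AMINO_ACIDS)
    if not meanings:
        raise ValueError("meanings must be non-empty")
    target_codon = target_codon.upper()
    for m in meanings:
        if m != STOP and m not in AMINO_ACIDS:
            raise ValueError(f"invalid meaning {m!r}")
    variants = []
    for meaning in meanings:
        proteins: list[tuple[str, str]] = []
        for orf in orfs:
            seq = orf.translation
            rt = orf.readthrough_positions
            if meaning == STOP:
                out = seq[: rt[0]] if rt else seq
            else:
                chars = list(seq)
                for pos in rt:
                    chars[pos] = meaning
                out = "".join(chars)
            if out:
                proteins.append((orf.id, out))
        variants.append(
            ProteomeVariant(
                variant_id=_variant_label(meaning),
                target_codon=target_codon,
                proteins=proteins,
            )
        )
    return variants


@dataclass
class DatabaseEntry:
    entry_id: str
    sequence: str
    provenance: dict = field(default_factory=dict)


@dataclass
class SearchDatabase:
    """Targets (variant proteins + contaminants) with reversed decoys."""

    targets: list[DatabaseEntry]
    decoys: list[DatabaseEntry]

    def __len__(self) -> int:
        return len(self.targets) + len(self.decoys)

    def manifest(self) -> str:
        return json.dumps(
            {
                "n_targets": len(self.targets),
                "n_decoys": len(self.decoys),
                "entries": [
                    {"id": e.entry_id, "length": len(e.sequence), **e.provenance}
                    for e in self.targets + self.decoys
                ],
            },
            indent=2,
            sort_keys=True,
        )


def add_decoys_and_contaminants(
    variants: list[ProteomeVariant],
    contaminants: list[tuple[str, str]] | None = None,
) -> SearchDatabase:
    """Assemble the search database: every variant protein and contaminant,
    each mirrored by its whole-sequence reversal (``DECOY_`` prefix)."""
    targets: list[DatabaseEntry] = []
    seen: set[str] = set()
    for v in variants:
        for pid, seq in v.proteins:
            eid = f"{pid}|variant={v.variant_id}"
            if eid in seen:
                raise ValueError(f"duplicate database id {eid!r}")
            seen.add(eid)
            targets.append(
                DatabaseEntry(eid, seq, {"kind": "variant", "variant": v.variant_id, "orf": pid})
            )
    for cid, seq in contaminants or []:
        if cid in seen:
            raise ValueError(f"duplicate database id {cid!r}")
        seen.add(cid)
        targets.append(DatabaseEntry(cid, seq, {"kind": "contaminant"}))
    decoys = []
    for e in targets:
        rev = e.sequence[::-1]
        prov = dict(e.provenance, kind="decoy", target=e.entry_id)
        if rev == e.sequence:
            prov["palindromic"] = True
        decoys.append(DatabaseEntry(DECOY_PREFIX + e.entry_id, rev, prov))
    return SearchDatabase(targets=targets, decoys=decoys)


def variant_fasta_records(variant: ProteomeVariant) -> list[tuple[str, str]]:
    """Header ``orf_id|variant=X`` per protein, for 60-column FASTA export."""
    return [(f"{pid}|variant={variant.variant_id}", seq) for pid, seq in variant.proteins]
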