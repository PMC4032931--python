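"""In-silico tryptic digestion, peptide masses, ppm filtering and the
unique-peptide arbitration between code hypotheses.

Identified peptides (sequence, observed neutral monoisotopic mass, spectral
count) are filtered for database membership, mass accuracy in ppm and a
minimum spectral count, then classified by which variant proteomes could
have produced them under tryptic digestion rules.  Peptides producible from
exactly one variant are *unique* to it; the hypothesis accumulating the
dominant unique count wins (e.g. glycine readthrough peptides that exist in
no other translation of the bin).

Trypsin cleaves C-terminal to K or R except when the next residue is P.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from pyteomics import mass as pmass
from pyteomics import parser as pparser

from .codes import AMINO_ACIDS
from .proteomes import ProteomeVariant

TRYPSIN_RULE = r"[KR](?!P)"
WATER_MONO = 18.010565

# common search-engine modifications (monoisotopic shifts, Da)
CARBAMIDOMETHYL_C = 57.021464
OXIDATION_M = 15.994915
CARBAMYL_NTERM = 43.005814

N_TERM = "N-term"


@dataclass(frozen=True)
class Modification:
    """A mass shift applied at a residue type or the peptide N-terminus."""

    target: str  # one-letter residue code or "N-term"
    mass_shift: float
    name: str = ""


DEFAULT_FIXED_MODS: tuple[Modification, ...] = (
    Modification("C", CARBAMIDOMETHYL_C, "carbamidomethyl"),
)
DEFAULT_VARIABLE_MODS: tuple[Modification, ...] = (
    Modification("M", OXIDATION_M, "oxidation"),
    Modification(N_TERM, CARBAMYL_NTERM, "carbamylation"),
)


@dataclass(frozen=True)
class DigestParams:
    missed_cleavages: int = 2
    min_length: int = 6
    max_length: int = 50


@dataclass(frozen=True)
class PeptideIdentification:
    sequence: str
    observed_mass: float  # neutral monoisotopic, Da
    spectral_count: int = 1
    modifications: tuple[tuple[str | int, float], ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        if self.observed_mass <= 0:
            raise ValueError("observed mass must be positive")
        if self.spectral_count < 1:
            raise ValueError("spectral count must be >= 1")


# ---------------------------------------------------------------------------
# digestion


def tryptic_digest(
    protein: str,
    missed_cleavages: int = 2,
    length_range: tuple[int, int] = (6, 50),
) -> list[str]:
    """Tryptic peptides of ``protein`` with up to ``missed_cleavages`` internal
    sites and lengths inside ``length_range``, ordered by position."""
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    lo, hi = length_range
    frags = {
        (start, pep)
        for start, pep in pparser.icleave(
            protein, TRYPSIN_RULE, missed_cleavages=missed_cleavages, regex=True
        )
        if lo <= len(pep) <= hi
    }
    return [pep for _, pep in sorted(frags, key=lambda sp: (sp[0], len(sp[1])))]


def digest_peptide_set(proteins, params: DigestParams) -> set[str]:
    """Non-redundant peptide set of a proteome (iterable of (id, seq) or seqs)."""
    peptides: set[str] = set()
    for item in proteins:
        seq = item[1] if isinstance(item, tuple) else item
        peptides.update(
            tryptic_digest(seq, params.missed_cleavages, (params.min_length, params.max_length))
        )
    return peptides


# ---------------------------------------------------------------------------
# masses


def peptide_monoisotopic_mass(
    sequence: str,
    fixed_mods: tuple[Modification, ...] = (),
    mod_shifts: float = 0.0,
) -> float:
    """Neutral monoisotopic mass: residue masses + water + fixed mods + extra shifts.

    ``fixed_mods`` are applied once per matching residue (or once for an
    N-terminal mod); ``mod_shifts`` adds any explicitly stated variable-mod
    mass.  Unknown residue symbols are rejected.
    """
    bad = set(sequence) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"unknown residue symbols: {sorted(bad)}")
    m = pmass.fast_mass(sequence)
    for mod in fixed_mods:
        if mod.target == N_TERM:
            m += mod.mass_shift
        else:
            m += mod.mass_shift * sequence.count(mod.target)
    return m + mod_shifts


def modform_masses(
    sequence: str,
    fixed_mods: tuple[Modification, ...] = DEFAULT_FIXED_MODS,
    variable_mods: tuple[Modification, ...] = (),
) -> list[float]:
    """All alternative masses under optional variable modifications.

    Each variable mod may occupy 0..n of its sites (the N-terminus counts as
    one site); returns the sorted unique masses of every combination.
    """
    base = peptide_monoisotopic_mass(sequence, fixed_mods)
    options: list[list[float]] = []
    for mod in variable_mods:
        n_sites = 1 if mod.target == N_TERM else sequence.count(mod.target)
        options.append([k * mod.mass_shift for k in range(n_sites + 1)])
    masses = {base + sum(combo) for combo in itertools.product(*options)} if options else {base}
    return sorted(masses)


def ppm_error(observed: float, theoretical: float) -> float:
    return (observed - theoretical) / theoretical * 1e6


# ---------------------------------------------------------------------------
# filtering


@dataclass
class FilterLog:
    n_input: int = 0
    removed_not_in_database: int = 0
    removed_ppm: int = 0
    removed_spectra: int = 0

    @property
    def n_retained(self) -> int:
        return (
            self.n_input
            - self.removed_not_in_database
            - self.removed_ppm
            - self.removed_spectra
        )


def ppm_filter(
    ids: list[PeptideIdentification],
    database,
    tol_ppm: float = 10.0,
    min_spectra: int = 2,
    fixed_mods: tuple[Modification, ...] = DEFAULT_FIXED_MODS,
    variable_mods: tuple[Modification, ...] = (),
) -> tuple[list[PeptideIdentification], FilterLog]:
    """Retain identifications that occur in a target protein, match their
    theoretical mass within ``tol_ppm`` and have >= ``min_spectra`` spectra.

    An identification with explicitly stated modifications is compared
    against the correspondingly shifted mass; otherwise against every
    modform generated by ``variable_mods`` (retained if any is in
    tolerance).  ``database`` is a SearchDatabase or an iterable of target
    protein sequences.
    """
    if tol_ppm < 0:
        raise ValueError("tol_ppm must be >= 0")
    target_seqs = [e.sequence for e in database.targets] if hasattr(database, "targets") else list(database)
    blob = "\x00".join(target_seqs)
    log = FilterLog(n_input=len(ids))
    retained = []
    for pid in ids:
        if pid.sequence not in blob:
            log.removed_not_in_database += 1
            continue
        if pid.modifications:
            shift = sum(s for _, s in pid.modifications)
            theos = [peptide_monoisotopic_mass(pid.sequence, fixed_mods, shift)]
        else:
            theos = modform_masses(pid.sequence, fixed_mods, variable_mods)
        if not any(abs(ppm_error(pid.observed_mass, t)) <= tol_ppm for t in theos):
            log.removed_ppm += 1
            continue
        if pid.spectral_count < min_spectra:
            log.removed_spectra += 1
            continue
        retained.append(pid)
    return retained, log


# ---------------------------------------------------------------------------
# uniqueness classification


class VariantDigestIndex:
    """Precomputed in-silico peptide set per proteome variant."""

    def __init__(self, variants: list[ProteomeVariant], params: DigestParams | None = None):
        self.params = params or DigestParams()
        self.variants = variants
        self.peptide_sets: dict[str, set[str]] = {
            v.variant_id: digest_peptide_set(v.proteins, self.params) for v in variants
        }

    def support(self, peptide: str) -> set[str]:
        return {vid for vid, peps in self.peptide_sets.items() if peptide in peps}


def classify_peptide(
    peptide: str,
    variants: list[ProteomeVariant],
    digest_params: DigestParams | None = None,
    index: VariantDigestIndex | None = None,
) -> set[str]:
    """Variant ids whose proteome can produce ``peptide`` under the digestion
    rules; a peptide is unique to a variant when the set is exactly one."""
    if not variants:
        raise ValueError("variants must be non-empty")
    if index is None:
        index = VariantDigestIndex(variants, digest_params)
    return index.support(peptide)


@dataclass
class UniquenessReport:
    unique_counts: dict[str, int]
    shared_counts: dict[str, int]
    n_retained: int
    n_shared: int
    n_unmatched: int
    n_contaminant: int
    decision: str  # variant_id or "undetermined"
    runner_up_ratio: float  # inf when the runner-up count is 0
    tie: bool = False
    filter_log: FilterLog | None = None

    def as_dict(self) -> dict:
        return {
            "unique_counts": dict(sorted(self.unique_counts.items())),
            "shared_counts": dict(sorted(self.shared_counts.items())),
            "n_retained": self.n_retained,
            "n_shared": self.n_shared,
            "n_unmatched": self.n_unmatched,
            "n_contaminant": self.n_contaminant,
            "decision": self.decision,
            "runner_up_ratio": self.runner_up_ratio if self.runner_up_ratio != float("inf") else "inf",
            "tie": self.tie,
        }


def uniqueness_report(
    ids: list[PeptideIdentification],
    variants: list[ProteomeVariant],
    decision_min_ratio: float = 10.0,
    digest_params: DigestParams | None = None,
    contaminants: list[tuple[str, str]] | None = None,
    filter_log: FilterLog | None = None,
) -> UniquenessReport:
    """Count non-redundant peptide sequences unique to each variant and decide.

    Peptides matching a contaminant protein are excluded from variant
    classification (logged).  The decision is the variant with the largest
    unique count, provided it is >= 1 and exceeds the runner-up by
    ``decision_min_ratio``; otherwise ``undetermined``.
    """
    index = VariantDigestIndex(variants, digest_params)
    contaminant_blob = "\x00".join(seq for _, seq in contaminants) if contaminants else ""
    unique = {v.variant_id: 0 for v in variants}
    shared = {v.variant_id: 0 for v in variants}
    n_shared = n_unmatched = n_contaminant = 0
    for seq in sorted({p.sequence for p in ids}):
        if contaminant_blob and seq in contaminant_blob:
            n_contaminant += 1
            continue
        support = index.support(seq)
        if not support:
            n_unmatched += 1
        elif len(support) == 1:
            unique[next(iter(support))] += 1
        else:
            n_shared += 1
            for vid in support:
                shared[vid] += 1
    ranked = sorted(unique.items(), key=lambda kv: (-kv[1], kv[0]))
    best_id, best_n = ranked[0]
    second_n = ranked[1][1] if len(ranked) > 1 else 0
    tie = len(ranked) > 1 and best_n == second_n and best_n > 0
    ratio = float("inf") if second_n == 0 else best_n / second_n
    if best_n >= 1 and not tie and ratio >= decision_min_ratio:
        decision = best_id
    else:
        decision = "undetermined"
    n_retained = len({p.sequence for p in ids})
    return UniquenessReport(
        unique_counts=unique,
        shared_counts=shared,
        n_retained=n_retained,
        n_shared=n_shared,
        n_unmatched=n_unmatched,
        n_contaminant=n_contaminant,
        decision=decision,
        runner_up_ratio=ratio,
        tie=tie,
        filter_log=filter_log,
    )
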