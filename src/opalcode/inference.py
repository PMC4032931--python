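"""Homology-based genetic-code inference from conserved protein families.

The idea: align the bin's ORF translations to families of conserved
reference proteins; at strongly conserved alignment columns the family
consensus residue is a reliable amino-acid label for the aligned query
codon.  Accumulating (codon, consensus residue) observations over all ORFs
gives a 64x20 matrix from which each codon's meaning can be read off:

- a codon whose usage is *depleted* relative to its GC-expected frequency is
  behaving as a stop codon (it is avoided inside coding regions);
- a codon observed at parity with expectation, consistently aligned to one
  amino acid, is a sense codon with that meaning — for a recoded stop codon
  (TGA -> glycine) the modal aligned residue reveals the reassignment.

The per-codon usage ratio is (observed share among all codon observations)
divided by (GC-null expected frequency), so ~1 means parity and ~0 means
depletion.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .codes import AMINO_ACIDS, CODONS, STOP, GcNullModel, expected_codon_frequency, standard_code
from .orfs import OpenReadingFrame

_CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

INSUFFICIENT_DATA = "insufficient_data"


# ---------------------------------------------------------------------------
# reference families


@dataclass
class ReferenceFamily:
    """A gapped multiple alignment of homologous reference proteins.

    ``consensus`` holds the per-column modal residue (may be '-') and
    ``column_conservation`` the fraction of members carrying that residue;
    both are computed from the members on construction.
    """

    family_id: str
    members: list[str]
    consensus: str = field(init=False)
    column_conservation: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"family {self.family_id!r} has no members")
        lengths = {len(m) for m in self.members}
        if len(lengths) != 1:
            raise ValueError(f"family {self.family_id!r}: members have unequal aligned lengths")
        n = len(self.members)
        cons_chars = []
        cons_frac = np.empty(next(iter(lengths)))
        for col in range(len(cons_frac)):
            counts = Counter(m[col] for m in self.members)
            residue, top = max(sorted(counts.items()), key=lambda kv: kv[1])
            cons_chars.append(residue)
            cons_frac[col] = top / n
        self.consensus = "".join(cons_chars)
        self.column_conservation = cons_frac

    @property
    def consensus_sequence(self) -> str:
        """Ungapped consensus, for pairwise alignment."""
        return self.consensus.replace("-", "")

    @property
    def consensus_columns(self) -> list[int]:
        """Original column index of each ungapped consensus position."""
        return [i for i, c in enumerate(self.consensus) if c != "-"]


# ---------------------------------------------------------------------------
# pairwise alignment to family consensus


@dataclass(frozen=True)
class AlignmentParams:
    """Affine-gap global alignment settings (BLOSUM62-style log-odds matrix)."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    significance_fraction: float = 0.4  # of the query's self-alignment score


def _make_matrix(name: str):
    m = substitution_matrices.load(name)
    m = m.copy()
    if "X" in m.alphabet:
        # ambiguous residues are uninformative, not penalised
        for a in m.alphabet:
            m["X", a] = 0.0
            m[a, "X"] = 0.0
    return m


_MATRIX_CACHE: dict[str, object] = {}


def _matrix(name: str):
    if name not in _MATRIX_CACHE:
        _MATRIX_CACHE[name] = _make_matrix(name)
    return _MATRIX_CACHE[name]


def _aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _matrix(params.matrix_name)
    aligner.open_gap_score = -(params.gap_open)
    aligner.extend_gap_score = -(params.gap_extend)
    return aligner


def self_alignment_score(query: str, params: AlignmentParams | None = None) -> float:
    """Sum of diagonal substitution scores over the query (X scores 0)."""
    params = params or AlignmentParams()
    m = _matrix(params.matrix_name)
    return float(sum(m[a, a] for a in query))


@dataclass(frozen=True)
class FamilyAlignment:
    family_id: str
    score: float
    significant: bool
    # (query position, family alignment column) pairs over aligned residues
    column_pairs: tuple[tuple[int, int], ...]


def align_to_family(
    query: str,
    family: ReferenceFamily,
    params: AlignmentParams | None = None,
) -> FamilyAlignment:
    """Global affine alignment of ``query`` against the family consensus.

    Returns the score and the (query position, original family column)
    mapping.  The alignment is flagged non-significant when its score is
    below ``significance_fraction`` of the query's self-alignment score.
    """
    if not query:
        raise ValueError("query must be non-empty")
    params = params or AlignmentParams()
    target = family.consensus_sequence
    if not target:
        raise ValueError(f"family {family.family_id!r} has an all-gap consensus")
    aligner = _aligner(params)
    alignment = aligner.align(query, target)[0]
    cols = family.consensus_columns
    pairs: list[tuple[int, int]] = []
    qblocks, tblocks = alignment.aligned
    for (qs, qe), (ts, te) in zip(qblocks, tblocks):
        for off in range(qe - qs):
            pairs.append((qs + off, cols[ts + off]))
    threshold = params.significance_fraction * self_alignment_score(query, params)
    return FamilyAlignment(
        family_id=family.family_id,
        score=float(alignment.score),
        significant=alignment.score >= threshold,
        column_pairs=tuple(pairs),
    )


def _kmer_set(seq: str, k: int = 5) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


# ---------------------------------------------------------------------------
# observation matrix


@dataclass
class CodonObservationMatrix:
    """64x20 counts of consensus residues aligned to query codons.

    ``counts[c, a]`` is the number of conserved reference columns whose
    consensus residue is amino acid ``a`` aligned to query codon ``c``.
    ``expected`` holds the GC-null frequency per codon.
    """

    counts: np.ndarray  # (64, 20) int
    gc_fraction: float
    expected: np.ndarray = field(init=False)  # (64,)

    def __post_init__(self) -> None:
        if self.counts.shape != (64, 20):
            raise ValueError("counts must be 64x20")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        model = GcNullModel(self.gc_fraction)
        self.expected = np.array([expected_codon_frequency(model, c) for c in CODONS])

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def usage_ratio(self) -> np.ndarray:
        """(observed share of each codon) / (GC-null expected frequency)."""
        grand = self.totals.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            share = self.totals / grand if grand else np.zeros(64)
            ratio = np.where(self.expected > 0, share / self.expected, 0.0)
        return ratio

    def row(self, codon: str) -> dict[str, int]:
        return {a: int(self.counts[_CODON_INDEX[codon], _AA_INDEX[a]]) for a in AMINO_ACIDS}

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=list(CODONS), columns=list(AMINO_ACIDS))
        df.index.name = "codon"
        return df

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    @classmethod
    def empty(cls, gc_fraction: float) -> "CodonObservationMatrix":
        return cls(counts=np.zeros((64, 20), dtype=int), gc_fraction=gc_fraction)


def collect_observations(
    orfs: list[OpenReadingFrame],
    families: list[ReferenceFamily],
    conservation_min: float = 0.9,
    gc: float = 0.5,
    params: AlignmentParams | None = None,
    prescreen_top: int = 5,
) -> CodonObservationMatrix:
    """Accumulate (codon, consensus residue) observations over all ORFs.

    Each ORF is aligned to candidate families and its best-scoring
    *significant* alignment contributes one observation per aligned column
    whose conservation is at least ``conservation_min``; codons containing N
    are skipped.  ``prescreen_top`` ranks families by shared 5-mers with the
    query and aligns only the top candidates (0 aligns against every family).
    """
    if not 0.0 < conservation_min <= 1.0:
        raise ValueError("conservation_min must be in (0, 1]")
    params = params or AlignmentParams()
    matrix = CodonObservationMatrix.empty(gc)
    if not families:
        warnings.warn("no reference families supplied; returning empty matrix")
        return matrix
    fam_kmers = [_kmer_set(f.consensus_sequence) for f in families]
    n_significant = 0
    for orf in orfs:
        query = orf.translation
        if not query:
            continue
        if prescreen_top and len(families) > prescreen_top:
            qk = _kmer_set(query)
            ranked = sorted(
                range(len(families)),
                key=lambda i: (-len(qk & fam_kmers[i]), families[i].family_id),
            )
            candidates = ranked[:prescreen_top]
        else:
            candidates = range(len(families))
        best: FamilyAlignment | None = None
        for i in candidates:
            aln = align_to_family(query, families[i], params)
            if aln.significant and (best is None or aln.score > best.score):
                best = aln
                best_family = families[i]
        if best is None:
            continue
        n_significant += 1
        cons = best_family.consensus
        conserv = best_family.column_conservation
        for qpos, col in best.column_pairs:
            if conserv[col] < conservation_min:
                continue
            residue = cons[col]
            if residue not in _AA_INDEX:
                continue
            codon = orf.codon_at(qpos)
            if "N" in codon:
                continue
            matrix.counts[_CODON_INDEX[codon], _AA_INDEX[residue]] += 1
    if n_significant == 0:
        warnings.warn("no significant family alignments; observation matrix is empty")
    return matrix


# ---------------------------------------------------------------------------
# code prediction


@dataclass(frozen=True)
class CodonCall:
    codon: str
    predicted_meaning: str  # amino acid, "*" (STOP), or "insufficient_data"
    support_freq: float
    n_obs: int
    usage_ratio: float
    tie: bool = False


@dataclass
class CodePrediction:
    calls: dict[str, CodonCall]
    min_obs: int
    min_freq: float
    min_usage: float

    def __getitem__(self, codon: str) -> CodonCall:
        return self.calls[codon]

    def to_json(self) -> str:
        payload = {
            "thresholds": {
                "min_obs": self.min_obs,
                "min_freq": self.min_freq,
                "min_usage": self.min_usage,
            },
            "codons": {
                c: {
                    "predicted_meaning": call.predicted_meaning,
                    "support_freq": round(call.support_freq, 6),
                    "n_obs": call.n_obs,
                    "usage_ratio": round(call.usage_ratio, 6),
                    "tie": call.tie,
                }
                for c, call in self.calls.items()
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def predict_code(
    matrix: CodonObservationMatrix,
    min_obs: int = 20,
    min_freq: float = 0.5,
    min_usage: float = 0.3,
) -> CodePrediction:
    """Call each codon's meaning from the observation matrix.

    Direct homology evidence outranks the usage heuristic: a codon with at
    least ``min_obs`` observations whose modal aligned amino acid reaches
    ``min_freq`` is called as that amino acid (alphabetical tie-break,
    flagged), even if its overall usage is depressed — recoded stop codons
    may occur in only a fraction of genes.  Without such evidence, a
    canonical stop codon whose usage ratio falls below ``min_usage`` is
    depleted from coding positions and called STOP (absence is the
    evidence, so this needs no minimum observation count).  Anything else
    is ``insufficient_data``.
    """
    if min_obs <= 0 or min_freq <= 0 or min_usage <= 0:
        raise ValueError("thresholds must be positive")
    std_stops = set(standard_code().stop_codons)
    totals = matrix.totals
    ratios = matrix.usage_ratio
    calls: dict[str, CodonCall] = {}
    for ci, codon in enumerate(CODONS):
        n = int(totals[ci])
        ratio = float(ratios[ci])
        row = matrix.counts[ci]
        if n > 0:
            top = row.max()
            modal = [AMINO_ACIDS[ai] for ai in np.flatnonzero(row == top)]
            support = top / n
        else:
            modal, support = [], 0.0
        tie = len(modal) > 1
        if n >= min_obs and support >= min_freq:
            meaning = sorted(modal)[0]
        elif codon in std_stops and ratio < min_usage:
            meaning = STOP
        else:
            meaning = INSUFFICIENT_DATA
        calls[codon] = CodonCall(
            codon=codon,
            predicted_meaning=meaning,
            support_freq=float(support),
            n_obs=n,
            usage_ratio=ratio,
            tie=tie,
        )
    return CodePrediction(calls=calls, min_obs=min_obs, min_freq=min_freq, min_usage=min_usage)


def logo_matrix(matrix: CodonObservationMatrix) -> dict[str, list[tuple[str, float]]]:
    """Per-codon letter heights: row frequency scaled by the usage ratio.

    The stack height of a codon equals its usage ratio, so depleted (stop)
    codons collapse and sense codons stand at ~1; the tallest letter is the
    codon's inferred meaning.
    """
    ratios = matrix.usage_ratio
    totals = matrix.totals
    out: dict[str, list[tuple[str, float]]] = {}
    for ci, codon in enumerate(CODONS):
        if totals[ci] == 0:
            out[codon] = []
            continue
        freqs = matrix.counts[ci] / totals[ci]
        heights = [
            (AMINO_ACIDS[ai], float(freqs[ai] * ratios[ci]))
            for ai in np.flatnonzero(freqs > 0)
        ]
        heights.sort(key=lambda t: (-t[1], t[0]))
        out[codon] = heights
    return out


def logo_to_tsv(logo: dict[str, list[tuple[str, float]]], path) -> None:
    rows = [
        {"codon": codon, "amino_acid": aa, "height": h}
        for codon, stack in logo.items()
        for aa, h in stack
    ]
    pd.DataFrame(rows, columns=["codon", "amino_acid", "height"]).to_csv(
        path, sep="\t", index=False
    )
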