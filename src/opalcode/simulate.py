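"""Synthetic genomes with planted genetic codes, divergent reference
families, and noisy peptide identifications.

The generator emulates the data regime of a low-GC genome bin from a
metagenome whose population recodes the opal stop codon: genes drawn from
the GC-null codon distribution restricted to the sense codons of a planted
code (TGA -> glycine by default), reference families made of diverged
copies of the true proteins, and tryptic peptide identifications carrying
Gaussian ppm mass error, geometric spectral counts and a known fraction of
false identifications.  Everything is deterministic given (parameters,
seed); ground truth (recoded positions, per-peptide true/false labels) is
recorded so every pipeline stage can be scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .codes import (
    CODONS,
    GcNullModel,
    GeneticCode,
    NucleotideSequence,
    expected_codon_frequency,
    make_variant_code,
    reverse_complement,
    standard_code,
)
from .inference import ReferenceFamily
from .peptides import (
    DEFAULT_FIXED_MODS,
    DigestParams,
    Modification,
    PeptideIdentification,
    digest_peptide_set,
    peptide_monoisotopic_mass,
)


@dataclass
class GeneTruth:
    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    protein: str
    recoded_positions: tuple[int, ...]  # protein coordinates of planted target codons


@dataclass
class SyntheticDataset:
    contigs: list[NucleotideSequence]
    true_code: GeneticCode
    true_proteins: list[tuple[str, str]]
    genes: list[GeneTruth]
    families: list[ReferenceFamily] = field(default_factory=list)
    peptide_ids: list[PeptideIdentification] = field(default_factory=list)
    peptide_labels: list[bool] = field(default_factory=list)  # True = genuine
    seed: int = 0


def default_planted_code() -> GeneticCode:
    """Opal-to-glycine: the recoding reported for BD1-5/SN-2-like genomes."""
    return make_variant_code(standard_code(), "TGA", "G")


def _codon_probs(model: GcNullModel, codons: list[str]) -> np.ndarray:
    p = np.array([expected_codon_frequency(model, c) for c in codons])
    total = p.sum()
    if total <= 0:
        raise ValueError("no codon in the pool has positive probability at this GC")
    return p / total


def generate_genome(
    n_genes: int = 100,
    gc: float = 0.332,
    code: GeneticCode | None = None,
    recoded_gene_fraction: float = 0.3,
    mean_gene_aa: int = 200,
    seed: int = 0,
    contig_id: str = "contig_1",
) -> SyntheticDataset:
    """A single-contig genome whose genes use the planted ``code``.

    Codons are drawn from the GC null restricted to the code's sense codons.
    A ``recoded_gene_fraction`` of genes contain at least one reassigned
    (target) codon; the remaining genes contain none, so code inference must
    rely on the recoded subset.  Genes get random strands and are separated
    by random intergenic spacers.  Gene length is normal around
    ``mean_gene_aa`` (sd 20%, floor 30 aa).
    """
    code = code or default_planted_code()
    rng = np.random.default_rng(seed)
    model = GcNullModel(gc)
    reassigned_codons = [c for c, m in code.reassigned if m != "*"]
    sense = list(code.sense_codons)
    plain_pool = [c for c in sense if c not in reassigned_codons]
    plain_probs = _codon_probs(model, plain_pool)
    recode_possible = bool(reassigned_codons) and any(
        expected_codon_frequency(model, c) > 0 for c in reassigned_codons
    )
    if recoded_gene_fraction > 0 and reassigned_codons and not recode_possible:
        raise ValueError("target codon has zero probability at this GC; cannot plant recoding")
    full_pool = sense if recode_possible else plain_pool
    full_probs = _codon_probs(model, full_pool)
    stops = list(code.stop_codons)
    stop_probs = _codon_probs(model, stops)
    nt_probs = np.array([model.nucleotide_probs[n] for n in "ACGT"])
    if nt_probs.sum() <= 0:
        raise ValueError("degenerate nucleotide model")

    n_recoded = int(round(n_genes * recoded_gene_fraction)) if reassigned_codons else 0
    recoded_flags = np.zeros(n_genes, dtype=bool)
    recoded_flags[:n_recoded] = True
    rng.shuffle(recoded_flags)

    def spacer() -> str:
        length = int(rng.integers(20, 101))
        return "".join(rng.choice(list("ACGT"), size=length, p=nt_probs / nt_probs.sum()))

    pieces: list[str] = [spacer()]
    offset = len(pieces[0])
    genes: list[GeneTruth] = []
    true_proteins: list[tuple[str, str]] = []
    for gi in range(n_genes):
        n_aa = max(30, int(round(rng.normal(mean_gene_aa, 0.2 * mean_gene_aa))))
        pool, probs = (full_pool, full_probs) if recoded_flags[gi] else (plain_pool, plain_probs)
        body = list(rng.choice(pool, size=n_aa - 1, p=probs))
        if recoded_flags[gi] and not any(c in reassigned_codons for c in body):
            body[int(rng.integers(0, len(body)))] = reassigned_codons[
                int(rng.integers(0, len(reassigned_codons)))
            ]
        codons = ["ATG"] + body
        stop = str(rng.choice(stops, p=stop_probs))
        gene_nt = "".join(codons) + stop
        protein = "".join(code.table[c] for c in codons)
        recoded_positions = tuple(i for i, c in enumerate(codons) if c in reassigned_codons)
        strand = "+" if rng.random() < 0.5 else "-"
        placed = gene_nt if strand == "+" else reverse_complement(gene_nt)
        gene_id = f"gene_{gi + 1:04d}"
        genes.append(
            GeneTruth(
                gene_id=gene_id,
                contig_id=contig_id,
                start=offset,
                end=offset + len(placed),
                strand=strand,
                protein=protein,
                recoded_positions=recoded_positions,
            )
        )
        true_proteins.append((gene_id, protein))
        pieces.append(placed)
        offset += len(placed)
        sp = spacer()
        pieces.append(sp)
        offset += len(sp)
    contig = NucleotideSequence(id=contig_id, residues="".join(pieces))
    return SyntheticDataset(
        contigs=[contig],
        true_code=code,
        true_proteins=true_proteins,
        genes=genes,
        seed=seed,
    )


def generate_reference_families(
    true_proteins: list[tuple[str, str]],
    n_members: int = 5,
    substitution_rate: float = 0.15,
    seed: int = 0,
    deletion_rate: float = 0.0,
) -> list[ReferenceFamily]:
    """One family per true protein: ``n_members`` diverged copies.

    Divergence is by point substitution at ``substitution_rate`` per site
    (uniform over the 19 other residues), keeping the trivial columnwise
    alignment exact.  ``deletion_rate`` optionally gaps residues out of
    members ('-' columns) to stress the aligner; no insertions.
    """
    if not 0.0 <= substitution_rate < 1.0:
        raise ValueError("substitution_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    families = []
    for gene_id, protein in true_proteins:
        arr = np.array(list(protein))
        members = []
        for _ in range(n_members):
            member = arr.copy()
            mask = rng.random(len(arr)) < substitution_rate
            for pos in np.flatnonzero(mask):
                choices = aas[aas != arr[pos]]
                member[pos] = choices[int(rng.integers(0, len(choices)))]
            if deletion_rate > 0:
                dmask = rng.random(len(arr)) < deletion_rate
                member[dmask] = "-"
            members.append("".join(member))
        families.append(ReferenceFamily(family_id=f"{gene_id}_fam", members=members))
    return families


def generate_peptide_ids(
    true_proteins: list[tuple[str, str]],
    n_true: int = 1000,
    false_id_rate: float = 0.01,
    mass_error_ppm_sd: float = 3.0,
    spectral_count_mean: float = 3.0,
    seed: int = 0,
    digest_params: DigestParams | None = None,
    fixed_mods: tuple[Modification, ...] = DEFAULT_FIXED_MODS,
) -> tuple[list[PeptideIdentification], list[bool]]:
    """Noisy peptide identifications from the true proteome.

    ``n_true`` peptides are sampled uniformly (without replacement when
    possible) from the non-redundant tryptic digest; observed masses are the
    theoretical mass (including fixed modifications) perturbed by Gaussian
    ppm error.  False identifications — random sequences with their own
    plausible masses — are added so they make up ``false_id_rate`` of all
    identifications.  Spectral counts are geometric with the given mean.
    Returns the identifications and their per-peptide truth labels.
    """
    if not 0.0 <= false_id_rate < 1.0:
        raise ValueError("false_id_rate must be in [0, 1)")
    params = digest_params or DigestParams()
    rng = np.random.default_rng(seed)
    digest = sorted(digest_peptide_set(true_proteins, params))
    if not digest:
        raise ValueError("true proteome digest is empty")
    replace = n_true > len(digest)
    if replace:
        warnings.warn("digest smaller than n_true; sampling with replacement")
    chosen = rng.choice(len(digest), size=n_true, replace=replace)
    p_geom = 1.0 / spectral_count_mean
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    ids: list[PeptideIdentification] = []
    labels: list[bool] = []

    def observe(seq: str) -> float:
        theo = peptide_monoisotopic_mass(seq, fixed_mods)
        eps = rng.normal(0.0, mass_error_ppm_sd)
        return theo * (1.0 + eps * 1e-6)

    for idx in chosen:
        seq = digest[int(idx)]
        ids.append(
            PeptideIdentification(
                sequence=seq,
                observed_mass=observe(seq),
                spectral_count=int(rng.geometric(p_geom)),
            )
        )
        labels.append(True)
    n_false = int(round(n_true * false_id_rate / (1.0 - false_id_rate)))
    true_lengths = [len(digest[int(i)]) for i in chosen] or [12]
    for _ in range(n_false):
        length = true_lengths[int(rng.integers(0, len(true_lengths)))]
        seq = "".join(rng.choice(aas, size=length))
        ids.append(
            PeptideIdentification(
                sequence=seq,
                observed_mass=observe(seq),
                spectral_count=int(rng.geometric(p_geom)),
            )
        )
        labels.append(False)
    return ids, labels


def generate_contaminants(
    n: int = 44, mean_aa: int = 250, seed: int = 0
) -> list[tuple[str, str]]:
    """Synthetic stand-ins for a common-contaminant protein list (random
    sequences; the real contaminant set is lab-specific)."""
    rng = np.random.default_rng(seed)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    out = []
    for i in range(n):
        length = max(50, int(round(rng.normal(mean_aa, 0.2 * mean_aa))))
        out.append((f"CONTAM_{i + 1:03d}", "".join(rng.choice(aas, size=length))))
    return out


def generate_dataset(
    n_genes: int = 100,
    gc: float = 0.332,
    code: GeneticCode | None = None,
    recoded_gene_fraction: float = 0.3,
    mean_gene_aa: int = 200,
    n_members: int = 5,
    substitution_rate: float = 0.15,
    n_true_peptides: int = 1000,
    false_id_rate: float = 0.01,
    mass_error_ppm_sd: float = 3.0,
    spectral_count_mean: float = 3.0,
    seed: int = 0,
    digest_params: DigestParams | None = None,
) -> SyntheticDataset:
    """A complete dataset: genome, reference families and peptide IDs."""
    rng = np.random.default_rng(seed)
    s_genome, s_fam, s_pep = (int(x) for x in rng.integers(0, 2**31 - 1, size=3))
    ds = generate_genome(
        n_genes=n_genes,
        gc=gc,
        code=code,
        recoded_gene_fraction=recoded_gene_fraction,
        mean_gene_aa=mean_gene_aa,
        seed=s_genome,
    )
    ds.seed = seed
    ds.families = generate_reference_families(
        ds.true_proteins,
        n_members=n_members,
        substitution_rate=substitution_rate,
        seed=s_fam,
    )
    ds.peptide_ids, ds.peptide_labels = generate_peptide_ids(
        ds.true_proteins,
        n_true=n_true_peptides,
        false_id_rate=false_id_rate,
        mass_error_ppm_sd=mass_error_ppm_sd,
        spectral_count_mean=spectral_count_mean,
        seed=s_pep,
        digest_params=digest_params,
    )
    return ds
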