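"""Readers/writers for FASTA, aligned-FASTA families, peptide tables and
the pipeline configuration."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codes import NucleotideSequence
from .inference import ReferenceFamily
from .peptides import PeptideIdentification

log = logging.getLogger("opalcode")


# ---------------------------------------------------------------------------
# FASTA


def read_nucleotide_fasta(path) -> list[NucleotideSequence]:
    """Contigs from FASTA; lowercase is uppercased (logged), ids must be unique."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if seq != seq.upper():
            log.info("uppercasing lowercase bases in %s", rec.id)
            seq = seq.upper()
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(NucleotideSequence(id=rec.id, residues=seq, description=rec.description))
    if not records:
        log.warning("no sequences found in %s", path)
    return records


def read_protein_fasta(path) -> list[tuple[str, str]]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.id, str(rec.seq).upper()))
    if not out:
        log.warning("no sequences found in %s", path)
    return out


def write_fasta(records: list[tuple[str, str]], path, width: int = 60) -> None:
    """Write (id, sequence) pairs as wrapped FASTA."""
    seqrecords = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=width)
    writer.write_file(seqrecords)


def read_family_fasta(path, family_id: str | None = None) -> ReferenceFamily:
    """One gapped aligned FASTA file -> one ReferenceFamily."""
    path = Path(path)
    members = [seq for _, seq in read_protein_fasta(path)]
    if not members:
        raise ValueError(f"family file {path} is empty")
    return ReferenceFamily(family_id=family_id or path.stem, members=members)


def read_families_dir(directory) -> list[ReferenceFamily]:
    """All ``*.fasta``/``*.afa``/``*.fa`` files in a directory, one family each."""
    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir() if p.suffix in (".fasta", ".afa", ".fa", ".faa")
    )
    return [read_family_fasta(p) for p in paths]


def write_family_fasta(family: ReferenceFamily, path) -> None:
    write_fasta(
        [(f"{family.family_id}_m{i + 1}", m) for i, m in enumerate(family.members)], path
    )


# ---------------------------------------------------------------------------
# peptide tables (TSV: peptide, observed_mass, spectral_count, mods)


def read_peptide_tsv(path) -> list[PeptideIdentification]:
    ids = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["peptide", "observed_mass", "spectral_count", "mods"]
        if header != expected:
            raise ValueError(f"peptide table header must be {expected}, got {header}")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            pep, mass_s, count_s, mods_s = fields
            mods = []
            if mods_s:
                for item in mods_s.split(";"):
                    site, shift = item.split(":")
                    site = int(site) if site.lstrip("-").isdigit() else site
                    mods.append((site, float(shift)))
            ids.append(
                PeptideIdentification(
                    sequence=pep,
                    observed_mass=float(mass_s),
                    spectral_count=int(count_s),
                    modifications=tuple(mods),
                )
            )
    return ids


def write_peptide_tsv(ids: list[PeptideIdentification], path) -> None:
    with open(path, "w") as fh:
        fh.write("peptide\tobserved_mass\tspectral_count\tmods\n")
        for p in ids:
            mods = ";".join(f"{site}:{shift}" for site, shift in p.modifications)
            fh.write(f"{p.sequence}\t{p.observed_mass:.6f}\t{p.spectral_count}\t{mods}\n")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """All thresholds and paths of the workflow; defaults follow the modules."""

    seed: int = 1
    target_codon: str = "TGA"
    gc: float | None = None  # None -> estimated from the contigs

    # ORF calling
    min_aa: int = 30

    # code inference
    conservation_min: float = 0.9
    min_obs: int = 20
    min_freq: float = 0.5
    min_usage: float = 0.3
    gap_open: float = 11.0
    gap_extend: float = 1.0
    significance_fraction: float = 0.4
    prescreen_top: int = 5

    # peptide validation
    tol_ppm: float = 10.0
    min_spectra: int = 2
    decision_min_ratio: float = 10.0
    missed_cleavages: int = 2
    peptide_min_len: int = 6
    peptide_max_len: int = 50

    # synthetic generator
    simulate: bool = True
    n_genes: int = 100
    sim_gc: float = 0.332
    recoded_gene_fraction: float = 0.3
    mean_gene_aa: int = 200
    planted_meaning: str = "G"  # "*" plants no recoding (standard code)
    n_members: int = 5
    substitution_rate: float = 0.15
    n_true_peptides: int = 1000
    false_id_rate: float = 0.01
    mass_error_ppm_sd: float = 3.0
    spectral_count_mean: float = 3.0
    n_contaminants: int = 44

    # file inputs (used when simulate is false)
    contigs_path: str | None = None
    families_dir: str | None = None
    peptides_path: str | None = None
    contaminants_path: str | None = None

    output_dir: str = "opalcode_out"

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("conservation_min", 0.0, 1.0),
            ("min_freq", 0.0, 1.0),
            ("recoded_gene_fraction", 0.0, 1.0),
            ("false_id_rate", 0.0, 1.0),
            ("substitution_rate", 0.0, 1.0),
            ("significance_fraction", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name} must be in [{lo}, {hi}], got {v}")
        if self.gc is not None and not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must be in [0, 1]")
        if self.tol_ppm < 0 or self.min_spectra < 1 or self.min_aa < 1:
            raise ValueError("invalid filter settings")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)
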