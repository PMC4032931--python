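"""End-to-end workflow: (simulate) -> ORFs -> code inference -> variant
proteomes -> search database -> peptide filtering -> uniqueness decision."""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import io as oio
from .codes import STOP, make_variant_code, standard_code
from .inference import (
    AlignmentParams,
    collect_observations,
    logo_matrix,
    logo_to_tsv,
    predict_code,
)
from .orfs import find_orfs, orfs_to_bed, orfs_to_protein_records
from .peptides import (
    DigestParams,
    ppm_filter,
    uniqueness_report,
)
from .proteomes import add_decoys_and_contaminants, build_variant_proteomes, variant_fasta_records
from .simulate import generate_contaminants, generate_dataset

log = logging.getLogger("opalcode")

REPORT_SCHEMA_VERSION = 1


def _empirical_gc(contigs) -> float:
    gc = total = 0
    for c in contigs:
        s = c.residues
        gc += s.count("G") + s.count("C")
        total += len(s) - s.count("N")
    if total == 0:
        raise ValueError("cannot estimate GC from empty contigs")
    return gc / total


def run_pipeline(config: oio.PipelineConfig) -> dict:
    """Execute the full workflow and return (and write) the report dict.

    Intermediates (ORF FASTA/BED, observation matrix and logo TSVs, code
    prediction JSON, variant FASTAs, database manifest, report JSON) are
    written under ``config.output_dir``.  Deterministic for a fixed config.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        # ------------------------------------------------------------ inputs
        stage = "simulate" if config.simulate else "load_inputs"
        if config.simulate:
            planted = (
                standard_code()
                if config.planted_meaning == STOP
                else make_variant_code(standard_code(), config.target_codon, config.planted_meaning)
            )
            ds = generate_dataset(
                n_genes=config.n_genes,
                gc=config.sim_gc,
                code=planted,
                recoded_gene_fraction=config.recoded_gene_fraction,
                mean_gene_aa=config.mean_gene_aa,
                n_members=config.n_members,
                substitution_rate=config.substitution_rate,
                n_true_peptides=config.n_true_peptides,
                false_id_rate=config.false_id_rate,
                mass_error_ppm_sd=config.mass_error_ppm_sd,
                spectral_count_mean=config.spectral_count_mean,
                seed=config.seed,
                digest_params=DigestParams(
                    config.missed_cleavages, config.peptide_min_len, config.peptide_max_len
                ),
            )
            contigs, families, peptide_ids = ds.contigs, ds.families, ds.peptide_ids
            contaminants = generate_contaminants(config.n_contaminants, seed=config.seed)
            oio.write_fasta([(c.id, c.residues) for c in contigs], out / "contigs.fasta")
            oio.write_peptide_tsv(peptide_ids, out / "peptide_ids.tsv")
            fam_dir = out / "families"
            fam_dir.mkdir(exist_ok=True)
            for fam in families:
                oio.write_family_fasta(fam, fam_dir / f"{fam.family_id}.fasta")
        else:
            if not (config.contigs_path and config.families_dir and config.peptides_path):
                raise ValueError("contigs_path, families_dir and peptides_path are required")
            contigs = oio.read_nucleotide_fasta(config.contigs_path)
            families = oio.read_families_dir(config.families_dir)
            peptide_ids = oio.read_peptide_tsv(config.peptides_path)
            contaminants = (
                oio.read_protein_fasta(config.contaminants_path)
                if config.contaminants_path
                else []
            )
        gc = config.gc if config.gc is not None else _empirical_gc(contigs)
        log.info("%d contigs, %d families, %d peptide IDs, GC=%.4f",
                 len(contigs), len(families), len(peptide_ids), gc)

        # -------------------------------------------------------------- ORFs
        stage = "find_orfs"
        code = standard_code()
        orfs = []
        for contig in contigs:
            orfs.extend(
                find_orfs(contig, code, min_aa=config.min_aa, readthrough_codon=config.target_codon)
            )
        log.info("%d ORFs called (min %d aa, readthrough %s)", len(orfs), config.min_aa, config.target_codon)
        oio.write_fasta(orfs_to_protein_records(orfs), out / "orfs.faa")
        (out / "orfs.bed").write_text(orfs_to_bed(orfs))

        # ---------------------------------------------------- code inference
        stage = "collect_observations"
        params = AlignmentParams(
            gap_open=config.gap_open,
            gap_extend=config.gap_extend,
            significance_fraction=config.significance_fraction,
        )
        matrix = collect_observations(
            orfs,
            families,
            conservation_min=config.conservation_min,
            gc=gc,
            params=params,
            prescreen_top=config.prescreen_top,
        )
        matrix.to_tsv(out / "observation_matrix.tsv")
        stage = "predict_code"
        prediction = predict_code(
            matrix, min_obs=config.min_obs, min_freq=config.min_freq, min_usage=config.min_usage
        )
        (out / "code_prediction.json").write_text(prediction.to_json())
        logo_to_tsv(logo_matrix(matrix), out / "logo.tsv")
        target_call = prediction[config.target_codon]
        log.info("inferred meaning of %s: %s (n=%d, support=%.3f, usage_ratio=%.3f)",
                 config.target_codon, target_call.predicted_meaning, target_call.n_obs,
                 target_call.support_freq, target_call.usage_ratio)

        # ------------------------------------------------- variant proteomes
        stage = "build_variant_proteomes"
        variants = build_variant_proteomes(orfs, target_codon=config.target_codon)
        var_dir = out / "variants"
        var_dir.mkdir(exist_ok=True)
        for v in variants:
            oio.write_fasta(variant_fasta_records(v), var_dir / f"variant_{v.variant_id}.fasta")
        stage = "add_decoys_and_contaminants"
        database = add_decoys_and_contaminants(variants, contaminants)
        (out / "database_manifest.json").write_text(database.manifest())

        # ------------------------------------------------ peptide validation
        stage = "ppm_filter"
        retained, flog = ppm_filter(
            peptide_ids, database, tol_ppm=config.tol_ppm, min_spectra=config.min_spectra
        )
        log.info("peptide filter: %d in, %d not in database, %d ppm, %d spectra -> %d retained",
                 flog.n_input, flog.removed_not_in_database, flog.removed_ppm,
                 flog.removed_spectra, flog.n_retained)
        stage = "uniqueness_report"
        report = uniqueness_report(
            retained,
            variants,
            decision_min_ratio=config.decision_min_ratio,
            digest_params=DigestParams(
                config.missed_cleavages, config.peptide_min_len, config.peptide_max_len
            ),
            contaminants=contaminants,
            filter_log=flog,
        )
        log.info("unique-peptide decision: %s (ratio %s)", report.decision, report.runner_up_ratio)

        # ------------------------------------------------------------ report
        stage = "write_report"
        payload = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "config": config.as_dict(),
            "gc_used": round(gc, 6),
            "n_contigs": len(contigs),
            "n_orfs": len(orfs),
            "code_inference": {
                "target_codon": config.target_codon,
                "predicted_meaning": target_call.predicted_meaning,
                "support_freq": round(target_call.support_freq, 6),
                "n_obs": target_call.n_obs,
                "usage_ratio": round(target_call.usage_ratio, 6),
            },
            "peptide_filter": {
                "n_input": flog.n_input,
                "removed_not_in_database": flog.removed_not_in_database,
                "removed_ppm": flog.removed_ppm,
                "removed_spectra": flog.removed_spectra,
                "n_retained": flog.n_retained,
            },
            "uniqueness": report.as_dict(),
        }
        report_text = json.dumps(payload, indent=2, sort_keys=True)
        (out / "report.json").write_text(report_text)
        return payload
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
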