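"""Tryptic digestion, peptide masses, ppm filtering and uniqueness logic."""

import numpy as np
import pytest
from _oracles import brute_force_classify, naive_tryptic_digest

from opalcode import (
    DigestParams,
    Modification,
    NucleotideSequence,
    PeptideIdentification,
    build_variant_proteomes,
    classify_peptide,
    find_orfs,
    peptide_monoisotopic_mass,
    ppm_filter,
    standard_code,
    tryptic_digest,
    uniqueness_report,
)
from opalcode.peptides import (
    CARBAMIDOMETHYL_C,
    WATER_MONO,
    VariantDigestIndex,
    modform_masses,
    ppm_error,
)


class TestTrypticDigest:
    @pytest.mark.parametrize(
        "protein,mc,expected",
        [
            ("MKAAAR", 0, ["MK", "AAAR"]),
            ("AKPAR", 0, ["AKPAR"]),  # K-P bond protected
            ("MKAAAR", 1, ["MK", "MKAAAR", "AAAR"]),
        ],
    )
    def test_examples(self, protein, mc, expected):
        assert tryptic_digest(protein, mc, (1, 50)) == expected

    def test_zero_missed_concatenation_reconstructs_protein(self):
        rng = np.random.default_rng(1)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(50):
            protein = "".join(rng.choice(aas, size=rng.integers(1, 120)))
            frags = tryptic_digest(protein, 0, (1, len(protein)))
            assert "".join(frags) == protein

    @pytest.mark.parametrize("mc", [0, 1, 2])
    def test_matches_brute_force_enumeration(self, mc):
        rng = np.random.default_rng(2)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(100):
            protein = "".join(rng.choice(aas, size=rng.integers(1, 60)))
            got = sorted(tryptic_digest(protein, mc, (1, 60)))
            want = sorted(naive_tryptic_digest(protein, mc, 1, 60))
            assert got == want

    def test_negative_missed_cleavages_rejected(self):
        with pytest.raises(ValueError):
            tryptic_digest("MK", -1, (1, 50))


class TestPeptideMass:
    def test_glycine_mass(self):
        assert peptide_monoisotopic_mass("G") == pytest.approx(57.02146 + WATER_MONO, abs=1e-5)

    def test_residue_additivity(self):
        dGG = peptide_monoisotopic_mass("GG") - peptide_monoisotopic_mass("G")
        assert dGG == pytest.approx(57.02146, abs=1e-5)

    def test_fixed_carbamidomethyl_on_cysteine(self):
        fixed = (Modification("C", CARBAMIDOMETHYL_C),)
        m = peptide_monoisotopic_mass("C", fixed)
        assert m == pytest.approx(103.00919 + 57.0214 + WATER_MONO, abs=1e-4)

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            peptide_monoisotopic_mass("GBZ")

    def test_modform_masses_enumerate_variable_sites(self):
        variable = (Modification("M", 15.994915), Modification("N-term", 43.005814))
        masses = modform_masses("MAMK", variable_mods=variable)
        base = peptide_monoisotopic_mass("MAMK")
        expected = sorted(
            base + k * 15.994915 + j * 43.005814 for k in (0, 1, 2) for j in (0, 1)
        )
        assert masses == pytest.approx(expected)


class TestPpmFilter:
    def _id(self, seq, ppm=0.0, spectra=3):
        theo = peptide_monoisotopic_mass(seq, (Modification("C", CARBAMIDOMETHYL_C),))
        return PeptideIdentification(seq, theo * (1 + ppm * 1e-6), spectra)

    def test_exact_mass_retained(self):
        db = ["MKAAARWWW"]
        kept, log = ppm_filter([self._id("AAAR")], db, tol_ppm=0.0, min_spectra=1)
        assert len(kept) == 1 and log.n_retained == 1

    def test_20ppm_error_removed_at_10ppm(self):
        db = ["MKAAARWWW"]
        kept, log = ppm_filter([self._id("AAAR", ppm=20)], db, tol_ppm=10)
        assert kept == [] and log.removed_ppm == 1

    def test_low_spectral_count_removed(self):
        db = ["MKAAARWWW"]
        kept, log = ppm_filter([self._id("AAAR", spectra=1)], db, min_spectra=2)
        assert kept == [] and log.removed_spectra == 1

    def test_sequence_absent_from_database_removed(self):
        kept, log = ppm_filter([self._id("AAAR")], ["MKWWW"], tol_ppm=10)
        assert kept == [] and log.removed_not_in_database == 1

    def test_stated_modification_shifts_theoretical_mass(self):
        db = ["MKAMAR"]
        theo = peptide_monoisotopic_mass("AMAR") + 15.994915
        oxidised = PeptideIdentification("AMAR", theo, 3, ((1, 15.994915),))
        kept, _ = ppm_filter([oxidised], db, tol_ppm=1)
        assert kept == [oxidised]

    def test_variable_modform_rescues_shifted_mass(self):
        db = ["MKAMAR"]
        theo = peptide_monoisotopic_mass("AMAR") + 15.994915
        unannotated = PeptideIdentification("AMAR", theo, 3)
        kept_no, _ = ppm_filter([unannotated], db, tol_ppm=1)
        kept_yes, _ = ppm_filter(
            [unannotated], db, tol_ppm=1, variable_mods=(Modification("M", 15.994915),)
        )
        assert kept_no == [] and kept_yes == [unannotated]

    def test_retention_matches_gaussian_tail(self):
        """Retention under Gaussian ppm error ~ P(|N(0,sd)| <= tol)."""
        from scipy import stats

        rng = np.random.default_rng(9)
        sd, tol, n = 3.0, 5.0, 10000
        db = ["MKAAARWWW"]
        theo = peptide_monoisotopic_mass("AAAR")
        ids = [
            PeptideIdentification("AAAR", theo * (1 + rng.normal(0, sd) * 1e-6), 3)
            for _ in range(n)
        ]
        kept, _ = ppm_filter(ids, db, tol_ppm=tol, min_spectra=1, fixed_mods=())
        p = 2 * stats.norm.cdf(tol / sd) - 1
        assert abs(len(kept) / n - p) <= 3 * np.sqrt(p * (1 - p) / n)


@pytest.fixture(scope="module")
def variants():
    contig = NucleotideSequence(
        "c1",
        # MKAVLIEGR [TGA->?] PLKWDETYR stop
        "ATG" + "AAAGCGGTGCTGATTGAAGGGCGT" + "TGA" + "CCGCTGAAATGGGATGAAACCTATCGT" + "TAA",
    )
    orfs = [
        o
        for o in find_orfs(contig, standard_code(), min_aa=5, readthrough_codon="TGA")
        if o.strand == "+" and o.start == 0
    ]
    return build_variant_proteomes(orfs)


class TestClassifyPeptide:
    def test_tga_free_peptide_supported_everywhere(self, variants):
        # every variant except proline: a P at the readthrough position
        # blocks cleavage of the preceding R, so that variant cannot
        # produce the peptide ending there
        support = classify_peptide("MKAVLIEGR", variants, DigestParams(2, 6, 50))
        assert support == {v.variant_id for v in variants} - {"P"}

    def test_readthrough_spanning_peptide_unique_to_one_variant(self, variants):
        # readthrough position carries G only in the glycine variant
        support = classify_peptide("GPLK", variants, DigestParams(0, 1, 50))
        assert support == {"G"}

    def test_matches_brute_force_scan(self, variants):
        rng = np.random.default_rng(4)
        params = DigestParams(2, 6, 50)
        index = VariantDigestIndex(variants, params)
        pool = sorted(set().union(*index.peptide_sets.values()))
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        peptides = [pool[i] for i in rng.integers(0, len(pool), 25)] + [
            "".join(rng.choice(aas, size=10)) for _ in range(25)
        ]
        for pep in peptides:
            fast = classify_peptide(pep, variants, params, index=index)
            slow = brute_force_classify(pep, variants, 2, 6, 50)
            assert fast == slow

    def test_monotone_in_proteome_growth(self, variants):
        """Adding proteins to a variant can only add it to support sets."""
        from opalcode.proteomes import ProteomeVariant

        grown = [
            ProteomeVariant(v.variant_id, v.target_codon, v.proteins + [("extra", "MKAVLIEGR")])
            if v.variant_id == "W"
            else v
            for v in variants
        ]
        params = DigestParams(2, 6, 50)
        for pep in ("MKAVLIEGR", "GPLK", "WDETYR"):
            before = classify_peptide(pep, variants, params)
            after = classify_peptide(pep, grown, params)
            assert before <= after

    def test_empty_variants_rejected(self):
        with pytest.raises(ValueError):
            classify_peptide("MK", [])


class TestUniquenessReport:
    def _ids(self, seqs):
        return [PeptideIdentification(s, 500.0, 3) for s in seqs]

    def test_partition_unique_xor_shared(self, variants):
        params = DigestParams(2, 6, 50)
        index = VariantDigestIndex(variants, params)
        pool = sorted(set().union(*index.peptide_sets.values()))
        report = uniqueness_report(self._ids(pool), variants, digest_params=params)
        n_unique = sum(report.unique_counts.values())
        assert n_unique + report.n_shared + report.n_unmatched == report.n_retained

    def test_papers_pattern_decides_gly(self):
        """97 Gly-unique vs 3 Trp-unique vs 0 stop-unique -> decision Gly."""
        from opalcode.proteomes import ProteomeVariant

        gly_peps = [f"AAGAA{i:03d}".replace("0", "V").replace("1", "L").replace(
            "2", "I").replace("3", "F").replace("4", "Y").replace("5", "W").replace(
            "6", "T").replace("7", "S").replace("8", "N").replace("9", "Q")
            for i in range(97)]
        trp_peps = ["WWAAK", "WWCCK", "WWDDK"]
        mk = lambda vid, peps: ProteomeVariant(vid, "TGA", [(f"{vid}_{i}", p) for i, p in enumerate(peps)])
        variants = [mk("G", gly_peps), mk("W", trp_peps), mk("STOP", [])]
        ids = self._ids(gly_peps + trp_peps)
        report = uniqueness_report(
            ids, variants, decision_min_ratio=10, digest_params=DigestParams(0, 1, 50)
        )
        assert report.unique_counts == {"G": 97, "W": 3, "STOP": 0}
        assert report.decision == "G"
        assert report.runner_up_ratio == pytest.approx(97 / 3)

    def test_all_zero_counts_undetermined(self, variants):
        report = uniqueness_report([], variants)
        assert report.decision == "undetermined"

    def test_tie_is_undetermined_and_flagged(self):
        from opalcode.proteomes import ProteomeVariant

        variants = [
            ProteomeVariant("A", "TGA", [("a", "CCCCCK")]),
            ProteomeVariant("K", "TGA", [("k", "DDDDDK")]),
        ]
        report = uniqueness_report(
            self._ids(["CCCCCK", "DDDDDK"]), variants, digest_params=DigestParams(0, 1, 50)
        )
        assert report.decision == "undetermined"
        assert report.tie

    def test_contaminant_matching_peptides_excluded(self, variants):
        contaminants = [("CON_1", "MKAVLIEGR")]
        report = uniqueness_report(
            self._ids(["MKAVLIEGR"]), variants, contaminants=contaminants
        )
        assert report.n_contaminant == 1
        assert sum(report.unique_counts.values()) + report.n_shared == 0

    def test_spectral_counts_do_not_weight_uniqueness(self, variants):
        """Uniqueness counts non-redundant sequences, not spectra."""
        ids = [
            PeptideIdentification("GPLK", 500.0, 50),
            PeptideIdentification("GPLK", 500.0, 2),
        ]
        report = uniqueness_report(ids, variants, digest_params=DigestParams(0, 1, 50))
        assert report.unique_counts["G"] == 1
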