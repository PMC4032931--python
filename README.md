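# opalcode

Detection and proteogenomic validation of **stop-codon reassignment** in a
genome bin — the situation where an organism (for example, a member of the
uncultivated BD1-5/SN-2 candidate phylum) translates the opal stop codon
UGA (DNA: TGA) as an amino acid such as glycine instead of terminating.

The package is aimed at microbial (meta)genomics practitioners who have a
set of binned contigs plus shotgun-proteomics peptide identifications and
want to ask, reproducibly: *does this population use a non-standard genetic
code, and can the peptides prove it?* Because raw data of this kind are
rarely redeposited in a directly re-analysable form, the package also ships
a fully deterministic synthetic-data generator that plants a known code, so
every stage of the method can be exercised and scored against ground truth.

## The method

Two independent lines of evidence are combined.

**1. Homology-based code inference.** ORFs are called in all six frames
with *readthrough* of the candidate codon (so recoded genes are not
truncated at their internal TGAs), and each ORF translation is aligned to
conserved reference protein families. At strongly conserved alignment
columns the family consensus residue labels the aligned query codon,
yielding a 64×20 observation matrix `N[c, a]`. Each codon's usage is
normalised by its expectation under a GC-null model with independent
positions, `P(codon) = ∏ᵢ p(nᵢ)` with `p(G) = p(C) = GC/2`:

```
usage_ratio(c) = ( N[c,·] / Σ N )  /  P(c)
```

A codon depleted from coding positions (`usage_ratio ≪ 1`) behaves as a
stop; a codon observed with a dominant aligned amino acid (support
frequency ≥ 0.5 over ≥ 20 observations) is called as that amino acid — for
a recoded TGA the modal residue reveals the reassignment.

**2. Unique-peptide arbitration.** The bin is translated once per
hypothesis for the target codon — STOP plus each of the 20 amino acids (21
variant proteomes; the classic 3-way comparison is {STOP, Trp, Gly}) — and
assembled into a search database together with contaminants and
reversed-sequence decoys. Identified peptides are filtered (±10 ppm
monoisotopic mass accuracy, ≥ 2 spectra) and classified by which variants'
tryptic digests can produce them. A peptide producible by exactly one
variant is *unique* to it; the hypothesis whose unique-peptide count
dominates (≥ 10× the runner-up) wins.

## Worked example

Run the full workflow on a simulated bin (GC 33.2 %, 100 genes, UGA→Gly
planted in 30 % of genes, 1000 true peptide IDs with 1 % false
identifications and 3 ppm mass-error sd):

```bash
opalcode --quiet run-all --seed 7 --outdir demo_out
```

```json
{
  "predicted_meaning": "G",
  "decision": "G",
  "report": "demo_out/report.json"
}
```

The report shows both stages agreeing on glycine. Inference stage: the TGA
row of the observation matrix has 64 observations, all of them glycine
(`support_freq = 1.0`), at `usage_ratio = 0.379` (TGA occurs in only a
fraction of genes, so it sits well below parity but far above a true
stop's ≈ 0). Proteogenomic stage: of 1010 peptide identifications, 672
survive the ±10 ppm / min-2-spectra filters; 54 peptides are unique to the
Gly variant and **zero** are unique to any of the other 20 variants
(runner-up ratio ∞), so the decision is `G`. A control genome using the
standard code instead yields `predicted_meaning = "*"` (STOP) and no
Gly-unique peptides.

Individual stages are available as subcommands (`simulate`, `infer-code`,
`build-proteomes`, `digest`, `validate-code`) and as library functions
(`opalcode.find_orfs`, `opalcode.collect_observations`,
`opalcode.predict_code`, `opalcode.uniqueness_report`, ...).

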