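# Methods

This note documents the models, defaults and design choices behind
`opalcode`, and what the synthetic benchmarks do and do not demonstrate.

## Problem setting

A genome bin is suspected of translating a canonical stop codon — by
default the opal codon TGA — as an amino acid. The package infers the
codon's meaning from homology evidence, then validates it independently
from peptide identifications. All sequence handling uses the DNA alphabet
(TGA, not UGA) and 0-based half-open coordinates on the forward strand.

## GC-null codon model

Expected codon frequency is modelled with independent nucleotide positions
parameterised only by genomic GC: `p(G) = p(C) = GC/2`,
`p(A) = p(T) = (1−GC)/2`, and `P(codon)` is the product over the three
positions. This is the simplest model in which "expected occurrence of a
codon" is a function of GC percentage alone; it is strand-symmetric and
sums to 1 over the 64 codons for any GC, including the degenerate GC = 0
and GC = 1 cases. Empirical mononucleotide frequencies could be substituted
by passing the fitted GC of the bin; position-specific or dinucleotide
models are deliberately out of scope.

## ORF calling with readthrough

A deliberately transparent six-frame scanner replaces statistical gene
callers: an ORF runs from a bacterial start codon (ATG/GTG/TTG) to the
first downstream stop of the calling code, and a designated readthrough
codon is exempted from terminating. Choices:

- Only stop-terminated ORFs are emitted; partial genes at contig edges are
  not modelled.
- Per stop, the most upstream start is taken (longest ORF). This is
  deterministic and maximises the number of codon observations available
  to code inference.
- Readthrough codons that the calling code maps to stop translate as `X`
  and their protein positions are recorded, so downstream stages can
  substitute any hypothesised meaning.
- Codons containing `N` translate to `X` and are skipped by the counting
  stage; metagenomic ambiguity should reduce evidence, not raise errors.

No ribosome-binding-site or coding-potential model is used: on synthetic
data the true genes dominate, and the spurious short ORFs a six-frame scan
also emits are rejected later by the alignment-significance filter.

## Code inference

Each ORF translation is aligned globally (affine gaps, open 11 / extend 1,
BLOSUM62 with `X` rescored to 0 against everything) to the consensus of
each candidate reference family; the best-scoring alignment is used if its
score reaches 40 % of the query's self-alignment score (a simple,
length-normalised significance rule). To bound runtime, families are first
ranked by shared 5-mers with the query and only the top 5 candidates are
aligned (`prescreen_top`, 0 = exhaustive; on the synthetic families the
prescreen is verified by test to reproduce the exhaustive scan exactly).

Observations are taken at columns with conservation ≥ 0.9 (fraction of
members carrying the modal residue), using the family **consensus** residue
rather than every member, to avoid multiplying evidence by family depth.

Per-codon calls use the following precedence:

1. **Sense call** — ≥ `min_obs` = 20 observations with modal amino-acid
   frequency ≥ `min_freq` = 0.5: the codon is called as the modal residue
   (ties broken alphabetically and flagged).
2. **Stop call** — otherwise, a canonical stop codon with
   `usage_ratio < min_usage` = 0.3 is called STOP.
3. `insufficient_data` otherwise.

Direct homology evidence deliberately outranks the usage heuristic: a
recently or partially recoded codon may appear in only a fraction of genes
(the generator's default plants TGA in 30 % of genes), which depresses its
genome-wide usage ratio to ≈ 0.3 even though its aligned-residue signal is
unambiguous. Conversely the stop call requires no minimum observation
count, because for a true stop codon *absence* from coding positions is
the evidence. `min_obs` protects the sense call from a handful of spurious
alignments ever recoding a genuine stop codon.

## Variant proteomes and search database

ORFs are called once with readthrough and then instantiated per hypothesis:
each amino-acid variant substitutes its symbol at every readthrough
position; the STOP variant truncates at the first readthrough position
(dropping empty truncations). Proteins without readthrough positions are
identical across variants, which is what makes *unique* peptides
informative. Decoys are whole-sequence reversals (palindromic sequences are
flagged); contaminants are any user-supplied protein FASTA — the package
generates a synthetic 44-entry stand-in, since real contaminant lists are
lab-specific.

## Peptide pipeline

- **Digestion**: cleavage C-terminal to K/R except before P, ≤ 2 missed
  cleavages, peptide length 6–50 — common proteomics practice. Cleavage
  positions come from `pyteomics`; tests cross-check against brute-force
  enumeration.
- **Masses**: monoisotopic residue masses + water (18.010565 Da). Fixed
  carbamidomethylation of cysteine (+57.021464 Da) is applied by default;
  oxidised methionine (+15.994915 Da) and N-terminal carbamylation
  (+43.005814 Da) are available as variable modifications, each generating
  alternative mass forms; a peptide passes the ppm filter if any form is
  within tolerance.
- **Filtering**: a peptide identification is retained iff its sequence
  occurs in at least one target protein, its observed neutral mass is
  within ±10 ppm of theoretical, and it has ≥ 2 spectra. Removal counts are
  logged per filter.
- **Uniqueness**: classification operates on non-redundant peptide
  *sequences* (spectral counts only feed the stringency filter). Peptides
  matching a contaminant are excluded from classification and logged.
  Isoleucine and leucine are kept distinct (sequence-level matching); MS
  cannot distinguish them, so an equating switch would be a conservative
  extension — noted as a limitation.
- **Decision**: the variant with the largest unique count wins if that
  count is ≥ 1 and ≥ 10× the runner-up (`decision_min_ratio`); ties or
  weaker margins give `undetermined`.

Spectrum-level search scoring and FDR estimation are replaced by this
transparent sequence + mass matching model; the synthetic generator injects
a known false-identification fraction instead of estimating one.

## Synthetic data generator

The generator's defaults define the study conditions: GC = 0.332 (the
low-GC regime of the motivating bin), 100 genes of mean length 200 aa
(typical bacterial genes; sd 20 %, floor 30 aa), TGA→Gly planted with 30 %
of genes carrying ≥ 1 in-frame TGA, reference families of 5 members at 15 %
point-substitution divergence, 1000 true peptides, 1 % false IDs, 3 ppm
Gaussian mass error, geometric spectral counts with mean 3.

Mechanics and caveats:

- Codons are drawn i.i.d. from the GC null restricted to the sense codons
  of the planted code, so the inference stage's normalisation assumptions
  hold *by construction*. This is the model under test, not a claim about
  real genomes (no codon-usage bias, no amino-acid composition bias).
- Non-recoded genes exclude the reassigned codon entirely; recoded genes
  draw it at its null rate (one is forced if none is drawn). Genes receive
  random strands and are separated by 20–100 nt random spacers.
- Families are mutated copies of the true proteins with a trivial
  (gap-free) columnwise alignment; an optional deletion rate introduces
  gap columns to stress the aligner. Real families would add indels,
  paralogy and phylogenetic correlation between members.
- False peptide identifications are uniform random sequences; real false
  IDs are homology-biased. The false-ID model is declared, not claimed
  realistic.
- Everything is deterministic from (parameters, seed); the top-level
  generator derives independent child seeds (< 2³¹) for genome, families
  and peptides.

Consequently, passing benchmarks shows the pipeline's logic is correct and
well-calibrated under its own assumptions; it does not show robustness to
codon-usage bias, assembly error, chimeric bins or search-engine score
artefacts.

## Benchmark problem sizes

The bundled validation runs use the generator defaults (100 genes) with 20
replicates for the recovery benchmarks, 20 random 10 kb contigs for the
ORF oracle comparison, 50 peptides × 21 variants for the classification
oracle, and n = 10,000 draws for the Gaussian-retention check; the
acceptance script uses 5 replicates per condition for its recovery rates.

## Numerical and degenerate-input conventions

- Codon frequencies at GC = 0 or 1 give zero-probability codon classes
  rather than errors; a planted recoding whose codon has zero probability
  is rejected.
- `usage_ratio` of a codon with zero expected frequency is reported as 0.
- An empty observation matrix (no significant alignments) warns and yields
  `insufficient_data`/STOP calls per the precedence above.
- Ratio of best to runner-up unique counts is ∞ when the runner-up is 0
  (serialised as the string `"inf"` in JSON reports).
- Reports are JSON with sorted keys and rounded floats, making reruns
  byte-identical for a fixed config and seed.

## Known limitations

- Pairwise alignment to family consensus, not profile HMMs; divergent
  homologs below the 40 % self-score threshold contribute nothing.
- Only one codon is interrogated per run (any codon may be designated, but
  joint reassignment of several codons is not modelled).
- No protein-level inference or quantitation; the decision is purely
  peptide-level.
- The six-frame ORF caller is not a gene finder; it is adequate where
  downstream filters can absorb spurious ORFs, as here.
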