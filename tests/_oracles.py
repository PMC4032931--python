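"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results from first principles (exhaustive
enumeration, naive string scanning) without calling the implementation
paths they check.
"""

from __future__ import annotations

_COMP = str.maketrans("ACGTN", "TGCAN")
_STARTS = ("ATG", "GTG", "TTG")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_force_orfs(
    residues: str,
    table: dict[str, str],
    min_aa: int,
    readthrough_codon: str | None = None,
):
    """All stop-terminated ORFs over six frames, one per stop (most upstream
    start), as (start, end, strand) forward-strand coordinates.

    Enumerates every candidate start/stop pair exhaustively.
    """
    L = len(residues)
    found = set()
    for strand, seq in (("+", residues), ("-", revcomp(residues))):
        for frame in range(3):
            offsets = list(range(frame, len(seq) - 2, 3))
            codons = {i: seq[i : i + 3] for i in offsets}

            def is_stop(i):
                c = codons[i]
                return "N" not in c and table[c] == "*" and c != readthrough_codon

            stops = [i for i in offsets if is_stop(i)]
            for k, j in enumerate(stops):
                # most upstream start in the stop-free segment ending at j
                segment_begin = stops[k - 1] + 3 if k else frame
                best = None
                for i in range(segment_begin, j, 3):
                    if codons[i] in _STARTS:
                        best = i
                        break
                if best is None:
                    continue
                n_aa = (j - best) // 3
                if n_aa < min_aa:
                    continue
                s, e = best, j + 3
                if strand == "-":
                    s, e = L - e, L - s
                found.add((s, e, strand))
    return found


def naive_tryptic_digest(protein: str, missed_cleavages: int, lo: int, hi: int):
    """All tryptic fragments with <= missed_cleavages internal sites, by
    direct enumeration over cut points (cleave after K/R unless before P)."""
    cuts = [0]
    cuts += [
        i + 1
        for i in range(len(protein) - 1)
        if protein[i] in "KR" and protein[i + 1] != "P"
    ]
    cuts.append(len(protein))
    frags = []
    for a in range(len(cuts) - 1):
        for b in range(a + 1, min(a + 2 + missed_cleavages, len(cuts))):
            pep = protein[cuts[a] : cuts[b]]
            if lo <= len(pep) <= hi:
                frags.append(pep)
    return frags


def brute_force_classify(peptide: str, variants, missed_cleavages: int, lo: int, hi: int):
    """Variant ids supporting a peptide, by scanning every protein of every
    variant with the naive digest."""
    support = set()
    for v in variants:
        for _, seq in v.proteins:
            if peptide in naive_tryptic_digest(seq, missed_cleavages, lo, hi):
                support.add(v.variant_id)
                break
    return support


def naive_variant_peptides(variants, missed_cleavages: int, lo: int, hi: int):
    """Full naive digest of every variant proteome: variant_id -> peptide set."""
    return {
        v.variant_id: {
            pep
            for _, seq in v.proteins
            for pep in naive_tryptic_digest(seq, missed_cleavages, lo, hi)
        }
        for v in variants
    }
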