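"""Coding-sequence translation and codon-level comparison.

Built for verifying a PCR-amplified cDNA against the reference gene-model
CDS: the two sequences are colinear, equal-length coding sequences, so the
comparison is per codon with no alignment step. Ambiguity symbols (IUPAC)
are resolved through the standard genetic code: a codon whose possible
resolutions all give the same amino acid translates normally, otherwise to X.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Data.IUPACData import ambiguous_dna_values

_STANDARD_TABLE = unambiguous_dna_by_id[1]
ACGT = frozenset("ACGT")
IUPAC_DNA = frozenset(ambiguous_dna_values)  # includes ACGT and ambiguity codes


def _codon_translations(codon: str, table=_STANDARD_TABLE) -> set:
    """Set of amino acids (or '*') over all resolutions of an ambiguous codon."""
    out = set()
    for b1 in ambiguous_dna_values[codon[0]]:
        for b2 in ambiguous_dna_values[codon[1]]:
            for b3 in ambiguous_dna_values[codon[2]]:
                c = b1 + b2 + b3
                out.add("*" if c in table.stop_codons else table.forward_table[c])
    return out


def translate(cdna: str, table_id: int = 1,
              trim_terminal_stop: bool = True) -> str:
    """Translate a CDS with the standard genetic code.

    Codons containing ambiguity symbols translate to the unique residue all
    their resolutions share, else to 'X'. A terminal stop codon is removed
    from the reported protein; internal stops are kept as '*'.
    """
    seq = cdna.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} is not a multiple of 3")
    for i, base in enumerate(seq, start=1):
        if base not in IUPAC_DNA:
            raise ValueError(f"non-IUPAC symbol {base!r} at position {i}")
    table = unambiguous_dna_by_id[table_id]
    residues = []
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        if set(codon) <= ACGT:
            residues.append("*" if codon in table.stop_codons
                            else table.forward_table[codon])
        else:
            options = _codon_translations(codon, table)
            residues.append(options.pop() if len(options) == 1 else "X")
    if trim_terminal_stop and residues and residues[-1] == "*":
        residues.pop()
    return "".join(residues)


@dataclass(frozen=True)
class CodonDifference:
    codon_index: int           # 1-based
    codon_a: str
    codon_b: str
    kind: str                  # identical | synonymous | nonsynonymous | unresolved


@dataclass
class CodingComparison:
    """Per-codon classification of two colinear coding sequences."""

    differences: list = field(default_factory=list)  # non-identical codons only
    n_codons: int = 0
    n_identical: int = 0
    n_synonymous: int = 0
    n_nonsynonymous: int = 0
    n_unresolved: int = 0
    unresolved_bases: int = 0

    def summary(self) -> dict:
        return {
            "codons": self.n_codons,
            "identical": self.n_identical,
            "synonymous": self.n_synonymous,
            "nonsynonymous": self.n_nonsynonymous,
            "unresolved": self.n_unresolved,
            "unresolved_bases": self.unresolved_bases,
        }


def compare_codons(cdna_a: str, cdna_b: str, table_id: int = 1) -> CodingComparison:
    """Classify every codon pair of two pre-aligned, equal-length CDS.

    Codons are synonymous when they differ in nucleotide but encode the same
    amino acid, nonsynonymous when the amino acid changes, and unresolved
    when either codon contains an ambiguity symbol (the unresolved base count
    counts ambiguity symbols, not codons). Indels are not handled.
    """
    a = cdna_a.upper().replace("U", "T")
    b = cdna_b.upper().replace("U", "T")
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)} nt")
    if len(a) % 3 != 0:
        raise ValueError(f"CDS length {len(a)} is not a multiple of 3")
    for seq, name in ((a, "first"), (b, "second")):
        for i, base in enumerate(seq, start=1):
            if base not in IUPAC_DNA:
                raise ValueError(
                    f"non-IUPAC symbol {base!r} at position {i} of {name} CDS")
    table = unambiguous_dna_by_id[table_id]
    cmp = CodingComparison(n_codons=len(a) // 3)
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        idx = i // 3 + 1
        ambiguous = not (set(ca) <= ACGT and set(cb) <= ACGT)
        if ambiguous:
            cmp.n_unresolved += 1
            cmp.unresolved_bases += sum(1 for x in ca if x not in ACGT)
            cmp.unresolved_bases += sum(1 for x in cb if x not in ACGT)
            cmp.differences.append(CodonDifference(idx, ca, cb, "unresolved"))
        elif ca == cb:
            cmp.n_identical += 1
        else:
            aa_a = "*" if ca in table.stop_codons else table.forward_table[ca]
            aa_b = "*" if cb in table.stop_codons else table.forward_table[cb]
            kind = "synonymous" if aa_a == aa_b else "nonsynonymous"
            if kind == "synonymous":
                cmp.n_synonymous += 1
            else:
                cmp.n_nonsynonymous += 1
            cmp.differences.append(CodonDifference(idx, ca, cb, kind))
    return cmp
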