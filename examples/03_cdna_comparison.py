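"""Codon-level comparison of a sequenced CDS against its reference.

Generates the synthetic CDS pair (a 1593-nt coding sequence and a copy with
five synonymous substitutions plus one codon of unresolved bases), translates
both and classifies every codon.
"""

from captx import cdna, synth

sequenced, reference, truth = synth.synthetic_ca6_cds_pair(seed=0)
print(f"CDS length {len(sequenced)} nt ({len(sequenced) // 3} codons incl. stop)")

comparison = cdna.compare_codons(sequenced, reference)
s = comparison.summary()
print(f"identical codons:      {s['identical']}")
print(f"synonymous changes:    {s['synonymous']}  (silent at the protein level)")
print(f"nonsynonymous changes: {s['nonsynonymous']}")
print(f"unresolved:            {s['unresolved']} codon, "
      f"{s['unresolved_bases']} ambiguous bases")
for d in comparison.differences:
    print(f"  codon {d.codon_index:4d}: {d.codon_a} vs {d.codon_b} ({d.kind})")

prot = cdna.translate(sequenced)
print(f"translation: {len(prot)} residues "
      f"(terminal stop trimmed), {prot.count('X')} unknown residue from the "
      "unresolved codon; otherwise identical to the reference translation")
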