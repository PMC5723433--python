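# captx

A Python toolkit for the computational characterization of a secretory
carbonic anhydrase–pentraxin fusion protein (non-mammalian CA VI–PTX, with
zebrafish CA VI–PTX as the model). Mammalian CA VI is a secreted carbonic
anhydrase; in fish, amphibians, reptiles and birds the same gene carries an
extra C-terminal pentraxin (PTX) domain that drives pentamerization, with a
short amphipathic-helix (APH) spacer between the two domains. Characterizing
such a protein spans several otherwise unrelated computations, and this
package implements each of them as a small, tested library module:

- **`captx.masses`** — residue-level mass tables; peptide, glycan and
  oligomer masses; the ProtParam-style extinction coefficient
  ε₂₈₀ = 5500·nW + 1490·nY + 125·n_cystine (M⁻¹cm⁻¹).
- **`captx.digest`** — non-reducing in-silico tryptic digestion (cleave
  after K/R, not before P, with missed cleavages), enumeration of
  disulfide-linked species (mass decrement 2.01565 Da per bond) and
  N-glycopeptides (sequon N-X-S/T, X ≠ P), matching of deconvoluted neutral
  monoisotopic masses at a ppm tolerance
  (ppm = 10⁶·(m_obs − m_theo)/m_theo), sequence coverage, and CID b/y +
  glycan Y-ladder annotation.
- **`captx.conserve`** — alignment QC (e-value, length, X characters,
  unique insertions at exon boundaries, missing internal exons),
  residue↔column mapping, and conservation censuses (perfectly conserved
  columns per window, sequon and single-residue conservation).
- **`captx.cdna`** — CDS translation with IUPAC-ambiguity handling and
  codon-level comparison (identical / synonymous / nonsynonymous /
  unresolved).
- **`captx.helix`** — helical-wheel projection (100°/residue), hydrophobic
  moment μH = |Σᵢ Hᵢ·e^(iδ(i−1))|/N, and APH detection via 3/4-spaced
  hydrophobic-site chains.
- **`captx.sizing`** — SEC standard-curve calibration (OLS of log₁₀MW on
  retention volume) and DLS conversions (diameter = 2·Rh; apparent globular
  MW from the power law Rh = a·MW^b).
- **`captx.behavior`** — larval swim-track metrics (distance, time in the
  upper tank half) and the two-sample Kolmogorov–Smirnov test
  (D = sup|F̂x − F̂y|, exact enumeration for small samples, Kolmogorov
  limiting distribution otherwise).
- **`captx.qpcr`** — the efficiency-corrected relative-expression ratio
  E_t^ΔCt_t / E_ref^ΔCt_ref with replicate averaging.
- **`captx.synth`** — seeded generators for all of the above, including
  synthetic stand-ins that plant the documented architecture of the
  zebrafish protein, its 78-sequence alignment and its sequenced CDS (the
  real sequences are not redistributed here; stand-ins are labelled as such).

## Worked example

`examples/01_digest_and_match.py` digests the stand-in precursor and assigns
three observed neutral monoisotopic masses:

```
precursor 530 aa, mature chain starts at 20; sequons at [210, 258, 339, 394]
105 fully specific peptides with up to 2 missed cleavages
6 glycoforms over the two occupied sequons, 78 disulfide-linked species from the 3 predicted pairs

assignments of the observed masses (best per observation):
   2819.3059 Da -> [331-347] HexNAc2Hex3@N339               +0.013 ppm
   2988.4744 Da -> [191-216]                                -0.012 ppm
   3416.5084 Da -> [248-266] HexNAc2Hex3dHex1@N258          -0.004 ppm
```

Reading the output: the 2819.3059 Da observation is the tryptic peptide
spanning precursor residues 331–347 carrying a paucimannose core glycan
(GlcNAc₂Man₃) on Asn339; the 3416.5084 Da observation is the peptide 248–266
with the core-fucosylated glycan (GlcNAc₂(Fuc)Man₃) on Asn258; the free
peptide 191–216 shows Asn210 unglycosylated. All assignments sit well inside
the 5 ppm tolerance. The other examples (`examples/02`–`06`) walk through
the conservation census, the CDS comparison, the APH scan, hydrodynamic
sizing and the behavior/qPCR statistics in the same style.

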