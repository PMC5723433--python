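# Methods

This note records the models behind each module, the defaults that matter,
what the synthetic generators do and do not emulate, and the design choices
made where the design was genuinely open. No empirical number is stated here
that the test suite or `scripts/acceptance.py` does not itself compute.

## Mass arithmetic (`captx.masses`)

Peptide masses are sums of standard residue masses plus one water
(monoisotopic water 18.010565 Da); the residue table is the standard
monoisotopic/average amino-acid table (e.g. G 57.02146, C 103.00919,
W 186.07931 Da monoisotopic). All masses are neutral; the proton constant
(1.00727646688 Da) is used only by the m/z↔neutral convenience converters.
A disulfide bond removes two hydrogens, 2.015650 Da. Glycans are dehydrated
monosaccharide residues added onto an intact peptide: HexNAc 203.079373,
Hex 162.052824, dHex 146.057909 Da, so GlcNAc₂Man₃ adds 892.3172 Da and
GlcNAc₂(Fuc)Man₃ adds 1038.3751 Da. Reported monoisotopic values are good
to 4 decimals at peptide scale; tests use an absolute tolerance of
5×10⁻⁵ Da against independently derived sums (pyteomics serves as a second,
elemental-composition oracle at 10⁻³ Da, the scale of the table-precision
difference).

The extinction coefficient follows the ProtParam convention, ε₂₈₀ =
5500·nTrp + 1490·nTyr + 125·⌊nCys/2⌋, default `all_cystine` (every possible
cysteine pair oxidized), since that is the convention sequence servers
report for secreted, disulfide-bonded proteins. The sequence to evaluate
(mature chain vs precursor vs tagged construct) is the caller's choice; the
package computes the documented 99,155 M⁻¹cm⁻¹ on the mature chain
(residues 20–530), whose composition implies 12 Trp, 22 Tyr and three
cystines from seven cysteines.

## Digestion and matching (`captx.digest`)

Trypsin is modeled as cleavage after K/R except before P, fully specific,
with missed cleavages 0..2 by default (larger observed peptides imply missed
cleavages occur; 2 is a conventional search bound). Numbering is 1-based and
inclusive on the precursor including the signal peptide, so spans line up
with annotation coordinates (the mature chain of the stand-in starts at
residue 20). Products never cross the mature-chain start.

Disulfide enumeration is hypothesis-driven: the caller supplies the pair
list (here the three documented pairs 44/226, 352/408, 487/518) and the
module emits every intra-/interpeptide combination of carrier peptides,
including multi-pair species connected through bridging peptides, with one
2.01565 Da decrement per bond. All-against-all cysteine combinatorics is
deliberately not offered — it does not match a targeted search and explodes
with missed cleavages.

Glycoform enumeration assigns each library glycan to each sequon
independently (combinatorial across sequons, bare form included). The
default library covers HexNAc₂Hex₃₋₉dHex₀₋₁ — the paucimannose core, its
core-fucosylated variant and the high-mannose series.

Matching reports *every* (observation, species) pair within the ppm
tolerance (default 5 ppm), ranked by |ppm| then by fewer modifications;
silent best-only reporting would hide ambiguous assignments. Unmatched
observations are listed separately. Coverage is the union of matched
peptide spans intersected with the mature chain, as a percentage.

CID annotation covers bare-peptide b/y ions and the glycopeptide Y-ladder,
all as singly protonated m/z. The canonical ladder loses hexoses first,
then the distal HexNAc, then the core fucose, then the core HexNAc — the
loss order consistent with core fucosylation surviving until late in the
ladder. Only species with at most one occupied sequon are supported;
multiply glycosylated fragments would need site-resolved ladders the data
cannot distinguish.

## Conservation (`captx.conserve`)

QC applies, in order: e-value ≤ 2×10⁻⁸⁰ (when supplied), ungapped length
≥ 485, no X characters, no unique insertion of ≥ 20 residues adjacent to an
exon-boundary column (an insertion is a maximal run of columns where only
that row has residues — the signature of a mispredicted intron), and no gap
run spanning the full open interval between consecutive boundary columns
(a missing internal exon). Each row gets exactly one verdict with the first
failing reason, which makes the filter idempotent on its kept set.

"Perfectly conserved" is implemented under two gap policies because the
notion is ambiguous for gapped columns: `strict` (default; any gap
disqualifies) and `ignore_gaps` (gap rows dropped before the identity
test). Strict is never larger, which is asserted as a property. The sequon
census uses N-X-S/T with X ≠ P — the canonical reading of the consensus —
with proline exclusion exposed as a flag. Exon-boundary columns are caller
input; deriving them from gene models is out of scope.

## cDNA comparison (`captx.cdna`)

The two sequences are colinear equal-length CDS, so comparison is per codon
with no alignment step; indels are rejected. The standard genetic code
(Biopython's table 1) is used, with IUPAC ambiguity resolved exhaustively:
a codon translates normally when all its resolutions agree, else to X.
Unresolved codons are counted separately from unresolved bases (one NNN
codon = three unresolved bases). Synonymous/nonsynonymous totals are
symmetric in the argument order by construction.

## Amphipathic helix (`captx.helix`)

The wheel advances 100° per residue (3.6 residues/turn, the classic
end-projection convention), and the hydrophobic moment is
μH = |Σ Hᵢ·e^(iδ(i−1))|/N on the Eisenberg consensus scale. Detection
builds chains of hydrophobic positions whose successive spacings are 3 or 4
residues; a candidate needs ≥ 5 sites with its first five sites inside a
17-residue window (one helix length), and overlapping chains merge into
maximal regions (the longest constituent chain supplies the reported sites,
keeping every reported spacing in the set). The default hydrophobic class
is {A,V,L,I,M,F,W,Y,C}; a stricter class without alanine and tyrosine is
provided for alanine-rich sequences, and both the class and the scale are
parameters since neither has a single canonical definition. On the stand-in
protein the detected spacer-helix candidate starts two residues before the
planted 293–309 region because the adjacent spacer Met/Cys (289/290) extend
the chain — detection reports maximal regions, so tests assert containment
rather than equality.

## Sizing (`captx.sizing`)

SEC calibration is ordinary least squares of log₁₀(MW) on retention volume
(scipy.stats.linregress), inverted for estimation; with two standards it
interpolates exactly, and the fitted slope is negative on any real column
(larger proteins elute earlier), giving a monotone estimator. The retention
volumes of the four standards (carbonic anhydrase 29 kDa, BSA 66 kDa,
alcohol dehydrogenase 150 kDa, β-amylase 200 kDa) are not published, so
`data/sec_standards_synthetic.csv` carries synthetic volumes on a plausible
log-linear column profile chosen so the main-peak estimate reproduces the
instrument-reported behavior qualitatively; they are data, not code.
DLS conversions: diameter = 2·Rh with doubled uncertainty, and apparent
globular MW from Rh = a·MW^b with defaults a = 0.066 nm, b = 0.37 (a widely
used globular-protein relation). Vendor software uses proprietary variants,
so the module exposes the coefficients and claims only qualitative
agreement with instrument outputs.

## Behavior statistics (`captx.behavior`)

Distance is the summed Euclidean step length times the pixel-to-cm scale.
Upper-half time classifies each inter-sample interval by its starting
point — the recordings do not resolve boundary crossings, so interpolation
would be invented precision. The KS statistic evaluates both ECDFs at all
pooled points (the standard tie-safe convention). Exact p enumerates all
C(n₁+n₂, n₁) assignments of the pooled values (feasible to n₁+n₂ = 12; the
3-vs-3 disjoint case gives D = 1, p = 2/20 = 0.1); the asymptotic p
evaluates the Kolmogorov limiting distribution at √(n₁n₂/(n₁+n₂))·D with no
small-sample correction — the plain form tracks the exact permutation
distribution within 0.01 at balanced n = 25 in our checks, while the
classic Stephens correction overshoots toward smaller p at that size.
Group summaries report median/mean/sample SD (n−1)/range; a single-value
group reports SD 0 with an explicit `sd_defined=False` flag.

## qPCR (`captx.qpcr`)

The ratio is E_t^ΔCt_t / E_ref^ΔCt_ref with ΔCt = Ct(calibrator) −
Ct(sample) and replicate Cts averaged before exponentiation. Efficiencies
default to 2.0 (perfect doubling) when not measured and the output flags
the assumption. The calibrator is a required explicit argument; published
tissue tables without raw Cts cannot be recomputed and serve only as input
schemas for the generator.

## Synthetic data (`captx.synth`)

Each generator derives an independent RNG stream from (seed, generator
name), so adding generators never shifts existing outputs, and every
generator is a pure function of its parameters and seed. Decoy masses are
placed by rejection sampling with an iteration cap.

The generic generators emulate, respectively: proteins with planted
sequons/cysteine pairs/ideal APH on a background free of Asn and Cys (so
planted features are the only features); deconvoluted mass lists with
Gaussian ppm noise (σ = 2 ppm by default, the scale of a well-calibrated
FT-ICR run) and far decoys; alignments as per-column mutated copies of a
master with planted invariant columns; bounded-random-walk swim tracks
whose mean distance scales with a per-group speed and whose vertical
occupancy follows an upper-bias parameter; and Ct tables generated from the
efficiency-corrected expression model so that zero noise recovers the
planted ratios exactly.

The `synthetic_ca6_*` stand-ins deserve explicit caveats. They are **not**
the real zebrafish sequences (which this repository does not redistribute);
they are constructed sequences carrying the protein's documented
architecture: 530 residues with a 19-residue signal peptide; sequons at
Asn210/258/339/394; cysteines only at 44/226/290/352/408/487/518; the
spacer peptide LSKGGMCR at 284–291; an ideal amphipathic region at 293–309;
tryptic boundaries such that [191–216], [248–266] and [331–347] are fully
specific peptides whose residue *compositions* were solved (by integer
programming over the residue-mass table, offline) to reproduce the reported
monoisotopic masses 2988.4744, 2378.1333 (+1038.3751 glyco) and 1926.9887
(+892.3172 glyco) Da to four decimals; and a mature-chain chromophore
content of 12 Trp + 22 Tyr matching the documented extinction coefficient.
The 78-row alignment stand-in likewise plants the documented census
structure — exactly 83 invariant columns in the window 30–288 and 19 in
355–566 (with an explicit repair pass so no unplanted column is accidentally
invariant), the sequon columns 266–268 conserved in 77/78 rows, and the
free-cysteine column in 76/78 — and the CDS pair plants five synonymous
substitutions and one NNN codon in a 1593-nt back-translation.

What passing tests on these stand-ins shows: the analysis paths compute the
documented quantities correctly when the input has the documented
structure. What it does not show: agreement with the real sequences'
residue order (compositions, not sequences, were matched), real
phylogenetic correlation structure in the alignment (rows are independent
mutations of one master, not a tree), real chromatographic or spectral
artifacts, or real larval behavior (tracks are reflected random walks, not
fish). The acceptance script's digest emulation treats fully cleaved
peptides of ≥ 6 residues as observable — short fragments elute with the
salt front and are rarely reported — which leaves a few percent of the
mature chain uncovered, as in the real experiment; the exact coverage value
is an output of that emulation, not a target.

## Problem sizes

The suite and acceptance script run at desk scale by design: 78×600
alignments, a 530-residue precursor (~10⁵ digest/species combinations),
1000-species mass lists, 1000 small random alignments for the brute-force
census cross-check, 171 simulated tracks at 5 Hz for 60 s, and exact KS
enumeration only to n₁+n₂ = 12. Everything completes in seconds on one CPU.
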