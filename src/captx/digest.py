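"""Non-reducing in-silico tryptic digestion and mass-list assignment.

The workflow mirrors a bottom-up FT-ICR experiment on a disulfide-bonded
glycoprotein: digest the mature chain with trypsin (cleavage after K/R except
before P), enumerate disulfide-linked and glycosylated species, then match
deconvoluted neutral monoisotopic masses within a ppm tolerance.

Residue numbering is 1-based and inclusive on the precursor (signal peptide
included), so peptide spans printed here line up with precursor annotations
such as glycosylation sites.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace

from .masses import (DEFAULT_TABLE, GlycoComposition, ResidueMassTable,
                     peptide_mass)

SEQUON_RE = re.compile(r"N[^PX](?=[ST])")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with optional precursor annotations.

    ``signal_peptide_end`` is the 1-based index of the last signal-peptide
    residue (0 for none); the mature chain starts at the next residue but the
    numbering of all peptides stays on the precursor.
    """

    id: str
    sequence: str
    signal_peptide_end: int = 0
    exon_boundaries: tuple = ()

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty protein sequence")
        if not 0 <= self.signal_peptide_end < len(self.sequence):
            raise ValueError("signal peptide span outside sequence")

    @property
    def mature_start(self) -> int:
        return self.signal_peptide_end + 1

    @property
    def mature_sequence(self) -> str:
        return self.sequence[self.signal_peptide_end:]

    def sequon_positions(self) -> list[int]:
        """1-based Asn positions of N-X-S/T motifs (X != P) on the precursor."""
        return [m.start() + 1 for m in SEQUON_RE.finditer(self.sequence)]

    def cys_positions(self) -> list[int]:
        return [i + 1 for i, aa in enumerate(self.sequence) if aa == "C"]


@dataclass(frozen=True)
class CleavageRule:
    """Protease specificity: cleave after ``cleave_after`` unless followed by
    a suppressing residue (trypsin: K/R but not before P)."""

    cleave_after: frozenset = frozenset({"K", "R"})
    suppress_before: frozenset = frozenset({"P"})
    max_missed: int = 2

    def __post_init__(self):
        if self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")

    def cut_sites(self, sequence: str) -> list[int]:
        """1-based positions i such that a cut occurs between i and i+1."""
        sites = []
        for i in range(len(sequence) - 1):
            if sequence[i] in self.cleave_after and \
                    sequence[i + 1] not in self.suppress_before:
                sites.append(i + 1)
        return sites


@dataclass(frozen=True)
class PeptideSpecies:
    """A digestion product, possibly glycosylated and/or disulfide-linked.

    A cross-linked species keeps one peptide as primary and lists the others
    in ``partners``; ``n_bonds`` counts disulfide bridges in the species.
    ``glycans`` maps sequon Asn position -> GlycoComposition for the primary
    peptide; partner glycans live on the partner species objects.
    """

    parent_id: str
    start: int
    end: int
    sequence: str
    missed: int = 0
    glycans: tuple = ()          # ((asn_position, GlycoComposition), ...)
    partners: tuple = ()         # other PeptideSpecies joined by disulfides
    n_bonds: int = 0

    def __post_init__(self):
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("span length disagrees with sequence length")
        for pos, _ in self.glycans:
            if not self.start <= pos <= self.end:
                raise ValueError(f"glycan at {pos} outside span")

    @property
    def span(self) -> tuple:
        return (self.start, self.end)

    @property
    def n_modifications(self) -> int:
        return len(self.glycans) + self.n_bonds \
            + sum(len(p.glycans) for p in self.partners)

    def spans(self) -> list[tuple]:
        return [self.span] + [p.span for p in self.partners]

    def cys_positions(self) -> list[int]:
        return [self.start + i for i, aa in enumerate(self.sequence) if aa == "C"]

    def sequon_positions(self) -> list[int]:
        return [self.start + m.start() for m in SEQUON_RE.finditer(self.sequence)]

    def mass(self, kind: str = "monoisotopic",
             table: ResidueMassTable = DEFAULT_TABLE) -> float:
        m = peptide_mass(self.sequence, kind, table)
        m += sum(g.mass(table) for _, g in self.glycans)
        for p in self.partners:
            m += p.mass(kind, table)
        return m - self.n_bonds * table.disulfide_delta

    def label(self) -> str:
        parts = [f"[{self.start}-{self.end}]"]
        parts += [f"[{p.start}-{p.end}]" for p in self.partners]
        lab = "+".join(parts)
        mods = [f"{g}@N{pos}" for pos, g in self.glycans]
        for p in self.partners:
            mods += [f"{g}@N{pos}" for pos, g in p.glycans]
        if self.n_bonds:
            mods.append(f"{self.n_bonds}xS-S")
        return lab + (" " + ",".join(mods) if mods else "")


def digest(protein: ProteinRecord,
           rule: CleavageRule = CleavageRule()) -> list[PeptideSpecies]:
    """Fully specific peptides of the mature chain, 0..max_missed cleavages.

    The signal peptide is excluded from products (no peptide crosses the
    mature-chain start) but spans keep precursor numbering. Output is ordered
    by start, then end.
    """
    seq = protein.sequence
    m0 = protein.signal_peptide_end  # 0-based offset of mature start
    if m0 >= len(seq):
        raise ValueError("empty mature chain")
    sites = [s for s in rule.cut_sites(seq) if s > m0]
    bounds = [m0] + sites + ([len(seq)] if (not sites or sites[-1] != len(seq))
                             else [])
    segments = [(bounds[i] + 1, bounds[i + 1]) for i in range(len(bounds) - 1)]
    peptides = []
    for i in range(len(segments)):
        for missed in range(rule.max_missed + 1):
            j = i + missed
            if j >= len(segments):
                break
            start, end = segments[i][0], segments[j][1]
            peptides.append(PeptideSpecies(
                parent_id=protein.id, start=start, end=end,
                sequence=seq[start - 1:end], missed=missed))
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def enumerate_disulfide_species(peptides: list[PeptideSpecies],
                                cys_pairs: list[tuple],
                                protein: ProteinRecord | None = None,
                                max_pairs: int = 8) -> list[PeptideSpecies]:
    """Disulfide-bonded species for a hypothesis list of cysteine pairs.

    Each pair names two 1-based precursor cysteine positions. A pair inside a
    single peptide yields an intrapeptide species (one bond decrement); a pair
    bridging two peptides yields an interpeptide species. Combinations of
    pairs whose peptides overlap through shared cysteines are emitted as
    multi-pair species. Pairs whose cysteines fall in no supplied peptide are
    silently skipped (those species were not recovered).
    """
    if len(cys_pairs) > max_pairs:
        raise ValueError("cysteine pair list too long for exhaustive enumeration")
    if protein is not None:
        for a, b in cys_pairs:
            for pos in (a, b):
                if protein.sequence[pos - 1] != "C":
                    raise ValueError(f"residue {pos} is not a cysteine")
    else:
        covered = {}
        for p in peptides:
            for pos in p.cys_positions():
                covered[pos] = True
        # without a protein record we can only check positions we can see
        for a, b in cys_pairs:
            for p in peptides:
                if p.start <= a <= p.end and p.sequence[a - p.start] != "C":
                    raise ValueError(f"residue {a} is not a cysteine")
                if p.start <= b <= p.end and p.sequence[b - p.start] != "C":
                    raise ValueError(f"residue {b} is not a cysteine")

    def carriers(pos):
        return [p for p in peptides if p.start <= pos <= p.end]

    species = []
    seen = set()
    n_pairs = len(cys_pairs)
    for r in range(1, n_pairs + 1):
        for subset in itertools.combinations(range(n_pairs), r):
            pairs = [cys_pairs[k] for k in subset]
            # choice of one carrier peptide per cysteine end
            options = []
            feasible = True
            for a, b in pairs:
                ca, cb = carriers(a), carriers(b)
                if not ca or not cb:
                    feasible = False
                    break
                options.append([(pa, pb) for pa in ca for pb in cb])
            if not feasible:
                continue
            for choice in itertools.product(*options):
                peps = []
                for pa, pb in choice:
                    for p in (pa, pb):
                        if p not in peps:
                            peps.append(p)
                # peptides in one species must not overlap on the precursor
                spans = sorted(p.span for p in peps)
                if any(spans[i][1] >= spans[i + 1][0]
                       for i in range(len(spans) - 1)):
                    continue
                # for r > 1 require connectivity: every peptide shares a pair
                if r > 1:
                    links = {p.span: set() for p in peps}
                    for (pa, pb), (a, b) in zip(choice, pairs):
                        links[pa.span].add((a, b))
                        links[pb.span].add((a, b))
                    if any(not v for v in links.values()):
                        continue
                    # single connected component over shared pairs
                    comp = {spans[0]}
                    changed = True
                    while changed:
                        changed = False
                        for s in list(links):
                            if s not in comp and links[s] & set().union(
                                    *(links[c] for c in comp)):
                                comp.add(s)
                                changed = True
                    if len(comp) != len(peps):
                        continue
                primary, *rest = sorted(peps, key=lambda p: p.span)
                key = (tuple(p.span for p in sorted(peps, key=lambda p: p.span)),
                       tuple(sorted(pairs)))
                if key in seen:
                    continue
                seen.add(key)
                species.append(replace(primary, partners=tuple(rest),
                                       n_bonds=r))
    return species


def enumerate_glycoforms(peptides: list[PeptideSpecies],
                         glycan_library: list[GlycoComposition]) -> list[PeptideSpecies]:
    """All (sequon, glycan) assignments per peptide, including the bare form.

    Assignment is combinatorial over multiple sequons; peptides without a
    sequon pass through unchanged.
    """
    out = []
    for p in peptides:
        sequons = p.sequon_positions()
        if not sequons:
            out.append(p)
            continue
        for assignment in itertools.product([None] + list(glycan_library),
                                            repeat=len(sequons)):
            glycans = tuple((pos, g) for pos, g in zip(sequons, assignment)
                            if g is not None)
            out.append(replace(p, glycans=glycans))
    return out


@dataclass(frozen=True)
class MassObservation:
    """A deconvoluted neutral monoisotopic mass from the instrument."""

    neutral_mass: float
    intensity: float | None = None


@dataclass(frozen=True)
class MatchResult:
    observation: MassObservation
    species: PeptideSpecies
    ppm_error: float


@dataclass
class MatchReport:
    matches: list = field(default_factory=list)
    unmatched: list = field(default_factory=list)
    tolerance_ppm: float = 5.0

    def matched_observations(self) -> list[MassObservation]:
        return sorted({id(m.observation): m.observation
                       for m in self.matches}.values(),
                      key=lambda o: o.neutral_mass)

    def best_per_observation(self) -> list[MatchResult]:
        best = {}
        for m in self.matches:
            k = id(m.observation)
            if k not in best:
                best[k] = m
        return sorted(best.values(), key=lambda m: m.observation.neutral_mass)


def ppm_error(observed: float, theoretical: float) -> float:
    return 1e6 * (observed - theoretical) / theoretical


def match(observations: list[MassObservation],
          species: list[PeptideSpecies],
          tolerance_ppm: float = 5.0,
          table: ResidueMassTable = DEFAULT_TABLE) -> MatchReport:
    """Assign observed neutral masses to candidate species within a tolerance.

    Every (observation, species) pair within tolerance is reported; ties are
    ranked by |ppm| then by fewer modifications (no silent best-only pick).
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance must be positive")
    obs = [o if isinstance(o, MassObservation) else MassObservation(float(o))
           for o in observations]
    theo = [(s, s.mass(table=table)) for s in species]
    report = MatchReport(tolerance_ppm=tolerance_ppm)
    for o in obs:
        hits = []
        for s, m in theo:
            err = ppm_error(o.neutral_mass, m)
            if abs(err) <= tolerance_ppm:
                hits.append(MatchResult(o, s, err))
        if hits:
            hits.sort(key=lambda h: (abs(h.ppm_error), h.species.n_modifications))
            report.matches.extend(hits)
        else:
            report.unmatched.append(o)
    return report


def coverage(matches: list[MatchResult] | MatchReport,
             protein: ProteinRecord) -> float:
    """Sequence coverage of the mature chain, as a percentage.

    The union of matched peptide spans (all members of cross-linked species)
    is intersected with the mature chain.
    """
    if isinstance(matches, MatchReport):
        matches = matches.matches
    covered = set()
    for m in matches:
        for start, end in m.species.spans():
            covered.update(range(start, end + 1))
    mature = set(range(protein.mature_start, len(protein.sequence) + 1))
    if not mature:
        return 0.0
    return 100.0 * len(covered & mature) / len(mature)


def y_glycan_ladder(composition: GlycoComposition) -> list[GlycoComposition | None]:
    """Canonical Y-ion ladder: sequential single-residue losses to the bare
    peptide. Hexoses are lost first, then the distal HexNAc, then the core
    fucose, then the core HexNAc (``None`` marks the bare peptide)."""
    ladder = []
    h, n, d = composition.hex, composition.hexnac, composition.dhex
    while h > 0:
        h -= 1
        ladder.append(None if h + n + d == 0
                      else GlycoComposition(hexnac=n, hex=h, dhex=d))
    while n > 1:
        n -= 1
        ladder.append(GlycoComposition(hexnac=n, hex=0, dhex=d))
    if d > 0:
        d = 0
        ladder.append(GlycoComposition(hexnac=n, hex=0, dhex=0) if n else None)
    if n > 0:
        ladder.append(None)
    return ladder


@dataclass(frozen=True)
class FragmentAssignment:
    observed_mz: float
    label: str                 # e.g. "b7", "y3", "Y2(HexNAc2)" or "unassigned"
    theoretical_mz: float | None
    ppm_error: float | None


def cid_annotate(species: PeptideSpecies, fragment_masses: list[float],
                 tolerance_ppm: float = 5.0,
                 table: ResidueMassTable = DEFAULT_TABLE) -> list[FragmentAssignment]:
    """Annotate CID fragments of a glycopeptide (singly protonated m/z).

    Candidates are the bare-peptide b/y ions plus the precursor Y-ladder
    (sequential monosaccharide losses down to the bare peptide). Only species
    with at most one occupied sequon are supported.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance must be positive")
    if len(species.glycans) > 1 or species.partners:
        raise ValueError("CID annotation supports a single occupied sequon "
                         "on a single peptide")
    seq = species.sequence
    proton = table.proton
    candidates = []
    prefix = 0.0
    for i in range(1, len(seq)):
        prefix += table.monoisotopic[seq[i - 1]]
        candidates.append((f"b{i}", prefix + proton))
    suffix = 0.0
    for i in range(1, len(seq)):
        suffix += table.monoisotopic[seq[len(seq) - i]]
        candidates.append((f"y{i}", suffix + table.water_mono + proton))
    bare = peptide_mass(seq, table=table)
    if species.glycans:
        _, glycan = species.glycans[0]
        candidates.append((f"Y({glycan})", bare + glycan.mass(table) + proton))
        steps = y_glycan_ladder(glycan)
        for k, g in enumerate(steps, start=1):
            if g is None:
                candidates.append(("Y0", bare + proton))
            else:
                candidates.append((f"Y({g})", bare + g.mass(table) + proton))
    else:
        candidates.append(("Y0", bare + proton))
    out = []
    for mz in fragment_masses:
        best = None
        for label, theo in candidates:
            err = ppm_error(mz, theo)
            if abs(err) <= tolerance_ppm and \
                    (best is None or abs(err) < abs(best[2])):
                best = (label, theo, err)
        if best is None:
            out.append(FragmentAssignment(mz, "unassigned", None, None))
        else:
            out.append(FragmentAssignment(mz, best[0], best[1], best[2]))
    return out
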