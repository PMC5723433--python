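"""Residue-level mass tables and sequence-derived physicochemical quantities.

All masses are neutral (uncharged) and in daltons. Monoisotopic values use the
standard amino-acid residue table (residue = amino acid minus one water), so a
peptide mass is the sum of its residue masses plus one water. Glycan residue
masses are the dehydrated monosaccharide increments added onto an intact
peptide. Charge handling lives with the matching layer, not here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


#: Monoisotopic residue masses (Da) for the 20 standard amino acids.
MONOISOTOPIC = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

#: Average (chemical) residue masses (Da).
AVERAGE = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

WATER_MONO = 18.010565
WATER_AVG = 18.01528
PROTON = 1.00727646688
#: Mass removed per disulfide bond (loss of two hydrogens).
DISULFIDE_DELTA = 2.015650

#: Dehydrated monosaccharide residue masses (monoisotopic Da).
HEXNAC = 203.079373
HEX = 162.052824
DHEX = 146.057909


@dataclass(frozen=True)
class ResidueMassTable:
    """Lookup table for residue masses plus the shared chemical constants."""

    monoisotopic: dict = field(default_factory=lambda: dict(MONOISOTOPIC))
    average: dict = field(default_factory=lambda: dict(AVERAGE))
    water_mono: float = WATER_MONO
    water_avg: float = WATER_AVG
    proton: float = PROTON
    disulfide_delta: float = DISULFIDE_DELTA
    hexnac: float = HEXNAC
    hex: float = HEX
    dhex: float = DHEX

    def residue(self, code: str, kind: str = "monoisotopic") -> float:
        table = self.monoisotopic if kind == "monoisotopic" else self.average
        try:
            return table[code]
        except KeyError:
            raise KeyError(f"unknown residue code {code!r}") from None


DEFAULT_TABLE = ResidueMassTable()


@dataclass(frozen=True)
class GlycoComposition:
    """An N-glycan as counts of HexNAc, Hex and dHex residues.

    The two compositions relevant to the insect-cell-produced enzyme are the
    paucimannose core GlcNAc2Man3 (hexnac=2, hex=3) and its core-fucosylated
    form GlcNAc2(Fuc)Man3 (hexnac=2, hex=3, dhex=1).
    """

    hexnac: int = 0
    hex: int = 0
    dhex: int = 0

    def __post_init__(self):
        for name in ("hexnac", "hex", "dhex"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative {name} count")
        if self.hexnac + self.hex + self.dhex == 0:
            raise ValueError("glycan composition must contain at least one residue")

    @property
    def n_residues(self) -> int:
        return self.hexnac + self.hex + self.dhex

    def mass(self, table: ResidueMassTable = DEFAULT_TABLE) -> float:
        return (self.hexnac * table.hexnac + self.hex * table.hex
                + self.dhex * table.dhex)

    def __str__(self) -> str:
        parts = []
        if self.hexnac:
            parts.append(f"HexNAc{self.hexnac}")
        if self.hex:
            parts.append(f"Hex{self.hex}")
        if self.dhex:
            parts.append(f"dHex{self.dhex}")
        return "".join(parts)


#: Paucimannose core and its core-fucosylated variant.
CORE_GLYCAN = GlycoComposition(hexnac=2, hex=3)
FUC_CORE_GLYCAN = GlycoComposition(hexnac=2, hex=3, dhex=1)


def default_glycan_library(hex_max: int = 9) -> list[GlycoComposition]:
    """High-mannose/paucimannose library: HexNAc2 Hex3..hex_max dHex0..1."""
    lib = []
    for h in range(3, hex_max + 1):
        for d in (0, 1):
            lib.append(GlycoComposition(hexnac=2, hex=h, dhex=d))
    return lib


def _check_sequence(sequence: str, table: dict) -> None:
    if not sequence:
        raise ValueError("empty sequence")
    for i, aa in enumerate(sequence, start=1):
        if aa not in table:
            raise ValueError(f"unknown residue {aa!r} at position {i}")


def peptide_mass(sequence: str, kind: str = "monoisotopic",
                 table: ResidueMassTable = DEFAULT_TABLE) -> float:
    """Neutral mass of a linear peptide: sum of residue masses plus one water."""
    if kind == "monoisotopic":
        masses, water = table.monoisotopic, table.water_mono
    elif kind == "average":
        masses, water = table.average, table.water_avg
    else:
        raise ValueError(f"kind must be 'monoisotopic' or 'average', got {kind!r}")
    _check_sequence(sequence, masses)
    return math.fsum(masses[aa] for aa in sequence) + water


def glycan_mass(composition: GlycoComposition,
                table: ResidueMassTable = DEFAULT_TABLE) -> float:
    """Monoisotopic mass increment of an N-glycan attached to an intact peptide."""
    return composition.mass(table)


def extinction_280(sequence: str, cystine_mode: str = "all_cystine") -> int:
    """Molar extinction coefficient at 280 nm (M^-1 cm^-1), ProtParam convention.

    epsilon = 5500*nTrp + 1490*nTyr + 125*nCystine, where under
    ``all_cystine`` every possible cysteine pair is assumed oxidized
    (nCystine = floor(nCys / 2)) and under ``all_reduced`` cystines
    contribute nothing.
    """
    _check_sequence(sequence, MONOISOTOPIC)
    if cystine_mode not in ("all_cystine", "all_reduced"):
        raise ValueError(f"unknown cystine_mode {cystine_mode!r}")
    n_trp = sequence.count("W")
    n_tyr = sequence.count("Y")
    n_cystine = sequence.count("C") // 2 if cystine_mode == "all_cystine" else 0
    return 5500 * n_trp + 1490 * n_tyr + 125 * n_cystine


def oligomer_mass(monomer_mass: float, n: int) -> float:
    """Mass of an n-mer of identical subunits (no linker chemistry)."""
    if monomer_mass <= 0:
        raise ValueError("monomer mass must be positive")
    if n < 1:
        raise ValueError("oligomer size must be >= 1")
    return n * monomer_mass


def mz_to_neutral(mz: float, charge: int,
                  table: ResidueMassTable = DEFAULT_TABLE) -> float:
    """Convenience: convert a positive-mode m/z to a neutral mass."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return mz * charge - charge * table.proton


def neutral_to_mz(neutral: float, charge: int,
                  table: ResidueMassTable = DEFAULT_TABLE) -> float:
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (neutral + charge * table.proton) / charge
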