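"""Helical-wheel geometry, hydrophobic moment, and amphipathic-helix detection.

An ideal alpha helix advances 100 degrees per residue (3.6 residues/turn), so
an amphipathic helix (APH) shows hydrophobic residues recurring every third
or fourth position — one face of the wheel. Detection therefore looks for
runs of hydrophobic sites with successive spacings of 3 or 4 residues, and
the hydrophobic moment quantifies the same periodicity as the magnitude of
the vector sum of per-residue hydrophobicities around the wheel.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass

#: Eisenberg consensus hydrophobicity scale.
EISENBERG = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}

#: Default hydrophobic residue class for site detection.
HYDROPHOBIC = frozenset("AVLIMFWYC")

#: Stronger class (aliphatic/aromatic core, alanine and tyrosine excluded),
#: useful when scanning sequences rich in alanine.
HYDROPHOBIC_STRICT = frozenset("VLIMFWC")


@dataclass(frozen=True)
class WheelPosition:
    index: int          # 1-based position in the input sequence
    residue: str
    angle: float        # degrees in [0, 360)


@dataclass
class WheelProjection:
    """End-projection of a hypothetical alpha helix."""

    positions: list
    step_degrees: float = 100.0

    def angles(self) -> list:
        return [p.angle for p in self.positions]


def wheel(sequence: str, step_degrees: float = 100.0,
          hydrophobic_set: frozenset = HYDROPHOBIC) -> WheelProjection:
    """Helical-wheel projection: residue i sits at ((i-1)*step) mod 360."""
    if not sequence:
        raise ValueError("empty sequence")
    positions = [WheelPosition(i, aa, ((i - 1) * step_degrees) % 360.0)
                 for i, aa in enumerate(sequence, start=1)]
    return WheelProjection(positions, step_degrees)


def hydrophobic_moment(sequence: str, scale: dict = EISENBERG,
                       step_degrees: float = 100.0) -> float:
    """Mean hydrophobic moment mu_H = |sum_i H_i exp(i*delta*(i-1))| / N."""
    if not sequence:
        raise ValueError("empty sequence")
    delta = math.radians(step_degrees)
    total = 0j
    for i, aa in enumerate(sequence):
        try:
            h = scale[aa]
        except KeyError:
            raise KeyError(f"residue {aa!r} missing from hydrophobicity scale") \
                from None
        total += h * cmath.exp(1j * delta * i)
    return abs(total) / len(sequence)


@dataclass(frozen=True)
class APHCandidate:
    """A candidate amphipathic-helix region."""

    start: int
    end: int
    sites: tuple          # 1-based hydrophobic site positions
    spacings: tuple       # successive site distances, each in the spacing set
    mean_moment: float


def _site_chains(sites: list, spacings: frozenset) -> list:
    """All maximal chains of sites whose successive distances are allowed."""
    site_set = set(sites)
    chains = []
    for s in sites:
        # only start chains that cannot be extended to the left
        if any(s - d in site_set for d in spacings):
            continue
        stack = [[s]]
        while stack:
            chain = stack.pop()
            extensions = [chain[-1] + d for d in sorted(spacings)
                          if chain[-1] + d in site_set]
            if not extensions:
                chains.append(chain)
            else:
                for nxt in extensions:
                    stack.append(chain + [nxt])
    return chains


def detect_aph(sequence: str, window: int = 17, min_sites: int = 5,
               spacings: frozenset = frozenset({3, 4}),
               hydrophobic_set: frozenset = HYDROPHOBIC,
               scale: dict = EISENBERG,
               step_degrees: float = 100.0) -> list:
    """Detect candidate APH regions by 3/4-spaced hydrophobic periodicity.

    A candidate is a maximal chain of at least ``min_sites`` hydrophobic
    positions whose successive spacings all lie in the spacing set and whose
    first ``min_sites`` sites fit inside ``window`` residues (one helix
    length). Overlapping chains are merged into maximal regions; each
    candidate reports its sites, spacings and the mean hydrophobic moment of
    the spanned subsequence.
    """
    if window < min_sites:
        raise ValueError("window shorter than the required site count")
    sites = [i + 1 for i, aa in enumerate(sequence) if aa in hydrophobic_set]
    chains = [c for c in _site_chains(sites, spacings)
              if len(c) >= min_sites
              and c[min_sites - 1] - c[0] + 1 <= window]
    if not chains:
        return []
    # merge chains with overlapping spans into maximal regions
    spans = sorted((c[0], c[-1], tuple(c)) for c in chains)
    merged = [list(spans[0])]
    for lo, hi, chain in spans[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
            # keep the longest constituent chain so spacings stay valid
            if len(chain) > len(merged[-1][2]):
                merged[-1][2] = chain
        else:
            merged.append([lo, hi, chain])
    out = []
    for lo, hi, chain in merged:
        sub = sequence[lo - 1:hi]
        gaps = tuple(b - a for a, b in zip(chain, chain[1:]))
        out.append(APHCandidate(start=lo, end=hi, sites=tuple(chain),
                                spacings=gaps,
                                mean_moment=hydrophobic_moment(
                                    sub, scale, step_degrees)))
    return out
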