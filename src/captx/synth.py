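"""Seeded generators for synthetic inputs with known ground truth.

Two layers live here. The generic generators (``gen_protein``,
``gen_mass_list``, ``gen_msa``, ``gen_tracks``, ``gen_ct``) produce inputs
with the statistical structure each analysis stage assumes — planted sequons
and cysteine pairs, ppm-scale mass noise with decoys, alignments with
invariant columns, swim tracks with group-level activity differences, Ct
values following the efficiency-corrected expression model — together with a
:class:`TruthRecord` for recovery tests.

The ``synthetic_ca6_*`` builders produce stand-ins for the zebrafish
CA VI–pentraxin study material whose real sequences are not redistributed
here. They are synthetic sequences constructed to carry the protein's
documented architecture: a 19-residue signal peptide on a 530-residue
precursor, N-glycosylation sequons at Asn210/258/339/394, cysteines at
44/226/290/352/408/487/518 (three disulfide pairs plus the free spacer
cysteine), an amphipathic-helix region at 293–309, tryptic peptides
[191–216], [248–266] and [331–347] whose residue compositions reproduce the
reported monoisotopic masses, the spacer peptide LSKGGMCR at 284–291, and a
mature-chain chromophore content of 12 Trp + 22 Tyr. Every generator is a
pure function of its parameters and seed.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import TrackSeries
from .conserve import Alignment
from .digest import MassObservation, PeptideSpecies, ProteinRecord
from .masses import MONOISOTOPIC

AMINO = "ACDEFGHIKLMNPQRSTVWY"
POLAR = "STQEDGH"              # background filler, free of hydrophobic-class residues
STRONG_HYDRO = "LVIFM"


def _rng(seed: int, name: str) -> np.random.Generator:
    """Independent stream per (seed, generator name); adding generators never
    shifts the outputs of existing ones."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF,
                                zlib.crc32(name.encode())]))


@dataclass
class TruthRecord:
    generator: str
    seed: int
    features: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps({"generator": self.generator, "seed": self.seed,
                           "features": self.features}, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "TruthRecord":
        text = str(text_or_path)
        if not text.lstrip().startswith("{"):
            with open(text_or_path) as fh:
                text = fh.read()
        d = json.loads(text)
        return cls(generator=d["generator"], seed=d["seed"],
                   features=d["features"])


# ---------------------------------------------------------------------------
# generic generators
# ---------------------------------------------------------------------------

def gen_protein(length: int, n_sequons: int = 0, n_cys_pairs: int = 0,
                aph_span: tuple | None = None, seed: int = 0,
                signal_peptide_end: int = 0):
    """Random protein with planted sequons, cysteine pairs and an APH region.

    The background alphabet excludes Asn and Cys, so the only sequons and
    cysteines are the planted ones. Features are placed non-overlapping;
    infeasible packing raises ``ValueError``.
    """
    rng = _rng(seed, "protein")
    if length < 1:
        raise ValueError("length must be positive")
    background = [c for c in AMINO if c not in "CN"]
    seq = [None] * length
    free = set(range(signal_peptide_end, length))

    def reserve(block):
        if not set(block) <= free:
            raise ValueError("feature packing infeasible: overlap or overflow")
        free.difference_update(block)

    truth = {"sequons": [], "cys_pairs": [], "aph_span": None}
    if aph_span is not None:
        start, end = aph_span
        if not (1 <= start < end <= length) or end - start + 1 < 9:
            raise ValueError("APH span out of range or too short")
        block = range(start - 1, end)
        reserve(block)
        sites = list(range(start - 1, end, 4))
        for i in block:
            seq[i] = str(rng.choice(list(POLAR)))
        for i in sites:
            seq[i] = str(rng.choice(list(STRONG_HYDRO)))
        truth["aph_span"] = [start, end]
        truth["aph_sites"] = [i + 1 for i in sites]

    for _ in range(n_sequons):
        candidates = [i for i in free
                      if {i, i + 1, i + 2} <= free and i + 2 < length]
        if not candidates:
            raise ValueError("no room left for a sequon")
        i = int(rng.choice(candidates))
        reserve(range(i, i + 3))
        x = str(rng.choice([c for c in background if c != "P"]))
        seq[i], seq[i + 1], seq[i + 2] = "N", x, str(rng.choice(["S", "T"]))
        truth["sequons"].append(i + 1)

    for _ in range(n_cys_pairs):
        if len(free) < 2:
            raise ValueError("no room left for a cysteine pair")
        pair = sorted(int(v) for v in rng.choice(sorted(free), size=2,
                                                 replace=False))
        reserve(pair)
        for i in pair:
            seq[i] = "C"
        truth["cys_pairs"].append([pair[0] + 1, pair[1] + 1])

    for i in range(length):
        if seq[i] is None:
            seq[i] = str(rng.choice(background))
    if signal_peptide_end:
        seq[0] = "M"
    protein = ProteinRecord(id=f"synthetic_protein_seed{seed}",
                            sequence="".join(seq),
                            signal_peptide_end=signal_peptide_end)
    truth["sequons"].sort()
    return protein, TruthRecord("protein", seed, truth)


def gen_mass_list(species, ppm_sigma: float = 2.0, n_decoys: int = 0,
                  decoy_min_ppm: float = 50.0, seed: int = 0,
                  max_tries: int = 10000):
    """Observed neutral-mass list: species masses with Gaussian ppm noise,
    plus decoy masses placed at least ``decoy_min_ppm`` from every species."""
    if ppm_sigma < 0:
        raise ValueError("ppm_sigma must be >= 0")
    rng = _rng(seed, "mass_list")
    theo = [s.mass() if isinstance(s, PeptideSpecies) else float(s)
            for s in species]
    if not theo:
        raise ValueError("no species supplied")
    obs = [MassObservation(m * (1 + 1e-6 * ppm_sigma * rng.standard_normal()))
           for m in theo]
    theo_arr = np.array(theo)
    decoys = []
    lo, hi = 0.8 * theo_arr.min(), 1.2 * theo_arr.max()
    tries = 0
    while len(decoys) < n_decoys:
        tries += 1
        if tries > max_tries:
            raise ValueError("decoy placement infeasible under the ppm floor")
        m = rng.uniform(lo, hi)
        if np.min(np.abs(1e6 * (m - theo_arr) / theo_arr)) >= decoy_min_ppm:
            decoys.append(MassObservation(m))
    truth = TruthRecord("mass_list", seed, {
        "species_masses": theo,
        "observed": [o.neutral_mass for o in obs],
        "decoys": [d.neutral_mass for d in decoys],
        "ppm_sigma": ppm_sigma,
    })
    return obs + decoys, truth


def gen_msa(master: str, n_rows: int, per_column_rate: float = 0.5,
            invariant_columns=(), seed: int = 0,
            unique_insertion: tuple | None = None):
    """Alignment of mutated copies of a master sequence.

    Planted ``invariant_columns`` (1-based) are never mutated; every other
    column mutates independently per row with ``per_column_rate``. An
    optional ``unique_insertion = (row_index, after_column, length)`` adds a
    run of columns where only that row carries residues (for QC testing).
    """
    if not 0 <= per_column_rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    rng = _rng(seed, "msa")
    invariant = set(invariant_columns)
    for c in invariant:
        if not 1 <= c <= len(master):
            raise ValueError(f"invariant column {c} outside master")
    rows = []
    for r in range(n_rows):
        chars = list(master)
        for c in range(len(master)):
            if (c + 1) in invariant:
                continue
            if rng.random() < per_column_rate:
                chars[c] = str(rng.choice(
                    [a for a in AMINO if a != master[c]]))
        rows.append("".join(chars))
    if unique_insertion is not None:
        row_idx, after_col, ins_len = unique_insertion
        ins = "".join(str(rng.choice(list(AMINO))) for _ in range(ins_len))
        new_rows = []
        for r, row in enumerate(rows):
            block = ins if r == row_idx else "-" * ins_len
            new_rows.append(row[:after_col] + block + row[after_col:])
        rows = new_rows
    aln = Alignment(ids=[f"seq{r + 1:03d}" for r in range(n_rows)], rows=rows)
    truth = TruthRecord("msa", seed, {
        "invariant_columns": sorted(invariant),
        "per_column_rate": per_column_rate,
        "unique_insertion": list(unique_insertion) if unique_insertion else None,
    })
    return aln, truth


def gen_tracks(n_per_group: dict | int, group_params: dict,
               duration: float = 60.0, fps: float = 25.0, seed: int = 0,
               tank_width_cm: float = 4.3, tank_height_cm: float = 4.5):
    """Bounded random-walk swim tracks with group-level differences.

    ``group_params`` maps a group label to ``{"speed": cm/s, "upper_bias":
    0..1}``. Mean travelled distance scales with ``speed``; vertical
    occupancy follows ``upper_bias`` (0 = pinned to the lower half, 1 = to
    the upper half).
    """
    if fps <= 0 or duration <= 0:
        raise ValueError("fps and duration must be positive")
    rng = _rng(seed, "tracks")
    if isinstance(n_per_group, int):
        n_per_group = {g: n_per_group for g in group_params}
    n_steps = int(round(duration * fps))
    t = np.arange(n_steps + 1) / fps
    mid = tank_height_cm / 2.0
    tracks = []
    for group, params in group_params.items():
        speed = float(params.get("speed", 1.0))
        bias = float(params.get("upper_bias", 0.5))
        eps = 1e-9 * tank_height_cm
        lo = mid + eps if bias >= 1.0 else 0.0
        hi = mid - eps if bias <= 0.0 else tank_height_cm
        for i in range(n_per_group[group]):
            x = np.empty(n_steps + 1)
            y = np.empty(n_steps + 1)
            x[0] = rng.uniform(0, tank_width_cm)
            y[0] = rng.uniform(lo, hi)
            step = speed / fps
            drift = (2 * bias - 1) * 0.5 * step
            for k in range(n_steps):
                theta = rng.uniform(0, 2 * np.pi)
                r = step * rng.uniform(0.5, 1.5)
                x[k + 1] = np.clip(x[k] + r * np.cos(theta), 0, tank_width_cm)
                y[k + 1] = np.clip(y[k] + r * np.sin(theta) + drift, lo, hi)
            tracks.append(TrackSeries(
                fish_id=f"{group}_{i + 1:03d}", group=group, t=t, x=x, y=y,
                scale=1.0, tank_height=tank_height_cm, boundary=mid,
                duration=duration))
    truth = TruthRecord("tracks", seed, {
        "group_params": {g: dict(p) for g, p in group_params.items()},
        "n_per_group": dict(n_per_group), "duration": duration, "fps": fps,
    })
    return tracks, truth


def gen_ct(true_ratios: dict, target: str = "ca6", reference: str = "gapdh",
           efficiencies: tuple = (2.0, 2.0), noise_sd: float = 0.2,
           n_replicates: int = 3, seed: int = 0,
           calibrator: str = "calibrator"):
    """Ct table consistent with the efficiency-corrected expression model.

    For each sample with true ratio r, the target Ct is shifted from the
    calibrator by -log_E(r) cycles while the reference gene stays flat, so a
    noise-free table recovers r exactly.
    """
    e_t, e_r = efficiencies
    if e_t <= 1 or e_r <= 1:
        raise ValueError("efficiencies must exceed 1")
    if any(r <= 0 for r in true_ratios.values()):
        raise ValueError("true ratios must be positive")
    rng = _rng(seed, "ct")
    base_target, base_ref = 24.0, 20.0
    rows = []

    def emit(gene, sample, center):
        for rep in range(1, n_replicates + 1):
            rows.append({"gene": gene, "sample": sample, "replicate": rep,
                         "ct": center + noise_sd * rng.standard_normal()})

    emit(target, calibrator, base_target)
    emit(reference, calibrator, base_ref)
    for sample, ratio in true_ratios.items():
        emit(target, sample, base_target - np.log(ratio) / np.log(e_t))
        emit(reference, sample, base_ref)
    truth = TruthRecord("ct", seed, {
        "true_ratios": dict(true_ratios), "efficiencies": [e_t, e_r],
        "noise_sd": noise_sd, "calibrator": calibrator,
        "target": target, "reference": reference,
    })
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# stand-ins for the zebrafish CA VI-pentraxin study material
# ---------------------------------------------------------------------------

#: Synthetic signal peptide (19 residues, no Trp/Tyr/Cys/Asn/Lys/Arg).
_SIGNAL = "MALLLSLALLGAVQAPSLA"

#: Synthetic tryptic peptides whose residue compositions reproduce the
#: reported monoisotopic masses (the real sequences are not public):
#: [191-216] 2988.4744 Da; [248-266] bare 2378.1333 Da so that the
#: GlcNAc2(Fuc)Man3 glycoform is 3416.5084 Da; [331-347] bare 1926.9887 Da so
#: that the GlcNAc2Man3 glycoform is 2819.3059 Da. Each carries its sequon at
#: the documented Asn position (210, 258, 339).
_PEPTIDE_191_216 = "WHDLAAADGAGLWMEPLHLNWTLPFK"
_PEPTIDE_248_266 = "YFEFGEEFLFNMTGFLLFK"
_PEPTIDE_331_347 = "SMHPHHPLNQTPPLPPK"

#: The spacer-region tryptic peptide carrying the free Cys290.
_CYS290_PEPTIDE = "LSKGGMCR"          # residues 284-291

#: Amphipathic-helix region 293-309: hydrophobic sites every 4th residue
#: (L293, F297, L301, V305, M309) with polar residues between them.
_APH_REGION = "LSEQFDTGLESHVGQTM"

CA6_LENGTH = 530
CA6_SIGNAL_END = 19
CA6_SEQUONS = (210, 258, 339, 394)
CA6_CYS_PAIRS = ((44, 226), (352, 408), (487, 518))
CA6_FREE_CYS = 290
CA6_APH_SPAN = (293, 309)
#: Mature-chain chromophore content (12 Trp, 22 Tyr, 7 Cys) matching the
#: enzyme's sequence-derived extinction coefficient of 99,155 M^-1 cm^-1.
CA6_TRP, CA6_TYR = 12, 22


def synthetic_ca6_protein(seed: int = 0) -> ProteinRecord:
    """Synthetic 530-residue stand-in for the zebrafish CA VI-PTX precursor.

    Not the real sequence: a constructed protein carrying the documented
    architecture (see module docstring) so that digestion, glycoform and
    disulfide enumeration, ppm matching, extinction and APH analyses can be
    exercised end to end with known ground truth. The background is polar so
    that hydrophobic periodicity is confined to the planted features.
    """
    rng = _rng(seed, "ca6_protein")
    seq = [None] * CA6_LENGTH

    def place(start, fragment):
        for k, aa in enumerate(fragment):
            pos = start - 1 + k
            if seq[pos] is not None and seq[pos] != aa:
                raise AssertionError(f"conflicting placement at {pos + 1}")
            seq[pos] = aa

    place(1, _SIGNAL)
    place(190, "K" + _PEPTIDE_191_216)
    place(247, "R" + _PEPTIDE_248_266)
    place(283, "K" + _CYS290_PEPTIDE)
    place(CA6_APH_SPAN[0], _APH_REGION)
    place(330, "K" + _PEPTIDE_331_347)
    place(394, "NAT")
    for a, b in CA6_CYS_PAIRS:
        place(a, "C")
        place(b, "C")
    # cleavage at the planted boundaries must not be proline-suppressed
    for pos in (217, 267, 292, 348):
        place(pos, str(rng.choice([c for c in POLAR if c != "P"])))

    # background: polar filler with tryptic K/R sites every ~8-16 residues
    gap_since_cut = 0
    next_cut = int(rng.integers(8, 17))
    for i in range(CA6_SIGNAL_END, CA6_LENGTH):
        if seq[i] is None:
            gap_since_cut += 1
            if gap_since_cut >= next_cut and i + 1 < CA6_LENGTH:
                seq[i] = str(rng.choice(["K", "R"]))
                gap_since_cut = 0
                next_cut = int(rng.integers(8, 17))
            else:
                seq[i] = str(rng.choice(list(POLAR + "P")))
        else:
            gap_since_cut = 0

    # plant the remaining Trp/Tyr so the mature chain carries 12 W + 22 Y;
    # spacings of 3 or 4 between planted aromatics are avoided so they never
    # extend a hydrophobic-periodicity chain on their own
    protected = set()
    for start, frag in ((1, _SIGNAL), (190, "K" + _PEPTIDE_191_216),
                        (247, "R" + _PEPTIDE_248_266),
                        (283, "K" + _CYS290_PEPTIDE),
                        (CA6_APH_SPAN[0], _APH_REGION),
                        (330, "K" + _PEPTIDE_331_347), (394, "NAT")):
        protected.update(range(start - 1, start - 1 + len(frag)))
    protected.update(a - 1 for pair in CA6_CYS_PAIRS for a in pair)
    protected.update(p - 1 for p in (217, 267, 292, 348))
    candidates = [i for i in range(CA6_SIGNAL_END, CA6_LENGTH)
                  if i not in protected and seq[i] not in ("K", "R")]
    rng.shuffle(candidates)
    need_w = CA6_TRP - _PEPTIDE_191_216.count("W")
    need_y = CA6_TYR - _PEPTIDE_248_266.count("Y")
    chosen = []
    for i in candidates:
        if len(chosen) == need_w + need_y:
            break
        if all(abs(i - j) not in (3, 4) for j in chosen):
            chosen.append(i)
    if len(chosen) < need_w + need_y:
        raise AssertionError("aromatic placement infeasible")
    for k, i in enumerate(chosen):
        seq[i] = "W" if k < need_w else "Y"

    sequence = "".join(seq)
    protein = ProteinRecord(id=f"synthetic_ca6_standin_seed{seed}",
                            sequence=sequence,
                            signal_peptide_end=CA6_SIGNAL_END)
    mature = protein.mature_sequence
    assert mature.count("W") == CA6_TRP and mature.count("Y") == CA6_TYR
    assert tuple(protein.sequon_positions()) == CA6_SEQUONS
    assert tuple(protein.cys_positions()) == tuple(sorted(
        [CA6_FREE_CYS] + [a for p in CA6_CYS_PAIRS for a in p]))
    return protein


def synthetic_ca6_alignment(seed: int = 0, n_rows: int = 78,
                            n_cols: int = 600):
    """Synthetic 78-row stand-in for the non-mammalian CA VI alignment.

    Emulates the documented structure of the published alignment rather than
    its sequences: the zebrafish-like stand-in occupies row 1 (residue i at
    column i + 8), the catalytic-domain window (columns 30-288) carries
    exactly 83 perfectly conserved columns and the pentraxin window
    (355-566) exactly 19, the Asn258 sequon columns 266-268 are conserved in
    77 of 78 rows, and the free-cysteine column (Cys290, column 298) is
    conserved in 76 of 78.
    """
    rng = _rng(seed, "ca6_msa")
    offset = 8
    zebra = synthetic_ca6_protein(seed).sequence
    n_res = len(zebra)
    ca_window = (30, 288)
    ptx_window = (355, 566)
    sequon_cols = (266, 267, 268)
    cys_col = CA6_FREE_CYS + offset          # 298
    assert ca_window[1] < cys_col < ptx_window[0]

    pool_ca = [c for c in range(offset + 24, ca_window[1] + 1)
               if c not in sequon_cols]
    ca_cols = sorted(int(c) for c in rng.choice(pool_ca, size=83, replace=False))
    pool_ptx = list(range(ptx_window[0], offset + n_res + 1))
    ptx_cols = sorted(int(c) for c in rng.choice(pool_ptx, size=19,
                                                 replace=False))
    invariant = set(ca_cols) | set(ptx_cols)

    broken_sequon_row = int(rng.integers(1, n_rows))     # never row 0
    non_cys_rows = sorted(int(r) for r in rng.choice(
        np.arange(1, n_rows), size=2, replace=False))

    master = ["-"] * n_cols
    for i, aa in enumerate(zebra, start=1):
        master[i + offset - 1] = aa

    rate = 0.35
    rows = [list(master)]
    for r in range(1, n_rows):
        chars = list(master)
        for c in range(offset, offset + n_res):
            col = c + 1
            if col in invariant or col in sequon_cols or col == cys_col:
                continue
            if rng.random() < rate:
                chars[c] = str(rng.choice([a for a in AMINO if a != master[c]]))
        # sequon columns: N-x-S/T kept except in the broken row
        if r == broken_sequon_row:
            chars[265], chars[266], chars[267] = "D", "A", "A"
        else:
            chars[265] = "N"
            chars[266] = str(rng.choice([a for a in AMINO if a != "P"]))
            chars[267] = str(rng.choice(["S", "T"]))
        chars[cys_col - 1] = "C"
        # C-terminal extensions beyond the zebrafish stand-in in half the rows
        if rng.random() < 0.5:
            ext = int(rng.integers(5, 30))
            for c in range(offset + n_res, min(offset + n_res + ext, n_cols)):
                chars[c] = str(rng.choice(list(AMINO)))
        rows.append(chars)
    for r in non_cys_rows:
        rows[r][cys_col - 1] = "S" if r == non_cys_rows[0] else "G"

    # a few rows get a gap block in the inter-domain spacer (outside windows)
    for r in sorted(int(v) for v in rng.choice(np.arange(1, n_rows), size=3,
                                               replace=False)):
        start = int(rng.integers(305, 320))
        for c in range(start, start + 12):
            if c + 1 != cys_col:
                rows[r][c] = "-"

    # repair: no accidental perfectly conserved column inside either window
    for lo, hi in (ca_window, ptx_window):
        for col in range(lo, hi + 1):
            if col in invariant:
                for row in rows:
                    assert row[col - 1] == master[col - 1] != "-"
                continue
            column = [row[col - 1] for row in rows]
            if "-" not in column and len(set(column)) == 1:
                rows[1][col - 1] = str(rng.choice(
                    [a for a in AMINO if a != column[0]]))

    ids = ["zebrafish_standin"] + [f"species{r:03d}" for r in range(1, n_rows)]
    aln = Alignment(ids=ids, rows=["".join(r) for r in rows])
    truth = TruthRecord("ca6_msa", seed, {
        "ca_window": list(ca_window), "ptx_window": list(ptx_window),
        "ca_invariant_columns": ca_cols, "ptx_invariant_columns": ptx_cols,
        "sequon_columns": list(sequon_cols),
        "sequon_conserved_rows": n_rows - 1,
        "cys_column": cys_col, "cys_conserved_rows": n_rows - 2,
    })
    return aln, truth


def synthetic_ca6_cds_pair(seed: int = 0):
    """Synthetic CDS pair emulating the sequenced-vs-reference comparison.

    The reference CDS back-translates the stand-in protein (530 codons plus a
    stop, 1593 nt). The "sequenced" copy differs by five planted synonymous
    substitutions and one codon of three unresolved bases (NNN), matching the
    study design: an otherwise identical translation with one unknown
    residue.
    """
    from Bio.Data.CodonTable import unambiguous_dna_by_id
    rng = _rng(seed, "ca6_cds")
    table = unambiguous_dna_by_id[1]
    back = {}
    for codon, aa in table.forward_table.items():
        back.setdefault(aa, []).append(codon)
    protein = synthetic_ca6_protein(seed).sequence
    codons = [str(rng.choice(back[aa])) for aa in protein] + ["TAA"]
    reference = "".join(codons)

    degenerate = [i for i, aa in enumerate(protein) if len(back[aa]) > 1]
    picks = sorted(int(v) for v in rng.choice(degenerate, size=6,
                                              replace=False))
    nnn_index, syn_indices = picks[0], picks[1:]
    sequenced = list(codons)
    for i in syn_indices:
        alternatives = [c for c in back[protein[i]] if c != codons[i]]
        sequenced[i] = str(rng.choice(alternatives))
    sequenced[nnn_index] = "NNN"
    truth = TruthRecord("ca6_cds", seed, {
        "synonymous_codons": [i + 1 for i in syn_indices],
        "unresolved_codon": nnn_index + 1, "unresolved_bases": 3,
        "protein_length": len(protein),
    })
    return "".join(sequenced), reference, truth
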