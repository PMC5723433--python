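"""Tryptic digestion, species enumeration, ppm matching and CID annotation."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from captx import digest as dg
from captx import masses, synth
from captx.digest import (CleavageRule, MassObservation, ProteinRecord,
                          cid_annotate, coverage, enumerate_disulfide_species,
                          enumerate_glycoforms, match)
from captx.masses import CORE_GLYCAN, FUC_CORE_GLYCAN, GlycoComposition


def pep_seqs(peptides, missed=None):
    return sorted(p.sequence for p in peptides
                  if missed is None or p.missed == missed)


def test_digest_respects_proline_suppression():
    prot = ProteinRecord(id="t", sequence="AKRPGK")
    peps = dg.digest(prot, CleavageRule(max_missed=0))
    assert pep_seqs(peps) == ["AK", "RPGK"]


def test_digest_missed_cleavage_enumeration_is_exhaustive():
    prot = ProteinRecord(id="t", sequence="KKK")
    peps = dg.digest(prot, CleavageRule(max_missed=1))
    assert pep_seqs(peps, missed=0) == ["K", "K", "K"]
    assert pep_seqs(peps, missed=1) == ["KK", "KK"]
    spans = [(p.start, p.end) for p in peps]
    assert spans == sorted(spans)


def test_digest_without_cut_sites_returns_whole_chain():
    prot = ProteinRecord(id="t", sequence="MAGICSEQ")
    peps = dg.digest(prot)
    assert pep_seqs(peps) == ["MAGICSEQ"]


def test_digest_excludes_signal_peptide_but_keeps_numbering():
    prot = ProteinRecord(id="t", sequence="MAKSVILKTTR", signal_peptide_end=3)
    peps = dg.digest(prot, CleavageRule(max_missed=0))
    assert all(p.start >= 4 for p in peps)
    assert pep_seqs(peps) == ["SVILK", "TTR"]
    first = min(peps, key=lambda p: p.start)
    assert (first.start, first.end) == (4, 8)


def test_digestion_reconstructs_mature_chain(ca6_protein):
    peps = dg.digest(ca6_protein, CleavageRule(max_missed=0))
    joined = "".join(p.sequence for p in sorted(peps, key=lambda p: p.start))
    assert joined == ca6_protein.mature_sequence


def test_interpeptide_disulfide_species_mass():
    pa = dg.PeptideSpecies("t", 1, 2, "CK")
    pb = dg.PeptideSpecies("t", 5, 6, "CR")
    species = enumerate_disulfide_species([pa, pb], [(1, 5)])
    assert len(species) == 1
    assert species[0].n_bonds == 1
    assert species[0].mass() == pytest.approx(524.2199, abs=5e-5)


def test_intrapeptide_disulfide_applies_single_decrement():
    p = dg.PeptideSpecies("t", 1, 5, "ACGCK")
    (sp,) = enumerate_disulfide_species([p], [(2, 4)])
    assert sp.mass() == pytest.approx(
        masses.peptide_mass("ACGCK") - masses.DISULFIDE_DELTA, abs=1e-9)


def test_disulfide_pair_outside_surviving_peptides_is_skipped():
    p = dg.PeptideSpecies("t", 1, 2, "AK")
    assert enumerate_disulfide_species([p], [(10, 20)]) == []


def test_disulfide_pair_on_non_cysteine_is_an_error():
    prot = ProteinRecord(id="t", sequence="ACKGCR")
    peps = dg.digest(prot)
    with pytest.raises(ValueError, match="not a cysteine"):
        enumerate_disulfide_species(peps, [(1, 5)], protein=prot)


def test_multi_pair_species_from_bridging_peptide():
    """A peptide spanning two paired cysteines links both partners."""
    prot = ProteinRecord(id="t", sequence="CAKACACKCR")
    peps = dg.digest(prot, CleavageRule(max_missed=0))
    species = enumerate_disulfide_species(peps, [(1, 5), (7, 9)])
    multi = [s for s in species if s.n_bonds == 2]
    assert multi, "expected a two-bond species through the bridging peptide"
    sp = multi[0]
    assert sorted(sp.spans()) == [(1, 3), (4, 8), (9, 10)]
    linear = sum(masses.peptide_mass(s) for s in ("CAK", "ACACK", "CR"))
    assert sp.mass() == pytest.approx(linear - 2 * masses.DISULFIDE_DELTA,
                                      abs=1e-9)


def test_glycoform_counting_per_sequon():
    p = dg.PeptideSpecies("t", 1, 6, "NATAGK")
    forms = enumerate_glycoforms([p], [CORE_GLYCAN, FUC_CORE_GLYCAN])
    assert len(forms) == 3        # bare + two glycoforms
    bare = [f for f in forms if not f.glycans]
    assert len(bare) == 1


def test_proline_blocks_the_sequon():
    p = dg.PeptideSpecies("t", 1, 6, "NPTAGK")
    forms = enumerate_glycoforms([p], [CORE_GLYCAN])
    assert len(forms) == 1 and not forms[0].glycans


def test_glycoforms_combinatorial_over_two_sequons():
    p = dg.PeptideSpecies("t", 1, 9, "NATANCSGK")
    forms = enumerate_glycoforms([p], [CORE_GLYCAN])
    # (none|core) x (none|core)
    assert len(forms) == 4


def test_glycoform_mass_adds_the_core_fucosylated_increment(ca6_protein):
    peps = dg.digest(ca6_protein)
    p248 = next(p for p in peps if (p.start, p.end) == (248, 266))
    forms = enumerate_glycoforms([p248], [FUC_CORE_GLYCAN])
    glyco = next(f for f in forms if f.glycans)
    assert glyco.glycans[0][0] == 258
    assert glyco.mass() == pytest.approx(p248.mass() + 1038.3751, abs=5e-5)


def test_ppm_match_boundary_cases():
    sp = dg.PeptideSpecies("t", 1, 2, "GG")
    theo = sp.mass()
    inside = MassObservation(theo * (1 + 4.0e-6))
    outside = MassObservation(theo * (1 + 6.0e-6))
    report = match([inside, outside], [sp], tolerance_ppm=5)
    assert len(report.matches) == 1
    assert report.matches[0].ppm_error == pytest.approx(4.0, abs=1e-6)
    assert report.unmatched == [outside]
    with pytest.raises(ValueError):
        match([inside], [sp], tolerance_ppm=0)


@given(tol=st.floats(min_value=0.5, max_value=5.0))
def test_shrinking_tolerance_never_adds_matches(tol):
    species = [dg.PeptideSpecies("t", 1, 2, s) for s in ("GG", "GA", "AV")]
    obs = [MassObservation(s.mass() * (1 + 3e-6)) for s in species]
    wide = match(obs, species, tolerance_ppm=5.0)
    narrow = match(obs, species, tolerance_ppm=tol)
    assert len(narrow.matches) <= len(wide.matches)


def test_synthetic_mass_list_recovery_with_decoys(ca6_protein):
    """20 species perturbed by 2 ppm noise and 10 far decoys: all species
    matched, no decoy matched."""
    peps = [p for p in dg.digest(ca6_protein) if len(p.sequence) >= 8][:20]
    obs, truth = synth.gen_mass_list(peps, ppm_sigma=2.0, n_decoys=10,
                                     decoy_min_ppm=50.0, seed=4)
    report = match(obs, peps, tolerance_ppm=5.0)
    matched = {m.observation.neutral_mass for m in report.matches}
    decoys = set(truth.features["decoys"])
    assert not matched & decoys
    missed = [o for o in truth.features["observed"] if o not in matched]
    assert not missed


def test_coverage_union_of_spans():
    prot = ProteinRecord(id="t", sequence="AAAAAAAAAA")
    sp1 = dg.PeptideSpecies("t", 1, 4, "AAAA")
    sp2 = dg.PeptideSpecies("t", 3, 8, "AAAAAA")
    obs = [MassObservation(sp1.mass()), MassObservation(sp2.mass())]
    report = match(obs, [sp1, sp2], tolerance_ppm=5)
    assert coverage(report, prot) == pytest.approx(80.0)
    assert coverage([], prot) == 0.0
    full = dg.PeptideSpecies("t", 1, 10, "AAAAAAAAAA")
    rep2 = match([MassObservation(full.mass())], [full], 5)
    assert coverage(rep2, prot) == pytest.approx(100.0)


def test_coverage_from_matches_equals_coverage_from_truth(ca6_protein):
    """With noise below tolerance and no decoys, recovered coverage equals
    the ground-truth coverage of the generated species."""
    peps = [p for p in dg.digest(ca6_protein, CleavageRule(max_missed=0))
            if len(p.sequence) >= 6]
    obs, _ = synth.gen_mass_list(peps, ppm_sigma=1.0, seed=11)
    report = match(obs, peps, tolerance_ppm=5.0)
    truth_cov = coverage([dg.MatchResult(None, p, 0.0) for p in peps],
                         ca6_protein)
    assert coverage(report, ca6_protein) == pytest.approx(truth_cov)


def test_cid_y1_of_lysine_terminated_peptide():
    sp = dg.PeptideSpecies("t", 1, 4, "GAGK")
    out = cid_annotate(sp, [147.1128], tolerance_ppm=5)
    assert out[0].label == "y1"
    assert out[0].theoretical_mz == pytest.approx(147.1128, abs=5e-5)


def test_cid_glycan_ladder_has_one_step_per_monosaccharide():
    from captx.digest import y_glycan_ladder
    steps = y_glycan_ladder(CORE_GLYCAN)
    assert len(steps) == CORE_GLYCAN.n_residues == 5
    assert steps[-1] is None     # ends at the bare peptide
    fuc = y_glycan_ladder(FUC_CORE_GLYCAN)
    assert len(fuc) == FUC_CORE_GLYCAN.n_residues == 6


def test_cid_self_consistency_on_theoretical_ladder():
    sp = dg.PeptideSpecies("t", 1, 6, "NATAGK",
                           glycans=((1, CORE_GLYCAN),))
    proton = masses.PROTON
    bare = masses.peptide_mass("NATAGK")
    mzs = [bare + CORE_GLYCAN.mass() + proton, bare + proton]
    out = cid_annotate(sp, mzs, tolerance_ppm=5)
    assert all(a.label != "unassigned" for a in out)
    assert out[1].label == "Y0"


def test_cid_rejects_multiple_occupied_sequons():
    sp = dg.PeptideSpecies("t", 1, 9, "NATANCSGK",
                           glycans=((1, CORE_GLYCAN), (5, CORE_GLYCAN)))
    with pytest.raises(ValueError):
        cid_annotate(sp, [100.0])


def test_species_mass_equals_corechem_arithmetic(ca6_protein):
    """Cross-module oracle: any enumerated species mass re-derives from
    peptide/glycan arithmetic."""
    peps = dg.digest(ca6_protein)
    species = enumerate_disulfide_species(
        peps, list(synth.CA6_CYS_PAIRS), protein=ca6_protein)
    assert species, "disulfide species expected from the planted pairs"
    for sp in species[:25]:
        expect = sum(masses.peptide_mass(s.sequence)
                     for s in [sp] + list(sp.partners))
        expect -= sp.n_bonds * masses.DISULFIDE_DELTA
        assert sp.mass() == pytest.approx(expect, abs=1e-9)
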