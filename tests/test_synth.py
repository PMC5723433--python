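"""Synthetic-data generators: determinism, planted-feature recovery, truth."""

import numpy as np
import pytest

from captx import behavior, conserve, digest, helix, masses, synth
from captx.synth import (TruthRecord, gen_ct, gen_mass_list, gen_msa,
                         gen_protein, gen_tracks)


def test_generators_are_pure_functions_of_seed():
    p1, t1 = gen_protein(120, n_sequons=2, n_cys_pairs=1, seed=42)
    p2, t2 = gen_protein(120, n_sequons=2, n_cys_pairs=1, seed=42)
    assert p1.sequence == p2.sequence and t1.features == t2.features
    p3, _ = gen_protein(120, n_sequons=2, n_cys_pairs=1, seed=43)
    assert p3.sequence != p1.sequence
    a1, _ = synth.synthetic_ca6_alignment(seed=5)
    a2, _ = synth.synthetic_ca6_alignment(seed=5)
    assert a1.rows == a2.rows


def test_planted_sequons_are_the_only_sequons():
    for seed in range(5):
        prot, truth = gen_protein(200, n_sequons=2, seed=seed)
        assert prot.sequon_positions() == truth.features["sequons"]
        assert len(truth.features["sequons"]) == 2


def test_planted_cys_pairs_are_the_only_cysteines():
    prot, truth = gen_protein(150, n_cys_pairs=2, seed=1)
    planted = sorted(p for pair in truth.features["cys_pairs"] for p in pair)
    assert prot.cys_positions() == planted


def test_planted_aph_span_is_recovered():
    prot, truth = gen_protein(160, aph_span=(60, 80), seed=2)
    cands = helix.detect_aph(prot.sequence)
    sites = truth.features["aph_sites"]
    assert any(c.start <= sites[0] and c.end >= sites[-1] for c in cands)


def test_infeasible_feature_packing_raises():
    with pytest.raises(ValueError):
        gen_protein(10, n_sequons=4, seed=0)
    with pytest.raises(ValueError):
        gen_protein(20, aph_span=(5, 30), seed=0)


def test_noise_free_mass_list_matches_at_zero_ppm():
    species = [digest.PeptideSpecies("t", 1, 5, s)
               for s in ("GAGAK", "WLRNK", "PEPTY")]
    obs, truth = gen_mass_list(species, ppm_sigma=0.0, seed=0)
    report = digest.match(obs, species, tolerance_ppm=5.0)
    assert all(abs(m.ppm_error) < 1e-9 for m in report.matches)
    assert not report.unmatched


def test_mass_list_recovery_rate_with_2ppm_noise():
    """P(|N(0,2)| > 5) ~ 1.2%, so >= 98% of 1000 species are recovered at a
    5 ppm tolerance, and far decoys never match."""
    rng = np.random.default_rng(0)
    species_masses = list(rng.uniform(800, 5000, size=1000))
    obs, truth = gen_mass_list(species_masses, ppm_sigma=2.0, n_decoys=25,
                               decoy_min_ppm=50.0, seed=6)
    theo = np.array(species_masses)
    recovered = 0
    for o in truth.features["observed"]:
        if np.min(np.abs(1e6 * (o - theo) / theo)) <= 5.0:
            recovered += 1
    assert recovered >= 980
    for d in truth.features["decoys"]:
        assert np.min(np.abs(1e6 * (d - theo) / theo)) >= 50.0


def test_decoy_placement_infeasibility_detected():
    with pytest.raises(ValueError):
        gen_mass_list([1000.0], ppm_sigma=0.0, n_decoys=50,
                      decoy_min_ppm=1e9, seed=0, max_tries=100)


def test_msa_rate_zero_conserves_master():
    master = "ACDEFGHIKL"
    aln, _ = gen_msa(master, n_rows=8, per_column_rate=0.0, seed=0)
    assert conserve.count_conserved_columns(aln, 1, len(master)) == len(master)


def test_msa_planted_invariant_columns_survive_high_mutation():
    """With 78 rows at rate 0.5 a non-planted column is essentially never
    identical across all rows, so the strict census equals the plant."""
    rng = np.random.default_rng(4)
    master = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=120))
    planted = sorted(int(c) for c in
                     rng.choice(np.arange(20, 103), size=83, replace=False))
    hits = 0
    for seed in range(5):
        aln, _ = gen_msa(master, n_rows=78, per_column_rate=0.5,
                         invariant_columns=planted, seed=seed)
        if conserve.count_conserved_columns(aln, 20, 102) == 83:
            hits += 1
    assert hits == 5


def test_msa_unique_insertion_is_rejected_by_qc():
    master = "A" * 500
    aln, truth = gen_msa(master, n_rows=6, per_column_rate=0.3, seed=2,
                         unique_insertion=(3, 250, 25))
    decisions = conserve.qc_filter(aln, exon_boundary_columns=[250])
    discarded = [d.record_id for d in decisions if not d.keep]
    assert discarded == [aln.ids[3]]
    assert [d.reason for d in decisions if not d.keep] == ["insertion"]


def test_tracks_zero_speed_gives_zero_distance():
    tracks, _ = gen_tracks(3, {"g": {"speed": 0.0, "upper_bias": 0.5}},
                           duration=10, fps=5, seed=0)
    assert all(behavior.track_distance(t) == 0.0 for t in tracks)


def test_tracks_full_upper_bias_pins_fish_to_upper_half():
    tracks, _ = gen_tracks(3, {"g": {"speed": 1.0, "upper_bias": 1.0}},
                           duration=10, fps=5, seed=1)
    for t in tracks:
        assert behavior.time_upper_half(t) == pytest.approx(t.t[-1] - t.t[0])


def test_separated_speed_groups_reject_ks_null():
    """Speeds 0.1 vs 2.0 cm/s with n=40 per group: KS p < 0.01 in at least
    19 of 20 seeds."""
    hits = 0
    for seed in range(20):
        tracks, _ = gen_tracks(
            40, {"slow": {"speed": 0.1}, "fast": {"speed": 2.0}},
            duration=20, fps=2, seed=seed)
        slow = [behavior.track_distance(t) for t in tracks
                if t.group == "slow"]
        fast = [behavior.track_distance(t) for t in tracks
                if t.group == "fast"]
        _, p = behavior.ks_two_sample(slow, fast, mode="asymptotic")
        hits += p < 0.01
    assert hits >= 19


def test_ct_truth_round_trips_through_json(tmp_path):
    _, truth = gen_ct({"a": 2.0}, seed=3)
    path = tmp_path / "truth.json"
    truth.to_json(path)
    back = TruthRecord.from_json(path)
    assert back == truth


def test_stand_in_protein_carries_documented_architecture(ca6_protein):
    p = ca6_protein
    assert len(p.sequence) == 530 and p.signal_peptide_end == 19
    assert p.sequon_positions() == [210, 258, 339, 394]
    assert p.cys_positions() == [44, 226, 290, 352, 408, 487, 518]
    assert p.sequence[283:291] == "LSKGGMCR"
    assert masses.extinction_280(p.mature_sequence) == 99155


def test_stand_in_alignment_truth_matches_census(ca6_alignment):
    aln, truth = ca6_alignment
    f = truth.features
    assert conserve.count_conserved_columns(aln, *f["ca_window"]) == \
        len(f["ca_invariant_columns"])
    assert conserve.count_sequon_conservation(
        aln, tuple(f["sequon_columns"])) == f["sequon_conserved_rows"]
    assert conserve.count_residue_conservation(
        aln, f["cys_column"], "C") == f["cys_conserved_rows"]


def test_stand_in_alignment_round_trips_through_fasta(tmp_path, ca6_alignment):
    aln, _ = ca6_alignment
    path = tmp_path / "standin.fasta"
    aln.write(path)
    back = conserve.Alignment.read(path)
    assert back.rows == aln.rows and back.ids == aln.ids
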