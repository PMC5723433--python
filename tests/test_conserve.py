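"""Alignment QC filtering, residue/column mapping and conservation censuses."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from captx import conserve, synth
from captx.conserve import (Alignment, column_to_residue,
                            count_conserved_columns,
                            count_residue_conservation,
                            count_sequon_conservation, qc_filter,
                            residue_to_column)


def aln(*rows, ids=None):
    return Alignment(ids=ids or [f"r{i}" for i in range(len(rows))],
                     rows=list(rows))


# ---------------------------------------------------------------- QC filter

def test_qc_discards_short_sequences():
    a = aln("A" * 600, "A" * 400 + "-" * 200)
    decisions = qc_filter(a)
    assert decisions[0].keep
    assert not decisions[1].keep and decisions[1].reason == "length"


def test_qc_discards_x_characters():
    a = aln("A" * 500, "A" * 250 + "X" + "A" * 249)
    decisions = qc_filter(a)
    assert decisions[1].reason == "x_char"


def test_qc_evalue_rule_applies_first():
    a = aln("A" * 500, "A" * 400 + "-" * 100)
    decisions = qc_filter(a, evalues={"r1": 1e-50})
    assert decisions[1].reason == "evalue"


def test_qc_discards_unique_insertion_at_exon_boundary():
    n = 500
    core = "A" * n
    ins = "L" * 25
    rows = [core[:100] + "-" * 25 + core[100:],
            core[:100] + ins + core[100:],
            core[:100] + "-" * 25 + core[100:]]
    decisions = qc_filter(aln(*rows), exon_boundary_columns=[101])
    assert [d.keep for d in decisions] == [True, False, True]
    assert decisions[1].reason == "insertion"
    # the same insertion far from any boundary is tolerated
    decisions = qc_filter(aln(*rows), exon_boundary_columns=[300])
    assert all(d.keep for d in decisions)


def test_qc_discards_gap_spanning_internal_exon():
    row_ok = "A" * 565
    row_gap = "A" * 100 + "-" * 40 + "A" * 425
    decisions = qc_filter(aln(row_ok, row_gap, row_ok),
                          exon_boundary_columns=[105, 135])
    assert decisions[1].reason == "internal_gap"
    assert decisions[0].keep and decisions[2].keep


def test_qc_boundary_columns_must_be_in_range():
    with pytest.raises(ValueError):
        qc_filter(aln("A" * 500), exon_boundary_columns=[501])


def test_qc_filter_is_idempotent_on_synthetic_alignment(ca6_alignment):
    alignment, _ = ca6_alignment
    decisions = qc_filter(alignment)
    kept = [i for i, d in enumerate(decisions) if d.keep]
    sub = Alignment(ids=[alignment.ids[i] for i in kept],
                    rows=[alignment.rows[i] for i in kept])
    again = qc_filter(sub)
    assert all(d.keep for d in again)


# ------------------------------------------------------- coordinate mapping

def test_residue_to_column_skips_gaps():
    a = aln("A-CG")
    assert residue_to_column(a, "r0", 2) == 3
    assert column_to_residue(a, "r0", 3) == 2


def test_gapless_row_maps_identically():
    a = aln("ACDEFG")
    for i in range(1, 7):
        assert residue_to_column(a, "r0", i) == i


@given(st.lists(st.sampled_from(list("ACDEFG-")), min_size=1, max_size=60)
       .filter(lambda r: any(c != "-" for c in r)))
def test_residue_column_round_trip(row):
    a = aln("".join(row))
    n = len([c for c in row if c != "-"])
    for i in range(1, n + 1):
        col = residue_to_column(a, "r0", i)
        assert column_to_residue(a, "r0", col) == i


def test_mapping_out_of_range_errors():
    a = aln("A-C")
    with pytest.raises(IndexError):
        residue_to_column(a, "r0", 3)
    with pytest.raises(ValueError):
        column_to_residue(a, "r0", 2)


# ------------------------------------------------------------ conservation

def test_conserved_columns_strict_gap_disqualifies():
    a = aln("AC-T", "ACGT", "ACGT")
    assert count_conserved_columns(a, 1, 4, "strict") == 3
    assert count_conserved_columns(a, 1, 4, "ignore_gaps") == 4


def test_single_row_alignment_every_residue_column_conserved():
    a = aln("AC-G")
    assert count_conserved_columns(a, 1, 4, "strict") == 3
    assert count_conserved_columns(a, 1, 4, "ignore_gaps") == 3


def test_conservation_invariant_under_row_reordering(ca6_alignment):
    alignment, _ = ca6_alignment
    rng = np.random.default_rng(3)
    order = rng.permutation(alignment.n_rows)
    shuffled = Alignment(ids=[alignment.ids[i] for i in order],
                         rows=[alignment.rows[i] for i in order])
    for window in ((30, 288), (355, 566)):
        assert count_conserved_columns(alignment, *window) == \
            count_conserved_columns(shuffled, *window)


def _brute_force_counts(rows, lo, hi):
    strict = ignore = 0
    for c in range(lo - 1, hi):
        col = [r[c] for r in rows]
        if len(set(col)) == 1 and col[0] != "-":
            strict += 1
        res = [x for x in col if x != "-"]
        if res and len(set(res)) == 1:
            ignore += 1
    return strict, ignore


def test_census_agrees_with_brute_force_on_random_alignments():
    """Column scanner vs an independent brute-force count, many alignments."""
    rng = np.random.default_rng(12)
    alphabet = np.array(list("ACDEFG-"))
    for _ in range(300):
        n_rows = int(rng.integers(2, 10))
        n_cols = int(rng.integers(4, 50))
        rows = ["".join(rng.choice(alphabet, size=n_cols))
                for _ in range(n_rows)]
        a = aln(*rows)
        lo = int(rng.integers(1, n_cols))
        hi = int(rng.integers(lo, n_cols)) + 1 if lo < n_cols else n_cols
        hi = min(hi, n_cols)
        strict, ignore = _brute_force_counts(rows, lo, hi)
        assert count_conserved_columns(a, lo, hi, "strict") == strict
        assert count_conserved_columns(a, lo, hi, "ignore_gaps") == ignore
        assert strict <= ignore


def test_planted_invariant_columns_recovered_from_generator():
    master = "ACDEFGHIKLMNPQRSTVWY" * 3
    invariant = [3, 17, 41, 55]
    a, truth = synth.gen_msa(master, n_rows=20, per_column_rate=0.6,
                             invariant_columns=invariant, seed=5)
    for c in invariant:
        assert len(set(a.column(c))) == 1
    assert count_conserved_columns(a, 1, len(master), "strict") >= len(invariant)


def test_sequon_census_rules():
    a = aln("NAT", "NPT", "N-T", "NVS", "QAT")
    assert count_sequon_conservation(a, (1, 2, 3)) == 2
    assert count_sequon_conservation(a, (1, 2, 3), exclude_proline=False) == 3
    with pytest.raises(ValueError):
        count_sequon_conservation(a, (3, 2, 1))


def test_residue_census_counts_exact_matches():
    a = aln("C", "C", "-", "S")
    assert count_residue_conservation(a, 1, "C") == 2
    assert count_residue_conservation(a, 1, "W") == 0


def test_empty_alignment_census_errors():
    a = Alignment(ids=[], rows=[])
    with pytest.raises(ValueError):
        count_conserved_columns(a, 1, 1)
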