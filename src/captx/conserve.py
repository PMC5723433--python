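"""Multiple-sequence-alignment quality control and conservation censuses.

The census operations answer questions of the form "how many alignment
columns inside a domain window are perfectly conserved across all rows", and
"in how many rows is a glycosylation sequon or a particular residue kept".
Columns are 1-based throughout, matching how alignment viewers number them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

GAP = "-"


@dataclass
class Alignment:
    """Row-major gapped sequence matrix with 1-based column indexing."""

    ids: list
    rows: list

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if self.rows:
            n = len(self.rows[0])
            if any(len(r) != n for r in self.rows):
                raise ValueError("alignment rows have unequal lengths")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, row_id: str) -> str:
        try:
            return self.rows[self.ids.index(row_id)]
        except ValueError:
            raise KeyError(f"no row {row_id!r} in alignment") from None

    def column(self, col: int) -> str:
        if not 1 <= col <= self.n_cols:
            raise IndexError(f"column {col} out of range 1..{self.n_cols}")
        return "".join(r[col - 1] for r in self.rows)

    def ungapped(self, row_id: str) -> str:
        return self.row(row_id).replace(GAP, "")

    @classmethod
    def read(cls, path, fmt: str | None = None) -> "Alignment":
        """Read an aligned FASTA or Clustal file (format guessed from suffix)."""
        from Bio import AlignIO
        if fmt is None:
            suffix = Path(path).suffix.lower()
            fmt = "clustal" if suffix in (".aln", ".clustal", ".clw") else "fasta"
        aln = AlignIO.read(str(path), fmt)
        return cls(ids=[rec.id for rec in aln],
                   rows=[str(rec.seq).upper() for rec in aln])

    def write(self, path, fmt: str = "fasta") -> None:
        from Bio import AlignIO, SeqIO
        from Bio.Align import MultipleSeqAlignment
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        msa = MultipleSeqAlignment(
            [SeqRecord(Seq(r), id=i, description="")
             for i, r in zip(self.ids, self.rows)])
        AlignIO.write(msa, str(path), fmt)


@dataclass(frozen=True)
class QCDecision:
    record_id: str
    keep: bool
    reason: str | None = None   # evalue | length | x_char | insertion | internal_gap


def qc_filter(alignment: Alignment,
              evalues: dict | None = None,
              exon_boundary_columns: list | None = None,
              evalue_threshold: float = 2e-80,
              min_length: int = 485,
              min_insertion: int = 20) -> list[QCDecision]:
    """Apply the retrieval quality-control rules to every alignment row.

    Rules, in order: similarity (e-value above threshold, when e-values are
    supplied); ungapped length below ``min_length``; any non-specific 'X'
    character; a unique insertion of at least ``min_insertion`` residues at an
    exon boundary (a run of columns where only this row has residues,
    adjacent to a boundary column -- the signature of a mispredicted intron);
    and a gap run fully spanning the interval between two consecutive exon
    boundary columns (a missing internal exon). Each row receives exactly one
    verdict with the first reason that applies.
    """
    if exon_boundary_columns:
        for c in exon_boundary_columns:
            if not 1 <= c <= alignment.n_cols:
                raise ValueError(f"exon boundary column {c} out of range")
        boundaries = sorted(exon_boundary_columns)
    else:
        boundaries = []

    decisions = []
    for idx, (rid, row) in enumerate(zip(alignment.ids, alignment.rows)):
        reason = None
        if evalues is not None and rid in evalues \
                and evalues[rid] > evalue_threshold:
            reason = "evalue"
        ungapped = row.replace(GAP, "")
        if reason is None and len(ungapped) < min_length:
            reason = "length"
        if reason is None and "X" in ungapped:
            reason = "x_char"
        if reason is None and boundaries:
            if _has_boundary_insertion(alignment, idx, boundaries, min_insertion):
                reason = "insertion"
        if reason is None and len(boundaries) >= 2:
            if _spans_internal_gap(row, boundaries):
                reason = "internal_gap"
        decisions.append(QCDecision(rid, keep=reason is None, reason=reason))
    return decisions


def _has_boundary_insertion(alignment: Alignment, row_idx: int,
                            boundaries: list, min_insertion: int) -> bool:
    row = alignment.rows[row_idx]
    others = [r for i, r in enumerate(alignment.rows) if i != row_idx]
    run_start = None
    for c in range(alignment.n_cols + 1):
        unique = (c < alignment.n_cols and row[c] != GAP
                  and all(o[c] == GAP for o in others))
        if unique and run_start is None:
            run_start = c
        elif not unique and run_start is not None:
            length = c - run_start
            if length >= min_insertion:
                lo, hi = run_start, c + 1  # 1-based: columns run_start+1..c
                if any(lo <= b <= hi for b in boundaries):
                    return True
            run_start = None
    return False


def _spans_internal_gap(row: str, boundaries: list) -> bool:
    for b1, b2 in zip(boundaries, boundaries[1:]):
        interval = row[b1:b2 - 1]  # columns strictly between b1 and b2
        if interval and set(interval) == {GAP}:
            return True
    return False


def residue_to_column(alignment: Alignment, row_id: str,
                      residue_index: int) -> int:
    """Map a 1-based ungapped residue index of one row to its column."""
    row = alignment.row(row_id)
    if residue_index < 1:
        raise IndexError("residue index must be >= 1")
    count = 0
    for col, ch in enumerate(row, start=1):
        if ch != GAP:
            count += 1
            if count == residue_index:
                return col
    raise IndexError(f"residue {residue_index} beyond ungapped length {count}")


def column_to_residue(alignment: Alignment, row_id: str, column: int) -> int:
    """Inverse mapping; the column must hold a residue in this row."""
    row = alignment.row(row_id)
    if not 1 <= column <= len(row):
        raise IndexError(f"column {column} out of range")
    if row[column - 1] == GAP:
        raise ValueError(f"column {column} is a gap in row {row_id!r}")
    return sum(1 for ch in row[:column] if ch != GAP)


def count_conserved_columns(alignment: Alignment, col_start: int, col_end: int,
                            gap_policy: str = "strict") -> int:
    """Number of perfectly conserved columns in a 1-based window.

    ``strict``: every row must carry the identical residue; any gap
    disqualifies the column. ``ignore_gaps``: gap rows are dropped before the
    identity test (a column of gaps only is never conserved).
    """
    if alignment.n_rows == 0:
        raise ValueError("empty alignment")
    if not (1 <= col_start <= col_end <= alignment.n_cols):
        raise ValueError("column window out of range")
    if gap_policy not in ("strict", "ignore_gaps"):
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    count = 0
    for col in range(col_start, col_end + 1):
        chars = alignment.column(col)
        if gap_policy == "strict":
            if GAP not in chars and len(set(chars)) == 1:
                count += 1
        else:
            residues = [c for c in chars if c != GAP]
            if residues and len(set(residues)) == 1:
                count += 1
    return count


def count_sequon_conservation(alignment: Alignment, col_triple: tuple,
                              exclude_proline: bool = True) -> int:
    """Rows keeping an N-glycosylation sequon at three given columns.

    A row counts when the three columns hold Asn, any residue (Pro excluded
    under the canonical reading), and Ser or Thr; a gap at any of the three
    columns is a failure.
    """
    c1, c2, c3 = col_triple
    if not c1 < c2 < c3:
        raise ValueError("columns must be strictly increasing")
    for c in (c1, c2, c3):
        if not 1 <= c <= alignment.n_cols:
            raise ValueError(f"column {c} out of range")
    count = 0
    for row in alignment.rows:
        a, x, b = row[c1 - 1], row[c2 - 1], row[c3 - 1]
        if GAP in (a, x, b):
            continue
        if a == "N" and b in ("S", "T") and not (exclude_proline and x == "P"):
            count += 1
    return count


def count_residue_conservation(alignment: Alignment, column: int,
                               residue: str) -> int:
    """Rows carrying exactly ``residue`` at a 1-based column."""
    return alignment.column(column).count(residue)
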