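"""Thin file-format helpers: FASTA proteins, CSV mass lists and reports."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .digest import MassObservation, MatchReport, ProteinRecord


def read_fasta_proteins(path, signal_peptide_end: int = 0) -> list:
    """Read protein records from FASTA (one ``signal_peptide_end`` for all)."""
    from Bio import SeqIO
    return [ProteinRecord(id=rec.id, sequence=str(rec.seq).upper(),
                          signal_peptide_end=signal_peptide_end)
            for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            seq = rec.sequence if hasattr(rec, "sequence") else rec[1]
            rid = rec.id if hasattr(rec, "id") else rec[0]
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def read_mass_list_csv(path) -> list:
    """Mass list CSV with columns neutral_mass_da[, intensity]."""
    df = pd.read_csv(path)
    has_int = "intensity" in df.columns
    return [MassObservation(float(r["neutral_mass_da"]),
                            float(r["intensity"]) if has_int else None)
            for _, r in df.iterrows()]


def write_mass_list_csv(observations, path) -> None:
    rows = [{"neutral_mass_da": o.neutral_mass, "intensity": o.intensity}
            for o in observations]
    pd.DataFrame(rows).to_csv(path, index=False)


def match_report_frame(report: MatchReport) -> pd.DataFrame:
    """Flatten a match report into a table (one row per reported match)."""
    rows = []
    for m in report.matches:
        rows.append({
            "observed_mass_da": m.observation.neutral_mass,
            "species": m.species.label(),
            "start": m.species.start, "end": m.species.end,
            "theoretical_mass_da": m.species.mass(),
            "ppm_error": m.ppm_error,
        })
    return pd.DataFrame(rows)


def qc_report_frame(decisions) -> pd.DataFrame:
    return pd.DataFrame([{"record_id": d.record_id, "keep": d.keep,
                          "reason": d.reason} for d in decisions])
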