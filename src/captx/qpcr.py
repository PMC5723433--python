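"""Efficiency-corrected relative expression (Pfaffl method).

The relative expression of a target gene in a sample versus a calibrator,
normalized to a reference (housekeeping) gene, is

    ratio = E_target ** dCt_target / E_ref ** dCt_ref

where E is the amplification efficiency in fold per cycle (2.0 = perfect
doubling) and dCt = Ct(calibrator) - Ct(sample) for each gene. Replicate Ct
values are averaged before exponentiation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import mean

import pandas as pd


@dataclass
class PfafflMeasurement:
    """One target-vs-reference measurement with replicate Ct values."""

    target_efficiency: float
    ref_efficiency: float
    target_ct_calibrator: list
    target_ct_sample: list
    ref_ct_calibrator: list
    ref_ct_sample: list
    efficiency_assumed: bool = False   # flagged when defaults were used

    def __post_init__(self):
        if self.target_efficiency <= 1 or self.ref_efficiency <= 1:
            raise ValueError("amplification efficiencies must exceed 1")
        for name in ("target_ct_calibrator", "target_ct_sample",
                     "ref_ct_calibrator", "ref_ct_sample"):
            vals = getattr(self, name)
            vals = [float(v) for v in (vals if hasattr(vals, "__iter__")
                                       else [vals])]
            if not vals:
                raise ValueError(f"{name} has no replicates")
            setattr(self, name, vals)

    @property
    def dct_target(self) -> float:
        return mean(self.target_ct_calibrator) - mean(self.target_ct_sample)

    @property
    def dct_ref(self) -> float:
        return mean(self.ref_ct_calibrator) - mean(self.ref_ct_sample)


def pfaffl_ratio(m: PfafflMeasurement) -> float:
    """Relative expression of the target in the sample vs the calibrator."""
    return (m.target_efficiency ** m.dct_target
            / m.ref_efficiency ** m.dct_ref)


def pfaffl_table(ct_table: pd.DataFrame, target: str, reference: str,
                 calibrator: str, efficiencies: dict | None = None) -> pd.DataFrame:
    """Pfaffl ratios for every sample in a long-format Ct table.

    ``ct_table`` needs columns (gene, sample, ct); a replicate column is
    optional — all rows for one (gene, sample) are treated as replicates.
    Efficiencies default to 2.0 per gene when not measured, and the output
    flags that assumption.
    """
    eff = dict(efficiencies or {})
    assumed = {g: g not in eff for g in (target, reference)}
    eff.setdefault(target, 2.0)
    eff.setdefault(reference, 2.0)

    def cts(gene, sample):
        sel = ct_table[(ct_table["gene"] == gene)
                       & (ct_table["sample"] == sample)]["ct"]
        if sel.empty:
            raise ValueError(f"no Ct values for gene {gene!r}, "
                             f"sample {sample!r}")
        return list(sel)

    rows = []
    for sample in ct_table["sample"].unique():
        if sample == calibrator:
            continue
        m = PfafflMeasurement(
            target_efficiency=eff[target], ref_efficiency=eff[reference],
            target_ct_calibrator=cts(target, calibrator),
            target_ct_sample=cts(target, sample),
            ref_ct_calibrator=cts(reference, calibrator),
            ref_ct_sample=cts(reference, sample),
            efficiency_assumed=any(assumed.values()))
        rows.append({"sample": sample, "ratio": pfaffl_ratio(m),
                     "dct_target": m.dct_target, "dct_ref": m.dct_ref,
                     "efficiency_assumed": m.efficiency_assumed})
    return pd.DataFrame(rows)
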