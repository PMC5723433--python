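"""Hydrodynamic sizing: SEC standard-curve MW estimation and DLS conversions.

Size-exclusion chromatography calibrates log10(MW) against retention volume
with ordinary least squares over a set of standard proteins; dynamic light
scattering yields a hydrodynamic radius Rh, converted to a diameter or, via
an empirical power law Rh = a * MW^b for globular proteins, to an apparent
molecular weight. The power-law coefficients are configurable because vendor
software uses proprietary variants of the relation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class Standard:
    name: str
    mw_da: float
    volume_ml: float


@dataclass
class SECCalibration:
    standards: list
    slope: float            # d log10(MW) / d volume (negative on a column)
    intercept: float
    residuals: np.ndarray   # per-standard log10(MW) fit residuals
    r_squared: float


def sec_calibrate(standards) -> SECCalibration:
    """OLS fit of log10(MW) on retention volume over >= 2 standards.

    ``standards`` is an iterable of (name, mw_da, volume_ml) triples,
    ``Standard`` objects, or a DataFrame with those columns.
    """
    rows = []
    try:
        import pandas as pd
        if isinstance(standards, pd.DataFrame):
            standards = list(standards[["name", "mw_da", "volume_ml"]]
                             .itertuples(index=False, name=None))
    except ImportError:          # pragma: no cover
        pass
    for s in standards:
        rows.append(s if isinstance(s, Standard) else Standard(*s))
    if len(rows) < 2:
        raise ValueError("need at least two standards")
    vols = np.array([s.volume_ml for s in rows], dtype=float)
    logmw = np.log10([s.mw_da for s in rows])
    if np.allclose(np.ptp(vols), 0):
        raise ValueError("standards have identical retention volumes")
    fit = stats.linregress(vols, logmw)
    resid = logmw - (fit.slope * vols + fit.intercept)
    return SECCalibration(standards=rows, slope=fit.slope,
                          intercept=fit.intercept, residuals=resid,
                          r_squared=fit.rvalue ** 2)


def sec_estimate(calibration: SECCalibration, volume_ml: float) -> float:
    """Invert the calibration: MW (Da) at a retention volume."""
    return float(10 ** (calibration.slope * volume_ml + calibration.intercept))


def rh_to_diameter(rh_nm: float, rh_err_nm: float | None = None):
    """Hydrodynamic diameter = 2 Rh; the uncertainty doubles with it."""
    if rh_nm <= 0:
        raise ValueError("hydrodynamic radius must be positive")
    if rh_err_nm is None:
        return 2.0 * rh_nm
    if rh_err_nm < 0:
        raise ValueError("uncertainty must be non-negative")
    return 2.0 * rh_nm, 2.0 * rh_err_nm


def rh_to_globular_mw(rh_nm: float, a: float = 0.066, b: float = 0.37) -> float:
    """Apparent MW (Da) of a globular particle with hydrodynamic radius Rh.

    Inverts the empirical power law Rh = a * MW^b (defaults a = 0.066 nm,
    b = 0.37, a widely used globular-protein relation). Off-globular shapes
    bias this estimate upward, so treat it as an apparent size.
    """
    if rh_nm <= 0 or a <= 0 or b <= 0:
        raise ValueError("inputs must be positive")
    return float((rh_nm / a) ** (1.0 / b))


def globular_mw_to_rh(mw_da: float, a: float = 0.066, b: float = 0.37) -> float:
    """Forward power law, the inverse pair of :func:`rh_to_globular_mw`."""
    if mw_da <= 0 or a <= 0 or b <= 0:
        raise ValueError("inputs must be positive")
    return float(a * mw_da ** b)
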