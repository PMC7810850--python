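"""External-calibration quantification of wort sugars and amino acids, and
Brix-to-specific-gravity conversion.

Targeted MRM peak areas are converted to concentrations by inverse prediction
against a linear standard curve (area = slope·concentration + intercept).
Curves must reach R² > 0.99 to be used — below that, quantification is
refused rather than degraded. Samples are assumed diluted (default 1:1000)
before measurement, so inverse-predicted concentrations are multiplied back
by the dilution factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationError",
    "CalibrationCurve",
    "AnalytePanel",
    "fit_calibration",
    "quantify",
    "quantify_table",
    "brix_to_sg",
]

log = logging.getLogger("micromash")

R2_THRESHOLD = 0.99

#: wort sugars measured by negative-mode MRM
SUGARS = ("glucose", "maltose", "maltotriose")
#: the 15 free amino acids measured by positive-mode MRM
AMINO_ACIDS = (
    "L-Serine", "L-Proline", "L-Valine", "L-Threonine", "L-Leucine",
    "L-Isoleucine", "L-Aspartic Acid", "L-Lysine", "L-Glutamic Acid",
    "L-Methionine", "L-Histidine", "L-Phenylalanine", "L-Arginine",
    "L-Tyrosine", "L-Cystine",
)


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted linear standard curve for one analyte."""

    analyte: str
    concentrations: tuple
    areas: tuple
    slope: float
    intercept: float
    r_squared: float
    r2_threshold: float = R2_THRESHOLD

    @property
    def valid(self) -> bool:
        return self.r_squared > self.r2_threshold


@dataclass(frozen=True)
class AnalytePanel:
    """The analyte panel and sample-dilution convention."""

    sugars: tuple = SUGARS
    amino_acids: tuple = AMINO_ACIDS
    dilution: float = 1000.0

    def __post_init__(self) -> None:
        if self.dilution <= 0:
            raise ValueError("dilution factor must be > 0")

    @property
    def analytes(self) -> tuple:
        return self.sugars + self.amino_acids


def fit_calibration(
    concentrations,
    areas,
    analyte: str = "",
    weighting: str | None = None,
    r2_threshold: float = R2_THRESHOLD,
) -> CalibrationCurve:
    """Ordinary least-squares linear fit of a multi-point standard curve.

    Needs >= 3 standard points with strictly increasing concentrations.
    ``weighting="1/x"`` enables inverse-concentration weighted least squares
    (off by default). R² is computed against the (unweighted) total sum of
    squares; constant areas give R² = 0 and an invalid curve.
    """
    conc = np.asarray(concentrations, dtype=float)
    area = np.asarray(areas, dtype=float)
    if conc.size != area.size:
        raise CalibrationError("concentrations and areas differ in length")
    if conc.size < 3:
        raise CalibrationError(f"{analyte or 'curve'}: need >= 3 standard points")
    if not np.all(np.diff(conc) > 0):
        raise CalibrationError(
            f"{analyte or 'curve'}: concentrations must be strictly increasing"
        )
    if weighting not in (None, "1/x"):
        raise CalibrationError("weighting must be None or '1/x'")
    w = None
    if weighting == "1/x":
        if np.any(conc <= 0):
            raise CalibrationError("1/x weighting needs positive concentrations")
        w = 1.0 / np.sqrt(conc)  # polyfit weights multiply residuals
    slope, intercept = np.polyfit(conc, area, 1, w=w)
    fitted = slope * conc + intercept
    ss_res = float(np.sum((area - fitted) ** 2))
    ss_tot = float(np.sum((area - area.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationCurve(
        analyte=analyte,
        concentrations=tuple(conc),
        areas=tuple(area),
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        r2_threshold=r2_threshold,
    )


def quantify(curve: CalibrationCurve, area: float, dilution: float = 1.0) -> float:
    """Inverse prediction: concentration in the original (undiluted) sample.

    ``conc = dilution * (area - intercept) / slope``. Refuses curves below
    the R² gate; a negative result (area below the intercept) is returned but
    flagged with a warning.
    """
    if not curve.valid:
        raise CalibrationError(
            f"{curve.analyte or 'curve'}: R² = {curve.r_squared:.4f} <= "
            f"{curve.r2_threshold} — quantification refused"
        )
    if curve.slope == 0:
        raise CalibrationError(f"{curve.analyte or 'curve'}: zero slope")
    if dilution <= 0:
        raise CalibrationError("dilution factor must be > 0")
    conc = dilution * (float(area) - curve.intercept) / curve.slope
    if conc < 0:
        log.warning(
            "%s: area %.4g below intercept, negative concentration %.4g",
            curve.analyte or "curve", area, conc,
        )
    return conc


def quantify_table(
    standards: pd.DataFrame,
    unknowns: pd.DataFrame,
    dilution: float = 1000.0,
    weighting: str | None = None,
) -> pd.DataFrame:
    """Fit per-analyte curves from a standards table and quantify unknowns.

    ``standards`` columns: analyte, concentration, area (replicate areas at
    the same concentration are averaged). ``unknowns`` columns: analyte,
    sample, area. Returns one row per unknown with the back-calculated
    concentration, curve R² and validity; invalid curves yield NaN
    concentrations rather than numbers.
    """
    rows = []
    curves: dict[str, CalibrationCurve] = {}
    for analyte, grp in standards.groupby("analyte"):
        pts = grp.groupby("concentration", sort=True)["area"].mean()
        curves[analyte] = fit_calibration(
            pts.index.to_numpy(), pts.to_numpy(), analyte=analyte, weighting=weighting
        )
    for _, r in unknowns.iterrows():
        curve = curves.get(r["analyte"])
        if curve is None:
            raise CalibrationError(f"no standards for analyte {r['analyte']!r}")
        if curve.valid:
            conc = quantify(curve, r["area"], dilution=dilution)
        else:
            conc = float("nan")
            log.warning("%s: curve invalid (R²=%.4f), not quantified",
                        r["analyte"], curve.r_squared)
        rows.append(
            {
                "analyte": r["analyte"],
                "sample": r["sample"],
                "area": r["area"],
                "concentration": conc,
                "r_squared": curve.r_squared,
                "curve_valid": curve.valid,
            }
        )
    return pd.DataFrame(rows)


def brix_to_sg(brix: float) -> float:
    """Convert a refractometer Brix reading to specific gravity.

    Uses the standard sucrose-scale quotient approximation
    ``SG = 1 + Bx / (258.6 - (Bx/258.2)*227.1)``, valid for wort-strength
    readings; input must lie in [0, 50) °Bx.
    """
    b = float(brix)
    if not (0.0 <= b < 50.0):
        raise ValueError(f"Brix reading {b} outside [0, 50)")
    return 1.0 + b / (258.6 - (b / 258.2) * 227.1)
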