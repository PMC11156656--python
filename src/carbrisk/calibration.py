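"""Internal-standard calibration, quantification and LOD/LOQ estimation.

Quantification in isotope-dilution LC-MS/MS uses the relative response
(analyte peak area / internal-standard peak area) against the nominal
concentration of each calibration level.  A straight line fitted by
ordinary least squares gives the slope ``m`` and intercept ``b``; unknowns
are back-calculated as ``(rr - b) / m``.

Detection and quantification limits follow the blank-signal convention:
the minimum distinguishable signal is ``S_m = S̄_bl + k·σ_bl`` with k = 3
(LOD) and k = 10 (LOQ), hence the minimum concentration

    c_m = (S_m - S̄_bl) / m = k·σ_bl / m

which forces LOQ/LOD = 10/3 exactly.  A ``formula="literal"`` variant
computing ``k·S̄_bl/m`` is kept for auditability of reports that use the
mean blank instead of its standard deviation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "relative_response",
    "CalibrationSeries",
    "CalibrationModel",
    "CalibrationResults",
    "fit_calibration",
    "quantify",
    "BlankSet",
    "lod_loq",
]

#: default 12-level calibration series (μg kg⁻¹)
DEFAULT_LEVELS = (0.001, 0.005, 0.01, 0.05, 0.1, 0.5, 1.0, 5.0, 10.0, 50.0, 100.0, 500.0)


def relative_response(analyte_area: float, is_area: float) -> float:
    """Analyte/IS peak-area ratio; the response variable of every curve."""
    if is_area <= 0:
        raise ValueError("internal standard not detected (is_area must be > 0)")
    return analyte_area / is_area


@dataclass(frozen=True)
class CalibrationSeries:
    """One calibration experiment: levels with analyte and IS peak areas."""

    concentrations: np.ndarray  # μg kg⁻¹
    analyte_areas: np.ndarray
    is_areas: np.ndarray
    medium: str = "solvent"  # "solvent" | "matrix"
    analyte: str = ""

    def __post_init__(self) -> None:
        for name in ("concentrations", "analyte_areas", "is_areas"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.medium not in ("solvent", "matrix"):
            raise ValueError(f"medium must be 'solvent' or 'matrix', got {self.medium!r}")
        n = self.concentrations.size
        if not (n == self.analyte_areas.size == self.is_areas.size):
            raise ValueError("concentrations, analyte_areas, is_areas must align")
        if n < 3:
            raise ValueError("a calibration series needs at least 3 points")
        if np.any(self.is_areas <= 0):
            raise ValueError("all IS areas must be positive")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        if np.allclose(self.concentrations, self.concentrations[0]):
            raise ValueError("degenerate design: all concentrations equal")

    @property
    def relative_responses(self) -> np.ndarray:
        return self.analyte_areas / self.is_areas

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, medium: str | None = None,
                       analyte: str = "") -> "CalibrationSeries":
        """Build from the calibration CSV schema
        (level_ug_per_kg, analyte_area, is_area, medium)."""
        med = medium if medium is not None else str(df["medium"].iloc[0])
        sub = df if medium is None else df[df["medium"] == medium]
        return cls(
            concentrations=sub["level_ug_per_kg"].to_numpy(),
            analyte_areas=sub["analyte_area"].to_numpy(),
            is_areas=sub["is_area"].to_numpy(),
            medium=med,
            analyte=analyte,
        )


@dataclass(frozen=True)
class CalibrationResults:
    """Fitted calibration line with goodness of fit and working range."""

    slope: float  # relative response per μg kg⁻¹
    intercept: float
    r_squared: float
    concentration_range: tuple[float, float]  # μg kg⁻¹
    medium: str
    analyte: str = ""
    n_points: int = 0
    informative: bool = True  # False when the response carries no signal

    def quantify(self, rr: float) -> "Quantification":
        return quantify(self, rr)

    def lod_loq(self, blanks: "BlankSet", formula: str = "sd") -> tuple[float, float]:
        return lod_loq(blanks, self, formula=formula)

    def summary(self) -> str:
        lo, hi = self.concentration_range
        lines = [
            f"Calibration curve ({self.medium}{', ' + self.analyte if self.analyte else ''})",
            f"  n points     : {self.n_points}",
            f"  slope m      : {self.slope:.6g} (RR per ug/kg)",
            f"  intercept b  : {self.intercept:.6g}",
            f"  R^2          : {self.r_squared:.6f}",
            f"  range        : {lo:g} - {hi:g} ug/kg",
        ]
        if not self.informative:
            lines.append("  WARNING      : non-informative fit (flat response)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "analyte": self.analyte,
            "medium": self.medium,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "range_ug_per_kg": list(self.concentration_range),
            "n_points": self.n_points,
            "informative": self.informative,
        }


class CalibrationModel:
    """OLS model of relative response vs nominal concentration.

    Parameters
    ----------
    series
        The calibration series (IS-normalised responses are computed here).
    weighting
        ``None`` (default, unweighted) or ``"1/x"`` for inverse-concentration
        weights, sometimes preferred over wide dynamic ranges.
    """

    def __init__(self, series: CalibrationSeries, weighting: str | None = None):
        if weighting not in (None, "1/x"):
            raise ValueError("weighting must be None or '1/x'")
        self.series = series
        self.weighting = weighting

    def fit(self) -> CalibrationResults:
        x = self.series.concentrations
        y = self.series.relative_responses
        informative = not np.allclose(y, y[0])
        if not informative:
            # flat response: slope 0, intercept at the common response
            slope, intercept, r2 = 0.0, float(y[0]), 0.0
        elif self.weighting == "1/x":
            w = 1.0 / np.where(x > 0, x, np.min(x[x > 0]))
            coef = np.polyfit(x, y, 1, w=np.sqrt(w))
            slope, intercept = float(coef[0]), float(coef[1])
            resid = y - (slope * x + intercept)
            ss_res = float(np.sum(w * resid**2))
            ybar = float(np.sum(w * y) / np.sum(w))
            ss_tot = float(np.sum(w * (y - ybar) ** 2))
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        else:
            res = stats.linregress(x, y)
            slope, intercept = float(res.slope), float(res.intercept)
            r2 = float(res.rvalue**2)
        return CalibrationResults(
            slope=slope,
            intercept=intercept,
            r_squared=min(max(r2, 0.0), 1.0),
            concentration_range=(float(x.min()), float(x.max())),
            medium=self.series.medium,
            analyte=self.series.analyte,
            n_points=int(x.size),
            informative=informative,
        )


def fit_calibration(series: CalibrationSeries, weighting: str | None = None) -> CalibrationResults:
    """Convenience wrapper: ``CalibrationModel(series, weighting).fit()``."""
    return CalibrationModel(series, weighting=weighting).fit()


@dataclass(frozen=True)
class Quantification:
    """Back-calculated concentration with range flags."""

    concentration: float  # μg kg⁻¹
    below_range: bool = False  # negative back-calculation clamped to 0
    extrapolated: bool = False  # outside the calibration range


def quantify(curve: CalibrationResults, rr: float) -> Quantification:
    """Invert the calibration line: concentration = (rr − b)/m.

    Negative back-calculations (responses below the intercept, legitimate
    near the blank) clamp to 0 and are flagged rather than raising.
    """
    if curve.slope == 0:
        raise ValueError("cannot quantify with a zero-slope curve")
    c = (rr - curve.intercept) / curve.slope
    below = c < 0
    if below:
        c = 0.0
    lo, hi = curve.concentration_range
    extrapolated = not below and not (lo <= c <= hi)
    return Quantification(concentration=float(c), below_range=bool(below),
                          extrapolated=bool(extrapolated))


@dataclass(frozen=True)
class BlankSet:
    """Replicate signals of blank samples; basis of the LOD/LOQ estimate."""

    signals: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "signals", np.asarray(self.signals, dtype=float))
        if self.signals.size < 2:
            raise ValueError("need at least 2 blank measurements")

    @property
    def mean_blank(self) -> float:
        return float(np.mean(self.signals))

    @property
    def sd_blank(self) -> float:
        # sample (n-1) SD: 20 blanks are a sample, not a population
        return float(np.std(self.signals, ddof=1))

    def minimum_signal(self, k: float) -> float:
        """Minimum distinguishable signal S_m = S̄_bl + k·σ_bl."""
        return self.mean_blank + k * self.sd_blank


def lod_loq(blanks: BlankSet, curve: CalibrationResults, formula: str = "sd") -> tuple[float, float]:
    """LOD and LOQ in μg kg⁻¹ from blank statistics and the curve slope.

    ``formula="sd"`` (default) is c_m = k·σ_bl/m (k = 3, 10), the form the
    S_m derivation and the S/N ≥ 3 / ≥ 10 convention imply.  ``"literal"``
    computes k·S̄_bl/m instead.
    """
    if curve.slope <= 0:
        raise ValueError("LOD/LOQ require a positive calibration slope")
    if formula == "sd":
        base = blanks.sd_blank
    elif formula == "literal":
        base = blanks.mean_blank
    else:
        raise ValueError("formula must be 'sd' or 'literal'")
    lod = 3.0 * base / curve.slope
    loq = 10.0 * base / curve.slope
    return float(lod), float(loq)


def write_curve_report(path, curve: CalibrationResults, lod: float | None = None,
                       loq: float | None = None, **stamp) -> None:
    """JSON curve report: slope, intercept, R², LOD/LOQ, range, medium."""
    payload = curve.to_dict()
    if lod is not None:
        payload["lod_ug_per_kg"] = lod
    if loq is not None:
        payload["loq_ug_per_kg"] = loq
    payload.update(stamp)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
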