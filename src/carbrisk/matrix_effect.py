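"""Matrix-effect assessment by solvent vs matrix-matched slope comparison.

Co-eluting matrix constituents suppress or enhance electrospray ionisation;
the standard slope-ratio definition quantifies this as

    ME% = 100 · (slope_matrix − slope_solvent) / slope_solvent

Negative values indicate ion suppression, positive ion enhancement.  An
effect within ±20 % is "soft" (negligible) and solvent-matched calibration
is permitted; outside that window it is "significant" and matrix-matched
calibration is required.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .calibration import CalibrationResults

__all__ = ["matrix_effect_percent", "classify_matrix_effect", "MatrixEffectResult",
           "assess_matrix_effect", "SOFT_LIMIT_PCT"]

SOFT_LIMIT_PCT = 20.0


def matrix_effect_percent(slope_matrix: float, slope_solvent: float) -> float:
    """Relative slope change in %, matrix vs solvent."""
    if slope_solvent == 0:
        raise ValueError("solvent slope must be nonzero")
    return 100.0 * (slope_matrix - slope_solvent) / slope_solvent


def classify_matrix_effect(me_percent: float) -> str:
    """'soft' if |ME| ≤ 20 % (boundary inclusive), else 'significant'."""
    if not math.isfinite(me_percent):
        raise ValueError("matrix effect must be finite")
    return "soft" if abs(me_percent) <= SOFT_LIMIT_PCT else "significant"


@dataclass(frozen=True)
class MatrixEffectResult:
    pesticide: str
    slope_solvent: float
    slope_matrix: float
    me_percent: float
    classification: str

    @property
    def solvent_calibration_permitted(self) -> bool:
        return self.classification == "soft"

    def to_dict(self) -> dict:
        return {
            "pesticide": self.pesticide,
            "slope_solvent": self.slope_solvent,
            "slope_matrix": self.slope_matrix,
            "me_percent": self.me_percent,
            "classification": self.classification,
        }


def assess_matrix_effect(solvent_curve: CalibrationResults,
                         matrix_curve: CalibrationResults,
                         pesticide: str = "") -> MatrixEffectResult:
    """Evaluate ME from two fitted curves (the fit policy stays in one place)."""
    if solvent_curve.medium != "solvent" or matrix_curve.medium != "matrix":
        raise ValueError("expected one solvent and one matrix curve, in that order")
    me = matrix_effect_percent(matrix_curve.slope, solvent_curve.slope)
    return MatrixEffectResult(
        pesticide=pesticide or solvent_curve.analyte,
        slope_solvent=solvent_curve.slope,
        slope_matrix=matrix_curve.slope,
        me_percent=me,
        classification=classify_matrix_effect(me),
    )
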