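"""Top-down measurement uncertainty from intra-laboratory validation data.

The combined relative standard uncertainty joins a bias component (from
spike-recovery experiments) and a precision component (the intermediate-
precision RSD):

    u(bias)      = sqrt(mean_bias² + SD.P_bias²)
    u(precision) = RSD (as a fraction)
    u            = sqrt(u(bias)² + u(precision)²)
    U            = 100 · k · u       (k = 2 ≈ 95 % coverage)

All internal quantities are fractions; only the expanded uncertainty U is
rendered in percent.  SD.P_bias is deliberately the population
(n-denominator) standard deviation of the relative bias, a convention kept
distinct from the sample SD used for RSDs.  Regulatory ceiling: U ≤ 50 %.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .validation import SpikeSet, precision_report

__all__ = ["relative_bias_stats", "u_bias", "expanded_uncertainty",
           "UncertaintyResult", "uncertainty_from_spikes", "MU_CEILING_PCT"]

MU_CEILING_PCT = 50.0
DEFAULT_COVERAGE_FACTOR = 2.0


def relative_bias_stats(measured: Sequence[float], true_value: float) -> tuple[float, float]:
    """Mean and population SD of the per-replicate relative bias
    (measured − true)/true."""
    if true_value <= 0:
        raise ValueError("true value must be positive")
    arr = np.asarray(measured, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 measurements")
    bias = (arr - true_value) / true_value
    return float(bias.mean()), float(bias.std(ddof=0))


def u_bias(mean_bias: float, sdp_bias: float) -> float:
    """Euclidean combination sqrt(mean_bias² + SD.P_bias²)."""
    if not (math.isfinite(mean_bias) and math.isfinite(sdp_bias)):
        raise ValueError("bias statistics must be finite")
    return math.hypot(mean_bias, sdp_bias)


@dataclass(frozen=True)
class UncertaintyResult:
    """Bias and precision components, combined and expanded uncertainty."""

    analyte: str
    spike_level: float  # μg kg⁻¹; 0 when not tied to a level
    mean_bias: float  # fraction
    sdp_bias: float  # fraction, population SD
    u_bias: float  # fraction
    u_precision: float  # fraction
    u_combined: float  # fraction
    u_expanded_percent: float  # %
    coverage_factor: float
    compliant: bool  # U ≤ 50 %

    def to_dict(self) -> dict:
        return {
            "analyte": self.analyte,
            "spike_level_ug_per_kg": self.spike_level,
            "mean_bias": self.mean_bias,
            "sdp_bias": self.sdp_bias,
            "u_bias": self.u_bias,
            "u_precision": self.u_precision,
            "u_combined": self.u_combined,
            "u_expanded_percent": self.u_expanded_percent,
            "coverage_factor": self.coverage_factor,
            "compliant": self.compliant,
        }


def expanded_uncertainty(u_bias_val: float, u_precision: float,
                         k: float = DEFAULT_COVERAGE_FACTOR,
                         mean_bias: float = float("nan"),
                         sdp_bias: float = float("nan"),
                         analyte: str = "", spike_level: float = 0.0) -> UncertaintyResult:
    """Combine bias and precision into U = 100·k·sqrt(u_b² + u_p²)."""
    if u_bias_val < 0 or u_precision < 0:
        raise ValueError("uncertainty components must be non-negative")
    u_comb = math.hypot(u_bias_val, u_precision)
    u_exp = 100.0 * k * u_comb
    return UncertaintyResult(
        analyte=analyte,
        spike_level=spike_level,
        mean_bias=mean_bias,
        sdp_bias=sdp_bias,
        u_bias=u_bias_val,
        u_precision=u_precision,
        u_combined=u_comb,
        u_expanded_percent=u_exp,
        coverage_factor=k,
        compliant=u_exp <= MU_CEILING_PCT,
    )


def uncertainty_from_spikes(spike_set: SpikeSet, k: float = DEFAULT_COVERAGE_FACTOR,
                            precision: str = "interday") -> UncertaintyResult:
    """Full uncertainty budget for one spike level.

    The precision component defaults to the interday (intermediate-
    precision) RSD; ``precision="intraday"`` uses the pooled within-day RSD.
    """
    mean_b, sdp_b = relative_bias_stats(spike_set.measured, spike_set.spike_level)
    report = precision_report(spike_set)
    if precision == "interday":
        rsd = report.rsd_interday if report.rsd_interday is not None else report.rsd_intraday_pooled
    elif precision == "intraday":
        rsd = report.rsd_intraday_pooled
    else:
        raise ValueError("precision must be 'interday' or 'intraday'")
    return expanded_uncertainty(
        u_bias(mean_b, sdp_b), rsd / 100.0, k=k,
        mean_bias=mean_b, sdp_bias=sdp_b,
        analyte=spike_set.analyte, spike_level=spike_set.spike_level,
    )
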