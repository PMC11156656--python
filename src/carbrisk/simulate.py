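"""Synthetic-data generators for every pipeline input, with known truth.

The generators emulate the statistical structure of a residue-monitoring
survey: lognormal per-pesticide residue concentrations with configurable
detection frequency and left-censoring at the LOD, linear internal-standard
calibration responses with a multiplicative matrix-effect slope perturbation
and additive Gaussian noise, Gaussian blank signals, and spike replicates
with configurable relative bias and RSD.

All randomness flows from one explicit seed through named substreams
(:func:`carbrisk._rand.substream`), so each stage can be regenerated
independently of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from ._rand import substream
from .calibration import DEFAULT_LEVELS, BlankSet, CalibrationSeries
from .risk import fit_lognormal_moments
from .validation import SpikeSet

__all__ = [
    "PesticideSimSpec", "ResidueSimSpec", "CalibrationSimSpec",
    "generate_residue_table", "generate_calibration_series",
    "generate_blank_signals", "generate_spike_replicates",
]


@dataclass(frozen=True)
class PesticideSimSpec:
    """Ground-truth residue distribution for one pesticide."""

    name: str
    target_mean: float  # μg kg⁻¹, arithmetic mean of the lognormal
    target_sd: float  # μg kg⁻¹
    detection_frequency: float  # fraction of samples carrying a detect
    censor_limit: float  # μg kg⁻¹ (LOD)

    def __post_init__(self) -> None:
        if self.target_mean <= 0:
            raise ValueError(f"{self.name}: target mean must be positive")
        if self.target_sd < 0:
            raise ValueError(f"{self.name}: target SD must be non-negative")
        if not 0.0 <= self.detection_frequency <= 1.0:
            raise ValueError(f"{self.name}: detection frequency must be in [0, 1]")
        if self.censor_limit < 0:
            raise ValueError(f"{self.name}: censor limit must be non-negative")


@dataclass(frozen=True)
class ResidueSimSpec:
    """Simulation design for a whole residue survey."""

    pesticides: tuple
    n_samples: int
    seed: int = 0
    censoring: str = "censor"  # "censor" | "truncate"

    def __post_init__(self) -> None:
        object.__setattr__(self, "pesticides", tuple(self.pesticides))
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.censoring not in ("censor", "truncate"):
            raise ValueError("censoring must be 'censor' or 'truncate'")
        if not self.pesticides:
            raise ValueError("need at least one pesticide spec")

    @classmethod
    def from_yaml(cls, path) -> "ResidueSimSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        pesticides = tuple(PesticideSimSpec(**p) for p in raw.pop("pesticides"))
        return cls(pesticides=pesticides, **raw)


def generate_residue_table(spec: ResidueSimSpec) -> pd.DataFrame:
    """Per-sample residue table (sample_id, pesticide, concentration, detected).

    Detection status is Bernoulli(detection_frequency), independent of
    magnitude — a documented simplification.  Concentrations of detects are
    lognormal draws matching (target_mean, target_sd) by method of moments.
    Censoring: under ``"censor"`` draws below the censor limit are marked
    non-detect; under ``"truncate"`` they are redrawn until above it.
    """
    rows = []
    sample_ids = [f"S{i + 1:03d}" for i in range(spec.n_samples)]
    for p in spec.pesticides:
        rng = substream(spec.seed, f"residues:{p.name}")
        mu, sigma = fit_lognormal_moments(p.target_mean, p.target_sd)
        detected = rng.random(spec.n_samples) < p.detection_frequency
        if sigma == 0:
            conc = np.full(spec.n_samples, p.target_mean)
        else:
            conc = rng.lognormal(mu, sigma, size=spec.n_samples)
        if spec.censoring == "truncate":
            # redraw below-limit values; LODs sit far in the lower tail so
            # a bounded number of rounds suffices
            for _ in range(1000):
                low = detected & (conc < p.censor_limit)
                if not low.any():
                    break
                conc[low] = rng.lognormal(mu, sigma, size=int(low.sum()))
        else:
            detected = detected & (conc >= p.censor_limit)
        for sid, det, c in zip(sample_ids, detected, conc):
            rows.append((sid, p.name, float(c) if det else np.nan, int(det)))
    return pd.DataFrame(rows, columns=[
        "sample_id", "pesticide", "concentration_ug_per_kg", "detected"])


@dataclass(frozen=True)
class CalibrationSimSpec:
    """Ground truth for a simulated calibration experiment."""

    true_slope: float
    true_intercept: float = 0.0
    noise_sd: float = 0.0  # additive, in relative-response units
    levels: tuple = DEFAULT_LEVELS
    matrix_effect_factor: float = 1.0  # multiplies the slope in matrix medium
    is_area: float = 1e5  # nominal IS peak area
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(float(x) for x in self.levels))
        if not self.levels:
            raise ValueError("levels must be non-empty")
        arr = np.asarray(self.levels)
        if np.any(arr <= 0) or np.any(np.diff(arr) <= 0):
            raise ValueError("levels must be strictly positive and increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "CalibrationSimSpec":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def generate_calibration_series(spec: CalibrationSimSpec,
                                medium: str = "solvent",
                                analyte: str = "") -> CalibrationSeries:
    """Simulate one calibration series in solvent or matrix medium.

    The matrix medium multiplies the true slope by ``matrix_effect_factor``
    (e.g. 0.8 emulates −20 % ion suppression); responses get additive
    Gaussian noise of SD ``noise_sd``.
    """
    if medium not in ("solvent", "matrix"):
        raise ValueError("medium must be 'solvent' or 'matrix'")
    rng = substream(spec.seed, f"calibration:{medium}:{analyte}")
    conc = np.asarray(spec.levels)
    slope = spec.true_slope * (spec.matrix_effect_factor if medium == "matrix" else 1.0)
    rr = slope * conc + spec.true_intercept + rng.normal(0.0, spec.noise_sd, conc.size)
    return CalibrationSeries(
        concentrations=conc,
        analyte_areas=rr * spec.is_area,
        is_areas=np.full(conc.size, spec.is_area),
        medium=medium,
        analyte=analyte,
    )


def generate_blank_signals(mean: float, sd: float, n: int = 20, seed: int = 0,
                           name: str = "") -> BlankSet:
    """n Gaussian blank-signal replicates (default n = 20)."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if n < 2:
        raise ValueError("need at least 2 blank measurements")
    rng = substream(seed, f"blanks:{name}")
    return BlankSet(signals=rng.normal(mean, sd, size=n))


def generate_spike_replicates(spike_level: float, bias_frac: float = 0.0,
                              rsd_frac: float = 0.0, n_per_day: int = 6,
                              n_days: int = 2, seed: int = 0,
                              analyte: str = "") -> SpikeSet:
    """Spike-recovery replicates with known relative bias and RSD.

    Measurements have expectation ``spike_level × (1 + bias_frac)`` and
    coefficient of variation ``rsd_frac``; the default design is the
    intermediate-precision layout of 6 replicates per day over 2 days.
    """
    if spike_level <= 0:
        raise ValueError("spike level must be positive")
    if rsd_frac < 0:
        raise ValueError("rsd_frac must be non-negative")
    if n_per_day < 1 or n_days < 1:
        raise ValueError("need at least 1 replicate per day and 1 day")
    rng = substream(seed, f"spikes:{analyte}:{spike_level}")
    expect = spike_level * (1.0 + bias_frac)
    measured = rng.normal(expect, abs(expect) * rsd_frac, size=n_per_day * n_days)
    days = tuple(f"day{d + 1}" for d in range(n_days) for _ in range(n_per_day))
    return SpikeSet(spike_level=spike_level, days=days, measured=measured,
                    analyte=analyte)


# ---------------------------------------------------------------------------
# CSV writers (stable schemas shared with the reading side of each module)

def residue_table_to_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def calibration_series_to_csv(series: CalibrationSeries, path) -> None:
    pd.DataFrame({
        "level_ug_per_kg": series.concentrations,
        "analyte_area": series.analyte_areas,
        "is_area": series.is_areas,
        "medium": series.medium,
    }).to_csv(path, index=False)


def spike_set_to_csv(spike_set: SpikeSet, path) -> None:
    pd.DataFrame({
        "day": spike_set.days,
        "replicate": np.arange(1, spike_set.measured.size + 1),
        "measured_ug_per_kg": spike_set.measured,
        "spike_level_ug_per_kg": spike_set.spike_level,
    }).to_csv(path, index=False)


def blank_set_to_csv(blanks: BlankSet, path) -> None:
    pd.DataFrame({
        "replicate": np.arange(1, blanks.signals.size + 1),
        "signal": blanks.signals,
    }).to_csv(path, index=False)
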