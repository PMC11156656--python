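"""Method validation: recovery, repeatability and intermediate precision.

Spike-recovery experiments estimate trueness (recovery %) and precision
(relative standard deviation) at a spike level.  Repeatability (intraday
RSD) uses replicates within a day; intermediate precision (interday RSD)
uses all replicates pooled across days.  Acceptance follows the SANTE
windows: recovery 60–140 %, RSD ≤ 20 % (boundaries inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["recovery_percent", "rsd_percent", "SpikeSet", "ValidationReport",
           "precision_report", "RECOVERY_WINDOW_PCT", "RSD_LIMIT_PCT"]

RECOVERY_WINDOW_PCT = (60.0, 140.0)
RSD_LIMIT_PCT = 20.0


def recovery_percent(measured_mean: float, spiked: float) -> float:
    """100 × amount measured / amount spiked."""
    if spiked <= 0:
        raise ValueError("spiked amount must be positive")
    return 100.0 * measured_mean / spiked


def rsd_percent(values: Sequence[float]) -> float:
    """Relative standard deviation: 100 × sample SD / mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("RSD needs at least 2 values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return float(100.0 * arr.std(ddof=1) / mean)


@dataclass(frozen=True)
class SpikeSet:
    """Replicate measurements of a spiked blank, labelled by day."""

    spike_level: float  # μg kg⁻¹
    days: tuple
    measured: np.ndarray  # μg kg⁻¹
    analyte: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "measured", np.asarray(self.measured, dtype=float))
        object.__setattr__(self, "days", tuple(self.days))
        if self.spike_level <= 0:
            raise ValueError("spike level must be positive")
        if len(self.days) != self.measured.size:
            raise ValueError("day labels must align with measurements")
        if any(d is None or str(d) == "" for d in self.days):
            raise ValueError("day labels must be non-empty")
        if self.measured.size < 2:
            raise ValueError("need at least 2 replicates")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, analyte: str = "") -> "SpikeSet":
        """Build from the spike CSV schema
        (day, replicate, measured_ug_per_kg, spike_level_ug_per_kg)."""
        levels = df["spike_level_ug_per_kg"].unique()
        if len(levels) != 1:
            raise ValueError("one SpikeSet per spike level; found " + repr(levels))
        return cls(spike_level=float(levels[0]), days=tuple(df["day"]),
                   measured=df["measured_ug_per_kg"].to_numpy(), analyte=analyte)

    def by_day(self) -> dict:
        out: dict = {}
        for d, m in zip(self.days, self.measured):
            out.setdefault(d, []).append(float(m))
        return out


@dataclass(frozen=True)
class ValidationReport:
    """Per-level validation statistics with SANTE pass flags."""

    analyte: str
    spike_level: float
    recovery_percent: float
    rsd_intraday_by_day: dict  # day -> RSD %
    rsd_intraday_pooled: float  # pooled within-day RSD %
    rsd_interday: float | None  # over all replicates across days; None if 1 day
    recovery_pass: bool
    precision_pass: bool
    n_replicates: int
    n_days: int

    def to_dict(self) -> dict:
        return {
            "analyte": self.analyte,
            "spike_level_ug_per_kg": self.spike_level,
            "recovery_percent": self.recovery_percent,
            "rsd_intraday_by_day": {str(k): v for k, v in self.rsd_intraday_by_day.items()},
            "rsd_intraday_pooled": self.rsd_intraday_pooled,
            "rsd_interday": self.rsd_interday,
            "recovery_pass": self.recovery_pass,
            "precision_pass": self.precision_pass,
            "n_replicates": self.n_replicates,
            "n_days": self.n_days,
        }


def _pooled_within_day_rsd(groups: Mapping, grand_mean: float) -> float:
    # pooled within-day variance, n_i - 1 degrees of freedom per day
    num = 0.0
    dof = 0
    for vals in groups.values():
        arr = np.asarray(vals, dtype=float)
        if arr.size >= 2:
            num += (arr.size - 1) * arr.var(ddof=1)
            dof += arr.size - 1
    if dof == 0:
        raise ValueError("no day has 2+ replicates; intraday RSD undefined")
    return float(100.0 * np.sqrt(num / dof) / grand_mean)


def precision_report(spike_set: SpikeSet,
                     interday_mode: str = "pooled") -> ValidationReport:
    """Recovery and intraday/interday RSD with SANTE pass flags.

    ``interday_mode="pooled"`` (default) computes the interday RSD over all
    replicates pooled across days (e.g. 12 replicates, 6 per day over two
    days); ``"mean_of_daily"`` averages the per-day RSDs instead.
    """
    groups = spike_set.by_day()
    grand_mean = float(spike_set.measured.mean())
    rec = recovery_percent(grand_mean, spike_set.spike_level)
    per_day = {d: rsd_percent(v) for d, v in groups.items() if len(v) >= 2}
    pooled_within = _pooled_within_day_rsd(groups, grand_mean)
    if len(groups) >= 2:
        if interday_mode == "pooled":
            interday = rsd_percent(spike_set.measured)
        elif interday_mode == "mean_of_daily":
            interday = float(np.mean(list(per_day.values())))
        else:
            raise ValueError("interday_mode must be 'pooled' or 'mean_of_daily'")
    else:
        interday = None
    all_rsds = list(per_day.values()) + [pooled_within] + ([interday] if interday is not None else [])
    lo, hi = RECOVERY_WINDOW_PCT
    return ValidationReport(
        analyte=spike_set.analyte,
        spike_level=spike_set.spike_level,
        recovery_percent=rec,
        rsd_intraday_by_day=per_day,
        rsd_intraday_pooled=pooled_within,
        rsd_interday=interday,
        recovery_pass=lo <= rec <= hi,
        precision_pass=all(r <= RSD_LIMIT_PCT for r in all_rsds),
        n_replicates=int(spike_set.measured.size),
        n_days=len(groups),
    )


def anova_precision(spike_set: SpikeSet) -> dict:
    """Optional diagnostic: one-way between/within variance decomposition.

    Not used for the acceptance flags; the reported interday RSD is the
    pooled-replicate figure from :func:`precision_report`.
    """
    groups = [np.asarray(v, float) for v in spike_set.by_day().values()]
    grand_mean = float(spike_set.measured.mean())
    k = len(groups)
    n_total = spike_set.measured.size
    ss_between = sum(g.size * (g.mean() - grand_mean) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ms_within = ss_within / (n_total - k) if n_total > k else float("nan")
    ms_between = ss_between / (k - 1) if k > 1 else float("nan")
    n_h = n_total / k  # balanced designs only; harmonic otherwise
    var_between = max((ms_between - ms_within) / n_h, 0.0) if k > 1 else 0.0
    return {
        "within_day_sd": float(np.sqrt(ms_within)),
        "between_day_sd": float(np.sqrt(var_between)),
        "intermediate_sd": float(np.sqrt(ms_within + var_between)),
        "intermediate_rsd_percent": float(100.0 * np.sqrt(ms_within + var_between) / grand_mean),
    }
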