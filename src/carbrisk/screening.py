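"""Residue-table summaries and MRL screening.

Per-sample residue tables (sample × pesticide × concentration, with
non-detect flags) are summarised per pesticide — detection counts and
percentages, MRL exceedances, range, mean, SD and SE over the detected
samples — in the layout of a monitoring-survey distribution table.

Conventions
-----------
* Summary statistics cover detected samples only; survey ranges exclude
  non-detects.  Substitution policies (0 or LOD/2) are provided for
  sensitivity analysis of the downstream risk stage, not for the summary.
* MRL exceedance is strict (concentration > MRL), the regulatory reading.
* Percentages are exact rationals × 100 internally; display rounds to one
  decimal (21/55 → 38.1818… shown as 38.2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["ResidueSummary", "summarize_residues", "mrl_exceedances",
           "build_summary_table", "substitute_nondetects"]

#: residue CSV column names
RESIDUE_COLUMNS = ("sample_id", "pesticide", "concentration_ug_per_kg", "detected")


def _detects(records: pd.DataFrame, pesticide: str) -> pd.DataFrame:
    sub = records[records["pesticide"] == pesticide]
    if sub.empty:
        raise KeyError(f"unknown pesticide: {pesticide!r}")
    return sub


@dataclass(frozen=True)
class ResidueSummary:
    """One distribution-table row for one pesticide (detects-only stats)."""

    pesticide: str
    n_total: int
    n_detected: int
    detection_pct: float
    n_above_mrl: int | None  # None when no MRL was supplied
    pct_above_mrl: float | None
    min: float | None  # μg kg⁻¹, over detects
    max: float | None
    mean: float | None
    sd: float | None  # sample SD over detects
    se: float | None  # SD / sqrt(n_detected)
    mrl: float | None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "pesticide", "n_total", "n_detected", "detection_pct",
            "n_above_mrl", "pct_above_mrl", "min", "max", "mean", "sd", "se", "mrl")}


def summarize_residues(records: pd.DataFrame, pesticide: str,
                       mrl_table: Mapping[str, float] | None = None) -> ResidueSummary:
    """Summarise one pesticide: detection stats and range/mean/SD/SE over detects."""
    if records.empty:
        raise ValueError("empty residue table")
    sub = _detects(records, pesticide)
    n_total = int(len(sub))
    det = sub[sub["detected"].astype(bool)]
    conc = det["concentration_ug_per_kg"].to_numpy(dtype=float)
    n_det = int(len(det))
    if np.any(~(conc > 0)):
        raise ValueError("detected records must carry positive concentrations")
    mrl = None if mrl_table is None else float(mrl_table[pesticide]) if pesticide in mrl_table else None
    n_above = pct_above = None
    if mrl is not None:
        _, n_above, pct_above = mrl_exceedances(records, {pesticide: mrl}, pesticide)
    if n_det == 0:
        return ResidueSummary(pesticide, n_total, 0, 0.0, n_above, pct_above,
                              None, None, None, None, None, mrl)
    sd = float(conc.std(ddof=1)) if n_det >= 2 else 0.0
    return ResidueSummary(
        pesticide=pesticide,
        n_total=n_total,
        n_detected=n_det,
        detection_pct=100.0 * n_det / n_total,
        n_above_mrl=n_above,
        pct_above_mrl=pct_above,
        min=float(conc.min()),
        max=float(conc.max()),
        mean=float(conc.mean()),
        sd=sd,
        se=sd / np.sqrt(n_det),
        mrl=mrl,
    )


def mrl_exceedances(records: pd.DataFrame, mrl_table: Mapping[str, float],
                    pesticide: str) -> tuple[pd.Series, int, float]:
    """Flag samples strictly above the MRL.

    Returns (per-sample boolean flags indexed like the pesticide's rows,
    number above, percentage of all samples above, at full precision).
    """
    if pesticide not in mrl_table:
        raise KeyError(f"no MRL for {pesticide!r}")
    mrl = float(mrl_table[pesticide])
    sub = _detects(records, pesticide)
    conc = sub["concentration_ug_per_kg"].astype(float)
    flags = sub["detected"].astype(bool) & (conc > mrl)
    n_above = int(flags.sum())
    pct_above = 100.0 * n_above / len(sub)
    return flags, n_above, pct_above


def round_pct(p: float | None, ndigits: int = 1) -> float | None:
    """Display rounding for percentages (one decimal by convention)."""
    return None if p is None else round(p, ndigits)


def build_summary_table(records: pd.DataFrame, mrl_table: Mapping[str, float],
                        order: Sequence[str] | None = None) -> pd.DataFrame:
    """One ResidueSummary row per pesticide, full precision.

    ``order`` fixes the row order (e.g. the survey's table layout); default
    is first appearance in the records.
    """
    pesticides = list(order) if order is not None else list(
        dict.fromkeys(records["pesticide"]))
    rows = [summarize_residues(records, p, mrl_table).to_dict() for p in pesticides]
    return pd.DataFrame(rows)


def render_summary_table(table: pd.DataFrame) -> pd.DataFrame:
    """Display form: one-decimal percentages, two-decimal concentrations."""
    disp = table.copy()
    for col in ("detection_pct", "pct_above_mrl"):
        disp[col] = disp[col].map(lambda v: None if pd.isna(v) else round(float(v), 1))
    for col in ("min", "max", "mean", "sd", "se"):
        disp[col] = disp[col].map(lambda v: None if pd.isna(v) else round(float(v), 2))
    return disp


def substitute_nondetects(records: pd.DataFrame, policy: str = "exclude",
                          lod_table: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Return detect-level concentrations per pesticide for downstream fitting.

    policy: 'exclude' drops non-detects; 'zero' counts them as 0;
    'half_lod' substitutes LOD/2 (requires ``lod_table``).
    """
    out = records.copy()
    detected = out["detected"].astype(bool)
    if policy == "exclude":
        return out[detected].reset_index(drop=True)
    if policy == "zero":
        out.loc[~detected, "concentration_ug_per_kg"] = 0.0
        return out
    if policy == "half_lod":
        if lod_table is None:
            raise ValueError("half_lod substitution needs an LOD table")
        nd = ~detected
        out.loc[nd, "concentration_ug_per_kg"] = [
            lod_table[p] / 2.0 for p in out.loc[nd, "pesticide"]]
        return out
    raise ValueError("policy must be 'exclude', 'zero' or 'half_lod'")
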