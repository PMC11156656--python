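"""Probabilistic non-carcinogenic dietary risk assessment.

For each pesticide a lognormal concentration distribution is fitted by
matching the arithmetic mean and standard deviation of the residue data
(method of moments):

    sigma² = ln(1 + s²/m²),   mu = ln(m² / sqrt(m² + s²))

Monte-Carlo replicates draw a concentration C (μg kg⁻¹, converted to
mg kg⁻¹), map it to a chronic daily intake

    CDI = C · IR / BW        [mg kg⁻¹ day⁻¹]

with the consumer's ingestion rate IR (g/day, converted to kg/day) and
body weight BW (kg), and to a hazard quotient HQ = CDI / RfDo against the
chronic oral reference dose.  The 95th percentile of each pesticide's HQ
distribution is the per-compound risk metric; the hazard index is their
sum, HI = Σ HQ_p95, with HI < 1 read as no non-carcinogenic risk.

Only the concentration is stochastic; IR and BW are fixed per profile.
All unit conversions (μg→mg, g→kg) happen here and nowhere else.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from ._rand import substream

__all__ = [
    "ExposureProfile", "ADULT_PROFILE", "CHILD_PROFILE",
    "LognormalConcentrationModel", "fit_lognormal_moments",
    "cdi", "hazard_quotient", "simulate_hq", "hq_p95_closed_form",
    "hazard_index", "DietaryRiskModel", "RiskResults",
]

Z_95 = float(stats.norm.ppf(0.95))  # ≈ 1.6449
DEFAULT_N_REPLICATES = 100_000
UG_TO_MG = 1e-3
G_TO_KG = 1e-3


@dataclass(frozen=True)
class ExposureProfile:
    """Consumer profile: ingestion rate (g/day) and body weight (kg)."""

    label: str
    ingestion_rate_g_per_day: float
    body_weight_kg: float

    def __post_init__(self) -> None:
        if self.ingestion_rate_g_per_day <= 0 or self.body_weight_kg <= 0:
            raise ValueError("IR and BW must be positive")

    @property
    def intake_factor(self) -> float:
        """(IR in kg/day) / BW — multiplies a mg/kg concentration into CDI."""
        return self.ingestion_rate_g_per_day * G_TO_KG / self.body_weight_kg


ADULT_PROFILE = ExposureProfile("adult", 114.3, 70.0)
CHILD_PROFILE = ExposureProfile("child", 35.0, 15.0)


def fit_lognormal_moments(arith_mean: float, arith_sd: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with given arithmetic mean and SD."""
    if arith_mean <= 0:
        raise ValueError("arithmetic mean must be positive")
    if arith_sd < 0:
        raise ValueError("arithmetic SD must be non-negative")
    cv2 = (arith_sd / arith_mean) ** 2
    sigma = math.sqrt(math.log1p(cv2))
    mu = math.log(arith_mean) - 0.5 * sigma**2
    return mu, sigma


@dataclass(frozen=True)
class LognormalConcentrationModel:
    """Residue concentration distribution for one pesticide (μg kg⁻¹)."""

    pesticide: str
    arith_mean: float
    arith_sd: float
    mu: float = field(default=float("nan"))
    sigma: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if math.isnan(self.mu) or math.isnan(self.sigma):
            mu, sigma = fit_lognormal_moments(self.arith_mean, self.arith_sd)
            object.__setattr__(self, "mu", mu)
            object.__setattr__(self, "sigma", sigma)
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    @classmethod
    def from_samples(cls, pesticide: str, concentrations: Sequence[float],
                     log_moments: bool = False) -> "LognormalConcentrationModel":
        """Fit from detected concentrations.

        ``log_moments=True`` matches the mean/SD of log concentrations
        instead of the arithmetic moments (alternative mode).
        """
        arr = np.asarray(concentrations, dtype=float)
        if arr.size < 2 or np.any(arr <= 0):
            raise ValueError("need >= 2 positive concentrations")
        if log_moments:
            mu, sigma = float(np.log(arr).mean()), float(np.log(arr).std(ddof=1))
            m = math.exp(mu + sigma**2 / 2)
            s = m * math.sqrt(math.expm1(sigma**2))
            return cls(pesticide, m, s, mu=mu, sigma=sigma)
        return cls(pesticide, float(arr.mean()), float(arr.std(ddof=1)))

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n concentration draws in μg kg⁻¹."""
        if n < 1:
            raise ValueError("need at least one replicate")
        if self.sigma == 0:
            return np.full(n, math.exp(self.mu))
        return rng.lognormal(self.mu, self.sigma, size=n)


def cdi(concentration_mg_per_kg: float | np.ndarray,
        profile: ExposureProfile) -> float | np.ndarray:
    """Chronic daily intake (mg kg⁻¹ day⁻¹) of a mg/kg residue concentration."""
    c = np.asarray(concentration_mg_per_kg, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    out = c * profile.intake_factor
    return float(out) if out.ndim == 0 else out


def hazard_quotient(cdi_value: float | np.ndarray, rfdo: float) -> float | np.ndarray:
    """HQ = CDI / RfDo; HQ < 1 read as no non-carcinogenic risk."""
    if rfdo <= 0:
        raise ValueError("RfDo must be positive")
    out = np.asarray(cdi_value, dtype=float) / rfdo
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class HQSummary:
    """Monte-Carlo HQ distribution summary for one pesticide × profile."""

    pesticide: str
    profile: str
    hq_mean: float
    hq_p95: float
    n_replicates: int


def simulate_hq(model: LognormalConcentrationModel, profile: ExposureProfile,
                rfdo: float, n_replicates: int = DEFAULT_N_REPLICATES,
                seed: int | None = None,
                rng: np.random.Generator | None = None,
                return_draws: bool = False):
    """Monte-Carlo HQ distribution for one pesticide and profile.

    Concentrations are drawn in μg kg⁻¹ and converted to mg kg⁻¹ before the
    CDI step.  The 95th percentile is the linear-interpolation empirical
    quantile.  Pass either ``seed`` (a named substream is derived) or an
    explicit ``rng`` (e.g. for common-random-number comparisons).
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    if rng is None:
        rng = substream(0 if seed is None else seed, f"risk:{model.pesticide}")
    conc_ug = model.draw(n_replicates, rng)
    hq = hazard_quotient(cdi(conc_ug * UG_TO_MG, profile), rfdo)
    summary = HQSummary(
        pesticide=model.pesticide,
        profile=profile.label,
        hq_mean=float(np.mean(hq)),
        hq_p95=float(np.quantile(hq, 0.95, method="linear")),
        n_replicates=n_replicates,
    )
    return (summary, hq) if return_draws else summary


def hq_p95_closed_form(model: LognormalConcentrationModel,
                       profile: ExposureProfile, rfdo: float) -> float:
    """Analytic 95th-percentile HQ (quantile of a scaled lognormal).

    HQ is the lognormal concentration times a positive constant, so its
    p95 is exp(mu + z_0.95·sigma) · 10⁻³ · (IR/BW) / RfDo.
    """
    if rfdo <= 0:
        raise ValueError("RfDo must be positive")
    conc_p95_ug = math.exp(model.mu + Z_95 * model.sigma)
    return conc_p95_ug * UG_TO_MG * profile.intake_factor / rfdo


def hazard_index(per_pesticide_p95: Sequence[float]) -> float:
    """HI = Σ per-pesticide 95th-percentile HQs; HI < 1 ⇒ no risk."""
    vals = list(per_pesticide_p95)
    if not vals:
        warnings.warn("hazard index of an empty pesticide set is 0", stacklevel=2)
        return 0.0
    if any(v < 0 for v in vals):
        raise ValueError("HQ percentiles must be non-negative")
    return float(sum(vals))


class DietaryRiskModel:
    """Monte-Carlo dietary risk model over a set of pesticides and profiles.

    Parameters
    ----------
    models
        Lognormal concentration models, one per pesticide.
    rfdo_table
        Chronic oral reference doses, mg kg⁻¹ day⁻¹.  Pesticides without an
        RfDo are excluded from the assessment with a logged notice.
    profiles
        Consumer exposure profiles (default: adult and child).
    """

    def __init__(self, models: Sequence[LognormalConcentrationModel],
                 rfdo_table: Mapping[str, float],
                 profiles: Sequence[ExposureProfile] = (ADULT_PROFILE, CHILD_PROFILE)):
        if not models:
            raise ValueError("need at least one concentration model")
        for name, val in rfdo_table.items():
            if val <= 0:
                raise ValueError(f"RfDo for {name} must be positive")
        self.models = list(models)
        self.rfdo_table = dict(rfdo_table)
        self.profiles = list(profiles)
        self.excluded = [m.pesticide for m in self.models if m.pesticide not in rfdo_table]
        self.included = [m for m in self.models if m.pesticide in rfdo_table]
        if self.excluded:
            warnings.warn(
                "excluded from HI (no RfDo): " + ", ".join(self.excluded), stacklevel=2)
        if not self.included:
            raise ValueError("no pesticide has an RfDo; nothing to assess")

    @classmethod
    def from_residue_table(cls, records, rfdo_table: Mapping[str, float],
                           profiles: Sequence[ExposureProfile] = (ADULT_PROFILE, CHILD_PROFILE),
                           nondetect_policy: str = "exclude",
                           lod_table: Mapping[str, float] | None = None,
                           log_moments: bool = False) -> "DietaryRiskModel":
        """Fit concentration models from a per-sample residue DataFrame."""
        from .screening import substitute_nondetects

        usable = substitute_nondetects(records, nondetect_policy, lod_table)
        models = []
        for pesticide, grp in usable.groupby("pesticide", sort=False):
            conc = grp["concentration_ug_per_kg"].to_numpy(dtype=float)
            conc = conc[conc > 0]  # zeros from substitution cannot enter a lognormal
            if conc.size >= 2 and pesticide in rfdo_table:
                models.append(LognormalConcentrationModel.from_samples(
                    str(pesticide), conc, log_moments=log_moments))
        return cls(models, rfdo_table, profiles)

    def fit(self, n_replicates: int = DEFAULT_N_REPLICATES, seed: int = 0,
            common_random_numbers: bool = True) -> "RiskResults":
        """Run the Monte-Carlo simulation and return the results object.

        With ``common_random_numbers`` (default) the same concentration
        draws feed every profile, so profile HIs differ exactly by the
        (IR/BW) ratio — the deterministic scaling the model implies.
        """
        per_profile: dict[str, list[HQSummary]] = {p.label: [] for p in self.profiles}
        diagnostics: dict[str, float] = {}
        for model in self.included:
            rng = substream(seed, f"risk:{model.pesticide}")
            conc_ug = model.draw(n_replicates, rng)
            for profile in self.profiles:
                if not common_random_numbers:
                    rng_p = substream(seed, f"risk:{model.pesticide}:{profile.label}")
                    draws = model.draw(n_replicates, rng_p)
                else:
                    draws = conc_ug
                hq = hazard_quotient(cdi(draws * UG_TO_MG, profile),
                                     self.rfdo_table[model.pesticide])
                per_profile[profile.label].append(HQSummary(
                    pesticide=model.pesticide, profile=profile.label,
                    hq_mean=float(np.mean(hq)),
                    hq_p95=float(np.quantile(hq, 0.95, method="linear")),
                    n_replicates=n_replicates,
                ))
        # optional non-standard diagnostic: p95 of the per-replicate HQ sum
        if common_random_numbers:
            for profile in self.profiles:
                total = np.zeros(n_replicates)
                for model in self.included:
                    rng = substream(seed, f"risk:{model.pesticide}")
                    conc_ug = model.draw(n_replicates, rng)
                    total += hazard_quotient(cdi(conc_ug * UG_TO_MG, profile),
                                             self.rfdo_table[model.pesticide])
                diagnostics[f"p95_of_hq_sum:{profile.label}"] = float(
                    np.quantile(total, 0.95, method="linear"))
        return RiskResults(model=self, per_profile=per_profile,
                           n_replicates=n_replicates, seed=seed,
                           diagnostics=diagnostics)

    def closed_form_hi(self, profile: ExposureProfile) -> float:
        """Analytic HI (sum of closed-form p95 HQs) — the simulation-free check."""
        return hazard_index([
            hq_p95_closed_form(m, profile, self.rfdo_table[m.pesticide])
            for m in self.included])


@dataclass(frozen=True)
class RiskResults:
    """Per-pesticide HQ summaries and hazard indices per consumer profile."""

    model: DietaryRiskModel
    per_profile: dict
    n_replicates: int
    seed: int
    diagnostics: dict = field(default_factory=dict)

    def hazard_index(self, profile_label: str) -> float:
        return hazard_index([s.hq_p95 for s in self.per_profile[profile_label]])

    @property
    def hazard_indices(self) -> dict:
        return {label: self.hazard_index(label) for label in self.per_profile}

    def verdict(self, profile_label: str) -> str:
        return ("no non-carcinogenic risk"
                if self.hazard_index(profile_label) < 1.0
                else "potential non-carcinogenic risk")

    def summary(self) -> str:
        lines = [
            "Monte-Carlo dietary risk assessment",
            f"  replicates : {self.n_replicates}",
            f"  seed       : {self.seed}",
        ]
        if self.model.excluded:
            lines.append("  excluded (no RfDo): " + ", ".join(self.model.excluded))
        for label, summaries in self.per_profile.items():
            lines.append(f"  profile {label}:")
            for s in summaries:
                lines.append(f"    {s.pesticide:<14} HQ mean {s.hq_mean:.3e}   HQ p95 {s.hq_p95:.3e}")
            hi = self.hazard_index(label)
            lines.append(f"    HI = {hi:.3g}  ({self.verdict(label)})")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "excluded_no_rfdo": self.model.excluded,
            "profiles": {
                label: {
                    "hq": [{"pesticide": s.pesticide, "hq_mean": s.hq_mean,
                            "hq_p95": s.hq_p95} for s in summaries],
                    "hazard_index": self.hazard_index(label),
                    "verdict": self.verdict(label),
                }
                for label, summaries in self.per_profile.items()
            },
            "diagnostics": self.diagnostics,
        }

    def to_json(self, path, **stamp) -> None:
        payload = self.to_dict()
        payload.update(stamp)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    def plot_hq_distributions(self, profile_label: str, seed: int | None = None,
                              n: int = 20_000, axes=None):
        """Histograms of the per-pesticide HQ distributions for one profile."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        models = self.model.included
        profile = next(p for p in self.model.profiles if p.label == profile_label)
        if axes is None:
            ncols = 3
            nrows = -(-len(models) // ncols)
            fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3 * nrows))
            axes = np.atleast_1d(axes).ravel()
        use_seed = self.seed if seed is None else seed
        for ax, model in zip(axes, models):
            rng = substream(use_seed, f"plot:{model.pesticide}")
            _, hq = simulate_hq(model, profile, self.model.rfdo_table[model.pesticide],
                                n_replicates=n, rng=rng, return_draws=True)
            ax.hist(hq, bins=60, color="steelblue", alpha=0.8)
            ax.axvline(np.quantile(hq, 0.95), color="crimson", ls="--", label="p95")
            ax.axvline(np.mean(hq), color="black", ls=":", label="mean")
            ax.set_title(f"{model.pesticide} ({profile_label})", fontsize=9)
            ax.legend(fontsize=7)
        for ax in axes[len(models):]:
            ax.set_visible(False)
        return axes
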