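"""Adenoma-carcinoma natural histories in continuous age.

Each simulated person carries a latent inventory of adenomas.  Adenomas arise
from a non-homogeneous Poisson process whose baseline age-hazard is modulated
by a person-level frailty (risk heterogeneity); each lesion grows linearly in
diameter through the size classes 1-5 mm, 6-9 mm and >=10 mm, may transform
into preclinical cancer with a size-class-dependent annual probability, and a
transformed lesion surfaces clinically after a random sojourn time.  Survival
after diagnosis depends on the mode of detection: screen-detected cancers have
a higher cure fraction and longer mean survival than clinically detected ones.

The unscreened history is fully realised here, independent of any screening.
Screening scenarios later *replay* the same latent inventory, so the natural
history of person ``i`` is identical across every scenario that consumes it
(common random numbers).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SizeClass",
    "DetectionMode",
    "LifeTable",
    "ModelPreset",
    "Adenoma",
    "LifeHistory",
    "person_rng",
    "other_cause_death_age",
    "simulate_life_history",
    "lesion_size_class",
    "crc_death_age",
    "survival_quantile",
    "life_histories_frame",
]


class ConfigurationError(ValueError):
    """Invalid model parameters (negative hazards, probabilities outside [0,1])."""


class SizeClass(enum.IntEnum):
    """Adenoma diameter category; ordering reflects lesion advancement."""

    SMALL = 1   # 1-5 mm
    MEDIUM = 2  # 6-9 mm
    LARGE = 3   # >= 10 mm


class DetectionMode(str, enum.Enum):
    SCREEN = "screen-detected"
    CLINICAL = "clinically-detected"


# --------------------------------------------------------------------------
# RNG substreams
# --------------------------------------------------------------------------

#: Substream domains.  Natural history and screening draws come from disjoint
#: per-person streams so that replaying a scenario never perturbs the latent
#: history, and person i's history is the same for every population size.
DOMAIN_NATURAL_HISTORY = 0
DOMAIN_SCREENING = 1


def person_rng(root_seed: int, person_id: int, domain: int = DOMAIN_NATURAL_HISTORY) -> np.random.Generator:
    """Reproducible per-person substream derived from one root seed.

    Uses :class:`numpy.random.SeedSequence` spawn keys, so the stream of
    person ``i`` is independent of the population size and of any other
    person's stream.
    """
    ss = np.random.SeedSequence(entropy=int(root_seed), spawn_key=(domain, int(person_id)))
    return np.random.default_rng(ss)


# --------------------------------------------------------------------------
# Life table
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LifeTable:
    """Cohort life table: annual other-cause death probability by integer age.

    The terminal age must carry probability 1 so every person dies by
    ``max_age``.
    """

    ages: np.ndarray
    annual_death_prob: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        q = np.asarray(self.annual_death_prob, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "annual_death_prob", q)
        if ages.shape != q.shape or ages.ndim != 1 or len(ages) == 0:
            raise ConfigurationError("life table must be two equal-length 1-d columns")
        if not np.array_equal(ages, np.arange(ages[0], ages[0] + len(ages))):
            raise ConfigurationError("life-table ages must be consecutive integers")
        if np.any((q < 0) | (q > 1)):
            raise ConfigurationError("death probabilities must lie in [0, 1]")
        if q[-1] != 1.0:
            raise ConfigurationError("terminal age must have death probability 1")

    @property
    def max_age(self) -> int:
        return int(self.ages[-1]) + 1

    def survival_curve(self) -> np.ndarray:
        """P(alive at exact age x) for x = ages[0] .. max_age."""
        s = np.concatenate([[1.0], np.cumprod(1.0 - self.annual_death_prob)])
        return s

    def death_age_cdf(self) -> np.ndarray:
        """P(dead by exact age x+1) for each tabulated year x."""
        return 1.0 - self.survival_curve()[1:]

    def expected_remaining_life(self, age: float) -> float:
        """E[death age - age | alive at age], with uniform within-year deaths."""
        if age >= self.max_age:
            return 0.0
        s = self.survival_curve()
        grid = np.concatenate([self.ages.astype(float), [float(self.max_age)]])
        # mean death age conditional on surviving to `age`
        lo = int(np.floor(age)) - int(self.ages[0])
        lo = max(lo, 0)
        # probability of dying within year k (unconditional from table start)
        dens = s[:-1] - s[1:]
        mid = (grid[:-1] + grid[1:]) / 2.0
        # condition on alive at `age`: drop mass before, re-normalise the year containing `age`
        frac = age - math.floor(age)
        p_alive = s[lo] - frac * dens[lo] if lo < len(dens) else 0.0
        if p_alive <= 0:
            return 0.0
        mass = dens.copy()
        mass[:lo] = 0.0
        if frac > 0:
            # death within the remaining part of the current year, mean at its midpoint
            mass[lo] = dens[lo] * (1 - frac)
            mid = mid.copy()
            mid[lo] = (age + grid[lo + 1]) / 2.0
        return float(np.sum(mass * mid) / p_alive - age)

    def to_csv(self, path) -> None:
        pd.DataFrame({"age": self.ages, "annual_death_prob": self.annual_death_prob}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        return cls(df["age"].to_numpy(), df["annual_death_prob"].to_numpy())


def other_cause_death_age(life_table: LifeTable, rng_stream: np.random.Generator) -> float:
    """Sample an other-cause death age from the discrete-hazard life table.

    The death year is drawn by inverting the life-table CDF with a single
    uniform; a second uniform places the death within the year.
    """
    cdf = life_table.death_age_cdf()
    u = rng_stream.random()
    year = int(np.searchsorted(cdf, u, side="right"))
    year = min(year, len(cdf) - 1)
    offset = rng_stream.random()
    return float(life_table.ages[0] + year + offset)


# --------------------------------------------------------------------------
# Model preset
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SurvivalParams:
    """Cure-mixture exponential survival after CRC diagnosis.

    With probability ``cure_probability`` the cancer never kills (death occurs
    from other causes); otherwise survival is exponential with mean
    ``exp_mean_years``.
    """

    cure_probability: float
    exp_mean_years: float


@dataclass(frozen=True)
class ModelPreset:
    """One natural-history parameterisation.

    Two presets are bundled (``preset-A``, ``preset-B``) so outcome ranges can
    be reported across structurally different models, mirroring comparative
    multi-model practice.  All parameters live in YAML under
    ``crc_disrupt/data/``.
    """

    label: str
    # adenoma onset: piecewise-constant baseline hazard on age bands
    onset_age_breaks: tuple  # ascending band starts; last band extends to max age
    onset_rates: tuple       # per-year hazard within each band
    frailty_distribution: str  # "lognormal" or "gamma", mean 1
    frailty_variance: float
    # growth: linear diameter growth, lognormal per-lesion rate
    growth_rate_median: float  # mm / year (median)
    growth_rate_sigma_log: float
    initial_diameter_mm: float
    medium_threshold_mm: float
    large_threshold_mm: float
    reach_probability: float
    # transformation: annual adenoma -> preclinical-cancer probability by size class
    transform_annual_prob: tuple  # (small, medium, large)
    # sojourn: lognormal preclinical-to-clinical time
    sojourn_mean_years: float
    sojourn_sd_years: float
    # survival after diagnosis by detection mode
    survival_clinical: SurvivalParams
    survival_screen: SurvivalParams
    # FIT behaviour of the model this preset stands in for
    fit_positivity_mode: str  # "per_person" or "per_lesion"
    fit_profile_key: str      # key into the bundled FIT test-profile table
    # design band for lifetime unscreened CRC incidence (documentation + tests)
    incidence_target_band: tuple = (0.04, 0.07)

    def __post_init__(self) -> None:
        if len(self.onset_age_breaks) != len(self.onset_rates) or not self.onset_age_breaks:
            raise ConfigurationError("onset breaks and rates must have equal nonzero length")
        if any(r < 0 for r in self.onset_rates):
            raise ConfigurationError("onset hazards must be >= 0")
        if np.any(np.diff(self.onset_age_breaks) <= 0):
            raise ConfigurationError("onset age breaks must be strictly increasing")
        if self.frailty_variance < 0:
            raise ConfigurationError("frailty variance must be >= 0")
        if self.frailty_distribution not in ("lognormal", "gamma"):
            raise ConfigurationError("frailty distribution must be lognormal or gamma")
        if not (0 < self.initial_diameter_mm <= self.medium_threshold_mm <= self.large_threshold_mm):
            raise ConfigurationError("size thresholds must be ordered")
        if any(not (0 <= p <= 1) for p in self.transform_annual_prob):
            raise ConfigurationError("transformation probabilities must lie in [0, 1]")
        if not (0 <= self.reach_probability <= 1):
            raise ConfigurationError("reach probability must lie in [0, 1]")
        for sp in (self.survival_clinical, self.survival_screen):
            if not (0 <= sp.cure_probability <= 1) or sp.exp_mean_years < 0:
                raise ConfigurationError("invalid survival parameters")
        if self.fit_positivity_mode not in ("per_person", "per_lesion"):
            raise ConfigurationError("fit positivity mode must be per_person or per_lesion")

    # ---- onset hazard helpers -------------------------------------------

    def onset_cumulative_hazard(self, age: float) -> float:
        """Integral of the baseline onset hazard from age 0 to ``age``."""
        breaks = np.asarray(self.onset_age_breaks, dtype=float)
        rates = np.asarray(self.onset_rates, dtype=float)
        total = 0.0
        for i, (b, r) in enumerate(zip(breaks, rates)):
            hi = breaks[i + 1] if i + 1 < len(breaks) else math.inf
            if age <= b:
                break
            total += r * (min(age, hi) - b)
        return total

    def onset_inverse_cumulative_hazard(self, h: float) -> float:
        """Age at which the baseline cumulative hazard reaches ``h``."""
        breaks = list(self.onset_age_breaks)
        rates = list(self.onset_rates)
        acc = 0.0
        for i, (b, r) in enumerate(zip(breaks, rates)):
            hi = breaks[i + 1] if i + 1 < len(breaks) else math.inf
            seg = r * (hi - b) if math.isfinite(hi) else math.inf
            if r > 0 and acc + seg >= h:
                return b + (h - acc) / r
            acc += seg
        return math.inf

    # ---- YAML round trip -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "adenoma_onset": {
                "age_breaks": list(self.onset_age_breaks),
                "rates": list(self.onset_rates),
                "frailty": {
                    "distribution": self.frailty_distribution,
                    "variance": self.frailty_variance,
                },
            },
            "growth": {
                "rate_median_mm_per_year": self.growth_rate_median,
                "rate_sigma_log": self.growth_rate_sigma_log,
                "initial_diameter_mm": self.initial_diameter_mm,
                "medium_threshold_mm": self.medium_threshold_mm,
                "large_threshold_mm": self.large_threshold_mm,
                "reach_probability": self.reach_probability,
            },
            "transformation": {
                "annual_prob_small": self.transform_annual_prob[0],
                "annual_prob_medium": self.transform_annual_prob[1],
                "annual_prob_large": self.transform_annual_prob[2],
            },
            "sojourn": {
                "distribution": "lognormal",
                "mean_years": self.sojourn_mean_years,
                "sd_years": self.sojourn_sd_years,
            },
            "crc_survival": {
                "clinically_detected": {
                    "cure_probability": self.survival_clinical.cure_probability,
                    "exp_mean_years": self.survival_clinical.exp_mean_years,
                },
                "screen_detected": {
                    "cure_probability": self.survival_screen.cure_probability,
                    "exp_mean_years": self.survival_screen.exp_mean_years,
                },
            },
            "fit": {
                "positivity_mode": self.fit_positivity_mode,
                "profile": self.fit_profile_key,
            },
            "incidence_target_band": list(self.incidence_target_band),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelPreset":
        onset = d["adenoma_onset"]
        growth = d["growth"]
        tr = d["transformation"]
        soj = d["sojourn"]
        surv = d["crc_survival"]
        return cls(
            label=d["label"],
            onset_age_breaks=tuple(onset["age_breaks"]),
            onset_rates=tuple(onset["rates"]),
            frailty_distribution=onset["frailty"]["distribution"],
            frailty_variance=float(onset["frailty"]["variance"]),
            growth_rate_median=float(growth["rate_median_mm_per_year"]),
            growth_rate_sigma_log=float(growth["rate_sigma_log"]),
            initial_diameter_mm=float(growth["initial_diameter_mm"]),
            medium_threshold_mm=float(growth["medium_threshold_mm"]),
            large_threshold_mm=float(growth["large_threshold_mm"]),
            reach_probability=float(growth.get("reach_probability", 1.0)),
            transform_annual_prob=(
                float(tr["annual_prob_small"]),
                float(tr["annual_prob_medium"]),
                float(tr["annual_prob_large"]),
            ),
            sojourn_mean_years=float(soj["mean_years"]),
            sojourn_sd_years=float(soj["sd_years"]),
            survival_clinical=SurvivalParams(
                float(surv["clinically_detected"]["cure_probability"]),
                float(surv["clinically_detected"]["exp_mean_years"]),
            ),
            survival_screen=SurvivalParams(
                float(surv["screen_detected"]["cure_probability"]),
                float(surv["screen_detected"]["exp_mean_years"]),
            ),
            fit_positivity_mode=d["fit"]["positivity_mode"],
            fit_profile_key=d["fit"]["profile"],
            incidence_target_band=tuple(d.get("incidence_target_band", (0.04, 0.07))),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelPreset":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# --------------------------------------------------------------------------
# Per-person history
# --------------------------------------------------------------------------


@dataclass
class Adenoma:
    """One latent lesion with its realised growth/transformation draws.

    ``transform_age`` / ``clinical_dx_age`` are latent event ages: they state
    when the lesion would transform (and its cancer surface) if the lesion is
    never removed.  Screening replays consult them without mutating anything.
    Both are ``None`` when the event falls after the person's other-cause
    death age (it can then never be observed in any scenario, because
    screening cannot extend life past other-cause death).
    """

    __slots__ = ("lesion_id", "onset_age", "growth_rate", "transform_age", "sojourn_years", "clinical_dx_age", "within_reach")

    lesion_id: int
    onset_age: float
    growth_rate: float
    transform_age: Optional[float]
    sojourn_years: Optional[float]
    clinical_dx_age: Optional[float]
    within_reach: bool


@dataclass
class LifeHistory:
    """One simulated person's unscreened life course.

    The realised fields (``clinical_dx_age``, ``crc_death_age``, ``death_age``,
    ``cause``) describe the *unscreened* course, censored at other-cause
    death.  The latent adenoma list is the common-random-numbers substrate
    that every screening scenario replays.
    """

    person_id: int
    birth_year: float
    adenomas: list
    preclinical_onset_age: Optional[float]
    clinical_dx_age: Optional[float]
    crc_death_age: Optional[float]
    other_cause_death_age: float
    death_age: float
    cause: str  # "CRC" or "other"
    u_survival: float  # shared survival quantile-coupling uniform


def survival_quantile(params: SurvivalParams, u: float) -> float:
    """Inverse CDF of cure-mixture exponential survival (years after dx).

    The cure mass sits at the top of the distribution, so quantile coupling on
    a shared uniform makes screen-detected survival dominate clinically
    detected survival pathwise whenever the screen-detected parameters
    dominate component-wise.
    """
    p_fatal = 1.0 - params.cure_probability
    if u >= p_fatal:
        return math.inf
    if params.exp_mean_years == 0:
        return 0.0
    return -params.exp_mean_years * math.log1p(-u / p_fatal)


def crc_death_age(
    preset: ModelPreset,
    clinical_dx_age: float,
    detection_mode: DetectionMode,
    rng_stream: np.random.Generator,
) -> float:
    """Age at CRC death given a diagnosis age and mode of detection."""
    params = preset.survival_screen if detection_mode is DetectionMode.SCREEN else preset.survival_clinical
    u = float(rng_stream.random())
    return clinical_dx_age + survival_quantile(params, u)


def lesion_size_class(adenoma: Adenoma, age: float, preset: ModelPreset) -> SizeClass:
    """Size class of a lesion at ``age``; monotone non-decreasing in age."""
    if age < adenoma.onset_age:
        raise ValueError("size class queried before lesion onset")
    diameter = preset.initial_diameter_mm + adenoma.growth_rate * (age - adenoma.onset_age)
    if diameter >= preset.large_threshold_mm:
        return SizeClass.LARGE
    if diameter >= preset.medium_threshold_mm:
        return SizeClass.MEDIUM
    return SizeClass.SMALL


def _lognormal_mu_sigma(mean: float, sd: float) -> tuple:
    """(mu, sigma) of a lognormal with the given mean and sd."""
    if mean <= 0:
        raise ConfigurationError("lognormal mean must be > 0")
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _draw_frailty(preset: ModelPreset, rng: np.random.Generator) -> float:
    v = preset.frailty_variance
    if v == 0:
        # keep the stream aligned with the heterogeneous case
        rng.random()
        return 1.0
    if preset.frailty_distribution == "lognormal":
        sigma2 = math.log(1.0 + v)
        z = rng.standard_normal()
        return math.exp(-sigma2 / 2.0 + math.sqrt(sigma2) * z)
    # gamma with mean 1, variance v
    shape = 1.0 / v
    return float(rng.gamma(shape, v))


def _transform_time(preset: ModelPreset, growth_rate: float, e: float) -> float:
    """Time from onset to malignant transformation given Exp(1) draw ``e``.

    The transformation hazard is piecewise constant in the three size-class
    windows delimited by the growth thresholds.
    """
    p_small, p_med, p_large = preset.transform_annual_prob
    h = [-math.log1p(-p) if p < 1 else math.inf for p in (p_small, p_med, p_large)]
    if growth_rate > 0:
        t_med = (preset.medium_threshold_mm - preset.initial_diameter_mm) / growth_rate
        t_large = (preset.large_threshold_mm - preset.initial_diameter_mm) / growth_rate
    else:
        t_med = t_large = math.inf
    t_med = max(t_med, 0.0)
    t_large = max(t_large, t_med)
    knots = [0.0, t_med, t_large, math.inf]
    acc = 0.0
    for i in range(3):
        width = knots[i + 1] - knots[i]
        seg = h[i] * width if math.isfinite(width) else (math.inf if h[i] > 0 else 0.0)
        if h[i] > 0 and acc + seg >= e:
            return knots[i] + (e - acc) / h[i]
        acc += seg
    return math.inf


def simulate_life_history(
    preset: ModelPreset,
    life_table: LifeTable,
    birth_year: float,
    rng_stream: np.random.Generator,
    person_id: int = 0,
) -> LifeHistory:
    """Simulate one complete unscreened life history.

    Deterministic given ``(preset, life_table, birth_year, rng_stream)``.
    Draw order is fixed: frailty, other-cause death, lesion count, then
    per-lesion onset/growth/reach/transformation/sojourn draws, then the
    person's survival-coupling uniform.
    """
    rng = rng_stream
    frailty = _draw_frailty(preset, rng)
    ocd = other_cause_death_age(life_table, rng)

    # adenoma onsets: Poisson process with cumulative hazard Z * Lambda(age),
    # simulated on [0, ocd] via the order-statistics construction
    lam_total = frailty * preset.onset_cumulative_hazard(ocd)
    n_lesions = int(rng.poisson(lam_total)) if lam_total > 0 else 0
    mu_g, sig_g = math.log(preset.growth_rate_median), preset.growth_rate_sigma_log
    mu_s, sig_s = _lognormal_mu_sigma(preset.sojourn_mean_years, preset.sojourn_sd_years)

    adenomas = []
    if n_lesions > 0:
        u_onsets = np.sort(rng.random(n_lesions))
        for j in range(n_lesions):
            onset = preset.onset_inverse_cumulative_hazard(u_onsets[j] * lam_total / frailty)
            rate = math.exp(mu_g + sig_g * rng.standard_normal())
            reach = bool(rng.random() < preset.reach_probability)
            e = float(rng.exponential())
            t_transform = _transform_time(preset, rate, e)
            transform_age: Optional[float] = onset + t_transform
            sojourn: Optional[float] = None
            dx_age: Optional[float] = None
            if transform_age is not None and transform_age < ocd:
                sojourn = math.exp(mu_s + sig_s * rng.standard_normal())
                dx_age = transform_age + sojourn
                if dx_age >= ocd:
                    dx_age = None
            else:
                transform_age = None
            adenomas.append(
                Adenoma(
                    lesion_id=j,
                    onset_age=float(onset),
                    growth_rate=float(rate),
                    transform_age=transform_age,
                    sojourn_years=sojourn,
                    clinical_dx_age=dx_age,
                    within_reach=reach,
                )
            )

    u_surv = float(rng.random())

    # unscreened realised course
    dx_candidates = [a.clinical_dx_age for a in adenomas if a.clinical_dx_age is not None]
    preclin = min((a.transform_age for a in adenomas if a.transform_age is not None), default=None)
    clinical_dx = min(dx_candidates) if dx_candidates else None
    crc_death: Optional[float] = None
    death = ocd
    cause = "other"
    if clinical_dx is not None:
        candidate = clinical_dx + survival_quantile(preset.survival_clinical, u_surv)
        if candidate < ocd:
            crc_death = candidate
            death = candidate
            cause = "CRC"
    return LifeHistory(
        person_id=person_id,
        birth_year=float(birth_year),
        adenomas=adenomas,
        preclinical_onset_age=preclin,
        clinical_dx_age=clinical_dx,
        crc_death_age=crc_death,
        other_cause_death_age=float(ocd),
        death_age=float(death),
        cause=cause,
        u_survival=u_surv,
    )


def life_histories_frame(histories: Sequence[LifeHistory]) -> pd.DataFrame:
    """Flat one-row-per-person table of key event ages (for export)."""
    return pd.DataFrame(
        {
            "person_id": [h.person_id for h in histories],
            "birth_year": [h.birth_year for h in histories],
            "n_adenomas": [len(h.adenomas) for h in histories],
            "preclinical_onset_age": [h.preclinical_onset_age for h in histories],
            "clinical_dx_age": [h.clinical_dx_age for h in histories],
            "crc_death_age": [h.crc_death_age for h in histories],
            "other_cause_death_age": [h.other_cause_death_age for h in histories],
            "death_age": [h.death_age for h in histories],
            "cause": [h.cause for h in histories],
        }
    )
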