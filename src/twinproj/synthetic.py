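"""Synthetic birth histories and population-projection tables with known truth.

Every downstream stage of the pipeline (delivery collapse, the linear
probability model of twinning on maternal age, the country panel, the
projections) is exercised against data generated here, where the true
country baseline twinning probabilities and maternal-age effects are known
exactly.

The generator emulates the structure of retrospective birth-history exports
(one row per child, mother and interview identifiers, month-resolution
dates, a multiple-birth flag) and of medium-variant population projections
(country x year x 5-year maternal age group: births, women, age-specific
fertility rates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ages import AGE_GROUPS_5YR, AGE_GROUP_LOWER, cmc, cmc_to_year_month

__all__ = [
    "SynthParams",
    "GroundTruth",
    "generate_birth_histories",
    "generate_projection_tables",
    "true_values",
]

# Default age profile of the twinning probability: zero at the reference
# group 15-19, rising to +0.01 by the late 30s and declining only slightly
# afterward -- the age pattern reported for low-income-country birth
# histories.
DEFAULT_AGE_EFFECTS: dict[str, float] = {
    "15-19": 0.0,
    "20-24": 0.002,
    "25-29": 0.004,
    "30-34": 0.007,
    "35-39": 0.010,
    "40-44": 0.009,
    "45-49": 0.008,
}

# Default maternal-age mix of deliveries: a high-fertility schedule with an
# early-20s peak, typical of the surveyed populations.
DEFAULT_FERTILITY_SCHEDULE: dict[str, float] = {
    "15-19": 0.12,
    "20-24": 0.25,
    "25-29": 0.24,
    "30-34": 0.18,
    "35-39": 0.13,
    "40-44": 0.06,
    "45-49": 0.02,
}

# Span of per-delivery twin probabilities across countries: roughly 7 to 26
# twin deliveries per 1000, the observed range from the lowest-rate to the
# highest-rate study country.
BASELINE_SPAN = (0.0069, 0.0263)


def _default_baselines(n_countries: int) -> dict[str, float]:
    lo, hi = BASELINE_SPAN
    if n_countries == 1:
        return {"S00": lo}
    vals = np.linspace(lo, hi, n_countries)
    return {f"S{i:02d}": float(v) for i, v in enumerate(vals)}


@dataclass
class SynthParams:
    """Parameters of the synthetic-data generating process.

    Parameters
    ----------
    n_countries, mothers_per_country
        Size of the simulated survey.
    year_range
        Inclusive calendar-year interval containing all birth dates.
    country_baselines
        Per-country twin probability per delivery at the reference age
        group (the generative counterpart of the country fixed effect).
        Defaults to an even spread over 0.0069-0.0263.
    age_effects
        Additive increment to the twin probability per age category; the
        reference category 15-19 must be 0.
    fertility_schedule
        Relative intensity of deliveries by age category (normalised to
        sum to 1).
    recall_years
        Retrospective window: every birth falls within this many years
        before its mother's interview.
    seed
        Master seed; per-country substreams are derived from it so that
        countries are independent.
    mean_extra_deliveries
        Deliveries per mother are ``1 + Poisson(mean_extra_deliveries)``.
    mother_frailty_sd
        Optional mother-level multiplicative frailty (mean-1 gamma) on the
        twin probability; 0 disables it and deliveries are independent.
    projection_base_year, aging_per_year, growth_per_year, base_annual_births
        Shape of the projection tables: calendar baseline, the per-year
        fraction of birth-share mass shifted one age group older, annual
        growth of total births, and the baseline birth count per country.
    """

    n_countries: int = 3
    mothers_per_country: int = 2000
    year_range: tuple[int, int] = (1980, 2015)
    country_baselines: Mapping[str, float] | None = None
    age_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_EFFECTS)
    )
    fertility_schedule: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FERTILITY_SCHEDULE)
    )
    recall_years: int = 10
    seed: int = 0
    mean_extra_deliveries: float = 1.8
    mother_frailty_sd: float = 0.0
    projection_base_year: int = 2010
    aging_per_year: float = 0.005
    growth_per_year: float = 0.010
    base_annual_births: float = 100_000.0

    def __post_init__(self) -> None:
        if self.country_baselines is None:
            self.country_baselines = _default_baselines(self.n_countries)
        else:
            self.country_baselines = dict(self.country_baselines)
            self.n_countries = len(self.country_baselines)
        self.age_effects = dict(self.age_effects)
        self.fertility_schedule = dict(self.fertility_schedule)
        self.validate()

    # -- validation -----------------------------------------------------

    def validate(self) -> None:
        if self.n_countries < 1 or self.mothers_per_country < 1:
            raise ValueError("n_countries and mothers_per_country must be positive")
        if self.recall_years < 1:
            raise ValueError("recall_years must be a positive integer")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be an inclusive (lo, hi) interval")
        missing = set(AGE_GROUPS_5YR) - set(self.age_effects)
        if missing:
            raise ValueError(f"age_effects missing categories: {sorted(missing)}")
        if self.age_effects["15-19"] != 0.0:
            raise ValueError("age_effects['15-19'] is the reference and must be 0")
        sched = np.array([self.fertility_schedule[a] for a in AGE_GROUPS_5YR], float)
        if np.any(sched < 0) or sched.sum() <= 0:
            raise ValueError("fertility_schedule must be nonnegative with positive sum")
        for cat, eff in self.age_effects.items():
            if not -1.0 <= eff <= 1.0:
                raise ValueError(f"age_effects[{cat!r}] = {eff} outside [-1, 1]")
        max_eff = max(self.age_effects.values())
        for country, base in self.country_baselines.items():
            if not 0.0 <= base <= 1.0:
                raise ValueError(
                    f"country_baselines[{country!r}] = {base} outside [0, 1]"
                )
            if base + max_eff > 1.0:
                raise ValueError(
                    f"country {country!r}: baseline + max age effect exceeds 1"
                )

    # -- derived quantities ---------------------------------------------

    @property
    def schedule_array(self) -> np.ndarray:
        s = np.array([self.fertility_schedule[a] for a in AGE_GROUPS_5YR], float)
        return s / s.sum()

    def twin_probability(self, country: str) -> np.ndarray:
        """Per-age-group twin probability for one country."""
        base = self.country_baselines[country]
        return np.array(
            [base + self.age_effects[a] for a in AGE_GROUPS_5YR], float
        )


@dataclass
class GroundTruth:
    """The exact generative parameters plus analytic expected rates."""

    country_baselines: dict[str, float]
    age_effects: dict[str, float]
    fertility_schedule: dict[str, float]
    #: per-delivery twin fraction expected under the generated age mix
    expected_twinning_rate: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "country": c,
                "baseline": self.country_baselines[c],
                "expected_twinning_rate": self.expected_twinning_rate[c],
            }
            for c in self.country_baselines
        ]
        return pd.DataFrame(rows)

    def expected_rate_under_shares(self, country: str, shares: Mapping[str, float]) -> float:
        """Expected per-delivery twin fraction under an arbitrary age mix."""
        return float(
            sum(
                shares[a] * (self.country_baselines[country] + self.age_effects[a])
                for a in AGE_GROUPS_5YR
            )
        )


def true_values(params: SynthParams) -> GroundTruth:
    """Ground truth for a parameter set: the inputs plus analytic rates.

    The expected per-country twinning rate is the fertility-schedule-weighted
    mean of the per-age twin probabilities.
    """
    sched = params.schedule_array
    expected = {
        c: float(np.dot(sched, params.twin_probability(c)))
        for c in params.country_baselines
    }
    return GroundTruth(
        country_baselines=dict(params.country_baselines),
        age_effects=dict(params.age_effects),
        fertility_schedule={
            a: float(s) for a, s in zip(AGE_GROUPS_5YR, sched)
        },
        expected_twinning_rate=expected,
    )


def _country_rng(params: SynthParams, country_index: int) -> np.random.Generator:
    # substream per country: independent across countries, reproducible
    return np.random.default_rng([params.seed, country_index])


def generate_birth_histories(params: SynthParams) -> pd.DataFrame:
    """Simulate a retrospective birth-history table (one row per child).

    Each mother receives an interview date and ``1 + Poisson`` deliveries at
    month-resolution dates inside the recall window. Delivery maternal-age
    categories are drawn from the fertility schedule (sorted within mother
    so age increases with parity), exact ages uniformly within category, and
    each delivery is a twin delivery with probability
    ``baseline + age_effect``; twin deliveries emit two child rows sharing
    the mother and birth date, both flagged as multiple.
    """
    y0, y1 = params.year_range
    lo_cmc = int(cmc(y0, 1))
    hi_cmc = int(cmc(y1, 12))
    window = params.recall_years * 12
    iv_lo = min(lo_cmc + window, hi_cmc)  # keep births >= start of year_range

    frames = []
    for ci, country in enumerate(params.country_baselines):
        rng = _country_rng(params, ci)
        n_m = params.mothers_per_country
        interview = rng.integers(iv_lo, hi_cmc + 1, n_m)
        n_del = 1 + rng.poisson(params.mean_extra_deliveries, n_m)
        total = int(n_del.sum())
        mother = np.repeat(np.arange(n_m), n_del)

        # dates: uniform within the recall window, sorted within mother;
        # distinct deliveries of a mother must fall in distinct months, or
        # the delivery collapse would read them as a false twin delivery
        offsets = rng.integers(1, window + 1, total)
        for _ in range(64):
            key = mother.astype(np.int64) * (window + 1) + offsets
            _, first = np.unique(key, return_index=True)
            dup = np.ones(total, dtype=bool)
            dup[first] = False
            if not dup.any():
                break
            offsets[dup] = rng.integers(1, window + 1, int(dup.sum()))
        birth = interview[mother] - offsets
        order = np.lexsort((birth, mother))
        birth = birth[order]

        # ages: iid categories from the schedule, sorted within mother so
        # age increases with birth order
        cat_idx = rng.choice(len(AGE_GROUPS_5YR), total, p=params.schedule_array)
        age = AGE_GROUP_LOWER[cat_idx] + rng.integers(0, 5, total)
        age = age[np.lexsort((age, mother))]
        cat_idx = (age - 15) // 5

        starts = np.concatenate([[0], np.cumsum(n_del)[:-1]])
        parity = np.arange(total) - np.repeat(starts, n_del) + 1

        probs = params.twin_probability(country)[cat_idx]
        if params.mother_frailty_sd > 0:
            shape = 1.0 / params.mother_frailty_sd**2
            frailty = rng.gamma(shape, 1.0 / shape, n_m)
            probs = np.clip(probs * frailty[mother], 0.0, 1.0)
        twin = rng.random(total) < probs

        education = rng.choice(3, n_m, p=[0.4, 0.4, 0.2])

        # expand twin deliveries into two child rows
        reps = np.where(twin, 2, 1)
        idx = np.repeat(np.arange(total), reps)
        by, bm = cmc_to_year_month(birth[idx])
        iy, im = cmc_to_year_month(interview[mother][idx])
        frames.append(
            pd.DataFrame(
                {
                    "country": country,
                    "mother_id": mother[idx],
                    "interview_year": iy,
                    "interview_month": im,
                    "birth_year": by,
                    "birth_month": bm,
                    "maternal_age_years": age[idx],
                    "parity": parity[idx],
                    "multiple_flag": twin[idx].astype(int),
                    "education": education[mother[idx]],
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out


def _shift_older(shares: np.ndarray, frac: float) -> np.ndarray:
    """Move a fraction of each age group's mass one group older (or younger).

    ``frac`` in (-1, 1): positive shifts mass up one 5-year group, negative
    shifts it down. Mass in the edge group stays put, so shares remain a
    distribution.
    """
    out = shares.astype(float).copy()
    if frac >= 0:
        move = shares[:-1] * frac
        out[:-1] -= move
        out[1:] += move
    else:
        move = shares[1:] * (-frac)
        out[1:] -= move
        out[:-1] += move
    return out


# women age-structure baseline: a mild population-pyramid taper
_WOMEN_SHARE0 = np.array([0.17, 0.16, 0.16, 0.15, 0.13, 0.12, 0.11])
_AGG_FERTILITY = 0.15  # births per woman of reproductive age per year


def generate_projection_tables(
    params: SynthParams, scenario_years: Sequence[int]
) -> pd.DataFrame:
    """Emulate medium-variant projection extracts for the given years.

    For each country x year the table carries births, women and ASFR per
    5-year maternal age group, mutually consistent
    (``births = asfr x women``). Relative to ``projection_base_year`` the
    birth age-shares shift older at ``aging_per_year`` (capped at 0.9 total)
    and total births grow at ``growth_per_year``; the women age structure
    absorbs half of the shift so that both composition and age-specific
    fertility change over time.
    """
    if len(scenario_years) == 0:
        raise ValueError("scenario_years must be nonempty")
    sched = params.schedule_array
    rows = []
    for country in params.country_baselines:
        for year in scenario_years:
            dt = year - params.projection_base_year
            frac = float(np.clip(params.aging_per_year * dt, -0.9, 0.9))
            shares = _shift_older(sched, frac)
            total_births = params.base_annual_births * (1 + params.growth_per_year) ** dt
            births = total_births * shares
            women_total = total_births / _AGG_FERTILITY
            women = women_total * _shift_older(_WOMEN_SHARE0, frac / 2.0)
            asfr = births / women
            if np.any(births < 0) or np.any(women <= 0):
                raise ValueError("negative counts in projection table")
            for a, b, w, f in zip(AGE_GROUPS_5YR, births, women, asfr):
                rows.append(
                    {
                        "country": country,
                        "year": year,
                        "age_group": a,
                        "births": b,
                        "women": w,
                        "asfr": f,
                    }
                )
    return pd.DataFrame(rows)
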