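"""Maternal age categories and date helpers shared across the package.

The analysis works on 5-year maternal age groups 15-19 ... 45-49 (the
groups used by survey recodes and by population-projection tables alike).
Finer 1- and 2-year schemes are supported for robustness fits of the
individual-level model.
"""

from __future__ import annotations

import numpy as np

#: canonical 5-year maternal age groups, youngest (reference) first
AGE_GROUPS_5YR: tuple[str, ...] = (
    "15-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49",
)

#: lower bound of each 5-year group, aligned with AGE_GROUPS_5YR
AGE_GROUP_LOWER = np.arange(15, 50, 5)

AGE_MIN, AGE_MAX = 10, 55  # plausibility bounds for maternal age at birth


def age_scheme_groups(scheme: str) -> tuple[str, ...]:
    """Return the ordered category labels for an age-dummy scheme.

    ``"5-year"`` gives the canonical seven groups; ``"2-year"`` and
    ``"1-year"`` give finer dummies over ages 15-49 (robustness schemes).
    The first label is always the reference category.
    """
    if scheme == "5-year":
        return AGE_GROUPS_5YR
    if scheme == "2-year":
        # 15-16, 17-18, ..., 47-48, then 49 folds into the last bin
        return tuple(f"{lo}-{lo + 1}" for lo in range(15, 49, 2))
    if scheme == "1-year":
        return tuple(str(a) for a in range(15, 50))
    raise ValueError(f"unknown age scheme: {scheme!r}")


def assign_age_category(age, scheme: str = "5-year"):
    """Map maternal age(s) in years to an age-category label.

    Ages below 15 clamp into the youngest category and ages above 49 into
    the oldest: retrospective histories do contain births to mothers
    outside survey eligibility ages, and dropping them would distort
    delivery counts. Ages outside [10, 55] are treated as data errors.

    Accepts a scalar or an array; returns a scalar label or an ndarray of
    labels accordingly.
    """
    arr = np.atleast_1d(np.asarray(age))
    if not np.issubdtype(arr.dtype, np.number):
        raise TypeError("age must be numeric")
    if np.any((arr < AGE_MIN) | (arr > AGE_MAX)):
        bad = arr[(arr < AGE_MIN) | (arr > AGE_MAX)]
        raise ValueError(
            f"maternal age outside plausible range [{AGE_MIN}, {AGE_MAX}]: {bad[:5]}"
        )
    clamped = np.clip(arr, 15, 49).astype(int)
    groups = age_scheme_groups(scheme)
    if scheme == "5-year":
        idx = (clamped - 15) // 5
    elif scheme == "2-year":
        idx = np.minimum((clamped - 15) // 2, len(groups) - 1)
    else:  # 1-year
        idx = clamped - 15
    out = np.asarray(groups, dtype=object)[idx]
    return out[0] if np.isscalar(age) else out


def cmc(year, month):
    """Century-month code: months elapsed since January 1900 (DHS style)."""
    return (np.asarray(year) - 1900) * 12 + np.asarray(month)


def cmc_to_year_month(code):
    """Inverse of :func:`cmc`; returns (year, month) arrays."""
    code = np.asarray(code)
    return 1900 + (code - 1) // 12, (code - 1) % 12 + 1
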