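"""Read, filter and restructure birth histories into delivery-level records.

A retrospective birth history lists one row per *child*; the analysis unit
of the twinning model is the *delivery* (a birth event that produced one or
two children). This module applies the recall window, country/period
exclusions, and collapses children sharing a mother and birth month into
deliveries with a binary twin outcome.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ages import AGE_MAX, AGE_MIN, assign_age_category, cmc

logger = logging.getLogger(__name__)

__all__ = [
    "read_birth_records",
    "apply_recall_window",
    "apply_exclusions",
    "collapse_to_deliveries",
    "assign_age_category",
    "twinning_rate_per_1000",
]

MANDATORY_COLUMNS = (
    "country",
    "mother_id",
    "interview_year",
    "interview_month",
    "birth_year",
    "birth_month",
    "maternal_age_years",
    "parity",
    "multiple_flag",
)

_INT_COLS = (
    "interview_year",
    "interview_month",
    "birth_year",
    "birth_month",
    "maternal_age_years",
    "parity",
    "multiple_flag",
)


def read_birth_records(path) -> pd.DataFrame:
    """Read a birth-history CSV into typed records.

    Rows violating basic validity (unparseable numbers, maternal age
    outside [10, 55], birth after interview, months outside 1-12) are
    dropped and reported with their file line numbers via the module
    logger. A missing mandatory column raises immediately.
    """
    raw = pd.read_csv(path, dtype={"country": str})
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"birth-history file missing mandatory columns: {missing}")

    bad = pd.Series(False, index=raw.index)
    for col in _INT_COLS:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad |= coerced.isna()
        raw[col] = coerced
    ok = raw[~bad].copy()
    for col in _INT_COLS:
        ok[col] = ok[col].astype(int)

    invalid = (
        (ok["maternal_age_years"] < AGE_MIN)
        | (ok["maternal_age_years"] > AGE_MAX)
        | (cmc(ok["birth_year"], ok["birth_month"])
           > cmc(ok["interview_year"], ok["interview_month"]))
        | ~ok["birth_month"].between(1, 12)
        | ~ok["interview_month"].between(1, 12)
    )
    n_dropped = int(bad.sum() + invalid.sum())
    if n_dropped:
        # +2: header line plus 1-based numbering
        lines = sorted(
            [i + 2 for i in raw.index[bad]] + [i + 2 for i in ok.index[invalid]]
        )
        logger.warning(
            "read_birth_records: dropped %d malformed/invalid rows (lines %s%s)",
            n_dropped,
            lines[:10],
            "..." if len(lines) > 10 else "",
        )
    out = ok[~invalid].reset_index(drop=True)
    if "education" not in out.columns:
        out["education"] = pd.NA
    return out


def apply_recall_window(records: pd.DataFrame, window_years: float = 10) -> pd.DataFrame:
    """Retain births that occurred within ``window_years`` of the interview.

    The comparison is at month resolution: a birth is kept when
    ``interview - birth <= window_years`` (an infinite window is the
    identity).
    """
    if np.isinf(window_years):
        return records.copy()
    gap_months = cmc(records["interview_year"], records["interview_month"]) - cmc(
        records["birth_year"], records["birth_month"]
    )
    keep = gap_months <= window_years * 12
    logger.info(
        "recall window %s y: kept %d of %d records",
        window_years, int(keep.sum()), len(records),
    )
    return records[keep].reset_index(drop=True)


def apply_exclusions(
    records: pd.DataFrame,
    rules: Iterable[tuple[str, int | None]],
) -> pd.DataFrame:
    """Drop records matching exclusion rules.

    Each rule is ``(country, after_year)``: with ``after_year=None`` every
    record of that country is removed; otherwise only births *after* that
    year (``birth_year > after_year``, so the threshold year itself is
    retained). Rules naming absent countries warn and are skipped.
    """
    drop = pd.Series(False, index=records.index)
    present = set(records["country"].unique())
    for country, after_year in rules:
        if country not in present:
            logger.warning("exclusion rule names absent country %r; skipped", country)
            continue
        if after_year is None:
            hit = records["country"] == country
        else:
            hit = (records["country"] == country) & (
                records["birth_year"] > after_year
            )
        logger.info(
            "exclusion (%s, %s): removed %d records", country, after_year, int(hit.sum())
        )
        drop |= hit
    return records[~drop].reset_index(drop=True)


def collapse_to_deliveries(records: pd.DataFrame, age_scheme: str = "5-year") -> pd.DataFrame:
    """Collapse child records into deliveries with a binary twin outcome.

    Children sharing (country, mother_id, birth year+month) form one
    delivery; the delivery is a twin delivery when it has >= 2 children *or*
    any child carries the multiple-birth flag (a flagged child whose co-twin
    is unlisted still marks a twin delivery). More than four children at one
    date is flagged as a data anomaly but still collapsed with twin = 1.

    Idempotent: applying it to its own output is the identity (each output
    row is one delivery).
    """
    if len(records) == 0:
        return pd.DataFrame(
            columns=[
                "country", "mother_id", "birth_year", "birth_month",
                "maternal_age_at_birth", "age_category", "parity", "twin",
            ]
        )
    # accept either the child-level schema or our own delivery-level output
    flag_col = "multiple_flag" if "multiple_flag" in records.columns else "twin"
    age_col = (
        "maternal_age_years"
        if "maternal_age_years" in records.columns
        else "maternal_age_at_birth"
    )
    keys = ["country", "mother_id", "birth_year", "birth_month"]
    grouped = records.groupby(keys, sort=False)
    agg = grouped.agg(
        n_children=(flag_col, "size"),
        any_flag=(flag_col, "max"),
        maternal_age_at_birth=(age_col, "first"),
        parity=("parity", "min"),
    ).reset_index()
    anomalies = agg["n_children"] > 4
    if anomalies.any():
        logger.warning(
            "collapse_to_deliveries: %d deliveries with >4 children flagged as anomalies",
            int(anomalies.sum()),
        )
    agg["twin"] = ((agg["n_children"] >= 2) | (agg["any_flag"] >= 1)).astype(int)
    agg["age_category"] = assign_age_category(
        agg["maternal_age_at_birth"].to_numpy(), age_scheme
    )
    out = agg[
        [
            "country", "mother_id", "birth_year", "birth_month",
            "maternal_age_at_birth", "age_category", "parity", "twin",
        ]
    ].reset_index(drop=True)
    return out


def twinning_rate_per_1000(deliveries: pd.DataFrame) -> pd.Series:
    """Observed twin deliveries per 1000 deliveries, by country."""
    g = deliveries.groupby("country")["twin"]
    return 1000.0 * g.mean()
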