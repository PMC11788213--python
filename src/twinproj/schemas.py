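"""Delimited-text schemas for pipeline inputs, with validation.

Three normalised CSV schemas are consumed:

* ``birth_history`` -- one row per child: country (ISO3-style code),
  mother_id, interview_year, interview_month, birth_year, birth_month,
  maternal_age_years, parity, multiple_flag (0/1), education (0/1/2,
  optional).
* ``projection`` -- one row per country x year x 5-year age group: country,
  year, age_group ("15-19" ... "45-49"), births, women (optional), asfr
  (optional).
* ``covariates`` -- country, year, gdp_per_capita,
  share_primary_education.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ages import AGE_GROUPS_5YR, AGE_MAX, AGE_MIN

__all__ = ["SCHEMAS", "ValidationReport", "validate_schemas"]

SCHEMAS: dict[str, dict] = {
    "birth_history": {
        "required": [
            "country", "mother_id", "interview_year", "interview_month",
            "birth_year", "birth_month", "maternal_age_years", "parity",
            "multiple_flag",
        ],
        "optional": ["education"],
    },
    "projection": {
        "required": ["country", "year", "age_group", "births"],
        "optional": ["women", "asfr"],
    },
    "covariates": {
        "required": ["country", "year", "gdp_per_capita", "share_primary_education"],
        "optional": [],
    },
}


@dataclass
class ValidationReport:
    """Outcome of a schema check; at most the first 10 violations are kept."""

    schema: str
    path: str
    n_rows: int
    violations: list[tuple[int | None, str]] = field(default_factory=list)
    n_violations: int = 0

    @property
    def ok(self) -> bool:
        return self.n_violations == 0

    def __str__(self) -> str:  # pragma: no cover - formatting
        if self.ok:
            return f"{self.path}: {self.n_rows} rows, schema {self.schema!r} OK"
        lines = [
            f"{self.path}: {self.n_violations} violations against schema {self.schema!r}:"
        ]
        for line, msg in self.violations:
            where = f"line {line}" if line is not None else "file"
            lines.append(f"  {where}: {msg}")
        return "\n".join(lines)


def _add(report: ValidationReport, line: int | None, msg: str) -> None:
    report.n_violations += 1
    if len(report.violations) < 10:
        report.violations.append((line, msg))


def _lines(index) -> list[int]:
    # +2: CSV header plus 1-based numbering
    return [int(i) + 2 for i in index]


def validate_schemas(path, schema_name: str) -> ValidationReport:
    """Check a CSV file against a named schema.

    Verifies column presence, types and ranges; row-level findings carry
    file line numbers (header = line 1). Only the first 10 violations are
    retained in the report (the total count is exact).
    """
    if schema_name not in SCHEMAS:
        raise ValueError(f"unknown schema {schema_name!r}; one of {sorted(SCHEMAS)}")
    df = pd.read_csv(path)
    report = ValidationReport(schema=schema_name, path=str(path), n_rows=len(df))
    spec = SCHEMAS[schema_name]
    missing = [c for c in spec["required"] if c not in df.columns]
    for col in missing:
        _add(report, None, f"missing mandatory column {col!r}")
    if missing:
        return report

    def numeric(col):
        return pd.to_numeric(df[col], errors="coerce")

    if schema_name == "birth_history":
        for col in SCHEMAS["birth_history"]["required"][2:]:
            vals = numeric(col)
            for ln in _lines(df.index[vals.isna()]):
                _add(report, ln, f"non-numeric value in {col!r}")
        age = numeric("maternal_age_years")
        for ln in _lines(df.index[(age < AGE_MIN) | (age > AGE_MAX)]):
            _add(report, ln, f"maternal_age_years outside [{AGE_MIN}, {AGE_MAX}]")
        for col in ("birth_month", "interview_month"):
            m = numeric(col)
            for ln in _lines(df.index[m.notna() & ~m.between(1, 12)]):
                _add(report, ln, f"{col} outside 1-12")
        flag = numeric("multiple_flag")
        for ln in _lines(df.index[flag.notna() & ~flag.isin([0, 1])]):
            _add(report, ln, "multiple_flag not 0/1")
        b_cmc = (numeric("birth_year") - 1900) * 12 + numeric("birth_month")
        i_cmc = (numeric("interview_year") - 1900) * 12 + numeric("interview_month")
        late = b_cmc > i_cmc  # NaN comparisons are False
        for ln in _lines(df.index[late]):
            _add(report, ln, "birth date after interview date")

    elif schema_name == "projection":
        births = numeric("births")
        for ln in _lines(df.index[births.isna() | (births < 0)]):
            _add(report, ln, "births missing or negative")
        bad_group = ~df["age_group"].isin(AGE_GROUPS_5YR)
        for ln in _lines(df.index[bad_group]):
            _add(report, ln, f"age_group not one of {AGE_GROUPS_5YR}")
        if "share" in df.columns:
            sums = df.groupby(["country", "year"])["share"].sum()
            for (c, y), s in sums.items():
                if abs(s - 1.0) > 1e-6:
                    _add(report, None, f"age shares for {c} {y} sum to {s:.6f}, not 1")
        complete = df.groupby(["country", "year"])["age_group"].nunique()
        for (c, y), n in complete.items():
            if n < len(AGE_GROUPS_5YR):
                _add(report, None, f"{c} {y}: only {n} of {len(AGE_GROUPS_5YR)} age groups present")
        if "women" in df.columns and "asfr" in df.columns:
            w, f, b = numeric("women"), numeric("asfr"), births
            mask = w.notna() & f.notna() & b.notna() & (b > 0)
            rel = np.abs(w[mask] * f[mask] - b[mask]) / b[mask]
            for ln in _lines(rel.index[rel > 0.005]):
                _add(report, ln, "births != asfr x women beyond 0.5%")

    elif schema_name == "covariates":
        share = numeric("share_primary_education")
        for ln in _lines(df.index[share.notna() & ~share.between(0, 1)]):
            _add(report, ln, "share_primary_education outside [0, 1]")
        gdp = numeric("gdp_per_capita")
        for ln in _lines(df.index[gdp.notna() & (gdp < 0)]):
            _add(report, ln, "negative gdp_per_capita")

    return report
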