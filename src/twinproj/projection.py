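"""Projection of twinning rates and twin-birth counts onto future age mixes.

Starting identities: the number of births ``b`` in a population-year is the
number of deliveries plus the number of twin deliveries (each twin delivery
contributes two children),

    b = d + dt,        tr = dt / d,        =>        d = b / (1 + tr).

Given a projected birth count ``b`` and posterior draws of the country
twinning rate ``tr``, deliveries ``d`` follow; they are partitioned across
maternal age groups by the projected age shares; the expected twin
deliveries are ``dt = sum_a d_a * p_{c,a}`` with ``p_{c,a}`` the posterior
age-specific twin probabilities (country effect + age effect). Scenario
results are summarised as posterior medians and interquartile ranges, and
changes versus the baseline year are reported per draw as percentages.

Counterfactual substitution over the factors behind a change (population
scale, women's age composition, age-specific fertility) decomposes rate and
count changes into named contributions.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ages import AGE_GROUPS_5YR
from .propensity import AgeEffectPosterior, CountryRatePosterior

logger = logging.getLogger(__name__)

__all__ = [
    "ProjectionInput",
    "PosteriorBundle",
    "ProjectionResult",
    "DecompositionResult",
    "deliveries_from_births",
    "partition_deliveries",
    "age_probabilities",
    "expected_twin_deliveries",
    "run_scenario",
    "pct_change",
    "twin_sibling_ratio",
    "decompose_change",
]


# ---------------------------------------------------------------------------
# inputs
# ---------------------------------------------------------------------------

@dataclass
class ProjectionInput:
    """One country-year extract of a population projection.

    ``age_shares`` is the distribution of births across 5-year maternal age
    groups (sums to 1); ``women`` and ``asfr`` are optional but required for
    source decompositions, and must satisfy ``sum(women * asfr) == births``
    within 0.5%.
    """

    country: str
    year: int
    births: float
    age_shares: pd.Series
    women: pd.Series | None = None
    asfr: pd.Series | None = None

    def __post_init__(self) -> None:
        self.age_shares = self.age_shares.reindex(AGE_GROUPS_5YR)
        if self.age_shares.isna().any():
            raise ValueError("age_shares must cover all 5-year groups 15-49")
        if self.births < 0:
            raise ValueError("births must be nonnegative")
        if np.any(self.age_shares.to_numpy() < 0):
            raise ValueError("negative age share")
        if abs(float(self.age_shares.sum()) - 1.0) > 1e-9:
            raise ValueError(
                f"age shares must sum to 1 (got {float(self.age_shares.sum()):.12f})"
            )
        if self.women is not None and self.asfr is not None:
            implied = float((self.women.reindex(AGE_GROUPS_5YR)
                             * self.asfr.reindex(AGE_GROUPS_5YR)).sum())
            if self.births > 0 and abs(implied - self.births) > 0.005 * self.births:
                raise ValueError(
                    "women x asfr inconsistent with births "
                    f"({implied:.1f} vs {self.births:.1f})"
                )

    @classmethod
    def from_frame(cls, table: pd.DataFrame, country: str, year: int) -> "ProjectionInput":
        """Build from a long projection table (country, year, age_group, ...)."""
        sub = table[(table["country"] == country) & (table["year"] == year)]
        if len(sub) == 0:
            raise ValueError(f"no projection rows for {country!r} year {year}")
        sub = sub.set_index("age_group")
        births = sub["births"].reindex(AGE_GROUPS_5YR)
        if births.isna().any():
            raise ValueError(f"{country} {year}: missing age groups in projection table")
        total = float(births.sum())
        shares = births / total
        shares = shares / float(shares.sum())  # exact renormalisation
        women = sub["women"].reindex(AGE_GROUPS_5YR) if "women" in sub.columns else None
        asfr = sub["asfr"].reindex(AGE_GROUPS_5YR) if "asfr" in sub.columns else None
        if women is not None and women.isna().all():
            women = None
        if asfr is not None and asfr.isna().all():
            asfr = None
        return cls(country=country, year=int(year), births=total,
                   age_shares=shares, women=women, asfr=asfr)


@dataclass
class PosteriorBundle:
    """Paired posterior draws of country rates and age-specific effects.

    The same draw index is used across the two posteriors so that
    correlations propagate through the projection; ``pair_draws=False``
    breaks the pairing by a seeded permutation of the age-effect draws
    (sensitivity mode).
    """

    country_rates: CountryRatePosterior
    age_effects: AgeEffectPosterior
    pair_draws: bool = True
    permute_seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.country_rates.draws) != self.age_effects.n_draws:
            raise ValueError("country-rate and age-effect posteriors must have equal draws")
        self._perm = None
        if not self.pair_draws:
            rng = np.random.default_rng(self.permute_seed)
            self._perm = rng.permutation(self.age_effects.n_draws)

    @property
    def n_draws(self) -> int:
        return self.age_effects.n_draws

    def rate_draws(self, country: str) -> np.ndarray:
        return self.country_rates.rate_draws(country)

    def probability_draws(self, country: str, clip: bool = False) -> np.ndarray:
        p = self.age_effects.probability_draws(country, clip=clip).to_numpy()
        if self._perm is not None:
            p = p[self._perm]
        return p


# ---------------------------------------------------------------------------
# elemental operations
# ---------------------------------------------------------------------------

def deliveries_from_births(b, tr):
    """Total deliveries implied by births and the twinning rate: d = b/(1+tr)."""
    b = np.asarray(b, dtype=float)
    tr = np.asarray(tr, dtype=float)
    if np.any(b < 0):
        raise ValueError("births must be nonnegative")
    if np.any(tr >= 1) or np.any(tr < 0):
        raise ValueError("twinning rate must be a per-delivery fraction in [0, 1)")
    return b / (1.0 + tr)


def partition_deliveries(d, age_shares) -> np.ndarray:
    """Split deliveries across age groups: d_a = d * s_a, summing to d exactly.

    ``d`` may be a scalar or a draw vector; the result gains a trailing age
    axis. The last group absorbs the (at most one-ulp) float residual so the
    partition sums to ``d`` exactly.
    """
    s = np.asarray(age_shares, dtype=float)
    if np.any(s < 0):
        raise ValueError("negative age share")
    if abs(s.sum() - 1.0) > 1e-9:
        raise ValueError("age shares must sum to 1")
    d = np.asarray(d, dtype=float)
    out = d[..., None] * s
    # last group is the exact remainder, so the re-summed total is d itself
    out[..., -1] = d - out[..., :-1].sum(axis=-1)
    return out


def _finalize_probs(
    raw: np.ndarray,
    mode: str,
    baseline_shares: pd.Series | None = None,
    tr_draws: np.ndarray | None = None,
) -> np.ndarray:
    if mode == "raw":
        return np.clip(raw, 0.0, 1.0)
    if mode != "recentered":
        raise ValueError(f"unknown mode {mode!r}")
    if baseline_shares is None or tr_draws is None:
        raise ValueError("recentered mode needs baseline_shares and tr_draws")
    s = baseline_shares.reindex(AGE_GROUPS_5YR).to_numpy(dtype=float)
    implied = raw @ s
    shift = np.asarray(tr_draws, dtype=float) - implied
    if np.abs(shift).max(initial=0.0) > 0.01:
        logger.info(
            "recentering shifted age probabilities by up to %.4f", float(np.abs(shift).max())
        )
    adj = raw + shift[:, None]
    clipped = np.clip(adj, 0.0, 1.0)
    n_clip = int((clipped != adj).sum())
    if n_clip:
        logger.warning("age_probabilities: clipped %d draw-cells into [0, 1]", n_clip)
    return clipped


def age_probabilities(
    posterior: AgeEffectPosterior,
    country: str,
    mode: str = "recentered",
    baseline_shares: pd.Series | None = None,
    tr_draws: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-draw twin probabilities by age group for one country.

    ``mode="raw"`` returns ``gamma_c + beta_a`` per draw, clipped into
    [0, 1]. ``mode="recentered"`` shifts each draw so that the
    baseline-share-weighted mean equals the same draw's country rate
    ``tr`` (the closure used when the age-free rate drives Eq (5)); it
    requires ``baseline_shares`` and ``tr_draws``.
    """
    raw = posterior.probability_draws(country, clip=False).to_numpy()
    return pd.DataFrame(
        _finalize_probs(raw, mode, baseline_shares, tr_draws),
        columns=list(AGE_GROUPS_5YR),
    )


def expected_twin_deliveries(d_a, p_a):
    """Expected twin deliveries by age and total: dt_a = d_a * p_a.

    Returns ``(dt_total, dt_by_age, implied_tr)`` where
    ``implied_tr = dt / d``. DataFrame inputs must share age-group columns.
    """
    if isinstance(d_a, pd.DataFrame) and isinstance(p_a, pd.DataFrame):
        if list(d_a.columns) != list(p_a.columns):
            raise ValueError("mismatched age groups between deliveries and probabilities")
    da = np.asarray(d_a, dtype=float)
    pa = np.asarray(p_a, dtype=float)
    if da.shape[-1] != pa.shape[-1]:
        raise ValueError("mismatched age groups between deliveries and probabilities")
    dt_a = da * pa
    dt = dt_a.sum(axis=-1)
    d = da.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tr = np.where(d > 0, dt / d, np.nan)
    return dt, dt_a, tr


def pct_change(scenario_value, baseline_value):
    """Relative change in percent, 100 * (scenario - baseline) / baseline.

    Computed element-wise (per posterior draw, before any summarising).
    """
    b = np.asarray(baseline_value, dtype=float)
    if np.any(b <= 0):
        raise ValueError("baseline value must be positive for a percent change")
    return 100.0 * (np.asarray(scenario_value, dtype=float) - b) / b


def twin_sibling_ratio(tr):
    """Children per one child with a twin sibling: (1 + tr) / (2 tr).

    Of ``b = d (1 + tr)`` children, ``2 d tr`` are members of a twin pair,
    so one child in every ``(1 + tr) / (2 tr)`` has a twin sibling. At
    ``tr = 0`` the ratio is infinite (flagged via a warning).
    """
    arr = np.asarray(tr, dtype=float)
    if np.any(arr < 0) or np.any(arr >= 1):
        raise ValueError("twinning rate must be a fraction in [0, 1)")
    if np.any(arr == 0):
        logger.warning("twin_sibling_ratio at tr=0 is infinite")
    with np.errstate(divide="ignore"):
        out = (1.0 + arr) / (2.0 * arr)
    return float(out) if np.isscalar(tr) else out


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def _summary(draws: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.percentile(draws, [25, 50, 75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3)}


@dataclass
class ProjectionResult:
    """Posterior projection of one scenario against its baseline year."""

    country: str
    baseline_year: int
    scenario_year: int
    draws: pd.DataFrame
    dt_by_age: pd.DataFrame
    flags: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = {}
        for col in self.draws.columns:
            vals = self.draws[col].to_numpy()
            vals = vals[np.isfinite(vals)]
            rows[col] = _summary(vals) if len(vals) else {"median": np.nan, "q1": np.nan, "q3": np.nan}
        return pd.DataFrame(rows).T


def _scenario_draws(
    b: float,
    shares: pd.Series,
    tr_draws: np.ndarray,
    p_draws: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    d = deliveries_from_births(b, np.clip(tr_draws, 0.0, 0.999999))
    d_a = partition_deliveries(d, shares.reindex(AGE_GROUPS_5YR).to_numpy())
    dt, dt_a, tr_implied = expected_twin_deliveries(d_a, p_draws)
    return d, dt, dt_a, tr_implied


def run_scenario(
    baseline: ProjectionInput,
    scenario: ProjectionInput,
    posteriors: PosteriorBundle,
    use_scenario_births: bool = True,
    use_scenario_shares: bool = True,
    mode: str = "recentered",
) -> ProjectionResult:
    """Project twin deliveries under a scenario and compare to baseline.

    Per posterior draw: the country rate ``tr`` gives total deliveries via
    ``d = b / (1 + tr)`` with the flag-selected births ``b``; deliveries are
    partitioned by the flag-selected age shares; age-specific probabilities
    (recentered by default so the baseline-share-weighted mean matches the
    draw's ``tr``) give expected twin deliveries. Percent changes in the
    implied twinning rate and in twin-delivery counts are computed per draw
    and summarised as median and Q1-Q3.
    """
    if baseline.country != scenario.country:
        raise ValueError(
            f"baseline and scenario countries differ: {baseline.country!r} vs {scenario.country!r}"
        )
    country = baseline.country
    tr_draws = posteriors.rate_draws(country)
    p_draws = _finalize_probs(
        posteriors.probability_draws(country, clip=False),
        mode,
        baseline_shares=baseline.age_shares,
        tr_draws=tr_draws,
    )

    b_scn = scenario.births if use_scenario_births else baseline.births
    s_scn = scenario.age_shares if use_scenario_shares else baseline.age_shares

    d0, dt0, _, tr0 = _scenario_draws(baseline.births, baseline.age_shares, tr_draws, p_draws)
    d1, dt1, dt1_a, tr1 = _scenario_draws(b_scn, s_scn, tr_draws, p_draws)

    with np.errstate(divide="ignore"):
        sib0 = (1.0 + tr0) / (2.0 * tr0)
        sib1 = (1.0 + tr1) / (2.0 * tr1)
    draws = pd.DataFrame(
        {
            "tr": tr_draws,
            "d": d1,
            "dt": dt1,
            "implied_tr": tr1,
            "d_baseline": d0,
            "dt_baseline": dt0,
            "implied_tr_baseline": tr0,
            "pct_change_rate": pct_change(tr1, tr0),
            "pct_change_count": pct_change(dt1, dt0),
            "children_per_twin_sibling": sib1,
            "children_per_twin_sibling_baseline": sib0,
        }
    )
    return ProjectionResult(
        country=country,
        baseline_year=baseline.year,
        scenario_year=scenario.year,
        draws=draws,
        dt_by_age=pd.DataFrame(dt1_a, columns=list(AGE_GROUPS_5YR)),
        flags={
            "use_scenario_births": use_scenario_births,
            "use_scenario_shares": use_scenario_shares,
            "mode": mode,
        },
    )


# ---------------------------------------------------------------------------
# counterfactual decomposition
# ---------------------------------------------------------------------------

@dataclass
class DecompositionResult:
    """Counterfactual-substitution decomposition of a change.

    ``sequential`` substitutes factors one at a time in the listed order
    (contributions sum to the total exactly); ``symmetrized`` averages the
    sequential contributions over every substitution order (a Shapley
    decomposition; also sums to the total exactly); ``pure`` holds all other
    factors at baseline, and ``interaction = total - sum(pure)`` so pure
    contributions plus the interaction equal the total exactly. All terms
    are per posterior draw.
    """

    factors: tuple[str, ...]
    total: np.ndarray
    sequential: dict[str, np.ndarray]
    symmetrized: dict[str, np.ndarray]
    pure: dict[str, np.ndarray]
    interaction: np.ndarray

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.factors:
            rows.append({"term": f"sequential:{name}", **_summary(self.sequential[name])})
            rows.append({"term": f"symmetrized:{name}", **_summary(self.symmetrized[name])})
            rows.append({"term": f"pure:{name}", **_summary(self.pure[name])})
        rows.append({"term": "interaction", **_summary(self.interaction)})
        rows.append({"term": "total", **_summary(self.total)})
        return pd.DataFrame(rows).set_index("term")


def _decompose(
    value_fn: Callable[[Mapping[str, object]], np.ndarray],
    baseline_factors: Mapping[str, object],
    scenario_factors: Mapping[str, object],
) -> DecompositionResult:
    names = tuple(baseline_factors)
    k = len(names)
    corners: dict[frozenset, np.ndarray] = {}
    for r in range(k + 1):
        for subset in itertools.combinations(names, r):
            fs = frozenset(subset)
            args = {
                n: (scenario_factors[n] if n in fs else baseline_factors[n])
                for n in names
            }
            corners[fs] = np.asarray(value_fn(args), dtype=float)
    full = frozenset(names)
    total = corners[full] - corners[frozenset()]

    sequential = {}
    acc: frozenset = frozenset()
    for n in names:
        nxt = acc | {n}
        sequential[n] = corners[nxt] - corners[acc]
        acc = nxt

    symmetrized = {n: np.zeros_like(total) for n in names}
    denom = math.factorial(k)
    for order in itertools.permutations(names):
        acc = frozenset()
        for n in order:
            nxt = acc | {n}
            symmetrized[n] = symmetrized[n] + (corners[nxt] - corners[acc]) / denom
            acc = nxt

    pure = {n: corners[frozenset({n})] - corners[frozenset()] for n in names}
    interaction = total - sum(pure.values())
    return DecompositionResult(
        factors=names,
        total=total,
        sequential=sequential,
        symmetrized=symmetrized,
        pure=pure,
        interaction=interaction,
    )


def decompose_change(
    baseline: ProjectionInput,
    scenario: ProjectionInput,
    posteriors: PosteriorBundle,
    mode: str = "recentered",
) -> dict[str, DecompositionResult]:
    """Decompose rate and count changes into named sources.

    The implied twinning rate depends on the maternal age mix of births,
    ``s_a proportional to W_a * ASFR_a``; its change decomposes into an
    age-specific-fertility (ASFR) contribution and a women's-age-composition
    contribution. The twin-delivery count additionally scales with total
    births, giving a three-way split (scale, composition, ASFR). Requires
    ``women`` and ``asfr`` on both inputs.
    """
    for inp, label in ((baseline, "baseline"), (scenario, "scenario")):
        if inp.women is None or inp.asfr is None:
            raise ValueError(
                f"{label} input lacks women/asfr columns; source decomposition "
                "needs them -- use run_scenario for share-only comparisons"
            )
    country = baseline.country
    tr_draws = posteriors.rate_draws(country)
    p_draws = _finalize_probs(
        posteriors.probability_draws(country, clip=False),
        mode,
        baseline_shares=baseline.age_shares,
        tr_draws=tr_draws,
    )

    def shares_from(w: pd.Series, f: pd.Series) -> np.ndarray:
        prod = (w.reindex(AGE_GROUPS_5YR) * f.reindex(AGE_GROUPS_5YR)).to_numpy(float)
        return prod / prod.sum()

    def implied_rate(args: Mapping[str, object]) -> np.ndarray:
        s = shares_from(args["composition"], args["asfr"])
        # tr implied by the age mix alone; births scale cancels
        d = deliveries_from_births(1.0, np.clip(tr_draws, 0.0, 0.999999))
        d_a = d[..., None] * s
        _, _, tr = expected_twin_deliveries(d_a, p_draws)
        return tr

    def twin_count(args: Mapping[str, object]) -> np.ndarray:
        s = shares_from(args["composition"], args["asfr"])
        d = deliveries_from_births(args["scale"], np.clip(tr_draws, 0.0, 0.999999))
        d_a = d[..., None] * s
        dt, _, _ = expected_twin_deliveries(d_a, p_draws)
        return dt

    rate = _decompose(
        implied_rate,
        {"asfr": baseline.asfr, "composition": baseline.women},
        {"asfr": scenario.asfr, "composition": scenario.women},
    )
    count = _decompose(
        twin_count,
        {
            "scale": baseline.births,
            "composition": baseline.women,
            "asfr": baseline.asfr,
        },
        {
            "scale": scenario.births,
            "composition": scenario.women,
            "asfr": scenario.asfr,
        },
    )
    return {"rate": rate, "count": count}
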