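"""Individual-level twinning propensity models.

The central model is a linear probability model (LPM) of the binary twin
outcome of a delivery on maternal-age-category dummies plus country fixed
effects:

    twin[i,c] = beta[age(i)] + gamma[c] + eps[i,c]

OLS on this design gives coefficients on the probability scale; with a flat
prior the Bayesian posterior of the coefficients coincides with the OLS
sampling distribution, so "posterior draws" are multivariate-normal draws
centred at the estimates with the (heteroskedasticity-robust) coefficient
covariance. A companion age-free model -- country indicators only -- yields
each country's average twinning rate, whose point estimates are exactly the
observed per-country twin fractions.

Estimators follow the scikit-learn protocol (``fit``, ``predict``,
``get_params``); the module-level functions are thin wrappers over them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from statsmodels.stats.meta_analysis import combine_effects

from .ages import age_scheme_groups, assign_age_category

logger = logging.getLogger(__name__)

__all__ = [
    "LpmFit",
    "AgeEffectPosterior",
    "CountryRatePosterior",
    "MetaResult",
    "TwinningPropensityLPM",
    "CountryTwinningRate",
    "fit_lpm",
    "fit_country_rates",
    "draw_posterior",
    "fit_per_country",
    "meta_analyze",
]

_COV_TYPES = {"robust": "HC1", "classical": "nonrobust", "cluster": "cluster"}


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class LpmFit:
    """Point estimates and covariance of the twinning LPM.

    ``age_coefficients`` includes the reference category at exactly 0;
    ``coefficient_covariance`` covers the *estimated* parameters only
    (country effects and non-reference age coefficients), with labels
    ``country:<code>`` and ``age:<category>``.
    """

    age_scheme: str
    age_coefficients: pd.Series
    country_effects: pd.Series
    residual_variance: float
    coefficient_covariance: pd.DataFrame
    n_deliveries: int
    reference_category: str
    dropped_categories: tuple[str, ...] = ()

    @property
    def param_names(self) -> list[str]:
        return list(self.coefficient_covariance.columns)

    def point_vector(self) -> pd.Series:
        vals = {}
        for c, v in self.country_effects.items():
            vals[f"country:{c}"] = v
        for a, v in self.age_coefficients.items():
            if a != self.reference_category:
                vals[f"age:{a}"] = v
        return pd.Series(vals).reindex(self.param_names)

    def fitted_probability(self, country, age_category) -> np.ndarray:
        """Unclipped fitted twin probability for country/age pairs."""
        g = self.country_effects.reindex(np.atleast_1d(country)).to_numpy()
        b = self.age_coefficients.reindex(np.atleast_1d(age_category)).to_numpy()
        return g + b


@dataclass
class AgeEffectPosterior:
    """Joint draws of LPM parameters (flat-prior posterior).

    ``draws`` is a D x P frame whose columns match the fit's parameter
    labels. Implied probabilities are formed (and clipped into [0, 1]) only
    at consumption time; the stored draws are never clipped.
    """

    draws: pd.DataFrame
    seed: int | None
    n_draws: int
    reference_category: str
    age_scheme: str = "5-year"

    def age_effect_draws(self, category: str) -> np.ndarray:
        if category == self.reference_category:
            return np.zeros(self.n_draws)
        return self.draws[f"age:{category}"].to_numpy()

    def country_effect_draws(self, country: str) -> np.ndarray:
        col = f"country:{country}"
        if col not in self.draws.columns:
            raise KeyError(f"country {country!r} not in posterior")
        return self.draws[col].to_numpy()

    def probability_draws(self, country: str, clip: bool = True) -> pd.DataFrame:
        """Per-draw twin probability by age group: gamma_c + beta_a."""
        gamma = self.country_effect_draws(country)
        cats = age_scheme_groups(self.age_scheme)
        out = {}
        for a in cats:
            p = gamma + self.age_effect_draws(a)
            out[a] = np.clip(p, 0.0, 1.0) if clip else p
        return pd.DataFrame(out)


@dataclass
class CountryRatePosterior:
    """Draws and point estimates of per-country twinning rates (fractions)."""

    draws: pd.DataFrame  # D x countries
    point: pd.Series  # per-country observed twin fraction
    seed: int | None = None

    def rate_draws(self, country: str, clip: bool = True) -> np.ndarray:
        d = self.draws[country].to_numpy()
        return np.clip(d, 0.0, None) if clip else d

    def per_1000(self) -> pd.Series:
        return 1000.0 * self.point

    def iqr(self) -> pd.DataFrame:
        q = self.draws.quantile([0.25, 0.5, 0.75]).T
        q.columns = ["q1", "median", "q3"]
        return q


@dataclass
class MetaResult:
    """Per-country age-coefficient estimates and their pooled meta-analysis."""

    age_scheme: str
    per_country_coefficients: pd.DataFrame  # country x category
    per_country_se: pd.DataFrame
    pooled: pd.DataFrame | None = None  # category x [estimate, se, tau2, ...]


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _prepare_deliveries(X: pd.DataFrame, age_scheme: str) -> pd.DataFrame:
    X = X.reset_index(drop=True)
    if "age_category" not in X.columns or age_scheme != "5-year":
        X["age_category"] = assign_age_category(
            X["maternal_age_at_birth"].to_numpy(), age_scheme
        )
    return X


def _build_design(
    X: pd.DataFrame, age_scheme: str, year_effects: bool
) -> tuple[pd.DataFrame, str, tuple[str, ...]]:
    """Country dummies (no global intercept) + non-reference age dummies."""
    cats = age_scheme_groups(age_scheme)
    present = [c for c in cats if c in set(X["age_category"])]
    dropped = tuple(c for c in cats if c not in present)
    if dropped:
        logger.warning("empty age categories dropped from design: %s", dropped)
    if len(present) < 2:
        raise ValueError("need >= 2 populated age categories to fit the LPM")
    reference = present[0]

    cdum = pd.get_dummies(X["country"], dtype=float)
    cdum.columns = [f"country:{c}" for c in cdum.columns]
    adum = pd.get_dummies(
        pd.Categorical(X["age_category"], categories=present), dtype=float
    ).iloc[:, 1:]
    adum.columns = [f"age:{a}" for a in adum.columns]
    design = pd.concat([cdum, adum], axis=1)
    if year_effects:
        period = (X["birth_year"] // 5) * 5
        pdum = pd.get_dummies(period, dtype=float).iloc[:, 1:]
        pdum.columns = [f"period:{p}" for p in pdum.columns]
        design = pd.concat([design, pdum], axis=1)
    return design, reference, dropped


class TwinningPropensityLPM(BaseEstimator):
    """Linear probability model of twinning on maternal age + country FE.

    Parameters
    ----------
    age_scheme : {"5-year", "2-year", "1-year"}
        Granularity of the maternal-age dummies; the youngest populated
        category is the reference.
    covariance : {"robust", "classical", "cluster"}
        Coefficient covariance: HC1 sandwich (default; LPM errors are
        heteroskedastic by construction), classical OLS, or clustered by
        mother.
    year_effects : bool
        Add 5-year birth-period dummies to the design (off by default; the
        base model has static country effects).

    Attributes
    ----------
    age_coefficients_ : pd.Series
        Probability-scale age effects, reference fixed at 0.
    country_effects_ : pd.Series
        Country fixed-effect levels (probability scale).
    cov_params_ : pd.DataFrame
        Covariance of the estimated parameters.
    result_ : LpmFit
        The full fit container.
    """

    def __init__(self, age_scheme: str = "5-year", covariance: str = "robust",
                 year_effects: bool = False):
        self.age_scheme = age_scheme
        self.covariance = covariance
        self.year_effects = year_effects

    def fit(self, X: pd.DataFrame, y=None):
        if self.covariance not in _COV_TYPES:
            raise ValueError(f"unknown covariance mode {self.covariance!r}")
        X = _prepare_deliveries(X, self.age_scheme)
        if X["country"].nunique() < 1 or len(X) == 0:
            raise ValueError("no deliveries to fit")
        design, reference, dropped = _build_design(
            X, self.age_scheme, self.year_effects
        )
        yvec = X["twin"].to_numpy(dtype=float)
        model = sm.OLS(yvec, design)
        if self.covariance == "cluster":
            if "mother_id" not in X.columns:
                raise ValueError("cluster covariance requires a mother_id column")
            groups = X["country"].astype(str) + ":" + X["mother_id"].astype(str)
            res = model.fit(cov_type="cluster", cov_kwds={"groups": groups})
        else:
            res = model.fit(cov_type=_COV_TYPES[self.covariance])

        params = pd.Series(res.params, index=design.columns)
        cats = age_scheme_groups(self.age_scheme)
        age_coefs = {reference: 0.0}
        for c in cats:
            key = f"age:{c}"
            if key in params.index:
                age_coefs[c] = float(params[key])
        self.age_coefficients_ = pd.Series(
            {c: age_coefs[c] for c in cats if c in age_coefs}
        )
        self.country_effects_ = pd.Series(
            {
                name.split(":", 1)[1]: float(v)
                for name, v in params.items()
                if name.startswith("country:")
            }
        )
        self.cov_params_ = pd.DataFrame(
            np.asarray(res.cov_params()), index=design.columns, columns=design.columns
        )
        self.residual_variance_ = float(res.mse_resid)
        self.n_deliveries_ = int(len(X))
        self.reference_category_ = reference
        self.dropped_categories_ = dropped
        self.result_ = LpmFit(
            age_scheme=self.age_scheme,
            age_coefficients=self.age_coefficients_,
            country_effects=self.country_effects_,
            residual_variance=self.residual_variance_,
            coefficient_covariance=self.cov_params_,
            n_deliveries=self.n_deliveries_,
            reference_category=reference,
            dropped_categories=dropped,
        )
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Unclipped fitted twin probability per delivery row."""
        X = _prepare_deliveries(X, self.age_scheme)
        return self.result_.fitted_probability(
            X["country"].to_numpy(), X["age_category"].to_numpy()
        )

    def sample_posterior(self, n_draws: int = 2000, seed: int | None = None) -> AgeEffectPosterior:
        return draw_posterior(self.result_, n_draws=n_draws, seed=seed)


class CountryTwinningRate(BaseEstimator):
    """Age-free country twinning rates (country-indicators-only LPM).

    The OLS point estimate for each country indicator is exactly that
    country's observed twin fraction; the posterior is normal with the
    binomial (HC0) standard error sqrt(p(1-p)/n).
    """

    def fit(self, X: pd.DataFrame, y=None):
        if len(X) == 0:
            raise ValueError("no deliveries to fit")
        g = X.groupby("country")["twin"]
        self.rates_ = g.mean().astype(float)
        self.n_ = g.size()
        p = self.rates_
        self.se_ = np.sqrt(p * (1.0 - p) / self.n_)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.rates_.reindex(X["country"]).to_numpy()

    def sample_posterior(self, n_draws: int = 2000, seed: int | None = None) -> CountryRatePosterior:
        rng = np.random.default_rng(seed)
        draws = rng.normal(
            self.rates_.to_numpy(), self.se_.to_numpy(), size=(n_draws, len(self.rates_))
        )
        return CountryRatePosterior(
            draws=pd.DataFrame(draws, columns=self.rates_.index),
            point=self.rates_.copy(),
            seed=seed,
        )


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_lpm(
    deliveries: pd.DataFrame,
    age_scheme: str = "5-year",
    covariance: str = "robust",
    year_effects: bool = False,
) -> LpmFit:
    """Fit the twinning LPM; see :class:`TwinningPropensityLPM`."""
    est = TwinningPropensityLPM(
        age_scheme=age_scheme, covariance=covariance, year_effects=year_effects
    ).fit(deliveries)
    return est.result_


def fit_country_rates(
    deliveries: pd.DataFrame, n_draws: int = 2000, seed: int | None = None
) -> CountryRatePosterior:
    """Observed per-country twinning rates with normal posterior draws."""
    est = CountryTwinningRate().fit(deliveries)
    return est.sample_posterior(n_draws=n_draws, seed=seed)


def _nearest_psd(cov: np.ndarray) -> tuple[np.ndarray, float]:
    """Clip negative eigenvalues to zero; returns (repaired, max adjustment)."""
    w, v = np.linalg.eigh((cov + cov.T) / 2.0)
    adj = float(max(0.0, -w.min(initial=0.0)))
    w = np.clip(w, 0.0, None)
    return (v * w) @ v.T, adj


def draw_posterior(
    fit: LpmFit, n_draws: int = 2000, seed: int | None = None
) -> AgeEffectPosterior:
    """Multivariate-normal parameter draws at the fit's estimates/covariance.

    This is the flat-prior posterior of the LPM, which coincides with the
    OLS sampling distribution. A covariance that is not positive
    semidefinite (numerically) is repaired by eigenvalue clipping, with the
    size of the adjustment logged.
    """
    mean = fit.point_vector().to_numpy(dtype=float)
    cov = fit.coefficient_covariance.to_numpy(dtype=float)
    w = np.linalg.eigvalsh((cov + cov.T) / 2.0)
    if w.min(initial=0.0) < -1e-12 * max(1.0, w.max(initial=1.0)):
        cov, adj = _nearest_psd(cov)
        logger.warning("covariance repaired to PSD; max eigen-adjustment %.3e", adj)
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(mean, cov, size=n_draws, method="eigh")
    return AgeEffectPosterior(
        draws=pd.DataFrame(draws, columns=fit.param_names),
        seed=seed,
        n_draws=n_draws,
        reference_category=fit.reference_category,
        age_scheme=fit.age_scheme,
    )


class PerCountryAgeEffects(BaseEstimator):
    """Separate per-country LPMs of twinning on age dummies.

    Countries with fewer than two populated age categories are skipped with
    a warning. Coefficients are relative to each country's youngest
    populated category.
    """

    def __init__(self, age_scheme: str = "5-year", covariance: str = "robust"):
        self.age_scheme = age_scheme
        self.covariance = covariance

    def fit(self, X: pd.DataFrame, y=None):
        X = _prepare_deliveries(X, self.age_scheme)
        cats = age_scheme_groups(self.age_scheme)
        coefs, ses = {}, {}
        skipped = []
        for country, sub in X.groupby("country"):
            present = [c for c in cats if c in set(sub["age_category"])]
            if len(present) < 2:
                skipped.append(country)
                continue
            adum = pd.get_dummies(
                pd.Categorical(sub["age_category"], categories=present), dtype=float
            ).iloc[:, 1:]
            adum.columns = [f"age:{a}" for a in adum.columns]
            design = sm.add_constant(adum)
            cov = _COV_TYPES.get(self.covariance, "HC1")
            if cov == "cluster":  # no within-country clustering here
                cov = "HC1"
            res = sm.OLS(sub["twin"].to_numpy(dtype=float), design).fit(cov_type=cov)
            row_c = {present[0]: 0.0}
            row_s = {present[0]: 0.0}
            for a in present[1:]:
                row_c[a] = float(res.params[f"age:{a}"])
                row_s[a] = float(res.bse[f"age:{a}"])
            coefs[country] = row_c
            ses[country] = row_s
        if skipped:
            logger.warning("per-country fit skipped countries: %s", skipped)
        if not coefs:
            raise ValueError("no country had >= 2 populated age categories")
        self.coefficients_ = pd.DataFrame(coefs).T.reindex(columns=list(cats))
        self.standard_errors_ = pd.DataFrame(ses).T.reindex(columns=list(cats))
        self.skipped_ = tuple(skipped)
        self.result_ = MetaResult(
            age_scheme=self.age_scheme,
            per_country_coefficients=self.coefficients_,
            per_country_se=self.standard_errors_,
        )
        return self


def fit_per_country(deliveries: pd.DataFrame, age_scheme: str = "5-year") -> MetaResult:
    """Per-country age-effect estimates (the inputs to the meta-analysis)."""
    return PerCountryAgeEffects(age_scheme=age_scheme).fit(deliveries).result_


def meta_analyze(per_country: MetaResult, method: str = "random") -> MetaResult:
    """Pool per-country age coefficients by inverse-variance meta-analysis.

    Random-effects pooling with the DerSimonian-Laird (method-of-moments)
    heterogeneity variance is the default; ``method="fixed"`` pools with
    inverse-variance weights only. Categories estimated in a single country
    are fixed to that estimate and flagged.
    """
    coefs = per_country.per_country_coefficients
    ses = per_country.per_country_se
    rows = []
    reference = coefs.columns[coefs.notna().any(axis=0)][0]
    for cat in coefs.columns:
        if cat == reference:
            continue
        mask = coefs[cat].notna() & ses[cat].notna() & (ses[cat] > 0)
        eff = coefs.loc[mask, cat].to_numpy(dtype=float)
        var = ses.loc[mask, cat].to_numpy(dtype=float) ** 2
        if len(eff) == 0:
            continue
        if len(eff) == 1:
            rows.append(
                {"category": cat, "estimate": float(eff[0]),
                 "se": float(np.sqrt(var[0])), "tau2": 0.0,
                 "n_countries": 1, "single_country": True}
            )
            logger.warning("meta_analyze: category %s has a single country", cat)
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            res = combine_effects(eff, var, method_re="dl")
            frame = res.summary_frame()
        # the method-of-moments tau2 is truncated at zero (standard DL);
        # when negative, random-effects pooling reduces to fixed-effects
        tau2 = float(res.tau2)
        row_name = "random effect" if method == "random" and tau2 > 0 else "fixed effect"
        rows.append(
            {
                "category": cat,
                "estimate": float(frame.loc[row_name, "eff"]),
                "se": float(frame.loc[row_name, "sd_eff"]),
                "tau2": max(0.0, tau2),
                "n_countries": int(len(eff)),
                "single_country": False,
            }
        )
    pooled = pd.DataFrame(rows).set_index("category")
    return MetaResult(
        age_scheme=per_country.age_scheme,
        per_country_coefficients=coefs,
        per_country_se=ses,
        pooled=pooled,
    )
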