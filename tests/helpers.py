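"""Independent brute-force oracles used across test modules.

These deliberately rebuild design matrices by hand and solve the normal
equations with numpy only, so they share no code path with the package's
estimators.
"""

import numpy as np

from twinproj.ages import AGE_GROUPS_5YR

MAB_CATEGORIES = ("<26", "26-26.5", "26.5-27", "27+")


def brute_force_lpm(deliveries):
    """Dummy-matrix least squares for twin ~ age dummies + country indicators."""
    countries = sorted(deliveries["country"].unique())
    present = [c for c in AGE_GROUPS_5YR if (deliveries["age_category"] == c).any()]
    ref = present[0]
    cols = []
    names = []
    for c in countries:
        cols.append((deliveries["country"] == c).to_numpy(float))
        names.append(("country", c))
    for a in present[1:]:
        cols.append((deliveries["age_category"] == a).to_numpy(float))
        names.append(("age", a))
    X = np.column_stack(cols)
    y = deliveries["twin"].to_numpy(float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    out = {"country": {}, "age": {ref: 0.0}}
    for (kind, label), b in zip(names, beta):
        out[kind][label] = float(b)
    return out


def _period_label(year, lo=1980, hi=2015):
    if year < lo:
        return f"<{lo}"
    if year > hi:
        return f">{hi}"
    start = (year // 5) * 5
    return f"{start}-{start + 4}"


def brute_force_panel(cells, controls=()):
    """Dummy-matrix least squares for the two-way FE panel regression."""
    countries = sorted(cells["country"].unique())
    periods = sorted({_period_label(int(y)) for y in cells["year_mid"]})
    present = [c for c in MAB_CATEGORIES if (cells["mab_category"] == c).any()]
    cell_period = cells["year_mid"].map(lambda y: _period_label(int(y)))
    cols, names = [], []
    for c in countries:
        cols.append((cells["country"] == c).to_numpy(float))
        names.append(("country", c))
    for p in periods[1:]:
        cols.append((cell_period == p).to_numpy(float))
        names.append(("period", p))
    for m in present[1:]:
        cols.append((cells["mab_category"] == m).to_numpy(float))
        names.append(("mab", m))
    for ctrl in controls:
        cols.append(cells[ctrl].to_numpy(float))
        names.append(("ctrl", ctrl))
    X = np.column_stack(cols)
    y = cells["period_twinning_rate"].to_numpy(float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    r2 = 1.0 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()
    out = {"country": {}, "period": {}, "mab": {present[0]: 0.0}, "ctrl": {},
           "r_squared": float(r2)}
    for (kind, label), b in zip(names, beta):
        out[kind][label] = float(b)
    return out


def dl_pool(effects, ses):
    """Hand-rolled DerSimonian-Laird random-effects pooling."""
    eff = np.asarray(effects, float)
    var = np.asarray(ses, float) ** 2
    w = 1.0 / var
    fe = (w * eff).sum() / w.sum()
    q = (w * (eff - fe) ** 2).sum()
    k = len(eff)
    tau2 = max(0.0, (q - (k - 1)) / (w.sum() - (w**2).sum() / w.sum()))
    ws = 1.0 / (var + tau2)
    pooled = (ws * eff).sum() / ws.sum()
    se = np.sqrt(1.0 / ws.sum())
    return pooled, se, tau2
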