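"""Willingness to travel: attribute coefficients expressed in kilometres.

Choice-model coefficients are scale dependent, but the ratio of an attribute's
coefficient to the distance coefficient is not: wtt_k = -beta_k / beta_d is the
extra straight-line distance a chooser would accept in exchange for one unit of
attribute k (positive for valued attributes when distance is a disutility).
Confidence intervals come from the delta method by default, or from simulating
the estimates' normal approximation (Krinsky–Robb style) as an option.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .choice import MixedLogitFit
from .errors import DataError, IdentificationError

BETA_D_FLOOR = 1e-8


def _check_distance(fit, distance_attr: str) -> float:
    if distance_attr not in fit.params.index:
        raise DataError(f"distance attribute {distance_attr!r} not in fitted attributes")
    beta_d = float(fit.params[distance_attr])
    if abs(beta_d) < BETA_D_FLOOR:
        raise IdentificationError("distance coefficient not identified")
    return beta_d


def willingness_to_travel(fit: MixedLogitFit, distance_attr: str = "distance_km") -> pd.DataFrame:
    """Point willingness-to-travel per non-distance attribute, in km per unit.

    Uses the estimated coefficient means only (one wtt per attribute), not the
    random-coefficient SDs.
    """
    beta_d = _check_distance(fit, distance_attr)
    rows = [
        {"attribute": attr, "wtt_km": -float(fit.params[attr]) / beta_d}
        for attr in fit.params.index
        if attr != distance_attr
    ]
    return pd.DataFrame(rows)


def wtt_confidence_interval(
    fit: MixedLogitFit,
    distance_attr: str = "distance_km",
    level: float = 0.95,
    method: str = "delta",
    n_sim: int = 200_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Willingness to travel with confidence intervals.

    delta: var(r) = var(b_k)/b_d^2 + b_k^2 var(b_d)/b_d^4 - 2 b_k cov/b_d^3,
    CI = r +/- z * SE.  simulation: draw (b_k, b_d) jointly from the estimates'
    normal approximation, form ratios, take empirical quantiles.
    """
    if method not in ("delta", "simulation"):
        raise DataError(f"unknown CI method {method!r}")
    beta_d = _check_distance(fit, distance_attr)
    cov = fit.cov_params
    attrs = [a for a in fit.params.index if a != distance_attr]
    z = stats.norm.ppf(0.5 + level / 2)
    rows = []
    if method == "delta":
        vd = float(cov.loc[distance_attr, distance_attr])
        if vd < 0:
            raise DataError("negative variance for the distance coefficient")
        for attr in attrs:
            bk = float(fit.params[attr])
            vk = float(cov.loc[attr, attr])
            ckd = float(cov.loc[attr, distance_attr])
            r = -bk / beta_d
            terms = (vk / beta_d**2, bk**2 * vd / beta_d**4, -2 * bk * ckd / beta_d**3)
            var = sum(terms)
            if var < -1e-8 * max(sum(abs(t) for t in terms), 1e-30):
                raise DataError(f"delta-method variance negative for {attr!r}")
            se = np.sqrt(max(var, 0.0))
            rows.append(
                {"attribute": attr, "wtt_km": r, "ci_low": r - z * se,
                 "ci_high": r + z * se, "se": se, "method": "delta"}
            )
    else:
        names = attrs + [distance_attr]
        sub = cov.loc[names, names].to_numpy()
        mean = fit.params[names].to_numpy()
        try:
            chol = np.linalg.cholesky(sub + 0.0)
        except np.linalg.LinAlgError as exc:
            raise DataError("covariance of estimates is not positive definite") from exc
        rng = np.random.default_rng(seed)
        draws = mean + rng.standard_normal((n_sim, len(names))) @ chol.T
        lo_q, hi_q = (1 - level) / 2, 0.5 + level / 2
        for j, attr in enumerate(attrs):
            ratios = -draws[:, j] / draws[:, -1]
            r = -float(fit.params[attr]) / beta_d
            rows.append(
                {"attribute": attr, "wtt_km": r,
                 "ci_low": float(np.quantile(ratios, lo_q)),
                 "ci_high": float(np.quantile(ratios, hi_q)),
                 "se": float(ratios.std()), "method": "simulation"}
            )
    return pd.DataFrame(rows)


def plot_wtt(table: pd.DataFrame, ax=None):
    """Simple forest plot of willingness-to-travel estimates with their CIs."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.5 * len(table) + 1))
    y = np.arange(len(table))[::-1]
    ax.errorbar(
        table["wtt_km"], y,
        xerr=[table["wtt_km"] - table["ci_low"], table["ci_high"] - table["wtt_km"]],
        fmt="o", capsize=3,
    )
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_yticks(y)
    ax.set_yticklabels(table["attribute"])
    ax.set_xlabel("willingness to travel (km)")
    return ax
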