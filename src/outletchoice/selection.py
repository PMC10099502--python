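"""Six-category multinomial logit for method-use/linkage status and IPW.

The first stage of the selection-on-observables strategy: model the probability
that a woman is a non-user, traditional user, unlinked modern user (long/short
acting) or linked modern user (long/short acting) as a function of demographics
and her supply environment; then weight the linked estimation sample by the
inverse of each woman's fitted probability of her own observed linked category.
Category 1 (no method) is the reference with coefficients fixed at zero.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .errors import ConvergenceError, DataError, IdentificationError, SeparationError
from .synthetic import CATEGORIES, LINKED_CATEGORIES

P_HAT_FLOOR = 1e-6


@dataclass(frozen=True)
class MNLSpec:
    """Covariate list for the selection model (a constant is always added)."""

    covariates: tuple[str, ...]
    robust: bool = False

    def __post_init__(self):
        if len(set(self.covariates)) != len(self.covariates):
            raise DataError("duplicate covariates in MNL spec")
        if "const" in self.covariates:
            raise DataError("do not list 'const'; an intercept is added automatically")


@dataclass
class MNLFit:
    """Fitted multinomial logit.  ``coefs`` has one column per non-reference
    category (2..6) and one row per covariate including 'const'."""

    coefs: pd.DataFrame
    bse: pd.DataFrame
    cov_params: np.ndarray
    loglik: float
    loglik_null: float
    n: int
    spec: MNLSpec
    categories: tuple[int, ...] = field(default=CATEGORIES)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "covariates": list(self.coefs.index),
            "categories": [int(c) for c in self.coefs.columns],
            "coefs": self.coefs.to_numpy().tolist(),
            "bse": self.bse.to_numpy().tolist(),
            "loglik": self.loglik,
            "loglik_null": self.loglik_null,
            "n": self.n,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _design(data: pd.DataFrame, covariates: tuple[str, ...]) -> pd.DataFrame:
    missing = [c for c in covariates if c not in data.columns]
    if missing:
        raise DataError(f"covariates missing from data: {missing}")
    x = data[list(covariates)].astype(float)
    x.insert(0, "const", 1.0)
    return x


def _locate_separating_covariate(data, covariates, categories) -> str | None:
    """Heuristic: a covariate whose support is disjoint between one category and
    the rest perfectly predicts membership."""
    for cov in covariates:
        v = data[cov].astype(float)
        for cat in np.unique(categories):
            inside, outside = v[categories == cat], v[categories != cat]
            if len(inside) and len(outside) and (
                inside.min() > outside.max() or inside.max() < outside.min()
            ):
                return cov
    return None


def fit_mnl(data: pd.DataFrame, spec: MNLSpec, category_col: str = "category") -> MNLFit:
    """Maximum-likelihood multinomial logit with category 1 as the reference.

    Covariates are standardized internally for a stable Newton solve and the
    estimates mapped back to the raw scale (the likelihood is globally concave,
    so this affects iteration count only).
    """
    y = data[category_col].astype(int)
    cats = np.sort(y.unique())
    counts = y.value_counts()
    if counts.min() < 1:
        raise DataError("every category present must have at least one observation")
    x = _design(data, spec.covariates)
    if np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
        raise IdentificationError("design matrix is rank deficient")

    mu = x.mean(axis=0)
    sd = x.std(axis=0).replace(0.0, 1.0)
    mu["const"], sd["const"] = 0.0, 1.0
    xs = (x - mu) / sd

    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            model = sm.MNLogit(y, xs)
            res = model.fit(method="newton", maxiter=200, disp=False)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            cov = _locate_separating_covariate(data, spec.covariates, y.to_numpy())
            raise SeparationError(
                f"perfect separation detected{f' (covariate {cov!r})' if cov else ''}"
            ) from exc

    max_score = float(np.max(np.abs(res.model.score(res.params.to_numpy().ravel(order="F")))))
    not_converged = max_score >= 1e-5 * max(1.0, len(y))
    if not_converged or np.max(np.abs(res.params.to_numpy())) > 20:
        cov = _locate_separating_covariate(data, spec.covariates, y.to_numpy())
        if cov is not None:
            raise SeparationError(f"quasi-separation: unbounded coefficient on {cov!r}")
        if not_converged:
            raise ConvergenceError(
                "MNL gradient not at optimum on standardized covariates",
                diagnostics={"max_score": max_score},
            )
        raise SeparationError("quasi-separation: unbounded coefficient")

    # map standardized-scale estimates back to the raw covariate scale and refit
    # one Newton pass there to obtain the raw-scale covariance directly
    params_std = res.params.to_numpy()  # (k_vars, n_cats-1)
    scale = sd.to_numpy()[:, None]
    params_raw = params_std / scale
    params_raw[0, :] = params_std[0, :] - (params_std[1:, :] * (mu.to_numpy()[1:, None] / sd.to_numpy()[1:, None])).sum(axis=0)
    model_raw = sm.MNLogit(y, x)
    fit_kwargs = {"cov_type": "HC0"} if spec.robust else {}
    res_raw = model_raw.fit(
        method="newton", maxiter=50, disp=False,
        start_params=params_raw.ravel(order="F"), **fit_kwargs
    )
    cov_params = np.asarray(res_raw.cov_params())
    bse = res_raw.bse.to_numpy()

    noncats = [int(c) for c in cats if c != cats[0]]
    coefs = pd.DataFrame(res_raw.params.to_numpy(), index=x.columns, columns=noncats)
    bse_df = pd.DataFrame(np.asarray(bse), index=x.columns, columns=noncats)
    return MNLFit(
        coefs=coefs,
        bse=bse_df,
        cov_params=np.asarray(cov_params),
        loglik=float(res_raw.llf),
        loglik_null=float(res_raw.llnull),
        n=len(y),
        spec=spec,
        categories=tuple(int(c) for c in cats),
    )


def predict_probs(fit: MNLFit, data: pd.DataFrame) -> pd.DataFrame:
    """Fitted category probabilities by explicit softmax over the linear indices.

    Returns an (n x n_categories) table with category labels as columns; rows sum
    to one.
    """
    x = _design(data, fit.spec.covariates)
    eta = x.to_numpy() @ fit.coefs.to_numpy()  # non-reference categories
    eta = np.column_stack([np.zeros(len(x)), eta])
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    idx = data["respondent_id"] if "respondent_id" in data.columns else data.index
    return pd.DataFrame(p, columns=list(fit.categories), index=idx)


def compute_ipw(
    probs: pd.DataFrame,
    categories: pd.Series,
    estimation_categories: tuple[int, ...] = LINKED_CATEGORIES,
) -> pd.DataFrame:
    """Inverse-probability weights for the linked estimation sample.

    The raw weight is the reciprocal of each respondent's fitted probability of
    her own observed linked category; weights are then rescaled to mean one over
    the estimation sample, which stabilizes the weighted likelihood without
    changing relative weighting.
    """
    categories = categories.reindex(probs.index)
    mask = categories.isin(estimation_categories)
    sample = probs.loc[mask]
    obs = categories.loc[mask].astype(int)
    p_hat = np.array([sample.at[i, c] for i, c in obs.items()])
    low = obs.index[p_hat < P_HAT_FLOOR]
    if len(low):
        raise DataError(
            f"fitted probability below floor {P_HAT_FLOOR:g} for respondents {list(low)}; "
            "the selection model badly misfits these observations"
        )
    raw = 1.0 / p_hat
    out = pd.DataFrame(
        {"respondent_id": obs.index, "p_hat": p_hat, "weight": raw / raw.mean()}
    ).reset_index(drop=True)
    return out
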