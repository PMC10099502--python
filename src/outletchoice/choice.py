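"""Weighted conditional logit and mixed logit by maximum simulated likelihood.

The conditional logit treats each woman's utility for an outlet as a linear
function of outlet attributes (including distance); choice probabilities are the
softmax over her choice set.  The mixed logit lets the attribute weights vary
across women, beta_i ~ N(beta, Sigma) with Sigma restricted to a diagonal
matrix, which relaxes the independence-of-irrelevant-alternatives substitution
pattern.  The mixing integral is approximated with Halton draws mapped through
the standard-normal quantile function (maximum simulated likelihood), and both
estimators accept inverse-probability weights; standard errors are sandwich
(robust) by default because weighting breaks the information equality.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from scipy.stats import qmc

from .errors import ConvergenceError, DataError, IdentificationError, SeparationError

#: coefficient magnitude beyond which a fit is treated as quasi-separated
#: (utilities are on the scale of a few km of distance disutility)
SEPARATION_BOUND = 10.0


@dataclass(frozen=True)
class HaltonConfig:
    """Quasi-random draw configuration for maximum simulated likelihood."""

    n_draws: int = 500
    burn: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_draws < 1:
            raise DataError("n_draws must be >= 1")
        if self.burn < 0:
            raise DataError("burn must be >= 0")


@dataclass
class CLogitFit:
    attributes: list[str]
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    loglik: float
    n_choosers: int
    wald_z: pd.Series
    wald_p: pd.Series

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "attributes": self.attributes,
                    "params": self.params.to_dict(),
                    "bse": self.bse.to_dict(),
                    "loglik": self.loglik,
                    "n_choosers": self.n_choosers,
                },
                indent=2,
            )
        )


@dataclass
class MixedLogitFit:
    attributes: list[str]
    random_attributes: list[str]
    params: pd.Series  # means, indexed by attribute
    sds: pd.Series  # |s_k|, indexed by random attribute
    bse: pd.Series  # SEs for means then sds, index 'attr' and 'sd:attr'
    cov_params: pd.DataFrame
    loglik: float
    n_choosers: int
    halton: HaltonConfig
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "attributes": self.attributes,
                    "random_attributes": self.random_attributes,
                    "means": self.params.to_dict(),
                    "sds": self.sds.to_dict(),
                    "bse": self.bse.to_dict(),
                    "loglik": self.loglik,
                    "n_choosers": self.n_choosers,
                    "halton": {
                        "n_draws": self.halton.n_draws,
                        "burn": self.halton.burn,
                        "seed": self.halton.seed,
                    },
                    "converged": self.converged,
                },
                indent=2,
            )
        )


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------


class _ChoiceData:
    """Choice sets flattened to arrays: rows sorted by chooser, group pointers,
    chosen-row indices, per-chooser weights."""

    def __init__(self, cs: pd.DataFrame, attributes: list[str], weights: pd.DataFrame | pd.Series | None):
        missing = [a for a in attributes if a not in cs.columns]
        if missing:
            raise DataError(f"attributes missing from choice-set table: {missing}")
        if "chosen" not in cs.columns:
            raise DataError("choice-set table must have a 'chosen' column")
        cs = cs.sort_values(["respondent_id", "outlet_id"], kind="stable").reset_index(drop=True)
        counts = cs.groupby("respondent_id", sort=False).size()
        chosen_per = cs.groupby("respondent_id", sort=False)["chosen"].sum()
        bad = chosen_per[chosen_per != 1]
        if len(bad):
            raise DataError(f"choosers without exactly one chosen alternative: {list(bad.index[:5])}")
        small = counts[counts < 2]
        if len(small):
            raise DataError(
                f"choosers with fewer than two alternatives: {list(small.index[:5])}"
            )
        self.group_codes, self.group_ids = pd.factorize(cs["respondent_id"])
        self.n_groups = len(self.group_ids)
        self.ptr = np.searchsorted(self.group_codes, np.arange(self.n_groups))
        self.x = cs[attributes].to_numpy(dtype=float)
        self.chosen_rows = np.flatnonzero(cs["chosen"].to_numpy() == 1)
        self.attributes = list(attributes)
        if weights is None:
            self.w = np.ones(self.n_groups)
        else:
            if isinstance(weights, pd.DataFrame):
                weights = weights.set_index("respondent_id")["weight"]
            w = weights.reindex(self.group_ids)
            if w.isna().any():
                raise DataError("weights missing for some choosers")
            self.w = w.to_numpy(dtype=float)

    def demeaned(self) -> np.ndarray:
        """Attributes centred within each choice set (identification check)."""
        group_means = np.add.reduceat(self.x, self.ptr, axis=0) / np.diff(
            np.append(self.ptr, len(self.x))
        )[:, None]
        return self.x - group_means[self.group_codes]


def _check_identification(data: _ChoiceData) -> None:
    xd = data.demeaned()
    const = np.ptp(xd, axis=0) == 0
    if const.any():
        names = [a for a, c in zip(data.attributes, const) if c]
        raise IdentificationError(
            f"attribute(s) constant within every choice set, not identified: {names}"
        )


def filter_estimable(cs: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Drop choosers with fewer than two alternatives (no choice to model);
    returns the filtered table and the excluded respondent ids."""
    sizes = cs.groupby("respondent_id").size()
    usable = sizes[sizes >= 2].index
    excluded = sorted(set(sizes.index) - set(usable))
    return cs[cs["respondent_id"].isin(usable)], excluded


def drop_collinear(cs: pd.DataFrame, attributes: list[str]) -> tuple[list[str], list[str]]:
    """Greedy rank filter on within-set demeaned attributes; returns (kept, dropped)."""
    data = _ChoiceData(cs, attributes, None)
    xd = data.demeaned()
    kept: list[int] = []
    dropped: list[str] = []
    for j in range(xd.shape[1]):
        cand = kept + [j]
        if np.linalg.matrix_rank(xd[:, cand]) == len(cand):
            kept.append(j)
        else:
            dropped.append(attributes[j])
    return [attributes[j] for j in kept], dropped


# ---------------------------------------------------------------------------
# conditional logit
# ---------------------------------------------------------------------------


def _clogit_parts(beta: np.ndarray, data: _ChoiceData):
    """Per-chooser log-probabilities of the chosen alternative, the softmax
    probabilities per row, and per-chooser score vectors."""
    u = data.x @ beta
    umax = np.maximum.reduceat(u, data.ptr)
    eu = np.exp(u - umax[data.group_codes])
    denom = np.add.reduceat(eu, data.ptr)
    p = eu / denom[data.group_codes]
    logp_chosen = np.log(p[data.chosen_rows])
    xbar = np.add.reduceat(data.x * p[:, None], data.ptr, axis=0)
    scores = data.x[data.chosen_rows] - xbar  # (n_groups, k)
    return logp_chosen, p, scores


def clogit_loglik(beta: np.ndarray, data: _ChoiceData) -> float:
    logp, _, _ = _clogit_parts(beta, data)
    return float(data.w @ logp)


def fit_conditional_logit(
    cs: pd.DataFrame,
    attributes: list[str],
    weights: pd.DataFrame | pd.Series | None = None,
) -> CLogitFit:
    """Weighted conditional logit by Newton's method with analytic Hessian.

    Maximizes sum_i w_i log[exp(z_chosen beta) / sum_m exp(z_m beta)]; converges
    to gradient max-norm < 1e-5.  Raises if an attribute is constant within every
    choice set (not identified) or if the likelihood is unbounded (separation).
    """
    data = _ChoiceData(cs, attributes, weights)
    _check_identification(data)
    k = len(attributes)
    beta = np.zeros(k)
    ll = clogit_loglik(beta, data)
    for _ in range(100):
        _, p, scores = _clogit_parts(beta, data)
        grad = (data.w[:, None] * scores).sum(axis=0)
        if np.max(np.abs(grad)) < 1e-6:
            break
        # H = -sum_i w_i sum_m p_m (x_m - xbar_i)(x_m - xbar_i)'
        xbar_rows = np.add.reduceat(data.x * p[:, None], data.ptr, axis=0)[data.group_codes]
        xc = data.x - xbar_rows
        wp = (data.w[data.group_codes] * p)[:, None] * xc
        hess = -(wp.T @ xc)
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError as exc:
            raise IdentificationError("singular Hessian in conditional logit") from exc
        # damped Newton: halve until the (concave) objective improves
        t = 1.0
        for _ in range(40):
            cand = beta + t * step
            ll_new = clogit_loglik(cand, data)
            if ll_new >= ll - 1e-12:
                break
            t /= 2
        beta, ll = beta + t * step, ll_new
        if np.max(np.abs(beta)) > 100:
            raise ConvergenceError(
                "conditional logit estimates diverging (possible separation)",
                diagnostics={"beta": beta.tolist()},
            )
    _, p, scores = _clogit_parts(beta, data)
    grad = (data.w[:, None] * scores).sum(axis=0)
    if np.max(np.abs(grad)) >= 1e-5:
        raise ConvergenceError(
            "conditional logit did not reach gradient tolerance",
            diagnostics={"max_grad": float(np.max(np.abs(grad)))},
        )
    if np.max(np.abs(beta)) > SEPARATION_BOUND:
        worst = attributes[int(np.argmax(np.abs(beta)))]
        raise SeparationError(
            f"coefficient on {worst!r} is unbounded (quasi-separation): "
            "an attribute level is never (or always) chosen"
        )
    xbar_rows = np.add.reduceat(data.x * p[:, None], data.ptr, axis=0)[data.group_codes]
    xc = data.x - xbar_rows
    wp = (data.w[data.group_codes] * p)[:, None] * xc
    hess = -(wp.T @ xc)
    bread = np.linalg.inv(-hess)
    meat = (data.w[:, None] * scores).T @ (data.w[:, None] * scores)
    cov = bread @ meat @ bread
    cov = 0.5 * (cov + cov.T)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    idx = pd.Index(attributes)
    return CLogitFit(
        attributes=list(attributes),
        params=pd.Series(beta, index=idx),
        bse=pd.Series(se, index=idx),
        cov_params=pd.DataFrame(cov, index=idx, columns=idx),
        loglik=float(data.w @ np.log(p[data.chosen_rows])),
        n_choosers=data.n_groups,
        wald_z=pd.Series(z, index=idx),
        wald_p=pd.Series(pvals, index=idx),
    )


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------


def screen_attributes(
    cs: pd.DataFrame,
    candidates: list[str],
    weights=None,
    p_drop: float = 0.3,
    protected: tuple[str, ...] = ("distance_km",),
) -> tuple[list[str], pd.DataFrame]:
    """Backward elimination on conditional-logit Wald p-values.

    Starts from the overfitted model with all candidates (collinear ones removed
    up front and logged), repeatedly drops the attribute with the largest p-value
    above ``p_drop`` and refits, stopping when every retained attribute has
    p <= p_drop.  Protected attributes (distance by default) are never dropped.
    Returns the retained list and a log of screening steps.
    """
    log_rows = []
    retained, dropped = drop_collinear(cs, list(candidates))
    for name in dropped:
        log_rows.append({"step": 0, "action": "drop_collinear", "attribute": name, "p_value": np.nan})
    step = 0
    while True:
        step += 1
        fit = fit_conditional_logit(cs, retained, weights)
        droppable = fit.wald_p.drop(labels=[a for a in protected if a in fit.wald_p.index])
        if droppable.empty or droppable.max() <= p_drop:
            for name in retained:
                log_rows.append(
                    {"step": step, "action": "retain", "attribute": name,
                     "p_value": float(fit.wald_p[name])}
                )
            break
        worst = droppable.idxmax()
        log_rows.append(
            {"step": step, "action": "drop", "attribute": worst, "p_value": float(droppable.max())}
        )
        retained = [a for a in retained if a != worst]
    return retained, pd.DataFrame(log_rows)


# ---------------------------------------------------------------------------
# Halton draws
# ---------------------------------------------------------------------------


def halton_draws(cfg: HaltonConfig, n_respondents: int, n_random_coefs: int) -> np.ndarray:
    """Standard-normal quasi-random draws, shape (respondent, draw, coefficient).

    One Halton sequence per coefficient dimension (bases 2, 3, 5, ...; scipy
    extends the prime list automatically), with the leading zero point and
    ``burn`` further points discarded, mapped through the normal quantile
    function.  Respondents take consecutive blocks of the sequence, shuffled by
    the configured permutation seed.  Deterministic given the config.
    """
    if n_random_coefs == 0:
        return np.zeros((n_respondents, cfg.n_draws, 0))
    total = n_respondents * cfg.n_draws
    eng = qmc.Halton(d=n_random_coefs, scramble=False)
    eng.fast_forward(1 + cfg.burn)  # skip the zero point and the burn
    u = eng.random(total)
    rng = np.random.default_rng(cfg.seed)
    u = u[rng.permutation(total)]
    return special.ndtri(u).reshape(n_respondents, cfg.n_draws, n_random_coefs)


def halton_sequence(base_index: int, n: int, burn: int = 0) -> np.ndarray:
    """First ``n`` points of the 1-d Halton (van der Corput) sequence in the
    ``base_index``-th prime base, after discarding ``burn`` points."""
    eng = qmc.Halton(d=base_index + 1, scramble=False)
    eng.fast_forward(1 + burn)
    return eng.random(n)[:, base_index]


# ---------------------------------------------------------------------------
# mixed logit (maximum simulated likelihood)
# ---------------------------------------------------------------------------


def _msl_objective(theta, data: _ChoiceData, rand_idx: np.ndarray, eta: np.ndarray):
    """Negative weighted simulated log-likelihood and its gradient.

    theta = (beta, s); the individual coefficient on random attribute k at draw r
    is beta_k + s_k * eta[i, r, k].  Probabilities are averaged over draws before
    taking logs.
    """
    k = data.x.shape[1]
    kr = len(rand_idx)
    beta, s = theta[:k], theta[k:]
    R = eta.shape[1]
    gc = data.group_codes
    xr = data.x[:, rand_idx]  # (n_rows, kr)

    u = (data.x @ beta)[:, None] + np.einsum("mk,mrk->mr", xr, (s * eta)[gc])
    umax = np.maximum.reduceat(u, data.ptr, axis=0)
    eu = np.exp(u - umax[gc])
    denom = np.add.reduceat(eu, data.ptr, axis=0)
    p = eu / denom[gc]  # (n_rows, R)
    pc = p[data.chosen_rows]  # (n_groups, R)
    pbar = pc.mean(axis=1)
    ll = float(data.w @ np.log(pbar))

    # a[i,r] = w_i * pc[i,r] / (R * pbar_i); note sum_r a[i,r] = w_i
    a = (data.w / (R * pbar))[:, None] * pc
    rw = np.einsum("mr,mr->m", p, a[gc])  # row weights for the mean gradient
    grad_beta = data.x[data.chosen_rows].T @ data.w - data.x.T @ rw
    grad_s = np.empty(kr)
    for j in range(kr):
        ae = a * eta[:, :, j]  # (n_groups, R)
        b = np.einsum("mr,mr->m", p, ae[gc])
        grad_s[j] = float(
            data.x[data.chosen_rows, rand_idx[j]] @ ae.sum(axis=1) - xr[:, j] @ b
        )
    return -ll, -np.concatenate([grad_beta, grad_s])


def _msl_chooser_scores(theta, data: _ChoiceData, rand_idx, eta) -> np.ndarray:
    """Per-chooser score vectors (unweighted) of the simulated log-likelihood."""
    k = data.x.shape[1]
    beta, s = theta[:k], theta[k:]
    R = eta.shape[1]
    gc = data.group_codes
    xr = data.x[:, rand_idx]
    u = (data.x @ beta)[:, None] + np.einsum("mk,mrk->mr", xr, (s * eta)[gc])
    umax = np.maximum.reduceat(u, data.ptr, axis=0)
    eu = np.exp(u - umax[gc])
    denom = np.add.reduceat(eu, data.ptr, axis=0)
    p = eu / denom[gc]
    pc = p[data.chosen_rows]
    pbar = pc.mean(axis=1)
    a0 = pc / (R * pbar[:, None])  # a with w_i = 1
    scores = np.empty((data.n_groups, k + len(rand_idx)))
    rw = np.einsum("mr,mr->m", p, a0[gc])
    xbar = np.add.reduceat(data.x * rw[:, None], data.ptr, axis=0)
    scores[:, :k] = data.x[data.chosen_rows] - xbar
    for j, rj in enumerate(rand_idx):
        ae = a0 * eta[:, :, j]
        b = np.einsum("mr,mr->m", p, ae[gc])
        xb = np.add.reduceat(xr[:, j] * b, data.ptr)
        scores[:, k + j] = data.x[data.chosen_rows, rj] * ae.sum(axis=1) - xb
    return scores


def simulated_choice_probabilities(
    fit: MixedLogitFit, cs: pd.DataFrame
) -> pd.DataFrame:
    """Simulated probabilities for every alternative in the given choice sets at
    the fitted parameters (averaged over the fit's Halton draws)."""
    data = _ChoiceData(cs, fit.attributes, None)
    rand_idx = np.array([fit.attributes.index(a) for a in fit.random_attributes], dtype=int)
    eta = halton_draws(fit.halton, data.n_groups, len(rand_idx))
    beta = fit.params.to_numpy()
    s = fit.sds.to_numpy() if len(rand_idx) else np.empty(0)
    gc = data.group_codes
    u = (data.x @ beta)[:, None] + np.einsum(
        "mk,mrk->mr", data.x[:, rand_idx], (s * eta)[gc]
    )
    umax = np.maximum.reduceat(u, data.ptr, axis=0)
    eu = np.exp(u - umax[gc])
    denom = np.add.reduceat(eu, data.ptr, axis=0)
    p = (eu / denom[gc]).mean(axis=1)
    out = cs.sort_values(["respondent_id", "outlet_id"], kind="stable").reset_index(drop=True)
    return pd.DataFrame(
        {"respondent_id": out["respondent_id"], "outlet_id": out["outlet_id"], "prob": p}
    )


def fit_mixed_logit(
    cs: pd.DataFrame,
    attributes: list[str],
    random_attributes: list[str],
    weights=None,
    halton: HaltonConfig | None = None,
    start: np.ndarray | None = None,
    sd_start: float = 0.1,
    gtol: float = 1e-6,
) -> MixedLogitFit:
    """Mixed logit with diagonal normal mixing, by maximum simulated likelihood.

    SD parameters enter unconstrained as s_k * eta and are reported as |s_k|,
    avoiding boundary failures at zero.  Starting values are the conditional
    logit estimates for the means and ``sd_start`` for the SDs.  With an empty
    random set the objective reduces exactly to the conditional logit objective.
    """
    halton = halton or HaltonConfig()
    bad = set(random_attributes) - set(attributes)
    if bad:
        raise DataError(f"random attributes not among attributes: {sorted(bad)}")
    if halton.n_draws < 25 and random_attributes:
        warnings.warn(
            f"only {halton.n_draws} draws per chooser; simulation noise may be large",
            stacklevel=2,
        )
    data = _ChoiceData(cs, attributes, weights)
    _check_identification(data)
    rand_idx = np.array([attributes.index(a) for a in random_attributes], dtype=int)
    eta = halton_draws(halton, data.n_groups, len(rand_idx))
    k, kr = len(attributes), len(random_attributes)

    clog_ll = None
    if start is None:
        clog = fit_conditional_logit(cs, attributes, weights)
        clog_ll = clog.loglik
        start = np.concatenate([clog.params.to_numpy(), np.full(kr, sd_start)])

    # optimize the average (per unit weight) log-likelihood so BFGS steps are
    # scale-free; multiply back afterwards
    wsum = float(data.w.sum())

    def scaled(theta):
        f, g = _msl_objective(theta, data, rand_idx, eta)
        return f / wsum, g / wsum

    def solve(x0):
        res = optimize.minimize(
            scaled, x0, jac=True, method="BFGS",
            options={"gtol": gtol, "maxiter": 500},
        )
        if not res.success and np.max(np.abs(res.jac)) > 100 * gtol:
            # line-search precision loss: restart with a fresh Hessian estimate
            res = optimize.minimize(
                scaled, res.x, jac=True, method="BFGS",
                options={"gtol": gtol, "maxiter": 500},
            )
        return res

    res = solve(start)
    # the conditional logit is nested at s = 0, so a simulated optimum below the
    # conditional-logit likelihood marks a bad basin; restart nearer the nest
    if clog_ll is not None and kr > 0 and -res.fun * wsum < clog_ll - 1e-6:
        alt = solve(np.concatenate([clog.params.to_numpy(), np.full(kr, 1e-3)]))
        if alt.fun < res.fun:
            res = alt
    gmax = float(np.max(np.abs(res.jac)))
    # BFGS can stall on precision loss while already at the optimum; accept if
    # the gradient is small relative to the tolerance, otherwise fail loudly
    if not res.success and gmax > 100 * gtol:
        raise ConvergenceError(
            "mixed logit did not converge",
            diagnostics={"message": res.message, "max_grad": gmax, "nit": res.nit},
        )
    theta = res.x
    ll = -res.fun * wsum
    if np.max(np.abs(theta[:k])) > SEPARATION_BOUND:
        worst = attributes[int(np.argmax(np.abs(theta[:k])))]
        raise SeparationError(
            f"mixed-logit mean coefficient on {worst!r} is unbounded (quasi-separation)"
        )

    # sandwich covariance: numerical Hessian of the objective (central differences
    # of the analytic gradient) as bread, per-chooser score outer products as meat
    npar = k + kr
    hess = np.empty((npar, npar))
    h = 1e-5 * (1.0 + np.abs(theta))
    for j in range(npar):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h[j]
        tm[j] -= h[j]
        gp = _msl_objective(tp, data, rand_idx, eta)[1]
        gm = _msl_objective(tm, data, rand_idx, eta)[1]
        hess[:, j] = (gp - gm) / (2 * h[j])
    hess = 0.5 * (hess + hess.T)
    scores = _msl_chooser_scores(theta, data, rand_idx, eta)
    # an SD estimate at (or crossing) zero leaves the objective locally flat in
    # that direction; floor the Hessian eigenvalues so the flat direction gets a
    # large-but-finite variance and the sandwich stays positive semidefinite
    evals, evecs = np.linalg.eigh(hess)
    floor = 1e-6 * max(float(evals.max()), 1e-12)
    bread = (evecs / np.maximum(evals, floor)) @ evecs.T
    meat = (data.w[:, None] * scores).T @ (data.w[:, None] * scores)
    cov = bread @ meat @ bread
    cov = 0.5 * (cov + cov.T)

    names = list(attributes) + [f"sd:{a}" for a in random_attributes]
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return MixedLogitFit(
        attributes=list(attributes),
        random_attributes=list(random_attributes),
        params=pd.Series(theta[:k], index=list(attributes)),
        sds=pd.Series(np.abs(theta[k:]), index=list(random_attributes)),
        bse=pd.Series(se, index=names),
        cov_params=pd.DataFrame(cov, index=names, columns=names),
        loglik=ll,
        n_choosers=data.n_groups,
        halton=halton,
        converged=bool(res.success or gmax <= 100 * gtol),
        diagnostics={"nit": int(res.nit), "max_grad": gmax, "message": str(res.message)},
    )


# ---------------------------------------------------------------------------
# likelihood-ratio test
# ---------------------------------------------------------------------------


def lr_test(clog: CLogitFit, mixl: MixedLogitFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of mixed logit against its nested conditional logit.

    Statistic 2(LL_mixed - LL_clogit) floored at zero, df = number of random
    coefficients, p-value from the chi-square upper tail.  Because the null puts
    the SD parameters on the boundary of the parameter space, the standard
    chi-square reference is conservative.
    """
    if list(clog.attributes) != list(mixl.attributes):
        raise DataError("models are not nested: attribute lists differ")
    stat = max(0.0, 2.0 * (mixl.loglik - clog.loglik))
    df = len(mixl.random_attributes)
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    if stat == 0.0:
        p = 1.0
    return stat, df, p
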