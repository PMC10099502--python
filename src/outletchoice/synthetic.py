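"""Synthetic linked household–outlet study generator.

Emulates the sampling design of an urban family-planning outlet census linked to a
household survey: service-delivery points of three types (public clinics, private
clinics, pharmacies) scattered in an outer ring, surveyed women in a nested inner
ring, a six-category method-use/linkage outcome driven by observable demographics,
and — for women linked to an outlet — an outlet choice generated from a
random-coefficients utility with additive Gumbel errors and distance disutility.

All coordinates are planar kilometres with the site centre at the origin, so
straight-line (Euclidean) distance is exact by construction.  Every draw is
controlled by an explicit integer seed; identical seeds give identical tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DataError

OUTLET_TYPES = ("public", "private", "pharmacy")

#: Binary structural-quality attributes audited at each outlet.
BINARY_ATTRIBUTES = (
    "stockout_injectables",
    "trained_provider",
    "fp_signage",
    "open7",
    "outreach",
    "counselling",
    "job_aids",
)

#: Attributes entering the outlet-choice utility, in canonical order.
#: distance_km is computed respondent-by-outlet; the rest are outlet columns.
CHOICE_ATTRIBUTES = (
    "distance_km",
    "n_methods",
    "open7",
    "stockout_injectables",
    "trained_provider",
    "fp_signage",
    "is_public",
    "is_pharmacy",
)

#: Respondent covariates usable in the selection model and preference shifts.
RESPONDENT_COVARIATES = (
    "age_25plus",
    "edu_secondary",
    "edu_college",
    "married",
    "parity",
    "top_wealth",
)

#: Method-use / linkage categories.  1 = no method (reference), 2 = traditional,
#: 3/4 = long-/short-acting method not linked to an outlet, 5/6 = long-/short-acting
#: method linked to an outlet.
CATEGORIES = (1, 2, 3, 4, 5, 6)
LINKED_CATEGORIES = (5, 6)
#: Empty-choice-set demotion: a linked category falls back to its unlinked twin.
UNLINKED_TWIN = {5: 3, 6: 4}


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteConfig:
    """Geometry and sample sizes for one study site."""

    site_id: str
    n_outlets_by_type: Mapping[str, int]
    outer_ring_radius: float  # km; outlets live in this disc
    inner_ring_radius: float  # km; households live in this disc
    choice_radius: float  # km; 3 for a Kenya-like site, 2 for a Uganda-like site
    n_respondents: int

    def __post_init__(self):
        if not 0 < self.inner_ring_radius < self.outer_ring_radius:
            raise ConfigurationError("inner_ring_radius must be in (0, outer_ring_radius)")
        if not 0 <= self.choice_radius <= self.outer_ring_radius:
            raise ConfigurationError("choice_radius must be in [0, outer_ring_radius]")
        if self.n_respondents < 0:
            raise ConfigurationError("n_respondents must be >= 0")
        unknown = set(self.n_outlets_by_type) - set(OUTLET_TYPES)
        if unknown:
            raise ConfigurationError(f"unknown outlet types: {sorted(unknown)}")
        if any(v < 0 for v in self.n_outlets_by_type.values()):
            raise ConfigurationError("outlet counts must be >= 0")

    @property
    def n_outlets(self) -> int:
        return sum(self.n_outlets_by_type.values())


@dataclass(frozen=True)
class CountDistribution:
    """Truncated shifted-Poisson distribution on an integer support.

    Draws ``lo + Poisson(mean - lo)`` clipped to ``[lo, hi]``; targets the given
    mean for means well inside the support.
    """

    mean: float
    support: tuple[int, int] = (1, 12)

    def __post_init__(self):
        lo, hi = self.support
        if not lo <= self.mean <= hi:
            raise ConfigurationError(f"count mean {self.mean} outside support {self.support}")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        lo, hi = self.support
        draws = lo + rng.poisson(max(self.mean - lo, 0.0), size=n)
        return np.clip(draws, lo, hi)


@dataclass(frozen=True)
class PriceDistribution:
    """Log-normal price with a target median (exp of the log-mean)."""

    median: float
    sigma: float = 0.5

    def __post_init__(self):
        if self.median < 0 or self.sigma < 0:
            raise ConfigurationError("price median and sigma must be >= 0")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.median == 0:
            return np.zeros(n)
        return rng.lognormal(np.log(self.median), self.sigma, size=n)


@dataclass(frozen=True)
class OutletTypeAttributes:
    """Attribute distributions for one outlet type."""

    prevalence: Mapping[str, float]  # binary attribute -> Bernoulli p
    n_methods: CountDistribution
    price_ocp: PriceDistribution
    price_injection: PriceDistribution

    def __post_init__(self):
        for attr, p in self.prevalence.items():
            if attr not in BINARY_ATTRIBUTES:
                raise ConfigurationError(f"unknown binary attribute {attr!r}")
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"prevalence of {attr!r} must be in [0,1], got {p}")
        missing = set(BINARY_ATTRIBUTES) - set(self.prevalence)
        if missing:
            raise ConfigurationError(f"missing prevalences for {sorted(missing)}")


@dataclass(frozen=True)
class AttributeModel:
    """Per-type outlet attribute distributions (the audit-table shape)."""

    by_type: Mapping[str, OutletTypeAttributes]

    def __post_init__(self):
        missing = set(OUTLET_TYPES) - set(self.by_type)
        if missing:
            raise ConfigurationError(f"attribute model missing outlet types {sorted(missing)}")


@dataclass(frozen=True)
class CovariateModel:
    """Respondent demographic distributions.

    Education is drawn on four levels (none, primary, secondary, college) and
    exposed as two dummies; parity is drawn on {0,1,2,3} where 3 stands for 3+.
    """

    age_25plus_prob: float = 0.66
    education_probs: tuple[float, float, float, float] = (0.14, 0.30, 0.27, 0.29)
    married_prob: float = 0.58
    parity_probs: tuple[float, float, float, float] = (0.33, 0.20, 0.19, 0.28)
    top_wealth_prob: float = 0.48

    def __post_init__(self):
        for name in ("age_25plus_prob", "married_prob", "top_wealth_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {p}")
        for name in ("education_probs", "parity_probs"):
            probs = np.asarray(getattr(self, name), dtype=float)
            if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must be nonnegative and sum to 1")


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth parameters of the generating process.

    beta_mean / beta_sd: population mean and SD (diagonal normal mixing) of the
    utility weight on each choice attribute.  selection_coefs: multinomial-logit
    coefficients (rows = categories 2..6, reference category 1 fixed at zero;
    columns = 'const' plus respondent covariates).  preference_shifts: optional
    covariate-dependent shifts of the individual coefficient means, the channel
    through which selection on observables becomes informative for preferences.
    """

    beta_mean: Mapping[str, float]
    beta_sd: Mapping[str, float]
    selection_coefs: pd.DataFrame
    seed: int = 0
    preference_shifts: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        for attr in self.beta_mean:
            if attr not in CHOICE_ATTRIBUTES:
                raise ConfigurationError(f"unknown choice attribute {attr!r} in beta_mean")
        for attr, sd in self.beta_sd.items():
            if attr not in CHOICE_ATTRIBUTES:
                raise ConfigurationError(f"unknown choice attribute {attr!r} in beta_sd")
            if sd < 0:
                raise ConfigurationError("beta_sd entries must be >= 0")
        if list(self.selection_coefs.index) != [2, 3, 4, 5, 6]:
            raise ConfigurationError("selection_coefs index must be categories [2,3,4,5,6]")
        if "const" not in self.selection_coefs.columns:
            raise ConfigurationError("selection_coefs must include a 'const' column")
        for cov, shifts in self.preference_shifts.items():
            if cov not in RESPONDENT_COVARIATES:
                raise ConfigurationError(f"unknown covariate {cov!r} in preference_shifts")
            for attr in shifts:
                if attr not in CHOICE_ATTRIBUTES:
                    raise ConfigurationError(f"unknown attribute {attr!r} in preference_shifts")

    def mean_vector(self) -> np.ndarray:
        return np.array([self.beta_mean.get(a, 0.0) for a in CHOICE_ATTRIBUTES])

    def sd_vector(self) -> np.ndarray:
        return np.array([self.beta_sd.get(a, 0.0) for a in CHOICE_ATTRIBUTES])


@dataclass(frozen=True)
class StudyDesign:
    """Bundle of everything needed to generate one synthetic study."""

    site: SiteConfig
    attributes: AttributeModel
    covariates: CovariateModel
    truth: TruthParams


@dataclass
class SyntheticStudy:
    """A fully generated study with its ground truth attached."""

    respondents: pd.DataFrame  # includes category and chosen_outlet_id
    outlets: pd.DataFrame
    truth: TruthParams
    coefficient_draws: pd.DataFrame  # realized beta_i for linked respondents
    choice_sets: pd.DataFrame  # long table for linked respondents, chosen flagged
    exclusions: dict  # respondents demoted/excluded and why

    @property
    def linked_respondents(self) -> pd.DataFrame:
        return self.respondents[self.respondents["category"].isin(LINKED_CATEGORIES)]


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _sample_disc(rng: np.random.Generator, n: int, radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Uniform points in a disc of the given radius centred at the origin."""
    r = radius * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2.0 * np.pi
    return r * np.cos(theta), r * np.sin(theta)


def generate_outlets(cfg: SiteConfig, attrs: AttributeModel, seed: int) -> pd.DataFrame:
    """Generate the outlet census: uniform locations in the outer ring, attributes
    drawn per type from the attribute model."""
    if cfg.n_outlets == 0:
        raise DataError("empty supply environment: zero outlets configured")
    rng = np.random.default_rng(seed)
    frames = []
    offset = 0
    for otype in OUTLET_TYPES:
        n = int(cfg.n_outlets_by_type.get(otype, 0))
        if n == 0:
            continue
        model = attrs.by_type[otype]
        x, y = _sample_disc(rng, n, cfg.outer_ring_radius)
        cols = {
            "outlet_id": [f"O{offset + i:04d}" for i in range(n)],
            "outlet_type": otype,
            "x_km": x,
            "y_km": y,
            "n_methods": model.n_methods.sample(rng, n),
            "price_ocp": model.price_ocp.sample(rng, n),
            "price_injection": model.price_injection.sample(rng, n),
        }
        for attr in BINARY_ATTRIBUTES:
            cols[attr] = (rng.random(n) < model.prevalence[attr]).astype(int)
        frames.append(pd.DataFrame(cols))
        offset += n
    out = pd.concat(frames, ignore_index=True)
    out["is_public"] = (out["outlet_type"] == "public").astype(int)
    out["is_pharmacy"] = (out["outlet_type"] == "pharmacy").astype(int)
    return out


def generate_respondents(cfg: SiteConfig, covariate_model: CovariateModel, seed: int) -> pd.DataFrame:
    """Generate surveyed women: uniform locations in the inner ring, demographics
    drawn independently from the covariate model."""
    if cfg.n_respondents < 1:
        raise ConfigurationError("n_respondents must be >= 1 to generate respondents")
    cm = covariate_model
    rng = np.random.default_rng(seed)
    n = cfg.n_respondents
    x, y = _sample_disc(rng, n, cfg.inner_ring_radius)
    edu = rng.choice(4, size=n, p=np.asarray(cm.education_probs))
    parity = rng.choice(4, size=n, p=np.asarray(cm.parity_probs))
    df = pd.DataFrame(
        {
            "respondent_id": [f"R{i:05d}" for i in range(n)],
            "x_km": x,
            "y_km": y,
            "age_25plus": (rng.random(n) < cm.age_25plus_prob).astype(int),
            "edu_level": edu,
            "edu_secondary": (edu == 2).astype(int),
            "edu_college": (edu == 3).astype(int),
            "married": (rng.random(n) < cm.married_prob).astype(int),
            "parity": parity,
            "top_wealth": (rng.random(n) < cm.top_wealth_prob).astype(int),
        }
    )
    return df


def selection_probabilities(respondents: pd.DataFrame, coefs: pd.DataFrame) -> np.ndarray:
    """Closed-form six-category MNL probabilities implied by the selection
    coefficients (category 1 is the zero-coefficient reference)."""
    covs = [c for c in coefs.columns if c != "const"]
    missing = [c for c in covs if c not in respondents.columns]
    if missing:
        raise DataError(f"selection covariates missing from respondents: {missing}")
    x = respondents[covs].to_numpy(dtype=float) if covs else np.empty((len(respondents), 0))
    eta = x @ coefs[covs].to_numpy(dtype=float).T + coefs["const"].to_numpy(dtype=float)
    eta = np.column_stack([np.zeros(len(respondents)), eta])  # category 1 reference
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    return p


def simulate_selection(respondents: pd.DataFrame, truth: TruthParams, seed: int) -> pd.Series:
    """Assign each respondent a method-use/linkage category 1..6 by sampling from
    the MNL probabilities implied by the truth's selection coefficients."""
    p = selection_probabilities(respondents, truth.selection_coefs)
    rng = np.random.default_rng(seed)
    u = rng.random(len(respondents))
    cum = np.cumsum(p, axis=1)
    idx = (u[:, None] > cum).sum(axis=1)
    return pd.Series(np.asarray(CATEGORIES)[idx], index=respondents.index, name="category")


def realized_coefficients(
    respondents: pd.DataFrame, truth: TruthParams, seed: int
) -> pd.DataFrame:
    """Draw each respondent's utility-weight vector beta_i ~ N(mean_i, diag(sd^2)),
    where mean_i is the population mean plus any covariate-dependent shifts."""
    n = len(respondents)
    k = len(CHOICE_ATTRIBUTES)
    mean = np.tile(truth.mean_vector(), (n, 1))
    for cov, shifts in truth.preference_shifts.items():
        xv = respondents[cov].to_numpy(dtype=float)
        for attr, delta in shifts.items():
            mean[:, CHOICE_ATTRIBUTES.index(attr)] += delta * xv
    rng = np.random.default_rng(seed)
    beta = mean + rng.standard_normal((n, k)) * truth.sd_vector()
    return pd.DataFrame(beta, columns=list(CHOICE_ATTRIBUTES), index=respondents["respondent_id"])


def simulate_outlet_choice(
    respondents: pd.DataFrame,
    choice_sets: pd.DataFrame,
    truth: TruthParams,
    seed: int,
) -> tuple[pd.Series, pd.DataFrame, list]:
    """Simulate the chosen outlet for each respondent present in the choice sets.

    Utility of each alternative is z'beta_i plus an independent standard Gumbel
    error; the alternative with maximal utility is chosen.  Returns the chosen
    outlet per respondent, the realized coefficient draws, and the list of
    respondent ids with empty choice sets (excluded, never silently dropped).
    """
    ids = respondents["respondent_id"].to_numpy()
    present = pd.Index(choice_sets["respondent_id"].unique())
    empty = [rid for rid in ids if rid not in present]
    active = respondents[respondents["respondent_id"].isin(present)].reset_index(drop=True)
    if active.empty:
        return pd.Series(dtype=object, name="chosen_outlet_id"), pd.DataFrame(), empty

    draws = realized_coefficients(active, truth, seed)
    cs = choice_sets.sort_values(["respondent_id", "outlet_id"], kind="stable").reset_index(drop=True)
    present = [a for a in CHOICE_ATTRIBUTES if a in cs.columns]
    needed = {a for a, v in truth.beta_mean.items() if v != 0}
    needed |= {a for a, v in truth.beta_sd.items() if v != 0}
    for shifts in truth.preference_shifts.values():
        needed |= {a for a, v in shifts.items() if v != 0}
    missing = needed - set(present)
    if missing:
        raise DataError(f"choice sets lack attributes the truth uses: {sorted(missing)}")
    z = cs[present].to_numpy(dtype=float)
    rid_codes, rid_order = pd.factorize(cs["respondent_id"])
    beta = draws.loc[rid_order, present].to_numpy()
    util = np.einsum("mk,mk->m", z, beta[rid_codes])
    rng = np.random.default_rng(seed + 1)
    util += rng.gumbel(size=len(util))
    best = (
        pd.DataFrame({"rid": cs["respondent_id"], "outlet_id": cs["outlet_id"], "u": util})
        .sort_values("u", kind="stable")
        .groupby("rid", sort=False)
        .tail(1)
    )
    chosen = best.set_index("rid")["outlet_id"]
    chosen.name = "chosen_outlet_id"
    return chosen, draws, empty


def population_mean_beta(truth: TruthParams, respondents: pd.DataFrame) -> pd.Series:
    """Population-average utility weights: the estimand targeted by IPW-weighted
    estimation when preferences shift with observables."""
    mean = truth.mean_vector().copy()
    for cov, shifts in truth.preference_shifts.items():
        xbar = float(respondents[cov].mean())
        for attr, delta in shifts.items():
            mean[CHOICE_ATTRIBUTES.index(attr)] += delta * xbar
    return pd.Series(mean, index=list(CHOICE_ATTRIBUTES))


def generate_study(design: StudyDesign, seed: int | None = None) -> SyntheticStudy:
    """Generate a complete synthetic study.

    Stages: outlet census, household survey, category assignment, and — for
    respondents in the linked categories — choice sets within the site's radius
    and a simulated outlet choice.  Linked respondents with no outlet within the
    radius are demoted to the unlinked twin category and recorded in exclusions.
    """
    from .supply import build_choice_sets  # local import to avoid cycle at import time

    if seed is None:
        seed = design.truth.seed
    ss = np.random.SeedSequence(seed)
    s_out, s_resp, s_sel, s_choice = (int(s) & 0x7FFFFFFF for s in ss.generate_state(4))

    outlets = generate_outlets(design.site, design.attributes, s_out)
    respondents = generate_respondents(design.site, design.covariates, s_resp)
    respondents["category"] = simulate_selection(respondents, design.truth, s_sel)

    linked = respondents[respondents["category"].isin(LINKED_CATEGORIES)]
    cs, _report = build_choice_sets(linked, outlets, design.site.choice_radius, chosen_links=None)
    chosen, draws, empty = simulate_outlet_choice(linked, cs, design.truth, s_choice)

    # respondents with no outlet in radius cannot be linked; demote to unlinked twin
    demoted = []
    for rid in empty:
        row = respondents["respondent_id"] == rid
        old = int(respondents.loc[row, "category"].iloc[0])
        respondents.loc[row, "category"] = UNLINKED_TWIN[old]
        demoted.append(rid)

    respondents["chosen_outlet_id"] = respondents["respondent_id"].map(chosen)
    cs = cs[cs["respondent_id"].isin(chosen.index)].copy()
    cs["chosen"] = (
        cs["outlet_id"] == cs["respondent_id"].map(chosen)
    ).astype(int)
    exclusions = {"demoted_empty_choice_set": demoted}
    return SyntheticStudy(respondents, outlets, design.truth, draws, cs, exclusions)


def generate_choice_study(design: StudyDesign, seed: int | None = None) -> SyntheticStudy:
    """Like :func:`generate_study` but every respondent is an outlet chooser
    (selection stage bypassed) — the workhorse for choice-model recovery studies."""
    from .supply import build_choice_sets

    if seed is None:
        seed = design.truth.seed
    ss = np.random.SeedSequence(seed)
    s_out, s_resp, _s_sel, s_choice = (int(s) & 0x7FFFFFFF for s in ss.generate_state(4))
    outlets = generate_outlets(design.site, design.attributes, s_out)
    respondents = generate_respondents(design.site, design.covariates, s_resp)
    cs, _report = build_choice_sets(respondents, outlets, design.site.choice_radius, chosen_links=None)
    chosen, draws, empty = simulate_outlet_choice(respondents, cs, design.truth, s_choice)
    respondents["category"] = np.where(respondents["respondent_id"].isin(chosen.index), 6, 4)
    respondents["chosen_outlet_id"] = respondents["respondent_id"].map(chosen)
    cs = cs[cs["respondent_id"].isin(chosen.index)].copy()
    cs["chosen"] = (cs["outlet_id"] == cs["respondent_id"].map(chosen)).astype(int)
    return SyntheticStudy(
        respondents, outlets, design.truth, draws, cs, {"empty_choice_set": empty}
    )


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def _attribute_model(table: Mapping[str, Mapping[str, float]]) -> AttributeModel:
    by_type = {}
    for otype, row in table.items():
        by_type[otype] = OutletTypeAttributes(
            prevalence={a: row[a] for a in BINARY_ATTRIBUTES},
            n_methods=CountDistribution(mean=row["n_methods_mean"]),
            price_ocp=PriceDistribution(median=row["price_ocp_median"]),
            price_injection=PriceDistribution(median=row["price_injection_median"]),
        )
    return AttributeModel(by_type=by_type)


#: Audit-shaped attribute prevalences for a Kenya-like site (shares of outlets of
#: each type with the attribute, plus mean method counts and median prices).
KENYA_ATTRIBUTE_TABLE = {
    "public": dict(
        stockout_injectables=0.054, trained_provider=0.453, fp_signage=0.359,
        open7=0.130, outreach=0.646, counselling=0.973, job_aids=0.659,
        n_methods_mean=4.70, price_ocp_median=2.02, price_injection_median=3.15,
    ),
    "private": dict(
        stockout_injectables=0.194, trained_provider=0.388, fp_signage=0.363,
        open7=0.510, outreach=0.140, counselling=0.912, job_aids=0.415,
        n_methods_mean=4.35, price_ocp_median=40.41, price_injection_median=113.03,
    ),
    "pharmacy": dict(
        stockout_injectables=0.202, trained_provider=0.239, fp_signage=0.170,
        open7=0.516, outreach=0.007, counselling=0.758, job_aids=0.128,
        n_methods_mean=3.23, price_ocp_median=102.70, price_injection_median=18.72,
    ),
}

UGANDA_ATTRIBUTE_TABLE = {
    "public": dict(
        stockout_injectables=0.232, trained_provider=0.536, fp_signage=0.214,
        open7=0.607, outreach=0.750, counselling=0.964, job_aids=0.786,
        n_methods_mean=4.30, price_ocp_median=160.71, price_injection_median=285.71,
    ),
    "private": dict(
        stockout_injectables=0.205, trained_provider=0.310, fp_signage=0.126,
        open7=0.811, outreach=0.090, counselling=0.792, job_aids=0.196,
        n_methods_mean=3.57, price_ocp_median=1038.84, price_injection_median=2333.84,
    ),
    "pharmacy": dict(
        stockout_injectables=0.127, trained_provider=0.356, fp_signage=0.0,
        open7=0.864, outreach=0.017, counselling=0.525, job_aids=0.051,
        n_methods_mean=3.35, price_ocp_median=2128.32, price_injection_median=466.10,
    ),
}


def default_truth(seed: int = 0, preference_shifts: Mapping | None = None) -> TruthParams:
    """Default ground truth: distance is a disutility with heterogeneous weight;
    public outlets and method variety are valued (with heterogeneity), other
    structural-quality attributes carry moderate fixed weights."""
    beta_mean = {
        "distance_km": -1.0,
        "n_methods": 0.15,
        "open7": 0.20,
        "stockout_injectables": -0.30,
        "trained_provider": 0.30,
        "fp_signage": 0.45,
        "is_public": 2.0,
        "is_pharmacy": 0.50,
    }
    beta_sd = {"distance_km": 0.5, "n_methods": 0.10, "is_public": 1.0}
    selection_coefs = pd.DataFrame(
        {
            "const": [-1.2, -2.0, -0.4, -2.2, -1.4],
            "age_25plus": [0.1, 0.5, 0.0, 0.5, 0.1],
            "edu_secondary": [0.0, 0.0, 0.1, -0.1, -0.1],
            "edu_college": [0.1, 0.0, 0.2, -0.4, -0.5],
            "married": [0.3, 0.4, 0.2, 0.7, 0.7],
            "parity": [0.05, 0.25, 0.05, 0.25, 0.15],
            "top_wealth": [0.0, 0.1, 0.1, 0.0, 0.0],
        },
        index=[2, 3, 4, 5, 6],
    )
    return TruthParams(
        beta_mean=beta_mean,
        beta_sd=beta_sd,
        selection_coefs=selection_coefs,
        seed=seed,
        preference_shifts=dict(preference_shifts or {}),
    )


def kenya_like(n_respondents: int = 400, n_outlets_scale: float = 1 / 30, seed: int = 0) -> StudyDesign:
    """Kenya-like site: pharmacy-heavy outlet mix (921:614:233 scaled down),
    3 km choice radius."""
    counts = {
        "pharmacy": max(1, round(921 * n_outlets_scale)),
        "private": max(1, round(614 * n_outlets_scale)),
        "public": max(1, round(233 * n_outlets_scale)),
    }
    site = SiteConfig(
        site_id="kenya_like",
        n_outlets_by_type=counts,
        outer_ring_radius=5.0,
        inner_ring_radius=2.0,
        choice_radius=3.0,
        n_respondents=n_respondents,
    )
    return StudyDesign(site, _attribute_model(KENYA_ATTRIBUTE_TABLE), CovariateModel(), default_truth(seed))


def uganda_like(n_respondents: int = 400, n_outlets_scale: float = 1 / 30, seed: int = 0) -> StudyDesign:
    """Uganda-like site: private-heavy outlet mix (826:56:18 scaled down),
    2 km choice radius."""
    counts = {
        "private": max(1, round(826 * n_outlets_scale)),
        "public": max(1, round(56 * n_outlets_scale)),
        "pharmacy": max(1, round(18 * n_outlets_scale)),
    }
    site = SiteConfig(
        site_id="uganda_like",
        n_outlets_by_type=counts,
        outer_ring_radius=5.0,
        inner_ring_radius=2.0,
        choice_radius=2.0,
        n_respondents=n_respondents,
    )
    return StudyDesign(site, _attribute_model(UGANDA_ATTRIBUTE_TABLE), CovariateModel(), default_truth(seed))


def observable_linkage(n_respondents: int = 1500, seed: int = 0) -> StudyDesign:
    """Kenya-like design where linkage depends strongly on education, wealth,
    marriage and parity, and preferences shift with the same observables — the
    configuration in which unweighted choice estimates are biased (the linked
    subsample over-represents preference types) and IPW corrects them.

    College-educated women value public outlets far less; top-wealth women are
    much less distance averse.  Both groups' linkage propensities differ sharply,
    so the linked sample's composition distorts the willingness-to-travel ratios.
    """
    shifts = {
        "edu_college": {"is_public": -2.0},
        "top_wealth": {"distance_km": 0.4},
        "parity": {"n_methods": 0.05},
    }
    truth = default_truth(seed, preference_shifts=shifts)
    selection = truth.selection_coefs.copy()
    selection.loc[5, ["married", "edu_college", "parity", "top_wealth"]] = [1.2, -2.0, 0.4, 1.0]
    selection.loc[6, ["married", "edu_college", "parity", "top_wealth"]] = [1.2, -2.0, 0.3, 1.0]
    truth = dataclasses.replace(truth, selection_coefs=selection)
    base = kenya_like(n_respondents=n_respondents, seed=seed)
    return dataclasses.replace(base, truth=truth)


PRESETS = {
    "kenya_like": kenya_like,
    "uganda_like": uganda_like,
    "observable_linkage": observable_linkage,
}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def truth_to_dict(truth: TruthParams) -> dict:
    return {
        "beta_mean": dict(truth.beta_mean),
        "beta_sd": dict(truth.beta_sd),
        "selection_coefs": {
            "index": [int(i) for i in truth.selection_coefs.index],
            "columns": list(truth.selection_coefs.columns),
            "values": truth.selection_coefs.to_numpy().tolist(),
        },
        "preference_shifts": {k: dict(v) for k, v in truth.preference_shifts.items()},
        "seed": int(truth.seed),
    }


def truth_from_dict(d: Mapping) -> TruthParams:
    sc = d["selection_coefs"]
    coefs = pd.DataFrame(sc["values"], index=sc["index"], columns=sc["columns"])
    return TruthParams(
        beta_mean=dict(d["beta_mean"]),
        beta_sd=dict(d["beta_sd"]),
        selection_coefs=coefs,
        seed=int(d.get("seed", 0)),
        preference_shifts={k: dict(v) for k, v in d.get("preference_shifts", {}).items()},
    )


def write_study(study: SyntheticStudy, outdir: str | Path) -> None:
    """Write respondents.csv, outlets.csv, choices.csv and truth.json (UTF-8,
    comma-delimited, '.' decimal separator)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study.respondents.to_csv(outdir / "respondents.csv", index=False)
    study.outlets.to_csv(outdir / "outlets.csv", index=False)
    linked = study.respondents.dropna(subset=["chosen_outlet_id"])
    linked[["respondent_id", "chosen_outlet_id"]].to_csv(outdir / "choices.csv", index=False)
    (outdir / "truth.json").write_text(json.dumps(truth_to_dict(study.truth), indent=2))


def load_design(path: str | Path) -> StudyDesign:
    """Load a study design from a YAML config file.

    Top-level keys: ``site`` (SiteConfig fields), ``attributes`` (per-type rows in
    the audit-table shape, or the name of a bundled table), ``covariates``
    (CovariateModel fields, optional), ``truth`` (optional overrides of the
    default truth), and mandatory ``seed``.
    """
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict) or "seed" not in cfg:
        raise ConfigurationError("config must be a mapping with a mandatory 'seed' key")
    seed = int(cfg["seed"])
    if "preset" in cfg:
        design = PRESETS[cfg["preset"]](seed=seed, **cfg.get("preset_args", {}))
        return design
    try:
        site = SiteConfig(**cfg["site"])
        attrs_cfg = cfg.get("attributes", "kenya")
        if attrs_cfg == "kenya":
            attrs = _attribute_model(KENYA_ATTRIBUTE_TABLE)
        elif attrs_cfg == "uganda":
            attrs = _attribute_model(UGANDA_ATTRIBUTE_TABLE)
        else:
            attrs = _attribute_model(attrs_cfg)
        covs = CovariateModel(**cfg.get("covariates", {}))
        truth = default_truth(seed)
        if "truth" in cfg:
            t = cfg["truth"]
            truth = dataclasses.replace(
                truth,
                beta_mean={**truth.beta_mean, **t.get("beta_mean", {})},
                beta_sd={**truth.beta_sd, **t.get("beta_sd", {})},
                preference_shifts=t.get("preference_shifts", truth.preference_shifts),
            )
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"invalid study config: {exc}") from exc
    return StudyDesign(site, attrs, covs, truth)
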