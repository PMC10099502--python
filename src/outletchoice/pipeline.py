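"""End-to-end pipeline: generate/load tables -> choice sets -> selection MNL and
IPW -> attribute screening -> conditional and mixed logit -> LR test ->
willingness to travel, with per-stage artifacts, record-count accounting, and a
deterministic report given the master seed."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .choice import HaltonConfig, fit_conditional_logit, fit_mixed_logit, lr_test, screen_attributes
from .errors import ConfigurationError, OutletChoiceError
from .selection import MNLSpec, compute_ipw, fit_mnl, predict_probs
from .supply import build_choice_sets, linkage_rate, summarize_environment
from .synthetic import (
    CATEGORIES,
    CHOICE_ATTRIBUTES,
    LINKED_CATEGORIES,
    PRESETS,
    RESPONDENT_COVARIATES,
    BINARY_ATTRIBUTES,
    StudyDesign,
    generate_study,
    load_design,
)

logger = logging.getLogger("outletchoice")

DEFAULT_ATTRIBUTES = [a for a in CHOICE_ATTRIBUTES]
DEFAULT_RANDOM_ATTRIBUTES = ["distance_km", "n_methods", "is_public"]
DEFAULT_COVARIATES = list(RESPONDENT_COVARIATES) + ["n_pharmacies", "n_public", "mean_methods"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.  Either a bundled preset name or paths
    to external respondent/outlet/link tables; the master seed is mandatory."""

    seed: int
    preset: str | None = "kenya_like"
    design_path: str | None = None
    respondents_path: str | None = None
    outlets_path: str | None = None
    links_path: str | None = None
    outdir: str | None = None
    choice_radius: float | None = None  # defaults to the site's radius
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    attributes: list[str] = field(default_factory=lambda: list(DEFAULT_ATTRIBUTES))
    random_attributes: list[str] = field(default_factory=lambda: list(DEFAULT_RANDOM_ATTRIBUTES))
    use_ipw: bool = True
    screen: bool = True
    p_drop: float = 0.3
    n_draws: int = 500
    burn: int = 10
    ci_method: str = "delta"
    n_respondents: int | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")


def load_run_config(path: str | Path) -> RunConfig:
    import yaml

    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ConfigurationError("run config must be a mapping")
    try:
        return RunConfig(**cfg)
    except TypeError as exc:
        raise ConfigurationError(f"invalid run config: {exc}") from exc


def stage_seeds(master_seed: int, n: int = 8) -> list[int]:
    """Per-stage seeds derived deterministically from the master seed via
    numpy's SeedSequence (values kept below 2^31)."""
    return [int(s) & 0x7FFFFFFF for s in np.random.SeedSequence(master_seed).generate_state(n)]


def validate_inputs(
    respondents: pd.DataFrame, outlets: pd.DataFrame, links: pd.DataFrame | None = None
) -> list[str]:
    """Structural validation; returns a list of violations (empty when clean)."""
    violations: list[str] = []
    if respondents["respondent_id"].duplicated().any():
        dup = respondents["respondent_id"][respondents["respondent_id"].duplicated()].tolist()
        violations.append(f"duplicated respondent ids: {dup[:5]}")
    if outlets["outlet_id"].duplicated().any():
        dup = outlets["outlet_id"][outlets["outlet_id"].duplicated()].tolist()
        violations.append(f"duplicated outlet ids: {dup[:5]}")
    for name, df in (("respondents", respondents), ("outlets", outlets)):
        coords = df[["x_km", "y_km"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(coords)):
            violations.append(f"non-finite coordinates in {name}")
    if "category" in respondents.columns:
        bad = respondents.loc[~respondents["category"].isin(CATEGORIES), "respondent_id"]
        if len(bad):
            violations.append(f"categories outside 1..6 for respondents: {bad.tolist()[:5]}")
    for attr in BINARY_ATTRIBUTES + ("is_public", "is_pharmacy"):
        if attr in outlets.columns and not outlets[attr].isin((0, 1)).all():
            violations.append(f"non-binary values in outlet attribute {attr!r}")
    if "n_methods" in outlets.columns:
        nm = outlets["n_methods"]
        if (nm < 1).any() or (nm > 12).any():
            violations.append("n_methods outside 1..12")
    if links is not None:
        unknown = set(links["chosen_outlet_id"].dropna()) - set(outlets["outlet_id"])
        if unknown:
            violations.append(f"chosen outlet ids absent from outlets: {sorted(unknown)[:5]}")
        unknown_r = set(links["respondent_id"]) - set(respondents["respondent_id"])
        if unknown_r:
            violations.append(f"link respondent ids absent from respondents: {sorted(unknown_r)[:5]}")
    return violations


def _load_tables(cfg: RunConfig):
    respondents = pd.read_csv(cfg.respondents_path)
    outlets = pd.read_csv(cfg.outlets_path)
    links = pd.read_csv(cfg.links_path) if cfg.links_path else None
    return respondents, outlets, links


def run_pipeline(cfg: RunConfig, design: StudyDesign | None = None) -> dict:
    """Execute all stages in order and return the run report.

    With ``use_ipw`` off, unit weights are used in the choice models.  Any stage
    error aborts the run with the stage named; artifacts of completed stages are
    retained in the output directory.
    """
    report: dict = {
        "config": {k: v for k, v in dataclasses.asdict(cfg).items()},
        "software": {"package": "outletchoice", "version": __version__},
        "stages": {},
    }
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(cfg.seed)
    stage = "setup"
    t_start = time.time()
    try:
        # -- stage: data ----------------------------------------------------
        stage = "data"
        if cfg.respondents_path:
            respondents, outlets, links = _load_tables(cfg)
            radius = cfg.choice_radius
            if radius is None:
                raise ConfigurationError("choice_radius required with external tables")
            truth = None
        else:
            if design is None:
                if cfg.design_path:
                    design = load_design(cfg.design_path)
                else:
                    kwargs = {"seed": seeds[0]}
                    if cfg.n_respondents:
                        kwargs["n_respondents"] = cfg.n_respondents
                    design = PRESETS[cfg.preset](**kwargs)
            study = generate_study(design, seed=seeds[0])
            respondents, outlets = study.respondents, study.outlets
            links = respondents.loc[
                respondents["chosen_outlet_id"].notna(), ["respondent_id", "chosen_outlet_id"]
            ]
            radius = cfg.choice_radius if cfg.choice_radius is not None else design.site.choice_radius
            truth = study.truth
            if outdir:
                from .synthetic import write_study

                write_study(study, outdir)
        violations = validate_inputs(respondents, outlets, links)
        if violations:
            raise OutletChoiceError(f"input validation failed: {violations}")
        report["stages"]["data"] = {
            "n_respondents": int(len(respondents)),
            "n_outlets": int(len(outlets)),
            "n_linked": int(len(links)) if links is not None else 0,
            "linkage_rate_pct": linkage_rate(len(respondents), len(links))
            if links is not None and len(respondents)
            else None,
        }

        # -- stage: supply environment --------------------------------------
        stage = "environment"
        env = summarize_environment(respondents, outlets, radius)
        # respondents with no in-radius outlet get an empty environment; impute
        # the population mean for the mean-methods covariate in the MNL design
        env_filled = env.copy()
        env_filled["mean_methods"] = env_filled["mean_methods"].fillna(
            env_filled["mean_methods"].mean()
        )
        mnl_data = respondents.merge(env_filled, on="respondent_id")
        if outdir:
            env.to_csv(outdir / "environment.csv", index=False)
        report["stages"]["environment"] = {
            "n_rows": int(len(env)),
            "n_empty_environments": int((env["n_outlets"] == 0).sum()),
        }

        # -- stage: selection model and weights ------------------------------
        stage = "selection"
        linked_mask = respondents["category"].isin(LINKED_CATEGORIES)
        if cfg.use_ipw:
            covs = [c for c in cfg.covariates if c in mnl_data.columns]
            mnl_fit = fit_mnl(mnl_data, MNLSpec(covariates=tuple(covs)))
            probs = predict_probs(mnl_fit, mnl_data)
            cats = mnl_data.set_index("respondent_id")["category"]
            probs.index = mnl_data["respondent_id"]
            weights = compute_ipw(probs, cats)
            if outdir:
                mnl_fit.to_json(outdir / "mnl_fit.json")
                weights.to_csv(outdir / "ipw.csv", index=False)
            report["stages"]["selection"] = {
                "n": mnl_fit.n,
                "loglik": mnl_fit.loglik,
                "n_weighted": int(len(weights)),
                "mean_weight": float(weights["weight"].mean()),
            }
        else:
            weights = pd.DataFrame(
                {
                    "respondent_id": respondents.loc[linked_mask, "respondent_id"],
                    "p_hat": np.nan,
                    "weight": 1.0,
                }
            )
            report["stages"]["selection"] = {"n_weighted": int(len(weights)), "ipw": False}

        # -- stage: choice sets ----------------------------------------------
        stage = "choice_sets"
        linked = respondents[linked_mask]
        chosen_links = linked.set_index("respondent_id")["chosen_outlet_id"]
        cs, cs_report = build_choice_sets(linked, outlets, radius, chosen_links=chosen_links)
        from .choice import filter_estimable

        cs, excluded_small = filter_estimable(cs)
        usable = cs["respondent_id"].unique()
        weights = weights[weights["respondent_id"].isin(usable)]
        if outdir:
            cs.to_csv(outdir / "choice_sets.csv", index=False)
            pd.DataFrame(
                {
                    "respondent_id": cs_report["empty_choice_sets"] + excluded_small,
                    "reason": ["empty_choice_set"] * len(cs_report["empty_choice_sets"])
                    + ["single_alternative"] * len(excluded_small),
                }
            ).to_csv(outdir / "exclusions.csv", index=False)
        report["stages"]["choice_sets"] = {
            "n_choosers_in": int(len(linked)),
            "n_choosers_used": int(len(usable)),
            "n_rows": int(len(cs)),
            "n_excluded": int(len(linked) - len(usable)),
            "n_out_of_radius_chosen": int(len(cs_report["out_of_radius_chosen"])),
        }

        # -- stage: screening -------------------------------------------------
        stage = "screening"
        if cfg.screen:
            retained, screen_log = screen_attributes(
                cs, list(cfg.attributes), weights, p_drop=cfg.p_drop
            )
            if outdir:
                screen_log.to_csv(outdir / "screening_log.csv", index=False)
        else:
            retained, screen_log = list(cfg.attributes), pd.DataFrame()
        report["stages"]["screening"] = {
            "candidates": list(cfg.attributes),
            "retained": retained,
        }

        # -- stage: conditional logit -----------------------------------------
        stage = "conditional_logit"
        clog = fit_conditional_logit(cs, retained, weights)
        if outdir:
            clog.to_json(outdir / "clogit_fit.json")
        report["stages"]["conditional_logit"] = {
            "loglik": clog.loglik,
            "n_choosers": clog.n_choosers,
            "params": clog.params.to_dict(),
        }

        # -- stage: mixed logit -------------------------------------------------
        stage = "mixed_logit"
        random_attrs = [a for a in cfg.random_attributes if a in retained]
        halton = HaltonConfig(n_draws=cfg.n_draws, burn=cfg.burn, seed=seeds[1])
        mixl = fit_mixed_logit(cs, retained, random_attrs, weights, halton)
        if outdir:
            mixl.to_json(outdir / "mixedlogit_fit.json")
        report["stages"]["mixed_logit"] = {
            "loglik": mixl.loglik,
            "means": mixl.params.to_dict(),
            "sds": mixl.sds.to_dict(),
            "converged": mixl.converged,
        }

        # -- stage: LR test -----------------------------------------------------
        stage = "lr_test"
        stat, df, p = lr_test(clog, mixl)
        report["stages"]["lr_test"] = {"statistic": stat, "df": df, "p_value": p}

        # -- stage: willingness to travel ----------------------------------------
        stage = "wtt"
        from .wtt import wtt_confidence_interval

        wtt_table = wtt_confidence_interval(
            mixl, method=cfg.ci_method, seed=seeds[2]
        )
        if outdir:
            wtt_table[["attribute", "wtt_km", "ci_low", "ci_high", "method"]].to_csv(
                outdir / "wtt.csv", index=False
            )
        report["stages"]["wtt"] = {
            "table": wtt_table[["attribute", "wtt_km", "ci_low", "ci_high"]].to_dict("records")
        }
        if truth is not None:
            report["truth_wtt"] = {
                a: -truth.beta_mean.get(a, 0.0) / truth.beta_mean["distance_km"]
                for a in retained
                if a != "distance_km"
            }
    except Exception as exc:
        raise OutletChoiceError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    logger.info("pipeline finished in %.1fs", time.time() - t_start)
    if outdir:
        (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
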