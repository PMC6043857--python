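"""End-to-end orchestration: generate/load -> prepare -> fit -> test -> report.

Produces, per outcome, a full-model parameter table (MAP and 95% HDI for
the 25 fixed effects and 4 variance-structure parameters), a
prior-sensitivity table with Savage-Dickey Bayes factors, model-implied
trajectories for chosen education offsets, and a plain-text log of seeds,
sampler settings and per-parameter R-hat so the convergence claim is
auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bayes_factors import SensitivityGrid, run_sensitivity, sensitivity_table
from .model import BayesianGrowthModel, PriorSpec, hdi, RHAT_THRESHOLD
from .names import FIXED_EFFECT_LABELS
from .prepare import PrepConfig, prepare
from .simulate import (
    LongitudinalDataset, StudyDesign, TrueParameters,
    betula_like_design, betula_like_truth, generate,
)

GAMMA05_LABEL = "Cohort x education"


@dataclass(frozen=True)
class TrajectoryProfile:
    """Covariate profile for model-implied trajectories.

    Default: men born in 1935, first sample, education 3 years below /
    at / above the education centre, ages 35-85.
    """

    birth_year: float = 1935.0
    sex: float = 0.0
    sample_code: float = 0.0
    education_offsets: tuple[float, ...] = (-3.0, 0.0, 3.0)
    age_start: float = 35.0
    age_stop: float = 85.0
    age_step: float = 1.0


@dataclass
class RunConfig:
    """Settings for a full analysis run."""

    input_path: str = "synthetic"          # CSV path, or "synthetic"
    outcomes: tuple[str, ...] = ("va", "sk", "em")
    seed: int = 0
    prep: PrepConfig = field(default_factory=PrepConfig)
    prior: PriorSpec = field(default_factory=PriorSpec)
    multipliers: tuple[float, ...] = (1.0, 2.0, 4.0)
    base_estimates: dict | None = None     # outcome -> |base effect| override
    n_chains: int = 4
    n_draws: int = 2000
    n_warmup: int | None = None
    design: StudyDesign | None = None      # used when input_path == "synthetic"
    truth: dict | TrueParameters | None = None
    profile: TrajectoryProfile = field(default_factory=TrajectoryProfile)
    output_dir: str = "eduslope_out"
    fail_on_nonconvergence: bool = True

    def __post_init__(self) -> None:
        if not self.outcomes:
            raise ValueError("outcome selection must be nonempty")


def implied_trajectories(gamma, profile: TrajectoryProfile,
                         centers: dict, quad_coefficients: dict) -> pd.DataFrame:
    """Fixed-effects trajectories over age for each education offset.

    ``gamma`` is a named vector over the 25 design columns; random effects
    are set to zero.  ``centers`` and ``quad_coefficients`` are the basis
    information recorded by the preparation stage, so the quadratic term is
    evaluated exactly as the model saw it.
    """
    from .prepare import build_design

    gamma = pd.Series(gamma)
    g = gamma[list(FIXED_EFFECT_LABELS)].to_numpy(dtype=float)
    ages = np.arange(profile.age_start, profile.age_stop + 1e-9,
                     profile.age_step)
    alpha, beta = quad_coefficients["alpha"], quad_coefficients["beta"]
    rows = []
    for off in profile.education_offsets:
        age_c = ages - centers["age"]
        covs = pd.DataFrame({
            "age_lin": age_c,
            "age_quad": age_c**2 - alpha - beta * age_c,
            "cohort_c": np.full_like(ages, profile.birth_year - centers["cohort"]),
            "edu_c": np.full_like(ages, off),
            "sex": np.full_like(ages, profile.sex),
            "sample_code": np.full_like(ages, profile.sample_code),
        })
        pred = build_design(covs).to_numpy() @ g
        rows.append(pd.DataFrame({
            "age": ages, "education_offset": off, "predicted": pred,
        }))
    return pd.concat(rows, ignore_index=True)


def trajectory_slope_differences(draws, profile: TrajectoryProfile,
                                 centers: dict,
                                 quad_coefficients: dict) -> dict:
    """Posterior draws of pairwise trajectory slope differences.

    For two education offsets e1 < e2 the difference of the two implied
    curves has age-derivative (e2 - e1) * (g12 + g22 * (2*age_c - beta) +
    cohort and sex modulation at the profile); averaged over the profile's
    age grid this is a single linear functional of the draws.  Under
    parallel trajectories (g12 = g22 = 0 at the profile) it is zero.
    """
    ages = np.arange(profile.age_start, profile.age_stop + 1e-9,
                     profile.age_step)
    age_c = ages - centers["age"]
    beta = quad_coefficients["beta"]
    dquad = float(np.mean(2 * age_c - beta))   # mean d(age_quad)/d(age)
    coh = profile.birth_year - centers["cohort"]
    sex = profile.sex

    def slope_coef(prefix: str) -> np.ndarray:
        # derivative of the education-linked part of the age slope
        g = draws.pooled(f"{prefix} x education") \
            + coh * draws.pooled(f"{prefix} x cohort x education") \
            + sex * draws.pooled(f"{prefix} x education x sex") \
            + coh * sex * draws.pooled(f"{prefix} x cohort x education x sex")
        return g

    per_edu_slope = slope_coef("LS") + dquad * slope_coef("QS")
    offs = profile.education_offsets
    out = {}
    for i in range(len(offs)):
        for j in range(i + 1, len(offs)):
            delta = offs[j] - offs[i]
            out[(offs[i], offs[j])] = delta * per_edu_slope
    return out


def exploratory_gamma05_report(summaries: dict) -> pd.DataFrame:
    """Interval-estimation report for the cohort-by-education parameter.

    ``summaries`` maps outcome label to a fit summary DataFrame.  The flag
    is True only when the 95% HDI strictly excludes zero (a boundary at
    zero counts as inclusion).  No Bayes factor is computed for this
    exploratory parameter.
    """
    rows = []
    for outcome, summary in summaries.items():
        s = summary.loc[GAMMA05_LABEL]
        lo, hi = float(s["hdi_low"]), float(s["hdi_high"])
        rows.append({
            "outcome": outcome,
            "map": float(s["map"]),
            "hdi_low": lo,
            "hdi_high": hi,
            "excludes_zero": bool(lo > 0 or hi < 0),
        })
    return pd.DataFrame(rows)


def _load_or_generate(cfg: RunConfig) -> LongitudinalDataset:
    if cfg.input_path != "synthetic":
        return LongitudinalDataset.read_csv(cfg.input_path)
    design = cfg.design or betula_like_design()
    truth = cfg.truth
    if truth is None:
        truth = {k: betula_like_truth(k) for k in ("va", "sk", "em")}
    return generate(design, truth, seed=cfg.seed)


def run_analysis(cfg: RunConfig) -> dict:
    """Run the full pipeline and write the report bundle.

    Per outcome: ``table1_<outcome>.csv`` (all-parameter MAP/HDI/R-hat under
    the weakly informative prior), ``table2_<outcome>.csv`` (sensitivity +
    Bayes factors), ``trajectories_<outcome>.csv``; plus
    ``gamma05_report.csv``, ``run_log.txt`` and ``metadata.json``.
    Returns the bundle as in-memory objects; raises if any headline fit
    fails the R-hat < 1.01 protocol.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = _load_or_generate(cfg)

    log_lines = [
        f"seed: {cfg.seed}",
        f"sampler: {cfg.n_chains} chains x {cfg.n_draws} draws "
        f"(warmup {cfg.n_warmup if cfg.n_warmup is not None else cfg.n_draws})",
    ]
    bundle: dict = {"tables1": {}, "tables2": {}, "trajectories": {},
                    "summaries": {}, "converged": True}
    for outcome in cfg.outcomes:
        prepared = prepare(data, outcome=outcome, cfg=cfg.prep)
        model = BayesianGrowthModel(
            prior=cfg.prior, n_chains=cfg.n_chains, n_draws=cfg.n_draws,
            n_warmup=cfg.n_warmup, random_state=cfg.seed,
        )
        model.fit_prepared(prepared)
        summary = model.summary_
        table1 = summary[["map", "hdi_low", "hdi_high", "rhat"]].copy()
        table1.index.name = "parameter"
        table1.to_csv(outdir / f"table1_{outcome}.csv", float_format="%.6g")

        grid = SensitivityGrid.for_outcome(
            outcome, multipliers=cfg.multipliers,
            base_estimates=cfg.base_estimates,
        )
        sens = run_sensitivity(
            prepared, grid, outcome=outcome, prior=cfg.prior,
            n_chains=cfg.n_chains, n_draws=cfg.n_draws,
            n_warmup=cfg.n_warmup, seed=cfg.seed,
        )
        table2 = sensitivity_table(sens)
        table2.to_csv(outdir / f"table2_{outcome}.csv", index=False,
                      float_format="%.6g")

        gamma_map = summary.loc[list(FIXED_EFFECT_LABELS), "map"]
        traj = implied_trajectories(gamma_map, cfg.profile,
                                    prepared.centers,
                                    prepared.quad_coefficients)
        traj.to_csv(outdir / f"trajectories_{outcome}.csv", index=False,
                    float_format="%.6g")

        max_rhat = float(summary["rhat"].max())
        bundle["tables1"][outcome] = table1
        bundle["tables2"][outcome] = table2
        bundle["trajectories"][outcome] = traj
        bundle["summaries"][outcome] = summary
        bundle["converged"] &= model.converged_
        log_lines.append(
            f"{outcome}: n_persons={prepared.n_persons} "
            f"n_obs={len(prepared.y)} max_rhat={max_rhat:.5f} "
            f"converged={model.converged_} "
            f"exclusions={prepared.exclusion_report}"
        )
        log_lines.append(
            f"{outcome} rhat: " + " ".join(
                f"{k}={v:.4f}" for k, v in summary["rhat"].items()
            )
        )

    g05 = exploratory_gamma05_report(bundle["summaries"])
    g05.to_csv(outdir / "gamma05_report.csv", index=False,
               float_format="%.6g")
    bundle["gamma05"] = g05

    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    with open(outdir / "metadata.json", "w") as fh:
        json.dump({
            "seed": cfg.seed,
            "outcomes": list(cfg.outcomes),
            "n_chains": cfg.n_chains,
            "n_draws": cfg.n_draws,
            "rhat_threshold": RHAT_THRESHOLD,
            "converged": bool(bundle["converged"]),
        }, fh, indent=1)
    if cfg.fail_on_nonconvergence and not bundle["converged"]:
        raise RuntimeError(
            "convergence protocol failed: some R-hat >= "
            f"{RHAT_THRESHOLD}; see run_log.txt"
        )
    return bundle


def load_run_config(path) -> RunConfig:
    """Read a RunConfig from a YAML file (flat keys; nested prep/prior maps)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "seed" not in raw:
        raise KeyError("config must contain a 'seed' key")
    kwargs = {}
    simple = {f.name for f in dc_fields(RunConfig)} - {"prep", "prior",
                                                       "design", "truth",
                                                       "profile"}
    for k in list(raw):
        if k in simple:
            v = raw.pop(k)
            kwargs[k] = tuple(v) if isinstance(v, list) else v
    if "prep" in raw:
        kwargs["prep"] = PrepConfig(**{
            k: tuple(tuple(b) if isinstance(b, list) else b for b in v)
            if k == "excluded_cohorts" else v
            for k, v in raw.pop("prep").items()
        })
    if "prior" in raw:
        kwargs["prior"] = PriorSpec(**raw.pop("prior"))
    if "design" in raw:
        d = {k: tuple(v) if isinstance(v, list) else v
             for k, v in raw.pop("design").items()}
        kwargs["design"] = StudyDesign(**d)
    if "truth" in raw:
        t = raw.pop("truth")
        gamma = {k: t.pop(k) for k in list(t)
                 if k.startswith("g") and k[1:].isdigit()}
        kwargs["truth"] = TrueParameters(gamma=gamma, **t)
    if "profile" in raw:
        p = {k: tuple(v) if isinstance(v, list) else v
             for k, v in raw.pop("profile").items()}
        kwargs["profile"] = TrajectoryProfile(**p)
    if raw:
        raise KeyError(f"unknown config keys: {sorted(raw)}")
    return RunConfig(**kwargs)
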