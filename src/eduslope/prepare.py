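"""Data preparation: exclusions, T-standardisation, centering, design matrices.

Turns long-format person-period records into the quantities the growth model
consumes: T-standardised outcomes (mean 50, SD 10 anchored to the first
measurement occasion), covariates centred at fixed constants (or at the
current data's means), a linear + orthogonalised-quadratic age basis, and a
25-column fixed-effects design matrix with named columns.

Conventions fixed here so results are bit-reproducible:

* the baseline SD for T-standardisation is the population SD (``ddof=0``);
* the quadratic age term is the raw residual of ``age_c**2`` after projection
  onto ``{1, age_c}`` over all retained person-period rows pooled, not
  rescaled to unit norm;
* sample is coded S1 -> 0, S3 (second sample) -> 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .names import (
    FIXED_EFFECT_LABELS,
    INTERCEPT_LABELS,
    LINEAR_LABELS,
    QUADRATIC_LABELS,
)
from .simulate import LongitudinalDataset, OUTCOMES

EXCLUSION_RULES = (
    "excluded_cohort",
    "education_missing",
    "education_above_max",
    "education_below_min",
)


@dataclass(frozen=True)
class PrepConfig:
    """Preparation settings; defaults follow the Betula analysis constants."""

    age_center: float = 62.9
    cohort_center: float = 1933.0
    education_center: float = 10.2
    t_mean: float = 50.0
    t_sd: float = 10.0
    education_max_allowed: float = 25.0
    # proxy for "less than compulsory schooling" (6-7 years for these cohorts)
    education_min_allowed: float = 6.0
    excluded_cohorts: tuple = ((1908, 1910), (1958, 1960))
    recompute_centers_from_data: bool = False

    def __post_init__(self) -> None:
        if self.t_sd <= 0:
            raise ValueError("t_sd must be positive")
        if not self.education_min_allowed < self.education_max_allowed:
            raise ValueError("education_min_allowed must be < education_max_allowed")

    def cohort_excluded(self, birth_year: float) -> bool:
        for band in self.excluded_cohorts:
            if isinstance(band, (tuple, list)):
                lo, hi = band
            else:  # single midpoint: 3-year band like the study's design cells
                lo, hi = band - 1, band + 1
            if lo <= birth_year <= hi:
                return True
        return False


class AgeBasis(NamedTuple):
    """Linear and orthogonalised quadratic age terms plus the projection
    coefficients (alpha, beta) with ``quad = age_c**2 - alpha - beta*age_c``."""

    lin: np.ndarray
    quad: np.ndarray
    alpha: float
    beta: float


@dataclass
class PreparedDataset:
    """Model-ready data for one outcome."""

    frame: pd.DataFrame          # person_id, wave, outcome_t + covariate columns
    X: pd.DataFrame              # 25 named fixed-effect columns, one row per obs
    y: np.ndarray                # T-standardised outcome
    person_ids: np.ndarray       # person id per row of X
    outcome: str
    baseline_mean: float
    baseline_sd: float
    centers: dict
    quad_coefficients: dict      # {"alpha": ..., "beta": ...}
    exclusion_report: dict
    config: PrepConfig

    @property
    def n_persons(self) -> int:
        return len(np.unique(self.person_ids))

    def write(self, prefix) -> None:
        """Persist as CSV: long rows, design matrix, and exclusion report."""
        import json
        from pathlib import Path

        prefix = Path(prefix)
        self.frame.to_csv(f"{prefix}_rows.csv", index=False, float_format="%.10g")
        self.X.to_csv(f"{prefix}_design.csv", index=False, float_format="%.10g")
        with open(f"{prefix}_exclusions.json", "w") as fh:
            json.dump(self.exclusion_report, fh, indent=1)


def derive_education(per_wave_reports: Sequence[float]) -> float:
    """Person-level education: the maximum of the per-wave self-reports.

    Missing entries (NaN/None) are ignored; all-missing yields NaN.
    """
    values = np.asarray(
        [np.nan if v is None else float(v) for v in per_wave_reports], dtype=float
    )
    finite = values[np.isfinite(values)]
    if np.any(finite < 0):
        raise ValueError("education years cannot be negative")
    if finite.size == 0:
        return float("nan")
    return float(finite.max())


def _person_education(frame: pd.DataFrame) -> pd.Series:
    edu = frame.groupby("person_id")["education"].max()
    neg = frame["education"].dropna() < 0
    if neg.any():
        raise ValueError("education years cannot be negative")
    return edu


def apply_exclusions(
    data: LongitudinalDataset, cfg: PrepConfig
) -> tuple[LongitudinalDataset, dict]:
    """Remove persons per the study's filters, in fixed order.

    Rules, each person counted once under the first that fires:
    (a) born in an excluded cohort band, (b) education missing at every wave,
    (c) derived education above the maximum allowed, (d) below the minimum.
    """
    frame = data.frame
    report = dict.fromkeys(EXCLUSION_RULES, 0)
    edu = _person_education(frame)
    birth = frame.groupby("person_id")["birth_year"].first()

    drop: dict = {}
    for pid, by in birth.items():
        if cfg.cohort_excluded(by):
            drop[pid] = "excluded_cohort"
        elif pd.isna(edu.get(pid, np.nan)):
            drop[pid] = "education_missing"
        elif edu[pid] > cfg.education_max_allowed:
            drop[pid] = "education_above_max"
        elif edu[pid] < cfg.education_min_allowed:
            drop[pid] = "education_below_min"
    for rule in drop.values():
        report[rule] += 1
    kept = frame[~frame["person_id"].isin(drop)].reset_index(drop=True)
    return LongitudinalDataset(frame=kept, meta=dict(data.meta)), report


def t_standardize(
    scores: Sequence[float], waves: Sequence[int], cfg: PrepConfig | None = None
) -> tuple[np.ndarray, float, float]:
    """T-standardise scores against the first measurement occasion.

    The baseline mean and (population) SD are computed from the non-missing
    scores at the earliest wave present; the same affine map is applied to
    every wave.  Returns ``(t_scores, baseline_mean, baseline_sd)``.
    """
    cfg = cfg or PrepConfig()
    scores = np.asarray(scores, dtype=float)
    waves = np.asarray(waves)
    first = waves.min()
    base = scores[(waves == first) & np.isfinite(scores)]
    if base.size < 2:
        raise ValueError("first occasion needs at least 2 non-missing scores")
    m = float(base.mean())
    s = float(base.std(ddof=0))
    if s == 0:
        raise ValueError(
            "first-occasion scores have zero standard deviation; "
            "T-standardisation is undefined"
        )
    return cfg.t_mean + cfg.t_sd * (scores - m) / s, m, s


def center_covariates(
    age, cohort, education, cfg: PrepConfig | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Subtract the configured centers from age, cohort and education."""
    cfg = cfg or PrepConfig()
    return (
        np.asarray(age, dtype=float) - cfg.age_center,
        np.asarray(cohort, dtype=float) - cfg.cohort_center,
        np.asarray(education, dtype=float) - cfg.education_center,
    )


def orthogonal_age_basis(ages_c: Sequence[float]) -> AgeBasis:
    """Decompose centred age into a linear term and an orthogonal quadratic.

    The quadratic is the least-squares residual of ``age_c**2`` on
    ``{1, age_c}`` over the supplied rows (observation-weighted), so that
    ``sum(quad) = sum(quad * lin) = 0`` up to round-off.
    """
    x = np.asarray(ages_c, dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct ages to identify a quadratic")
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, x**2, rcond=None)
    alpha, beta = float(coef[0]), float(coef[1])
    return AgeBasis(lin=x, quad=x**2 - alpha - beta * x, alpha=alpha, beta=beta)


def build_design(rows: pd.DataFrame) -> pd.DataFrame:
    """Assemble the 25-column fixed-effects design matrix.

    ``rows`` must provide age_lin, age_quad, cohort_c, edu_c, sex and
    sample_code.  Sample enters the intercept block only (a main effect);
    cohort, education and sex interact with each other and with both age
    terms.
    """
    required = ["age_lin", "age_quad", "cohort_c", "edu_c", "sex", "sample_code"]
    missing = [c for c in required if c not in rows.columns]
    if missing:
        raise ValueError(f"missing covariate columns: {missing}")
    if rows[required].isna().any().any():
        raise ValueError("covariates contain missing values")

    one = np.ones(len(rows))
    coh = rows["cohort_c"].to_numpy(float)
    edu = rows["edu_c"].to_numpy(float)
    sex = rows["sex"].to_numpy(float)
    smp = rows["sample_code"].to_numpy(float)
    lin = rows["age_lin"].to_numpy(float)
    qua = rows["age_quad"].to_numpy(float)

    base = [one, coh, edu, sex, coh * edu, coh * sex, edu * sex, coh * edu * sex]
    cols = {}
    intercept_block = base[:4] + [smp] + base[4:]
    for name, col in zip(INTERCEPT_LABELS, intercept_block):
        cols[name] = col
    for name, col in zip(LINEAR_LABELS, (lin * b for b in base)):
        cols[name] = col
    for name, col in zip(QUADRATIC_LABELS, (qua * b for b in base)):
        cols[name] = col
    X = pd.DataFrame(cols, index=rows.index)
    assert list(X.columns) == list(FIXED_EFFECT_LABELS)
    return X


def prepare(
    data: LongitudinalDataset,
    outcome: str = "em",
    cfg: PrepConfig | None = None,
) -> PreparedDataset:
    """Full preparation for one outcome: filter, standardise, centre, design."""
    preparer = GrowthDataPreparer(outcome=outcome, config=cfg)
    return preparer.fit_transform(data)


class GrowthDataPreparer:
    """Estimator-style preparer: ``fit`` learns the standardisation constants,
    centers and age-basis coefficients from a dataset; ``transform`` applies
    them.  ``fit_transform`` on the analysis data is the ordinary path; a
    fitted preparer can also transform new data on the training basis.
    """

    def __init__(self, outcome: str = "em", config: PrepConfig | None = None):
        self.outcome = outcome
        self.config = config

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"outcome": self.outcome, "config": self.config}

    def set_params(self, **params) -> "GrowthDataPreparer":
        for k, v in params.items():
            if k not in ("outcome", "config"):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    # ---------------------------------------------------------------------
    def _retained(self, data: LongitudinalDataset, cfg: PrepConfig):
        if self.outcome not in OUTCOMES:
            raise ValueError(f"outcome must be one of {OUTCOMES}")
        filtered, report = apply_exclusions(data, cfg)
        frame = filtered.frame.copy()
        edu = _person_education(frame)
        frame["education_derived"] = frame["person_id"].map(edu)
        frame["age"] = (frame["test_year"] - frame["birth_year"]).astype(float)
        keep = np.isfinite(frame[self.outcome].to_numpy(float))
        keep &= np.isfinite(frame["education_derived"].to_numpy(float))
        return frame[keep].reset_index(drop=True), report

    def fit(self, data: LongitudinalDataset) -> "GrowthDataPreparer":
        cfg = self.config or PrepConfig()
        frame, report = self._retained(data, cfg)
        if len(frame) == 0:
            raise ValueError("no rows retained after exclusions")
        _, m, s = t_standardize(
            frame[self.outcome].to_numpy(float), frame["wave"].to_numpy(), cfg
        )
        if cfg.recompute_centers_from_data:
            centers = {
                "age": float(frame["age"].mean()),
                "cohort": float(frame["birth_year"].mean()),
                "education": float(frame["education_derived"].mean()),
            }
        else:
            centers = {
                "age": cfg.age_center,
                "cohort": cfg.cohort_center,
                "education": cfg.education_center,
            }
        basis = orthogonal_age_basis(frame["age"].to_numpy(float) - centers["age"])
        self.config_ = cfg
        self.baseline_mean_ = m
        self.baseline_sd_ = s
        self.centers_ = centers
        self.quad_coefficients_ = {"alpha": basis.alpha, "beta": basis.beta}
        self.exclusion_report_ = report
        return self

    def transform(self, data: LongitudinalDataset) -> PreparedDataset:
        if not hasattr(self, "baseline_mean_"):
            raise RuntimeError("preparer is not fitted")
        cfg = self.config_
        frame, report = self._retained(data, cfg)
        raw = frame[self.outcome].to_numpy(float)
        y = cfg.t_mean + cfg.t_sd * (raw - self.baseline_mean_) / self.baseline_sd_
        c = self.centers_
        age_c = frame["age"].to_numpy(float) - c["age"]
        alpha, beta = self.quad_coefficients_["alpha"], self.quad_coefficients_["beta"]
        covs = pd.DataFrame({
            "age_lin": age_c,
            "age_quad": age_c**2 - alpha - beta * age_c,
            "cohort_c": frame["birth_year"].to_numpy(float) - c["cohort"],
            "edu_c": frame["education_derived"].to_numpy(float) - c["education"],
            "sex": frame["sex"].to_numpy(float),
            "sample_code": (frame["sample"] == "S3").astype(float).to_numpy(),
        })
        X = build_design(covs)
        out_frame = pd.concat(
            [frame[["person_id", "wave", "test_year"]].reset_index(drop=True),
             pd.Series(y, name="outcome_t"),
             covs.reset_index(drop=True)],
            axis=1,
        )
        return PreparedDataset(
            frame=out_frame,
            X=X,
            y=y,
            person_ids=frame["person_id"].to_numpy(),
            outcome=self.outcome,
            baseline_mean=self.baseline_mean_,
            baseline_sd=self.baseline_sd_,
            centers=dict(c),
            quad_coefficients={"alpha": alpha, "beta": beta},
            exclusion_report=report,
            config=cfg,
        )

    def fit_transform(self, data: LongitudinalDataset) -> PreparedDataset:
        return self.fit(data).transform(data)
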