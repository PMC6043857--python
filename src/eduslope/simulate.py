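"""Synthetic cohort-sequential longitudinal data with known ground truth.

Emulates the design of the Betula study: 5-year birth cohorts, two samples
entering the study five years apart, five measurement waves at 5-year
intervals, ~100 persons per (sample, cohort) cell, monotone attrition, and
three cognitive outcomes (visuospatial ability ``va``, semantic knowledge
``sk``, episodic memory ``em``) produced by the hierarchical growth model
this package fits.  Because the truth is known, every downstream stage
(preparation, MCMC fit, Bayes-factor test) is testable without access to
the original cohort data, which are not publicly deposited.

Outcomes are generated on the same centred / orthogonalised covariate basis
the preparation stage builds, so that preparing the generated data with
``recompute_centers_from_data=True`` reproduces the generating design matrix
exactly — the round-trip is exact, not approximate, even under dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .names import (
    FIXED_EFFECT_LABELS,
    VARIANCE_LABELS,
    normalize_gamma_name,
)

OUTCOMES = ("va", "sk", "em")

CSV_COLUMNS = [
    "person_id", "birth_year", "sex", "sample", "wave", "test_year",
    "education", "va", "sk", "em",
]


@dataclass(frozen=True)
class StudyDesign:
    """Structural description of a cohort-sequential study.

    ``cohort_birth_years`` are the midpoints of the (3-year wide) birth bands;
    ``sample_entry_waves`` maps sample label to the wave index at which that
    sample enters; everyone present at a wave is retested at later waves
    unless lost to dropout (``dropout_hazard`` per attended wave).
    """

    cohort_birth_years: tuple[int, ...] = tuple(range(1909, 1960, 5))
    persons_per_cell: int = 100
    sample_entry_waves: Mapping[str, int] = field(
        default_factory=lambda: {"S1": 0, "S3": 1}
    )
    wave_years: tuple[int, ...] = (1989, 1994, 1999, 2004, 2009)
    wave_spacing: int = 5
    dropout_hazard: float = 0.15
    female_fraction: float = 0.54
    education_mean: float = 10.2
    education_sd: float = 3.0
    education_min: int = 0
    education_max: int = 30
    age_jitter: bool = False
    education_report_noise: bool = False

    def __post_init__(self) -> None:
        wy = np.asarray(self.wave_years)
        if len(wy) < 2 or np.any(np.diff(wy) != self.wave_spacing):
            raise ValueError(
                "wave_years must be strictly increasing with constant "
                f"spacing {self.wave_spacing}"
            )
        if self.persons_per_cell <= 0:
            raise ValueError("persons_per_cell must be positive")
        for label, w in self.sample_entry_waves.items():
            if not 0 <= int(w) < len(self.wave_years):
                raise ValueError(f"entry wave {w} for sample {label} out of range")
        for name in ("dropout_hazard", "female_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not self.education_min <= self.education_mean <= self.education_max:
            raise ValueError("education_min <= education_mean <= education_max required")

    @property
    def n_waves(self) -> int:
        return len(self.wave_years)


@dataclass(frozen=True)
class TrueParameters:
    """Ground-truth parameters of the generating growth model.

    ``gamma`` maps fixed-effect names (labels or short ids like ``g12``) to
    values in T-score units per covariate unit; unnamed effects default to 0.
    ``sd_u0``/``sd_u1`` are the between-person SDs of the random intercept
    and random linear age slope, ``rho`` their correlation, and ``sd_resid``
    the occasion-level residual SD, all on the T-score scale.
    """

    gamma: Mapping[str, float] = field(default_factory=dict)
    sd_u0: float = 5.7
    sd_u1: float = 0.075
    rho: float = 0.49
    sd_resid: float = 6.4

    def __post_init__(self) -> None:
        full = dict.fromkeys(FIXED_EFFECT_LABELS, 0.0)
        for name, value in dict(self.gamma).items():
            full[normalize_gamma_name(name)] = float(value)
        object.__setattr__(self, "gamma", full)
        for name in ("sd_u0", "sd_u1", "sd_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if abs(self.rho) > 1:
            raise ValueError("|rho| must not exceed 1")

    def gamma_vector(self) -> np.ndarray:
        return np.array([self.gamma[k] for k in FIXED_EFFECT_LABELS])

    def random_effects_cov(self) -> np.ndarray:
        c = self.rho * self.sd_u0 * self.sd_u1
        return np.array([[self.sd_u0**2, c], [c, self.sd_u1**2]])


# MAP estimates of the episodic-memory fit of the Betula data; used as the
# default "realistic" truth profile for the generator.
_BETULA_LIKE_TRUTH = {
    "em": TrueParameters(
        gamma={
            "g00": 47.294, "g01": 0.248, "g02": 0.445, "g03": 1.835,
            "g04": -0.959, "g05": -0.001, "g06": -0.116, "g07": 0.344,
            "g08": -0.006, "g10": -0.198, "g11": 0.001, "g12": 0.006,
            "g13": -0.030, "g14": -0.001, "g15": -0.004, "g16": 0.002,
            "g17": 0.000, "g20": -0.121, "g21": 0.002, "g22": -0.013,
            "g23": -0.074, "g24": 0.001, "g25": 0.001, "g26": 0.011,
            "g27": 0.000,
        },
        sd_u0=5.703, sd_u1=0.075, rho=0.494, sd_resid=6.434,
    ),
    "va": TrueParameters(
        gamma={
            "g00": 48.441, "g01": 0.096, "g02": 0.655, "g03": -1.444,
            "g04": -0.588, "g05": -0.007, "g06": -0.034, "g07": -0.004,
            "g08": -0.001, "g10": -0.308, "g11": -0.001, "g12": -0.001,
            "g13": -0.009, "g14": -0.001, "g15": 0.000, "g16": -0.002,
            "g17": 0.000, "g20": -0.142, "g21": 0.000, "g22": -0.008,
            "g23": 0.029, "g24": 0.000, "g25": -0.002, "g26": 0.004,
            "g27": 0.000,
        },
        sd_u0=6.887, sd_u1=0.042, rho=-0.514, sd_resid=4.330,
    ),
    "sk": TrueParameters(
        gamma={
            "g00": 48.758, "g01": 0.031, "g02": 1.295, "g03": 2.649,
            "g04": 0.461, "g05": -0.019, "g06": 0.059, "g07": -0.048,
            "g08": -0.034, "g10": -0.021, "g11": -0.006, "g12": 0.001,
            "g13": 0.028, "g14": 0.000, "g15": 0.005, "g16": -0.008,
            "g17": -0.001, "g20": -0.150, "g21": 0.002, "g22": 0.001,
            "g23": 0.018, "g24": 0.000, "g25": 0.000, "g26": -0.010,
            "g27": 0.000,
        },
        sd_u0=7.213, sd_u1=0.143, rho=0.490, sd_resid=3.821,
    ),
}


def betula_like_design(**overrides) -> StudyDesign:
    """The default study design: Betula-like cohorts, samples and waves."""
    return StudyDesign(**overrides) if overrides else StudyDesign()


def betula_like_truth(outcome: str = "em", **overrides) -> TrueParameters:
    """A realistic truth profile for one outcome (va, sk or em)."""
    truth = _BETULA_LIKE_TRUTH[outcome]
    return replace(truth, **overrides) if overrides else truth


@dataclass
class LongitudinalDataset:
    """Long-format person-period records plus generation metadata.

    ``frame`` has one row per attended (person, wave); ``meta`` records, for
    generated data, the covariate centers and the orthogonal quadratic-basis
    coefficients actually used to compute the outcomes.
    """

    frame: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = self.frame
        missing = [c for c in CSV_COLUMNS if c not in f.columns]
        if missing:
            raise ValueError(f"dataset is missing columns: {missing}")
        if f.duplicated(["person_id", "wave"]).any():
            raise ValueError("(person_id, wave) pairs must be unique")
        per = f.groupby("person_id")[["birth_year", "sex", "sample"]].nunique()
        if (per > 1).any().any():
            raise ValueError("birth_year, sex and sample must be constant per person")

    @property
    def n_persons(self) -> int:
        return self.frame["person_id"].nunique()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def read_csv(cls, path) -> "LongitudinalDataset":
        frame = pd.read_csv(path)
        return cls(frame=frame)


def _orthogonal_quad_coefficients(age_c: np.ndarray) -> tuple[float, float]:
    """Least-squares coefficients (alpha, beta) of age_c**2 on {1, age_c}.

    The orthogonalised quadratic is then q = age_c**2 - alpha - beta*age_c,
    which satisfies sum(q) = sum(q*age_c) = 0 over the rows used.
    """
    design = np.column_stack([np.ones_like(age_c), age_c])
    coef, *_ = np.linalg.lstsq(design, age_c**2, rcond=None)
    return float(coef[0]), float(coef[1])


def _mean_structure(frame: pd.DataFrame, centers: dict, quad: tuple[float, float],
                    gamma: np.ndarray) -> np.ndarray:
    """Fixed-effects linear predictor on the generator's own basis."""
    from .prepare import build_design  # local import to avoid cycle

    if "age" in frame.columns:
        age = frame["age"].to_numpy(float)
    else:
        age = frame["test_year"].to_numpy(float) - frame["birth_year"].to_numpy(float)
    age_c = age - centers["age"]
    alpha, beta = quad
    covs = pd.DataFrame({
        "age_lin": age_c,
        "age_quad": age_c**2 - alpha - beta * age_c,
        "cohort_c": frame["birth_year"].to_numpy(float) - centers["cohort"],
        "edu_c": frame["education"].to_numpy(float) - centers["education"],
        "sex": frame["sex"].to_numpy(float),
        "sample_code": (frame["sample"] == "S3").astype(float).to_numpy(),
    })
    X = build_design(covs)
    return X.to_numpy() @ gamma


def generate(
    design: StudyDesign,
    truth: TrueParameters | Mapping[str, TrueParameters],
    seed: int,
) -> LongitudinalDataset:
    """Generate a cohort-sequential dataset from known true parameters.

    ``truth`` is either a single :class:`TrueParameters` (applied to all
    three outcomes, with independent random effects and residuals per
    outcome) or a mapping ``{"va": ..., "sk": ..., "em": ...}``.

    Identical ``(design, truth, seed)`` yield a byte-identical dataset.
    """
    if isinstance(truth, TrueParameters):
        truths = {k: truth for k in OUTCOMES}
    else:
        truths = dict(truth)
        unknown = set(truths) - set(OUTCOMES)
        if unknown:
            raise ValueError(f"unknown outcome keys in truth: {sorted(unknown)}")
        for k in OUTCOMES:
            if k not in truths:
                raise ValueError(f"truth missing outcome {k!r}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    samples = sorted(design.sample_entry_waves)
    cohorts = list(design.cohort_birth_years)
    ppc = design.persons_per_cell
    n_persons = len(samples) * len(cohorts) * ppc

    person_id = np.arange(1, n_persons + 1)
    sample = np.repeat(samples, len(cohorts) * ppc)
    birth_year = np.tile(np.repeat(cohorts, ppc), len(samples))
    sex = (rng.random(n_persons) < design.female_fraction).astype(int)
    education = np.clip(
        np.rint(rng.normal(design.education_mean, design.education_sd, n_persons)),
        design.education_min, design.education_max,
    ).astype(int)

    # Attendance: enter at the sample's entry wave; after each attended wave
    # drop out permanently with probability dropout_hazard (monotone missingness).
    entry = np.array([design.sample_entry_waves[s] for s in sample])
    drop_draws = rng.random((n_persons, design.n_waves))
    rows = []
    for i in range(n_persons):
        last = entry[i]
        for w in range(entry[i], design.n_waves):
            last = w
            if w < design.n_waves - 1 and drop_draws[i, w] < design.dropout_hazard:
                break
        rows.append((entry[i], last))
    attend_lo = np.array([r[0] for r in rows])
    attend_hi = np.array([r[1] for r in rows])
    counts = attend_hi - attend_lo + 1

    idx = np.repeat(np.arange(n_persons), counts)
    wave = np.concatenate([np.arange(lo, hi + 1) for lo, hi in zip(attend_lo, attend_hi)])
    test_year = np.asarray(design.wave_years)[wave]
    age = (test_year - birth_year[idx]).astype(float)
    if design.age_jitter:
        age = age + rng.uniform(-2.0, 2.0, size=age.shape)

    frame = pd.DataFrame({
        "person_id": person_id[idx],
        "birth_year": birth_year[idx],
        "sex": sex[idx],
        "sample": sample[idx],
        "wave": wave,
        "test_year": test_year,
        "age": age,
        "education": education[idx].astype(float),
    })
    if design.education_report_noise:
        noise = rng.integers(-1, 2, size=len(frame))
        frame["education"] = np.clip(
            frame["education"] + noise, design.education_min, design.education_max
        )

    # Centered / orthogonalised covariates over the emitted rows: this is the
    # basis on which the Level-1 / Level-2 mean structure is evaluated.
    centers = {
        "age": float(age.mean()),
        "cohort": float(frame["birth_year"].mean()),
        "education": float(frame["education"].mean()),
    }
    age_c = age - centers["age"]
    quad = _orthogonal_quad_coefficients(age_c)

    for outcome in OUTCOMES:
        t = truths[outcome]
        mean = _mean_structure(frame, centers, quad, t.gamma_vector())
        cov = t.random_effects_cov()
        # Cholesky-like factor valid also for degenerate (zero-SD) components
        u = rng.multivariate_normal(
            np.zeros(2), cov, size=n_persons, method="svd"
        )
        eps = rng.normal(0.0, t.sd_resid, size=len(frame)) if t.sd_resid > 0 \
            else np.zeros(len(frame))
        frame[outcome] = mean + u[idx, 0] + u[idx, 1] * age_c + eps

    frame = frame.drop(columns="age")
    meta = {
        "seed": int(seed),
        "centers": centers,
        "quad_coefficients": {"alpha": quad[0], "beta": quad[1]},
        "design": design,
        "truth": truths,
    }
    return LongitudinalDataset(frame=frame[CSV_COLUMNS], meta=meta)


def attrition(data: LongitudinalDataset, hazard: float, seed: int) -> LongitudinalDataset:
    """Apply additional monotone dropout to an existing dataset.

    After each attended wave a person drops out permanently with probability
    ``hazard``; the first attended wave is never removed.
    """
    if not 0.0 <= hazard <= 1.0:
        raise ValueError(f"hazard must lie in [0, 1], got {hazard}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    frame = data.frame.sort_values(["person_id", "wave"], kind="stable")
    keep_parts = []
    for _, g in frame.groupby("person_id", sort=True):
        n = len(g)
        keep = n
        draws = rng.random(n)
        for j in range(n - 1):
            if draws[j] < hazard:
                keep = j + 1
                break
        keep_parts.append(g.iloc[:keep])
    out = pd.concat(keep_parts, ignore_index=True)
    return LongitudinalDataset(frame=out, meta=dict(data.meta))


def truth_table(truth: TrueParameters) -> pd.Series:
    """Flatten a truth to one named entry per model parameter (29 entries)."""
    values = list(truth.gamma_vector()) + [
        truth.sd_u0, truth.sd_u1, truth.rho, truth.sd_resid
    ]
    return pd.Series(values, index=list(FIXED_EFFECT_LABELS) + list(VARIANCE_LABELS))


def truth_from_table(table: pd.Series) -> TrueParameters:
    """Inverse of :func:`truth_table`."""
    gamma = {k: float(table[k]) for k in FIXED_EFFECT_LABELS}
    sd_u0, sd_u1, rho, sd_resid = (float(table[k]) for k in VARIANCE_LABELS)
    return TrueParameters(gamma=gamma, sd_u0=sd_u0, sd_u1=sd_u1, rho=rho,
                          sd_resid=sd_resid)


def rescale_truth(truth: TrueParameters, baseline_mean: float,
                  baseline_sd: float, t_mean: float = 50.0,
                  t_sd: float = 10.0) -> TrueParameters:
    """Map a truth onto the scale of T-standardised outcomes.

    Preparation applies the affine map T = t_mean + t_sd*(y - m)/s anchored
    to the first occasion; under that map every regression coefficient and
    SD scales by b = t_sd/s, the intercept additionally shifts, and the
    correlation is unchanged.  The returned truth is the exact ground truth
    for parameters estimated from the standardised outcomes.
    """
    b = t_sd / baseline_sd
    c = t_mean - b * baseline_mean
    gamma = {k: b * v for k, v in truth.gamma.items()}
    gamma["Intercept"] = b * truth.gamma["Intercept"] + c
    return TrueParameters(
        gamma=gamma,
        sd_u0=b * truth.sd_u0,
        sd_u1=b * truth.sd_u1,
        rho=truth.rho,
        sd_resid=b * truth.sd_resid,
    )


def load_sim_config(path) -> tuple[StudyDesign, TrueParameters, int]:
    """Read a flat YAML config mirroring StudyDesign / TrueParameters fields.

    ``seed`` is required.  Fixed effects may be given as ``g12: 0.006`` style
    keys; design fields by their dataclass names.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "seed" not in cfg:
        raise KeyError("config must contain a 'seed' key")
    seed = int(cfg.pop("seed"))
    design_fields = set(StudyDesign.__dataclass_fields__)
    design_kwargs = {}
    for k in list(cfg):
        if k in design_fields:
            v = cfg.pop(k)
            design_kwargs[k] = tuple(v) if isinstance(v, list) else v
    gamma = {k: cfg.pop(k) for k in list(cfg) if k.startswith("g") and k[1:].isdigit()}
    truth_kwargs = {k: cfg.pop(k) for k in ("sd_u0", "sd_u1", "rho", "sd_resid")
                    if k in cfg}
    if cfg:
        raise KeyError(f"unknown config keys: {sorted(cfg)}")
    return (StudyDesign(**design_kwargs),
            TrueParameters(gamma=gamma, **truth_kwargs),
            seed)
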