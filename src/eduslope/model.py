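"""Bayesian hierarchical growth model with marginalized random effects.

The model for person *i* at occasion *t* is

    y_ti = x_ti' gamma + u0_i + u1_i * age_lin_ti + eps_ti

with (u0, u1) bivariate normal (SDs sd_u0, sd_u1, correlation rho) and
eps ~ Normal(0, sd_resid).  The random effects are integrated out
analytically, so each person's observed outcomes are jointly normal with
mean X_i gamma and covariance Z_i S_u Z_i' + sd_resid^2 I, where Z_i has
columns (1, age_lin).  The quadratic age slope has no random component.

Priors (weakly informative except for the focal term): Normal(50, 20) on
the intercept, Normal(0, 3) on other regression coefficients, half-Cauchy
(0, 10) on the three scale parameters, LKJ(1) (flat) on the 2x2
random-effects correlation.  The education-by-linear-slope coefficient
optionally gets a Normal(0, sigma_focal) prior, which is what the
Savage-Dickey Bayes-factor machinery in :mod:`eduslope.bayes_factors`
manipulates.

Sampling uses a blocked scheme that exploits the model's partial
conjugacy: given the variance components, the regression coefficients have
an exactly normal conditional posterior and are drawn directly; the four
variance-structure parameters are updated by adaptive random-walk
Metropolis on an unconstrained scale (log SDs, atanh correlation) with the
Jacobian terms included, so the invariant distribution is exactly
proportional to exp(log_likelihood + log_prior) on the constrained space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_solve, solve_triangular

from .names import FOCAL_LABEL, INTERCEPT_LABEL, VARIANCE_LABELS, normalize_param_name

__all__ = [
    "PriorSpec", "PosteriorDraws", "BayesianGrowthModel",
    "log_likelihood", "log_prior", "fit", "rhat", "summarize", "hdi", "kde_map",
]

RHAT_THRESHOLD = 1.01


@dataclass(frozen=True)
class PriorSpec:
    """Prior family and hyperparameters for every model parameter."""

    intercept_mean: float = 50.0
    intercept_sd: float = 20.0
    coef_sd: float = 3.0
    scale_cauchy: float = 10.0   # half-Cauchy scale for sd_u0, sd_u1, sd_resid
    lkj_eta: float = 1.0         # LKJ shape; 1 = flat on the correlation
    sigma_focal: float | None = None
    focal_param: str = FOCAL_LABEL
    intercept_param: str = INTERCEPT_LABEL

    def __post_init__(self) -> None:
        for name in ("intercept_sd", "coef_sd", "scale_cauchy", "lkj_eta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sigma_focal is not None and self.sigma_focal <= 0:
            raise ValueError("sigma_focal must be positive when set")

    def gamma_moments(self, names) -> tuple[np.ndarray, np.ndarray]:
        """Prior mean and SD per regression coefficient, by column name."""
        mu = np.zeros(len(names))
        sd = np.full(len(names), self.coef_sd)
        for j, name in enumerate(names):
            if name == self.intercept_param:
                mu[j], sd[j] = self.intercept_mean, self.intercept_sd
            elif name == self.focal_param and self.sigma_focal is not None:
                sd[j] = self.sigma_focal
        return mu, sd

    def to_dict(self) -> dict:
        return {
            "intercept_mean": self.intercept_mean,
            "intercept_sd": self.intercept_sd,
            "coef_sd": self.coef_sd,
            "scale_cauchy": self.scale_cauchy,
            "lkj_eta": self.lkj_eta,
            "sigma_focal": self.sigma_focal,
            "focal_param": self.focal_param,
        }


# --------------------------------------------------------------------------
# log densities (public, reference implementations)
# --------------------------------------------------------------------------

def _params_to_series(params) -> pd.Series:
    if isinstance(params, pd.Series):
        s = params
    else:
        s = pd.Series(dict(params))
    return pd.Series(s.values, index=[normalize_param_name(k) for k in s.index],
                     dtype=float)


def log_likelihood(params, prepared) -> float:
    """Marginal log likelihood with random effects integrated out.

    ``params`` maps parameter names (labels or short ids) to values and must
    cover every design column of ``prepared`` plus the four variance-structure
    parameters.  Computed person by person with dense covariance matrices;
    this is the reference implementation the fast sampler path is tested
    against.  Raises if an implied covariance is not positive definite.
    """
    s = _params_to_series(params)
    cols = list(prepared.X.columns)
    gamma = s[cols].to_numpy()
    sd_u0, sd_u1, rho, sd_resid = (s[k] for k in VARIANCE_LABELS)
    if min(sd_u0, sd_u1, sd_resid) < 0 or abs(rho) > 1:
        raise ValueError("variance parameters out of range")

    X = prepared.X.to_numpy()
    y = np.asarray(prepared.y, dtype=float)
    age_lin = prepared.X["Linear slope (LS)"].to_numpy() \
        if "Linear slope (LS)" in prepared.X.columns else np.zeros(len(y))
    groups = np.asarray(prepared.person_ids)

    cov_u = np.array([
        [sd_u0**2, rho * sd_u0 * sd_u1],
        [rho * sd_u0 * sd_u1, sd_u1**2],
    ])
    total = 0.0
    for pid in pd.unique(groups):
        m = groups == pid
        yy = y[m]
        ok = np.isfinite(yy)
        if not ok.any():
            continue
        yy = yy[ok]
        Z = np.column_stack([np.ones(ok.sum()), age_lin[m][ok]])
        V = Z @ cov_u @ Z.T + sd_resid**2 * np.eye(ok.sum())
        sign, logdet = np.linalg.slogdet(V)
        if sign <= 0:
            raise ValueError(
                f"implied covariance for person {pid!r} is not positive "
                f"definite (slogdet sign {sign}); variance parameters: "
                f"sd_u0={sd_u0}, sd_u1={sd_u1}, rho={rho}, sd_resid={sd_resid}"
            )
        r = yy - X[m][ok] @ gamma
        total += -0.5 * (ok.sum() * np.log(2 * np.pi) + logdet
                         + r @ np.linalg.solve(V, r))
    return float(total)


def log_prior(params, prior: PriorSpec) -> float:
    """Joint log prior density of a full parameter vector.

    Out-of-support scale parameters give ``-inf`` (log zero), not an error;
    the LKJ(1) term is flat in the correlation.
    """
    s = _params_to_series(params)
    gamma_names = [k for k in s.index if k not in VARIANCE_LABELS]
    mu, sd = prior.gamma_moments(gamma_names)
    total = float(np.sum(stats.norm.logpdf(s[gamma_names].to_numpy(), mu, sd)))
    sd_u0, sd_u1, rho, sd_resid = (float(s[k]) for k in VARIANCE_LABELS)
    for v in (sd_u0, sd_u1, sd_resid):
        if v <= 0:
            return float("-inf")
        total += stats.halfcauchy.logpdf(v, scale=prior.scale_cauchy)
    if abs(rho) >= 1:
        return float("-inf")
    # 2x2 LKJ(eta): density prop. to (1 - rho^2)^(eta - 1); normalised via
    # (rho + 1)/2 ~ Beta(eta, eta)
    total += stats.beta.logpdf((rho + 1) / 2, prior.lkj_eta, prior.lkj_eta) \
        - np.log(2.0)
    return float(total)


# --------------------------------------------------------------------------
# posterior container and summaries
# --------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Per-chain, per-draw parameter values with aligned names."""

    draws: np.ndarray            # (n_chains, n_draws, n_params)
    names: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.draws.ndim != 3 or self.draws.shape[2] != len(self.names):
            raise ValueError("draws must be (chains, iterations, parameters)")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """All chains concatenated for one parameter."""
        if name not in self.names:
            name = normalize_param_name(name)
        j = self.names.index(name)
        return self.draws[:, :, j].reshape(-1)

    def to_dataframe(self) -> pd.DataFrame:
        c, d, p = self.draws.shape
        out = pd.DataFrame(self.draws.reshape(c * d, p), columns=self.names)
        out.insert(0, "chain", np.repeat(np.arange(c), d))
        out.insert(1, "iteration", np.tile(np.arange(d), c))
        return out

    def save(self, prefix) -> None:
        prefix = Path(prefix)
        self.to_dataframe().to_csv(f"{prefix}_draws.csv", index=False,
                                   float_format="%.10g")
        meta = {k: v for k, v in self.metadata.items()}
        with open(f"{prefix}_meta.json", "w") as fh:
            json.dump(meta, fh, indent=1, default=str)


def hdi(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` of the draws."""
    if not 0 < mass < 1:
        raise ValueError("mass must lie in (0, 1)")
    s = np.sort(np.asarray(samples, dtype=float))
    n = s.size
    if n == 0:
        raise ValueError("no draws")
    k = int(np.ceil(mass * n))
    if k >= n:
        return float(s[0]), float(s[-1])
    widths = s[k - 1:] - s[: n - k + 1]
    i = int(np.argmin(widths))
    return float(s[i]), float(s[i + k - 1])


def kde_map(samples) -> float:
    """Posterior mode from a Gaussian KDE (Silverman bandwidth, 512 grid)."""
    s = np.asarray(samples, dtype=float)
    # relative guard: numerically constant draws defeat the KDE covariance
    if s.std() <= 1e-12 * max(1.0, abs(s.mean())):
        return float(np.median(s))
    kde = stats.gaussian_kde(s, bw_method="silverman")
    grid = np.linspace(s.min(), s.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def rhat(draws: PosteriorDraws) -> pd.Series:
    """Split-chain Gelman-Rubin potential scale reduction factor.

    Each chain is split in half, giving 2*m sequences; R-hat compares the
    between- and within-sequence variances.  Degenerate draws (zero total
    variance) return exactly 1.0 rather than 0/0.
    """
    x = draws.draws
    c, n, p = x.shape
    if c < 2:
        raise ValueError("R-hat requires at least 2 chains")
    if n < 4:
        raise ValueError("R-hat requires at least 4 iterations per chain")
    half = n // 2
    split = np.concatenate([x[:, :half, :], x[:, half: 2 * half, :]], axis=0)
    out = np.empty(p)
    for j in range(p):
        seq = split[:, :, j]
        if np.var(seq) == 0:
            out[j] = 1.0
            continue
        within = seq.var(axis=1, ddof=1).mean()
        between = half * seq.mean(axis=1).var(ddof=1)
        if within == 0:
            out[j] = 1.0 if between == 0 else np.inf
            continue
        var_plus = (half - 1) / half * within + between / half
        out[j] = float(np.sqrt(var_plus / within))
    return pd.Series(out, index=draws.names)


def summarize(draws: PosteriorDraws, hdi_mass: float = 0.95) -> pd.DataFrame:
    """MAP, posterior mean, HDI bounds and R-hat per parameter."""
    if not 0 < hdi_mass < 1:
        raise ValueError("hdi_mass must lie in (0, 1)")
    if draws.draws.size == 0:
        raise ValueError("no draws to summarise")
    rh = rhat(draws) if draws.n_chains >= 2 and draws.n_draws >= 4 else \
        pd.Series(np.nan, index=draws.names)
    rows = []
    for name in draws.names:
        pooled = draws.pooled(name)
        lo, hi = hdi(pooled, hdi_mass)
        rows.append({
            "map": kde_map(pooled),
            "mean": float(pooled.mean()),
            "sd": float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0,
            "hdi_low": lo,
            "hdi_high": hi,
            "rhat": float(rh[name]),
        })
    return pd.DataFrame(rows, index=draws.names)


# --------------------------------------------------------------------------
# the sampler
# --------------------------------------------------------------------------

class _MarginalGrowthPosterior:
    """Precomputed sufficient statistics and conditional updates.

    Persons are grouped by their number of observed occasions so every
    per-person 2x2 operation is batched; the regression-coefficient draw and
    the variance-block likelihood both reduce to a handful of einsums.
    """

    def __init__(self, X, y, age_lin, groups, prior, names,
                 include_random_effects=True, fixed_resid_sd=None):
        self.p = X.shape[1]
        self.names = names
        self.prior = prior
        self.include_re = include_random_effects
        self.fixed_resid_sd = fixed_resid_sd
        self.n_obs = len(y)

        mu0, sd0 = prior.gamma_moments(names)
        self.prior_prec = 1.0 / sd0**2
        self.prior_prec_mean = mu0 / sd0**2

        self._terms_cache = None
        codes, _ = pd.factorize(np.asarray(groups))
        counts = np.bincount(codes) if len(codes) else np.array([], dtype=int)
        order = np.argsort(codes, kind="stable")
        Xs, ys, zs = X[order], y[order], age_lin[order]
        offsets = np.concatenate([[0], np.cumsum(counts)])
        self.kgroups = []
        self.TXX = X.T @ X if len(y) else np.zeros((self.p, self.p))
        self.TXy = X.T @ y if len(y) else np.zeros(self.p)
        for k in np.unique(counts):
            pidx = np.flatnonzero(counts == k)
            rows = (offsets[pidx][:, None] + np.arange(k)[None, :]).reshape(-1)
            Xg = Xs[rows].reshape(len(pidx), k, self.p)
            yg = ys[rows].reshape(len(pidx), k)
            Zg = np.stack(
                [np.ones((len(pidx), k)), zs[rows].reshape(len(pidx), k)], axis=2
            )
            ZX = np.einsum("mka,mkp->map", Zg, Xg)
            self.kgroups.append({
                "k": int(k),
                "X": Xg, "y": yg, "Z": Zg,
                "G": np.einsum("mka,mkb->mab", Zg, Zg),
                "ZX": ZX,
                "ZXf": np.ascontiguousarray(ZX.reshape(-1, self.p)),
                "Zy": np.einsum("mka,mk->ma", Zg, yg),
            })

    # -- variance-component plumbing --------------------------------------
    @staticmethod
    def _cov_u(s0, s1, r):
        c = r * s0 * s1
        return np.array([[s0 * s0, c], [c, s1 * s1]])

    @staticmethod
    def _batch_inv2(B):
        a, b = B[:, 0, 0], B[:, 0, 1]
        c, d = B[:, 1, 0], B[:, 1, 1]
        det = a * d - b * c
        inv = np.empty_like(B)
        inv[:, 0, 0] = d
        inv[:, 0, 1] = -b
        inv[:, 1, 0] = -c
        inv[:, 1, 1] = a
        return inv / det[:, None, None], det

    def _person_terms(self, s0, s1, r, se):
        """Per k-group Woodbury factor A and log|V| pieces (cached).

        V^{-1} = se^{-2} (I - Z A Z') with A = S_u (se^2 I + G S_u)^{-1};
        log|V| = (k - 2) log se^2 + log|se^2 I + G S_u|.
        """
        key = (s0, s1, r, se)
        if self._terms_cache is not None and self._terms_cache[0] == key:
            return self._terms_cache[1]
        cov_u = self._cov_u(s0, s1, r)
        out = []
        for g in self.kgroups:
            B = se**2 * np.eye(2)[None, :, :] + g["G"] @ cov_u
            Binv, det = self._batch_inv2(B)
            if np.any(det <= 0):
                return None
            A = np.einsum("ab,mbc->mac", cov_u, Binv)
            A = 0.5 * (A + np.swapaxes(A, 1, 2))
            logdet_v = (g["k"] - 2) * 2 * np.log(se) + np.log(det)
            out.append((g, A, logdet_v))
        self._terms_cache = (key, out)
        return out

    def loglik(self, gamma, s0, s1, r, se) -> float:
        """Marginal log likelihood via the batched Woodbury identities."""
        if se <= 0:
            return -np.inf
        if not self.include_re:
            s0 = s1 = r = 0.0
        terms = self._person_terms(s0, s1, r, se)
        if terms is None:
            return -np.inf
        total = 0.0
        for g, A, logdet_v in terms:
            rg = g["y"] - np.einsum("mkp,p->mk", g["X"], gamma)
            rr = np.einsum("mk,mk->m", rg, rg)
            Zr = np.einsum("mka,mk->ma", g["Z"], rg)
            quad = (rr - np.einsum("ma,mab,mb->m", Zr, A, Zr)) / se**2
            total += -0.5 * np.sum(g["k"] * np.log(2 * np.pi) + logdet_v + quad)
        return float(total)

    def draw_gamma(self, s0, s1, r, se, rng) -> np.ndarray:
        """Exact draw from the normal conditional posterior of gamma."""
        P = np.diag(self.prior_prec).astype(float)
        b = self.prior_prec_mean.copy()
        if self.n_obs:
            if self.include_re:
                terms = self._person_terms(s0, s1, r, se)
                XVX = self.TXX.copy()
                XVy = self.TXy.copy()
                for g, A, _ in terms:
                    W = A @ g["ZX"]                      # (m, 2, p) batched
                    XVX -= g["ZXf"].T @ W.reshape(-1, self.p)
                    XVy -= np.einsum("maj,ma->j", W, g["Zy"])
                P += XVX / se**2
                b += XVy / se**2
            else:
                P += self.TXX / se**2
                b += self.TXy / se**2
        P = 0.5 * (P + P.T)
        L = np.linalg.cholesky(P)
        mean = cho_solve((L, True), b)
        z = rng.standard_normal(self.p)
        return mean + solve_triangular(L.T, z, lower=False)

    # -- variance block log target on the unconstrained scale --------------
    def variance_names(self) -> list[str]:
        names = []
        if self.include_re:
            names += ["sd_u0", "sd_u1", "rho"]
        if self.fixed_resid_sd is None:
            names += ["sd_resid"]
        return names

    def unconstrain(self, values: dict) -> np.ndarray:
        t = []
        if self.include_re:
            t += [np.log(values["sd_u0"]), np.log(values["sd_u1"]),
                  np.arctanh(values["rho"])]
        if self.fixed_resid_sd is None:
            t += [np.log(values["sd_resid"])]
        return np.array(t)

    def constrain(self, t: np.ndarray) -> dict:
        values, i = {}, 0
        if self.include_re:
            values["sd_u0"] = float(np.exp(t[0]))
            values["sd_u1"] = float(np.exp(t[1]))
            values["rho"] = float(np.tanh(t[2]))
            i = 3
        else:
            values["sd_u0"] = values["sd_u1"] = values["rho"] = 0.0
        values["sd_resid"] = float(self.fixed_resid_sd) \
            if self.fixed_resid_sd is not None else float(np.exp(t[i]))
        return values

    def variance_logpost(self, t: np.ndarray, gamma: np.ndarray) -> float:
        """log p(variances | gamma, y) on the unconstrained scale."""
        v = self.constrain(t)
        prior = self.prior
        sc = prior.scale_cauchy
        # half-Cauchy(0, sc) log density: log(2/(pi*sc)) - log1p((x/sc)^2)
        hc = lambda x: np.log(2.0 / (np.pi * sc)) - np.log1p((x / sc) ** 2)
        lp = 0.0
        i = 0
        if self.include_re:
            lp += hc(v["sd_u0"]) + hc(v["sd_u1"])
            rho = v["rho"]
            lp += (prior.lkj_eta - 1.0) * np.log1p(-rho**2)
            # Jacobians: d s / d log s = s;  d rho / d atanh(rho) = 1 - rho^2
            lp += t[0] + t[1] + np.log1p(-rho**2)
            i = 3
        if self.fixed_resid_sd is None:
            lp += hc(v["sd_resid"])
            lp += t[i]
        if not np.isfinite(lp):
            return -np.inf
        if self.n_obs:
            lp += self.loglik(gamma, v["sd_u0"], v["sd_u1"], v["rho"],
                              v["sd_resid"])
        return float(lp)


class _AdaptiveRW:
    """Adaptive random-walk Metropolis proposal (Haario-style).

    The proposal covariance tracks the empirical covariance of accepted
    states during warmup (scaled by 2.38^2/d), with a Robbins-Monro global
    scale tuned toward 30% acceptance; both are frozen after warmup so the
    post-warmup chain has the exact target as invariant distribution.
    """

    TARGET = 0.30

    def __init__(self, dim: int, init_scale: float = 0.1):
        self.dim = dim
        self.log_scale = np.log(init_scale)
        self.mean = np.zeros(dim)
        self.cov = np.eye(dim)
        self.count = 0
        self.frozen = False
        self._chol = np.eye(dim)

    def freeze(self) -> None:
        self.frozen = True
        self._chol = np.linalg.cholesky(self.cov + 1e-10 * np.eye(self.dim))

    def propose(self, t: np.ndarray, rng) -> np.ndarray:
        if not self.frozen:
            self._chol = np.linalg.cholesky(self.cov + 1e-10 * np.eye(self.dim))
        step = self._chol @ rng.standard_normal(self.dim)
        return t + np.exp(self.log_scale) * step

    def adapt(self, t: np.ndarray, accept_prob: float) -> None:
        if self.frozen:
            return
        self.count += 1
        w = (self.count + 5.0) ** -0.7
        delta = t - self.mean
        self.mean += w * delta
        self.cov = (1 - w) * self.cov + w * np.outer(delta, delta)
        self.log_scale += w * (accept_prob - self.TARGET)


def _run_chain(post: _MarginalGrowthPosterior, n_warmup, n_draws, mh_steps, rng,
               init):
    dim = len(post.variance_names())
    t = post.unconstrain(init) if dim else np.empty(0)
    gamma = np.asarray(init["gamma"], dtype=float)
    prop = _AdaptiveRW(dim) if dim else None
    lp_t = post.variance_logpost(t, gamma) if dim else 0.0
    out = np.empty((n_draws, post.p + 4))
    accepts = 0
    proposals = 0
    for it in range(n_warmup + n_draws):
        if dim and it == n_warmup:
            prop.freeze()
        v = post.constrain(t) if dim else post.constrain(np.empty(0))
        gamma = post.draw_gamma(v["sd_u0"], v["sd_u1"], v["rho"], v["sd_resid"],
                                rng)
        if dim:
            lp_t = post.variance_logpost(t, gamma)
            for _ in range(mh_steps):
                t_new = prop.propose(t, rng)
                lp_new = post.variance_logpost(t_new, gamma)
                log_r = lp_new - lp_t
                accept_prob = min(1.0, np.exp(min(log_r, 0.0)))
                if np.log(rng.random()) < log_r:
                    t, lp_t = t_new, lp_new
                prop.adapt(t, accept_prob)
                if it >= n_warmup:
                    proposals += 1
                    accepts += accept_prob
        if it >= n_warmup:
            v = post.constrain(t) if dim else post.constrain(np.empty(0))
            out[it - n_warmup, : post.p] = gamma
            out[it - n_warmup, post.p:] = [v["sd_u0"], v["sd_u1"], v["rho"],
                                           v["sd_resid"]]
    rate = accepts / proposals if proposals else float("nan")
    return out, rate


class BayesianGrowthModel:
    """Bayesian linear mixed growth model, scikit-learn style.

    Parameters
    ----------
    prior : PriorSpec or None
        Prior specification; None means the default weakly informative set.
    n_chains, n_draws : int
        Chains and post-warmup draws per chain (published protocol: 4 x 2000).
    n_warmup : int or None
        Warmup iterations per chain; None means equal to ``n_draws``.
    mh_steps : int
        Metropolis sub-steps on the variance block per scan.
    include_random_effects : bool
        If False, fit a fixed-effects-only normal regression (used e.g. for
        conjugate cross-checks).
    resid_sd : float or None
        If set, the residual SD is held fixed at this value.
    random_state : int
        Seed for all chains (each chain gets an independent child stream).

    After ``fit``: ``draws_`` (:class:`PosteriorDraws`), ``summary_``,
    ``rhat_``, ``converged_``, ``param_names_``.
    """

    def __init__(self, prior: PriorSpec | None = None, n_chains: int = 4,
                 n_draws: int = 2000, n_warmup: int | None = None,
                 mh_steps: int = 5, include_random_effects: bool = True,
                 resid_sd: float | None = None, random_state: int = 0,
                 slope_column: str = "Linear slope (LS)"):
        self.prior = prior
        self.n_chains = n_chains
        self.n_draws = n_draws
        self.n_warmup = n_warmup
        self.mh_steps = mh_steps
        self.include_random_effects = include_random_effects
        self.resid_sd = resid_sd
        self.random_state = random_state
        self.slope_column = slope_column

    # -- sklearn plumbing -------------------------------------------------
    _param_names = ("prior", "n_chains", "n_draws", "n_warmup", "mh_steps",
                    "include_random_effects", "resid_sd", "random_state",
                    "slope_column")

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params) -> "BayesianGrowthModel":
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    # ---------------------------------------------------------------------
    def fit(self, X, y, groups=None, age_lin=None) -> "BayesianGrowthModel":
        """Sample the posterior given a design matrix and outcomes.

        ``groups`` assigns rows to persons (None: one row per person);
        ``age_lin`` is the within-person regressor carrying the random slope
        (None: taken from ``slope_column`` of a DataFrame ``X``, or zero).
        """
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            Xv = X.to_numpy(dtype=float)
            if age_lin is None and self.slope_column in X.columns:
                age_lin = X[self.slope_column].to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            names = [f"x{j}" for j in range(Xv.shape[1])]
        y = np.asarray(y, dtype=float)
        if Xv.shape[0] != y.shape[0]:
            raise ValueError("X and y have different numbers of rows")
        keep = np.isfinite(y)
        Xv, y = Xv[keep], y[keep]
        if groups is None:
            groups = np.arange(len(y))
        else:
            groups = np.asarray(groups)[keep]
        if age_lin is None:
            if self.include_random_effects and len(y):
                raise ValueError(
                    "random effects require age_lin (or a slope column in X)"
                )
            age_lin = np.zeros(len(y))
        else:
            age_lin = np.asarray(age_lin, dtype=float)[keep]

        prior = self.prior or PriorSpec()
        n_warmup = self.n_draws if self.n_warmup is None else self.n_warmup
        post = _MarginalGrowthPosterior(
            Xv, y, age_lin, groups, prior, names,
            include_random_effects=self.include_random_effects,
            fixed_resid_sd=self.resid_sd,
        )
        ss = np.random.SeedSequence(self.random_state)
        children = ss.spawn(self.n_chains)
        chains = []
        rates = []
        for c in range(self.n_chains):
            rng = np.random.default_rng(children[c])
            init = self._initial_values(post, Xv, y, rng)
            draws, rate = _run_chain(post, n_warmup, self.n_draws,
                                     self.mh_steps, rng, init)
            chains.append(draws)
            rates.append(rate)

        all_names = names + list(VARIANCE_LABELS)
        draws = PosteriorDraws(
            draws=np.stack(chains), names=all_names,
            metadata={
                "seed": self.random_state,
                "n_chains": self.n_chains,
                "n_iterations": self.n_draws,
                "n_warmup": n_warmup,
                "prior_spec": prior.to_dict(),
                "include_random_effects": self.include_random_effects,
                "fixed_resid_sd": self.resid_sd,
                "mh_acceptance": rates,
                "n_persons": int(pd.unique(groups).size),
                "n_obs": int(len(y)),
            },
        )
        self.param_names_ = all_names
        self.summary_ = summarize(draws)
        self.rhat_ = self.summary_["rhat"]
        fitted_cols = names + ([] if not self.include_random_effects else
                               ["SD intercept", "SD linear slope",
                                "Correlation (intercept, slope)"]) + \
            ([] if self.resid_sd is not None else ["Residual error"])
        self.converged_ = bool((self.rhat_[fitted_cols] < RHAT_THRESHOLD).all())
        draws.metadata["rhat_max"] = float(self.rhat_[fitted_cols].max())
        draws.metadata["converged"] = self.converged_
        self.draws_ = draws
        return self

    def fit_prepared(self, prepared) -> "BayesianGrowthModel":
        return self.fit(prepared.X, prepared.y, groups=prepared.person_ids)

    def _initial_values(self, post, Xv, y, rng) -> dict:
        p = Xv.shape[1]
        if len(y):
            XtX = post.TXX + 1e-6 * len(y) * np.eye(p)
            gamma0 = np.linalg.solve(XtX, post.TXy)
            resid = y - Xv @ gamma0
            s_e = float(resid.std()) or 1.0
        else:
            gamma0 = post.prior_prec_mean / post.prior_prec
            s_e = 1.0
        jitter = lambda: float(np.exp(rng.normal(0.0, 0.3)))
        init = {
            "gamma": gamma0 + rng.normal(0.0, 0.05 * (np.abs(gamma0) + 0.1)),
            "sd_u0": 0.7 * s_e * jitter(),
            "sd_u1": 0.05 * jitter(),
            "rho": float(np.tanh(rng.normal(0.0, 0.3))),
            "sd_resid": self.resid_sd if self.resid_sd is not None
            else 0.7 * s_e * jitter(),
        }
        return init


def fit(prepared, prior: PriorSpec | None = None, n_chains: int = 4,
        n_iterations: int = 2000, seed: int = 0, n_warmup: int | None = None,
        **kwargs) -> PosteriorDraws:
    """Fit the growth model to a prepared dataset; returns posterior draws."""
    model = BayesianGrowthModel(
        prior=prior, n_chains=n_chains, n_draws=n_iterations,
        n_warmup=n_warmup, random_state=seed, **kwargs,
    )
    model.fit_prepared(prepared)
    return model.draws_
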