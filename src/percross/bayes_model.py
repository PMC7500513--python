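"""Hierarchical Bayesian probit path model for dyadic recognition data.

The model ties together, per player-trial observation:

* **Individual success** ``S`` (click assigned to the partner's avatar):
  binary probit with a piecewise-linear learning curve per individual
  (intercept ``a_i``, non-negative slope ``b_i``, breakpoint ``tauS_i``)
  plus a synchrony effect ``lambda_S * D``.
* **Joint success** ``G`` (both players correct in the trial): binary probit
  at team level with intercept ``c_j`` and synchrony effect ``lambda_G * D``.
* **PAS rating** ``Y`` in 1..4: ordinal probit with its own piecewise
  learning curve per individual (``u_i``, ``v_i``, ``tauP_i``), effects
  ``gamma_S * S + gamma_G * G + gamma_D * D``, three free cutpoints, and a
  residual within-dyad correlation ``rho`` between the two players' latent
  PAS variables in the same trial.

``D`` is the trial-level synchrony indicator: both players clicked within
3 s of each other.  The hierarchy uses dyad/individual random effects with
normal (or half-normal, for the non-negative slopes and SDs) hyperpriors;
breakpoints follow truncated normals on [1, T] with a hierarchical mean.

Identification of the ordinal submodel is standard: latent residual SD is
fixed to 1, the hyper-mean of the PAS intercepts ``u_i`` is fixed to 0, and
the three cutpoints are free.

Sampling uses an adaptive random-walk Metropolis-within-Gibbs scheme,
vectorised across teams and individuals (unit-level parameters in different
dyads are conditionally independent, so they are proposed and accepted in
parallel).  Proposal scales adapt toward a 0.44 acceptance rate during
warmup and are frozen afterwards.  Convergence is reported via split R-hat
and effective sample size (arviz).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import log_ndtr, ndtr, ndtri

logger = logging.getLogger(__name__)

__all__ = [
    "ModelData",
    "PriorConfig",
    "McmcConfig",
    "PosteriorDraws",
    "Hpdi",
    "piecewise_predictor",
    "ordinal_probit_probs",
    "log_likelihood",
    "fit",
    "hpdi",
    "posterior_summary",
    "indirect_effect",
    "rw_metropolis",
    "REPORTED_PARAMS",
]

# Parameters surfaced in summaries (field-standard names).  ``mean_tau_*``
# are derived per draw: the mean of the truncated-normal breakpoint
# distribution.  The raw location parameters ``mu_tau_*`` are reported too,
# but they are only weakly identified: on a bounded trial range, a low
# location with a large scale and a central location with a moderate scale
# imply nearly the same breakpoint distribution — its mean is the
# identified "average breakpoint" quantity.
REPORTED_PARAMS = (
    "lambda_S",
    "lambda_G",
    "gamma_S",
    "gamma_G",
    "gamma_D",
    "mu_tau_S",
    "mu_tau_P",
    "mean_tau_S",
    "mean_tau_P",
    "rho",
)


def truncnorm_mean(mu, sigma, lo: float, hi: float):
    """Mean of a Normal(mu, sigma^2) truncated to [lo, hi]."""
    from scipy.stats import norm as _norm

    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    a = (lo - mu) / sigma
    b = (hi - mu) / sigma
    out = mu + sigma * (_norm.pdf(a) - _norm.pdf(b)) / (ndtr(b) - ndtr(a))
    return float(out) if np.ndim(out) == 0 else out

_TINY = 1e-300


# ---------------------------------------------------------------------------
# data container

@dataclass
class ModelData:
    """Flattened observation-level design arrays.

    ``S`` observations: one per click.  ``G`` observations: one per recorded
    trial.  ``Y`` observations: one per click with an observed PAS response;
    ``pair_idx`` indexes the Y observations of dyad-mates in the same trial
    (column 0 = member 1, column 1 = member 2), which share a residual
    correlation; ``single_idx`` are the remaining Y observations.
    """

    n_teams: int
    n_individuals: int
    n_trials_max: int
    # individual-success observations
    s_ind: np.ndarray
    s_team: np.ndarray
    s_trial: np.ndarray
    s_val: np.ndarray
    s_delay: np.ndarray
    # joint-success observations (one per trial)
    g_team: np.ndarray
    g_val: np.ndarray
    g_delay: np.ndarray
    # PAS observations
    y_ind: np.ndarray
    y_team: np.ndarray
    y_trial: np.ndarray
    y_val: np.ndarray
    y_S: np.ndarray
    y_G: np.ndarray
    y_D: np.ndarray
    pair_idx: np.ndarray  # (n_pairs, 2)
    single_idx: np.ndarray

    @classmethod
    def from_outcomes(cls, outcomes, n_trials_max: int | None = None) -> "ModelData":
        """Build design arrays from :class:`~percross.descriptives.TrialOutcome`s.

        The individual index of player ``m`` (1 or 2) of the ``k``-th team
        (teams ordered by id) is ``2 k + m - 1``.
        """
        team_ids = sorted({o.team_id for o in outcomes})
        team_pos = {tid: k for k, tid in enumerate(team_ids)}
        s_rows, g_rows, y_rows = [], [], []
        for o in outcomes:
            j = team_pos[o.team_id]
            g_rows.append((j, int(o.joint_success), o.delay_indicator))
            for p in (0, 1):
                if not o.clicked[p]:
                    continue
                i = 2 * j + p
                s = int(bool(o.correct[p]))
                s_rows.append((i, j, o.trial_number, s, o.delay_indicator))
                if o.pas[p] is not None:
                    y_rows.append(
                        (i, j, o.trial_number, o.pas[p], s, int(o.joint_success), o.delay_indicator)
                    )
        return cls.from_rows(
            n_teams=len(team_ids),
            s_rows=s_rows,
            g_rows=g_rows,
            y_rows=y_rows,
            n_trials_max=n_trials_max
            or max((o.trial_number for o in outcomes), default=20),
        )

    @classmethod
    def from_rows(cls, n_teams, s_rows, g_rows, y_rows, n_trials_max) -> "ModelData":
        s = np.asarray(s_rows, dtype=float).reshape(-1, 5)
        g = np.asarray(g_rows, dtype=float).reshape(-1, 3)
        y = np.asarray(y_rows, dtype=float).reshape(-1, 7)
        # pair up Y observations of the two members of a team in one trial
        key = {}
        pairs, singles = [], []
        for n in range(len(y)):
            k = (int(y[n, 1]), int(y[n, 2]))  # (team, trial)
            if k in key:
                m = key.pop(k)
                first, second = (m, n) if int(y[m, 0]) % 2 == 0 else (n, m)
                pairs.append((first, second))
            else:
                key[k] = n
        singles = sorted(key.values())
        return cls(
            n_teams=n_teams,
            n_individuals=2 * n_teams,
            n_trials_max=int(n_trials_max),
            s_ind=s[:, 0].astype(int),
            s_team=s[:, 1].astype(int),
            s_trial=s[:, 2],
            s_val=s[:, 3],
            s_delay=s[:, 4],
            g_team=g[:, 0].astype(int),
            g_val=g[:, 1],
            g_delay=g[:, 2],
            y_ind=y[:, 0].astype(int),
            y_team=y[:, 1].astype(int),
            y_trial=y[:, 2],
            y_val=y[:, 3].astype(int),
            y_S=y[:, 4],
            y_G=y[:, 5],
            y_D=y[:, 6],
            pair_idx=np.asarray(pairs, dtype=int).reshape(-1, 2),
            single_idx=np.asarray(singles, dtype=int),
        )

    @property
    def n_obs(self) -> int:
        return len(self.s_val)


# ---------------------------------------------------------------------------
# model building blocks

def piecewise_predictor(t, tau, intercept, slope):
    """Latent learning curve: rises until the breakpoint, then consolidates.

    ``intercept + slope * (min(t, tau) - 1)``: equals the intercept at trial
    1 and is constant for ``t >= tau``.
    """
    t = np.asarray(t, dtype=float)
    out = intercept + slope * (np.minimum(t, tau) - 1.0)
    return float(out) if np.ndim(out) == 0 else out


def ordinal_probit_probs(eta, cutpoints):
    """Category probabilities of a 4-level ordinal probit.

    ``P(Y = k) = Phi(kappa_k - eta) - Phi(kappa_{k-1} - eta)`` with
    ``kappa_0 = -inf`` and ``kappa_4 = +inf``.
    """
    cutpoints = np.asarray(cutpoints, dtype=float)
    if cutpoints.shape != (3,) or not np.all(np.diff(cutpoints) > 0):
        raise ValueError("cutpoints must be three strictly increasing values")
    eta = np.asarray(eta, dtype=float)
    cum = ndtr(cutpoints - eta[..., None])  # (..., 3)
    ones = np.ones(eta.shape + (1,))
    zeros = np.zeros(eta.shape + (1,))
    cum_full = np.concatenate([zeros, cum, ones], axis=-1)
    return np.diff(cum_full, axis=-1)


def _bernoulli_probit_loglik(eta, val):
    """Per-observation log-likelihood of a binary probit, numerically stable."""
    return np.where(val > 0.5, log_ndtr(eta), log_ndtr(-eta))


from functools import lru_cache


@lru_cache(maxsize=8)
def _gl_nodes(nq: int):
    x, w = np.polynomial.legendre.leggauss(nq)
    return x, w


def bvn_rect_prob(a1, b1, a2, b2, rho, nq: int = 48):
    """P(a1 < Z1 < b1, a2 < Z2 < b2) for standard bivariate normal (Z1, Z2).

    Gauss-Legendre quadrature of the conditional-normal representation,
    vectorised over observations; infinite bounds are passed as +-inf and
    clipped to +-8.5 where the mass is negligible.
    """
    a1 = np.clip(np.asarray(a1, dtype=float), -8.5, 8.5)
    b1 = np.clip(np.asarray(b1, dtype=float), -8.5, 8.5)
    a2 = np.asarray(a2, dtype=float)
    b2 = np.asarray(b2, dtype=float)
    if abs(rho) < 1e-12:
        return (ndtr(b1) - ndtr(a1)) * (ndtr(np.clip(b2, -9, 9)) - ndtr(np.clip(a2, -9, 9)))
    s = np.sqrt(1.0 - rho * rho)
    x, w = _gl_nodes(nq)
    half = 0.5 * (b1 - a1)
    mid = 0.5 * (b1 + a1)
    z = mid[..., None] + half[..., None] * x  # (..., nq)
    phi = np.exp(-0.5 * z * z) / np.sqrt(2 * np.pi)
    inner = ndtr((b2[..., None] - rho * z) / s) - ndtr((a2[..., None] - rho * z) / s)
    out = half * np.einsum("...q,q->...", phi * inner, w)
    return np.maximum(out, 0.0)


# ---------------------------------------------------------------------------
# parameters, priors, configuration

VECTOR_PARAMS = ("a", "b", "tau_S", "u", "v", "tau_P", "c")
SCALAR_PARAMS = (
    "lambda_S",
    "lambda_G",
    "gamma_S",
    "gamma_G",
    "gamma_D",
    "rho",
    "mu_a",
    "sigma_a",
    "sigma_b",
    "mu_tau_S",
    "sigma_tau_S",
    "mu_c",
    "sigma_c",
    "sigma_u",
    "sigma_v",
    "mu_tau_P",
    "sigma_tau_P",
)


@dataclass(frozen=True)
class PriorConfig:
    """Weakly informative defaults; all overridable.

    Regression effects are Normal(0, effect_sd^2); random-effect SDs are
    Half-Normal(sd_scale); breakpoint SDs Half-Normal(tau_sd_scale);
    breakpoint hyper-means Uniform(1, T); cutpoints Normal(0, kappa_sd^2)
    under an ordering constraint; rho Uniform(-1, 1).
    """

    effect_sd: float = 2.5
    sd_scale: float = 1.0
    tau_sd_scale: float = 5.0
    kappa_sd: float = 5.0


@dataclass(frozen=True)
class McmcConfig:
    chains: int = 2
    warmup: int = 800
    draws: int = 800
    quad_nodes: int = 32
    target_accept: float = 0.44
    fixed: dict = field(default_factory=dict)  # parameter name -> pinned value
    rhat_threshold: float = 1.01
    ess_threshold: float = 400.0

    def __post_init__(self):
        if self.chains < 1:
            raise ValueError("need at least 1 chain")


def _log_halfnormal(x, scale):
    x = np.asarray(x, dtype=float)
    return np.where(x >= 0, -0.5 * (x / scale) ** 2 - np.log(scale), -np.inf)


def _log_normal(x, mu, sd):
    return -0.5 * ((np.asarray(x) - mu) / sd) ** 2 - np.log(sd)


def _log_truncnorm(x, mu, sd, lo, hi):
    """log density of Normal(mu, sd) truncated to [lo, hi], incl. normalisation."""
    x = np.asarray(x, dtype=float)
    z = np.log(ndtr((hi - mu) / sd) - ndtr((lo - mu) / sd) + _TINY)
    core = -0.5 * ((x - mu) / sd) ** 2 - np.log(sd) - 0.5 * np.log(2 * np.pi)
    return np.where((x >= lo) & (x <= hi), core - z, -np.inf)


# ---------------------------------------------------------------------------
# likelihood

def _eta_S(p, data: ModelData):
    return (
        p["a"][data.s_ind]
        + p["b"][data.s_ind] * (np.minimum(data.s_trial, p["tau_S"][data.s_ind]) - 1.0)
        + p["lambda_S"] * data.s_delay
    )


def _eta_G(p, data: ModelData):
    return p["c"][data.g_team] + p["lambda_G"] * data.g_delay


def _eta_Y(p, data: ModelData):
    return (
        p["u"][data.y_ind]
        + p["v"][data.y_ind] * (np.minimum(data.y_trial, p["tau_P"][data.y_ind]) - 1.0)
        + p["gamma_S"] * data.y_S
        + p["gamma_G"] * data.y_G
        + p["gamma_D"] * data.y_D
    )


def _y_bounds(p, data: ModelData, eta):
    kappa_ext = np.concatenate([[-np.inf], p["kappa"], [np.inf]])
    lower = kappa_ext[data.y_val - 1] - eta
    upper = kappa_ext[data.y_val] - eta
    return lower, upper


def _loglik_S(p, data: ModelData):
    return _bernoulli_probit_loglik(_eta_S(p, data), data.s_val)


def _loglik_G(p, data: ModelData):
    return _bernoulli_probit_loglik(_eta_G(p, data), data.g_val)


def _loglik_Y_parts(p, data: ModelData, nq: int = 48):
    """(per-single log-lik, per-pair log-lik) of the ordinal PAS submodel."""
    eta = _eta_Y(p, data)
    lower, upper = _y_bounds(p, data, eta)
    rho = p["rho"]
    si = data.single_idx
    ll_single = np.log(
        np.maximum(ndtr(np.clip(upper[si], -9, 9)) - ndtr(np.clip(lower[si], -9, 9)), _TINY)
    )
    i1, i2 = data.pair_idx[:, 0], data.pair_idx[:, 1]
    prob = bvn_rect_prob(lower[i1], upper[i1], lower[i2], upper[i2], rho, nq=nq)
    ll_pair = np.log(np.maximum(prob, _TINY))
    return ll_single, ll_pair


def log_likelihood(data: ModelData, params: dict, nq: int = 48) -> float:
    """Total log-likelihood of the three submodels at ``params``.

    ``params`` maps names to values: vector parameters ``a, b, tau_S, u, v,
    tau_P`` (length = individuals), ``c`` (length = teams), ``kappa`` (3
    increasing cutpoints), and scalars ``lambda_S, lambda_G, gamma_S,
    gamma_G, gamma_D, rho``.  Missing PAS responses contribute nothing; dyad
    trials where both PAS values are observed use the bivariate-normal
    rectangle probability with correlation ``rho``.
    """
    for k, v in params.items():
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite value in parameter {k!r}")
    kappa = np.asarray(params["kappa"], dtype=float)
    if not np.all(np.diff(kappa) > 0):
        raise ValueError("cutpoints must be strictly increasing")
    ll = float(np.sum(_loglik_S(params, data))) + float(np.sum(_loglik_G(params, data)))
    ll_single, ll_pair = _loglik_Y_parts(params, data, nq=nq)
    return ll + float(np.sum(ll_single)) + float(np.sum(ll_pair))


def _log_prior(p, data: ModelData, pr: PriorConfig, T: float) -> float:
    lp = 0.0
    lp += np.sum(_log_normal(p["a"], p["mu_a"], p["sigma_a"]))
    lp += np.sum(_log_halfnormal(p["b"], p["sigma_b"]))
    lp += np.sum(_log_truncnorm(p["tau_S"], p["mu_tau_S"], p["sigma_tau_S"], 1.0, T))
    lp += np.sum(_log_normal(p["c"], p["mu_c"], p["sigma_c"]))
    lp += np.sum(_log_normal(p["u"], 0.0, p["sigma_u"]))
    lp += np.sum(_log_halfnormal(p["v"], p["sigma_v"]))
    lp += np.sum(_log_truncnorm(p["tau_P"], p["mu_tau_P"], p["sigma_tau_P"], 1.0, T))
    for name in ("lambda_S", "lambda_G", "gamma_S", "gamma_G", "gamma_D"):
        lp += _log_normal(p[name], 0.0, pr.effect_sd)
    lp += np.sum(_log_normal(p["kappa"], 0.0, pr.kappa_sd))
    for name in ("sigma_a", "sigma_b", "sigma_c", "sigma_u", "sigma_v"):
        lp += _log_halfnormal(p[name], pr.sd_scale)
    for name in ("sigma_tau_S", "sigma_tau_P"):
        lp += _log_halfnormal(p[name], pr.tau_sd_scale)
    if not (1.0 <= p["mu_tau_S"] <= T and 1.0 <= p["mu_tau_P"] <= T):
        return -np.inf
    if not (-1.0 < p["rho"] < 1.0):
        return -np.inf
    return float(lp)


# ---------------------------------------------------------------------------
# generic scalar Metropolis (also the unit used in degenerate-submodel tests)

def rw_metropolis(logpdf, x0: float, n: int, seed: int, warmup: int = 500, scale: float = 1.0):
    """Adaptive scalar random-walk Metropolis; returns post-warmup draws."""
    rng = np.random.default_rng(seed)
    x = float(x0)
    lp = logpdf(x)
    ls = np.log(scale)
    out = np.empty(n)
    for k in range(warmup + n):
        prop = x + np.exp(ls) * rng.standard_normal()
        lp_prop = logpdf(prop)
        acc = np.log(rng.uniform()) < lp_prop - lp
        if acc:
            x, lp = prop, lp_prop
        if k < warmup:
            ls += (float(acc) - 0.44) / (1 + k) ** 0.6
        else:
            out[k - warmup] = x
    return out


# ---------------------------------------------------------------------------
# the sampler

class _ChainState:
    """One chain: current parameters, cached predictors/log-likelihoods, scales.

    Linear predictors of the three submodels are cached and updated
    incrementally on acceptance; unit-level parameters are proposed in small
    blocks (all of an individual's parameters for one submodel at once) and
    accepted per unit, vectorised across units.  Dyad-mates are coupled by
    the bivariate PAS terms, so PAS-side unit updates run in two passes (one
    per member slot); within a pass all touched individuals belong to
    different dyads and factorise.
    """

    BLOCK_TARGET = 0.30  # acceptance target for multi-parameter blocks

    def __init__(self, data, priors, cfg, rng):
        # Sample in a centered parametrization: covariates of the probit
        # submodels are mean-centered (exact reparametrization absorbing the
        # shifts into intercepts/cutpoints), which decorrelates the effect
        # parameters from the cutpoints and intercept fields.  ``snapshot``
        # converts draws back to the standard parametrization.
        self._m_sD = float(np.mean(data.s_delay)) if len(data.s_delay) else 0.0
        self._m_gD = float(np.mean(data.g_delay)) if len(data.g_delay) else 0.0
        self._m_yS = float(np.mean(data.y_S)) if len(data.y_S) else 0.0
        self._m_yG = float(np.mean(data.y_G)) if len(data.y_G) else 0.0
        self._m_yD = float(np.mean(data.y_D)) if len(data.y_D) else 0.0
        self.data = replace(
            data,
            s_delay=data.s_delay - self._m_sD,
            g_delay=data.g_delay - self._m_gD,
            y_S=data.y_S - self._m_yS,
            y_G=data.y_G - self._m_yG,
            y_D=data.y_D - self._m_yD,
        )
        data = self.data
        self.priors = priors
        self.cfg = cfg
        self.rng = rng
        self.T = float(data.n_trials_max)
        self.p = self._init_params()
        for name, val in cfg.fixed.items():
            if name == "kappa":
                self.p[name] = np.asarray(val, dtype=float)
            elif name in VECTOR_PARAMS:
                self.p[name] = np.full_like(self.p[name], float(val))
            else:
                self.p[name] = float(val)
        self.nq = cfg.quad_nodes
        self._glx, self._glw = _gl_nodes(self.nq)
        self._refresh_caches()
        I, J = data.n_individuals, data.n_teams
        self.ls = {n: np.full(I, np.log(0.3)) for n in ("a", "b", "u", "v")}
        self.ls["tau_S"] = np.full(I, np.log(2.0))
        self.ls["tau_P"] = np.full(I, np.log(2.0))
        self.ls["c"] = np.full(J, np.log(0.3))
        for n in SCALAR_PARAMS:
            self.ls[n] = np.log(0.15 if n.startswith(("lambda", "gamma", "rho")) else 0.3)
        self.ls["mu_tau_S"] = self.ls["mu_tau_P"] = np.log(1.5)
        self.ls["kappa"] = np.full(3, np.log(0.15))
        self.ls["tau_shift_S"] = np.log(1.0)
        self.ls["tau_shift_P"] = np.log(1.0)
        self.ls["tau_scale_S"] = np.log(0.3)
        self.ls["tau_scale_P"] = np.log(0.3)

    def _init_params(self):
        d, rng = self.data, self.rng
        I, J = d.n_individuals, d.n_teams
        sbar = float(np.clip(np.mean(d.s_val), 0.05, 0.95)) if len(d.s_val) else 0.5
        gbar = float(np.clip(np.mean(d.g_val), 0.05, 0.95)) if len(d.g_val) else 0.5
        p = {
            "a": ndtri(sbar) + 0.2 * rng.standard_normal(I),
            "b": np.abs(0.1 + 0.05 * rng.standard_normal(I)),
            "tau_S": rng.uniform(2.0, min(8.0, self.T), I),
            "c": ndtri(gbar) + 0.2 * rng.standard_normal(J),
            "u": 0.1 * rng.standard_normal(I),
            "v": np.abs(0.1 + 0.05 * rng.standard_normal(I)),
            "tau_P": rng.uniform(2.0, min(10.0, self.T), I),
            "lambda_S": 0.1 * rng.standard_normal(),
            "lambda_G": 0.1 * rng.standard_normal(),
            "gamma_S": 0.1 * rng.standard_normal(),
            "gamma_G": 0.1 * rng.standard_normal(),
            "gamma_D": 0.1 * rng.standard_normal(),
            "rho": 0.0,
            "mu_a": ndtri(sbar),
            "sigma_a": 0.5,
            "sigma_b": 0.2,
            "mu_tau_S": 4.0,
            "sigma_tau_S": 2.5,
            "mu_c": ndtri(gbar),
            "sigma_c": 0.5,
            "sigma_u": 0.5,
            "sigma_v": 0.2,
            "mu_tau_P": 5.0,
            "sigma_tau_P": 2.5,
        }
        # start cutpoints at the empirical marginal quantiles of Y
        if len(d.y_val):
            cum = np.clip(
                np.cumsum(np.bincount(d.y_val, minlength=5)[1:4]) / len(d.y_val),
                0.02,
                0.98,
            )
            kappa = ndtri(cum)
        else:
            kappa = np.array([-1.0, 0.0, 1.0])
        kappa = np.sort(kappa + 0.05 * rng.standard_normal(3))
        while np.any(np.diff(kappa) <= 1e-3):
            kappa += np.array([-0.1, 0.0, 0.1])
            kappa = np.sort(kappa)
        p["kappa"] = kappa
        return p

    # -- cached predictors and likelihood pieces -----------------------------
    def _refresh_caches(self):
        self.eta_s = _eta_S(self.p, self.data)
        self.eta_g = _eta_G(self.p, self.data)
        self.eta_y = _eta_Y(self.p, self.data)
        self.ll_s = _bernoulli_probit_loglik(self.eta_s, self.data.s_val)
        self.ll_g = _bernoulli_probit_loglik(self.eta_g, self.data.g_val)
        self.ll_ys, self.ll_yp = self._y_ll(self.eta_y, self.p["kappa"], self.p["rho"])

    def _y_ll(self, eta, kappa, rho):
        d = self.data
        kappa_ext = np.concatenate([[-np.inf], kappa, [np.inf]])
        lower = kappa_ext[d.y_val - 1] - eta
        upper = kappa_ext[d.y_val] - eta
        si = d.single_idx
        ll_single = np.log(
            np.maximum(
                ndtr(np.clip(upper[si], -9, 9)) - ndtr(np.clip(lower[si], -9, 9)), _TINY
            )
        )
        i1, i2 = d.pair_idx[:, 0], d.pair_idx[:, 1]
        prob = bvn_rect_prob(lower[i1], upper[i1], lower[i2], upper[i2], rho, nq=self.nq)
        ll_pair = np.log(np.maximum(prob, _TINY))
        return ll_single, ll_pair

    def total_loglik(self):
        return (
            float(np.sum(self.ll_s))
            + float(np.sum(self.ll_g))
            + float(np.sum(self.ll_ys))
            + float(np.sum(self.ll_yp))
        )

    # -- adaptation -----------------------------------------------------------
    def _adapt(self, name, acc, k, target, idx=None):
        step = 1.0 / (1 + k) ** 0.6
        delta = step * (np.asarray(acc, dtype=float) - target)
        if idx is None:
            self.ls[name] = self.ls[name] + delta
        else:
            self.ls[name][idx] = self.ls[name][idx] + delta

    def _propose(self, name, idx=None):
        cur = self.p[name]
        if np.ndim(cur) == 0 or isinstance(cur, float):
            return float(cur) + np.exp(self.ls[name]) * self.rng.standard_normal()
        noise = np.exp(self.ls[name]) * self.rng.standard_normal(len(cur))
        if idx is None:
            return cur + noise
        prop = np.array(cur, copy=True)
        prop[idx] = prop[idx] + noise[idx]
        return prop

    # -- unit-level block updates --------------------------------------------
    def _s_prior(self, a, b, tau):
        p = self.p
        return (
            _log_normal(a, p["mu_a"], p["sigma_a"])
            + _log_halfnormal(b, p["sigma_b"])
            + _log_truncnorm(tau, p["mu_tau_S"], p["sigma_tau_S"], 1.0, self.T)
        )

    def _y_prior(self, u, v, tau):
        p = self.p
        return (
            _log_normal(u, 0.0, p["sigma_u"])
            + _log_halfnormal(v, p["sigma_v"])
            + _log_truncnorm(tau, p["mu_tau_P"], p["sigma_tau_P"], 1.0, self.T)
        )

    def _update_s_block(self, warm, k):
        """Joint per-individual proposal of (a_i, b_i, tau_S_i)."""
        d, p = self.data, self.p
        I = d.n_individuals
        names = [n for n in ("a", "b", "tau_S") if n not in self.cfg.fixed]
        if not names:
            return
        prop = {n: (self._propose(n) if n in names else p[n]) for n in ("a", "b", "tau_S")}
        prior_delta = self._s_prior(prop["a"], prop["b"], prop["tau_S"]) - self._s_prior(
            p["a"], p["b"], p["tau_S"]
        )
        eta_try = (
            prop["a"][d.s_ind]
            + prop["b"][d.s_ind] * (np.minimum(d.s_trial, prop["tau_S"][d.s_ind]) - 1.0)
            + p["lambda_S"] * d.s_delay
        )
        ll_new = _bernoulli_probit_loglik(eta_try, d.s_val)
        lik_delta = np.bincount(d.s_ind, weights=ll_new - self.ll_s, minlength=I)
        accept = np.log(self.rng.uniform(size=I)) < prior_delta + lik_delta
        if np.any(accept):
            for n in names:
                p[n] = np.where(accept, prop[n], p[n])
            keep = accept[d.s_ind]
            self.eta_s = np.where(keep, eta_try, self.eta_s)
            self.ll_s = np.where(keep, ll_new, self.ll_s)
        if warm:
            for n in names:
                self._adapt(n, accept, k, self.BLOCK_TARGET)

    def _update_c(self, warm, k):
        if "c" in self.cfg.fixed:
            return
        d, p = self.data, self.p
        J = d.n_teams
        prop = self._propose("c")
        prior_delta = _log_normal(prop, p["mu_c"], p["sigma_c"]) - _log_normal(
            p["c"], p["mu_c"], p["sigma_c"]
        )
        eta_try = self.eta_g + (prop - p["c"])[d.g_team]
        ll_new = _bernoulli_probit_loglik(eta_try, d.g_val)
        lik_delta = np.bincount(d.g_team, weights=ll_new - self.ll_g, minlength=J)
        accept = np.log(self.rng.uniform(size=J)) < prior_delta + lik_delta
        if np.any(accept):
            p["c"] = np.where(accept, prop, p["c"])
            keep = accept[d.g_team]
            self.eta_g = np.where(keep, eta_try, self.eta_g)
            self.ll_g = np.where(keep, ll_new, self.ll_g)
        if warm:
            self._adapt("c", accept, k, self.cfg.target_accept)

    def _apply_y_eta(self, eta_try, ys_new, yp_new, accept_ind):
        """Commit per-individual acceptances of a PAS-side local update."""
        d = self.data
        keep_obs = accept_ind[d.y_ind]
        self.eta_y = np.where(keep_obs, eta_try, self.eta_y)
        if len(d.single_idx):
            keep = accept_ind[d.y_ind[d.single_idx]]
            self.ll_ys = np.where(keep, ys_new, self.ll_ys)
        if len(d.pair_idx):
            # both members of a pair are in the same team but different
            # slots; within one slot pass only one side can change
            keep = accept_ind[d.y_ind[d.pair_idx[:, 0]]] | accept_ind[
                d.y_ind[d.pair_idx[:, 1]]
            ]
            self.ll_yp = np.where(keep, yp_new, self.ll_yp)

    def _update_y_block(self, warm, k):
        """Joint per-individual proposal of (u_i, v_i, tau_P_i), two slot passes."""
        d, p = self.data, self.p
        I = d.n_individuals
        names = [n for n in ("u", "v", "tau_P") if n not in self.cfg.fixed]
        if not names:
            return
        for slot in (0, 1):
            sel = np.arange(I) % 2 == slot
            prop = {
                n: (self._propose(n, idx=sel) if n in names else p[n])
                for n in ("u", "v", "tau_P")
            }
            prior_delta = self._y_prior(prop["u"], prop["v"], prop["tau_P"]) - self._y_prior(
                p["u"], p["v"], p["tau_P"]
            )
            eta_try = (
                prop["u"][d.y_ind]
                + prop["v"][d.y_ind] * (np.minimum(d.y_trial, prop["tau_P"][d.y_ind]) - 1.0)
                + p["gamma_S"] * d.y_S
                + p["gamma_G"] * d.y_G
                + p["gamma_D"] * d.y_D
            )
            ys_new, yp_new = self._y_ll(eta_try, p["kappa"], p["rho"])
            delta = np.zeros(I)
            if len(d.single_idx):
                np.add.at(delta, d.y_ind[d.single_idx], ys_new - self.ll_ys)
            if len(d.pair_idx):
                owner = d.y_ind[d.pair_idx[:, slot]]
                np.add.at(delta, owner, yp_new - self.ll_yp)
            log_acc = np.where(sel, prior_delta + delta, -np.inf)
            accept = np.log(self.rng.uniform(size=I)) < log_acc
            if np.any(accept):
                for n in names:
                    p[n] = np.where(accept, prop[n], p[n])
                self._apply_y_eta(eta_try, ys_new, yp_new, accept)
            if warm:
                for n in names:
                    self._adapt(n, accept[sel], k, self.BLOCK_TARGET, idx=sel)

    # -- global updates -------------------------------------------------------
    def _update_lambda_S(self, warm, k):
        if "lambda_S" in self.cfg.fixed:
            return
        d, p, pr = self.data, self.p, self.priors
        prop = self._propose("lambda_S")
        eta_try = self.eta_s + (prop - p["lambda_S"]) * d.s_delay
        ll_new = _bernoulli_probit_loglik(eta_try, d.s_val)
        delta = float(
            _log_normal(prop, 0.0, pr.effect_sd)
            - _log_normal(p["lambda_S"], 0.0, pr.effect_sd)
            + np.sum(ll_new) - np.sum(self.ll_s)
        )
        accept = np.log(self.rng.uniform()) < delta
        if accept:
            p["lambda_S"] = prop
            self.eta_s, self.ll_s = eta_try, ll_new
        if warm:
            self._adapt("lambda_S", float(accept), k, self.cfg.target_accept)

    def _update_lambda_G(self, warm, k):
        if "lambda_G" in self.cfg.fixed:
            return
        d, p, pr = self.data, self.p, self.priors
        prop = self._propose("lambda_G")
        eta_try = self.eta_g + (prop - p["lambda_G"]) * d.g_delay
        ll_new = _bernoulli_probit_loglik(eta_try, d.g_val)
        delta = float(
            _log_normal(prop, 0.0, pr.effect_sd)
            - _log_normal(p["lambda_G"], 0.0, pr.effect_sd)
            + np.sum(ll_new) - np.sum(self.ll_g)
        )
        accept = np.log(self.rng.uniform()) < delta
        if accept:
            p["lambda_G"] = prop
            self.eta_g, self.ll_g = eta_try, ll_new
        if warm:
            self._adapt("lambda_G", float(accept), k, self.cfg.target_accept)

    def _update_gammas(self, warm, k):
        """Joint proposal of the PAS effects (gamma_S, gamma_G, gamma_D)."""
        d, p, pr = self.data, self.p, self.priors
        names = [n for n in ("gamma_S", "gamma_G", "gamma_D") if n not in self.cfg.fixed]
        if not names:
            return
        prop = {n: (self._propose(n) if n in names else p[n]) for n in ("gamma_S", "gamma_G", "gamma_D")}
        eta_try = (
            self.eta_y
            + (prop["gamma_S"] - p["gamma_S"]) * d.y_S
            + (prop["gamma_G"] - p["gamma_G"]) * d.y_G
            + (prop["gamma_D"] - p["gamma_D"]) * d.y_D
        )
        ys_new, yp_new = self._y_ll(eta_try, p["kappa"], p["rho"])
        delta = float(
            sum(
                _log_normal(prop[n], 0.0, pr.effect_sd) - _log_normal(p[n], 0.0, pr.effect_sd)
                for n in names
            )
            + np.sum(ys_new) - np.sum(self.ll_ys)
            + np.sum(yp_new) - np.sum(self.ll_yp)
        )
        accept = np.log(self.rng.uniform()) < delta
        if accept:
            for n in names:
                p[n] = prop[n]
            self.eta_y, self.ll_ys, self.ll_yp = eta_try, ys_new, yp_new
        if warm:
            for n in names:
                self._adapt(n, float(accept), k, self.BLOCK_TARGET)

    def _update_kappa(self, warm, k):
        if "kappa" in self.cfg.fixed:
            return
        p, pr = self.p, self.priors
        kappa = p["kappa"] + np.exp(self.ls["kappa"]) * self.rng.standard_normal(3)
        accept = False
        if np.all(np.diff(kappa) > 0):
            ys_new, yp_new = self._y_ll(self.eta_y, kappa, p["rho"])
            delta = float(
                np.sum(_log_normal(kappa, 0.0, pr.kappa_sd))
                - np.sum(_log_normal(p["kappa"], 0.0, pr.kappa_sd))
                + np.sum(ys_new) - np.sum(self.ll_ys)
                + np.sum(yp_new) - np.sum(self.ll_yp)
            )
            accept = np.log(self.rng.uniform()) < delta
            if accept:
                p["kappa"] = kappa
                self.ll_ys, self.ll_yp = ys_new, yp_new
        if warm:
            self._adapt("kappa", float(accept), k, self.BLOCK_TARGET)

    def _update_rho(self, warm, k):
        if "rho" in self.cfg.fixed or not len(self.data.pair_idx):
            return
        p = self.p
        prop = self._propose("rho")
        if not (-0.999 < prop < 0.999):
            if warm:
                self._adapt("rho", 0.0, k, self.cfg.target_accept)
            return
        _, yp_new = self._y_ll_pairs_only(prop)
        delta = float(np.sum(yp_new) - np.sum(self.ll_yp))
        accept = np.log(self.rng.uniform()) < delta
        if accept:
            p["rho"] = prop
            self.ll_yp = yp_new
        if warm:
            self._adapt("rho", float(accept), k, self.cfg.target_accept)

    def _y_ll_pairs_only(self, rho):
        d, p = self.data, self.p
        kappa_ext = np.concatenate([[-np.inf], p["kappa"], [np.inf]])
        lower = kappa_ext[d.y_val - 1] - self.eta_y
        upper = kappa_ext[d.y_val] - self.eta_y
        i1, i2 = d.pair_idx[:, 0], d.pair_idx[:, 1]
        prob = bvn_rect_prob(lower[i1], upper[i1], lower[i2], upper[i2], rho, nq=self.nq)
        return None, np.log(np.maximum(prob, _TINY))

    def _update_tau_shift(self, which, warm, k):
        """Translate a whole breakpoint field together with its hyper-mean.

        Breakpoints of individuals are weakly identified, so single-site
        moves let the hyper-mean drift only slowly; this joint translation
        move restores mixing of ``mu_tau_*``.  The shift is a symmetric
        proposal; moves that would push any breakpoint (or the hyper-mean)
        out of [1, T] are rejected.
        """
        tau_name, mu_name, ls_name = (
            ("tau_S", "mu_tau_S", "tau_shift_S")
            if which == "S"
            else ("tau_P", "mu_tau_P", "tau_shift_P")
        )
        if tau_name in self.cfg.fixed or mu_name in self.cfg.fixed:
            return
        d, p = self.data, self.p
        delta = np.exp(self.ls[ls_name]) * self.rng.standard_normal()
        tau_try = p[tau_name] + delta
        mu_try = float(p[mu_name] + delta)
        if (
            np.any(tau_try < 1.0)
            or np.any(tau_try > self.T)
            or not (1.0 <= mu_try <= self.T)
        ):
            if warm:
                self._adapt(ls_name, 0.0, k, self.cfg.target_accept)
            return
        sig = p["sigma_tau_S" if which == "S" else "sigma_tau_P"]
        prior_delta = float(
            np.sum(_log_truncnorm(tau_try, mu_try, sig, 1.0, self.T))
            - np.sum(_log_truncnorm(p[tau_name], p[mu_name], sig, 1.0, self.T))
        )
        if which == "S":
            eta_try = (
                p["a"][d.s_ind]
                + p["b"][d.s_ind] * (np.minimum(d.s_trial, tau_try[d.s_ind]) - 1.0)
                + p["lambda_S"] * d.s_delay
            )
            ll_new = _bernoulli_probit_loglik(eta_try, d.s_val)
            lik_delta = float(np.sum(ll_new) - np.sum(self.ll_s))
            accept = np.log(self.rng.uniform()) < prior_delta + lik_delta
            if accept:
                p[tau_name], p[mu_name] = tau_try, mu_try
                self.eta_s, self.ll_s = eta_try, ll_new
        else:
            eta_try = (
                p["u"][d.y_ind]
                + p["v"][d.y_ind] * (np.minimum(d.y_trial, tau_try[d.y_ind]) - 1.0)
                + p["gamma_S"] * d.y_S
                + p["gamma_G"] * d.y_G
                + p["gamma_D"] * d.y_D
            )
            ys_new, yp_new = self._y_ll(eta_try, p["kappa"], p["rho"])
            lik_delta = float(
                np.sum(ys_new) - np.sum(self.ll_ys) + np.sum(yp_new) - np.sum(self.ll_yp)
            )
            accept = np.log(self.rng.uniform()) < prior_delta + lik_delta
            if accept:
                p[tau_name], p[mu_name] = tau_try, mu_try
                self.eta_y, self.ll_ys, self.ll_yp = eta_try, ys_new, yp_new
        if warm:
            self._adapt(ls_name, float(accept), k, self.cfg.target_accept)

    def _update_tau_scale(self, which, warm, k):
        """Multiplicative group move on a breakpoint field.

        Rescales (tau_i - 1) for all individuals together with the
        hyper-location (mu - 1) and the hyper-scale by a common factor
        e^delta (log-Jacobian (I + 2) delta).  Complements the additive
        translation, which is blocked whenever some breakpoint sits near
        the lower bound; scaling leaves such breakpoints near 1.
        """
        tau_name, mu_name, sig_name, ls_name = (
            ("tau_S", "mu_tau_S", "sigma_tau_S", "tau_scale_S")
            if which == "S"
            else ("tau_P", "mu_tau_P", "sigma_tau_P", "tau_scale_P")
        )
        fixed = self.cfg.fixed
        if tau_name in fixed or mu_name in fixed or sig_name in fixed:
            return
        d, p, pr = self.data, self.p, self.priors
        delta = np.exp(self.ls[ls_name]) * self.rng.standard_normal()
        f = np.exp(delta)
        tau_try = 1.0 + (p[tau_name] - 1.0) * f
        mu_try = float(1.0 + (p[mu_name] - 1.0) * f)
        sig_try = float(p[sig_name] * f)
        if np.any(tau_try > self.T) or not (1.0 <= mu_try <= self.T) or sig_try < 1e-2:
            if warm:
                self._adapt(ls_name, 0.0, k, self.cfg.target_accept)
            return
        log_jac = (d.n_individuals + 2) * delta
        prior_delta = float(
            np.sum(_log_truncnorm(tau_try, mu_try, sig_try, 1.0, self.T))
            - np.sum(_log_truncnorm(p[tau_name], p[mu_name], p[sig_name], 1.0, self.T))
            + _log_halfnormal(sig_try, pr.tau_sd_scale)
            - _log_halfnormal(p[sig_name], pr.tau_sd_scale)
        )
        if which == "S":
            eta_try = (
                p["a"][d.s_ind]
                + p["b"][d.s_ind] * (np.minimum(d.s_trial, tau_try[d.s_ind]) - 1.0)
                + p["lambda_S"] * d.s_delay
            )
            ll_new = _bernoulli_probit_loglik(eta_try, d.s_val)
            lik_delta = float(np.sum(ll_new) - np.sum(self.ll_s))
            accept = np.log(self.rng.uniform()) < prior_delta + lik_delta + log_jac
            if accept:
                p[tau_name], p[mu_name], p[sig_name] = tau_try, mu_try, sig_try
                self.eta_s, self.ll_s = eta_try, ll_new
        else:
            eta_try = (
                p["u"][d.y_ind]
                + p["v"][d.y_ind] * (np.minimum(d.y_trial, tau_try[d.y_ind]) - 1.0)
                + p["gamma_S"] * d.y_S
                + p["gamma_G"] * d.y_G
                + p["gamma_D"] * d.y_D
            )
            ys_new, yp_new = self._y_ll(eta_try, p["kappa"], p["rho"])
            lik_delta = float(
                np.sum(ys_new) - np.sum(self.ll_ys) + np.sum(yp_new) - np.sum(self.ll_yp)
            )
            accept = np.log(self.rng.uniform()) < prior_delta + lik_delta + log_jac
            if accept:
                p[tau_name], p[mu_name], p[sig_name] = tau_try, mu_try, sig_try
                self.eta_y, self.ll_ys, self.ll_yp = eta_try, ys_new, yp_new
        if warm:
            self._adapt(ls_name, float(accept), k, self.cfg.target_accept)

    def _grid_conditional_draw(self, grid, logp, cur, cur_logp_fn):
        """Independence-Metropolis draw from a 1-D conditional tabulated on a grid.

        The proposal is the piecewise-constant density given by ``logp`` on
        ``grid`` (a value is drawn by inverting the CDF and jittered
        uniformly within its cell); the Metropolis correction against the
        exact conditional makes the step exact.  Acceptance is near 1 for a
        smooth conditional.
        """
        widths = np.diff(grid)
        logw = logp[:-1] + np.log(widths)  # cell mass = density x width
        logw = logw - np.max(logw)
        cdf = np.cumsum(np.exp(logw))
        cdf /= cdf[-1]
        u = self.rng.uniform()
        kcell = min(int(np.searchsorted(cdf, u)), len(grid) - 2)
        prop = grid[kcell] + self.rng.uniform() * widths[kcell]
        # proposal log-density is piecewise constant: cell mass / cell width
        kcur = int(np.clip(np.searchsorted(grid, cur) - 1, 0, len(grid) - 2))
        log_q_prop = logw[kcell] - np.log(widths[kcell])
        log_q_cur = logw[kcur] - np.log(widths[kcur])
        log_acc = (cur_logp_fn(prop) - cur_logp_fn(cur)) - (log_q_prop - log_q_cur)
        if np.log(self.rng.uniform()) < log_acc:
            return float(prop)
        return float(cur)

    def _update_tau_hypers_gibbs(self, which):
        """Near-exact conditional draws of (mu_tau, sigma_tau) given the field.

        The conditional depends on the breakpoints only through their sum
        and sum of squares, so it is tabulated cheaply on a fine grid;
        random-walk updates of these hypers mix far too slowly inside the
        breakpoint funnel.
        """
        tau_name, mu_name, sig_name = (
            ("tau_S", "mu_tau_S", "sigma_tau_S")
            if which == "S"
            else ("tau_P", "mu_tau_P", "sigma_tau_P")
        )
        fixed = self.cfg.fixed
        p, pr, T = self.p, self.priors, self.T
        tau = p[tau_name]
        I = len(tau)
        s1, s2 = float(np.sum(tau)), float(np.sum(tau * tau))

        def log_cond_mu(mu, sig):
            mu = np.asarray(mu, dtype=float)
            sq = s2 - 2.0 * mu * s1 + I * mu * mu
            logZ = np.log(ndtr((T - mu) / sig) - ndtr((1.0 - mu) / sig) + _TINY)
            return -0.5 * sq / (sig * sig) - I * logZ

        if mu_name not in fixed:
            sig = float(p[sig_name])
            grid = np.linspace(1.0, T, 1024)
            p[mu_name] = self._grid_conditional_draw(
                grid, log_cond_mu(grid, sig), float(p[mu_name]),
                lambda m: float(log_cond_mu(m, sig)),
            )
        if sig_name not in fixed:
            mu = float(p[mu_name])

            def log_cond_sig(sig):
                sig = np.asarray(sig, dtype=float)
                sq = s2 - 2.0 * mu * s1 + I * mu * mu
                logZ = np.log(ndtr((T - mu) / sig) - ndtr((1.0 - mu) / sig) + _TINY)
                return (
                    -0.5 * sq / (sig * sig)
                    - I * (np.log(sig) + logZ)
                    - 0.5 * (sig / pr.tau_sd_scale) ** 2
                )

            grid = np.exp(np.linspace(np.log(5e-2), np.log(3 * pr.tau_sd_scale + T), 1024))
            p[sig_name] = self._grid_conditional_draw(
                grid, log_cond_sig(grid), float(p[sig_name]),
                lambda s: float(log_cond_sig(s)),
            )

    def _sample_truncnorm(self, mu, sd, size):
        from scipy.stats import truncnorm as _tn

        a, b = (1.0 - mu) / sd, (self.T - mu) / sd
        return _tn.rvs(a, b, loc=mu, scale=sd, size=size, random_state=self.rng)

    def _update_tau_independence(self, which, warm, k):
        """Refresh breakpoints from their hierarchical prior.

        Independence proposal from TruncNormal(mu_tau, sigma_tau, [1, T]);
        the prior cancels against the proposal density, so acceptance uses
        the likelihood ratio only.  Breakpoints of individuals with flat
        learning curves are likelihood-free and re-mix immediately, which
        keeps the hyper-mean from being dragged by stale values.
        """
        d, p = self.data, self.p
        I = d.n_individuals
        if which == "S":
            if "tau_S" in self.cfg.fixed:
                return
            prop = self._sample_truncnorm(p["mu_tau_S"], p["sigma_tau_S"], I)
            eta_try = (
                p["a"][d.s_ind]
                + p["b"][d.s_ind] * (np.minimum(d.s_trial, prop[d.s_ind]) - 1.0)
                + p["lambda_S"] * d.s_delay
            )
            ll_new = _bernoulli_probit_loglik(eta_try, d.s_val)
            lik_delta = np.bincount(d.s_ind, weights=ll_new - self.ll_s, minlength=I)
            accept = np.log(self.rng.uniform(size=I)) < lik_delta
            if np.any(accept):
                p["tau_S"] = np.where(accept, prop, p["tau_S"])
                keep = accept[d.s_ind]
                self.eta_s = np.where(keep, eta_try, self.eta_s)
                self.ll_s = np.where(keep, ll_new, self.ll_s)
            return
        if "tau_P" in self.cfg.fixed:
            return
        for slot in (0, 1):
            sel = np.arange(I) % 2 == slot
            prop = np.where(
                sel, self._sample_truncnorm(p["mu_tau_P"], p["sigma_tau_P"], I), p["tau_P"]
            )
            eta_try = (
                p["u"][d.y_ind]
                + p["v"][d.y_ind] * (np.minimum(d.y_trial, prop[d.y_ind]) - 1.0)
                + p["gamma_S"] * d.y_S
                + p["gamma_G"] * d.y_G
                + p["gamma_D"] * d.y_D
            )
            ys_new, yp_new = self._y_ll(eta_try, p["kappa"], p["rho"])
            delta = np.zeros(I)
            if len(d.single_idx):
                np.add.at(delta, d.y_ind[d.single_idx], ys_new - self.ll_ys)
            if len(d.pair_idx):
                owner = d.y_ind[d.pair_idx[:, slot]]
                np.add.at(delta, owner, yp_new - self.ll_yp)
            log_acc = np.where(sel, delta, -np.inf)
            accept = np.log(self.rng.uniform(size=I)) < log_acc
            if np.any(accept):
                p["tau_P"] = np.where(accept, prop, p["tau_P"])
                self._apply_y_eta(eta_try, ys_new, yp_new, accept)

    def _update_hyper(self, name, logp_fn, warm, k, support=None):
        if name in self.cfg.fixed:
            return
        cur = float(self.p[name])
        prop = cur + np.exp(self.ls[name]) * self.rng.standard_normal()
        if support is not None and not (support[0] < prop < support[1]):
            if warm:
                self._adapt(name, 0.0, k, self.cfg.target_accept)
            return
        delta = logp_fn(prop) - logp_fn(cur)
        accept = np.isfinite(delta) and np.log(self.rng.uniform()) < delta
        if accept:
            self.p[name] = prop
        if warm:
            self._adapt(name, float(accept), k, self.cfg.target_accept)

    # -- one full sweep -------------------------------------------------------
    def sweep(self, warm: bool, k: int):
        p, pr, T = self.p, self.priors, self.T

        self._update_s_block(warm, k)
        self._update_c(warm, k)
        self._update_y_block(warm, k)
        self._update_lambda_S(warm, k)
        self._update_lambda_G(warm, k)
        self._update_gammas(warm, k)
        self._update_kappa(warm, k)
        self._update_rho(warm, k)
        self._update_tau_shift("S", warm, k)
        self._update_tau_shift("P", warm, k)
        self._update_tau_independence("S", warm, k)
        self._update_tau_independence("P", warm, k)
        self._update_tau_scale("S", warm, k)
        self._update_tau_scale("P", warm, k)

        # hyperparameters (touch only their children's priors)
        self._update_hyper(
            "mu_a",
            lambda m: float(np.sum(_log_normal(p["a"], m, p["sigma_a"])))
            + float(_log_normal(m, 0.0, pr.effect_sd)),
            warm,
            k,
        )
        self._update_hyper(
            "sigma_a",
            lambda s: float(np.sum(_log_normal(p["a"], p["mu_a"], s)))
            + float(_log_halfnormal(s, pr.sd_scale)),
            warm,
            k,
            support=(1e-3, np.inf),
        )
        self._update_hyper(
            "sigma_b",
            lambda s: float(np.sum(_log_halfnormal(p["b"], s)))
            + float(_log_halfnormal(s, pr.sd_scale)),
            warm,
            k,
            support=(1e-3, np.inf),
        )
        # breakpoint hierarchy: near-exact conditional draws (random-walk
        # updates mix far too slowly inside the breakpoint funnel)
        self._update_tau_hypers_gibbs("S")
        self._update_tau_hypers_gibbs("P")
        self._update_hyper(
            "mu_c",
            lambda m: float(np.sum(_log_normal(p["c"], m, p["sigma_c"])))
            + float(_log_normal(m, 0.0, pr.effect_sd)),
            warm,
            k,
        )
        self._update_hyper(
            "sigma_c",
            lambda s: float(np.sum(_log_normal(p["c"], p["mu_c"], s)))
            + float(_log_halfnormal(s, pr.sd_scale)),
            warm,
            k,
            support=(1e-3, np.inf),
        )
        self._update_hyper(
            "sigma_u",
            lambda s: float(np.sum(_log_normal(p["u"], 0.0, s)))
            + float(_log_halfnormal(s, pr.sd_scale)),
            warm,
            k,
            support=(1e-3, np.inf),
        )
        self._update_hyper(
            "sigma_v",
            lambda s: float(np.sum(_log_halfnormal(p["v"], s)))
            + float(_log_halfnormal(s, pr.sd_scale)),
            warm,
            k,
            support=(1e-3, np.inf),
        )
    def snapshot(self):
        """Current parameters, converted back to the uncentered parametrization."""
        out = {}
        for name, val in self.p.items():
            out[name] = np.array(val, dtype=float, copy=True)
        out["a"] = out["a"] - out["lambda_S"] * self._m_sD
        out["mu_a"] = out["mu_a"] - out["lambda_S"] * self._m_sD
        out["c"] = out["c"] - out["lambda_G"] * self._m_gD
        out["mu_c"] = out["mu_c"] - out["lambda_G"] * self._m_gD
        shift = (
            out["gamma_S"] * self._m_yS
            + out["gamma_G"] * self._m_yG
            + out["gamma_D"] * self._m_yD
        )
        out["u"] = out["u"] - shift
        return out


# ---------------------------------------------------------------------------
# public fitting interface

@dataclass
class PosteriorDraws:
    """Labelled MCMC output: ``draws[name]`` has shape (chains, iters, ...)."""

    draws: dict
    seed: int
    config: McmcConfig
    diagnostics: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated along the draw axis."""
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:])

    def to_frame(self) -> pd.DataFrame:
        """Long format: chain, iter, parameter, value."""
        rows = []
        for name, arr in self.draws.items():
            C, N = arr.shape[:2]
            flat = arr.reshape(C, N, -1)
            for dim in range(flat.shape[2]):
                label = name if flat.shape[2] == 1 else f"{name}[{dim}]"
                for c in range(C):
                    rows.append(
                        pd.DataFrame(
                            {
                                "chain": c,
                                "iter": np.arange(N),
                                "parameter": label,
                                "value": flat[c, :, dim],
                            }
                        )
                    )
        return pd.concat(rows, ignore_index=True)


def fit(
    data: ModelData,
    priors: PriorConfig | None = None,
    mcmc: McmcConfig | None = None,
    seed: int = 0,
) -> PosteriorDraws:
    """Sample the posterior of the path model.

    Reproducible given ``seed``; each chain gets an independent child
    stream.  Convergence problems (split R-hat above threshold or low ESS on
    a reported parameter) are surfaced as warnings in the result, never as
    exceptions.  Degenerate data (e.g. all successes) yields a
    prior-dominated fit with a warning.
    """
    priors = priors or PriorConfig()
    mcmc = mcmc or McmcConfig()
    if data.n_teams < 2:
        raise ValueError("need at least 2 teams to fit the hierarchical model")
    warns: list[str] = []
    for label, vals in (("individual success", data.s_val), ("joint success", data.g_val)):
        if len(vals) and (np.all(vals == 1) or np.all(vals == 0)):
            msg = f"degenerate data: {label} constant; fit will be prior-dominated"
            warns.append(msg)
            warnings.warn(msg)

    seeds = np.random.SeedSequence(seed).spawn(mcmc.chains)
    chain_draws: list[dict] = []
    for c in range(mcmc.chains):
        rng = np.random.default_rng(seeds[c])
        state = _ChainState(data, priors, mcmc, rng)
        store: dict[str, list] = {}
        for k in range(mcmc.warmup + mcmc.draws):
            state.sweep(warm=k < mcmc.warmup, k=min(k, mcmc.warmup))
            if k >= mcmc.warmup:
                snap = state.snapshot()
                for name, val in snap.items():
                    store.setdefault(name, []).append(val)
        chain_draws.append({name: np.stack(vals) for name, vals in store.items()})

    draws = {
        name: np.stack([cd[name] for cd in chain_draws]) for name in chain_draws[0]
    }
    # derived: identified mean of the breakpoint distributions
    T = float(data.n_trials_max)
    draws["mean_tau_S"] = truncnorm_mean(draws["mu_tau_S"], draws["sigma_tau_S"], 1.0, T)
    draws["mean_tau_P"] = truncnorm_mean(draws["mu_tau_P"], draws["sigma_tau_P"], 1.0, T)
    diagnostics = _diagnostics(draws, mcmc, warns)
    return PosteriorDraws(
        draws=draws, seed=seed, config=mcmc, diagnostics=diagnostics, warnings=warns
    )


def _diagnostics(draws: dict, mcmc: McmcConfig, warns: list[str]) -> pd.DataFrame:
    rows = []
    for name in REPORTED_PARAMS + ("kappa",):
        if name in mcmc.fixed or name not in draws:
            continue
        arr = draws[name]
        flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
        for dim in range(flat.shape[2]):
            x = flat[:, :, dim]
            label = name if flat.shape[2] == 1 else f"{name}[{dim}]"
            if np.allclose(x, x.flat[0]):
                rhat, ess = np.nan, 0.0
            else:
                rhat = float(np.asarray(az.rhat(az.convert_to_dataset(x))["x"].values))
                ess = float(np.asarray(az.ess(az.convert_to_dataset(x))["x"].values))
            rows.append({"parameter": label, "rhat": rhat, "ess": ess})
    diag = pd.DataFrame(rows, columns=["parameter", "rhat", "ess"])
    bad_rhat = diag[diag["rhat"] > mcmc.rhat_threshold]["parameter"].tolist()
    bad_ess = diag[diag["ess"] < mcmc.ess_threshold]["parameter"].tolist()
    if bad_rhat:
        msg = f"convergence warning: R-hat > {mcmc.rhat_threshold} for {bad_rhat}"
        warns.append(msg)
        logger.warning(msg)
    if bad_ess:
        msg = f"convergence warning: ESS < {mcmc.ess_threshold:g} for {bad_ess}"
        warns.append(msg)
        logger.warning(msg)
    return diag


# ---------------------------------------------------------------------------
# posterior summaries

@dataclass(frozen=True)
class Hpdi:
    lower: float
    upper: float
    mass: float = 0.95


def hpdi(draws, mass: float = 0.95) -> Hpdi:
    """Narrowest interval containing ``mass`` of the draws."""
    if not (0.0 < mass < 1.0):
        raise ValueError("mass must be in (0, 1)")
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = len(x)
    if n < 100:
        raise ValueError(f"need at least 100 draws for an HPDI, got {n}")
    m = int(np.ceil(mass * n))
    widths = x[m - 1 :] - x[: n - m + 1]
    k = int(np.argmin(widths))
    return Hpdi(lower=float(x[k]), upper=float(x[k + m - 1]), mass=mass)


def posterior_summary(result: PosteriorDraws, mass: float = 0.95) -> pd.DataFrame:
    """Mean and HPDI for every reported parameter, with convergence flags."""
    rows = []
    diag = result.diagnostics.set_index("parameter") if len(result.diagnostics) else None
    for name in REPORTED_PARAMS:
        if name not in result.draws:
            continue
        x = result.stacked(name)
        if name in result.config.fixed:
            rows.append(
                {
                    "parameter": name,
                    "mean": float(np.mean(x)),
                    "hpdi_lower": float(np.mean(x)),
                    "hpdi_upper": float(np.mean(x)),
                    "rhat": np.nan,
                    "ess": np.nan,
                    "converged": True,
                }
            )
            continue
        iv = hpdi(x, mass)
        rhat = ess = np.nan
        if diag is not None and name in diag.index:
            rhat = diag.loc[name, "rhat"]
            ess = diag.loc[name, "ess"]
        rows.append(
            {
                "parameter": name,
                "mean": float(np.mean(x)),
                "hpdi_lower": iv.lower,
                "hpdi_upper": iv.upper,
                "rhat": rhat,
                "ess": ess,
                "converged": bool(
                    (not np.isfinite(rhat) or rhat <= result.config.rhat_threshold)
                ),
            }
        )
    return pd.DataFrame(rows)


def indirect_effect(result: PosteriorDraws, mode: str = "product") -> np.ndarray:
    """Posterior of the synchrony -> joint success -> PAS pathway.

    ``product`` (default): the draw-wise product ``lambda_G * gamma_G`` on
    the probit scale.  ``contrast``: the difference in the expected PAS
    category under D=1 vs D=0 that is mediated through G, evaluated at the
    population-level consolidation stage of the PAS learning curve.
    """
    lamG = result.stacked("lambda_G")
    gG = result.stacked("gamma_G")
    if mode == "product":
        return lamG * gG
    if mode != "contrast":
        raise ValueError("mode must be 'product' or 'contrast'")
    mu_c = result.stacked("mu_c")
    kappa = result.stacked("kappa")
    sig_v = result.stacked("sigma_v")
    mu_tauP = result.stacked("mu_tau_P")
    eta0 = sig_v * np.sqrt(2 / np.pi) * (mu_tauP - 1.0)  # plateau of the PAS curve
    cats = np.arange(1, 5)
    out = np.empty(len(lamG))
    for n in range(len(lamG)):
        ey = []
        for dval in (1.0, 0.0):
            pg = ndtr(mu_c[n] + lamG[n] * dval)
            e = 0.0
            for gval, w in ((1.0, pg), (0.0, 1 - pg)):
                probs = ordinal_probit_probs(eta0[n] + gG[n] * gval, kappa[n])
                e += w * float(np.sum(cats * probs))
            ey.append(e)
        out[n] = ey[0] - ey[1]
    return out
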