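"""Bayesian bivariate Gamma cost-effectiveness model.

Costs and transformed effects (1 - QALY) are modelled as Gamma distributed
on the mean scale with arm-specific means, baseline-cost and
baseline-utility covariates, and a conditional-mean link from cost residual
to effect, so the two outcomes are dependent:

    c_i ~ Gamma(s_c, mean m_ci),  m_ci = mu_c[arm] + g1*x1_i + g2*x2_i
    e_i ~ Gamma(s_e, mean m_ei),  m_ei = nu_e[arm] + d1*x1_i + d2*x2_i
                                          + beta*(c_i - m_ci)

with x1, x2 the baseline cost/utility centred at configurable values, so
the arm-level means are evaluated at those centring points.  Vague priors
throughout; sampling is adaptive Metropolis-within-Gibbs with proposal
scales frozen after burn-in.  Incremental cost is intervention - control;
incremental QALY is control - intervention on the 1-QALY scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist

from .trial_data import ValidationError

DEFAULT_WTP_GRID = (0.0, 5000.0, 10000.0, 15000.0, 20000.0, 25000.0, 30000.0, 40000.0, 50000.0)

_PARAM_NAMES = (
    "mu_cost_intervention", "mu_cost_control", "gamma_cost_baseline", "gamma_cost_utility",
    "log_shape_cost",
    "nu_effect_intervention", "nu_effect_control", "delta_effect_baseline", "delta_effect_utility",
    "beta_dependence", "log_shape_effect",
)


@dataclass
class CeaModelConfig:
    burn_in: int = 20000
    kept: int = 20000
    chains: int = 2
    seed: int = 0
    centering_baseline_cost: float = 1850.0
    centering_baseline_utility: float = 0.70
    wtp_grid: Sequence[float] = DEFAULT_WTP_GRID
    prior_coef_sd: float = 1e5
    prior_shape_rate: float = 0.001
    rhat_threshold: float = 1.05
    zero_cost_offset: float = 0.01

    def validate(self) -> None:
        if self.burn_in <= 0 or self.kept <= 0 or self.chains < 1:
            raise ValidationError("burn_in, kept and chains must be positive")
        grid = list(self.wtp_grid)
        if any(w < 0 for w in grid) or grid != sorted(grid):
            raise ValidationError("wtp_grid must be nonnegative and ascending")


@dataclass
class CeaPosterior:
    """Pooled posterior draws (all chains concatenated) plus diagnostics."""

    delta_cost: np.ndarray            # intervention - control, GBP
    delta_qaly: np.ndarray            # QALY gain of intervention
    mu_cost: dict[str, np.ndarray] = field(default_factory=dict)
    mu_qaly: dict[str, np.ndarray] = field(default_factory=dict)
    shape_cost: np.ndarray | None = None
    shape_effect: np.ndarray | None = None
    dependence: np.ndarray | None = None
    coefficients: dict[str, np.ndarray] = field(default_factory=dict)
    rhat: dict[str, float] = field(default_factory=dict)
    ess: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    n_chains: int = 1

    @classmethod
    def from_deltas(cls, delta_cost, delta_qaly) -> "CeaPosterior":
        return cls(delta_cost=np.asarray(delta_cost, float), delta_qaly=np.asarray(delta_qaly, float))

    def __len__(self) -> int:
        return len(self.delta_cost)


@dataclass
class IcerResult:
    value: float
    dominant: bool
    label: str

    def __float__(self) -> float:
        return self.value


@dataclass
class CeacCurve:
    points: list[tuple[float, float]]

    def probability_at(self, wtp: float) -> float:
        for w, p in self.points:
            if w == wtp:
                return p
        raise KeyError(wtp)


@dataclass
class NetBenefitSummary:
    wtp: float
    mean: float
    sd: float
    ci_low: float
    ci_high: float


@dataclass
class CePlane:
    center: tuple[float, float]          # (delta_qaly, delta_cost)
    covariance: np.ndarray               # 2x2 over (delta_qaly, delta_cost)
    level: float
    quadrant_proportions: dict[str, float]

    def ellipse_points(self, n: int = 200) -> np.ndarray:
        """(n, 2) boundary points of the level-set ellipse."""
        r = np.sqrt(chi2_dist.ppf(self.level, df=2))
        theta = np.linspace(0, 2 * np.pi, n)
        circle = np.stack([np.cos(theta), np.sin(theta)])
        L = np.linalg.cholesky(self.covariance + 1e-300 * np.eye(2))
        pts = (np.asarray(self.center)[:, None] + r * (L @ circle)).T
        return pts


@dataclass
class CeaSummary:
    mean_cost_saving: float
    cost_saving_ci: tuple[float, float]
    mean_delta_qaly: float
    delta_qaly_ci: tuple[float, float]
    icer: IcerResult
    p_ce_at: dict[float, float]
    plane: CePlane
    converged: bool = True


def _gamma_loglik(x: np.ndarray, logx_sum: float, shape: float, mean: np.ndarray) -> float:
    """Sum of Gamma log-densities with common shape and per-point mean."""
    if shape <= 0 or np.any(mean <= 0):
        return -np.inf
    n = len(x)
    return (
        n * (shape * np.log(shape) - gammaln(shape))
        - shape * np.sum(np.log(mean))
        + (shape - 1) * logx_sum
        - shape * np.sum(x / mean)
    )


class _CeaTarget:
    """Log posterior with cached per-block likelihood pieces."""

    def __init__(self, cost, effect, is_intervention, x1, x2, config: CeaModelConfig):
        self.c = cost
        self.e = effect
        self.ki = is_intervention
        self.x1 = x1
        self.x2 = x2
        self.sum_log_c = float(np.sum(np.log(cost)))
        self.sum_log_e = float(np.sum(np.log(effect)))
        self.cfg = config

    def cost_mean(self, th) -> np.ndarray:
        mu = np.where(self.ki, th[0], th[1])
        return mu + th[2] * self.x1 + th[3] * self.x2

    def effect_mean(self, th, m_c) -> np.ndarray:
        nu = np.where(self.ki, th[5], th[6])
        return nu + th[7] * self.x1 + th[8] * self.x2 + th[9] * (self.c - m_c)

    def log_prior(self, th) -> float:
        lp = -0.5 * np.sum(np.square(th[[0, 1, 2, 3, 5, 6, 7, 8, 9]] / self.cfg.prior_coef_sd))
        # Exponential(rate) prior on each shape, with log-scale Jacobian
        for j in (4, 10):
            s = np.exp(th[j])
            lp += th[j] - self.cfg.prior_shape_rate * s
        return lp

    def log_post(self, th) -> tuple[float, np.ndarray]:
        m_c = self.cost_mean(th)
        if np.any(m_c <= 0):
            return -np.inf, m_c
        ll = _gamma_loglik(self.c, self.sum_log_c, np.exp(th[4]), m_c)
        if not np.isfinite(ll):
            return -np.inf, m_c
        m_e = self.effect_mean(th, m_c)
        if np.any(m_e <= 0):
            return -np.inf, m_c
        ll += _gamma_loglik(self.e, self.sum_log_e, np.exp(th[10]), m_e)
        lp = ll + self.log_prior(th)
        return (lp if np.isfinite(lp) else -np.inf), m_c


def _init_theta(target: _CeaTarget, rng: np.random.Generator) -> np.ndarray:
    c, e, ki = target.c, target.e, target.ki
    th = np.zeros(11)
    th[0] = np.mean(c[ki])
    th[1] = np.mean(c[~ki])
    th[5] = np.mean(e[ki])
    th[6] = np.mean(e[~ki])
    # method-of-moments shapes
    th[4] = np.log(max(np.mean(c) ** 2 / max(np.var(c), 1e-12), 0.1))
    th[10] = np.log(max(np.mean(e) ** 2 / max(np.var(e), 1e-12), 0.1))
    jitter = rng.normal(0, 0.02, 11)
    th[[0, 1]] *= 1 + jitter[[0, 1]]
    th[[5, 6]] *= 1 + jitter[[5, 6]]
    th[[4, 10]] += jitter[[4, 10]]
    return th


def _run_chain(target: _CeaTarget, config: CeaModelConfig, rng: np.random.Generator) -> np.ndarray:
    th = _init_theta(target, rng)
    scales = np.empty(11)
    scales[[0, 1]] = 0.05 * np.abs(th[[0, 1]]) + 1e-3
    scales[[5, 6]] = 0.05 * np.abs(th[[5, 6]]) + 1e-4
    scales[[2, 7]] = 0.02   # per-GBP covariate slopes
    scales[[3, 8]] = 0.1 * (np.abs(th[[5, 6]]).mean() + 1e-3) / 0.25
    scales[9] = 1e-4
    scales[[4, 10]] = 0.1
    lp, _ = target.log_post(th)
    if not np.isfinite(lp):
        th = _init_theta(target, np.random.default_rng(0))
        lp, _ = target.log_post(th)

    def _pieces(theta):
        m_c = target.cost_mean(theta)
        ll_c = _gamma_loglik(target.c, target.sum_log_c, np.exp(theta[4]), m_c)
        ll_e = (
            _gamma_loglik(target.e, target.sum_log_e, np.exp(theta[10]), target.effect_mean(theta, m_c))
            if np.isfinite(ll_c)
            else -np.inf
        )
        return m_c, ll_c, ll_e

    m_c, ll_c, ll_e = _pieces(th)
    lpri = target.log_prior(th)
    n_iter = config.burn_in + config.kept
    draws = np.empty((config.kept, 11))
    accept = np.zeros(11)
    batch = 50
    for it in range(n_iter):
        for j in range(11):
            prop = th.copy()
            prop[j] += scales[j] * rng.standard_normal()
            # only the affected likelihood block is recomputed:
            # j < 4 changes the cost mean (and hence the effect link);
            # j == 4 the cost shape only; j >= 5 the effect side only.
            if j < 4:
                m_c_p, ll_c_p, ll_e_p = _pieces(prop)
            elif j == 4:
                m_c_p = m_c
                ll_c_p = _gamma_loglik(target.c, target.sum_log_c, np.exp(prop[4]), m_c)
                ll_e_p = ll_e
            else:
                m_c_p, ll_c_p = m_c, ll_c
                ll_e_p = _gamma_loglik(
                    target.e, target.sum_log_e, np.exp(prop[10]), target.effect_mean(prop, m_c)
                )
            if not np.isfinite(ll_c_p + ll_e_p):
                continue
            lpri_p = target.log_prior(prop)
            if np.log(rng.random()) < (ll_c_p + ll_e_p + lpri_p) - (ll_c + ll_e + lpri):
                th, m_c, ll_c, ll_e, lpri = prop, m_c_p, ll_c_p, ll_e_p, lpri_p
                accept[j] += 1
        if it < config.burn_in and (it + 1) % batch == 0:
            rate = accept / batch
            scales *= np.exp((rate - 0.44) / np.sqrt((it + 1) / batch))
            accept[:] = 0
        if it >= config.burn_in:
            draws[it - config.burn_in] = th
    return draws


def _split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor; chains shape (m, n)."""
    m, n = chains.shape
    half = n // 2
    if half < 2:
        return np.nan
    segs = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    means = segs.mean(axis=1)
    vars_ = segs.var(axis=1, ddof=1)
    W = vars_.mean()
    B = half * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_hat = (half - 1) / half * W + B / half
    return float(np.sqrt(var_hat / W))


def _ess(chains: np.ndarray) -> float:
    """Effective sample size via initial positive sequence of autocorrelations."""
    m, n = chains.shape
    x = chains - chains.mean(axis=1, keepdims=True)
    total_var = np.mean(chains.var(axis=1, ddof=1))
    if total_var <= 0:
        return float(m * n)
    acf = np.zeros(n)
    for c in x:
        f = np.fft.rfft(np.concatenate([c, np.zeros(n)]))
        ac = np.fft.irfft(f * np.conj(f))[:n] / n
        acf += ac / m
    acf /= acf[0]
    tau = 1.0
    for k in range(1, n - 1, 2):
        pair = acf[k] + acf[k + 1]
        if pair < 0:
            break
        tau += 2 * pair
    return float(m * n / tau)


def fit_cea(
    costs: Sequence[float],
    qalys: Sequence[float],
    arm: Sequence[str],
    baseline_cost: Sequence[float],
    baseline_utility: Sequence[float],
    config: CeaModelConfig | None = None,
) -> CeaPosterior:
    """Fit the bivariate Gamma model by MCMC; deterministic given seed."""
    config = config or CeaModelConfig()
    config.validate()
    costs = np.asarray(costs, float)
    qalys = np.asarray(qalys, float)
    arm = np.asarray(arm)
    x1 = np.asarray(baseline_cost, float) - config.centering_baseline_cost
    x2 = np.asarray(baseline_utility, float) - config.centering_baseline_utility
    if not (len(costs) == len(qalys) == len(arm) == len(x1) == len(x2)):
        raise ValidationError("all inputs must have equal length")
    is_intervention = arm == "intervention"
    if not is_intervention.any() or is_intervention.all():
        raise ValidationError("both arms must be present")
    if np.any(~np.isfinite(costs)) or np.any(costs < 0):
        raise ValidationError("costs must be finite and nonnegative")
    effect = 1.0 - qalys
    if np.any(effect <= 0):
        raise ValidationError(
            "all (1 - QALY) values must be positive; check the horizon (QALY >= 1 found)"
        )
    costs = np.where(costs == 0, config.zero_cost_offset, costs)

    target = _CeaTarget(costs, effect, is_intervention, x1, x2, config)
    seed_seq = np.random.SeedSequence(config.seed)
    chain_draws = [
        _run_chain(target, config, np.random.default_rng(s))
        for s in seed_seq.spawn(config.chains)
    ]
    stacked = np.stack(chain_draws)           # (chains, kept, 11)
    pooled = stacked.reshape(-1, 11)

    rhat, ess = {}, {}
    for j, name in enumerate(_PARAM_NAMES):
        rhat[name] = _split_rhat(stacked[:, :, j]) if config.chains > 1 else np.nan
        ess[name] = _ess(stacked[:, :, j])
    converged = config.chains < 2 or all(
        (not np.isfinite(v)) or v < config.rhat_threshold for v in rhat.values()
    )
    if not converged:
        bad = {k: round(v, 3) for k, v in rhat.items() if np.isfinite(v) and v >= config.rhat_threshold}
        warnings.warn(f"MCMC convergence diagnostic above threshold: {bad}", stacklevel=2)

    mu_ci, mu_cc = pooled[:, 0], pooled[:, 1]
    nu_ei, nu_ec = pooled[:, 5], pooled[:, 6]
    return CeaPosterior(
        delta_cost=mu_ci - mu_cc,
        delta_qaly=nu_ec - nu_ei,            # 1-QALY scale flips the sign
        mu_cost={"intervention": mu_ci, "control": mu_cc},
        mu_qaly={"intervention": 1.0 - nu_ei, "control": 1.0 - nu_ec},
        shape_cost=np.exp(pooled[:, 4]),
        shape_effect=np.exp(pooled[:, 10]),
        dependence=pooled[:, 9],
        coefficients={
            "gamma_cost_baseline": pooled[:, 2],
            "gamma_cost_utility": pooled[:, 3],
            "delta_effect_baseline": pooled[:, 7],
            "delta_effect_utility": pooled[:, 8],
        },
        rhat=rhat,
        ess=ess,
        converged=converged,
        n_chains=config.chains,
    )


def icer(delta_cost: float, delta_qaly: float) -> IcerResult:
    """|delta_cost| / delta_qaly with a dominance label.

    Follows the reporting convention of quoting a positive cost-per-QALY
    figure alongside a mean saving when the intervention is dominant
    (saves money, gains QALYs).
    """
    if delta_qaly == 0:
        raise ZeroDivisionError("ICER undefined: delta_qaly is 0")
    value = abs(delta_cost) / delta_qaly
    dominant = delta_cost < 0 and delta_qaly > 0
    if dominant:
        label = "dominant"
    elif delta_cost > 0 and delta_qaly < 0:
        label = "dominated"
    else:
        label = "tradeoff"
    return IcerResult(value=float(value), dominant=dominant, label=label)


def ceac(posterior: CeaPosterior, wtp_grid: Sequence[float] = DEFAULT_WTP_GRID) -> CeacCurve:
    """P(cost-effective) = P(wtp * delta_qaly - delta_cost > 0) per threshold."""
    if len(posterior) == 0:
        raise ValidationError("empty posterior")
    points = [
        (float(w), float(np.mean(w * posterior.delta_qaly - posterior.delta_cost > 0)))
        for w in wtp_grid
    ]
    return CeacCurve(points=points)


def net_benefit(posterior: CeaPosterior, wtp: float) -> NetBenefitSummary:
    if len(posterior) == 0:
        raise ValidationError("empty posterior")
    nb = wtp * posterior.delta_qaly - posterior.delta_cost
    lo, hi = np.percentile(nb, [2.5, 97.5])
    return NetBenefitSummary(
        wtp=float(wtp), mean=float(nb.mean()), sd=float(nb.std(ddof=1)) if len(nb) > 1 else 0.0,
        ci_low=float(lo), ci_high=float(hi),
    )


def ce_plane(posterior: CeaPosterior, level: float = 0.95) -> CePlane:
    """Draw cloud summary: mean, covariance ellipse, quadrant proportions."""
    if len(posterior) < 100:
        raise ValidationError("need at least 100 draws for a CE plane summary")
    dq, dc = posterior.delta_qaly, posterior.delta_cost
    pts = np.stack([dq, dc])
    cov = np.cov(pts) if len(dq) > 1 else np.zeros((2, 2))
    quadrants = {
        "NE_more_costly_more_effective": float(np.mean((dq > 0) & (dc > 0))),
        "SE_cost_saving_more_effective": float(np.mean((dq > 0) & (dc <= 0))),
        "SW_cost_saving_less_effective": float(np.mean((dq <= 0) & (dc <= 0))),
        "NW_more_costly_less_effective": float(np.mean((dq <= 0) & (dc > 0))),
    }
    return CePlane(
        center=(float(dq.mean()), float(dc.mean())),
        covariance=np.atleast_2d(cov),
        level=level,
        quadrant_proportions=quadrants,
    )


def summarize(
    posterior: CeaPosterior,
    wtp_grid: Sequence[float] = (20000.0, 30000.0),
) -> CeaSummary:
    """Headline table: mean saving, mean QALY gain, ICER, P(CE), plane."""
    saving = -posterior.delta_cost
    s_lo, s_hi = np.percentile(saving, [2.5, 97.5])
    q_lo, q_hi = np.percentile(posterior.delta_qaly, [2.5, 97.5])
    curve = ceac(posterior, wtp_grid)
    return CeaSummary(
        mean_cost_saving=float(saving.mean()),
        cost_saving_ci=(float(s_lo), float(s_hi)),
        mean_delta_qaly=float(posterior.delta_qaly.mean()),
        delta_qaly_ci=(float(q_lo), float(q_hi)),
        icer=icer(float(posterior.delta_cost.mean()), float(posterior.delta_qaly.mean())),
        p_ce_at={w: p for w, p in curve.points},
        plane=ce_plane(posterior),
        converged=posterior.converged,
    )
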