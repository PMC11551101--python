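"""Intention-to-treat and per-protocol HRQoL outcome analysis.

Implements single imputation by carrying the last observed value forward,
baseline- and age-adjusted ANCOVA via ordinary least squares, proper
multiple imputation from linear-regression predictive draws, and pooling of
per-imputation estimates (pooled point estimate, within/between variance
decomposition, small-sample degrees of freedom).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .trial_data import ParticipantRecord, TrialDataset, ValidationError

_VISIT_CHAIN = {
    "mcs": ("week0", "week12", "week24"),
    "pcs": ("week0", "week12", "week24"),
    "eq5d": ("month0", "month3", "month6"),
}

POPULATIONS = ("ITT_LOCF", "ITT_MI", "per_protocol")


class EstimationError(RuntimeError):
    pass


@dataclass
class AncovaEstimate:
    effect: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    population: str
    covariates: list[str] = field(default_factory=lambda: ["baseline", "age"])

    @property
    def df_residual(self) -> int:
        # intercept + arm + covariates
        return self.n_used - (2 + len(self.covariates))


@dataclass
class PooledEstimate:
    effect: float
    within_var: float
    between_var: float
    total_var: float
    m: int
    ci_low: float
    ci_high: float
    p_value: float

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))


def locf_impute(dataset: TrialDataset, outcome: str) -> TrialDataset:
    """Carry the most recent earlier observed value into missing follow-ups.

    Records with a missing baseline cannot be carried forward and are
    excluded with a warning.  Imputed cells are flagged in the record's
    provenance set so later stages can distinguish them from observations.
    """
    chain = _VISIT_CHAIN[outcome]
    out = dataset.copy()
    kept: list[ParticipantRecord] = []
    for rec in out.records:
        values = rec.outcome_values(outcome)
        if values[chain[0]] is None:
            warnings.warn(
                f"LOCF: excluding {rec.participant_id} (missing baseline {outcome})",
                stacklevel=2,
            )
            continue
        last = values[chain[0]]
        for visit in chain[1:]:
            if values[visit] is None:
                values[visit] = last
                rec.imputed.add((outcome, visit))
            else:
                last = values[visit]
        kept.append(rec)
    out.records = kept
    return out


def _design_matrix(dataset: TrialDataset, outcome: str, followup_visit: str):
    chain = _VISIT_CHAIN[outcome]
    rows = []
    for rec in dataset.records:
        values = rec.outcome_values(outcome)
        y = values[followup_visit]
        b = values[chain[0]]
        if y is None or b is None:
            continue
        rows.append((y, 1.0 if rec.arm == "intervention" else 0.0, b, rec.age))
    if not rows:
        raise EstimationError("no usable records for ANCOVA")
    arr = np.asarray(rows, dtype=float)
    y = arr[:, 0]
    X = sm.add_constant(arr[:, 1:], has_constant="add")
    return y, X


def ancova_fit(
    dataset: TrialDataset,
    outcome: str = "mcs",
    followup_visit: str = "week24",
    population: str = "ITT_LOCF",
) -> AncovaEstimate:
    """OLS of follow-up value on arm + baseline + age.

    The reported effect is the arm coefficient (intervention - control),
    identical to the adjusted between-group difference in change because
    baseline enters as a covariate.  Diagnostics (residual normality,
    covariate balance) are emitted as warnings, never hard failures.
    """
    y, X = _design_matrix(dataset, outcome, followup_visit)
    n = len(y)
    n_arm = int(X[:, 1].sum())
    if n_arm < 3 or n - n_arm < 3:
        raise EstimationError(f"need >= 3 records per arm, got {n_arm}/{n - n_arm}")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise EstimationError("singular design matrix")
    fit = sm.OLS(y, X).fit()
    effect = float(fit.params[1])
    se = float(fit.bse[1])
    ci = fit.conf_int(alpha=0.05)
    if n > 7:
        _, jb_p, *_ = sm.stats.jarque_bera(fit.resid)
        if jb_p < 0.01:
            warnings.warn(f"residual normality suspect (Jarque-Bera p={jb_p:.3g})", stacklevel=2)
        bal = st.ttest_ind(X[X[:, 1] == 1, 2], X[X[:, 1] == 0, 2])
        if bal.pvalue < 0.01:
            warnings.warn("baseline covariate imbalanced across arms", stacklevel=2)
    return AncovaEstimate(
        effect=effect,
        se=se,
        ci_low=float(ci[1][0]),
        ci_high=float(ci[1][1]),
        p_value=float(fit.pvalues[1]),
        n_used=n,
        population=population,
    )


def _proper_draw(rng, y, X, X_mis):
    """One proper-imputation draw: sigma^2 and beta from their posterior, then noise."""
    n, k = X.shape
    beta_hat, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_hat
    df = n - k
    if df <= 0:
        raise EstimationError("imputation model unidentifiable (too few complete cases)")
    sse = float(resid @ resid)
    sigma2 = sse / rng.chisquare(df)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = rng.multivariate_normal(beta_hat, sigma2 * xtx_inv, method="cholesky")
    return X_mis @ beta + rng.normal(0.0, np.sqrt(sigma2), len(X_mis))


def mi_impute(
    dataset: TrialDataset,
    outcome: str,
    m: int = 5,
    seed: int | None = None,
    stochastic: bool = True,
) -> list[TrialDataset]:
    """Multiple imputation of missing follow-ups by linear regression.

    Visit-by-visit: the intermediate visit is imputed from (arm, age,
    baseline); the final visit from (arm, age, baseline, intermediate),
    using the imputed intermediate where needed.  With ``stochastic`` the
    imputations are proper (posterior coefficient draw + residual noise);
    otherwise deterministic predictions are used (variance understated --
    sensitivity option only).
    """
    if m < 2:
        raise ValidationError("m must be >= 2")
    chain = _VISIT_CHAIN[outcome]
    base, mid, final = chain
    for arm in ("intervention", "control"):
        arm_recs = [r for r in dataset.records if r.arm == arm]
        if arm_recs and all(r.outcome_values(outcome)[final] is None for r in arm_recs):
            raise EstimationError(f"all {final} values missing in {arm} arm: model unidentifiable")
    rng = np.random.default_rng(seed)
    imputations = []
    for _ in range(m):
        imp = dataset.copy()
        recs = [r for r in imp.records if r.outcome_values(outcome)[base] is not None]

        def predictors(rec: ParticipantRecord, with_mid: bool) -> list[float]:
            v = rec.outcome_values(outcome)
            row = [1.0, 1.0 if rec.arm == "intervention" else 0.0, rec.age, v[base]]
            if with_mid:
                row.append(v[mid])
            return row

        for visit, with_mid in ((mid, False), (final, True)):
            obs = [r for r in recs if r.outcome_values(outcome)[visit] is not None]
            mis = [r for r in recs if r.outcome_values(outcome)[visit] is None]
            if not mis:
                continue
            X = np.array([predictors(r, with_mid) for r in obs])
            y = np.array([r.outcome_values(outcome)[visit] for r in obs], dtype=float)
            X_mis = np.array([predictors(r, with_mid) for r in mis])
            if stochastic:
                y_new = _proper_draw(rng, y, X, X_mis)
            else:
                beta_hat, *_ = np.linalg.lstsq(X, y, rcond=None)
                y_new = X_mis @ beta_hat
            for rec, val in zip(mis, y_new):
                rec.outcome_values(outcome)[visit] = float(val)
                rec.imputed.add((outcome, visit))
        imputations.append(imp)
    return imputations


def rubin_pool(estimates: list[AncovaEstimate]) -> PooledEstimate:
    """Combine per-imputation estimates.

    Pooled effect is the mean; total variance is within + (1 + 1/m) x
    between; the confidence interval uses the small-sample degrees of
    freedom that interpolate between the complete-data df and the classic
    (m - 1) / lambda^2 value.
    """
    if not estimates:
        raise ValidationError("rubin_pool needs at least one estimate")
    m = len(estimates)
    effects = np.array([e.effect for e in estimates])
    effect = float(effects.mean())
    within = float(np.mean([e.se**2 for e in estimates]))
    between = float(effects.var(ddof=1)) if m > 1 else 0.0
    total = within + (1 + 1 / m) * between
    se = np.sqrt(total)
    df_com = min(e.df_residual for e in estimates)
    if between == 0 or m == 1:
        df = float(df_com)
    else:
        lam = (1 + 1 / m) * between / total
        df_old = (m - 1) / lam**2
        df_obs = (df_com + 1) / (df_com + 3) * df_com * (1 - lam)
        df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
    tcrit = st.t.ppf(0.975, df)
    p = 2 * st.t.sf(abs(effect) / se, df) if se > 0 else (0.0 if effect != 0 else 1.0)
    return PooledEstimate(
        effect=effect,
        within_var=within,
        between_var=between,
        total_var=total,
        m=m,
        ci_low=effect - tcrit * se,
        ci_high=effect + tcrit * se,
        p_value=float(p),
    )


def per_protocol_filter(dataset: TrialDataset, outcome: str) -> TrialDataset:
    """Keep only records with genuinely observed baseline AND final-visit values."""
    chain = _VISIT_CHAIN[outcome]
    out = dataset.copy()
    out.records = [
        r for r in out.records
        if r.is_observed(outcome, chain[0]) and r.is_observed(outcome, chain[-1])
    ]
    return out


def analyze(
    dataset: TrialDataset,
    outcome: str,
    population: str = "ITT_LOCF",
    m: int = 5,
    seed: int | None = None,
) -> AncovaEstimate | PooledEstimate:
    """One-call analysis for a population label (used by the CLI)."""
    final = _VISIT_CHAIN[outcome][-1]
    if population == "ITT_LOCF":
        return ancova_fit(locf_impute(dataset, outcome), outcome, final, population)
    if population == "per_protocol":
        return ancova_fit(per_protocol_filter(dataset, outcome), outcome, final, "per_protocol")
    if population == "ITT_MI":
        imps = mi_impute(dataset, outcome, m=m, seed=seed)
        ests = [ancova_fit(d, outcome, final, "ITT_MI") for d in imps]
        return rubin_pool(ests)
    raise ValidationError(f"unknown population {population!r}")
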