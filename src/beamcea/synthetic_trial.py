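"""Synthetic two-arm trial generator.

Produces datasets with a configurable statistical structure: bivariate
Gaussian HRQoL scores with a fixed baseline--follow-up correlation and an
additive arm effect at the final visit, truncated-Gaussian utilities,
Gamma-distributed (optionally lognormal) costs, and differential dropout
applied after generation so baseline data are never removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .trial_data import (
    ARMS,
    COST_WINDOWS,
    CostLedger,
    ParticipantRecord,
    TrialDataset,
    TRIAL_WINDOWS,
    ValidationError,
)

#: share of the non-intervention cost mean attributed to each care component
COMPONENT_SHARES = {
    "primary_care": 0.15,
    "medications": 0.35,
    "hospital": 0.40,
    "social_care": 0.10,
}

#: window lengths in weeks, used to scale per-window cost means
WINDOW_WEEKS = {"pretrial_12wk": 12.0, "trial_0_3mo": 13.0, "trial_3_6mo": 13.0}


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic trial generator.

    Defaults are anchored to the published design: 173/167 allocation,
    MCS ~ Normal(45, 10.5) with a 0.7 baseline--follow-up correlation and
    a +5.9 AU arm effect at week 24, utilities around 0.65--0.73
    (SD 0.25), right-skewed costs with a pre-trial mean of ~1850 GBP, and
    dropout of ~39%/15% concentrated in the first week.
    """

    n_intervention: int = 173
    n_control: int = 167
    mcs_baseline_mean: float = 45.0
    mcs_baseline_sd: float = 10.5
    baseline_followup_correlation: float = 0.7
    true_effect_mcs: float = 5.9
    utility_baseline_mean_by_arm: Mapping[str, float] = field(
        default_factory=lambda: {"intervention": 0.65, "control": 0.73}
    )
    utility_sd: float = 0.25
    true_effect_utility: float = 0.10
    cost_mean_pretrial: float = 1850.0
    cost_gamma_shape: float = 2.0
    cost_arm_multiplier: float = 1.025
    dropout_rate_by_arm: Mapping[str, float] = field(
        default_factory=lambda: {"intervention": 0.393, "control": 0.150}
    )
    dropout_first_week_fraction: float = 0.75
    intervention_cost_per_year: float = 15.0
    seed: int = 2021
    cost_family: str = "gamma"  # or "lognormal" for misspecification runs
    dropout_mechanism: str = "mcar"  # or "mar": dropout odds depend on baseline MCS
    mar_log_odds_per_sd: float = 0.5

    def validate(self) -> None:
        if self.n_intervention < 2 or self.n_control < 2:
            raise ValidationError("each arm needs n >= 2")
        if not -1 < self.baseline_followup_correlation < 1:
            raise ValidationError("correlation must be in (-1, 1)")
        if self.mcs_baseline_sd <= 0 or self.utility_sd <= 0:
            raise ValidationError("SDs must be > 0")
        if self.cost_gamma_shape <= 0 or self.cost_arm_multiplier <= 0:
            raise ValidationError("cost shape and arm multiplier must be > 0")
        for arm in ARMS:
            rate = self.dropout_rate_by_arm.get(arm)
            if rate is None or not 0 <= rate <= 1:
                raise ValidationError(f"dropout rate for {arm} must be in [0, 1]")
        if not 0 <= self.dropout_first_week_fraction <= 1:
            raise ValidationError("dropout_first_week_fraction must be in [0, 1]")
        if self.cost_mean_pretrial <= 0:
            raise ValidationError("cost_mean_pretrial must be > 0")
        if self.cost_family not in ("gamma", "lognormal"):
            raise ValidationError(f"unknown cost_family {self.cost_family!r}")
        if self.dropout_mechanism not in ("mcar", "mar"):
            raise ValidationError(f"unknown dropout_mechanism {self.dropout_mechanism!r}")


def _longitudinal_scores(
    rng: np.random.Generator,
    n: int,
    mean: float,
    sd: float,
    rho: float,
    effect_w24: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(w0, w12, w24): w24 marginally Normal(mean+effect, sd), corr(w0, w24)=rho."""
    z0 = rng.standard_normal(n)
    z1 = rng.standard_normal(n)
    w0 = mean + sd * z0
    w24 = mean + effect_w24 + sd * (rho * z0 + math.sqrt(1 - rho * rho) * z1)
    mid_noise = rng.normal(0.0, 0.5 * sd * math.sqrt(max(1 - rho, 0.0)), n)
    w12 = 0.5 * (w0 + w24) + mid_noise
    return w0, w12, w24


def _cost_draw(rng: np.random.Generator, mean: float, shape: float, family: str, n: int) -> np.ndarray:
    if family == "gamma":
        return rng.gamma(shape, mean / shape, n)
    # lognormal with matching mean and the same coefficient of variation as
    # a Gamma(shape) draw: cv^2 = 1/shape
    sigma2 = math.log1p(1.0 / shape)
    mu = math.log(mean) - sigma2 / 2
    return rng.lognormal(mu, math.sqrt(sigma2), n)


def generate_trial(config: SimulationConfig) -> TrialDataset:
    """Generate a complete (pre-dropout) trial dataset; deterministic given seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[ParticipantRecord] = []
    horizon = 0.5

    for arm, n in (("intervention", config.n_intervention), ("control", config.n_control)):
        effect = config.true_effect_mcs if arm == "intervention" else 0.0
        mcs0, mcs12, mcs24 = _longitudinal_scores(
            rng, n, config.mcs_baseline_mean, config.mcs_baseline_sd,
            config.baseline_followup_correlation, effect,
        )
        pcs0, pcs12, pcs24 = _longitudinal_scores(
            rng, n, config.mcs_baseline_mean - 5.0, config.mcs_baseline_sd,
            config.baseline_followup_correlation, 0.0,
        )
        u_mean = config.utility_baseline_mean_by_arm[arm]
        u_effect = config.true_effect_utility if arm == "intervention" else 0.0
        z0 = rng.standard_normal(n)
        rho = config.baseline_followup_correlation
        u0 = u_mean + config.utility_sd * z0
        # arm effect sustained from month 3 onward
        u3 = u_mean + u_effect + config.utility_sd * (
            rho * z0 + math.sqrt(1 - rho * rho) * rng.standard_normal(n)
        )
        u6 = u_mean + u_effect + config.utility_sd * (
            rho * z0 + math.sqrt(1 - rho * rho) * rng.standard_normal(n)
        )
        u0, u3, u6 = (np.minimum(u, 1.0) for u in (u0, u3, u6))

        ages = np.clip(rng.normal(54.0, 13.5, n), 19.0, 95.0)
        sexes = rng.choice(["male", "female"], n)
        sessions = rng.integers(0, 25, n) if arm == "intervention" else np.zeros(n, dtype=int)
        edu_sessions = rng.integers(0, 13, n) if arm == "intervention" else np.zeros(n, dtype=int)
        minutes = sessions * rng.uniform(25.0, 45.0, n)

        cost_mult = 1.0 if arm == "intervention" else config.cost_arm_multiplier
        costs_by_window: dict[str, dict[str, np.ndarray]] = {}
        for w in COST_WINDOWS:
            scale = WINDOW_WEEKS[w] / WINDOW_WEEKS["pretrial_12wk"]
            arm_scale = 1.0 if w == "pretrial_12wk" else cost_mult
            costs_by_window[w] = {
                c: _cost_draw(
                    rng,
                    config.cost_mean_pretrial * share * scale * arm_scale,
                    config.cost_gamma_shape,
                    config.cost_family,
                    n,
                )
                for c, share in COMPONENT_SHARES.items()
            }

        for i in range(n):
            ledger = CostLedger.empty()
            for w in COST_WINDOWS:
                for c in COMPONENT_SHARES:
                    ledger.set(w, c, float(costs_by_window[w][c][i]))
                if arm == "intervention" and w in TRIAL_WINDOWS:
                    # full annual price attributed to the horizon, split evenly
                    ledger.set(w, "intervention", config.intervention_cost_per_year / len(TRIAL_WINDOWS))
            records.append(
                ParticipantRecord(
                    participant_id=f"{arm[:2].upper()}{i + 1:04d}",
                    arm=arm,
                    age=float(ages[i]),
                    sex=str(sexes[i]),
                    mcs={"week0": float(mcs0[i]), "week12": float(mcs12[i]), "week24": float(mcs24[i])},
                    pcs={"week0": float(pcs0[i]), "week12": float(pcs12[i]), "week24": float(pcs24[i])},
                    eq5d={"month0": float(u0[i]), "month3": float(u3[i]), "month6": float(u6[i])},
                    costs=ledger,
                    completed_week24=True,
                    sessions_structured=int(sessions[i]),
                    sessions_education=int(edu_sessions[i]),
                    minutes_structured=float(minutes[i]),
                )
            )

    ds = TrialDataset(records=records, horizon_years=horizon, allocation_seed=config.seed)
    ds.validate()
    return ds


def apply_dropout(dataset: TrialDataset, config: SimulationConfig) -> TrialDataset:
    """Inject the configured per-arm dropout into a complete dataset.

    A deterministically rounded fraction of each arm drops out; of those, the
    configured first-week fraction loses all post-baseline data, the rest lose
    only the final visit (week 24 / month 6 and the second cost window).
    Baseline fields are never touched.
    """
    config.validate()
    for r in dataset.records:
        for outcome in ("mcs", "pcs"):
            if any(r.outcome_values(outcome)[v] is None for v in ("week12", "week24")):
                raise ValidationError("apply_dropout expects a complete dataset")
    out = dataset.copy()
    rng = np.random.default_rng(None if config.seed is None else config.seed + 1)
    for arm in ARMS:
        arm_records = [r for r in out.records if r.arm == arm]
        n = len(arm_records)
        n_drop = _round_half_up(config.dropout_rate_by_arm[arm] * n)
        if config.dropout_mechanism == "mar":
            mcs0 = np.array([r.mcs["week0"] for r in arm_records])
            z = (mcs0 - np.mean(mcs0)) / (np.std(mcs0) or 1.0)
            w = np.exp(-config.mar_log_odds_per_sd * z)  # lower baseline -> higher dropout odds
            p = w / w.sum()
        else:
            p = None
        drop_idx = rng.choice(n, size=n_drop, replace=False, p=p)
        n_first_week = _round_half_up(config.dropout_first_week_fraction * n_drop)
        for j, idx in enumerate(drop_idx):
            rec = arm_records[idx]
            early = j < n_first_week
            visits_scores = ("week12", "week24") if early else ("week24",)
            visits_util = ("month3", "month6") if early else ("month6",)
            windows = TRIAL_WINDOWS if early else ("trial_3_6mo",)
            for v in visits_scores:
                rec.mcs[v] = None
                rec.pcs[v] = None
            for v in visits_util:
                rec.eq5d[v] = None
            for w_ in windows:
                for c in COMPONENT_SHARES:
                    rec.costs.set(w_, c, None)
            rec.completed_week24 = False
    return out
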