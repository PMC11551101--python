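"""QALY and cost construction for the within-trial economic analysis.

QALYs are the trapezoid area under each participant's utility curve over the
analysis horizon.  Costs are aggregated per window from the ledger with
missing resource items carried forward from the most recent earlier window
(scaled by window length), a parameter-driven intervention cost added to
intervention-arm within-trial totals, and an optional user-supplied
inflation index applied per component.  All money arithmetic is done in
integer pence so component sums are exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .trial_data import (
    COST_COMPONENTS,
    COST_WINDOWS,
    CostLedger,
    TRIAL_WINDOWS,
    TrialDataset,
    UTILITY_VISITS,
    ValidationError,
)

#: default window lengths in years (12 weeks pre-trial, 13-week trial windows)
DEFAULT_WINDOW_YEARS: dict[str, float] = {
    "pretrial_12wk": 12.0 / 52.0,
    "trial_0_3mo": 13.0 / 52.0,
    "trial_3_6mo": 13.0 / 52.0,
}

#: utility assessment times in years for the three-visit schedule
UTILITY_TIMES_YEARS: dict[str, float] = {"month0": 0.0, "month3": 0.25, "month6": 0.5}

CARE_COMPONENTS = tuple(c for c in COST_COMPONENTS if c != "intervention")


@dataclass
class QalyResult:
    participant_id: str
    qaly: float
    utilities_used: list[tuple[float, float]]
    any_imputed: bool = False


@dataclass
class CostSummary:
    participant_id: str
    baseline_cost: float
    trial_cost: float
    components: dict[str, float]
    any_imputed: bool = False


@dataclass
class UtilityMapping:
    """5L -> 3L utility conversion: explicit table or affine map u' = a*u + b."""

    table: Mapping[float, float] | None = None
    affine: tuple[float, float] | None = None

    def apply(self, u: float) -> float:
        if self.affine is not None:
            a, b = self.affine
            out = a * u + b
        elif self.table is not None:
            if u not in self.table:
                raise KeyError(u)
            out = self.table[u]
        else:
            out = u  # identity
        if out > 1.0:
            raise ValidationError(f"mapped utility above 1.0: {out}")
        return out


def _to_pence(x: float) -> int:
    return int(round(x * 100))


def qaly_auc(utilities: Sequence[tuple[float, float]], horizon: float) -> float:
    """Trapezoid area under the (time, utility) curve; times in years."""
    if len(utilities) < 2:
        raise ValidationError("need at least two utility time points")
    times = [t for t, _ in utilities]
    if times[0] != 0.0:
        raise ValidationError("utility series must start at time 0")
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValidationError("utility times must be strictly increasing")
    if abs(times[-1] - horizon) > 1e-12:
        raise ValidationError(f"last utility time {times[-1]} must equal horizon {horizon}")
    area = 0.0
    for (t0, u0), (t1, u1) in zip(utilities, utilities[1:]):
        area += (t1 - t0) * (u0 + u1) / 2.0
    return area


def participant_qalys(dataset: TrialDataset, locf_utilities: bool = True) -> list[QalyResult]:
    """QALYs per participant over the dataset horizon.

    Missing follow-up utilities are carried forward (last observation) when
    ``locf_utilities`` is set; records with a missing baseline utility are
    skipped with a warning.
    """
    results = []
    for rec in dataset.records:
        if rec.eq5d["month0"] is None:
            warnings.warn(f"skipping {rec.participant_id}: missing baseline utility", stacklevel=2)
            continue
        series: list[tuple[float, float]] = []
        any_imputed = False
        last = rec.eq5d["month0"]
        for visit in UTILITY_VISITS:
            u = rec.eq5d[visit]
            if u is None:
                if not locf_utilities:
                    break
                u = last
                any_imputed = True
            else:
                any_imputed = any_imputed or (("eq5d", visit) in rec.imputed)
                last = u
            series.append((UTILITY_TIMES_YEARS[visit], u))
        if len(series) < len(UTILITY_VISITS):
            continue
        results.append(
            QalyResult(
                participant_id=rec.participant_id,
                qaly=qaly_auc(series, dataset.horizon_years),
                utilities_used=series,
                any_imputed=any_imputed,
            )
        )
    return results


def lvcf_costs(
    ledger: CostLedger,
    window_years: Mapping[str, float] | None = None,
    zero_fill_pretrial: bool = False,
) -> CostLedger:
    """Fill missing within-trial cost items from the most recent earlier window.

    Carried values are scaled by the ratio of window lengths, so a 13-week
    trial window filled from the 12-week pre-trial window carries 13/12 of
    the pre-trial amount.  Idempotent; carried cells are flagged.
    """
    wy = dict(window_years or DEFAULT_WINDOW_YEARS)
    out = ledger.copy()
    for c in CARE_COMPONENTS:
        if out.get("pretrial_12wk", c) is None:
            if not zero_fill_pretrial:
                raise ValidationError(
                    f"pre-trial cost {c!r} missing; complete it or pass zero_fill_pretrial=True"
                )
            out.set("pretrial_12wk", c, 0.0)
            out.imputed.add(("pretrial_12wk", c))
    for c in CARE_COMPONENTS:
        prev_window = "pretrial_12wk"
        for w in TRIAL_WINDOWS:
            if out.get(w, c) is None:
                scale = wy[w] / wy[prev_window]
                carried = out.get(prev_window, c) * scale
                out.set(w, c, _to_pence(carried) / 100.0)
                out.imputed.add((w, c))
            prev_window = w
    return out


def aggregate_costs(
    dataset: TrialDataset,
    intervention_cost_per_year: float = 15.0,
    horizon: float | None = None,
    inflation_index: Mapping[str, float] | None = None,
    attribution: str = "full",
    component_source_years: Mapping[str, str] | None = None,
    window_years: Mapping[str, float] | None = None,
    zero_fill_pretrial: bool = False,
) -> list[CostSummary]:
    """Per-participant baseline and within-trial cost totals in GBP.

    The intervention cost is computed from the arm and the per-year price
    (full attribution charges the whole annual price to the horizon;
    ``attribution="prorata"`` charges ``price x horizon``); ledger
    intervention cells are ignored to avoid double counting.  Inflation
    factors are looked up per component source year (default: the dataset
    currency year, factor 1).
    """
    if attribution not in ("full", "prorata"):
        raise ValidationError(f"attribution must be 'full' or 'prorata', got {attribution!r}")
    horizon = dataset.horizon_years if horizon is None else horizon
    index = dict(inflation_index or {dataset.currency_year: 1.0})
    source_years = dict(component_source_years or {})
    summaries = []
    for rec in dataset.records:
        ledger = lvcf_costs(rec.costs, window_years, zero_fill_pretrial)
        factors = {}
        for c in CARE_COMPONENTS:
            year = source_years.get(c, dataset.currency_year)
            if year not in index:
                raise ValidationError(f"no inflation factor for source year {year!r} (component {c})")
            factors[c] = index[year]
        baseline_p = sum(
            _to_pence(ledger.get("pretrial_12wk", c) * factors[c]) for c in CARE_COMPONENTS
        )
        components_p = {
            c: sum(_to_pence(ledger.get(w, c) * factors[c]) for w in TRIAL_WINDOWS)
            for c in CARE_COMPONENTS
        }
        if rec.arm == "intervention":
            amount = intervention_cost_per_year * (1.0 if attribution == "full" else horizon)
            components_p["intervention"] = _to_pence(amount)
        else:
            components_p["intervention"] = 0
        summaries.append(
            CostSummary(
                participant_id=rec.participant_id,
                baseline_cost=baseline_p / 100.0,
                trial_cost=sum(components_p.values()) / 100.0,
                components={c: p / 100.0 for c, p in components_p.items()},
                any_imputed=bool(ledger.imputed),
            )
        )
    return summaries


def map_utilities(dataset: TrialDataset, mapping: UtilityMapping) -> TrialDataset:
    """Apply a 5L -> 3L utility conversion to every observed utility."""
    out = dataset.copy()
    unmapped = []
    for rec in out.records:
        original = dict(rec.eq5d)
        for visit, u in rec.eq5d.items():
            if u is None:
                continue
            try:
                rec.eq5d[visit] = mapping.apply(u)
            except KeyError:
                unmapped.append(u)
        rec.original_eq5d = original  # provenance of pre-mapping values
    if unmapped:
        raise ValidationError(f"utility values missing from mapping table: {sorted(set(unmapped))}")
    return out


def annual_cost_saving(comparator_cost_per_year: float, intervention_cost_per_year: float) -> float:
    """Per-participant annual saving of the intervention versus a comparator."""
    return comparator_cost_per_year - intervention_cost_per_year
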