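"""Synthetic patient-level cohorts with the statistical structure the
estimators assume.

Each patient is pushed through the first-cycle transition row to a 6-month
state and, while still on PER, through the subsequent row to a 12-month
state. Follow-up seizure frequencies are then constructed to be exactly
consistent with the drawn category (zero for seizure freedom, a reduction in
[50%, 100%) for response, in [0%, 50%) for no response), so classification
round-trips by construction. Per-period costs are drawn from per-state gamma
distributions and TDM counts from a gamma anchored at the study's mean of
1.74 tests per cycle.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import Arm, HealthState, PatientRecord

__all__ = ["GeneratorSpec", "generate_cohort", "roundtrip_check"]

# study-anchored defaults: printed pooled rows and enrolment sizes
_DEFAULT_FIRST = {"tdm": (0.200, 0.267, 0.241, 0.292),
                  "nontdm": (0.200, 0.267, 0.241, 0.292)}
_DEFAULT_SUB = {"tdm": ((0.708, 0.042, 0.000, 0.250),
                        (0.031, 0.875, 0.063, 0.031)),
                "nontdm": ((0.708, 0.042, 0.000, 0.250),
                           (0.031, 0.875, 0.063, 0.031))}
_DEFAULT_COSTS = {  # mean 6-month cost per state (study totals)
    "tdm": (988.95, 872.10, 609.16, 787.31),
    "nontdm": (807.08, 641.99, 488.70, 787.31)}


@dataclass
class GeneratorSpec:
    """Configuration of the synthetic cohort generator.

    ``first_row``/``subsequent_rows`` are per-arm true transition rows
    (subsequent rows: from no-response and from response). The baseline
    seizure frequency is log-normal (median ~8 seizures per 28 days by
    default, matching a moderately refractory pediatric cohort); per-state
    cost distributions are gamma with coefficient of variation ``cost_cv``.
    """

    seed: int
    n_tdm: int = 78
    n_nontdm: int = 42
    first_row: dict = field(default_factory=lambda: {k: np.array(v) for k, v
                                                     in _DEFAULT_FIRST.items()})
    subsequent_rows: dict = field(default_factory=lambda: {k: np.array(v) for k, v
                                                           in _DEFAULT_SUB.items()})
    state_cost_mean: dict = field(default_factory=lambda: {k: np.array(v) for k, v
                                                           in _DEFAULT_COSTS.items()})
    cost_cv: float = 0.4
    baseline_log_median: float = np.log(8.0)
    baseline_log_sigma: float = 1.0
    tdm_count_mean: float = 1.74
    tdm_count_cv: float = 0.35

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if min(self.n_tdm, self.n_nontdm) < 1:
            raise ValueError("need at least one patient per arm")
        for arm in ("tdm", "nontdm"):
            rows = [self.first_row[arm]] + list(self.subsequent_rows[arm])
            for r in rows:
                r = np.asarray(r, float)
                if np.any(r < 0) or not np.isclose(r.sum(), 1.0, atol=1e-9):
                    raise ValueError(f"{arm}: transition row {r} not stochastic")


def _freq_for_state(state: int, baseline: float, rng: np.random.Generator) -> Optional[float]:
    if state == int(HealthState.SEIZURE_FREE):
        return 0.0
    if state == int(HealthState.RESPONSE):
        r = rng.uniform(0.5, 1.0)          # reduction in [50%, 100%)
        f = baseline * (1.0 - r)
        return baseline * 0.5 if f == 0 else f   # keep >0 and within response band
    if state == int(HealthState.NO_RESPONSE):
        r = rng.uniform(0.0, 0.5)          # reduction in [0%, 50%)
        f = baseline * (1.0 - r)
        return f
    return None                             # discontinued: no follow-up frequency


def generate_cohort(spec: GeneratorSpec) -> list[PatientRecord]:
    """Draw a full two-arm cohort; byte-identical for identical seeds."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    records = []
    for arm_name, n in (("tdm", spec.n_tdm), ("nontdm", spec.n_nontdm)):
        arm = Arm(arm_name)
        first = np.asarray(spec.first_row[arm_name], float)
        sub = {int(HealthState.NO_RESPONSE): np.asarray(spec.subsequent_rows[arm_name][0], float),
               int(HealthState.RESPONSE): np.asarray(spec.subsequent_rows[arm_name][1], float)}
        costs = np.asarray(spec.state_cost_mean[arm_name], float)
        for i in range(n):
            baseline = float(np.exp(rng.normal(spec.baseline_log_median,
                                               spec.baseline_log_sigma)))
            s6 = int(rng.choice(4, p=first))
            if s6 == int(HealthState.SEIZURE_FREE):
                s12 = s6                              # seizure freedom is absorbing
            elif s6 == int(HealthState.DISCONTINUE):
                s12 = None
            else:
                s12 = int(rng.choice(4, p=sub[s6]))
            freq6 = _freq_for_state(s6, baseline, rng)
            freq12 = None if s12 is None else _freq_for_state(s12, baseline, rng)
            disc = 1 if s6 == int(HealthState.DISCONTINUE) else (
                2 if s12 == int(HealthState.DISCONTINUE) else None)
            period_costs = {}
            for period, st in ((1, s6), (2, s12)):
                if st is None:
                    st = int(HealthState.DISCONTINUE)
                m = costs[st]
                cv = spec.cost_cv
                total = m if cv <= 0 else float(rng.gamma((1 / cv) ** 2, m * cv ** 2))
                # category split sums to 1 so category means recompose the total
                if arm is Arm.TDM and st != int(HealthState.DISCONTINUE):
                    split = {"per": 0.25, "other_asm": 0.30, "outpatient": 0.15,
                             "hospitalization": 0.28, "tdm": 0.02}
                else:
                    split = {"per": 0.25, "other_asm": 0.30, "outpatient": 0.15,
                             "hospitalization": 0.30, "tdm": 0.0}
                cats = {k: v * total for k, v in split.items()}
                period_costs[period] = cats
            tdm_count = 0
            if arm is Arm.TDM:
                cv = spec.tdm_count_cv
                raw = rng.gamma((1 / cv) ** 2, spec.tdm_count_mean * cv ** 2)
                tdm_count = int(round(raw))
            records.append(PatientRecord(
                patient_id=f"{arm_name}-{i:04d}", arm=arm, baseline_freq=baseline,
                freq_6m=freq6, freq_12m=freq12, discontinued_cycle=disc,
                period_costs=period_costs, tdm_count=tdm_count))
    return records


def roundtrip_check(spec: GeneratorSpec) -> dict:
    """Generate -> classify -> tabulate -> fit -> estimate round trip.

    Reports recovered versus true transition rows, the proportional-odds OR
    implied by the two arms' 12-month category distributions, and state-cost
    means, each tagged with the stage that produced it.
    """
    from .clinical import (build_outcome_table, estimate_state_costs,
                           estimate_transitions, fit_proportional_odds)
    records = generate_cohort(spec)
    report: dict = {"n_records": len(records)}
    table = build_outcome_table(records, "12m")
    report["outcome_table"] = table.counts
    try:
        fit = fit_proportional_odds(table)
        report["or_fit"] = {"or": fit.or_value, "ci": (fit.ci_low, fit.ci_high)}
    except ValueError as e:
        report["or_fit"] = {"error": f"fit_proportional_odds: {e}"}
    first = estimate_transitions(records, "first")
    sub = estimate_transitions(records, "subsequent")
    report["transitions"] = {}
    for arm in ("tdm", "nontdm"):
        report["transitions"][arm] = {
            "first": {"estimated": first[arm], "true": np.asarray(spec.first_row[arm])},
            "subsequent": {"estimated": sub[arm],
                           "true": {"no_response": np.asarray(spec.subsequent_rows[arm][0]),
                                    "response": np.asarray(spec.subsequent_rows[arm][1])}},
        }
    report["state_costs"] = estimate_state_costs(records)
    return report
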