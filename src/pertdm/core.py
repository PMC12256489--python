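"""Shared domain types for the perampanel TDM cost-effectiveness model.

The model tracks a pediatric epilepsy cohort on perampanel (PER) through four
health states defined by seizure-frequency reduction relative to baseline:
no response (<50% reduction), response (>=50% and <100%), seizure freedom
(100% reduction) and discontinuation of PER. Two strategies are compared:
PER dosing guided by therapeutic drug monitoring (TDM) versus usual titration
without TDM.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np


class Arm(str, enum.Enum):
    TDM = "tdm"
    NON_TDM = "nontdm"


class HealthState(enum.IntEnum):
    """Markov states, in the fixed state order used by every matrix and trace."""

    NO_RESPONSE = 0
    RESPONSE = 1
    SEIZURE_FREE = 2
    DISCONTINUE = 3


STATE_NAMES = ("no_response", "response", "seizure_free", "discontinue")
ON_PER_STATES = (HealthState.NO_RESPONSE, HealthState.RESPONSE, HealthState.SEIZURE_FREE)

#: ordered clinical outcome categories (worst to best) used by the ordinal model
class Outcome(enum.IntEnum):
    UNCONTROLLED = 0
    RESPONSE = 1
    SEIZURE_FREE = 2


#: sentinel outcome for a patient who stopped PER before the visit
DISCONTINUED = "discontinued"

AE_EVENTS = ("dizziness", "somnolence", "irritability", "ataxia")

WTP_HIGH = 12_814.0      # Chinese GDP per capita, USD 2022
WTP_INTERMEDIATE = 38_442.0   # three times GDP per capita
USD_PER_RMB_RATE = 6.73  # RMB per USD, 2022
INFLATION_RATE = 0.0148  # mean annual inflation used to express costs in 2022 USD


@dataclass
class AdverseEventProfile:
    """Per-cycle adverse-event layer for one arm.

    probability: per-cycle probability of each event while on PER.
    cost: USD per event; disutility: QALY decrement per expected event
    (stored as a positive magnitude, subtracted during accumulation).
    """

    probability: dict[str, float]
    cost: dict[str, float]
    disutility: dict[str, float]

    @property
    def expected_cost(self) -> float:
        return sum(self.probability[e] * self.cost[e] for e in self.probability)

    @property
    def expected_disutility(self) -> float:
        return sum(self.probability[e] * self.disutility[e] for e in self.probability)


@dataclass
class ArmParameters:
    """Everything one arm contributes to the cohort model.

    Transition rows are over ``STATE_NAMES`` order. ``state_cost`` and
    ``state_utility`` are per-cycle (6-month) values; ``components`` keeps the
    printed cost components (hospitalization, outpatient, drug costs) for
    sensitivity recomposition and validation, keyed ``(family, state, item)``.
    """

    arm: Arm
    first_cycle_row: np.ndarray
    subsequent_rows: np.ndarray          # 4x4, absorbing rows included
    state_cost: np.ndarray               # USD per cycle, state order
    state_utility: np.ndarray            # SF-6D weights, state order
    ae: AdverseEventProfile
    tdm_cost_per_cycle: float = 0.0
    components: dict = field(default_factory=dict)

    def validate(self) -> list[str]:
        problems = []
        if not np.isclose(self.first_cycle_row.sum(), 1.0, atol=1e-9):
            problems.append(f"{self.arm}: first-cycle row sums to {self.first_cycle_row.sum()}")
        for i, row in enumerate(self.subsequent_rows):
            if not np.isclose(row.sum(), 1.0, atol=1e-9):
                problems.append(f"{self.arm}: subsequent row {STATE_NAMES[i]} sums to {row.sum()}")
        if np.any(self.state_cost < 0):
            problems.append(f"{self.arm}: negative state cost")
        if np.any((self.state_utility < 0) | (self.state_utility > 1)):
            problems.append(f"{self.arm}: utility outside [0, 1]")
        for e, p in self.ae.probability.items():
            if not 0 <= p <= 1:
                problems.append(f"{self.arm}: AE probability {e}={p} outside [0, 1]")
        return problems


@dataclass
class ModelConfig:
    """Run configuration for the cohort model.

    The reward-accounting flags default to the calibrated convention that
    reproduces the study's published totals: a reward point at every cycle
    boundary including entry (``include_initial_occupancy``), utility accrued
    per cycle without scaling by cycle length (``utility_full_cycle``), and the
    annual discount rate compounded once per cycle (``discount_per_cycle``).
    Setting all three to the textbook alternative gives conventional
    half-year-scaled, per-annum-discounted accounting.
    """

    horizon_years: float = 15.0
    cycle_length_years: float = 0.5
    cost_discount_rate: float = 0.05
    effect_discount_rate: float = 0.05
    wtp_thresholds: tuple[float, float] = (WTP_HIGH, WTP_INTERMEDIATE)
    or_mode: str = "printed_is_pooled"   # printed_is_tdm | printed_is_nontdm | printed_is_pooled
    or_scope: str = "first_cycle"        # first_cycle | all_phases
    or_includes_discontinue: bool = True
    half_cycle_correction: bool = False
    include_initial_occupancy: bool = True
    utility_full_cycle: bool = True
    discount_per_cycle: bool = True
    ae_states: tuple[HealthState, ...] = ON_PER_STATES
    psa_arm_correlation: str = "shared"  # shared | independent

    @property
    def n_cycles(self) -> int:
        n = self.horizon_years / self.cycle_length_years
        if abs(n - round(n)) > 1e-9:
            raise ValueError("horizon must be a whole number of cycles")
        n = int(round(n))
        if n < 1:
            raise ValueError("horizon must cover at least one cycle")
        return n

    def replace(self, **kw) -> "ModelConfig":
        import dataclasses
        return dataclasses.replace(self, **kw)


@dataclass
class PatientRecord:
    """One child's observed course over the 12-month follow-up."""

    patient_id: str
    arm: Arm
    baseline_freq: float                  # seizures per 28 days
    freq_6m: Optional[float] = None       # None iff discontinued before 6m
    freq_12m: Optional[float] = None      # None iff discontinued before 12m
    discontinued_cycle: Optional[int] = None   # 1, 2 or None
    period_costs: dict = field(default_factory=dict)  # period -> category -> USD
    tdm_count: int = 0

    def validate(self) -> list[str]:
        problems = []
        if self.baseline_freq < 0:
            problems.append(f"{self.patient_id}: negative baseline frequency")
        if self.arm is Arm.NON_TDM and self.tdm_count != 0:
            problems.append(f"{self.patient_id}: non-TDM patient with tdm_count != 0")
        if self.discontinued_cycle == 1 and self.freq_6m is not None:
            problems.append(f"{self.patient_id}: freq_6m present despite cycle-1 discontinuation")
        if self.discontinued_cycle is not None and self.freq_12m is not None:
            problems.append(f"{self.patient_id}: freq_12m present despite discontinuation")
        for period, cats in self.period_costs.items():
            for cat, v in cats.items():
                if v < 0:
                    problems.append(f"{self.patient_id}: negative {cat} cost in period {period}")
                if cat == "tdm" and self.arm is Arm.NON_TDM and v != 0:
                    problems.append(f"{self.patient_id}: non-TDM patient with TDM cost")
        return problems
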