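"""Four-state Markov cohort engine: OR-based arm derivation, cohort trace,
and discounted cost/QALY accumulation with the adverse-event layer.

The printed transition rows describe one strategy (or the pooled cohort); the
other strategy's rows are derived by shifting the destination distribution on
the cumulative-logit scale by the clinical odds ratio, so that an OR of 1
leaves the rows untouched and a smaller OR moves mass away from the better
destinations.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Arm, ArmParameters, HealthState, ModelConfig

__all__ = ["apply_or_adjustment", "build_arm_matrices", "run_cohort",
           "discount_factor", "accumulate", "run_arm", "CohortTrace", "ArmResult"]


def _shift_ordered(p: np.ndarray, or_value: float) -> np.ndarray:
    """Shift an ordered distribution by ``or_value`` on every cumulative cut.

    For each cut j, odds'(dest > j) = or_value * odds(dest > j). Degenerate
    cuts (cumulative probability 0 or 1) are fixed points, so point masses are
    preserved and the result is always a valid ordered distribution.
    """
    k = len(p)
    q = np.cumsum(p[::-1])[::-1][1:]          # P(dest > j), j = 0..k-2
    qq = np.empty_like(q)
    for j, qj in enumerate(q):
        if qj >= 1.0:
            qq[j] = 1.0
        elif qj <= 0.0:
            qq[j] = 0.0
        else:
            odds = or_value * qj / (1.0 - qj)
            qq[j] = odds / (1.0 + odds)
    # enforce monotone cumulative probabilities (guards rounding at the ends)
    for j in range(1, k - 1):
        qq[j] = min(qq[j], qq[j - 1])
    out = np.empty(k)
    out[0] = 1.0 - qq[0]
    for j in range(1, k - 1):
        out[j] = qq[j - 1] - qq[j]
    out[-1] = qq[-1]
    return out


def apply_or_adjustment(reference_row: np.ndarray, or_value: float,
                        include_discontinue: bool = True) -> np.ndarray:
    """Derive one arm's transition row from a reference row and an odds ratio.

    ``reference_row`` is over (no_response, response, seizure_free,
    discontinue). With ``include_discontinue`` the shift acts on all four
    destinations ordered discontinue < no_response < response < seizure_free,
    so a favourable OR also lowers the discontinuation probability. Otherwise
    the discontinue probability is held fixed and only the on-PER destination
    distribution, conditioned on staying on PER, is shifted; the row is then
    renormalized exactly.
    """
    row = np.asarray(reference_row, dtype=float)
    if or_value <= 0:
        raise ValueError("or_value must be positive")
    if not np.isclose(row.sum(), 1.0, atol=1e-9):
        raise ValueError("reference row must sum to 1")
    if or_value == 1.0:
        return row.copy()
    if include_discontinue:
        ordered = np.array([row[3], row[0], row[1], row[2]])
        shifted = _shift_ordered(ordered, or_value)
        return np.array([shifted[1], shifted[2], shifted[3], shifted[0]])
    on_per = row[:3]
    mass = on_per.sum()
    if mass <= 0:
        raise ValueError("reference row has no on-PER mass; adjustment undefined")
    shifted = _shift_ordered(on_per / mass, or_value)
    return np.concatenate([shifted * mass, [row[3]]])


def _absorbing(i: int) -> np.ndarray:
    row = np.zeros(4)
    row[i] = 1.0
    return row


def _phase_matrices(first_row, nr_row, r_row) -> dict[str, np.ndarray]:
    sf = _absorbing(int(HealthState.SEIZURE_FREE))
    d = _absorbing(int(HealthState.DISCONTINUE))
    return {"first_cycle": np.array([first_row, r_row, sf, d]),
            "subsequent": np.array([nr_row, r_row, sf, d])}


def build_arm_matrices(printed_first: np.ndarray, printed_subsequent: np.ndarray,
                       or_value: float, config: ModelConfig
                       ) -> dict[str, dict[str, np.ndarray]]:
    """Build both arms' phase matrices from the printed rows and the OR.

    ``printed_subsequent`` is the full 4x4 printed subsequent-phase matrix.
    ``config.or_mode`` states which arm the printed rows describe; the other
    arm (or, for pooled rows, both arms symmetrically with half the log-odds
    shift each way) is derived with :func:`apply_or_adjustment`.
    ``config.or_scope`` restricts the derivation to the first-cycle row
    (the calibrated default) or applies it to every non-absorbing row.
    """
    if or_value <= 0:
        raise ValueError("or_value must be positive")
    first = np.asarray(printed_first, dtype=float)
    sub = np.asarray(printed_subsequent, dtype=float)
    nr_row, r_row = sub[0], sub[1]
    inc = config.or_includes_discontinue

    def derive(rows, factor):
        f, nr, r = rows
        f2 = apply_or_adjustment(f, factor, inc)
        if config.or_scope == "all_phases":
            return f2, apply_or_adjustment(nr, factor, inc), apply_or_adjustment(r, factor, inc)
        if config.or_scope != "first_cycle":
            raise ValueError(f"unknown or_scope: {config.or_scope}")
        return f2, nr, r

    printed = (first, nr_row, r_row)
    if config.or_mode == "printed_is_tdm":
        tdm_rows = printed
        non_rows = derive(printed, or_value)
    elif config.or_mode == "printed_is_nontdm":
        non_rows = printed
        tdm_rows = derive(printed, 1.0 / or_value)
    elif config.or_mode == "printed_is_pooled":
        half = np.sqrt(or_value)
        tdm_rows = derive(printed, 1.0 / half)
        non_rows = derive(printed, half)
    else:
        raise ValueError(f"unknown or_mode: {config.or_mode}")
    return {Arm.TDM.value: _phase_matrices(*tdm_rows),
            Arm.NON_TDM.value: _phase_matrices(*non_rows)}


@dataclass
class CohortTrace:
    """State-occupancy fractions: ``occupancy[t]`` after t cycles (row 0 = entry)."""

    occupancy: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1


def run_cohort(matrices: dict[str, np.ndarray], config: ModelConfig) -> CohortTrace:
    """Propagate the cohort from (1, 0, 0, 0) through the horizon.

    The first-cycle matrix drives cycle 1 and the subsequent matrix every
    later cycle.
    """
    for name, P in matrices.items():
        P = np.asarray(P, float)
        if P.shape != (4, 4) or np.any(P < -1e-12) or \
                not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"{name} matrix is not row-stochastic")
    n = config.n_cycles
    occ = np.zeros((n + 1, 4))
    occ[0, int(HealthState.NO_RESPONSE)] = 1.0
    for t in range(1, n + 1):
        P = matrices["first_cycle"] if t == 1 else matrices["subsequent"]
        occ[t] = occ[t - 1] @ P
    return CohortTrace(occupancy=occ)


def discount_factor(cycle_index: int, annual_rate: float,
                    cycle_length_years: float = 0.5,
                    per_cycle: bool = False) -> float:
    """Discount factor for a reward at ``cycle_index`` (cycle 1 undiscounted).

    The conventional factor is ``(1+r)^(-(cycle_index-1)*cycle_length)``;
    with ``per_cycle`` the annual rate is compounded once per cycle
    regardless of cycle length, the accounting used by the source model.
    """
    if annual_rate < 0:
        raise ValueError("rate must be >= 0")
    exponent = (cycle_index - 1) * (1.0 if per_cycle else cycle_length_years)
    return float((1.0 + annual_rate) ** (-exponent))


@dataclass
class ArmResult:
    arm: str
    total_cost: float
    total_qalys: float
    cycle_costs: np.ndarray
    cycle_qalys: np.ndarray


def _reward_points(trace: CohortTrace, config: ModelConfig) -> np.ndarray:
    occ = trace.occupancy
    if config.half_cycle_correction:
        return 0.5 * (occ[:-1] + occ[1:])
    if config.include_initial_occupancy:
        return occ
    return occ[1:]


def accumulate(trace: CohortTrace, params: ArmParameters, config: ModelConfig,
               cost_override: np.ndarray | None = None,
               ae_override=None) -> ArmResult:
    """Accumulate discounted costs and QALYs over a cohort trace.

    Per reward point: cost = occupancy . state_cost plus the expected
    adverse-event cost applied to the on-PER occupancy; QALY = occupancy .
    utility times the per-cycle utility weight, minus the expected
    adverse-event disutility on the on-PER occupancy. ``cost_override`` and
    ``ae_override``, when given, are arrays/lists with one entry per reward
    point (used by the 1-year-TDM scenario to switch the cost and AE layer
    mid-run).
    """
    if np.any(params.state_cost < 0):
        raise ValueError("negative state cost")
    if np.any((params.state_utility < 0) | (params.state_utility > 1)):
        raise ValueError("utility outside [0, 1]")
    W = _reward_points(trace, config)
    K = W.shape[0]
    mask = np.zeros(4)
    for s in config.ae_states:
        mask[int(s)] = 1.0
    uweight = 1.0 if config.utility_full_cycle else config.cycle_length_years
    costs = np.empty(K)
    qalys = np.empty(K)
    for k in range(K):
        w = W[k]
        sc = params.state_cost if cost_override is None else cost_override[k]
        ae = params.ae if ae_override is None else ae_override[k]
        exposed = float(w @ mask)
        costs[k] = float(w @ sc) + exposed * ae.expected_cost
        qalys[k] = float(w @ params.state_utility) * uweight - exposed * ae.expected_disutility
    dfc = np.array([discount_factor(k + 1, config.cost_discount_rate,
                                    config.cycle_length_years, config.discount_per_cycle)
                    for k in range(K)])
    dfe = np.array([discount_factor(k + 1, config.effect_discount_rate,
                                    config.cycle_length_years, config.discount_per_cycle)
                    for k in range(K)])
    cycle_costs = costs * dfc
    cycle_qalys = qalys * dfe
    return ArmResult(arm=params.arm.value,
                     total_cost=float(cycle_costs.sum()),
                     total_qalys=float(cycle_qalys.sum()),
                     cycle_costs=cycle_costs,
                     cycle_qalys=cycle_qalys)


def run_arm(params: ArmParameters, config: ModelConfig) -> ArmResult:
    """Convenience: trace + accumulate for one arm's own matrices."""
    matrices = _phase_matrices(params.first_cycle_row,
                               params.subsequent_rows[0],
                               params.subsequent_rows[1])
    trace = run_cohort(matrices, config)
    return accumulate(trace, params, config)
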