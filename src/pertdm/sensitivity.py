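"""Sensitivity machinery: the uncertain-parameter registry, one-way
(tornado) analysis, probabilistic sensitivity analysis with CEAC, and the
scenario engine.

Every uncertain input enumerated from the printed tables becomes one
``ParamSpec`` per arm whose computation it enters, giving the registry of
one-way factors. The PSA samples the same quantities with role-specific
distributions (gamma for costs and counts, beta for probabilities, normal for
utilities and outpatient-visit counts, lognormal for the odds ratio, gamma on
magnitude for disutilities), re-deriving each arm's transition rows per draw
from the sampled pooled rows and sampled OR.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import AE_EVENTS, Arm, ModelConfig, STATE_NAMES
from .economics import CEResult, icer
from .io import COMBO_DRUGS, ON_PER, ParameterTable, copy_inputs
from .markov import accumulate, run_arm

Z95 = 1.959963984540054

__all__ = ["ParamSpec", "TornadoEntry", "PSAResult", "build_param_registry",
           "fit_distribution", "one_way_sa", "run_psa", "run_scenario",
           "run_base_case"]


# ---------------------------------------------------------------------------
@dataclass
class ParamSpec:
    """One uncertain parameter: base value, one-way range, distribution."""

    param_id: str
    family: str
    item: str
    state: str
    arm: str                       # tdm | nontdm | shared
    base_value: float
    low: float
    high: float
    distribution: str              # gamma | beta | normal | lognormal
    role: str                      # probability | cost | utility | ratio | disutility | count
    target: tuple                  # path into the model-input mapping
    shared_origin: bool = False    # printed once for both arms
    psa_sampled: bool = True       # derived per-arm transitions are re-derived, not sampled

    def __post_init__(self):
        if not self.low <= self.base_value <= self.high:
            raise ValueError(
                f"{self.param_id}: range ({self.low}, {self.high}) does not "
                f"bracket base {self.base_value}")

    def apply(self, inputs: dict, value: float) -> None:
        t = self.target
        if t[0] == "or":
            inputs["or"] = value
        elif t[0] == "transition_override":
            inputs["transition_override"][t[1:]] = value
        elif t[0] == "arm_scalar":
            inputs[t[1]][t[2]] = value
        else:  # ("arm_keyed", arm, family, key)
            inputs[t[1]][t[2]][t[3]] = value

    @property
    def se(self) -> float:
        """Standard error: from the 95% range when present, else 20% of base."""
        if self.high > self.low:
            return (self.high - self.low) / (2 * Z95)
        return 0.2 * abs(self.base_value)


def _default_range(value: float, lo, hi, clip01: bool = False):
    if lo is None or hi is None or hi < lo:
        span = Z95 * 0.2 * abs(value)
        lo, hi = value - span, value + span
    if clip01:
        lo, hi = max(lo, 0.0), min(hi, 1.0)
    lo, hi = min(lo, value), max(hi, value)
    return lo, hi


_ARM_TAG = {"tdm": "TDM", "nontdm": "NTDM"}
# tornado label prefixes, following the published figure's naming convention
_ROLE_LETTER = {"probability": "P", "cost": "C", "utility": "U",
                "ratio": "OR", "disutility": "D", "count": "N"}


def build_param_registry(table: ParameterTable, config: ModelConfig) -> list[ParamSpec]:
    """Enumerate the one-way/PSA parameter registry from the printed tables.

    One entry per (parameter, arm) for every uncertain input entering each
    arm's computation; quantities printed once for both arms contribute one
    per-arm copy each (flagged ``shared_origin``). Transition cells enter per
    arm at their derived base values and are varied as one-way factors but
    re-derived (pooled rows + OR) rather than sampled in the PSA.
    """
    specs: list[ParamSpec] = []
    inputs = table.base_inputs()
    mats = table.build_matrices(inputs, config)

    def rng_of(family, **keys):
        v, lo, hi = table._range(family, **keys)
        return v, lo, hi

    # odds ratio
    v, lo, hi = rng_of("or", item="seizure_reduction_vs_tdm")
    specs.append(ParamSpec("OR_seizure_reduction_NTDM_vs_TDM", "or", "or", "", "shared",
                           v, lo, hi, "lognormal", "ratio", ("or",)))

    # per-arm derived transition cells (13 printed cells per arm)
    printed_cells = ([("first_cycle", 0, j) for j in range(4)]
                     + [("subsequent", 0, j) for j in range(4)]
                     + [("subsequent", 1, j) for j in range(4)]
                     + [("subsequent", 2, 2)])
    for arm in ("tdm", "nontdm"):
        for phase, i, j in printed_cells:
            base = float(mats[arm][phase][i, j])
            lo, hi = _default_range(base, None, None, clip01=True)
            specs.append(ParamSpec(
                f"P_{phase}_{STATE_NAMES[i]}_to_{STATE_NAMES[j]}_{_ARM_TAG[arm]}",
                "transition", f"{phase}:{STATE_NAMES[i]}->{STATE_NAMES[j]}",
                STATE_NAMES[i], arm, base, lo, hi, "beta", "probability",
                ("transition_override", arm, phase, i, j), psa_sampled=False))

    return _finish_registry(table, specs)


def _finish_registry(table: ParameterTable, specs: list[ParamSpec]) -> list[ParamSpec]:
    def add(family, item, state, arm, dist, role, target, *, keys,
            clip01=False, shared=False, magnitude=False):
        v, lo, hi = table._range(family, **keys)
        if magnitude:
            v = abs(v)
            lo = None if lo is None else abs(lo)
            hi = None if hi is None else abs(hi)
            if lo is not None and hi is not None and lo > hi:
                lo, hi = hi, lo
        lo, hi = _default_range(v, lo, hi, clip01=clip01)
        name = f"{family}_{item}" + (f"_{state}" if state else "")
        tag = _ARM_TAG.get(arm)
        letter = _ROLE_LETTER[role]
        pid = f"{letter}_{name}_{tag}" if tag else f"{letter}_{name}"
        specs.append(ParamSpec(pid, family, item, state, arm, v, lo, hi,
                               dist, role, target, shared_origin=shared))

    for arm in ("tdm", "nontdm"):
        for e in AE_EVENTS:
            add("ae_prob", e, "", arm, "beta", "probability",
                ("arm_keyed", arm, "ae_prob", e), keys=dict(arm=arm, item=e),
                clip01=True)
        for st in ON_PER:
            for fam, dist, role in (("hosp_prob", "beta", "probability"),
                                    ("hosp_number", "gamma", "count"),
                                    ("hosp_days", "gamma", "count"),
                                    ("hosp_daily_cost", "gamma", "cost")):
                add(fam, "per_event", st, arm, dist, role,
                    ("arm_keyed", arm, fam, st), keys=dict(arm=arm, state=st),
                    clip01=(dist == "beta"))
            add("consult_cost", "per_event", st, arm, "gamma", "cost",
                ("arm_keyed", arm, "consult_cost", st), keys=dict(arm=arm, state=st))
            add("per_cost", "per_cycle", st, arm, "gamma", "cost",
                ("arm_keyed", arm, "per_cost", st), keys=dict(arm=arm, state=st))
        # discontinued patients keep no-response outpatient usage
        add("consult_cost", "per_event", "discontinue", arm, "gamma", "cost",
            ("arm_keyed", arm, "consult_cost", "discontinue"),
            keys=dict(arm=arm, state="no_response"))
        for st in STATE_NAMES:
            add("state_cost_total", "per_cycle", st, arm, "gamma", "cost",
                ("arm_keyed", arm, "state_cost_total", st), keys=dict(arm=arm, state=st))
            add("outpatient_cost_total", "per_cycle", st, arm, "gamma", "cost",
                ("arm_keyed", arm, "outpatient_cost_total", st), keys=dict(arm=arm, state=st))
            add("outpatient_number", "per_cycle", st, arm, "normal", "count",
                ("arm_keyed", arm, "outpatient_number", st), keys=dict(arm=arm, state=st))
            add("other_asm_cost", "per_cycle", st, arm, "gamma", "cost",
                ("arm_keyed", arm, "other_asm_cost", st), keys=dict(arm=arm, state=st))
        for e in AE_EVENTS:
            add("ae_cost", e, "", arm, "gamma", "cost",
                ("arm_keyed", arm, "ae_cost", e), keys=dict(arm="shared", item=e),
                shared=True)
            add("ae_disutility", e, "", arm, "gamma", "disutility",
                ("arm_keyed", arm, "ae_disutility", e), keys=dict(arm="shared", item=e),
                shared=True, magnitude=True)
        for st in STATE_NAMES:
            add("utility", "sf6d", st, arm, "normal", "utility",
                ("arm_keyed", arm, "utility", st), keys=dict(arm="shared", state=st),
                shared=True, clip01=True)
        for d in COMBO_DRUGS:
            for st in ON_PER:
                add("combo_prob", d, st, arm, "beta", "probability",
                    ("arm_keyed", arm, "combo_prob", (d, st)),
                    keys=dict(arm=arm, item=d, state=st), clip01=True)
            add("drug_price", d, "", arm, "gamma", "cost",
                ("arm_keyed", arm, "drug_price", d), keys=dict(arm="shared", item=d),
                shared=True)
        add("test_cost", "per_visit", "", arm, "gamma", "cost",
            ("arm_scalar", arm, "test_cost"), keys=dict(arm="shared"), shared=True)
        add("exam_cost", "per_visit", "", arm, "gamma", "cost",
            ("arm_scalar", arm, "exam_cost"), keys=dict(arm="shared"), shared=True)
    add("per_unit_price", "PER", "", "shared", "gamma", "cost",
        ("arm_scalar", "tdm", "per_unit_price"), keys=dict(item="PER"))
    add("tdm_number", "per_cycle", "", "tdm", "gamma", "count",
        ("arm_scalar", "tdm", "tdm_number"), keys=dict(arm="tdm"))
    add("tdm_unit_cost", "per_test", "", "tdm", "gamma", "cost",
        ("arm_scalar", "tdm", "tdm_unit_cost"), keys=dict(arm="tdm"))

    ids = [s.param_id for s in specs]
    dup = {i for i in ids if ids.count(i) > 1}
    if dup:
        raise RuntimeError(f"duplicate registry ids: {sorted(dup)[:5]}")
    return specs


# ---------------------------------------------------------------------------
class Sampler:
    """Seedable sampler for one ParamSpec, parameterized by moments."""

    def __init__(self, spec: ParamSpec):
        self.spec = spec
        m, s = spec.base_value, spec.se
        self.kind = spec.distribution
        self.mean = m
        if s <= 0 or (self.kind == "beta" and (m <= 0 or m >= 1)) or \
                (self.kind in ("gamma", "lognormal") and m <= 0):
            self.kind = "point"
            return
        if self.kind == "gamma":
            self.shape = (m / s) ** 2
            self.scale = s ** 2 / m
        elif self.kind == "beta":
            var = min(s ** 2, 0.99 * m * (1 - m))   # moment-matching feasibility
            t = m * (1 - m) / var - 1.0
            self.a, self.b = m * t, (1 - m) * t
        elif self.kind == "normal":
            self.sd = s
        elif self.kind == "lognormal":
            if spec.high > spec.low > 0:
                self.sigma = (math.log(spec.high) - math.log(spec.low)) / (2 * Z95)
            else:
                self.sigma = 0.2
            self.mu = math.log(m)
        else:
            raise ValueError(f"unknown distribution {self.kind}")

    def sample(self, rng: np.random.Generator, size=None):
        if self.kind == "point":
            return np.full(size, self.mean) if size else self.mean
        if self.kind == "gamma":
            return rng.gamma(self.shape, self.scale, size)
        if self.kind == "beta":
            return rng.beta(self.a, self.b, size)
        if self.kind == "normal":
            return rng.normal(self.mean, self.sd, size)
        return rng.lognormal(self.mu, self.sigma, size)


def fit_distribution(spec: ParamSpec) -> Sampler:
    """Method-of-moments sampler for a ParamSpec (point mass when SE = 0)."""
    if spec.distribution == "beta" and not 0 <= spec.base_value <= 1:
        raise ValueError(f"{spec.param_id}: beta mean outside [0, 1]")
    return Sampler(spec)


# ---------------------------------------------------------------------------
def run_base_case(table: ParameterTable, config: ModelConfig,
                  inputs: Optional[dict] = None,
                  base: Optional[dict] = None) -> CEResult:
    """Assemble both arms and compute TDM-vs-non-TDM cost effectiveness."""
    base = base if base is not None else table.base_inputs()
    inputs = inputs if inputs is not None else base
    params = table.build_arm_parameters(inputs, config, base=base)
    res_t = run_arm(params[Arm.TDM.value], config)
    res_n = run_arm(params[Arm.NON_TDM.value], config)
    return icer(res_t.total_cost, res_t.total_qalys,
                res_n.total_cost, res_n.total_qalys, config.wtp_thresholds)


@dataclass
class TornadoEntry:
    param_id: str
    low: float
    high: float
    icer_at_low: Optional[float]
    icer_at_high: Optional[float]
    spread: float
    error: Optional[str] = None


def one_way_sa(registry: Sequence[ParamSpec], table: ParameterTable,
               config: ModelConfig) -> pd.DataFrame:
    """Tornado analysis: rerun the model at each parameter's range ends.

    Returns a DataFrame sorted by descending ICER spread, with the base-case
    ICER attached as ``DataFrame.attrs['base_icer']``. A failed extreme run is
    flagged in the ``error`` column, never dropped silently.
    """
    base_inputs = table.base_inputs()
    base_result = run_base_case(table, config, base_inputs, base_inputs)
    entries = []
    for spec in registry:
        vals = {}
        err = None
        for end, v in (("low", spec.low), ("high", spec.high)):
            try:
                work = copy_inputs(base_inputs)
                spec.apply(work, v)
                r = run_base_case(table, config, work, base_inputs)
                vals[end] = r.icer
            except Exception as e:  # surfaced, not dropped
                vals[end] = None
                err = f"{end}: {e}"
        lo_icer, hi_icer = vals.get("low"), vals.get("high")
        spread = abs(hi_icer - lo_icer) if None not in (lo_icer, hi_icer) else np.nan
        entries.append(TornadoEntry(spec.param_id, spec.low, spec.high,
                                    lo_icer, hi_icer, spread, err))
    df = pd.DataFrame([e.__dict__ for e in entries])
    df = df.sort_values("spread", ascending=False, na_position="last").reset_index(drop=True)
    df.attrs["base_icer"] = base_result.icer
    return df


# ---------------------------------------------------------------------------
@dataclass
class PSAResult:
    draws: pd.DataFrame                # columns dc, de
    ceac: pd.DataFrame                 # columns wtp, probability
    p_highly_ce: float
    wtp_high: float
    n_resampled: int
    seed: int

    def ceac_at(self, wtp: float) -> float:
        m = np.isclose(self.ceac["wtp"], wtp)
        if m.any():
            return float(self.ceac.loc[m, "probability"].iloc[0])
        return float(np.mean(self.draws["de"] * wtp - self.draws["dc"] > 0))


def _transition_units(table: ParameterTable):
    """Beta samplers for the printed pooled transition cells, grouped by row."""
    first = table.pooled_first_row()
    sub = table.pooled_subsequent_matrix()
    rows = [("first", first.copy()), ("sub_nr", sub[0].copy()), ("sub_r", sub[1].copy())]
    units = []
    for name, row in rows:
        samplers = []
        for j, p in enumerate(row):
            spec = ParamSpec(f"pooled_{name}_{j}", "transition", name, "", "pooled",
                             float(p), *(_default_range(float(p), None, None, True)),
                             "beta", "probability", ("or",))
            samplers.append(fit_distribution(spec))
        units.append((name, samplers))
    return units


def run_psa(registry: Sequence[ParamSpec], table: ParameterTable, config: ModelConfig,
            n_draws: int = 10_000, seed: int = 0,
            wtp_grid: Optional[Sequence[float]] = None) -> PSAResult:
    """Probabilistic sensitivity analysis with CEAC.

    Each draw samples every samplable parameter, rebuilds both arms'
    transition rows from the sampled pooled rows and odds ratio (renormalizing
    each row to sum to 1), reruns both arms and records (ΔC, ΔE). With
    ``config.psa_arm_correlation == 'shared'`` the per-arm copies of
    quantities printed once for both arms receive a common draw. Identical
    seeds give identical draws.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    base_inputs = table.base_inputs()

    value_specs = [s for s in registry if s.psa_sampled and s.family != "transition"
                   and s.family != "or"]
    or_spec = next(s for s in registry if s.family == "or")
    shared_mode = config.psa_arm_correlation == "shared"

    # presample; draw order is fixed by registry order, so results are seed-stable
    draws_or = fit_distribution(or_spec).sample(rng, n_draws)
    trans_units = _transition_units(table)
    trans_draws = {name: np.column_stack([s.sample(rng, n_draws) for s in samplers])
                   for name, samplers in trans_units}
    shared_cache: dict[tuple, np.ndarray] = {}
    value_draws = []
    for spec in value_specs:
        if shared_mode and spec.shared_origin:
            key = (spec.family, spec.item, spec.state)
            if key not in shared_cache:
                shared_cache[key] = fit_distribution(spec).sample(rng, n_draws)
            value_draws.append(shared_cache[key])
        else:
            value_draws.append(fit_distribution(spec).sample(rng, n_draws))

    dc = np.empty(n_draws)
    de = np.empty(n_draws)
    n_resampled = 0
    for i in range(n_draws):
        ok = False
        attempts = 0
        while not ok:
            work = copy_inputs(base_inputs)
            work["or"] = float(draws_or[i]) if attempts == 0 else \
                float(fit_distribution(or_spec).sample(rng))
            rows = {}
            for name, samplers in trans_units:
                v = trans_draws[name][i] if attempts == 0 else \
                    np.array([s.sample(rng) for s in samplers])
                rows[name] = v
            valid = all(r.sum() > 0 for r in rows.values())
            if valid:
                work["pooled_first"] = rows["first"] / rows["first"].sum()
                sub = work["pooled_sub"].copy()
                sub[0] = rows["sub_nr"] / rows["sub_nr"].sum()
                sub[1] = rows["sub_r"] / rows["sub_r"].sum()
                work["pooled_sub"] = sub
                for k, spec in enumerate(value_specs):
                    v = value_draws[k][i] if attempts == 0 else \
                        float(fit_distribution(spec).sample(rng))
                    spec.apply(work, float(v))
                try:
                    r = run_base_case(table, config, work, base_inputs)
                    dc[i], de[i] = r.incremental_cost, r.incremental_qaly
                    ok = True
                except ValueError:
                    valid = False
            if not valid:
                attempts += 1
                n_resampled += 1
                if attempts > 100:
                    raise RuntimeError("PSA draw could not be made valid")

    if wtp_grid is None:
        wtp_grid = sorted(set(np.arange(0, 40_001, 500).tolist()
                              + [config.wtp_thresholds[0], config.wtp_thresholds[1]]))
    ceac = pd.DataFrame({
        "wtp": wtp_grid,
        "probability": [float(np.mean(w * de - dc > 0)) for w in wtp_grid],
    })
    wtp_high = config.wtp_thresholds[0]
    p_high = float(np.mean(wtp_high * de - dc > 0))
    return PSAResult(draws=pd.DataFrame({"dc": dc, "de": de}), ceac=ceac,
                     p_highly_ce=p_high, wtp_high=wtp_high,
                     n_resampled=n_resampled, seed=seed)


# ---------------------------------------------------------------------------
def run_scenario(name: str, table: ParameterTable, config: ModelConfig,
                 horizon_years: Optional[float] = None,
                 overrides: Optional[dict] = None) -> CEResult:
    """Named scenario analyses.

    ``time_horizon`` reruns the base case with only the horizon changed.
    ``one_year_tdm`` keeps TDM-guided care for the first two cycles (1 year)
    and then switches the TDM arm to the non-TDM transition matrix and
    adverse-event profile, dropping the TDM testing cost from its on-PER state
    costs, while retaining the state occupancy reached. ``override`` applies
    user-supplied ArmParameters (the vehicle for subgroup scenarios whose
    inputs are not published).
    """
    if name == "time_horizon":
        if horizon_years is None:
            raise ValueError("time_horizon scenario needs horizon_years")
        return run_base_case(table, config.replace(horizon_years=horizon_years))
    if name == "one_year_tdm":
        return _one_year_tdm(table, config)
    if name == "override":
        return _override_scenario(table, config, overrides)
    raise ValueError(f"unknown scenario: {name}")


def _one_year_tdm(table: ParameterTable, config: ModelConfig) -> CEResult:
    from .markov import _phase_matrices  # shared builder for phase matrices

    base = table.base_inputs()
    params = table.build_arm_parameters(base, config)
    pt, pn = params[Arm.TDM.value], params[Arm.NON_TDM.value]
    n = config.n_cycles
    if n < 2:
        raise ValueError("one_year_tdm needs a horizon of at least 1 year")
    # trace: TDM matrices for cycles 1-2, non-TDM subsequent matrix afterwards
    occ = np.zeros((n + 1, 4))
    occ[0, 0] = 1.0
    mt = _phase_matrices(pt.first_cycle_row, pt.subsequent_rows[0], pt.subsequent_rows[1])
    for t in range(1, n + 1):
        P = mt["first_cycle"] if t == 1 else (
            mt["subsequent"] if t == 2 else pn.subsequent_rows)
        occ[t] = occ[t - 1] @ P
    from .markov import CohortTrace
    trace = CohortTrace(occupancy=occ)
    K = n + 1 if config.include_initial_occupancy else n
    offset = 0 if config.include_initial_occupancy else 1
    late_cost = pt.state_cost.copy()
    for s in range(3):   # TDM testing no longer bought once TDM stops
        late_cost[s] = max(late_cost[s] - pt.tdm_cost_per_cycle, 0.0)
    cost_override = [pt.state_cost if (k + offset) <= 2 else late_cost for k in range(K)]
    ae_override = [pt.ae if (k + offset) <= 2 else pn.ae for k in range(K)]
    res_t = accumulate(trace, pt, config, cost_override=cost_override,
                       ae_override=ae_override)
    res_n = run_arm(pn, config)
    return icer(res_t.total_cost, res_t.total_qalys,
                res_n.total_cost, res_n.total_qalys, config.wtp_thresholds)


def _override_scenario(table: ParameterTable, config: ModelConfig,
                       overrides: Optional[dict]) -> CEResult:
    required = {"tdm", "nontdm"}
    if not overrides or not required <= set(overrides):
        missing = sorted(required - set(overrides or {}))
        raise ValueError(f"override scenario missing ArmParameters for: {missing}")
    res_t = run_arm(overrides["tdm"], config)
    res_n = run_arm(overrides["nontdm"], config)
    return icer(res_t.total_cost, res_t.total_qalys,
                res_n.total_cost, res_n.total_qalys, config.wtp_thresholds)
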