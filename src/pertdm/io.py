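"""Parameter tables, model-input assembly, patient-record CSV, config and
run manifests.

The packaged fixture ``data/parameters.csv`` transcribes the study's printed
input tables: one row per printed quantity with its sensitivity range where
one was printed. ``ParameterTable`` turns it into the nested model-input
mapping that the engine, the one-way sensitivity analysis and the PSA all
share, so a perturbed parameter flows through exactly one assembly path.

Costs are stored in USD-2022; the single RMB row (the TDM test price) is
converted at load time at the study exchange rate.
"""
from __future__ import annotations

import copy
import csv
import dataclasses
import datetime as _dt
import json
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .clinical import convert_currency
from .core import (AE_EVENTS, AdverseEventProfile, Arm, ArmParameters,
                   HealthState, ModelConfig, PatientRecord, STATE_NAMES)
from .markov import build_arm_matrices

ON_PER = STATE_NAMES[:3]
COMBO_DRUGS = ("LTG", "TPM", "LEV", "CLZ", "ZNS", "VPA", "CBZ",
               "XXP", "OXC", "LCS", "CLB", "VGB", "PB")

__all__ = ["ParameterTable", "load_parameter_tables", "load_reference_results",
           "read_patient_records", "write_patient_records", "load_config",
           "save_config", "RunManifest"]


def _fixture_path(name: str) -> Path:
    return Path(resources.files("pertdm.data") / name)


def load_reference_results(path: Optional[str] = None) -> pd.DataFrame:
    """Published result rows used only by the calibration report."""
    return pd.read_csv(path or _fixture_path("reference_results.csv"))


class ParameterTable:
    """The study's printed model inputs plus assembly into ``ArmParameters``."""

    def __init__(self, df: pd.DataFrame):
        self.df = df
        report = self.validate()
        errors = [r for r in report if r.startswith("error")]
        if errors:
            raise ValueError("parameter table invalid:\n" + "\n".join(errors))

    # -- loading ---------------------------------------------------------
    @classmethod
    def from_csv(cls, path: Optional[str] = None) -> "ParameterTable":
        df = pd.read_csv(path or _fixture_path("parameters.csv"),
                         dtype={"family": str, "item": str, "state": str, "arm": str})
        required = {"family", "item", "state", "arm", "value", "low", "high", "currency"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"parameter table missing columns: {sorted(missing)}")
        df["state"] = df["state"].fillna("")
        for col in ("value", "low", "high"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        rmb = df["currency"] == "RMB"
        for col in ("value", "low", "high"):
            df.loc[rmb, col] = df.loc[rmb, col].apply(
                lambda v: convert_currency(v) if pd.notna(v) else v)
        df.loc[rmb, "currency"] = "USD"
        return cls(df)

    def validate(self) -> list[str]:
        """Itemized validation report (strings prefixed 'error'/'warning')."""
        report = []
        df = self.df
        cost_like = {"state_cost_total", "hosp_cost_total", "outpatient_cost_total",
                     "per_cost", "other_asm_cost", "ae_cost", "consult_cost",
                     "test_cost", "exam_cost", "drug_price", "per_unit_price",
                     "hosp_daily_cost", "tdm_unit_cost"}
        for _, r in df.iterrows():
            ident = f"{r.family}/{r.item}/{r.state}/{r.arm}"
            if pd.isna(r.value):
                report.append(f"error: {ident}: missing value")
                continue
            if r.family in cost_like and r.value < 0:
                report.append(f"error: {ident}: negative cost {r.value}")
            if "prob" in r.family and not 0 <= r.value <= 1:
                report.append(f"error: {ident}: probability {r.value} outside [0,1]")
            if pd.notna(r.low) and pd.notna(r.high) and r.low > r.high:
                report.append(f"error: {ident}: inverted range ({r.low} > {r.high})")
            if pd.notna(r.low) and pd.notna(r.high) and not r.low <= r.value <= r.high:
                report.append(f"warning: {ident}: value outside its printed range")
        # transition rows must be stochastic
        first = self.pooled_first_row()
        if not np.isclose(first.sum(), 1.0, atol=1e-6):
            report.append(f"error: first-cycle transition row sums to {first.sum():.4f}")
        sub = self.pooled_subsequent_matrix()
        for i in (0, 1):
            if not np.isclose(sub[i].sum(), 1.0, atol=1e-6):
                report.append(f"error: subsequent {STATE_NAMES[i]} row sums to {sub[i].sum():.4f}")
        # hospitalization component identity vs printed totals (informational)
        for arm in (Arm.TDM, Arm.NON_TDM):
            for st in ON_PER:
                prod = 1.0
                for fam in ("hosp_prob", "hosp_number", "hosp_days", "hosp_daily_cost"):
                    prod *= self._one(fam, arm=arm.value, state=st)
                total = self._one("hosp_cost_total", arm=arm.value, state=st)
                rel = abs(prod - total) / total
                if rel > 0.01:
                    report.append(
                        f"warning: hospitalization identity off by {rel:.1%} for "
                        f"{arm.value}/{st}: {prod:.2f} vs printed {total:.2f}")
        return report

    # -- raw accessors ---------------------------------------------------
    def _rows(self, family: str, **keys) -> pd.DataFrame:
        m = self.df["family"] == family
        for k, v in keys.items():
            m &= self.df[k] == v
        return self.df[m]

    def _one(self, family: str, **keys) -> float:
        rows = self._rows(family, **keys)
        if len(rows) != 1:
            raise KeyError(f"expected one row for {family} {keys}, found {len(rows)}")
        return float(rows["value"].iloc[0])

    def _range(self, family: str, **keys):
        rows = self._rows(family, **keys)
        r = rows.iloc[0]
        lo = None if pd.isna(r.low) else float(r.low)
        hi = None if pd.isna(r.high) else float(r.high)
        return float(r.value), lo, hi

    def pooled_first_row(self) -> np.ndarray:
        out = np.zeros(4)
        for j, dest in enumerate(STATE_NAMES):
            out[j] = self._one("transition", item=f"first:no_response->{dest}")
        return out

    def pooled_subsequent_matrix(self) -> np.ndarray:
        m = np.zeros((4, 4))
        for i, frm in enumerate(("no_response", "response")):
            for j, dest in enumerate(STATE_NAMES):
                m[i, j] = self._one("transition", item=f"subsequent:{frm}->{dest}")
        m[2, 2] = self._one("transition", item="subsequent:seizure_free->seizure_free")
        m[3, 3] = 1.0
        return m

    @property
    def or_value(self) -> float:
        return self._one("or", item="seizure_reduction_vs_tdm")

    @property
    def tdm_test_cost_per_cycle(self) -> float:
        """Per-cycle TDM testing component implied by the printed state totals.

        Each TDM state total exceeds its printed components by exactly the
        USD price of one test; the printed per-cycle totals govern.
        """
        return self._one("tdm_unit_cost", item="per_test")

    # -- model inputs ----------------------------------------------------
    def base_inputs(self) -> dict:
        """Nested mapping of every model input at its printed base value."""
        inputs: dict = {
            "or": self.or_value,
            "pooled_first": self.pooled_first_row(),
            "pooled_sub": self.pooled_subsequent_matrix(),
            "transition_override": {},
        }
        for arm in (Arm.TDM.value, Arm.NON_TDM.value):
            a: dict = {}
            for fam, states in [("state_cost_total", STATE_NAMES),
                                ("outpatient_cost_total", STATE_NAMES),
                                ("outpatient_number", STATE_NAMES),
                                ("other_asm_cost", STATE_NAMES),
                                ("per_cost", ON_PER),
                                ("hosp_prob", ON_PER), ("hosp_number", ON_PER),
                                ("hosp_days", ON_PER), ("hosp_daily_cost", ON_PER)]:
                a[fam] = {st: self._one(fam, arm=arm, state=st) for st in states}
            a["consult_cost"] = {st: self._one("consult_cost", arm=arm, state=st)
                                 for st in ON_PER}
            # discontinued patients keep no-response outpatient usage
            a["consult_cost"]["discontinue"] = a["consult_cost"]["no_response"]
            a["test_cost"] = self._one("test_cost", arm="shared")
            a["exam_cost"] = self._one("exam_cost", arm="shared")
            a["utility"] = {st: self._one("utility", arm="shared", state=st)
                            for st in STATE_NAMES}
            a["ae_prob"] = {e: self._one("ae_prob", arm=arm, item=e) for e in AE_EVENTS}
            a["ae_cost"] = {e: self._one("ae_cost", arm="shared", item=e) for e in AE_EVENTS}
            a["ae_disutility"] = {e: self._one("ae_disutility", arm="shared", item=e)
                                  for e in AE_EVENTS}
            a["combo_prob"] = {(d, st): self._one("combo_prob", arm=arm, item=d, state=st)
                               for d in COMBO_DRUGS for st in ON_PER}
            a["drug_price"] = {d: self._one("drug_price", arm="shared", item=d)
                               for d in COMBO_DRUGS}
            a["per_unit_price"] = self._one("per_unit_price", item="PER")
            if arm == Arm.TDM.value:
                a["tdm_number"] = self._one("tdm_number", arm="tdm")
                a["tdm_unit_cost"] = self.tdm_test_cost_per_cycle
            inputs[arm] = a
        return inputs

    # -- assembly --------------------------------------------------------
    def build_matrices(self, inputs: dict, config: ModelConfig) -> dict:
        mats = build_arm_matrices(inputs["pooled_first"], inputs["pooled_sub"],
                                  inputs["or"], config)
        for (arm, phase, i, j), v in inputs["transition_override"].items():
            row = mats[arm][phase][i]
            v = min(max(v, 0.0), 1.0)
            rest = 1.0 - row[j]
            if rest > 0:
                scale = (1.0 - v) / rest
                for k in range(4):
                    if k != j:
                        row[k] *= scale
            else:  # perturbing an absorbing certainty: spread the remainder evenly
                for k in range(4):
                    if k != j:
                        row[k] = (1.0 - v) / 3.0
            row[j] = v
        return mats

    def effective_state_costs(self, inputs: dict, base: dict, arm: str) -> np.ndarray:
        """Per-state per-cycle cost: printed total plus component deltas.

        Perturbed components move the state cost by the change in their
        printed formula (hospitalization probability x number x days x daily
        cost; outpatient visits x unit costs; drug mix x unit prices; TDM
        tests x unit price), anchored so the printed totals hold at base.
        """
        a, b = inputs[arm], base[arm]
        out = np.zeros(4)
        for si, st in enumerate(STATE_NAMES):
            c = a["state_cost_total"][st] - b["state_cost_total"][st] \
                + b["state_cost_total"][st]
            c += a["outpatient_cost_total"][st] - b["outpatient_cost_total"][st]
            c += (a["outpatient_number"][st]
                  * (a["consult_cost"][st] + a["test_cost"] + a["exam_cost"])
                  - b["outpatient_number"][st]
                  * (b["consult_cost"][st] + b["test_cost"] + b["exam_cost"]))
            if st in ON_PER:
                hosp = lambda d: (d["hosp_prob"][st] * d["hosp_number"][st]
                                  * d["hosp_days"][st] * d["hosp_daily_cost"][st])
                c += hosp(a) - hosp(b)
                c += a["per_cost"][st] - b["per_cost"][st]
                c += b["per_cost"][st] * (a["per_unit_price"] / b["per_unit_price"] - 1.0)
                w_base = sum(b["combo_prob"][(d, st)] * b["drug_price"][d]
                             for d in COMBO_DRUGS)
                if w_base > 0:
                    w_now = sum(a["combo_prob"][(d, st)] * a["drug_price"][d]
                                for d in COMBO_DRUGS)
                    c += b["other_asm_cost"][st] * (w_now / w_base - 1.0)
                c += a["other_asm_cost"][st] - b["other_asm_cost"][st]
                if arm == Arm.TDM.value:
                    scale = (a["tdm_number"] * a["tdm_unit_cost"]
                             / (b["tdm_number"] * b["tdm_unit_cost"]))
                    c += self.tdm_test_cost_per_cycle * (scale - 1.0)
            out[si] = max(c, 0.0)
        return out

    def build_arm_parameters(self, inputs: dict, config: ModelConfig,
                             base: Optional[dict] = None) -> dict[str, ArmParameters]:
        base = base if base is not None else self.base_inputs()
        mats = self.build_matrices(inputs, config)
        params = {}
        for arm in (Arm.TDM, Arm.NON_TDM):
            a = inputs[arm.value]
            ae = AdverseEventProfile(
                probability={e: min(max(a["ae_prob"][e], 0.0), 1.0) for e in AE_EVENTS},
                cost={e: max(a["ae_cost"][e], 0.0) for e in AE_EVENTS},
                disutility={e: abs(a["ae_disutility"][e]) for e in AE_EVENTS})
            util = np.array([min(max(a["utility"][st], 0.0), 1.0) for st in STATE_NAMES])
            params[arm.value] = ArmParameters(
                arm=arm,
                first_cycle_row=mats[arm.value]["first_cycle"][0],
                subsequent_rows=mats[arm.value]["subsequent"],
                state_cost=self.effective_state_costs(inputs, base, arm.value),
                state_utility=util,
                ae=ae,
                tdm_cost_per_cycle=(self.tdm_test_cost_per_cycle
                                    if arm is Arm.TDM else 0.0),
            )
        return params


def load_parameter_tables(path: Optional[str] = None) -> ParameterTable:
    """Load (and validate) the packaged or a user-supplied parameter table."""
    return ParameterTable.from_csv(path)


# -- patient-record CSV ---------------------------------------------------
_COST_CATS = ("per", "other_asm", "tdm", "outpatient", "hospitalization")


def write_patient_records(records, path) -> None:
    cols = ["patient_id", "arm", "baseline_freq", "freq_6m", "freq_12m",
            "discontinued_cycle", "tdm_count"]
    cols += [f"cost{p}_{c}" for p in (1, 2) for c in _COST_CATS]
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(cols)
        for r in records:
            row = [r.patient_id, r.arm.value, r.baseline_freq,
                   "" if r.freq_6m is None else r.freq_6m,
                   "" if r.freq_12m is None else r.freq_12m,
                   "" if r.discontinued_cycle is None else r.discontinued_cycle,
                   r.tdm_count]
            for p in (1, 2):
                cats = r.period_costs.get(p, {})
                row += [cats.get(c, "") if cats else "" for c in _COST_CATS]
            w.writerow(row)


def read_patient_records(path):
    """Read the patient-record CSV; returns (records, row_error_report)."""
    records, errors = [], []
    df = pd.read_csv(path)
    for idx, r in df.iterrows():
        try:
            period_costs = {}
            for p in (1, 2):
                cats = {c: float(r[f"cost{p}_{c}"]) for c in _COST_CATS
                        if f"cost{p}_{c}" in df.columns and pd.notna(r[f"cost{p}_{c}"])}
                if cats:
                    period_costs[p] = cats
            rec = PatientRecord(
                patient_id=str(r["patient_id"]),
                arm=Arm(r["arm"]),
                baseline_freq=float(r["baseline_freq"]),
                freq_6m=None if pd.isna(r["freq_6m"]) else float(r["freq_6m"]),
                freq_12m=None if pd.isna(r["freq_12m"]) else float(r["freq_12m"]),
                discontinued_cycle=(None if pd.isna(r["discontinued_cycle"])
                                    else int(r["discontinued_cycle"])),
                period_costs=period_costs,
                tdm_count=int(r["tdm_count"]) if pd.notna(r["tdm_count"]) else 0,
            )
            problems = rec.validate()
            if problems:
                errors += [f"row {idx}: {p}" for p in problems]
            else:
                records.append(rec)
        except (ValueError, KeyError) as e:
            errors.append(f"row {idx}: {e}")
    return records, errors


# -- config and manifest --------------------------------------------------
def load_config(path: Optional[str] = None, **overrides) -> ModelConfig:
    cfg = {}
    if path:
        with open(path) as f:
            cfg = yaml.safe_load(f) or {}
    cfg.update(overrides)
    if "wtp_thresholds" in cfg:
        cfg["wtp_thresholds"] = tuple(cfg["wtp_thresholds"])
    if "ae_states" in cfg:
        cfg["ae_states"] = tuple(HealthState[s.upper()] if isinstance(s, str)
                                 else HealthState(s) for s in cfg["ae_states"])
    return ModelConfig(**cfg)


def save_config(config: ModelConfig, path) -> None:
    d = dataclasses.asdict(config)
    d["wtp_thresholds"] = list(config.wtp_thresholds)
    d["ae_states"] = [s.name.lower() for s in config.ae_states]
    with open(path, "w") as f:
        yaml.safe_dump(d, f, sort_keys=False)


@dataclasses.dataclass
class RunManifest:
    """Reproducibility record written once per pipeline run."""

    config: dict
    seed: Optional[int]
    calibration_mode: Optional[dict]
    outputs: list
    stages: dict
    timestamp: str = ""

    def __post_init__(self):
        if not self.timestamp:
            self.timestamp = _dt.datetime.now(_dt.timezone.utc).isoformat()

    def write(self, path) -> None:
        with open(path, "w") as f:
            json.dump(dataclasses.asdict(self), f, indent=2, default=str)

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as f:
            return cls(**json.load(f))


def copy_inputs(inputs: dict) -> dict:
    """Deep copy of a model-input mapping (perturbation working copy)."""
    return copy.deepcopy(inputs)
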