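"""Markov engine: OR-based row derivation, cohort trace, discounting and
reward accumulation."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pertdm import (Arm, ModelConfig, apply_or_adjustment, build_arm_matrices,
                    discount_factor, run_cohort, run_arm)
from pertdm.core import AdverseEventProfile, ArmParameters, HealthState
from pertdm.markov import _phase_matrices

PRINTED_FIRST = np.array([0.200, 0.267, 0.241, 0.292])
PRINTED_SUB = np.array([[0.708, 0.042, 0.000, 0.250],
                        [0.031, 0.875, 0.063, 0.031],
                        [0.0, 0.0, 1.0, 0.0],
                        [0.0, 0.0, 0.0, 1.0]])


def _simple_params(arm=Arm.TDM, cost=(100.0, 80.0, 50.0, 70.0),
                   util=(0.5, 0.6, 0.65, 0.5), ae_p=0.0,
                   first=PRINTED_FIRST, sub=PRINTED_SUB):
    ae = AdverseEventProfile(probability={"e": ae_p}, cost={"e": 100.0},
                             disutility={"e": 0.004})
    return ArmParameters(arm=arm, first_cycle_row=np.array(first),
                         subsequent_rows=np.array(sub),
                         state_cost=np.array(cost), state_utility=np.array(util),
                         ae=ae)


class TestOrAdjustment:
    @pytest.mark.parametrize("include_disc", [True, False])
    def test_or_one_is_identity(self, include_disc):
        row = PRINTED_FIRST
        out = apply_or_adjustment(row, 1.0, include_disc)
        assert np.allclose(out, row, atol=1e-15)

    def test_shift_direction_and_fixed_discontinue(self):
        out = apply_or_adjustment(PRINTED_FIRST, 0.461, include_discontinue=False)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        assert out[3] == pytest.approx(0.292)            # discontinue held fixed
        assert out[2] < PRINTED_FIRST[2]                  # seizure-free shrinks
        assert out[0] > PRINTED_FIRST[0]                  # no-response grows

    def test_four_category_shift_lowers_discontinue_for_favourable_or(self):
        out = apply_or_adjustment(PRINTED_FIRST, 1 / 0.461, include_discontinue=True)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        assert out[3] < PRINTED_FIRST[3]                  # discontinue is the worst state
        assert out[2] > PRINTED_FIRST[2]

    def test_closed_form_two_cut_system(self):
        """Conditional three-category shift agrees with direct odds algebra."""
        orv = 0.461
        out = apply_or_adjustment(PRINTED_FIRST, orv, include_discontinue=False)
        p = PRINTED_FIRST[:3] / PRINTED_FIRST[:3].sum()
        for j, q in enumerate([p[1] + p[2], p[2]]):
            odds = orv * q / (1 - q)
            want = odds / (1 + odds)
            got = out[:3].sum() and (out[2] if j == 1 else out[1] + out[2]) / out[:3].sum()
            assert got == pytest.approx(want, abs=1e-12)

    def test_vanishing_or_empties_top_category(self):
        out = apply_or_adjustment(PRINTED_FIRST, 1e-12, include_discontinue=False)
        assert out[2] == pytest.approx(0.0, abs=1e-9)

    def test_preserves_point_mass(self):
        row = np.array([0.0, 0.0, 1.0, 0.0])
        out = apply_or_adjustment(row, 0.3, include_discontinue=False)
        assert np.allclose(out, row)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            apply_or_adjustment(PRINTED_FIRST, -1.0)
        with pytest.raises(ValueError):
            apply_or_adjustment(np.array([0.5, 0.2, 0.2, 0.2]), 0.5)
        with pytest.raises(ValueError):
            apply_or_adjustment(np.array([0.0, 0.0, 0.0, 1.0]), 0.5,
                                include_discontinue=False)

    @given(orv=st.floats(0.05, 20.0),
           raw=st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4),
           inc=st.booleans())
    @settings(max_examples=150, derandomize=True)
    def test_rows_stay_stochastic_and_invert(self, orv, raw, inc):
        row = np.array(raw) / np.sum(raw)
        out = apply_or_adjustment(row, orv, inc)
        assert np.all(out >= -1e-12)
        assert out.sum() == pytest.approx(1.0, abs=1e-9)
        back = apply_or_adjustment(out, 1.0 / orv, inc)
        assert np.allclose(back, row, atol=1e-9)


class TestBuildArmMatrices:
    def test_printed_rows_are_stochastic(self):
        assert PRINTED_FIRST.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(PRINTED_SUB.sum(axis=1), 1.0, atol=1e-12)

    @pytest.mark.parametrize("mode,holder", [
        ("printed_is_tdm", "tdm"), ("printed_is_nontdm", "nontdm")])
    def test_printed_arm_keeps_printed_rows(self, mode, holder):
        cfg = ModelConfig(or_mode=mode)
        mats = build_arm_matrices(PRINTED_FIRST, PRINTED_SUB, 0.461, cfg)
        assert np.allclose(mats[holder]["first_cycle"][0], PRINTED_FIRST)
        other = "nontdm" if holder == "tdm" else "tdm"
        assert not np.allclose(mats[other]["first_cycle"][0], PRINTED_FIRST)

    @pytest.mark.parametrize("mode", ["printed_is_tdm", "printed_is_nontdm",
                                      "printed_is_pooled"])
    @pytest.mark.parametrize("scope", ["first_cycle", "all_phases"])
    def test_absorbing_rows_are_unit_vectors(self, mode, scope):
        cfg = ModelConfig(or_mode=mode, or_scope=scope)
        mats = build_arm_matrices(PRINTED_FIRST, PRINTED_SUB, 0.461, cfg)
        for arm in ("tdm", "nontdm"):
            for phase in ("first_cycle", "subsequent"):
                P = mats[arm][phase]
                assert np.allclose(P[2], [0, 0, 1, 0])
                assert np.allclose(P[3], [0, 0, 0, 1])
                assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_or_one_makes_arms_identical(self):
        cfg = ModelConfig(or_mode="printed_is_tdm", or_scope="all_phases")
        mats = build_arm_matrices(PRINTED_FIRST, PRINTED_SUB, 1.0, cfg)
        for phase in ("first_cycle", "subsequent"):
            assert np.allclose(mats["tdm"][phase], mats["nontdm"][phase])

    def test_derived_nontdm_has_lower_longrun_seizure_freedom(self):
        cfg = ModelConfig(or_mode="printed_is_tdm", or_scope="all_phases",
                          horizon_years=15)
        mats = build_arm_matrices(PRINTED_FIRST, PRINTED_SUB, 0.461, cfg)
        sf = {}
        for arm in ("tdm", "nontdm"):
            trace = run_cohort(mats[arm], cfg)
            sf[arm] = trace.occupancy[-1, int(HealthState.SEIZURE_FREE)]
        assert sf["nontdm"] < sf["tdm"]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            build_arm_matrices(PRINTED_FIRST, PRINTED_SUB, 0.461,
                               ModelConfig(or_mode="nope"))


class TestRunCohort:
    def test_identity_matrices_freeze_occupancy(self):
        cfg = ModelConfig()
        mats = {"first_cycle": np.eye(4), "subsequent": np.eye(4)}
        trace = run_cohort(mats, cfg)
        assert np.allclose(trace.occupancy, np.tile([1, 0, 0, 0], (31, 1)))

    def test_first_cycle_occupancy_equals_printed_row(self):
        cfg = ModelConfig()
        mats = _phase_matrices(PRINTED_FIRST, PRINTED_SUB[0], PRINTED_SUB[1])
        trace = run_cohort(mats, cfg)
        assert np.allclose(trace.occupancy[1], PRINTED_FIRST)

    def test_engine_equals_hand_matrix_product(self):
        """Three-cycle trace equals the explicit matrix-product oracle, 1e-12."""
        cfg = ModelConfig(horizon_years=1.5)
        mats = _phase_matrices(PRINTED_FIRST, PRINTED_SUB[0], PRINTED_SUB[1])
        trace = run_cohort(mats, cfg)
        e0 = np.array([1.0, 0, 0, 0])
        P1, P2 = mats["first_cycle"], mats["subsequent"]
        assert np.allclose(trace.occupancy[1], e0 @ P1, atol=1e-12)
        assert np.allclose(trace.occupancy[2], e0 @ P1 @ P2, atol=1e-12)
        assert np.allclose(trace.occupancy[3], e0 @ P1 @ P2 @ P2, atol=1e-12)

    def test_conservation_on_1000_random_stochastic_matrices(self):
        rng = np.random.default_rng(42)
        cfg = ModelConfig(horizon_years=5)
        for _ in range(1000):
            P1 = rng.dirichlet(np.ones(4), size=4)
            P2 = rng.dirichlet(np.ones(4), size=4)
            trace = run_cohort({"first_cycle": P1, "subsequent": P2}, cfg)
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(trace.occupancy >= -1e-12)

    def test_absorption_monotonicity_under_study_matrices(self):
        cfg = ModelConfig()
        mats = _phase_matrices(PRINTED_FIRST, PRINTED_SUB[0], PRINTED_SUB[1])
        occ = run_cohort(mats, cfg).occupancy
        absorbed = occ[:, 2] + occ[:, 3]
        assert np.all(np.diff(absorbed) >= -1e-12)

    def test_non_stochastic_matrix_rejected(self):
        bad = np.eye(4) * 0.9
        with pytest.raises(ValueError):
            run_cohort({"first_cycle": bad, "subsequent": np.eye(4)}, ModelConfig())


class TestDiscounting:
    def test_examples(self):
        assert discount_factor(1, 0.05, 0.5) == 1.0
        assert discount_factor(3, 0.05, 0.5) == pytest.approx(1 / 1.05)
        assert discount_factor(7, 0.0, 0.5) == 1.0
        # per-cycle compounding treats each cycle as a full year
        assert discount_factor(3, 0.05, 0.5, per_cycle=True) == pytest.approx(1.05 ** -2)

    def test_rejects_negative_rate(self):
        with pytest.raises(ValueError):
            discount_factor(1, -0.01, 0.5)

    def test_discount_monotonicity_in_rate(self):
        p = _simple_params()
        results = []
        for rate in (0.0, 0.03, 0.08):
            cfg = ModelConfig(cost_discount_rate=rate, effect_discount_rate=rate)
            results.append(run_arm(p, cfg))
        costs = [r.total_cost for r in results]
        qalys = [r.total_qalys for r in results]
        assert costs == sorted(costs, reverse=True)
        assert qalys == sorted(qalys, reverse=True)


class TestAccumulate:
    def test_single_cycle_all_seizure_free_textbook_accounting(self):
        """One undiscounted half-year in the seizure-free state: 0.65 x 0.5 QALY."""
        cfg = ModelConfig(horizon_years=0.5, cost_discount_rate=0.0,
                          effect_discount_rate=0.0, include_initial_occupancy=False,
                          utility_full_cycle=False, discount_per_cycle=False)
        p = _simple_params(first=np.array([0.0, 0.0, 1.0, 0.0]),
                           cost=(0.0, 0.0, 200.0, 0.0))
        r = run_arm(p, cfg)
        assert r.total_qalys == pytest.approx(0.65 * 0.5)
        assert r.total_cost == pytest.approx(200.0)

    def test_zero_costs_and_utilities_give_zero_totals(self):
        p = _simple_params(cost=(0, 0, 0, 0), util=(0, 0, 0, 0))
        r = run_arm(p, ModelConfig())
        assert r.total_cost == 0.0
        assert r.total_qalys == 0.0

    def test_totals_equal_per_cycle_sums(self):
        r = run_arm(_simple_params(ae_p=0.1), ModelConfig())
        assert r.total_cost == pytest.approx(r.cycle_costs.sum(), abs=1e-9)
        assert r.total_qalys == pytest.approx(r.cycle_qalys.sum(), abs=1e-9)

    def test_adverse_events_add_cost_and_remove_qalys(self):
        base = run_arm(_simple_params(ae_p=0.0), ModelConfig())
        worse = run_arm(_simple_params(ae_p=0.2), ModelConfig())
        assert worse.total_cost > base.total_cost
        assert worse.total_qalys < base.total_qalys

    def test_ae_exposure_excludes_discontinued(self):
        """With everyone discontinued immediately, the AE layer contributes nothing."""
        first = np.array([0.0, 0.0, 0.0, 1.0])
        with_ae = run_arm(_simple_params(first=first, ae_p=0.5), ModelConfig(
            include_initial_occupancy=False))
        without = run_arm(_simple_params(first=first, ae_p=0.0), ModelConfig(
            include_initial_occupancy=False))
        assert with_ae.total_cost == pytest.approx(without.total_cost)

    def test_invalid_utilities_rejected(self):
        p = _simple_params(util=(0.5, 0.6, 1.2, 0.5))
        with pytest.raises(ValueError):
            run_arm(p, ModelConfig())

    def test_half_cycle_correction_averages_neighbours(self):
        cfg = ModelConfig(half_cycle_correction=True, horizon_years=1.0,
                          cost_discount_rate=0.0, effect_discount_rate=0.0,
                          utility_full_cycle=False, discount_per_cycle=False)
        p = _simple_params(ae_p=0.0)
        mats = _phase_matrices(p.first_cycle_row, p.subsequent_rows[0],
                               p.subsequent_rows[1])
        occ = run_cohort(mats, cfg).occupancy
        want_q = sum(0.5 * (occ[t - 1] + occ[t]) @ p.state_utility * 0.5
                     for t in (1, 2))
        want_c = sum(0.5 * (occ[t - 1] + occ[t]) @ p.state_cost for t in (1, 2))
        r = run_arm(p, cfg)
        assert r.total_qalys == pytest.approx(want_q, abs=1e-12)
        assert r.total_cost == pytest.approx(want_c, abs=1e-9)
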