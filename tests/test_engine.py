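"""Cohort engine: kernels, conservation, closed forms, cross-checks."""

import dataclasses

import numpy as np
import pytest

from cardiocea.engine import (
    ARMS,
    DEATH_IDX,
    RISK_BEARING,
    STRATA,
    RunConfig,
    build_kernel,
    default_strategies,
    run_cohort,
    total_outcomes,
)
from cardiocea.fixtures import LifeTable, synth_life_table
from cardiocea.parameters import apply_relative_effect
from cardiocea.state_space import PceRisk, PrsGroup

EVENT_RISK_PARAMS = [
    "risk_cad_high_pce",
    "risk_cad_moderate_pce",
    "risk_cad_after_ischemic_stroke",
    "risk_ischemic_stroke",
    "risk_ischemic_stroke_after_cad",
    "risk_ischemic_stroke_post_hemorrhagic",
    "risk_myopathy",
    "risk_statin_diabetes",
    "risk_statin_hemorrhagic_stroke",
]


def _zero_events(ps):
    out = ps
    for name in EVENT_RISK_PARAMS:
        out = out.with_value(name, 0.0)
    return out


def _micro_index(pce, prs, cond_tag):
    # flat micro-state index used by the kernel
    s = STRATA.index((pce, prs))
    from cardiocea.engine import COND_STATES, N_CSTATE
    from cardiocea.state_space import Condition

    tags = {
        "event_free": frozenset(),
        "cad": frozenset({Condition.CAD}),
        "ischemic_stroke": frozenset({Condition.ISCHEMIC_STROKE}),
    }
    return s * N_CSTATE + COND_STATES.index(tags[cond_tag])


def test_kernel_rows_stochastic_for_all_strategies_arms_cycles(ps, lt, strategies):
    for strat in strategies.values():
        for arm in ARMS:
            for cycle in (0, 4):
                kernel = build_kernel(strat, ps, lt, cycle, arm=arm)
                kernel.validate(atol=1e-9)  # raises on failure
                assert kernel.matrix.sum(axis=1) == pytest.approx(
                    np.ones(kernel.matrix.shape[0]), abs=1e-9
                )


def test_treated_high_pce_high_prs_cad_probability_composition(ps, lt, strategies):
    # documented composition: direct 1.9-fold PRS multiplier, then the
    # statin hazard ratio -> annual risk ~0.0236 before case fatality
    expected_p = apply_relative_effect(
        apply_relative_effect(0.022, 1.9, "direct"), 0.560, "hazard"
    )
    assert expected_p == pytest.approx(0.0236, abs=5e-5)
    kernel = build_kernel(strategies["CardioriskSCORE"], ps, lt, 0, arm="adherent")
    src = _micro_index(PceRisk.HIGH, PrsGroup.HIGH, "event_free")
    dst = _micro_index(PceRisk.HIGH, PrsGroup.HIGH, "cad")
    cf = ps.value("mort_acute_cad")
    assert kernel.matrix[src, dst] == pytest.approx(expected_p * (1 - cf), rel=1e-9)


def test_non_risk_bearing_strata_accrue_no_events(ps, lt, strategies):
    kernel = build_kernel(strategies["NoWHP"], ps, lt, 0, arm="unenrolled")
    src = _micro_index(PceRisk.LOW, PrsGroup.LOW, "event_free")
    row = kernel.matrix[src]
    q = lt.q(50)
    assert row[src] == pytest.approx(1 - q)
    assert row[DEATH_IDX] == pytest.approx(q)
    assert np.count_nonzero(row) == 2


def test_cohort_mass_conserved_and_death_monotone(base_traces):
    for trace in base_traces.values():
        sums = trace.occupancy.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)
        death = trace.occupancy[:, -1, 0]
        assert np.all(np.diff(death) >= -1e-15)


def test_event_free_cohort_closed_form_under_start_accrual(ps, strategies):
    # with all event risks zero and (near) zero background mortality the
    # start-of-cycle accrual has the closed form sum (1 - 0.004 t) / 1.03^t
    quiet = _zero_events(ps)
    lt = LifeTable(start_age=50, qx=np.full(30, 1e-12))
    trace = run_cohort(
        strategies["NoWHP"], quiet, lt, config=RunConfig(cycle_correction="none")
    )
    expected = sum((1 - 0.004 * t) / 1.03**t for t in range(5))
    assert trace.total_qalys == pytest.approx(expected, abs=1e-9)


def test_survival_matches_life_table_product_when_event_free(ps, lt, strategies):
    quiet = _zero_events(ps)
    trace = run_cohort(strategies["NoWHP"], quiet, lt)
    alive = 1.0 - trace.occupancy[:, -1, 0]
    expected = np.concatenate([[1.0], np.cumprod(1.0 - lt.qx[:5])])
    assert np.allclose(alive, expected, atol=1e-12)


def test_stronger_statin_effect_never_reduces_qalys(ps, lt, strategies):
    base = run_cohort(strategies["CardioriskSCORE"], ps, lt).total_qalys
    stronger = run_cohort(
        strategies["CardioriskSCORE"], ps.with_value("statin_hr_cad", 0.40), lt
    ).total_qalys
    weaker = run_cohort(
        strategies["CardioriskSCORE"], ps.with_value("statin_hr_cad", 0.78), lt
    ).total_qalys
    assert stronger >= base >= weaker


def test_zero_adherence_collapses_clinical_dynamics_to_no_program(ps, lt, strategies):
    numb = ps.with_value("statin_adherence", 0.0)
    cardio = run_cohort(strategies["CardioriskSCORE"], numb, lt)
    std = run_cohort(strategies["StandardWHP"], numb, lt)
    nowhp = run_cohort(strategies["NoWHP"], numb, lt)
    # nobody is treated, so occupancy and QALYs coincide across strategies
    assert np.allclose(cardio.occupancy, nowhp.occupancy, atol=1e-12)
    assert np.allclose(cardio.occupancy, std.occupancy, atol=1e-12)
    assert cardio.total_qalys == pytest.approx(nowhp.total_qalys, abs=1e-12)
    # program costs still differ (screening continues without initiation)
    assert cardio.total_cost > nowhp.total_cost


def test_zero_costs_give_zero_total_cost(ps, lt, strategies):
    free = ps
    for spec in ps:
        if spec.role == "cost":
            free = free.with_value(spec.name, 0.0)
    trace = run_cohort(strategies["NoWHP"], free, lt)
    assert trace.total_cost == pytest.approx(0.0, abs=1e-12)


def test_matrix_propagation_agrees_with_flux_engine(ps, lt, strategies):
    """Independent route: propagate each arm's occupancy through the dense
    kernel matrices and compare against the engine's flux bookkeeping."""
    from cardiocea.engine import COND_STATES, N_CSTATE, N_FLAT, _arm_weights, _initial_shares

    strat = strategies["CardioriskSCORE"]
    cfg = RunConfig()
    weights = _arm_weights(strat, ps)
    shares = _initial_shares(ps, cfg)
    occ = np.zeros(N_FLAT)
    horizon = 5
    totals = np.zeros((horizon + 1, N_FLAT))
    for arm in ARMS:
        occ = np.zeros(N_FLAT)
        for s in range(6):
            occ[s * N_CSTATE] = float(weights[arm]) * float(shares[s])
        for t in range(horizon + 1):
            totals[t] += occ
            if t < horizon:
                occ = occ @ build_kernel(strat, ps, lt, t, arm=arm).matrix
    trace = run_cohort(strat, ps, lt)
    # compare on the aggregated 22-state view
    death = totals[:, DEATH_IDX]
    assert np.allclose(death, trace.occupancy[:, -1, 0], atol=1e-12)
    alive = totals[:, :DEATH_IDX].sum(axis=1)
    assert np.allclose(alive + death, 1.0, atol=1e-9)
    assert np.allclose(
        trace.occupancy[:, :, 0].sum(axis=1), 1.0, atol=1e-9
    )
    # event-free occupancy per stratum matches exactly
    for s in range(6):
        assert np.allclose(
            totals[:, s * N_CSTATE], trace.occupancy[:, s, 0], atol=1e-12
        )


def test_both_cost_normalizations_are_emitted(base_traces, ps):
    cardio = base_traces["CardioriskSCORE"]
    per_member = cardio.total_cost
    per_enrolled = cardio.total_cost_per_enrolled()
    assert per_enrolled == pytest.approx(per_member / ps.value("enrollment"))
    with pytest.raises(ValueError):
        base_traces["NoWHP"].total_cost_per_enrolled()


def test_horizon_must_be_positive(ps, lt, strategies):
    with pytest.raises(ValueError):
        run_cohort(strategies["NoWHP"], ps, lt, horizon=0)


def test_trace_export_covers_all_states_and_cycles(base_traces):
    frame = base_traces["NoWHP"].occupancy_frame()
    assert len(frame) == 6 * 22
    assert frame.groupby("cycle")["occupancy"].sum().round(9).eq(1.0).all()


def test_vectorized_run_matches_scalar_runs(ps, lt, strategies):
    """Broadcasting over draws must equal independent scalar runs."""
    import dataclasses as dc

    values = [0.45, 0.56, 0.70]
    batched = ps.with_value("statin_hr_cad", np.array(values))
    tr = run_cohort(strategies["CardioriskSCORE"], batched, lt)
    for i, v in enumerate(values):
        single = run_cohort(strategies["CardioriskSCORE"], ps.with_value("statin_hr_cad", v), lt)
        assert tr.total_cost[i] == pytest.approx(single.total_cost, rel=1e-12)
        assert tr.total_qalys[i] == pytest.approx(single.total_qalys, rel=1e-12)
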