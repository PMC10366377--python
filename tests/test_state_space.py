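"""State space: enumeration, utilities and cost schedules."""

import json
from itertools import combinations

import pytest

from cardiocea.state_space import (
    Condition,
    HealthState,
    PhaseContext,
    build_state_space,
    state_cost,
    state_space_json,
    state_utility,
)

CAD = Condition.CAD
IS = Condition.ISCHEMIC_STROKE
DM = Condition.DIABETES


@pytest.fixture(scope="module")
def states():
    return build_state_space()


def _by_conds(states, *conds):
    want = frozenset(conds)
    for s in states:
        if not s.is_death and s.conditions == want and (want or s.risk_stratum is None):
            return s
    # event-free states carry strata; return the first one for empty conds
    return next(s for s in states if s.is_event_free)


def test_state_space_counts(states):
    assert len(states) == 22
    assert sum(1 for s in states if s.is_event_free) == 6
    assert sum(1 for s in states if len(s.conditions) == 1) == 5
    assert sum(1 for s in states if len(s.conditions) == 2) == 10
    assert sum(1 for s in states if s.is_death) == 1
    assert len({s.id for s in states}) == 22
    # the ten comorbid states are exactly the unordered condition pairs
    pairs = {s.conditions for s in states if len(s.conditions) == 2}
    assert pairs == {frozenset(p) for p in combinations(Condition, 2)}


def test_states_reject_more_than_two_conditions():
    with pytest.raises(ValueError):
        HealthState(id="bad", conditions=frozenset({CAD, IS, DM}))


def test_utilities_match_weights_and_combine_multiplicatively(states, ps):
    chronic = PhaseContext.chronic()
    death = next(s for s in states if s.is_death)
    assert state_utility(death, chronic, ps, 0) == 0.0
    cad = _by_conds(states, CAD)
    assert state_utility(cad, chronic, ps, 0) == pytest.approx(0.790)
    cad_dm = _by_conds(states, CAD, DM)
    assert state_utility(cad_dm, chronic, ps, 0) == pytest.approx(0.790 * 0.800)
    # acute entry disutility and aging decrement
    assert state_utility(cad, PhaseContext.entering(CAD), ps, 0) == pytest.approx(
        0.790 - 0.041
    )
    ef = next(s for s in states if s.is_event_free)
    assert state_utility(ef, chronic, ps, 3) == pytest.approx(1 - 0.004 * 3)


def test_comorbid_utility_never_exceeds_component_utilities(states, ps):
    chronic = PhaseContext.chronic()
    singles = {
        next(iter(s.conditions)): state_utility(s, chronic, ps, 0)
        for s in states
        if len(s.conditions) == 1
    }
    for s in states:
        if len(s.conditions) == 2:
            u = state_utility(s, chronic, ps, 0)
            assert u <= min(singles[c] for c in s.conditions) + 1e-12


def test_all_utilities_bounded_over_horizon(states, ps):
    for s in states:
        for cycle in range(6):
            for ctx in (PhaseContext.chronic(), PhaseContext(frozenset(s.conditions))):
                u = state_utility(s, ctx, ps, cycle)
                assert 0.0 <= u <= 1.0


def test_event_free_cost_is_background_only_without_program(states, ps):
    ef = next(s for s in states if s.is_event_free)
    assert state_cost(ef, PhaseContext.chronic(), None, ps, 0) == pytest.approx(4941)


def test_cad_entry_costs_split_by_survival(states, ps):
    cad = _by_conds(states, CAD)
    ctx = PhaseContext.entering(CAD)
    survivor = state_cost(cad, ctx, None, ps, 0, died_this_cycle=False, components=True)
    assert survivor["productivity"] == pytest.approx(73_492)
    assert survivor["medical"] == pytest.approx(65_442)
    fatal = state_cost(cad, ctx, None, ps, 0, died_this_cycle=True, components=True)
    assert fatal["medical"] == pytest.approx(18_246)
    assert fatal["productivity"] == 0.0


def test_death_state_accrues_nothing(states, ps):
    death = next(s for s in states if s.is_death)
    assert state_cost(death, PhaseContext.chronic(), None, ps, 3) == 0.0


def test_cost_ledger_components_sum_to_total(states, ps):
    for s in states:
        for entered in (frozenset(), frozenset(s.conditions)):
            ctx = PhaseContext(entered)
            parts = state_cost(s, ctx, None, ps, 2, components=True)
            total = state_cost(s, ctx, None, ps, 2)
            assert total == pytest.approx(sum(parts.values()))


def test_followup_costs_are_additive_over_pair(states, ps):
    chronic = PhaseContext.chronic()
    cad_dm = _by_conds(states, CAD, DM)
    parts = state_cost(cad_dm, chronic, None, ps, 1, components=True)
    assert parts["medical"] == pytest.approx(11_815 + 10_026)
    assert parts["productivity"] == pytest.approx(9_056 + 9_242)


def test_state_space_json_dump_is_complete():
    dump = json.loads(state_space_json())
    assert len(dump) == 22
    assert {d["id"] for d in dump} == {s.id for s in build_state_space()}
    death = next(d for d in dump if d["is_death"])
    assert death["conditions"] == []
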