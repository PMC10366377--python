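"""The 22-state health-state space and its reward (utility, cost) schedules.

The cohort moves between mutually exclusive health states on an annual
cycle:

* 6 event-free states: {low, moderate, high} 10-year pooled-cohort-equation
  (PCE) risk crossed with {bottom-80%, top-20%} of the coronary-artery-
  disease polygenic risk score (CAD-PRS) distribution;
* 5 single-condition states: CAD, ischemic stroke, hemorrhagic stroke,
  statin-induced diabetes, statin-induced myopathy;
* 10 comorbid states: every unordered pair of the five conditions (a cohort
  fraction never carries more than two conditions -- one that would acquire
  a third stays where it is);
* 1 absorbing death state.

A condition's *acute* (entry-cycle) parameters -- case fatality, acute event
cost, acute disutility, first-year lost productivity -- apply only in the
cycle the condition is entered; follow-up parameters apply in every later
cycle.  Entry-cycle handling is carried by :class:`PhaseContext` rather than
by expanding the nominal 22-state space with tunnel states.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import FrozenSet, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Condition",
    "PceRisk",
    "PrsGroup",
    "HealthState",
    "PhaseContext",
    "build_state_space",
    "state_utility",
    "state_cost",
    "condition_utility",
    "acute_disutility",
    "followup_medical_cost",
    "followup_productivity_cost",
    "state_space_json",
]


class Condition(enum.Enum):
    CAD = "CAD"
    ISCHEMIC_STROKE = "ISCHEMIC_STROKE"
    HEMORRHAGIC_STROKE = "HEMORRHAGIC_STROKE"
    DIABETES = "DIABETES"
    MYOPATHY = "MYOPATHY"

    def __lt__(self, other: "Condition") -> bool:
        order = list(Condition)
        return order.index(self) < order.index(other)


class PceRisk(enum.Enum):
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"


class PrsGroup(enum.Enum):
    LOW = "bottom80"
    HIGH = "top20"


STROKES = frozenset({Condition.ISCHEMIC_STROKE, Condition.HEMORRHAGIC_STROKE})


@dataclass(frozen=True)
class HealthState:
    """One of the 22 nominal model states.

    ``risk_stratum`` is populated for the six event-free states; condition
    states are reported in aggregate over strata (the engine internally
    tracks the stratum a condition-state fraction came from, because
    residual event risks in the diabetes/myopathy states still depend on
    it).
    """

    id: str
    conditions: FrozenSet[Condition] = frozenset()
    risk_stratum: Optional[Tuple[PceRisk, PrsGroup]] = None
    is_death: bool = False

    def __post_init__(self) -> None:
        if len(self.conditions) > 2:
            raise ValueError("states carry at most two conditions")
        if self.is_death and (self.conditions or self.risk_stratum):
            raise ValueError("death carries no conditions or stratum")

    @property
    def is_event_free(self) -> bool:
        return not self.is_death and not self.conditions


def _cond_id(conds: FrozenSet[Condition]) -> str:
    short = {
        Condition.CAD: "cad",
        Condition.ISCHEMIC_STROKE: "ischemic_stroke",
        Condition.HEMORRHAGIC_STROKE: "hemorrhagic_stroke",
        Condition.DIABETES: "diabetes",
        Condition.MYOPATHY: "myopathy",
    }
    return "+".join(short[c] for c in sorted(conds))


def build_state_space() -> list[HealthState]:
    """The 22 states in canonical order: 6 event-free strata (PCE major,
    PRS minor), 5 single conditions, the C(5,2)=10 pairs in lexicographic
    condition order, then death."""
    states: list[HealthState] = []
    for pce in PceRisk:
        for prs in PrsGroup:
            states.append(
                HealthState(
                    id=f"event_free_{pce.value}_pce_{prs.value}_prs",
                    risk_stratum=(pce, prs),
                )
            )
    for cond in Condition:
        states.append(HealthState(id=_cond_id(frozenset({cond})), conditions=frozenset({cond})))
    for pair in combinations(Condition, 2):
        states.append(HealthState(id=_cond_id(frozenset(pair)), conditions=frozenset(pair)))
    states.append(HealthState(id="death", is_death=True))
    assert len(states) == 22
    return states


@dataclass(frozen=True)
class PhaseContext:
    """Which conditions were entered this cycle (acute phase)."""

    entered: FrozenSet[Condition] = frozenset()

    @classmethod
    def chronic(cls) -> "PhaseContext":
        return cls(frozenset())

    @classmethod
    def entering(cls, *conds: Condition) -> "PhaseContext":
        return cls(frozenset(conds))


# ---------------------------------------------------------------------------
# Utilities
# ---------------------------------------------------------------------------

_UTILITY_PARAM = {
    Condition.CAD: "u_cad",
    Condition.ISCHEMIC_STROKE: "u_stroke",
    Condition.HEMORRHAGIC_STROKE: "u_stroke",
    Condition.DIABETES: "u_diabetes",
    Condition.MYOPATHY: "u_myopathy",
}


def condition_utility(conds: FrozenSet[Condition], ps) -> float:
    """Multiplicative combination of the condition utility weights
    (1 for the event-free state)."""
    u = 1.0
    for c in conds:
        u = u * ps.value(_UTILITY_PARAM[c])
    return u


def acute_disutility(cond: Condition, ps):
    if cond is Condition.CAD:
        return ps.value("du_acute_cad")
    if cond in STROKES:
        return ps.value("du_acute_stroke")
    return 0.0


def state_utility(state: HealthState, ctx: PhaseContext, ps, cycle: int):
    """Utility weight of a state in a given cycle.

    Death is 0.  Alive states take the product of their condition weights,
    minus acute-event disutility for conditions entered this cycle, minus
    the cumulative aging decrement (annual decrement x elapsed years),
    floored at 0.
    """
    if state.is_death:
        return 0.0
    u = condition_utility(state.conditions, ps)
    for c in ctx.entered:
        u = u - acute_disutility(c, ps)
    u = u - ps.value("du_age_annual") * cycle
    return np.maximum(u, 0.0)


# ---------------------------------------------------------------------------
# Costs
# ---------------------------------------------------------------------------

_FOLLOWUP_MEDICAL = {
    Condition.CAD: "cost_followup_cad",
    Condition.ISCHEMIC_STROKE: "cost_followup_stroke",
    Condition.HEMORRHAGIC_STROKE: "cost_followup_stroke",
    Condition.DIABETES: "cost_followup_diabetes",
    Condition.MYOPATHY: "cost_followup_myopathy",
}

_ACUTE_COST = {
    Condition.CAD: ("cost_acute_cad_nonfatal", "cost_acute_cad_fatal"),
    Condition.ISCHEMIC_STROKE: (
        "cost_acute_ischemic_stroke_nonfatal",
        "cost_acute_ischemic_stroke_fatal",
    ),
    Condition.HEMORRHAGIC_STROKE: (
        "cost_acute_hemorrhagic_stroke_nonfatal",
        "cost_acute_hemorrhagic_stroke_fatal",
    ),
}

_FOLLOWUP_PRODUCTIVITY = {
    Condition.CAD: "cost_productivity_followup_cad_stroke",
    Condition.ISCHEMIC_STROKE: "cost_productivity_followup_cad_stroke",
    Condition.HEMORRHAGIC_STROKE: "cost_productivity_followup_cad_stroke",
    Condition.DIABETES: "cost_productivity_diabetes",
    Condition.MYOPATHY: "cost_productivity_followup_myopathy",
}


def followup_medical_cost(conds: FrozenSet[Condition], ps):
    """Annual follow-up treatment cost, additive over conditions."""
    return sum(ps.value(_FOLLOWUP_MEDICAL[c]) for c in conds) if conds else 0.0


def followup_productivity_cost(conds: FrozenSet[Condition], ps):
    """Annual absenteeism + presenteeism loss, additive over conditions."""
    return sum(ps.value(_FOLLOWUP_PRODUCTIVITY[c]) for c in conds) if conds else 0.0


def acute_medical_cost(cond: Condition, ps, died_this_cycle: bool):
    """Acute event treatment cost (fatal or non-fatal variant)."""
    if cond not in _ACUTE_COST:
        # diabetes/myopathy have no acute cost variant; their follow-up cost
        # applies from the entry cycle
        return ps.value(_FOLLOWUP_MEDICAL[cond])
    nonfatal, fatal = _ACUTE_COST[cond]
    return ps.value(fatal) if died_this_cycle else ps.value(nonfatal)


def entry_productivity_cost(cond: Condition, ps, died_this_cycle: bool):
    """Lost productivity in the year of diagnosis (survivors only for the
    CAD/stroke first-year figure)."""
    if died_this_cycle:
        return 0.0
    if cond is Condition.CAD or cond in STROKES:
        return ps.value("cost_productivity_first_year_cad_stroke")
    return ps.value(_FOLLOWUP_PRODUCTIVITY[cond])


def state_cost(
    state: HealthState,
    ctx: PhaseContext,
    strategy,
    ps,
    cycle: int,
    died_this_cycle: bool = False,
    components: bool = False,
):
    """Annual cost of occupying a state under a strategy.

    Sums background healthcare cost (alive occupants), acute event costs
    for conditions entered this cycle (fatal variant if the occupant dies
    within the cycle), follow-up treatment costs for established
    conditions, lost productivity, and expected per-member program costs
    from the strategy schedule.  ``strategy`` may be ``None`` (no program,
    i.e. the no-program comparator) or any object exposing
    ``expected_program_cost(ps, cycle, state)``.

    With ``components=True`` returns a dict ledger whose values sum to the
    total.
    """
    ledger = {"background": 0.0, "medical": 0.0, "productivity": 0.0, "program": 0.0}
    if not state.is_death:
        ledger["background"] = ps.value("cost_background")
        chronic = state.conditions - ctx.entered
        ledger["medical"] = followup_medical_cost(chronic, ps)
        ledger["productivity"] = followup_productivity_cost(chronic, ps)
        for c in ctx.entered & state.conditions:
            ledger["medical"] = ledger["medical"] + acute_medical_cost(c, ps, died_this_cycle)
            ledger["productivity"] = ledger["productivity"] + entry_productivity_cost(
                c, ps, died_this_cycle
            )
        if strategy is not None:
            ledger["program"] = strategy.expected_program_cost(ps, cycle, state)
    if components:
        return ledger
    return sum(ledger.values())


def state_space_json() -> str:
    """JSON dump of the state space (ids, tags, reward hooks) for docs and
    fixtures."""
    out = []
    for s in build_state_space():
        out.append(
            {
                "id": s.id,
                "conditions": [c.value for c in sorted(s.conditions)],
                "risk_stratum": None
                if s.risk_stratum is None
                else {"pce": s.risk_stratum[0].value, "prs": s.risk_stratum[1].value},
                "is_death": s.is_death,
                "utility_weights": [_UTILITY_PARAM[c] for c in sorted(s.conditions)],
                "followup_costs": [_FOLLOWUP_MEDICAL[c] for c in sorted(s.conditions)],
            }
        )
    return json.dumps(out, indent=2)
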