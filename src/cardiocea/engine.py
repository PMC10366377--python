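"""Annual-cycle Markov cohort engine for the three prevention strategies.

The cohort starts disease-free at age 50, distributed over six risk strata
(PCE low/moderate/high x CAD-PRS bottom-80%/top-20%).  The fixed
*risk-bearing* set -- high CAD-PRS with moderate or high PCE risk, plus low
CAD-PRS with high PCE risk -- incurs coronary-artery-disease and ischemic
stroke incidence in every strategy; strategies differ only in who initiates
statin prevention therapy:

* ``CardioriskSCORE``: every enrolled risk-bearing member initiates;
* ``StandardWHP``: only enrolled high-PCE members initiate (CAD-PRS unknown);
* ``NoWHP``: nobody initiates and no program costs accrue.

Half of initiators are adherent for the whole horizon; only adherent
initiators receive the statin risk reductions, pay the statin cost, and are
exposed to statin side-effect risks (myopathy, new-onset diabetes,
hemorrhagic stroke).  Enrollment mixes program dynamics with no-program
dynamics: the cohort is propagated as three persistent sub-cohorts ("arms")
-- enrolled-adherent, enrolled-non-adherent, and non-enrolled.

Within a cycle, events are resolved first and the acute case fatality of
the entered state is applied within the same cycle.  Acute-event
consequences (fatal/non-fatal acute cost, first-year lost productivity for
survivors, acute disutility) are charged as transition tolls at the cycle
of the event; survivors occupy the chronic condition state from the next
cycle, which keeps the nominal state count at exactly 22.

All probability inputs may be scalars or ``(n,)`` arrays; the engine
broadcasts, so a probabilistic sensitivity analysis is a single vectorized
cohort run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .fixtures import LifeTable
from .parameters import ParameterSet, apply_relative_effect
from .state_space import (
    Condition,
    HealthState,
    PceRisk,
    PrsGroup,
    build_state_space,
    condition_utility,
)

__all__ = [
    "StrategyConfig",
    "RunConfig",
    "CohortTrace",
    "TransitionKernel",
    "default_strategies",
    "run_cohort",
    "run_strategies",
    "total_outcomes",
    "build_kernel",
    "simulate_individuals",
    "STRATA",
    "RISK_BEARING",
    "COND_STATES",
]

CAD = Condition.CAD
IS = Condition.ISCHEMIC_STROKE
HEM = Condition.HEMORRHAGIC_STROKE
DM = Condition.DIABETES
MYO = Condition.MYOPATHY

#: Canonical stratum order (PCE major, PRS minor), matching the state space.
STRATA: list[tuple[PceRisk, PrsGroup]] = [
    (pce, prs) for pce in PceRisk for prs in PrsGroup
]

#: Strata that incur CAD / ischemic-stroke incidence (identical in every
#: strategy): high PRS with moderate/high PCE, or low PRS with high PCE.
RISK_BEARING = frozenset(
    {
        (PceRisk.MODERATE, PrsGroup.HIGH),
        (PceRisk.HIGH, PrsGroup.HIGH),
        (PceRisk.HIGH, PrsGroup.LOW),
    }
)

#: Condition-state layout per stratum: event-free, the five single
#: conditions, then the ten pairs in lexicographic condition order.
COND_STATES: list[frozenset] = (
    [frozenset()]
    + [frozenset({c}) for c in Condition]
    + [frozenset(p) for p in combinations(Condition, 2)]
)
_CIDX = {c: i for i, c in enumerate(COND_STATES)}
N_CSTATE = len(COND_STATES)  # 16
N_FLAT = 6 * N_CSTATE + 1  # 96 alive micro-states + shared death
DEATH_IDX = N_FLAT - 1

ARMS = ("adherent", "enrolled_untreated", "unenrolled")


class InternalConsistencyError(RuntimeError):
    """A computed transition row failed the stochasticity check."""


# ---------------------------------------------------------------------------
# Strategy configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrategyConfig:
    """Enrollment, treatment eligibility and program-cost schedule for one
    strategy."""

    name: str
    has_program: bool
    uses_prs: bool
    treat_eligible: Callable[[PceRisk, PrsGroup], bool]
    statin_initiation: float = 1.0
    enrollment_param: Optional[str] = "enrollment"
    adherence_param: Optional[str] = "statin_adherence"

    def enrollment(self, ps: ParameterSet):
        if not self.has_program or self.enrollment_param is None:
            return 0.0
        return ps.value(self.enrollment_param)

    def adherence(self, ps: ParameterSet):
        if self.adherence_param is None:
            return 0.0
        return ps.value(self.adherence_param)

    def screening_cost(self, ps: ParameterSet, cycle: int, prs: PrsGroup):
        """Per-enrolled-member program cost in a cycle (excluding statin)."""
        if not self.has_program:
            return 0.0
        base = ps.value("cost_standard_whp_screening")
        if not self.uses_prs:
            return base
        if cycle == 0:
            extra = ps.value("cost_prs_test")
            if prs is PrsGroup.HIGH:
                extra = extra + ps.value("cost_primary_care_visit")
            return base + extra
        return base + ps.value("cost_mobile_app")

    def expected_program_cost(self, ps: ParameterSet, cycle: int, state: HealthState):
        """Expected per-cohort-member program cost of occupying ``state``.

        For event-free states the stratum is known exactly.  Condition
        states are reported in aggregate over strata, so the PRS mix uses
        the population top-quintile share (20%) and the statin charge uses
        the enrolled-adherent fraction; the engine itself resolves these
        exactly per sub-cohort, this helper is the display/accounting view.
        """
        if state.is_death or not self.has_program:
            return 0.0
        e = self.enrollment(ps)
        if state.risk_stratum is not None:
            pce, prs = state.risk_stratum
            cost = e * self.screening_cost(ps, cycle, prs)
            if self.treat_eligible(pce, prs):
                cost = cost + e * self.statin_initiation * self.adherence(ps) * ps.value(
                    "cost_statin"
                )
            return cost
        prs_hi = 0.2
        cost = e * (
            prs_hi * self.screening_cost(ps, cycle, PrsGroup.HIGH)
            + (1 - prs_hi) * self.screening_cost(ps, cycle, PrsGroup.LOW)
        )
        return cost + e * self.statin_initiation * self.adherence(ps) * ps.value(
            "cost_statin"
        )


def _eligible_cardiorisk(pce: PceRisk, prs: PrsGroup) -> bool:
    return (prs is PrsGroup.HIGH and pce in (PceRisk.MODERATE, PceRisk.HIGH)) or (
        prs is PrsGroup.LOW and pce is PceRisk.HIGH
    )


def _eligible_standard(pce: PceRisk, prs: PrsGroup) -> bool:
    return pce is PceRisk.HIGH


def _eligible_none(pce: PceRisk, prs: PrsGroup) -> bool:
    return False


def default_strategies() -> dict[str, StrategyConfig]:
    return {
        "CardioriskSCORE": StrategyConfig(
            name="CardioriskSCORE",
            has_program=True,
            uses_prs=True,
            treat_eligible=_eligible_cardiorisk,
        ),
        "StandardWHP": StrategyConfig(
            name="StandardWHP",
            has_program=True,
            uses_prs=False,
            treat_eligible=_eligible_standard,
        ),
        "NoWHP": StrategyConfig(
            name="NoWHP",
            has_program=False,
            uses_prs=False,
            treat_eligible=_eligible_none,
            enrollment_param=None,
            adherence_param=None,
        ),
    }


# ---------------------------------------------------------------------------
# Run configuration and results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Simulation conventions.

    ``cycle_correction``: ``"half"`` (trapezoidal accrual of continuous
    rewards over occupancy at cycle boundaries 0..horizon -- the default),
    ``"none"`` (start-of-cycle accrual over cycles 0..horizon-1) or
    ``"end"``.  Scheduled program charges are always applied to
    start-of-cycle alive occupancy, and acute-event tolls at the cycle of
    the event, under every convention.

    ``condition_mortality_includes_background``: if True, condition states
    face their disease-specific death risk combined with the age-specific
    life-table hazard; the default uses the disease-specific risk alone.
    """

    start_age: int = 50
    prs_high_share: float = 0.2
    cycle_correction: str = "half"
    condition_mortality_includes_background: bool = False
    migration_start_cycle: int = 1

    def __post_init__(self) -> None:
        if self.cycle_correction not in ("half", "none", "end"):
            raise ValueError(f"unknown cycle_correction {self.cycle_correction!r}")


@dataclass
class CohortTrace:
    """Per-cycle occupancy and discounted reward accumulators for one
    strategy (cohort of 1; all money per cohort member)."""

    strategy: str
    horizon: int
    discount: float
    occupancy: np.ndarray  # (horizon+1, 22, n)
    discounted_costs: np.ndarray  # (horizon+1, n)
    discounted_qalys: np.ndarray  # (horizon+1, n)
    ledgers: dict  # component -> (horizon+1, n)
    enrollment: np.ndarray | float
    state_ids: list[str] = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return self.occupancy.shape[-1]

    def _maybe_scalar(self, arr: np.ndarray):
        arr = np.asarray(arr)
        return float(arr.reshape(-1)[0]) if arr.size == 1 else arr

    @property
    def total_cost(self):
        return self._maybe_scalar(self.discounted_costs.sum(axis=0))

    @property
    def total_qalys(self):
        return self._maybe_scalar(self.discounted_qalys.sum(axis=0))

    def total_cost_per_enrolled(self):
        """Alternative normalization: per enrolled employee (undefined for a
        no-program strategy)."""
        e = np.asarray(self.enrollment, dtype=float)
        if np.any(e <= 0):
            raise ValueError("per-enrolled normalization needs enrollment > 0")
        return self._maybe_scalar(self.discounted_costs.sum(axis=0) / e)

    def occupancy_frame(self):
        import pandas as pd

        if self.n_draws != 1:
            raise ValueError("occupancy export is for single (base-case) runs")
        occ = self.occupancy[..., 0]
        return pd.DataFrame(
            [
                {"cycle": t, "state": sid, "occupancy": occ[t, j]}
                for t in range(occ.shape[0])
                for j, sid in enumerate(self.state_ids)
            ]
        )


def total_outcomes(trace: CohortTrace):
    """Total discounted (cost, QALYs) per cohort member."""
    return trace.total_cost, trace.total_qalys


# ---------------------------------------------------------------------------
# Probability building blocks (scalar or (n,) array valued)
# ---------------------------------------------------------------------------

def _primary_cad_risk(stratum, treated: bool, ps: ParameterSet):
    """Annual first-CAD risk of a risk-bearing stratum (0 otherwise)."""
    pce, prs = stratum
    if stratum not in RISK_BEARING:
        return 0.0
    base = ps.value("risk_cad_high_pce" if pce is PceRisk.HIGH else "risk_cad_moderate_pce")
    if prs is PrsGroup.HIGH:
        base = apply_relative_effect(base, ps.value("or_cad_high_prs"), "direct")
    if treated:
        base = apply_relative_effect(base, ps.value("statin_hr_cad"), "hazard")
    return base


def _primary_is_risk(stratum, treated: bool, ps: ParameterSet):
    if stratum not in RISK_BEARING:
        return 0.0
    base = ps.value("risk_ischemic_stroke")
    if treated:
        base = apply_relative_effect(base, ps.value("statin_hr_ischemic_stroke"), "hazard")
    return base


def _state_death_prob(conds: frozenset, q_age, ps: ParameterSet, cfg: RunConfig):
    """Annual death probability of an established (chronic) state."""
    has_cad = CAD in conds
    has_stroke = IS in conds or HEM in conds
    if has_cad and has_stroke:
        d = ps.value("mort_stroke_and_cad")
    elif has_cad:
        d = ps.value("mort_chronic_cad")
        if DM in conds:
            d = apply_relative_effect(d, ps.value("hr_mort_cad_diabetes"), "hazard")
    elif has_stroke:
        d = ps.value("mort_chronic_stroke")
        if DM in conds and IS in conds:
            d = apply_relative_effect(d, ps.value("rr_mort_stroke_diabetes"), "hazard")
    else:
        d = q_age
        if DM in conds:
            d = apply_relative_effect(d, ps.value("hr_mort_diabetes"), "hazard")
    if conds and cfg.condition_mortality_includes_background:
        d = 1.0 - (1.0 - d) * (1.0 - q_age)
    return d


def _acute_case_fatality(new_cond, dest: frozenset, q_age, ps, cfg: RunConfig):
    """Within-cycle death risk of entering ``dest`` via ``new_cond``."""
    if new_cond is CAD:
        cf = ps.value("mort_acute_cad")
        if DM in dest:
            cf = apply_relative_effect(cf, ps.value("hr_mort_cad_diabetes"), "hazard")
        return cf
    if new_cond is IS:
        cf = ps.value("mort_acute_ischemic_stroke")
        if DM in dest:
            cf = apply_relative_effect(cf, ps.value("rr_mort_stroke_diabetes"), "hazard")
        return cf
    if new_cond is HEM:
        return ps.value("mort_acute_hemorrhagic_stroke")
    # diabetes / myopathy onset has no acute case fatality of its own; the
    # destination's chronic risk applies in the entry cycle
    return _state_death_prob(dest, q_age, ps, cfg)


def _event_outflows(conds: frozenset, stratum, treated: bool, ps: ParameterSet):
    """List of (new_condition, probability) acquisitions from a state.

    Pair states acquire nothing (a fraction that would acquire a third
    condition stays put).  Side-effect risks apply only to the statin-
    treated sub-cohort.
    """
    if len(conds) >= 2:
        return []
    out: list[tuple[Condition, object]] = []
    if not conds:  # event-free
        p_cad = _primary_cad_risk(stratum, treated, ps)
        p_is = _primary_is_risk(stratum, treated, ps)
        if not np.all(np.asarray(p_cad) == 0):
            out.append((CAD, p_cad))
        if not np.all(np.asarray(p_is) == 0):
            out.append((IS, p_is))
    elif conds == {CAD}:
        out.append((IS, ps.value("risk_ischemic_stroke_after_cad")))
    elif conds == {IS}:
        out.append((CAD, ps.value("risk_cad_after_ischemic_stroke")))
    elif conds == {HEM}:
        out.append((IS, ps.value("risk_ischemic_stroke_post_hemorrhagic")))
        p_cad = _primary_cad_risk(stratum, treated, ps)
        if not np.all(np.asarray(p_cad) == 0):
            out.append((CAD, p_cad))
    elif conds == {DM}:
        p_cad = _primary_cad_risk(stratum, treated, ps)
        if not np.all(np.asarray(p_cad) == 0):
            out.append((CAD, apply_relative_effect(p_cad, ps.value("hr_cad_diabetes"), "hazard")))
        p_is = _primary_is_risk(stratum, treated, ps)
        if not np.all(np.asarray(p_is) == 0):
            out.append(
                (IS, apply_relative_effect(p_is, ps.value("hr_ischemic_stroke_diabetes"), "hazard"))
            )
    elif conds == {MYO}:
        p_cad = _primary_cad_risk(stratum, treated, ps)
        if not np.all(np.asarray(p_cad) == 0):
            out.append((CAD, p_cad))
        p_is = _primary_is_risk(stratum, treated, ps)
        if not np.all(np.asarray(p_is) == 0):
            out.append((IS, p_is))
    if treated:
        for cond, pname in (
            (MYO, "risk_myopathy"),
            (DM, "risk_statin_diabetes"),
            (HEM, "risk_statin_hemorrhagic_stroke"),
        ):
            if cond not in conds:
                out.append((cond, ps.value(pname)))
    return out


# ---------------------------------------------------------------------------
# Cohort propagation
# ---------------------------------------------------------------------------

def _flat(s: int, c: int) -> int:
    return s * N_CSTATE + c


def _n_draws(ps: ParameterSet) -> int:
    n = 1
    for spec in ps:
        v = np.asarray(spec.baseline)
        if v.ndim > 0:
            n = max(n, v.shape[0])
    return n


def _initial_shares(ps: ParameterSet, cfg: RunConfig):
    """Stratum shares: renormalized PCE shares x PRS split (20% top)."""
    raw = np.array(
        [
            np.asarray(ps.value("init_low_pce"), dtype=float),
            np.asarray(ps.value("init_moderate_pce"), dtype=float),
            np.asarray(ps.value("init_high_pce"), dtype=float),
        ]
    )
    shares = raw / raw.sum(axis=0)
    prs_split = {PrsGroup.LOW: 1.0 - cfg.prs_high_share, PrsGroup.HIGH: cfg.prs_high_share}
    pce_ix = {PceRisk.LOW: 0, PceRisk.MODERATE: 1, PceRisk.HIGH: 2}
    return [shares[pce_ix[pce]] * prs_split[prs] for (pce, prs) in STRATA]


def _arm_weights(strategy: StrategyConfig, ps: ParameterSet):
    e = strategy.enrollment(ps)
    a = strategy.adherence(ps)
    i = strategy.statin_initiation
    w_adh = e * i * a
    return {
        "adherent": w_adh,
        "enrolled_untreated": e - w_adh,
        "unenrolled": 1.0 - e,
    }


def run_cohort(
    strategy: StrategyConfig,
    ps: ParameterSet,
    life_table: LifeTable,
    horizon: int = 5,
    discount: float = 0.03,
    start_age: int | None = None,
    config: RunConfig | None = None,
    migration=None,
) -> CohortTrace:
    """Propagate the cohort for ``horizon`` annual cycles and accumulate
    discounted costs and QALYs.

    ``migration`` is an optional 3x3 row-stochastic annual matrix over PCE
    categories (see :mod:`cardiocea.scenario`), applied to event-free
    strata before event transitions from ``config.migration_start_cycle``
    onwards.  Returns a :class:`CohortTrace`; with array-valued parameters
    the trace carries one column per draw.
    """
    if horizon < 1:
        raise ValueError("horizon must be at least one cycle")
    cfg = config or RunConfig()
    if start_age is not None:
        cfg = replace(cfg, start_age=start_age)
    n = _n_draws(ps)
    mig = None if migration is None else np.asarray(getattr(migration, "matrix", migration), dtype=float)

    treated = {
        s: (STRATA[s] in RISK_BEARING) and strategy.treat_eligible(*STRATA[s])
        for s in range(6)
    }
    arm_w = _arm_weights(strategy, ps)
    shares = _initial_shares(ps, cfg)

    disc = (1.0 + discount) ** -np.arange(horizon + 1)

    # Per-cycle accumulators (time point index 0..horizon).
    zeros = lambda: np.zeros((horizon + 1, n))
    led = {k: zeros() for k in ("background", "medical", "productivity", "program")}
    qalys = zeros()
    occ_total = np.zeros((horizon + 1, N_FLAT, n))

    ef_rows_by_prs = {
        prs: [si for si, (p, pr) in enumerate(STRATA) if pr is prs] for prs in PrsGroup
    }

    for arm in ARMS:
        w = np.asarray(arm_w[arm], dtype=float) * np.ones(n)
        if np.all(w == 0):
            continue
        enrolled = arm in ("adherent", "enrolled_untreated")
        occ = np.zeros((N_FLAT, n))
        for s in range(6):
            occ[_flat(s, 0)] = w * shares[s]

        for t in range(horizon + 1):
            occ_total[t] += occ
            # scheduled program charges on start-of-cycle alive occupancy
            if t < horizon and strategy.has_program and enrolled:
                for s, (pce, prs) in enumerate(STRATA):
                    alive_s = occ[_flat(s, 0) : _flat(s, 0) + N_CSTATE].sum(axis=0)
                    led["program"][t] += alive_s * strategy.screening_cost(ps, t, prs) * disc[t]
                    if arm == "adherent" and treated[s]:
                        led["program"][t] += alive_s * ps.value("cost_statin") * disc[t]
            if t == horizon:
                break

            # ---- transition t -> t+1 ----
            if mig is not None and t >= cfg.migration_start_cycle:
                for prs, rows in ef_rows_by_prs.items():
                    ef_idx = [_flat(s, 0) for s in rows]
                    block = occ[ef_idx]  # (3, n) in PCE order low/mod/high
                    occ[ef_idx] = mig.T @ block

            q_age = life_table.q(cfg.start_age + t)
            new_occ = np.zeros_like(occ)
            new_occ[DEATH_IDX] = occ[DEATH_IDX]
            for s in range(6):
                tau = treated[s] and arm == "adherent"
                for ci, conds in enumerate(COND_STATES):
                    src = _flat(s, ci)
                    mass = occ[src]
                    if np.all(mass == 0):
                        continue
                    events = _event_outflows(conds, STRATA[s], tau, ps)
                    if events:
                        total_p = sum(np.asarray(p, dtype=float) for _, p in events)
                        scale = np.where(total_p > 1.0, 1.0 / np.maximum(total_p, 1e-300), 1.0)
                    else:
                        total_p = 0.0
                        scale = 1.0
                    remainder = mass * (1.0 - total_p * scale)
                    d = _state_death_prob(conds, q_age, ps, cfg)
                    new_occ[src] += remainder * (1.0 - d)
                    new_occ[DEATH_IDX] += remainder * d
                    for new_cond, p in events:
                        flux = mass * p * scale
                        dest = frozenset(conds | {new_cond})
                        cf = _acute_case_fatality(new_cond, dest, q_age, ps, cfg)
                        new_occ[_flat(s, _CIDX[dest])] += flux * (1.0 - cf)
                        new_occ[DEATH_IDX] += flux * cf
                        # acute-event tolls at the cycle of the event
                        if new_cond in (CAD, IS, HEM):
                            if new_cond is CAD:
                                c_nf = ps.value("cost_acute_cad_nonfatal")
                                c_f = ps.value("cost_acute_cad_fatal")
                                du = ps.value("du_acute_cad")
                            elif new_cond is IS:
                                c_nf = ps.value("cost_acute_ischemic_stroke_nonfatal")
                                c_f = ps.value("cost_acute_ischemic_stroke_fatal")
                                du = ps.value("du_acute_stroke")
                            else:
                                c_nf = ps.value("cost_acute_hemorrhagic_stroke_nonfatal")
                                c_f = ps.value("cost_acute_hemorrhagic_stroke_fatal")
                                du = ps.value("du_acute_stroke")
                            led["medical"][t] += flux * (cf * c_f + (1.0 - cf) * c_nf) * disc[t]
                            led["productivity"][t] += (
                                flux
                                * (1.0 - cf)
                                * ps.value("cost_productivity_first_year_cad_stroke")
                                * disc[t]
                            )
                            qalys[t] -= flux * du * disc[t]
            occ = new_occ

    # ---- continuous (state-membership) rewards over snapshots ----
    if cfg.cycle_correction == "half":
        w_t = np.ones(horizon + 1)
        w_t[0] = w_t[-1] = 0.5
    elif cfg.cycle_correction == "none":
        w_t = np.ones(horizon + 1)
        w_t[-1] = 0.0
    else:  # end
        w_t = np.ones(horizon + 1)
        w_t[0] = 0.0

    from .state_space import followup_medical_cost, followup_productivity_cost

    age_du = ps.value("du_age_annual")
    bg = ps.value("cost_background")
    for ci, conds in enumerate(COND_STATES):
        mass_c = occ_total[:, [_flat(s, ci) for s in range(6)], :].sum(axis=1)  # (T+1, n)
        u_base = condition_utility(conds, ps)
        med = followup_medical_cost(conds, ps)
        prod = followup_productivity_cost(conds, ps)
        for t in range(horizon + 1):
            wt = w_t[t] * disc[t]
            if wt == 0.0:
                continue
            u_t = np.maximum(u_base - age_du * t, 0.0)
            qalys[t] += wt * mass_c[t] * u_t
            led["background"][t] += wt * mass_c[t] * bg
            if conds:
                led["medical"][t] += wt * mass_c[t] * med
                led["productivity"][t] += wt * mass_c[t] * prod

    # aggregate micro-states to the nominal 22-state occupancy
    states = build_state_space()
    occ22 = np.zeros((horizon + 1, 22, n))
    for j, st in enumerate(states):
        if st.is_death:
            occ22[:, j] = occ_total[:, DEATH_IDX]
        elif st.is_event_free:
            s = STRATA.index(st.risk_stratum)
            occ22[:, j] = occ_total[:, _flat(s, 0)]
        else:
            ci = _CIDX[st.conditions]
            occ22[:, j] = occ_total[:, [_flat(s, ci) for s in range(6)], :].sum(axis=1)

    sums = occ22.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-9):
        raise InternalConsistencyError(
            f"cohort mass not conserved: max deviation {np.abs(sums - 1).max():.3e}"
        )

    costs = sum(led.values())
    return CohortTrace(
        strategy=strategy.name,
        horizon=horizon,
        discount=discount,
        occupancy=occ22,
        discounted_costs=costs,
        discounted_qalys=qalys,
        ledgers=led,
        enrollment=strategy.enrollment(ps),
        state_ids=[st.id for st in states],
    )


def run_strategies(
    strategies: Mapping[str, StrategyConfig],
    ps: ParameterSet,
    life_table: LifeTable,
    horizon: int = 5,
    discount: float = 0.03,
    config: RunConfig | None = None,
    migration: Optional[Mapping[str, object]] = None,
) -> dict[str, CohortTrace]:
    """Run every strategy; ``migration`` optionally maps strategy name to a
    migration matrix."""
    out = {}
    for name, strat in strategies.items():
        mig = None if migration is None else migration.get(name)
        out[name] = run_cohort(
            strat, ps, life_table, horizon=horizon, discount=discount, config=config, migration=mig
        )
    return out


# ---------------------------------------------------------------------------
# Explicit kernel (scalar parameters) and individual-level oracle
# ---------------------------------------------------------------------------

@dataclass
class TransitionKernel:
    """Dense one-cycle transition matrix over the 97 micro-states
    (6 strata x 16 condition layouts + death) for one sub-cohort arm."""

    matrix: np.ndarray  # (97, 97)
    labels: list[str]
    cycle: int
    arm: str

    def validate(self, atol: float = 1e-9) -> None:
        rows = self.matrix.sum(axis=1)
        if np.any(self.matrix < -atol) or np.any(self.matrix > 1 + atol):
            raise InternalConsistencyError("kernel entries outside [0, 1]")
        if not np.allclose(rows, 1.0, atol=atol):
            raise InternalConsistencyError(
                f"kernel rows off-stochastic by {np.abs(rows - 1).max():.3e}"
            )


def _micro_labels() -> list[str]:
    labels = []
    for pce, prs in STRATA:
        for conds in COND_STATES:
            tag = "+".join(sorted(c.name.lower() for c in conds)) or "event_free"
            labels.append(f"{pce.value}_{prs.value}:{tag}")
    labels.append("death")
    return labels


def build_kernel(
    strategy: StrategyConfig,
    ps: ParameterSet,
    life_table: LifeTable,
    cycle: int,
    arm: str = "adherent",
    config: RunConfig | None = None,
    migration=None,
) -> TransitionKernel:
    """Assemble the one-cycle transition matrix a sub-cohort faces.

    Uses the same outflow primitives as :func:`run_cohort`; rows are checked
    to be stochastic within 1e-9.  Requires scalar parameter values.
    """
    cfg = config or RunConfig()
    if _n_draws(ps) != 1:
        raise ValueError("build_kernel requires scalar parameter values")
    q_age = life_table.q(cfg.start_age + cycle)
    P = np.zeros((N_FLAT, N_FLAT))
    P[DEATH_IDX, DEATH_IDX] = 1.0
    for s in range(6):
        tau = (
            arm == "adherent"
            and STRATA[s] in RISK_BEARING
            and strategy.treat_eligible(*STRATA[s])
        )
        for ci, conds in enumerate(COND_STATES):
            src = _flat(s, ci)
            events = _event_outflows(conds, STRATA[s], tau, ps)
            total_p = sum(float(p) for _, p in events)
            scale = 1.0 / total_p if total_p > 1.0 else 1.0
            d = float(_state_death_prob(conds, q_age, ps, cfg))
            P[src, src] += (1.0 - total_p * scale) * (1.0 - d)
            P[src, DEATH_IDX] += (1.0 - total_p * scale) * d
            for new_cond, p in events:
                dest = frozenset(conds | {new_cond})
                cf = float(_acute_case_fatality(new_cond, dest, q_age, ps, cfg))
                P[src, _flat(s, _CIDX[dest])] += float(p) * scale * (1.0 - cf)
                P[src, DEATH_IDX] += float(p) * scale * cf
    if migration is not None and cycle >= cfg.migration_start_cycle:
        mig = np.asarray(getattr(migration, "matrix", migration), dtype=float)
        M = np.eye(N_FLAT)
        for prs in PrsGroup:
            rows = [si for si, (p, pr) in enumerate(STRATA) if pr is prs]
            for a, sa in enumerate(rows):
                for b, sb in enumerate(rows):
                    M[_flat(sa, 0), _flat(sb, 0)] = mig[a, b]
        P = M @ P
    kernel = TransitionKernel(matrix=P, labels=_micro_labels(), cycle=cycle, arm=arm)
    kernel.validate()
    return kernel


def simulate_individuals(
    strategy: StrategyConfig,
    ps: ParameterSet,
    life_table: LifeTable,
    n_persons: int,
    seed: int,
    horizon: int = 5,
    config: RunConfig | None = None,
    migration=None,
) -> np.ndarray:
    """Individual-level Monte-Carlo simulation through the same per-cycle
    kernels; returns occupancy fractions (horizon+1, 22).

    Serves as an independent cross-check of the cohort propagation: persons
    are assigned to arms and strata at random and stepped through sampled
    categorical transitions rather than expected-value bookkeeping.
    """
    cfg = config or RunConfig()
    rng = np.random.default_rng(seed)
    arm_w = {k: float(v) for k, v in _arm_weights(strategy, ps).items()}
    shares = [float(x) for x in _initial_shares(ps, cfg)]

    arm_of = rng.choice(len(ARMS), size=n_persons, p=[arm_w[a] for a in ARMS])
    stratum = rng.choice(6, size=n_persons, p=shares)
    state = np.array([_flat(s, 0) for s in stratum])

    counts = np.zeros((horizon + 1, N_FLAT))
    kernels = {}
    for t in range(horizon + 1):
        np.add.at(counts[t], state, 1.0)
        if t == horizon:
            break
        for ai, arm in enumerate(ARMS):
            if arm not in kernels or kernels[arm].cycle != t:
                kernels[arm] = build_kernel(
                    strategy, ps, life_table, t, arm=arm, config=cfg, migration=migration
                )
            sel = arm_of == ai
            if not sel.any():
                continue
            cur = state[sel]
            nxt = np.empty_like(cur)
            for u in np.unique(cur):
                m = cur == u
                cum = np.cumsum(kernels[arm].matrix[u])
                nxt[m] = np.searchsorted(cum, rng.random(m.sum()), side="right")
            out = state[sel]
            out[:] = np.minimum(nxt, DEATH_IDX)
            state[sel] = out
        state = np.minimum(state, DEATH_IDX)

    counts /= n_persons
    # aggregate to nominal 22 states
    states = build_state_space()
    occ22 = np.zeros((horizon + 1, 22))
    for j, st in enumerate(states):
        if st.is_death:
            occ22[:, j] = counts[:, DEATH_IDX]
        elif st.is_event_free:
            s = STRATA.index(st.risk_stratum)
            occ22[:, j] = counts[:, _flat(s, 0)]
        else:
            ci = _CIDX[st.conditions]
            occ22[:, j] = counts[:, [_flat(s, ci) for s in range(6)]].sum(axis=1)
    return occ22
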