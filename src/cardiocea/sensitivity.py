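"""One-way (tornado) and probabilistic sensitivity analysis.

Both analyses rerun the full cohort model; neither approximates.  The
one-way analysis perturbs each parameter that ships with a range to its
low and high endpoint while holding everything else at baseline, and ranks
parameters by the width of the induced swing in incremental net monetary
benefit.  The probabilistic analysis draws every non-fixed parameter from
its distribution (independent draws, per-parameter substreams) and reruns
the model per draw; because the engine broadcasts over draws, the whole
PSA is a single vectorized cohort run per strategy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cea import nmb
from .engine import RunConfig, StrategyConfig, default_strategies, run_strategies
from .fixtures import LifeTable
from .parameters import ParameterSet, sample_parameters

__all__ = ["TornadoEntry", "OWSAResult", "PSAResult", "one_way", "psa"]

logger = logging.getLogger(__name__)

DEFAULT_WTP_GRID = tuple(range(0, 200_001, 10_000))


@dataclass(frozen=True)
class TornadoEntry:
    """INMB of the focal comparison at a parameter's range endpoints."""

    parameter: str
    low: float
    high: float
    inmb_at_low: float
    inmb_at_high: float

    @property
    def bar_width(self) -> float:
        return abs(self.inmb_at_high - self.inmb_at_low)


@dataclass
class OWSAResult:
    """Tornado entries (sorted by descending bar width) plus the baseline
    INMB they swing around."""

    comparison: tuple[str, str]
    wtp: float
    base_inmb: float
    entries: list

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    def __getitem__(self, i):
        return self.entries[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "parameter": e.parameter,
                    "low": e.low,
                    "high": e.high,
                    "inmb_at_low": e.inmb_at_low,
                    "inmb_at_high": e.inmb_at_high,
                    "bar_width": e.bar_width,
                }
                for e in self.entries
            ]
        )


def _batched_parameter_set(ps: ParameterSet, varied: Sequence[str]) -> ParameterSet:
    """One draw-column per (parameter, endpoint) plus a final baseline
    column; column 2i is parameter i at its low endpoint, 2i+1 at its
    high."""
    k = 2 * len(varied) + 1
    entries = {}
    for spec in ps:
        entries[spec.name] = replace(spec, baseline=np.full(k, spec.baseline))
    for i, name in enumerate(varied):
        spec = ps[name]
        col = entries[name].baseline.copy()
        col[2 * i] = spec.low
        col[2 * i + 1] = spec.high
        entries[name] = replace(entries[name], baseline=col)
    return ParameterSet(entries, provenance=f"{ps.provenance} [owsa batch]")


def one_way(
    ps: ParameterSet,
    life_table: LifeTable,
    comparison: tuple[str, str] = ("CardioriskSCORE", "StandardWHP"),
    wtp: float = 50_000.0,
    strategies: Optional[Mapping[str, StrategyConfig]] = None,
    horizon: int = 5,
    discount: float = 0.03,
    config: Optional[RunConfig] = None,
    parameters: Optional[Sequence[str]] = None,
) -> OWSAResult:
    """Tornado analysis of incremental net monetary benefit.

    Every parameter with a genuine range (low < high) is varied unless an
    explicit ``parameters`` subset is given; range-less parameters are
    skipped with a logged warning.  The full three-strategy model is rerun
    at each endpoint (batched into one vectorized run).
    """
    strategies = strategies or default_strategies()
    focal, comparator = comparison
    if parameters is None:
        varied = [s.name for s in ps if s.has_range]
        for s in ps:
            if not s.has_range:
                logger.warning("one_way: %s has no range, skipped", s.name)
    else:
        # an explicitly requested range-less parameter yields a zero-width
        # bar (both endpoints collapse to the baseline) rather than a skip
        varied = []
        for name in parameters:
            if not ps[name].has_range:
                logger.warning("one_way: %s has no range, zero-width bar", name)
            varied.append(name)

    batched = _batched_parameter_set(ps, varied)
    traces = run_strategies(
        {k: strategies[k] for k in (focal, comparator)},
        batched,
        life_table,
        horizon=horizon,
        discount=discount,
        config=config,
    )
    dc = np.atleast_1d(traces[focal].total_cost) - np.atleast_1d(traces[comparator].total_cost)
    de = np.atleast_1d(traces[focal].total_qalys) - np.atleast_1d(traces[comparator].total_qalys)
    inmb = wtp * de - dc
    entries = [
        TornadoEntry(
            parameter=name,
            low=float(ps[name].low),
            high=float(ps[name].high),
            inmb_at_low=float(inmb[2 * i]),
            inmb_at_high=float(inmb[2 * i + 1]),
        )
        for i, name in enumerate(varied)
    ]
    entries.sort(key=lambda e: e.bar_width, reverse=True)
    return OWSAResult(
        comparison=comparison, wtp=wtp, base_inmb=float(inmb[-1]), entries=entries
    )


@dataclass
class PSAResult:
    """Draw-level incremental cost/effect clouds and acceptability curves.

    ``draws`` maps comparator name to an ``(n, 2)`` array of
    (delta cost, delta QALYs) for the focal strategy vs that comparator;
    ``ceac`` maps comparator name to {wtp: probability cost-effective},
    where the probability is the fraction of draws with positive
    incremental net monetary benefit.
    """

    focal: str
    n_draws: int
    seed: int
    draws: dict
    ceac: dict
    totals: dict = field(default_factory=dict, repr=False)  # name -> (cost, qalys) arrays

    def prob_cost_effective(self, wtp: float, comparator: str) -> float:
        dc, de = self.draws[comparator][:, 0], self.draws[comparator][:, 1]
        return float(np.mean(wtp * de - dc > 0))

    def ce_plane_frame(self, comparator: str) -> pd.DataFrame:
        dc, de = self.draws[comparator][:, 0], self.draws[comparator][:, 1]
        return pd.DataFrame({"delta_cost": dc, "delta_qalys": de})

    def ceac_frame(self) -> pd.DataFrame:
        rows = [
            {"comparator": comp, "wtp": w, "prob_cost_effective": p}
            for comp, curve in self.ceac.items()
            for w, p in curve.items()
        ]
        return pd.DataFrame(rows)


def psa(
    ps: ParameterSet,
    n: int,
    seed: int,
    wtp: float = 50_000.0,
    life_table: Optional[LifeTable] = None,
    strategies: Optional[Mapping[str, StrategyConfig]] = None,
    focal: str = "CardioriskSCORE",
    horizon: int = 5,
    discount: float = 0.03,
    config: Optional[RunConfig] = None,
    wtp_grid: Sequence[float] = DEFAULT_WTP_GRID,
) -> PSAResult:
    """Monte-Carlo probabilistic sensitivity analysis with ``n`` draws.

    Parameters are drawn independently from their Table-style
    distributions, the full model is rerun per draw, and acceptability
    curves are evaluated on ``wtp_grid`` (always including ``wtp``).
    Reproducible under ``seed``.
    """
    if n < 1:
        raise ValueError("need at least one draw")
    if life_table is None:
        from .fixtures import synth_life_table

        life_table = synth_life_table()
    strategies = strategies or default_strategies()
    sampled = sample_parameters(ps, seed, n=n)
    traces = run_strategies(
        strategies, sampled, life_table, horizon=horizon, discount=discount, config=config
    )
    costs = {k: np.atleast_1d(t.total_cost) for k, t in traces.items()}
    qalys = {k: np.atleast_1d(t.total_qalys) for k, t in traces.items()}
    grid = sorted(set(float(w) for w in wtp_grid) | {float(wtp)})
    draws, ceac = {}, {}
    for name in strategies:
        if name == focal:
            continue
        dc = costs[focal] - costs[name]
        de = qalys[focal] - qalys[name]
        draws[name] = np.column_stack([dc, de])
        ceac[name] = {w: float(np.mean(w * de - dc > 0)) for w in grid}
    return PSAResult(
        focal=focal,
        n_draws=n,
        seed=seed,
        draws=draws,
        ceac=ceac,
        totals={k: (costs[k], qalys[k]) for k in strategies},
    )
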