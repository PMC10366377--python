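"""Strategy comparison: incremental costs/QALYs, dominance, ICER and
(incremental) net monetary benefit.

A strategy *dominates* a comparator when it costs less and yields more
QALYs; a dominant comparison is reported with the label rather than a
(negative, meaningless) ICER.  Net monetary benefit at willingness-to-pay
``wtp`` is ``wtp * QALYs - cost``; the incremental version
``wtp * dE - dC`` is positive exactly when the focal strategy is
cost-effective at that threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = ["Comparison", "CEAResult", "compare", "nmb"]

DOMINANT = "Dominant"
DOMINATED = "Dominated"


def nmb(cost, qalys, wtp: float):
    """Net monetary benefit ``wtp * qalys - cost``."""
    return wtp * qalys - cost


@dataclass(frozen=True)
class Comparison:
    """Focal strategy vs one comparator."""

    comparator: str
    delta_cost: float
    delta_qalys: float
    icer: Union[float, str, None]
    inmb: float

    @property
    def dominant(self) -> bool:
        return self.icer == DOMINANT


@dataclass
class CEAResult:
    """Totals, pairwise incrementals and net monetary benefit at one WTP."""

    wtp: float
    focal: str
    totals: dict  # name -> (cost, qalys)
    nmb: dict  # name -> value
    comparisons: list  # [Comparison]
    traces: Optional[dict] = field(default=None, repr=False)

    def comparison(self, comparator: str) -> Comparison:
        for c in self.comparisons:
            if c.comparator == comparator:
                return c
        raise KeyError(comparator)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        by_comp = {c.comparator: c for c in self.comparisons}
        for name, (cost, q) in self.totals.items():
            c = by_comp.get(name)
            rows.append(
                {
                    "strategy": name,
                    "cost": float(cost),
                    "qalys": float(q),
                    "incremental_cost": None if c is None else -c.delta_cost,
                    "qalys_gained": None if c is None else -c.delta_qalys,
                    "icer": "Dominant"
                    if name == self.focal and all(x.dominant for x in self.comparisons)
                    else None,
                    "nmb": float(self.nmb[name]),
                }
            )
        return pd.DataFrame(rows)


def _icer_label(dc: float, de: float):
    if dc < 0 and de > 0:
        return DOMINANT
    if dc > 0 and de < 0:
        return DOMINATED
    if de == 0:
        return None
    return dc / de


def compare(
    results: Mapping[str, tuple],
    wtp: float = 50_000.0,
    focal: str = "CardioriskSCORE",
    comparators: Optional[Sequence[str]] = None,
) -> CEAResult:
    """Pairwise comparison of the focal strategy against each comparator.

    ``results`` maps strategy name to ``(total_cost, total_qalys)`` (e.g.
    from :func:`cardiocea.engine.total_outcomes`).  Dominance is detected
    before any ICER division; the ICER field carries the label instead of a
    ratio when the signs make the ratio meaningless.
    """
    if len(results) < 2:
        raise ValueError("need at least two strategies to compare")
    if focal not in results:
        raise ValueError(f"focal strategy {focal!r} not among results")
    if comparators is None:
        comparators = [k for k in results if k != focal]
    fc, fq = results[focal]
    comparisons = []
    for name in comparators:
        cc, cq = results[name]
        dc = float(fc - cc)
        de = float(fq - cq)
        comparisons.append(
            Comparison(
                comparator=name,
                delta_cost=dc,
                delta_qalys=de,
                icer=_icer_label(dc, de),
                inmb=float(wtp * de - dc),
            )
        )
    return CEAResult(
        wtp=wtp,
        focal=focal,
        totals={k: (float(c), float(q)) for k, (c, q) in results.items()},
        nmb={k: float(nmb(c, q, wtp)) for k, (c, q) in results.items()},
        comparisons=comparisons,
    )
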