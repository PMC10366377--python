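"""Packaged inputs: default parameter table, synthetic period life table,
and model-validation helpers.

The default parameter CSV under ``cardiocea/data`` is the golden transcription
of the model's annual inputs (see ``data/data_dictionary.md``).  Background
mortality for event-free employees comes from a period life table of annual
all-cause death probabilities by age; since the published US Social Security
table is not bundled, a Gompertz-style synthetic stand-in is the default and
any user-supplied ``age,qx`` CSV can be loaded in its place.  Over a 5-year
horizon starting at age 50 the results are insensitive to the exact table.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import ParameterSet, load_parameters

__all__ = [
    "LifeTable",
    "synth_life_table",
    "load_life_table",
    "default_parameters",
    "default_parameters_path",
    "write_default_parameters",
    "validate_life_expectancy",
    "first_year_productivity",
    "followup_productivity",
    "annual_ischemic_stroke_risk",
]


@dataclass(frozen=True)
class LifeTable:
    """Annual all-cause death probability q(age) for integer ages."""

    start_age: int
    qx: np.ndarray  # q at start_age, start_age+1, ...

    def __post_init__(self) -> None:
        q = np.asarray(self.qx, dtype=float)
        if q.ndim != 1 or len(q) == 0:
            raise ValueError("qx must be a nonempty 1-d array")
        if np.any(q <= 0) or np.any(q >= 1):
            raise ValueError("death probabilities must lie in (0, 1)")
        object.__setattr__(self, "qx", q)

    @property
    def max_age(self) -> int:
        return self.start_age + len(self.qx) - 1

    def q(self, age) -> np.ndarray | float:
        """q at ``age``; ages beyond the table reuse the last entry."""
        idx = np.clip(np.asarray(age, dtype=int) - self.start_age, 0, len(self.qx) - 1)
        out = self.qx[idx]
        return float(out) if np.isscalar(age) else out

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(
            {"age": np.arange(self.start_age, self.max_age + 1), "qx": self.qx}
        ).to_csv(path, index=False, float_format="%.10g")
        return path


def synth_life_table(
    start_age: int = 50,
    span: int = 70,
    base_q: float = 0.004,
    growth: float = 0.09,
) -> LifeTable:
    """Gompertz-style synthetic life table.

    ``q(age) = base_q * exp(growth * (age - start_age))``, capped just below
    1.  The defaults (q(50)=0.004, 9%/year growth) match the order of
    magnitude of published US period tables at age 50 and give a remaining
    life expectancy at 50 in the low thirties.
    """
    if not (0.0 < base_q < 0.1):
        raise ValueError("base_q must lie in (0, 0.1)")
    if growth < 0:
        raise ValueError("growth must be nonnegative")
    if span < 1:
        raise ValueError("span must be at least one year")
    ages = np.arange(span, dtype=float)
    q = np.minimum(base_q * np.exp(growth * ages), 1.0 - 1e-9)
    return LifeTable(start_age=start_age, qx=q)


def load_life_table(path: str | Path) -> LifeTable:
    """Read an ``age,qx`` CSV (contiguous integer ages)."""
    frame = pd.read_csv(path)
    if not {"age", "qx"} <= set(frame.columns):
        raise ValueError(f"{path}: expected columns age,qx")
    frame = frame.sort_values("age")
    ages = frame["age"].to_numpy(dtype=int)
    if np.any(np.diff(ages) != 1):
        raise ValueError(f"{path}: ages must be contiguous")
    return LifeTable(start_age=int(ages[0]), qx=frame["qx"].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Packaged parameter defaults
# ---------------------------------------------------------------------------

def default_parameters_path() -> Path:
    return Path(resources.files("cardiocea").joinpath("data/annual_parameters.csv"))


def default_parameters() -> ParameterSet:
    """The packaged default parameter set (validated and complete)."""
    return load_parameters(default_parameters_path())


def write_default_parameters(path: str | Path) -> Path:
    """Copy the packaged default parameter CSV to ``path`` byte-identically."""
    path = Path(path)
    shutil.copyfile(default_parameters_path(), path)
    return path


# ---------------------------------------------------------------------------
# Derivation helpers for constructed inputs
# ---------------------------------------------------------------------------

def first_year_productivity(absenteeism: float, presenteeism_multiplier: float = 4.0) -> float:
    """Total lost productivity in the year of diagnosis: absenteeism plus
    presenteeism at ``presenteeism_multiplier`` times the absenteeism cost."""
    return absenteeism * (1.0 + presenteeism_multiplier)


followup_productivity = first_year_productivity  # same construction, later years


def annual_ischemic_stroke_risk(
    annual_strokes: float = 800_000,
    ischemic_fraction: float = 0.9,
    adult_population: float = 200_000_000,
) -> float:
    """General-population annual ischemic stroke risk from national counts."""
    return annual_strokes * ischemic_fraction / adult_population


# ---------------------------------------------------------------------------
# Life-expectancy validation
# ---------------------------------------------------------------------------

def validate_life_expectancy(
    ps: ParameterSet | None,
    lt: LifeTable,
    band: tuple[float, float] = (28.0, 35.0),
) -> float:
    """Undiscounted remaining life expectancy at the table's start age for a
    disease-free cohort (all event risks zero), by running the survival
    curve to the end of the table.

    Uses the same trapezoidal (half-cycle) person-year accrual as the
    cohort engine, so a degenerate table with q=1 everywhere yields 0.5.
    Returns the life expectancy; raise-free -- callers compare against
    ``band`` (the default 28-35 years brackets US period tables at age 50).
    """
    survival = np.concatenate([[1.0], np.cumprod(1.0 - lt.qx)])
    le = float(np.sum((survival[:-1] + survival[1:]) / 2.0))
    return le
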