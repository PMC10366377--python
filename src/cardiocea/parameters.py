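"""Model parameter registry: specifications, validation, risk-scale
conversions and probabilistic sampling.

Every annual input of the decision model (probabilities, relative effects,
utilities, disutilities and costs) is carried as a :class:`ParameterSpec`
with a baseline value, a one-way sensitivity range and a sampling
distribution for probabilistic sensitivity analysis.  The packaged default
set ships as a CSV fixture (see :mod:`cardiocea.fixtures`); this module is
agnostic about where the numbers come from.

Distribution conventions
------------------------
* ``beta(a, b)``      -- probabilities, utilities and disutilities; mean a/(a+b).
* ``lognormal(mu, sigma)`` -- relative effects (hazard/odds/risk ratios);
  parameters on the log scale.
* ``gamma(a, b)``     -- costs, with ``b`` a *rate*, so the mean is a/b.
* ``fixed``           -- never sampled.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "ParameterSpec",
    "ParameterSet",
    "ParameterValidationError",
    "ParameterParseError",
    "load_parameters",
    "write_parameters",
    "annualize_risk",
    "apply_relative_effect",
    "sample_parameters",
    "REQUIRED_PARAMETERS",
]


class ParameterValidationError(ValueError):
    """A parameter specification violates a model invariant."""


class ParameterParseError(ValueError):
    """A parameter file row could not be parsed."""


DIST_FAMILIES = ("beta", "lognormal", "gamma", "fixed")
ROLES = ("probability", "relative_effect", "utility", "disutility", "cost")

# Which sampling families are admissible for which role (mirrors the
# distribution assignment rule: beta for probability-like quantities,
# log-normal for ratios, gamma for costs).
_ROLE_FAMILIES = {
    "probability": {"beta", "fixed"},
    "utility": {"beta", "fixed"},
    "disutility": {"beta", "fixed"},
    "relative_effect": {"lognormal", "fixed"},
    "cost": {"gamma", "fixed"},
}

#: Identifiers the transition engine and reward schedules dereference.  A
#: ParameterSet missing any of these fails validation at load time.
REQUIRED_PARAMETERS = frozenset(
    {
        "init_low_pce",
        "init_moderate_pce",
        "init_high_pce",
        "enrollment",
        "risk_cad_high_pce",
        "risk_cad_moderate_pce",
        "or_cad_high_prs",
        "hr_cad_diabetes",
        "risk_cad_after_ischemic_stroke",
        "risk_ischemic_stroke",
        "risk_ischemic_stroke_after_cad",
        "hr_ischemic_stroke_diabetes",
        "risk_ischemic_stroke_post_hemorrhagic",
        "statin_hr_cad",
        "statin_hr_ischemic_stroke",
        "statin_adherence",
        "risk_myopathy",
        "risk_statin_diabetes",
        "risk_statin_hemorrhagic_stroke",
        "mort_acute_cad",
        "mort_chronic_cad",
        "hr_mort_cad_diabetes",
        "mort_stroke_and_cad",
        "mort_acute_ischemic_stroke",
        "mort_chronic_stroke",
        "rr_mort_stroke_diabetes",
        "mort_acute_hemorrhagic_stroke",
        "hr_mort_diabetes",
        "u_cad",
        "u_myopathy",
        "u_diabetes",
        "u_stroke",
        "du_acute_cad",
        "du_acute_stroke",
        "du_age_annual",
        "cost_prs_test",
        "cost_standard_whp_screening",
        "cost_mobile_app",
        "cost_primary_care_visit",
        "cost_statin",
        "cost_background",
        "cost_acute_cad_nonfatal",
        "cost_acute_cad_fatal",
        "cost_acute_ischemic_stroke_nonfatal",
        "cost_acute_ischemic_stroke_fatal",
        "cost_acute_hemorrhagic_stroke_nonfatal",
        "cost_acute_hemorrhagic_stroke_fatal",
        "cost_followup_cad",
        "cost_followup_stroke",
        "cost_followup_myopathy",
        "cost_followup_diabetes",
        "cost_productivity_first_year_cad_stroke",
        "cost_productivity_followup_cad_stroke",
        "cost_productivity_diabetes",
        "cost_productivity_followup_myopathy",
    }
)


@dataclass(frozen=True)
class ParameterSpec:
    """One model input with its uncertainty specification.

    ``low``/``high`` are the one-way sensitivity endpoints; ``low == high ==
    baseline`` marks a value that is held fixed in one-way analysis.
    ``shape_a``/``shape_b`` parameterise the sampling family (see module
    docstring); they are ignored for ``fixed``.
    """

    name: str
    baseline: float
    low: float
    high: float
    dist_family: str
    shape_a: float = float("nan")
    shape_b: float = float("nan")
    units: str = ""
    role: str = "probability"
    source: str = ""

    def validate(self) -> None:
        if self.role not in ROLES:
            raise ParameterValidationError(f"{self.name}: unknown role {self.role!r}")
        if self.dist_family not in DIST_FAMILIES:
            raise ParameterValidationError(
                f"{self.name}: unknown distribution family {self.dist_family!r}"
            )
        base = np.asarray(self.baseline, dtype=float)
        if not (np.all(self.low <= base) and np.all(base <= self.high)):
            raise ParameterValidationError(
                f"{self.name}: range [{self.low}, {self.high}] does not bracket "
                f"baseline {self.baseline}"
            )
        if self.role in ("probability", "utility", "disutility"):
            if np.any(base < 0.0) or np.any(base > 1.0):
                raise ParameterValidationError(
                    f"{self.name}: {self.role} baseline {self.baseline} outside [0, 1]"
                )
        elif self.role == "cost":
            if np.any(base < 0.0):
                raise ParameterValidationError(
                    f"{self.name}: cost baseline {self.baseline} is negative"
                )
        elif self.role == "relative_effect":
            if np.any(base <= 0.0):
                raise ParameterValidationError(
                    f"{self.name}: relative effect baseline must be positive"
                )
        if self.dist_family not in _ROLE_FAMILIES[self.role]:
            raise ParameterValidationError(
                f"{self.name}: family {self.dist_family!r} not admissible for "
                f"role {self.role!r}"
            )
        if self.dist_family != "fixed":
            if not (np.isfinite(self.shape_a) and np.isfinite(self.shape_b)):
                raise ParameterValidationError(
                    f"{self.name}: missing shape parameters for {self.dist_family}"
                )
            if self.dist_family in ("beta", "gamma") and (
                self.shape_a <= 0 or self.shape_b <= 0
            ):
                raise ParameterValidationError(
                    f"{self.name}: {self.dist_family} shapes must be positive"
                )
            if self.dist_family == "lognormal" and self.shape_b <= 0:
                raise ParameterValidationError(
                    f"{self.name}: lognormal sigma must be positive"
                )

    @property
    def has_range(self) -> bool:
        return self.low < self.high

    def distribution_mean(self) -> float:
        """Mean implied by the sampling distribution (baseline if fixed)."""
        if self.dist_family == "beta":
            return self.shape_a / (self.shape_a + self.shape_b)
        if self.dist_family == "gamma":
            return self.shape_a / self.shape_b
        if self.dist_family == "lognormal":
            return float(np.exp(self.shape_a + self.shape_b**2 / 2.0))
        return self.baseline


@dataclass
class ParameterSet:
    """Named, validated collection of :class:`ParameterSpec` entries."""

    entries: dict[str, ParameterSpec]
    provenance: str = ""

    def __post_init__(self) -> None:
        for name, spec in self.entries.items():
            if name != spec.name:
                raise ParameterValidationError(
                    f"entry key {name!r} does not match spec name {spec.name!r}"
                )
            spec.validate()

    def __getitem__(self, name: str) -> ParameterSpec:
        return self.entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __iter__(self):
        return iter(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)

    def value(self, name: str):
        """Baseline (or sampled) value of a parameter; hard error if absent."""
        try:
            return self.entries[name].baseline
        except KeyError:
            raise ParameterValidationError(
                f"parameter {name!r} required by the model is missing"
            ) from None

    def check_complete(self, required: Iterable[str] = REQUIRED_PARAMETERS) -> None:
        missing = sorted(set(required) - set(self.entries))
        if missing:
            raise ParameterValidationError(
                "parameter set is missing required entries: " + ", ".join(missing)
            )

    def with_value(self, name: str, value: float) -> "ParameterSet":
        """Copy of the set with one baseline replaced (range left alone).

        Used by one-way sensitivity analysis; the replacement is not
        re-checked against the original range on purpose.
        """
        if name not in self.entries:
            raise ParameterValidationError(f"unknown parameter {name!r}")
        new = dict(self.entries)
        spec = self.entries[name]
        new[name] = replace(
            spec,
            baseline=value,
            low=min(spec.low, np.min(value)),
            high=max(spec.high, np.max(value)),
        )
        return ParameterSet(new, provenance=self.provenance)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "name": s.name,
                "baseline": s.baseline,
                "low": s.low,
                "high": s.high,
                "dist_family": s.dist_family,
                "shape_a": s.shape_a,
                "shape_b": s.shape_b,
                "units": s.units,
                "role": s.role,
                "source": s.source,
            }
            for s in self.entries.values()
        ]
        return pd.DataFrame(rows)


_COLUMNS = [
    "name",
    "baseline",
    "low",
    "high",
    "dist_family",
    "shape_a",
    "shape_b",
    "units",
    "role",
    "source",
]


def _specs_from_records(records: Iterable[Mapping], provenance: str) -> ParameterSet:
    entries: dict[str, ParameterSpec] = {}
    for i, row in enumerate(records):
        try:
            name = str(row["name"]).strip()
            spec = ParameterSpec(
                name=name,
                baseline=float(row["baseline"]),
                low=float(row.get("low", row["baseline"])),
                high=float(row.get("high", row["baseline"])),
                dist_family=str(row.get("dist_family", "fixed")).strip(),
                shape_a=float(row.get("shape_a", float("nan"))),
                shape_b=float(row.get("shape_b", float("nan"))),
                units=str(row.get("units", "") or ""),
                role=str(row["role"]).strip(),
                source=str(row.get("source", "") or ""),
            )
        except ParameterValidationError:
            raise
        except (KeyError, TypeError, ValueError) as exc:
            raise ParameterParseError(f"row {i} ({row!r}): {exc}") from exc
        if name in entries:
            raise ParameterParseError(f"row {i}: duplicate parameter {name!r}")
        entries[name] = spec
    return ParameterSet(entries, provenance=provenance)


def load_parameters(path: str | Path, *, require_complete: bool = True) -> ParameterSet:
    """Read a parameter file (CSV or YAML) into a validated :class:`ParameterSet`.

    CSV files need the columns ``name, baseline, low, high, dist_family,
    shape_a, shape_b, units, role, source``; the YAML dialect is a mapping
    ``parameters: [ {name: ..., baseline: ..., ...}, ... ]``.  Both formats
    round-trip losslessly through :func:`write_parameters`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict) or "parameters" not in doc:
            raise ParameterParseError(f"{path}: expected a 'parameters' list")
        ps = _specs_from_records(doc["parameters"], provenance=str(path))
    else:
        try:
            frame = pd.read_csv(path, comment="#")
        except Exception as exc:  # malformed CSV
            raise ParameterParseError(f"{path}: {exc}") from exc
        missing_cols = {"name", "baseline", "role"} - set(frame.columns)
        if missing_cols:
            raise ParameterParseError(
                f"{path}: missing columns {sorted(missing_cols)}"
            )
        frame = frame.where(pd.notna(frame), other=float("nan"))
        records = frame.to_dict(orient="records")
        for rec in records:
            for key in ("units", "source"):
                if isinstance(rec.get(key), float) and np.isnan(rec[key]):
                    rec[key] = ""
        ps = _specs_from_records(records, provenance=str(path))
    if require_complete:
        ps.check_complete()
    return ps


def write_parameters(ps: ParameterSet, path: str | Path) -> Path:
    """Write a ParameterSet to CSV or YAML (chosen by extension)."""
    path = Path(path)
    frame = ps.to_frame()[_COLUMNS]
    if path.suffix.lower() in (".yaml", ".yml"):
        records = frame.to_dict(orient="records")
        with open(path, "w") as fh:
            yaml.safe_dump({"parameters": records}, fh, sort_keys=False)
    else:
        frame.to_csv(path, index=False, float_format="%.10g")
    return path


# ---------------------------------------------------------------------------
# Risk-scale conversions
# ---------------------------------------------------------------------------

def annualize_risk(p_horizon, years):
    """Constant-hazard annual probability from a multi-year probability.

    ``1 - (1 - p)**(1/years)``: e.g. a 20% ten-year risk is a 0.022 annual
    risk.  ``p_horizon`` must lie in [0, 1).
    """
    p = np.asarray(p_horizon, dtype=float)
    if np.any(p < 0) or np.any(p >= 1):
        raise ValueError("p_horizon must lie in [0, 1)")
    if years <= 0:
        raise ValueError("years must be positive")
    out = 1.0 - (1.0 - p) ** (1.0 / years)
    return float(out) if np.isscalar(p_horizon) else out


def apply_relative_effect(p, effect, method: str = "hazard"):
    """Apply a relative effect to a probability on a chosen scale.

    ``hazard``: ``1 - (1 - p)**effect`` (hazard ratios);
    ``direct``: ``min(p * effect, 1)`` (plain risk multipliers, e.g. the
    1.9-fold high-PRS increase);
    ``odds``: transform on the odds scale (odds ratios).
    """
    p_arr = np.asarray(p, dtype=float)
    e_arr = np.asarray(effect, dtype=float)
    if np.any(e_arr <= 0):
        raise ValueError("effect must be positive")
    if np.any(p_arr < 0) or np.any(p_arr > 1):
        raise ValueError("p must lie in [0, 1]")
    if method == "hazard":
        out = 1.0 - (1.0 - p_arr) ** e_arr
    elif method == "direct":
        out = np.minimum(p_arr * e_arr, 1.0)
    elif method == "odds":
        odds = p_arr / (1.0 - p_arr) * e_arr
        out = odds / (1.0 + odds)
        out = np.where(p_arr >= 1.0, 1.0, out)
    else:
        raise ValueError(f"unknown method {method!r}")
    if np.isscalar(p) and np.isscalar(effect):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Probabilistic sampling
# ---------------------------------------------------------------------------

def _param_rng(seed: int, name: str) -> np.random.Generator:
    # Independent, reproducible substream per parameter: adding or removing
    # a parameter does not perturb any other parameter's draws.
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(int(seed), zlib.crc32(name.encode())))
    )


def sample_parameters(
    ps: ParameterSet, rng_seed: int, n: int | None = None
) -> ParameterSet:
    """Independent draw(s) from every non-fixed entry's distribution.

    With ``n=None`` each baseline is replaced by a single scalar draw; with
    an integer ``n`` each baseline becomes an ``(n,)`` array (the transition
    engine broadcasts over draws).  Fixed entries are left unchanged.  Draws
    are reproducible under ``rng_seed`` and uncorrelated across parameters.
    """
    size = 1 if n is None else int(n)
    new: dict[str, ParameterSpec] = {}
    for spec in ps:
        if spec.dist_family == "fixed":
            value = np.full(size, spec.baseline) if n is not None else spec.baseline
        else:
            rng = _param_rng(rng_seed, spec.name)
            if spec.dist_family == "beta":
                draws = stats.beta.rvs(
                    spec.shape_a, spec.shape_b, size=size, random_state=rng
                )
            elif spec.dist_family == "gamma":
                # shape_b is a rate
                draws = stats.gamma.rvs(
                    spec.shape_a, scale=1.0 / spec.shape_b, size=size, random_state=rng
                )
            else:  # lognormal
                draws = stats.lognorm.rvs(
                    spec.shape_b, scale=np.exp(spec.shape_a), size=size, random_state=rng
                )
            value = draws if n is not None else float(draws[0])
        lo = float(np.min(value))
        hi = float(np.max(value))
        new[spec.name] = replace(
            spec,
            baseline=value,
            low=min(spec.low, lo),
            high=max(spec.high, hi),
        )
    return ParameterSet(new, provenance=f"{ps.provenance} [sampled seed={rng_seed}]")
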