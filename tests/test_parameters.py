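"""Parameter registry: loading, validation, risk conversions, sampling."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cardiocea.parameters import (
    ParameterSet,
    ParameterSpec,
    ParameterValidationError,
    annualize_risk,
    apply_relative_effect,
    load_parameters,
    sample_parameters,
    write_parameters,
)
from cardiocea.fixtures import default_parameters_path


def test_packaged_defaults_load_and_match_key_entries(ps):
    spec = ps["statin_hr_cad"]
    assert spec.baseline == pytest.approx(0.560)
    assert (spec.low, spec.high) == (0.400, 0.780)
    assert spec.dist_family == "lognormal"
    assert (spec.shape_a, spec.shape_b) == (-0.580, 0.090)
    assert ps.value("cost_prs_test") == 145
    assert ps.value("u_stroke") == pytest.approx(0.630)
    assert len(ps) == 55


def test_missing_required_parameter_is_hard_error(ps):
    entries = {k: v for k, v in ps.entries.items() if k != "risk_ischemic_stroke"}
    broken = ParameterSet(entries)
    with pytest.raises(ParameterValidationError, match="risk_ischemic_stroke"):
        broken.check_complete()
    with pytest.raises(ParameterValidationError):
        broken.value("risk_ischemic_stroke")


@pytest.mark.parametrize(
    "kwargs,match",
    [
        (dict(baseline=1.2, low=1.0, high=1.3, role="utility", dist_family="fixed"), "outside"),
        (dict(baseline=0.5, low=0.6, high=0.7, role="probability", dist_family="fixed"), "bracket"),
        (dict(baseline=10.0, low=5.0, high=15.0, role="cost", dist_family="beta",
              shape_a=2.0, shape_b=2.0), "not admissible"),
        (dict(baseline=0.5, low=0.4, high=0.6, role="probability", dist_family="beta",
              shape_a=-1.0, shape_b=2.0), "positive"),
    ],
)
def test_spec_validation_rejects_invariant_violations(kwargs, match):
    with pytest.raises(ParameterValidationError, match=match):
        ParameterSpec(name="bad", **kwargs).validate()


def test_parameter_files_round_trip_csv_and_yaml(ps, tmp_path):
    for ext in ("csv", "yaml"):
        path = tmp_path / f"params.{ext}"
        write_parameters(ps, path)
        again = load_parameters(path)
        assert set(again.entries) == set(ps.entries)
        for name, spec in ps.entries.items():
            other = again[name]
            assert other.baseline == pytest.approx(spec.baseline)
            assert other.dist_family == spec.dist_family
            assert other.shape_a == pytest.approx(spec.shape_a, nan_ok=True)
            assert other.shape_b == pytest.approx(spec.shape_b, nan_ok=True)


def test_annualize_risk_examples_match_printed_values():
    assert round(annualize_risk(0.20, 10), 3) == 0.022
    assert round(annualize_risk(0.125, 10), 3) == 0.013
    assert annualize_risk(0.0, 7) == 0.0
    with pytest.raises(ValueError):
        annualize_risk(1.0, 10)


@given(st.floats(0.0, 0.99), st.floats(0.001, 0.99))
def test_annualize_risk_monotone_and_identity(p1, p2):
    lo, hi = sorted([p1, p2])
    assert annualize_risk(lo, 10) <= annualize_risk(hi, 10) + 1e-15
    assert annualize_risk(p1, 1) == pytest.approx(p1)


def test_apply_relative_effect_examples():
    assert apply_relative_effect(0.022, 1.9, "direct") == pytest.approx(0.0418)
    assert apply_relative_effect(0.004, 2.27, "hazard") == pytest.approx(0.00906, abs=5e-6)
    for method in ("hazard", "direct", "odds"):
        assert apply_relative_effect(0.37, 1.0, method) == pytest.approx(0.37)
    assert apply_relative_effect(0.9, 5.0, "direct") == 1.0  # capped
    with pytest.raises(ValueError):
        apply_relative_effect(0.1, 0.0, "hazard")
    with pytest.raises(ValueError):
        apply_relative_effect(0.1, 2.0, "nonsense")


@given(st.floats(0.0, 1.0), st.floats(0.05, 5.0), st.floats(0.05, 5.0))
def test_hazard_scale_effects_compose_multiplicatively(p, e1, e2):
    once = apply_relative_effect(p, e1 * e2, "hazard")
    twice = apply_relative_effect(apply_relative_effect(p, e1, "hazard"), e2, "hazard")
    assert twice == pytest.approx(once, abs=1e-12)


def test_shipped_beta_gamma_means_match_baselines_within_2pct(ps):
    for spec in ps:
        if spec.dist_family in ("beta", "gamma"):
            assert spec.distribution_mean() == pytest.approx(
                spec.baseline, rel=0.02
            ), spec.name


def test_sampling_means_and_bounds(ps):
    sampled = sample_parameters(ps, rng_seed=123, n=10_000)
    low_pce = np.asarray(sampled.value("init_low_pce"))
    assert low_pce.mean() == pytest.approx(8.660 / (8.660 + 12.460), rel=0.01)
    hr = np.asarray(sampled.value("statin_hr_cad"))
    assert hr.mean() == pytest.approx(np.exp(-0.580 + 0.090**2 / 2), rel=0.01)
    for spec in sampled:
        v = np.asarray(spec.baseline)
        if spec.role in ("probability", "utility", "disutility"):
            assert np.all((v >= 0) & (v <= 1)), spec.name
        elif spec.role == "cost":
            assert np.all(v >= 0), spec.name


def test_sampling_reproducible_and_per_parameter_streams(ps):
    a = sample_parameters(ps, rng_seed=42)
    b = sample_parameters(ps, rng_seed=42)
    for name in ps.entries:
        assert a.value(name) == b.value(name)
    # dropping one parameter must not perturb any other parameter's draw
    entries = {k: v for k, v in ps.entries.items() if k != "u_cad"}
    c = sample_parameters(ParameterSet(entries), rng_seed=42)
    for name in entries:
        assert c.value(name) == a.value(name)


def test_fixed_entries_are_never_perturbed(ps):
    frozen = ParameterSet(
        {
            k: dataclasses.replace(v, dist_family="fixed")
            for k, v in ps.entries.items()
        }
    )
    sampled = sample_parameters(frozen, rng_seed=9)
    for name, spec in ps.entries.items():
        assert sampled.value(name) == spec.baseline


def test_with_value_replaces_baseline_only():
    ps = default_parameters_path()
    base = load_parameters(ps)
    bumped = base.with_value("cost_statin", 200.0)
    assert bumped.value("cost_statin") == 200.0
    assert base.value("cost_statin") == 132
    with pytest.raises(ParameterValidationError):
        base.with_value("no_such_parameter", 1.0)
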