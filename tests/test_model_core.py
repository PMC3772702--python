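"""Core equations: baseline values, derivatives, Jacobian, parameter I/O."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from meiosim import (
    ParameterSet,
    default_parameters,
    jacobian,
    load_parameters,
    mitotic_initial_state,
    override,
    rate_from_half_life,
    rhs,
    save_parameters,
    wild_type,
)
from meiosim.model_core import PARAM_NAMES

from conftest import random_admissible_states

TABLE_BASELINE = {
    "s_ime1": 10, "s_ime2": 10, "s2_ime2": 3, "d_ime1": 1, "d2_ime1": 1,
    "d_pime1": 1, "d_ime2": 8, "p_rim11": 0.01, "u_rim11": 0.1,
    "p_ume6": 0.3, "u_ume6": 0.01, "p_sok2": 0.7, "u_sok2": 1,
    "p_ime1": 2, "c_sok2": 0.05, "c_ime1": 0.01, "c1": 0.01,
    "c2": 1.4, "c3": 2,
}


class TestDefaults:
    def test_baseline_values(self, params):
        for name, value in TABLE_BASELINE.items():
            assert getattr(params, name) == value, name
        assert params.hill_n == 5

    def test_all_rates_nonnegative(self, params):
        assert all(getattr(params, n) >= 0 for n in PARAM_NAMES if n != "hill_n")

    def test_rejects_negative_and_nan(self):
        with pytest.raises(ValueError):
            ParameterSet(s_ime1=-1.0)
        with pytest.raises(ValueError):
            ParameterSet(d_ime2=float("nan"))
        with pytest.raises(ValueError):
            ParameterSet(hill_n=0)

    def test_inf_only_for_limit_capable(self):
        ParameterSet(c2=math.inf)  # allowed
        with pytest.raises(ValueError):
            ParameterSet(d_ime2=math.inf)


class TestRateFromHalfLife:
    @pytest.mark.parametrize(
        "half_life, expected",
        [(1.0, math.log(2)), (1 / 12, 12 * math.log(2)), (0.5, 2 * math.log(2))],
    )
    def test_exponential_decay_formula(self, half_life, expected):
        assert rate_from_half_life(half_life) == pytest.approx(expected)

    def test_five_minute_half_life_rounds_to_eight_per_hour(self):
        # Ime2's ~5 min half-life motivates the baseline value 8/h
        assert round(rate_from_half_life(1 / 12)) == 8

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            rate_from_half_life(bad)


class TestMitoticState:
    def test_only_psok2_is_one(self):
        y = mitotic_initial_state()
        assert y[2] == 1.0
        assert np.all(np.delete(y, 2) == 0.0)
        assert np.all(y[:3] >= 0) and np.all(y[:3] <= 1)


class TestRhs:
    def test_near_zero_at_published_steady_state(self, params, wt):
        # residual only from 2-decimal rounding of the published fixed point
        state = np.array([0.91, 0.96, 0.25, 0.05, 0.10, 0.27])
        assert np.max(np.abs(rhs(state, params, wt))) <= 0.1

    def test_mitotic_state_derivatives(self, params, wt):
        d = rhs(mitotic_initial_state(), params, wt)
        assert d[0] == pytest.approx(0.1)    # u_rim11 * (1 - 0)
        assert d[2] == pytest.approx(-1.0)   # (1 - pSok2) = 0, so -u_sok2 * 1
        assert d[3] == pytest.approx(10 * 0.01 / (0.01 + 1))

    def test_all_zero_state(self, params, wt):
        d = rhs(np.zeros(6), params, wt)
        assert d[2] == pytest.approx(0.7)    # p_sok2 at empty pSok2 pool, Ime1=0
        assert d[5] == 0.0                   # no source, auto-regulation off at 0

    def test_linear_in_synthesis_rates(self, params, wt, rng):
        state = random_admissible_states(rng, 1)[0]
        base = rhs(state, params, wt)
        doubled = rhs(state, params.with_overrides(s_ime1=2 * params.s_ime1), wt)
        synth = params.s_ime1 * params.c_ime1 / (params.c_ime1 + state[2])
        assert doubled[3] - base[3] == pytest.approx(synth, rel=1e-12)

    def test_boundary_derivatives_point_inward(self, params, wt, rng):
        # conserved pools cannot leave [0, 1]
        for i in range(3):
            lo = random_admissible_states(rng, 1)[0]
            lo[i] = 0.0
            assert rhs(lo, params, wt)[i] >= 0
            hi = random_admissible_states(rng, 1)[0]
            hi[i] = 1.0
            assert rhs(hi, params, wt)[i] <= 0

    def test_negative_state_rejected_but_roundoff_clamped(self, params, wt):
        y = mitotic_initial_state()
        y[3] = -1e-10  # integrator round-off: clamped
        rhs(y, params, wt)
        y[3] = -1e-6   # genuine violation
        with pytest.raises(ValueError):
            rhs(y, params, wt)

    def test_infinite_constants_take_analytic_limits(self, wt, rng):
        state = random_admissible_states(rng, 1)[0]
        p = default_parameters()
        # c_ime1 = inf: synthesis factor -> 1
        d = rhs(state, p.with_overrides(c_ime1=math.inf), wt)
        assert np.isfinite(d).all()
        expected = (
            p.s_ime1
            - p.p_ime1 * state[0] * state[3]
            - p.d_ime1 * state[3]
            - p.d2_ime1 * state[5] * state[3] / (p.c1 + state[3])
        )
        assert d[3] == pytest.approx(expected)
        # c1 = inf: Ime2-activated degradation vanishes at any state
        d = rhs(state, p.with_overrides(c1=math.inf), wt)
        no_fb = (
            p.s_ime1 * p.c_ime1 / (p.c_ime1 + state[2])
            - p.p_ime1 * state[0] * state[3]
            - p.d_ime1 * state[3]
        )
        assert d[3] == pytest.approx(no_fb)
        # c2 = inf: auto-regulation term vanishes
        d = rhs(state, p.with_overrides(c2=math.inf), wt)
        assert d[5] == pytest.approx(
            p.s_ime2 * state[1] * state[4] - p.d_ime2 * state[5] / (p.c3 + state[5])
        )

    def test_override_to_inf_via_variant(self, params, rng):
        v = override(wild_type(), "c1", "inf")
        state = random_admissible_states(rng, 1)[0]
        d_with = rhs(state, params, v)
        d_manual = rhs(state, params.with_overrides(c1=math.inf), wild_type())
        np.testing.assert_allclose(d_with, d_manual)


def _fd_jacobian(state, params, variant, eps=1e-6):
    J = np.zeros((6, 6))
    for j in range(6):
        e = np.zeros(6)
        e[j] = eps
        J[:, j] = (rhs(state + e, params, variant) - rhs(state - e, params, variant)) / (
            2 * eps
        )
    return J


class TestJacobian:
    def test_rim11_diagonal_is_constant(self, params, wt, rng):
        state = random_admissible_states(rng, 1)[0]
        assert jacobian(state, params, wt)[0, 0] == pytest.approx(-0.11)

    def test_ime2_source_partial_vanishes_at_zero_pume6(self, params, wt):
        assert jacobian(np.zeros(6), params, wt)[5, 4] == 0.0

    def test_matches_finite_differences_on_random_states(self, params, wt, rng):
        states = random_admissible_states(rng, 20)
        states += 0.05  # keep away from the FD-hostile clamping boundary
        states[:, :3] = np.clip(states[:, :3], 0.05, 0.95)
        for s in states:
            J = jacobian(s, params, wt)
            Jfd = _fd_jacobian(s, params, wt)
            scale = max(1.0, np.max(np.abs(Jfd)))
            assert np.max(np.abs(J - Jfd)) / scale < 1e-5

    def test_finite_differences_with_inf_constants(self, wt, rng):
        p = default_parameters().with_overrides(c_ime1=math.inf, c2=math.inf)
        s = random_admissible_states(rng, 1)[0] + 0.05
        s[:3] = np.clip(s[:3], 0.05, 0.95)
        J = jacobian(s, p, wt)
        Jfd = _fd_jacobian(s, p, wt)
        assert np.max(np.abs(J - Jfd)) < 1e-5


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    hl=st.floats(min_value=1e-3, max_value=1e3, allow_nan=False),
)
def test_half_life_rate_roundtrip(hl):
    rate = rate_from_half_life(hl)
    assert rate > 0
    assert math.log(2) / rate == pytest.approx(hl, rel=1e-12)


class TestParameterIO:
    def test_json_roundtrip_with_inf(self, tmp_path):
        p = default_parameters().with_overrides(c2=math.inf, s2_ime2=0.0)
        path = tmp_path / "params.json"
        save_parameters(p, path)
        q = load_parameters(path)
        assert q == p
        assert json.loads(path.read_text())["c2"] == "inf"

    def test_yaml_accepts_inf_string(self, tmp_path):
        path = tmp_path / "params.yaml"
        path.write_text("c_ime1: inf\nd_ime2: 4\n")
        p = load_parameters(path)
        assert math.isinf(p.c_ime1)
        assert p.d_ime2 == 4.0
        assert p.s_ime1 == 10.0  # untouched keys keep baseline values

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "params.json"
        path.write_text('{"nope": 1}')
        with pytest.raises(KeyError):
            load_parameters(path)
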