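"""One-compartment infusion kinetics: examples, invariants, ODE oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from piperpk.pk_core import (
    DoseEvent,
    StructuralParams,
    conc_events,
    conc_piecewise_cl,
    conc_total,
    events_to_array,
    profile,
    unbound,
)


def ode_profile(cl, v, doses, times, rtol=1e-11):
    """Independent oracle: integrate dC/dt = R(t)/V - (CL/V) C piecewise
    between infusion boundaries so the integrator never crosses a
    discontinuity in the input rate."""
    k = cl / v
    edges = sorted({0.0, *[d.start_time for d in doses], *[d.end_time for d in doses],
                    *times})

    def rate(t):
        return sum(d.rate for d in doses if d.start_time <= t < d.end_time)

    sol_at = {0.0: 0.0}
    c = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        r = rate(0.5 * (a + b))
        sol = solve_ivp(
            lambda t, y: [r / v - k * y[0]], (a, b), [c], rtol=rtol, atol=1e-12,
            dense_output=True,
        )
        for t in times:
            if a < t <= b:
                sol_at[t] = float(sol.sol(t)[0])
        c = float(sol.y[0, -1])
    return np.array([sol_at.get(t, 0.0) for t in times])


class TestConcTotal:
    def test_steady_state_continuous_infusion(self):
        # Css = R0/CL = 500/12 = 41.667 mg/L, independent of V
        params = StructuralParams(cl=12.0, v=50.0)
        long = [DoseEvent(0.0, 500.0 * 1000.0, 1000.0)]  # 500 mg/h for 1000 h
        assert conc_total(params, long, 900.0) == pytest.approx(41.667, abs=0.01)

    def test_zero_before_any_dose(self):
        params = StructuralParams(cl=12.0, v=29.8)
        assert conc_total(params, [DoseEvent(1.0, 4000.0, 0.5)], 0.0) == 0.0

    def test_single_infusion_end_value(self):
        # 4 g over 0.5 h, CL 12, V 29.8: (8000/12)(1 - e^(-0.402685*0.5))
        params = StructuralParams(cl=12.0, v=29.8)
        c = conc_total(params, [DoseEvent(0.0, 4000.0, 0.5)], 0.5)
        assert c == pytest.approx(121.57, abs=0.05)

    def test_superposition_of_simultaneous_events(self):
        params = StructuralParams(cl=9.0, v=31.0)
        one = [DoseEvent(0.0, 4000.0, 0.5)]
        two = [DoseEvent(0.0, 2000.0, 0.5), DoseEvent(0.0, 2000.0, 0.5)]
        t = np.linspace(0.0, 12.0, 37)
        np.testing.assert_allclose(
            conc_total(params, one, t), conc_total(params, two, t), rtol=1e-12
        )

    def test_input_validation(self):
        params = StructuralParams(cl=12.0, v=29.8)
        with pytest.raises(ValueError):
            conc_total(params, [DoseEvent(0.0, 4000.0, 0.5)], -1.0)
        with pytest.raises(ValueError):
            conc_total(params, [], 1.0)
        with pytest.raises(ValueError):
            DoseEvent(0.0, 4000.0, 0.0)
        with pytest.raises(ValueError):
            StructuralParams(cl=-1.0, v=29.8)


class TestUnbound:
    @pytest.mark.parametrize(
        "total,expected", [(100.0, 70.0), (0.0, 0.0), (160.0 / 0.7, 160.0)]
    )
    def test_thirty_percent_binding(self, total, expected):
        assert unbound(total) == pytest.approx(expected, rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            unbound(-1.0)


class TestProfile:
    def test_grid_validation(self):
        params = StructuralParams(cl=12.0, v=29.8)
        doses = [DoseEvent(0.0, 4000.0, 0.5)]
        with pytest.raises(ValueError):
            profile(params, doses, [0.0, 2.0, 1.0])

    def test_asymptote_of_continuous_infusion(self):
        # after >= 10 half-lives the level is within 0.1% of R0/CL
        params = StructuralParams(cl=12.0, v=29.8)
        t_half = np.log(2) / params.k
        doses = [DoseEvent(0.0, 500.0 * 200, 200.0)]
        grid = np.linspace(12 * t_half, 100.0, 20)
        np.testing.assert_allclose(profile(params, doses, grid), 500.0 / 12.0, rtol=1e-3)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_ode_oracle_on_random_regimens(self, seed):
        rng = np.random.default_rng(seed)
        cl = rng.uniform(4.0, 25.0)
        v = rng.uniform(15.0, 60.0)
        doses = [
            DoseEvent(float(s), float(rng.uniform(500, 6000)), float(rng.uniform(0.3, 6)))
            for s in np.sort(rng.uniform(0, 40, size=5))
        ]
        times = np.sort(rng.uniform(0.05, 48.0, size=25))
        got = profile(StructuralParams(cl, v), doses, times)
        want = ode_profile(cl, v, doses, times)
        np.testing.assert_allclose(got, want, rtol=1e-6, atol=1e-9)

    def test_linearity_and_time_shift(self):
        params = StructuralParams(cl=10.0, v=30.0)
        doses = [DoseEvent(0.0, 4000.0, 0.5), DoseEvent(6.0, 4000.0, 3.0)]
        scaled = [DoseEvent(d.start_time, 2.5 * d.amount, d.duration) for d in doses]
        shifted = [DoseEvent(d.start_time + 3.0, d.amount, d.duration) for d in doses]
        t = np.linspace(0.0, 24.0, 49)
        np.testing.assert_allclose(
            conc_total(params, scaled, t), 2.5 * np.asarray(conc_total(params, doses, t)),
            rtol=1e-12,
        )
        np.testing.assert_allclose(
            conc_total(params, shifted, t + 3.0), conc_total(params, doses, t), rtol=1e-12
        )

    def test_nonnegative_and_monotone_decay_after_last_infusion(self):
        params = StructuralParams(cl=10.0, v=30.0)
        doses = [DoseEvent(0.0, 4000.0, 0.5), DoseEvent(6.0, 4000.0, 3.0)]
        t = np.linspace(0.0, 48.0, 500)
        c = np.asarray(conc_total(params, doses, t))
        assert np.all(c >= 0)
        tail = c[t >= 9.0]
        assert np.all(np.diff(tail) <= 1e-12)


@st.composite
def regimens(draw):
    n = draw(st.integers(1, 4))
    starts = sorted(draw(st.lists(st.floats(0, 30), min_size=n, max_size=n)))
    return [
        DoseEvent(s, draw(st.floats(100, 8000)), draw(st.floats(0.25, 8)))
        for s in starts
    ]


class TestKineticsProperties:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        doses=regimens(),
        cl=st.floats(2, 40),
        v=st.floats(10, 80),
        alpha=st.floats(0.1, 10),
        delta=st.floats(0, 12),
    )
    def test_linearity_and_shift_equivariance(self, doses, cl, v, alpha, delta):
        params = StructuralParams(cl, v)
        t = np.linspace(0.0, 60.0, 61)
        base = np.asarray(conc_total(params, doses, t))
        assert np.all(base >= 0)
        scaled = [DoseEvent(d.start_time, alpha * d.amount, d.duration) for d in doses]
        np.testing.assert_allclose(
            conc_total(params, scaled, t), alpha * base, rtol=1e-9, atol=1e-12
        )
        shifted = [DoseEvent(d.start_time + delta, d.amount, d.duration) for d in doses]
        np.testing.assert_allclose(
            conc_total(params, shifted, t + delta), base, rtol=1e-9, atol=1e-12
        )


class TestPiecewiseClearance:
    def test_constant_cl_reduces_to_plain_superposition(self):
        events = events_to_array([DoseEvent(0.0, 4000.0, 0.5), DoseEvent(6.0, 4000.0, 3.0)])
        times = np.linspace(0.0, 48.0, 97)
        flat = conc_events(10.0, 30.0, events, times)
        piece = conc_piecewise_cl(
            np.array([[10.0, 10.0]]), np.array([30.0]), events, [0.0, 24.0, 48.0], times
        )[0]
        np.testing.assert_allclose(piece, flat, rtol=1e-10)

    def test_profile_continuous_at_occasion_boundary(self):
        events = events_to_array([DoseEvent(0.0, 12000.0, 48.0)])
        cl_occ = np.array([[8.0, 16.0]])
        t = np.array([23.999, 24.0, 24.001])
        c = conc_piecewise_cl(cl_occ, np.array([30.0]), events, [0.0, 24.0, 48.0], t)[0]
        assert abs(c[1] - c[0]) < 1e-2
        assert abs(c[2] - c[1]) < 1e-2

    def test_matches_ode_with_switching_clearance(self):
        doses = [DoseEvent(0.0, 4000.0, 0.5), DoseEvent(30.0, 6000.0, 2.0)]
        events = events_to_array(doses)
        v = 30.0
        cl1, cl2 = 9.0, 14.0
        times = np.linspace(0.1, 48.0, 40)
        got = conc_piecewise_cl(
            np.array([[cl1, cl2]]), np.array([v]), events, [0.0, 24.0, 48.0], times
        )[0]
        # oracle: integrate the ODE with time-varying k
        def rhs(t, y):
            r = sum(d.rate for d in doses if d.start_time <= t < d.end_time)
            k = (cl1 if t < 24.0 else cl2) / v
            return [r / v - k * y[0]]

        edges = sorted({0.0, 24.0, 48.0, *[d.start_time for d in doses],
                        *[d.end_time for d in doses], *times})
        c, want = 0.0, {}
        for a, b in zip(edges[:-1], edges[1:]):
            sol = solve_ivp(rhs, (a, b), [c], rtol=1e-11, atol=1e-12, dense_output=True)
            for t in times:
                if a < t <= b:
                    want[t] = float(sol.sol(t)[0])
            c = float(sol.y[0, -1])
        np.testing.assert_allclose(got, [want[t] for t in times], rtol=1e-6, atol=1e-9)
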