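"""Corridor inversion: closure, minimal-change flow, scheme, cube sweep."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stemfate import (
    CHANNELS,
    CorridorModel,
    CurveFamilyParams,
    InitialTriple,
    ProbabilityState,
    RateParams,
    close_probabilities,
    extremal_trajectory,
    integrate_scheme,
    make_ground_truth_bundle,
    make_reference_curve,
    minimal_change_rhs,
    scan_corridors,
    stem_fraction_rate,
)
from stemfate.errors import NoSolutionError, SingularClosureError

from conftest import constant_curve


def _closed_state(p1, p2, q2, s, sdot, rates):
    p3, p4, q1 = close_probabilities(p1, p2, q2, s, sdot, rates)
    return np.array([p1, p2, p3, p4, q1, q2])


class TestClosure:
    def test_balanced_state(self):
        rates = RateParams(1, 1)
        p3, p4, q1 = close_probabilities(0.0, 0.0, 0.0, 0.5, 0.0, rates)
        assert p3 == pytest.approx(1.0, abs=1e-14)
        assert p4 == pytest.approx(0.0, abs=1e-14)
        assert q1 == pytest.approx(1.0)

    def test_dedifferentiation_offset(self):
        rates = RateParams(1, 1)
        p3, p4, _ = close_probabilities(0.0, 0.0, 0.2, 0.5, 0.0, rates)
        assert p3 == pytest.approx(13.0 / 15.0, abs=1e-14)
        assert p4 == pytest.approx(2.0 / 15.0, abs=1e-14)

    def test_singular_at_zero_fraction(self):
        with pytest.raises(SingularClosureError):
            close_probabilities(0.1, 0.1, 0.1, 0.0, 0.0, RateParams(1, 1))

    def test_pure_stem_fraction_is_legal(self):
        p3, p4, q1 = close_probabilities(0.2, 0.1, 0.0, 1.0, -0.9, RateParams(1, 1))
        assert np.isfinite([p3, p4, q1]).all()

    @settings(derandomize=True, max_examples=200)
    @given(
        p1=st.floats(0, 0.6), p2=st.floats(0, 0.4), q2=st.floats(0, 1),
        s=st.floats(0.02, 1.0), sdot=st.floats(-0.5, 0.5),
        l1=st.floats(0.2, 5), l2=st.floats(0.2, 5),
        g1=st.floats(0, 1), g2=st.floats(0, 1),
    )
    def test_closure_identity(self, p1, p2, q2, s, sdot, l1, l2, g1, g2):
        """Substituting the closed state into the stem-fraction balance
        reproduces sdot exactly — the defining property of the closure."""
        rates = RateParams(l1, l2, g1, g2)
        p3, p4, q1 = close_probabilities(p1, p2, q2, s, sdot, rates)
        state = ProbabilityState.__new__(ProbabilityState)  # bypass [0,1] checks
        object.__setattr__(state, "p1", p1)
        object.__setattr__(state, "p2", p2)
        object.__setattr__(state, "p3", p3)
        object.__setattr__(state, "p4", p4)
        object.__setattr__(state, "q1", q1)
        object.__setattr__(state, "q2", q2)
        assert stem_fraction_rate(s, state, rates) == pytest.approx(sdot, abs=1e-10)


def _min_norm_rhs(p1, p2, q2, s, sdot, sddot, rates):
    """Independent oracle: the minimal-change derivatives are the minimum-
    norm solution for all six probability derivatives under (i) the
    differentiated stem-fraction balance and (ii) both simplex
    conservation laws."""
    l1, l2, g1, g2 = rates.lambda1, rates.lambda2, rates.gamma1, rates.gamma2
    p3, p4, _ = close_probabilities(p1, p2, q2, s, sdot, rates)
    dRds = ((p3 - p2 - p4) * l1 - (1 + q2) * l2 + g2 - g1) \
        + 2 * (l2 - (1 - p4) * l1 - g2 + g1) * s
    A = np.array([
        [0, -l1 * s, l1 * s, l1 * (s * s - s), 0, l2 * (1 - s)],
        [1, 1, 1, 1, 0, 0],
        [0, 0, 0, 0, 1, 1],
    ])
    b = np.array([sddot - dRds * sdot, 0.0, 0.0])
    x = A.T @ np.linalg.solve(A @ A.T, b)
    return x  # ordered (dp1, dp2, dp3, dp4, dq1, dq2)


class TestMinimalChangeRHS:
    def test_constant_curve_fixed_point(self):
        out = minimal_change_rhs(0.3, 0.1, 0.2, 0.5, 0.0, 0.0, RateParams(1, 5, 0.1, 0.1))
        assert out == (0.0, 0.0, 0.0)

    def test_pure_stem_freezes_p1_q2(self):
        dp1, dp2, dq2 = minimal_change_rhs(0.3, 0.1, 0.2, 1.0, -0.3, 0.1, RateParams(1, 2))
        assert dp1 == 0.0 and dq2 == 0.0
        assert dp2 != 0.0

    def test_matches_minimum_norm_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            l1, l2 = rng.uniform(0.2, 5, 2)
            g1, g2 = rng.uniform(0, 1, 2)
            rates = RateParams(l1, l2, g1, g2)
            s = rng.uniform(0.05, 1.0)
            sdot, sddot = rng.uniform(-0.5, 0.5, 2)
            p1, p2, q2 = rng.uniform(0, 0.5, 3)
            got = minimal_change_rhs(p1, p2, q2, s, sdot, sddot, rates)
            want = _min_norm_rhs(p1, p2, q2, s, sdot, sddot, rates)
            assert np.allclose(got, want[[0, 1, 5]], atol=1e-10, rtol=1e-8)


class TestIntegrateScheme:
    def test_constant_curve_constant_trajectory(self, rates_155):
        curve = constant_curve(0.4)
        # find an admissible triple: closure at s=0.4 must stay in [0,1]
        found = None
        for p1 in np.linspace(0, 1, 11):
            for p2 in np.linspace(0, 1, 11):
                for q2 in np.linspace(0, 1, 11):
                    p3, p4, _ = close_probabilities(p1, p2, q2, 0.4, 0.0, rates_155)
                    if 0 <= p3 <= 1 and 0 <= p4 <= 1:
                        found = (p1, p2, q2)
                        break
                if found:
                    break
            if found:
                break
        assert found is not None
        traj = integrate_scheme(InitialTriple(*found), curve, rates_155, dt=0.01)
        assert traj.feasible
        assert np.allclose(traj.probabilities, traj.probabilities[0], atol=1e-14)

    def test_ground_truth_recovery(self, rates_155, truth_state):
        curve, truth = make_ground_truth_bundle(rates_155, truth_state, T=10, n_points=201)
        traj = integrate_scheme(InitialTriple(truth.p1, truth.p2, truth.q2),
                                curve, rates_155, dt=0.001)
        assert traj.feasible
        assert np.max(np.abs(traj.probabilities - truth.as_array())) < 1e-3

    def test_simplex_sums_machine_exact(self, rates_155):
        curve = make_reference_curve(CurveFamilyParams(s_eq=0.1, k=1.0))
        traj = integrate_scheme(InitialTriple(0.3, 0.1, 0.3), curve, rates_155, dt=0.01)
        P = traj.probabilities
        assert np.max(np.abs(P[:, :4].sum(axis=1) - 1.0)) < 1e-14
        assert np.max(np.abs(P[:, 4:].sum(axis=1) - 1.0)) < 1e-14

    def test_second_order_convergence(self, rates_155):
        curve = make_reference_curve(CurveFamilyParams(s_eq=0.1, k=1.0, T=5.0))
        trip = InitialTriple(0.3, 0.1, 0.2)

        def end_state(dt):
            return integrate_scheme(trip, curve, rates_155, dt=dt).probabilities[-1]

        ref = end_state(0.0025)
        e1 = np.max(np.abs(end_state(0.04) - ref))
        e2 = np.max(np.abs(end_state(0.02) - ref))
        assert 3.0 <= e1 / e2 <= 5.0

    def test_infeasible_triple_flagged(self, rates_155):
        curve = make_reference_curve(CurveFamilyParams(s_eq=0.1, k=1.0))
        # p10 = 1 forces p4 < 0 at t=0 (closure cap on p1 is -sdot(0)/lambda1)
        traj = integrate_scheme(InitialTriple(1.0, 0.0, 0.0), curve, rates_155, dt=0.01)
        assert not traj.feasible
        assert traj.first_violation == 0


class TestScanCorridors:
    def test_constant_curve_matches_direct_closure(self):
        """On a flat curve the flow is frozen, so admissibility is exactly
        the t=0 closure feasibility of each lattice triple."""
        rates = RateParams(1, 1)
        curve = constant_curve(0.5)
        cs = scan_corridors(curve, rates, grid_step=0.25, dt=0.05)
        assert cs.n_swept == 125
        axis = np.linspace(0, 1, 5)
        expected = []
        for p1 in axis:
            for p2 in axis:
                for q2 in axis:
                    p3, p4, _ = close_probabilities(p1, p2, q2, 0.5, 0.0, rates)
                    if -1e-9 <= p3 <= 1 + 1e-9 and -1e-9 <= p4 <= 1 + 1e-9:
                        expected.append((p1, p2, q2))
        got = {tuple(t) for t in np.round(cs.admissible_triples, 10)}
        assert got == {tuple(np.round(e, 10)) for e in expected}
        assert np.allclose(cs.lower, cs.lower[0], atol=1e-12)
        assert np.allclose(cs.upper, cs.upper[0], atol=1e-12)

    def test_ground_truth_containment(self, rates_155, truth_state):
        curve, truth = make_ground_truth_bundle(rates_155, truth_state, T=10, n_points=201)
        cs = scan_corridors(curve, rates_155, grid_step=0.05, dt=0.02)
        lattice = np.round(cs.admissible_triples / 0.05) * 0.05
        assert any(np.allclose(t, [truth.p1, truth.p2, truth.q2], atol=1e-9) for t in lattice)
        flat_truth = np.tile(truth.as_array(), (len(cs.times), 1))
        assert cs.contains(flat_truth, tol=1e-9)

    def test_surviving_trajectories_inside_envelopes(self, rates_155):
        curve = make_reference_curve(CurveFamilyParams(s_eq=0.1, k=1.0))
        cs = scan_corridors(curve, rates_155, grid_step=0.2, dt=0.02)
        assert not cs.empty
        rng = np.random.default_rng(0)
        pick = rng.choice(len(cs.admissible_triples), size=min(5, len(cs.admissible_triples)),
                          replace=False)
        for i in pick:
            traj = integrate_scheme(InitialTriple(*cs.admissible_triples[i]),
                                    curve, rates_155, dt=0.02)
            assert traj.feasible
            assert cs.contains(traj.probabilities, tol=1e-9)

    def test_empty_corridor_is_legal(self):
        # initial slope steeper than lambda1 can absorb: at s(0)=1 the
        # closure needs p2 >= -1 - sdot/lambda1 > 1, impossible
        rates = RateParams(1.0, 5.0, 0.1, 0.1)
        curve = make_reference_curve(CurveFamilyParams(s_eq=0.1, k=6.0))
        cs = scan_corridors(curve, rates, grid_step=0.5, dt=0.1)
        assert cs.empty
        with pytest.raises(NoSolutionError):
            extremal_trajectory(curve, rates, "max_p10", corridors=cs)


class TestExtremalTrajectory:
    def test_constant_curve_max_p10_exhaustive(self):
        rates = RateParams(1, 1)
        curve = constant_curve(0.5)
        cs = scan_corridors(curve, rates, grid_step=0.25, dt=0.05)
        best = max(cs.admissible_triples[:, 0])
        traj = extremal_trajectory(curve, rates, "max_p10", corridors=cs)
        assert traj.triple.p10 == pytest.approx(best)
        assert np.allclose(traj.probabilities, traj.probabilities[0], atol=1e-12)

    def test_truth_attains_q20_bound(self, rates_155):
        # ground truth without dedifferentiation: q2 = 0 is admissible
        probs = ProbabilityState(0.2, 0.1, 0.6, 0.1, 1.0, 0.0)
        curve, _ = make_ground_truth_bundle(rates_155, probs, T=5, n_points=101)
        traj = extremal_trajectory(curve, rates_155, "min_q20", grid_step=0.1, dt=0.02)
        assert traj.triple.q20 == 0.0

    def test_model_results_wrapper(self, rates_155):
        curve = make_reference_curve(CurveFamilyParams(s_eq=0.1, k=1.0))
        res = CorridorModel(curve, rates_155).fit(grid_step=0.2, dt=0.02)
        traj = res.extremal("min_q20")
        assert traj.feasible
        text = res.summary()
        assert "admissible" in text and "q2" in text
        for name in CHANNELS:
            lo, hi = res.corridors.channel_bounds(name)
            assert np.all(lo <= hi + 1e-12)
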