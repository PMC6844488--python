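"""Shared fixtures: synthetic curves and factor sets with known ground truth."""

import numpy as np
import pytest

from stemfate import (
    CurveFamilyParams,
    FactorSet,
    FieldFactor,
    ProbabilityState,
    RateParams,
    ReferenceCurve,
    make_reference_curve,
)


@pytest.fixture
def rates_155() -> RateParams:
    """The reference rate set: slow stem divisions, 5x faster non-stem."""
    return RateParams(lambda1=1.0, lambda2=5.0, gamma1=0.1, gamma2=0.1)


@pytest.fixture
def fig_curve() -> ReferenceCurve:
    """Stabilization curve: pure stem culture relaxing to a 10% plateau."""
    return make_reference_curve(CurveFamilyParams(s_eq=0.1, k=1.0))


@pytest.fixture
def truth_state() -> ProbabilityState:
    """A constant scenario state on the 0.05 sweep lattice."""
    return ProbabilityState(0.55, 0.05, 0.3, 0.1, 0.8, 0.2)


def constant_curve(s_value: float, T: float = 10.0, n_points: int = 101) -> ReferenceCurve:
    """A flat stem-fraction curve (zero derivatives), analytic evaluators."""
    t = np.linspace(0.0, T, n_points)
    return ReferenceCurve(
        times=t,
        s=np.full(n_points, s_value),
        sdot=np.zeros(n_points),
        sddot=np.zeros(n_points),
        provenance="parametric",
        _s_fun=lambda tt: np.full_like(np.asarray(tt, dtype=float), s_value),
        _sdot_fun=lambda tt: np.zeros_like(np.asarray(tt, dtype=float)),
        _sddot_fun=lambda tt: np.zeros_like(np.asarray(tt, dtype=float)),
    )


def random_factor_set(seed: int, K: int = 3, span: float = 10.0) -> FactorSet:
    """Seeded random bump factors with separated centers.

    Centers keep at least 2 * a^(-1/m) apart (adjacent bumps overlap only
    in their tails) and amplitudes stay positive so channel sums remain
    inside [0, 1] for K <= 3.
    """
    rng = np.random.default_rng(seed)
    factors = []
    while True:
        a = rng.uniform(0.5, 2.0, K)
        half_widths = a ** (-1.0 / 6.0)
        c = np.sort(rng.uniform(0.08 * span, 0.92 * span, K))
        gaps = np.diff(c)
        need = half_widths[:-1] + half_widths[1:]
        if K == 1 or np.all(gaps >= need):
            break
    for k in range(K):
        b = rng.uniform(0.08, 0.3, 6)
        factors.append(FieldFactor(a=float(a[k]), c=float(c[k]), m=6, b_weights=b))
    return FactorSet(factors=factors)
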