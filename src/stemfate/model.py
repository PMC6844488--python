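"""Two-compartment stem / non-stem population model.

A cancer cell population is split into stem cells S and non-stem
("daughter") cells D.  Each cell-cycle event of an S cell realizes one of
four scenarios with probabilities p1..p4 (asymmetric division S->S+D,
symmetric differentiation S->D+D, symmetric renewal S->S+S, direct
transition S->D), and each event of a D cell one of two (symmetric
division D->D+D with q1, dedifferentiating asymmetric division D->S+D
with q2).  Events occur at rates lambda1 (S) and lambda2 (D); death rates
are gamma1 and gamma2.  The resulting mean-field dynamics are linear:

    dS/dt = alphaS * S + betaD * D
    dD/dt = betaS  * S + alphaD * D

with  alphaS = (p1 + 2 p3 - 1) lambda1 - gamma1,   betaD = q2 lambda2,
      betaS  = (p1 + 2 p2 + p4) lambda1,           alphaD = q1 lambda2 - gamma2.

The stem fraction s = S / (S + D) obeys the scalar Riccati equation used
throughout the inverse machinery:

    sdot = c0 + c1 s + c2 s^2,
    c0 = q2 lambda2,
    c1 = (p3 - p2 - p4) lambda1 - (1 + q2) lambda2 + gamma2 - gamma1,
    c2 = lambda2 - (1 - p4) lambda1 - gamma2 + gamma1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Union

import numpy as np

from .curves import ReferenceCurve
from .errors import DegeneratePopulationError, IntegrationError, ParameterError

__all__ = [
    "RateParams",
    "ProbabilityState",
    "PopulationTrajectory",
    "division_coefficients",
    "simulate_population",
    "stem_fraction",
    "stem_fraction_rate",
    "steady_state_fractions",
    "ANY_FRACTION",
]

_SUM_TOL = 1e-12

#: Sentinel returned by :func:`steady_state_fractions` when the balance
#: equation vanishes identically (S and D grow identically, every fraction
#: is stationary).
ANY_FRACTION = "any"


@dataclass(frozen=True)
class RateParams:
    """Constant per-capita event rates (per time unit; days by convention).

    lambda1 / lambda2: division-or-transition rates of S / D cells (> 0).
    gamma1 / gamma2: death rates of S / D cells (>= 0).
    """

    lambda1: float
    lambda2: float
    gamma1: float = 0.0
    gamma2: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise ParameterError("division rates lambda1, lambda2 must be > 0")
        if self.gamma1 < 0 or self.gamma2 < 0:
            raise ParameterError("death rates gamma1, gamma2 must be >= 0")


@dataclass(frozen=True)
class ProbabilityState:
    """One simplex point of the six cell-fate scenario probabilities."""

    p1: float
    p2: float
    p3: float
    p4: float
    q1: float
    q2: float

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p3", "p4", "q1", "q2"):
            v = getattr(self, name)
            if not (-_SUM_TOL <= v <= 1 + _SUM_TOL):
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if abs(self.p1 + self.p2 + self.p3 + self.p4 - 1.0) > 1e-9:
            raise ParameterError("p1 + p2 + p3 + p4 must equal 1")
        if abs(self.q1 + self.q2 - 1.0) > 1e-9:
            raise ParameterError("q1 + q2 must equal 1")

    @classmethod
    def from_arrays(cls, p, q) -> "ProbabilityState":
        p = np.asarray(p, dtype=float)
        q = np.asarray(q, dtype=float)
        return cls(p[0], p[1], p[2], p[3], q[0], q[1])

    def as_array(self) -> np.ndarray:
        return np.array([self.p1, self.p2, self.p3, self.p4, self.q1, self.q2])


Schedule = Union[ProbabilityState, Callable[[float], ProbabilityState]]


@dataclass
class PopulationTrajectory:
    """Time-ordered S(t), D(t) on a uniform grid with its generating inputs."""

    times: np.ndarray
    S: np.ndarray
    D: np.ndarray
    rates: RateParams
    schedule: Schedule = field(repr=False, default=None)

    @property
    def total(self) -> np.ndarray:
        return self.S + self.D


def division_coefficients(probs: ProbabilityState, rates: RateParams):
    """Linear-system coefficients (alphaS, betaD, betaS, alphaD).

    betaS is the pure per-stem-cell rate (p1 + 2 p2 + p4) * lambda1 of
    daughter production by S cells; see module docstring.
    """
    alphaS = (probs.p1 + 2.0 * probs.p3 - 1.0) * rates.lambda1 - rates.gamma1
    betaD = probs.q2 * rates.lambda2
    betaS = (probs.p1 + 2.0 * probs.p2 + probs.p4) * rates.lambda1
    alphaD = probs.q1 * rates.lambda2 - rates.gamma2
    return alphaS, betaD, betaS, alphaD


def _system_matrix(probs: ProbabilityState, rates: RateParams) -> np.ndarray:
    aS, bD, bS, aD = division_coefficients(probs, rates)
    return np.array([[aS, bD], [bS, aD]])


def simulate_population(
    rates: RateParams,
    schedule: Schedule,
    S0: float = 1.0,
    D0: float = 0.0,
    T: float = 10.0,
    dt: float = 0.01,
) -> PopulationTrajectory:
    """Integrate the S/D system with the classic fixed-step 4th-order scheme.

    ``schedule`` is either a constant :class:`ProbabilityState` or a callable
    t -> ProbabilityState (piecewise-linear system).  Raises
    :class:`IntegrationError` if an abundance goes negative beyond roundoff,
    which signals inconsistent parameters or too coarse a step.
    """
    if S0 < 0 or D0 < 0 or S0 + D0 <= 0:
        raise ParameterError("need S0 >= 0, D0 >= 0, S0 + D0 > 0")
    if dt <= 0 or T < dt:
        raise ParameterError("need dt > 0 and T >= dt")

    n_steps = int(round(T / dt))
    times = np.arange(n_steps + 1) * dt
    constant = isinstance(schedule, ProbabilityState)
    if constant:
        A = _system_matrix(schedule, rates)
        matrix_at = lambda t: A  # noqa: E731
    else:
        matrix_at = lambda t: _system_matrix(schedule(t), rates)  # noqa: E731

    out = np.empty((n_steps + 1, 2))
    x = np.array([S0, D0], dtype=float)
    out[0] = x
    for n in range(n_steps):
        t = times[n]
        A1 = matrix_at(t)
        Amid = A1 if constant else matrix_at(t + 0.5 * dt)
        Aend = A1 if constant else matrix_at(t + dt)
        k1 = A1 @ x
        k2 = Amid @ (x + 0.5 * dt * k1)
        k3 = Amid @ (x + 0.5 * dt * k2)
        k4 = Aend @ (x + dt * k3)
        x = x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        scale = max(1.0, float(np.max(np.abs(x))))
        if np.any(x < -1e-9 * scale):
            raise IntegrationError(
                f"negative abundance at t={times[n + 1]:.6g}: S={x[0]:.3g}, D={x[1]:.3g}"
            )
        x = np.maximum(x, 0.0)
        out[n + 1] = x

    return PopulationTrajectory(times=times, S=out[:, 0], D=out[:, 1], rates=rates, schedule=schedule)


def stem_fraction(traj: PopulationTrajectory) -> ReferenceCurve:
    """Stem fraction curve s(t) = S / (S + D) of a simulated trajectory.

    For a constant schedule the curve carries analytic continuous-time
    evaluators (matrix exponential of the 2x2 system) and analytic
    derivatives from the Riccati form, so downstream half-step evaluation
    is exact.
    """
    total = traj.total
    if np.any(total <= 0):
        raise DegeneratePopulationError("S + D hit zero; fraction undefined")
    s = traj.S / total

    if isinstance(traj.schedule, ProbabilityState):
        probs, rates = traj.schedule, traj.rates
        A = _system_matrix(probs, rates)
        evals, evecs = np.linalg.eig(A)
        x0 = np.array([traj.S[0], traj.D[0]])
        coef = np.linalg.solve(evecs, x0)
        c0, c1, c2 = _riccati_coefficients(probs, rates)

        def s_fun(tt):
            tt_arr = np.atleast_1d(np.asarray(tt, dtype=float))
            # S(t), D(t) via eigen-decomposition; shift by the largest
            # eigenvalue so exponentials stay bounded (fraction is invariant)
            lam_max = np.max(evals.real)
            w = coef[None, :] * np.exp(np.outer(tt_arr, evals - lam_max))
            x = (w @ evecs.T).real
            val = x[:, 0] / (x[:, 0] + x[:, 1])
            return val if np.ndim(tt) else float(val[0])

        def sdot_fun(tt):
            sv = s_fun(tt)
            return c0 + c1 * sv + c2 * sv * sv

        def sddot_fun(tt):
            sv = s_fun(tt)
            sd = c0 + c1 * sv + c2 * sv * sv
            return (c1 + 2.0 * c2 * sv) * sd

        return ReferenceCurve(
            times=traj.times,
            s=s,
            sdot=sdot_fun(traj.times),
            sddot=sddot_fun(traj.times),
            provenance="simulated",
            meta={"rates": rates, "probs": probs},
            _s_fun=s_fun,
            _sdot_fun=sdot_fun,
            _sddot_fun=sddot_fun,
        )

    # time-varying schedule: numeric derivatives via spline
    from .curves import differentiate_sampled_curve

    curve = differentiate_sampled_curve(traj.times, s, smoothing=0)
    curve.provenance = "simulated"
    return curve


def _riccati_coefficients(probs: ProbabilityState, rates: RateParams):
    """Coefficients (c0, c1, c2) of sdot = c0 + c1 s + c2 s^2."""
    l1, l2 = rates.lambda1, rates.lambda2
    g1, g2 = rates.gamma1, rates.gamma2
    c0 = probs.q2 * l2
    c1 = (probs.p3 - probs.p2 - probs.p4) * l1 - (1.0 + probs.q2) * l2 + g2 - g1
    c2 = l2 - (1.0 - probs.p4) * l1 - g2 + g1
    return c0, c1, c2


def stem_fraction_rate(s, probs: ProbabilityState, rates: RateParams):
    """Instantaneous sdot at stem fraction ``s`` (the Riccati right side)."""
    c0, c1, c2 = _riccati_coefficients(probs, rates)
    s = np.asarray(s, dtype=float)
    out = c0 + c1 * s + c2 * s * s
    return out if out.ndim else float(out)


def steady_state_fractions(probs: ProbabilityState, rates: RateParams, tol: float = 1e-12):
    """All stationary stem fractions in [0, 1].

    Roots of the Riccati balance c0 + c1 s + c2 s^2 = 0.  Degenerate cases:
    a vanishing quadratic term falls back to the linear root; all three
    coefficients zero returns :data:`ANY_FRACTION` (S and D grow at
    identical rates, so every fraction is stationary).  An empty array is a
    legal return (no equilibrium inside the unit interval).
    """
    c0, c1, c2 = _riccati_coefficients(probs, rates)
    scale = max(abs(c0), abs(c1), abs(c2), 1.0)
    if abs(c2) <= tol * scale:
        if abs(c1) <= tol * scale:
            if abs(c0) <= tol * scale:
                return ANY_FRACTION
            return np.array([])
        roots = np.array([-c0 / c1])
    else:
        disc = c1 * c1 - 4.0 * c2 * c0
        if disc < 0:
            return np.array([])
        sq = np.sqrt(disc)
        roots = np.array([(-c1 - sq) / (2 * c2), (-c1 + sq) / (2 * c2)])
    roots = np.unique(roots[(roots >= -1e-12) & (roots <= 1 + 1e-12)])
    return np.clip(roots, 0.0, 1.0)
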