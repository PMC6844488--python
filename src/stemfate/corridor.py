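"""Minimal-change inversion: probability corridors from a stem-fraction curve.

Given a stem-fraction curve s(t) with derivatives and fixed rates, the six
scenario probabilities are underdetermined: the Riccati relation and the
two simplex constraints leave three degrees of freedom, here parametrized
by (p1, p2, q2).  The remaining three follow from the algebraic *closure*

    p3 = [sdot - lambda2 q2 + (...) s] / [lambda1 s (2 - s)],
    p4 = 1 - p1 - p2 - p3,        q1 = 1 - q2.

The minimal-change principle selects, at every instant, the time
derivatives (p1dot, p2dot, q2dot) that minimize the summed squared change
of all six probabilities subject to the differentiated Riccati constraint
— biologically, cells keep their division program as steady as the
observed population dynamics permits.  The resulting explicit ODE system
is integrated with an implicit midpoint (second-order) scheme whose
update is linear in the unknowns, so each step is one rank-one solve.

Sweeping the cube of initial conditions (p10, p20, q20) and discarding
every triple whose trajectory leaves [0, 1] in any component yields the
*corridors*: pointwise min/max envelopes of all admissible probability
trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd

from .curves import ReferenceCurve
from .errors import NoSolutionError, ParameterError, SingularClosureError
from .model import RateParams

__all__ = [
    "InitialTriple",
    "ProbabilityTrajectory",
    "CorridorSet",
    "CHANNELS",
    "close_probabilities",
    "minimal_change_rhs",
    "integrate_scheme",
    "scan_corridors",
    "extremal_trajectory",
    "CorridorModel",
    "CorridorResults",
]

CHANNELS = ("p1", "p2", "p3", "p4", "q1", "q2")

_S_SINGULAR_TOL = 1e-12
_DEFAULT_FEAS_TOL = 1e-9  # slack on the [0, 1] bounds, absorbs roundoff


@dataclass(frozen=True)
class InitialTriple:
    """Initial values (p1, p2, q2) at t = 0 parametrizing one trajectory."""

    p10: float
    p20: float
    q20: float

    def __post_init__(self) -> None:
        for name in ("p10", "p20", "q20"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name}={v} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.p10, self.p20, self.q20])


@dataclass
class ProbabilityTrajectory:
    """Six probability channels on a uniform grid, from one initial triple."""

    times: np.ndarray
    probabilities: np.ndarray  # (n_times, 6) columns ordered as CHANNELS
    triple: InitialTriple
    feasible: bool
    first_violation: Optional[int] = None  # grid index of first bound breach

    def channel(self, name: str) -> np.ndarray:
        return self.probabilities[:, CHANNELS.index(name)]

    def as_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probabilities, columns=list(CHANNELS))
        df.insert(0, "time", self.times)
        return df


@dataclass
class CorridorSet:
    """Pointwise envelopes of all admissible probability trajectories."""

    times: np.ndarray
    lower: np.ndarray  # (n_times, 6)
    upper: np.ndarray  # (n_times, 6)
    admissible_triples: np.ndarray  # (n_admissible, 3) columns p10, p20, q20
    grid_step: float
    n_swept: int = 0

    @property
    def empty(self) -> bool:
        return self.admissible_triples.shape[0] == 0

    def channel_bounds(self, name: str) -> Tuple[np.ndarray, np.ndarray]:
        i = CHANNELS.index(name)
        return self.lower[:, i], self.upper[:, i]

    def contains(self, probabilities: np.ndarray, tol: float = 1e-9) -> bool:
        """Whether a (n_times, 6) trajectory lies inside all six envelopes."""
        return bool(
            np.all(probabilities >= self.lower - tol)
            and np.all(probabilities <= self.upper + tol)
        )

    def as_dataframe(self) -> pd.DataFrame:
        data = {"time": self.times}
        for i, name in enumerate(CHANNELS):
            data[f"{name}_min"] = self.lower[:, i]
            data[f"{name}_max"] = self.upper[:, i]
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# closure and minimal-change right-hand sides
# ---------------------------------------------------------------------------

def _check_closure_s(s) -> None:
    s = np.asarray(s, dtype=float)
    if np.any(s <= _S_SINGULAR_TOL) or np.any(s >= 2.0 - _S_SINGULAR_TOL):
        raise SingularClosureError(
            "closure is singular: need 0 < s < 2 (division by s(2-s))"
        )


def close_probabilities(p1, p2, q2, s, sdot, rates: RateParams):
    """Complete (p1, p2, q2) to the full simplex state given s and sdot.

    Returns (p3, p4, q1).  Substituting the closed state back into the
    Riccati relation reproduces sdot identically (the defining property).
    Accepts scalars or broadcastable arrays.
    """
    _check_closure_s(s)
    l1, l2 = rates.lambda1, rates.lambda2
    g1, g2 = rates.gamma1, rates.gamma2
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    num = sdot - l2 * q2 + (
        g1 - g2 + l1 + l2 - l1 * p1 + l2 * q2 + (g2 - g1 - l2 + l1 * (p1 + p2)) * s
    ) * s
    p3 = num / (l1 * s * (2.0 - s))
    p4 = 1.0 - p1 - p2 - p3
    q1 = 1.0 - q2
    if p3.ndim == 0:
        return float(p3), float(p4), float(q1)
    return p3, p4, q1


def _rhs_pieces(s, sdot, sddot, rates: RateParams):
    """Shared pieces of the minimal-change right-hand sides.

    The numerator is linear in the free probabilities:
        F = F0 + cp * (p1 + 2 p2) + cq * q2
    and the channel gains are k = (k1, k2, k3) such that
        dp1/dt = k1 F,  dp2/dt = k2 F,  dq2/dt = k3 F.
    """
    l1, l2 = rates.lambda1, rates.lambda2
    g1, g2 = rates.gamma1, rates.gamma2
    G = 2.0 + (s - 2.0) * s
    E = g2 - g1 + l1 - l2
    cp = l1 * s * s * sdot
    cq = l2 * G * sdot
    F0 = -2.0 * sdot * sdot + s * (s * (E * sdot - sddot) + 2.0 * (sdot * sdot + sddot))
    den = (s - 2.0) * (4.0 * l2 ** 2 * (1.0 - s) ** 2 + 2.0 * l1 ** 2 * s * s * (11.0 + 3.0 * s * (s - 2.0)))
    k1 = 2.0 * l1 * (s - 1.0) / den
    k2 = 2.0 * l1 * (s + 3.0) / den
    k3 = 4.0 * l2 * (s - 1.0) / (s * den)
    return k1, k2, k3, cp, cq, F0


def minimal_change_rhs(p1, p2, q2, s, sdot, sddot, rates: RateParams):
    """Time derivatives (dp1/dt, dp2/dt, dq2/dt) of the minimal-change flow.

    Equivalent to the minimum-norm solution for all six probability
    derivatives under the differentiated Riccati constraint and the two
    simplex conservation laws (the property the tests assert).
    """
    _check_closure_s(s)
    k1, k2, k3, cp, cq, F0 = _rhs_pieces(s, sdot, sddot, rates)
    p1 = np.asarray(p1, dtype=float)
    F = F0 + cp * (p1 + 2.0 * np.asarray(p2, dtype=float)) + cq * np.asarray(q2, dtype=float)
    out = k1 * F, k2 * F, k3 * F
    if out[0].ndim == 0:
        return float(out[0]), float(out[1]), float(out[2])
    return out


# ---------------------------------------------------------------------------
# implicit midpoint integration
# ---------------------------------------------------------------------------

def _grid(curve: ReferenceCurve, dt: float):
    t0 = float(curve.times[0])
    T = curve.T
    n_steps = int(round(T / dt))
    if abs(n_steps * dt - T) > 1e-9 * max(T, 1.0):
        n_steps = int(np.ceil(T / dt - 1e-12))
    times = t0 + np.arange(n_steps + 1) * dt
    half = t0 + (np.arange(n_steps) + 0.5) * dt
    return times, half


def _curve_tables(curve: ReferenceCurve, dt: float):
    times, half = _grid(curve, dt)
    s_n = np.asarray(curve.s_at(times), dtype=float)
    sd_n = np.asarray(curve.sdot_at(times), dtype=float)
    s_h = np.asarray(curve.s_at(half), dtype=float)
    sd_h = np.asarray(curve.sdot_at(half), dtype=float)
    sdd_h = np.asarray(curve.sddot_at(half), dtype=float)
    if np.any(s_n <= _S_SINGULAR_TOL) or np.any(s_h <= _S_SINGULAR_TOL):
        idx = int(np.argmax(np.minimum.reduce([s_n[: len(s_h)], s_h]) <= _S_SINGULAR_TOL))
        raise SingularClosureError(f"curve hits s <= 0 near step {idx}; closure singular")
    return times, s_n, sd_n, s_h, sd_h, sdd_h


def _step_update(X: np.ndarray, dt: float, k1, k2, k3, cp, cq, F0) -> np.ndarray:
    """One implicit-midpoint step for states X of shape (m, 3).

    The numerator F is evaluated at the midpoint average of the unknowns,
    so the update is I - (dt/2) k w^T applied to the new state: a rank-one
    system solved exactly by the Sherman-Morrison identity.
    """
    k = np.array([k1, k2, k3])
    w = np.array([cp, 2.0 * cp, cq])
    alpha = 0.5 * dt
    r = X + dt * np.outer(F0 + 0.5 * (X @ w), k)
    denom = 1.0 - alpha * float(w @ k)
    if abs(denom) < 1e-14:
        raise SingularClosureError("implicit step singular; reduce dt")
    return r + np.outer((alpha / denom) * (r @ w), k)


def _full_state(X: np.ndarray, s, sdot, rates: RateParams) -> np.ndarray:
    """(m, 3) free state -> (m, 6) full probability state via closure."""
    p3, p4, q1 = close_probabilities(X[:, 0], X[:, 1], X[:, 2], s, sdot, rates)
    return np.column_stack([X[:, 0], X[:, 1], p3, p4, q1, X[:, 2]])


def _violations(P6: np.ndarray, tol: float) -> np.ndarray:
    return np.any((P6 < -tol) | (P6 > 1.0 + tol), axis=1)


def integrate_scheme(
    triple: InitialTriple,
    curve: ReferenceCurve,
    rates: RateParams,
    dt: float = 0.01,
    feas_tol: float = _DEFAULT_FEAS_TOL,
) -> ProbabilityTrajectory:
    """Integrate the minimal-change system for one initial triple.

    The full trajectory is always produced; ``feasible`` records whether
    every component stayed inside [0, 1] (within ``feas_tol``) for the
    whole period, and ``first_violation`` the first offending grid index.
    The simplex identities hold exactly at every step because p3 comes
    from the closure and p4, q1 from the conservation laws.
    """
    times, s_n, sd_n, s_h, sd_h, sdd_h = _curve_tables(curve, dt)
    n_steps = len(times) - 1
    X = triple.as_array()[None, :].copy()
    P = np.empty((n_steps + 1, 6))
    P[0] = _full_state(X, s_n[0], sd_n[0], rates)[0]
    first_violation: Optional[int] = 0 if _violations(P[[0]], feas_tol)[0] else None
    for n in range(n_steps):
        pieces = _rhs_pieces(s_h[n], sd_h[n], sdd_h[n], rates)
        X = _step_update(X, dt, *pieces)
        P[n + 1] = _full_state(X, s_n[n + 1], sd_n[n + 1], rates)[0]
        if first_violation is None and _violations(P[[n + 1]], feas_tol)[0]:
            first_violation = n + 1
    return ProbabilityTrajectory(
        times=times,
        probabilities=P,
        triple=triple,
        feasible=first_violation is None,
        first_violation=first_violation,
    )


def _triple_grid(grid_step: float) -> np.ndarray:
    if not (0.0 < grid_step <= 0.5):
        raise ParameterError("grid_step must lie in (0, 0.5]")
    n = int(round(1.0 / grid_step))
    axis = np.linspace(0.0, 1.0, n + 1)
    g1, g2, g3 = np.meshgrid(axis, axis, axis, indexing="ij")
    return np.column_stack([g1.ravel(), g2.ravel(), g3.ravel()])


def scan_corridors(
    curve: ReferenceCurve,
    rates: RateParams,
    grid_step: float = 0.05,
    dt: float = 0.01,
    feas_tol: float = _DEFAULT_FEAS_TOL,
) -> CorridorSet:
    """Sweep the (p10, p20, q20) cube and assemble probability corridors.

    Every triple on the cube lattice is integrated; a triple is discarded
    the moment any of its six probabilities leaves [0, 1] (within
    ``feas_tol``).  The envelopes are the pointwise min/max over the
    trajectories that survive the whole period, computed in a second pass
    over survivors only.  Deterministic for fixed inputs.
    """
    triples = _triple_grid(grid_step)
    times, s_n, sd_n, s_h, sd_h, sdd_h = _curve_tables(curve, dt)
    n_steps = len(times) - 1

    # pass 1: survival
    alive = ~_violations(_full_state(triples, s_n[0], sd_n[0], rates), feas_tol)
    idx = np.flatnonzero(alive)
    X = triples[idx].copy()
    for n in range(n_steps):
        if idx.size == 0:
            break
        pieces = _rhs_pieces(s_h[n], sd_h[n], sdd_h[n], rates)
        X = _step_update(X, dt, *pieces)
        bad = _violations(_full_state(X, s_n[n + 1], sd_n[n + 1], rates), feas_tol)
        if bad.any():
            X = X[~bad]
            idx = idx[~bad]

    survivors = triples[idx]
    if idx.size == 0:
        nan = np.full((n_steps + 1, 6), np.nan)
        return CorridorSet(times=times, lower=nan, upper=nan.copy(),
                           admissible_triples=survivors, grid_step=grid_step,
                           n_swept=len(triples))

    # pass 2: envelopes over survivors
    X = survivors.copy()
    P6 = _full_state(X, s_n[0], sd_n[0], rates)
    lower = np.empty((n_steps + 1, 6))
    upper = np.empty((n_steps + 1, 6))
    lower[0] = P6.min(axis=0)
    upper[0] = P6.max(axis=0)
    for n in range(n_steps):
        pieces = _rhs_pieces(s_h[n], sd_h[n], sdd_h[n], rates)
        X = _step_update(X, dt, *pieces)
        P6 = _full_state(X, s_n[n + 1], sd_n[n + 1], rates)
        lower[n + 1] = P6.min(axis=0)
        upper[n + 1] = P6.max(axis=0)

    return CorridorSet(
        times=times,
        lower=np.clip(lower, 0.0, 1.0),
        upper=np.clip(upper, 0.0, 1.0),
        admissible_triples=survivors,
        grid_step=grid_step,
        n_swept=len(triples),
    )


_OBJECTIVES = {
    "min_q20": (2, +1),
    "max_p10": (0, -1),
    "min_p10": (0, +1),
    "max_q20": (2, -1),
    "min_p20": (1, +1),
    "max_p20": (1, -1),
}


def extremal_trajectory(
    curve: ReferenceCurve,
    rates: RateParams,
    objective: Union[str, Tuple[int, int]] = "min_q20",
    grid_step: float = 0.05,
    dt: float = 0.01,
    corridors: Optional[CorridorSet] = None,
) -> ProbabilityTrajectory:
    """The unique admissible trajectory extremizing one initial component.

    ``objective`` is a named rule (``"min_q20"``: least possible
    dedifferentiation at t=0; ``"max_p10"``: most asymmetric stem division)
    or a pair (component index in (p10, p20, q20), direction +1 min / -1
    max).  Ties are broken lexicographically ascending over
    (p10, p20, q20).  Pass a precomputed ``corridors`` to reuse a sweep.
    """
    if isinstance(objective, str):
        try:
            comp, sign = _OBJECTIVES[objective]
        except KeyError:
            raise ParameterError(f"unknown objective {objective!r}") from None
    else:
        comp, sign = objective
        if comp not in (0, 1, 2) or sign not in (-1, +1):
            raise ParameterError("custom objective must be (component in 0..2, ±1)")

    if corridors is None:
        corridors = scan_corridors(curve, rates, grid_step=grid_step, dt=dt)
    if corridors.empty:
        raise NoSolutionError("no admissible initial triple for this curve and rates")
    cand = corridors.admissible_triples
    key = np.column_stack([sign * cand[:, comp], cand[:, 0], cand[:, 1], cand[:, 2]])
    best = cand[np.lexsort((key[:, 3], key[:, 2], key[:, 1], key[:, 0]))][0]
    return integrate_scheme(InitialTriple(*best), curve, rates, dt=dt)


# ---------------------------------------------------------------------------
# model / results wrappers
# ---------------------------------------------------------------------------

class CorridorModel:
    """Corridor inversion of a stem-fraction curve, statsmodels-style.

    Parameters
    ----------
    curve : ReferenceCurve
        The observed (or synthetic) stem-fraction dynamics.
    rates : RateParams
        The four constant division/death rates.
    """

    def __init__(self, curve: ReferenceCurve, rates: RateParams):
        self.curve = curve
        self.rates = rates

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, rates: RateParams,
                       smoothing: Optional[float] = None) -> "CorridorModel":
        """Build from a DataFrame with columns ``time`` and ``s``."""
        from .curves import differentiate_sampled_curve

        curve = differentiate_sampled_curve(df["time"].to_numpy(), df["s"].to_numpy(),
                                            smoothing=smoothing)
        return cls(curve, rates)

    def integrate(self, triple: InitialTriple, dt: float = 0.01) -> ProbabilityTrajectory:
        return integrate_scheme(triple, self.curve, self.rates, dt=dt)

    def fit(self, grid_step: float = 0.05, dt: float = 0.01) -> "CorridorResults":
        """Sweep the initial-condition cube and return corridor results."""
        cs = scan_corridors(self.curve, self.rates, grid_step=grid_step, dt=dt)
        return CorridorResults(self, cs, dt=dt)


class CorridorResults:
    """Fitted corridors plus accessors for extremal unique solutions."""

    def __init__(self, model: CorridorModel, corridors: CorridorSet, dt: float):
        self.model = model
        self.corridors = corridors
        self.dt = dt

    @property
    def admissible_triples(self) -> np.ndarray:
        return self.corridors.admissible_triples

    def extremal(self, objective: Union[str, Tuple[int, int]] = "min_q20") -> ProbabilityTrajectory:
        return extremal_trajectory(
            self.model.curve, self.model.rates, objective=objective,
            dt=self.dt, corridors=self.corridors,
        )

    def summary(self) -> str:
        cs = self.corridors
        r = self.model.rates
        lines = [
            "Probability corridors (minimal-change inversion)",
            "=" * 52,
            f"rates: lambda1={r.lambda1:g} lambda2={r.lambda2:g} "
            f"gamma1={r.gamma1:g} gamma2={r.gamma2:g}",
            f"sweep: step {cs.grid_step:g} over {cs.n_swept} triples; "
            f"{len(cs.admissible_triples)} admissible",
            f"time span: [{cs.times[0]:g}, {cs.times[-1]:g}], dt={self.dt:g}",
            "",
            f"{'channel':>8} {'min over t':>12} {'max over t':>12}",
        ]
        if not cs.empty:
            for i, name in enumerate(CHANNELS):
                lines.append(f"{name:>8} {cs.lower[:, i].min():12.4f} {cs.upper[:, i].max():12.4f}")
        else:
            lines.append("  (empty corridor: no admissible triples)")
        return "\n".join(lines)
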