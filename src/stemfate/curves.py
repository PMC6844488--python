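"""Stem-fraction reference curves and derivative estimation.

The inverse machinery consumes a sampled stem-cell fraction s(t) together
with its first two time derivatives.  This module provides the container
(:class:`ReferenceCurve`), an analytic exponential-relaxation family that
emulates the canonical stabilization experiment (a pure stem-cell culture
relaxing to its basal stem fraction), and a smoothing-spline differentiator
for measured curves, where the second derivative would otherwise amplify
sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.interpolate import CubicSpline, make_smoothing_spline

from .errors import GridError, ParameterError

__all__ = [
    "ReferenceCurve",
    "CurveFamilyParams",
    "make_reference_curve",
    "differentiate_sampled_curve",
]

_GRID_RTOL = 1e-8


def _check_uniform(times: np.ndarray) -> float:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise GridError("time grid must be one-dimensional with at least 2 points")
    steps = np.diff(times)
    if np.any(steps <= 0):
        raise GridError("time grid must be strictly increasing")
    h = steps.mean()
    if np.max(np.abs(steps - h)) > _GRID_RTOL * max(abs(h), 1.0):
        raise GridError("time grid must be uniform")
    return h


@dataclass
class ReferenceCurve:
    """A sampled stem-cell fraction s(t) with derivative access.

    Parameters
    ----------
    times : ndarray
        Uniform, strictly increasing time grid.
    s : ndarray
        Stem fraction in [0, 1] on the grid.
    sdot, sddot : ndarray
        First and second time derivatives of s on the grid.
    provenance : str
        One of ``"parametric"``, ``"simulated"``, ``"measured"``.

    Continuous evaluation between grid points goes through ``s_at`` /
    ``sdot_at`` / ``sddot_at``: analytic for parametric and simulated
    curves, spline-based for measured ones.
    """

    times: np.ndarray
    s: np.ndarray
    sdot: np.ndarray
    sddot: np.ndarray
    provenance: str = "measured"
    meta: dict = field(default_factory=dict)
    _s_fun: Optional[Callable] = field(default=None, repr=False)
    _sdot_fun: Optional[Callable] = field(default=None, repr=False)
    _sddot_fun: Optional[Callable] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        self.sdot = np.asarray(self.sdot, dtype=float)
        self.sddot = np.asarray(self.sddot, dtype=float)
        _check_uniform(self.times)
        if not (self.times.shape == self.s.shape == self.sdot.shape == self.sddot.shape):
            raise GridError("times, s, sdot, sddot must share one shape")
        if np.any(self.s < -1e-9) or np.any(self.s > 1 + 1e-9):
            raise ParameterError("stem fraction must lie in [0, 1]")

    # -- continuous access -------------------------------------------------
    def _spline(self) -> CubicSpline:
        if "_spl" not in self.meta:
            self.meta["_spl"] = CubicSpline(self.times, self.s)
        return self.meta["_spl"]

    def s_at(self, t):
        if self._s_fun is not None:
            return self._s_fun(t)
        return self._spline()(t)

    def sdot_at(self, t):
        if self._sdot_fun is not None:
            return self._sdot_fun(t)
        return self._spline()(t, 1)

    def sddot_at(self, t):
        if self._sddot_fun is not None:
            return self._sddot_fun(t)
        return self._spline()(t, 2)

    @property
    def d(self) -> np.ndarray:
        """Non-stem (daughter) fraction d(t) = 1 - s(t)."""
        return 1.0 - self.s

    def d_at(self, t):
        return 1.0 - self.s_at(t)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def T(self) -> float:
        return float(self.times[-1] - self.times[0])

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class CurveFamilyParams:
    """Parameters of the exponential stabilization family.

    s(t) = s_eq + (s0 - s_eq) * exp(-k t): a monotone relaxation from an
    initial stem fraction ``s0`` (default 1, a sorted pure-stem culture)
    down to the basal plateau ``s_eq`` at rate ``k`` (per time unit).
    """

    s_eq: float
    k: float
    s0: float = 1.0
    T: float = 10.0
    n_points: int = 201

    def __post_init__(self) -> None:
        if not (0.0 < self.s_eq < self.s0 <= 1.0):
            raise ParameterError(f"need 0 < s_eq < s0 <= 1, got s_eq={self.s_eq}, s0={self.s0}")
        if self.k <= 0:
            raise ParameterError(f"relaxation rate k must be > 0, got {self.k}")
        if self.T <= 0 or self.n_points < 2:
            raise ParameterError("need T > 0 and n_points >= 2")


def make_reference_curve(params: CurveFamilyParams) -> ReferenceCurve:
    """Build an analytic stabilization curve from family parameters.

    Derivatives are exact:  sdot = -k (s0-s_eq) e^{-kt},
    sddot = k^2 (s0-s_eq) e^{-kt}.
    """
    t = np.linspace(0.0, params.T, params.n_points)
    amp = params.s0 - params.s_eq
    k = params.k

    def s_fun(tt):
        return params.s_eq + amp * np.exp(-k * np.asarray(tt, dtype=float))

    def sdot_fun(tt):
        return -k * amp * np.exp(-k * np.asarray(tt, dtype=float))

    def sddot_fun(tt):
        return k * k * amp * np.exp(-k * np.asarray(tt, dtype=float))

    return ReferenceCurve(
        times=t,
        s=s_fun(t),
        sdot=sdot_fun(t),
        sddot=sddot_fun(t),
        provenance="parametric",
        meta={"family": "exp_relaxation", "params": params},
        _s_fun=s_fun,
        _sdot_fun=sdot_fun,
        _sddot_fun=sddot_fun,
    )


def differentiate_sampled_curve(times, s_values, smoothing: Optional[float] = None) -> ReferenceCurve:
    """Estimate s, sdot, sddot from a sampled curve via spline fitting.

    Parameters
    ----------
    times, s_values : array-like
        Uniform grid and sampled fractions (>= 7 samples).
    smoothing : float or None
        ``0`` fits an interpolating cubic spline (not-a-knot; exact for
        polynomial data of degree <= 3).  A positive value is used as the
        roughness-penalty weight of a smoothing spline.  ``None`` selects
        the penalty by generalized cross-validation.
    """
    times = np.asarray(times, dtype=float)
    s_values = np.asarray(s_values, dtype=float)
    if times.size < 7:
        raise GridError(f"need at least 7 samples, got {times.size}")
    _check_uniform(times)
    if smoothing is not None and smoothing < 0:
        raise ParameterError("smoothing must be >= 0 or None")

    if smoothing == 0:
        spl = CubicSpline(times, s_values)  # not-a-knot: reproduces cubics
    else:
        spl = make_smoothing_spline(times, s_values, lam=smoothing)

    return ReferenceCurve(
        times=times,
        s=np.clip(spl(times), 0.0, 1.0),
        sdot=spl(times, 1),
        sddot=spl(times, 2),
        provenance="measured",
        meta={"smoothing": smoothing},
        _s_fun=lambda tt: np.clip(spl(tt), 0.0, 1.0),
        _sdot_fun=lambda tt: spl(tt, 1),
        _sddot_fun=lambda tt: spl(tt, 2),
    )
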