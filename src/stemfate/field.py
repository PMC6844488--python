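"""Decomposition of probability trajectories onto secreted-factor kinetics.

The six scenario-probability trajectories y_i(t) (i = 1..6 for p1..p4,
q1, q2) are modelled as driven by K secreted "underlying field" factors,
each a bump function in time:

    u_k(t) = b_k exp(-a_k (t - c_k)^m),

where a_k sets the width, c_k the peak time, m (even, default 6) the
shoulder sharpness, and each channel responds with its own amplitude
b_ik:

    y_i(t_n) = sum_k b_ik exp(-a_k (t_n - c_k)^m).

The reported factor height b_k = max_i |b_ik| is a proxy for the relative
concentration of the compound in the medium.  Coefficients are fitted by
least squares: the stationarity system (the exact gradient of the total
quadratic deviation) is relaxed in pseudo-time with adaptive, backtracked
steps, which keeps the objective monotonically non-increasing.  The
goodness of fit is the mean absolute deviation over all channels and
time points, expressed in percent of the unit probability scale:

    epsilon = 100 * sum_{n,i} |y_i(t_n) - y_in| / (6 N).

The factor count is the smallest K whose epsilon drops below a
permissible variation epsilon_p; factors whose height falls below a
negligibility threshold are pruned, so an oversized starting K collapses
to the essential set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np

from .errors import ParameterError

__all__ = [
    "FieldFactor",
    "FactorSet",
    "RelaxationConfig",
    "factor_value",
    "predict_probabilities",
    "epsilon_deviation",
    "fit_factors",
    "select_factor_count",
    "FactorModel",
]

_EXP_FLOOR = -745.0  # exp underflows to exactly 0 below this
_A_MIN = 1e-10

CHANNEL_LABELS = ("p1", "p2", "p3", "p4", "q1", "q2")


@dataclass
class FieldFactor:
    """One bump-shaped factor u(t) = b exp(-a (t-c)^m)."""

    a: float
    c: float
    m: int = 6
    b_weights: np.ndarray = field(default_factory=lambda: np.zeros(6))

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ParameterError(f"width coefficient a must be > 0, got {self.a}")
        if self.m < 2 or self.m % 2 != 0:
            raise ParameterError(f"shape exponent m must be an even integer >= 2, got {self.m}")
        self.b_weights = np.asarray(self.b_weights, dtype=float)
        if self.b_weights.shape != (6,):
            raise ParameterError("b_weights must have 6 entries (one per channel)")

    @property
    def b_k(self) -> float:
        """Concentration proxy: the largest absolute channel amplitude."""
        return float(np.max(np.abs(self.b_weights)))

    def envelope(self, t) -> np.ndarray:
        """exp(-a (t-c)^m), underflow-safe."""
        t = np.asarray(t, dtype=float)
        expo = np.maximum(-self.a * (t - self.c) ** self.m, _EXP_FLOOR)
        return np.exp(expo)


@dataclass
class FactorSet:
    """A fitted collection of factors with its deviation diagnostics."""

    factors: List[FieldFactor]
    epsilon: float = np.nan  # mean absolute deviation, percent
    objective: float = np.nan  # total quadratic deviation
    times: Optional[np.ndarray] = None
    converged: bool = False
    n_iter: int = 0
    target_ids: Sequence[str] = CHANNEL_LABELS

    @property
    def K(self) -> int:
        return len(self.factors)

    @property
    def m(self) -> int:
        return self.factors[0].m

    def heights(self) -> np.ndarray:
        return np.array([f.b_k for f in self.factors])

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "m": self.m,
            "epsilon": float(self.epsilon),
            "converged": bool(self.converged),
            "factors": [
                {"a": f.a, "c": f.c, "b_weights": f.b_weights.tolist(), "b_k": f.b_k}
                for f in self.factors
            ],
        }


@dataclass(frozen=True)
class RelaxationConfig:
    """Settings of the pseudo-time relaxation.

    ``dtq, dtc, dtb`` seed the adaptive step sizes for the width, center
    and amplitude blocks (``None`` auto-scales from the first gradient);
    steps grow 1.2x on accepted iterations and halve on rejected ones, so
    the quadratic objective never increases.  ``tol`` bounds the largest
    stationarity-system residual at convergence.  ``b_exact`` refreshes
    amplitudes by linear least squares each iteration (variable
    projection), which zeroes the amplitude residuals exactly.
    """

    dtq: Optional[float] = None
    dtc: Optional[float] = None
    dtb: Optional[float] = None
    max_iters: int = 4000
    tol: float = 1e-6
    seed: int = 0
    b_exact: bool = True
    n_restarts: int = 0

    def __post_init__(self) -> None:
        if self.max_iters < 1:
            raise ParameterError("max_iters must be >= 1")
        if self.tol <= 0:
            raise ParameterError("tol must be > 0")


def factor_value(factor: FieldFactor, t, b: Optional[float] = None):
    """Evaluate b * exp(-a (t-c)^m); ``b`` defaults to the height b_k."""
    height = factor.b_k if b is None else b
    out = height * factor.envelope(t)
    return float(out) if out.ndim == 0 else out


def predict_probabilities(fset: FactorSet, times) -> np.ndarray:
    """Predicted six channels, shape (6, n_times).  No clipping to [0, 1]."""
    times = np.asarray(times, dtype=float)
    out = np.zeros((6, times.size))
    for f in fset.factors:
        out += np.outer(f.b_weights, f.envelope(times))
    return out


def epsilon_deviation(predicted, observed) -> float:
    """Mean absolute channel deviation in percent of the unit scale."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ParameterError(f"shape mismatch: {predicted.shape} vs {observed.shape}")
    if predicted.size == 0:
        raise ParameterError("empty arrays")
    n_times = predicted.shape[-1]
    return float(np.sum(np.abs(predicted - observed)) / (6 * n_times) * 100.0)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _basis(a, c, m, times, modulators=None):
    """E[n, k] = exp(-a_k (t_n - c_k)^m), optionally times a modulator."""
    expo = -a[None, :] * (times[:, None] - c[None, :]) ** m
    E = np.exp(np.maximum(expo, _EXP_FLOOR))
    if modulators is not None:
        E = E * modulators
    return E


def _lstsq_b(E, Y):
    """Per-channel least-squares amplitudes; Y is (6, N), returns (6, K)."""
    coef, *_ = np.linalg.lstsq(E, Y.T, rcond=None)
    return coef.T


def _objective(E, b, Y):
    R = b @ E.T - Y
    return float(np.sum(R * R)), R


def _gradients(a, c, m, times, E, b, R, modulators=None):
    """Exact gradients of the quadratic objective (the stationarity system).

    g_a[k] = -2 sum_n (t_n-c_k)^m E_nk sum_i b_ik R_in
    g_c[k] = 2 a_k m sum_n (t_n-c_k)^(m-1) E_nk sum_i b_ik R_in
    g_b[i,k] = 2 sum_n E_nk R_in
    """
    dtc = times[:, None] - c[None, :]
    S = (b.T @ R).T * E  # (N, K): E_nk * sum_i b_ik R_in ... rows n
    # note: (b.T @ R) is (K, N); transpose to (N, K)
    g_a = -2.0 * np.sum(dtc ** m * S, axis=0)
    g_c = 2.0 * a * m * np.sum(dtc ** (m - 1) * S, axis=0)
    g_b = 2.0 * (R @ E)
    return g_a, g_c, g_b


def _init_factors(times, Y, K, m):
    """Deterministic start: centers at the K strongest peaks of the total
    signal (equispaced fill when there are fewer), bump half-width
    span/(2K), amplitudes from linear least squares given (a, c)."""
    from scipy.signal import find_peaks, peak_widths

    t0, t1 = float(times[0]), float(times[-1])
    span = t1 - t0
    h = float(times[1] - times[0])
    default_a = (span / (2.0 * K)) ** (-m)
    energy = np.sum(np.abs(Y), axis=0)
    peaks, props = find_peaks(energy, prominence=1e-6)
    order = np.argsort(props["prominences"])[::-1][:K]
    c, a = [], []
    if peaks.size:
        fwhm = peak_widths(energy, peaks, rel_height=0.5)[0] * h
        for i in order:
            c.append(float(times[peaks[i]]))
            # bump exp(-a x^m) reaches half height at x = (ln2 / a)^(1/m)
            half = max(fwhm[i] / 2.0, 2.0 * h)
            a.append(np.log(2.0) / half ** m)
    while len(c) < K:  # fill at the point farthest from chosen centers
        grid = np.linspace(t0, t1, 101)
        if c:
            dist = np.min(np.abs(grid[:, None] - np.asarray(c)[None, :]), axis=1)
            c.append(float(grid[np.argmax(dist)]))
        else:
            c.append(t0 + span / (2.0 * K))
        a.append(default_a)
    idx = np.argsort(c)
    c = np.asarray(c, dtype=float)[idx]
    a = np.asarray(a, dtype=float)[idx]
    E = _basis(a, c, m, times)
    b = _lstsq_b(E, Y)
    return a, c, b


def fit_factors(
    observed,
    times,
    K: int,
    m: int = 6,
    config: Optional[RelaxationConfig] = None,
    modulators=None,
    init: Optional[FactorSet] = None,
) -> FactorSet:
    """Fit K bump factors to the six observed channels.

    Parameters
    ----------
    observed : array-like, shape (6, N)
        Channel data y_in ordered p1, p2, p3, p4, q1, q2.
    times : array-like, shape (N,)
        Sample times.
    K : int
        Number of factors.
    m : int
        Even shape exponent (default 6).
    config : RelaxationConfig, optional
        Relaxation settings; defaults are deterministic.
    modulators : array-like (N, K), optional
        Per-factor multiplicative kinetics (used by the attribution stage);
        default all ones.
    init : FactorSet, optional
        Warm start; otherwise the deterministic initialization is used.

    Returns
    -------
    FactorSet
        Stationary point of the quadratic objective, with ``converged``
        False if the iteration cap was hit first (best iterate returned).
    """
    if K < 1:
        raise ParameterError("K must be >= 1")
    cfg = config or RelaxationConfig()
    Y = np.asarray(observed, dtype=float)
    times = np.asarray(times, dtype=float)
    if Y.shape != (6, times.size):
        raise ParameterError(f"observed must be (6, {times.size}), got {Y.shape}")
    if not np.all(np.isfinite(Y)):
        raise ParameterError("observed contains non-finite values")
    if modulators is not None:
        modulators = np.asarray(modulators, dtype=float)
        if modulators.shape != (times.size, K):
            raise ParameterError("modulators must have shape (n_times, K)")

    if init is not None:
        if init.K != K:
            raise ParameterError("warm start has wrong K")
        a = np.array([f.a for f in init.factors], dtype=float)
        c = np.array([f.c for f in init.factors], dtype=float)
        b = np.array([f.b_weights for f in init.factors], dtype=float).T
    else:
        a, c, b = _init_factors(times, Y, K, m)
        if modulators is not None:
            b = _lstsq_b(_basis(a, c, m, times, modulators), Y)

    best = _relax(a, c, b, times, Y, m, cfg, modulators)
    if init is None:  # warm starts are trusted; cold starts get refinement
        best = _relocate_weak_factors(best, times, Y, m, cfg, modulators)

    # optional seeded random restarts around the deterministic start
    if cfg.n_restarts > 0 and init is None:
        rng = np.random.default_rng(cfg.seed)
        span = float(times[-1] - times[0])
        for _ in range(cfg.n_restarts):
            cj = np.sort(rng.uniform(times[0], times[-1], K))
            aj = np.full(K, (span / (2.0 * K)) ** (-m)) * np.exp(rng.normal(0, 0.3, K))
            bj = _lstsq_b(_basis(aj, cj, m, times, modulators), Y)
            cand = _relax(aj, cj, bj, times, Y, m, cfg, modulators)
            if cand[3] < best[3]:
                best = cand

    a, c, b, f_val, converged, it = best
    factors = [FieldFactor(a=float(a[k]), c=float(c[k]), m=m, b_weights=b[:, k]) for k in range(K)]
    E = _basis(a, c, m, times, modulators)
    pred = b @ E.T
    return FactorSet(
        factors=factors,
        epsilon=epsilon_deviation(pred, Y),
        objective=f_val,
        times=times,
        converged=converged,
        n_iter=it,
    )


def _relocate_weak_factors(state, times, Y, m, cfg, modulators):
    """Deterministic escape from flat local minima.

    The equispaced initialization can strand a bump far from any signal,
    where the objective surface is nearly flat (the bump tail is
    super-exponentially small).  Greedy refinement: move the weakest
    factor (smallest height) to the time of the largest remaining
    residual with a fresh medium width, re-relax, and keep the move only
    if the objective improves.  Repeats at most K times.
    """
    a, c, b, f_val, converged, it = state
    K = a.size
    span = float(times[-1] - times[0])
    fresh_a = (span / (2.0 * K)) ** (-m)
    total_it = it
    for _ in range(K):
        if f_val <= 1e-24:
            break
        E = _basis(a, c, m, times, modulators)
        R = b @ E.T - Y
        t_star = times[int(np.argmax(np.sum(np.abs(R), axis=0)))]
        k_weak = int(np.argmin(np.max(np.abs(b), axis=0)))
        a_try, c_try, b_try = a.copy(), c.copy(), b.copy()
        a_try[k_weak] = fresh_a
        c_try[k_weak] = t_star
        b_try = _lstsq_b(_basis(a_try, c_try, m, times, modulators), Y)
        cand = _relax(a_try, c_try, b_try, times, Y, m, cfg, modulators)
        total_it += cand[5]
        if cand[3] < f_val * (1.0 - 1e-9):
            a, c, b, f_val, converged, _ = cand
        else:
            break
    return a, c, b, f_val, converged, total_it


def _relax(a, c, b, times, Y, m, cfg: RelaxationConfig, modulators):
    """Pseudo-time relaxation of the stationarity system.

    Sequential block descent: width, center, then amplitude updates, each
    backtracked until the quadratic objective does not increase (the steps
    grow on success and halve on failure, replacing hand-tuned pseudo-time
    steps).  Widths move in log space — a spans orders of magnitude while
    its gradient scales oppositely, and the stationarity condition is
    unchanged (a > 0 makes d/d(log a) = a d/da zero at the same points).
    With ``b_exact`` the amplitude block is solved exactly by per-channel
    least squares (variable projection), zeroing its residuals.
    """
    a = np.maximum(np.asarray(a, dtype=float).copy(), _A_MIN)
    c = np.asarray(c, dtype=float).copy()
    b = np.asarray(b, dtype=float).copy()
    span = float(times[-1] - times[0])

    E = _basis(a, c, m, times, modulators)
    if cfg.b_exact:
        b = _lstsq_b(E, Y)
    f_val, R = _objective(E, b, Y)

    def eval_at(a_, c_, b_):
        E_ = _basis(a_, c_, m, times, modulators)
        b_ = _lstsq_b(E_, Y) if cfg.b_exact else b_
        f_, R_ = _objective(E_, b_, Y)
        return f_, R_, E_, b_

    eta_a = cfg.dtq if cfg.dtq is not None else 0.1   # step in log a
    eta_c = cfg.dtc if cfg.dtc is not None else None  # set from first gradient
    eta_b = cfg.dtb if cfg.dtb is not None else None

    converged = False
    it = 0
    f_scale = max(f_val, float(np.sum(Y * Y)), 1e-30)
    for it in range(1, cfg.max_iters + 1):
        g_a, g_c, g_b = _gradients(a, c, m, times, E, b, R, modulators)
        g_loga = a * g_a
        if eta_c is None:
            gn = np.max(np.abs(g_c))
            eta_c = 0.02 * span / gn if gn > 0 else 1.0
        if eta_b is None:
            gn = np.max(np.abs(g_b))
            eta_b = 0.1 * max(np.max(np.abs(b)), 1e-3) / gn if gn > 0 else 1.0

        grad_norm = max(np.max(np.abs(g_a)), np.max(np.abs(g_c)),
                        0.0 if cfg.b_exact else np.max(np.abs(g_b)))
        if grad_norm < cfg.tol:
            converged = True
            break

        f_before = f_val
        # width block (log space)
        for _ in range(30):
            a_try = np.maximum(a * np.exp(-np.clip(eta_a * g_loga, -5.0, 5.0)), _A_MIN)
            f_new, R_new, E_new, b_new = eval_at(a_try, c, b)
            if f_new <= f_val * (1 + 1e-15):
                a, b, E, R, f_val = a_try, b_new, E_new, R_new, f_new
                eta_a = min(eta_a * 1.3, 10.0)
                break
            eta_a *= 0.5
        g_a, g_c, g_b = _gradients(a, c, m, times, E, b, R, modulators)
        # center block
        for _ in range(30):
            c_try = np.clip(c - eta_c * g_c, times[0] - span, times[-1] + span)
            f_new, R_new, E_new, b_new = eval_at(a, c_try, b)
            if f_new <= f_val * (1 + 1e-15):
                c, b, E, R, f_val = c_try, b_new, E_new, R_new, f_new
                eta_c *= 1.3
                break
            eta_c *= 0.5
        # amplitude block (only when not projected exactly)
        if not cfg.b_exact:
            g_a, g_c, g_b = _gradients(a, c, m, times, E, b, R, modulators)
            for _ in range(30):
                b_try = b - eta_b * g_b
                f_new, R_new = _objective(E, b_try, Y)
                if f_new <= f_val * (1 + 1e-15):
                    b, R, f_val = b_try, R_new, f_new
                    eta_b *= 1.3
                    break
                eta_b *= 0.5

        if f_before - f_val < 1e-16 * f_scale:
            g_a, g_c, g_b = _gradients(a, c, m, times, E, b, R, modulators)
            converged = max(np.max(np.abs(g_a)), np.max(np.abs(g_c)),
                            0.0 if cfg.b_exact else np.max(np.abs(g_b))) < cfg.tol
            break
    return a, c, b, f_val, converged, it


def select_factor_count(
    observed,
    times,
    epsilon_p: float,
    K_start: int = 4,
    m: int = 6,
    config: Optional[RelaxationConfig] = None,
    K_max: int = 10,
    prune_threshold: float = 0.01,
) -> FactorSet:
    """Smallest K >= K_start with epsilon < epsilon_p, with pruning.

    The search fits K_start factors and, while the permissible variation
    epsilon_p is not met, retries with K+1 up to ``K_max``.  After an
    accepted fit, factors whose height b_k falls below ``prune_threshold``
    (1% of the probability scale by default) are dropped and the reduced
    set refit, so the reported K is the *essential* factor count.  If the
    cap is reached the best fit is returned with ``converged`` untouched
    and ``meta['epsilon_met'] = False`` semantics via the returned
    epsilon > epsilon_p.
    """
    if epsilon_p <= 0:
        raise ParameterError("epsilon_p must be > 0")
    if K_start < 1:
        raise ParameterError("K_start must be >= 1")
    best: Optional[FactorSet] = None
    for K in range(K_start, K_max + 1):
        fset = fit_factors(observed, times, K=K, m=m, config=config)
        if best is None or fset.epsilon < best.epsilon:
            best = fset
        if fset.epsilon < epsilon_p:
            pruned = _prune(fset, observed, times, m, config, epsilon_p, prune_threshold)
            return pruned
    return best


def _prune(fset: FactorSet, observed, times, m, config, epsilon_p, threshold) -> FactorSet:
    """Drop negligible factors and refit; keep the original if the pruned
    refit no longer satisfies epsilon_p."""
    keep = [f for f in fset.factors if f.b_k >= threshold]
    if len(keep) == fset.K or len(keep) == 0:
        return fset
    warm = FactorSet(factors=[replace(f, b_weights=f.b_weights.copy()) for f in keep])
    refit = fit_factors(observed, times, K=len(keep), m=m, config=config, init=warm)
    if refit.epsilon < epsilon_p:
        return _prune(refit, observed, times, m, config, epsilon_p, threshold)
    return fset


# ---------------------------------------------------------------------------
# model / results wrapper
# ---------------------------------------------------------------------------

class FactorModel:
    """Underlying-field decomposition of probability trajectories.

    Parameters
    ----------
    observed : array-like (6, N) or ProbabilityTrajectory
        Channel data ordered p1, p2, p3, p4, q1, q2.
    times : array-like, optional
        Required when ``observed`` is a bare array.
    """

    def __init__(self, observed, times=None, m: int = 6):
        if hasattr(observed, "probabilities"):  # ProbabilityTrajectory
            self.times = np.asarray(observed.times, dtype=float)
            self.observed = np.asarray(observed.probabilities, dtype=float).T
        else:
            if times is None:
                raise ParameterError("times is required with array input")
            self.times = np.asarray(times, dtype=float)
            self.observed = np.asarray(observed, dtype=float)
        self.m = m

    def fit(self, K: int, config: Optional[RelaxationConfig] = None) -> "FactorResults":
        fset = fit_factors(self.observed, self.times, K=K, m=self.m, config=config)
        return FactorResults(self, fset)

    def fit_select(self, epsilon_p: float = 1.0, K_start: int = 4,
                   config: Optional[RelaxationConfig] = None, **kw) -> "FactorResults":
        fset = select_factor_count(self.observed, self.times, epsilon_p=epsilon_p,
                                   K_start=K_start, m=self.m, config=config, **kw)
        return FactorResults(self, fset)


class FactorResults:
    """A fitted FactorSet with prediction and reporting helpers."""

    def __init__(self, model: FactorModel, fset: FactorSet):
        self.model = model
        self.fset = fset

    @property
    def epsilon(self) -> float:
        return self.fset.epsilon

    @property
    def K(self) -> int:
        return self.fset.K

    def predict(self, times=None) -> np.ndarray:
        return predict_probabilities(self.fset, self.model.times if times is None else times)

    def factor_curves(self, times=None) -> np.ndarray:
        """(K, N) matrix of u_k(t) at height b_k (reporting convention)."""
        t = self.model.times if times is None else np.asarray(times, dtype=float)
        return np.array([factor_value(f, t) for f in self.fset.factors])

    def summary(self) -> str:
        fs = self.fset
        lines = [
            "Underlying-field factor decomposition",
            "=" * 52,
            f"K = {fs.K} factors, shape exponent m = {fs.m}",
            f"epsilon = {fs.epsilon:.4f}%  (mean abs deviation, unit scale)",
            f"converged: {fs.converged} after {fs.n_iter} iterations",
            "",
            f"{'k':>3} {'a (width coef)':>15} {'c (center)':>11} {'b_k (height)':>13}",
        ]
        for i, f in enumerate(fs.factors, 1):
            lines.append(f"{i:>3} {f.a:>15.6g} {f.c:>11.4f} {f.b_k:>13.4f}")
        return "\n".join(lines)
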