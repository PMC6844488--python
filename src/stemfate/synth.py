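"""Closed-loop synthetic fixtures: curves and probability data with known truth.

Everything the inference stages consume can be generated here without
external data: forward-simulated stem-fraction curves whose generating
scenario probabilities are known exactly, and probability channel data
assembled from known bump factors, for validating the decomposition and
attribution stages.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np

from .curves import ReferenceCurve
from .errors import ParameterError
from .field import FactorSet, predict_probabilities
from .model import (
    ProbabilityState,
    RateParams,
    simulate_population,
    stem_fraction,
)

__all__ = [
    "make_probability_curves_from_factors",
    "make_ground_truth_bundle",
    "make_attributed_channels",
]


def make_probability_curves_from_factors(factors: FactorSet, times) -> Tuple[np.ndarray, bool]:
    """Six probability channels from known factors, plus a validity flag.

    Returns ``(channels, valid)`` where channels has shape (6, n_times)
    and ``valid`` is False when any channel leaves [0, 1] (ground-truth
    fixtures must be constructed inside the unit interval).
    """
    times = np.asarray(times, dtype=float)
    channels = predict_probabilities(factors, times)
    valid = bool(np.all((channels >= 0.0) & (channels <= 1.0)))
    return channels, valid


def make_attributed_channels(
    factors: FactorSet,
    assignment: Sequence[str],
    curve: ReferenceCurve,
    times=None,
) -> Tuple[np.ndarray, bool]:
    """Channels generated under a known production assignment.

    Each factor k is multiplied by s(t), d(t) or 1 according to
    ``assignment`` before summation — the ground truth for the
    attribution stage.
    """
    from .attribution import _modulator_matrix

    t = np.asarray(curve.times if times is None else times, dtype=float)
    mod = _modulator_matrix(assignment, curve, t)
    channels = np.zeros((6, t.size))
    for k, f in enumerate(factors.factors):
        channels += np.outer(f.b_weights, f.envelope(t) * mod[:, k])
    valid = bool(np.all((channels >= 0.0) & (channels <= 1.0)))
    return channels, valid


def make_ground_truth_bundle(
    rates: RateParams,
    probs: ProbabilityState,
    T: float = 10.0,
    n_points: int = 201,
    S0: float = 1.0,
    D0: float = 0.0,
) -> Tuple[ReferenceCurve, ProbabilityState]:
    """Forward-simulate constant probabilities and return (curve, truth).

    The curve has ``simulated`` provenance with analytic continuous-time
    derivatives (first derivative from the Riccati relation along the
    solution, second from its chain rule), so inversion tests close the
    loop exactly up to the integrator's own error.
    """
    if n_points < 2:
        raise ParameterError("n_points must be >= 2")
    dt = T / (n_points - 1)
    traj = simulate_population(rates, probs, S0=S0, D0=D0, T=T, dt=dt)
    curve = stem_fraction(traj)
    # snap grid arrays to the analytic (eigen-decomposition) solution so the
    # sampled values and the continuous evaluators agree exactly
    curve.s = np.asarray(curve.s_at(curve.times), dtype=float)
    curve.meta["ground_truth"] = probs
    return curve, probs
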