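"""Optional matplotlib convenience plots (not part of the tested contract)."""

from __future__ import annotations

import numpy as np

from .corridor import CHANNELS, CorridorSet, ProbabilityTrajectory
from .field import FactorSet, factor_value


def plot_corridors(cs: CorridorSet, trajectory: ProbabilityTrajectory = None, axes=None):
    """Shade the six probability corridors; optionally overlay a trajectory."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(2, 3, figsize=(12, 6), sharex=True, sharey=True)
    axes = np.asarray(axes).ravel()
    for i, name in enumerate(CHANNELS):
        ax = axes[i]
        ax.fill_between(cs.times, cs.lower[:, i], cs.upper[:, i], alpha=0.4)
        if trajectory is not None:
            ax.plot(trajectory.times, trajectory.channel(name), lw=1.2)
        ax.set_title(name)
        ax.set_ylim(-0.05, 1.05)
    return axes


def plot_factors(fset: FactorSet, times=None, ax=None):
    """Plot each u_k(t) at its reported height b_k."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    t = fset.times if times is None else np.asarray(times, dtype=float)
    for k, f in enumerate(fset.factors, 1):
        ax.plot(t, factor_value(f, t), label=f"u{k} (b={f.b_k:.3f})")
    ax.set_xlabel("time")
    ax.set_ylabel("factor level")
    ax.legend()
    return ax
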