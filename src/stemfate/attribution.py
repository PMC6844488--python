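"""Attribution of secreted factors to stem cells, non-stem cells, or neither.

A factor produced by stem cells should scale with the stem fraction s(t),
one produced by non-stem cells with d(t) = 1 - s(t), and one produced
indifferently (or by the environment) with neither.  Each factor k is
therefore multiplied by a modulator M in {s(t), d(t), 1} — labels "S",
"D", "1" — and the decomposition refit under the modulated basis

    U_k(t) = u_k(t) * M(t).

All 3^K assignments are enumerated, each refit warm-started from the
unmodulated optimum, and ranked by the epsilon deviation; the assignment
with the smallest epsilon is the predicted production pattern.  When the
curve keeps s close to d the S/D labels are not identifiable; swap-tied
variants are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .curves import ReferenceCurve
from .errors import ParameterError, SizeError
from .field import (
    FactorSet,
    FieldFactor,
    RelaxationConfig,
    epsilon_deviation,
    factor_value,
    fit_factors,
)

__all__ = [
    "LABELS",
    "AttributionVariant",
    "modulated_basis",
    "rank_attributions",
    "AttributionResults",
]

LABELS = ("S", "D", "1")
_TIE_TOL = 1e-4  # percentage points of epsilon


@dataclass
class AttributionVariant:
    """One production-assignment hypothesis with its refit quality."""

    assignment: tuple
    epsilon: float
    fset: FactorSet
    tied_with_best: bool = False
    degenerate_swap: bool = False  # S/D swap of an equal-epsilon partner


def _modulator_values(label: str, curve: ReferenceCurve, t) -> np.ndarray:
    if label == "S":
        return np.asarray(curve.s_at(t), dtype=float)
    if label == "D":
        return np.asarray(curve.d_at(t), dtype=float)
    if label == "1":
        return np.ones_like(np.asarray(t, dtype=float))
    raise ParameterError(f"label must be one of {LABELS}, got {label!r}")


def modulated_basis(factor: FieldFactor, label: str, curve: ReferenceCurve, t):
    """u_k(t) * M(t) for M in {s, d, 1} selected by ``label``."""
    out = factor_value(factor, t) * _modulator_values(label, curve, np.asarray(t, dtype=float))
    return float(out) if np.ndim(out) == 0 else out


def _modulator_matrix(assignment: Sequence[str], curve: ReferenceCurve, times) -> np.ndarray:
    return np.column_stack([_modulator_values(lab, curve, times) for lab in assignment])


def rank_attributions(
    observed,
    times,
    curve: ReferenceCurve,
    warm_start: FactorSet,
    config: Optional[RelaxationConfig] = None,
    refit: bool = True,
    cap: int = 8,
) -> List[AttributionVariant]:
    """Enumerate and rank all 3^K production assignments by epsilon.

    Each variant refits (a, c, b) under its modulated basis, warm-started
    from ``warm_start`` (the optimal unmodulated set).  With
    ``refit=False`` only the amplitudes are re-solved by least squares (a
    fast screening mode).  Returns variants sorted by epsilon ascending;
    ties within 1e-4 percentage points of the best are flagged, and
    exact S/D swap ties (the s = d degeneracy) are marked.
    """
    K = warm_start.K
    if K > cap:
        raise SizeError(f"K={K} gives 3^{K} variants; cap is {cap}")
    Y = np.asarray(observed, dtype=float)
    times = np.asarray(times, dtype=float)
    m = warm_start.m

    variants: List[AttributionVariant] = []
    for assignment in product(LABELS, repeat=K):
        mod = _modulator_matrix(assignment, curve, times)
        warm = FactorSet(factors=[replace(f, b_weights=f.b_weights.copy())
                                  for f in warm_start.factors])
        if refit:
            fset = fit_factors(Y, times, K=K, m=m, config=config,
                               modulators=mod, init=warm)
            eps = fset.epsilon
        else:
            from .field import _basis, _lstsq_b  # amplitude-only screening

            a = np.array([f.a for f in warm.factors])
            c = np.array([f.c for f in warm.factors])
            E = _basis(a, c, m, times, mod)
            b = _lstsq_b(E, Y)
            eps = epsilon_deviation(b @ E.T, Y)
            for k, f in enumerate(warm.factors):
                f.b_weights = b[:, k]
            fset = FactorSet(factors=warm.factors, epsilon=eps, times=times)
        variants.append(AttributionVariant(assignment=assignment, epsilon=eps, fset=fset))

    variants.sort(key=lambda v: (v.epsilon, v.assignment))
    best_eps = variants[0].epsilon
    by_assignment = {v.assignment: v for v in variants}
    for v in variants:
        v.tied_with_best = abs(v.epsilon - best_eps) < _TIE_TOL
        swap = tuple("D" if x == "S" else ("S" if x == "D" else x) for x in v.assignment)
        partner = by_assignment.get(swap)
        if partner is not None and swap != v.assignment:
            v.degenerate_swap = abs(v.epsilon - partner.epsilon) < _TIE_TOL
    return variants


class AttributionResults:
    """Ranked attribution variants with a tabular report."""

    def __init__(self, variants: List[AttributionVariant]):
        self.variants = variants

    @property
    def best(self) -> AttributionVariant:
        return self.variants[0]

    @property
    def null_variant(self) -> AttributionVariant:
        K = len(self.variants[0].assignment)
        target = tuple("1") * K
        for v in self.variants:
            if v.assignment == target:
                return v
        raise RuntimeError("all-1 variant missing")

    def as_dataframe(self) -> pd.DataFrame:
        K = len(self.variants[0].assignment)
        rows = []
        for v in self.variants:
            row = {f"u_{k + 1}": v.assignment[k] for k in range(K)}
            row["epsilon_percent"] = v.epsilon
            row["tied_with_best"] = v.tied_with_best
            row["degenerate_swap"] = v.degenerate_swap
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self, top: int = 10) -> str:
        K = len(self.variants[0].assignment)
        lines = [
            "Factor production attribution (ranked by epsilon)",
            "=" * 52,
            "  ".join(f"u_{k + 1:<2}" for k in range(K)) + "  epsilon(%)",
        ]
        for v in self.variants[:top]:
            mark = " *" if v.assignment == tuple("1") * K else ""
            flag = " (tie)" if v.tied_with_best and v is not self.variants[0] else ""
            lines.append("  ".join(f"{x:<4}" for x in v.assignment)
                         + f"  {v.epsilon:.4f}{mark}{flag}")
        lines.append("")
        lines.append("* all-1 variant: no dependence on S or D kinetics")
        return "\n".join(lines)
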