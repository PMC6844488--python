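"""CSV/JSON readers and writers, run configuration, and the pipeline driver.

Fractions in [0, 1] are canonical everywhere inside the package; percent
input (columns maxing above 1.5, or an explicit flag) is divided by 100 on
read.  All writers use a fixed float format so reruns with the same
configuration are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .corridor import CHANNELS, CorridorModel, CorridorSet, ProbabilityTrajectory
from .curves import CurveFamilyParams, ReferenceCurve, differentiate_sampled_curve, make_reference_curve
from .errors import GridError, ParameterError
from .field import FactorModel, FactorSet, RelaxationConfig
from .model import ProbabilityState, RateParams
from .synth import make_ground_truth_bundle

logger = logging.getLogger("stemfate")

_FLOAT_FMT = "%.12g"

__all__ = [
    "read_curve",
    "write_curve",
    "read_trajectory",
    "write_trajectory",
    "write_corridors",
    "write_triples",
    "write_factor_set",
    "write_ranking",
    "RunConfig",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_curve(
    path,
    percent: Optional[bool] = None,
    smoothing: Optional[float] = None,
    decimal_comma: bool = False,
) -> ReferenceCurve:
    """Read a stem-fraction CSV with header ``time,s`` (>= 7 uniform rows).

    ``percent=None`` auto-detects a percent scale when max(s) > 1.5;
    ``decimal_comma`` normalizes European comma decimals on read.
    Derivatives are estimated by :func:`differentiate_sampled_curve`.
    """
    kwargs = {"decimal": ",", "sep": ";"} if decimal_comma else {}
    df = pd.read_csv(path, **kwargs)
    cols = [c.strip().lower() for c in df.columns]
    if cols[:2] != ["time", "s"]:
        raise ParameterError(f"curve CSV must start with columns time,s; got {list(df.columns)}")
    df.columns = cols + list(df.columns[len(cols):])
    if len(df) < 7:
        raise GridError(f"need at least 7 samples, got {len(df)}")
    s = df["s"].to_numpy(dtype=float)
    if percent is None:
        percent = bool(np.nanmax(s) > 1.5)
    if percent:
        s = s / 100.0
    if np.any(s < -1e-9) or np.any(s > 1 + 1e-9):
        raise ParameterError("stem fraction outside [0, 1] after scaling")
    return differentiate_sampled_curve(df["time"].to_numpy(dtype=float), s, smoothing=smoothing)


def write_curve(curve: ReferenceCurve, path, sidecar: bool = True) -> None:
    """Write ``time,s,sdot,sddot`` plus a JSON sidecar with provenance."""
    df = pd.DataFrame({"time": curve.times, "s": curve.s,
                       "sdot": curve.sdot, "sddot": curve.sddot})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    if sidecar:
        meta = {"provenance": curve.provenance}
        for key, val in curve.meta.items():
            if key.startswith("_"):
                continue
            meta[key] = val if isinstance(val, (int, float, str, bool)) else repr(val)
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def write_trajectory(traj: ProbabilityTrajectory, path) -> None:
    traj.as_dataframe().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trajectory(path) -> tuple:
    """Read ``time,p1,...,q2`` back as (times, channels (6, N))."""
    df = pd.read_csv(path)
    missing = [c for c in ("time",) + CHANNELS if c not in df.columns]
    if missing:
        raise ParameterError(f"trajectory CSV missing columns {missing}")
    return df["time"].to_numpy(dtype=float), df[list(CHANNELS)].to_numpy(dtype=float).T


def write_corridors(cs: CorridorSet, path) -> None:
    cs.as_dataframe().to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_triples(cs: CorridorSet, path) -> None:
    pd.DataFrame(cs.admissible_triples, columns=["p10", "p20", "q20"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT)


def write_factor_set(fset: FactorSet, json_path, curves_path=None) -> None:
    """FactorSet JSON and optional ``time,u1..uK`` curve CSV at b_k heights."""
    Path(json_path).write_text(json.dumps(fset.to_dict(), indent=2, sort_keys=True))
    if curves_path is not None:
        if fset.times is None:
            raise ParameterError("factor set has no fit grid; cannot write curves")
        data = {"time": fset.times}
        for k, f in enumerate(fset.factors, 1):
            data[f"u{k}"] = f.b_k * f.envelope(fset.times)
        pd.DataFrame(data).to_csv(curves_path, index=False, float_format=_FLOAT_FMT)


def write_ranking(results, path) -> None:
    df = results.as_dataframe()
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end pipeline settings (YAML/JSON loadable)."""

    rates: RateParams = None
    # curve source: exactly one of the three below
    curve_path: Optional[str] = None
    synthetic: Optional[dict] = None     # CurveFamilyParams fields
    simulated: Optional[dict] = None     # {probs: {...}, T, n_points}
    # stage toggles
    run_corridor: bool = True
    run_decomposition: bool = True
    run_attribution: bool = False
    # corridor settings
    grid_step: float = 0.05
    dt: float = 0.01
    objective: str = "min_q20"
    # decomposition settings
    K_start: int = 4
    epsilon_p: float = 1.0
    m: int = 6
    max_iters: int = 4000
    # attribution settings
    variant_cap: int = 8
    # bookkeeping
    output_dir: str = "stemfate_out"
    seed: int = 0
    smoothing: Optional[float] = None

    def __post_init__(self) -> None:
        if self.rates is None:
            raise ParameterError("config requires rates")
        if isinstance(self.rates, dict):
            self.rates = RateParams(**self.rates)
        sources = [x is not None for x in (self.curve_path, self.synthetic, self.simulated)]
        if sum(sources) != 1:
            raise ParameterError("config needs exactly one curve source "
                                 "(curve_path | synthetic | simulated)")
        if self.curve_path is not None and not Path(self.curve_path).exists():
            raise ParameterError(f"curve_path does not exist: {self.curve_path}")
        if not (0 < self.grid_step <= 0.5):
            raise ParameterError("grid_step must be in (0, 0.5]")
        if self.dt <= 0:
            raise ParameterError("dt must be > 0")
        if self.epsilon_p <= 0 or self.K_start < 1:
            raise ParameterError("epsilon_p must be > 0 and K_start >= 1")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ParameterError(f"config file {path} must contain a mapping")
        try:
            return cls(**data)
        except TypeError as exc:
            raise ParameterError(f"bad config key: {exc}") from None

    def load_curve(self) -> ReferenceCurve:
        if self.curve_path is not None:
            return read_curve(self.curve_path, smoothing=self.smoothing)
        if self.synthetic is not None:
            return make_reference_curve(CurveFamilyParams(**self.synthetic))
        sim = dict(self.simulated)
        probs = ProbabilityState(**sim.pop("probs"))
        curve, _ = make_ground_truth_bundle(self.rates, probs, **sim)
        return curve


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run curve -> corridors -> extremal solutions -> decomposition
    -> attribution, writing one artifact file per stage plus a manifest.

    Returns the manifest dict.  Reruns with identical configuration
    produce byte-identical numeric outputs (everything is deterministic).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "config": _jsonable(asdict(config)), "stages": {}}
    stage = "curve"
    try:
        curve = config.load_curve()
        write_curve(curve, out / "curve.csv")
        manifest["stages"]["curve"] = {
            "provenance": curve.provenance, "n_points": len(curve),
            "s_range": [float(curve.s.min()), float(curve.s.max())],
        }
        logger.info("curve: %d points, provenance=%s", len(curve), curve.provenance)

        traj_for_decomp = None
        if config.run_corridor:
            stage = "corridor"
            res = CorridorModel(curve, config.rates).fit(grid_step=config.grid_step, dt=config.dt)
            cs = res.corridors
            write_corridors(cs, out / "corridors.csv")
            write_triples(cs, out / "admissible_triples.csv")
            info = {"n_swept": cs.n_swept, "n_admissible": int(len(cs.admissible_triples))}
            if not cs.empty:
                for name, fname in (("min_q20", "trajectory_q20_min.csv"),
                                    ("max_p10", "trajectory_p10_max.csv")):
                    traj = res.extremal(name)
                    write_trajectory(traj, out / fname)
                    if name == config.objective:
                        traj_for_decomp = traj
                truth = curve.meta.get("ground_truth")
                if truth is not None:
                    contained = cs.contains(
                        np.tile(truth.as_array(), (len(cs.times), 1)))
                    info["truth_contained"] = bool(contained)
            manifest["stages"]["corridor"] = info
            logger.info("corridor: %d/%d triples admissible", info["n_admissible"], cs.n_swept)

        if config.run_decomposition and traj_for_decomp is not None:
            stage = "decomposition"
            fm = FactorModel(traj_for_decomp, m=config.m)
            fr = fm.fit_select(epsilon_p=config.epsilon_p, K_start=config.K_start,
                               config=RelaxationConfig(max_iters=config.max_iters,
                                                       seed=config.seed))
            write_factor_set(fr.fset, out / "factors.json", out / "factor_curves.csv")
            manifest["stages"]["decomposition"] = {
                "K": fr.K, "epsilon": float(fr.epsilon),
                "epsilon_met": bool(fr.epsilon < config.epsilon_p),
            }
            logger.info("decomposition: K=%d, epsilon=%.4f%%", fr.K, fr.epsilon)

            if config.run_attribution:
                stage = "attribution"
                from .attribution import AttributionResults, rank_attributions

                variants = rank_attributions(
                    fm.observed, fm.times, curve, fr.fset,
                    config=RelaxationConfig(max_iters=config.max_iters, seed=config.seed),
                    cap=config.variant_cap,
                )
                results = AttributionResults(variants)
                write_ranking(results, out / "attribution_ranking.csv")
                manifest["stages"]["attribution"] = {
                    "n_variants": len(variants),
                    "best_assignment": list(results.best.assignment),
                    "best_epsilon": float(results.best.epsilon),
                }
                logger.info("attribution: best %s at epsilon=%.4f%%",
                            results.best.assignment, results.best.epsilon)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2, sort_keys=True))
        raise

    (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2, sort_keys=True))
    return manifest
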