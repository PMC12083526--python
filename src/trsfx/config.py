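"""Pipeline configuration and reproducible stage execution.

The config is plain YAML with all analysis defaults embedded; unknown keys
are rejected.  ``run_pipeline`` executes declared stages in order and writes
a manifest capturing the package version, seeds, and a hash of the canonical
config so identical runs are provably identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml

from . import __version__
from .ded_analysis import RegionMask, integrate_region
from .kinetics import TimeTrace, fit_trace
from .synthetic import (asn_chi2_perturbation, make_toy_crystal,
                        simulate_dataset)
from .xtal_core import ded_map

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    """Stage parameters; defaults are the analysis constants used throughout."""

    snr_min: float = 3.0
    d_low: float = 10.0
    d_min: float = 1.8
    contour_sigma: float = 3.0
    sg_window: int = 21
    sg_order: int = 3
    band: tuple = (580.0, 640.0)
    norm_band: tuple = (456.0, 490.0)
    dfocc_angle_floor: float = 0.1
    dfocc_distance_floor: float = 0.1
    seed: int = 0
    stages: list = field(default_factory=list)
    out_dir: str = "."

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band"] = list(d["band"])
        d["norm_band"] = list(d["norm_band"])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kw = dict(data)
        for key in ("band", "norm_band"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return cls(**kw)

    def canonical_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh))


# --------------------------------------------------------------------------- #
# stage registry: each stage reads/writes the shared context dict


def _stage_simulate_crystal(ctx, cfg: PipelineConfig, params):
    ctx["dark_model"] = make_toy_crystal(params.get("seed", cfg.seed))
    return {"atoms": len(ctx["dark_model"])}


def _stage_simulate_dataset(ctx, cfg: PipelineConfig, params):
    from .synthetic import apply_perturbation
    dark = ctx["dark_model"]
    spec = asn_chi2_perturbation(params.get("chi2_deg", -86.4))
    light = apply_perturbation(dark, spec)
    dark_obs, light_obs = simulate_dataset(
        dark, light, alpha=params.get("alpha", 0.2),
        noise_frac=params.get("noise_frac", 0.01),
        seed=params.get("seed", cfg.seed), d_min=cfg.d_min)
    ctx["dark_obs"], ctx["light_obs"] = dark_obs, light_obs
    return {"n_reflections": len(dark_obs), "alpha": params.get("alpha", 0.2)}


def _stage_ded(ctx, cfg: PipelineConfig, params):
    ctx["ded_map"] = ded_map(ctx["light_obs"], ctx["dark_obs"],
                             ctx["dark_model"], snr_min=cfg.snr_min,
                             d_low=cfg.d_low)
    return {"map_sigma": ctx["ded_map"].map_sigma,
            "grid": list(ctx["ded_map"].shape)}


def _stage_integrate(ctx, cfg: PipelineConfig, params):
    mask = RegionMask.from_selection(ctx["dark_model"],
                                     params.get("select", "resi 2"),
                                     radius=params.get("radius", 2.0))
    value = integrate_region(ctx["ded_map"], mask,
                             sign=params.get("sign", "total"),
                             threshold_sigma=cfg.contour_sigma)
    return {"integrated": value, "sign": params.get("sign", "total")}


def _stage_fit_trace(ctx, cfg: PipelineConfig, params):
    trace = ctx.get("trace")
    if trace is None:
        trace = TimeTrace(np.asarray(params["times"], float),
                          np.asarray(params["values"], float))
    fit = fit_trace(trace, params.get("model", "first_order"))
    ctx["fit"] = fit
    return {"model": fit.model, "params": fit.params, "rss": fit.rss}


_STAGES = {
    "simulate_crystal": _stage_simulate_crystal,
    "simulate_dataset": _stage_simulate_dataset,
    "ded": _stage_ded,
    "integrate": _stage_integrate,
    "fit_trace": _stage_fit_trace,
}


class StageError(RuntimeError):
    def __init__(self, message: str, manifest: dict):
        super().__init__(message)
        self.manifest = manifest


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the declared stages in order; returns the run manifest."""
    manifest = {
        "version": __version__,
        "config_hash": config.canonical_hash(),
        "seed": config.seed,
        "stages": [],
    }
    ctx: dict = {}
    for stage in config.stages:
        kind = stage["kind"]
        params = stage.get("params", {})
        if kind not in _STAGES:
            manifest["stages"].append({"kind": kind, "status": "error",
                                       "error": "unknown stage"})
            raise StageError(f"unknown stage kind {kind!r}", manifest)
        try:
            result = _STAGES[kind](ctx, config, params)
        except Exception as exc:
            manifest["stages"].append({"kind": kind, "status": "error",
                                       "error": str(exc)})
            raise StageError(f"stage {kind!r} failed: {exc}", manifest) from exc
        manifest["stages"].append({"kind": kind, "status": "ok",
                                   "result": _jsonable(result)})
    return manifest


def _jsonable(obj):
    return json.loads(json.dumps(obj, default=_coerce))


def _coerce(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")
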