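"""dFoCC: refinement of side-chain reaction coordinates against observed DED.

Conformers are generated by rigid rotation of declared downstream atoms about
pivot-axis bonds; each candidate is scored by the Pearson correlation between
its calculated difference map (|F_c,l| - |F_c,dark|, dark phases) and the
observed difference map over a mask covering the moving atoms.  Refinement is
deterministic coordinate descent with step shrinking, converging at the
resolution floor (0.1 deg / 0.1 A).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .ded_analysis import RegionMask
from .xtal_core import (AtomModel, DensityMap, ReflectionSet,
                        calc_structure_factors, synthesize_map)

__all__ = [
    "RotationAxis",
    "RotationAxisSet",
    "Conformer",
    "generate_conformers",
    "score_conformer",
    "dfocc_refine",
    "DfoccScorer",
    "RefineConfig",
    "asn_axes",
    "load_axes",
    "ZeroVarianceError",
]

ANGLE_FLOOR_DEG = 0.1
DISTANCE_FLOOR_A = 0.1


class ZeroVarianceError(ValueError):
    pass


Label = tuple[int, str]


@dataclass(frozen=True)
class RotationAxis:
    """Rotation about the pivot->axis bond moving the downstream atoms."""

    pivot: Label
    axis: Label
    moving: tuple[Label, ...]
    name: str = ""
    main_chain: bool = False

    def validate(self, model: AtomModel) -> None:
        for lb in (self.pivot, self.axis, *self.moving):
            try:
                model.index_of(lb)
            except KeyError:
                raise KeyError(
                    f"axis {self.name or self.pivot}: atom {lb!r} missing from model"
                ) from None


@dataclass
class RotationAxisSet:
    axes: list[RotationAxis]
    offsets: np.ndarray | None = None  # degrees, one per axis

    def __post_init__(self) -> None:
        if self.offsets is None:
            self.offsets = np.zeros(len(self.axes))
        self.offsets = np.asarray(self.offsets, dtype=float)
        if len(self.offsets) != len(self.axes):
            raise ValueError("one offset per axis required")

    def __len__(self) -> int:
        return len(self.axes)

    def validate(self, model: AtomModel) -> None:
        for ax in self.axes:
            ax.validate(model)


def wrap_angle(a: float) -> float:
    """Wrap to (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def rotate_about_axis(xyz: np.ndarray, origin: np.ndarray, direction: np.ndarray,
                      angle_deg: float) -> np.ndarray:
    """Rodrigues rotation of points about the line origin + t*direction."""
    u = np.asarray(direction, float)
    u = u / np.linalg.norm(u)
    th = np.radians(angle_deg)
    c, s = np.cos(th), np.sin(th)
    rel = xyz - origin
    return (origin + rel * c + np.cross(u, rel) * s
            + np.outer(rel @ u, u) * (1.0 - c))


def apply_axis_offsets(model: AtomModel, axes: RotationAxisSet,
                       offsets=None) -> AtomModel:
    """New model with each axis rotated by its offset, in declared order."""
    offsets = axes.offsets if offsets is None else np.asarray(offsets, float)
    out = model.copy()
    for ax, ang in zip(axes.axes, offsets):
        if ang == 0.0:
            continue
        pivot = out.xyz[out.index_of(ax.pivot)]
        axis_pt = out.xyz[out.index_of(ax.axis)]
        idx = out.indices_of(ax.moving)
        out.xyz[idx] = rotate_about_axis(out.xyz[idx], pivot, axis_pt - pivot, ang)
    return out


@dataclass
class Conformer:
    base: AtomModel
    axes: RotationAxisSet
    offsets: np.ndarray
    cc: float | None = None
    _model: AtomModel | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)

    @property
    def model(self) -> AtomModel:
        if self._model is None:
            self._model = apply_axis_offsets(self.base, self.axes, self.offsets)
        return self._model

    def moving_indices(self) -> np.ndarray:
        labels = sorted({lb for ax in self.axes.axes for lb in ax.moving})
        return self.base.indices_of(labels)


def generate_conformers(model: AtomModel, axes: RotationAxisSet,
                        step_deg: float, span_deg: float,
                        mode: str = "product") -> list[Conformer]:
    """Conformer library around the current axis offsets.

    ``product``: full Cartesian product of per-axis offset grids in
    [-span, +span] at the given step.  ``axis``: per-axis 1-D sweeps keeping
    the other axes at their current offsets (coordinate-descent neighborhood).
    """
    if step_deg <= 0:
        raise ValueError("step must be positive")
    if span_deg < step_deg:
        raise ValueError("span must be at least one step")
    axes.validate(model)
    n_steps = int(np.floor(span_deg / step_deg + 1e-9))
    deltas = np.arange(-n_steps, n_steps + 1) * step_deg
    base_off = axes.offsets
    combos: list[np.ndarray] = []
    if mode == "product":
        mesh = np.meshgrid(*[deltas] * len(axes), indexing="ij")
        flat = np.stack([m.ravel() for m in mesh], axis=1)
        combos = [base_off + row for row in flat]
    elif mode == "axis":
        seen = set()
        for i in range(len(axes)):
            for dlt in deltas:
                off = base_off.copy()
                off[i] += dlt
                key = tuple(np.round(off, 9))
                if key not in seen:
                    seen.add(key)
                    combos.append(off)
    else:
        raise ValueError("mode must be product|axis")
    return [Conformer(base=model, axes=axes,
                      offsets=np.array([wrap_angle(a) for a in off]))
            for off in combos]


class DfoccScorer:
    """Caches the dark structure factors, grid and mask for repeated scoring."""

    def __init__(self, dark_model: AtomModel, ded_o: DensityMap,
                 mask: RegionMask, d_min: float, form_mode: str = "cm"):
        self.dark_model = dark_model
        self.ded_o = ded_o
        self.mask = mask
        self.form_mode = form_mode
        self.dark_calc = calc_structure_factors(dark_model, d_min,
                                                form_mode=form_mode)
        self.grid = ded_o.shape
        self.voxels = mask.voxel_mask(self.grid, ded_o.cell)
        obs = ded_o.values[self.voxels]
        self.obs = obs - obs.mean()
        self.obs_norm = float(np.sqrt(np.sum(self.obs**2)))

    def ded_c(self, conf: Conformer) -> DensityMap:
        light_calc = calc_structure_factors(conf.model, self.dark_calc.d_min,
                                            hkl=self.dark_calc.hkl,
                                            form_mode=self.form_mode)
        signed = light_calc.amp - self.dark_calc.amp
        return synthesize_map(self.dark_calc, grid=self.grid, signed_amp=signed,
                              provenance="calculated-DED")

    def score(self, conf: Conformer) -> float:
        calc = self.ded_c(conf).values[self.voxels]
        calc = calc - calc.mean()
        denom = np.sqrt(np.sum(calc**2)) * self.obs_norm
        if denom == 0:
            raise ZeroVarianceError(
                "calculated DED has zero variance in the mask (no atoms moved?)")
        cc = float(np.sum(calc * self.obs) / denom)
        conf.cc = cc
        return cc


def score_conformer(conf: Conformer, dark_model: AtomModel, ded_o: DensityMap,
                    mask: RegionMask, d_min: float,
                    form_mode: str = "cm") -> float:
    """Pearson CC between the conformer's DED_c and DED_o over the mask."""
    return DfoccScorer(dark_model, ded_o, mask, d_min, form_mode).score(conf)


@dataclass(frozen=True)
class RefineConfig:
    step_deg: float = 10.0
    span_deg: float = 60.0
    shrink: float = 0.5
    cc_tol: float = 1e-5
    max_rounds: int = 60
    d_min: float = 2.0
    form_mode: str = "cm"
    mask_radius: float = 2.5
    angle_floor_deg: float = ANGLE_FLOOR_DEG
    distance_floor_a: float = DISTANCE_FLOOR_A  # 0 disables the distance stop


def _score_mask(dark_model: AtomModel, axes: RotationAxisSet,
                probe_offsets, radius: float) -> RegionMask:
    """Union of spheres around moving atoms in dark and probe positions."""
    labels = sorted({lb for ax in axes.axes for lb in ax.moving})
    idx = dark_model.indices_of(labels)
    pts = [dark_model.xyz[idx]]
    for off in probe_offsets:
        probe = apply_axis_offsets(dark_model, axes, off)
        pts.append(probe.xyz[idx])
    return RegionMask(np.vstack(pts), radius=radius, label="dfocc-moving")


def dfocc_refine(dark_model: AtomModel, axes: RotationAxisSet,
                 ded_o: DensityMap, mask: RegionMask | None = None,
                 config: RefineConfig = RefineConfig()) -> Conformer:
    """Deterministic coordinate-descent maximization of the DED correlation.

    Each round sweeps every axis over a 1-D grid around the current offsets,
    re-centers on the best conformer (ties: smaller total |offset|, then
    earlier axis order), and shrinks step and span when no axis improves the
    CC by more than `cc_tol`.  Stops at the angular floor (0.1 deg) or when a
    step would move no atom by more than 0.1 A.  The returned conformer
    carries the per-round best-CC trace in ``trace``.
    """
    axes = RotationAxisSet(list(axes.axes), np.asarray(axes.offsets, float).copy())
    axes.validate(dark_model)
    if mask is None:
        span = config.span_deg
        probes = []
        for i in range(len(axes)):
            for sgn in (-1.0, 1.0):
                off = axes.offsets.copy()
                off[i] += sgn * span
                probes.append(off)
        mask = _score_mask(dark_model, axes, [axes.offsets, *probes],
                           config.mask_radius)
    scorer = DfoccScorer(dark_model, ded_o, mask, config.d_min, config.form_mode)
    if scorer.obs_norm == 0:
        warnings.warn("observed DED carries no signal in the mask; returning "
                      "base offsets", UserWarning, stacklevel=2)
        base = Conformer(dark_model, axes, axes.offsets.copy())
        base.trace = np.array([])  # type: ignore[attr-defined]
        return base

    # max lever arm of any moving atom about its axis, for the distance floor
    def max_lever() -> float:
        lev = 0.0
        for ax in axes.axes:
            pivot = dark_model.xyz[dark_model.index_of(ax.pivot)]
            direction = dark_model.xyz[dark_model.index_of(ax.axis)] - pivot
            u = direction / np.linalg.norm(direction)
            for lb in ax.moving:
                rel = dark_model.xyz[dark_model.index_of(lb)] - pivot
                lev = max(lev, float(np.linalg.norm(rel - (rel @ u) * u)))
        return lev

    lever = max_lever()
    current = Conformer(dark_model, axes, axes.offsets.copy())
    try:
        best_cc = scorer.score(current)
    except ZeroVarianceError:
        best_cc = -np.inf
    trace = [best_cc] if np.isfinite(best_cc) else []

    step, span = config.step_deg, config.span_deg
    improved_ever = False
    for _ in range(config.max_rounds):
        round_best = current
        round_cc = best_cc
        for conf in generate_conformers(dark_model,
                                        RotationAxisSet(axes.axes,
                                                        current.offsets.copy()),
                                        step, span, mode="axis"):
            try:
                cc = scorer.score(conf)
            except ZeroVarianceError:
                continue
            better = cc > round_cc + 1e-12
            tie = abs(cc - round_cc) <= 1e-12
            if better or (tie and _prefer(conf.offsets, round_best.offsets)):
                round_best, round_cc = conf, cc
        if round_cc > best_cc + config.cc_tol:
            improved_ever = True
            current, best_cc = round_best, round_cc
            trace.append(best_cc)
            continue
        if round_cc > best_cc:
            current, best_cc = round_best, round_cc
        trace.append(best_cc)
        step *= config.shrink
        span = max(step, span * config.shrink)
        if step < config.angle_floor_deg:
            break
        if (config.distance_floor_a > 0
                and lever * np.radians(step) < config.distance_floor_a):
            break
    if not improved_ever and not np.isfinite(best_cc):
        raise ZeroVarianceError("no conformer could be scored")
    if not improved_ever:
        warnings.warn("dFoCC found no improving move; returning base offsets",
                      UserWarning, stacklevel=2)
    current.cc = best_cc if np.isfinite(best_cc) else None
    current.trace = np.asarray(trace, dtype=float)  # type: ignore[attr-defined]
    return current


def _prefer(off_a: np.ndarray, off_b: np.ndarray) -> bool:
    """Tie-break: smaller total |offset| wins, then lexicographic axis order."""
    sa, sb = np.sum(np.abs(off_a)), np.sum(np.abs(off_b))
    if not np.isclose(sa, sb):
        return sa < sb
    return tuple(off_a) < tuple(off_b)


# --------------------------------------------------------------------------- #
# axis templates and declaration files

_SIDE_CHAIN_TEMPLATES: dict[str, list[tuple[str, str, str, list[str]]]] = {
    # residue type -> (axis name, pivot, axis atom, downstream atoms)
    "ASN": [("chi1", "CA", "CB", ["CG", "OD1", "ND2"]),
            ("chi2", "CB", "CG", ["OD1", "ND2"])],
    "ASP": [("chi1", "CA", "CB", ["CG", "OD1", "OD2"]),
            ("chi2", "CB", "CG", ["OD1", "OD2"])],
    "GLU": [("chi1", "CA", "CB", ["CG", "CD", "OE1", "OE2"]),
            ("chi2", "CB", "CG", ["CD", "OE1", "OE2"]),
            ("chi3", "CG", "CD", ["OE1", "OE2"])],
    "HIS": [("chi1", "CA", "CB", ["CG", "ND1", "CD2", "CE1", "NE2"]),
            ("chi2", "CB", "CG", ["ND1", "CD2", "CE1", "NE2"])],
}


def sidechain_axes(res_id: int, res_type: str) -> RotationAxisSet:
    """Template rotation axes for a standard side chain at residue `res_id`."""
    try:
        template = _SIDE_CHAIN_TEMPLATES[res_type.upper()]
    except KeyError:
        raise KeyError(f"no side-chain template for {res_type!r}") from None
    axes = [RotationAxis(pivot=(res_id, piv), axis=(res_id, axm),
                         moving=tuple((res_id, m) for m in moving), name=name)
            for name, piv, axm, moving in template]
    return RotationAxisSet(axes)


def asn_axes(res_id: int) -> RotationAxisSet:
    return sidechain_axes(res_id, "ASN")


def load_axes(path) -> RotationAxisSet:
    """Read axis declarations from JSON.

    Format: {"axes": [{"name": ..., "pivot": [resi, atom],
    "axis": [resi, atom], "moving": [[resi, atom], ...],
    "main_chain": false}, ...]}
    """
    with open(path) as fh:
        data = json.load(fh)
    axes = [RotationAxis(pivot=(int(a["pivot"][0]), a["pivot"][1]),
                         axis=(int(a["axis"][0]), a["axis"][1]),
                         moving=tuple((int(r), n) for r, n in a["moving"]),
                         name=a.get("name", ""),
                         main_chain=bool(a.get("main_chain", False)))
            for a in data["axes"]]
    return RotationAxisSet(axes)


def save_axes(axes: RotationAxisSet, path) -> None:
    data = {"axes": [{"name": ax.name,
                      "pivot": [ax.pivot[0], ax.pivot[1]],
                      "axis": [ax.axis[0], ax.axis[1]],
                      "moving": [[r, n] for r, n in ax.moving],
                      "main_chain": ax.main_chain} for ax in axes.axes]}
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)
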