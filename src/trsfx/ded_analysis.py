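"""Quantitative analysis of difference electron density (DED) maps.

Sigma thresholding, signed integration within atom-derived masks, feature
time traces, pairwise Pearson correlation maps, and SVD of masked map series
with reconvolution from leading components.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .xtal_core import AtomModel, DensityMap, UnitCell

__all__ = [
    "RegionMask",
    "DEDTrace",
    "SVDResult",
    "select_atoms",
    "threshold_map",
    "integrate_region",
    "feature_correlation_map",
    "svd_decompose",
    "svd_reconvolute",
    "integrate_series",
    "EmptyMaskError",
]


class EmptyMaskError(ValueError):
    pass


# --------------------------------------------------------------------------- #
# atom selections

_SELECTION_CLAUSE = re.compile(r"^(resi|name|elem)\s+(\S.*)$")


def select_atoms(model: AtomModel, selection: str) -> list[tuple[int, str]]:
    """Resolve a selection string to (residue id, atom name) labels.

    Grammar: clauses joined by ``and``; each clause is one of
    ``resi 321`` / ``resi 484-494`` / ``resi 2,5,9`` (ranges and lists mix),
    ``name CA,CB``, ``elem C,N``.  Matching is case-insensitive for names.
    """
    mask = np.ones(len(model), dtype=bool)
    for raw in selection.split(" and "):
        clause = raw.strip()
        m = _SELECTION_CLAUSE.match(clause)
        if not m:
            raise ValueError(f"cannot parse selection clause {clause!r}")
        kind, arg = m.group(1), m.group(2).strip()
        if kind == "resi":
            wanted: set[int] = set()
            for part in arg.split(","):
                part = part.strip()
                if "-" in part[1:]:
                    lo, hi = part.split("-", 1)
                    wanted.update(range(int(lo), int(hi) + 1))
                else:
                    wanted.add(int(part))
            mask &= np.isin(model.res_ids, list(wanted))
        elif kind == "name":
            names = {x.strip().upper() for x in arg.split(",")}
            mask &= np.array([a.upper() in names for a in model.atom_names])
        else:  # elem
            els = {x.strip().capitalize() for x in arg.split(",")}
            mask &= np.array([e.capitalize() in els for e in model.elements])
    labels = [lb for lb, keep in zip(model.labels(), mask) if keep]
    if not labels:
        raise EmptyMaskError(f"selection {selection!r} matches no atoms")
    return labels


@dataclass
class RegionMask:
    """Union of spheres of `radius` around reference points (Cartesian A)."""

    points: np.ndarray
    radius: float = 2.0
    label: str = ""
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.radius <= 0:
            raise ValueError("mask radius must be positive")
        if self.points.shape[0] == 0:
            raise EmptyMaskError("mask has no reference points")

    @classmethod
    def from_selection(cls, model: AtomModel, selection: str,
                       radius: float = 2.0) -> "RegionMask":
        labels = select_atoms(model, selection)
        idx = model.indices_of(labels)
        return cls(points=model.xyz[idx], radius=radius, label=selection)

    @classmethod
    def from_labels(cls, model: AtomModel, labels, radius: float = 2.0) -> "RegionMask":
        idx = model.indices_of(labels)
        return cls(points=model.xyz[idx], radius=radius, label=",".join(
            f"{r}:{a}" for r, a in labels))

    def voxel_mask(self, shape: tuple[int, int, int], cell: UnitCell) -> np.ndarray:
        """Boolean voxel array; periodic minimum-image distances."""
        key = (shape, id(cell))
        if key in self._cache:
            return self._cache[key]
        nx, ny, nz = shape
        fx, fy, fz = np.meshgrid(
            np.arange(nx) / nx, np.arange(ny) / ny, np.arange(nz) / nz,
            indexing="ij")
        vox_frac = np.stack([fx, fy, fz], axis=-1).reshape(-1, 3)
        pts_frac = cell.fractionalize(self.points)
        out = np.zeros(vox_frac.shape[0], dtype=bool)
        for p in pts_frac:
            dfrac = vox_frac - p
            dfrac -= np.round(dfrac)
            dcart = cell.orthogonalize(dfrac)
            out |= np.einsum("ij,ij->i", dcart, dcart) <= self.radius**2
        mask = out.reshape(shape)
        if not mask.any():
            raise EmptyMaskError("mask covers no voxels on this grid")
        self._cache[key] = mask
        return mask


# --------------------------------------------------------------------------- #
# traces


@dataclass
class DEDTrace:
    """Signed integrated density versus time for one region."""

    times: np.ndarray
    positive: np.ndarray
    negative: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positive = np.asarray(self.positive, dtype=float)
        self.negative = np.asarray(self.negative, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def total(self) -> np.ndarray:
        return self.positive + self.negative


# --------------------------------------------------------------------------- #
# map operations


def threshold_map(dmap: DensityMap, level_sigma: float) -> DensityMap:
    """Zero every voxel with |value| below level_sigma x map RMS."""
    if level_sigma < 0:
        raise ValueError("sigma level must be >= 0")
    cut = level_sigma * dmap.map_sigma
    vals = np.where(np.abs(dmap.values) >= cut, dmap.values, 0.0)
    out = DensityMap(vals, dmap.cell, provenance=dmap.provenance)
    return out


def integrate_region(
    dmap: DensityMap,
    mask: RegionMask,
    sign: str = "total",
    threshold_sigma: float = 3.0,
    apply_threshold: bool = True,
) -> float:
    """Sum of (optionally 3-sigma-thresholded) voxel values of one sign in a region.

    Negative sums are returned as negative numbers; ``total`` is their sum
    with the positive part.
    """
    if sign not in ("positive", "negative", "total"):
        raise ValueError("sign must be positive|negative|total")
    vox = mask.voxel_mask(dmap.shape, dmap.cell)
    src = threshold_map(dmap, threshold_sigma) if apply_threshold else dmap
    vals = src.values[vox]
    pos = float(vals[vals > 0].sum())
    neg = float(vals[vals < 0].sum())
    if sign == "positive":
        return pos
    if sign == "negative":
        return neg
    return pos + neg


def integrate_series(
    maps: list[DensityMap],
    times,
    mask: RegionMask,
    threshold_sigma: float = 3.0,
    label: str = "",
) -> DEDTrace:
    pos = [integrate_region(m, mask, "positive", threshold_sigma) for m in maps]
    neg = [integrate_region(m, mask, "negative", threshold_sigma) for m in maps]
    return DEDTrace(times=np.asarray(times, float), positive=np.array(pos),
                    negative=np.array(neg), label=label)


def feature_correlation_map(vectors) -> np.ndarray:
    """Pairwise Pearson correlation between per-time feature vectors.

    Zero-variance vectors yield NaN in their row/column (flagged via warning)
    rather than a silent zero; the diagonal is exactly 1 where defined.
    """
    arr = np.asarray(vectors, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 equal-length feature vectors")
    n = arr.shape[0]
    sd = arr.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance vector(s): correlation undefined (NaN)",
            UserWarning, stacklevel=2)
    centered = arr - arr.mean(axis=1, keepdims=True)
    cov = centered @ centered.T / arr.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = cov / np.outer(sd, sd)
    cc[degenerate, :] = np.nan
    cc[:, degenerate] = np.nan
    good = ~degenerate
    cc[np.ix_(good, good)] = np.clip(cc[np.ix_(good, good)], -1.0, 1.0)
    cc[good, good] = 1.0
    return cc


# --------------------------------------------------------------------------- #
# SVD of map series


@dataclass
class SVDResult:
    """SVD of a masked DED map series: voxels x time = lSV . diag(SV) . rSV."""

    lsv: np.ndarray            # (n_voxels_masked, k) orthonormal columns
    sv: np.ndarray             # (k,) decreasing, non-negative
    rsv: np.ndarray            # (k, n_times) orthonormal rows
    voxel_index: np.ndarray    # flat indices of masked voxels
    shape: tuple[int, int, int]
    cell: UnitCell
    mask: RegionMask
    times: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return len(self.sv)

    def lsv_map(self, i: int) -> DensityMap:
        """One left singular vector embedded as a full-grid map."""
        flat = np.zeros(int(np.prod(self.shape)))
        flat[self.voxel_index] = self.lsv[:, i]
        return DensityMap(flat.reshape(self.shape), self.cell,
                          provenance="calculated-DED")


def svd_decompose(series: list[DensityMap], mask: RegionMask,
                  times=None) -> SVDResult:
    """Decompose a DED map series restricted to `mask` into lSV/SV/rSV.

    Rows are masked voxels, columns are time points; sign convention: the
    masked voxel of largest |loading| in each lSV is positive.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 maps")
    shape = series[0].shape
    cell = series[0].cell
    for m in series[1:]:
        if m.shape != shape:
            raise ValueError("maps in a series must share one grid")
    vox = mask.voxel_mask(shape, cell)
    voxel_index = np.flatnonzero(vox.ravel())
    a = np.stack([m.values.ravel()[voxel_index] for m in series], axis=1)
    u, s, vt = np.linalg.svd(a, full_matrices=False)
    for i in range(len(s)):
        j = int(np.argmax(np.abs(u[:, i])))
        if u[j, i] < 0:
            u[:, i] *= -1
            vt[i, :] *= -1
    return SVDResult(lsv=u, sv=s, rsv=vt, voxel_index=voxel_index,
                     shape=shape, cell=cell, mask=mask,
                     times=None if times is None else np.asarray(times, float))


def svd_reconvolute(result: SVDResult, n_components: int) -> list[DensityMap]:
    """Per-time maps rebuilt from the first n components; zero outside the mask."""
    if not 1 <= n_components <= result.n_components:
        raise ValueError(
            f"n_components must be in [1, {result.n_components}], got {n_components}")
    a = (result.lsv[:, :n_components]
         * result.sv[:n_components]) @ result.rsv[:n_components, :]
    maps = []
    for t in range(a.shape[1]):
        flat = np.zeros(int(np.prod(result.shape)))
        flat[result.voxel_index] = a[:, t]
        maps.append(DensityMap(flat.reshape(result.shape), result.cell,
                               provenance="calculated-DED"))
    return maps
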