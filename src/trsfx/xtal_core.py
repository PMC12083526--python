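"""Minimal P1 crystallographic engine.

Structure factors by direct summation over atoms, SCALEIT-style relative
scaling, SNR/resolution-filtered difference amplitudes, and FFT Fourier
synthesis of real-space maps.  Everything operates on triclinic P1 cells;
no space-group machinery is provided or wanted here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "UnitCell",
    "AtomModel",
    "ReflectionSet",
    "DensityMap",
    "calc_structure_factors",
    "scale_to_reference",
    "difference_amplitudes",
    "synthesize_map",
    "ded_map",
    "default_grid",
    "UnknownElementError",
    "InsufficientOverlapError",
    "MissingPhaseError",
]


class UnknownElementError(ValueError):
    pass


class InsufficientOverlapError(ValueError):
    pass


class MissingPhaseError(ValueError):
    pass


# --------------------------------------------------------------------------- #
# unit cell


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell (lengths in Angstrom, angles in degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180)")
        if self.volume <= 0:
            raise ValueError("cell volume must be positive")

    @property
    def volume(self) -> float:
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            return -1.0
        return self.a * self.b * self.c * float(np.sqrt(arg))

    @property
    def orth_matrix(self) -> np.ndarray:
        """3x3 matrix taking fractional to Cartesian coordinates."""
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = np.sin(np.radians(self.gamma))
        v = self.volume / (self.a * self.b * self.c)
        return np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, self.c * v / sg],
            ]
        )

    @property
    def frac_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.orth_matrix)

    def fractionalize(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz) @ self.frac_matrix.T

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac) @ self.orth_matrix.T

    def d_spacing(self, hkl: np.ndarray) -> np.ndarray:
        """Resolution d (Angstrom) of reflections (n, 3)."""
        hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
        # reciprocal metric tensor
        g = self.orth_matrix.T @ self.orth_matrix
        g_star = np.linalg.inv(g)
        inv_d2 = np.einsum("ni,ij,nj->n", hkl, g_star, hkl)
        with np.errstate(divide="ignore"):
            return 1.0 / np.sqrt(inv_d2)


# --------------------------------------------------------------------------- #
# atomic model

# Cromer-Mann 4-Gaussian coefficients (a1..a4, b1..b4, c) for the elements the
# toy systems use.  f(s) = sum a_i exp(-b_i s^2) + c with s = sin(theta)/lambda.
CROMER_MANN = {
    "H": ([0.489918, 0.262003, 0.196767, 0.049879],
          [20.6593, 7.74039, 49.5519, 2.20159], 0.001305),
    "C": ([2.31000, 1.02000, 1.58860, 0.865000],
          [20.8439, 10.2075, 0.568700, 51.6512], 0.215600),
    "N": ([12.2126, 3.13220, 2.01250, 1.16630],
          [0.005700, 9.89330, 28.9975, 0.582600], -11.529),
    "O": ([3.04850, 2.28680, 1.54630, 0.867000],
          [13.2771, 5.70110, 0.323900, 32.9089], 0.250800),
    "P": ([6.43450, 4.17910, 1.78000, 1.49080],
          [1.90670, 27.1570, 0.526000, 68.1645], 1.11490),
    "S": ([6.90530, 5.20340, 1.43790, 1.58630],
          [1.46790, 22.2151, 0.253600, 56.1720], 0.866900),
}

ELEMENT_Z = {"H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16}

# width of the single-Gaussian "toy" form factor (b coefficient, A^2)
_TOY_B = 16.0


def form_factor(element: str, s2: np.ndarray, mode: str = "cm") -> np.ndarray:
    """Atomic scattering factor at s^2 = (sin(theta)/lambda)^2 = 1/(4 d^2)."""
    el = element.capitalize()
    if el not in ELEMENT_Z:
        raise UnknownElementError(f"no form factor for element {element!r}")
    if mode == "toy":
        return ELEMENT_Z[el] * np.exp(-_TOY_B * s2)
    a, b, c = CROMER_MANN[el]
    f = np.full_like(np.asarray(s2, dtype=float), c)
    for ai, bi in zip(a, b):
        f += ai * np.exp(-bi * s2)
    return f


@dataclass
class AtomModel:
    """Coordinate model: parallel arrays over atoms, Cartesian Angstrom."""

    elements: list[str]
    res_ids: np.ndarray
    res_names: list[str]
    atom_names: list[str]
    xyz: np.ndarray
    occ: np.ndarray
    b: np.ndarray
    cell: UnitCell

    def __post_init__(self) -> None:
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        self.occ = np.asarray(self.occ, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        n = len(self.elements)
        if not (len(self.res_ids) == len(self.res_names) == len(self.atom_names)
                == self.xyz.shape[0] == len(self.occ) == len(self.b) == n):
            raise ValueError("inconsistent atom array lengths")
        if np.any((self.occ < 0) | (self.occ > 1)):
            raise ValueError("occupancies must lie in [0, 1]")
        if np.any(self.b < 0):
            raise ValueError("B-factors must be non-negative")
        labels = self.labels()
        if len(set(labels)) != n:
            raise ValueError("duplicate (residue, atom-name) labels")

    def __len__(self) -> int:
        return len(self.elements)

    def labels(self) -> list[tuple[int, str]]:
        return [(int(r), a) for r, a in zip(self.res_ids, self.atom_names)]

    def index_of(self, label: tuple[int, str]) -> int:
        try:
            return self.labels().index((int(label[0]), label[1]))
        except ValueError:
            raise KeyError(f"no atom labelled {label!r}") from None

    def indices_of(self, labels) -> np.ndarray:
        return np.array([self.index_of(lb) for lb in labels], dtype=int)

    def frac(self) -> np.ndarray:
        return self.cell.fractionalize(self.xyz)

    def copy(self) -> "AtomModel":
        return AtomModel(
            elements=list(self.elements),
            res_ids=self.res_ids.copy(),
            res_names=list(self.res_names),
            atom_names=list(self.atom_names),
            xyz=self.xyz.copy(),
            occ=self.occ.copy(),
            b=self.b.copy(),
            cell=self.cell,
        )


# --------------------------------------------------------------------------- #
# reflections


@dataclass
class ReflectionSet:
    """Unique P1 reflections with amplitude/sigma and optional phase (deg)."""

    hkl: np.ndarray
    amp: np.ndarray
    sigma: np.ndarray
    cell: UnitCell
    d_min: float
    d_max: float = np.inf
    phase: np.ndarray | None = None  # degrees; NaN where unknown
    role: str = "plain"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        self.amp = np.asarray(self.amp, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=float)
        n = self.hkl.shape[0]
        if len(self.amp) != n or len(self.sigma) != n:
            raise ValueError("inconsistent reflection array lengths")
        if self.phase is not None and len(self.phase) != n:
            raise ValueError("phase array length mismatch")
        if np.any(self.amp < 0):
            raise ValueError("amplitudes must be non-negative")
        if np.any(np.all(self.hkl == 0, axis=1)):
            raise ValueError("the (0,0,0) term is not allowed")
        keys = {tuple(h) for h in self.hkl}
        if len(keys) != n:
            raise ValueError("duplicate Miller indices")

    def __len__(self) -> int:
        return self.hkl.shape[0]

    def d(self) -> np.ndarray:
        return self.cell.d_spacing(self.hkl)

    def has_phases(self) -> bool:
        return self.phase is not None and not np.any(np.isnan(self.phase))

    def complex_f(self) -> np.ndarray:
        if not self.has_phases():
            missing = ([] if self.phase is None
                       else [tuple(h) for h in self.hkl[np.isnan(self.phase)]])
            raise MissingPhaseError(f"phases missing for reflections {missing[:10] or 'all'}")
        return self.amp * np.exp(1j * np.radians(self.phase))

    def index_map(self) -> dict[tuple[int, int, int], int]:
        return {tuple(h): i for i, h in enumerate(self.hkl)}

    def common_with(self, other: "ReflectionSet") -> tuple[np.ndarray, np.ndarray]:
        """Index arrays (into self, into other) of shared Miller indices."""
        omap = other.index_map()
        ii, jj = [], []
        for i, h in enumerate(self.hkl):
            j = omap.get(tuple(h))
            if j is not None:
                ii.append(i)
                jj.append(j)
        return np.array(ii, dtype=int), np.array(jj, dtype=int)

    def subset(self, idx: np.ndarray, **overrides) -> "ReflectionSet":
        kw = dict(
            hkl=self.hkl[idx],
            amp=self.amp[idx],
            sigma=self.sigma[idx],
            cell=self.cell,
            d_min=self.d_min,
            d_max=self.d_max,
            phase=None if self.phase is None else self.phase[idx],
            role=self.role,
            meta=dict(self.meta),
        )
        kw.update(overrides)
        return ReflectionSet(**kw)


# --------------------------------------------------------------------------- #
# maps


@dataclass
class DensityMap:
    """Real-space scalar map over a P1 cell (values typically e/A^3)."""

    values: np.ndarray
    cell: UnitCell
    provenance: str = "plain"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("map must be a 3-D grid with >= 2 points per axis")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def map_sigma(self) -> float:
        """RMS deviation of voxel values (maps lack F000, so mean ~ 0)."""
        return float(np.sqrt(np.mean((self.values - self.values.mean()) ** 2)))

    def sigma_scaled(self) -> np.ndarray:
        s = self.map_sigma
        return self.values / s if s > 0 else self.values.copy()

    def voxel_centers_frac(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        nx, ny, nz = self.shape
        return (np.arange(nx) / nx, np.arange(ny) / ny, np.arange(nz) / nz)

    def copy(self) -> "DensityMap":
        return DensityMap(self.values.copy(), self.cell, self.provenance)


def default_grid(cell: UnitCell, d_min: float, spacing_factor: float = 3.0) -> tuple[int, int, int]:
    """Grid with spacing <= d_min / spacing_factor along each axis."""
    return tuple(int(np.ceil(length / (d_min / spacing_factor)))
                 for length in (cell.a, cell.b, cell.c))


# --------------------------------------------------------------------------- #
# operations


def unique_hkl(cell: UnitCell, d_min: float, d_max: float = np.inf) -> np.ndarray:
    """All unique P1 reflections (one Friedel mate each) with d in [d_min, d_max]."""
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    g_star = np.linalg.inv(cell.orth_matrix.T @ cell.orth_matrix)
    # per-axis index bound: |h_i| <= a_i* norm backed out of |h . a*| <= 1/d
    lims = [int(np.ceil(np.sqrt(g_star[i, i]) ** -1 / d_min)) + 1 for i in range(3)]
    h = np.arange(-lims[0], lims[0] + 1)
    k = np.arange(-lims[1], lims[1] + 1)
    l = np.arange(-lims[2], lims[2] + 1)
    hkl = np.array(np.meshgrid(h, k, l, indexing="ij")).reshape(3, -1).T
    hkl = hkl[np.any(hkl != 0, axis=1)]
    # unique hemisphere: h > 0, or h == 0 and k > 0, or h == k == 0 and l > 0
    keep = (hkl[:, 0] > 0) | ((hkl[:, 0] == 0) & (hkl[:, 1] > 0)) | (
        (hkl[:, 0] == 0) & (hkl[:, 1] == 0) & (hkl[:, 2] > 0))
    hkl = hkl[keep]
    d = cell.d_spacing(hkl)
    sel = (d >= d_min) & (d <= d_max)
    hkl = hkl[sel]
    if hkl.shape[0] == 0:
        raise ValueError(f"no reflections with d >= {d_min} A in this cell")
    order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0]))
    return hkl[order]


def calc_structure_factors(
    model: AtomModel,
    d_min: float,
    d_max: float = np.inf,
    hkl: np.ndarray | None = None,
    form_mode: str = "cm",
    role: str = "calculated-dark",
) -> ReflectionSet:
    """Direct-summation structure factors for every unique P1 reflection.

    F(h) = sum_j occ_j f_j(s) exp(-B_j s^2) exp(2 pi i h.x_j),
    s^2 = 1/(4 d^2).  Friedel mates are implied by conjugation.
    """
    if len(model) == 0:
        raise ValueError("model has no atoms")
    if hkl is None:
        hkl = unique_hkl(model.cell, d_min, d_max)
    else:
        hkl = np.asarray(hkl, dtype=int).reshape(-1, 3)
    d = model.cell.d_spacing(hkl)
    s2 = 1.0 / (4.0 * d * d)
    frac = model.frac()
    f_total = np.zeros(hkl.shape[0], dtype=complex)
    # group atoms by (element, B, occ) would micro-optimize; plain loop is fine
    phases = np.exp(2j * np.pi * (hkl @ frac.T))  # (n_refl, n_atoms)
    for j, el in enumerate(model.elements):
        fj = form_factor(el, s2, mode=form_mode)
        f_total += model.occ[j] * fj * np.exp(-model.b[j] * s2) * phases[:, j]
    amp = np.abs(f_total)
    phase = np.degrees(np.angle(f_total))
    return ReflectionSet(
        hkl=hkl, amp=amp, sigma=np.zeros_like(amp), cell=model.cell,
        d_min=float(d_min), d_max=float(d_max) if np.isfinite(d_max) else np.inf,
        phase=phase, role=role,
    )


def scale_to_reference(moving: ReflectionSet, reference: ReflectionSet) -> ReflectionSet:
    """SCALEIT-style isotropic scaling k*exp(-B_rel/(4 d^2)) of `moving` onto `reference`.

    Minimizes the sigma-weighted squared amplitude residual over common
    reflections; the fitted per-reflection factor multiplies amplitudes and
    sigmas alike.
    """
    im, ir = moving.common_with(reference)
    if len(im) < 10:
        raise InsufficientOverlapError(
            f"only {len(im)} common reflections; need >= 10 to scale")
    fm = moving.amp[im]
    fr = reference.amp[ir]
    s2 = 1.0 / (4.0 * moving.d()[im] ** 2)
    var = moving.sigma[im] ** 2 + reference.sigma[ir] ** 2
    w = np.where(var > 0, 1.0 / np.where(var > 0, var, 1.0), 1.0)
    ok = (fm > 0) & (fr > 0)
    # log-linear initial guess, then exact weighted non-linear refinement
    if np.count_nonzero(ok) >= 2:
        coef = np.polyfit(s2[ok], np.log(fr[ok] / fm[ok]), 1)
        k0, b0 = float(np.exp(coef[1])), float(-4.0 * coef[0])
    else:  # pragma: no cover - degenerate input
        k0, b0 = 1.0, 0.0

    def resid(p):
        k, b = p
        return np.sqrt(w) * (fr - k * np.exp(-b * s2) * fm)

    sol = least_squares(resid, x0=[k0, b0], method="lm", xtol=1e-14, ftol=1e-14)
    k, b_rel = float(sol.x[0]), float(sol.x[1])
    factor = k * np.exp(-b_rel / (4.0 * moving.d() ** 2))
    out = replace(
        moving,
        amp=moving.amp * factor,
        sigma=moving.sigma * factor,
        meta={**moving.meta, "scale_k": k, "scale_b_rel": b_rel},
    )
    return out


def difference_amplitudes(
    light: ReflectionSet,
    dark: ReflectionSet,
    snr_min: float = 3.0,
    d_low: float = 10.0,
) -> ReflectionSet:
    """Filtered difference set dF = |F_o,l| - |F_o,dark|.

    Keeps common reflections with d < d_low (low-resolution cut), d above the
    stricter of both high-resolution limits, and amplitude/sigma > snr_min in
    both parents.  Sigmas combine in quadrature.
    """
    if snr_min < 0:
        raise ValueError("snr_min must be >= 0")
    il, id_ = light.common_with(dark)
    d = light.d()[il]
    d_hi = max(light.d_min, dark.d_min)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr_l = np.where(light.sigma[il] > 0, light.amp[il] / light.sigma[il], np.inf)
        snr_d = np.where(dark.sigma[id_] > 0, dark.amp[id_] / dark.sigma[id_], np.inf)
    keep = (d < d_low) & (d >= d_hi) & (snr_l > snr_min) & (snr_d > snr_min)
    if not np.any(keep):
        warnings.warn("no reflections survive the SNR/resolution filters",
                      UserWarning, stacklevel=2)
    il, id_ = il[keep], id_[keep]
    diff = light.amp[il] - dark.amp[id_]
    sig = np.sqrt(light.sigma[il] ** 2 + dark.sigma[id_] ** 2)
    return ReflectionSet(
        hkl=light.hkl[il],
        amp=np.abs(diff),
        sigma=sig,
        cell=light.cell,
        d_min=d_hi,
        d_max=d_low,
        phase=None,
        role="difference",
        meta={"delta_f": diff, "snr_min": snr_min, "d_low": d_low},
    )


def delta_f(diff: ReflectionSet) -> np.ndarray:
    """Signed difference amplitudes of a difference set."""
    if "delta_f" in diff.meta:
        return np.asarray(diff.meta["delta_f"], dtype=float)
    return diff.amp.copy()


def synthesize_map(
    reflections: ReflectionSet,
    grid: tuple[int, int, int] | None = None,
    signed_amp: np.ndarray | None = None,
    provenance: str = "plain",
) -> DensityMap:
    """Fourier synthesis rho(x) = (1/V) sum_h F(h) exp(-2 pi i h.x).

    The set holds one Friedel mate per reflection; the conjugate mate is added
    automatically so the map is real.  F000 is omitted, hence zero mean.
    `signed_amp` overrides amplitudes (used for signed difference syntheses).
    """
    if grid is None:
        grid = default_grid(reflections.cell, reflections.d_min)
    f = reflections.complex_f()
    if signed_amp is not None:
        f = np.asarray(signed_amp, dtype=float) * np.exp(1j * np.radians(reflections.phase))
    nx, ny, nz = grid
    hkl = reflections.hkl
    if np.any(np.abs(hkl) * 2 >= np.array([nx, ny, nz])):
        raise ValueError("grid too coarse for the highest-index reflection (Nyquist)")
    g = np.zeros((nx, ny, nz), dtype=complex)
    idx = (hkl[:, 0] % nx, hkl[:, 1] % ny, hkl[:, 2] % nz)
    np.add.at(g, idx, f)
    neg = (-hkl[:, 0] % nx, -hkl[:, 1] % ny, -hkl[:, 2] % nz)
    np.add.at(g, neg, np.conj(f))
    rho = np.real(np.fft.fftn(g)) / reflections.cell.volume
    return DensityMap(rho, reflections.cell, provenance=provenance)


def ded_map(
    light: ReflectionSet,
    dark: ReflectionSet,
    dark_model: AtomModel,
    weights: np.ndarray | None = None,
    snr_min: float = 3.0,
    d_low: float = 10.0,
    grid: tuple[int, int, int] | None = None,
    scale: bool = True,
    form_mode: str = "cm",
) -> DensityMap:
    """Observed difference map: scale, filter, phase with the dark model, synthesize."""
    if scale:
        light = scale_to_reference(light, dark)
    diff = difference_amplitudes(light, dark, snr_min=snr_min, d_low=d_low)
    dvals = delta_f(diff)
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if len(weights) != len(diff):
            raise ValueError("one weight per difference reflection required")
        dvals = dvals * weights
    dark_calc = calc_structure_factors(dark_model, d_min=diff.d_min, hkl=diff.hkl,
                                       form_mode=form_mode)
    phased = ReflectionSet(
        hkl=diff.hkl, amp=diff.amp, sigma=diff.sigma, cell=diff.cell,
        d_min=diff.d_min, d_max=diff.d_max, phase=dark_calc.phase,
        role="difference", meta=diff.meta,
    )
    if grid is None:
        grid = default_grid(diff.cell, diff.d_min)
    return synthesize_map(phased, grid=grid, signed_amp=dvals, provenance="observed-DED")
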