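"""Seeded generators for every pipeline input.

A deterministic ~30-atom P1 toy crystal with a pivotable Asn-analog side
chain and a flat fused-ring chromophore mimic, partial-occupancy dark/light
reflection datasets with fractional Gaussian noise, kinetic time series of
datasets, and synthetic crystal absorption spectra series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dfocc import RotationAxis, RotationAxisSet, apply_axis_offsets, asn_axes
from .icos_spectra import ExtinctionTable, Spectrum
from .kinetics import eval_first_order, eval_two_step, two_step_peak_time
from .xtal_core import AtomModel, ReflectionSet, UnitCell, calc_structure_factors

__all__ = [
    "PerturbationSpec",
    "DisorderSpec",
    "KineticScenario",
    "TimeSeriesResult",
    "make_toy_crystal",
    "toy_asn_axes",
    "apply_perturbation",
    "asn_chi2_perturbation",
    "simulate_dataset",
    "simulate_timeseries",
    "simulate_spectra_series",
    "DEFAULT_DELAYS",
    "TOY_CELL",
    "TOY_ATOM_COUNT",
    "ASN_RES_ID",
]

TOY_CELL = UnitCell(18.0, 15.0, 12.0, 90.0, 90.0, 90.0)
ASN_RES_ID = 2
TOY_ATOM_COUNT = 32

# 12 named snapshot delays padded with log-spaced fillers to 19 points (s)
DEFAULT_DELAYS = np.array(sorted(
    [10e-9, 100e-9, 1e-6, 30e-6, 1e-3, 7e-3, 10e-3, 33e-3, 66e-3, 100e-3,
     133e-3, 233e-3]
    + [300e-9, 3e-6, 10e-6, 100e-6, 300e-6, 3e-3, 20e-3]))


# --------------------------------------------------------------------------- #
# geometry helpers


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float,
          angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom d bonded to c with angle(b,c,d) and dihedral(a,b,c,d)."""
    theta = np.radians(angle_deg)
    phi = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * np.cos(theta),
                        bond * np.sin(theta) * np.cos(phi),
                        bond * np.sin(theta) * np.sin(phi)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _ring_coords(center: np.ndarray, bond: float = 1.40) -> np.ndarray:
    """Ten unique vertices of two fused, coplanar hexagons (naphthalene-like)."""
    h = bond * np.sqrt(3.0) / 2.0
    centers = [center + np.array([-h, 0, 0]), center + np.array([h, 0, 0])]
    pts = []
    for c in centers:
        for k in range(6):
            ang = np.radians(60.0 * k + 30.0)
            pts.append(c + bond * np.array([np.cos(ang), np.sin(ang), 0.0]))
    uniq: list[np.ndarray] = []
    for p in pts:
        if not any(np.linalg.norm(p - q) < 1e-6 for q in uniq):
            uniq.append(p)
    assert len(uniq) == 10
    return np.array(uniq)


# --------------------------------------------------------------------------- #
# toy crystal


def make_toy_crystal(seed: int = 0) -> AtomModel:
    """Deterministic 32-atom toy model in an 18 x 15 x 12 A P1 cell.

    Residues: GLY 1, ASN 2 (chi1/chi2 pivotable side chain), GLY 3, a flat
    10-atom fused-ring chromophore mimic (residue 4, RNG), and six waters
    (residues 10-15) whose positions carry a small seeded jitter.
    """
    elements: list[str] = []
    res_ids: list[int] = []
    res_names: list[str] = []
    atom_names: list[str] = []
    xyz: list[np.ndarray] = []
    b: list[float] = []

    def add(el, ri, rn, an, pos, bfac):
        elements.append(el)
        res_ids.append(ri)
        res_names.append(rn)
        atom_names.append(an)
        xyz.append(np.asarray(pos, float))
        b.append(bfac)

    # GLY 1 backbone
    add("N", 1, "GLY", "N", (3.00, 7.00, 6.00), 10.0)
    add("C", 1, "GLY", "CA", (4.45, 7.00, 6.05), 10.0)
    add("C", 1, "GLY", "C", (5.15, 8.25, 6.35), 10.0)
    add("O", 1, "GLY", "O", (4.60, 9.32, 6.30), 11.0)

    # ASN 2 backbone
    n2 = np.array([6.48, 8.22, 6.45])
    ca2 = np.array([7.38, 9.33, 6.70])
    c2 = np.array([8.80, 8.92, 7.05])
    o2 = np.array([9.18, 7.78, 6.90])
    add("N", 2, "ASN", "N", n2, 10.0)
    add("C", 2, "ASN", "CA", ca2, 10.0)
    add("C", 2, "ASN", "C", c2, 10.0)
    add("O", 2, "ASN", "O", o2, 11.0)
    # side chain placed by internal coordinates so chi1/chi2 are well defined
    cb = _nerf(n2, c2, ca2, 1.53, 110.5, -122.0)
    cg = _nerf(n2, ca2, cb, 1.52, 113.0, -65.0)    # chi1 = -65 deg
    od1 = _nerf(ca2, cb, cg, 1.23, 120.8, -20.0)   # chi2 = -20 deg
    nd2 = _nerf(ca2, cb, cg, 1.33, 116.5, 160.0)
    add("C", 2, "ASN", "CB", cb, 12.0)
    add("C", 2, "ASN", "CG", cg, 12.0)
    add("O", 2, "ASN", "OD1", od1, 13.0)
    add("N", 2, "ASN", "ND2", nd2, 13.0)

    # GLY 3 backbone
    add("N", 3, "GLY", "N", (9.62, 9.90, 7.30), 10.0)
    add("C", 3, "GLY", "CA", (11.02, 9.80, 7.60), 10.0)
    add("C", 3, "GLY", "C", (11.72, 11.10, 7.95), 10.0)
    add("O", 3, "GLY", "O", (11.18, 12.20, 7.85), 11.0)

    # flat fused-ring chromophore mimic, residue 4
    ring = _ring_coords(np.array([13.2, 4.2, 3.2]))
    ring_elements = ["N", "C", "C", "C", "C", "C", "C", "C", "C", "N"]
    for i, (p, el) in enumerate(zip(ring, ring_elements), start=1):
        add(el, 4, "RNG", f"R{i}", p, 8.0)

    # solvent
    rng = np.random.default_rng(seed)
    waters = np.array([
        (2.0, 2.2, 2.1), (15.2, 12.1, 9.3), (9.1, 2.4, 9.6),
        (3.2, 12.3, 3.4), (15.6, 3.1, 8.2), (6.3, 5.6, 10.4),
    ])
    waters = waters + rng.normal(0.0, 0.15, size=waters.shape)
    for i, p in enumerate(waters):
        add("O", 10 + i, "HOH", "O", p, 20.0)

    model = AtomModel(
        elements=elements,
        res_ids=np.array(res_ids),
        res_names=res_names,
        atom_names=atom_names,
        xyz=np.array(xyz),
        occ=np.ones(len(elements)),
        b=np.array(b),
        cell=TOY_CELL,
    )
    assert len(model) == TOY_ATOM_COUNT
    return model


def toy_asn_axes() -> RotationAxisSet:
    """chi1/chi2 rotation axes of the toy crystal's Asn-analog residue."""
    return asn_axes(ASN_RES_ID)


# --------------------------------------------------------------------------- #
# perturbations


@dataclass
class DisorderSpec:
    """Occupancy drop and/or B-factor inflation of an atom set."""

    labels: list
    occupancy: float | None = None
    b_add: float | None = None


@dataclass
class PerturbationSpec:
    """Light-state recipe: axis rotations, displacements, then disorder."""

    rotations: list[tuple[RotationAxis, float]] = field(default_factory=list)
    displacements: dict = field(default_factory=dict)
    disorder: DisorderSpec | None = None


def apply_perturbation(model: AtomModel, spec: PerturbationSpec) -> AtomModel:
    """Light-state model: rotations in declared order, then displacements/disorder."""
    out = model.copy()
    for axis, angle in spec.rotations:
        axis.validate(out)
        axset = RotationAxisSet([axis], np.array([angle]))
        out = apply_axis_offsets(out, axset)
    for label, vec in spec.displacements.items():
        out.xyz[out.index_of(label)] += np.asarray(vec, float)
    if spec.disorder is not None:
        idx = out.indices_of(spec.disorder.labels)
        if spec.disorder.occupancy is not None:
            out.occ[idx] = spec.disorder.occupancy
        if spec.disorder.b_add is not None:
            out.b[idx] += spec.disorder.b_add
    return out


def asn_chi2_perturbation(angle_deg: float = -86.4) -> PerturbationSpec:
    """The standard toy light state: Asn-analog chi2 rotation."""
    axes = toy_asn_axes()
    return PerturbationSpec(rotations=[(axes.axes[1], angle_deg)])


# --------------------------------------------------------------------------- #
# reflection datasets


def _observe(f_complex: np.ndarray, template: ReflectionSet, noise_frac: float,
             rng: np.random.Generator, role: str) -> ReflectionSet:
    amp_true = np.abs(f_complex)
    if noise_frac > 0:
        amp = amp_true * (1.0 + rng.normal(0.0, noise_frac, size=amp_true.shape))
        amp = np.clip(amp, 0.0, None)
        sigma = noise_frac * amp_true
    else:
        amp = amp_true.copy()
        sigma = np.zeros_like(amp_true)
    return ReflectionSet(hkl=template.hkl.copy(), amp=amp, sigma=sigma,
                         cell=template.cell, d_min=template.d_min,
                         d_max=template.d_max, phase=None, role=role)


def simulate_dataset(
    dark: AtomModel,
    light: AtomModel,
    alpha: float,
    noise_frac: float = 0.0,
    seed: int = 0,
    d_min: float = 1.8,
    form_mode: str = "cm",
) -> tuple[ReflectionSet, ReflectionSet]:
    """Observed dark/light amplitude datasets for a crystal activated at `alpha`.

    Partial occupancy is modeled as complex structure-factor mixing
    F_mix = (1 - alpha) F_dark + alpha F_light, then fractional Gaussian
    amplitude noise with matching sigmas (seeded).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    f_dark_set = calc_structure_factors(dark, d_min, form_mode=form_mode)
    f_light_set = calc_structure_factors(light, d_min, hkl=f_dark_set.hkl,
                                         form_mode=form_mode)
    f_dark = f_dark_set.complex_f()
    f_mix = (1.0 - alpha) * f_dark + alpha * f_light_set.complex_f()
    dark_obs = _observe(f_dark, f_dark_set, noise_frac, rng, "observed-dark")
    light_obs = _observe(f_mix, f_dark_set, noise_frac, rng, "observed-light")
    return dark_obs, light_obs


# --------------------------------------------------------------------------- #
# kinetic time series of datasets


@dataclass
class KineticScenario:
    """Per-locus kinetics driving activated fractions over a delay grid."""

    loci: dict  # name -> ("first_order", tau) | ("two_step", tau1, tau2)
    delays: np.ndarray = field(default_factory=lambda: DEFAULT_DELAYS.copy())
    alpha_max: float = 0.2
    noise_frac: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        if np.any(self.delays <= 0) or np.any(np.diff(self.delays) <= 0):
            raise ValueError("delays must be positive and increasing")
        if not 0.0 < self.alpha_max <= 1.0:
            raise ValueError("alpha_max must lie in (0, 1]")
        if len(self.loci) > 3:
            raise ValueError("at most 3 loci supported")

    def alpha_locus(self, name: str, t) -> np.ndarray:
        kind, *params = self.loci[name]
        t = np.asarray(t, dtype=float)
        if kind == "first_order":
            (tau,) = params
            return self.alpha_max * (1.0 - np.exp(-t / tau))
        if kind == "two_step":
            tau1, tau2 = params
            peak = eval_two_step(two_step_peak_time(tau1, tau2), 1.0, tau1, tau2)
            return self.alpha_max * eval_two_step(t, 1.0, tau1, tau2) / peak
        raise ValueError(f"unknown kinetic kind {kind!r}")


@dataclass
class TimeSeriesResult:
    delays: np.ndarray
    dark_obs: ReflectionSet
    light_obs: list[ReflectionSet]
    alphas: dict  # locus name -> fraction per delay


def simulate_timeseries(
    scenario: KineticScenario,
    dark: AtomModel,
    perturbations: dict,
    d_min: float = 1.8,
    form_mode: str = "cm",
) -> TimeSeriesResult:
    """Noisy light datasets along a delay grid under per-locus kinetics.

    Loci activate independently; the crystal-average structure factors are
    the Bernoulli mixture over the 2^k locus-state combinations, each
    combination's factors computed from the correspondingly perturbed model.
    """
    names = list(scenario.loci)
    if set(names) != set(perturbations):
        raise ValueError("perturbations must cover exactly the scenario loci")
    moved: dict[str, set] = {}
    for name in names:
        spec = perturbations[name]
        atoms = {lb for ax, _ in spec.rotations for lb in ax.moving}
        atoms |= set(spec.displacements)
        if spec.disorder is not None:
            atoms |= {tuple(lb) for lb in spec.disorder.labels}
        moved[name] = atoms
    for i, a in enumerate(names):
        for bn in names[i + 1:]:
            if moved[a] & moved[bn]:
                raise ValueError(f"loci {a!r} and {bn!r} move overlapping atoms")

    rng = np.random.default_rng(scenario.seed)
    f_dark_set = calc_structure_factors(dark, d_min, form_mode=form_mode)
    hkl = f_dark_set.hkl
    # structure factors of every locus-state combination
    combos: list[tuple[tuple[str, ...], np.ndarray]] = []
    for bits in range(2 ** len(names)):
        active = tuple(n for i, n in enumerate(names) if bits >> i & 1)
        model = dark
        for n in active:
            model = apply_perturbation(model, perturbations[n])
        fs = (f_dark_set if not active else
              calc_structure_factors(model, d_min, hkl=hkl, form_mode=form_mode))
        combos.append((active, fs.complex_f()))

    alphas = {n: scenario.alpha_locus(n, scenario.delays) for n in names}
    dark_obs = _observe(f_dark_set.complex_f(), f_dark_set,
                        scenario.noise_frac, rng, "observed-dark")
    light_obs = []
    for ti in range(len(scenario.delays)):
        p = {n: alphas[n][ti] for n in names}
        f_mix = np.zeros(len(hkl), dtype=complex)
        for active, f in combos:
            wgt = 1.0
            for n in names:
                wgt *= p[n] if n in active else (1.0 - p[n])
            f_mix += wgt * f
        light_obs.append(_observe(f_mix, f_dark_set, scenario.noise_frac, rng,
                                  "observed-light"))
    return TimeSeriesResult(delays=scenario.delays, dark_obs=dark_obs,
                            light_obs=light_obs, alphas=alphas)


# --------------------------------------------------------------------------- #
# spectra series


def simulate_spectra_series(
    tau_s: float,
    delays,
    path_cm: float = 0.002,
    noise: float = 0.0,
    seed: int = 0,
    table: ExtinctionTable | None = None,
    conversion_max: float = 0.8,
    concentration_m: float = 0.02,
    path_factor_range: tuple[float, float] = (1.0, 1.0),
    scatter_b: float = 2.0e9,
) -> list[tuple[float, Spectrum, Spectrum]]:
    """Per-delay (transient, dark) crystal spectrum pairs under first-order kinetics.

    The dark spectrum is an oxidized-flavin Gaussian band plus Rayleigh
    scattering b/lambda^4; the transient converts a first-order-growing
    fraction into a semiquinone-like band centered at 600 nm.  Band peak
    absorbances honour the extinction table at 450/635 nm.  Each delay uses a
    fresh crystal: a random path-length factor scales both spectra of a pair.
    """
    table = table or ExtinctionTable()
    rng = np.random.default_rng(seed)
    wl = np.arange(350.0, 801.0, 1.0)

    def gauss(center, width):
        return np.exp(-0.5 * ((wl - center) / width) ** 2)

    # species shapes (per M per cm) tied to the tabulated coefficients
    shape_ox = table.eps_ox[0] * gauss(450.0, 28.0)
    sq_main = gauss(600.0, 30.0)
    sq_main *= table.eps_sq[1] / np.exp(-0.5 * ((635.0 - 600.0) / 30.0) ** 2)
    shape_sq = table.eps_sq[0] * gauss(450.0, 28.0) + sq_main
    scatter = scatter_b * wl**-4.0

    out = []
    a_ref = float((concentration_m * path_cm * shape_ox).max())
    for t in np.asarray(delays, dtype=float):
        pf = rng.uniform(*path_factor_range)
        frac = conversion_max * float(eval_first_order(t, 1.0, tau_s))
        dark_a = pf * (concentration_m * path_cm * shape_ox + scatter)
        trans_a = pf * (concentration_m * path_cm
                        * ((1.0 - frac) * shape_ox + frac * shape_sq) + scatter)
        if noise > 0:
            dark_a = dark_a + rng.normal(0.0, noise * a_ref * pf, size=wl.shape)
            trans_a = trans_a + rng.normal(0.0, noise * a_ref * pf, size=wl.shape)
        out.append((float(t),
                    Spectrum(wl, trans_a, {"delay_s": float(t), "path_factor": pf}),
                    Spectrum(wl, dark_a, {"delay_s": float(t), "path_factor": pf})))
    return out
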