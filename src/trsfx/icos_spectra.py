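"""In crystallo UV/Vis spectral pipeline.

Savitzky-Golay smoothing, Rayleigh-scattering correction, band integration,
path-length normalization, correlation maps between difference spectra, and
two-wavelength Lambert-Beer deconvolution of flavin redox states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .ded_analysis import feature_correlation_map
from .kinetics import TimeTrace

__all__ = [
    "Spectrum",
    "ExtinctionTable",
    "FLAVIN_EXTINCTIONS",
    "smooth_sg",
    "subtract_scattering",
    "integrate_band",
    "build_difference_trace",
    "spectra_correlation_map",
    "lambert_beer_deconvolve",
]

# FADox / neutral-semiquinone molar extinction coefficients (M^-1 cm^-1)
# at the two analysis wavelengths.
FLAVIN_EXTINCTIONS = {
    "FAD_ox": {450.0: 11204.0, 635.0: 0.0},
    "FADH_sq": {450.0: 3833.0, 635.0: 4958.0},
}

FADH_SQ_BAND = (580.0, 640.0)
FAD_OX_BAND = (456.0, 490.0)


@dataclass
class Spectrum:
    """Absorbance (AU) over a strictly increasing wavelength grid (nm)."""

    wavelengths: np.ndarray
    absorbance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if len(self.wavelengths) != len(self.absorbance):
            raise ValueError("wavelength/absorbance length mismatch")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    def __len__(self) -> int:
        return len(self.wavelengths)

    def with_values(self, values: np.ndarray, **meta) -> "Spectrum":
        return Spectrum(self.wavelengths, np.asarray(values, float),
                        {**self.meta, **meta})


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction coefficients for two species at two wavelengths."""

    lambda_ox: float = 450.0
    lambda_sq: float = 635.0
    eps_ox: tuple[float, float] = (11204.0, 0.0)     # (at lambda_ox, at lambda_sq)
    eps_sq: tuple[float, float] = (3833.0, 4958.0)

    def matrix(self) -> np.ndarray:
        m = np.array([[self.eps_ox[0], self.eps_sq[0]],
                      [self.eps_ox[1], self.eps_sq[1]]])
        if np.any(m < 0):
            raise ValueError("extinction coefficients must be >= 0")
        return m


def smooth_sg(spec: Spectrum, window: int = 21, order: int = 3) -> Spectrum:
    """Savitzky-Golay smoothing; the window shrinks symmetrically near edges.

    Interior points use the standard filter; within half a window of either
    edge a symmetric window of reduced length (same polynomial order, minimum
    order+1 points) is fitted locally, avoiding padding artifacts.
    """
    if window % 2 == 0 or window <= order:
        raise ValueError("window must be odd and greater than the polynomial order")
    n = len(spec)
    if n < window:
        raise ValueError(f"spectrum has {n} points; needs >= window ({window})")
    wl, a = spec.wavelengths, spec.absorbance
    steps = np.diff(wl)
    uniform = np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9)
    out = np.empty(n)
    half = window // 2
    if uniform:
        out[:] = savgol_filter(a, window, order)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        if uniform and h == half:
            continue
        h = max(h, (order + 1) // 2)
        lo, hi = max(0, i - h), min(n, i + h + 1)
        k = min(order, hi - lo - 1)
        coef = np.polyfit(wl[lo:hi] - wl[i], a[lo:hi], k)
        out[i] = coef[-1]
    return spec.with_values(out, smoothed=f"sg({window},{order})")


def subtract_scattering(dark: Spectrum,
                        fit_window: tuple[float, float] = (700.0, 800.0)
                        ) -> tuple[Spectrum, float, float]:
    """Fit b/lambda^4 + c over an absorption-free window; subtract b/lambda^4.

    Returns (corrected spectrum, b, c).
    """
    wl = dark.wavelengths
    lo, hi = fit_window
    sel = (wl >= lo) & (wl <= hi)
    if sel.sum() < 2:
        raise ValueError(f"fit window {fit_window} outside the wavelength grid")
    x = wl[sel] ** -4.0
    coef = np.polyfit(x, dark.absorbance[sel], 1)
    b, c = float(coef[0]), float(coef[1])
    corrected = dark.absorbance - b * wl**-4.0
    return dark.with_values(corrected, scatter_b=b, scatter_c=c), b, c


def integrate_band(spec: Spectrum, lo: float, hi: float) -> float:
    """Trapezoidal absorbance integral over [lo, hi] nm (AU*nm)."""
    if hi <= lo:
        raise ValueError("band upper edge must exceed lower edge")
    wl, a = spec.wavelengths, spec.absorbance
    if lo < wl[0] or hi > wl[-1]:
        raise ValueError(f"band [{lo}, {hi}] outside grid [{wl[0]}, {wl[-1]}]")
    # include exact band edges by interpolation
    grid = np.unique(np.concatenate([[lo, hi], wl[(wl > lo) & (wl < hi)]]))
    vals = np.interp(grid, wl, a)
    return float(np.trapezoid(vals, grid))


def build_difference_trace(
    series,
    band: tuple[float, float] = FADH_SQ_BAND,
    norm_band: tuple[float, float] = FAD_OX_BAND,
    window: int = 21,
    order: int = 3,
    scatter_window: tuple[float, float] = (700.0, 800.0),
    standardize: bool = True,
    label: str = "",
) -> TimeTrace:
    """Species-band time trace from (delay, transient, dark) spectrum triples.

    Per delay: difference = transient - dark, Savitzky-Golay smoothed; its
    band integral is normalized by the scattering-corrected dark integral of
    the reference band (cancelling optical path length).  Repeated delays are
    averaged and the trace is finally standardized to a maximum of 1.
    """
    delays, values = [], []
    for delay, transient, dark in series:
        if not np.array_equal(transient.wavelengths, dark.wavelengths):
            raise ValueError("transient and dark must share one wavelength grid")
        diff = transient.with_values(transient.absorbance - dark.absorbance)
        diff = smooth_sg(diff, window=window, order=order)
        signal = integrate_band(diff, *band)
        corrected, _, _ = subtract_scattering(dark, scatter_window)
        norm = integrate_band(corrected, *norm_band)
        if norm <= 0:
            raise ValueError(
                f"non-positive dark normalizer ({norm:.3g}) at delay {delay}")
        delays.append(float(delay))
        values.append(signal / norm)
    order_idx = np.argsort(delays, kind="stable")
    trace = TimeTrace(np.asarray(delays)[order_idx],
                      np.asarray(values)[order_idx], label=label).averaged()
    if standardize:
        peak = np.abs(trace.values).max()
        if peak > 0:
            trace = TimeTrace(trace.times, trace.values / peak, label=label)
    return trace


def spectra_correlation_map(diff_spectra, window: int = 21, order: int = 3,
                            smooth: bool = True) -> np.ndarray:
    """Pairwise Pearson correlation between (smoothed) difference spectra."""
    vecs = []
    for s in diff_spectra:
        s2 = smooth_sg(s, window=window, order=order) if smooth else s
        vecs.append(s2.absorbance)
    return feature_correlation_map(vecs)


def lambert_beer_deconvolve(
    a_ox_wl: float,
    a_sq_wl: float,
    path_cm: float,
    table: ExtinctionTable | None = None,
) -> tuple[float, float]:
    """Two-state concentrations (M) from absorbances at the two table wavelengths.

    Solves A_lambda = path * (eps_ox(lambda) c_ox + eps_sq(lambda) c_sq);
    negative solutions are returned as-is (caller may flag them).
    """
    if path_cm <= 0:
        raise ValueError("path length must be positive")
    table = table or ExtinctionTable()
    m = table.matrix()
    if abs(np.linalg.det(m)) < 1e-12:
        raise ValueError("extinction table is singular at this wavelength pair")
    c = np.linalg.solve(path_cm * m, np.array([a_ox_wl, a_sq_wl], dtype=float))
    return float(c[0]), float(c[1])
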