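"""Plate-reader spectrum processing for stability readouts.

Turns raw UV-Vis absorbance and intrinsic-fluorescence spectra into the
scalar responses the kinetics pipeline consumes:

* turbidity — apparent absorbance at 350 nm, a light-scattering proxy for
  aggregate content (read from the *uncorrected* spectrum, since the
  scattering signal is exactly what turbidity quantifies);
* scatter-corrected absorbance — a power-law baseline s(λ) = a + b·λ^c is
  fitted to the protein-free window (350–500 nm), extrapolated over the
  full 250–500 nm range and subtracted;
* fluorescence AUC — trapezoidal area of the emission spectrum over
  300–450 nm (excitation 280 nm), which falls as tryptophan environments
  change on unfolding/aggregation;
* barycentric mean (BCM) — the intensity-weighted centroid wavelength
  Σλ_i·I_i / ΣI_i over 300–450 nm, a noise-robust measure of the red-shift
  that accompanies solvent exposure of buried tryptophans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

ABS_WINDOW = (350.0, 500.0)
EMISSION_RANGE = (300.0, 450.0)
TURBIDITY_WL = 350.0

_SCALE_WL = 400.0  # internal wavelength scaling for a well-conditioned fit


class SpectrumError(ValueError):
    """Invalid spectrum input or failed baseline fit."""


@dataclass(frozen=True)
class Spectrum:
    """Wavelength–intensity series with sample metadata."""

    wavelengths: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", it)
        if wl.shape != it.shape or wl.ndim != 1:
            raise SpectrumError("wavelengths and intensities must be equal-length 1-D")
        if wl.size and np.any(np.diff(wl) <= 0):
            raise SpectrumError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(it)):
            raise SpectrumError("intensities must be finite")


@dataclass(frozen=True)
class ScatterBaseline:
    """Power-law scattering background s(λ) = a + b·λ^c (λ in nm)."""

    a: float
    b: float
    c: float

    def evaluate(self, wavelengths) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        return self.a + self.b * np.power(wl, self.c)


def fit_scatter_baseline(spec: Spectrum, window: tuple[float, float] = ABS_WINDOW) -> ScatterBaseline:
    """Least-squares fit of the power-law background over ``window``.

    Fitted internally as a + b'·(λ/400)^c so b' lives on the intensity
    scale; the Rayleigh exponent c = −4 is the deterministic starting point
    and c is unconstrained in sign.  Needs ≥ 5 points in the window.
    """
    lo, hi = window
    mask = (spec.wavelengths >= lo) & (spec.wavelengths <= hi)
    if not np.any(mask):
        raise SpectrumError(f"no spectrum points inside window {window}")
    if mask.sum() < 5:
        raise SpectrumError(f"need >= 5 points inside window {window}, got {mask.sum()}")
    wl = spec.wavelengths[mask] / _SCALE_WL
    y = spec.intensities[mask]

    def resid(theta):
        a, b_s, c = theta
        return a + b_s * np.power(wl, c) - y

    a0 = float(np.min(y))
    b0 = max(float(np.mean(y) - a0), 1e-12)
    res = least_squares(
        resid,
        x0=(a0, b0, -4.0),
        bounds=((-np.inf, 0.0, -12.0), (np.inf, np.inf, 12.0)),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
    )
    if res.status <= 0 or not np.all(np.isfinite(res.x)):
        raise SpectrumError("scatter-baseline fit did not converge")
    a, b_s, c = res.x
    return ScatterBaseline(a=float(a), b=float(b_s / _SCALE_WL**c), c=float(c))


def correct_scattering(spec: Spectrum, baseline: ScatterBaseline) -> Spectrum:
    """Subtract the (extrapolated) scattering baseline at every wavelength."""
    return Spectrum(
        wavelengths=spec.wavelengths,
        intensities=spec.intensities - baseline.evaluate(spec.wavelengths),
        meta=dict(spec.meta),
    )


def turbidity_at(spec: Spectrum, wavelength: float = TURBIDITY_WL) -> float:
    """Uncorrected absorbance at ``wavelength``, linearly interpolated."""
    wl = spec.wavelengths
    if not wl.size or wavelength < wl[0] or wavelength > wl[-1]:
        raise SpectrumError(
            f"wavelength {wavelength} nm outside spectrum range [{wl[0]}, {wl[-1]}]"
        )
    return float(np.interp(wavelength, wl, spec.intensities))


def _in_range_with_edges(spec: Spectrum, rng: tuple[float, float]):
    """In-range grid plus interpolated endpoint values for exact integrals."""
    lo, hi = rng
    wl, it = spec.wavelengths, spec.intensities
    lo = max(lo, wl[0])
    hi = min(hi, wl[-1])
    if hi <= lo:
        raise SpectrumError(f"integration range {rng} outside spectrum")
    inner = (wl > lo) & (wl < hi)
    grid = np.concatenate([[lo], wl[inner], [hi]])
    vals = np.concatenate([[np.interp(lo, wl, it)], it[inner], [np.interp(hi, wl, it)]])
    return grid, vals


def spectrum_auc(spec: Spectrum, rng: tuple[float, float] = EMISSION_RANGE) -> float:
    """Trapezoidal integral of intensity over ``rng`` (units·nm)."""
    grid, vals = _in_range_with_edges(spec, rng)
    if grid.size < 2:
        raise SpectrumError("need >= 2 points in integration range")
    return float(np.trapezoid(vals, grid))


def barycentric_mean(spec: Spectrum, rng: tuple[float, float] = EMISSION_RANGE) -> float:
    """Intensity-weighted centroid wavelength over ``rng`` (nm).

    Small negative noise excursions are tolerated; a non-positive total
    intensity makes the centroid undefined and raises.
    """
    lo, hi = rng
    mask = (spec.wavelengths >= lo) & (spec.wavelengths <= hi)
    if not np.any(mask):
        raise SpectrumError(f"no spectrum points inside range {rng}")
    wl = spec.wavelengths[mask]
    it = spec.intensities[mask]
    total = it.sum()
    if total <= 0:
        raise SpectrumError("undefined centroid: non-positive total intensity")
    return float(np.dot(wl, it) / total)
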