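"""Cumulant analysis of dynamic light scattering correlograms.

The intensity autocorrelation of a dilute particle suspension decays as
g₂(τ) − 1 = β·exp(−2Γτ) for monodisperse particles, where Γ = D·q² is the
mean decay rate, D the translational diffusion coefficient and q the
scattering vector.  Polydispersity is captured by the second-order cumulant
expansion in the squared (Frisken) form

    g₂(τ) = 1 + β · exp(−2Γτ) · (1 + (μ₂/2)·τ²)²,

with polydispersity index PDI = μ₂/Γ².  The mean hydrodynamic radius then
follows from Stokes–Einstein:

    q = (4π·n_ri/λ)·sin(θ/2),   D = Γ/q²,   R_h = k_B·T/(6π·η·D).

Instrument defaults (θ = 158°, λ = 830 nm, n_ri = 1.33, η = 0.89 mPa·s at
298.15 K) are typical of plate-reader DLS and live in
:class:`DLSInstrument`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

BOLTZMANN = 1.380649e-23  # J/K


class DLSError(ValueError):
    """Invalid correlogram, missing instrument metadata, or failed fit."""


@dataclass(frozen=True)
class DLSInstrument:
    """Optics and solvent constants needed to convert Γ to a radius."""

    temperature_k: float = 298.15
    angle_deg: float = 158.0
    wavelength_nm: float = 830.0
    refractive_index: float = 1.33
    viscosity_pa_s: float = 0.89e-3

    def scattering_vector(self) -> float:
        """q in 1/m."""
        for name in ("temperature_k", "angle_deg", "wavelength_nm", "refractive_index", "viscosity_pa_s"):
            v = getattr(self, name)
            if v is None or v <= 0:
                raise DLSError(f"instrument metadata {name} must be positive, got {v}")
        lam = self.wavelength_nm * 1e-9
        return 4.0 * math.pi * self.refractive_index / lam * math.sin(math.radians(self.angle_deg) / 2.0)


@dataclass(frozen=True)
class Correlogram:
    """Intercept-normalized autocorrelation g₂(τ) with instrument metadata."""

    lags: np.ndarray
    g2: np.ndarray
    meta: DLSInstrument = field(default_factory=DLSInstrument)

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        g2 = np.asarray(self.g2, dtype=float)
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "g2", g2)
        if lags.shape != g2.shape or lags.ndim != 1:
            raise DLSError("lags and g2 must be equal-length 1-D arrays")
        if np.any(lags <= 0) or np.any(np.diff(lags) <= 0):
            raise DLSError("lags must be positive and strictly increasing")
        if np.any(g2 - 1.0 < -0.2):
            raise DLSError("g2 must not fall far below its long-lag limit of 1")


@dataclass(frozen=True)
class CumulantFit:
    """Result of a cumulant fit: intercept β, decay rate Γ (1/s), second
    cumulant μ₂ (1/s²) and PDI = μ₂/Γ²."""

    beta: float
    gamma: float
    mu2: float
    pdi: float
    residual_rms: float


def cumulant_fit(corr: Correlogram, order: int = 2) -> CumulantFit:
    """Least-squares cumulant fit of a correlogram.

    ``order=2`` fits the Frisken form above; ``order=1`` drops the μ₂ term
    (monodisperse model).  Needs ≥ 10 lag points spanning the decay.
    Raises :class:`DLSError` on non-convergence or non-positive Γ.
    """
    if order not in (1, 2):
        raise DLSError("cumulant order must be 1 or 2")
    tau = corr.lags
    y = corr.g2
    if tau.size < 10:
        raise DLSError(f"need >= 10 lag points, got {tau.size}")

    beta0 = max(float(y[0] - 1.0), 1e-3)
    # log-linear slope over the early decay gives the Γ start
    decay = y - 1.0
    sel = decay > 0.2 * beta0
    if sel.sum() >= 2:
        slope = np.polyfit(tau[sel], np.log(decay[sel]), 1)[0]
        gamma0 = max(-slope / 2.0, 1.0 / tau[-1])
    else:
        gamma0 = 1.0 / float(np.median(tau))

    def model(theta):
        beta, ln_gamma, mu2 = theta
        gamma = np.exp(ln_gamma)
        poly = 1.0 + 0.5 * mu2 * tau**2 if order == 2 else 1.0
        return 1.0 + beta * np.exp(-2.0 * gamma * tau) * poly**2

    def resid(theta):
        return model(theta) - y

    theta0 = np.array([beta0, math.log(gamma0), 0.0])
    lower = [1e-6, math.log(gamma0) - 20.0, -np.inf]
    upper = [2.0, math.log(gamma0) + 20.0, np.inf]
    if order == 1:
        lower[2], upper[2], theta0[2] = -1e-30, 1e-30, 0.0
    res = least_squares(resid, theta0, bounds=(lower, upper), method="trf", xtol=1e-14, ftol=1e-14)
    if res.status <= 0 or not np.all(np.isfinite(res.x)):
        raise DLSError("cumulant fit did not converge")
    beta, ln_gamma, mu2 = res.x
    gamma = float(np.exp(ln_gamma))
    if gamma <= 0:
        raise DLSError("fitted decay rate must be positive")
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return CumulantFit(
        beta=float(beta),
        gamma=gamma,
        mu2=float(mu2),
        pdi=float(mu2) / gamma**2,
        residual_rms=rms,
    )


def hydrodynamic_radius(gamma: float, meta: DLSInstrument) -> float:
    """Mean hydrodynamic radius (nm) from a decay rate via Stokes–Einstein."""
    if gamma <= 0:
        raise DLSError("decay rate must be positive")
    q = meta.scattering_vector()
    diffusion = gamma / q**2
    radius_m = BOLTZMANN * meta.temperature_k / (6.0 * math.pi * meta.viscosity_pa_s * diffusion)
    return radius_m * 1e9


def decay_rate_from_radius(radius_nm: float, meta: DLSInstrument) -> float:
    """Inverse of :func:`hydrodynamic_radius`: Γ (1/s) for a given R_h."""
    if radius_nm <= 0:
        raise DLSError("radius must be positive")
    q = meta.scattering_vector()
    diffusion = BOLTZMANN * meta.temperature_k / (
        6.0 * math.pi * meta.viscosity_pa_s * radius_nm * 1e-9
    )
    return diffusion * q**2
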