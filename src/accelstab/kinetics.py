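"""Forward kinetic models for thermal degradation of biologics.

The rate law is the truncated Šesták–Berggren equation,

    dα/dt = k(T) · (1−α)^n · α^m,      k(T) = A · exp(−Ea / (R·T)),

where α is the dimensionless reaction progress (0 = intact, 1 = fully
reacted), n is the reaction order and m the autocatalytic order.  Special
cases: n=0 gives linear kinetics, n=1/m=0 first-order decay, and n=1/m=1
the Prout–Tompkins equation with its logistic (S-shaped) solution that is
classic for nucleation and aggregation.

A model may consist of one or two parallel sub-reactions, each with its own
Arrhenius parameters and orders; for two-step models the first step is
constrained to be non-autocatalytic (m₁ = 0).  Each sub-reaction carries its
own progress variable α_i, and the observable response is the affine map

    y(t) = y0 + Σ_i dY_i · α_i(t),

so the same machinery fits decreasing responses (purity, acetate content)
and increasing ones (hydrodynamic radius, turbidity) by the sign of dY_i.

Because α=0 is a fixed point of the rate law when m>0, autocatalytic steps
are seeded with a small initial conversion α₀ (default 1e−6), standard
Prout–Tompkins practice.  Steps with m=0 always start at α=0; their
trajectory does not depend on α₀.

Temperature programs are piecewise-constant (isothermal segments), which
covers both constant-temperature storage and temperature-cycling studies.
Integration uses exact closed forms where they exist (any n with m=0;
n=1,m=1) and an adaptive stiff-capable ODE solver otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

GAS_CONSTANT = 8.314
"""Universal gas constant R, J/(mol·K)."""

T_REF = 298.15
"""Reference temperature (K) used for the ln k_ref fitting parameterization."""

#: Default seed conversion for autocatalytic steps (dimensionless).
DEFAULT_ALPHA0 = 1e-6

_ALPHA_CAP = 1.0 - 1e-12


class KineticsError(ValueError):
    """Invalid kinetic input (domain violation, malformed model)."""


class IntegrationError(RuntimeError):
    """The ODE solver failed to integrate a step/segment."""


def celsius_to_kelvin(temp_c: float) -> float:
    """Convert °C to K (K = °C + 273.15)."""
    return float(temp_c) + 273.15


@dataclass(frozen=True)
class KineticModelSpec:
    """Structure of a kinetic model: number of steps and their orders.

    Parameters
    ----------
    orders
        One ``(n_i, m_i)`` pair per sub-reaction; 1 or 2 steps.  For
        two-step models the first step must have m₁ = 0.
    """

    orders: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        orders = tuple((float(n), float(m)) for n, m in self.orders)
        object.__setattr__(self, "orders", orders)
        if len(orders) not in (1, 2):
            raise KineticsError(f"model must have 1 or 2 steps, got {len(orders)}")
        for n, m in orders:
            if n < 0 or m < 0:
                raise KineticsError(f"orders must be non-negative, got n={n}, m={m}")
        if len(orders) == 2 and orders[0][1] != 0.0:
            raise KineticsError("two-step models require m1 = 0 for the first step")

    @property
    def n_steps(self) -> int:
        return len(self.orders)

    @property
    def spec_id(self) -> str:
        """Compact identifier, e.g. ``'n1m0'`` or ``'n1m0+n1m1'``."""

        def fmt(x: float) -> str:
            return f"{x:g}"

        return "+".join(f"n{fmt(n)}m{fmt(m)}" for n, m in self.orders)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.spec_id


@dataclass(frozen=True)
class KineticParameters:
    """Parameter values for a :class:`KineticModelSpec`.

    Per step: pre-exponential factor ``A`` (1/month), activation energy
    ``Ea`` (J/mol) and seed conversion ``alpha0``.  Per model: observable
    baseline ``y0`` and signed step amplitudes ``dY`` (assay units).
    """

    A: tuple[float, ...]
    Ea: tuple[float, ...]
    y0: float
    dY: tuple[float, ...]
    alpha0: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        A = tuple(float(a) for a in self.A)
        Ea = tuple(float(e) for e in self.Ea)
        dY = tuple(float(d) for d in self.dY)
        alpha0 = tuple(float(a) for a in self.alpha0)
        if not alpha0:
            alpha0 = (DEFAULT_ALPHA0,) * len(A)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "Ea", Ea)
        object.__setattr__(self, "dY", dY)
        object.__setattr__(self, "alpha0", alpha0)
        if not (len(A) == len(Ea) == len(dY) == len(alpha0)):
            raise KineticsError("per-step parameter tuples must share length")
        for a in A:
            if a <= 0:
                raise KineticsError("pre-exponential factors must be > 0")
        for e in Ea:
            if e < 0:
                raise KineticsError("activation energies must be >= 0")
        for a0 in alpha0:
            if not 0 < a0 < 1:
                raise KineticsError("seed conversions must lie in (0, 1)")

    @property
    def n_steps(self) -> int:
        return len(self.A)

    def k(self, step: int, temperature_k: float) -> float:
        """Arrhenius rate constant of ``step`` at ``temperature_k`` (1/month)."""
        return rate_constant(self.A[step], self.Ea[step], temperature_k)


@dataclass(frozen=True)
class TemperatureProfile:
    """Piecewise-constant temperature program.

    ``segments`` is an ordered tuple of ``(duration_months, temperature_K)``.
    """

    segments: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        segments = tuple((float(d), float(t)) for d, t in self.segments)
        object.__setattr__(self, "segments", segments)
        if not segments:
            raise KineticsError("profile needs at least one segment")
        for d, t in segments:
            if d <= 0:
                raise KineticsError("segment durations must be > 0")
            if t <= 0:
                raise KineticsError("temperatures must be > 0 K")

    @classmethod
    def isothermal(
        cls,
        temp_c: float | None = None,
        *,
        temp_k: float | None = None,
        duration_months: float = 36.0,
    ) -> "TemperatureProfile":
        """Single constant-temperature segment; give `temp_c` or `temp_k`."""
        if (temp_c is None) == (temp_k is None):
            raise KineticsError("give exactly one of temp_c or temp_k")
        t = celsius_to_kelvin(temp_c) if temp_c is not None else float(temp_k)
        return cls(((duration_months, t),))

    @classmethod
    def cycling(
        cls,
        low_c: float,
        high_c: float,
        half_period_months: float,
        n_cycles: int,
    ) -> "TemperatureProfile":
        """Alternating low/high program, e.g. 8↔25 °C excursion studies."""
        lo, hi = celsius_to_kelvin(low_c), celsius_to_kelvin(high_c)
        segs: list[tuple[float, float]] = []
        for _ in range(int(n_cycles)):
            segs.append((half_period_months, lo))
            segs.append((half_period_months, hi))
        return cls(tuple(segs))

    @classmethod
    def from_config(cls, entries: Sequence[dict], default_duration: float = 36.0) -> "TemperatureProfile":
        """Build from config entries ``{duration_months, temp_C}``.

        The isothermal shorthand ``{temp_C}`` uses ``default_duration``.
        """
        segs = []
        for e in entries:
            if "temp_C" not in e:
                raise KineticsError(f"profile entry missing temp_C: {e!r}")
            dur = float(e.get("duration_months", default_duration))
            segs.append((dur, celsius_to_kelvin(e["temp_C"])))
        return cls(tuple(segs))

    @property
    def total_duration(self) -> float:
        return sum(d for d, _ in self.segments)

    def boundaries(self) -> np.ndarray:
        """Cumulative segment end times, starting at 0."""
        return np.concatenate([[0.0], np.cumsum([d for d, _ in self.segments])])


@dataclass(frozen=True)
class ConversionTrajectory:
    """Per-step conversion α_i(t) on a common time grid.

    ``alpha`` has shape ``(n_steps, len(times))``; every row is clipped to
    [0, 1] and non-decreasing.
    """

    times: np.ndarray
    alpha: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        alpha = np.atleast_2d(np.asarray(self.alpha, dtype=float))
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "alpha", alpha)
        if alpha.shape[1] != times.size:
            raise KineticsError("alpha/time shape mismatch")

    @property
    def n_steps(self) -> int:
        return self.alpha.shape[0]


def rate_constant(A: float, Ea: float, temperature_k: float) -> float:
    """Arrhenius rate constant k = A·exp(−Ea/(R·T)).

    Parameters are the pre-exponential factor ``A`` (1/month), activation
    energy ``Ea`` (J/mol) and absolute temperature (K).  Returns k in
    1/month; k ∈ (0, A] since Ea ≥ 0.
    """
    if A <= 0:
        raise KineticsError(f"pre-exponential factor must be > 0, got {A}")
    if Ea < 0:
        raise KineticsError(f"activation energy must be >= 0, got {Ea}")
    if temperature_k <= 0:
        raise KineticsError(f"temperature must be > 0 K, got {temperature_k}")
    return float(A) * math.exp(-float(Ea) / (GAS_CONSTANT * float(temperature_k)))


def reaction_rate(alpha, k: float, n: float, m: float):
    """Instantaneous rate dα/dt = k·(1−α)^n·α^m.

    Vectorized over ``alpha``; raises on α outside [0, 1].  The conventions
    0^0 = 1 apply, so the rate vanishes at α=1 only when n>0 and at α=0 only
    when m>0.
    """
    a = np.asarray(alpha, dtype=float)
    if np.any(a < 0) or np.any(a > 1):
        raise KineticsError("conversion alpha must lie in [0, 1]")
    out = k * np.power(1.0 - a, n) * np.power(a, m)
    if np.isscalar(alpha) or np.ndim(alpha) == 0:
        return float(out)
    return out


def _alpha_closed_form(n: float, m: float, a0: float, tau: np.ndarray) -> np.ndarray | None:
    """Exact isothermal solution in scaled time τ = k·t, or None.

    Closed forms exist for all m=0 models and for the Prout–Tompkins case
    n=1, m=1.
    """
    tau = np.asarray(tau, dtype=float)
    if m == 0.0:
        if n == 0.0:
            return np.clip(a0 + tau, 0.0, 1.0)
        if n == 1.0:
            return 1.0 - (1.0 - a0) * np.exp(-tau)
        # general order: (1-α)^(1-n) evolves linearly in τ
        u = (1.0 - a0) ** (1.0 - n) - (1.0 - n) * tau
        if n < 1.0:
            # completes in finite time where u crosses 0
            out = np.where(u > 0.0, 1.0 - np.maximum(u, 0.0) ** (1.0 / (1.0 - n)), 1.0)
        else:
            out = 1.0 - u ** (1.0 / (1.0 - n))
        return np.clip(out, 0.0, 1.0)
    if n == 1.0 and m == 1.0:
        if a0 <= 0.0:
            return np.zeros_like(tau)
        # logistic solution, written to avoid overflow at large τ
        r = (1.0 - a0) / a0
        return 1.0 / (1.0 + r * np.exp(-tau))
    return None


def _alpha_numeric_multi(
    n: float, m: float, a0: float, tau_arrays: list[np.ndarray]
) -> list[np.ndarray]:
    """Adaptive ODE solution of dα/dτ = (1−α)^n α^m, shared across arrays.

    One dense solve over the pooled τ range serves every requested grid
    (different temperatures reuse the same scaled-time solution).
    """
    if a0 <= 0.0 and m > 0.0:
        return [np.zeros_like(np.asarray(t, float)) for t in tau_arrays]
    tau_max = max((float(np.max(t)) if np.size(t) else 0.0) for t in tau_arrays)
    if tau_max <= 0.0:
        return [np.full(np.shape(t), a0) for t in tau_arrays]

    def rhs(_t, y):
        a = min(max(y[0], 0.0), 1.0)
        return ((1.0 - a) ** n * a**m,)

    def done(_t, y):
        return y[0] - _ALPHA_CAP

    done.terminal = True
    done.direction = 1.0

    sol = solve_ivp(
        rhs,
        (0.0, tau_max),
        (a0,),
        method="LSODA",
        rtol=1e-8,
        # absolute tolerance must sit well below the smallest seed conversion
        # so relative accuracy holds through the lag phase
        atol=min(1e-12, 1e-8 * a0) if a0 > 0 else 1e-12,
        dense_output=True,
        events=done,
    )
    if not sol.success:
        raise IntegrationError(
            f"ODE integration failed for step (n={n}, m={m}): {sol.message}"
        )
    t_end = sol.t[-1]
    out = []
    for tau in tau_arrays:
        tau = np.asarray(tau, dtype=float)
        inside = np.minimum(tau, t_end)
        a = sol.sol(inside)[0]
        # past the α≈1 stopping event the solution is pinned at 1
        a = np.where(tau > t_end, 1.0, a)
        out.append(np.clip(a, 0.0, 1.0))
    return out


def isothermal_alpha_multi(
    n: float,
    m: float,
    a0: float,
    tau_arrays: list[np.ndarray],
    method: str = "auto",
) -> list[np.ndarray]:
    """Isothermal step conversion at scaled times τ = k·t, batched.

    ``method='auto'`` uses the closed form when one exists, ``'numeric'``
    forces the ODE solver (useful for cross-checking the two routes).
    """
    if method not in ("auto", "numeric"):
        raise KineticsError(f"unknown integration method {method!r}")
    if method == "auto":
        closed = _alpha_closed_form(n, m, a0, np.asarray([0.0]))
        if closed is not None:
            return [
                _alpha_closed_form(n, m, a0, np.asarray(t, dtype=float))
                for t in tau_arrays
            ]
    return _alpha_numeric_multi(n, m, a0, tau_arrays)


def isothermal_alpha(
    n: float, m: float, a0: float, tau, method: str = "auto"
) -> np.ndarray:
    """Single-grid convenience wrapper around :func:`isothermal_alpha_multi`."""
    return isothermal_alpha_multi(n, m, a0, [np.asarray(tau, dtype=float)], method)[0]


def integrate_conversion(
    spec: KineticModelSpec,
    params: KineticParameters,
    profile: TemperatureProfile,
    times,
    method: str = "auto",
) -> ConversionTrajectory:
    """Integrate every sub-reaction along a piecewise-constant profile.

    Within each segment the rate constant is held fixed at the segment
    temperature and the step is advanced from its carried-over conversion;
    requested ``times`` must be sorted, non-negative and within the profile
    duration.
    """
    times = np.asarray(times, dtype=float)
    if times.size and (np.any(np.diff(times) < 0) or times[0] < 0):
        raise KineticsError("times must be sorted and non-negative")
    bounds = profile.boundaries()
    if times.size and times[-1] > bounds[-1] + 1e-9:
        raise KineticsError(
            f"requested time {times[-1]} exceeds profile duration {bounds[-1]}"
        )
    if spec.n_steps != params.n_steps:
        raise KineticsError("spec and parameters disagree on step count")

    alpha = np.empty((spec.n_steps, times.size))
    for i, (n, m) in enumerate(spec.orders):
        a_cur = params.alpha0[i] if m > 0 else 0.0
        assigned = np.zeros(times.size, dtype=bool)
        for seg_idx, (dur, temp_k) in enumerate(profile.segments):
            t0, t1 = bounds[seg_idx], bounds[seg_idx + 1]
            k = params.k(i, temp_k)
            sel = (~assigned) & (times <= t1 + 1e-9)
            try:
                if np.any(sel):
                    tau = k * np.clip(times[sel] - t0, 0.0, dur)
                    vals, (a_end,) = isothermal_alpha_multi(
                        n, m, a_cur, [tau, np.asarray([k * dur])], method
                    )
                    alpha[i, sel] = vals
                    assigned |= sel
                else:
                    (a_end,) = isothermal_alpha(
                        n, m, a_cur, np.asarray([k * dur]), method
                    )
            except IntegrationError as err:
                raise IntegrationError(
                    f"step {i + 1}, segment {seg_idx + 1}: {err}"
                ) from err
            a_cur = float(np.clip(a_end, 0.0, 1.0))
        # guard against solver-level wiggles
        alpha[i] = np.maximum.accumulate(np.clip(alpha[i], 0.0, 1.0))
    return ConversionTrajectory(times=times, alpha=alpha)


def conversion_to_signal(traj: ConversionTrajectory, params: KineticParameters) -> np.ndarray:
    """Map per-step conversions to the observable, y = y0 + Σ dY_i·α_i."""
    if traj.n_steps != params.n_steps:
        raise KineticsError("trajectory and parameters disagree on step count")
    return params.y0 + np.asarray(params.dY) @ traj.alpha


def predict_signal(
    spec: KineticModelSpec,
    params: KineticParameters,
    profile: TemperatureProfile,
    times,
    method: str = "auto",
) -> np.ndarray:
    """Forward model: integrate the kinetics and map to the observable."""
    return conversion_to_signal(
        integrate_conversion(spec, params, profile, times, method), params
    )


def total_conversion(
    spec: KineticModelSpec,
    params: KineticParameters,
    profile: TemperatureProfile,
    times,
    method: str = "auto",
) -> np.ndarray:
    """Amplitude-weighted mean conversion, normalized to [0, 1].

    Steps are weighted by |dY_i| (equal weights if all amplitudes are zero),
    so the result tracks the fraction of the total observable change.
    """
    traj = integrate_conversion(spec, params, profile, times, method)
    w = np.abs(np.asarray(params.dY))
    if not np.any(w > 0):
        w = np.ones(spec.n_steps)
    return (w @ traj.alpha) / w.sum()


def lag_time(
    spec: KineticModelSpec,
    params: KineticParameters,
    temperature_k: float,
    threshold: float,
    horizon_months: float = 120.0,
) -> float:
    """Earliest time at which total normalized conversion reaches `threshold`.

    Solved by bracketing plus Brent root finding on the integrated
    trajectory at the given constant temperature.  Returns ``inf`` when the
    threshold is not reached within ``horizon_months`` (beyond-horizon
    sentinel).  The autocatalytic order m controls this lag: larger m delays
    the onset of the accelerating phase.
    """
    if not 0 <= threshold < 1:
        raise KineticsError("threshold must lie in [0, 1)")
    if threshold == 0:
        return 0.0
    profile = TemperatureProfile(((horizon_months, float(temperature_k)),))

    def excess(t: float) -> float:
        return float(total_conversion(spec, params, profile, [t])[0]) - threshold

    if excess(horizon_months) < 0:
        return math.inf
    return float(brentq(excess, 0.0, horizon_months, xtol=1e-10, rtol=1e-12))
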