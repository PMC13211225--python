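"""Global non-linear least-squares fitting of kinetic models.

All temperatures are fitted simultaneously: each sub-reaction has a single
(A_i, Ea_i) pair shared across the whole dataset, so the temperature
dependence is constrained to be Arrhenius rather than fitted per-condition.

To avoid the notorious A–Ea correlation of the naive parameterization, the
optimizer works in (ln k_ref, Ea) where k_ref is the rate constant at
T_ref = 298.15 K; the pre-exponential factor is recovered as
A = k_ref·exp(Ea/(R·T_ref)).  Reaction orders are frozen at the values of
the candidate-model grid by default (``vary_orders`` releases them as
continuous parameters in [0, 3]).  Autocatalytic seed conversions default
to 1e−6 and can optionally be fitted on a log scale in [1e−9, 1e−2].

Optimization uses trust-region-reflective least squares with a fixed,
deterministic multi-start schedule over activation energies
{30, 60, 90, 120} kJ/mol plus a slow-rate variant; bootstrap refits instead
warm-start from the base estimate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from . import selection
from .dataset import StabilityDataset
from .kinetics import (
    GAS_CONSTANT,
    T_REF,
    IntegrationError,
    KineticModelSpec,
    KineticParameters,
    TemperatureProfile,
    isothermal_alpha_multi,
    predict_signal,
)

logger = logging.getLogger("accelstab.fitting")

DEFAULT_N_VALUES = (0.0, 0.5, 1.0, 2.0)
DEFAULT_M_VALUES = (0.0, 0.5, 1.0)


class FitError(RuntimeError):
    """Fitting could not produce a usable result."""


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings for :func:`fit_model`.

    ``n_starts`` multi-starts are drawn deterministically from
    ``ea_starts`` (J/mol) with data-scaled rate guesses; extra starts
    beyond the built-in schedule are seeded jitter.
    """

    n_starts: int = 5
    ea_starts: tuple[float, ...] = (30e3, 60e3, 90e3, 120e3)
    lnk_bounds: tuple[float, float] = (-30.0, 8.0)
    ea_bounds: tuple[float, float] = (0.0, 400e3)
    vary_orders: bool = False
    order_bounds: tuple[float, float] = (0.0, 3.0)
    fit_alpha0: bool = False
    alpha0: float = 1e-6
    alpha0_bounds: tuple[float, float] = (1e-9, 1e-2)
    integration: str = "auto"
    ftol: float = 1e-10
    xtol: float = 1e-10
    max_nfev: int = 1000
    seed: int = 0


@dataclass(frozen=True)
class FitResult:
    """A fitted kinetic model with its goodness-of-fit statistics.

    ``n_params`` counts the fitted model parameters (the error variance is
    added internally when computing AIC/BIC); ``rmse = sqrt(rss/n_points)``.
    """

    spec: KineticModelSpec
    params: KineticParameters
    rss: float
    rmse: float
    n_points: int
    n_params: int
    aic: float
    bic: float
    residuals: np.ndarray
    converged: bool
    bounds_hit: tuple[str, ...] = ()

    def predict(self, profile: TemperatureProfile, times, method: str = "auto") -> np.ndarray:
        """Forward-model prediction under an arbitrary temperature program."""
        return predict_signal(self.spec, self.params, profile, times, method)


def enumerate_model_grid(
    max_steps: int = 2,
    n_values: Sequence[float] = DEFAULT_N_VALUES,
    m_values: Sequence[float] = DEFAULT_M_VALUES,
) -> list[KineticModelSpec]:
    """All admissible candidate structures, deterministically ordered.

    One-step models come first (lexicographic in (n, m)), then two-step
    models with the first step forced non-autocatalytic (m₁ = 0).
    """
    if max_steps not in (1, 2):
        raise FitError("max_steps must be 1 or 2")
    n_values = sorted(set(float(v) for v in n_values))
    m_values = sorted(set(float(v) for v in m_values))
    if not n_values or not m_values:
        raise FitError("order value sets must be non-empty")
    if any(v < 0 for v in n_values + m_values):
        raise FitError("orders must be >= 0")
    grid = [KineticModelSpec(((n, m),)) for n in n_values for m in m_values]
    if max_steps == 2:
        for n1 in n_values:
            for n2 in n_values:
                for m2 in m_values:
                    grid.append(KineticModelSpec(((n1, 0.0), (n2, m2))))
    return grid


class _ParamLayout:
    """Maps between the optimizer vector and :class:`KineticParameters`."""

    def __init__(self, spec: KineticModelSpec, options: FitOptions):
        self.spec = spec
        self.options = options
        names: list[str] = []
        lo: list[float] = []
        hi: list[float] = []
        for i, (n, m) in enumerate(spec.orders):
            names.append(f"lnk{i + 1}")
            lo.append(options.lnk_bounds[0])
            hi.append(options.lnk_bounds[1])
            names.append(f"Ea{i + 1}")
            lo.append(options.ea_bounds[0])
            hi.append(options.ea_bounds[1])
            if options.fit_alpha0 and m > 0:
                names.append(f"ln_a0_{i + 1}")
                lo.append(math.log(options.alpha0_bounds[0]))
                hi.append(math.log(options.alpha0_bounds[1]))
            if options.vary_orders:
                names.append(f"n{i + 1}")
                lo.append(options.order_bounds[0])
                hi.append(options.order_bounds[1])
                names.append(f"m{i + 1}")
                # two-step models keep the first step non-autocatalytic
                m_hi = 0.0 if (spec.n_steps == 2 and i == 0) else options.order_bounds[1]
                lo.append(0.0)
                hi.append(m_hi)
        names.append("y0")
        lo.append(-np.inf)
        hi.append(np.inf)
        for i in range(spec.n_steps):
            names.append(f"dY{i + 1}")
            lo.append(-np.inf)
            hi.append(np.inf)
        self.names = names
        self.lower = np.array(lo)
        self.upper = np.array(hi)

    def unpack(self, theta: np.ndarray):
        """Return (orders, A, Ea, alpha0, y0, dY) from an optimizer vector."""
        pos = 0
        A, Ea, alpha0, orders = [], [], [], []
        for i, (n, m) in enumerate(self.spec.orders):
            lnk = theta[pos]; pos += 1
            ea = theta[pos]; pos += 1
            if self.options.fit_alpha0 and m > 0:
                alpha0.append(math.exp(theta[pos])); pos += 1
            else:
                alpha0.append(self.options.alpha0)
            if self.options.vary_orders:
                n = theta[pos]; pos += 1
                m = theta[pos]; pos += 1
            orders.append((float(n), float(m)))
            A.append(math.exp(lnk + ea / (GAS_CONSTANT * T_REF)))
            Ea.append(float(ea))
        y0 = theta[pos]; pos += 1
        dY = [float(v) for v in theta[pos:]]
        return orders, A, Ea, alpha0, float(y0), dY

    def to_params(self, theta: np.ndarray) -> KineticParameters:
        _, A, Ea, alpha0, y0, dY = self.unpack(theta)
        return KineticParameters(A=tuple(A), Ea=tuple(Ea), y0=y0, dY=tuple(dY), alpha0=tuple(alpha0))

    def pack(self, params: KineticParameters) -> np.ndarray:
        """Optimizer vector for a known parameter set (warm starts)."""
        theta: list[float] = []
        for i, (n, m) in enumerate(self.spec.orders):
            k_ref = params.k(i, T_REF)
            theta.append(math.log(max(k_ref, 1e-300)))
            theta.append(params.Ea[i])
            if self.options.fit_alpha0 and m > 0:
                theta.append(math.log(params.alpha0[i]))
            if self.options.vary_orders:
                theta.append(n)
                theta.append(m)
        theta.append(params.y0)
        theta.extend(params.dY)
        out = np.array(theta, dtype=float)
        eps = 1e-12
        return np.clip(out, self.lower + eps, np.where(np.isfinite(self.upper), self.upper - eps, self.upper))


def _initial_guesses(data: StabilityDataset, spec: KineticModelSpec, options: FitOptions) -> list[np.ndarray]:
    """Deterministic multi-start vectors scaled to the data at hand."""
    df = data.frame
    t_min, t_max = df["time_months"].min(), df["time_months"].max()
    hot = df["temp_K"].max()
    y_start = df.loc[df["time_months"] == t_min, "value"].mean()
    hot_rows = df[df["temp_K"] == hot]
    y_end = hot_rows.loc[hot_rows["time_months"] == hot_rows["time_months"].max(), "value"].mean()
    dy_total = y_end - y_start
    if abs(dy_total) < 1e-12:
        spread = df["value"].std()
        dy_total = spread if spread > 0 else 1.0
    horizon = max(t_max - t_min, 1e-6)
    k_hot = 1.0 / horizon  # ~63% conversion of a first-order step over the study

    def make(theta_k_hot: float, ea: float) -> np.ndarray:
        layout = _ParamLayout(spec, options)
        theta: list[float] = []
        for i, (n, m) in enumerate(spec.orders):
            lnk_ref = math.log(theta_k_hot) - (ea / GAS_CONSTANT) * (1.0 / T_REF - 1.0 / hot)
            theta.append(lnk_ref)
            theta.append(ea)
            if options.fit_alpha0 and m > 0:
                theta.append(math.log(options.alpha0))
            if options.vary_orders:
                theta.append(n)
                theta.append(max(m, 1e-3) if (spec.n_steps == 1 or i > 0) else 0.0)
        theta.append(y_start)
        theta.extend([dy_total / spec.n_steps] * spec.n_steps)
        out = np.array(theta, dtype=float)
        eps = 1e-12
        return np.clip(out, layout.lower + eps, np.where(np.isfinite(layout.upper), layout.upper - eps, layout.upper))

    starts = [make(k_hot, ea) for ea in options.ea_starts]
    starts.append(make(k_hot * 0.1, 90e3))
    if options.n_starts <= len(starts):
        return starts[: options.n_starts]
    rng = np.random.default_rng(options.seed)
    layout = _ParamLayout(spec, options)
    while len(starts) < options.n_starts:
        jitter = starts[len(starts) % 5].copy()
        jitter += rng.normal(0.0, 0.3, size=jitter.size) * np.maximum(np.abs(jitter), 1.0)
        starts.append(np.clip(jitter, layout.lower + 1e-12, layout.upper - 1e-12))
    return starts


def _residual_factory(data: StabilityDataset, spec: KineticModelSpec, layout: _ParamLayout, options: FitOptions):
    groups = list(data.groups())
    sizes = [len(t) for _, t, _ in groups]
    values = np.concatenate([v for _, _, v in groups])

    def residual(theta: np.ndarray) -> np.ndarray:
        orders, A, Ea, alpha0, y0, dY = layout.unpack(theta)
        pred = np.full(values.shape, y0)
        offset_list = np.cumsum([0] + sizes)
        try:
            for i, (n, m) in enumerate(orders):
                a_init = alpha0[i] if m > 0 else 0.0
                taus = []
                for temp_k, times, _ in groups:
                    k = A[i] * math.exp(-Ea[i] / (GAS_CONSTANT * temp_k))
                    taus.append(k * times)
                alphas = isothermal_alpha_multi(n, m, a_init, taus, options.integration)
                for g, a in enumerate(alphas):
                    pred[offset_list[g]: offset_list[g + 1]] += dY[i] * a
        except IntegrationError:
            return np.full(values.shape, 1e6)
        return pred - values

    return residual, values


def fit_model(
    data: StabilityDataset,
    spec: KineticModelSpec,
    options: FitOptions | None = None,
    start: KineticParameters | None = None,
) -> FitResult:
    """Fit one candidate structure to a single-assay dataset.

    Minimizes Σ(y_obs − y_pred)² with kinetic parameters shared across all
    temperatures.  Runs the deterministic multi-start schedule unless a
    ``start`` parameter set is given (single warm start, as used for
    bootstrap refits).  Raises :class:`FitError` on refusal
    (over-parameterized) or when every start fails.
    """
    options = options or FitOptions()
    data.require_fittable()
    layout = _ParamLayout(spec, options)
    n_free = len(layout.names)
    n_pts = data.n_points
    if n_free + 1 >= n_pts:
        raise FitError(
            f"model {spec.spec_id} has {n_free} free parameters (+1 variance) "
            f"for only {n_pts} points"
        )
    residual, values = _residual_factory(data, spec, layout, options)
    if start is not None:
        starts = [layout.pack(start)]
    else:
        starts = _initial_guesses(data, spec, options)

    best = None
    for theta0 in starts:
        try:
            res = least_squares(
                residual,
                theta0,
                bounds=(layout.lower, layout.upper),
                method="trf",
                ftol=options.ftol,
                xtol=options.xtol,
                max_nfev=options.max_nfev,
            )
        except Exception as err:  # noqa: BLE001 - solver-side failures are per-start
            logger.debug("start failed for %s: %s", spec.spec_id, err)
            continue
        if res.status <= 0 or not np.all(np.isfinite(res.x)):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError(f"no start converged for model {spec.spec_id}")

    resid = residual(best.x)
    rss = float(np.dot(resid, resid))
    rmse = math.sqrt(rss / n_pts)
    aic, bic = selection.information_criteria(rss, n_pts, n_free + 1)
    tol = 1e-8
    hit = tuple(
        name
        for name, x, lo, hi in zip(layout.names, best.x, layout.lower, layout.upper)
        if (np.isfinite(lo) and x - lo < tol * max(1, abs(lo)))
        or (np.isfinite(hi) and hi - x < tol * max(1, abs(hi)))
    )
    # vary_orders mode: rebuild the spec at the fitted orders
    fitted_orders, *_ = layout.unpack(best.x)
    fitted_spec = KineticModelSpec(tuple(fitted_orders)) if options.vary_orders else spec
    return FitResult(
        spec=fitted_spec,
        params=layout.to_params(best.x),
        rss=rss,
        rmse=rmse,
        n_points=n_pts,
        n_params=n_free,
        aic=aic,
        bic=bic,
        residuals=resid,
        converged=True,
        bounds_hit=hit,
    )


def fit_all(
    data: StabilityDataset,
    grid: Sequence[KineticModelSpec],
    options: FitOptions | None = None,
) -> list[FitResult]:
    """Fit every candidate in ``grid`` (order preserved), skipping failures.

    Raises :class:`FitError` if no candidate converges.
    """
    results: list[FitResult] = []
    for spec in grid:
        try:
            results.append(fit_model(data, spec, options))
        except FitError as err:
            logger.warning("skipping model %s: %s", spec.spec_id, err)
    if not results:
        raise FitError("no candidate model converged")
    return results
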