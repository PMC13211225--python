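"""Bootstrap uncertainty for kinetic predictions.

The noise bootstrap refits the selected model to copies of the dataset
perturbed with Gaussian noise (SD = the base fit's RMSE by default, standing
in for assay variability).  With the default B = 200 the ensemble is the
base fit plus 199 perturbed refits.  Long-term predictions from every
ensemble member give the percentile confidence band (2.5th/97.5th at the
95% level), and the prediction band inflates each side separately,

    pred_width = sqrt(conf_width² + (t_{α/2, n−p} · RMSE)²),

so the interval expected to contain a future *observation* is asymmetric
whenever the bootstrap percentiles are.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import StabilityDataset
from .fitting import FitError, FitOptions, FitResult, fit_model
from .kinetics import KineticParameters, TemperatureProfile, predict_signal

logger = logging.getLogger("accelstab.uncertainty")

DEFAULT_B = 200


class BootstrapError(RuntimeError):
    """Too many replicate refits failed to form an ensemble."""


def perturb_dataset(
    data: StabilityDataset, noise_sd: float, seed: int | np.random.Generator
) -> StabilityDataset:
    """Add i.i.d. Gaussian noise of the given SD to every response value."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = data.frame["value"].to_numpy()
    return data.with_values(values + rng.normal(0.0, noise_sd, size=values.size))


@dataclass(frozen=True)
class BootstrapEnsemble:
    """Parameter sets from the base fit plus perturbed refits.

    ``replicates[0]`` is always the base fit's estimate.
    """

    replicates: tuple[KineticParameters, ...]
    base_fit: FitResult
    b: int
    seed: int
    n_failed: int = 0

    def predict_matrix(self, profile: TemperatureProfile, times) -> np.ndarray:
        """Predicted responses, shape (n_replicates, len(times))."""
        return np.vstack(
            [
                predict_signal(self.base_fit.spec, p, profile, times)
                for p in self.replicates
            ]
        )


def bootstrap_fits(
    data: StabilityDataset,
    spec,
    base_fit: FitResult,
    b: int = DEFAULT_B,
    seed: int = 0,
    options: FitOptions | None = None,
    noise_sd: float | None = None,
) -> BootstrapEnsemble:
    """Build a B-member ensemble: base fit + (B−1) refits to noisy data.

    Refits warm-start at the base estimate; a failed warm start falls back
    to the full multi-start schedule and is dropped (with a warning) if that
    fails too.  More than 20% drops aborts with :class:`BootstrapError`.
    ``noise_sd`` defaults to the base fit's RMSE.
    """
    if not base_fit.converged:
        raise BootstrapError("base fit did not converge")
    if b < 1:
        raise BootstrapError("ensemble size must be >= 1")
    options = options or FitOptions()
    sd = base_fit.rmse if noise_sd is None else float(noise_sd)
    rng = np.random.default_rng(seed)
    replicates: list[KineticParameters] = [base_fit.params]
    n_failed = 0
    for _ in range(b - 1):
        perturbed = perturb_dataset(data, sd, rng)
        try:
            fit = fit_model(perturbed, spec, options, start=base_fit.params)
        except FitError:
            try:
                fit = fit_model(perturbed, spec, options)
            except FitError as err:
                n_failed += 1
                logger.warning("bootstrap replicate dropped: %s", err)
                continue
        replicates.append(fit.params)
    if n_failed > 0.2 * b:
        raise BootstrapError(f"{n_failed}/{b} bootstrap refits failed")
    return BootstrapEnsemble(
        replicates=tuple(replicates), base_fit=base_fit, b=b, seed=int(seed), n_failed=n_failed
    )


@dataclass(frozen=True)
class ConfidenceBand:
    """Percentile band of ensemble predictions around the base prediction."""

    times: np.ndarray
    point: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    level: float


@dataclass(frozen=True)
class PredictionBand:
    """Point predictions with confidence and prediction limits.

    Invariant by construction: pred_lo ≤ conf_lo ≤ point ≤ conf_hi ≤ pred_hi.
    """

    times: np.ndarray
    point: np.ndarray
    conf_lo: np.ndarray
    conf_hi: np.ndarray
    pred_lo: np.ndarray
    pred_hi: np.ndarray
    level: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_months": self.times,
                "point": self.point,
                "conf_lo": self.conf_lo,
                "conf_hi": self.conf_hi,
                "pred_lo": self.pred_lo,
                "pred_hi": self.pred_hi,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def confidence_band(
    ensemble: BootstrapEnsemble,
    profile: TemperatureProfile,
    times,
    level: float = 0.95,
) -> ConfidenceBand:
    """Empirical percentile band of the ensemble predictions.

    At the default 95% level these are the 2.5th and 97.5th percentiles
    (linear interpolation between order statistics); the point prediction is
    the base fit's.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    times = np.asarray(times, dtype=float)
    mat = ensemble.predict_matrix(profile, times)
    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    return ConfidenceBand(
        times=times,
        point=mat[0],
        lo=np.percentile(mat, lo_q, axis=0),
        hi=np.percentile(mat, hi_q, axis=0),
        level=level,
    )


def prediction_band(
    conf: ConfidenceBand,
    rmse: float,
    n_points: int,
    n_params: int,
    level: float | None = None,
) -> PredictionBand:
    """Inflate a confidence band into a prediction band.

    Each side's width is sqrt(conf_width² + (t·RMSE)²) with the two-sided
    t-quantile at n − p degrees of freedom, computed separately for the
    upper and lower percentile distances so the band stays asymmetric.
    """
    level = conf.level if level is None else float(level)
    dof = int(n_points) - int(n_params)
    if dof <= 0:
        raise ValueError(f"need n_points > n_params, got dof={dof}")
    t_q = float(stats.t.ppf((1 + level) / 2, dof))
    inflate = t_q * float(rmse)
    lo_w = np.sqrt((conf.point - conf.lo) ** 2 + inflate**2)
    hi_w = np.sqrt((conf.hi - conf.point) ** 2 + inflate**2)
    return PredictionBand(
        times=conf.times,
        point=conf.point,
        conf_lo=conf.lo,
        conf_hi=conf.hi,
        pred_lo=conf.point - lo_w,
        pred_hi=conf.point + hi_w,
        level=level,
    )


def prediction_band_from_ensemble(
    ensemble: BootstrapEnsemble,
    profile: TemperatureProfile,
    times,
    level: float = 0.95,
) -> PredictionBand:
    """Confidence + prediction band in one call, using the base fit's RMSE."""
    conf = confidence_band(ensemble, profile, times, level)
    base = ensemble.base_fit
    return prediction_band(conf, base.rmse, base.n_points, base.n_params, level)
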