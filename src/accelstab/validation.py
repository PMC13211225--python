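"""Simulation studies that quantify how well the pipeline performs.

These are end-to-end checks run against the synthetic-data generators'
known ground truth: prediction-interval coverage, Arrhenius parameter
recovery, and model-structure recovery through the information-criterion
ranking.  They are the package's own calibration experiments and are used
both by the test suite and by ``scripts/acceptance.py``.

All randomness flows from one root seed through ``numpy`` seed sequences,
so every study is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import FitOptions, enumerate_model_grid, fit_all, fit_model
from .kinetics import TemperatureProfile
from .selection import rank_models
from .simulate import (
    ScenarioConfig,
    aggregation_scenario,
    first_order_scenario,
    generate_stability_dataset,
    true_signal,
)
from .uncertainty import bootstrap_fits, prediction_band_from_ensemble


def _child_seeds(seed: int, n: int, per_child: int = 3) -> np.ndarray:
    """Deterministic 31-bit seeds, ``per_child`` per replicate."""
    ss = np.random.SeedSequence(seed)
    return ss.generate_state(n * per_child).reshape(n, per_child) % (2**31)


@dataclass(frozen=True)
class StudyResult:
    """Outcome counts of a simulation study."""

    n_success: int
    n_total: int
    details: dict

    @property
    def fraction(self) -> float:
        return self.n_success / self.n_total


def coverage_study(
    n_datasets: int = 100,
    b: int = 200,
    seed: int = 0,
    level: float = 0.95,
    holdout_temp_c: float = 5.0,
    holdout_month: float = 12.0,
) -> StudyResult:
    """Empirical coverage of the bootstrap prediction interval.

    For each replicate: draw a dataset from the correctly specified
    first-order Arrhenius scenario (4 temperatures, 8 time points, 2% CV
    noise), fit the true structure, build the nominal-``level`` prediction
    band from a ``b``-member bootstrap, and test whether a freshly drawn
    noisy observation at the held-out low-temperature/long-horizon point
    (default 5 °C, 12 months) falls inside.  Nominal behaviour puts the
    success count in the binomial range around ``level``.
    """
    cfg = first_order_scenario()
    (assay, truth), = cfg.assays.items()
    seeds = _child_seeds(seed, n_datasets)
    profile = TemperatureProfile.isothermal(holdout_temp_c, duration_months=holdout_month)
    y_true = float(true_signal(cfg, assay, holdout_temp_c, [holdout_month])[0])
    covered = 0
    widths = []
    for data_seed, boot_seed, obs_seed in seeds:
        data = generate_stability_dataset(cfg, int(data_seed)).select(assay)
        fit = fit_model(data, truth.spec)
        ensemble = bootstrap_fits(data, truth.spec, fit, b=b, seed=int(boot_seed))
        band = prediction_band_from_ensemble(ensemble, profile, [holdout_month], level)
        obs = y_true + np.random.default_rng(int(obs_seed)).normal(0.0, truth.noise_sd)
        if band.pred_lo[0] <= obs <= band.pred_hi[0]:
            covered += 1
        widths.append(float(band.pred_hi[0] - band.pred_lo[0]))
    return StudyResult(
        n_success=covered,
        n_total=n_datasets,
        details={
            "coverage_pct": 100.0 * covered / n_datasets,
            "nominal_pct": 100.0 * level,
            "mean_band_width": float(np.mean(widths)),
            "holdout": (holdout_temp_c, holdout_month),
        },
    )


def parameter_recovery_study(
    n_reps: int = 50,
    seed: int = 0,
    ea_rel_tol: float = 0.10,
    pred_sd_tol: float = 2.0,
    pred_temp_c: float = 5.0,
    pred_month: float = 36.0,
) -> StudyResult:
    """Recovery of the activation energy and the long-term extrapolation.

    Success per replicate: fitted Ea within ``ea_rel_tol`` of truth *and*
    the extrapolated response at 5 °C/36 months within ``pred_sd_tol``
    noise SDs of the noise-free truth.
    """
    cfg = first_order_scenario()
    (assay, truth), = cfg.assays.items()
    seeds = _child_seeds(seed, n_reps)
    ea_true = truth.params.Ea[0]
    y_true = float(true_signal(cfg, assay, pred_temp_c, [pred_month])[0])
    profile = TemperatureProfile.isothermal(pred_temp_c, duration_months=pred_month)
    n_ok = 0
    ea_errors = []
    for data_seed, *_ in seeds:
        data = generate_stability_dataset(cfg, int(data_seed)).select(assay)
        fit = fit_model(data, truth.spec)
        ea_err = abs(fit.params.Ea[0] - ea_true) / ea_true
        pred = float(fit.predict(profile, [pred_month])[0])
        ea_errors.append(ea_err)
        if ea_err <= ea_rel_tol and abs(pred - y_true) <= pred_sd_tol * truth.noise_sd:
            n_ok += 1
    return StudyResult(
        n_success=n_ok,
        n_total=n_reps,
        details={"median_ea_rel_error": float(np.median(ea_errors))},
    )


def structure_recovery_study(
    n_reps: int = 50,
    seed: int = 0,
    grid=None,
    n_starts: int = 3,
) -> StudyResult:
    """How often wAIC ranks the generating structure first.

    Datasets come from the first-order scenario; the candidate grid
    defaults to all one-step order combinations n ∈ {0, 0.5, 1, 2},
    m ∈ {0, 0.5, 1}.
    """
    cfg = first_order_scenario()
    (assay, truth), = cfg.assays.items()
    if grid is None:
        grid = enumerate_model_grid(max_steps=1)
    options = FitOptions(n_starts=n_starts)
    seeds = _child_seeds(seed, n_reps)
    n_ok = 0
    winners: dict[str, int] = {}
    for data_seed, *_ in seeds:
        data = generate_stability_dataset(cfg, int(data_seed)).select(assay)
        ranking = rank_models(fit_all(data, grid, options), "wAIC")
        winner = ranking.best.spec.spec_id
        winners[winner] = winners.get(winner, 0) + 1
        if ranking.best.spec == truth.spec:
            n_ok += 1
    return StudyResult(n_success=n_ok, n_total=n_reps, details={"winners": winners})


def autocatalysis_detection(seed: int = 0) -> dict:
    """Does aggregation-like data select a model with m > 0?

    Fits a small nested candidate set (one- and two-step, m ∈ {0, 1}) to a
    dataset from the autocatalytic aggregation scenario and reports the
    wAIC-selected structure's maximal autocatalytic order.
    """
    cfg = aggregation_scenario()
    (assay, truth), = cfg.assays.items()
    data = generate_stability_dataset(cfg, seed).select(assay)
    grid = enumerate_model_grid(max_steps=2, n_values=(1.0,), m_values=(0.0, 1.0))
    ranking = rank_models(fit_all(data, grid), "wAIC")
    best = ranking.best.spec
    return {
        "best_spec": best.spec_id,
        "max_m": max(m for _, m in best.orders),
        "ranking": ranking,
    }
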