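"""End-to-end orchestration: simulate/load → fit grid → rank → bootstrap →
predict → report.

A single YAML config (one root seed) drives the whole run; per-stage seeds
are derived from it so reruns are byte-identical.  Each stage records its
outputs and their SHA-256 digests in a :class:`RunManifest` written next to
the artifacts.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as asio
from .dataset import DatasetError, StabilityDataset
from .dls import cumulant_fit, hydrodynamic_radius
from .fitting import (
    DEFAULT_M_VALUES,
    DEFAULT_N_VALUES,
    FitOptions,
    FitResult,
    enumerate_model_grid,
    fit_all,
)
from .kinetics import TemperatureProfile
from .selection import rank_models
from .simulate import SCENARIOS, generate_stability_dataset
from .spectra import barycentric_mean, spectrum_auc, turbidity_at
from .uncertainty import (
    BootstrapEnsemble,
    ConfidenceBand,
    PredictionBand,
    bootstrap_fits,
    prediction_band,
    prediction_band_from_ensemble,
)


class ConfigError(ValueError):
    """The run configuration does not validate."""


def demo_config() -> dict:
    """A small self-contained scenario exercising every stage."""
    return {
        "seed": 7,
        "scenario": "first_order",
        "assay": "purity_pct",
        "grid": {"max_steps": 1, "n_values": [0.0, 1.0], "m_values": [0.0, 1.0]},
        "fit": {"n_starts": 5},
        "criterion": "wAIC",
        "bootstrap": {"b": 50},
        "level": 0.95,
        "predictions": [
            {
                "name": "longterm_5C",
                "profile": [{"temp_C": 5, "duration_months": 36}],
                "n_times": 37,
            },
            {
                "name": "cycling_8_25",
                "profile": [
                    {"temp_C": 8, "duration_months": 1},
                    {"temp_C": 25, "duration_months": 1},
                    {"temp_C": 8, "duration_months": 1},
                    {"temp_C": 25, "duration_months": 1},
                ],
                "n_times": 25,
            },
        ],
    }


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} must be a YAML mapping")
    return cfg


def _validate_config(cfg: dict) -> None:
    if "seed" not in cfg:
        raise ConfigError("config requires a root 'seed'")
    if ("scenario" in cfg) == ("data" in cfg):
        raise ConfigError("config needs exactly one of 'scenario' or 'data'")
    if "scenario" in cfg and cfg["scenario"] not in SCENARIOS:
        raise ConfigError(
            f"unknown scenario {cfg['scenario']!r}; available: {sorted(SCENARIOS)}"
        )
    for pred in cfg.get("predictions", []):
        if "profile" not in pred or "name" not in pred:
            raise ConfigError("each prediction needs 'name' and 'profile'")


def _stage_seeds(seed: int) -> dict[str, int]:
    names = ["simulate", "fit", "bootstrap"]
    state = np.random.SeedSequence(seed).generate_state(len(names)) % (2**31)
    return dict(zip(names, (int(s) for s in state)))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record: config snapshot, seed, per-stage digests."""

    seed: int
    config: dict
    stages: list[dict] = field(default_factory=list)

    def record(self, name: str, t0: float, outputs: dict[str, Path]) -> None:
        self.stages.append(
            {
                "name": name,
                "status": "ok",
                "elapsed_s": round(time.perf_counter() - t0, 3),
                "outputs": {k: _sha256(Path(p)) for k, p in outputs.items()},
            }
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"seed": self.seed, "config": self.config, "stages": self.stages}, indent=1)
        )


def derive_responses(
    emission=None, absorbance=None, correlograms=None
) -> StabilityDataset:
    """Reduce raw HTS measurements to stability-table responses.

    Emission spectra yield fluorescence AUC and barycentric-mean rows,
    absorbance spectra yield 350 nm turbidity, and DLS correlograms yield
    the cumulant hydrodynamic radius.  Sample metadata (temp_C,
    time_months, replicate) is carried through so the output feeds fitting
    directly.
    """
    records = []

    def meta_of(m: dict) -> dict:
        return {
            "temp_C": float(m.get("temp_C", np.nan)),
            "time_months": float(m.get("time_months", np.nan)),
            "replicate": m.get("replicate", 1),
        }

    for s in emission or []:
        base = meta_of(s.meta)
        records.append({"assay": "fluor_auc", "value": spectrum_auc(s), **base})
        records.append({"assay": "fluor_bcm_nm", "value": barycentric_mean(s), **base})
    for s in absorbance or []:
        base = meta_of(s.meta)
        records.append({"assay": "turbidity_350nm", "value": turbidity_at(s), **base})
    for _, (corr, sample_meta) in (correlograms or {}).items():
        base = meta_of(sample_meta)
        fit = cumulant_fit(corr)
        records.append(
            {"assay": "radius_nm", "value": hydrodynamic_radius(fit.gamma, corr.meta), **base}
        )
    if not records:
        raise DatasetError("no HTS inputs supplied")
    return StabilityDataset.from_records(records)


def predict_at(
    source: BootstrapEnsemble | FitResult,
    profile: TemperatureProfile,
    horizon: float | None = None,
    times=None,
    level: float = 0.95,
) -> PredictionBand:
    """Forward prediction with bands over an arbitrary temperature program.

    Accepts either a bootstrap ensemble (percentile + t-inflated bands) or
    a bare fit (bands from the t·RMSE term alone, zero-width confidence).
    """
    if times is None:
        if horizon is None:
            horizon = profile.total_duration
        if horizon <= 0:
            raise ValueError("horizon must be > 0")
        times = np.linspace(0.0, float(horizon), 73)
    times = np.asarray(times, dtype=float)
    if times.size and times[-1] > profile.total_duration + 1e-9:
        raise ValueError(
            f"profile covers {profile.total_duration} months but "
            f"{times[-1]} months requested"
        )
    if isinstance(source, BootstrapEnsemble):
        return prediction_band_from_ensemble(source, profile, times, level)
    point = source.predict(profile, times)
    conf = ConfidenceBand(times=times, point=point, lo=point.copy(), hi=point.copy(), level=level)
    return prediction_band(conf, source.rmse, source.n_points, source.n_params, level)


def _plot_band(data: StabilityDataset | None, band: PredictionBand, title: str, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(band.times, band.pred_lo, band.pred_hi, alpha=0.2, label="95% PI")
    ax.fill_between(band.times, band.conf_lo, band.conf_hi, alpha=0.3, label="95% CI")
    ax.plot(band.times, band.point, lw=1.5, label="model")
    if data is not None:
        for temp_k, t, v in data.groups():
            ax.plot(t, v, "o", ms=3, label=f"{temp_k - 273.15:.0f} °C data")
    ax.set_xlabel("time (months)")
    ax.set_ylabel("response")
    ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def run_pipeline(config: dict | str | Path, outdir: str | Path, seed: int | None = None) -> RunManifest:
    """Run every stage of the workflow and write artifacts to ``outdir``.

    Returns the manifest (also written as ``manifest.json``).  Raises
    ConfigError/DatasetError/FitError/SelectionError/BootstrapError on
    stage failures; the CLI maps these to distinct exit codes.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = dict(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    _validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(int(cfg["seed"]))
    manifest = RunManifest(seed=int(cfg["seed"]), config=cfg)

    # -- data ------------------------------------------------------------
    t0 = time.perf_counter()
    if "scenario" in cfg:
        scenario = SCENARIOS[cfg["scenario"]]()
        data = generate_stability_dataset(scenario, seeds["simulate"])
    else:
        data = StabilityDataset.from_csv(cfg["data"])
    assay = cfg.get("assay") or data.assays[0]
    data = data.select(assay)
    data_path = outdir / "dataset.csv"
    data.to_csv(data_path)
    manifest.record("data", t0, {"dataset": data_path})

    # -- fit + rank ------------------------------------------------------
    t0 = time.perf_counter()
    grid_cfg = cfg.get("grid", {})
    grid = enumerate_model_grid(
        grid_cfg.get("max_steps", 2),
        grid_cfg.get("n_values", DEFAULT_N_VALUES),
        grid_cfg.get("m_values", DEFAULT_M_VALUES),
    )
    options = FitOptions(seed=seeds["fit"], **cfg.get("fit", {}))
    fits = fit_all(data, grid, options)
    fits_path = outdir / "fits.json"
    asio.write_fits_json(fits, fits_path)
    ranking = rank_models(fits, cfg.get("criterion", "wAIC"))
    ranking_path = outdir / "ranking.csv"
    ranking.to_csv(ranking_path)
    best_path = outdir / "best_fit.json"
    asio.write_fits_json([ranking.best], best_path)
    manifest.record("fit_rank", t0, {"fits": fits_path, "ranking": ranking_path, "best": best_path})

    # -- bootstrap -------------------------------------------------------
    t0 = time.perf_counter()
    b = int(cfg.get("bootstrap", {}).get("b", 200))
    ensemble = bootstrap_fits(data, ranking.best.spec, ranking.best, b=b, seed=seeds["bootstrap"], options=options)
    ens_path = outdir / "ensemble.json"
    asio.write_ensemble_json(ensemble, ens_path)
    manifest.record("bootstrap", t0, {"ensemble": ens_path})

    # -- predictions -----------------------------------------------------
    level = float(cfg.get("level", 0.95))
    for pred in cfg.get("predictions", []):
        t0 = time.perf_counter()
        profile = TemperatureProfile.from_config(pred["profile"])
        times = np.linspace(0.0, profile.total_duration, int(pred.get("n_times", 73)))
        band = predict_at(ensemble, profile, times=times, level=level)
        band_path = outdir / f"band_{pred['name']}.csv"
        band.to_csv(band_path)
        plot_path = outdir / f"plot_{pred['name']}.png"
        _plot_band(data, band, pred["name"], plot_path)
        manifest.record(f"predict_{pred['name']}", t0, {"band": band_path, "plot": plot_path})

    manifest.to_json(outdir / "manifest.json")
    return manifest
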