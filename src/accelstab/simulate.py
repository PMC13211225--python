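"""Synthetic stability data with known ground truth.

Generates every input the pipeline consumes — stability tables, emission
and absorbance spectra, DLS correlograms — from known kinetic/optical
truth, so each processing stage can be tested by parameter recovery without
any external data.

The default study design mirrors a short accelerated stability study on a
refrigerated biologic: four stress temperatures (5, 25, 40, 45 °C), eight
time points over 0–3 months, triplicate measurements per condition (the
usual plate-reader layout), homoscedastic Gaussian assay noise at ~2% CV.
Two stock scenarios are provided:

* ``first_order_scenario`` — a purity-like response decaying by one-step
  first-order Arrhenius kinetics (the classic chemical-degradation case,
  e.g. O-acetyl ester hydrolysis);
* ``aggregation_scenario`` — a radius-like response rising by a two-step
  model whose second step is autocatalytic (n=1, m=1), giving the flat
  5/25 °C, accelerating 40/45 °C pattern characteristic of lag-phase
  aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import StabilityDataset
from .dls import Correlogram, DLSInstrument, decay_rate_from_radius
from .kinetics import (
    KineticModelSpec,
    KineticParameters,
    TemperatureProfile,
    celsius_to_kelvin,
    predict_signal,
)
from .spectra import Spectrum

DEFAULT_TEMPS_C = (5.0, 25.0, 40.0, 45.0)
DEFAULT_TIMES = (0.0, 0.25, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0)


@dataclass(frozen=True)
class AssayTruth:
    """Generating model and noise level for one assay."""

    spec: KineticModelSpec
    params: KineticParameters
    noise_sd: float


@dataclass(frozen=True)
class ScenarioConfig:
    """Study design + ground truth for a synthetic stability dataset."""

    assays: dict[str, AssayTruth]
    temperatures_c: tuple[float, ...] = DEFAULT_TEMPS_C
    times: tuple[float, ...] = DEFAULT_TIMES
    replicates: int = 3

    def truth(self, assay: str) -> AssayTruth:
        return self.assays[assay]


def first_order_scenario(noise_cv: float = 0.02) -> ScenarioConfig:
    """Purity-like one-step first-order decay (Ea = 80 kJ/mol).

    The rate is pinned so k(45 °C) = 1.0/month: the hottest arm runs to
    ~95% conversion within the 3-month study (a forced-degradation arm
    that clearly resolves the curve shape), while storage at 5 °C loses
    ~37% over 36 months.  Noise SD is ``noise_cv`` of the 100-unit
    baseline.
    """
    ea = 80e3
    k45 = 1.0
    from .kinetics import GAS_CONSTANT

    A = k45 * np.exp(ea / (GAS_CONSTANT * celsius_to_kelvin(45.0)))
    truth = AssayTruth(
        spec=KineticModelSpec(((1.0, 0.0),)),
        params=KineticParameters(A=(float(A),), Ea=(ea,), y0=100.0, dY=(-100.0,)),
        noise_sd=100.0 * noise_cv,
    )
    return ScenarioConfig(assays={"purity_pct": truth})


def aggregation_scenario(noise_cv: float = 0.02) -> ScenarioConfig:
    """Radius-like two-step model with an autocatalytic second step.

    Step 1 (n=1, m=0, Ea = 60 kJ/mol) is a small gradual drift; step 2
    (n=1, m=1, Ea = 100 kJ/mol, seed α₀ = 1e−6) is the lag-then-accelerate
    aggregation term, with k(45 °C) = 8/month placing the logistic midpoint
    near 1.7 months at 45 °C and far beyond the study at 5/25 °C.
    """
    from .kinetics import GAS_CONSTANT

    t45 = celsius_to_kelvin(45.0)
    A1 = 0.15 * np.exp(60e3 / (GAS_CONSTANT * t45))
    A2 = 8.0 * np.exp(100e3 / (GAS_CONSTANT * t45))
    truth = AssayTruth(
        spec=KineticModelSpec(((1.0, 0.0), (1.0, 1.0))),
        params=KineticParameters(
            A=(float(A1), float(A2)),
            Ea=(60e3, 100e3),
            y0=10.0,
            dY=(2.0, 20.0),
            alpha0=(1e-6, 1e-6),
        ),
        noise_sd=10.0 * noise_cv,
    )
    return ScenarioConfig(assays={"radius_nm": truth})


SCENARIOS = {
    "first_order": first_order_scenario,
    "aggregation": aggregation_scenario,
}


def generate_stability_dataset(cfg: ScenarioConfig, seed: int) -> StabilityDataset:
    """Draw one noisy dataset from the scenario's ground truth.

    Responses are the forward kinetic model plus i.i.d. Gaussian noise;
    identical seeds give identical datasets.
    """
    rng = np.random.default_rng(seed)
    records = []
    for assay, truth in cfg.assays.items():
        for temp_c in cfg.temperatures_c:
            profile = TemperatureProfile.isothermal(
                temp_c, duration_months=max(cfg.times) or 1.0
            )
            clean = predict_signal(truth.spec, truth.params, profile, cfg.times)
            for rep in range(cfg.replicates):
                noisy = clean + rng.normal(0.0, truth.noise_sd, size=clean.size)
                for t, v in zip(cfg.times, noisy):
                    records.append(
                        {
                            "assay": assay,
                            "temp_C": temp_c,
                            "time_months": t,
                            "replicate": rep + 1,
                            "value": v,
                        }
                    )
    return StabilityDataset.from_records(records)


def true_signal(cfg: ScenarioConfig, assay: str, temp_c: float, times) -> np.ndarray:
    """Noise-free response of the generating model (for recovery tests)."""
    truth = cfg.truth(assay)
    profile = TemperatureProfile.isothermal(temp_c, duration_months=float(np.max(times)) or 1.0)
    return predict_signal(truth.spec, truth.params, profile, times)


def generate_emission_series(
    centers,
    amplitudes,
    widths=8.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    grid=None,
) -> list[Spectrum]:
    """Gaussian emission bands drifting red and losing amplitude.

    Emulates intrinsic tryptophan fluorescence under thermal stress: the
    band center marches to longer wavelengths while the amplitude decays.
    """
    centers = np.asarray(centers, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if centers.shape != amplitudes.shape:
        raise ValueError("centers and amplitudes must have equal length")
    widths = np.broadcast_to(np.asarray(widths, dtype=float), centers.shape)
    if grid is None:
        grid = np.arange(300.0, 450.5, 1.0)
    rng = np.random.default_rng(seed)
    out = []
    for idx, (c, a, w) in enumerate(zip(centers, amplitudes, widths)):
        band = a * np.exp(-0.5 * ((grid - c) / w) ** 2)
        band = band + rng.normal(0.0, noise_sd, size=grid.size)
        out.append(Spectrum(grid, band, meta={"index": idx, "center": c, "amplitude": a}))
    return out


def generate_absorbance_series(
    b_schedule,
    band_amplitude: float = 0.5,
    band_center: float = 280.0,
    band_width: float = 12.0,
    a: float = 0.01,
    c: float = -4.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    grid=None,
) -> list[Spectrum]:
    """Analyte band plus growing power-law scatter baseline a + b·λ^c.

    ``b_schedule`` drives the scattering term over the series, so the
    350 nm turbidity read tracks it — an aggregating sample in absorbance.
    """
    if grid is None:
        grid = np.arange(250.0, 500.5, 1.0)
    rng = np.random.default_rng(seed)
    out = []
    for idx, b in enumerate(np.asarray(b_schedule, dtype=float)):
        baseline = a + b * np.power(grid, c)
        band = band_amplitude * np.exp(-0.5 * ((grid - band_center) / band_width) ** 2)
        y = band + baseline + rng.normal(0.0, noise_sd, size=grid.size)
        out.append(Spectrum(grid, y, meta={"index": idx, "a": a, "b": b, "c": c}))
    return out


def generate_correlogram(
    radius_nm: float = 10.0,
    meta: DLSInstrument | None = None,
    beta: float = 0.9,
    noise_sd: float = 0.0,
    seed: int = 0,
    lags=None,
    components: list[tuple[float, float]] | None = None,
) -> Correlogram:
    """Single- or multi-exponential correlogram from known radii.

    ``components`` may list (radius_nm, weight) pairs for polydisperse
    mixtures; weights are normalized.  g₂ = 1 + β·(Σ w_i e^{−Γ_i τ})² with
    each Γ_i from the inverted Stokes–Einstein chain.
    """
    meta = meta or DLSInstrument()
    if lags is None:
        lags = np.logspace(-7, -2, 200)
    lags = np.asarray(lags, dtype=float)
    if components is None:
        components = [(radius_nm, 1.0)]
    weights = np.array([w for _, w in components], dtype=float)
    weights = weights / weights.sum()
    g1 = np.zeros_like(lags)
    for (rh, _), w in zip(components, weights):
        gamma = decay_rate_from_radius(rh, meta)
        g1 += w * np.exp(-gamma * lags)
    rng = np.random.default_rng(seed)
    g2 = 1.0 + beta * g1**2 + rng.normal(0.0, noise_sd, size=lags.size)
    return Correlogram(lags=lags, g2=g2, meta=meta)
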