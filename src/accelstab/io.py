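"""CSV and JSON serialization for pipeline artifacts.

Formats (all plain text):

* stability tables — ``assay,temp_C,time_months,replicate,value``
  (see :mod:`accelstab.dataset`);
* spectra — long format ``sample_id,assay,wavelength_nm,intensity`` with
  optional ``temp_C,time_months,replicate`` metadata columns carried
  through to derived responses;
* correlograms — ``sample_id,lag_s,g2`` plus the same optional metadata;
* fit results and bootstrap ensembles — JSON documents so the CLI stages
  (fit → rank → bootstrap → predict) can hand work to each other.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dls import Correlogram, DLSInstrument
from .fitting import FitResult
from .kinetics import KineticModelSpec, KineticParameters
from .spectra import Spectrum
from .uncertainty import BootstrapEnsemble

_META_COLS = ["temp_C", "time_months", "replicate"]


def read_spectra_csv(path: str | Path) -> list[Spectrum]:
    """Read a long-format spectra CSV into per-sample :class:`Spectrum` objects."""
    df = pd.read_csv(path)
    required = ["sample_id", "assay", "wavelength_nm", "intensity"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"spectra CSV {path} missing columns: {missing}")
    out = []
    for (sample, assay), sub in df.groupby(["sample_id", "assay"], sort=True):
        sub = sub.sort_values("wavelength_nm")
        meta = {"sample_id": sample, "assay": assay}
        for c in _META_COLS:
            if c in sub.columns:
                meta[c] = sub[c].iloc[0]
        out.append(Spectrum(sub["wavelength_nm"].to_numpy(), sub["intensity"].to_numpy(), meta))
    return out


def write_spectra_csv(spectra: list[Spectrum], path: str | Path) -> None:
    rows = []
    for i, s in enumerate(spectra):
        for wl, it in zip(s.wavelengths, s.intensities):
            row = {
                "sample_id": s.meta.get("sample_id", i),
                "assay": s.meta.get("assay", "spectrum"),
                "wavelength_nm": wl,
                "intensity": it,
            }
            for c in _META_COLS:
                if c in s.meta:
                    row[c] = s.meta[c]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_correlograms_csv(path: str | Path, meta: DLSInstrument | None = None) -> dict[str, tuple[Correlogram, dict]]:
    """Read correlograms; returns ``{sample_id: (Correlogram, sample_meta)}``."""
    df = pd.read_csv(path)
    required = ["sample_id", "lag_s", "g2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"correlogram CSV {path} missing columns: {missing}")
    meta = meta or DLSInstrument()
    out = {}
    for sample, sub in df.groupby("sample_id", sort=True):
        sub = sub.sort_values("lag_s")
        sample_meta = {c: sub[c].iloc[0] for c in _META_COLS if c in sub.columns}
        out[sample] = (Correlogram(sub["lag_s"].to_numpy(), sub["g2"].to_numpy(), meta), sample_meta)
    return out


# -- JSON round trips -----------------------------------------------------

def spec_to_dict(spec: KineticModelSpec) -> dict:
    return {"orders": [list(pair) for pair in spec.orders]}


def spec_from_dict(d: dict) -> KineticModelSpec:
    return KineticModelSpec(tuple(tuple(pair) for pair in d["orders"]))


def params_to_dict(params: KineticParameters) -> dict:
    return {
        "A": list(params.A),
        "Ea": list(params.Ea),
        "y0": params.y0,
        "dY": list(params.dY),
        "alpha0": list(params.alpha0),
    }


def params_from_dict(d: dict) -> KineticParameters:
    return KineticParameters(
        A=tuple(d["A"]),
        Ea=tuple(d["Ea"]),
        y0=d["y0"],
        dY=tuple(d["dY"]),
        alpha0=tuple(d.get("alpha0", ())),
    )


def fit_to_dict(fit: FitResult) -> dict:
    return {
        "spec": spec_to_dict(fit.spec),
        "params": params_to_dict(fit.params),
        "rss": fit.rss,
        "rmse": fit.rmse,
        "n_points": fit.n_points,
        "n_params": fit.n_params,
        "aic": fit.aic,
        "bic": fit.bic,
        "residuals": np.asarray(fit.residuals).tolist(),
        "converged": fit.converged,
        "bounds_hit": list(fit.bounds_hit),
    }


def fit_from_dict(d: dict) -> FitResult:
    return FitResult(
        spec=spec_from_dict(d["spec"]),
        params=params_from_dict(d["params"]),
        rss=d["rss"],
        rmse=d["rmse"],
        n_points=d["n_points"],
        n_params=d["n_params"],
        aic=d["aic"],
        bic=d["bic"],
        residuals=np.asarray(d["residuals"]),
        converged=d["converged"],
        bounds_hit=tuple(d.get("bounds_hit", ())),
    )


def write_fits_json(fits: list[FitResult], path: str | Path) -> None:
    Path(path).write_text(json.dumps({"fits": [fit_to_dict(f) for f in fits]}, indent=1))


def read_fits_json(path: str | Path) -> list[FitResult]:
    doc = json.loads(Path(path).read_text())
    return [fit_from_dict(d) for d in doc["fits"]]


def ensemble_to_dict(ens: BootstrapEnsemble) -> dict:
    return {
        "replicates": [params_to_dict(p) for p in ens.replicates],
        "base_fit": fit_to_dict(ens.base_fit),
        "b": ens.b,
        "seed": ens.seed,
        "n_failed": ens.n_failed,
    }


def write_ensemble_json(ens: BootstrapEnsemble, path: str | Path) -> None:
    Path(path).write_text(json.dumps(ensemble_to_dict(ens), indent=1))


def read_ensemble_json(path: str | Path) -> BootstrapEnsemble:
    d = json.loads(Path(path).read_text())
    return BootstrapEnsemble(
        replicates=tuple(params_from_dict(p) for p in d["replicates"]),
        base_fit=fit_from_dict(d["base_fit"]),
        b=d["b"],
        seed=d["seed"],
        n_failed=d.get("n_failed", 0),
    )
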