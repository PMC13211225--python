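"""Information-criterion scoring, Akaike weighting and model ranking.

Candidate kinetic models fitted to the same dataset are compared with the
Gaussian least-squares forms of AIC and BIC,

    AIC = n·ln(RSS/n) + 2p,      BIC = n·ln(RSS/n) + p·ln(n),

where p counts every fitted parameter including the implicit error
variance.  Criteria are converted to weights w_i ∝ exp(−Δ_i/2) (Δ_i the
criterion excess over the best model), which sum to one over the candidate
set; models are ranked by the selected weight and the rank-1 model supplies
the headline predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class SelectionError(ValueError):
    """Ranking is impossible (no converged fits, bad inputs)."""


def information_criteria(
    rss: float, n_points: int, n_params: int, small_sample: bool = False
) -> tuple[float, float]:
    """AIC and BIC from a least-squares fit.

    ``n_params`` must already include the error-variance parameter.  A fit
    with rss = 0 returns −inf for both criteria (the model wins any
    comparison); ranking handles the sentinel.  ``small_sample`` switches
    the first criterion to AICc (adds 2p(p+1)/(n−p−1)); off by default.
    """
    if n_points <= n_params:
        raise SelectionError(
            f"need n_points > n_params, got n={n_points}, p={n_params}"
        )
    if rss < 0:
        raise SelectionError("rss must be >= 0")
    if rss == 0:
        return -math.inf, -math.inf
    n, p = int(n_points), int(n_params)
    base = n * math.log(rss / n)
    aic = base + 2 * p
    if small_sample:
        if n - p - 1 <= 0:
            raise SelectionError("AICc needs n_points > n_params + 1")
        aic += 2 * p * (p + 1) / (n - p - 1)
    return aic, base + p * math.log(n)


def akaike_weights(criteria: Sequence[float]) -> np.ndarray:
    """Exponential-relative weights w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2).

    Numerically stable for large criterion spreads; −inf criteria (perfect
    fits) take all the weight, shared equally if tied.
    """
    c = np.asarray(criteria, dtype=float)
    if c.size == 0:
        raise SelectionError("empty criterion list")
    if np.any(np.isnan(c)) or np.any(c == np.inf):
        raise SelectionError("criteria must be finite or -inf")
    if np.any(np.isneginf(c)):
        w = np.where(np.isneginf(c), 1.0, 0.0)
        return w / w.sum()
    delta = c - c.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


@dataclass(frozen=True)
class ModelRanking:
    """Ranked candidate set: one row per converged fit.

    ``table`` columns: spec_id, n_steps, n_params, rss, rmse, aic, bic,
    waic, wbic, rank (rank 1 = highest selected weight).  ``fits`` holds the
    corresponding FitResult objects in ranked order.
    """

    table: pd.DataFrame
    fits: tuple
    criterion: str

    @property
    def best(self):
        """The rank-1 fit under the selected criterion."""
        return self.fits[0]

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def rank_models(fits: Sequence, criterion: str = "wAIC") -> ModelRanking:
    """Weight and rank fitted models by wAIC (default) or wBIC.

    Ties in weight are broken by fewer parameters, then by original (grid)
    order, so the ranking is deterministic.
    """
    if criterion not in ("wAIC", "wBIC"):
        raise SelectionError(f"criterion must be 'wAIC' or 'wBIC', got {criterion!r}")
    fits = [f for f in fits if getattr(f, "converged", True)]
    if not fits:
        raise SelectionError("no converged fits to rank")
    waic = akaike_weights([f.aic for f in fits])
    wbic = akaike_weights([f.bic for f in fits])
    chosen = waic if criterion == "wAIC" else wbic
    order = sorted(
        range(len(fits)), key=lambda i: (-chosen[i], fits[i].n_params, i)
    )
    rows = []
    ranked = []
    for rank, i in enumerate(order, start=1):
        f = fits[i]
        ranked.append(f)
        rows.append(
            {
                "spec_id": f.spec.spec_id,
                "n_steps": f.spec.n_steps,
                "n_params": f.n_params,
                "rss": f.rss,
                "rmse": f.rmse,
                "aic": f.aic,
                "bic": f.bic,
                "waic": waic[i],
                "wbic": wbic[i],
                "rank": rank,
            }
        )
    return ModelRanking(table=pd.DataFrame(rows), fits=tuple(ranked), criterion=criterion)
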