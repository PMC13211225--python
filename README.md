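# accelstab

Kinetic shelf-life prediction for biologics from short accelerated
stability studies.

Temperature-sensitive products — vaccines, therapeutic proteins,
glycoconjugates — must demonstrate multi-year stability at their storage
temperature, yet development timelines only allow a few months of data.
`accelstab` implements the accelerated-kinetics workflow that bridges that
gap: degradation measured for ~3 months at several stress temperatures
(e.g. 5, 25, 40, 45 °C) is fitted globally with a family of kinetic
models, the best-supported model is selected statistically, and long-term
predictions are extrapolated with bootstrap prediction intervals.  It is
aimed at formulation and CMC scientists, and at anyone who needs a
transparent, fully scriptable alternative to vendor stability-modeling
software.

## The model

Reaction progress α (0 = intact, 1 = fully reacted) follows the truncated
Šesták–Berggren rate law with Arrhenius temperature dependence:

    dα/dt = A · exp(−Ea / (R·T)) · (1−α)^n · α^m

* `n` — reaction order (`n=0` linear, `n=1` first-order kinetics),
* `m` — autocatalytic order; `m>0` produces the lag-then-accelerate
  S-curves typical of protein aggregation (`n=1, m=1` is the classic
  Prout–Tompkins equation),
* one or two parallel sub-reactions, the first non-autocatalytic
  (`m₁ = 0`); the observable is `y(t) = y0 + Σᵢ dYᵢ·αᵢ(t)`.

All temperatures are fitted simultaneously (one `A`, `Ea` per step), a
grid of candidate orders is scored with Akaike/Bayes information-criterion
weights (wAIC/wBIC), and prediction intervals come from a 200-member noise
bootstrap: the 2.5th/97.5th percentile confidence band is inflated per
side by `sqrt(conf_width² + (t_{α/2,n−p}·RMSE)²)`, giving asymmetric 95%
prediction limits.

Companion modules turn high-throughput plate-reader measurements into the
scalar responses the kinetics consume: scatter-corrected UV-Vis absorbance
(power-law baseline `a + b·λ^c` fitted on 350–500 nm), turbidity at
350 nm, fluorescence AUC and barycentric-mean emission (300–450 nm), and
DLS cumulant analysis yielding the mean hydrodynamic radius via
Stokes–Einstein.  Synthetic-data generators provide ground-truthed
stability tables, spectra and correlograms, so the whole pipeline is
testable end to end without instrument data.

## Worked example

```python
from accelstab import *

cfg = first_order_scenario()                       # known ground truth: n=1, m=0, Ea=80 kJ/mol
data = generate_stability_dataset(cfg, seed=1).select("purity_pct")

grid = enumerate_model_grid(max_steps=1, n_values=(0, 1), m_values=(0, 1))
ranking = rank_models(fit_all(data, grid), "wAIC")
print(ranking.table[["spec_id", "rmse", "aic", "waic", "rank"]])

best = ranking.best
ens = bootstrap_fits(data, best.spec, best, seed=2)          # base fit + 199 refits
profile = TemperatureProfile.isothermal(5.0, duration_months=36.0)
band = prediction_band_from_ensemble(ens, profile, [36.0])
```

Output:

```
spec_id  n_params      rmse        aic         waic  rank
   n1m0         4  1.695155 111.332684 1.000000e+00     1
   n0m0         4  4.514185 299.387117 1.460490e-41     2
   n1m1         4 10.968956 469.853262 1.406843e-78     3
   n0m1         4 12.037031 487.693661 1.880408e-82     4
Ea (kJ/mol): 79.6
36-month 5C prediction: 62.3  95% PI [57.9, 66.8]
```

The first-order structure the data were generated from wins essentially
all the Akaike weight; its fitted activation energy (79.6 kJ/mol) recovers
the true 80 kJ/mol; and the 36-month extrapolation to the 5 °C storage
condition comes with an asymmetric 95% prediction interval that brackets
the true value (62.8).

The same workflow runs from the shell:

```sh
accelstab run --demo --out results/demo          # simulate → fit → rank → bootstrap → predict
accelstab simulate --scenario aggregation --seed 1 --out agg.csv
accelstab fit --data agg.csv --out fits.json
accelstab rank --fits fits.json --out ranking.csv
```

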