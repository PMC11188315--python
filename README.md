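# soilrbf

Soil-nutrient and crop-yield prediction with grey-wolf-optimized radial
basis function networks.

Precision fertilization in tropical orchards (the motivating case is durian
plantations) needs plot-level predictions of soil nutrient supply —
alkaline-hydrolyzable N, available P, available K (mg/kg) — and of the
nutrient→yield relationship. `soilrbf` implements a hybrid regression
model for this setting:

* a **Gaussian RBF network** `ŷ(x) = Σₛ wₛ exp(−‖x − oₛ‖²/2σₛ²) + b`,
* trained by a **grey wolf optimizer (GWO)** that searches the network's
  full parameter vector (centers, log-widths, output weights, bias) with
  the mean relative prediction error as the fitness, optionally followed by
  a gradient fine-tuning pass,
* with **z-score standardization** `H̄ᵢ = (Hᵢ − R)/αₕ` fitted on the
  training split only,
* evaluation by **MAPE, MAE and R²** with benchmark tables against a
  conventional least-squares RBF fit ("plain RBNNA") and a one-hidden-layer
  sigmoid **BPNN** (mini-batch SGD, lr schedule `lr/(1 + decay·e)`),
* and a **forward stepwise linear regression**
  `Y = e₀ + e₁X₁ + … + e_zX_z` (partial-F entry/removal at α = 0.05/0.10)
  for yield modelling.

Because plot-level survey data of this kind are rarely published, the
package ships a seeded synthetic generator calibrated to reported orchard
statistics (e.g. alkaline-hydrolyzable N 21.5 ± 3.0 mg/kg) with planted
ground truth, so every component is testable end to end.

## Worked example

```bash
soilrbf simulate --preset plantation --n 500 --seed 11 --out data.csv
soilrbf train --data data.csv -K 10 --n-wolves 30 --k-max 100 --seed 11 \
        --refine --out model.json
soilrbf evaluate --model model.json --data data.csv
```

prints (abridged):

```
wrote 500 rows to data.csv
final training mean relative error: 0.0234
{
  "mape": 2.335...,
  "mae": 3.911...,
  "r2": 0.910...
}
```

The trained model predicts yield (kg) from the three standardized nutrient
contents with a mean relative error of about 2.3% on its training file —
close to the floor implied by the generator's additive noise (sd 5 kg on
yields near 170 kg). The same workflow applies to any CSV with the schema
`plot_id, alk_N, avail_P, avail_K, applied_P, applied_N, applied_K,
yield_actual`.

The same pipeline is available as a library:

```python
from soilrbf import plantation_config, generate, split, standardize, TrainConfig, train

data, truth = generate(plantation_config(n=500, seed=11))
tr, va = split(data, ratio=0.7, seed=11)
X, params = standardize(tr, columns=["alk_N", "avail_P", "avail_K"])
net, trace = train(X, tr["yield_actual"].to_numpy(), TrainConfig(K=10, seed=11))
```

`soilrbf benchmark` renders the three-model comparison table (MAPE/MAE/R²
rows, one column per model, relative-change columns for the hybrid).

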