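# satspline

Saturating adaptive regression splines: degree-one splines with adaptively
chosen knots, constrained to extend as constants outside the (scaled) data
range. Fitting is a convex program over signed measures — the spline's
"second derivative" — solved with a fully-corrective conditional gradient
method: an exact linear-time oracle proposes a two-point measure
`(tau/2)·(δ_{t+} − δ_{t−})`, a pairwise-vertex Frank–Wolfe step (with Newton
acceleration on the active face) re-solves the weights at the collected
knots, and a duality gap certifies suboptimality at every iteration.

The additive-model (GAM) extension attaches every knot to one coordinate
and enforces zero net mass per coordinate. Because saturation makes linear
coordinate functions infeasible, coordinates without knots drop out of the
model entirely: knot selection and feature selection happen simultaneously.

## Supported losses

- `squared` — standard regression.
- `logistic` — labels in {−1, +1}, computed overflow-safely.
- `pseudo_huber` — robust regression, `δ(√(1+u²/δ) − 1)` with default
  `δ = 0.0015` (quadratic-to-linear transition near `√δ ≈ 0.039`).

## Library quick start

```python
import numpy as np
from satspline import FitOptions, LossSpec, fit_gam, fit_path, default_tau_grid

X = np.random.default_rng(0).uniform(size=(200, 5))
y = np.sin(6 * X[:, 0]) + 0.1 * np.random.default_rng(1).normal(size=200)

fit = fit_gam(X, y, LossSpec("squared"), FitOptions(tau=3.0))
fit.model.predict(X)          # saturating predictions, raw feature space
fit.model.active_coords()     # selected features
fit.final_gap                 # certified suboptimality bound

path = fit_path(X, y, LossSpec("squared"), default_tau_grid(X, y))
print(path.summary)           # tau, objective, gap, n_knots, n_active_features
```

`fit.model.save("model.json")` / `SplineModel.load(...)` round-trip models
bit-faithfully through JSON.

## CLI

```sh
satspline simulate --n 300 --d 5 --active 0,1 --noise-sd 0.1 --seed 1 --out data.csv
satspline fit --data data.csv --response y --loss squared --tau 3 --out model.json
satspline path --data data.csv --response y --summary path.csv
satspline predict --model model.json --data data.csv --response y --out preds.csv
```

`--quiet` suppresses the per-iteration objective/gap/knot-count log.

## Layout

- `satspline.measures` — atoms, measures, saturating spline models, JSON i/o
- `satspline.losses` — loss values and gradients
- `satspline.lmo` — exact two-point linear minimization oracle + gap
- `satspline.corrective` — restricted weight problem at fixed knots
- `satspline.fit` — outer loops: univariate, GAM, warm-started path
- `satspline.synthetic` — ground-truth generators and the gridded reference solver
- `satspline.io` / `satspline.cli` — CSV/JSON i/o, scaling, command line
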