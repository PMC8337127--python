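# gtskfs

Graph-regularized Takagi–Sugeno–Kang fuzzy regression for noninvasive
prediction of hemodialysis adequacy.

Dialysis dose is quantified by Kt/V, computed from pre- and post-session
blood urea via the Daugirdas second-generation formula
Kt/V = −ln(R − 0.008·Thd) + (4 − 3.5·R)·Uf/BW. Because that requires
repeated blood draws, clinicians cannot track it at every session.
`gtskfs` predicts Kt/V from covariates that are recorded anyway — sex,
age, ultrafiltration, pre/post weight, blood pressure, heart rate, blood
flow — using a first-order TSK fuzzy system:

- **rule premises** from fuzzy C-means clustering (Gaussian memberships,
  centers and widths from membership-weighted moments, width scale h),
- **firing strengths** μ̄ᵏ(x) normalized across the K rules (log-sum-exp,
  underflow-safe),
- **affine consequents** solved in closed form,
  p_g = (X_gᵀX_g + λI + βX_gᵀLX_g)⁻¹X_gᵀy, where L is the normalized
  Laplacian of a cosine-similarity patient graph — the β term pulls
  similar patients toward similar predictions.

The package also ships the full evaluation protocol (10-fold CV with
RMSE / R² / adjusted R², the two-stage K–λ–β grid search, Bland–Altman
limits of agreement) and synthetic-data generators (a cohort emulator
matched to published population statistics, and a TSK-oracle sampler for
recovery experiments), so everything is runnable and testable without
clinical data. See `docs/methods.md` for the model details and design
choices.

## Worked example

```python
from gtskfs import CohortSpec, Hyperparams, cross_validate, generate_cohort, linear_baseline
from gtskfs.cohort import from_dataframe

data = from_dataframe(generate_cohort(CohortSpec(n=250, seed=2)))
hp = Hyperparams(seed=2)                    # K=2, lambda=2^-6, beta=2^-5, h=2
gtsk = cross_validate(data, hp, variant="gtsk", folds=10, seed=2)
tsk  = cross_validate(data, hp, variant="tsk",  folds=10, seed=2)
lr   = linear_baseline(data, folds=10, seed=2)
for name, rep in [("G-TSK-FS", gtsk), ("TSK-FS", tsk), ("LR", lr)]:
    print(f"{name:<10} {rep.rmse:>8.4f} {rep.r_squared:>8.4f} {rep.adj_r_squared:>8.4f}")
```

prints

```
G-TSK-FS     0.1563   0.6644   0.6474
TSK-FS       0.1563   0.6640   0.6470
LR           0.1563   0.6640   0.6470
```

i.e. pooled out-of-fold RMSE around the generator's irreducible noise
(0.15), with R² ≈ 0.66 of the Kt/V variance explained; the graph penalty
gives a small edge over the plain fuzzy system, and both sit at the linear
baseline here because the synthetic Kt/V surface is only mildly nonlinear.
The `examples/` scripts walk through each capability one at a time
(simulation, fit/predict/serialize, CV comparison, grid search,
Bland–Altman agreement).

There is also a thin CLI:

```sh
gtskfs simulate -n 250 --seed 0 -o cohort.csv
gtskfs fit --data cohort.csv -o model.json
gtskfs cv --data cohort.csv -o report.json
gtskfs predict --model model.json --data cohort.csv -o pred.csv
```

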