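# Methods

## The problem

Dialysis adequacy is monitored with the dose index Kt/V (dialyzer clearance
K × session time t over urea distribution volume V; ≥ 1.2 per session is
the usual adequacy floor). Measuring it requires pre- and post-dialysis
blood draws, so it cannot be tracked at every session. `gtskfs` implements
a noninvasive surrogate: a regression model that predicts single-pool Kt/V
from routinely recorded covariates (sex, age, ultrafiltration, pre/post
weight, pre/post blood pressure and heart rate, blood flow).

The reference measurement is the Daugirdas second-generation single-pool
estimator

    Kt/V = −ln(R − 0.008·Thd) + (4 − 3.5·R)·Uf/BW,

with R = U_post/U_pre the urea ratio, Thd the session length in hours, Uf
the ultrafiltration and BW the post-dialysis weight in the same mass units
(the package converts the CSV's ml to kg at 1 ml = 1 g). The forward map is
strictly decreasing in R, so `invert_ktv` recovers R from a prescribed
Kt/V by bracketed Brent root finding on R ∈ (0.008·Thd, 1].

## The model

A first-order Takagi–Sugeno–Kang (TSK) fuzzy system with K rules. Rule k
carries per-dimension Gaussian membership functions with center c_i^k and
width δ_i^k, and an affine consequent f^k(x) = p_0^k + p^k·x. The system
output is the normalized-firing-strength-weighted sum

    ŷ(x) = Σ_k μ̄^k(x) f^k(x),   μ̄^k = μ^k / Σ_l μ^l,
    μ^k(x) = Π_i exp(−(x_i − c_i^k)² / (2 δ_i^k)).

Note the membership denominator is 2δ (not 2δ²): δ is itself an h-scaled
variance (below), so it already carries squared units.

**Premises.** Fuzzy C-means (fuzzifier m = 2, tolerance 1e−6, ≤ 300
iterations, Dirichlet-initialized memberships keyed to a required seed)
soft-partitions the standardized training features. Rule premises are the
membership-weighted moments with *first-power* weights u_jk:

    c_i^k = Σ_j u_jk x_ji / Σ_j u_jk,
    δ_i^k = h · Σ_j u_jk (x_ji − c_i^k)² / Σ_j u_jk,

floored at 1e−6 so zero-variance clusters keep well-defined memberships.
The kernel-width scale h defaults to 2.

**Consequents.** Stacking each row's rule blocks μ̄^k·(1, xᵀ) into
x_g ∈ R^{K(d+1)} makes the system linear in the stacked consequent vector
p_g, so training is a convex quadratic program with closed form

    p_g = (X_gᵀX_g + λI + βX_gᵀLX_g)^{−1} X_gᵀ y,

solved by Cholesky factorization of the SPD normal matrix (never an
explicit inverse), or by a QR/SVD least-squares solve when λ = β = 0 to
avoid squaring the condition number. I is the K(d+1) identity; the ridge
shrinks the per-rule bias terms too.

**Graph penalty.** L is the symmetric-normalized Laplacian
D^{−1/2}(D − S)D^{−1/2} of the cosine-similarity affinity S over the
standardized input features (not the mapped features). Cosine similarity
of centered data can be negative; negative entries are clipped to 0 by
default so S is a valid affinity and L is positive semidefinite (a
(1+cos)/2 rescaling is available via `mode="shift"`). The penalty
β·(X_g p_g)ᵀL(X_g p_g) pulls similar patients toward similar predictions.
Matrices are dense; cohorts here are a few hundred patients.

**Prediction is purely inductive.** Test samples never enter L; a new
sample is standardized with the training scaler, mapped, and dotted with
p_g. This keeps cross-validation honest (no transductive leakage).

## Hyperparameters

| name | meaning | default | why |
|---|---|---|---|
| K | rule count | 2 | grid-search winner on the reference cohort |
| λ | ridge coefficient | 2⁻⁶ | grid-search winner (stage 1) |
| β | graph coefficient | 2⁻⁵ | grid-search winner (stage 2) |
| h | kernel width scale | 2 | reference setting |
| m | FCM fuzzifier | 2 | the standard choice; the source protocol does not state one |
| seed | FCM init seed | required | exact reproducibility |

The two-stage search mirrors the reference protocol exactly: stage 1 fixes
β = 2⁰ and scans K ∈ {1..10} × λ ∈ {2⁻¹⁰..2⁰} (110 cells, 10-fold CV RMSE
each); stage 2 fixes the winners and scans the 11 β values. Ties break
toward smaller K, then larger λ, then larger β (parsimony).

## Evaluation protocol

10-fold cross-validation with seeded shuffling; every stage (scaler, FCM,
premises, graph, solver) is refit on each training split. Pooled
out-of-fold predictions are scored once with RMSE, R² and adjusted R²
(adjusting for the number of *raw* input features d, not the K(d+1) mapped
columns — the mapped columns are not free parameters chosen per fold);
per-fold RMSEs are also reported. Pooling was chosen over per-fold
averaging because R² on 25-patient folds is unstable.

Bland–Altman agreement uses ratio-style percent differences
d_i = 100·(ŷ_i − y_i)/((ŷ_i + y_i)/2), limits of agreement at
mean ± 1.96·SD (n−1 denominator), and reports the count of samples outside
the limits. The pair-mean denominator is the standard Bland–Altman
convention for percent-scale comparisons of two methods measuring the same
positive quantity.

The linear-regression baseline is ordinary least squares on the
standardized features under the identical CV protocol, solved by `lstsq`
(an independent route from the TSK solver, so the K=1, λ=β=0 degeneracy
check compares two genuinely different code paths).

## Synthetic data

**Cohort generator.** Features are truncated normals at the published
cohort marginals (age 57.51 ± 13.58 y; UF 2186.02 ± 1074.41 ml; postBW
61.75 ± 12.91 kg; pressures, heart rates, blood flow likewise) with
Bernoulli categoricals (male 144/250; HDF 34/250; catheter 41/250).
Truncation bounds are symmetric about the mean with half-width
min(3.5·SD, mean − physiological floor), so truncation never biases the
mean. Features are independent except preBW = postBW + UF_kg, enforced
exactly. A joint correlation structure is *not* emulated — passing tests
show the pipeline handles realistic marginals and scales, not that it
would reach any particular accuracy on real, correlated clinical data.

The latent true Kt/V is 1.3 + 0.35·tanh(z_ratio) + 0.10·tanh(z_bf) −
0.05·tanh(z_age), with z-scores taken at the published moments (UF/postBW
ratio at 0.0354 ± 0.018): monotone in relative fluid removal and blood
flow, mildly decreasing with age, range ⊂ (0.8, 1.8) so the 1.2 adequacy
threshold is exercised from both sides. Observation noise is Gaussian with
SD 0.15 by default, putting the irreducible error on the order of the
reported model errors for this task (≈ 0.16). The post/pre urea ratio R is
back-solved per patient so the Daugirdas formula on (R, 4 h, UF, postBW)
reproduces the noisy target to ~1e−12; infeasible noise draws (target
below the R = 1 minimum) are redrawn and counted.

**TSK oracle.** For recovery experiments, inputs are standard normal and
targets come from a known rule base plus Gaussian noise; the generating
model itself is returned so the noiseless targets can be reproduced
through the package's own prediction path. Because isotropic inputs carry
no cluster structure, FCM's split orientation is determined by its
initialization, and an arbitrary fixed gate orientation would not be
identifiable — the experiment would measure an irreducible misfit, not
estimation quality. The default (`premises="fcm"`) therefore builds the
true rule base by the same FCM premise estimation the fit uses, placing
the truth exactly in the estimable family (the standard well-specified
setting for a recovery study); `premises="random"` (separated random
centers, widths h·U(0.8, 1.2)) remains available for robustness
experiments. Recovery fits use `scale_features=False` since oracle inputs
are already standardized; re-standardizing perturbs the data slightly and
can tip FCM into a different (equally good for prediction of the blend,
but differently oriented) basin on isotropic data.

## Numerical choices

- Membership products are evaluated in log space with log-sum-exp
  normalization; firing strengths survive d = 40 with narrow widths. If
  every rule's log-membership overflows to −inf (wildly out-of-range
  query), the row falls back to uniform 1/K with a logged warning.
- FCM handles points coincident with a center by assigning full
  membership there (split equally among coincident centers).
- Degenerate inputs fail loudly: zero-variance features, empty clusters,
  zero-norm similarity rows, isolated graph nodes, singular unregularized
  normal matrices (with advice to set λ > 0) all raise typed errors.
- Model JSON serializes arrays as plain nested lists; Python's float repr
  round-trips IEEE doubles exactly, so reload is bit-identical.

## Problem sizes

The test suite and the acceptance script run everything at desk scale:
250-patient cohorts for CV metrics (matching the reference cohort size),
a 60-patient cohort for the full 110+11-cell grid-search protocol check,
N = 1000 (+500 held out) for recovery, and 10⁴ samples for moment and
calibration checks. These sizes give stable statistics for the properties
asserted while keeping the whole suite in well under a minute of compute
for everything but the grid search.

## Known limitations

- Independent feature marginals: real dialysis covariates are correlated
  (weight with blood pressure, age with heart rate); results on synthetic
  cohorts do not quantify accuracy on real data.
- FCM premises are a heuristic rule induction: with overlapping or
  isotropic data the rule partition is seed-dependent; only well-separated
  cluster structure yields seed-stable premises.
- The closed-form solver is dense and O(N²) in memory through the
  Laplacian; cohorts beyond ~10⁴ patients would need a sparse k-NN graph,
  which is out of scope.
- Only single-pool Kt/V is modelled; equilibrated Kt/V and urea rebound
  are not.
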