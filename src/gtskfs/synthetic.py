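"""Synthetic data generators: hemodialysis cohorts and TSK-oracle sets.

Two generators make the whole package testable without clinical data:

* :func:`generate_cohort` emulates a maintenance-hemodialysis cohort whose
  per-feature marginals match the published population statistics (age
  57.51 +/- 13.58 y, ultrafiltration 2186 +/- 1074 ml, post-dialysis weight
  61.75 +/- 12.91 kg, ...).  Features are drawn from truncated normals /
  Bernoulli categoricals, independent except for the accounting identity
  preBW = postBW + UF (in kg), which is enforced exactly.  Truncation
  bounds are symmetric about the mean (clipped at physiological floors),
  so sample means converge to the published values.  A latent "true" Kt/V
  is a smooth deterministic function of the features — monotone increasing
  in the ultrafiltration-to-weight ratio and blood flow, mildly decreasing
  in age — bounded to roughly [0.8, 1.8] so the 1.2 adequacy threshold is
  exercised on both sides.  Gaussian noise is added, and the post/pre urea
  ratio consistent with each (noisy) Kt/V under 4-hour sessions is emitted
  alongside, so the kinetics formula reproduces the target exactly.

* :func:`generate_tsk_oracle` samples from the TSK model family itself
  (standard-normal inputs, known rules, additive Gaussian noise) and
  returns the generating model, enabling parameter-recovery experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from . import antecedent
from .antecedent import FuzzyRuleBase
from .cohort import FeatureMatrix
from .errors import InfeasibleError, NoSolutionError
from .ktv import DialysisSession, ML_PER_KG, daugirdas_ktv, invert_ktv
from .model import GTskModel, Hyperparams

logger = logging.getLogger(__name__)

#: Published cohort marginals: name -> (mean, SD, physiological floor).
COHORT_NUMERIC = {
    "age": (57.51, 13.582, 18.0),
    "uf_ml": (2186.02, 1074.408, 0.0),
    "post_bw_kg": (61.75, 12.91, 20.0),
    "sbp_pre": (142.18, 20.941, 40.0),
    "dbp_pre": (73.98, 12.907, 20.0),
    "sbp_post": (130.7, 17.204, 40.0),
    "dbp_post": (71.47, 11.094, 20.0),
    "hr_pre": (74.82, 10.747, 30.0),
    "hr_post": (74.73, 9.676, 30.0),
    "blood_flow_ml_min": (274.36, 26.202, 100.0),
}

EXTENDED_NUMERIC = {
    "dry_weight_kg": (62.042, 12.8788, 20.0),
    "conductivity_ms_cm": (14.50, 8.003, 0.5),
    "venous_pressure_mmhg": (123.70, 37.318, 0.0),
    "tmp_mmhg": (76.22, 34.528, 0.0),
}

#: Categorical proportions: name -> probability of coding 1.
COHORT_CATEGORICAL = {
    "sex": 144 / 250,            # 1 = male (144/106 male/female)
    "dialysis_hdf": 34 / 250,    # 1 = hemodiafiltration (HD/HDF 216/34)
    "vascular_catheter": 41 / 250,  # 1 = catheter access (fistula/catheter 209/41)
}


@dataclass(frozen=True)
class CohortSpec:
    """Conditions a synthetic cohort is generated under."""

    n: int = 250
    seed: int = 0
    noise_sd: float = 0.15
    thd: float = 4.0
    extended: bool = False
    max_resample: int = 100

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InfeasibleError(f"cohort size must be >= 1, got {self.n}")
        if self.noise_sd < 0:
            raise InfeasibleError("noise SD must be >= 0")
        if self.thd <= 0:
            raise InfeasibleError("session duration must be > 0")


def _truncated_normal(rng, mean: float, sd: float, floor: float, n: int) -> np.ndarray:
    """Truncated normal with bounds symmetric about the mean.

    The half-width is min(3.5 SD, mean - floor); symmetry keeps the sample
    mean an unbiased estimator of the published mean.
    """
    half = min(3.5 * sd, mean - floor)
    a, b = -half / sd, half / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def latent_ktv(
    uf_ml: np.ndarray, post_bw_kg: np.ndarray, blood_flow: np.ndarray, age: np.ndarray
) -> np.ndarray:
    """Deterministic 'true' Kt/V surface of the generator.

    1.3 + 0.35 tanh(z_ratio) + 0.10 tanh(z_bf) - 0.05 tanh(z_age), where
    z_* are the features centered/scaled at the published cohort moments
    (the UF/postBW ratio at 0.0354 +/- 0.018).  Monotone increasing in the
    relative fluid removal and in blood flow, decreasing in age; range is
    a subset of (0.8, 1.8).
    """
    ratio = (uf_ml / ML_PER_KG) / post_bw_kg
    z_ratio = (ratio - 0.0354) / 0.018
    z_bf = (blood_flow - 274.36) / 26.202
    z_age = (age - 57.51) / 13.582
    return 1.3 + 0.35 * np.tanh(z_ratio) + 0.10 * np.tanh(z_bf) - 0.05 * np.tanh(z_age)


def generate_cohort(spec: CohortSpec = CohortSpec()):
    """Draw a synthetic cohort; returns a pandas DataFrame.

    Columns: the clinical features, ``true_ktv`` (noiseless latent value),
    ``ktv`` (the noisy target) and ``urea_ratio`` (post/pre urea ratio R
    such that the Daugirdas formula on R, the session length, UF and postBW
    reproduces ``ktv`` exactly).
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    n = spec.n
    cols: dict[str, np.ndarray] = {}
    cols["sex"] = (rng.random(n) < COHORT_CATEGORICAL["sex"]).astype(float)
    for name, (mean, sd, floor) in COHORT_NUMERIC.items():
        cols[name] = _truncated_normal(rng, mean, sd, floor, n)
    cols["pre_bw_kg"] = cols["post_bw_kg"] + cols["uf_ml"] / ML_PER_KG
    if spec.extended:
        for name, (mean, sd, floor) in EXTENDED_NUMERIC.items():
            cols[name] = _truncated_normal(rng, mean, sd, floor, n)
        for name in ("dialysis_hdf", "vascular_catheter"):
            cols[name] = (rng.random(n) < COHORT_CATEGORICAL[name]).astype(float)

    true_ktv = latent_ktv(
        cols["uf_ml"], cols["post_bw_kg"], cols["blood_flow_ml_min"], cols["age"]
    )
    uf_kg = cols["uf_ml"] / ML_PER_KG
    ktv = np.empty(n)
    urea_ratio = np.empty(n)
    resampled = 0
    for i in range(n):
        for attempt in range(spec.max_resample + 1):
            target = true_ktv[i] + rng.normal(0.0, spec.noise_sd)
            try:
                urea_ratio[i] = invert_ktv(target, spec.thd, uf_kg[i], cols["post_bw_kg"][i])
                ktv[i] = target
                break
            except NoSolutionError:
                resampled += 1
                if attempt == spec.max_resample:
                    raise
    if resampled:
        logger.info("resampled %d infeasible Kt/V noise draws", resampled)

    order = ["sex", "age", "uf_ml", "pre_bw_kg", "post_bw_kg", "sbp_pre", "dbp_pre",
             "sbp_post", "dbp_post", "hr_pre", "hr_post", "blood_flow_ml_min"]
    if spec.extended:
        order += list(EXTENDED_NUMERIC) + ["dialysis_hdf", "vascular_catheter"]
    df = pd.DataFrame({c: cols[c] for c in order})
    df["true_ktv"] = true_ktv
    df["urea_ratio"] = urea_ratio
    df["ktv"] = ktv
    return df


def verify_cohort_kinetics(df, thd: float = 4.0) -> float:
    """Max |Daugirdas(R) - ktv| over the cohort (construction self-check)."""
    err = 0.0
    for _, row in df.iterrows():
        k = daugirdas_ktv(
            DialysisSession(row["urea_ratio"], thd, row["uf_ml"] / ML_PER_KG, row["post_bw_kg"])
        )
        err = max(err, abs(k - row["ktv"]))
    return err


@dataclass
class TskOracleSpec:
    """Conditions for sampling from a known TSK model (recovery tests).

    premises="fcm" (default): the true rule base is built by the package's
    own FCM premise estimation on the drawn inputs, so the truth lies
    exactly in the family the fitting pipeline can estimate — the
    well-specified setting a recovery experiment needs (standard-normal
    inputs carry no cluster structure, so an arbitrary fixed gate
    orientation would not be identifiable).  premises="random": centers
    from N(0, 1) resampled to a minimum pairwise separation of 1.5, widths
    h x U(0.8, 1.2).  Either way consequent blocks are N(0, 1) unless
    given explicitly.
    """

    k_true: int = 2
    d: int = 4
    n: int = 1000
    noise_sd: float = 0.05
    seed: int = 0
    h: float = 2.0
    premises: str = "fcm"
    centers: np.ndarray | None = None
    widths: np.ndarray | None = None
    consequents: np.ndarray | None = field(default=None)  # (K, d+1), bias first
    min_separation: float = 1.5

    def __post_init__(self) -> None:
        if self.k_true < 1 or self.n < 1 or self.d < 1:
            raise InfeasibleError("k_true, d and n must all be >= 1")
        if self.noise_sd < 0:
            raise InfeasibleError("noise SD must be >= 0")
        if self.premises not in ("fcm", "random"):
            raise InfeasibleError(f"unknown premises mode {self.premises!r}")


def _draw_separated_centers(rng, k: int, d: int, min_sep: float) -> np.ndarray:
    for _ in range(500):
        centers = rng.normal(0.0, 1.0, size=(k, d))
        if k == 1:
            return centers
        dists = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        if dists[np.triu_indices(k, 1)].min() >= min_sep:
            return centers
    raise InfeasibleError(f"could not place {k} centers {min_sep} apart in {d}-d")


def generate_tsk_oracle(spec: TskOracleSpec = TskOracleSpec()):
    """Sample (features, noisy targets) from a known TSK model.

    Returns ``(FeatureMatrix, GTskModel)`` — the data and the generating
    model itself (identity scaler), so recovery experiments can compare a
    refit against the truth through the package's own prediction path.
    """
    rng = np.random.default_rng(spec.seed)
    X = rng.normal(0.0, 1.0, size=(spec.n, spec.d))

    if spec.centers is not None or spec.widths is not None:
        rule_base = FuzzyRuleBase(
            centers=np.asarray(spec.centers, dtype=float),
            widths=np.asarray(spec.widths, dtype=float),
            h=spec.h,
        )
    elif spec.premises == "fcm":
        from . import fcm as _fcm  # local import: fcm depends on antecedent

        clustering = _fcm.fcm_fit(X, k=spec.k_true, m=2.0, seed=spec.seed)
        rule_base = _fcm.premise_from_fcm(X, clustering, h=spec.h)
    else:
        centers = _draw_separated_centers(rng, spec.k_true, spec.d, spec.min_separation)
        widths = spec.h * rng.uniform(0.8, 1.2, size=(spec.k_true, spec.d))
        rule_base = FuzzyRuleBase(centers=centers, widths=widths, h=spec.h)

    consequents = (
        np.asarray(spec.consequents, dtype=float)
        if spec.consequents is not None
        else rng.normal(0.0, 1.0, size=(spec.k_true, spec.d + 1))
    )
    p_g = consequents.reshape(-1)
    mapped = antecedent.map_features(rule_base, X)
    y_clean = antecedent.predict_output(mapped, p_g)
    y = y_clean + rng.normal(0.0, spec.noise_sd, size=spec.n)

    columns = [f"x{i + 1}" for i in range(spec.d)]
    data = FeatureMatrix(X=X, columns=columns, y=y)
    truth = GTskModel(
        rule_base=rule_base,
        p_g=p_g,
        hyperparams=Hyperparams(
            k=spec.k_true, lam=0.0, beta=0.0, h=spec.h, m=2.0, seed=spec.seed
        ),
        feature_names=columns,
        variant="tsk",
        scaler_mean=None,
        scaler_scale=None,
        diagnostics={"generator": "tsk_oracle", "noise_sd": spec.noise_sd},
    )
    return data, truth


def sample_from_model(
    truth: GTskModel, n: int, noise_sd: float = 0.0, seed: int = 0
) -> FeatureMatrix:
    """Fresh standard-normal inputs with targets from a (true) TSK model.

    Used to score held-out error against a generating model returned by
    :func:`generate_tsk_oracle`.
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(0.0, 1.0, size=(n, truth.rule_base.d))
    fm = FeatureMatrix(X=X, columns=list(truth.feature_names))
    from . import model as gtsk_model  # local import avoids cycle at import time

    y = gtsk_model.predict(truth, fm) + rng.normal(0.0, noise_sd, size=n)
    return FeatureMatrix(X=X, columns=list(truth.feature_names), y=y)
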