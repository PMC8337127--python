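"""End-to-end G-TSK-FS model: fit, predict, serialize.

The fitting pipeline is: standardize features (scaler fitted on the
training data only) -> FCM clustering -> Gaussian rule premises -> fuzzy
feature map -> (gtsk variant only) cosine-similarity graph and normalized
Laplacian -> closed-form consequent solve.  Prediction is purely inductive:
a new sample is standardized with the training scaler, mapped through the
rule base and dotted with the consequents — the graph is a training-time
penalty only, so cross-validation never leaks test rows into the Laplacian.

Models serialize to a single human-inspectable JSON document (nested plain
arrays at full float precision, schema-tagged) and round-trip losslessly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import antecedent, fcm, graph, solver
from .antecedent import FuzzyRuleBase
from .cohort import FeatureMatrix, apply_scaler, standardize
from .errors import FormatError, InfeasibleError, SchemaError

MODEL_SCHEMA = "gtsk-fs-model/1"

#: Hyperparameters selected by the two-stage grid search on the study cohort.
PAPER_DEFAULTS = dict(k=2, lam=2.0**-6, beta=2.0**-5, h=2.0, m=2.0)


@dataclass(frozen=True)
class Hyperparams:
    """Model hyperparameters.

    k : number of fuzzy rules (FCM clusters).
    lam : ridge coefficient lambda >= 0.
    beta : graph-regularization coefficient >= 0 (ignored by the plain TSK
        variant).
    h : Gaussian kernel-width scale (> 0); widths are h x weighted variance.
    m : FCM fuzzifier (> 1).
    seed : RNG seed for the FCM membership initialization.
    """

    k: int = PAPER_DEFAULTS["k"]
    lam: float = PAPER_DEFAULTS["lam"]
    beta: float = PAPER_DEFAULTS["beta"]
    h: float = PAPER_DEFAULTS["h"]
    m: float = PAPER_DEFAULTS["m"]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise InfeasibleError(f"need k >= 1 rules, got {self.k}")
        if self.lam < 0 or self.beta < 0:
            raise InfeasibleError("lambda and beta must be >= 0")
        if self.h <= 0:
            raise InfeasibleError(f"width scale h must be > 0, got {self.h}")
        if self.m <= 1:
            raise InfeasibleError(f"fuzzifier must be > 1, got {self.m}")


@dataclass
class GTskModel:
    """A fitted (G-)TSK fuzzy regression model."""

    rule_base: FuzzyRuleBase
    p_g: np.ndarray
    hyperparams: Hyperparams
    feature_names: list[str]
    variant: str = "gtsk"
    scaler_mean: np.ndarray | None = None
    scaler_scale: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)


def fit(
    train: FeatureMatrix,
    hp: Hyperparams = Hyperparams(),
    variant: str = "gtsk",
    scale_features: bool = True,
    similarity_mode: str = "clip",
) -> GTskModel:
    """Fit a TSK ("tsk") or graph-regularized TSK ("gtsk") model.

    The two variants share the whole pipeline; "tsk" simply drops the graph
    term (beta treated as 0), so gtsk with beta=0 and tsk coincide exactly.
    """
    if variant not in ("tsk", "gtsk"):
        raise SchemaError(f"unknown variant {variant!r}; expected 'tsk' or 'gtsk'")
    if train.y is None:
        raise SchemaError("training data must carry targets")
    if train.n < max(2, hp.k):
        raise InfeasibleError(f"n={train.n} samples cannot support k={hp.k} rules")

    work = standardize(train) if scale_features else train
    clustering = fcm.fcm_fit(work, k=hp.k, m=hp.m, seed=hp.seed)
    rule_base = fcm.premise_from_fcm(work, clustering, h=hp.h)
    mapped = antecedent.map_features(rule_base, work)

    beta = hp.beta if variant == "gtsk" else 0.0
    penalty = None
    if beta > 0:
        S = graph.cosine_similarity_matrix(work, mode=similarity_mode)
        penalty = graph.normalized_laplacian(S)
    spec = solver.ObjectiveSpec(lam=hp.lam, beta=beta)
    p_g = solver.solve_consequents(mapped, train.y, graph=penalty, spec=spec)

    yhat = antecedent.predict_output(mapped, p_g)
    _, terms = solver.objective_value(mapped, train.y, penalty, spec, p_g)
    diagnostics = {
        "train_rmse": float(np.sqrt(np.mean((train.y - yhat) ** 2))),
        "objective_terms": terms,
        "fcm_iterations": clustering.n_iter,
    }
    return GTskModel(
        rule_base=rule_base,
        p_g=p_g,
        hyperparams=hp,
        feature_names=list(train.columns),
        variant=variant,
        scaler_mean=None if not scale_features else work.scaler_mean,
        scaler_scale=None if not scale_features else work.scaler_scale,
        diagnostics=diagnostics,
    )


def predict(model: GTskModel, x: FeatureMatrix) -> np.ndarray:
    """Predict Kt/V for new patients with a fitted model."""
    if list(x.columns) != list(model.feature_names):
        missing = set(model.feature_names) - set(x.columns)
        extra = set(x.columns) - set(model.feature_names)
        if missing or extra:
            raise SchemaError(
                f"feature mismatch: missing {sorted(missing)}, unknown {sorted(extra)}"
            )
        # same names, different order: realign
        order = [list(x.columns).index(c) for c in model.feature_names]
        x = FeatureMatrix(X=x.X[:, order], columns=list(model.feature_names), y=x.y)
    if model.scaler_mean is not None:
        x = apply_scaler(x, model.scaler_mean, model.scaler_scale)
    mapped = antecedent.map_features(model.rule_base, x)
    return antecedent.predict_output(mapped, model.p_g)


def _arr(a: np.ndarray | None) -> list | None:
    return None if a is None else np.asarray(a, dtype=float).tolist()


def save_model(model: GTskModel, path) -> None:
    """Serialize a model to versioned JSON (lossless float round-trip)."""
    doc = {
        "schema": MODEL_SCHEMA,
        "variant": model.variant,
        "hyperparams": asdict(model.hyperparams),
        "feature_names": list(model.feature_names),
        "rule_base": {
            "centers": _arr(model.rule_base.centers),
            "widths": _arr(model.rule_base.widths),
            "h": model.rule_base.h,
            "column_order": "per-rule blocks k=1..K, bias first then features",
        },
        "p_g": _arr(model.p_g),
        "scaler_mean": _arr(model.scaler_mean),
        "scaler_scale": _arr(model.scaler_scale),
        "diagnostics": model.diagnostics,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path) -> GTskModel:
    """Load a model saved by :func:`save_model`."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise FormatError(f"not a valid model file: {path} ({exc})") from exc
    if not isinstance(doc, dict) or doc.get("schema") != MODEL_SCHEMA:
        raise FormatError(
            f"unrecognized model schema {doc.get('schema') if isinstance(doc, dict) else None!r}"
        )
    try:
        rb = FuzzyRuleBase(
            centers=np.asarray(doc["rule_base"]["centers"], dtype=float),
            widths=np.asarray(doc["rule_base"]["widths"], dtype=float),
            h=float(doc["rule_base"]["h"]),
        )
        model = GTskModel(
            rule_base=rb,
            p_g=np.asarray(doc["p_g"], dtype=float),
            hyperparams=Hyperparams(**doc["hyperparams"]),
            feature_names=list(doc["feature_names"]),
            variant=doc["variant"],
            scaler_mean=None
            if doc["scaler_mean"] is None
            else np.asarray(doc["scaler_mean"], dtype=float),
            scaler_scale=None
            if doc["scaler_scale"] is None
            else np.asarray(doc["scaler_scale"], dtype=float),
            diagnostics=doc.get("diagnostics", {}),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"truncated or corrupted model file: {path}") from exc
    return model
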