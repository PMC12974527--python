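"""Instability classification: nested cross-validation, training, prediction.

Four model families are evaluated on the labeled proteins — L1 logistic
regression, random forest, a single-hidden-layer perceptron, and
gradient-boosted trees (XGBoost) — by repeated nested cross-validation:
for each round a fresh stratified outer split is drawn; within every
outer training set an inner stratified grid search picks the
hyperparameters maximizing mean inner average precision; the winner is
refit on the whole outer training set with inverse-class-frequency
sample weights (normalized to mean one) and scored on the held-out
fold.  Imputation and scaling live inside the estimator pipeline, so
they are refit on every training fold and never see held-out data.

Mean average precision (MAP) is reported both as the grand mean over
all round x fold average precisions (primary) and as the mean of round
means; the baseline is the positive-class prevalence.  The selected
family is refit on all labeled data and used to assign instability
probabilities to proteins never quantified in the screens.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from .enrichment import RankTestResult, mann_whitney
from .errors import ConfigError, InputError
from .mining import AnnotationCatalog

FAMILIES = ("l1_logistic", "random_forest", "mlp", "gradient_boosted_trees")

DEFAULT_GRIDS = {
    "l1_logistic": {"clf__C": [0.01, 0.1, 1.0, 10.0]},
    "random_forest": {"clf__n_estimators": [200, 500],
                      "clf__max_depth": [None, 8]},
    "mlp": {"clf__hidden_layer_sizes": [(32,), (128,)]},
    "gradient_boosted_trees": {"clf__max_depth": [3, 6],
                               "clf__learning_rate": [0.05, 0.1],
                               "clf__n_estimators": [200, 500]},
}

#: whether each family's estimator accepts per-sample weights
_SUPPORTS_WEIGHT = {"l1_logistic": True, "random_forest": True,
                    "mlp": False, "gradient_boosted_trees": True}


@dataclass
class CVSpec:
    """Nested cross-validation design."""

    rounds: int = 10
    outer_folds: int = 10
    inner_folds: int = 10
    families: tuple = FAMILIES
    grids: dict = field(default_factory=lambda: DEFAULT_GRIDS)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ConfigError("rounds must be >= 1")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ConfigError("folds must be >= 2")
        unknown = set(self.families) - set(FAMILIES)
        if unknown:
            raise ConfigError(f"unknown model families: {sorted(unknown)}")


def _build_pipeline(family: str, random_state: int) -> Pipeline:
    if family == "l1_logistic":
        clf = LogisticRegression(penalty="l1", solver="liblinear", max_iter=2000,
                                 random_state=random_state)
        steps = [("impute", SimpleImputer(strategy="median")),
                 ("scale", StandardScaler()), ("clf", clf)]
    elif family == "random_forest":
        clf = RandomForestClassifier(n_jobs=1, random_state=random_state)
        steps = [("impute", SimpleImputer(strategy="median")), ("clf", clf)]
    elif family == "mlp":
        clf = MLPClassifier(early_stopping=True, max_iter=300,
                            random_state=random_state)
        steps = [("impute", SimpleImputer(strategy="median")),
                 ("scale", StandardScaler()), ("clf", clf)]
    elif family == "gradient_boosted_trees":
        clf = XGBClassifier(tree_method="hist", n_jobs=1, eval_metric="logloss",
                            random_state=random_state)
        steps = [("impute", SimpleImputer(strategy="median")), ("clf", clf)]
    else:
        raise ConfigError(f"unknown family {family!r}")
    return Pipeline(steps)


def _sample_weights(y: np.ndarray) -> np.ndarray:
    """Inverse class frequency, normalized to mean 1."""
    counts = np.bincount(y, minlength=2).astype(float)
    w = 1.0 / counts[y]
    return w / w.mean()


def _check_xy(X: pd.DataFrame, y: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    if not X.index.equals(y.index):
        y = y.reindex(X.index)
        if y.isna().any():
            raise InputError("labels missing for some feature-table proteins")
    yv = y.to_numpy(dtype=int)
    if set(np.unique(yv)) != {0, 1}:
        raise InputError("labels must contain both classes (0 and 1)")
    return X.to_numpy(dtype=float), yv


@dataclass
class CVReport:
    folds: pd.DataFrame            # round, outer_fold, family, ap, roc_auc, params
    summary: pd.DataFrame          # per family: map, roc_auc, map_of_round_means
    baseline_precision: float

    def best_family(self) -> str:
        return self.summary.sort_values("map", ascending=False).index[0]

    def to_json(self, path) -> None:
        payload = {
            "baseline_precision": self.baseline_precision,
            "summary": self.summary.reset_index().to_dict(orient="records"),
            "folds": self.folds.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)


def nested_cv_evaluate(X: pd.DataFrame, y: pd.Series, spec: CVSpec) -> CVReport:
    """Repeated nested CV over all configured model families."""
    Xv, yv = _check_xy(X, y)
    n_pos = int(yv.sum())
    if n_pos < spec.outer_folds:
        raise InputError(
            f"only {n_pos} positives for {spec.outer_folds} outer folds; "
            "reduce outer_folds or enlarge the data")
    baseline = n_pos / len(yv)

    rows = []
    for rnd in range(spec.rounds):
        seed_r = spec.seed + rnd
        outer = StratifiedKFold(n_splits=spec.outer_folds, shuffle=True,
                                random_state=seed_r)
        for fold, (tr, te) in enumerate(outer.split(Xv, yv)):
            y_tr, y_te = yv[tr], yv[te]
            if y_te.sum() == 0 or y_tr.sum() == 0:
                raise InputError("an outer fold has zero positives; n too small")
            for family in spec.families:
                pipe = _build_pipeline(family, random_state=seed_r)
                inner = StratifiedKFold(n_splits=spec.inner_folds, shuffle=True,
                                        random_state=seed_r)
                search = GridSearchCV(pipe, spec.grids[family],
                                      scoring="average_precision", cv=inner,
                                      n_jobs=1, refit=True, error_score="raise")
                fit_params = {}
                if _SUPPORTS_WEIGHT[family]:
                    fit_params["clf__sample_weight"] = _sample_weights(y_tr)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    search.fit(Xv[tr], y_tr, **fit_params)
                proba = search.predict_proba(Xv[te])[:, 1]
                rows.append({
                    "round": rnd, "outer_fold": fold, "family": family,
                    "average_precision": average_precision_score(y_te, proba),
                    "roc_auc": roc_auc_score(y_te, proba),
                    "best_params": json.dumps(search.best_params_, default=str),
                })

    folds = pd.DataFrame(rows)
    grand = folds.groupby("family")["average_precision"].mean().rename("map")
    auc = folds.groupby("family")["roc_auc"].mean().rename("roc_auc")
    round_means = (folds.groupby(["family", "round"])["average_precision"].mean()
                   .groupby("family").mean().rename("map_of_round_means"))
    summary = pd.concat([grand, auc, round_means], axis=1)
    summary["fold_over_baseline"] = summary["map"] / baseline
    return CVReport(folds=folds, summary=summary, baseline_precision=baseline)


# --------------------------------------------------------------------------
# final training and prediction
# --------------------------------------------------------------------------

def _validate_hyperparams(family: str, hyperparams: dict, grids: dict) -> None:
    grid = grids[family]
    for key, val in hyperparams.items():
        if key not in grid:
            raise ConfigError(f"hyperparameter {key!r} not in the {family} grid")
        if val not in grid[key]:
            raise ConfigError(
                f"value {val!r} for {key!r} outside the declared grid {grid[key]}")


@dataclass
class ModelArtifact:
    model: Pipeline
    family: str
    feature_names: list
    hyperparams: dict
    training_ids: list
    seed: int
    spec_hash: str

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ModelArtifact":
        return joblib.load(path)


def train_final(X: pd.DataFrame, y: pd.Series, family: str,
                hyperparams: dict | None = None,
                spec: CVSpec | None = None) -> ModelArtifact:
    """Fit the selected family on all labeled data.

    When ``hyperparams`` is None a full-data grid search using the inner
    fold scheme selects them; otherwise they must come from the declared
    grid.
    """
    spec = spec or CVSpec()
    if family not in FAMILIES:
        raise ConfigError(f"unknown family {family!r}")
    Xv, yv = _check_xy(X, y)
    pipe = _build_pipeline(family, random_state=spec.seed)
    fit_params = {}
    if _SUPPORTS_WEIGHT[family]:
        fit_params["clf__sample_weight"] = _sample_weights(yv)
    if hyperparams is None:
        inner = StratifiedKFold(n_splits=spec.inner_folds, shuffle=True,
                                random_state=spec.seed)
        search = GridSearchCV(pipe, spec.grids[family],
                              scoring="average_precision", cv=inner, n_jobs=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            search.fit(Xv, yv, **fit_params)
        hyperparams = search.best_params_
        model = search.best_estimator_
    else:
        _validate_hyperparams(family, hyperparams, spec.grids)
        pipe.set_params(**hyperparams)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pipe.fit(Xv, yv, **fit_params)
        model = pipe
    spec_hash = hashlib.sha256(
        json.dumps({"family": family, "hyperparams": hyperparams,
                    "seed": spec.seed, "features": list(X.columns)},
                   sort_keys=True, default=str).encode()).hexdigest()[:16]
    return ModelArtifact(model=model, family=family,
                         feature_names=list(X.columns),
                         hyperparams=dict(hyperparams),
                         training_ids=list(X.index), seed=spec.seed,
                         spec_hash=spec_hash)


def predict_unseen(artifact: ModelArtifact, X_unseen: pd.DataFrame,
                   threshold: float = 0.5) -> pd.DataFrame:
    """Score proteins the model never saw.

    Returns a table with ``probability_unstable`` and ``predicted_class``
    at the given threshold.  Refuses feature-manifest mismatches and any
    overlap with training ids (leakage guard).
    """
    missing = [c for c in artifact.feature_names if c not in X_unseen.columns]
    if missing:
        raise InputError(f"feature table missing manifest features: {missing[:5]}")
    overlap = set(X_unseen.index) & set(artifact.training_ids)
    if overlap:
        raise InputError(
            f"{len(overlap)} unseen proteins overlap the training set "
            f"(e.g. {sorted(overlap)[:3]})")
    if len(X_unseen) == 0:
        return pd.DataFrame(columns=["probability_unstable", "predicted_class"],
                            index=X_unseen.index)
    Xv = X_unseen[artifact.feature_names].to_numpy(dtype=float)
    proba = artifact.model.predict_proba(Xv)[:, 1]
    return pd.DataFrame({
        "probability_unstable": proba,
        "predicted_class": (proba >= threshold).astype(int),
    }, index=X_unseen.index.rename("protein_id"))


def score_group_separation(predictions: pd.DataFrame,
                           catalog: AnnotationCatalog) -> RankTestResult:
    """Do cataloged substrates receive higher instability probabilities?

    Splits prediction probabilities by catalog membership and runs the
    two-sided Mann–Whitney U test (annotated vs unannotated).
    """
    annotated = catalog.annotated_ids()
    mask = predictions.index.isin(annotated)
    scores_a = predictions.loc[mask, "probability_unstable"]
    scores_b = predictions.loc[~mask, "probability_unstable"]
    if len(scores_a) == 0 or len(scores_b) == 0:
        raise InputError("both annotated and unannotated groups must be nonempty")
    return mann_whitney(scores_a, scores_b)


def fold_over_baseline(map_score: float, baseline_precision: float) -> float:
    """MAP expressed as a fold over the positive-class prevalence."""
    if baseline_precision <= 0:
        raise InputError("baseline precision must be > 0")
    return map_score / baseline_precision
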