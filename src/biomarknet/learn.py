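"""Tree-ensemble classifiers, validation battery, and centralities.

Two decision-tree ensemble families are trained on the labelled
neighbour-target pairs: Random Forest (scikit-learn) and gradient-boosted
trees (XGBoost).  With four training scopes (three networks plus their
combination) and four disorder-annotation scopes (DisProt, AlphaFold,
IUPred, all) this spans 32 models; the class-1 probabilities of a scope's
eight models feed the rank-based Biomarker Probability Score.

Hyperparameters are chosen by successive halving over randomly sampled
configurations: all sampled candidates are scored by cross-validated
accuracy on a small stratified subsample, the better half survives to a
larger subsample, and so on until one winner is refit on the full
training data.  Every random operation takes an explicit seed and is
bit-reproducible run to run.

Betweenness centrality is computed on the directed unweighted graph.  The
bridging role of a node is approximated by ``bridgeness_proxy`` =
betweenness x bridging coefficient, where the bridging coefficient is the
inverse-degree ratio of Hwang et al. (a node bridges when it is itself
low-degree relative to its neighbours); this is a documented stand-in for
module-overlap bridgeness values that require an external modularisation
tool, and the column name avoids claiming equivalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (accuracy_score, f1_score, precision_score,
                             recall_score, roc_auc_score)
from sklearn.model_selection import (LeaveOneOut, StratifiedKFold,
                                     cross_val_predict, train_test_split)
from xgboost import XGBClassifier

from .features import Dataset
from .motifs import SignedNetwork

__all__ = [
    "ModelSpec",
    "ValidationReport",
    "node_centralities",
    "make_estimator",
    "train_model",
    "halving_random_search",
    "validate",
    "ablation_by_feature_group",
    "cross_network_validate",
    "predict_probabilities",
    "default_feature_groups",
    "DEFAULT_GRID",
    "ALGORITHMS",
    "ANNOTATION_SCOPES",
]

ALGORITHMS = ("random_forest", "gradient_boosted_trees")
ANNOTATION_SCOPES = ("disprot", "alphafold", "iupred", "all")

#: hyperparameter sampling grid for the halving random search
DEFAULT_GRID: dict[str, dict[str, list]] = {
    "random_forest": {
        "n_estimators": [100, 200, 300, 500, 700, 1000],
        "max_depth": [2, 3, 4, 6, 8, 10, None],
        "max_features": ["sqrt", "log2", None],
        "min_samples_leaf": [1, 2, 4],
    },
    "gradient_boosted_trees": {
        "n_estimators": [100, 200, 300, 500, 700, 1000],
        "max_depth": [2, 3, 4, 6, 8, 10],
        "learning_rate": [0.01, 0.03, 0.1, 0.2, 0.3],
        "subsample": [0.5, 0.7, 0.85, 1.0],
        "colsample_bytree": [0.5, 0.7, 1.0],
    },
}


class LearnError(ValueError):
    pass


class DegenerateLabelsError(LearnError):
    pass


class SchemaError(LearnError):
    pass


@dataclass
class ModelSpec:
    """One trained-model configuration."""

    algorithm: str
    hyperparameters: dict = field(default_factory=dict)
    random_state: int = 0
    training_scope: str = "combined"
    annotation_scope: str = "all"

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise LearnError(f"unknown algorithm {self.algorithm!r}")

    @property
    def name(self) -> str:
        return f"{self.algorithm}:{self.training_scope}:{self.annotation_scope}"


@dataclass
class ValidationReport:
    scheme: str
    metrics: dict[str, float]
    per_fold: list[dict[str, float]] = field(default_factory=list)
    probabilities: np.ndarray | None = None   # held-out class-1 probs per record

    def to_dict(self) -> dict:
        return {"scheme": self.scheme, "metrics": self.metrics,
                "per_fold": self.per_fold}


# ---------------------------------------------------------------------------
# centralities

def node_centralities(net: SignedNetwork) -> dict[str, tuple[float, float]]:
    """Betweenness and bridgeness-proxy centrality for every node.

    Betweenness is normalised to [0, 1] on the directed sign-blind graph.
    The bridging coefficient uses total degree on the undirected skeleton;
    isolated nodes score 0 on both.
    """
    g = net.to_networkx()
    betweenness = nx.betweenness_centrality(g, normalized=True)
    adj = net.undirected_adjacency()
    out: dict[str, tuple[float, float]] = {}
    for node in sorted(net.nodes):
        deg = len(adj[node])
        if deg == 0:
            out[node] = (0.0, 0.0)
            continue
        inv_neigh = sum(1.0 / len(adj[x]) for x in adj[node])
        bridging_coef = (1.0 / deg) / inv_neigh if inv_neigh > 0 else 0.0
        bet = betweenness.get(node, 0.0)
        out[node] = (bet, bet * bridging_coef)
    return out


# ---------------------------------------------------------------------------
# estimators

def make_estimator(spec: ModelSpec):
    """Instantiate the scikit-learn / XGBoost estimator for a spec."""
    params = dict(spec.hyperparameters)
    if spec.algorithm == "random_forest":
        params.setdefault("n_estimators", 300)
        return RandomForestClassifier(random_state=spec.random_state,
                                      n_jobs=1, **params)
    params.setdefault("n_estimators", 300)
    params.setdefault("learning_rate", 0.1)
    params.setdefault("max_depth", 4)
    return XGBClassifier(random_state=spec.random_state, n_jobs=1,
                         eval_metric="logloss", **params)


def _check_labelled(dataset: Dataset) -> tuple[np.ndarray, np.ndarray]:
    lab = dataset.labelled()
    X, y = lab.X, lab.y.astype(int)
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError(
            "training data must contain both classes")
    return X, y


def train_model(dataset: Dataset, spec: ModelSpec):
    """Fit the spec's estimator on the dataset's labelled rows.

    Rows are put in canonical (sorted pair-key) order before fitting so
    the fitted model does not depend on how the caller ordered them.
    """
    lab = dataset.labelled().table
    order = np.lexsort((lab["network"].to_numpy(),
                        lab["target_id"].to_numpy(),
                        lab["neighbour_id"].to_numpy()))
    X, y = _check_labelled(dataset)
    est = make_estimator(spec)
    est.fit(X[order], y[order])
    return est


# ---------------------------------------------------------------------------
# hyperparameter search

def _sample_candidates(grid: Mapping[str, list], budget: int,
                       rng: np.random.Generator) -> list[dict]:
    keys = sorted(grid)
    return [{k: grid[k][rng.integers(len(grid[k]))] for k in keys}
            for _ in range(budget)]


def _cv_accuracy(est, X, y, seed: int, n_splits: int = 3) -> float:
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    scores = []
    for train_idx, test_idx in cv.split(X, y):
        est_ = est.__class__(**est.get_params())
        est_.fit(X[train_idx], y[train_idx])
        scores.append(accuracy_score(y[test_idx], est_.predict(X[test_idx])))
    return float(np.mean(scores))


def halving_random_search(dataset: Dataset, algorithm: str, budget: int = 16,
                          seed: int = 0,
                          grid: Mapping[str, list] | None = None,
                          ) -> tuple[ModelSpec, object, list[dict]]:
    """Successive-halving hyperparameter search over random candidates.

    ``budget`` candidates are sampled from the grid.  Each round scores
    the surviving candidates by 3-fold cross-validated accuracy on a
    stratified subsample that doubles every round (starting from roughly
    ``n / 2**rounds`` records, never below 30 or the full data); the top
    half survives.  The winner is refit on the full labelled data.

    Returns ``(spec, fitted_estimator, trace)`` where the trace records
    every (round, candidate, score).
    """
    grid = grid or DEFAULT_GRID[algorithm]
    X, y = _check_labelled(dataset)
    rng = np.random.default_rng(seed)
    candidates = _sample_candidates(grid, budget, rng)
    n = len(y)
    n_rounds = max(1, math.ceil(math.log2(max(1, len(candidates)))))
    trace: list[dict] = []
    for rnd in range(n_rounds):
        frac = 1.0 / (2 ** (n_rounds - 1 - rnd))
        n_sub = max(min(n, 30), int(round(frac * n)))
        if n_sub < n:
            sub_idx, _ = train_test_split(
                np.arange(n), train_size=n_sub, stratify=y,
                random_state=seed + rnd)
        else:
            sub_idx = np.arange(n)
        scored = []
        for cand in candidates:
            spec = ModelSpec(algorithm=algorithm, hyperparameters=cand,
                             random_state=seed)
            score = _cv_accuracy(make_estimator(spec), X[sub_idx], y[sub_idx],
                                 seed=seed)
            scored.append((score, cand))
            trace.append({"round": rnd, "n_samples": int(n_sub),
                          "params": dict(cand), "cv_accuracy": score})
        scored.sort(key=lambda sc: (-sc[0], sorted(sc[1].items()).__repr__()))
        keep = max(1, len(scored) // 2)
        candidates = [cand for _, cand in scored[:keep]]
        if len(candidates) == 1 and rnd < n_rounds - 1:
            break
    winner = ModelSpec(algorithm=algorithm, hyperparameters=candidates[0],
                       random_state=seed)
    est = make_estimator(winner)
    est.fit(X, y)
    return winner, est, trace


# ---------------------------------------------------------------------------
# validation battery

def _metrics(y_true, y_pred, y_prob) -> dict[str, float]:
    out = {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "precision": float(precision_score(y_true, y_pred, zero_division=0)),
        "recall": float(recall_score(y_true, y_pred, zero_division=0)),
        "f1": float(f1_score(y_true, y_pred, zero_division=0)),
    }
    if len(np.unique(y_true)) == 2:
        out["roc_auc"] = float(roc_auc_score(y_true, y_prob))
    else:
        out["roc_auc"] = float("nan")
    return out


def validate(dataset: Dataset, spec: ModelSpec, scheme: str = "loocv",
             seed: int = 0, n_splits: int = 5, n_repeats: int = 100,
             test_size: float = 0.30) -> ValidationReport:
    """Run one validation scheme and report the standard metrics.

    Schemes: ``loocv`` (one held-out class-1 probability per record, kept
    on the report for downstream score fusion), ``repeated_kfold``
    (defaults to 100 x stratified 5-fold with re-shuffled folds per
    repeat; metrics averaged over repeats), ``split_70_30`` (stratified
    single split), ``resubstitution`` (fit and evaluate on the same data;
    degenerate, for sanity checks only).
    """
    X, y = _check_labelled(dataset)
    if len(y) < 10 and scheme != "resubstitution":
        raise LearnError(f"need at least 10 labelled records, have {len(y)}")
    # canonical row order (sorted pair keys) so held-out probabilities do
    # not depend on how the caller ordered the records; results are mapped
    # back to the caller's order
    lab = dataset.labelled().table
    order = np.lexsort((lab["network"].to_numpy(),
                        lab["target_id"].to_numpy(),
                        lab["neighbour_id"].to_numpy()))
    inverse = np.empty_like(order)
    inverse[order] = np.arange(len(order))
    X, y = X[order], y[order]
    est = make_estimator(spec)

    if scheme == "loocv":
        prob = cross_val_predict(est, X, y, cv=LeaveOneOut(),
                                 method="predict_proba")[:, 1]
        pred = (prob >= 0.5).astype(int)
        return ValidationReport("loocv", _metrics(y, pred, prob),
                                probabilities=prob[inverse])

    if scheme == "repeated_kfold":
        per_fold = []
        probs = np.zeros(len(y))
        for rep in range(n_repeats):
            cv = StratifiedKFold(n_splits=n_splits, shuffle=True,
                                 random_state=seed + rep)
            _check_folds(cv, y)
            prob = cross_val_predict(est, X, y, cv=cv,
                                     method="predict_proba")[:, 1]
            probs += prob
            pred = (prob >= 0.5).astype(int)
            per_fold.append(_metrics(y, pred, prob))
        probs /= n_repeats
        mean = {k: float(np.mean([m[k] for m in per_fold]))
                for k in per_fold[0]}
        return ValidationReport("repeated_kfold", mean, per_fold,
                                probabilities=probs[inverse])

    if scheme == "split_70_30":
        idx_train, idx_test = train_test_split(
            np.arange(len(y)), test_size=test_size, stratify=y,
            random_state=seed)
        est.fit(X[idx_train], y[idx_train])
        prob = est.predict_proba(X[idx_test])[:, 1]
        pred = (prob >= 0.5).astype(int)
        return ValidationReport("split_70_30",
                                _metrics(y[idx_test], pred, prob))

    if scheme == "resubstitution":
        est.fit(X, y)
        prob = est.predict_proba(X)[:, 1]
        pred = (prob >= 0.5).astype(int)
        return ValidationReport("resubstitution", _metrics(y, pred, prob),
                                probabilities=prob[inverse])

    raise LearnError(f"unknown validation scheme {scheme!r}")


def _check_folds(cv, y) -> None:
    for train_idx, _ in cv.split(np.zeros_like(y), y):
        if len(np.unique(y[train_idx])) < 2:
            raise LearnError("a fold lost one of the classes; "
                             "use fewer splits or more data")


def ablation_by_feature_group(dataset: Dataset,
                              groups: Mapping[str, Sequence[str]],
                              spec: ModelSpec, seed: int = 0,
                              scheme: str = "loocv",
                              ) -> dict[str, ValidationReport]:
    """One validation report per feature subset (LOOCV by default)."""
    reports = {}
    for name, cols in groups.items():
        if not cols:
            raise LearnError(f"feature group {name!r} is empty")
        sub = dataset.restrict_features(list(cols))
        reports[name] = validate(sub, spec, scheme=scheme, seed=seed)
    return reports


def default_feature_groups(feature_names: Sequence[str]) -> dict[str, list[str]]:
    """The standard ablation groups, selected by column-name convention.

    ``biological`` covers disorder contents/scores (including third-node
    disorder aggregates), target status and drug modality; ``topological``
    covers network participation, motif counts, edge signs, third-node
    target counts and centralities.  ``centralities`` and ``motif_counts``
    are the two small topological subgroups.
    """
    bio_markers = ("disprot", "alphafold", "iupred", "is_target",
                   "modality")
    centralities = [n for n in feature_names
                    if "betweenness" in n or "bridgeness" in n]
    motif_counts = [n for n in feature_names
                    if n in ("n_triangles", "n_unbalanced", "n_cycles")]
    biological = [n for n in feature_names
                  if any(m in n for m in bio_markers)]
    topological = [n for n in feature_names if n not in biological]
    return {"biological": biological, "topological": topological,
            "centralities": centralities, "motif_counts": motif_counts}


def cross_network_validate(train_dataset: Dataset, test_dataset: Dataset,
                           spec: ModelSpec) -> ValidationReport:
    """Fit on one network's labelled rows, evaluate on another's."""
    if list(train_dataset.feature_names) != list(test_dataset.feature_names):
        raise SchemaError("feature schemas differ between datasets")
    est = train_model(train_dataset, spec)
    X_test, y_test = _check_labelled(test_dataset)
    prob = est.predict_proba(X_test)[:, 1]
    pred = (prob >= 0.5).astype(int)
    return ValidationReport("cross_network", _metrics(y_test, pred, prob),
                            probabilities=prob)


def predict_probabilities(dataset: Dataset,
                          models: Sequence[tuple[ModelSpec, object]],
                          ) -> pd.DataFrame:
    """Class-1 probability of every pair under every fitted model.

    Rows follow the dataset order (indexed by the pair key columns);
    columns follow the supplied model order and are named by spec.
    """
    if not models:
        raise LearnError("no models supplied")
    out = {}
    for spec, est in models:
        n_feat = getattr(est, "n_features_in_", None)
        if n_feat is not None and n_feat != len(dataset.feature_names):
            raise SchemaError(
                f"model {spec.name} expects {n_feat} features, dataset "
                f"has {len(dataset.feature_names)}")
        out[spec.name] = est.predict_proba(dataset.X)[:, 1]
    idx = pd.MultiIndex.from_frame(
        dataset.table[["neighbour_id", "target_id", "network"]])
    return pd.DataFrame(out, index=idx)
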