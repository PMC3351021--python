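"""The three-tier top-down classifier cascade and the direct sub-class model.

Model 1 routes a query top-down: level 1 separates enzymes from
non-enzymes, level 2 assigns surviving rows one of the six main classes,
and level 3 holds one sub-class forest per main class, trained on that
class's level-2 training rows relabeled by sub-class. Model 2 is a single
multi-class forest over all sub-class labels.

The forest learner is scikit-learn's :class:`RandomForestClassifier`
(bootstrap sampling, per-node random feature subsets, majority vote, OOB
estimate); this module owns the cascade logic, parameter tuning, routing,
and reproducibility. Feature values are used unnormalized. Vote ties are
broken toward the lowest class label.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold

from .evaluation import ConfusionSummary
from .records import NON_ENZYME, ECLabel

ENZYME = "enzyme"

DEFAULT_LEVEL_PARAMS = {
    "level1": {"ntree": 200, "mtry": 25},
    "level2": {"ntree": 200, "mtry": 7},
    "level3": {"ntree": 200, "mtry": 7},
}
DEFAULT_DIRECT_PARAMS = {"ntree": 200, "mtry": 5}


@dataclass(frozen=True)
class ForestParams:
    ntree: int = 200
    mtry: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.mtry < 1:
            raise ValueError("mtry must be >= 1")


class _ConstantClassifier:
    """Degenerate stand-in when a training split holds a single label."""

    def __init__(self, label: str):
        self.classes_ = np.array([label])

    def predict(self, X):
        return np.repeat(self.classes_, len(X))

    def predict_proba(self, X):
        return np.ones((len(X), 1))


def train_forest(
    table: pd.DataFrame,
    labels: Sequence[str],
    params: ForestParams,
) -> Tuple[RandomForestClassifier, float]:
    """Fit a random forest and report its out-of-bag error fraction."""
    labels = np.asarray([str(lab) for lab in labels])
    if len(labels) != len(table):
        raise ValueError("labels length must match table rows")
    if len(set(labels)) < 2:
        raise ValueError("training data must contain at least 2 classes")
    if params.mtry > table.shape[1]:
        raise ValueError(
            f"mtry={params.mtry} exceeds feature count {table.shape[1]}"
        )
    clf = RandomForestClassifier(
        n_estimators=params.ntree,
        max_features=params.mtry,
        oob_score=True,
        bootstrap=True,
        random_state=params.seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB")
        clf.fit(table.to_numpy(), labels)
    return clf, 1.0 - float(clf.oob_score_)


def tune_parameters(
    table: pd.DataFrame,
    labels: Sequence[str],
    ntree_grid: Sequence[int],
    mtry_grid: Sequence[int],
    seed: int = 0,
) -> Tuple[ForestParams, Dict[Tuple[int, int], float]]:
    """Grid search over (ntree, mtry) minimizing OOB error.

    Ties break toward smaller ntree, then smaller mtry. The full error
    surface is returned for plotting.
    """
    if not ntree_grid or not mtry_grid:
        raise ValueError("parameter grids must be nonempty")
    surface: Dict[Tuple[int, int], float] = {}
    for ntree in ntree_grid:
        for mtry in mtry_grid:
            _, oob = train_forest(table, labels, ForestParams(ntree, mtry, seed))
            surface[(ntree, mtry)] = oob
    best_key = min(surface, key=lambda k: (surface[k], k[0], k[1]))
    return ForestParams(best_key[0], best_key[1], seed), surface


@dataclass
class Prediction:
    """One routed query: level-1 verdict, then main/sub class when enzyme."""

    id: str
    is_enzyme: bool
    enzyme_vote: float
    main_class: Optional[int] = None
    main_votes: Optional[Dict[str, float]] = None
    sub_class: Optional[str] = None
    sub_votes: Optional[Dict[str, float]] = None


@dataclass
class CascadeModel:
    level1: object
    level2: object
    level3: Dict[int, object]
    params: Dict[str, ForestParams]
    oob_errors: Dict[str, float]
    feature_names: Tuple[str, ...]
    schema_version: str
    metadata: Dict[str, object] = field(default_factory=dict)


@dataclass
class DirectModel:
    classifier: object
    params: ForestParams
    oob_error: float
    feature_names: Tuple[str, ...]
    schema_version: str
    metadata: Dict[str, object] = field(default_factory=dict)


def _check_schema(feature_names: Sequence[str], table: pd.DataFrame) -> None:
    missing = [c for c in feature_names if c not in table.columns]
    extra = [c for c in table.columns if c not in feature_names]
    if missing or extra:
        raise ValueError(
            f"feature schema mismatch: missing columns {missing}, extra columns {extra}"
        )


def _main_class_str(label: ECLabel) -> str:
    return str(label.main_class)


def train_cascade(
    enzyme_table: pd.DataFrame,
    enzyme_labels: Mapping[str, ECLabel],
    nonenzyme_table: pd.DataFrame,
    params_by_level: Optional[Mapping[str, ForestParams]] = None,
    seed: int = 0,
) -> CascadeModel:
    """Train the three-tier model.

    Level 1 trains on a balanced enzyme/non-enzyme set (equal counts,
    sampled with the run seed when the pools differ); level 2 on enzymes by
    main class; level-3 forest *k* on level-2 training rows of main class
    *k* relabeled by sub-class. A main class with a single sub-class gets a
    constant predictor, flagged in the metadata.
    """
    params = {
        lvl: ForestParams(seed=seed, **DEFAULT_LEVEL_PARAMS[lvl])
        for lvl in ("level1", "level2", "level3")
    }
    if params_by_level:
        params.update(params_by_level)

    labels = [enzyme_labels[i] for i in enzyme_table.index]
    for i, lab in zip(enzyme_table.index, labels):
        if not isinstance(lab, ECLabel) or lab.sub_class is None:
            raise ValueError(f"enzyme {i!r} lacks a sub-class label")

    rng = np.random.default_rng(seed)
    n_bal = min(len(enzyme_table), len(nonenzyme_table))
    enz_rows = enzyme_table
    non_rows = nonenzyme_table
    if len(enzyme_table) > n_bal:
        idx = rng.choice(len(enzyme_table), size=n_bal, replace=False)
        enz_rows = enzyme_table.iloc[np.sort(idx)]
    if len(nonenzyme_table) > n_bal:
        idx = rng.choice(len(nonenzyme_table), size=n_bal, replace=False)
        non_rows = nonenzyme_table.iloc[np.sort(idx)]
    level1_X = pd.concat([enz_rows, non_rows])
    level1_y = [ENZYME] * len(enz_rows) + [NON_ENZYME] * len(non_rows)
    level1, oob1 = train_forest(level1_X, level1_y, params["level1"])

    level2_y = [_main_class_str(lab) for lab in labels]
    level2, oob2 = train_forest(enzyme_table, level2_y, params["level2"])

    level3: Dict[int, object] = {}
    oob3: Dict[str, float] = {}
    constant_classes: List[int] = []
    for k in sorted({lab.main_class for lab in labels}):
        mask = [lab.main_class == k for lab in labels]
        sub_X = enzyme_table.loc[mask]
        sub_y = [lab.sub_class for lab, m in zip(labels, mask) if m]
        if len(set(sub_y)) < 2:
            level3[k] = _ConstantClassifier(sub_y[0])
            constant_classes.append(k)
            oob3[str(k)] = 0.0
        else:
            level3[k], oob3[str(k)] = train_forest(sub_X, sub_y, params["level3"])

    class_counts: Dict[str, int] = {}
    for lab in labels:
        class_counts[lab.sub_class] = class_counts.get(lab.sub_class, 0) + 1
    return CascadeModel(
        level1=level1,
        level2=level2,
        level3=level3,
        params=params,
        oob_errors={"level1": oob1, "level2": oob2, **{f"level3.{k}": v for k, v in oob3.items()}},
        feature_names=tuple(enzyme_table.columns),
        schema_version=enzyme_table.attrs.get("schema_version", "unknown"),
        metadata={
            "seed": seed,
            "class_counts": class_counts,
            "n_nonenzyme": int(len(nonenzyme_table)),
            "constant_level3_classes": constant_classes,
        },
    )


def _vote_row(clf, proba_row: np.ndarray) -> Dict[str, float]:
    return {str(c): float(p) for c, p in zip(clf.classes_, proba_row)}


def predict_cascade(model: CascadeModel, table: pd.DataFrame) -> List[Prediction]:
    """Route each row top-down; non-enzyme verdicts stop at level 1."""
    _check_schema(model.feature_names, table)
    X = table[list(model.feature_names)].to_numpy()
    ids = list(table.index)

    proba1 = model.level1.predict_proba(X)
    enzyme_col = list(model.level1.classes_).index(ENZYME)
    pred1 = model.level1.predict(X)
    proba2 = model.level2.predict_proba(X)
    pred2 = model.level2.predict(X)

    # level 3 batched per predicted main class
    sub_pred: Dict[int, np.ndarray] = {}
    sub_proba: Dict[int, np.ndarray] = {}
    row_pos: Dict[int, int] = {}
    enzyme_rows = np.flatnonzero(pred1 == ENZYME)
    for main in np.unique(pred2[enzyme_rows]).tolist():
        rows = enzyme_rows[pred2[enzyme_rows] == main]
        clf3 = model.level3[int(main)]
        sub_pred[int(main)] = clf3.predict(X[rows])
        sub_proba[int(main)] = clf3.predict_proba(X[rows])
        row_pos[int(main)] = 0

    out: List[Prediction] = []
    for i, seq_id in enumerate(ids):
        enzyme_vote = float(proba1[i, enzyme_col])
        if pred1[i] != ENZYME:
            out.append(Prediction(id=seq_id, is_enzyme=False, enzyme_vote=enzyme_vote))
            continue
        main = int(pred2[i])
        pos = row_pos[main]
        row_pos[main] = pos + 1
        clf3 = model.level3[main]
        out.append(
            Prediction(
                id=seq_id,
                is_enzyme=True,
                enzyme_vote=enzyme_vote,
                main_class=main,
                main_votes=_vote_row(model.level2, proba2[i]),
                sub_class=str(sub_pred[main][pos]),
                sub_votes=_vote_row(clf3, sub_proba[main][pos]),
            )
        )
    return out


def train_direct(
    enzyme_table: pd.DataFrame,
    sub_class_labels: Mapping[str, ECLabel],
    params: Optional[ForestParams] = None,
    nonenzyme_table: Optional[pd.DataFrame] = None,
    seed: int = 0,
) -> DirectModel:
    """Train the single-step sub-class model (optionally with a non-enzyme
    class when a background table is supplied)."""
    if params is None:
        params = ForestParams(seed=seed, **DEFAULT_DIRECT_PARAMS)
    y = []
    for i in enzyme_table.index:
        lab = sub_class_labels[i]
        if not isinstance(lab, ECLabel) or lab.sub_class is None:
            raise ValueError(f"enzyme {i!r} lacks a sub-class label")
        y.append(lab.sub_class)
    X = enzyme_table
    if nonenzyme_table is not None:
        X = pd.concat([enzyme_table, nonenzyme_table])
        y = y + [NON_ENZYME] * len(nonenzyme_table)
    clf, oob = train_forest(X, y, params)
    return DirectModel(
        classifier=clf,
        params=params,
        oob_error=oob,
        feature_names=tuple(enzyme_table.columns),
        schema_version=enzyme_table.attrs.get("schema_version", "unknown"),
        metadata={
            "seed": params.seed,
            "labels": sorted(set(y)),
            "includes_nonenzyme": nonenzyme_table is not None,
        },
    )


def predict_direct(model: DirectModel, table: pd.DataFrame) -> pd.DataFrame:
    _check_schema(model.feature_names, table)
    X = table[list(model.feature_names)].to_numpy()
    pred = model.classifier.predict(X)
    proba = model.classifier.predict_proba(X)
    vote = proba.max(axis=1)
    return pd.DataFrame(
        {"sub_class": pred, "vote": vote}, index=table.index
    )


def cross_validate(
    table: pd.DataFrame,
    labels: Sequence[str],
    k: int,
    params: ForestParams,
    seed: int = 0,
) -> ConfusionSummary:
    """Stratified k-fold cross-validation with pooled confusion counts.

    Every row is predicted exactly once by a model not trained on it.
    ``k`` equal to the row count degrades to leave-one-out (unstratified).
    """
    labels = np.asarray([str(lab) for lab in labels])
    if k < 2:
        raise ValueError("k must be >= 2")
    n = len(table)
    counts = pd.Series(labels).value_counts()
    if k == n:
        splitter = KFold(n_splits=n)
    else:
        if counts.min() < k:
            raise ValueError(
                f"class {counts.idxmin()!r} has only {counts.min()} rows; "
                f"use k <= {counts.min()}"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    X = table.to_numpy()
    y_pred = np.empty(n, dtype=object)
    for train_idx, test_idx in splitter.split(X, labels):
        clf, _ = train_forest(table.iloc[train_idx], labels[train_idx], params)
        y_pred[test_idx] = clf.predict(X[test_idx])
    return ConfusionSummary.from_predictions(list(labels), list(y_pred))


# --- persistence -----------------------------------------------------------

_MANIFEST = "manifest.json"


def save_model(model: Union[CascadeModel, DirectModel], directory: Union[str, Path]) -> None:
    """Persist a model as a directory: JSON manifest + joblib classifiers."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if isinstance(model, CascadeModel):
        manifest = {
            "kind": "cascade",
            "schema_version": model.schema_version,
            "feature_names": list(model.feature_names),
            "params": {k: asdict(v) for k, v in model.params.items()},
            "oob_errors": model.oob_errors,
            "metadata": model.metadata,
            "level3_keys": sorted(model.level3),
        }
        joblib.dump(model.level1, directory / "level1.joblib")
        joblib.dump(model.level2, directory / "level2.joblib")
        for key, clf in model.level3.items():
            joblib.dump(clf, directory / f"level3_{key}.joblib")
    else:
        manifest = {
            "kind": "direct",
            "schema_version": model.schema_version,
            "feature_names": list(model.feature_names),
            "params": asdict(model.params),
            "oob_error": model.oob_error,
            "metadata": model.metadata,
        }
        joblib.dump(model.classifier, directory / "direct.joblib")
    with open(directory / _MANIFEST, "w", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=1)


def load_model(directory: Union[str, Path]) -> Union[CascadeModel, DirectModel]:
    directory = Path(directory)
    with open(directory / _MANIFEST, encoding="utf-8") as handle:
        manifest = json.load(handle)
    if manifest["kind"] == "cascade":
        return CascadeModel(
            level1=joblib.load(directory / "level1.joblib"),
            level2=joblib.load(directory / "level2.joblib"),
            level3={
                int(k): joblib.load(directory / f"level3_{k}.joblib")
                for k in manifest["level3_keys"]
            },
            params={k: ForestParams(**v) for k, v in manifest["params"].items()},
            oob_errors=manifest["oob_errors"],
            feature_names=tuple(manifest["feature_names"]),
            schema_version=manifest["schema_version"],
            metadata=manifest["metadata"],
        )
    if manifest["kind"] == "direct":
        return DirectModel(
            classifier=joblib.load(directory / "direct.joblib"),
            params=ForestParams(**manifest["params"]),
            oob_error=manifest["oob_error"],
            feature_names=tuple(manifest["feature_names"]),
            schema_version=manifest["schema_version"],
            metadata=manifest["metadata"],
        )
    raise ValueError(f"unknown model kind {manifest['kind']!r}")


def predictions_to_frame(predictions: Sequence[Prediction]) -> pd.DataFrame:
    rows = []
    for p in predictions:
        rows.append(
            {
                "id": p.id,
                "is_enzyme": p.is_enzyme,
                "vote": p.enzyme_vote,
                "main_class": p.main_class,
                "main_vote": None if p.main_votes is None else p.main_votes[str(p.main_class)],
                "sub_class": p.sub_class,
                "sub_vote": None if p.sub_votes is None else p.sub_votes[p.sub_class],
            }
        )
    return pd.DataFrame(rows).set_index("id")
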