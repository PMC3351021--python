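"""Feature ranking by permutation importance and per-class distributions.

Importance is the mean decrease in accuracy: accuracy on evaluation rows is
measured before and after randomly permuting one feature column, averaged
over repeats. Scores are fractions in [0, 1]. Evaluation rows come from a
seeded held-out split (the ensemble implementation used here does not
expose per-tree out-of-bag membership publicly). Impurity-based (Gini)
importances are exposed read-only for comparison but never used for
ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .cascade import ForestParams, train_forest


@dataclass
class ImportanceRanking:
    scores: pd.DataFrame  # indexed by feature: mean_decrease_accuracy, rank
    repeats: int
    seed: int

    def top(self, n: int) -> List[str]:
        return list(self.scores.sort_values("rank").index[:n])


def permutation_importance(
    classifier,
    table: pd.DataFrame,
    labels: Sequence[str],
    repeats: int = 10,
    seed: int = 0,
) -> ImportanceRanking:
    """Mean-decrease-in-accuracy score for every feature column.

    ``table``/``labels`` are evaluation rows the classifier was *not*
    trained on. Ranks are 1..n_features, ordered by decreasing score with
    ties broken by feature name.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    y = np.asarray([str(lab) for lab in labels])
    X = table.to_numpy().copy()
    rng = np.random.default_rng(seed)
    base_acc = float(np.mean(classifier.predict(X) == y))
    drops: Dict[str, float] = {}
    for j, name in enumerate(table.columns):
        total = 0.0
        original = X[:, j].copy()
        for _ in range(repeats):
            X[:, j] = original[rng.permutation(len(X))]
            total += base_acc - float(np.mean(classifier.predict(X) == y))
        X[:, j] = original
        drops[name] = total / repeats
    frame = pd.DataFrame({"mean_decrease_accuracy": pd.Series(drops)})
    ordered = sorted(
        frame.index, key=lambda f: (-frame.loc[f, "mean_decrease_accuracy"], f)
    )
    frame["rank"] = [ordered.index(f) + 1 for f in frame.index]
    frame.index.name = "feature"
    return ImportanceRanking(scores=frame, repeats=repeats, seed=seed)


def rank_features(
    table: pd.DataFrame,
    labels: Sequence[str],
    params: Optional[ForestParams] = None,
    repeats: int = 10,
    holdout_fraction: float = 0.3,
    seed: int = 0,
) -> ImportanceRanking:
    """Train a forest on a split and rank features on the held-out rows."""
    if params is None:
        params = ForestParams(seed=seed)
    y = np.asarray([str(lab) for lab in labels])
    X_train, X_eval, y_train, y_eval = train_test_split(
        table, y, test_size=holdout_fraction, random_state=seed, stratify=y
    )
    clf, _ = train_forest(X_train, y_train, params)
    return permutation_importance(clf, X_eval, y_eval, repeats=repeats, seed=seed)


def gini_importance(classifier, feature_names: Sequence[str]) -> pd.Series:
    """Impurity-based importances, read-only companion to the ranking."""
    return pd.Series(
        classifier.feature_importances_, index=list(feature_names), name="gini"
    )


def _five_number(values: np.ndarray) -> Dict[str, float]:
    """Min/Q1/median/Q3/max with quartiles by the inclusive median-of-halves
    convention (the median joins both halves when n is odd)."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n == 0:
        raise ValueError("empty group")

    def median(a: np.ndarray) -> float:
        m = len(a)
        mid = m // 2
        return float(a[mid]) if m % 2 else float(0.5 * (a[mid - 1] + a[mid]))

    half = n // 2 + (n % 2)  # inclusive halves
    return {
        "min": float(v[0]),
        "q1": median(v[:half]),
        "median": median(v),
        "q3": median(v[n - half:]),
        "max": float(v[-1]),
    }


def class_distribution(
    table: pd.DataFrame,
    labels: Sequence[str],
    feature_name: str,
) -> pd.DataFrame:
    """Per-class five-number summary of one feature (box-plot statistics)."""
    if feature_name not in table.columns:
        raise KeyError(f"unknown feature {feature_name!r}")
    y = [str(lab) for lab in labels]
    if len(y) != len(table):
        raise ValueError("labels length must match table rows")
    col = table[feature_name].to_numpy()
    rows = {}
    for lab in sorted(set(y)):
        mask = np.array([t == lab for t in y])
        rows[lab] = _five_number(col[mask])
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "class"
    return frame
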