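"""Majority-voting feature selection.

Seven scoring methods vote on each of the 26 cluster features: four filters
(chi-square, Fisher score, information gain, ANOVA F) and three wrappers
(recursive feature elimination, permutation importance, and a Boruta-style
shadow-feature procedure, all on a random-forest base estimator). Each
score-based method marks its top-``k_select`` features True; Boruta marks its
confirmed features True regardless of k. A feature is selected when it
collects at least ``min_votes`` votes (default 4 of 7).

A frozen reference vote matrix for the 26 features ships with the package
(``data/reference_votes.csv``); with min_votes=4 it selects 16 of the 26.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE, chi2, f_classif, mutual_info_classif
from sklearn.inspection import permutation_importance

METHOD_NAMES: tuple[str, ...] = (
    "chi2",
    "fisher_score",
    "info_gain",
    "anova",
    "rfe",
    "permutation_importance",
    "boruta",
)

DEFAULT_MIN_VOTES = 4
DEFAULT_K_SELECT = 16


class SelectionError(ValueError):
    pass


def _as_xy(feature_table, labels) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(feature_table, pd.DataFrame):
        names = list(feature_table.columns)
        x = feature_table.to_numpy(dtype=float)
    else:
        x = np.asarray(feature_table, dtype=float)
        names = [f"f{i}" for i in range(x.shape[1])]
    y = np.asarray(labels)
    if len(y) != len(x):
        raise SelectionError("labels and feature table have different lengths")
    return x, y, names


def _top_k_mask(scores: np.ndarray, k: int) -> np.ndarray:
    # stable: ties resolved toward the earlier feature
    order = np.lexsort((np.arange(len(scores)), -scores))
    mask = np.zeros(len(scores), dtype=bool)
    mask[order[:k]] = True
    return mask


def fisher_scores(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-feature Fisher score: between-class over within-class variance.

    F_r = sum_c n_c (mu_rc - mu_r)^2 / sum_c n_c sigma_rc^2, with population
    variances. Features whose within-class variance is 0 everywhere score 0
    when their class means agree, +inf otherwise.
    """
    classes = np.unique(y)
    mu = x.mean(axis=0)
    between = np.zeros(x.shape[1])
    within = np.zeros(x.shape[1])
    for c in classes:
        xc = x[y == c]
        between += len(xc) * (xc.mean(axis=0) - mu) ** 2
        within += len(xc) * xc.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(within > 0, between / np.where(within > 0, within, 1.0), np.where(between > 0, np.inf, 0.0))
    return score


def boruta_select(
    x: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    n_iterations: int = 30,
    alpha: float = 0.05,
    n_estimators: int = 200,
) -> np.ndarray:
    """Boruta-style all-relevant selection with shadow features.

    Each round appends a column-permuted copy of the table ("shadow"
    features), fits a random forest on the union, and scores a hit for every
    real feature whose importance exceeds the round's maximum shadow
    importance. A feature is confirmed when its hit count is significantly
    above the fair-coin rate (one-sided binomial test at ``alpha``).
    """
    rng = np.random.default_rng(seed)
    hits = np.zeros(x.shape[1], dtype=int)
    for it in range(n_iterations):
        shadow = x.copy()
        for col in range(shadow.shape[1]):
            rng.shuffle(shadow[:, col])
        both = np.hstack([x, shadow])
        forest = RandomForestClassifier(
            n_estimators=n_estimators, random_state=int(rng.integers(2**31))
        ).fit(both, y)
        importances = forest.feature_importances_
        threshold = importances[x.shape[1]:].max()
        hits += importances[: x.shape[1]] > threshold
    return np.array(
        [binomtest(int(h), n_iterations, 0.5, alternative="greater").pvalue < alpha for h in hits]
    )


def score_method(
    feature_table,
    labels,
    method_name: str,
    k_select: int = DEFAULT_K_SELECT,
    seed: int = 0,
) -> np.ndarray:
    """Boolean selection vector of one scoring method.

    Score-based methods (all but Boruta) mark their top-``k_select`` features
    True; Boruta marks its confirmed features. Chi-square sees the features
    min-max scaled to [0, 1] since it is undefined on negatives.
    """
    x, y, _ = _as_xy(feature_table, labels)
    if method_name not in METHOD_NAMES:
        raise SelectionError(f"unknown method {method_name!r}; choose from {METHOD_NAMES}")
    if method_name != "boruta" and k_select > x.shape[1]:
        raise SelectionError(f"k_select={k_select} exceeds n_features={x.shape[1]}")
    # a constant feature carries no class association; estimator noise must
    # never promote it into anyone's selection
    informative = np.ptp(x, axis=0) > 0

    def _top_k(scores: np.ndarray) -> np.ndarray:
        return _top_k_mask(np.where(informative, scores, -np.inf), k_select)

    if method_name == "chi2":
        span = x.max(axis=0) - x.min(axis=0)
        scaled = (x - x.min(axis=0)) / np.where(span > 0, span, 1.0)
        scores = np.nan_to_num(chi2(scaled, y)[0], nan=0.0)
        return _top_k(scores)
    if method_name == "fisher_score":
        return _top_k(np.nan_to_num(fisher_scores(x, y), posinf=np.finfo(float).max))
    if method_name == "info_gain":
        return _top_k(mutual_info_classif(x, y, random_state=seed))
    if method_name == "anova":
        return _top_k(np.nan_to_num(f_classif(x, y)[0], nan=0.0))
    if method_name == "rfe":
        estimator = RandomForestClassifier(n_estimators=500, random_state=seed)
        return RFE(estimator, n_features_to_select=k_select).fit(x, y).support_ & informative
    if method_name == "permutation_importance":
        forest = RandomForestClassifier(n_estimators=500, random_state=seed).fit(x, y)
        result = permutation_importance(forest, x, y, n_repeats=10, random_state=seed)
        return _top_k(result.importances_mean)
    return boruta_select(x, y, seed=seed) & informative


def build_vote_matrix(
    feature_table,
    labels,
    k_select: int = DEFAULT_K_SELECT,
    min_votes: int = DEFAULT_MIN_VOTES,
    seed: int = 0,
) -> pd.DataFrame:
    """Run all seven methods and assemble the boolean vote matrix.

    Rows are features, columns the seven methods, plus ``votes`` (row sum)
    and ``decision`` ("Select" iff votes >= min_votes).
    """
    x, y, names = _as_xy(feature_table, labels)
    table = pd.DataFrame(index=names)
    for method in METHOD_NAMES:
        table[method] = score_method(feature_table, labels, method, k_select=k_select, seed=seed)
    return _finalize(table, min_votes)


def _finalize(votes: pd.DataFrame, min_votes: int) -> pd.DataFrame:
    out = votes[list(METHOD_NAMES)].astype(bool).copy()
    out["votes"] = out.sum(axis=1).astype(int)
    out["decision"] = np.where(out["votes"] >= min_votes, "Select", "Reject")
    return out


def tally_votes(vote_matrix: pd.DataFrame, min_votes: int = DEFAULT_MIN_VOTES):
    """Split features into (selected, rejected) name lists, order preserved.

    ``vote_matrix`` needs the seven boolean method columns indexed by feature
    name; votes/decision columns are recomputed.
    """
    table = _finalize(vote_matrix, min_votes)
    selected = [name for name, row in table.iterrows() if row["decision"] == "Select"]
    rejected = [name for name in table.index if name not in selected]
    return selected, rejected


def load_reference_votes() -> pd.DataFrame:
    """The frozen reference vote matrix over the 26 cluster features."""
    with resources.files("nucleiclust.data").joinpath("reference_votes.csv").open() as f:
        table = pd.read_csv(f, index_col="feature")  # True/False parse as bool
    return _finalize(table, DEFAULT_MIN_VOTES)
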