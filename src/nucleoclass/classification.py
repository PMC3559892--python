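"""Balanced random-forest classification with OOB evaluation and
permutation-tested Gini importance.

The larger class is repeatedly down-sampled to the smaller class's size
(ten balanced repeats by default) and a random forest (500 trees,
``m_try = floor(sqrt(p))`` features per split) is fit on each balanced
matrix.  Performance is estimated out-of-bag: each sample is predicted by
averaging the votes of the trees whose bootstrap excluded it, yielding an
unbiased accuracy and an auROC from OOB class-vote fractions.  Feature
importance is the mean decrease in Gini impurity (MDG) over trees,
averaged across repeats; its significance is assessed against a null
distribution of MDG scores from refits on label-permuted data, with an
add-one permutation p-value (never zero) and Bonferroni adjustment.

Permutation refits use a reduced forest size (``perm_n_tree``, default
100) for tractability; the observed MDG inside the permutation test is
recomputed with the same reduced forest so that the observed statistic and
the null draws are exchangeable, which keeps the p-values calibrated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve

from .io_formats import LABEL_COLUMN


@dataclass
class ClassifierConfig:
    n_tree: int = 500
    m_try: int | None = None  # None -> floor(sqrt(p))
    n_balance_repeats: int = 10
    n_permutations: int = 1000
    perm_n_tree: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tree < 1 or self.perm_n_tree < 1:
            raise ValueError("tree counts must be >= 1")
        if self.n_balance_repeats < 1:
            raise ValueError("n_balance_repeats must be >= 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    def resolve_m_try(self, p: int) -> int:
        m = self.m_try if self.m_try is not None else int(math.floor(math.sqrt(p)))
        return max(1, min(m, p))


@dataclass
class FitResult:
    accuracy: float
    auroc: float
    mdg: pd.Series
    oob_scores: pd.Series  # OOB vote fraction for the positive (second) class
    labels: pd.Series


@dataclass
class EvaluationResult:
    """Mean +/- SD OOB performance over balanced repeats, with mean MDG.

    ``direction`` marks, per feature, the class in which the feature's mean
    value is higher.  SD fields are 0 when a single repeat was run.
    """

    accuracies: list[float]
    aurocs: list[float]
    mdg: pd.Series
    direction: pd.Series
    n_repeats: int
    per_repeat_mdg: list[pd.Series] = field(default_factory=list)

    @property
    def accuracy_mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def accuracy_sd(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if self.n_repeats > 1 else 0.0

    @property
    def auroc_mean(self) -> float:
        return float(np.mean(self.aurocs))

    @property
    def auroc_sd(self) -> float:
        return float(np.std(self.aurocs, ddof=1)) if self.n_repeats > 1 else 0.0

    def feature_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mdg": self.mdg, "direction": self.direction}
        ).sort_values("mdg", ascending=False)


def _split(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    if LABEL_COLUMN not in matrix.columns:
        raise ValueError(f"matrix must carry a {LABEL_COLUMN!r} column")
    return matrix.drop(columns=LABEL_COLUMN), matrix[LABEL_COLUMN]


def balance_downsample(matrix: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Down-sample the larger class (without replacement) to the smaller's size."""
    _, labels = _split(matrix)
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {list(classes)}")
    counts = labels.value_counts()
    if (counts == 0).any():
        raise ValueError("both classes must be non-empty")
    small = counts.idxmin() if counts.iloc[0] != counts.iloc[1] else classes[0]
    target = int(counts.min())
    rng = np.random.default_rng(seed)
    parts = []
    for cls in classes:
        idx = matrix.index[labels == cls]
        if len(idx) > target:
            keep = np.sort(rng.choice(len(idx), size=target, replace=False))
            idx = idx[keep]
        parts.append(matrix.loc[idx])
    return pd.concat(parts)


def fit_and_evaluate(
    matrix: pd.DataFrame, config: ClassifierConfig, seed: int | None = None, n_tree: int | None = None
) -> FitResult:
    """Fit one forest and estimate OOB accuracy, auROC and per-feature MDG.

    MDG is the per-tree Gini-impurity decrease summed over a feature's
    splits (weighted by node sample fraction), averaged over trees — the
    unnormalized mean decrease in Gini.
    """
    X, labels = _split(matrix)
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("constant-label input: need two classes to classify")
    y = labels.to_numpy()
    forest = RandomForestClassifier(
        n_estimators=n_tree if n_tree is not None else config.n_tree,
        max_features=config.resolve_m_try(X.shape[1]),
        oob_score=True,
        bootstrap=True,
        random_state=(seed if seed is not None else config.seed) % (2**31),
        n_jobs=1,
    )
    forest.fit(X.to_numpy(), y)
    votes = forest.oob_decision_function_
    valid = ~np.isnan(votes).any(axis=1)
    pos_idx = 1  # classes_ is sorted; second class is the "positive" score column
    pos_class = forest.classes_[pos_idx]
    pred = forest.classes_[np.argmax(votes[valid], axis=1)]
    accuracy = float(np.mean(pred == y[valid]))
    auroc = float(roc_auc_score(y[valid] == pos_class, votes[valid, pos_idx]))
    per_tree = np.array(
        [t.tree_.compute_feature_importances(normalize=False) for t in forest.estimators_]
    )
    mdg = pd.Series(per_tree.mean(axis=0), index=X.columns)
    scores = pd.Series(np.where(valid, votes[:, pos_idx], np.nan), index=X.index)
    return FitResult(accuracy, auroc, mdg, scores, labels)


def feature_directions(matrix: pd.DataFrame) -> pd.Series:
    """Per feature, the class with the higher mean value (ties -> first class)."""
    X, labels = _split(matrix)
    classes = sorted(labels.unique())
    means = X.groupby(labels).mean()
    return pd.Series(
        np.where(means.loc[classes[0]] >= means.loc[classes[1]], classes[0], classes[1]),
        index=X.columns,
    )


def run_balanced_evaluation(
    matrix: pd.DataFrame, config: ClassifierConfig
) -> EvaluationResult:
    """Repeat balance + fit ``n_balance_repeats`` times with derived seeds."""
    seeds = np.random.SeedSequence(config.seed % (2**31)).generate_state(
        2 * config.n_balance_repeats
    ) % (2**31)
    accuracies, aurocs, mdgs = [], [], []
    for r in range(config.n_balance_repeats):
        balanced = balance_downsample(matrix, int(seeds[2 * r]))
        fit = fit_and_evaluate(balanced, config, seed=int(seeds[2 * r + 1]))
        accuracies.append(fit.accuracy)
        aurocs.append(fit.auroc)
        mdgs.append(fit.mdg)
    mean_mdg = pd.concat(mdgs, axis=1).mean(axis=1)
    return EvaluationResult(
        accuracies, aurocs, mean_mdg, feature_directions(matrix),
        config.n_balance_repeats, per_repeat_mdg=mdgs,
    )


def bonferroni(p: float, n_tests: int) -> float:
    return min(1.0, p * n_tests)


def permutation_test_importance(
    matrix: pd.DataFrame, config: ClassifierConfig
) -> pd.DataFrame:
    """Permutation significance of per-feature MDG.

    Labels are permuted uniformly ``n_permutations`` times and the forest is
    refit (``perm_n_tree`` trees) each time; the observed MDG is computed
    with an identical refit on the unpermuted labels.  The add-one estimator
    ``p = (1 + #{permuted >= observed}) / (1 + B)`` can never return zero.
    Returns a DataFrame indexed by feature with columns ``mdg``,
    ``p_value`` and ``p_adjusted`` (Bonferroni over features).
    """
    X, labels = _split(matrix)
    if labels.nunique() < 2:
        raise ValueError("constant-label input: need two classes")
    seeds = np.random.SeedSequence(
        [config.seed % (2**31), 0x5EED]
    ).generate_state(config.n_permutations + 1) % (2**31)
    perm_rng = np.random.default_rng([config.seed % (2**31), 0xA11])

    observed_fit = fit_and_evaluate(
        matrix, config, seed=int(seeds[0]), n_tree=config.perm_n_tree
    )
    observed = observed_fit.mdg.to_numpy()
    y = labels.to_numpy()
    exceed = np.zeros(X.shape[1], dtype=int)
    permuted = matrix.copy()
    for b in range(config.n_permutations):
        permuted[LABEL_COLUMN] = perm_rng.permutation(y)
        fit = fit_and_evaluate(
            permuted, config, seed=int(seeds[b + 1]), n_tree=config.perm_n_tree
        )
        exceed += fit.mdg.to_numpy() >= observed
    p = (1.0 + exceed) / (1.0 + config.n_permutations)
    n_features = X.shape[1]
    return pd.DataFrame(
        {
            "mdg": observed,
            "p_value": p,
            "p_adjusted": [bonferroni(v, n_features) for v in p],
        },
        index=X.columns,
    )


def combine_matrices(
    mod_matrix: pd.DataFrame,
    motif_matrix: pd.DataFrame,
    prefixes: tuple[str, str] = ("mod", "motif"),
) -> pd.DataFrame:
    """Column-wise concatenation of two feature matrices on identical rows."""
    if set(mod_matrix.index) != set(motif_matrix.index):
        raise ValueError("row id sets differ; cannot combine matrices")
    motif_matrix = motif_matrix.reindex(mod_matrix.index)
    if not mod_matrix[LABEL_COLUMN].equals(motif_matrix[LABEL_COLUMN]):
        raise ValueError("row labels differ between matrices")
    left, labels = _split(mod_matrix)
    right, _ = _split(motif_matrix)
    left = left.add_prefix(prefixes[0] + ":")
    right = right.add_prefix(prefixes[1] + ":")
    combined = pd.concat([left, right], axis=1)
    combined.insert(0, LABEL_COLUMN, labels)
    return combined


def roc_points(labels: Sequence, scores: Sequence[float], pos_label) -> pd.DataFrame:
    """ROC coordinates (FPR, TPR) from OOB vote fractions."""
    mask = ~np.isnan(np.asarray(scores, dtype=float))
    fpr, tpr, _ = roc_curve(
        np.asarray(labels)[mask] == pos_label, np.asarray(scores, dtype=float)[mask]
    )
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})
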