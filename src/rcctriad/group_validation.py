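"""Statistical validation of the tumor grouping.

The grouping is validated two ways: (1) how accurately a classifier built
on very few genes reproduces the labels — genes are ranked by random-forest
impurity importance and the top few are refit (random forest, with linear
discriminant analysis reported alongside); (2) a constrained label-shuffling
permutation test — group labels are shuffled many times with group sizes
preserved and a quota forcing at least a fraction of the largest group's
slots to be filled by a histology stratum drawn from the other groups, the
identical select-then-refit pipeline is rerun on each shuffle (so selection
bias is preserved under the null), and the empirical p-value is the
add-one-smoothed fraction of shuffles reaching the original accuracy.

The test statistic is the out-of-bag (OOB) accuracy of the refit forest;
resubstitution accuracy of a random forest saturates near 1 regardless of
labels and carries no signal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import cross_val_score

from .io_core import ExpressionMatrix, SampleAnnotation

logger = logging.getLogger(__name__)


@dataclass
class ShuffleTestParams:
    n_shuffles: int = 500
    n_top_variables: int = 4
    constraint_fraction: float = 1 / 3
    constraint_stratum: tuple[str, str] = ("subtype", "ccRCC")
    constrained_group: str = "A"
    n_trees: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        if self.n_top_variables < 1:
            raise ValueError("n_top_variables must be >= 1")
        if not 0 <= self.constraint_fraction <= 1:
            raise ValueError("constraint_fraction must be in [0, 1]")


@dataclass
class ShuffleTestResult:
    original_accuracy: float
    n_misclassified: int
    shuffle_accuracies: list[float]
    n_as_good: int
    p_value: float
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "original_accuracy": self.original_accuracy,
            "n_misclassified": self.n_misclassified,
            "n_shuffles": len(self.shuffle_accuracies),
            "n_as_good": self.n_as_good,
            "p_value": self.p_value,
            **self.extras,
        }


def rank_variables(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    params: ShuffleTestParams | None = None,
    seed: int | None = None,
) -> pd.Series:
    """Genes ordered by random-forest impurity-decrease importance."""
    params = params or ShuffleTestParams()
    labels = labels.loc[matrix.sample_ids]
    classes = labels.value_counts()
    if len(classes) < 2 or (classes < 2).any():
        raise ValueError("need >= 2 classes with >= 2 samples each")
    values = matrix.values
    if np.allclose(values, values[0]):
        raise ValueError("expression matrix is constant; nothing to rank")
    forest = RandomForestClassifier(
        n_estimators=params.n_trees,
        max_features="sqrt",
        random_state=params.seed if seed is None else seed,
        n_jobs=1,
    )
    forest.fit(values, labels.to_numpy())
    importances = pd.Series(
        forest.feature_importances_, index=matrix.gene_ids, name="importance"
    )
    return importances.sort_values(ascending=False)


def lda_accuracy(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    gene_subset,
    cross_validate: int = 0,
) -> tuple[float, int, pd.DataFrame]:
    """Linear discriminant classifier on a gene subset.

    Returns resubstitution accuracy (or k-fold CV accuracy when
    ``cross_validate`` > 1), misclassification count, and the confusion
    matrix.  A singular pooled covariance falls back to a shrinkage solver.
    """
    gene_subset = list(gene_subset)
    if not gene_subset:
        raise ValueError("gene_subset must be non-empty")
    labels = labels.loc[matrix.sample_ids]
    # plain column selection: subsets may be smaller than the 2-gene minimum
    # enforced for full expression matrices
    X = matrix.data.loc[:, gene_subset].to_numpy()
    y = labels.to_numpy()
    lda = LinearDiscriminantAnalysis()
    try:
        lda.fit(X, y)
    except np.linalg.LinAlgError:
        logger.warning("singular pooled covariance; refitting with shrinkage")
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        lda.fit(X, y)
    if cross_validate > 1:
        acc = float(cross_val_score(lda, X, y, cv=cross_validate).mean())
    else:
        acc = float((lda.predict(X) == y).mean())
    pred = lda.predict(X)
    n_mis = int((pred != y).sum())
    classes = sorted(set(y))
    conf = pd.DataFrame(
        confusion_matrix(y, pred, labels=classes), index=classes, columns=classes
    )
    return acc, n_mis, conf


def constrained_shuffle(
    labels: pd.Series,
    annotation: SampleAnnotation | pd.DataFrame,
    params: ShuffleTestParams,
    rng: np.random.Generator,
) -> pd.Series:
    """Shuffle group labels preserving group sizes, forcing at least
    ceil(constraint_fraction * |constrained_group|) of the constrained
    group's slots to hold stratum samples originally labelled otherwise."""
    ann = annotation.table if isinstance(annotation, SampleAnnotation) else annotation
    ann = ann.loc[labels.index]
    field_name, stratum_value = params.constraint_stratum
    group = params.constrained_group

    counts = labels.value_counts()
    if group not in counts.index:
        raise ValueError(f"constrained group {group!r} absent from labels")
    quota = math.ceil(params.constraint_fraction * counts[group])

    in_stratum = ann[field_name] == stratum_value
    pool = labels.index[(labels != group) & in_stratum]
    if len(pool) < quota:
        raise ValueError(
            f"infeasible constraint: need {quota} {stratum_value!r} samples "
            f"outside group {group!r}, only {len(pool)} available"
        )

    samples = list(labels.index)
    forced = list(rng.choice(pool, size=quota, replace=False)) if quota else []
    rest = [s for s in samples if s not in set(forced)]
    rng.shuffle(rest)

    new = pd.Series(index=labels.index, dtype=object, name=labels.name)
    new.loc[forced] = group
    slots: list[str] = []
    for g, cnt in counts.items():
        need = cnt - (quota if g == group else 0)
        slots.extend([g] * need)
    # remaining slots in a fixed group order; samples already randomised
    new.loc[rest] = slots[: len(rest)]
    return new


def _pipeline_accuracy(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    params: ShuffleTestParams,
    seed: int,
) -> dict:
    """Rank genes, take the top few, refit; return the accuracy readouts."""
    ranking = rank_variables(matrix, labels, params, seed=seed)
    top = list(ranking.index[: params.n_top_variables])
    X = matrix.data.loc[:, top].to_numpy()
    y = labels.loc[matrix.sample_ids].to_numpy()
    forest = RandomForestClassifier(
        n_estimators=params.n_trees,
        max_features="sqrt",
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    oob = float(forest.oob_score_)
    resub = float((forest.predict(X) == y).mean())
    lda_acc, _, _ = lda_accuracy(matrix, labels, top)
    return {
        "top_genes": top,
        "oob_accuracy": oob,
        "resub_accuracy": resub,
        "lda_accuracy": lda_acc,
    }


def shuffle_significance_test(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    annotation: SampleAnnotation | pd.DataFrame,
    params: ShuffleTestParams | None = None,
) -> ShuffleTestResult:
    """Constrained label-shuffling significance test of the grouping.

    p = (#{shuffle accuracy >= original} + 1) / (n_shuffles + 1), with the
    full variable-selection pipeline rerun inside every shuffle.
    """
    params = params or ShuffleTestParams()
    labels = labels.loc[matrix.sample_ids]
    rng = np.random.default_rng(params.seed)
    seed_seq = np.random.SeedSequence(params.seed)
    sub_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                 seed_seq.spawn(params.n_shuffles + 1)]

    original = _pipeline_accuracy(matrix, labels, params, seed=sub_seeds[0])
    stat = original["oob_accuracy"]
    n = len(labels)

    shuffle_acc: list[float] = []
    for i in range(params.n_shuffles):
        shuffled = constrained_shuffle(labels, annotation, params, rng)
        res = _pipeline_accuracy(matrix, shuffled, params, seed=sub_seeds[i + 1])
        shuffle_acc.append(res["oob_accuracy"])

    n_as_good = int(sum(a >= stat for a in shuffle_acc))
    p_value = (n_as_good + 1) / (params.n_shuffles + 1)
    return ShuffleTestResult(
        original_accuracy=stat,
        n_misclassified=int(round((1 - stat) * n)),
        shuffle_accuracies=shuffle_acc,
        n_as_good=n_as_good,
        p_value=p_value,
        extras={
            "resub_accuracy": original["resub_accuracy"],
            "lda_accuracy": original["lda_accuracy"],
            "top_genes": original["top_genes"],
        },
    )
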