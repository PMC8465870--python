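"""External cluster validity: majority labeling, purity / precision /
recall / F-measure, their analytic floors and ceilings, the repeated
clustering protocol, and the ML-vs-AP statistical comparison.

Given a clustering of samples whose true class (the mCTSIB condition) is
known, cross-tabulate clusters against classes (counts n_ij, cluster totals
n_i, class totals m_j, grand total n) and label each cluster by its
majority class.  Then

    purity    = sum_i (n_i / n) * purity_i,  purity_i = max_j n_ij / n_i
    prec_i    = max_j n_ij / n_i             (precision of a cluster equals
                                              its purity)
    recall_i  = n_{i, j_i} / m_{j_i}          (j_i: majority class of i)
    F_i       = 2 prec_i recall_i / (prec_i + recall_i),  F = mean_i F_i

precision, recall and F are unweighted means over clusters; purity is the
cluster-size-weighted mean of the same per-cluster fractions.  For a
balanced two-class design the collapse of everything into one cluster
floors purity and precision at 1/2, and the minimum cluster-averaged
recall over all K-cluster assignments is 1/K (computed here exactly by
dynamic-programming enumeration over cluster compositions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, InvalidArgumentError

logger = logging.getLogger(__name__)


@dataclass
class ContingencyTable:
    """Cluster x class count matrix with consistent margins."""

    counts: pd.DataFrame    # rows: cluster ids, columns: class labels

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise InvalidArgumentError("counts must be non-negative")
        if self.n == 0:
            raise InvalidArgumentError("contingency table is empty")

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def cluster_totals(self) -> np.ndarray:
        return self.counts.to_numpy().sum(axis=1)

    @property
    def class_totals(self) -> np.ndarray:
        return self.counts.to_numpy().sum(axis=0)


@dataclass
class ExternalMeasures:
    purity: float
    precision: float
    recall: float
    f_measure: float
    per_cluster: pd.DataFrame   # cluster, majority_class, purity_i, recall_i, f_i

    def as_dict(self) -> dict[str, float]:
        return {
            "purity": self.purity,
            "precision": self.precision,
            "recall": self.recall,
            "f": self.f_measure,
        }


class MinBounds(NamedTuple):
    min_purity: float
    min_precision: float
    min_recall: float
    max_all: float


def contingency(assignment, class_labels) -> ContingencyTable:
    """Exact cross-tabulation of cluster assignment against class labels."""
    assignment = np.asarray(assignment)
    class_labels = np.asarray(class_labels)
    if assignment.shape != class_labels.shape:
        raise InvalidArgumentError("assignment and labels must align")
    counts = pd.crosstab(pd.Series(assignment, name="cluster"),
                         pd.Series(class_labels, name="class"))
    counts = counts.sort_index().sort_index(axis=1)
    return ContingencyTable(counts=counts)


def _per_cluster(table: ContingencyTable) -> pd.DataFrame:
    """Majority label (ties: the earlier-sorted, i.e. lower, class) and the
    per-cluster fractions behind all four measures."""
    counts = table.counts.to_numpy()
    classes = list(table.counts.columns)
    m = table.class_totals
    rows = []
    for i, cluster in enumerate(table.counts.index):
        j = int(np.argmax(counts[i]))     # first max -> lower class label
        n_i = counts[i].sum()
        maj = counts[i, j]
        prec_i = maj / n_i
        recall_i = maj / m[j]
        f_i = 0.0 if prec_i + recall_i == 0 else 2 * prec_i * recall_i / (prec_i + recall_i)
        rows.append(
            {
                "cluster": cluster,
                "majority_class": classes[j],
                "n_i": int(n_i),
                "purity_i": prec_i,
                "recall_i": recall_i,
                "f_i": f_i,
            }
        )
    return pd.DataFrame(rows)


def external_measures(table: ContingencyTable) -> ExternalMeasures:
    """All four measures from one contingency table."""
    per = _per_cluster(table)
    n = table.n
    purity_val = float((per["n_i"] / n * per["purity_i"]).sum())
    return ExternalMeasures(
        purity=purity_val,
        precision=float(per["purity_i"].mean()),
        recall=float(per["recall_i"].mean()),
        f_measure=float(per["f_i"].mean()),
        per_cluster=per,
    )


def purity(table: ContingencyTable) -> float:
    """Cluster-size-weighted majority fraction."""
    return external_measures(table).purity


def precision_avg(table: ContingencyTable) -> float:
    """Unweighted mean of per-cluster precisions (= per-cluster purities)."""
    return external_measures(table).precision


def recall_avg(table: ContingencyTable) -> float:
    """Unweighted mean over clusters of majority count / that class's total."""
    return external_measures(table).recall


def f_measure(table: ContingencyTable) -> float:
    """Mean over clusters of the per-cluster precision/recall harmonic mean."""
    return external_measures(table).f_measure


def min_bounds(K: int, class_sizes) -> MinBounds:
    """Analytic floors and ceiling of the external measures for two classes.

    Purity and average precision are floored by the full collapse of all
    samples into one cluster: largest class share of the total.  The
    minimum cluster-averaged recall over every assignment into exactly K
    non-empty clusters is found exactly by dynamic programming over integer
    cluster compositions (a_i of class 1, b_i of class 2, a_i + b_i >= 1):
    minimise (1/K) sum_i recall_i with recall_i = a_i/A if a_i >= b_i else
    b_i/B.  For balanced classes this equals 1/K.  The ceiling of all four
    measures is 1, attained by a pure and complete clustering.
    """
    class_sizes = [int(s) for s in class_sizes]
    if K < 1:
        raise InvalidArgumentError("K must be >= 1")
    if len(class_sizes) != 2 or any(s < 1 for s in class_sizes):
        raise InvalidArgumentError("min_bounds supports two non-empty classes")
    A, B = class_sizes
    if K > A + B:
        raise InvalidArgumentError("more clusters than samples")

    collapse_floor = max(A, B) / (A + B)

    # recall_i cost of putting (a, b) samples of the two classes in a cluster;
    # ties (a == b) label by the lower class index, i.e. class 1
    a_grid = np.arange(A + 1)[:, None]
    b_grid = np.arange(B + 1)[None, :]
    cost = np.where(a_grid >= b_grid, a_grid / A, b_grid / B)
    cost[0, 0] = np.inf    # clusters must be non-empty

    INF = np.inf
    f_prev = np.full((A + 1, B + 1), INF)
    f_prev[0, 0] = 0.0
    for _ in range(K):
        f_new = np.full((A + 1, B + 1), INF)
        for a in range(A + 1):
            for b in range(B + 1):
                c = cost[a, b]
                if not np.isfinite(c):
                    continue
                shifted = f_prev[: A + 1 - a, : B + 1 - b] + c
                f_new[a:, b:] = np.minimum(f_new[a:, b:], shifted)
        f_prev = f_new
    total = f_prev[A, B]
    if not np.isfinite(total):
        raise InvalidArgumentError("no feasible assignment for this K")
    min_recall = float(total / K)
    return MinBounds(
        min_purity=collapse_floor,
        min_precision=collapse_floor,
        min_recall=min_recall,
        max_all=1.0,
    )


def compare_directions(
    ml_values, ap_values, alpha: float = 0.05, method: str = "auto"
) -> tuple[str, float, float]:
    """Normality-gated two-sample comparison of ML vs AP measure values.

    Shapiro-Wilk on each sample; if both pass, an independent-samples
    t-test, otherwise a two-sided Mann-Whitney U-test.  ``method`` can force
    "t" or "mannwhitney".  Returns (test_name, statistic, p).
    """
    ml = np.asarray(ml_values, dtype=float)
    ap = np.asarray(ap_values, dtype=float)
    if ml.size < 3 or ap.size < 3:
        raise InsufficientDataError("need at least 3 values per sample")
    if method == "auto":
        use_t = all(
            np.ptp(v) > 0 and stats.shapiro(v).pvalue >= alpha for v in (ml, ap)
        )
        method = "t" if use_t else "mannwhitney"
    if method == "t":
        res = stats.ttest_ind(ml, ap)
        return "t", float(res.statistic), float(res.pvalue)
    if method == "mannwhitney":
        res = stats.mannwhitneyu(ml, ap, alternative="two-sided")
        return "mannwhitney", float(res.statistic), float(res.pvalue)
    raise InvalidArgumentError("method must be auto, t or mannwhitney")


def repeat_pipeline(
    X: np.ndarray,
    class_labels: np.ndarray,
    K: int,
    cluster_once: Callable[[np.ndarray, np.ndarray, int, int], ExternalMeasures],
    n_reps: int = 30,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Run a clustering callable ``n_reps`` times with fresh seeds.

    ``cluster_once(X, labels, K, seed)`` performs one randomized
    shuffle-train-cluster-evaluate pass (see :mod:`swaysom.pipeline`); seeds
    are derived from the master seed by counter, so the report is
    deterministic.  Returns a long table with one row per repetition.
    """
    if n_reps < 1:
        raise InvalidArgumentError("n_reps must be >= 1")
    rows = []
    for rep in range(n_reps):
        seed = np.random.SeedSequence([int(master_seed), rep])
        measures = cluster_once(X, class_labels, K, seed)
        row = {"rep": rep}
        row.update(measures.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_measures(per_rep: pd.DataFrame, keys=("purity", "precision", "recall", "f")) -> pd.DataFrame:
    """Median and interquartile range per measure over repetitions."""
    rows = []
    for key in keys:
        v = per_rep[key].to_numpy()
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        rows.append({"measure": key, "median": med, "iqr": q3 - q1})
    return pd.DataFrame(rows)
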