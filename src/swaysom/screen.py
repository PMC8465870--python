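"""Normality-gated correlation screening of the RMS sway features.

Before clustering, features that are highly collinear are removed: each
feature's pooled sample is tested for normality (Shapiro-Wilk, alpha 0.05);
a pair of features is correlated with Pearson's r when both are normal and
with Kendall's tau-b otherwise; any pair with |coefficient| >= 0.85 loses
one member.  The member dropped is the later-listed one: candidate order
encodes the kinematic derivative ladder (position, velocity, acceleration),
so of a collinear pair the lower-order quantity is kept.  The rule is
deterministic and idempotent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, InvalidArgumentError

logger = logging.getLogger(__name__)


@dataclass
class CorrelationReport:
    """Record of the screening decisions."""

    pairs: pd.DataFrame          # feature_a, feature_b, method, coefficient, p_value
    normality: pd.DataFrame      # feature, p_value, is_normal
    retained: list[str]
    dropped: list[str]

    def to_csv(self, path: str | Path) -> None:
        out = self.pairs.copy()
        out["retained_set"] = ",".join(self.retained)
        out.to_csv(path, index=False)


def normality_test(values, alpha: float = 0.05) -> tuple[float, bool]:
    """Shapiro-Wilk normality p-value and verdict at the given alpha.

    A zero-variance sample is degenerate for the test; it is reported as
    non-normal (p = 0) with a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise InsufficientDataError("Shapiro-Wilk needs at least 3 values")
    if np.ptp(values) == 0.0:
        warnings.warn("constant sample: normality test degenerate, reported non-normal")
        return 0.0, False
    p = float(stats.shapiro(values).pvalue)
    return p, p >= alpha


def kendall_tau(x, y) -> tuple[float, float]:
    """Kendall's tau-b (tie-corrected) with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidArgumentError("x and y must have equal length")
    if x.size < 2:
        raise InvalidArgumentError("need at least 2 observations")
    res = stats.kendalltau(x, y)
    return float(res.statistic), float(res.pvalue)


def pearson(x, y) -> tuple[float, float]:
    """Pearson's r with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidArgumentError("x and y must have equal length")
    if x.size < 2:
        raise InvalidArgumentError("need at least 2 observations")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def select_features(
    data: pd.DataFrame,
    threshold: float = 0.85,
    alpha: float = 0.05,
) -> tuple[list[str], CorrelationReport]:
    """Drop one member of every feature pair correlating at |coef| >= threshold.

    ``data`` holds one column per candidate feature (rows are pooled
    observations).  Pairs where both features pass the Shapiro-Wilk gate use
    Pearson; all others use Kendall's tau-b.  While any retained pair reaches
    the threshold, the strongest such pair is resolved by dropping its
    later-listed member, so column order states the preference (kinematic
    features are listed position, velocity, acceleration: the lower-order,
    more directly measured quantity survives).
    """
    features = list(data.columns)
    if len(features) < 2:
        raise InvalidArgumentError("need at least 2 candidate features")

    norm_rows = []
    is_normal = {}
    for f in features:
        p, ok = normality_test(data[f].to_numpy(), alpha)
        is_normal[f] = ok
        norm_rows.append({"feature": f, "p_value": p, "is_normal": ok})

    coef = pd.DataFrame(np.eye(len(features)), index=features, columns=features)
    pair_rows = []
    for a, b in combinations(features, 2):
        if is_normal[a] and is_normal[b]:
            method, (c, p) = "pearson", pearson(data[a], data[b])
        else:
            method, (c, p) = "kendall", kendall_tau(data[a], data[b])
        coef.loc[a, b] = coef.loc[b, a] = c
        pair_rows.append(
            {"feature_a": a, "feature_b": b, "method": method,
             "coefficient": c, "p_value": p}
        )

    retained = list(features)
    dropped: list[str] = []
    while True:
        over = [
            (abs(coef.loc[a, b]), a, b)
            for a, b in combinations(retained, 2)
            if abs(coef.loc[a, b]) >= threshold
        ]
        if not over:
            break
        _, a, b = max(over, key=lambda t: t[0])
        victim = b if features.index(b) > features.index(a) else a
        logger.info(
            "screening: dropping %r (|coef| %.3f with %r)", victim,
            abs(coef.loc[a, b]), a if victim == b else b,
        )
        retained.remove(victim)
        dropped.append(victim)

    report = CorrelationReport(
        pairs=pd.DataFrame(pair_rows),
        normality=pd.DataFrame(norm_rows),
        retained=retained,
        dropped=dropped,
    )
    return retained, report
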