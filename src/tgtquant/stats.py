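"""Condition comparisons and force-threshold grouping.

Two layers: pairwise two-tailed t-tests between conditions (Welch's
unequal-variance test by default, the pooled Student variant on request),
and a grouping procedure that classifies an ascending force panel into
statistically distinct response levels.  The grouping is an agglomerative
sweep: walking up the force order, a sensor joins the current group unless
it differs significantly from the group's pooled sample, in which case a
new group starts.  Because the sweep performs k-1 boundary tests, each test
runs at alpha/(k-1) (Bonferroni) so that ``alpha`` bounds the probability
of any spurious split across the whole panel.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "ThresholdGrouping",
    "t_test_two_tailed",
    "cross_compare",
    "group_force_levels",
]


@dataclass(frozen=True)
class ComparisonResult:
    """A two-sample comparison: t statistic, two-tailed p, group sizes."""

    condition_a: str
    condition_b: str
    t_statistic: float
    p_value: float
    df: float
    n_a: int
    n_b: int
    mean_difference: float  # mean(a) - mean(b)


@dataclass(frozen=True)
class ThresholdGrouping:
    """Partition of an ascending force panel into contiguous response groups."""

    forces: tuple[float, ...]
    assignments: tuple[int, ...]  # group index per force, 0-based, contiguous
    n_groups: int
    alpha: float

    @property
    def boundaries(self) -> tuple[tuple[float, float], ...]:
        """(force below, force above) pairs where a new group starts."""
        out = []
        for i in range(1, len(self.forces)):
            if self.assignments[i] != self.assignments[i - 1]:
                out.append((self.forces[i - 1], self.forces[i]))
        return tuple(out)


def _validate_sample(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError(f"sample {name} needs n >= 2")
    if np.var(x, ddof=1) == 0:
        raise ValueError(f"sample {name} has zero variance")
    return x


def t_test_two_tailed(
    a: Sequence[float],
    b: Sequence[float],
    equal_var: bool = False,
    label_a: str = "a",
    label_b: str = "b",
) -> ComparisonResult:
    """Two-tailed two-sample t-test (Welch by default).

    Welch's statistic uses per-sample variances and Welch–Satterthwaite
    degrees of freedom; ``equal_var=True`` switches to the classical
    pooled-variance Student test.
    """
    a = _validate_sample(a, label_a)
    b = _validate_sample(b, label_b)
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return ComparisonResult(
        condition_a=label_a,
        condition_b=label_b,
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(res.df),
        n_a=a.size,
        n_b=b.size,
        mean_difference=float(a.mean() - b.mean()),
    )


def _holm(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    m = pvals.size
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(running, 1.0)
    return adj


def cross_compare(
    table: Mapping[str, Sequence[float]], equal_var: bool = False
) -> pd.DataFrame:
    """All pairwise two-tailed t-tests between conditions.

    Raw p-values are the primary output; Holm-adjusted p-values are reported
    alongside for transparency.  Pairs whose test cannot be computed (tiny
    n, zero variance) are flagged in the ``error`` column rather than
    aborting the whole matrix.
    """
    labels = list(table)
    if len(labels) < 2:
        raise ValueError("need at least 2 conditions")
    rows = []
    for la, lb in itertools.combinations(labels, 2):
        row = {"condition_a": la, "condition_b": lb, "error": ""}
        try:
            r = t_test_two_tailed(table[la], table[lb], equal_var, la, lb)
            row.update(
                t_statistic=r.t_statistic, p_value=r.p_value, df=r.df,
                n_a=r.n_a, n_b=r.n_b, mean_difference=r.mean_difference,
            )
        except ValueError as e:
            row.update(
                t_statistic=np.nan, p_value=np.nan, df=np.nan,
                n_a=len(table[la]), n_b=len(table[lb]),
                mean_difference=np.nan, error=str(e),
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    valid = df["p_value"].notna()
    df["p_holm"] = np.nan
    if valid.any():
        df.loc[valid, "p_holm"] = _holm(df.loc[valid, "p_value"].to_numpy())
    return df


def group_force_levels(
    per_sensor_samples: Mapping[float, Sequence[float]],
    alpha: float = 0.05,
    equal_var: bool = False,
) -> ThresholdGrouping:
    """Classify the force panel into contiguous response-level groups.

    Sensors are visited in ascending force order; each is tested (two-tailed
    t-test at the Bonferroni-corrected level alpha/(k-1)) against the pooled
    sample of the current group and starts a new group on a significant
    difference.  ``alpha`` therefore bounds the family-wise probability of
    declaring any extra group on a flat panel.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    forces = sorted(per_sensor_samples)
    if len(forces) != len(set(forces)):
        raise ValueError("duplicate forces")
    samples = {f: _validate_sample(per_sensor_samples[f], str(f)) for f in forces}
    k = len(forces)
    if k == 1:
        return ThresholdGrouping(tuple(forces), (0,), 1, alpha)
    per_test_alpha = alpha / (k - 1)

    assignments = [0]
    current = [samples[forces[0]]]
    group = 0
    for f in forces[1:]:
        pooled = np.concatenate(current)
        res = t_test_two_tailed(pooled, samples[f], equal_var)
        if res.p_value < per_test_alpha:
            group += 1
            current = [samples[f]]
        else:
            current.append(samples[f])
        assignments.append(group)
    return ThresholdGrouping(tuple(forces), tuple(assignments), group + 1, alpha)
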