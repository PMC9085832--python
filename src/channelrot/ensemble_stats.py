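"""Aggregation and testing shared by all structural metrics.

The channel is a homotetramer simulated in independent replicas, so every
structural metric yields one value per (subunit, replica).  Following the
study design these are treated as independent measurements (n = 4 subunits
x 20 replicas = 80) and reported as mean ± SEM; a per-replica-collapsed
variant (n = replicas) is provided so the pseudo-replication choice stays
visible.  Two-sample two-tailed t-tests compare states, Welch by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["TestResult", "summarize", "summarize_by_replica", "two_sample_ttest"]


@dataclass(frozen=True)
class TestResult:
    t_statistic: float
    p_value: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def summarize(values: np.ndarray) -> tuple[float, float, int]:
    """Mean, SEM (sd with n-1 denominator over sqrt(n)) and n of a sample."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    n = int(v.size)
    mean = float(v.mean())
    sem = 0.0 if n == 1 else float(v.std(ddof=1) / np.sqrt(n))
    return mean, sem, n


def summarize_by_replica(df: pd.DataFrame, value_col: str, replica_col: str = "replica"):
    """Summary after collapsing subunit values within each replica (n = replicas)."""
    collapsed = df.groupby(replica_col)[value_col].mean().to_numpy()
    return summarize(collapsed)


def two_sample_ttest(
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    variant: str = "welch",
    alpha: float = 0.05,
) -> TestResult:
    """Two-tailed two-sample t-test.

    ``variant='welch'`` (unequal variances) or ``'pooled'`` (classic
    Student).  Two zero-variance samples with equal means give p = 1 by
    convention.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown variant {variant!r}")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return TestResult(t_statistic=0.0, p_value=1.0, alpha=alpha)
        return TestResult(t_statistic=np.sign(a.mean() - b.mean()) * np.inf,
                          p_value=0.0, alpha=alpha)
    res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return TestResult(t_statistic=float(res.statistic), p_value=float(res.pvalue),
                      alpha=alpha)
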