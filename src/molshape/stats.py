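"""The two inferential statistics the comparative results rely on:
two-sample t tests (biochemical properties between clades) and Kendall rank
correlation (shape PCs vs chemical properties)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import BadParameter, LengthMismatch, TooFewSamples


@dataclass
class TestResult:
    """Outcome of a two-sample t test or a Kendall correlation."""

    statistic: float            # t or tau
    p_value: float              # two-sided
    df: float | None = None
    n: tuple[int, ...] = ()
    variant: str = ""           # pooled | welch | tau-b
    group_means: tuple[float, float] | None = None
    low_power: bool = False


def two_sample_t(x, y, variant: str = "welch") -> TestResult:
    """Two-sided two-sample t test; ``variant`` picks the pooled-variance or
    Welch standard error (and the matching degrees of freedom)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise TooFewSamples("each sample needs at least 2 values")
    if variant not in ("pooled", "welch"):
        raise BadParameter(f"unknown t-test variant {variant!r}")
    res = sps.ttest_ind(x, y, equal_var=(variant == "pooled"))
    return TestResult(statistic=float(res.statistic),
                      p_value=float(res.pvalue), df=float(res.df),
                      n=(len(x), len(y)), variant=variant,
                      group_means=(float(x.mean()), float(y.mean())))


def kendall_tau(x, y) -> TestResult:
    """Kendall tau-b (tie-corrected) with a two-sided p-value: exact over
    the permutation distribution for n <= 10 without ties, the normal
    approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise LengthMismatch(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 2:
        raise TooFewSamples("need at least 2 paired values")
    ties = (len(np.unique(x)) < len(x)) or (len(np.unique(y)) < len(y))
    method = "exact" if (len(x) <= 10 and not ties) else "asymptotic"
    res = sps.kendalltau(x, y, variant="b", method=method)
    return TestResult(statistic=float(res.statistic),
                      p_value=float(res.pvalue), n=(len(x),),
                      variant="tau-b")


@dataclass
class CorrelationGrid:
    """All pairwise Kendall correlations of a trait table; symmetric with a
    unit diagonal."""

    tau: pd.DataFrame
    p_value: pd.DataFrame


def correlation_matrix(traits: pd.DataFrame) -> CorrelationGrid:
    cols = list(traits.columns)
    if len(cols) < 2:
        raise BadParameter("need at least 2 columns")
    k = len(cols)
    tau = np.eye(k)
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            r = kendall_tau(traits[cols[i]], traits[cols[j]])
            tau[i, j] = tau[j, i] = r.statistic
            p[i, j] = p[j, i] = r.p_value
    return CorrelationGrid(pd.DataFrame(tau, index=cols, columns=cols),
                           pd.DataFrame(p, index=cols, columns=cols))
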