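"""Statistical utilities for cross-instance reporting.

One-sample and paired t-tests (two-sided, df = n - 1), percentile
bootstrap confidence bands for learning curves, and Benjamini-Hochberg
FDR flags.  The heavy lifting is delegated to scipy/statsmodels; this
module fixes the reporting conventions (estimates, confidence intervals)
used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class TestResult:
    estimate: float
    t: float
    df: int
    p: float
    ci_low: float
    ci_high: float

    def __str__(self) -> str:  # journal-style reporting line
        return (
            f"mean = {self.estimate:.3f}, t({self.df}) = {self.t:.3f}, "
            f"p = {self.p:.3g}"
        )


def one_sample_t(
    values, null: float = 0.0, ci_level: float = 0.95
) -> TestResult:
    """Two-sided one-sample t-test of the mean against ``null``."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two observations")
    if np.ptp(x) == 0:
        raise ValueError("zero variance sample")
    res = sps.ttest_1samp(x, null)
    ci = res.confidence_interval(ci_level)
    return TestResult(
        estimate=float(x.mean()),
        t=float(res.statistic),
        df=x.size - 1,
        p=float(res.pvalue),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
    )


def paired_t(values_a, values_b, ci_level: float = 0.95) -> TestResult:
    """Paired t-test: one-sample test on the element-wise differences."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    if np.ptp(d) == 0 and d.size >= 2 and d[0] == 0:
        # identical samples: a zero difference with zero spread
        return TestResult(0.0, 0.0, d.size - 1, 1.0, 0.0, 0.0)
    return one_sample_t(d, 0.0, ci_level)


def bootstrap_band(
    values: np.ndarray,
    n_boot: int = 10000,
    level: float = 0.95,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Percentile bootstrap band for the across-instance mean.

    ``values`` is (n_instances, n_rounds); resampling is over instances,
    identically at every round.  Returns mean, lower and upper band.
    """
    x = np.atleast_2d(np.asarray(values, dtype=float))
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least two instances")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = x[idx].mean(axis=1)  # (n_boot, n_rounds)
    alpha = (1.0 - level) / 2.0
    return {
        "mean": x.mean(axis=0),
        "lower": np.quantile(boot_means, alpha, axis=0),
        "upper": np.quantile(boot_means, 1.0 - alpha, axis=0),
    }


def bh_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject
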