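"""Group-level statistics on per-fiber R values.

Each fiber contributes a single R datapoint to its treatment group
(enzyme x washed/unwashed).  The analysis steps are:

1. flag suspected outliers per group (Tukey fences at 1.5 x IQR by default;
   a manual flag list is also accepted, mirroring eyeballed exclusion);
2. pool the washed and unwashed groups of the same enzyme when a
   pooled-variance two-sample test finds no difference between them;
3. compare enzymes with the pooled-variance two-sample t-test:

   s²_pooled = (SS1 + SS2) / (n1 + n2 - 2)
   SEM_diff  = sqrt(s²_pooled x (1/n1 + 1/n2))
   CI        = (mean1 - mean2) ± t_crit(n1+n2-2, alpha) x SEM_diff

   and the difference is declared significant iff the CI excludes 0
   (algebraically the same decision as |t| > t_crit).

Note the two distinct standard errors: :func:`sem_of_mean` is the standard
error of a *single group's mean* (sd/sqrt(n), the error bar on a group
mean), while ``TestResult.sem`` is the standard error of a *difference of
means*.  Both travel under the acronym SEM in practice; they are named
apart here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RGroup",
    "TestResult",
    "PoolingRefusal",
    "flag_outliers",
    "sem_of_mean",
    "critical_t",
    "pooled_two_sample_test",
    "pooled_test_from_summary",
    "pool_washed_unwashed",
]


@dataclass
class RGroup:
    """Per-fiber R values of one treatment group.

    ``washed`` is True/False, or None for a pooled washed+unwashed group.
    """

    label: str
    R_values: np.ndarray
    washed: bool | None = False
    outlier_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.R_values = np.asarray(self.R_values, dtype=float)
        if self.R_values.ndim != 1:
            raise ValueError("R_values must be one-dimensional")
        if np.any(self.R_values <= 0):
            raise ValueError("R values must be positive")
        if self.outlier_flags is None:
            self.outlier_flags = np.zeros(len(self.R_values), dtype=bool)
        else:
            self.outlier_flags = np.asarray(self.outlier_flags, dtype=bool)
            if self.outlier_flags.shape != self.R_values.shape:
                raise ValueError("outlier_flags must parallel R_values")

    @property
    def n(self) -> int:
        return len(self.R_values)

    def without_outliers(self) -> "RGroup":
        """Group restricted to unflagged values (flag removal is explicit)."""
        keep = ~self.outlier_flags
        if keep.sum() < 2:
            raise ValueError(
                f"group {self.label!r} has fewer than 2 values after "
                "outlier removal"
            )
        return RGroup(
            label=self.label,
            R_values=self.R_values[keep],
            washed=self.washed,
        )


@dataclass(frozen=True)
class TestResult:
    """Full record of one pooled-variance two-sample comparison."""

    mean1: float
    mean2: float
    n1: int
    n2: int
    ss1: float
    ss2: float
    s2_pooled: float
    sem: float
    t_crit: float
    mean_diff: float
    ci_low: float
    ci_high: float
    significant: bool
    alpha: float = 0.05

    @property
    def df(self) -> int:
        return self.n1 + self.n2 - 2

    def as_dict(self) -> dict:
        return {
            "mean1": self.mean1, "mean2": self.mean2,
            "n1": self.n1, "n2": self.n2,
            "ss1": self.ss1, "ss2": self.ss2,
            "s2_pooled": self.s2_pooled, "sem": self.sem,
            "t_crit": self.t_crit, "mean_diff": self.mean_diff,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "significant": self.significant, "alpha": self.alpha,
        }


class PoolingRefusal(RuntimeError):
    """Washed/unwashed groups differ; pooling refused."""

    def __init__(self, test: TestResult):
        self.test = test
        super().__init__(
            f"washed and unwashed groups differ (mean diff "
            f"{test.mean_diff:.4g}, CI [{test.ci_low:.4g}, "
            f"{test.ci_high:.4g}]); refusing to pool"
        )


def flag_outliers(values: np.ndarray | list[float]) -> np.ndarray:
    """Tukey-fence outlier flags: outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Quartiles use the inclusive-median convention.  With fewer than 4
    values no flagging is attempted (a warning is issued) — the fences are
    meaningless at that size.  Flags only; removal is a separate step.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if len(v) < 4:
        warnings.warn(
            f"outlier flagging skipped: need at least 4 values, got {len(v)}",
            stacklevel=2,
        )
        return np.zeros(len(v), dtype=bool)
    s = np.sort(v)
    half = (len(s) + 1) // 2  # inclusive-median halves (Tukey hinges)
    q1 = float(np.median(s[:half]))
    q3 = float(np.median(s[len(s) - half:]))
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return (v < lo) | (v > hi)


def sem_of_mean(values: np.ndarray | list[float]) -> float:
    """Standard error of one group's mean: sample sd (n-1) over sqrt(n)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("SEM of a mean needs at least 2 values")
    return float(np.std(v, ddof=1) / math.sqrt(len(v)))


def critical_t(df: int, alpha: float = 0.05) -> float:
    """Two-tailed critical value of the central t distribution."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return float(stats.t.ppf(1.0 - alpha / 2.0, df))


def pooled_test_from_summary(
    mean1: float, mean2: float, n1: int, n2: int,
    ss1: float, ss2: float, alpha: float = 0.05,
) -> TestResult:
    """Pooled-variance comparison from sufficient statistics.

    ``ss1``/``ss2`` are sums of squared deviations about each group mean.
    Edge case: zero pooled variance gives a zero-width CI at the mean
    difference — significant iff the means differ.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 values")
    if ss1 < 0 or ss2 < 0:
        raise ValueError("sums of squares must be non-negative")
    df = n1 + n2 - 2
    s2_pooled = (ss1 + ss2) / df
    sem = math.sqrt(s2_pooled * (1.0 / n1 + 1.0 / n2))
    t_crit = critical_t(df, alpha)
    mean_diff = mean1 - mean2
    ci_low = mean_diff - t_crit * sem
    ci_high = mean_diff + t_crit * sem
    significant = not (ci_low <= 0.0 <= ci_high)
    return TestResult(
        mean1=float(mean1), mean2=float(mean2), n1=n1, n2=n2,
        ss1=float(ss1), ss2=float(ss2), s2_pooled=float(s2_pooled),
        sem=float(sem), t_crit=float(t_crit), mean_diff=float(mean_diff),
        ci_low=float(ci_low), ci_high=float(ci_high),
        significant=bool(significant), alpha=alpha,
    )


def pooled_two_sample_test(
    g1: RGroup, g2: RGroup, alpha: float = 0.05
) -> TestResult:
    """Pooled-variance two-sample t-test between two groups of R values.

    Outliers are expected to be resolved before calling (values flagged in
    the groups are *not* dropped here; use :meth:`RGroup.without_outliers`).
    """
    v1, v2 = g1.R_values, g2.R_values
    if len(v1) < 2 or len(v2) < 2:
        raise ValueError("each group needs at least 2 values")
    ss1 = float(np.sum((v1 - v1.mean()) ** 2))
    ss2 = float(np.sum((v2 - v2.mean()) ** 2))
    return pooled_test_from_summary(
        float(v1.mean()), float(v2.mean()), len(v1), len(v2), ss1, ss2, alpha
    )


def pool_washed_unwashed(
    g_washed: RGroup, g_unwashed: RGroup, alpha: float = 0.05
) -> RGroup:
    """Merge the washed/unwashed groups of one enzyme when justified.

    Runs the pooled-variance test between them; if not significant at
    ``alpha``, returns the merged group (washed = None).  If significant,
    raises :class:`PoolingRefusal` carrying the test so the caller can
    report it.
    """
    if g_washed.label != g_unwashed.label:
        raise ValueError(
            f"cannot pool different enzymes: {g_washed.label!r} vs "
            f"{g_unwashed.label!r}"
        )
    test = pooled_two_sample_test(g_washed, g_unwashed, alpha)
    if test.significant:
        raise PoolingRefusal(test)
    return RGroup(
        label=g_washed.label,
        R_values=np.concatenate([g_washed.R_values, g_unwashed.R_values]),
        washed=None,
        outlier_flags=np.concatenate(
            [g_washed.outlier_flags, g_unwashed.outlier_flags]
        ),
    )
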