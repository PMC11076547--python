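"""Shared statistical machinery.

All bespoke hypothesis tests in this package are permutation tests built
on one framework: a statistic is computed on the observed units, a
*resampler* draws a null replicate of the statistic (resampling without
replacement within each draw), and the p-value uses the add-one
convention

    p = (#{null statistics at least as extreme} + 1) / (n_resamples + 1),

which is conservative and bounds p from below by 1/(n_resamples+1).
Classical tests (Spearman rank correlation, two-sample Kolmogorov-
Smirnov, Fisher's exact) are delegated to scipy.stats and wrapped so
every test in the package emits the same :class:`TestResult` record.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass
from typing import Callable

import numpy as np
from scipy import stats as sps

from .model import InsufficientDataError, ParameterError

__all__ = [
    "TestResult",
    "permutation_test",
    "spearman_correlation",
    "ks_two_sample",
    "fisher_exact",
]


@dataclass(frozen=True)
class TestResult:
    """Uniform record of a hypothesis-test outcome.

    ``observed`` is the test statistic; ``null_value`` is the mean of the
    null-resampled statistics for permutation tests (None otherwise);
    ``n`` is the sample size, or a tuple of group sizes.
    """

    __test__ = False  # not a test class, despite the name

    method: str
    observed: float
    p_value: float
    n: int | tuple[int, ...]
    alternative: str
    null_value: float | None = None
    n_resamples: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def permutation_test(
    observed: float,
    null_statistic: Callable[[np.random.Generator], float],
    n_resamples: int = 10_000,
    alternative: str = "less",
    seed: int | None = None,
    method: str = "permutation",
    n: int | tuple[int, ...] = 0,
) -> TestResult:
    """Generic permutation test with add-one p-value.

    Parameters
    ----------
    observed
        Statistic computed on the observed configuration.
    null_statistic
        Callable drawing one null replicate of the statistic from the
        supplied random generator.  Each call must resample without
        replacement within the draw (the framework does not check this;
        it is the contract of the resampler).
    alternative
        ``"less"`` (observed expected smaller than null), ``"greater"``,
        or ``"two-sided"``.
    """
    if n_resamples < 100:
        warnings.warn(f"n_resamples={n_resamples} is very small; "
                      "p-value resolution is 1/(n_resamples+1)")
    if not np.isfinite(observed):
        raise ValueError("observed statistic is not finite")
    if alternative not in ("less", "greater", "two-sided"):
        raise ParameterError(f"unknown alternative {alternative!r}")
    rng = np.random.default_rng(seed)
    null = np.array([null_statistic(rng) for _ in range(n_resamples)])
    if not np.all(np.isfinite(null)):
        raise ValueError("null statistic produced non-finite values")

    if alternative == "less":
        extreme = int(np.sum(null <= observed))
    elif alternative == "greater":
        extreme = int(np.sum(null >= observed))
    else:
        centre = float(null.mean())
        extreme = int(np.sum(np.abs(null - centre) >= abs(observed - centre)))
    p = (extreme + 1) / (n_resamples + 1)
    return TestResult(
        method=method, observed=float(observed), p_value=p, n=n,
        alternative=alternative, null_value=float(null.mean()),
        n_resamples=n_resamples, seed=seed,
    )


def spearman_correlation(x, y) -> TestResult:
    """Spearman rank correlation with mid-rank ties, two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise InsufficientDataError("need at least 3 pairs for a rank correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InsufficientDataError("rank correlation undefined for constant input")
    r, p = sps.spearmanr(x, y)
    return TestResult(method="spearman", observed=float(r),
                      p_value=max(float(p), np.finfo(float).tiny),
                      n=int(x.size), alternative="two-sided")


def ks_two_sample(a, b) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test (asymptotic two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both samples must be non-empty")
    res = sps.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return TestResult(method="ks_two_sample", observed=float(res.statistic),
                      p_value=max(float(res.pvalue), np.finfo(float).tiny),
                      n=(int(a.size), int(b.size)),
                      alternative="two-sided")


def fisher_exact(table) -> TestResult:
    """Fisher's exact test on a 2x2 table, two-sided.

    The reported odds ratio is the sample odds ratio (a*d)/(b*c); when a
    cell is zero it is computed with the Haldane-Anscombe 0.5 correction
    and the result's method name is suffixed ``"+haldane"`` (the exact
    p-value is unaffected).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("need a 2x2 table of non-negative integers")
    (a, b), (c, d) = t
    _, p = sps.fisher_exact(t, alternative="two-sided")
    method = "fisher_exact"
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        method += "+haldane"
    oddsratio = (a * d) / (b * c)
    return TestResult(method=method, observed=float(oddsratio),
                      p_value=float(p), n=int(t.sum()),
                      alternative="two-sided")
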