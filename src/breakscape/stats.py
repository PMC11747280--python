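"""Statistics kernels matching the study's reporting conventions.

Two-group comparisons with equal n use a one-tailed paired t-test; unequal-n
comparisons use Welch's t (unequal-variance two-sample t with Satterthwaite
degrees of freedom). Box summaries use type-7 (linear-interpolation)
quartiles with whiskers one IQR beyond each quartile, not clamped to data.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .model import ValidationError


class DegenerateInputError(ValueError):
    """Raised when a test statistic is undefined (e.g. zero variance)."""


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    tails: str  # "one" or "two"
    flavor: str  # "paired" or "welch"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError("p-value outside [0, 1]")
        if self.df <= 0:
            raise ValidationError("non-positive degrees of freedom")


@dataclass(frozen=True)
class BoxSummary:
    q1: float
    median: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    n: int


def _check_tails(tails: str) -> None:
    if tails not in ("one", "two"):
        raise ValidationError(f"tails must be 'one' or 'two', got {tails!r}")


def _p_from_t(t: float, df: float, tails: str) -> float:
    # one-tailed p is for the "greater" alternative
    if tails == "one":
        return float(sps.t.sf(t, df))
    return float(2.0 * sps.t.sf(abs(t), df))


def paired_t(x, y, tails: str = "one") -> TestResult:
    """Paired t-test; one-tailed p is for mean(x - y) > 0."""
    _check_tails(tails)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("paired_t requires two equal-length vectors")
    n = len(x)
    if n < 2:
        raise ValidationError("paired_t requires n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("all paired differences are equal")
    t = float(d.mean() / (sd / np.sqrt(n)))
    df = n - 1
    return TestResult(t, df, _p_from_t(t, df, tails), tails, "paired")


def one_sample_t(x, popmean: float = 1.0, tails: str = "one") -> TestResult:
    """One-sample t against a reference value (paired-vs-constant)."""
    x = np.asarray(x, dtype=float)
    return paired_t(x, np.full_like(x, popmean), tails=tails)


def welch_t(x, y, tails: str = "one") -> TestResult:
    """Welch's unequal-variance t; one-tailed p is for mean(x) > mean(y)."""
    _check_tails(tails)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) < 2 or len(y) < 2:
        raise ValidationError("welch_t requires two vectors with n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    if se2 == 0:
        raise DegenerateInputError("both samples have zero variance")
    t = float((x.mean() - y.mean()) / np.sqrt(se2))
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return TestResult(t, float(df), _p_from_t(t, float(df), tails), tails, "welch")


def box_summary(values) -> BoxSummary:
    """Quartile/IQR box summary (type-7 quantiles, whiskers at q +/- IQR)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("box_summary of an empty vector")
    q1, med, q3 = (float(q) for q in np.quantile(v, [0.25, 0.5, 0.75]))
    iqr = q3 - q1
    return BoxSummary(q1, med, q3, q1 - iqr, q3 + iqr, int(v.size))


def significance_stars(p: float) -> str:
    """Star annotation: *P<0.05, **P<0.01, ***P<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
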