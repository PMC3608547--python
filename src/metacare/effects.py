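"""Effect-size conversion for comparative meta-analysis.

Reported test statistics (t, F, chi-square, z, two-tailed p, or a raw
correlation) are converted to a signed Pearson correlation r, then to
Fisher's Z, ``zr = atanh(r)``, whose large-sample sampling variance is
``1/(n - 3)``.  Inverse-variance weights ``n - 3`` follow directly.
Posterior summaries on the Z scale are mapped back to r with ``tanh``.

Because most test statistics discard the direction of the association,
every conversion requires an explicit sign; records without a stated
direction are rejected rather than defaulted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from scipy import stats as _stats

__all__ = [
    "TestStatistic",
    "EffectSize",
    "statistic_to_r",
    "fisher_z",
    "back_transform",
    "zr_variance",
    "two_tailed_p",
]

_STAT_KINDS = ("t", "F", "chi2", "r", "z", "p_two_tailed")

#: statistic kinds whose reported value can itself carry a sign
_SIGNED_KINDS = ("t", "r", "z")


@dataclass(frozen=True)
class TestStatistic:
    """A test statistic as reported in a primary study.

    Parameters
    ----------
    kind:
        One of ``t``, ``F``, ``chi2``, ``r``, ``z``, ``p_two_tailed``.
    value:
        The reported value (for ``t`` the t statistic, for ``r`` the
        correlation itself, for ``p_two_tailed`` the two-tailed p value).
    df1:
        Degrees of freedom (the df of a t test; numerator df of an F).
    df2:
        Denominator df of an F test.
    n:
        Total sample size of the study; required to attach a sampling
        variance and for chi2/z/p conversions.
    sign:
        Direction of the paternity-care relationship, +1 or -1.
        Mandatory for kinds that cannot carry a sign (F, chi2,
        p_two_tailed); optional for t/r/z where the value's own sign is
        used when no explicit direction is given.
    """

    kind: str
    value: float
    df1: Optional[int] = None
    df2: Optional[int] = None
    n: Optional[int] = None
    sign: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in _STAT_KINDS:
            raise ValueError(f"unknown statistic kind {self.kind!r}")
        if not math.isfinite(self.value):
            raise ValueError("statistic value must be finite")
        if self.sign is not None and self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")
        if self.kind == "p_two_tailed" and not (0.0 < self.value <= 1.0):
            raise ValueError("p value must lie in (0, 1]")
        if self.kind in ("F", "chi2") and self.value < 0:
            raise ValueError(f"{self.kind} statistic must be non-negative")
        if self.kind == "r" and not abs(self.value) < 1:
            raise ValueError("reported r must satisfy |r| < 1")

    @property
    def direction(self) -> int:
        """Resolved sign of the effect (+1/-1)."""
        if self.sign is not None:
            return self.sign
        if self.kind in _SIGNED_KINDS:
            if self.value == 0:
                return 1
            return 1 if self.value > 0 else -1
        raise ValueError(
            f"{self.kind} statistics carry no direction; an explicit sign is required"
        )


def statistic_to_r(stat: TestStatistic) -> float:
    """Convert a reported test statistic to a signed Pearson r.

    Conversions follow the standard meta-analytic formulas:
    ``r = sqrt(t^2 / (t^2 + df))``, ``r = sqrt(F / (F + df2))`` (only for
    numerator df 1), ``r = sqrt(chi2 / n)``, ``r = z / sqrt(n)``, and for a
    two-tailed p the corresponding standard-normal quantile divided by
    ``sqrt(n)``.
    """
    sign = stat.direction
    kind = stat.kind
    if kind == "r":
        return abs(stat.value) * sign
    if kind == "t":
        if stat.df1 is None or stat.df1 <= 0:
            raise ValueError("t statistic requires df1 > 0")
        t2 = stat.value**2
        return sign * math.sqrt(t2 / (t2 + stat.df1))
    if kind == "F":
        if stat.df1 != 1:
            raise ValueError(
                "F statistics with numerator df > 1 have no unique r conversion"
            )
        if stat.df2 is None or stat.df2 <= 0:
            raise ValueError("F statistic requires df2 > 0")
        return sign * math.sqrt(stat.value / (stat.value + stat.df2))
    if kind == "chi2":
        _require_n(stat)
        r = math.sqrt(stat.value / stat.n)
        if r >= 1:
            raise ValueError("chi2/n >= 1 implies |r| >= 1; statistic unusable")
        return sign * r
    if kind == "z":
        _require_n(stat)
        r = abs(stat.value) / math.sqrt(stat.n)
        if r >= 1:
            raise ValueError("z/sqrt(n) >= 1 implies |r| >= 1; statistic unusable")
        return sign * r
    if kind == "p_two_tailed":
        _require_n(stat)
        z = float(_stats.norm.isf(stat.value / 2.0))
        r = z / math.sqrt(stat.n)
        if r >= 1:
            raise ValueError("p-derived z/sqrt(n) >= 1; statistic unusable")
        return sign * r
    raise ValueError(f"unsupported statistic kind {kind!r}")  # pragma: no cover


def _require_n(stat: TestStatistic) -> None:
    if stat.n is None or stat.n <= 0:
        raise ValueError(f"{stat.kind} conversion requires a positive sample size n")


def fisher_z(r: float) -> float:
    """Fisher's variance-stabilising transform ``zr = atanh(r)``."""
    if not abs(r) < 1:
        raise ValueError("|r| must be < 1 for Fisher's Z")
    return math.atanh(r)


def back_transform(zr: float) -> float:
    """Inverse of :func:`fisher_z`: ``r = tanh(zr)``."""
    return math.tanh(zr)


def zr_variance(n: int) -> float:
    """Large-sample variance of Fisher's Z, ``1/(n - 3)``.

    Requires ``n >= 4``; studies with fewer observations carry no usable
    effect size.
    """
    if n is None or n <= 3:
        raise ValueError("effect size unusable: sampling variance requires n >= 4")
    return 1.0 / (n - 3)


@dataclass(frozen=True)
class EffectSize:
    """One converted effect size on both the r and Fisher-Z scales."""

    r: float
    zr: float
    n: int
    var_zr: float
    weight: float

    def __post_init__(self) -> None:
        if not abs(self.r) < 1:
            raise ValueError("|r| must be < 1")
        if abs(self.zr - math.atanh(self.r)) > 1e-12:
            raise ValueError("zr inconsistent with atanh(r)")
        if self.var_zr <= 0 or abs(self.weight * self.var_zr - 1.0) > 1e-9:
            raise ValueError("weight must equal 1/var_zr with var_zr > 0")

    @classmethod
    def from_r(cls, r: float, n: int) -> "EffectSize":
        var = zr_variance(n)
        return cls(r=r, zr=fisher_z(r), n=n, var_zr=var, weight=1.0 / var)

    @classmethod
    def from_statistic(cls, stat: TestStatistic) -> "EffectSize":
        if stat.n is None:
            raise ValueError("sample size n is required to build an EffectSize")
        return cls.from_r(statistic_to_r(stat), stat.n)


def two_tailed_p(stat: TestStatistic) -> float:
    """Two-tailed p value reconstructed from a reported statistic.

    Used to profile what fraction of primary studies would have been
    counted as "significant" under conventional vote-counting.
    """
    kind = stat.kind
    if kind == "p_two_tailed":
        return stat.value
    if kind == "t":
        if stat.df1 is None or stat.df1 <= 0:
            raise ValueError("t statistic requires df1 > 0")
        return 2.0 * float(_stats.t.sf(abs(stat.value), stat.df1))
    if kind == "F":
        if stat.df1 is None or stat.df2 is None:
            raise ValueError("F statistic requires df1 and df2")
        return float(_stats.f.sf(stat.value, stat.df1, stat.df2))
    if kind == "chi2":
        df = stat.df1 if stat.df1 is not None else 1
        return float(_stats.chi2.sf(stat.value, df))
    if kind == "z":
        return 2.0 * float(_stats.norm.sf(abs(stat.value)))
    if kind == "r":
        _require_n(stat)
        if stat.n <= 2:
            raise ValueError("p from r requires n > 2")
        df = stat.n - 2
        denom = 1.0 - stat.value**2
        t = abs(stat.value) * math.sqrt(df / denom)
        return 2.0 * float(_stats.t.sf(t, df))
    raise ValueError(f"unsupported statistic kind {kind!r}")  # pragma: no cover
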