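"""Two-group inference at the target wavelength.

The group comparison of the 930 nm lipid score is an unpaired pooled-variance
(Student) t-test preceded by a Shapiro–Wilk normality check, reported with
Cohen's d.  Two entry points are provided:

* :func:`compare_groups` — operates on raw per-subject values (scipy-backed).
* :func:`t_test_summary` / :func:`cohens_d_summary` — closed forms on summary
  statistics (mean, SEM, n), which is how printed group tables are
  recomputed when raw data are unavailable.

The pooled test uses sd_i = sem_i * sqrt(n_i),
sp^2 = ((n1-1) sd1^2 + (n2-1) sd2^2) / (n1+n2-2),
t = (m1-m2) / (sp * sqrt(1/n1 + 1/n2)), df = n1+n2-2, and
d = (m1-m2)/sp.  A Welch variant is available but is not the default because
equal-variance pooling is the convention the summary tables follow.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics of one group: n, mean and SEM."""

    label: str
    n: int
    mean: float
    sem: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError("group size must be >= 2")
        if self.sem < 0:
            raise ValidationError("SEM must be non-negative")

    @property
    def sd(self) -> float:
        return self.sem * math.sqrt(self.n)

    @classmethod
    def from_values(cls, values: Sequence[float], label: str = "") -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise ValidationError("need at least 2 values")
        return cls(
            label=label,
            n=int(v.size),
            mean=float(v.mean()),
            sem=float(v.std(ddof=1) / math.sqrt(v.size)),
        )


@dataclass(frozen=True)
class GroupComparison:
    """Result of a two-group test at one wavelength."""

    group_a: GroupSummary
    group_b: GroupSummary
    t_statistic: float
    df: float
    p_two_sided: float
    cohens_d: float
    method: str = "student"
    normality_p: tuple[float, float] | None = None
    mannwhitney_p: float | None = None

    def to_record(self) -> dict:
        rec = {
            "groups": {
                s.label or k: {"n": s.n, "mean": s.mean, "sem": s.sem}
                for k, s in (("a", self.group_a), ("b", self.group_b))
            },
            "t": self.t_statistic,
            "df": self.df,
            "p": self.p_two_sided,
            "cohens_d": self.cohens_d,
            "method": self.method,
        }
        if self.normality_p is not None:
            rec["shapiro_p"] = list(self.normality_p)
        if self.mannwhitney_p is not None:
            rec["mannwhitney_p"] = self.mannwhitney_p
        return rec


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk W and p for a small sample (3 <= n <= 50)."""
    v = np.asarray(values, dtype=float)
    if not 3 <= v.size <= 50:
        raise ValidationError("Shapiro-Wilk supported for 3 <= n <= 50")
    if np.ptp(v) == 0:
        raise DegenerateDataError("Shapiro-Wilk undefined on a constant sample")
    w, p = stats.shapiro(v)
    return float(w), float(p)


def _pooled_sd(a: GroupSummary, b: GroupSummary) -> float:
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
    return math.sqrt(sp2)


def t_test_summary(
    a: GroupSummary, b: GroupSummary, welch: bool = False
) -> GroupComparison:
    """Unpaired two-sided t-test from summary statistics.

    Default is the pooled-variance Student test (df = n1+n2-2); ``welch=True``
    switches to the Welch unequal-variance test with Satterthwaite df.
    """
    diff = a.mean - b.mean
    if welch:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        se = math.sqrt(va + vb)
        if se == 0:
            return _degenerate_comparison(a, b, diff, method="welch")
        t = diff / se
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
        method = "welch"
    else:
        sp = _pooled_sd(a, b)
        if sp == 0:
            return _degenerate_comparison(a, b, diff, method="student")
        t = diff / (sp * math.sqrt(1 / a.n + 1 / b.n))
        df = a.n + b.n - 2
        method = "student"
    p = 2 * stats.t.sf(abs(t), df)
    return GroupComparison(
        group_a=a,
        group_b=b,
        t_statistic=float(t),
        df=float(df),
        p_two_sided=float(p),
        cohens_d=cohens_d_summary(a, b),
        method=method,
    )


def _degenerate_comparison(
    a: GroupSummary, b: GroupSummary, diff: float, method: str
) -> GroupComparison:
    if diff != 0:
        raise DegenerateDataError(
            "zero pooled variance with unequal means: t undefined"
        )
    return GroupComparison(
        group_a=a, group_b=b, t_statistic=0.0, df=float(a.n + b.n - 2),
        p_two_sided=1.0, cohens_d=0.0, method=method,
    )


def cohens_d_summary(a: GroupSummary, b: GroupSummary) -> float:
    """Standardized mean difference (m1-m2)/sp with the pooled sd."""
    sp = _pooled_sd(a, b)
    if sp == 0:
        if a.mean == b.mean:
            return 0.0
        raise DegenerateDataError("zero pooled variance: Cohen's d undefined")
    return (a.mean - b.mean) / sp


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    gate_alpha: float = 0.05,
    labels: tuple[str, str] = ("a", "b"),
    welch: bool = False,
) -> GroupComparison:
    """Shapiro–Wilk gate followed by an unpaired t-test on raw values.

    If either group fails the normality gate the t-test is still reported (the
    convention the summary tables follow) but a warning is logged and a
    Mann–Whitney U p-value is attached as a rank-based fallback.
    """
    va = np.asarray(values_a, dtype=float)
    vb = np.asarray(values_b, dtype=float)
    if va.size < 2 or vb.size < 2:
        raise ValidationError("need n >= 2 per group")

    def _gate(v: np.ndarray) -> float:
        # The gate needs n >= 3 and a non-constant sample (e.g. every
        # normalized spectrum peaking exactly at the target wavelength makes
        # the group constant); it is skipped, not fatal, in those cases.
        if v.size < 3:
            logger.warning("n < 3; Shapiro-Wilk gate skipped")
            return float("nan")
        try:
            return shapiro_wilk(v)[1]
        except DegenerateDataError:
            logger.warning("constant group; Shapiro-Wilk gate skipped")
            return float("nan")

    shapiro_ps = (_gate(va), _gate(vb))
    finite_ps = [p for p in shapiro_ps if not math.isnan(p)]
    mw_p = None
    if finite_ps and min(finite_ps) < gate_alpha:
        logger.warning(
            "normality gate failed (Shapiro p = %.4g, %.4g < alpha = %g); "
            "reporting t-test plus Mann-Whitney fallback",
            shapiro_ps[0], shapiro_ps[1], gate_alpha,
        )
        mw_p = float(stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue)

    a = GroupSummary.from_values(va, labels[0])
    b = GroupSummary.from_values(vb, labels[1])
    sp = _pooled_sd(a, b)
    if sp == 0:
        # Both groups constant: t = 0, p = 1 when equal, undefined otherwise.
        if a.mean != b.mean:
            raise DegenerateDataError("zero pooled variance with unequal means")
        deg = _degenerate_comparison(a, b, 0.0, "welch" if welch else "student")
        return GroupComparison(
            group_a=a, group_b=b, t_statistic=deg.t_statistic, df=deg.df,
            p_two_sided=deg.p_two_sided, cohens_d=deg.cohens_d,
            method=deg.method, normality_p=shapiro_ps, mannwhitney_p=mw_p,
        )
    res = stats.ttest_ind(va, vb, equal_var=not welch)
    return GroupComparison(
        group_a=a,
        group_b=b,
        t_statistic=float(res.statistic),
        df=float(res.df),
        p_two_sided=float(res.pvalue),
        cohens_d=float((a.mean - b.mean) / sp),
        method="welch" if welch else "student",
        normality_p=shapiro_ps,
        mannwhitney_p=mw_p,
    )
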