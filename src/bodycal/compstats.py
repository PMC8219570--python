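"""Body-composition measurement statistics.

Utilities for validating bioimpedance (BIA) composition estimates against
skinfold anthropometry: ISAK repeat-measurement consolidation, the Jackson
& Pollock 4-site percent-body-fat equations (abdominal, tricep, front
thigh, iliac crest), Bland–Altman agreement between paired methods, and
test–retest reliability via the intraclass correlation coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

#: Jackson & Pollock 4-site quadratic coefficients: %BF =
#: a*S + b*S^2 + c*age + d, with S the 4-site skinfold sum in mm.
_JP_COEF = {
    "male": (0.29288, -0.0005, 0.15845, -5.76377),
    "female": (0.29669, -0.00043, 0.02963, 1.4072),
}


class IncompleteMeasurementError(ValueError):
    """A third skinfold repeat is required but missing."""


def isak_value(m1: float, m2: float, m3: float | None = None) -> float:
    """Consolidate repeated skinfold measures per the ISAK rule.

    The mean of two measurements is used unless they differ by >= 5%
    (relative to their mean), in which case a third measure is required and
    the median of the three is used.
    """
    if m1 <= 0 or m2 <= 0:
        raise ValueError("skinfold measures must be positive")
    rel = abs(m1 - m2) / ((m1 + m2) / 2.0)
    if rel < 0.05:
        return (m1 + m2) / 2.0
    if m3 is None:
        raise IncompleteMeasurementError(
            f"measures differ by {100 * rel:.1f}% (>= 5%); third measure required"
        )
    if m3 <= 0:
        raise ValueError("skinfold measures must be positive")
    return float(np.median([m1, m2, m3]))


def jackson_pollock_bodyfat(sex: str, S: float, age: float) -> float:
    """Percent body fat from the 4-site skinfold sum S (mm) and age (years).

    Results outside [0, 75]% are returned but flagged implausible with a
    warning (the quadratic is only meaningful over ordinary skinfold sums).
    """
    if sex not in _JP_COEF:
        raise ValueError("sex must be 'male' or 'female'")
    if S < 0:  # S = 0 is allowed as a limit case (constant term only)
        raise ValueError("skinfold sum must be nonnegative")
    if age < 0:
        raise ValueError("age must be nonnegative")
    a, b, c, d = _JP_COEF[sex]
    pct = a * S + b * S * S + c * age + d
    if not 0.0 <= pct <= 75.0:
        warnings.warn(f"implausible percent body fat {pct:.2f}% (S={S}, age={age})")
    return float(pct)


def fat_mass_from_percent(percent: float, weight: float) -> float:
    """Total fat mass (kg) from percent body fat and body weight (kg)."""
    if not 0.0 <= percent <= 100.0:
        raise ValueError("percent must be in [0, 100]")
    if weight <= 0:
        raise ValueError("weight must be positive")
    return weight * percent / 100.0


@dataclass
class AgreementStats:
    """Bland–Altman agreement between two paired measurement methods."""

    mean_diff: float
    sd_diff: float
    loa_low: float  # mean_diff - 1.96 * sd_diff
    loa_high: float  # mean_diff + 1.96 * sd_diff
    pearson_r: float
    n: int


def bland_altman(a: np.ndarray, b: np.ndarray) -> AgreementStats:
    """Bland–Altman statistics for paired measurements (differences a − b).

    Limits of agreement are mean ± 1.96 SD of the differences; the Pearson
    correlation of a vs b is reported alongside.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D arrays of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        r = np.nan
    else:
        r = float(stats.pearsonr(a, b).statistic)
    return AgreementStats(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - 1.96 * sd_diff,
        loa_high=mean_diff + 1.96 * sd_diff,
        pearson_r=r,
        n=a.size,
    )


def icc_agreement(t1: np.ndarray, t2: np.ndarray, kind: str = "single") -> float:
    """Two-way, absolute-agreement intraclass correlation for test–retest.

    ``kind='single'`` gives ICC(2,1) (reliability of one measurement),
    ``kind='average'`` gives ICC(2,k) for the mean of both occasions.
    Computed from the standard two-way ANOVA mean squares with subjects as
    random rows and occasions as columns.
    """
    t1 = np.asarray(t1, float)
    t2 = np.asarray(t2, float)
    if t1.shape != t2.shape or t1.ndim != 1:
        raise ValueError("t1 and t2 must be 1-D arrays of equal length")
    n = t1.size
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if kind not in ("single", "average"):
        raise ValueError("kind must be 'single' or 'average'")
    x = np.column_stack([t1, t2])
    k = 2
    grand = x.mean()
    subj_means = x.mean(axis=1)
    occ_means = x.mean(axis=0)
    ss_rows = k * np.sum((subj_means - grand) ** 2)
    ss_cols = n * np.sum((occ_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if msr <= 0 or np.isclose(ss_rows, 0.0):
        warnings.warn("zero between-subject variance; ICC undefined")
        return np.nan
    if kind == "single":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    else:
        denom = msr + (msc - mse) / n
    return float((msr - mse) / denom)
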