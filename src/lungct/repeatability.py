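"""Repeatability and agreement statistics (Bland–Altman style).

Measurement error of the volume quantification is characterised from
repeated scans of the same animals: the within-subject standard deviation
sw is the square root of the residual mean square of a one-way ANOVA with
subject as the factor, and the 95% repeatability coefficient
1.96·√2·sw is the range within which 95% of paired repeat readings on one
subject are expected to fall. Heteroscedasticity (error growing with
magnitude) is screened by the Spearman correlation of per-subject mean
against per-subject SD. Agreement between the image-derived volume and an
external standard (histology score, collagen content) is summarised by
ordinary least squares with 95% prediction intervals. Group comparisons
use Welch's t-test throughout — the unequal-variance correction is always
applied, which is uniformly valid and avoids an ad-hoc trigger rule.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RepeatedMeasures",
    "RepeatabilityReport",
    "AgreementFit",
    "within_subject_sd",
    "repeatability_coefficient",
    "variance_magnitude_check",
    "agreement_regression",
    "welch_t_test",
    "repeatability_report",
]

#: 1.96 · √2 — multiplies sw to give the 95% repeatability coefficient
RC_FACTOR = 1.96 * math.sqrt(2.0)


@dataclass
class RepeatedMeasures:
    """Repeated measurements grouped by subject.

    Subjects contributing a single measurement carry no information about
    within-subject variability; they are dropped with a warning when sw is
    estimated.
    """

    groups: dict[str, np.ndarray]

    @classmethod
    def from_arrays(cls, subject_ids, measurements) -> "RepeatedMeasures":
        df = pd.DataFrame({"subject": subject_ids, "value": measurements})
        return cls(
            {str(s): g["value"].to_numpy(dtype=np.float64) for s, g in df.groupby("subject")}
        )

    @classmethod
    def from_csv(cls, path) -> "RepeatedMeasures":
        df = pd.read_csv(path)
        return cls.from_arrays(df["subject_id"], df["measurement"])

    def usable(self) -> dict[str, np.ndarray]:
        """Subjects with ≥ 2 measurements; warns about the dropped ones."""
        dropped = [s for s, v in self.groups.items() if v.size < 2]
        if dropped:
            warnings.warn(
                f"excluding subjects with a single measurement: {dropped}",
                stacklevel=3,
            )
        return {s: v for s, v in self.groups.items() if v.size >= 2}


@dataclass
class RepeatabilityReport:
    sw: float
    repeatability_coefficient: float
    spearman_r: float
    spearman_p: float
    n_subjects: int
    n_measurements: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class AgreementFit:
    """OLS agreement fit with a 95% prediction band.

    ``prediction_halfwidth(x)`` gives the half-width of the 95% prediction
    interval at new x, from the residual variance plus leverage.
    """

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    residual_sd: float
    _results: object = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("R² outside [0, 1]")

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=np.float64)

    def prediction_halfwidth(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=np.float64))
        X = sm.add_constant(x, has_constant="add")
        pred = self._results.get_prediction(X)
        lo, hi = pred.conf_int(obs=True, alpha=0.05).T
        return (hi - lo) / 2.0


def within_subject_sd(data: RepeatedMeasures) -> float:
    """Within-subject SD from one-way ANOVA with subject as the factor.

    sw = √(residual SS / (N − k)) for N total measurements over k
    subjects; unbalanced designs supported. For balanced designs sw²
    equals the mean of the per-subject variances.
    """
    groups = data.usable()
    if len(groups) < 2:
        raise ValueError("sw estimation needs at least 2 subjects with repeats")
    rss = sum(float(np.sum((v - v.mean()) ** 2)) for v in groups.values())
    n_total = sum(v.size for v in groups.values())
    return math.sqrt(rss / (n_total - len(groups)))


def repeatability_coefficient(sw: float) -> float:
    """95% repeatability coefficient 1.96·√2·sw."""
    if sw < 0:
        raise ValueError("sw must be non-negative")
    return RC_FACTOR * sw


def variance_magnitude_check(data: RepeatedMeasures) -> tuple[float, float]:
    """Spearman correlation of per-subject mean vs per-subject SD.

    A significant positive correlation signals heteroscedasticity, i.e.
    measurement error growing with the measured volume, which would
    invalidate a single pooled sw.
    """
    groups = data.usable()
    if len(groups) < 3:
        raise ValueError("variance-magnitude check needs at least 3 subjects")
    means = [v.mean() for v in groups.values()]
    sds = [v.std(ddof=1) for v in groups.values()]
    r, p = stats.spearmanr(means, sds)
    return float(r), float(p)


def repeatability_report(data: RepeatedMeasures) -> RepeatabilityReport:
    """sw, repeatability coefficient and heteroscedasticity check in one go."""
    sw = within_subject_sd(data)
    r, p = variance_magnitude_check(data)
    groups = data.usable()
    return RepeatabilityReport(
        sw=sw,
        repeatability_coefficient=repeatability_coefficient(sw),
        spearman_r=r,
        spearman_p=p,
        n_subjects=len(groups),
        n_measurements=sum(v.size for v in groups.values()),
    )


def agreement_regression(x, y) -> AgreementFit:
    """OLS of y on x with R², slope p-value and 95% prediction band."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("agreement regression needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression undefined")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return AgreementFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        p_value=float(res.pvalues[1]),
        residual_sd=float(np.sqrt(res.mse_resid)),
        _results=res,
    )


def welch_t_test(group_a, group_b) -> tuple[float, float, float]:
    """Welch two-sample t-test: statistic, Welch–Satterthwaite df, two-sided p."""
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0:
        return 0.0, float(na + nb - 2), 1.0
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)
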