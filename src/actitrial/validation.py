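"""Validation statistics for digital outcome measures.

Reusable implementations of the analytical- and clinical-validation statistics
commonly required when qualifying a wearable-derived endpoint:

* split-period test-retest reliability via the intraclass correlation (one-way
  random effects, single measurement, ICC(1,1));
* robustness of the summary to the length of the measurement period (a
  stability curve of coefficient of variation vs number of days);
* convergent validity (Pearson/Spearman correlation with a traditional
  outcome measure);
* known-groups validity (median comparison between a disease cohort and
  healthy controls).

All functions consume plain per-subject vectors or subject-by-day matrices, so
they apply equally to simulated and real summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .exceptions import InvalidParameterError


@dataclass(frozen=True)
class ReliabilityResult:
    """Test-retest reliability: ICC plus its variance components."""

    icc: float
    n_subjects: int
    variance_between: float  # MSB, between-subject mean square
    variance_within: float   # MSW, within-subject mean square
    model: str = "ICC(1,1) one-way random effects"


@dataclass(frozen=True)
class StabilityCurve:
    """Variability (CV %) of a summary as the measurement period lengthens."""

    period_lengths: tuple[int, ...]
    variability: tuple[float, ...]

    def __post_init__(self) -> None:
        if list(self.period_lengths) != sorted(set(self.period_lengths)):
            raise InvalidParameterError("period lengths must be strictly increasing")


def icc_test_retest(first_period: Sequence[float],
                    second_period: Sequence[float]) -> ReliabilityResult:
    """One-way random-effects ICC between two repeated summaries per subject.

    With k=2 repeats, ICC = (MSB - MSW) / (MSB + (k-1) MSW), where MSB and MSW
    are the between- and within-subject mean squares of the one-way ANOVA.
    Ranges over [-1, 1]: 1 for perfect agreement, negative when within-subject
    disagreement exceeds between-subject spread.
    """
    x = np.asarray(first_period, dtype=float)
    y = np.asarray(second_period, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidParameterError("paired vectors of equal length required")
    n = x.size
    if n < 3:
        raise InvalidParameterError("need at least 3 subjects")
    data = np.column_stack([x, y])  # n subjects x k=2 repeats
    k = 2
    subject_means = data.mean(axis=1)
    grand_mean = data.mean()
    ss_between = k * np.sum((subject_means - grand_mean) ** 2)
    ss_within = np.sum((data - subject_means[:, None]) ** 2)
    msb = ss_between / (n - 1)
    msw = ss_within / (n * (k - 1))
    denom = msb + (k - 1) * msw
    if denom == 0.0:
        raise InvalidParameterError("zero total variance: ICC undefined")
    return ReliabilityResult(
        icc=float((msb - msw) / denom),
        n_subjects=n,
        variance_between=float(msb),
        variance_within=float(msw),
    )


def convergent_correlation(digital: Sequence[float], traditional: Sequence[float],
                           method: str = "pearson") -> float:
    """Correlation between a digital summary and a traditional outcome measure."""
    x = np.asarray(digital, dtype=float)
    y = np.asarray(traditional, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise InvalidParameterError("paired vectors with n >= 3 required")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise InvalidParameterError("zero variance: correlation undefined")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise InvalidParameterError("method must be 'pearson' or 'spearman'")


def known_groups(disease: Sequence[float],
                 control: Sequence[float]) -> tuple[float, float, float]:
    """Group medians of the summary and their difference (disease - control)."""
    d = np.asarray(disease, dtype=float)
    c = np.asarray(control, dtype=float)
    if d.size == 0 or c.size == 0:
        raise InvalidParameterError("both groups must be non-empty")
    med_d, med_c = float(np.median(d)), float(np.median(c))
    return med_d, med_c, med_d - med_c


def stability_curve(daily: np.ndarray,
                    summary_fn: Callable[[np.ndarray], float] = np.mean,
                    period_lengths: Sequence[int] = (7, 14, 21, 28),
                    n_replicates: int = 200,
                    rng: np.random.Generator | None = None) -> StabilityCurve:
    """Variability of a per-subject summary vs length of the measurement period.

    For each period length L, each subject's summary is recomputed over
    ``n_replicates`` bootstrap resamples of L days drawn from that subject's
    available days; the subject-level coefficient of variation (SD/mean, %) of
    those replicate summaries is averaged across subjects.  For an iid daily
    signal summarised by the mean, the curve decays like 1/sqrt(L).
    """
    daily = np.atleast_2d(np.asarray(daily, dtype=float))
    n_days = daily.shape[1]
    lengths = tuple(int(l) for l in period_lengths)
    if any(l < 1 or l > n_days for l in lengths):
        raise InvalidParameterError("period lengths must lie within the available days")
    if rng is None:
        rng = np.random.default_rng()
    cvs = []
    for L in lengths:
        subject_cvs = []
        for row in daily:
            idx = rng.integers(0, n_days, size=(n_replicates, L))
            reps = np.apply_along_axis(summary_fn, 1, row[idx])
            mean = reps.mean()
            sd = reps.std(ddof=1)
            subject_cvs.append(0.0 if mean == 0.0 else 100.0 * sd / abs(mean))
        cvs.append(float(np.mean(subject_cvs)))
    return StabilityCurve(period_lengths=lengths, variability=tuple(cvs))
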