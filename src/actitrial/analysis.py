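"""Follow-up summary and the baseline-adjusted primary analysis (ANCOVA).

The trial's estimand is the coefficient beta2 (and its standard error) in

    ybar_i = beta0 + beta1 * baseline_i + beta2 * treat_i + eps_i,

where ``ybar_i`` is the mean daily MVPA over the participant's observed
(compliant) days within the measurement period, and only participants who
meet the compliance rule are analysed (complete-case analysis).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dgm import TrialDataset
from .exceptions import AnalysisError, EstimabilityError, SingularityError
from .missingness import ComplianceRule, compliance_filter


@dataclass(frozen=True)
class FollowUpSummary:
    """Per-participant analysis row: mean over observed days plus covariates."""

    participant_id: int
    ybar: float            # mean MVPA (min/day) over observed days in the period
    n_compliant_days: int
    baseline: float
    arm: int
    winter: int = 0


@dataclass(frozen=True)
class PrimaryAnalysisResult:
    """Fitted ANCOVA: coefficients, SE of the treatment effect, diagnostics."""

    beta0: float
    beta1: float
    beta2: float
    se_beta2: float
    residual_var: float
    n_analysed: int
    n_excluded: int


def summarize_followup(dataset: TrialDataset, rule: ComplianceRule | None = None,
                       period_days: Optional[int] = None) -> list[FollowUpSummary]:
    """Per-participant follow-up means over observed days in the period.

    Participants failing the compliance rule are omitted (their count is
    recoverable as ``n_participants - len(result)``).
    """
    if rule is None:
        rule = ComplianceRule()
    if period_days is None:
        period_days = dataset.scenario.measurement_period_days
    ids = compliance_filter(dataset, rule, period_days)
    mask = dataset.observed_mask[:, :period_days]
    counts = mask.sum(axis=1)
    sums = np.where(mask, dataset.daily[:, :period_days], 0.0).sum(axis=1)
    return [
        FollowUpSummary(
            participant_id=int(i),
            ybar=float(sums[i] / counts[i]),
            n_compliant_days=int(counts[i]),
            baseline=float(dataset.baseline[i]),
            arm=int(dataset.arm[i]),
            winter=int(dataset.winter[i]),
        )
        for i in ids
    ]


def summaries_to_frame(summaries: Sequence[FollowUpSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [s.participant_id for s in summaries],
            "arm": [s.arm for s in summaries],
            "winter": [s.winter for s in summaries],
            "baseline": [s.baseline for s in summaries],
            "ybar": [s.ybar for s in summaries],
            "n_compliant_days": [s.n_compliant_days for s in summaries],
        }
    )


def fit_primary_model(summaries: Sequence[FollowUpSummary],
                      n_excluded: int = 0) -> PrimaryAnalysisResult:
    """Ordinary least squares of ybar on intercept, baseline and arm.

    The SE of the treatment coefficient uses the usual unbiased residual
    variance estimator, ``s^2 = RSS / (n - 3)``, and the corresponding
    diagonal element of ``(X'X)^{-1}``.
    """
    n = len(summaries)
    if n < 4:
        raise AnalysisError(f"need at least 4 analysable participants, got {n}")
    y = np.array([s.ybar for s in summaries], dtype=float)
    baseline = np.array([s.baseline for s in summaries], dtype=float)
    arm = np.array([s.arm for s in summaries], dtype=float)
    if arm.min() == arm.max():
        raise EstimabilityError("only one arm present among analysable participants")

    X = np.column_stack([np.ones(n), baseline, arm])
    xtx = X.T @ X
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as exc:
        raise SingularityError("design matrix is singular") from exc
    if np.linalg.matrix_rank(xtx) < 3:
        raise SingularityError("design matrix is rank deficient")
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    residual_var = float(resid @ resid) / (n - 3)
    se_beta2 = float(np.sqrt(residual_var * xtx_inv[2, 2]))
    return PrimaryAnalysisResult(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        beta2=float(beta[2]),
        se_beta2=se_beta2,
        residual_var=residual_var,
        n_analysed=n,
        n_excluded=n_excluded,
    )


def analyse_trial(dataset: TrialDataset, rule: ComplianceRule | None = None,
                  period_days: Optional[int] = None) -> PrimaryAnalysisResult:
    """Convenience chain: compliance filter -> follow-up summary -> ANCOVA fit."""
    summaries = summarize_followup(dataset, rule, period_days)
    n_excluded = dataset.design.n_participants - len(summaries)
    return fit_primary_model(summaries, n_excluded=n_excluded)
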