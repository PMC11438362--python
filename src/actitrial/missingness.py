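"""Day-level missingness mechanisms and the wear-compliance inclusion rule.

Two mechanisms from the missing-data scenarios are implemented:

* **MCAR** — for an exact fraction of participants, an exact fraction of days
  in the measurement period is deleted uniformly at random, independently of
  the outcome values.
* **MNAR** — the same exact counts, but each affected participant loses the
  days with the *lowest* activity, mimicking a device not worn on sedentary
  days.  This weakly raises every affected participant's observed mean.

A day here is either fully observed or fully missing: wear time is not
simulated at the minute level, so "compliant day" (>= 600 min wear while
awake in the motivating trial) is operationalised directly as an observed
day.  A participant enters the analysis only if they have at least
``min_compliant_days`` observed days in the measurement period (14 for the
month-long period, inclusive threshold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._utils import round_half_away
from .dgm import TrialDataset
from .exceptions import AnalysisError, InvalidParameterError

MECHANISMS = ("none", "MCAR", "MNAR")


@dataclass(frozen=True)
class MissingnessSpec:
    """Which mechanism to apply and with what exact proportions.

    ``prop_participants`` of the cohort are affected; each affected
    participant loses ``prop_days`` of the days in the measurement period.
    """

    mechanism: str = "none"
    prop_participants: float = 0.0
    prop_days: float = 0.0

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise InvalidParameterError(f"mechanism must be one of {MECHANISMS}")
        for name in ("prop_participants", "prop_days"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise InvalidParameterError(f"{name} must be in [0, 1]")
        if self.mechanism == "none" and (self.prop_participants or self.prop_days):
            raise InvalidParameterError("mechanism 'none' requires zero proportions")


@dataclass(frozen=True)
class ComplianceRule:
    """Inclusion rule for the primary analysis.

    ``min_wear_minutes_per_day`` documents what a day-level missing value
    means (it is not computed here).  ``min_compliant_days`` is the inclusive
    participant-level threshold; when ``None`` it scales with the measurement
    period as ``ceil(period / 2)``, which gives the stated 14 days for the
    28-day period.
    """

    min_wear_minutes_per_day: float = 600.0
    min_compliant_days: Optional[int] = None

    def threshold(self, period_days: int) -> int:
        if self.min_compliant_days is not None:
            if not 1 <= self.min_compliant_days <= period_days:
                raise InvalidParameterError(
                    "min_compliant_days must be between 1 and the measurement period"
                )
            return self.min_compliant_days
        return math.ceil(period_days / 2)


def _select_participants(dataset: TrialDataset, spec: MissingnessSpec,
                         rng: np.random.Generator) -> np.ndarray:
    n = dataset.design.n_participants
    k = round_half_away(n * spec.prop_participants)
    return rng.choice(n, size=k, replace=False)


def apply_mcar(dataset: TrialDataset, spec: MissingnessSpec,
               rng: np.random.Generator) -> TrialDataset:
    """Delete randomly chosen days for randomly chosen participants.

    Exact counts: ``round(prop_participants * n)`` participants, each losing
    ``round(prop_days * period)`` uniformly chosen days within the measurement
    period.  Only the observed mask changes.
    """
    if spec.mechanism != "MCAR":
        raise InvalidParameterError("apply_mcar requires mechanism='MCAR'")
    period = dataset.scenario.measurement_period_days
    n_days = round_half_away(period * spec.prop_days)
    mask = dataset.observed_mask.copy()
    for i in _select_participants(dataset, spec, rng):
        days = rng.choice(period, size=n_days, replace=False)
        mask[i, days] = False
    return dataset.copy_with_mask(mask)


def apply_mnar(dataset: TrialDataset, spec: MissingnessSpec,
               rng: np.random.Generator) -> TrialDataset:
    """Delete each affected participant's lowest-activity days.

    Participants are selected as under MCAR, but the deleted days are the
    ``round(prop_days * period)`` smallest outcome values in the measurement
    period (ties broken by earliest day).  Missingness therefore depends on
    the unobserved values themselves — the defining feature of MNAR.
    """
    if spec.mechanism != "MNAR":
        raise InvalidParameterError("apply_mnar requires mechanism='MNAR'")
    period = dataset.scenario.measurement_period_days
    n_days = round_half_away(period * spec.prop_days)
    mask = dataset.observed_mask.copy()
    for i in _select_participants(dataset, spec, rng):
        # stable sort -> ties broken by earliest day index
        order = np.argsort(dataset.daily[i, :period], kind="stable")
        mask[i, order[:n_days]] = False
    return dataset.copy_with_mask(mask)


def apply_missingness(dataset: TrialDataset, spec: MissingnessSpec,
                      rng: np.random.Generator) -> TrialDataset:
    """Dispatch on the mechanism; 'none' returns the dataset unchanged."""
    if spec.mechanism == "none":
        return dataset
    if spec.mechanism == "MCAR":
        return apply_mcar(dataset, spec, rng)
    return apply_mnar(dataset, spec, rng)


def compliance_filter(dataset: TrialDataset, rule: ComplianceRule,
                      period_days: Optional[int] = None) -> np.ndarray:
    """IDs of participants analysable under the compliance rule.

    A participant is analysable iff the number of observed days within the
    first ``period_days`` follow-up days reaches the rule's (inclusive)
    threshold.
    """
    if period_days is None:
        period_days = dataset.scenario.measurement_period_days
    if period_days > dataset.design.n_followup_days:
        raise InvalidParameterError("measurement period exceeds follow-up length")
    counts = dataset.observed_mask[:, :period_days].sum(axis=1)
    ids = np.flatnonzero(counts >= rule.threshold(period_days))
    if ids.size == 0:
        raise AnalysisError("no participant meets the compliance rule")
    return ids
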