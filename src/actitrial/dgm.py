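"""Data-generating mechanism for a trial with a daily wearable endpoint.

Simulates daily minutes of moderate-to-vigorous physical activity (MVPA) at
follow-up for a parallel-group randomised trial.  The daily outcome for
participant *i* on day *j* is log-normal on the natural scale with mean

    mu_ij = baseline_i
            + delta1 * I(treated_i)
            + delta2 * I(winter_i) + delta3 * I(winter_i) * I(treated_i)
            + delta4 * I(j in week 1) + delta5 * I(j in week 1) * I(treated_i)
            + alpha_i

and a fixed natural-scale standard deviation, where ``baseline_i`` is itself a
log-normal draw (the participant's average MVPA over a one-month baseline
period) and ``alpha_i`` is a normal participant random effect.  Conditional on
``alpha_i`` the days are independent.

The defaults reproduce a 44-participant trial with 2:1 allocation, 28 follow-up
days, baseline mean 77 / SD 52 min/day, daily SD 46 min/day, and random-effect
variance 4 (min/day)^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._utils import round_half_away
from .exceptions import DesignError, InvalidParameterError

WEEK1_DAYS = 7  # "week 1" = follow-up days 1..7, 1-indexed


@dataclass(frozen=True)
class DesignConfig:
    """Fixed trial parameters of the simulated study.

    Parameters
    ----------
    n_participants : int
        Number of randomised participants.
    allocation_ratio : (int, int)
        ``(treatment, control)`` allocation ratio, e.g. ``(2, 1)``.
    n_followup_days : int
        Length of the follow-up period in days.
    baseline_mean, baseline_sd : float
        Natural-scale mean and SD (min/day) of the log-normal baseline MVPA.
    daily_sd : float
        Natural-scale SD (min/day) of the daily log-normal outcome.
    random_effect_var : float
        Variance of the normal participant random effect, (min/day)^2.
    mean_floor : float
        Lower floor (min/day) applied to mu_ij before moment matching, so the
        log-normal stays defined when a tiny baseline draw meets a negative
        random effect.
    """

    n_participants: int = 44
    allocation_ratio: tuple[int, int] = (2, 1)
    n_followup_days: int = 28
    baseline_mean: float = 77.0
    baseline_sd: float = 52.0
    daily_sd: float = 46.0
    random_effect_var: float = 4.0
    mean_floor: float = 1.0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise InvalidParameterError("n_participants must be >= 2")
        if self.n_followup_days < 1:
            raise InvalidParameterError("n_followup_days must be >= 1")
        r_t, r_c = self.allocation_ratio
        if not (isinstance(r_t, (int, np.integer)) and isinstance(r_c, (int, np.integer))):
            raise InvalidParameterError("allocation_ratio must be a pair of integers")
        if r_t < 1 or r_c < 1:
            raise InvalidParameterError("allocation_ratio components must be positive")
        for name in ("baseline_mean", "baseline_sd", "daily_sd", "mean_floor"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        if self.random_effect_var < 0:
            raise InvalidParameterError("random_effect_var must be non-negative")


@dataclass(frozen=True)
class EffectScenario:
    """Effect parameters of one simulation scenario.

    ``delta1`` is the additive treatment effect (min/day); ``delta2``/``delta3``
    the seasonal effect and its interaction with treatment; ``delta4``/``delta5``
    the week-1 observer (Hawthorne) effect and its interaction.  ``prop_winter``
    is the fraction of the cohort recruited in winter (whose follow-up is
    season-affected), and ``measurement_period_days`` the analysis window
    (first *k* follow-up days) used for the compliance rule and summary.
    """

    delta1: float = 12.5
    delta2: float = 0.0
    delta3: float = 0.0
    delta4: float = 0.0
    delta5: float = 0.0
    prop_winter: float = 0.0
    measurement_period_days: int = 28

    def __post_init__(self) -> None:
        if not 0.0 <= self.prop_winter <= 1.0:
            raise InvalidParameterError("prop_winter must be in [0, 1]")
        if self.measurement_period_days < 1:
            raise InvalidParameterError("measurement_period_days must be >= 1")
        negatives = [n for n in ("delta2", "delta3", "delta4", "delta5") if getattr(self, n) < 0]
        if negatives:
            warnings.warn(
                f"negative nuisance effect(s) {negatives}: outside the standard scenario grids",
                stacklevel=2,
            )

    @classmethod
    def with_interaction(cls, **kwargs) -> "EffectScenario":
        """Scenario with the interaction convention delta3 = 0.1*delta2 and
        delta5 = 0.1*delta4 applied to whichever main effects are given."""
        scen = cls(**kwargs)
        return replace(scen, delta3=0.1 * scen.delta2, delta5=0.1 * scen.delta4)


@dataclass(frozen=True)
class Participant:
    """One simulated participant."""

    id: int
    arm: int           # 0 control, 1 treatment
    winter: int        # 1 if recruited in winter
    baseline: float    # baseline mean MVPA, min/day (log-normal draw, > 0)
    random_effect: float  # alpha_i, min/day


@dataclass
class TrialDataset:
    """One simulated trial: participant covariates plus the daily outcome matrix.

    ``daily`` has shape ``(n_participants, n_followup_days)``; ``observed_mask``
    is the same shape and is all-True at generation time — missingness
    mechanisms only ever clear entries of the mask, never touch ``daily``.
    """

    design: DesignConfig
    scenario: EffectScenario
    arm: np.ndarray
    winter: np.ndarray
    baseline: np.ndarray
    random_effect: np.ndarray
    daily: np.ndarray
    observed_mask: np.ndarray
    seed: int
    rng_algorithm: str = "numpy.random.PCG64"
    meta: dict = field(default_factory=dict)

    @property
    def participants(self) -> list[Participant]:
        return [
            Participant(
                id=i,
                arm=int(self.arm[i]),
                winter=int(self.winter[i]),
                baseline=float(self.baseline[i]),
                random_effect=float(self.random_effect[i]),
            )
            for i in range(self.design.n_participants)
        ]

    def copy_with_mask(self, mask: np.ndarray) -> "TrialDataset":
        """A shallow copy sharing the daily values but with a new observed mask."""
        return TrialDataset(
            design=self.design,
            scenario=self.scenario,
            arm=self.arm,
            winter=self.winter,
            baseline=self.baseline,
            random_effect=self.random_effect,
            daily=self.daily,
            observed_mask=mask,
            seed=self.seed,
            rng_algorithm=self.rng_algorithm,
            meta=dict(self.meta),
        )

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format view: participant_id, arm, winter, baseline, day, value, observed."""
        n, d = self.daily.shape
        return pd.DataFrame(
            {
                "participant_id": np.repeat(np.arange(n), d),
                "arm": np.repeat(self.arm, d),
                "winter": np.repeat(self.winter, d),
                "baseline": np.repeat(self.baseline, d),
                "day": np.tile(np.arange(1, d + 1), n),
                "value": self.daily.ravel(),
                "observed": self.observed_mask.ravel(),
            }
        )


def moment_match_lognormal(mean, sd):
    """Log-scale parameters of a log-normal with given natural-scale moments.

    Solves ``exp(m + s^2/2) = mean`` and ``mean^2 (exp(s^2) - 1) = sd^2``:

        s^2 = ln(1 + (sd/mean)^2),   m = ln(mean) - s^2 / 2.

    Accepts scalars or arrays (broadcast).  ``sd = 0`` gives the degenerate
    point mass at ``mean``.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(mean <= 0):
        raise InvalidParameterError("log-normal natural mean must be strictly positive")
    if np.any(sd < 0):
        raise InvalidParameterError("log-normal natural SD must be non-negative")
    log_var = np.log1p((sd / mean) ** 2)
    log_mean = np.log(mean) - log_var / 2.0
    log_sd = np.sqrt(log_var)
    if log_mean.ndim == 0:
        return float(log_mean), float(log_sd)
    return log_mean, log_sd


def allocate_arms(n: int, ratio: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Randomly allocate ``n`` participants in the given treatment:control ratio.

    Exactly ``round_half_away(n * r_t / (r_t + r_c))`` participants are treated
    (29:15 for the default 44 at 2:1); the assignment order is uniformly random.
    """
    if n < 2:
        raise DesignError("need at least 2 participants to form two arms")
    r_t, r_c = ratio
    n_treat = round_half_away(n * r_t / (r_t + r_c))
    if n_treat == 0 or n_treat == n:
        raise DesignError(f"allocation {r_t}:{r_c} with n={n} leaves an empty arm")
    arm = np.zeros(n, dtype=np.int64)
    arm[rng.permutation(n)[:n_treat]] = 1
    return arm


def assign_winter(n: int, prop_winter: float, rng: np.random.Generator) -> np.ndarray:
    """Flag exactly ``round_half_away(n * prop_winter)`` participants as
    winter-recruited, uniformly at random and independently of arm."""
    if not 0.0 <= prop_winter <= 1.0:
        raise InvalidParameterError("prop_winter must be in [0, 1]")
    n_winter = round_half_away(n * prop_winter)
    winter = np.zeros(n, dtype=np.int64)
    winter[rng.permutation(n)[:n_winter]] = 1
    return winter


def daily_mean(participant: Participant, day: int, scenario: EffectScenario,
               mean_floor: float = 1.0) -> float:
    """Natural-scale mean mu_ij for one participant-day (1-indexed day).

    Sum of baseline, treatment, season, week-1 observer effects, their
    treatment interactions, and the participant random effect, floored at
    ``mean_floor``.
    """
    if day < 1:
        raise InvalidParameterError("days are 1-indexed")
    treated = participant.arm == 1
    wk1 = day <= WEEK1_DAYS
    mu = (
        participant.baseline
        + scenario.delta1 * treated
        + scenario.delta2 * participant.winter
        + scenario.delta3 * participant.winter * treated
        + scenario.delta4 * wk1
        + scenario.delta5 * wk1 * treated
        + participant.random_effect
    )
    return max(float(mu), mean_floor)


def simulate_trial(design: DesignConfig, scenario: EffectScenario, seed) -> TrialDataset:
    """Generate one complete trial dataset.

    Random draws are consumed in a fixed order — baselines, random effects,
    arm allocation, winter flags, then the daily matrix row-major — so a seed
    identifies a dataset independently of downstream options.  The returned
    mask is all-True; missingness is applied downstream.
    """
    rng = np.random.default_rng(seed)
    n, d = design.n_participants, design.n_followup_days

    log_mean_b, log_sd_b = moment_match_lognormal(design.baseline_mean, design.baseline_sd)
    baseline = rng.lognormal(log_mean_b, log_sd_b, size=n)
    alpha = rng.normal(0.0, np.sqrt(design.random_effect_var), size=n)
    arm = allocate_arms(n, design.allocation_ratio, rng)
    winter = assign_winter(n, scenario.prop_winter, rng)

    week1 = (np.arange(1, d + 1) <= WEEK1_DAYS).astype(float)
    mu = (
        baseline[:, None]
        + scenario.delta1 * arm[:, None]
        + scenario.delta2 * winter[:, None]
        + scenario.delta3 * (winter * arm)[:, None]
        + alpha[:, None]
        + scenario.delta4 * week1[None, :]
        + scenario.delta5 * week1[None, :] * arm[:, None]
    )
    n_floored = int(np.count_nonzero(mu < design.mean_floor))
    mu = np.maximum(mu, design.mean_floor)
    log_mu, log_sd = moment_match_lognormal(mu, design.daily_sd)
    z = rng.standard_normal(size=(n, d))
    daily = np.exp(log_mu + log_sd * z)

    seed_int = int(seed) if np.isscalar(seed) else -1
    return TrialDataset(
        design=design,
        scenario=scenario,
        arm=arm,
        winter=winter,
        baseline=baseline,
        random_effect=alpha,
        daily=daily,
        observed_mask=np.ones((n, d), dtype=bool),
        seed=seed_int,
        meta={"n_floored_means": n_floored},
    )
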