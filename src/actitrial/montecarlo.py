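"""Monte Carlo evaluation of the primary analysis over scenario grids.

For each scenario cell, many trials are simulated, missingness applied, the
ANCOVA fitted, and the performance measures collected: the mean of the
estimated treatment effect and the mean of its standard error across
replications, each with its Monte Carlo error (sample SD of the draws divided
by sqrt(nsim)).  Figure-style reports multiply the Monte Carlo error by 1.96
for error bars; that factor is applied at plotting time, not here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._utils import derive_seed
from .analysis import analyse_trial
from .dgm import DesignConfig, EffectScenario, simulate_trial
from .exceptions import AnalysisError, CellError, ConfigError
from .missingness import ComplianceRule, MissingnessSpec, apply_missingness

MAX_FAILURE_FRACTION = 0.01  # a cell errors out if >1% of replications fail


@dataclass(frozen=True)
class ScenarioCell:
    """One point of a simulation grid: design + effects + missingness + size."""

    design: DesignConfig = field(default_factory=DesignConfig)
    scenario: EffectScenario = field(default_factory=EffectScenario)
    missingness: MissingnessSpec = field(default_factory=MissingnessSpec)
    nsim: int = 10_000
    base_seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.nsim < 2:
            raise ConfigError("nsim must be >= 2")
        if not self.label:
            object.__setattr__(self, "label", self._default_label())

    def _default_label(self) -> str:
        s, m = self.scenario, self.missingness
        r_t, r_c = self.design.allocation_ratio
        parts = [
            f"alloc{r_t}to{r_c}",
            f"d2={s.delta2:g}", f"d3={s.delta3:g}", f"d4={s.delta4:g}", f"d5={s.delta5:g}",
            f"pw={s.prop_winter:g}", f"period={s.measurement_period_days}",
            f"miss={m.mechanism}", f"pp={m.prop_participants:g}", f"pd={m.prop_days:g}",
        ]
        return "|".join(parts)


@dataclass(frozen=True)
class PerformanceSummary:
    """Performance measures for one cell."""

    cell: ScenarioCell
    mean_beta2: float
    mc_error_mean: float
    mean_se: float
    mc_error_se: float
    nsim_effective: int
    n_failed: int

    def to_row(self) -> dict:
        s, m, d = self.cell.scenario, self.cell.missingness, self.cell.design
        return {
            "label": self.cell.label,
            "n_participants": d.n_participants,
            "allocation": f"{d.allocation_ratio[0]}:{d.allocation_ratio[1]}",
            "delta1": s.delta1, "delta2": s.delta2, "delta3": s.delta3,
            "delta4": s.delta4, "delta5": s.delta5,
            "prop_winter": s.prop_winter,
            "measurement_period_days": s.measurement_period_days,
            "mechanism": m.mechanism,
            "prop_participants": m.prop_participants,
            "prop_days": m.prop_days,
            "mean_beta2": self.mean_beta2,
            "mc_error_mean": self.mc_error_mean,
            "mean_se": self.mean_se,
            "mc_error_se": self.mc_error_se,
            "nsim_effective": self.nsim_effective,
            "n_failed": self.n_failed,
            "base_seed": self.cell.base_seed,
        }


def mc_error(draws: Sequence[float]) -> float:
    """Monte Carlo error of a simulation mean: sample SD / sqrt(n draws)."""
    draws = np.asarray(draws, dtype=float)
    if draws.size < 2:
        raise ValueError("Monte Carlo error needs at least 2 draws")
    return float(np.std(draws, ddof=1) / np.sqrt(draws.size))


def run_cell(cell: ScenarioCell, rule: ComplianceRule | None = None) -> PerformanceSummary:
    """Replicate one cell ``nsim`` times and summarise beta2 and its SE.

    Replication *r* draws its seed deterministically from
    ``(base_seed, cell.label, r)``; failed fits (non-compliant cohorts,
    degenerate designs) are counted and excluded, and the cell errors out if
    more than 1% fail.
    """
    if rule is None:
        rule = ComplianceRule()
    beta2 = np.empty(cell.nsim)
    se = np.empty(cell.nsim)
    n_ok = 0
    n_failed = 0
    for r in range(cell.nsim):
        seed = derive_seed(cell.base_seed, cell.label, r)
        try:
            dataset = simulate_trial(cell.design, cell.scenario, seed)
            miss_rng = np.random.default_rng(derive_seed(cell.base_seed, cell.label, r, "miss"))
            dataset = apply_missingness(dataset, cell.missingness, miss_rng)
            result = analyse_trial(dataset, rule)
        except AnalysisError:
            n_failed += 1
            continue
        beta2[n_ok] = result.beta2
        se[n_ok] = result.se_beta2
        n_ok += 1
    if n_failed > MAX_FAILURE_FRACTION * cell.nsim or n_ok < 2:
        raise CellError(
            f"cell '{cell.label}': {n_failed}/{cell.nsim} replications failed to fit"
        )
    beta2, se = beta2[:n_ok], se[:n_ok]
    return PerformanceSummary(
        cell=cell,
        mean_beta2=float(beta2.mean()),
        mc_error_mean=mc_error(beta2),
        mean_se=float(se.mean()),
        mc_error_se=mc_error(se),
        nsim_effective=n_ok,
        n_failed=n_failed,
    )


def run_grid(cells: Iterable[ScenarioCell],
             rule: ComplianceRule | None = None,
             progress: bool = False) -> pd.DataFrame:
    """Run every cell of a grid and return one results row per cell.

    Cells are seeded independently (each derives its stream from its own
    label), so results do not depend on execution order.
    """
    cells = list(cells)
    if not cells:
        raise ConfigError("empty scenario grid")
    labels = [c.label for c in cells]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ConfigError(f"duplicate cell labels: {dupes}")
    rows = []
    for i, cell in enumerate(cells):
        summary = run_cell(cell, rule)
        rows.append(summary.to_row())
        if progress:
            print(f"[{i + 1}/{len(cells)}] {cell.label}: "
                  f"mean_beta2={summary.mean_beta2:.3f} mean_se={summary.mean_se:.3f}")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Built-in scenario grids mirroring the three study questions
# ---------------------------------------------------------------------------

EFFECT_GRID = (0.0, 2.5, 5.0, 7.5, 10.0)
WINTER_PROPS = (0.1, 0.2, 0.5)
MISSING_PARTICIPANT_PROPS = (0.1, 0.2, 0.5)
MISSING_DAY_PROPS = tuple(np.round(np.arange(0.05, 0.501, 0.05), 2))


def _alloc_tag(design: DesignConfig) -> str:
    return f"alloc{design.allocation_ratio[0]}to{design.allocation_ratio[1]}"


def seasonality_cells(design: DesignConfig | None = None, nsim: int = 10_000,
                      base_seed: int = 0) -> list[ScenarioCell]:
    """Seasonal-effect grid: delta2 x prop_winter x interaction on/off (30 cells).

    The delta2 = 0 reference appears in both interaction panels, so labels
    carry the panel explicitly to keep cells distinguishable.
    """
    design = design or DesignConfig()
    cells = []
    for interaction in (False, True):
        for pw in WINTER_PROPS:
            for d2 in EFFECT_GRID:
                scen = EffectScenario(delta2=d2, delta3=0.1 * d2 if interaction else 0.0,
                                      prop_winter=pw)
                label = (f"seasonality|{_alloc_tag(design)}|int={int(interaction)}"
                         f"|pw={pw:g}|d2={d2:g}")
                cells.append(ScenarioCell(design=design, scenario=scen,
                                          nsim=nsim, base_seed=base_seed,
                                          label=label))
    return cells


def observer_cells(design: DesignConfig | None = None, nsim: int = 10_000,
                   base_seed: int = 0) -> list[ScenarioCell]:
    """Observer-effect grid: delta4 x measurement period {14, 28} x interaction (20 cells)."""
    design = design or DesignConfig()
    cells = []
    for interaction in (False, True):
        for period in (28, 14):
            for d4 in EFFECT_GRID:
                scen = EffectScenario(delta4=d4, delta5=0.1 * d4 if interaction else 0.0,
                                      measurement_period_days=period)
                label = (f"observer|{_alloc_tag(design)}|int={int(interaction)}"
                         f"|period={period}|d4={d4:g}")
                cells.append(ScenarioCell(design=design, scenario=scen,
                                          nsim=nsim, base_seed=base_seed,
                                          label=label))
    return cells


def missingness_cells(design: DesignConfig | None = None, nsim: int = 10_000,
                      base_seed: int = 0) -> list[ScenarioCell]:
    """Missing-data grid: complete-data reference + mechanism x prop_participants
    x prop_days (61 cells)."""
    design = design or DesignConfig()
    cells = [ScenarioCell(design=design, nsim=nsim, base_seed=base_seed)]
    for mechanism in ("MCAR", "MNAR"):
        for pp in MISSING_PARTICIPANT_PROPS:
            for pd_ in MISSING_DAY_PROPS:
                spec = MissingnessSpec(mechanism=mechanism,
                                       prop_participants=pp, prop_days=float(pd_))
                cells.append(ScenarioCell(design=design, missingness=spec,
                                          nsim=nsim, base_seed=base_seed))
    return cells
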