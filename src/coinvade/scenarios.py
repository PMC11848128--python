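"""Scenario drivers: the four standard simulation sets as parameter sweeps.

Set 1 — symmetric kernels (all variances 0.05), competition grid over
        (tau_12, tau_21) in [0, 0.4]^2, with and without the mutualist.
Set 2 — sweep the mutualist's kernel variance sigma2_P over [0, 0.099] at
        three competition levels (weak/intermediate/strong), reporting the
        spatial-dominance coefficient rho.
Set 3 — competition grid at fixed sigma2_P in {0.01, 0.05, 0.075}, competitors
        with equal kernels (0.05): mutualist slower / equal / faster.
Set 4 — as Set 3 but with asymmetric competitor kernels from the
        dependence-dispersal trade-off (effective variances 0.03 / 0.02, the
        more dependent F1 dispersing further), sigma2_P in {0.01, 0.025, 0.075}.

Each driver returns a tidy DataFrame with one row per grid point: the swept
parameters, rho, range sizes, coverages, speeds and the outcome label.
All runs are deterministic; rerunning a sweep reproduces the table exactly.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .engine import SimulationResult, run
from .metrics import OutcomeReport, evaluate_outcome
from .params import (DispersalParams, GrowthParams, SimulationConfig)

__all__ = [
    "OUTCOME_PRESETS",
    "COMPETITION_LEVELS",
    "make_config",
    "run_single",
    "run_set1",
    "run_set2",
    "run_set3",
    "run_set4",
    "default_tau_grid",
    "default_sigma2_P_grid",
]

#: Parameter presets (tau_12, tau_21, sigma2_P) canonically used to illustrate
#: the six qualitative outcomes, keyed a-f. All other parameters at defaults.
OUTCOME_PRESETS: dict[str, tuple[float, float, float]] = {
    "a": (0.05, 0.02, 0.05),
    "b": (0.05, 0.05, 0.05),
    "c": (0.05, 0.15, 0.05),
    "d": (0.15, 0.05, 0.05),
    "e": (0.30, 0.20, 0.05),
    "f": (0.02, 0.02, 0.02),
}

#: (tau_12, tau_21) pairs for weak / intermediate / strong competition.
COMPETITION_LEVELS: dict[str, tuple[float, float]] = {
    "weak": (0.02, 0.02),
    "intermediate": (0.20, 0.15),
    "strong": (0.37, 0.29),
}


def make_config(tau_12: float = 0.0, tau_21: float = 0.0,
                sigma2_P: float = 0.05, sigma2_F1: float = 0.05,
                sigma2_F2: float = 0.05, mutualist_present: bool = True,
                tradeoff_enabled: bool = False,
                n_iterations: int = 500, **overrides) -> SimulationConfig:
    """Standard-parameter config with the commonly varied knobs exposed."""
    growth_over = {k: overrides.pop(k) for k in list(overrides)
                   if k in GrowthParams.__dataclass_fields__}
    growth = GrowthParams(tau_12=tau_12, tau_21=tau_21, **growth_over)
    dispersal = DispersalParams(
        sigma2_P=sigma2_P, sigma2_F1=sigma2_F1, sigma2_F2=sigma2_F2,
        tradeoff_enabled=tradeoff_enabled,
        delta_F1=growth.delta_F1, delta_F2=growth.delta_F2)
    return SimulationConfig(growth=growth, dispersal=dispersal,
                            mutualist_present=mutualist_present,
                            n_iterations=n_iterations, **overrides)


def run_single(config: SimulationConfig) -> tuple[SimulationResult, OutcomeReport]:
    """Run one simulation and classify it: (SimulationResult, OutcomeReport)."""
    result = run(config)
    return result, evaluate_outcome(result)


def default_tau_grid(step: float = 0.05, maximum: float = 0.4) -> np.ndarray:
    """Competition-coefficient grid [0, maximum] at the given step."""
    n = round(maximum / step)
    return np.round(np.linspace(0.0, maximum, n + 1), 10)


def default_sigma2_P_grid(step: float = 0.005, maximum: float = 0.099) -> np.ndarray:
    """Mutualist-variance sweep [0, maximum]; the full-resolution study used
    step 0.001, the default here is a 5x coarser desk-scale grid."""
    vals = np.arange(0.0, maximum + step / 2, step)
    return np.round(np.minimum(vals, maximum), 10)


def _sweep(configs: Iterable[tuple[dict, SimulationConfig]]) -> pd.DataFrame:
    rows = []
    for keys, config in configs:
        _, report = run_single(config)
        row = dict(keys)
        row.update(report.to_row())
        rows.append(row)
    return pd.DataFrame(rows)


def run_set1(tau_grid: Optional[Sequence[float]] = None,
             mutualist_present: bool = True, **config_kwargs) -> pd.DataFrame:
    """Outcome per (tau_12, tau_21) with symmetric kernels (all 0.05)."""
    taus = np.asarray(tau_grid if tau_grid is not None else default_tau_grid())
    return _sweep(
        (({"tau_12": t12, "tau_21": t21, "mutualist_present": mutualist_present},
          make_config(tau_12=t12, tau_21=t21,
                      mutualist_present=mutualist_present, **config_kwargs))
         for t12 in taus for t21 in taus))


def run_set2(sigma2_P_grid: Optional[Sequence[float]] = None,
             competition_levels: Optional[dict[str, tuple[float, float]]] = None,
             **config_kwargs) -> pd.DataFrame:
    """rho (and outcome) versus sigma2_P at each competition level."""
    grid = np.asarray(sigma2_P_grid if sigma2_P_grid is not None
                      else default_sigma2_P_grid())
    levels = competition_levels or COMPETITION_LEVELS
    return _sweep(
        (({"level": name, "tau_12": t12, "tau_21": t21, "sigma2_P": s2},
          make_config(tau_12=t12, tau_21=t21, sigma2_P=s2, **config_kwargs))
         for name, (t12, t21) in levels.items() for s2 in grid))


def run_set3(tau_grid: Optional[Sequence[float]] = None,
             sigma2_P_values: Sequence[float] = (0.01, 0.05, 0.075),
             **config_kwargs) -> pd.DataFrame:
    """Outcome maps over (tau_12, tau_21) for slow/equal/fast mutualist."""
    taus = np.asarray(tau_grid if tau_grid is not None else default_tau_grid())
    return _sweep(
        (({"sigma2_P": s2, "tau_12": t12, "tau_21": t21},
          make_config(tau_12=t12, tau_21=t21, sigma2_P=s2, **config_kwargs))
         for s2 in sigma2_P_values for t12 in taus for t21 in taus))


def run_set4(tau_grid: Optional[Sequence[float]] = None,
             sigma2_F1: float = 0.03, sigma2_F2: float = 0.02,
             sigma2_P_values: Sequence[float] = (0.01, 0.025, 0.075),
             **config_kwargs) -> pd.DataFrame:
    """Outcome maps with asymmetric competitor kernels (trade-off in effect).

    The stated competitor variances are the *effective* kernel variances, the
    dependence-dispersal trade-off having already been folded in (the more
    dependent F1 disperses further: 0.03 > 0.02). Applying the delta-scaling
    on top of these values is still available through
    ``make_config(tradeoff_enabled=True)``.
    """
    taus = np.asarray(tau_grid if tau_grid is not None else default_tau_grid())
    return _sweep(
        (({"sigma2_P": s2, "tau_12": t12, "tau_21": t21},
          make_config(tau_12=t12, tau_21=t21, sigma2_P=s2,
                      sigma2_F1=sigma2_F1, sigma2_F2=sigma2_F2, **config_kwargs))
         for s2 in sigma2_P_values for t12 in taus for t21 in taus))
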