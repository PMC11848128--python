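"""Ranges, spread speeds, spatial dominance and coexistence classification.

A species' range is the set of cells where its density is at least the
occupancy threshold epsilon. The spatial-dominance coefficient

    rho = (|R_F1| - |R_F2|) / |R_F1 u R_F2|

is a signed measure of relative range size (rho > 0: F1's range is larger;
|rho| = 1 exactly when one competitor is extinct and the other is not).
Outcomes are classified from mutual range coverage: both competitors covering
>= 95% of each other's range is local coexistence; one nested in the other is
local coexistence with dominance of the larger-ranged species; mostly
non-overlapping ranges are regional coexistence; an empty range is a win for
the other species.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .params import ParameterError

__all__ = [
    "Outcome",
    "RangeSet",
    "OutcomeReport",
    "occupied_range",
    "spatial_dominance",
    "spread_speed",
    "classify_outcome",
    "evaluate_outcome",
]

COVERAGE_THRESHOLD = 0.95


class Outcome(str, enum.Enum):
    """Qualitative coexistence outcome of a co-invasion run."""

    F1_WIN = "F1_win"
    F2_WIN = "F2_win"
    LOCAL_COEXISTENCE = "local_coexistence"
    LOCAL_COEXISTENCE_F1_DOMINANCE = "local_coexistence_F1_dominance"
    LOCAL_COEXISTENCE_F2_DOMINANCE = "local_coexistence_F2_dominance"
    REGIONAL_COEXISTENCE = "regional_coexistence"
    DEGENERATE = "degenerate"  # both competitors extinct

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    def swapped(self) -> "Outcome":
        """The label with the two competitors' identities exchanged."""
        swap = {
            Outcome.F1_WIN: Outcome.F2_WIN,
            Outcome.F2_WIN: Outcome.F1_WIN,
            Outcome.LOCAL_COEXISTENCE_F1_DOMINANCE: Outcome.LOCAL_COEXISTENCE_F2_DOMINANCE,
            Outcome.LOCAL_COEXISTENCE_F2_DOMINANCE: Outcome.LOCAL_COEXISTENCE_F1_DOMINANCE,
        }
        return swap.get(self, self)


@dataclass(frozen=True)
class RangeSet:
    """Occupied-cell mask of one species with set algebra on masks.

    Ranges need not be contiguous; all sizes are mask measures (cells x dx).
    """

    mask: np.ndarray
    dx: float

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        if m.ndim != 1:
            raise ParameterError("range mask must be 1-D")
        if self.dx <= 0:
            raise ParameterError("dx must be positive")

    @property
    def size(self) -> float:
        return float(self.mask.sum()) * self.dx

    @property
    def is_empty(self) -> bool:
        return not self.mask.any()

    def union(self, other: "RangeSet") -> "RangeSet":
        return RangeSet(self.mask | other.mask, self.dx)

    def intersection(self, other: "RangeSet") -> "RangeSet":
        return RangeSet(self.mask & other.mask, self.dx)

    def bounds(self, coordinates: np.ndarray) -> tuple[float, float]:
        """(leftmost, rightmost) occupied coordinates; (nan, nan) if empty."""
        occ = np.flatnonzero(self.mask)
        if not occ.size:
            return math.nan, math.nan
        return float(coordinates[occ[0]]), float(coordinates[occ[-1]])


def occupied_range(density: np.ndarray, epsilon: float, dx: float) -> RangeSet:
    """Cells with density >= epsilon, as a RangeSet."""
    if epsilon <= 0:
        raise ParameterError("epsilon must be > 0")
    return RangeSet(np.asarray(density, dtype=float) >= epsilon, dx)


def spatial_dominance(range_F1: RangeSet, range_F2: RangeSet) -> float:
    """rho = (|R_F1| - |R_F2|) / |R_F1 u R_F2|; NaN when both ranges are empty."""
    union = range_F1.union(range_F2).size
    if union == 0.0:
        return math.nan
    return (range_F1.size - range_F2.size) / union


def spread_speed(edge_positions: np.ndarray, window: int) -> float:
    """Mean per-iteration displacement of an edge over the trailing window.

    NaN entries mean the species was unoccupied; a window containing any is
    rejected. Returns NaN if the series is shorter than window+1.
    """
    e = np.asarray(edge_positions, dtype=float)
    if window < 1:
        raise ParameterError("window must be >= 1")
    if e.size < window + 1:
        return math.nan
    tail = e[-(window + 1):]
    if np.any(np.isnan(tail)):
        return math.nan
    return float((tail[-1] - tail[0]) / window)


def classify_outcome(range_F1: RangeSet, range_F2: RangeSet,
                     coverage_threshold: float = COVERAGE_THRESHOLD) -> Outcome:
    """Map final competitor ranges to one of the six qualitative outcomes.

    Decision order: both empty -> degenerate; one empty -> the other wins;
    both coverages >= threshold -> local coexistence; exactly one coverage >=
    threshold (that species nested inside the other's range) -> local
    coexistence with dominance of the larger-ranged species; both coverages
    below threshold -> regional coexistence.
    """
    if range_F1.is_empty and range_F2.is_empty:
        return Outcome.DEGENERATE
    if range_F2.is_empty:
        return Outcome.F1_WIN
    if range_F1.is_empty:
        return Outcome.F2_WIN
    overlap = range_F1.intersection(range_F2).size
    cov1 = overlap / range_F1.size
    cov2 = overlap / range_F2.size
    if cov1 >= coverage_threshold and cov2 >= coverage_threshold:
        return Outcome.LOCAL_COEXISTENCE
    if cov2 >= coverage_threshold:
        return Outcome.LOCAL_COEXISTENCE_F1_DOMINANCE
    if cov1 >= coverage_threshold:
        return Outcome.LOCAL_COEXISTENCE_F2_DOMINANCE
    return Outcome.REGIONAL_COEXISTENCE


@dataclass(frozen=True)
class OutcomeReport:
    """Summary of a finished run: ranges, overlap, rho, speeds, outcome."""

    outcome: Outcome
    rho: float
    range_size_F1: float
    range_size_F2: float
    range_size_P: float
    overlap_size: float
    coverage_F1: float  # overlap / |R_F1|
    coverage_F2: float
    speed_P: float
    speed_F1: float
    speed_F2: float
    degenerate: bool
    steady_state_reached: bool = False
    steady_state_iteration: Optional[int] = None

    def to_row(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "rho", "range_size_F1", "range_size_F2", "range_size_P",
            "overlap_size", "coverage_F1", "coverage_F2",
            "speed_P", "speed_F1", "speed_F2", "degenerate",
            "steady_state_reached", "steady_state_iteration")}
        d["outcome"] = self.outcome.value
        return d


def evaluate_outcome(result, epsilon: Optional[float] = None,
                     speed_window: int = 50) -> OutcomeReport:
    """Compute the full outcome report from a :class:`SimulationResult`.

    Speeds are trailing-window means of the right edge; a left/right speed
    discrepancy above one grid cell per iteration triggers a warning since the
    dynamics are mirror-symmetric.
    """
    eps = epsilon if epsilon is not None else result.config.occupancy_epsilon
    dx = result.landscape.dx
    fld = result.final
    r1 = occupied_range(fld.F1, eps, dx)
    r2 = occupied_range(fld.F2, eps, dx)
    rP = occupied_range(fld.P, eps, dx)
    outcome = classify_outcome(r1, r2)
    rho = spatial_dominance(r1, r2)
    overlap = r1.intersection(r2).size
    cov1 = overlap / r1.size if r1.size else math.nan
    cov2 = overlap / r2.size if r2.size else math.nan

    speeds = {}
    for name in ("P", "F1", "F2"):
        right = spread_speed(result.edge_series(name, "right"), speed_window)
        left = spread_speed(result.edge_series(name, "left"), speed_window)
        if not (math.isnan(right) or math.isnan(left)):
            if abs(right + left) > dx:  # left edge moves in -x
                warnings.warn(
                    f"left/right spread speeds of {name} disagree by more than dx: "
                    f"{-left:.4g} vs {right:.4g}", RuntimeWarning, stacklevel=2)
        speeds[name] = right

    return OutcomeReport(
        outcome=outcome, rho=rho,
        range_size_F1=r1.size, range_size_F2=r2.size, range_size_P=rP.size,
        overlap_size=overlap, coverage_F1=cov1, coverage_F2=cov2,
        speed_P=speeds["P"], speed_F1=speeds["F1"], speed_F2=speeds["F2"],
        degenerate=outcome is Outcome.DEGENERATE,
        steady_state_reached=result.steady_state_reached,
        steady_state_iteration=result.steady_state_iteration,
    )
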