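"""Growth-dispersal iteration engine.

One model iteration (a year or generation) is: integrate the growth ODEs at
every point for a duration ``T_growth``, then redistribute each species with
its own dispersal kernel. Simulations start from a small central introduction
and invade symmetrically in both directions; the engine tracks range edges and
total mass per species every iteration and reports when a steady state
(constant front speed, equilibrated core density) has been reached.

Everything is deterministic: no random numbers are used anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from . import growth as _growth
from .dispersal import DiscreteKernel, build_kernel, disperse
from .params import (GrowthParams, Landscape, ParameterError, SimulationConfig,
                     SolverSettings)

__all__ = [
    "SPECIES",
    "BoundaryContactError",
    "CommunityField",
    "SimulationResult",
    "initialize",
    "build_kernels",
    "integrate_growth",
    "step",
    "run",
    "detect_steady_state",
]

SPECIES = ("P", "F1", "F2")


class BoundaryContactError(RuntimeError):
    """A spreading population got within one kernel truncation width of the
    habitat edge, violating the no-edge-interaction assumption."""


@dataclass
class CommunityField:
    """Densities of the three species on the landscape at one iteration."""

    landscape: Landscape
    P: np.ndarray
    F1: np.ndarray
    F2: np.ndarray
    iteration: int = 0

    def __post_init__(self) -> None:
        n = self.landscape.n_points
        for name in SPECIES:
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (n,):
                raise ParameterError(f"{name} has shape {arr.shape}, expected ({n},)")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ParameterError(f"{name} densities must be finite and >= 0")

    def density(self, species: str) -> np.ndarray:
        return getattr(self, species)

    def copy(self) -> "CommunityField":
        return CommunityField(self.landscape, self.P.copy(), self.F1.copy(),
                              self.F2.copy(), self.iteration)


def initialize(config: SimulationConfig) -> CommunityField:
    """Introduce all species at ``init_density`` on the central cells.

    With ``mutualist_present=False`` the partner P is absent (identically 0)
    and only the two competitors are introduced; with
    ``competitors_present=False`` the partner invades alone (the
    single-species logistic limit).
    """
    landscape = config.resolved_landscape()
    n = landscape.n_points
    if config.init_width_cells >= n:
        raise ParameterError("init_width_cells must be smaller than the grid")
    c = landscape.center_index
    w = config.init_width_cells
    lo = c - (w - 1) // 2
    zeros = np.zeros(n)
    comp = zeros.copy()
    comp[lo:lo + w] = config.init_density
    P = comp.copy() if config.mutualist_present else zeros.copy()
    if not config.competitors_present:
        comp = zeros.copy()
    return CommunityField(landscape, P, comp.copy(), comp.copy(), iteration=0)


def build_kernels(config: SimulationConfig,
                  landscape: Optional[Landscape] = None) -> dict[str, DiscreteKernel]:
    """One discretized Gaussian kernel per species (trade-off scaling applied)."""
    landscape = landscape or config.resolved_landscape()
    s2P, s2F1, s2F2 = config.dispersal.effective_variances()
    return {
        "P": build_kernel(s2P, landscape.dx, config.truncation_sigmas),
        "F1": build_kernel(s2F1, landscape.dx, config.truncation_sigmas),
        "F2": build_kernel(s2F2, landscape.dx, config.truncation_sigmas),
    }


def integrate_growth(field: CommunityField, params: GrowthParams,
                     solver: SolverSettings = SolverSettings(),
                     density_floor: float = 1e-12) -> CommunityField:
    """Growth phase only: integrate the point ODEs everywhere, no dispersal."""
    P, F1, F2 = _growth.integrate_growth_arrays(
        field.P, field.F1, field.F2, params, solver, density_floor)
    return CommunityField(field.landscape, P, F1, F2, field.iteration)


def step(field: CommunityField, growth_params: GrowthParams,
         kernels: dict[str, DiscreteKernel],
         solver: SolverSettings = SolverSettings(),
         density_floor: float = 1e-12) -> CommunityField:
    """One full iteration on the whole grid: growth, then per-species dispersal."""
    grown = integrate_growth(field, growth_params, solver, density_floor)
    out = {}
    for name in SPECIES:
        arr = disperse(grown.density(name), kernels[name])
        arr[arr < density_floor] = 0.0
        out[name] = arr
    return CommunityField(field.landscape, out["P"], out["F1"], out["F2"],
                          field.iteration + 1)


@dataclass
class SimulationResult:
    """Trajectory summary of one simulation.

    ``edges`` has shape (n_recorded, 3, 2): per iteration and species the
    (left, right) coordinates of the outermost cells with density >=
    ``occupancy_epsilon`` (NaN while unoccupied). ``masses`` and
    ``center_density`` have shape (n_recorded, 3). Row 0 is the initial
    condition; row t is the state after iteration t.
    """

    config: SimulationConfig
    landscape: Landscape
    final: CommunityField
    edges: np.ndarray
    masses: np.ndarray
    center_density: np.ndarray
    steady_state_reached: bool
    steady_state_iteration: Optional[int]
    snapshots: list[tuple[int, CommunityField]] = dc_field(default_factory=list)

    @property
    def n_iterations_run(self) -> int:
        return self.edges.shape[0] - 1

    def edge_series(self, species: str, side: str = "right") -> np.ndarray:
        s = SPECIES.index(species)
        return self.edges[:, s, 0 if side == "left" else 1]

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for t in range(self.edges.shape[0]):
            for s, name in enumerate(SPECIES):
                rows.append((t, name, self.edges[t, s, 0], self.edges[t, s, 1],
                             self.masses[t, s]))
        return pd.DataFrame(rows, columns=["iteration", "species", "left_edge",
                                           "right_edge", "mass"])

    def snapshot_table(self) -> pd.DataFrame:
        frames = []
        items = self.snapshots or [(self.final.iteration, self.final)]
        for t, fld in items:
            frames.append(pd.DataFrame({
                "iteration": t, "x": self.landscape.coordinates,
                "P": fld.P, "F1": fld.F1, "F2": fld.F2,
            }))
        return pd.concat(frames, ignore_index=True)


def _record(P, F1, F2, eps, coords, dx, edges_row, mass_row, center_row, c):
    for s, arr in enumerate((P, F1, F2)):
        occ = np.flatnonzero(arr >= eps)
        if occ.size:
            edges_row[s, 0] = coords[occ[0]]
            edges_row[s, 1] = coords[occ[-1]]
        else:
            edges_row[s, 0] = edges_row[s, 1] = np.nan
        mass_row[s] = arr.sum() * dx
        center_row[s] = arr[c]


def run(config: SimulationConfig, check_clearance: bool = True) -> SimulationResult:
    """Run the full iteration from the central introduction.

    Raises :class:`BoundaryContactError` if the pre-run clearance estimate
    (``n_iterations`` x linearized speed bound, plus kernel truncation width)
    exceeds the half-length, or if during the run any population support
    reaches within one truncation width of the boundary. Pass
    ``check_clearance=False`` to skip the a-priori estimate only.

    Growth and dispersal are evaluated only on the occupied support window
    (fields are exactly zero elsewhere), which is numerically identical to
    the full-grid :func:`step`.
    """
    landscape = config.resolved_landscape()
    field0 = initialize(config)
    kernels = build_kernels(config, landscape)
    hmax = max(k.half_width for k in kernels.values())
    n = landscape.n_points
    dx = landscape.dx
    coords = landscape.coordinates
    c = landscape.center_index
    eps = config.occupancy_epsilon
    floor = config.density_floor

    if check_clearance:
        reach = config.n_iterations * config.speed_bound() + hmax * dx
        if reach >= landscape.half_length:
            raise BoundaryContactError(
                f"estimated maximum front displacement {reach:.2f} exceeds the "
                f"half-length {landscape.half_length:.2f}; enlarge the landscape "
                "or pass check_clearance=False")

    P, F1, F2 = field0.P.copy(), field0.F1.copy(), field0.F2.copy()
    support = np.flatnonzero((P > 0) | (F1 > 0) | (F2 > 0))
    lo, hi = int(support[0]), int(support[-1])

    n_it = config.n_iterations
    edges = np.full((n_it + 1, 3, 2), np.nan)
    masses = np.zeros((n_it + 1, 3))
    center = np.zeros((n_it + 1, 3))
    _record(P, F1, F2, eps, coords, dx, edges[0], masses[0], center[0], c)
    snapshots: list[tuple[int, CommunityField]] = []
    if config.snapshot_stride:
        snapshots.append((0, field0.copy()))

    speed_tol = config.speed_tol if config.speed_tol is not None else 2.0 * dx
    steady_reached = False
    steady_iter: Optional[int] = None
    last_t = n_it

    for t in range(1, n_it + 1):
        if lo - hmax < 0 or hi + hmax > n - 1:
            raise BoundaryContactError(
                f"population support reached within one truncation width of the "
                f"boundary at iteration {t} (support cells [{lo}, {hi}] of {n})")
        sl = slice(lo, hi + 1)
        gP, gF1, gF2 = _growth.integrate_growth_arrays(
            P[sl], F1[sl], F2[sl], config.growth, config.solver, floor)
        news = []
        for grown, name in ((gP, "P"), (gF1, "F1"), (gF2, "F2")):
            k = kernels[name]
            arr = np.zeros(n)
            if k.is_identity:
                arr[sl] = grown
            else:
                conv = fftconvolve(grown, k.weights, mode="full")
                np.maximum(conv, 0.0, out=conv)
                arr[lo - k.half_width: hi + k.half_width + 1] = conv
            arr[arr < floor] = 0.0
            news.append(arr)
        P, F1, F2 = news
        wlo, whi = lo - hmax, hi + hmax
        sup = np.flatnonzero((P[wlo:whi + 1] > 0) | (F1[wlo:whi + 1] > 0)
                             | (F2[wlo:whi + 1] > 0))
        if sup.size:
            lo, hi = wlo + int(sup[0]), wlo + int(sup[-1])
        _record(P, F1, F2, eps, coords, dx, edges[t], masses[t], center[t], c)
        if config.snapshot_stride and (t % config.snapshot_stride == 0 or t == n_it):
            snapshots.append((t, CommunityField(landscape, P.copy(), F1.copy(),
                                                F2.copy(), t)))
        if not steady_reached and t >= config.steady_window:
            ok, _ = detect_steady_state(edges[:t + 1], center[:t + 1],
                                        config.steady_window, speed_tol,
                                        config.density_tol)
            if ok:
                steady_reached = True
                steady_iter = t
                if config.early_stop:
                    last_t = t
                    break

    final = CommunityField(landscape, P, F1, F2, last_t)
    return SimulationResult(
        config=config, landscape=landscape, final=final,
        edges=edges[:last_t + 1], masses=masses[:last_t + 1],
        center_density=center[:last_t + 1],
        steady_state_reached=steady_reached, steady_state_iteration=steady_iter,
        snapshots=snapshots,
    )


def detect_steady_state(edges: np.ndarray, center_density: np.ndarray,
                        window: int, speed_tol: float,
                        density_tol: float) -> tuple[bool, Optional[int]]:
    """Has the invasion settled into constant-speed, equilibrated spread?

    Over the trailing ``window`` iterations: (a) every species occupied at the
    last iteration must have been occupied throughout and its per-iteration
    right-edge displacement must vary by no more than ``speed_tol``; (b) the
    density of every species at the domain center must change by less than
    ``density_tol`` per iteration. Returns (flag, last iteration index) —
    iteration is None when the flag is False.
    """
    t = edges.shape[0] - 1
    if t < window:
        return False, None
    for s in range(edges.shape[1]):
        right = edges[t - window:t + 1, s, 1]
        if np.isnan(edges[t, s, 1]):
            continue  # extinct at the end: no front to settle
        if np.any(np.isnan(right)):
            return False, None
        disp = np.diff(right)
        # edge coordinates are grid multiples of dx; allow rounding fuzz
        if disp.max() - disp.min() > speed_tol * (1.0 + 1e-9):
            return False, None
    dens = center_density[t - window:t + 1]
    if np.abs(np.diff(dens, axis=0)).max() >= density_tol:
        return False, None
    return True, t
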