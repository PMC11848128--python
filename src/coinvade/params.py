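"""Parameter containers and validation for the three-species co-invasion model.

The community is a mutualist partner ``P`` (e.g. a mycorrhizal fungus) shared
by two competing focal species ``F1`` and ``F2`` (e.g. congeneric plants).
``F1`` is, by convention, the species more dependent on the mutualist.
All parameters are named after the symbols conventionally used for this
model family (``tau_12`` is the competitive effect ON F1 BY F2, etc.).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace, asdict
from typing import Optional

import numpy as np
import yaml

__all__ = [
    "ParameterError",
    "GrowthParams",
    "DispersalParams",
    "SolverSettings",
    "Landscape",
    "SimulationConfig",
    "load_config",
    "save_config",
]


class ParameterError(ValueError):
    """A parameter violates its contract (negative rate, delta outside [0,1], ...)."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass(frozen=True)
class GrowthParams:
    """Per-species rates and interaction coefficients of the growth ODEs.

    The within-generation dynamics at a point are::

        dP/dt  = P  [ r_P + a_PF1 F1/(h_P+F1) + a_PF2 F2/(h_P+F2) - d_P P ]
        dF1/dt = F1 [ (1-delta_F1) r_F1 + delta_F1 a_F1P P/(h_F1+P)
                      - d_F1 F1 - tau_12 F2 ]
        dF2/dt = F2 [ (1-delta_F2) r_F2 + delta_F2 a_F2P P/(h_F2+P)
                      - d_F2 F2 - tau_21 F1 ]

    ``delta_Fi`` is the mutualism dependence: the fraction of Fi's growth
    derived from partner benefits rather than intrinsic growth. Benefits
    saturate with partner density (half-saturation ``h``). Defaults are the
    standard simulation values for this model (growth rates 0.3, self-limitation
    0.1, benefit to the plants 0.5, benefit to the fungus 0.01, dependences
    0.9 / 0.1).
    """

    r_P: float = 0.3
    r_F1: float = 0.3
    r_F2: float = 0.3
    d_P: float = 0.1
    d_F1: float = 0.1
    d_F2: float = 0.1
    h_P: float = 0.3
    h_F1: float = 0.3
    h_F2: float = 0.3
    alpha_P_F1: float = 0.01
    alpha_P_F2: float = 0.01
    alpha_F1_P: float = 0.5
    alpha_F2_P: float = 0.5
    tau_12: float = 0.0
    tau_21: float = 0.0
    delta_F1: float = 0.9
    delta_F2: float = 0.1
    T_growth: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "r_P", "r_F1", "r_F2", "d_P", "d_F1", "d_F2",
            "h_P", "h_F1", "h_F2",
            "alpha_P_F1", "alpha_P_F2", "alpha_F1_P", "alpha_F2_P",
            "tau_12", "tau_21",
        ):
            v = getattr(self, name)
            _require(math.isfinite(v) and v >= 0.0, f"{name} must be finite and >= 0, got {v}")
        for name in ("delta_F1", "delta_F2"):
            v = getattr(self, name)
            _require(0.0 <= v <= 1.0, f"{name} must lie in [0, 1], got {v}")
        for name in ("tau_12", "tau_21"):
            v = getattr(self, name)
            _require(v <= 0.4, f"{name} must lie in [0, 0.4], got {v}")
        _require(self.T_growth > 0.0, f"T_growth must be > 0, got {self.T_growth}")

    def max_percapita_rate(self) -> float:
        """Upper bound on any species' low-density per-capita growth rate.

        Benefit terms saturate below their alpha, so the bound holds for any
        partner density. Used to size landscapes via the linearized spread
        speed sqrt(2 sigma^2 ln(lambda)).
        """
        return max(
            self.r_P + self.alpha_P_F1 + self.alpha_P_F2,
            (1.0 - self.delta_F1) * self.r_F1 + self.delta_F1 * self.alpha_F1_P,
            (1.0 - self.delta_F2) * self.r_F2 + self.delta_F2 * self.alpha_F2_P,
        )


@dataclass(frozen=True)
class DispersalParams:
    """Gaussian kernel variances, optionally scaled by mutualism dependence.

    With ``tradeoff_enabled`` the dependence-dispersal trade-off is active and
    competitor Fi disperses with effective variance ``delta_Fi * sigma2_Fi``
    (more dependent species invest in long-distance-dispersal structures);
    otherwise the stated variances are used as-is.
    """

    sigma2_P: float = 0.05
    sigma2_F1: float = 0.05
    sigma2_F2: float = 0.05
    tradeoff_enabled: bool = False
    delta_F1: float = 0.9
    delta_F2: float = 0.1

    def __post_init__(self) -> None:
        for name in ("sigma2_P", "sigma2_F1", "sigma2_F2"):
            v = getattr(self, name)
            _require(math.isfinite(v) and v >= 0.0, f"{name} must be finite and >= 0, got {v}")
        for name in ("delta_F1", "delta_F2"):
            v = getattr(self, name)
            _require(0.0 <= v <= 1.0, f"{name} must lie in [0, 1], got {v}")

    def effective_variances(self) -> tuple[float, float, float]:
        """(sigma2_P, sigma2_F1_eff, sigma2_F2_eff) after any trade-off scaling."""
        from .dispersal import effective_variance

        return (
            self.sigma2_P,
            effective_variance(self.sigma2_F1, self.delta_F1, self.tradeoff_enabled),
            effective_variance(self.sigma2_F2, self.delta_F2, self.tradeoff_enabled),
        )


@dataclass(frozen=True)
class SolverSettings:
    """Numerical settings for the within-generation ODE integration.

    method "rk4": classical fixed-step 4th-order Runge-Kutta, vectorized over
    grid points, ``n_steps`` substeps per growth phase. method "adaptive":
    scipy's RK45 with the given tolerances (slower; used for verification).
    """

    method: str = "rk4"
    n_steps: int = 20
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self) -> None:
        _require(self.method in ("rk4", "adaptive"), f"unknown solver method {self.method!r}")
        _require(self.n_steps >= 1, "n_steps must be >= 1")
        _require(self.rtol > 0 and self.atol > 0, "solver tolerances must be positive")


@dataclass(frozen=True)
class Landscape:
    """Uniform 1-D grid, symmetric about 0, with an exact center cell."""

    half_length: float
    dx: float = 0.01

    def __post_init__(self) -> None:
        _require(self.dx > 0, "dx must be positive")
        _require(self.half_length >= self.dx, "half_length must be at least one cell")
        # snap half_length onto the grid so dx*(n-1) == 2*half_length exactly
        m = round(self.half_length / self.dx)
        object.__setattr__(self, "half_length", m * self.dx)

    @property
    def n_points(self) -> int:
        return 2 * round(self.half_length / self.dx) + 1

    @property
    def center_index(self) -> int:
        return self.n_points // 2

    @property
    def coordinates(self) -> np.ndarray:
        n = self.n_points
        return (np.arange(n) - n // 2) * self.dx


# a wide default window/tolerances for steady-state reporting
_DEFAULT_STEADY_WINDOW = 50


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to run one simulation.

    ``landscape=None`` auto-sizes the domain so that ``n_iterations`` of
    spread at the linearized speed bound stay clear of the boundary (factor
    1.2 plus the kernel truncation width); the model assumes fronts never
    interact with the habitat edge.
    """

    growth: GrowthParams = field(default_factory=GrowthParams)
    dispersal: DispersalParams = field(default_factory=DispersalParams)
    landscape: Optional[Landscape] = None
    solver: SolverSettings = field(default_factory=SolverSettings)
    init_density: float = 0.1
    init_width_cells: int = 1
    n_iterations: int = 500
    occupancy_epsilon: float = 1e-3
    density_floor: float = 1e-12
    truncation_sigmas: float = 8.0
    mutualist_present: bool = True
    competitors_present: bool = True
    early_stop: bool = False
    steady_window: int = _DEFAULT_STEADY_WINDOW
    speed_tol: Optional[float] = None  # None -> 2*dx at run time
    density_tol: float = 1e-6
    snapshot_stride: int = 0  # 0 -> keep only the final field

    def __post_init__(self) -> None:
        _require(self.init_density > 0, "init_density must be > 0")
        _require(self.init_width_cells >= 1, "init_width_cells must be >= 1")
        _require(self.n_iterations >= 1, "n_iterations must be >= 1")
        _require(self.occupancy_epsilon > 0, "occupancy_epsilon must be > 0")
        _require(self.density_floor >= 0, "density_floor must be >= 0")
        _require(self.truncation_sigmas >= 6, "truncation_sigmas must be >= 6")
        _require(self.steady_window >= 1, "steady_window must be >= 1")
        _require(self.snapshot_stride >= 0, "snapshot_stride must be >= 0")
        if self.speed_tol is not None:
            _require(self.speed_tol > 0, "speed_tol must be > 0")
        _require(self.density_tol > 0, "density_tol must be > 0")
        # keep the dependence values of the two parameter blocks in sync
        if (self.dispersal.delta_F1 != self.growth.delta_F1
                or self.dispersal.delta_F2 != self.growth.delta_F2):
            object.__setattr__(
                self, "dispersal",
                replace(self.dispersal,
                        delta_F1=self.growth.delta_F1,
                        delta_F2=self.growth.delta_F2),
            )

    def speed_bound(self) -> float:
        """Generous per-iteration spread-speed bound sqrt(2 sigma2_max rate_max T)."""
        s2 = max(self.dispersal.effective_variances())
        return math.sqrt(2.0 * s2 * self.growth.max_percapita_rate() * self.growth.T_growth)

    def resolved_landscape(self) -> Landscape:
        if self.landscape is not None:
            return self.landscape
        s2max = max(self.dispersal.effective_variances())
        clearance = self.truncation_sigmas * math.sqrt(s2max)
        half = max(20.0, 1.2 * self.n_iterations * self.speed_bound() + clearance)
        return Landscape(half_length=half)


# ---------------------------------------------------------------------------
# flat key:value config files
# ---------------------------------------------------------------------------

_GROWTH_KEYS = {f.name for f in fields(GrowthParams)}
_DISPERSAL_KEYS = {f.name for f in fields(DispersalParams)}
_TOP_KEYS = {
    "init_density", "init_width_cells", "n_iterations", "occupancy_epsilon",
    "density_floor", "truncation_sigmas", "mutualist_present",
    "competitors_present", "early_stop",
    "steady_window", "speed_tol", "density_tol", "snapshot_stride",
}
_LANDSCAPE_KEYS = {"half_length", "dx"}
_SOLVER_KEYS = {"solver_method", "solver_n_steps", "solver_rtol", "solver_atol"}


def config_from_dict(data: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a flat mapping of field names."""
    data = dict(data)
    unknown = set(data) - _GROWTH_KEYS - _DISPERSAL_KEYS - _TOP_KEYS - _LANDSCAPE_KEYS - _SOLVER_KEYS
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")
    growth = GrowthParams(**{k: data[k] for k in _GROWTH_KEYS if k in data})
    disp_kwargs = {k: data[k] for k in _DISPERSAL_KEYS if k in data}
    disp_kwargs.setdefault("delta_F1", growth.delta_F1)
    disp_kwargs.setdefault("delta_F2", growth.delta_F2)
    dispersal = DispersalParams(**disp_kwargs)
    landscape = None
    if "half_length" in data:
        landscape = Landscape(half_length=data["half_length"], dx=data.get("dx", 0.01))
    elif "dx" in data:
        raise ParameterError("dx given without half_length; provide both or neither")
    solver = SolverSettings(
        method=data.get("solver_method", "rk4"),
        n_steps=int(data.get("solver_n_steps", 20)),
        rtol=float(data.get("solver_rtol", 1e-8)),
        atol=float(data.get("solver_atol", 1e-10)),
    )
    top = {k: data[k] for k in _TOP_KEYS if k in data}
    return SimulationConfig(growth=growth, dispersal=dispersal, landscape=landscape,
                            solver=solver, **top)


def config_to_dict(config: SimulationConfig) -> dict:
    """Flatten a config back to the key:value form accepted by config files."""
    out: dict = {}
    out.update(asdict(config.growth))
    for k in ("sigma2_P", "sigma2_F1", "sigma2_F2", "tradeoff_enabled"):
        out[k] = getattr(config.dispersal, k)
    if config.landscape is not None:
        out["half_length"] = config.landscape.half_length
        out["dx"] = config.landscape.dx
    if config.solver != SolverSettings():
        out["solver_method"] = config.solver.method
        out["solver_n_steps"] = config.solver.n_steps
    for k in sorted(_TOP_KEYS):
        v = getattr(config, k)
        if v is not None:
            out[k] = v
    return out


def load_config(path) -> SimulationConfig:
    """Read a flat ``key: value`` config file (YAML syntax)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ParameterError(f"config file {path} must contain a flat mapping")
    return config_from_dict(data)


def save_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)
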