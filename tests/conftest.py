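import dataclasses

import pytest

import coinvade as cv


@pytest.fixture(scope="session")
def defaults() -> cv.GrowthParams:
    return cv.GrowthParams()


def small_config(**kw) -> cv.SimulationConfig:
    """Desk-scale config for unit tests: small fixed landscape, short run."""
    kw.setdefault("n_iterations", 40)
    cfg = cv.make_config(**kw)
    return dataclasses.replace(cfg, landscape=cv.Landscape(half_length=20.0))


@pytest.fixture(scope="session")
def single_species_P_run() -> cv.SimulationResult:
    """The partner mutualist invading alone (logistic limit), 300 iterations.

    Shared by the carrying-capacity, density-ratio and speed checks.
    """
    cfg = cv.make_config(n_iterations=300, competitors_present=False)
    return cv.run(cfg)


@pytest.fixture(scope="session")
def preset_runs() -> dict:
    """Full default-protocol runs of the six canonical outcome presets."""
    out = {}
    for panel, (t12, t21, s2P) in cv.OUTCOME_PRESETS.items():
        cfg = cv.make_config(tau_12=t12, tau_21=t21, sigma2_P=s2P)
        result = cv.run(cfg)
        out[panel] = (result, cv.evaluate_outcome(result))
    return out
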