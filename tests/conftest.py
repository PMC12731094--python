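import pytest
from hypothesis import HealthCheck, settings

from bioaxsim import (
    analytic_fixture,
    paper_scenario,
    run_scenario,
    solve_steady_flow,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def bulk_result():
    """Steady chamber run with homogeneous bulk consumption (11e6 cells)."""
    return run_scenario(paper_scenario("bulk_11M"))


@pytest.fixture(scope="session")
def scaffold_results():
    """Steady chamber runs with surface consumption on 12 scaffolds."""
    return {
        name: run_scenario(paper_scenario(name))
        for name in ("scaffolds_400k", "scaffolds_4M")
    }


@pytest.fixture(scope="session")
def pipe_case():
    """Laminar pipe fixture solved once for all Poiseuille checks."""
    fx = analytic_fixture("poiseuille_pipe")
    sol = solve_steady_flow(
        fx.domain, fx.fluid, fx.flow_rate,
        include_advection=fx.include_advection,
    )
    return fx, sol
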