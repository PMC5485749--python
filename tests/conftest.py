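import numpy as np
import pytest

import mcapop as mp
from mcapop import synthetic as syn


@pytest.fixture(scope="session")
def scenario():
    return syn.make_scenario()


@pytest.fixture(scope="session")
def scenario_flux(scenario):
    return scenario.solve_flux()


@pytest.fixture(scope="session")
def scenario_population(scenario, scenario_flux):
    """The reference population: 200 displacement profiles x 5 saturation draws."""
    cfg = mp.PipelineConfig(n_conc=200, n_sat=5, seed=0)
    return mp.run_pipeline(scenario.model, scenario_flux, cfg, scenario.mechanisms)


@pytest.fixture(scope="session")
def toy_models():
    return {
        "chain_first_order": syn.gen_toy_chain(3, "first_order", seed=1),
        "chain_rev_mm": syn.gen_toy_chain(3, "rev_mm", seed=2),
        "branch": syn.gen_toy_branch(seed=3),
        "moiety_cycle": syn.gen_toy_moiety(seed=4),
    }


def engine_control_sample(toy):
    """Run a toy model through the control-analysis engine."""
    x, fp = toy.flux_profile()
    E = toy.elasticity_matrix_at(x)
    red = mp.reduce_structure(toy.network)
    xv = np.array([x[m] for m in toy.internal_ids])
    return x, fp, mp.control_coefficients(
        red,
        fp,
        E,
        concentrations=xv,
        met_ids=[toy.internal_ids[i] for i in red.independent_rows],
    )
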