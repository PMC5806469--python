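import pytest

import lignflux as lf


@pytest.fixture(scope="session")
def illustration():
    return lf.load_builtin("illustration")


@pytest.fixture(scope="session")
def fig4():
    return lf.load_builtin("brachy_fig4")


@pytest.fixture(scope="session")
def fig5():
    return lf.load_builtin("brachy_fig5")


@pytest.fixture(scope="session")
def fig6():
    return lf.load_builtin("brachy_fig6")


@pytest.fixture(scope="session")
def table1():
    return lf.load_table1_constraints()


@pytest.fixture(scope="session")
def sink_toy():
    """One input, a 3-way branch into H/G/S sinks, no diffusion."""
    return lf.load_network(
        {
            "name": "sink_toy",
            "metabolites": [
                {"id": "X", "compartment": "cytosol", "roles": ["input_pool"]},
                {"id": "H", "compartment": "cytosol", "roles": ["H_sink"]},
                {"id": "G", "compartment": "cytosol", "roles": ["G_sink"]},
                {"id": "S", "compartment": "cytosol", "roles": ["S_sink"]},
            ],
            "fluxes": [
                {"id": "VIN", "kind": "input", "products": [["X", 1]], "value": 100.0},
                {"id": "VH", "kind": "enzymatic", "substrates": [["X", 1]], "products": [["H", 1]]},
                {"id": "VG", "kind": "enzymatic", "substrates": [["X", 1]], "products": [["G", 1]]},
                {"id": "VS", "kind": "enzymatic", "substrates": [["X", 1]], "products": [["S", 1]]},
                {"id": "EH", "kind": "efflux", "substrates": [["H", 1]]},
                {"id": "EG", "kind": "efflux", "substrates": [["G", 1]]},
                {"id": "ES", "kind": "efflux", "substrates": [["S", 1]]},
            ],
        }
    )


@pytest.fixture(scope="session")
def mirror_toy():
    """Two symmetric pools of one species exchanging by diffusion."""
    return lf.load_network(
        {
            "name": "mirror",
            "metabolites": [
                {"id": "A", "compartment": "cytosol", "species": "Z",
                 "roles": ["input_pool"]},
                {"id": "B", "compartment": "ER", "species": "Z",
                 "roles": ["input_pool"]},
            ],
            "fluxes": [
                {"id": "INA", "kind": "input", "products": [["A", 1]], "value": 100.0},
                {"id": "INB", "kind": "input", "products": [["B", 1]], "value": 100.0},
                {"id": "D", "kind": "diffusion_net", "substrates": [["A", 1]],
                 "products": [["B", 1]]},
                {"id": "EA", "kind": "efflux", "substrates": [["A", 1]]},
                {"id": "EB", "kind": "efflux", "substrates": [["B", 1]]},
            ],
        }
    )
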