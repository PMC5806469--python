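"""Network loading, validation, stoichiometry and branch-point structure."""

import json

import numpy as np
import pytest

import lignflux as lf
from lignflux.steady import compile_network


def test_illustration_structure_matches_toy_odes(illustration):
    """The shipped illustration network encodes the four-pool toy system."""
    assert set(illustration.metabolites) == {"X1", "X2", "X3", "X4"}
    S = lf.build_stoichiometric_matrix(illustration)
    assert S.row("X1") == {"VIN1": 1, "V1": -1}
    assert S.row("X2") == {"V1": 1, "V2": -1, "D": -1}
    assert S.row("X3") == {"VIN2": 1, "V3": -1}
    assert S.row("X4") == {"V3": 1, "D": 1, "V4": -1, "V5": -1}


def test_minimal_single_metabolite_network():
    net = lf.load_network(
        {
            "name": "min",
            "metabolites": [{"id": "X", "compartment": "cytosol"}],
            "fluxes": [
                {"id": "IN", "kind": "input", "products": [["X", 1]], "value": 1.0},
                {"id": "OUT", "kind": "efflux", "substrates": [["X", 1]]},
            ],
        }
    )
    S = lf.build_stoichiometric_matrix(net)
    assert S.row("X") == {"IN": 1, "OUT": -1}


def test_column_sums_encode_edge_kinds(fig6):
    """Internal conversions conserve mass; inputs/effluxes are sources/sinks."""
    S = lf.build_stoichiometric_matrix(fig6)
    sums = S.matrix.sum(axis=0)
    for j, fid in enumerate(S.flux_ids):
        kind = fig6.fluxes[fid].kind
        expected = {"input": 1, "efflux": -1}.get(kind, 0)
        assert sums[j] == expected, (fid, kind)


@pytest.mark.parametrize(
    "mutate, exc",
    [
        # duplicate flux id
        (lambda d: d["fluxes"].append(dict(d["fluxes"][2])), lf.DuplicateIdError),
        # diffusion edge joining two cytosol pools
        (
            lambda d: [m.update(compartment="cytosol") for m in d["metabolites"]
                       if m["id"] == "X4"],
            lf.DiffusionPairError,
        ),
        # diffusion edge joining different species
        (
            lambda d: [m.update(species="other") for m in d["metabolites"]
                       if m["id"] == "X4"],
            lf.DiffusionPairError,
        ),
        # cycle in the net-flux graph
        (
            lambda d: d["fluxes"].append(
                {"id": "BACK", "kind": "enzymatic",
                 "substrates": [["X4", 1]], "products": [["X1", 1]]}
            ),
            lf.CyclicNetworkError,
        ),
        # non-unit stoichiometric coefficient
        (
            lambda d: d["fluxes"][2].update(substrates=[["X1", 2]]),
            lf.SchemaError,
        ),
        # duplicated unique role
        (
            lambda d: [m.update(roles=["H_sink"]) for m in d["metabolites"]
                       if m["id"] in ("X1", "X3")],
            lf.RoleError,
        ),
    ],
)
def test_validation_failures_are_distinct(illustration, mutate, exc):
    doc = json.loads(illustration.serialize())
    mutate(doc)
    with pytest.raises(exc):
        lf.load_network(doc)


def test_malformed_json_is_a_schema_error():
    with pytest.raises(lf.SchemaError):
        lf.load_network("{not json")


@pytest.mark.parametrize(
    "name", ["illustration", "brachy_fig4", "brachy_fig5", "brachy_fig6"]
)
def test_serialize_round_trip(name):
    net = lf.load_builtin(name)
    again = lf.load_network(net.serialize())
    assert again.to_dict() == net.to_dict()


@pytest.mark.parametrize(
    "name", ["illustration", "brachy_fig4", "brachy_fig5", "brachy_fig6"]
)
def test_every_shipped_network_admits_a_positive_steady_state(name):
    """S.V = 0 has a strictly positive solution (equal splits everywhere)."""
    net = lf.load_builtin(name)
    compiled = compile_network(net)
    fracs = [
        np.full((1, len(out)), 1.0 / len(out)) for _, out in compiled.branches
    ]
    F = compiled.propagate(fracs)
    assert (F > 0).all()
    S = lf.build_stoichiometric_matrix(net)
    assert tuple(S.flux_ids) == tuple(compiled.edge_ids)
    resid = S.matrix.astype(float) @ F[0]
    assert np.abs(resid).max() < 1e-9


def test_branch_points_and_degrees_of_freedom(illustration, fig6):
    bp = lf.branch_points(illustration)
    assert [(m, set(e)) for m, e in bp] == [
        ("X2", {"V2", "D"}),
        ("X4", {"V4", "V5"}),
    ]
    assert lf.degrees_of_freedom(illustration) == 2
    # three-way branches contribute k - 1 degrees of freedom each
    bp6 = dict(lf.branch_points(fig6))
    assert set(bp6["PCA_e"]) == {"D2", "V20", "V21"}
    assert lf.degrees_of_freedom(fig6) == 8


def test_linear_chain_has_no_branch_points():
    net = lf.load_network(
        {
            "name": "chain",
            "metabolites": [
                {"id": "A", "compartment": "cytosol"},
                {"id": "B", "compartment": "cytosol"},
            ],
            "fluxes": [
                {"id": "IN", "kind": "input", "products": [["A", 1]], "value": 1.0},
                {"id": "AB", "kind": "enzymatic", "substrates": [["A", 1]],
                 "products": [["B", 1]]},
                {"id": "OUT", "kind": "efflux", "substrates": [["B", 1]]},
            ],
        }
    )
    assert lf.branch_points(net) == []
    assert lf.degrees_of_freedom(net) == 0


def test_speculative_c3h_edge_is_toggleable(fig6):
    """Removing the cytosolic C3H step leaves a valid, smaller scheme."""
    without = fig6.without_edges(["V4"])
    assert "V4" not in without.fluxes
    assert "CAF_c" in without.metabolites  # still fed from the ER side
    with pytest.raises(lf.SchemaError):
        fig6.without_edges(["NOPE"])


def test_stoichiometric_matrix_tsv_round_trip(tmp_path, illustration):
    S = lf.build_stoichiometric_matrix(illustration)
    p = tmp_path / "S.tsv"
    S.to_tsv(p)
    import pandas as pd

    df = pd.read_csv(p, sep="\t", index_col=0)
    assert df.loc["X2", "D"] == -1
    assert df.shape == (4, 8)
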