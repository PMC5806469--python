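"""Observable computation and threshold screening."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lignflux as lf
from lignflux.observables import ConstraintSet, Target


def _toy_flux(sink_toy, h, g, s):
    tot = h + g + s
    fsr = lf.FSRVector(
        {
            ("X", "VH"): h / tot,
            ("X", "VG"): g / tot,
            ("X", "VS"): s / tot,
        }
    )
    return lf.fluxes_from_fsr(sink_toy, fsr, inputs={"VIN": float(tot)})


def test_monomer_fractions_and_sg_ratio(sink_toy):
    flux = _toy_flux(sink_toy, 4, 45, 51)
    obs = lf.compute_observables(sink_toy, flux)
    assert obs.h_frac == pytest.approx(4.0)
    assert obs.g_frac == pytest.approx(45.0)
    assert obs.s_frac == pytest.approx(51.0)
    assert obs.sg_ratio == pytest.approx(51 / 45)
    assert obs.h_frac + obs.g_frac + obs.s_frac == pytest.approx(100, abs=1e-6)


def test_equal_g_and_s_effluxes_give_unit_ratio(sink_toy):
    obs = lf.compute_observables(sink_toy, _toy_flux(sink_toy, 10, 45, 45))
    assert obs.sg_ratio == pytest.approx(1.0)


def test_uniform_labels_give_uniform_incorporation(sink_toy):
    """When every pool carries label L, every incorporation equals 100 L."""
    flux = _toy_flux(sink_toy, 10, 40, 50)
    accepted = lf.sample_label_states(
        sink_toy, flux, ("X", 0.35), 1, seed=0
    )
    labels, labeled = accepted[0]
    obs = lf.compute_observables(sink_toy, flux, {"exp": labeled})
    for name in ("H", "G", "S", "total_lignin"):
        assert obs.incorporation["exp"][name] == pytest.approx(35.0)


def test_observables_invariant_under_flux_rescaling(sink_toy):
    a = lf.compute_observables(sink_toy, _toy_flux(sink_toy, 4, 45, 51))
    b = lf.compute_observables(
        sink_toy,
        lf.FluxVector({k: 3.7 * v for k, v in
                       _toy_flux(sink_toy, 4, 45, 51).values.items()}),
    )
    assert a.composition() == pytest.approx(b.composition())


def test_missing_role_raises(illustration):
    with pytest.raises(lf.RoleError):
        lf.compute_observables(
            illustration,
            lf.FluxVector({e: 1.0 for e in illustration.fluxes}),
        )


def test_check_constraints_table_style(sink_toy):
    """Model composition near the experimental row passes at 10% relative."""
    obs = lf.compute_observables(sink_toy, _toy_flux(sink_toy, 4.1, 45, 51))
    cs = ConstraintSet(
        name="tbl",
        targets=(
            Target("H_frac", 4.0, 0.10, "rel"),
            Target("G_frac", 45.0, 0.10, "rel"),
            Target("S_frac", 51.0, 0.10, "rel"),
            Target("SG_ratio", 1.09, 0.10, "rel"),
        ),
    )
    rep = lf.check_constraints(obs, cs)
    assert rep.passed
    assert len(rep.rows) == 4


def test_self_comparison_passes_at_vanishing_tolerance(sink_toy):
    obs = lf.compute_observables(sink_toy, _toy_flux(sink_toy, 4, 45, 51))
    cs = ConstraintSet(
        name="self",
        targets=tuple(
            Target(k, v, 1e-12, "abs") for k, v in obs.composition().items()
        ),
    )
    assert lf.check_constraints(obs, cs).passed


def test_infeasible_target_fails_with_residual(sink_toy):
    obs = lf.compute_observables(sink_toy, _toy_flux(sink_toy, 4, 45, 51))
    cs = ConstraintSet(name="bad", targets=(Target("H_frac", 150.0, 2.0, "abs"),))
    rep = lf.check_constraints(obs, cs)
    assert not rep.passed
    assert rep.rows[0]["residual"] == pytest.approx(4 - 150)


@settings(derandomize=True, deadline=None, max_examples=40)
@given(h=st.floats(1, 40), g=st.floats(1, 60), scale=st.floats(1.1, 8))
def test_tolerance_monotonicity(h, g, scale):
    """Any pass at tolerance t also passes at t' > t (and failures can only
    turn into passes, never the reverse)."""
    sink_toy = lf.load_network(
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
    s = max(100 - h - g, 1)
    obs = lf.compute_observables(sink_toy, _toy_flux(sink_toy, h, g, s))
    cs = ConstraintSet(
        name="m",
        targets=(
            Target("H_frac", 6.0, 2.0, "abs"),
            Target("G_frac", 45.0, 3.0, "abs"),
            Target("SG_ratio", 1.1, 0.1, "rel"),
        ),
    )
    tight = lf.check_constraints(obs, cs).passed
    loose = lf.check_constraints(obs, cs.with_tolerance_scale(scale)).passed
    assert loose or not tight


def test_table1_constraint_file_contents(table1):
    assert table1.feedings == {"phe": ("PHE", 0.35), "tyr": ("TYR", 0.35)}
    assert len(table1.label_free_targets()) == 4
    assert len(table1.labeled_targets("phe")) == 5
    assert len(table1.labeled_targets("tyr")) == 5
    # H incorporation is deliberately absent from the screening targets
    assert not any(
        t.observable == "incorporation.H" for t in table1.targets
    )


def test_unknown_observable_rejected():
    with pytest.raises(lf.SchemaError):
        Target("nonsense", 1.0, 0.1, "abs")
    with pytest.raises(lf.SchemaError):
        Target("H_frac", 1.0, -0.1, "abs")
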