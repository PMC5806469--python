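"""Synthetic feeding experiments with known ground truth.

No raw labeling data are deposited for the organism, so pipeline recovery
behavior is exercised on generated experiments: a ground-truth flux
distribution is drawn from the same FSR prior the sampler uses, admissible
label states are drawn for every feeding scenario, exact observables are
computed, and independent Gaussian noise (in percentage points) is added to
every observed percentage.  The noisy table is emitted as a constraint file
in the shipped Table-style schema, so the pipeline can be run against it
unchanged.

Individual fluxes are not point-identifiable from these observables (the
steady state is underdetermined by construction), so recovery is asserted
on observables, not on flux point values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import LignfluxError
from .labeling import LabelPlan, LabelState, solve_labels
from .network import PathwayNetwork
from .observables import (
    ConstraintSet,
    Observables,
    Target,
    composition_arrays,
    incorporation_arrays,
)
from .steady import FluxVector, compile_network

#: default screening tolerances, matching the shipped constraint table
DEFAULT_COMP_TOL = 5.0  # percentage points, absolute
DEFAULT_INC_TOL = 5.0  # percentage points, absolute

_LABEL_BATCH = 256


@dataclass
class SyntheticExperiment:
    """Ground truth plus noise-perturbed observations for one network."""

    network_name: str
    seed: int
    noise_sd: float
    fsr: Mapping[str, Mapping[str, float]]
    flux: FluxVector
    label_states: Mapping[str, LabelState]
    truth: Observables
    observed: Observables
    constraints: ConstraintSet
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "network": self.network_name,
            "seed": self.seed,
            "noise_sd": self.noise_sd,
            "fsr": {m: dict(v) for m, v in self.fsr.items()},
            "flux": dict(self.flux.values),
            "labels": {
                tag: dict(st.labels) for tag, st in self.label_states.items()
            },
            "truth": self.truth.to_dict(),
            "observed": self.observed.to_dict(),
            "meta": self.meta,
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "truth.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
        with open(out / "constraints.json", "w") as fh:
            json.dump(self.constraints.to_dict(), fh, indent=2)


def _default_feedings(network: PathwayNetwork) -> dict[str, tuple[str, float]]:
    pools = [m.id for m in network.metabolites.values() if "input_pool" in m.roles]
    if {"PHE", "TYR"} <= set(pools):
        return {"phe": ("PHE", 0.35), "tyr": ("TYR", 0.35)}
    # generic fallback: one experiment per input pool, 35% label each
    return {p.lower(): (p, 0.35) for p in pools}


def generate_experiment(
    network: PathwayNetwork,
    seed: int,
    noise_sd: float = 1.0,
    feedings: Mapping[str, tuple[str, float]] | None = None,
    require_channelled: bool = False,
    channel_edge: str = "V8",
    channel_min: float = 5.0,
    ferulic_min: float = 25.0,
    comp_tol: float = DEFAULT_COMP_TOL,
    inc_tol: float = DEFAULT_INC_TOL,
    max_tries: int = 2000,
) -> SyntheticExperiment:
    """Draw a ground-truth experiment and its noisy observation table.

    With ``require_channelled`` the draw is repeated until the metabolic
    channel is actually expressed in the data: the channel edge carries at
    least ``channel_min`` flux units and the first experiment's wall-bound
    ferulic acid incorporation reaches ``ferulic_min`` percent - the
    signature that a channel-free scheme cannot reproduce.  Identical
    arguments (including ``seed``) regenerate the identical experiment.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    compiled = compile_network(network)
    plan = LabelPlan(compiled)
    feedings = dict(feedings) if feedings is not None else _default_feedings(network)
    if not feedings:
        raise LignfluxError("network has no input_pool roles to feed")
    first_tag = next(iter(feedings))

    for _ in range(max_tries):
        fracs = compiled.sample_fractions(1, rng)
        F = compiled.propagate(fracs)
        if require_channelled:
            j = compiled.edge_index.get(channel_edge)
            if j is None:
                raise LignfluxError(
                    f"network has no channel edge {channel_edge!r}"
                )
            if F[0, j] < channel_min:
                continue
        solutions = {}
        for tag, (pool, fraction) in feedings.items():
            Fb = np.tile(F, (_LABEL_BATCH, 1))
            sol = solve_labels(plan, Fb, pool, fraction, rng=rng)
            hits = np.flatnonzero(sol.valid)
            if hits.size == 0:
                solutions = None
                break
            i = hits[0]
            solutions[tag] = (sol, int(i))
        if solutions is None:
            continue

        comp = composition_arrays(compiled, F)
        inc = {}
        label_states = {}
        for tag, (sol, i) in solutions.items():
            VL = sol.labeled_fluxes(np.tile(F, (_LABEL_BATCH, 1)))[i : i + 1]
            arrs = incorporation_arrays(compiled, F, VL)
            inc[tag] = {k: float(v[0]) for k, v in arrs.items()}
            label_states[tag] = LabelState(
                labels=dict(zip(compiled.pool_ids, sol.L[i])),
                feeding_pool=feedings[tag][0],
                feeding_fraction=feedings[tag][1],
            )
        truth = Observables(
            h_frac=float(comp["H_frac"][0]),
            g_frac=float(comp["G_frac"][0]),
            s_frac=float(comp["S_frac"][0]),
            sg_ratio=float(comp["SG_ratio"][0]),
            incorporation=inc,
        )
        if require_channelled and (
            truth.incorporation[first_tag]["wall_ferulic"] < ferulic_min
        ):
            continue
        break
    else:
        raise LignfluxError(
            f"no admissible ground truth found in {max_tries} tries"
        )

    observed = _perturb(truth, noise_sd, rng)
    constraints = _constraints_from(observed, feedings, comp_tol, inc_tol,
                                    network.name, seed, noise_sd)
    fsr = {
        compiled.pool_ids[i]: {
            compiled.edge_ids[j]: float(fracs[b][0, c])
            for c, j in enumerate(out)
        }
        for b, (i, out) in enumerate(compiled.branches)
    }
    return SyntheticExperiment(
        network_name=network.name,
        seed=seed,
        noise_sd=noise_sd,
        fsr=fsr,
        flux=FluxVector(dict(zip(compiled.edge_ids, F[0]))),
        label_states=label_states,
        truth=truth,
        observed=observed,
        constraints=constraints,
        meta={"require_channelled": require_channelled},
    )


def _perturb(truth: Observables, sd: float, rng: np.random.Generator) -> Observables:
    """Additive Gaussian noise on every observed percentage.

    Noisy composition percentages are clipped at zero and renormalized to
    sum to 100 (an instrument reports shares); S/G is the ratio of the noisy
    shares.  Incorporation percentages are clipped to [0, 100].
    """
    comp = np.array([truth.h_frac, truth.g_frac, truth.s_frac])
    comp = np.clip(comp + rng.normal(0.0, sd, size=3), 0.0, None)
    comp = 100 * comp / comp.sum()
    inc = {
        tag: {
            k: float(np.clip(v + rng.normal(0.0, sd), 0.0, 100.0))
            for k, v in vals.items()
        }
        for tag, vals in truth.incorporation.items()
    }
    return Observables(
        h_frac=float(comp[0]),
        g_frac=float(comp[1]),
        s_frac=float(comp[2]),
        sg_ratio=float(comp[2] / comp[1]) if comp[1] > 0 else float("nan"),
        incorporation=inc,
    )


def _constraints_from(
    observed: Observables,
    feedings: Mapping[str, tuple[str, float]],
    comp_tol: float,
    inc_tol: float,
    network_name: str,
    seed: int,
    noise_sd: float,
) -> ConstraintSet:
    # no S/G target: the ratio is fully determined by the two share targets,
    # and its relative noise is unbounded for G-poor ground truths
    targets = [
        Target("H_frac", observed.h_frac, comp_tol, "abs"),
        Target("G_frac", observed.g_frac, comp_tol, "abs"),
        Target("S_frac", observed.s_frac, comp_tol, "abs"),
    ]
    for tag in feedings:
        for name in ("H", "G", "S", "total_lignin", "wall_coumaric",
                     "wall_ferulic"):
            targets.append(
                Target(
                    f"incorporation.{name}",
                    observed.incorporation[tag][name],
                    inc_tol,
                    "abs",
                    experiment=tag,
                )
            )
    return ConstraintSet(
        name=f"synthetic({network_name}, seed={seed}, sd={noise_sd})",
        targets=tuple(targets),
        feedings=dict(feedings),
    )
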