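"""Flux-split-ratio (FSR) parameterization of underdetermined steady states.

At steady state the flux vector of a monomolecular network satisfies
``S . V = 0``, which leaves one degree of freedom per extra outgoing edge at
every diverging branch point.  The method samples the split fractions at
each branch (uniformly on the simplex; ``U[0, 1]`` for two-way branches),
propagates the fixed boundary inputs through the network in topological
order, and keeps only flux vectors that satisfy the active observation
constraints.  Non-negativity holds by construction on a DAG, and is
re-checked anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import FSRMismatchError
from .network import PathwayNetwork, branch_points

_SUM_TOL = 1e-12


# ---------------------------------------------------------------------------
# compiled network: integer-indexed arrays for vectorized propagation
# ---------------------------------------------------------------------------


class CompiledNetwork:
    """Index tables for vectorized flux propagation over one network."""

    def __init__(self, net: PathwayNetwork):
        self.net = net
        self.pool_ids: list[str] = net.topological_metabolites()
        self.pool_index = {p: i for i, p in enumerate(self.pool_ids)}
        self.edge_ids: list[str] = list(net.fluxes)
        self.edge_index = {e: j for j, e in enumerate(self.edge_ids)}
        self.edge_src = np.array(
            [
                self.pool_index.get(net.fluxes[e].substrate, -1)
                for e in self.edge_ids
            ],
            dtype=np.int64,
        )
        self.edge_dst = np.array(
            [self.pool_index.get(net.fluxes[e].product, -1) for e in self.edge_ids],
            dtype=np.int64,
        )
        self.input_edges = [
            (self.edge_index[e.id], float(v))
            for e in net.input_edges()
            for v in [net.input_values()[e.id]]
        ]
        # branch structure in topological pool order
        self.branches: list[tuple[int, list[int]]] = []
        self.single_out: list[tuple[int, int]] = []
        for pid in self.pool_ids:
            out = [self.edge_index[e.id] for e in net.consumers(pid)]
            i = self.pool_index[pid]
            if len(out) >= 2:
                self.branches.append((i, out))
            elif len(out) == 1:
                self.single_out.append((i, out[0]))
        self.diffusion_edge_ids = [e.id for e in net.diffusion_edges()]

    # -- propagation ---------------------------------------------------------

    def propagate(
        self,
        fractions: Sequence[np.ndarray],
        input_values: Mapping[str, float] | None = None,
    ) -> np.ndarray:
        """Distribute inflows over branches; returns flux matrix (n, n_edges).

        ``fractions[b]`` has shape ``(n, k_b)`` with rows on the simplex for
        branch ``b`` in ``self.branches`` order.
        """
        if len(fractions) != len(self.branches):
            raise FSRMismatchError(
                f"expected fractions for {len(self.branches)} branches, "
                f"got {len(fractions)}"
            )
        n = fractions[0].shape[0] if fractions else 1
        F = np.zeros((n, len(self.edge_ids)))
        inflow = np.zeros((n, len(self.pool_ids)))
        for j, val in self.input_edges:
            if input_values is not None:
                val = float(input_values[self.edge_ids[j]])
            F[:, j] = val
            if self.edge_dst[j] >= 0:
                inflow[:, self.edge_dst[j]] += val
        branch_of_pool = {i: b for b, (i, _) in enumerate(self.branches)}
        single = dict(self.single_out)
        for i in range(len(self.pool_ids)):
            if i in branch_of_pool:
                b = branch_of_pool[i]
                _, out = self.branches[b]
                fr = fractions[b]
                for col, j in enumerate(out):
                    F[:, j] = fr[:, col] * inflow[:, i]
                    if self.edge_dst[j] >= 0:
                        inflow[:, self.edge_dst[j]] += F[:, j]
            elif i in single:
                j = single[i]
                F[:, j] = inflow[:, i]
                if self.edge_dst[j] >= 0:
                    inflow[:, self.edge_dst[j]] += F[:, j]
        return F

    def sample_fractions(
        self, n: int, rng: np.random.Generator
    ) -> list[np.ndarray]:
        """Uniform Dirichlet(1, ..., 1) rows per branch (U[0,1] for 2-way)."""
        out = []
        for _, edges in self.branches:
            k = len(edges)
            out.append(rng.dirichlet(np.ones(k), size=n))
        return out


def compile_network(net: PathwayNetwork) -> CompiledNetwork:
    return CompiledNetwork(net)


# ---------------------------------------------------------------------------
# public value types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FSRVector:
    """Split fractions keyed by (branch metabolite id, outgoing flux id)."""

    values: Mapping[tuple[str, str], float]

    def for_network(self, net: PathwayNetwork) -> dict[str, dict[str, float]]:
        """Group by branch metabolite, verifying coverage and simplex sums."""
        grouped: dict[str, dict[str, float]] = {}
        for (mid, fid), v in self.values.items():
            grouped.setdefault(mid, {})[fid] = float(v)
        expected = dict(branch_points(net))
        if set(grouped) != set(expected):
            raise FSRMismatchError(
                f"FSR branches {sorted(grouped)} do not match network branch "
                f"points {sorted(expected)}"
            )
        for mid, fr in grouped.items():
            if set(fr) != set(expected[mid]):
                raise FSRMismatchError(
                    f"branch {mid!r}: FSR edges {sorted(fr)} do not match "
                    f"outgoing edges {sorted(expected[mid])}"
                )
            s = sum(fr.values())
            if abs(s - 1.0) > 1e-9 or any(not (0 <= v <= 1) for v in fr.values()):
                raise FSRMismatchError(
                    f"branch {mid!r}: fractions must lie in [0,1] and sum to 1 "
                    f"(sum={s!r})"
                )
        return grouped


@dataclass(frozen=True)
class FluxVector:
    """Steady-state total fluxes, units of mass per unit time."""

    values: Mapping[str, float]

    def __getitem__(self, fid: str) -> float:
        return self.values[fid]

    def as_array(self, compiled: CompiledNetwork) -> np.ndarray:
        return np.array([self.values[e] for e in compiled.edge_ids])


@dataclass
class FluxEnsemble:
    """Accepted steady-state flux vectors plus sampler metadata."""

    network_name: str
    edge_ids: list[str]
    fluxes: np.ndarray  # (n_accepted, n_edges)
    n_samples: int
    seed: int
    accepted: int = field(init=False)

    def __post_init__(self) -> None:
        self.accepted = int(self.fluxes.shape[0])

    @property
    def members(self) -> list[FluxVector]:
        return [
            FluxVector(dict(zip(self.edge_ids, row))) for row in self.fluxes
        ]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.fluxes, columns=self.edge_ids)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# network: {self.network_name}\n")
            fh.write(f"# seed: {self.seed}\n")
            fh.write(f"# samples: {self.n_samples}\n")
            fh.write(f"# accepted: {self.accepted}\n")
            self.to_dataframe().to_csv(fh, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def fluxes_from_fsr(
    network: PathwayNetwork,
    fsr: FSRVector,
    inputs: Mapping[str, float] | None = None,
) -> FluxVector:
    """Propagate fixed inputs through the network under the given FSRs.

    Each pool's total inflow is distributed over its outgoing edges
    according to the split fractions; ``S . V = 0`` then holds exactly up
    to floating point.
    """
    compiled = compile_network(network)
    grouped = fsr.for_network(network)
    fracs = []
    for i, out in compiled.branches:
        mid = compiled.pool_ids[i]
        row = np.array([[grouped[mid][compiled.edge_ids[j]] for j in out]])
        fracs.append(row)
    F = compiled.propagate(fracs, input_values=inputs)
    return FluxVector(dict(zip(compiled.edge_ids, F[0])))


def sample_admissible_fluxes(
    network: PathwayNetwork,
    constraints,
    n_samples: int,
    seed: int,
) -> FluxEnsemble:
    """Monte-Carlo FSR sampling filtered by label-free constraints.

    Draws ``n_samples`` FSR vectors, propagates each to a full flux vector,
    and retains members that are non-negative and satisfy every
    label-independent target (compositions, S/G, flux ratios) in
    ``constraints``.  Label-incorporation targets require the labeling stage
    and are handled by the pipeline; they are ignored here.  An empty result
    is returned (with a logged warning) rather than raised: emptiness is the
    scientific outcome for an infeasible scheme.
    """
    import logging

    from .observables import constraint_mask_label_free

    rng = np.random.default_rng(seed)
    compiled = compile_network(network)
    fracs = compiled.sample_fractions(n_samples, rng)
    F = compiled.propagate(fracs)
    mask = np.all(F >= 0, axis=1)
    if constraints is not None:
        mask &= constraint_mask_label_free(compiled, F, constraints)
    if not mask.any():
        logging.getLogger(__name__).warning(
            "no admissible flux vectors for network %r (%d samples)",
            network.name,
            n_samples,
        )
    return FluxEnsemble(
        network_name=network.name,
        edge_ids=list(compiled.edge_ids),
        fluxes=F[mask],
        n_samples=n_samples,
        seed=seed,
    )


def feasibility_report(
    networks: Sequence[PathwayNetwork],
    constraints,
    n_samples: int,
    seed: int,
    label_attempts: int = 100,
) -> list[dict]:
    """Full-pipeline acceptance counts per network under shared constraints.

    Runs the complete two-stage screen (steady-state FSR sampling followed by
    label-state sampling for every feeding experiment) so that schemes that
    fail only on labeling data are correctly reported as infeasible.  Returns
    one record per network, in input order.
    """
    from .pipeline import run_pipeline

    report: list[dict] = []
    for net in networks:
        res = run_pipeline(
            net,
            constraints,
            n_samples=n_samples,
            label_attempts=label_attempts,
            seed=seed,
            out_dir=None,
            make_plots=False,
        )
        report.append(
            {
                "network": net.name,
                "samples": n_samples,
                "flux_admissible": res.counts["flux_admissible"],
                "accepted": res.counts["accepted"],
            }
        )
    return report
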