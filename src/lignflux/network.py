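"""Compartmental pathway networks and their stoichiometric systems.

A :class:`PathwayNetwork` is a declarative description of a monomolecular
metabolic network: compartment-tagged metabolite pools connected by typed
flux edges (enzymatic conversions, net diffusion between a cytosolic and an
ER pool of the same chemical species, boundary inputs and effluxes).  The
steady state obeys ``S . V = 0`` where ``S`` is the signed incidence
(stoichiometric) matrix built by :func:`build_stoichiometric_matrix`.

The package ships ready-made configs for the four networks used throughout:
a small illustration network with one diffusion pair, and three variants of
the lignin (monolignol) biosynthesis pathway of *Brachypodium distachyon* -
a baseline compartmental scheme, an extended scheme with ER-side 4CL/C3H
activity and a long metabolic channel, and a minimal scheme whose only
channel is a CCR/CAD step on the ER surface.  Flux/metabolite ids in these
configs are local to this package and documented as provisional.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .errors import (
    CyclicNetworkError,
    DiffusionPairError,
    DuplicateIdError,
    RoleError,
    SchemaError,
)

COMPARTMENTS = ("cytosol", "ER", "external")
EDGE_KINDS = ("enzymatic", "diffusion_net", "efflux", "input")
ROLES = ("H_sink", "G_sink", "S_sink", "wall_ferulic", "wall_coumaric", "input_pool")
#: roles that may be assigned to at most one metabolite per network
UNIQUE_ROLES = ("H_sink", "G_sink", "S_sink", "wall_ferulic", "wall_coumaric")

BUILTIN_NETWORKS = ("illustration", "brachy_fig4", "brachy_fig5", "brachy_fig6")


@dataclass(frozen=True)
class Metabolite:
    """A metabolite pool in one compartment.

    ``species`` names the chemical species independently of the compartment
    so that a diffusion edge can be checked to join the cytosolic and ER
    pools of the same compound; it defaults to the pool id.
    """

    id: str
    name: str = ""
    compartment: str = "cytosol"
    roles: tuple[str, ...] = ()
    species: str = ""

    def __post_init__(self) -> None:
        if not self.species:
            object.__setattr__(self, "species", self.id)


@dataclass(frozen=True)
class FluxEdge:
    """A monomolecular flux edge.

    Stoichiometric coefficients are restricted to unity (the pathway is
    monomolecular throughout); the +/-1 signs live in the stoichiometric
    matrix, not here.  ``value`` carries the fixed magnitude of an input
    edge (mass per unit time); ``volume_factor`` is the compartment-volume
    compensation constant ``r`` attached to diffusion edges, carried but
    inert in steady-state mode.
    """

    id: str
    kind: str
    substrate: str | None = None
    product: str | None = None
    enzyme: str | None = None
    volume_factor: float = 1.0
    value: float | None = None


@dataclass
class PathwayNetwork:
    """A validated compartmental network."""

    name: str
    metabolites: dict[str, Metabolite]
    fluxes: dict[str, FluxEdge]
    meta: dict = field(default_factory=dict)

    # -- structural accessors -------------------------------------------------

    def producers(self, mid: str) -> list[FluxEdge]:
        return [e for e in self.fluxes.values() if e.product == mid]

    def consumers(self, mid: str) -> list[FluxEdge]:
        return [e for e in self.fluxes.values() if e.substrate == mid]

    def graph(self) -> nx.DiGraph:
        """Net-flux graph over metabolite pools (inputs/effluxes omitted)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.metabolites)
        for e in self.fluxes.values():
            if e.substrate is not None and e.product is not None:
                g.add_edge(e.substrate, e.product, flux=e.id)
        return g

    def topological_metabolites(self) -> list[str]:
        order = list(nx.lexicographical_topological_sort(self.graph()))
        return order

    def diffusion_edges(self) -> list[FluxEdge]:
        return [e for e in self.fluxes.values() if e.kind == "diffusion_net"]

    def role_metabolite(self, role: str) -> str:
        for m in self.metabolites.values():
            if role in m.roles:
                return m.id
        raise RoleError(f"network {self.name!r} assigns no metabolite the role {role!r}")

    def input_edges(self) -> list[FluxEdge]:
        return [e for e in self.fluxes.values() if e.kind == "input"]

    def input_values(self) -> dict[str, float]:
        vals = {}
        for e in self.input_edges():
            if e.value is None:
                raise SchemaError(f"input edge {e.id!r} has no magnitude")
            vals[e.id] = float(e.value)
        return vals

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "metabolites": [
                {
                    "id": m.id,
                    "name": m.name,
                    "compartment": m.compartment,
                    "species": m.species,
                    "roles": list(m.roles),
                }
                for m in self.metabolites.values()
            ],
            "fluxes": [
                {
                    "id": e.id,
                    "kind": e.kind,
                    **({"substrates": [[e.substrate, 1]]} if e.substrate else {}),
                    **({"products": [[e.product, 1]]} if e.product else {}),
                    **({"enzyme": e.enzyme} if e.enzyme else {}),
                    **({"value": e.value} if e.value is not None else {}),
                    **(
                        {"volume_factor": e.volume_factor}
                        if e.volume_factor != 1.0
                        else {}
                    ),
                }
                for e in self.fluxes.values()
            ],
        }

    def serialize(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def without_edges(self, edge_ids: Iterable[str]) -> "PathwayNetwork":
        """Return a copy with the given edges (and orphaned pools) removed.

        Used for topology toggles such as the speculative cytosolic C3H step.
        """
        drop = set(edge_ids)
        missing = drop - set(self.fluxes)
        if missing:
            raise SchemaError(f"unknown edge ids {sorted(missing)}")
        fluxes = {k: v for k, v in self.fluxes.items() if k not in drop}
        touched = {e.substrate for e in fluxes.values()} | {
            e.product for e in fluxes.values()
        }
        mets = {k: v for k, v in self.metabolites.items() if k in touched}
        net = PathwayNetwork(
            name=f"{self.name} (without {','.join(sorted(drop))})",
            metabolites=mets,
            fluxes=fluxes,
            meta=dict(self.meta),
        )
        _validate(net)
        return net


# ---------------------------------------------------------------------------
# loading and validation
# ---------------------------------------------------------------------------


def _parse_side(raw: object, eid: str, side: str) -> str | None:
    if raw is None:
        return None
    if not isinstance(raw, list):
        raise SchemaError(f"flux {eid!r}: {side} must be a list of [id, coeff] pairs")
    if len(raw) == 0:
        return None
    if len(raw) > 1:
        raise SchemaError(
            f"flux {eid!r}: the pathway is monomolecular, {side} lists one metabolite"
        )
    pair = raw[0]
    if (
        not isinstance(pair, (list, tuple))
        or len(pair) != 2
        or not isinstance(pair[0], str)
    ):
        raise SchemaError(f"flux {eid!r}: malformed {side} entry {pair!r}")
    if pair[1] not in (1, -1, 1.0, -1.0):
        raise SchemaError(
            f"flux {eid!r}: stoichiometric coefficients are restricted to +/-1, "
            f"got {pair[1]!r}"
        )
    return pair[0]


def load_network(config_text: str | Mapping) -> PathwayNetwork:
    """Parse and validate a network config (JSON text or an equivalent dict).

    Raises a distinct, named validation failure for each class of problem:
    :class:`SchemaError`, :class:`DuplicateIdError`,
    :class:`DiffusionPairError`, :class:`CyclicNetworkError`,
    :class:`RoleError`.
    """
    if isinstance(config_text, Mapping):
        doc = dict(config_text)
    else:
        try:
            doc = json.loads(config_text)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"config is not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise SchemaError("config root must be a JSON object")
    for key in ("metabolites", "fluxes"):
        if key not in doc or not isinstance(doc[key], list):
            raise SchemaError(f"config must contain a {key!r} list")

    metabolites: dict[str, Metabolite] = {}
    for raw in doc["metabolites"]:
        if not isinstance(raw, dict) or "id" not in raw:
            raise SchemaError(f"malformed metabolite entry {raw!r}")
        m = Metabolite(
            id=raw["id"],
            name=raw.get("name", ""),
            compartment=raw.get("compartment", "cytosol"),
            roles=tuple(raw.get("roles", ())),
            species=raw.get("species", ""),
        )
        if m.compartment not in COMPARTMENTS:
            raise SchemaError(
                f"metabolite {m.id!r}: unknown compartment {m.compartment!r}"
            )
        for r in m.roles:
            if r not in ROLES:
                raise RoleError(f"metabolite {m.id!r}: unknown role {r!r}")
        if m.id in metabolites:
            raise DuplicateIdError(f"duplicate metabolite id {m.id!r}")
        metabolites[m.id] = m

    fluxes: dict[str, FluxEdge] = {}
    for raw in doc["fluxes"]:
        if not isinstance(raw, dict) or "id" not in raw or "kind" not in raw:
            raise SchemaError(f"malformed flux entry {raw!r}")
        eid = raw["id"]
        if eid in fluxes:
            raise DuplicateIdError(f"duplicate flux id {eid!r}")
        if raw["kind"] not in EDGE_KINDS:
            raise SchemaError(f"flux {eid!r}: unknown kind {raw['kind']!r}")
        e = FluxEdge(
            id=eid,
            kind=raw["kind"],
            substrate=_parse_side(raw.get("substrates"), eid, "substrates"),
            product=_parse_side(raw.get("products"), eid, "products"),
            enzyme=raw.get("enzyme"),
            volume_factor=float(raw.get("volume_factor", 1.0)),
            value=(float(raw["value"]) if raw.get("value") is not None else None),
        )
        fluxes[eid] = e

    net = PathwayNetwork(
        name=doc.get("name", "unnamed"),
        metabolites=metabolites,
        fluxes=fluxes,
        meta=doc.get("meta", {}),
    )
    _validate(net)
    return net


def _validate(net: PathwayNetwork) -> None:
    for e in net.fluxes.values():
        for mid in (e.substrate, e.product):
            if mid is not None and mid not in net.metabolites:
                raise SchemaError(f"flux {e.id!r} references unknown metabolite {mid!r}")
        if e.kind == "input":
            if e.substrate is not None or e.product is None:
                raise SchemaError(f"input edge {e.id!r} must have a product only")
        elif e.kind == "efflux":
            if e.product is not None or e.substrate is None:
                raise SchemaError(f"efflux edge {e.id!r} must have a substrate only")
        else:
            if e.substrate is None or e.product is None:
                raise SchemaError(
                    f"{e.kind} edge {e.id!r} needs one substrate and one product"
                )
        if e.volume_factor <= 0:
            raise SchemaError(f"flux {e.id!r}: volume_factor must be positive")
        if e.kind == "diffusion_net":
            a = net.metabolites[e.substrate]
            b = net.metabolites[e.product]
            if {a.compartment, b.compartment} != {"cytosol", "ER"}:
                raise DiffusionPairError(
                    f"diffusion edge {e.id!r} must join one cytosol and one ER pool, "
                    f"got {a.compartment}/{b.compartment}"
                )
            if a.species != b.species:
                raise DiffusionPairError(
                    f"diffusion edge {e.id!r} joins different species "
                    f"{a.species!r} and {b.species!r}"
                )

    for role in UNIQUE_ROLES:
        holders = [m.id for m in net.metabolites.values() if role in m.roles]
        if len(holders) > 1:
            raise RoleError(f"role {role!r} assigned to several metabolites {holders}")

    g = net.graph()
    if not nx.is_directed_acyclic_graph(g):
        cyc = nx.find_cycle(g)
        raise CyclicNetworkError(f"net-flux graph contains a cycle: {cyc}")

    for m in net.metabolites.values():
        if m.compartment == "external":
            continue
        if not net.producers(m.id):
            raise SchemaError(f"metabolite {m.id!r} has no producing edge")
        if not net.consumers(m.id):
            raise SchemaError(f"metabolite {m.id!r} has no consuming edge")


def load_builtin(name: str) -> PathwayNetwork:
    """Load one of the shipped network configs by short name."""
    if name not in BUILTIN_NETWORKS:
        raise SchemaError(
            f"unknown builtin network {name!r}; available: {BUILTIN_NETWORKS}"
        )
    text = resources.files("lignflux.data").joinpath(f"{name}.json").read_text()
    return load_network(text)


# ---------------------------------------------------------------------------
# stoichiometric matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StoichiometricMatrix:
    """Signed incidence matrix ``S`` with labelled rows and columns.

    ``S[i, j]`` is +1 if flux ``j`` produces metabolite ``i``, -1 if it
    consumes it, 0 otherwise.
    """

    matrix: "np.ndarray"
    metabolite_ids: tuple[str, ...]
    flux_ids: tuple[str, ...]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.matrix, index=self.metabolite_ids, columns=self.flux_ids
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    def row(self, mid: str) -> dict[str, int]:
        i = self.metabolite_ids.index(mid)
        return {
            f: int(v) for f, v in zip(self.flux_ids, self.matrix[i]) if v != 0
        }


def build_stoichiometric_matrix(network: PathwayNetwork) -> StoichiometricMatrix:
    """Build ``S`` for a validated network (metabolite rows, flux columns)."""
    import numpy as np

    mids = tuple(m for m in network.metabolites if
                 network.metabolites[m].compartment != "external")
    fids = tuple(network.fluxes)
    S = np.zeros((len(mids), len(fids)), dtype=np.int8)
    mindex = {m: i for i, m in enumerate(mids)}
    for j, f in enumerate(fids):
        e = network.fluxes[f]
        if e.substrate in mindex:
            S[mindex[e.substrate], j] = -1
        if e.product in mindex:
            S[mindex[e.product], j] = 1
    return StoichiometricMatrix(matrix=S, metabolite_ids=mids, flux_ids=fids)


# ---------------------------------------------------------------------------
# branch points
# ---------------------------------------------------------------------------


def branch_points(network: PathwayNetwork) -> list[tuple[str, tuple[str, ...]]]:
    """Metabolites with two or more outgoing net edges, in topological order.

    Each k-way split contributes ``k - 1`` degrees of freedom; the total over
    the returned list is the dimension of the flux-split-ratio space that
    parameterizes the underdetermined steady state.
    """
    order = network.topological_metabolites()
    out: list[tuple[str, tuple[str, ...]]] = []
    for mid in order:
        outgoing = tuple(e.id for e in network.consumers(mid))
        if len(outgoing) >= 2:
            out.append((mid, outgoing))
    return out


def degrees_of_freedom(network: PathwayNetwork) -> int:
    return sum(len(edges) - 1 for _, edges in branch_points(network))
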