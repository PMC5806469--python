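"""Resolution of isotope-label flow across bidirectional diffusion fluxes.

A net diffusion flux ``D`` between a cytosolic and an ER pool of the same
species is the difference of two opposing unidirectional components,
``D = D_f - D_r``.  Only the net value matters for total mass balance, but
a labeling experiment sees both directions, because each component carries
the label fraction of its *source* pool.  For a pair with one independent
influx and efflux on each side (the illustration network's X2/X4 pair) the
node balances

    V1 + D_r = V2 + D_f
    L1 V1 + L4 D_r = L2 (V2 + D_f)

close to the familiar forms

    L4  = (L2 V2 - L1 V1 - L3 V3) / (V2 - V1 - V3)
    D_r = (L2 - L1) V1 / (L4 - L2)
    D_f = (L4 - L1) V1 / (L4 - L2) - V2

so that sampling the cytosol pool's label fraction L2 on [0, 1] determines
the partner label and both diffusion components.  This module implements
those closed forms, their generalization to arbitrary pairs (see
:class:`PairKind`), the labeled/unlabeled decomposition of every flux, and
the Monte-Carlo sampling of whole label states with rejection of any draw
that produces a label outside [0, 1] or a negative diffusion component.

The labeled part of a net diffusion flux is ``L2 D_f - L4 D_r``, which
differs from the naive net-only value ``L2 (D_f - D_r)`` whenever the two
pool labels differ and exchange is present - the observation that motivates
the explicit two-direction treatment.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    DegenerateLabelError,
    DegenerateTopologyError,
    InfeasibleLabelError,
    LignfluxError,
)
from .network import PathwayNetwork
from .steady import CompiledNetwork, FluxVector, compile_network

_EPS = 1e-12
_LAB_TOL = 1e-9  # slack on label range / balance residual checks


# ---------------------------------------------------------------------------
# scalar closed forms (illustration-pair geometry)
# ---------------------------------------------------------------------------


def partner_label(
    L1: float, L2: float, L3: float, V1: float, V2: float, V3: float
) -> float:
    """Label fraction of the diffusion partner pool.

    Arguments follow the illustration pair: ``V1`` feeds the sampled pool
    (label ``L1`` at its source), ``V2`` drains it, ``V3`` independently
    feeds the partner pool with label ``L3``; ``L2`` is the sampled pool's
    label.  The returned value satisfies both node balances simultaneously.
    """
    den = V2 - V1 - V3
    if abs(den) < _EPS:
        raise DegenerateTopologyError(
            "partner label undefined: V2 - V1 - V3 = 0 (no efflux from the "
            "partner pool at steady state)"
        )
    L4 = (L2 * V2 - L1 * V1 - L3 * V3) / den
    if not (-_LAB_TOL <= L4 <= 1 + _LAB_TOL):
        raise InfeasibleLabelError(
            f"partner label {L4} outside [0, 1]; the sampled label {L2} is "
            "inconsistent with the flux distribution"
        )
    return float(min(max(L4, 0.0), 1.0))


@dataclass(frozen=True)
class DiffusionResolution:
    """Forward/reverse components of one diffusion flux.

    ``feasible`` is False when a component is negative; inside Monte-Carlo
    sampling that is a counted rejection rather than an exception.
    """

    d_f: float
    d_r: float
    feasible: bool = True

    @property
    def net(self) -> float:
        return self.d_f - self.d_r


def resolve_diffusion(
    L1: float, L2: float, L4: float, V1: float, V2: float
) -> DiffusionResolution:
    """Resolve ``D_f`` and ``D_r`` from pool labels and steady-state totals.

    ``L2``/``L4`` are the labels of the pool and its diffusion partner,
    ``V1``/``V2`` the pool's independent influx and efflux; the net
    ``D_f - D_r = V1 - V2`` holds by construction.  If ``L4 == L2`` the
    exchange magnitude is unidentifiable; when the labeling is uniform the
    net-only fallback (``D_f = max(D, 0)``, ``D_r = 0``) is returned,
    otherwise the degenerate-label failure is raised.
    """
    net = V1 - V2
    if abs(L4 - L2) < _EPS:
        if abs(L2 - L1) * V1 < _LAB_TOL:
            # uniform labeling: any exchange is admissible; report e = 0
            return DiffusionResolution(d_f=max(net, 0.0), d_r=max(-net, 0.0))
        raise DegenerateLabelError(
            "L4 = L2 with unbalanced labeled inflow: exchange flux "
            "unidentifiable and no net-only resolution exists"
        )
    d_r = (L2 - L1) * V1 / (L4 - L2)
    d_f = (L4 - L1) * V1 / (L4 - L2) - V2
    feasible = d_f >= -_LAB_TOL and d_r >= -_LAB_TOL
    return DiffusionResolution(d_f=float(d_f), d_r=float(d_r), feasible=feasible)


# ---------------------------------------------------------------------------
# label states and labeled flux vectors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabelState:
    """Pool label fractions plus the feeding specification."""

    labels: Mapping[str, float]
    feeding_pool: str
    feeding_fraction: float
    base_fraction: float = 0.0

    def __getitem__(self, mid: str) -> float:
        return self.labels[mid]


@dataclass(frozen=True)
class LabeledFluxVector:
    """Labeled/unlabeled decomposition of a flux vector.

    For conversion/input/efflux edges the labeled part is the source pool's
    label times the magnitude.  For diffusion edges ``labeled[edge]`` is the
    net labeled flow ``L_src D_f - L_dst D_r`` and the per-direction
    components are kept in ``diffusion``.
    """

    labeled: Mapping[str, float]
    unlabeled: Mapping[str, float]
    diffusion: Mapping[str, DiffusionResolution]

    def total(self, fid: str) -> float:
        return self.labeled[fid] + self.unlabeled[fid]


def split_labeled_fluxes(
    network: PathwayNetwork,
    flux: FluxVector,
    labels: LabelState,
    diffusion: Mapping[str, DiffusionResolution],
) -> LabeledFluxVector:
    """Split every flux into labeled and unlabeled components.

    Requires a label for every metabolite and a resolved
    :class:`DiffusionResolution` for every diffusion edge.
    """
    lab: dict[str, float] = {}
    unlab: dict[str, float] = {}
    for e in network.fluxes.values():
        v = float(flux.values[e.id])
        if e.kind == "input":
            frac = (
                labels.feeding_fraction
                if e.product == labels.feeding_pool
                else labels.base_fraction
            )
        elif e.kind == "diffusion_net":
            if e.id not in diffusion:
                raise LignfluxError(f"diffusion edge {e.id!r} not resolved")
            res = diffusion[e.id]
            Ls = labels.labels[e.substrate]
            Ld = labels.labels[e.product]
            lab[e.id] = Ls * res.d_f - Ld * res.d_r
            unlab[e.id] = (1 - Ls) * res.d_f - (1 - Ld) * res.d_r
            continue
        else:
            if e.substrate not in labels.labels:
                raise LignfluxError(
                    f"no label for pool {e.substrate!r} feeding flux {e.id!r}"
                )
            frac = labels.labels[e.substrate]
        lab[e.id] = frac * v
        unlab[e.id] = (1 - frac) * v
    return LabeledFluxVector(labeled=lab, unlabeled=unlab, diffusion=dict(diffusion))


# ---------------------------------------------------------------------------
# compiled label plan
# ---------------------------------------------------------------------------


class PairKind(enum.Enum):
    """How a diffusion pair is resolved during sampling.

    SAMPLED: both pools have independent influx and efflux; the cytosol
    member's label is drawn uniformly on [0, 1], the partner follows from
    the joint balance, and draws with a label outside [0, 1] or a negative
    diffusion component are rejected.

    PINNED: one pool has no independent efflux, so total label conservation
    pins the *other* pool's label; the free pool's label only sets the
    (unidentifiable downstream) exchange level and is drawn uniformly over
    its feasible interval, parameterized by exchange u with
    D_r = net * u / (1 - u).

    UNIFORM: one pool has no independent influx; both labels provably equal
    the fed side's mixture and only the net component is identifiable
    (D_f = net, D_r = 0).
    """

    SAMPLED = "sampled"
    PINNED = "pinned"
    UNIFORM = "uniform"


@dataclass
class _Pair:
    edge_j: int
    src_pool: int  # P: net flows P -> Q
    dst_pool: int
    kind: PairKind
    sampled_pool: int  # pool whose label is drawn (SAMPLED/PINNED)


@dataclass
class _Step:
    pool: int | None = None  # plain deterministic pool
    pair: _Pair | None = None


class LabelPlan:
    """Static resolution order for the label state of one network."""

    def __init__(self, compiled: CompiledNetwork):
        import networkx as nx

        self.compiled = compiled
        net = compiled.net
        pidx = compiled.pool_index
        eidx = compiled.edge_index

        # producing / consuming non-diffusion edges per pool
        self.indep_in: list[list[int]] = [[] for _ in compiled.pool_ids]
        self.indep_out: list[list[int]] = [[] for _ in compiled.pool_ids]
        for e in net.fluxes.values():
            if e.kind == "diffusion_net":
                continue
            if e.product is not None:
                self.indep_in[pidx[e.product]].append(eidx[e.id])
            if e.substrate is not None:
                self.indep_out[pidx[e.substrate]].append(eidx[e.id])

        pair_of_pool: dict[int, _Pair] = {}
        self.pairs: list[_Pair] = []
        for e in net.diffusion_edges():
            p, q = pidx[e.substrate], pidx[e.product]
            if p in pair_of_pool or q in pair_of_pool:
                raise LignfluxError(
                    "a pool participates in more than one diffusion edge; "
                    "this topology is not supported"
                )
            cytosol = p if net.metabolites[e.substrate].compartment == "cytosol" else q
            if not self.indep_in[p] or not self.indep_in[q]:
                kind, samp = PairKind.UNIFORM, -1
            elif not self.indep_out[p]:
                kind, samp = PairKind.PINNED, p
            elif not self.indep_out[q]:
                kind, samp = PairKind.PINNED, q
            else:
                kind, samp = PairKind.SAMPLED, cytosol
            if kind is PairKind.PINNED and samp != p:
                raise LignfluxError(
                    f"diffusion edge {e.id!r}: the pool without independent "
                    "efflux must be the net-flow source; reverse the edge's "
                    "net direction in the config"
                )
            pair = _Pair(
                edge_j=eidx[e.id], src_pool=p, dst_pool=q, kind=kind,
                sampled_pool=samp,
            )
            pair_of_pool[p] = pair
            pair_of_pool[q] = pair
            self.pairs.append(pair)

        # merged dependency graph: pair members collapse into one node
        rep = {
            i: (
                min(pair_of_pool[i].src_pool, pair_of_pool[i].dst_pool)
                if i in pair_of_pool
                else i
            )
            for i in range(len(compiled.pool_ids))
        }
        g = nx.DiGraph()
        g.add_nodes_from(set(rep.values()))
        for e in net.fluxes.values():
            if e.kind == "diffusion_net" or e.substrate is None or e.product is None:
                continue
            a, b = rep[pidx[e.substrate]], rep[pidx[e.product]]
            if a != b:
                g.add_edge(a, b)
        if not nx.is_directed_acyclic_graph(g):
            raise LignfluxError(
                "label resolution order undefined: merging diffusion pairs "
                "creates a dependency cycle"
            )
        self.steps: list[_Step] = []
        for node in nx.lexicographical_topological_sort(g):
            if node in pair_of_pool:
                self.steps.append(_Step(pair=pair_of_pool[node]))
            else:
                self.steps.append(_Step(pool=node))
        self.n_sampled = sum(
            1 for pr in self.pairs if pr.kind in (PairKind.SAMPLED, PairKind.PINNED)
        )


# ---------------------------------------------------------------------------
# vectorized label solver
# ---------------------------------------------------------------------------


@dataclass
class LabelSolution:
    """Vectorized label states for a batch of flux vectors (rows)."""

    plan: LabelPlan
    L: np.ndarray  # (n, n_pools)
    Df: np.ndarray  # (n, n_diffusion_edges), aligned with plan.pairs
    Dr: np.ndarray
    valid: np.ndarray  # (n,) bool
    feeding_pool: str
    feeding_fraction: float
    base_fraction: float = 0.0

    def labeled_fluxes(self, F: np.ndarray) -> np.ndarray:
        """Labeled component per edge; diffusion edges carry the net value."""
        c = self.plan.compiled
        VL = np.zeros_like(F)
        fed = c.pool_index[self.feeding_pool]
        for j, e in enumerate(c.edge_ids):
            edge = c.net.fluxes[e]
            if edge.kind == "input":
                frac = (
                    self.feeding_fraction
                    if c.edge_dst[j] == fed
                    else self.base_fraction
                )
                VL[:, j] = frac * F[:, j]
            elif edge.kind == "diffusion_net":
                k = [p.edge_j for p in self.plan.pairs].index(j)
                p = self.plan.pairs[k]
                VL[:, j] = (
                    self.L[:, p.src_pool] * self.Df[:, k]
                    - self.L[:, p.dst_pool] * self.Dr[:, k]
                )
            else:
                VL[:, j] = self.L[:, c.edge_src[j]] * F[:, j]
        return VL


def _edge_label_columns(
    plan: LabelPlan, L: np.ndarray, feeding_pool: str, frac: float, base: float
):
    """Label fraction carried by each non-diffusion edge (callable by index)."""
    c = plan.compiled
    fed = c.pool_index[feeding_pool]

    def lab(j: int) -> np.ndarray | float:
        if c.edge_src[j] < 0:  # input edge
            return frac if c.edge_dst[j] == fed else base
        return L[:, c.edge_src[j]]

    return lab


def solve_labels(
    plan: LabelPlan,
    F: np.ndarray,
    feeding_pool: str,
    feeding_fraction: float,
    rng: np.random.Generator | None = None,
    base_fraction: float = 0.0,
    draws: Mapping[int, np.ndarray] | None = None,
) -> LabelSolution:
    """Resolve a full label state for every row of the flux matrix ``F``.

    Pools are processed in the plan's dependency order: plain pools take the
    flux-weighted mixture of their inflow labels; diffusion pairs are
    resolved per their :class:`PairKind`.  Uniform draws come from ``rng``
    (or may be supplied explicitly per sampled pool via ``draws`` keyed by
    pool index, for deterministic evaluation).  Rows whose draw leads to a
    label outside [0, 1] or a negative diffusion component are flagged
    invalid rather than raising.
    """
    c = plan.compiled
    n = F.shape[0]
    L = np.zeros((n, len(c.pool_ids)))
    Df = np.zeros((n, len(plan.pairs)))
    Dr = np.zeros((n, len(plan.pairs)))
    valid = np.ones(n, dtype=bool)
    lab_of_edge = _edge_label_columns(
        plan, L, feeding_pool, feeding_fraction, base_fraction
    )

    def in_lab_tot(pool: int) -> tuple[np.ndarray, np.ndarray]:
        labsum = np.zeros(n)
        tot = np.zeros(n)
        for j in plan.indep_in[pool]:
            labsum += lab_of_edge(j) * F[:, j]
            tot += F[:, j]
        return labsum, tot

    def out_tot(pool: int) -> np.ndarray:
        tot = np.zeros(n)
        for j in plan.indep_out[pool]:
            tot += F[:, j]
        return tot

    for step in plan.steps:
        if step.pool is not None:
            labsum, tot = in_lab_tot(step.pool)
            with np.errstate(invalid="ignore", divide="ignore"):
                L[:, step.pool] = np.where(tot > _EPS, labsum / tot, base_fraction)
            continue

        pair = step.pair
        k = plan.pairs.index(pair)
        P, Q = pair.src_pool, pair.dst_pool
        nflux = F[:, pair.edge_j]
        inP_lab, inP_tot = in_lab_tot(P)
        inQ_lab, inQ_tot = in_lab_tot(Q)
        outP, outQ = out_tot(P), out_tot(Q)

        if pair.kind is PairKind.UNIFORM:
            # the side with independent influx sets the common label
            fed_side, labsum, tot = (
                (P, inP_lab, inP_tot) if plan.indep_in[P] else (Q, inQ_lab, inQ_tot)
            )
            with np.errstate(invalid="ignore", divide="ignore"):
                common = np.where(tot > _EPS, labsum / tot, base_fraction)
            L[:, P] = common
            L[:, Q] = common
            Df[:, k] = np.maximum(nflux, 0.0)
            Dr[:, k] = 0.0
            continue

        if pair.kind is PairKind.PINNED:
            free = pair.sampled_pool
            pinned = Q if free == P else P
            out_pinned = outQ if pinned == Q else outP
            with np.errstate(invalid="ignore", divide="ignore"):
                L_pin = np.where(
                    out_pinned > _EPS,
                    (inP_lab + inQ_lab) / out_pinned,
                    base_fraction,
                )
            # throughput of the free pool; its inflow mixture label
            in_free_lab, in_free_tot = (
                (inP_lab, inP_tot) if free == P else (inQ_lab, inQ_tot)
            )
            with np.errstate(invalid="ignore", divide="ignore"):
                Lbar = np.where(
                    in_free_tot > _EPS, in_free_lab / in_free_tot, base_fraction
                )
            if draws is not None and free in draws:
                u = np.asarray(draws[free], dtype=float)
            elif rng is not None:
                u = rng.random(n)
            else:
                u = np.zeros(n)
            u = np.clip(u, 0.0, 1.0 - 1e-9)
            exch = in_free_tot * u / (1.0 - u)
            L[:, free] = Lbar + u * (L_pin - Lbar)
            L[:, pinned] = L_pin
            # free pool is the net-flow source (enforced at compile time)
            Dr[:, k] = exch
            Df[:, k] = exch + nflux
            valid &= (L_pin >= -_LAB_TOL) & (L_pin <= 1 + _LAB_TOL)
            continue

        # SAMPLED pair: draw the cytosol member, derive the partner.  The
        # admissible labels of the sampled pool form the interval swept by
        # the exchange magnitude, from its no-exchange inflow mixture to the
        # full-mixing label of the joint pair; a uniform draw on that
        # interval has the same conditional law as a uniform draw on [0, 1]
        # followed by rejection of infeasible values, without the waste.
        s = pair.sampled_pool
        o = Q if s == P else P
        out_s = outP if s == P else outQ
        out_o = outQ if s == P else outP
        if draws is not None and s in draws:
            u = np.asarray(draws[s], dtype=float)
        elif rng is not None:
            u = rng.random(n)
        else:
            raise LignfluxError("sampled pair needs an rng or explicit draws")
        u = np.clip(u, 0.0, 1.0 - 1e-9)
        with np.errstate(invalid="ignore", divide="ignore"):
            LP0 = np.where(inP_tot > _EPS, inP_lab / inP_tot, base_fraction)
            # no-exchange label of Q: P's outflow at LP0 feeds it through n
            LQ0 = np.where(
                outQ > _EPS,
                (inQ_lab + LP0 * nflux) / np.where(outQ > _EPS, outQ, 1.0),
                base_fraction,
            )
            mix = np.where(
                out_s + out_o > _EPS,
                (inP_lab + inQ_lab) / (out_s + out_o),
                base_fraction,
            )
        Ls0 = LP0 if s == P else LQ0
        Ls = Ls0 + u * (mix - Ls0)
        with np.errstate(invalid="ignore", divide="ignore"):
            Lo = np.where(
                out_o > _EPS,
                (inP_lab + inQ_lab - Ls * out_s) / out_o,
                base_fraction,
            )
        L[:, s] = Ls
        L[:, o] = Lo
        LP = L[:, P]
        LQ = L[:, Q]
        den = LP - LQ
        num = inP_lab - LP * (outP + nflux)
        degen = np.abs(den) < 1e-10
        with np.errstate(invalid="ignore", divide="ignore"):
            dr = np.where(degen, 0.0, num / np.where(degen, 1.0, den))
        # degenerate rows are admissible only if the net-only balance closes
        bal_ok = np.abs(num) < 1e-7
        dr = np.where(degen & bal_ok, 0.0, dr)
        df = dr + nflux
        valid &= (Lo >= -_LAB_TOL) & (Lo <= 1 + _LAB_TOL)
        valid &= (~degen) | bal_ok
        valid &= (dr >= -1e-9) & (df >= -1e-9)
        Df[:, k] = np.maximum(df, 0.0)
        Dr[:, k] = np.maximum(dr, 0.0)

    # global sanity: all labels within range
    valid &= np.all((L >= -_LAB_TOL) & (L <= 1 + _LAB_TOL), axis=1)
    np.clip(L, 0.0, 1.0, out=L)
    return LabelSolution(
        plan=plan,
        L=L,
        Df=Df,
        Dr=Dr,
        valid=valid,
        feeding_pool=feeding_pool,
        feeding_fraction=feeding_fraction,
        base_fraction=base_fraction,
    )


# ---------------------------------------------------------------------------
# public sampling operation
# ---------------------------------------------------------------------------


def sample_label_states(
    network: PathwayNetwork,
    flux: FluxVector,
    feeding: tuple[str, float],
    n_samples: int,
    seed: int,
    constraints=None,
    experiment: str | None = None,
    base_fraction: float = 0.0,
) -> list[tuple[LabelState, LabeledFluxVector]]:
    """Monte-Carlo sample admissible label states for one steady state.

    ``feeding`` is (input pool id, label fraction), e.g. ``("PHE", 0.35)``.
    Returns accepted (LabelState, LabeledFluxVector) pairs; a sample is
    rejected if any label leaves [0, 1], any diffusion component is
    negative, or a labeling constraint of ``constraints`` (for the given
    ``experiment`` tag) fails.
    """
    compiled = compile_network(network)
    plan = LabelPlan(compiled)
    rng = np.random.default_rng(seed)
    F = np.tile(flux.as_array(compiled), (n_samples, 1))
    sol = solve_labels(
        plan, F, feeding[0], feeding[1], rng=rng, base_fraction=base_fraction
    )
    keep = sol.valid.copy()
    if constraints is not None:
        from .observables import constraint_mask_labeled

        keep &= constraint_mask_labeled(
            compiled, F, sol.labeled_fluxes(F), constraints, experiment
        )
    out: list[tuple[LabelState, LabeledFluxVector]] = []
    pool_ids = compiled.pool_ids
    for i in np.flatnonzero(keep):
        labels = LabelState(
            labels=dict(zip(pool_ids, sol.L[i])),
            feeding_pool=feeding[0],
            feeding_fraction=feeding[1],
            base_fraction=base_fraction,
        )
        diff = {
            compiled.edge_ids[p.edge_j]: DiffusionResolution(
                d_f=float(sol.Df[i, k]), d_r=float(sol.Dr[i, k])
            )
            for k, p in enumerate(plan.pairs)
        }
        out.append((labels, split_labeled_fluxes(network, flux, labels, diff)))
    return out


def labeled_balance_residuals(
    network: PathwayNetwork,
    flux: FluxVector,
    labeled: LabeledFluxVector,
) -> dict[str, float]:
    """Labeled-mass balance residual at every internal metabolite.

    A diffusion edge's directional components ``L_src D_f`` and ``L_dst D_r``
    enter the two node balances only through their difference, so the stored
    net labeled flow closes both balances exactly when the resolution is
    consistent.
    """
    res = {m: 0.0 for m in network.metabolites}
    for e in network.fluxes.values():
        if e.product is not None:
            res[e.product] += labeled.labeled[e.id]
        if e.substrate is not None:
            res[e.substrate] -= labeled.labeled[e.id]
    return res
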