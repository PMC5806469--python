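"""Observables of (labeled) flux distributions and admissibility screening.

The experimentally accessible quantities are the lignin monomer composition
(H/G/S fractions of total monolignol efflux, in percent, and the S/G
ratio) and, per feeding experiment, the label-incorporation percentages:
100 x labeled efflux / total efflux for each monomer class, for total
lignin, and for the wall-bound p-coumaric and ferulic acid effluxes.

A :class:`ConstraintSet` holds screening targets with per-target tolerances
(absolute percentage points or relative fractions).  Screening is a
threshold test, not a likelihood: a flux vector either reproduces every
observation within tolerance or is discarded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .errors import RoleError, SchemaError
from .network import PathwayNetwork
from .steady import CompiledNetwork, FluxVector, compile_network

COMPOSITION_OBSERVABLES = ("H_frac", "G_frac", "S_frac", "SG_ratio")
INCORPORATION_NAMES = (
    "H",
    "G",
    "S",
    "total_lignin",
    "wall_coumaric",
    "wall_ferulic",
)
_SINK_ROLE = {"H": "H_sink", "G": "G_sink", "S": "S_sink",
              "wall_coumaric": "wall_coumaric", "wall_ferulic": "wall_ferulic"}


# ---------------------------------------------------------------------------
# observable computation
# ---------------------------------------------------------------------------


def _role_efflux_indices(compiled: CompiledNetwork, role: str) -> list[int]:
    net = compiled.net
    mid = net.role_metabolite(role)  # raises RoleError if unassigned
    idx = [
        compiled.edge_index[e.id]
        for e in net.consumers(mid)
        if e.kind == "efflux"
    ]
    if not idx:
        raise RoleError(
            f"metabolite {mid!r} holds role {role!r} but has no efflux edge"
        )
    return idx


def composition_arrays(compiled: CompiledNetwork, F: np.ndarray):
    """Vectorized H/G/S percentages and S/G ratio for flux rows."""
    h = F[:, _role_efflux_indices(compiled, "H_sink")].sum(axis=1)
    g = F[:, _role_efflux_indices(compiled, "G_sink")].sum(axis=1)
    s = F[:, _role_efflux_indices(compiled, "S_sink")].sum(axis=1)
    tot = h + g + s
    with np.errstate(invalid="ignore", divide="ignore"):
        hf = np.where(tot > 0, 100 * h / tot, np.nan)
        gf = np.where(tot > 0, 100 * g / tot, np.nan)
        sf = np.where(tot > 0, 100 * s / tot, np.nan)
        sg = np.where(g > 0, s / g, np.nan)
    return {"H_frac": hf, "G_frac": gf, "S_frac": sf, "SG_ratio": sg}


def incorporation_arrays(
    compiled: CompiledNetwork,
    F: np.ndarray,
    VL: np.ndarray,
    names: Sequence[str] | None = None,
) -> dict[str, np.ndarray]:
    """Vectorized label-incorporation percentages for flux rows.

    With ``names=None`` every observable whose role is assigned in the
    network is computed and the rest are silently omitted; explicitly
    requested names raise :class:`RoleError` when their role is missing.
    """
    requested = list(names) if names is not None else list(INCORPORATION_NAMES)
    out: dict[str, np.ndarray] = {}
    sink_idx: dict[str, list[int]] = {}

    def _indices(name: str) -> list[int] | None:
        if name in sink_idx:
            return sink_idx[name]
        try:
            sink_idx[name] = _role_efflux_indices(compiled, _SINK_ROLE[name])
        except RoleError:
            if names is not None:
                raise
            sink_idx[name] = None
        return sink_idx[name]

    for name in requested:
        if name == "total_lignin":
            parts = [_indices(k) for k in ("H", "G", "S")]
            if any(p is None for p in parts):
                if names is not None:
                    raise RoleError(
                        "total_lignin incorporation needs all three sink roles"
                    )
                continue
            idx = [j for p in parts for j in p]
        else:
            idx = _indices(name)
            if idx is None:
                continue
        tot = F[:, idx].sum(axis=1)
        lab = VL[:, idx].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[name] = np.where(tot > 0, 100 * lab / tot, np.nan)
    return out


@dataclass(frozen=True)
class Observables:
    """Lignin composition and per-experiment label incorporation (percent)."""

    h_frac: float
    g_frac: float
    s_frac: float
    sg_ratio: float
    incorporation: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def composition(self) -> dict[str, float]:
        return {
            "H_frac": self.h_frac,
            "G_frac": self.g_frac,
            "S_frac": self.s_frac,
            "SG_ratio": self.sg_ratio,
        }

    def value(self, observable: str, experiment: str | None = None) -> float:
        if observable in COMPOSITION_OBSERVABLES:
            return self.composition()[observable]
        if observable.startswith("incorporation."):
            name = observable.split(".", 1)[1]
            return self.incorporation[experiment][name]
        raise SchemaError(f"unknown observable {observable!r}")

    def to_dict(self) -> dict:
        return {
            "composition": self.composition(),
            "incorporation": {k: dict(v) for k, v in self.incorporation.items()},
        }


def compute_observables(
    network: PathwayNetwork,
    total: FluxVector,
    labeled: Mapping[str, "object"] | None = None,
) -> Observables:
    """Observables of one flux vector (plus labeled vectors per experiment).

    ``labeled`` maps experiment tags to :class:`~.labeling.LabeledFluxVector`
    objects; incorporation percentages are only reported for the supplied
    experiments.
    """
    compiled = compile_network(network)
    F = total.as_array(compiled)[None, :]
    comp = composition_arrays(compiled, F)
    inc: dict[str, dict[str, float]] = {}
    if labeled:
        for tag, lv in labeled.items():
            VL = np.array([[lv.labeled[e] for e in compiled.edge_ids]])
            arrs = incorporation_arrays(compiled, F, VL)
            inc[tag] = {k: float(v[0]) for k, v in arrs.items()}
    return Observables(
        h_frac=float(comp["H_frac"][0]),
        g_frac=float(comp["G_frac"][0]),
        s_frac=float(comp["S_frac"][0]),
        sg_ratio=float(comp["SG_ratio"][0]),
        incorporation=inc,
    )


# ---------------------------------------------------------------------------
# constraint sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Target:
    """One screening target.

    ``observable`` is a composition name, ``incorporation.<name>``, or
    ``flux_ratio`` (with ``num``/``den`` edge ids).  ``mode`` is ``"abs"``
    (tolerance in the observable's own units, percentage points for
    percentages) or ``"rel"`` (tolerance as a fraction of the target value).
    """

    observable: str
    value: float
    tol: float
    mode: str = "abs"
    experiment: str | None = None
    num: str | None = None
    den: str | None = None

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise SchemaError(f"target {self.observable!r}: tolerance must be > 0")
        if self.mode not in ("abs", "rel"):
            raise SchemaError(f"target {self.observable!r}: unknown mode {self.mode!r}")
        ok = (
            self.observable in COMPOSITION_OBSERVABLES
            or (
                self.observable.startswith("incorporation.")
                and self.observable.split(".", 1)[1] in INCORPORATION_NAMES
            )
            or (self.observable == "flux_ratio" and self.num and self.den)
        )
        if not ok:
            raise SchemaError(f"unknown observable {self.observable!r}")

    @property
    def needs_labels(self) -> bool:
        return self.observable.startswith("incorporation.")

    def band(self) -> tuple[float, float]:
        half = self.tol if self.mode == "abs" else self.tol * abs(self.value)
        return self.value - half, self.value + half

    def residual(self, x: float) -> float:
        return x - self.value

    def ok(self, x: float) -> bool:
        lo, hi = self.band()
        return bool(np.isfinite(x)) and lo <= x <= hi


@dataclass(frozen=True)
class ConstraintSet:
    """Observation targets plus the feeding scenario per experiment."""

    name: str
    targets: tuple[Target, ...]
    feedings: Mapping[str, tuple[str, float]] = field(default_factory=dict)
    nonnegative: bool = True
    meta: Mapping = field(default_factory=dict)

    def label_free_targets(self) -> list[Target]:
        return [t for t in self.targets if not t.needs_labels]

    def labeled_targets(self, experiment: str) -> list[Target]:
        return [
            t for t in self.targets if t.needs_labels and t.experiment == experiment
        ]

    @property
    def experiments(self) -> list[str]:
        return list(self.feedings)

    def with_tolerance_scale(self, scale: float) -> "ConstraintSet":
        """Same targets with all tolerances multiplied by ``scale``."""
        return ConstraintSet(
            name=f"{self.name} (tol x {scale})",
            targets=tuple(
                Target(
                    observable=t.observable,
                    value=t.value,
                    tol=t.tol * scale,
                    mode=t.mode,
                    experiment=t.experiment,
                    num=t.num,
                    den=t.den,
                )
                for t in self.targets
            ),
            feedings=dict(self.feedings),
            nonnegative=self.nonnegative,
            meta=dict(self.meta),
        )

    def to_dict(self) -> dict:
        comp = [
            {"observable": t.observable, "value": t.value, "tol": t.tol,
             "mode": t.mode}
            for t in self.targets
            if t.experiment is None and t.observable != "flux_ratio"
        ]
        exps = []
        for tag, (pool, frac) in self.feedings.items():
            exps.append(
                {
                    "id": tag,
                    "feeding": {"pool": pool, "fraction": frac},
                    "targets": [
                        {
                            "observable": t.observable,
                            "value": t.value,
                            "tol": t.tol,
                            "mode": t.mode,
                        }
                        for t in self.labeled_targets(tag)
                    ],
                }
            )
        return {
            "name": self.name,
            "nonnegative": self.nonnegative,
            "composition": comp,
            "experiments": exps,
        }


def load_constraints(config_text: str | Mapping) -> ConstraintSet:
    """Parse a constraint file (JSON text or an equivalent dict)."""
    if isinstance(config_text, Mapping):
        doc = dict(config_text)
    else:
        try:
            doc = json.loads(config_text)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"constraint file is not valid JSON: {exc}") from exc
    targets: list[Target] = []
    for raw in doc.get("composition", []):
        targets.append(
            Target(
                observable=raw["observable"],
                value=float(raw["value"]),
                tol=float(raw["tol"]),
                mode=raw.get("mode", "abs"),
            )
        )
    feedings: dict[str, tuple[str, float]] = {}
    for exp in doc.get("experiments", []):
        tag = exp["id"]
        feedings[tag] = (exp["feeding"]["pool"], float(exp["feeding"]["fraction"]))
        for raw in exp.get("targets", []):
            targets.append(
                Target(
                    observable=raw["observable"],
                    value=float(raw["value"]),
                    tol=float(raw["tol"]),
                    mode=raw.get("mode", "abs"),
                    experiment=tag,
                )
            )
    return ConstraintSet(
        name=doc.get("name", "unnamed"),
        targets=tuple(targets),
        feedings=feedings,
        nonnegative=bool(doc.get("nonnegative", True)),
        meta=doc.get("meta", {}),
    )


def load_table1_constraints() -> ConstraintSet:
    """The shipped lignin composition / label-incorporation constraint table."""
    text = (
        resources.files("lignflux.data").joinpath("table1_constraints.json").read_text()
    )
    return load_constraints(text)


# ---------------------------------------------------------------------------
# checking
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConstraintReport:
    passed: bool
    rows: tuple[dict, ...]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(list(self.rows))


def check_constraints(
    obs: Observables,
    constraints: ConstraintSet,
    flux: FluxVector | None = None,
) -> ConstraintReport:
    """Evaluate every target; pass iff all are met within tolerance.

    The residual report is returned regardless of the outcome.  Checking is
    monotone in tolerance: any pass at tolerance t also passes at any
    larger tolerance.
    """
    rows = []
    passed = True
    for t in constraints.targets:
        if t.observable == "flux_ratio":
            if flux is None:
                raise SchemaError(
                    "flux_ratio target requires the flux vector to be supplied"
                )
            den = flux.values[t.den]
            x = flux.values[t.num] / den if den != 0 else np.nan
        else:
            try:
                x = obs.value(t.observable, t.experiment)
            except KeyError:
                x = np.nan
        ok = t.ok(x)
        passed &= ok
        rows.append(
            {
                "observable": t.observable,
                "experiment": t.experiment,
                "measured": x,
                "target": t.value,
                "tol": t.tol,
                "mode": t.mode,
                "residual": t.residual(x) if np.isfinite(x) else np.nan,
                "ok": ok,
            }
        )
    return ConstraintReport(passed=bool(passed), rows=tuple(rows))


# ---------------------------------------------------------------------------
# vectorized masks for the samplers
# ---------------------------------------------------------------------------


def _target_mask(t: Target, x: np.ndarray) -> np.ndarray:
    lo, hi = t.band()
    return np.isfinite(x) & (x >= lo) & (x <= hi)


def constraint_mask_label_free(
    compiled: CompiledNetwork, F: np.ndarray, constraints: ConstraintSet
) -> np.ndarray:
    """Rows of ``F`` satisfying every label-independent target."""
    mask = np.ones(F.shape[0], dtype=bool)
    targets = constraints.label_free_targets()
    comp_needed = any(t.observable in COMPOSITION_OBSERVABLES for t in targets)
    comp = composition_arrays(compiled, F) if comp_needed else {}
    for t in targets:
        if t.observable == "flux_ratio":
            num = F[:, compiled.edge_index[t.num]]
            den = F[:, compiled.edge_index[t.den]]
            with np.errstate(invalid="ignore", divide="ignore"):
                x = np.where(den != 0, num / den, np.nan)
        else:
            x = comp[t.observable]
        mask &= _target_mask(t, x)
    return mask


def constraint_mask_labeled(
    compiled: CompiledNetwork,
    F: np.ndarray,
    VL: np.ndarray,
    constraints: ConstraintSet,
    experiment: str | None,
) -> np.ndarray:
    """Rows satisfying every incorporation target of one experiment."""
    mask = np.ones(F.shape[0], dtype=bool)
    targets = (
        constraints.labeled_targets(experiment) if experiment is not None else []
    )
    if not targets:
        return mask
    names = [t.observable.split(".", 1)[1] for t in targets]
    arrs = incorporation_arrays(compiled, F, VL, names=names)
    for t, name in zip(targets, names):
        mask &= _target_mask(t, arrs[name])
    return mask
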