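"""End-to-end screening pipeline and ensemble reporting.

The pipeline mirrors the two-stage study design: (1) Monte-Carlo sampling
of flux split ratios, propagated to steady-state total fluxes and screened
against the label-free observations (composition, S/G); (2) for every
surviving flux vector and every feeding experiment, Monte-Carlo sampling of
label states with the bidirectional-diffusion resolution, screened against
the label-incorporation observations.  A flux vector joins the final
ensemble only if at least one admissible label state is found for *every*
experiment (joint filtering).  Ensembles are summarized with five-number
statistics (whiskers at 1.5 x IQR) matching boxplot reporting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import EmptyEnsembleError, RoleError
from .labeling import LabelPlan, solve_labels
from .network import PathwayNetwork
from .observables import (
    ConstraintSet,
    composition_arrays,
    constraint_mask_label_free,
    constraint_mask_labeled,
    incorporation_arrays,
)
from .steady import compile_network


@dataclass
class _ExperimentResult:
    success: np.ndarray  # (n_survivors,)
    L: np.ndarray
    Df: np.ndarray
    Dr: np.ndarray
    VL: np.ndarray


def _label_stage(
    plan: LabelPlan,
    Fs: np.ndarray,
    pool: str,
    fraction: float,
    constraints: ConstraintSet | None,
    tag: str | None,
    attempts: int,
    rng: np.random.Generator,
    base_fraction: float,
) -> _ExperimentResult:
    """Repeated label draws per flux row; first admissible draw is kept."""
    compiled = plan.compiled
    n = Fs.shape[0]
    res = _ExperimentResult(
        success=np.zeros(n, dtype=bool),
        L=np.zeros((n, len(compiled.pool_ids))),
        Df=np.zeros((n, len(plan.pairs))),
        Dr=np.zeros((n, len(plan.pairs))),
        VL=np.zeros_like(Fs),
    )
    remaining = np.arange(n)
    for _ in range(max(attempts, 1)):
        if remaining.size == 0:
            break
        sol = solve_labels(
            plan, Fs[remaining], pool, fraction, rng=rng,
            base_fraction=base_fraction,
        )
        VLr = sol.labeled_fluxes(Fs[remaining])
        acc = sol.valid.copy()
        if constraints is not None:
            acc &= constraint_mask_labeled(compiled, Fs[remaining], VLr,
                                           constraints, tag)
        hit = remaining[acc]
        res.success[hit] = True
        res.L[hit] = sol.L[acc]
        res.Df[hit] = sol.Df[acc]
        res.Dr[hit] = sol.Dr[acc]
        res.VL[hit] = VLr[acc]
        remaining = remaining[~acc]
    return res


@dataclass
class EnsembleSummary:
    """Five-number summaries per ensemble column (whiskers at 1.5 x IQR)."""

    table: pd.DataFrame  # index: column name; cols: n, lo, q1, median, q3, hi
    n: int

    def row(self, column: str) -> dict:
        return self.table.loc[column].to_dict()


def summarize_ensemble(ensemble: pd.DataFrame) -> EnsembleSummary:
    """Classical boxplot statistics for every numeric ensemble column."""
    if ensemble is None or len(ensemble) == 0:
        raise EmptyEnsembleError("cannot summarize an empty ensemble")
    rows = {}
    n = len(ensemble)
    for col in ensemble.columns:
        x = ensemble[col].to_numpy(dtype=float)
        x = x[np.isfinite(x)]
        if x.size == 0:
            continue
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        iqr = q3 - q1
        lo = x[x >= q1 - 1.5 * iqr].min()
        hi = x[x <= q3 + 1.5 * iqr].max()
        rows[col] = {
            "n": n, "whisker_lo": lo, "q1": q1, "median": med,
            "q3": q3, "whisker_hi": hi,
        }
    return EnsembleSummary(table=pd.DataFrame(rows).T, n=n)


@dataclass
class RunResult:
    """Everything a pipeline run produced."""

    network_name: str
    counts: dict
    ensemble: pd.DataFrame
    summary: EnsembleSummary | None
    manifest: dict
    out_dir: Path | None = None

    @property
    def empty(self) -> bool:
        return len(self.ensemble) == 0


def run_pipeline(
    network: PathwayNetwork,
    constraints: ConstraintSet | None,
    n_samples: int = 10_000,
    label_attempts: int = 100,
    seed: int = 0,
    out_dir: str | Path | None = None,
    make_plots: bool = True,
    base_fraction: float = 0.0,
) -> RunResult:
    """Run the full two-stage screen and (optionally) write a run directory.

    The run directory receives the accepted-member ensemble CSV (with
    ``#``-prefixed metadata lines), a summary table, per-member constraint
    residuals, boxplot figures, and a machine-readable manifest from which
    the run is exactly reproducible.
    """
    rng = np.random.default_rng(seed)
    compiled = compile_network(network)
    plan = LabelPlan(compiled)

    fracs = compiled.sample_fractions(n_samples, rng)
    F = compiled.propagate(fracs)
    mask = np.all(F >= 0, axis=1)
    if constraints is not None:
        mask &= constraint_mask_label_free(compiled, F, constraints)
    surv = np.flatnonzero(mask)
    Fs = F[surv]

    experiments = list(constraints.feedings) if constraints is not None else []
    per_exp: dict[str, _ExperimentResult] = {}
    joint = np.ones(len(surv), dtype=bool)
    for tag in experiments:
        pool, fraction = constraints.feedings[tag]
        res = _label_stage(
            plan, Fs, pool, fraction, constraints, tag, label_attempts, rng,
            base_fraction,
        )
        per_exp[tag] = res
        joint &= res.success

    members = np.flatnonzero(joint)
    ensemble = _assemble(compiled, plan, Fs, per_exp, members, experiments)
    counts = {
        "samples": int(n_samples),
        "flux_admissible": int(len(surv)),
        "accepted": int(len(members)),
    }
    manifest = {
        "package_version": __version__,
        "network": network.to_dict(),
        "constraints": constraints.to_dict() if constraints is not None else None,
        "n_samples": int(n_samples),
        "label_attempts": int(label_attempts),
        "seed": int(seed),
        "base_fraction": base_fraction,
        "counts": counts,
    }
    summary = summarize_ensemble(ensemble) if len(ensemble) else None
    result = RunResult(
        network_name=network.name,
        counts=counts,
        ensemble=ensemble,
        summary=summary,
        manifest=manifest,
        out_dir=Path(out_dir) if out_dir is not None else None,
    )
    if out_dir is not None:
        _write_run(result, network, constraints, compiled, make_plots)
    return result


def _assemble(compiled, plan, Fs, per_exp, members, experiments) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    Fm = Fs[members]
    for j, e in enumerate(compiled.edge_ids):
        cols[e] = Fm[:, j]
    if len(members):
        try:
            comp = composition_arrays(compiled, Fm)
        except RoleError:
            comp = {}  # networks without sink roles get no composition cols
        for k, v in comp.items():
            cols[k] = v
    for tag in experiments:
        res = per_exp[tag]
        L = res.L[members]
        VL = res.VL[members]
        for i, p in enumerate(compiled.pool_ids):
            cols[f"{tag}.L.{p}"] = L[:, i]
        for k, pr in enumerate(plan.pairs):
            e = compiled.edge_ids[pr.edge_j]
            cols[f"{tag}.Df.{e}"] = res.Df[members][:, k]
            cols[f"{tag}.Dr.{e}"] = res.Dr[members][:, k]
            # labeled percentage per diffusion direction = source pool label
            with np.errstate(invalid="ignore"):
                cols[f"{tag}.pct.{e}f"] = np.where(
                    res.Df[members][:, k] > 0, 100 * L[:, pr.src_pool], np.nan
                )
                cols[f"{tag}.pct.{e}r"] = np.where(
                    res.Dr[members][:, k] > 0, 100 * L[:, pr.dst_pool], np.nan
                )
        diff_js = {pr.edge_j for pr in plan.pairs}
        for j, e in enumerate(compiled.edge_ids):
            cols[f"{tag}.VL.{e}"] = VL[:, j]
            if j not in diff_js:
                with np.errstate(invalid="ignore", divide="ignore"):
                    cols[f"{tag}.pct.{e}"] = np.where(
                        Fm[:, j] > 0, 100 * VL[:, j] / Fm[:, j], np.nan
                    )
        if len(members):
            inc = incorporation_arrays(compiled, Fm, VL, names=None)
            for k, v in inc.items():
                cols[f"{tag}.inc.{k}"] = v
    return pd.DataFrame(cols)


def _write_run(result: RunResult, network, constraints, compiled, make_plots):
    out = result.out_dir
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "ensemble.csv", "w") as fh:
        fh.write(f"# network: {result.network_name}\n")
        fh.write(f"# seed: {result.manifest['seed']}\n")
        fh.write(f"# samples: {result.counts['samples']}\n")
        fh.write(f"# flux_admissible: {result.counts['flux_admissible']}\n")
        fh.write(f"# accepted: {result.counts['accepted']}\n")
        result.ensemble.to_csv(fh, index=False, lineterminator="\n")
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)
    if result.summary is not None:
        result.summary.table.to_csv(out / "summary.csv")
    _write_residuals(result, constraints, out)
    if make_plots and not result.empty:
        _plots(result, compiled, out)


def _write_residuals(result: RunResult, constraints, out: Path) -> None:
    if constraints is None or result.empty:
        (out / "residuals.tsv").write_text("")
        return
    rows = []
    df = result.ensemble
    for t in constraints.targets:
        if t.observable == "flux_ratio":
            x = df[t.num] / df[t.den]
        elif t.experiment is None:
            x = df[t.observable]
        else:
            x = df[f"{t.experiment}.inc.{t.observable.split('.', 1)[1]}"]
        for i, xi in enumerate(np.asarray(x, dtype=float)):
            rows.append(
                {
                    "member": i,
                    "observable": t.observable,
                    "experiment": t.experiment,
                    "measured": xi,
                    "target": t.value,
                    "residual": xi - t.value,
                }
            )
    pd.DataFrame(rows).to_csv(out / "residuals.tsv", sep="\t", index=False)


def _plots(result: RunResult, compiled, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = result.ensemble
    flux_cols = [e for e in compiled.edge_ids if e in df.columns]
    fig, ax = plt.subplots(figsize=(max(6, 0.45 * len(flux_cols)), 4))
    ax.boxplot([df[c].dropna() for c in flux_cols], tick_labels=flux_cols,
               whis=1.5)
    ax.set_ylabel("total flux (mass / time)")
    ax.set_title(
        f"{result.network_name}: total steady-state fluxes "
        f"(n={len(df)}; whiskers 1.5 x IQR)"
    )
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    fig.savefig(out / "boxplot_total_fluxes.png", dpi=120)
    plt.close(fig)

    tags = sorted({c.split(".")[0] for c in df.columns if ".pct." in c})
    for tag in tags:
        cols = [c for c in df.columns if c.startswith(f"{tag}.pct.")]
        labels = [c.split(".", 2)[2] for c in cols]
        data = [df[c].dropna() for c in cols]
        keep = [(l, d) for l, d in zip(labels, data) if len(d)]
        if not keep:
            continue
        fig, ax = plt.subplots(figsize=(max(6, 0.45 * len(keep)), 4))
        ax.boxplot([d for _, d in keep], tick_labels=[l for l, _ in keep],
                   whis=1.5)
        ax.set_ylabel("labeled share of flux (%)")
        ax.set_title(
            f"{result.network_name}: labeled flux percentages, "
            f"{tag} feeding (n={len(df)}; whiskers 1.5 x IQR)"
        )
        ax.tick_params(axis="x", rotation=90)
        fig.tight_layout()
        fig.savefig(out / f"boxplot_labeled_pct_{tag}.png", dpi=120)
        plt.close(fig)
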