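# Methods

## Model

A pathway is a monomolecular reaction network over compartment-tagged
metabolite pools (cytosol, ER). Edge kinds are enzymatic conversions,
boundary inputs and effluxes, and *net diffusion* edges joining the
cytosolic and ER pools of one chemical species. The steady state satisfies
`S·V = 0` with `S` the signed incidence matrix (+1 producing, −1
consuming); stoichiometric coefficients other than ±1 are rejected at load
time, which keeps the split-ratio algebra exact. The net-flux graph must be
a DAG from inputs to effluxes, so flux vectors can be built by topological
propagation: each pool's inflow is distributed over its outgoing edges by
flux split ratios (FSRs). Conservation and non-negativity then hold by
construction, and are still re-checked on every accepted member
(residual tolerance 1e−9).

### Sampling the underdetermined steady state

FSRs at a k-way branch are drawn from Dirichlet(1,…,1) — uniform on the
simplex, reducing to U[0,1] for the two-way branches. The default budget is
10,000 samples per run (configurable); "thousands" is the intended working
regime and the default runs in well under a second because propagation is
vectorized across samples. No objective function is used: the screen keeps
*every* flux vector compatible with the observations, and the ensemble
(reported as boxplot five-number summaries, whiskers at 1.5×IQR) is the
result. An empty ensemble is a *finding* (the scheme is infeasible), not an
error; the CLI signals it with exit code 3.

### Label flow across bidirectional diffusion

Each diffusion edge hides two unidirectional components `D_f` (along the
configured net direction) and `D_r` (opposed), with `D_f − D_r` equal to
the net flux. Writing total and labeled balances at the two member pools
and summing eliminates the exchange, giving the partner label in closed
form; substituting back yields `D_f` and `D_r`. The solver classifies every
pair structurally at compile time:

- **two-sided** (independent influx and efflux on both sides — e.g. the
  *p*-coumarate pair, fed by phenylalanine on the ER side and tyrosine on
  the cytosol side): one pool label is a genuine degree of freedom. The
  admissible values of the cytosol member's label form an interval swept
  monotonically by the exchange magnitude, from its no-exchange inflow
  mixture to the pair's full-mixing label; the sampler draws uniformly on
  that interval. This has the identical conditional law as drawing on
  [0,1] and rejecting infeasible values (both are uniform over the same
  feasible set) but wastes no draws; range and sign checks are still
  applied and violations are counted rejections.
- **pinned** (one side has no independent efflux — e.g. ER coniferyl
  alcohol, whose only outlet is diffusion to the cytosol): total label
  conservation fixes the *other* side's label exactly; the dead-end pool's
  label only parameterizes the unidentifiable exchange level and is drawn
  uniformly over its feasible interval via `D_r = n·u/(1−u)`, `u ~ U[0,1)`.
- **uniform** (one side has no independent influx — e.g. ER
  coniferaldehyde, fed only from the cytosol): both labels provably equal
  the fed side's mixture; only the net component is identifiable and the
  resolution falls back to `D_f = net`, `D_r = 0`.

Non-pair pools take the flux-weighted mixture of their inflow labels, in a
dependency order that treats each pair as one node (cyclic merged
dependencies are rejected at compile time). Direct calls to the scalar
operations raise named errors on degenerate denominators or out-of-range
labels; inside Monte-Carlo the same conditions are counted rejections.

The labeled part of every ordinary flux is its source-pool label times its
magnitude; a diffusion edge's net labeled flow is `L_src·D_f − L_dst·D_r`,
deliberately *not* `L_src·(D_f − D_r)` — the two differ whenever the pool
labels differ and exchange is present, and conflating them misstates label
transport.

### Two-stage screen

Stage 1 filters flux vectors by the label-free targets (composition, S/G,
optional flux ratios). Stage 2, for each survivor and each feeding
experiment, draws up to 100 label states (configurable) and keeps the first
that satisfies the experiment's incorporation targets; a member joins the
final ensemble only if every experiment succeeds (joint filtering — one
total-flux vector must explain both feeding experiments, with labels
resolved per experiment). Labels are conditioned on already-accepted flux
vectors rather than jointly resampled, matching the net-first /
bidirectional-second staging of the analysis.

## Shipped networks

Four configs ship with the package: the four-pool illustration network,
and three variants of the *Brachypodium* monolignol pathway. Topology was
reconstructed from the pathway chemistry (PAL/TAL entries; 4CL, HCT/C3′H/
CCoAOMT shikimate shunt; CCR/CAD; C3H–COMT acid route; F5H/COMT 5-hydroxy
route) and the compartment rule that C4H, C3′H and F5H are ER-bound with
all other activities cytosolic. **Flux ids are local to this package and
provisional.** Two simplifications are applied and documented in the
configs: single-source monomolecular chains that cross a compartment
boundary are lumped into one edge (e.g. PAL+C4H, F5H/COMT/CAD), which is
label-neutral because every pool on such a chain provably carries the
source label; and the speculative cytosolic C3H step is included by
default but removable (`PathwayNetwork.without_edges`).

- `brachy_fig4` — baseline compartmental scheme: diffusion returns the
  whole phenylalanine-derived flux to the cytosol at *p*-coumarate; ER
  coniferaldehyde feeds the S branch. Because everything funnels through
  cytosolic *p*-coumarate, conservation pins that pool's label at the
  perfect-mixing value (17.5 % when 35 % of one of two equal inputs is
  labeled), forcing equal G and S labeling and capping wall-ferulate
  incorporation below the measured value — the structural reason this
  scheme is infeasible.
- `brachy_fig5` — adds ER-side 4CL and C3H activity (feeding diffusions
  D9 and D10, which deliver undiluted label to the cytosolic H- and
  ferulate routes) plus a long ER channel from *p*-coumaroyl-CoA to
  coniferyl alcohol.
- `brachy_fig6` — the minimal-channel variant: same ER-side activity, but
  the only channel is a CCR/CAD step (V8) carrying ER feruloyl-CoA to ER
  coniferyl alcohol without exposing coniferaldehyde. Feasible, with V8
  small relative to its cytosolic parallels.

Both inputs default to 100 units of mass per unit time ("nearly equal
contribution" taken as exactly equal; magnitudes are configurable but not
sampled). The diffusion volume factor `r` is carried on edges but inert in
steady-state mode. Observables are ratios, so the 100-unit normalization is
arbitrary and the screen is invariant under uniform flux rescaling.

## Constraint table and tolerances

The shipped constraint table holds the experimental lignin composition
(H/G/S = 4/41/55 %, S/G = 1.09) and per-experiment label-incorporation
percentages for G, S, total lignin, wall-bound *p*-coumarate and ferulate
(35 % feed label, phenylalanine or tyrosine). Defaults: ±5 percentage
points absolute on compositions and incorporations, ±10 % relative on S/G,
all configurable per target and recorded in run manifests. The 5-point
band is the package's reading of "compatible with experimental data" for
this data set: reference solutions known to be acceptable deviate from the
printed measurements by up to 5 points, so a tighter band would reject the
very solutions the data support. H-lignin incorporation is excluded from
screening in both experiments: the phenylalanine-feeding H measurement
exceeds the 35 % feed label (physically impossible, hence unreliable), and
H is a minor monomer whose remaining information is carried by the
composition targets. Wall-bound acid incorporation is bookkept on
dedicated efflux edges (an assumption; the measurements could also be read
as pool-level quantities).

## Synthetic experiments

`generate_experiment` draws a ground-truth FSR vector from the sampler's
own prior, resolves admissible label states for both feedings, computes
exact observables, and perturbs every observed percentage with independent
Gaussian noise (default sd 1 percentage point — a realistic precision for
lignin analytics); noisy compositions are clipped at zero and renormalized
to 100, incorporations clipped to [0,100]. The emitted constraint file
uses the same schema and default tolerances as the real table, with two
differences: H incorporation is included (the synthetic instrument has no
unreliable-H problem) and the redundant S/G target is omitted (it is
determined by the G and S share targets, and its relative error is
unbounded for G-poor truths). `require_channelled` rejection-samples
truths until the channel is expressed in the data (channel flux ≥ 5 units
and phenylalanine-feeding wall-ferulate incorporation ≥ 25 %, above the
perfect-mixing cap of any channel-free explanation).

What passing synthetic tests shows — and does not: the generator emulates
threshold-screened percentage observables under additive noise. It does not
emulate isotopologue spectra, correlated measurement error, pool-size
effects, or model misspecification; recovery results therefore speak to
the pipeline's internal consistency, not to robustness against structural
error in real data. Individual fluxes are not point-identifiable (the
steady state is underdetermined), so recovery is asserted on observables.

## Numerical choices

- Tolerances: 1e−12 on FSR simplex sums, 1e−9 on conservation and label
  balances, 1e−10 degenerate-denominator guard in pair resolution.
- Degenerate pairs (uniform labeling): net-only fallback with zero
  exchange, accepted only when the labeled balance already closes.
- Zero-throughput pools take the base label (0.0 by default; the fully
  labeled isotopologue has negligible natural abundance).
- One seeded `numpy` Generator per run drives all sampling; identical
  inputs give byte-identical ensemble CSVs. Run manifests embed the full
  network and constraint definitions, so a run is reproducible from its
  manifest alone.
- Problem sizes: 10,000 flux samples and 100 label attempts per survivor
  for the main screen; 6,000/80 per seed for the 50-seed synthetic
  recovery study and 4,000/50 for the discrimination runs. All are
  configurable; these defaults put Monte-Carlo error well inside the
  screening tolerances.

## Known limitations

- No kinetics: the package analyses steady states only; the volume factor
  `r` awaits a dynamic extension.
- Scalar label fractions per pool; no positional or mass-isotopomer
  detail.
- A pool may participate in at most one diffusion pair, and merged pair
  dependencies must stay acyclic — sufficient for the shipped topologies,
  checked at compile time.
- The screen is a threshold test, not an inference: ensemble spread
  reflects the admissible set under the stated tolerances, not a
  posterior.
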