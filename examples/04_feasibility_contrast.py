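"""Compare the three pathway schemes under identical constraints.

The baseline compartmental scheme (no ER-side 4CL/C3H, no channel) funnels
every flux through the cytosolic p-coumarate pool, which pins its label at
the perfect-mixing value; the measured wall-ferulate incorporation then
cannot be reached and the screen rejects every sample.  The extended and
minimal-channel schemes admit solutions.
"""

import lignflux as lf

nets = [lf.load_builtin(n) for n in
        ("brachy_fig4", "brachy_fig5", "brachy_fig6")]
cons = lf.load_table1_constraints()
report = lf.feasibility_report(nets, cons, n_samples=10_000, seed=1,
                               label_attempts=100)
for r in report:
    verdict = "infeasible" if r["accepted"] == 0 else "feasible"
    print(f"{r['network']:12s}: {r['flux_admissible']:4d} flux-admissible, "
          f"{r['accepted']:4d} accepted -> {verdict}")
print(
    "\nOnly the schemes with ER-side activity feeding the diffusion fluxes\n"
    "and a metabolic channel across coniferaldehyde can reproduce the\n"
    "labeling data; emptiness of the baseline ensemble is the evidence for\n"
    "channeling."
)
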