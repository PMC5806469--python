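"""Generate a noisy synthetic experiment and recover its ground truth.

A random admissible flux distribution and label states are drawn from the
minimal-channel scheme, exact observables computed, and 1-percentage-point
Gaussian noise added.  Screening the same scheme against the noisy table
should place the ensemble medians close to the hidden truth.
"""

import lignflux as lf

net = lf.load_builtin("brachy_fig6")
exp = lf.generate_experiment(net, seed=11, noise_sd=1.0)
res = lf.run_pipeline(net, exp.constraints, n_samples=6000, label_attempts=80,
                      seed=12, out_dir=None, make_plots=False)
print("accepted members:", res.counts["accepted"])
med = res.summary.table["median"]
rows = [
    ("H fraction (%)", exp.truth.h_frac, med["H_frac"]),
    ("G fraction (%)", exp.truth.g_frac, med["G_frac"]),
    ("S fraction (%)", exp.truth.s_frac, med["S_frac"]),
    ("phe total incorporation (%)",
     exp.truth.incorporation["phe"]["total_lignin"],
     med["phe.inc.total_lignin"]),
    ("tyr total incorporation (%)",
     exp.truth.incorporation["tyr"]["total_lignin"],
     med["tyr.inc.total_lignin"]),
]
print(f"{'observable':30s} {'truth':>8s} {'median':>8s} {'abs dev':>8s}")
for name, t, m in rows:
    print(f"{name:30s} {t:8.2f} {m:8.2f} {abs(t - m):8.2f}")
print(
    "\nMedians track the hidden truth to about the noise level; individual\n"
    "fluxes remain unidentifiable (the steady state is underdetermined),\n"
    "so recovery is asserted on observables."
)
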