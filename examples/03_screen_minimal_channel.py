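"""Screen the minimal-channel Brachypodium scheme against the data table.

Draws 10,000 flux-split-ratio vectors, keeps steady states compatible with
the lignin composition and S/G ratio, then samples label states for the
phenylalanine and tyrosine feeding experiments and keeps members matching
every label-incorporation observation.  Prints the accepted ensemble's
median observables.
"""

import lignflux as lf

net = lf.load_builtin("brachy_fig6")
cons = lf.load_table1_constraints()
res = lf.run_pipeline(net, cons, n_samples=10_000, label_attempts=100,
                      seed=1, out_dir=None, make_plots=False)
print("counts:", res.counts)
med = res.summary.table["median"]
print(f"median H/G/S composition : "
      f"{med['H_frac']:.1f} / {med['G_frac']:.1f} / {med['S_frac']:.1f} %")
print(f"median S/G ratio         : {med['SG_ratio']:.2f}")
print(f"median total-lignin label incorporation: "
      f"phe {med['phe.inc.total_lignin']:.1f} %, "
      f"tyr {med['tyr.inc.total_lignin']:.1f} %")
print(f"median channel flux V8   : {med['V8']:.1f} "
      f"(cytosolic parallels V22 {med['V22']:.1f}, V23 {med['V23']:.1f})")
print(
    "\nEvery member reproduces the measured composition and the differential\n"
    "label incorporation; the ER-surface CCR/CAD channel carries only a\n"
    "small flux next to its cytosolic parallels, yet it is what lets the\n"
    "scheme match the data at all (compare the next example)."
)
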