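"""Probabilistic sensitivity analysis: 1,000 Monte Carlo draws, the
cost-effectiveness plane of IPC against each comparator, and the
acceptability curve at the R$15,000 willingness-to-pay threshold.

Run:  python examples/probabilistic_analysis.py
"""

import numpy as np

from vtecea import acceptability_curve, ce_plane_summary, default_parameters, run_psa

params = default_parameters()
run = run_psa(params, n=1_000, seed=1)
print(
    f"{len(run)} draws ({run.n_product_clamped} probability products clamped, "
    f"{run.n_renormalized} draws renormalized)\n"
)

for ref in ("LMWH", "no_prophylaxis"):
    summary = ce_plane_summary(run, ref=ref, comp="IPC", wtp=params.wtp)
    print(
        f"IPC vs {ref}: dominant (cheaper and more effective) in "
        f"{100 * summary.p_superior:.1f}% of draws; below the WTP line in "
        f"{100 * summary.p_acceptable:.1f}%"
    )

curve = acceptability_curve(run)
at_wtp = int(np.where(curve.wtp_grid == params.wtp)[0][0])
print(f"\nP(cost-effective) at WTP R${params.wtp:,.0f}:")
for name, probs in curve.probabilities.items():
    print(f"  {name:<16} {probs[at_wtp]:.3f}")
print(
    "\nEach probability is the fraction of draws in which that strategy\n"
    "attains the maximum net monetary benefit (WTP x effectiveness - cost)."
)
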