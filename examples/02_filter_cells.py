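"""Posterior-based filtering with the two corrections, versus baselines.

Cells with >= 75% posterior probability of being compromised are removed;
cells under the intact line are rescued, and cells dominated by the
lowest-mito removed cell are additionally dropped.  The uniform 10%
threshold and the 3-MAD rule are run on the same cells for comparison.
"""

from mixqc import (
    SyntheticParams,
    filter_cells,
    fit_mixture,
    mad_threshold_filter,
    percent_threshold_filter,
    prefilter,
    simulate_qc_metrics,
)

cells, _ = prefilter(simulate_qc_metrics(SyntheticParams(seed=1)))
fit = fit_mixture(cells, seed=1)

decisions = filter_cells(cells, fit)  # default: cutoff 0.75, both corrections
print("mixture-model filter:")
for reason, count in decisions.reason.value_counts().items():
    print(f"  {reason:>22}: {count}")
removed_pct = 100 * (~decisions.keep).mean()
print(f"  removed {removed_pct:.1f}% of cells")

truth = cells.true_state == "compromised"
acc = (truth.to_numpy() == (~decisions.keep).to_numpy()).mean()
print(f"  agreement with true labels: {acc:.1%}")

for name, dec in (
    ("uniform 10% threshold", percent_threshold_filter(cells, 10.0)),
    ("3-MAD rule", mad_threshold_filter(cells)),
):
    print(f"{name}: removed {100 * (~dec.keep).mean():.1f}% of cells")
# On this well-separated sample all three filters agree closely; the
# model-based filter differs on real tumor data where the intact
# population itself has a high mitochondrial fraction.
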