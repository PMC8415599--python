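"""The three functional forms of the component mean curves.

Besides the default pair of straight lines, the compromised component can
be a B-spline smooth (intact stays linear), or both components can be
flat (a one-dimensional Gaussian mixture on the mito percentage alone).
"""

from mixqc import ModelSpec, SyntheticParams, fit_mixture, predict_component, prefilter, simulate_qc_metrics

cells, _ = prefilter(simulate_qc_metrics(SyntheticParams(n_cells=3000, seed=2)))

for label, spec in (
    ("linear / linear", ModelSpec("linear", "linear")),
    ("linear / spline", ModelSpec("linear", "spline", spline_df=4)),
    ("gaussian (intercept-only)", ModelSpec("intercept_only", "intercept_only")),
):
    fit = fit_mixture(cells, spec, seed=2)
    at = 1000.0
    lo = predict_component(fit, fit.intact_index, at)
    hi = predict_component(fit, fit.compromised_index, at)
    print(f"{label:>26}: E[pct_mito | genes={at:.0f}] intact {lo:5.2f}, "
          f"compromised {hi:5.2f}; pi_compromised {fit.weights[fit.compromised_index]:.3f}")
# All variants should agree on the broad picture: a low intact level and
# a high compromised one, with roughly a quarter of cells compromised.
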