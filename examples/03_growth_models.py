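"""Fit the five latent growth curve variants and select the best one.

Simulates a 5-occasion longitudinal panel (years 0, 1, 2, 4, 7) with
monotone dropout from a random-intercept-and-slope truth, fits all five
model variants by full-information maximum likelihood, and applies the
rule-based selection (most good fit indicators, BIC tie-break, Heywood
solutions disqualified).
"""

from netgrowth import (PanelTruth, fit_all_variants, select_model,
                       simulate_panel)

truth = PanelTruth(
    latent_means=[50.0, 0.4],                 # T-score intercept, yearly slope
    latent_cov=[[25.0, 0.0], [0.0, 1.0]],     # intercept/slope variance
    theta=4.0,                                # occasion residual variance
    covariate_effects=[[-0.28, 1.0, 1.5],     # age/sex/education -> intercept
                       [-0.01, 0.0, 0.0]])    # age -> slope
panel = simulate_panel(300, truth, dropout_per_wave=0.15, seed=42)

fits = fit_all_variants(panel)
sel = select_model(fits)
print(sel.audit.to_string(index=False))
print(f"\nselected: variant {sel.selected_variant} "
      "(the generating model has intercept and slope variance -> variant 3)")

best = sel.selected
for name in ("mean_intercept", "mean_linear", "var_intercept", "var_linear",
             "age0_on_intercept", "resid_var"):
    lo, hi = best.ci95[name]
    print(f"  {name:18s} = {best.estimates[name]:7.3f}  "
          f"[{lo:7.3f}, {hi:7.3f}]")
print("\nEstimates are in T-score units; the 95% CIs come from the inverse "
      "observed information. Compare them with the truth above.")
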