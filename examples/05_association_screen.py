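"""Screen covariates against delay and fit the marginal-delay mixed model.

The bivariate screen runs Spearman (continuous) or Kruskal-Wallis
(categorical, eta-squared from H) tests of every baseline covariate
against DUP-total/-demand/-supply with Bonferroni correction. The mixed
model then asks whether a covariate predicts per-encounter marginal delay
after node-type differences and per-participant propensity are absorbed.
The generator injects a negative GAF-12 effect, so GAF-12 is the row that
should light up.
"""

from ptcdelay import (aggregate_decompositions, bivariate_screen,
                      decompose_delays, default_config,
                      fit_marginal_delay_mixed_model, simulate_cohort)

cohort = simulate_cohort(default_config(seed=42))
ds = [decompose_delays(p) for p in cohort.pathways.values()]

res = bivariate_screen(cohort, ds)
flagged = res[res.p_bonferroni < 0.05]
print("screen rows significant after Bonferroni "
      f"(m = {res.bonferroni_m.iloc[0]} per outcome):")
print(flagged[["covariate", "outcome", "test", "statistic",
               "p_bonferroni", "effect_size"]].round(4).to_string(index=False))

table = aggregate_decompositions(ds, cohort.covariates)
mm = fit_marginal_delay_mixed_model(table, "gaf_12")
row = mm.term_estimate("gaf_12")
print(f"\nmixed model (log1p marginal delay, random intercept/participant):")
print(f"  gaf_12 estimate = {row.estimate:+.4f} per GAF point "
      f"(SE {row.se:.4f}, p = {row.p:.2e})")
print(f"  random-intercept variance = {mm.random_intercept_var:.3f}, "
      f"converged = {mm.converged}")
print("\nA negative estimate means participants with better functioning a")
print("year before enrollment moved faster through every node type.")
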