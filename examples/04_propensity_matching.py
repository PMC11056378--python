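"""Propensity-score matching and weighting with balance diagnostics.

Estimates the probability of exposure from age, ventilation and SOFA,
matches exposed to controls 1:1 within a 0.2-SD logit caliper, and
checks standardized mean differences before/after.
"""

from pehr import (SimulationConfig, estimate_propensity, ipw_weights,
                  matched_km, nn_match, simulate_patients, smd_table)

pat, truth = simulate_patients(SimulationConfig(n_patients=2000, seed=4))
pat["exposed"] = truth["true_exposure"]
cov = ["age", "ventilation", "sofa"]

ps = estimate_propensity(pat, cov)
match = nn_match(ps, caliper_multiplier=0.2, seed=4)
print(f"matched {match.n_matched} of {match.n_exposed} exposed "
      f"(caliper {match.caliper:.4f} logits)")

crude = smd_table(ps, cov)
matched = smd_table(ps, cov, pairs=match.pairs)
weighted = smd_table(ps, cov, weights=ipw_weights(ps))
for i, c in enumerate(cov):
    print(f"SMD {c:12s} crude {crude.smd[i]:.3f} -> matched "
          f"{matched.smd[i]:.3f} -> weighted {weighted.smd[i]:.3f}")

fits, stat, p = matched_km(match, pat)
print(f"matched-sample log-rank p = {p:.2e}")
# SMDs fall from >0.1 (confounded) to <0.1 (balanced); the exposure
# effect survives adjustment because it is real in the generator
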