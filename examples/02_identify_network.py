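"""Identify the real network of one stage from its candidate superset.

Each node is fitted by constrained least squares (repression abilities kept
non-negative) and pruned by minimizing AIC(Y) = ln(RSS/N) + 2(Y+1)/N over
nested model orders.  Because the generator planted the truth, recovery can
be scored exactly.
"""

import warnings

import gwgen

warnings.simplefilter("ignore")

config = gwgen.SimulationConfig(seed=0)
truth = gwgen.generate_ground_truth(config)
data = gwgen.simulate_expression(truth, 118, "quiet")
candidate = gwgen.corrupt_candidate(truth, config.spurious_multiplier, seed=1)

real = gwgen.identify_gwgen(candidate, data, "quiet")
scores = gwgen.recovery_scores(truth, real)
rmse = gwgen.coefficient_rmse(truth, real)

print(f"candidate edges: {len(candidate.edges)}  ->  real edges: {len(real.edges)}")
print(f"edge recovery: precision {scores['precision']:.2f}, "
      f"recall {scores['recall']:.2f}, F1 {scores['f1']:.2f}")
print(f"coefficient RMSE on retained true terms: {rmse['rmse']:.4f} "
      f"({rmse['n_matched']} of {rmse['n_truth']} truth coefficients retained)")
print()
print("Directed regulations are recovered well; the bilinear protein-"
      "interaction regressor contains the response itself, so spurious PPI")
print("candidates are rarely rejected at this expression scale — see the "
      "methods note for why precision is PPI-limited.")
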