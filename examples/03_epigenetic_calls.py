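"""Flag putatively epigenetically modified nodes from basal levels.

The basal (intercept) estimate of each node model absorbs regulation outside
the genetic interaction equations; nodes whose |basal| exceeds the 90th
percentile of their model class are flagged, and flagged proteins inherit a
modification kind from enzyme-annotated interaction partners.
"""

import warnings

import gwgen

warnings.simplefilter("ignore")

config = gwgen.SimulationConfig(seed=0)
truth = gwgen.generate_ground_truth(config)
data = gwgen.simulate_expression(truth, 118, "quiet")
candidate = gwgen.corrupt_candidate(truth, config.spurious_multiplier, seed=1)
real = gwgen.identify_gwgen(candidate, data, "quiet")

calls = gwgen.call_modifications(real, real.nodes, gwgen.ThresholdSpec(quantile=0.9))
flagged = calls[calls.flagged]
print(f"{len(flagged)} of {len(calls)} node-models flagged at the "
      "90th-percentile |basal| threshold (per model class):")
print(flagged.head(10).to_string(index=False))
print()
print("A flagged PPIN basal suggests post-translational modification of the "
      "protein; a flagged GRN basal suggests DNA methylation/demethylation "
      "of the gene.  These are network-level associations, not measurements.")
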