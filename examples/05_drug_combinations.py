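"""Score drugs against stage signatures and integrate multi-drug combinations.

Works on the packaged published tables: five biomarker targets per asthma
stage with their dysregulation signs, and five candidate drugs per stage with
signed expression effects.  A drug reverses a target when its effect sign
opposes the disease sign; the combination call per target is the majority of
the drugs' nonzero effect signs.
"""

import gwgen
from gwgen.drugs import effects_from_frame, integrate_combination, signature_from_frame

sigs = gwgen.load_asthma_signatures()
effs = gwgen.load_asthma_drug_effects()

for stage in ("quiet", "exacerbation", "follow_up"):
    sig = signature_from_frame(sigs, stage)
    eff = effects_from_frame(effs, stage)
    res = integrate_combination(sig, eff)
    print(f"== {stage} ==")
    print(res.table().to_string())
    print(f"per-drug reversal scores: {res.per_drug_scores}")
    print(f"{res.n_reversed}/{len(sig.targets)} targets reversed by the "
          "integrated combination\n")

print("A '+' in the Expression row is a disease-upregulated target; the "
      "combination aims for the opposite sign in the Final result row.")
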