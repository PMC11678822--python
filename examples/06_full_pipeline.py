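"""Full pilot-study pipeline: simulate -> NCA -> ANOVA -> f2 -> decision.

Equivalent to `bequiv run --in study.csv --mode pilot` on a saved CSV.
"""

import bequiv as bq

params, var, design = bq.preset("pazopanib_200", n_subjects=24, iscv=0.5,
                                gmr_true=1.0, seed=42)
study = bq.simulate_study(params, var, design, label="200 mg pilot (simulated)")

report = bq.run_pipeline(study, mode="pilot")
print(report.to_text())
print()
print("JSON keys:", ", ".join(report.to_dict().keys()))
# In pivotal mode the same call skips f2 (reported "NC"), matching the
# convention that full-size studies are decided on the 90% CI alone.
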