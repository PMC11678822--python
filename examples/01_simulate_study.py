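"""Simulate a pazopanib-like 24-subject crossover pilot and save it as CSV.

The preset encodes slow elimination (t1/2 ~ 40 h), absorption peaking near
3-4 h, an apparent volume of 25 L and a within-subject CV of 50% on
exposure — the regime in which pilot bioequivalence studies routinely fail
on the confidence interval despite a well-matched Test product.
"""

import bequiv as bq

params, var, design = bq.preset("pazopanib_200", n_subjects=24, iscv=0.5,
                                gmr_true=1.0, seed=42)
study = bq.simulate_study(params, var, design, label="200 mg pilot (simulated)")
bq.write_study(study, "study.csv")

n_blq = int(study.records["blq"].sum())
print(f"subjects:        {design.n_subjects} (balanced TR/RT)")
print(f"sampling points: {len(design.nominal_times_h)} per period, 0-72 h")
print(f"records written: {len(study.records)} ({n_blq} below the 50 ng/mL LLOQ)")
print(f"completers:      {len(bq.completers(study))}")
# Every subject yields one profile per period; BLQ rows are pre-dose samples
# and late tail samples that fell under the assay's quantification limit.
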