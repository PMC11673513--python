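"""Simulate an unbalanced 2x2 metabolomics cohort with planted effects.

Generates 49 subjects (13 LeanLow, 7 LeanHigh, 20 ObeseLow, 9 ObeseHigh),
a 2534-feature log-normal abundance table with 64/5/26 features carrying
BMI/IPAQ/interaction effects, and 6 pooled-QC replicates.
"""

import phenonet as pn

config = pn.SimConfig(seed=1)
meta, table = pn.generate_cohort(config)
table = pn.add_qc_samples(table, config)

print("subjects per cell:", meta["cell"].value_counts().to_dict())
print("lean/obese:", (meta["bmi_class"] == "lean").sum(), "/",
      (meta["bmi_class"] == "overweight_obese").sum())
print("table:", table.n_samples, "samples x", table.n_features, "features")
print("truth labels:", table.truth_labels.value_counts().to_dict())
# The truth labels record which features genuinely carry an effect (and
# which are planted to fail the QC filter), so downstream selection can be
# scored against ground truth.
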