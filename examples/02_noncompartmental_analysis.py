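"""Noncompartmental analysis of the simulated study.

Computes per-subject Cmax, Tmax, AUC, lambda_z and apparent clearance, and
summarizes them as geometric mean x/ geometric SD, the standard scale for
log-normally distributed PK metrics.
"""

import salbupop as sp

dataset = sp.simulate_dataset(
    sp.default_virtual_cohort(), sp.default_popmodel(), seed=20240630
)
table = sp.nca_dataset(dataset)
print(table[["ID", "cmax", "tmax", "auc_inf", "cl_f", "lambda_z"]].head())

for metric in ("cmax", "auc_inf", "cl_f"):
    ok = table[~table.lambda_z_failed][metric].dropna()
    gm, gsd = sp.summarize_geometric(ok)
    print(f"{metric:8s} geometric mean {gm:8.3f}  geometric SD {gsd:6.3f}")
# cl_f is dose/AUC: its geometric mean sits near the generating clearance
# (24.33 L/h) because AUC identifies clearance regardless of the
# compartmental structure
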