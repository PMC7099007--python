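"""Build direction-clipped, normalized delta matrices from two-visit tables.

Regions lose volume with disease (ventricles gain); severity-oriented task
scores rise.  Change running the "wrong" way is clipped to zero, then each
feature is min-max normalized so both modalities live on [0, 1].
"""

import pandas as pd

import phenofactor as pf

visit1 = pd.DataFrame({
    "subject_id": ["s01", "s02", "s03"],
    "hippocampus_L": [4100.0, 3900.0, 4300.0],
    "ventricle_L": [21000.0, 24000.0, 19500.0],
})
visit2 = pd.DataFrame({
    "subject_id": ["s01", "s02", "s03"],
    "hippocampus_L": [3950.0, 3905.0, 4080.0],   # s02 "grew": artifact, clipped
    "ventricle_L": [22500.0, 25100.0, 19400.0],  # s03 shrank: artifact, clipped
})

directions = pf.FeatureDirectionMap({
    "hippocampus_L": "loss_is_signal",
    "ventricle_L": "gain_is_signal",   # the ventricular exception
})

raw = pf.compute_delta(visit1, visit2, directions)
print("raw deterioration (mm^3):")
print(raw.to_frame(), "\n")

normalized = pf.minmax_normalize(raw)
print("column-wise min-max normalized to [0, 1]:")
print(normalized.to_frame())
print("\nper-column (min, max) used:", normalized.column_stats)
# Each entry is now a unitless amount of deterioration; 0 means least
# affected subject for that feature, 1 the most affected.
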