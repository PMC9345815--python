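"""Quality filtering of a binned intensity matrix.

Two pre-treatment filters: class occupancy (keep bins detected in more
than 2/3 of the samples of at least one class) and QC relative standard
deviation (keep bins with RSD < 50% across quality-control injections).
"""

import numpy as np
import pandas as pd

from fiebin import SampleInfo, occupancy_filter, rsd_filter
from fiebin.binning import IntensityMatrix

rng = np.random.default_rng(0)
samples = [f"s{i:02d}" for i in range(12)]
infos = [
    SampleInfo(s, ["control", "treated", "QC"][i // 4], is_qc=i // 4 == 2)
    for i, s in enumerate(samples)
]

# three archetypes: a solid feature, a sparse one, and an unstable one
values = pd.DataFrame(
    {
        "p144.10": rng.normal(5e5, 3e4, 12).clip(0),          # robust
        "p163.12": rng.normal(2e5, 1e4, 12) * (rng.random(12) < 0.3),  # sparse
        "n212.00": rng.normal(1e5, 9e4, 12).clip(0),          # wildly variable
    },
    index=samples,
)
bin_table = pd.DataFrame(
    {"polarity": ["positive", "positive", "negative"],
     "center": [144.10, 163.12, 212.00],
     "accurate_mz": [144.1016, 163.1225, 212.0022],
     "purity": 0.99, "centrality": 0.6,
     "occupancy": values.gt(0).mean(axis=0).to_numpy()},
    index=values.columns,
)
matrix = IntensityMatrix(values, bin_table, width=0.01)

occ = occupancy_filter(matrix, infos, threshold=2 / 3)
print(f"occupancy > 2/3 in some class: kept {occ.bins}")

both = rsd_filter(occ, infos, threshold_pct=50.0)
print(f"QC RSD < 50% as well:          kept {both.bins}")
# The sparse bin fails occupancy; the variable bin survives occupancy
# but fails the QC RSD criterion; only the robust feature remains.
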