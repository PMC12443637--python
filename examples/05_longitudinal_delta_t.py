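"""Screen for treatment-responsive lipids with the ΔT statistic.

Generates the longitudinal design (3 brains × {D0, D5} × {control,
treated}), builds the tumour-mean abundance series, and runs the
time-effect and ΔT treatment-effect screens.
"""

import numpy as np

from replicamap.longitudinal import (
    build_series,
    delta_t,
    time_effect,
    treatment_effect,
    tumour_abundance,
)
from replicamap.pipeline import standard_preprocess
from replicamap.preprocess import BinAxis
from replicamap.simulate import (
    LongitudinalSpec,
    generate_longitudinal,
    truth_region_labels,
)

spec = LongitudinalSpec(seed=0)
datasets, tables = generate_longitudinal(spec)
axis = BinAxis(600, 900, 0.5)
cells = {}
for key, (ds, truth) in datasets.items():
    res = standard_preprocess(ds, axis=axis)
    labels = truth_region_labels(truth, ds.pixel_size)
    cells[key] = tumour_abundance(res.tic, labels, "T")
series = build_series(cells)

te = time_effect(series)
print(f"time effect (untreated, P<0.01 & |log2|>2): "
      f"{int(te.table.significant.sum())} species called "
      f"({len(tables['time_effects'])} planted)")

result = treatment_effect(series)
table = result.table.sort_values("z_delta")
print(f"treatment effect (P<0.01 & |z(ΔT)|>0.5): "
      f"{int(table.significant.sum())} species called "
      f"({len(tables['treatment_effects'])} planted)")
print("\nmost negative standardized responses:")
print(table[["species_mz", "delta_t", "z_delta", "p_treatment"]]
      .head(5).to_string(index=False))
# The species planted to vanish in treated tumours (m/z 692.45) carries the
# most negative z(ΔT): a net decrease attributable to treatment, not drift.
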