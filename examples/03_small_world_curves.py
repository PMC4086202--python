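"""Efficiency curves, small-world cost range, and the cost-efficiency peak.

For one subject's correlation matrix, networks are built across a grid of
wiring costs and compared with degree-preserving random graphs and ring
lattices. The small-world regime is where the observed network is less
globally efficient than random but more than a lattice, and more locally
efficient than random. The cost-efficiency (E_glob - cost) peak marks the
most economical operating point.
"""

import numpy as np

from costnet import (
    SimConfig,
    SubjectTimeSeries,
    correlation_matrix,
    efficiency_curves,
    generate_cohort,
    normalize_run,
    segment_and_concatenate,
    small_world_cost_range,
    smooth_and_peak,
)

cohort, _ = generate_cohort(SimConfig(seed=1))
ts = cohort.timeseries["HV01"]
normed = SubjectTimeSeries(
    [normalize_run(r) for r in ts.runs], ts.roi_names, ts.tr_seconds, ts.schedule
)
corr = correlation_matrix(segment_and_concatenate(normed, "SI", 10.0))

grid = np.round(np.arange(0.05, 0.50, 0.02), 3)
curve = efficiency_curves(corr, cost_grid=grid, n_null=5, seed=0)
print(curve.table.round(3).to_string(index=False))

sw = small_world_cost_range(curve)
peak = smooth_and_peak(curve.table["cost"], curve.table["ce"])
if sw:
    print(f"\nsmall-world cost range: [{sw.cost_min:.3f}, {sw.cost_max:.3f}]")
print(f"cost-efficiency peak (shape-preserving smoothing): {peak:.3f}")
print(
    "\nInside the small-world range the modular synthetic network shows the"
    "\nclassic signature: high clustering with short paths at moderate cost."
)
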