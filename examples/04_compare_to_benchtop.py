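"""Percent-error comparison against user-supplied benchtop measurements.

Measured CO2 removal and oxygenation rates are not bundled with the
package; this example writes a synthetic measurements CSV (labelled as
such) purely to demonstrate the comparison workflow, then joins it
against model predictions at exactly matching flows.
"""

import tempfile
from pathlib import Path

from hfmox import (
    compare_to_experiment,
    flow_sweep,
    read_experiment_csv,
    results_table,
)

# Synthetic stand-in measurements (NOT real benchtop data).
synthetic_csv = Path(tempfile.gettempdir()) / "synthetic_benchtop.csv"
synthetic_csv.write_text(
    "flow_ml_min,vco2_obs_ml_min,vo2_obs_ml_min\n"
    "240,36.0,17.0\n"
    "500,55.0,31.0\n"
)

experiment = read_experiment_csv(synthetic_csv)
results = []
for variant in ("haldane", "static"):
    results.extend(flow_sweep([240.0, 500.0], variant))

comparison = compare_to_experiment(results_table(results), experiment)
print(comparison.to_string(index=False))

# Each row gives the unsigned percent error 100*|pred - obs|/obs per
# flow; the 'max' row summarizes the worst error per model variant.
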