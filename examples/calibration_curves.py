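"""Fit and inspect a transformation function for one simulated tool.

The tool's confidence c is constructed so that P(correct | c) = c: a
perfectly honest confidence scale.  The fitted calibration curve (60
equal-count bins, 5-bin moving average) should therefore track the
identity line.
"""

import numpy as np

from snpconsensus import (
    BinSpec,
    ToolProfile,
    fit_continuous,
    generate_mutations,
    labels_by_key,
    simulate_tool,
)

mutations = generate_mutations(30_000, seed=7)
profile = ToolProfile(
    "honest", "continuous", ("identity",), ("uniform", 0.5, 1.0)
)
predictions = simulate_tool(
    profile, mutations, np.zeros(len(mutations)), rho=0.0, seed=7
)
labels = labels_by_key(mutations)

for cls in ("neutral", "deleterious"):
    entry = fit_continuous(predictions, labels, cls, BinSpec(60, 5))
    err = np.abs(np.array(entry.accuracies) - np.array(entry.representatives))
    print(f"predicted {cls}: {entry.n_bins} bins over "
          f"{entry.n_records} records, max |curve - identity| = {err.max():.3f}")
    for i in (0, len(entry.representatives) // 2, -1):
        print(f"  raw confidence {entry.representatives[i]:.3f} "
              f"-> observed accuracy {entry.accuracies[i]:.3f}")

# Each printed pair is one bin of the transformation function: the mean
# raw confidence of its members against the smoothed fraction of correct
# predictions.  A max deviation of a few percent shows the binned
# estimator recovering the true accuracy curve.
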