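#!/usr/bin/env python
"""Transition accounting on the reference scenario.

For each consecutive period: the binary ecological/non-ecological
transition matrix, its B (contribution, destination-normalized) and C
(probability, origin-normalized) percentages, per-class net changes, and
gain/loss areas.  Also verifies the Markov identity: projecting the t0
state through the estimated matrix returns the t1 areas.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ecoland.grids import binary_eco_scheme, default_scheme, to_binary_eco
from ecoland.synth import SyntheticConfig, generate_scenario
from ecoland.transitions import (
    compute_transition_matrix,
    contribution_and_probability,
    gains_losses_map,
    markov_project,
    net_change,
)

SEED = 1
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    scheme = default_scheme()
    eco2 = binary_eco_scheme()
    bundle = generate_scenario(SyntheticConfig(seed=SEED), scheme)
    years = bundle.years
    out = ROOT / "results"
    out.mkdir(exist_ok=True)

    bc_rows, net_rows, gl_rows = [], [], []
    for y0, y1 in zip(years[:-1], years[1:]):
        b0 = to_binary_eco(bundle.landuse[y0], scheme)
        b1 = to_binary_eco(bundle.landuse[y1], scheme)
        tm = compute_transition_matrix(b0, b1, eco2)
        B, C = contribution_and_probability(tm)
        bc_rows.append({"period": f"{y0}-{y1}",
                        "C_eco_to_noneco_pct": round(float(C[0, 1]), 1),
                        "B_eco_to_noneco_pct": round(float(B[0, 1]), 1)})
        tm10 = compute_transition_matrix(bundle.landuse[y0],
                                         bundle.landuse[y1], scheme)
        for nc in net_change(tm10):
            net_rows.append({"period": f"{y0}-{y1}", "class": nc.label,
                             "net_change_km2": nc.change})
        _, summary = gains_losses_map(bundle.landuse[y0], bundle.landuse[y1],
                                      scheme)
        gl_rows.append({"period": f"{y0}-{y1}", **summary})

        # Markov identity check
        P = np.nan_to_num(tm.probabilities)
        s1 = markov_project(P, tm.t0_areas, 1)
        assert np.allclose(s1, tm.t1_areas)

    pd.DataFrame(bc_rows).to_csv(out / "02_bc_statistics.csv", index=False)
    pd.DataFrame(net_rows).to_csv(out / "02_net_changes.csv", index=False)
    pd.DataFrame(gl_rows).to_csv(out / "02_gainloss.csv", index=False)

    print("per-period eco->non-eco transition statistics:")
    for r in bc_rows:
        print(f"  {r['period']}: C = {r['C_eco_to_noneco_pct']}%  "
              f"B = {r['B_eco_to_noneco_pct']}%")
    print("the Markov projection of each period's start state reproduces "
          "the end state exactly (definitional identity verified)")


if __name__ == "__main__":
    main()
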