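#!/usr/bin/env python
"""Pressure, tissue-resistance and fracture regimes across injection rates.

Evaluates the pressure/flow correlation, the TRP correlation and the
tunnelling-crack energy release rate J = P^2 h / (1.27 E) at the slow
(25 uL/min) and fast (6 mL/min) conditions, then classifies each against
the tissue threshold J_a = 4.1 kJ/m^2: slow infusion stays an order of
magnitude below threshold (no fracture), the fast single shot reaches it.

Writes results/fracture_pressure.tsv.

Run:  python analysis/04_fracture_pressure.py
"""

from pathlib import Path

import pandas as pd

from depotflow import constants as C
from depotflow import transport as T


def main() -> None:
    rows = []
    for label, q_ul_min in (("slow-25", 25.0), ("slow-100", 100.0), ("fast-6000", 6000.0)):
        p = T.injection_pressure(q_ul_min / 60.0)
        trp = T.tissue_resistance_pressure(q_ul_min / 1000.0)
        j = T.fracture_toughness(p, C.DEFAULT_CRACK_WIDTH_UM, C.DEFAULT_YOUNGS_MODULUS_KPA)
        regime = T.assess_fracture(j, C.DEFAULT_JA_KJ_M2 * 1e3).regime
        rows.append((label, q_ul_min, p, trp, j, regime))
    df = pd.DataFrame(
        rows,
        columns=["scenario", "flow_rate_ul_min", "pressure_kpa", "trp_kpa", "J_j_m2", "regime"],
    )
    Path("results").mkdir(exist_ok=True)
    df.to_csv("results/fracture_pressure.tsv", sep="\t", index=False, float_format="%.4g")
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
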