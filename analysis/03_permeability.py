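#!/usr/bin/env python
"""Estimate directional Darcy permeabilities from the tracked depots.

For each scenario the final injection-region wetting fronts feed the
point-source Darcy estimate k = q / (4 pi p r_t), with p from the
pressure/flow correlation.  Also reports the idealized spherical-depot
value at 25 uL/min, which falls inside the 1.07-4.41e-13 m^4/(N s) band
reported for slow subcutaneous infusions.

Writes results/permeability_summary.tsv.

Run:  python analysis/03_permeability.py
"""

from pathlib import Path

import pandas as pd

from depotflow import transport as T

SCENARIOS = ["slow-25", "slow-100", "fast-6000"]


def main() -> None:
    rows = []
    for name in SCENARIOS:
        perm = Path("scratch/analysis") / name / "permeability.tsv"
        if not perm.exists():
            raise SystemExit(f"missing {perm} — run 02_track_fronts.py first")
        df = pd.read_csv(perm, sep="\t")
        for _, r in df.iterrows():
            rows.append((name, r.tissue, r.flow_rate_ml_min, r.k_horizontal, r.k_vertical, "tracked"))

    proto = T.InjectionProtocol(25, 500)
    r_t = T.wf_spherical(25, proto.duration_s, 1.0)
    k = T.permeability_darcy(25, r_t, T.injection_pressure(25 / 60))
    rows.append(("slow-25-ideal", "subcutaneous", 0.025, k, k, "spherical model"))

    out = pd.DataFrame(
        rows, columns=["scenario", "tissue", "flow_rate_ml_min", "k_horizontal", "k_vertical", "source"]
    )
    Path("results").mkdir(exist_ok=True)
    out.to_csv("results/permeability_summary.tsv", sep="\t", index=False, float_format="%.4g")
    print(out.to_string(index=False))
    in_band = 1.07e-13 <= k <= 4.41e-13
    print(f"\nidealized slow-infusion k = {k:.3g} m^4/(N s); inside reported band: {in_band}")


if __name__ == "__main__":
    main()
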