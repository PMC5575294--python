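#!/usr/bin/env python
"""Generate the three studied injection scenarios as synthetic stacks.

Renders down-scaled radiograph stacks (256 px at 40 um) for the two
continuous infusions (25 and 100 uL/min, 500 uL) and the 6 mL/min single
shot, with per-scenario onset lags and depot anisotropies, plus flat-field
calibration frames and ground-truth manifests.  Stacks go to scratch/sim/
(bulky, regenerable); nothing here is measured yet.

Run:  python analysis/01_simulate.py [--seed 0]
"""

import argparse
from pathlib import Path

from depotflow.pipeline import RunConfig, run_simulate

SCENARIOS = ["slow-25", "slow-100", "fast-6000"]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("scratch/sim"))
    args = ap.parse_args()

    for name in SCENARIOS:
        out = args.out / name
        info = run_simulate(RunConfig(out_dir=out, scenario=name, seed=args.seed))
        man = info["manifest"]
        print(
            f"{name}: {len(man['drift_rc'])} frames, "
            f"onset lag {man['onset_time_s']:.0f} s, "
            f"final semi-axes {man['final_semi_axis_h_mm']:.2f} x "
            f"{man['final_semi_axis_v_mm']:.2f} mm -> {out}"
        )


if __name__ == "__main__":
    main()
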