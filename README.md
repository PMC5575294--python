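# depotflow

Quantification of drug-depot permeation in subcutaneous and muscle tissue
from time-lapse X-ray radiographs.

When a drug solution is infused into tissue through a needle it forms a
growing depot around the tip. Time-lapse radiography of an iodinated
solution makes that depot visible: each frame records, per pixel, the X-ray
attenuation along the beam, and hence the path length of solution at that
position. `depotflow` implements the full measurement chain for such data
— and a synthetic radiograph generator that provides ground truth for every
stage — for researchers studying injection devices, drug-depot formation
and tissue transport.

## The models

**Detector corrections.** Raw frames are flat-field corrected with
sample-free (gain) and beam-off (offset) exposures,
`FFC = (object − offset)/(gain − offset)`, and attenuation is inverted by
the Beer–Lambert law `I = I₀ e^(−μx)` to the solution path length
`x = −ln(T)/μ`. Sample drift is compensated by integer-pixel
cross-correlation registration.

**Depot growth.** Treating the tissue as a homogeneous porous medium and
the needle tip as a point source, Darcy flow gives the radial velocity
`v(r) = q/(4πr²)` and the needle-tip pressure `p_t = q/(4πk r_t)` at depot
radius `r_t`, which inverts to the permeability `k = q/(4π p_t r_t)`
[m⁴/(N·s)]. Volume balance of a spherical depot,
`ε·(4/3)π·WF(t)³ = q·t`, yields the cube-root wetting-front law
`WF(t) = (3qt/4πε)^(1/3)` and its normalized form `R(t) = (qt/Q)^(1/3)`.
The applied pressure follows the empirical correlation
`p [kPa] = 0.74·q + 23` (q in µL/s) and the tissue resistance pressure
`TRP = 10.4·q + 1.14` (q in mL/min).

**Fracture criterion.** Pressurized injection can open micro-crack
networks; the energy release rate `J = P²h/(1.27E)` of a tunnelling crack
of width `h` is compared against the tissue threshold `J_a = 4.1 kJ/m²`.

**Measurements.** Per frame, the package extracts RCS (relative content of
solution) maps and axial profiles, horizontal/vertical wetting fronts,
depot aspect ratios in the injection (IR) and diffusion (DR) regions,
onset and quasi-saturation times, temporal RCS variation and ROI
coefficients of variation `C_v = σ/μ`.

## Worked example

```sh
depotflow simulate --config slow-100 --out scratch/demo --seed 7
depotflow analyze  --stack scratch/demo/stack.tif --out scratch/demo_analysis
depotflow recover  --stack scratch/demo/stack.tif --out scratch/demo_analysis
```

simulates a 500 µL infusion at 100 µL/min (onset dead volume 100 µL, depot
axis ratio 0.94) on a down-scaled 256 px / 40 µm detector, analyzes it, and
benchmarks the estimates against the generator truth
(`scratch/demo_analysis/recovery.tsv`):

```
quantity         truth         estimate      rel_error  passed
semi_axis_h_mm   4.666033e+00  4.640000e+00  0.005579   True
semi_axis_v_mm   4.386071e+00  4.360000e+00  0.005944   True
anisotropy       9.400000e-01  9.389773e-01  0.001088   True
onset_time_s     6.000000e+01  7.500000e+01  0.250000   True
k_horizontal     1.172946e-12  1.179530e-12  0.005614   True
```

The final depot semi-axes are recovered to ~0.03 mm (under one pixel), the
axis ratio to 0.001, onset within one 15 s frame interval of the true 60 s
lag, and the Darcy permeability equivalent to 0.6%.

The same chain drives the numbered scripts under `analysis/`
(`01_simulate.py` … `05_recovery_benchmark.py`), which simulate the three
studied injection conditions (25 µL/min, 100 µL/min, 6 mL/min single shot),
track their fronts, estimate permeabilities, evaluate the fracture
criterion and write summary tables under `results/`. Running
`analysis/04_fracture_pressure.py` prints, e.g., J = 338.8 J/m² /
`no_fracture` at 25 µL/min versus J = 5868.2 J/m² / `fracture` at
6 mL/min.

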