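# Methods

## Physical model

The injected solution is treated as incompressible, quasi-steady Darcy flow
from a point source in a homogeneous porous medium. The depot boundary (the
wetting front, WF) encloses the injected volume: for a spherical depot
`ε·(4/3)π·WF³ = q·t`, where ε is the effective volume fraction of the
injection region actually occupied by solution. Two empirical correlations
close the model: the applied pressure `p [kPa] = 0.74·q + 23` and the
tissue resistance pressure `TRP [kPa] = 10.4·q + 1.14`. Their unit
conventions are not intrinsic to the linear forms and were fixed by
back-calculation against the anchor values the correlations reproduce:
q enters the pressure correlation in µL/s (25 µL/min → 23.3 kPa) and the
TRP correlation in mL/min (0.025 → 1.4 kPa). All public interfaces take
explicit lab units (µL/min, kPa, mm, µm) and convert to SI internally.

Permeability is estimated as `k = q/(4π p r_t)` with `r_t` the final
injection-region front distance per direction. The folded closed form
`k = 1/(2.96π r_t) · q/(q+31.08)` is provided too; the two agree to
relative 10⁻⁶ whenever p comes from the pressure correlation (tested over
q ∈ [10 µL/min, 10 mL/min], r ∈ [1, 20] mm). Directional estimates reuse
the same isotropic point-source formula with the directional radius — a
deliberate simplification; no anisotropic Darcy tensor is solved.

The fracture criterion uses the tunnelling-crack energy release rate
`J = P²h/(1.27E)` with crack width h = 800 µm. The Young's modulus is not
directly specified; the default E = 1.01 kPa is the value jointly
consistent (least squares) with the two anchor pairs
(23.3 kPa, 340 J/m²) and (94 kPa, 5.5 kJ/m²) at that h. The fracture
regime is declared at J ≥ J_a (boundary inclusive; only orders of magnitude
are compared in practice). Note the pressure correlation evaluated at
6 mL/min gives 97.0 kPa, whereas the anchor pair uses 94 kPa; the
correlation value is used when computing pressures, and the cross-checks
anchor on the (P, J) pairs as given.

## Image processing

Flat-field correction follows `(object − offset)/(gain − offset)` with the
gain image averaged over 10 sample-free exposures; pixels with zero
denominator are masked, and masks propagate through every downstream map.
Beer–Lambert inversion `x = −ln T/μ` masks non-positive transmission. The
default absorption coefficient μ = 0.15 mm⁻¹ is representative of a ~25%
iodinated-contrast dilution imaged at ~80 kVp; it is configurable and every
RCS quantity scales linearly with 1/μ, so WF positions, aspect ratios and
timing are insensitive to it.

Drift registration uses integer-pixel phase correlation against a reference
frame (sub-pixel accuracy is not needed: front detection is itself
pixel-quantized). Parallel projection is assumed throughout; the cone-beam
magnification of a real source–detector geometry is ignored — a documented
limitation, acceptable because magnification is a global scale absorbed
into the effective pixel size.

## Measurements

RCS maps are `ln(baseline/frame)/μ` against a pre-onset baseline, negatives
clipped. Axial RCS profiles average a 0.9 mm × 0.9 mm sliding window
outward from the needle; a profile series is normalized by its global
maximum so temporal comparisons share one scale. Wetting fronts are
detected on thin (3-pixel) line profiles instead, because the 0.9 mm window
smears the front inward by up to half a window; profiles are median-3
smoothed and the front is the outermost crossing of
`noise_floor + 0.1·(peak − noise_floor)`, with the noise floor estimated
from the first frame's own profile (median + 3σ). "No front" is a
distinguished missing value, not zero.

IR/DR labels split at t = Q/q (end of infusion). Aspect ratio is the mean ±
population SD of WF_v/WF_h over a region's frames. Onset is the first time
the needle-adjacent RCS exceeds baseline mean + 3σ sustained for 3 frames;
quasi-saturation the earliest time after which every fully contained 60 s
sliding window changes the WF by < 1% (trailing partial windows are
inconclusive by construction). C_v uses population σ.

## Synthetic generator

The generator emulates: dead-volume onset lag (no solution enters the
tissue until V_lag has accumulated — an interpretation of the observed
delays, not a stated mechanism), ellipsoidal depot growth at fixed
vertical/horizontal axis ratio satisfying the volume balance, Beer–Lambert
attenuation of the analytic ellipsoid chord map under parallel projection,
smooth fixed-pattern detector gain/offset, Poisson shot noise plus Gaussian
read noise, and linear sample drift. After infusion the front is frozen by
default (matching the observed quasi-saturation); an optional power-law
relaxation supports diffusion-region experiments. Concentration inside the
depot is uniform (sharp front) by default, with an optional linear rim
taper.

Scenario presets encode the studied conditions: 500 µL at 25 µL/min
(lag volume 91.7 µL → 220 s onset, axis ratio 0.89), at 100 µL/min
(100 µL → 60 s, ratio 0.94), and a 6 mL/min single shot (ratio 0.5, the
fast-injection regime where the horizontal front initially doubles the
vertical one). The lag volume is per-scenario because a single dead volume
cannot reproduce both observed delays exactly.

Detector defaults — gain 30 000 counts, offset 1000, ±3% smooth
fixed-pattern gain, 10⁴ photons/pixel (≈1% shot noise), 30 counts read
noise — describe a well-exposed 16-bit X-ray CCD. All randomness descends
from one `numpy.random.SeedSequence`, so a scenario regenerates
bit-identically from its seed.

### What the generator does not emulate

Real tissue has aligned intercellular gaps that produce preferential flow,
multi-peaked RCS profiles and graded concentration fields; the generator's
depots are smooth ellipsoids. Scatter, beam hardening, polychromatic
spectra and cone-beam geometry are absent. Passing recovery tests therefore
demonstrate that the measurement chain is unbiased on data obeying the
stated model, not that the model captures tissue heterogeneity.

## Problem sizes and numerical choices

Simulated detectors are down-scaled to 256 px at 40 µm (56 µm for the
elongated fast-injection depot) with ~20 frames per infusion — chosen so
the full 500 µL depot stays in view while recovery benchmarks over many
seeds remain desk-scale; at the native 9 µm pitch the same chain applies
unchanged. Front-detection accuracy is pixel-limited: noiseless recovery is
within 2 pixels, with default noise within 5% over seeds. Degenerate inputs
are handled explicitly: constant/decreasing WF traces flag a degenerate fit
(R² still reported), featureless frames register with zero shift and a
warning, empty regions and too-short traces raise errors.

## Known limitations

- Isotropic point-source pressure field applied per direction rather than a
  true anisotropic Darcy solution.
- Measured depot radii, not reported ones, drive permeability: exact
  reproduction of published per-tissue permeability tables is not possible
  without the underlying radii, so only order-of-magnitude agreement is
  checked.
- Onset detection needs ≥3 pre-onset frames; a 6 mL/min single shot at 1 s
  framing has none, and onset is reported as missing there.
- The DR-phase relaxation model is phenomenological and off by default.
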