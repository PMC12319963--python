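# Methods

This note describes the models and numerical procedures implemented in
`mtmskit`, the parameters that matter, and the choices made where the
design was genuinely open.

## Forward model: induced E-field in a spherical conductor

All E-field computations assume a spherically symmetric volume conductor
(quasi-static regime). The component of the induced field along a unit
vector `p` at a point `r` inside the conductor equals `-dI/dt` times the
magnetic flux that a unit current dipole `p` at `r` would send through the
stimulating circuit (reciprocity between magnetic lead fields and inductive
stimulation). The external field of a current dipole inside a sphere has
the closed-form Sarvas solution, so the total field — the primary `-dA/dt`
term plus the secondary field of the surface charges — is evaluated in
closed form, with no discretization of the conductor. Two classical
properties fall out exactly: the induced field is purely tangential
(asserted to 1e-6 relative in tests, achieved at machine precision), and it
is independent of the radial conductivity profile, so the model stores no
conductivity value.

Coils enter the formula as flux integrals:

* a discrete winding — signed-fan quadrature over a spanning surface of
  each closed loop (fan triangles subdivided twice, centroid sampling);
* a stream-function surface current `psi` on the planar former — the
  identity that such a current is equivalent to a sheet of magnetic
  dipoles of density `psi * n`, sampled with a degree-2 triangle rule.

Both routes share one kernel, so the discretized winding and its
originating stream function are directly comparable (tested at < 5%
deviation). An independent surface-charge boundary-element solver lives in
the test suite only and agrees with the closed form to < 1% on the
2562-vertex sphere.

## Inductance and resistance

The design-stage energy matrix `L` over interior mesh vertices is the
Neumann double surface integral of the hat-function current elements with
centroid quadrature, 4-fold subdivision for near pairs, and a self-similar
subdivision estimate for the singular self-terms; it is symmetric positive
definite by construction (verified spectrally in tests).

Winding inductance uses the Neumann double line integral over wire
segments (8-point Gauss–Legendre per segment pair) plus the thin-wire
self-term `mu0 l/(2 pi) (ln(2l/a) - 1)` per segment with `a` the wire
radius; this reproduces the closed form for a circular loop to 0.5%.
DC internal inductance is neglected, consistent with the external-only
closed form. Resistance treats the litz wire as solid copper of equal
outer diameter (DC value); the manufactured coil's litz construction and
feed leads make the physical resistance several times larger, which is a
known limitation, not a target of this model.

## Coil-array design pipeline

1. **Reference field.** The commercial 35-mm figure-of-eight coil is
   modelled as two coplanar circular wings (outer diameter 35 mm, 10 turns
   per wing linearly spaced from a 5-mm inner radius, opposing currents).
   Its field is evaluated at the 2562 vertices of a 13.7-mm-radius sphere
   (the rat cortex model) whose closest surface point is 15 mm from the
   bottom coil former.
2. **Minimum-energy stream function.** On each rectangular former
   (19 cm x 9.5 cm, 1953-vertex structured mesh; bottom at 15 mm, top at
   20 mm from the cortical surface) we minimize the magnetic energy
   `0.5 psi' L psi` subject to (a) the field at the reference peak point
   equal to the reference peak vector, (b) every field sample within
   `tolerance * |E_peak|` of the reference per Cartesian component, and
   (c) a wire-density bound on the in-plane surface-current components.
3. **SVD.** The two streams are orthogonalized by singular value
   decomposition; each output component is paired with the input stream it
   correlates with most strongly (singular-value order does not encode
   bottom/top), and its sign is fixed so the bottom coil's peak field
   points along +x and the top coil's along +y.
4. **Isolines.** Contour levels sit at the midpoints of 14 equal-width
   bins spanning the stream range (so a two-lobed stream yields seven
   closed turns per wing); each contour becomes one turn carrying
   `current_per_turn` equal to the bin width, with polarity the local
   stream sign. Turns alternate between two layers that straddle the
   nominal winding plane, one 1.7-mm wire diameter apart, keeping the
   effective source plane at the designed standoff.

### Field tolerance: why 10%

The published description of this design step requires the plane current
to induce a field "with focality and intensity similar to" the reference
coil — a loose, qualitative constraint. A tight pointwise band (2%) makes
the optimizer reproduce the reference coil geometry almost literally
(35-mm wings, 1.7 uH), leaving energy minimization no room to act. We set
the default band to 10% of the peak: empirically the smallest tolerance at
which the shape constraint ceases to bind, so the design is governed by
the peak-intensity equality, energy minimization, and manufacturability
(wire density). At this setting the simulated focality of the designed
array matches the published values to within ~1% (perpendicular 10.8 mm,
parallel 23.9 mm for the bottom coil on the rat sphere).

### Wire-density bound

The bound couples to the solution scale (`current_per_turn` =
stream-range / 14), so it is applied in two passes: solve without the
bound, set `bound = range / (n_isolines * wire_diameter)` (minimum wire
spacing of one wire diameter), and re-solve warm-started. The deviation
band is enforced per Cartesian component (a linear program row) rather
than per-point vector norm, which keeps the problem a QP; the bound is
conservative by at most sqrt(2).

### QP solver

No QP library is assumed; the solver (`mtmskit._qp`) is an operator-
splitting (ADMM) method in the OSQP style: over-relaxation `alpha = 1.6`,
per-class penalty parameters (equalities 1000x stiffer), cached Gram
matrices so penalty adaptation refactors in O(n^2), and unit-infinity-norm
row equilibration (the density rows are ~3 orders of magnitude larger than
the field rows). Every 500 iterations, once primal feasibility reaches
1e-4, an active-set "polish" solves the equality KKT system on the
constraints at their bounds and is accepted when the full KKT residual
drops below tolerance; in practice the design problems polish to ~1e-13.
Primal infeasibility is detected by the standard certificate on the dual
update direction, and reported with the binding constraint family.
The solver is validated against dense KKT solves (equality case, 1e-8) and
SLSQP (inequality case) in the test suite. Determinism: no randomization,
fixed iteration caps.

## Field metrics

Focality is the full width of `|E|` at `1/sqrt(2)` (71%) of its maximum
along great-circle geodesics on the cortex sphere through the peak vertex,
in the directions parallel and perpendicular to the tangential projection
of the peak field. Profiles are sampled every 0.1 mm of arclength with
barycentric interpolation on the cortex mesh (containing triangles found
by gnomonic projection); crossings are linearly interpolated, and the
*outermost* crossing is used on each side so secondary lobes extend the
width rather than truncating it. Rising-phase intensity is the mean `|E|`
over the 60-us linear current rise, i.e. exactly
`|E_per_dIdt| * I_peak / t_rise`.

## Electronic orientation control

Calibration takes the two coils' unit-field maps on a common point set,
normalizes them to equal peak `|E|`, and inverts the 2x2 in-plane mixing
matrix so the superposed field at the calibration point lies along any
requested angle; 0 deg coincides with the bottom coil's peak direction.
The achieved orientation for a requested angle is measured at the argmax
of the superposed `|E|`; over all integer angles the designed array's
error is at numerical precision (the two unit fields are orthogonal at a
common peak by construction). Channel commands map intensity linearly to
capacitor voltage with 100% MSO = 1500 V, referenced to the bottom coil;
voltage is the inductive requirement `L dI/dt`, with the resistive drop
reported separately and the inter-coil mutual inductance computed but not
compensated.

## MRI interference analyses

* FID corruption: ratio of power-spectrum integrals (unwindowed FFT)
  against a no-pulse reference; corrupted below 0.95; ratios above 1.05
  logged as anomalous. The minimum artifact-free delay is the first grid
  delay after the last corrupted one (0 if clean everywhere, NaN if all
  corrupted; non-monotone patterns are logged).
* B0 maps: per-voxel linear fit of phase vs TE. The default TE grid
  {1.6, 2.1, 2.6, 3.6, 4.6, 6.6, 8.6, 10.6} ms is non-uniform, so naive
  sequential unwrapping aliases above ~250 Hz across the 2-ms gaps; the
  implementation first estimates the slope from the closest-spaced echo
  pair (unambiguous to +-1 kHz at 0.5-ms spacing) and then anchors every
  echo's wrap integer to that model. Homogeneity is the standard deviation
  of the shift inside an ellipsoid ROI given in 0-based voxel coordinates.
* B1+ maps: per-voxel nonlinear fit of `A |sin(c alpha)|` over the
  10-180 deg flip-angle series; flat or non-convergent voxels are masked.
* Eddy curves: power integral and first-sample phase normalized to the
  2-s-delay reference; a zero reference phase falls back to difference
  normalization (offset to 1) with a warning.
* Interleaving: slices every `TR/n_slices`; each gap's stimulation window
  opens after the acquisition and closes `required_delay` before the next.

## Acoustics

Peak SPL is the mean across pulses of `20 log10(|p|_max / 20 uPa)` using
absolute instantaneous pressure (Z-weighted, i.e. unweighted). Spectra
window 3 ms before to 40 ms after a pulse, Tukey-tapered (ratio 0.1), and
partition the spectral energy into 1/3-octave bands at the base-10
preferred centre frequencies (band edges `fc * 10^(+-1/20)`, 20 Hz-20 kHz)
by exact FFT-bin summation. The partition conserves energy by
construction; time-domain 6-pole band-pass sections were measured to
overcount total energy by ~3% at band centres through band overlap, which
is why the partition route was chosen. The earplug (dampener) correction
is the mean without-minus-with SPL difference over matched stimulus
settings, applied additively.

## MEP pipeline

Continuous EMG is blanked by linear interpolation from the last
pre-stimulus sample to 2 ms after each marker (a documented stand-in for
commercial decay-model artifact removal) and band-pass filtered 15-1000 Hz
with a zero-phase 3rd-order Butterworth cascade (zero-phase preserves
latency). Epochs span [-5, 20) ms; rejection discards epochs with MEP
window (5-20 ms) peak-to-peak below 10 uV or baseline peak-to-peak above
100 uV (a configurable numeric proxy for visual screening of artifacts
and heartbeats). Latency is automated as the first post-stimulus run of
rectified signal above baseline mean + 3 SD lasting at least 1 ms; a run
must also reach 10% of the response maximum, which rejects the faint
non-causal pre-ringing of the zero-phase filter, and a manual-override
field is provided since the published analysis annotated latencies by
hand. The RMT staircase descends in 1% MSO steps from a suprathreshold
start and returns the lowest intensity with >= 3 of 6 responses.
Orientation tuning reports medians and seeded 2000-resample bootstrap
percentile CIs over the -135..180 deg grid in 45-deg steps.

## Synthetic data

Generators mirror each analysis: complex-exponential FIDs (T2* 5 ms,
optional 122-Hz shift, pulse ring-down attenuation below the corruption
threshold up to a configurable cutoff, exponentially decaying eddy
frequency modulation with tau = 0.3 ms), wrapped multi-echo phase and
flip-angle magnitude stacks, EMG with a Gaussian-windowed 250-Hz biphasic
MEP template, decaying stimulus artifact and per-orientation amplitude
laws, and damped-oscillation acoustic pulse trains normalized to an exact
peak pressure. One global seed fans out to named per-scenario substreams
(SeedSequence spawn keys), so adding scenarios never perturbs existing
fixtures, and identical configurations are bit-identical. The generators
emulate signal structure, not receiver-chain physics: passing recovery
tests demonstrates correctness of the analysis code, not performance on
real recordings with colored noise, drift, or motion.

## Problem sizes and runtime

The default design pipeline (2562-vertex sphere, 1953-vertex formers, two
two-pass QP solves) completes in about 4 minutes on one CPU core; the test
suite runs it once as a session fixture. Unit tests use a 642-vertex
sphere and 100-800-vertex formers. The BEM cross-check runs at the full
2562-vertex resolution.

## Known limitations

* The minimum-energy optimum under the stated constraints concentrates
  the winding within a ~10-cm footprint; the manufactured array's windings
  span the full former, and its measured inductance (12.7/16.7 uH) and
  resistance (122/133 mOhm) are several-fold larger than this model's
  values for the idealized windings. The published method description does
  not determine the winding spread, and no constraint in this pipeline
  reproduces it; inductance-dependent quantities inherit the discrepancy,
  while focality and orientation control do not.
* Litz-wire AC losses, feed leads, connection boxes and frequency-
  dependent effects are out of scope; resistance is DC solid-copper.
* The spherical conductor is an idealization: no realistic rat-head
  geometry, anisotropy, or tissue heterogeneity.
* The acoustic model knows nothing about the measurement tube's transfer
  function; calibration is assumed to embed it.
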