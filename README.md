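# mtmskit

Design and characterization toolkit for multi-coil transcranial magnetic
stimulation (mTMS) arrays operating inside preclinical ultra-high-field MRI
scanners.

Concurrent TMS and fMRI in small animals requires a stimulation coil array
that fits a narrow scanner bore, steers the induced electric field
electronically (no mechanical repositioning inside the magnet), and
provably does not corrupt the MR measurement. `mtmskit` implements the
computational side of such a system for an anesthetized-rat setting:

* **Coil-array design** — a two-coil array is synthesized by minimum-energy
  surface-current optimization: the stream function `psi` on a rectangular
  former minimizes the magnetic energy `1/2 psi' L psi` subject to
  reproducing the peak E-field of a 35-mm figure-of-eight reference coil on
  a 13.7-mm spherical rat cortex model (field shape within a tolerance
  band, surface current bounded by wire density). The two optimized
  streams (formers at 15 and 20 mm from the cortex) are orthogonalized by
  SVD and contoured into 14 isolines, yielding two orthogonal
  figure-of-eight windings with seven turns per wing.
* **E-field simulation** — closed-form induced E-field of any winding or
  stream function in a spherically symmetric conductor, via the
  reciprocity between magnetic lead fields (Sarvas solution) and inductive
  stimulation; Neumann-formula inductance and DC resistance.
* **Stimulus targeting** — trapezoidal monophasic pulse model and
  two-channel orientation calibration: the stimulus orientation is rotated
  electronically with better-than-1-degree accuracy by reweighting the two
  coils' currents.
* **Characterization analyses** — focality (full width at 1/sqrt(2) of the
  peak |E| along geodesic profiles), FID power-spectrum corruption and
  minimum artifact-free delays, B0 / B1+ field mapping, eddy-current
  recovery curves, pulse/slice interleaving planning, Z-weighted peak SPL
  and 1/3-octave spectra, and a motor-evoked-potential (MEP) pipeline with
  rejection rules, latency extraction, resting-motor-threshold staircase
  and orientation-tuning statistics.
* **Synthetic data** — seeded generators with known ground truth for every
  analysis above.

## Worked example

Design the default array and inspect it (about 4 minutes on one core):

```python
from mtmskit.design import design_two_coil_array

bottom, top, report = design_two_coil_array()
print(report.n_loops)            # {'bottom': 14, 'top': 14}
print(report.focality_perp_mm)   # {'bottom': 10.83, 'top': 10.95}
print(report.focality_par_mm)    # {'bottom': 23.91, 'top': 23.79}
print(report.inductance_uH)      # {'bottom': 2.65, 'top': 2.22}
```

Each winding has 14 closed turns (seven per wing, opposite polarities).
The bottom coil's simulated field on the rat cortex sphere has a
perpendicular focality of 10.8 mm and a parallel focality of 23.9 mm —
the array stimulates a cortical patch comparable to the commercial rodent
coil it was matched against, despite being flat and bore-compatible. The
inductance of the idealized winding geometry is 2.65 uH (see
`docs/methods.md` for why the manufactured article, with litz wire, leads
and plate-spanning windings, measures higher).

Electronic orientation control from the two unit fields:

```python
from mtmskit.efield import efield_segments
from mtmskit.geometry import SphericalHeadModel
from mtmskit.pulse import calibrate_orientation, orientation_sweep_error

head = SphericalHeadModel.at_standoff(0.0137, 0.015)
eb = efield_segments(bottom, head, head.cortex_mesh.vertices)
et = efield_segments(top, head, head.cortex_mesh.vertices)
cal = calibrate_orientation(eb, et)
err, _ = orientation_sweep_error(cal)
print(f"max orientation error over 360 deg: {err:.2e} deg")
# max orientation error over 360 deg: 5.68e-14 deg
```

Interleaving a pulse train with an EPI readout (TR 2000 ms, 15 slices,
40-ms slice acquisition, 40-ms post-pulse delay):

```python
from mtmskit.mri_qa import plan_interleaving

plan = plan_interleaving(2000, 15, 40, 40)
print(plan.slice_interval_ms)  # 133.33 ms between slice starts
print(plan.window_length_ms)   # 53.33 ms usable per gap
```

The same operations are available from the shell:

```bash
mtmskit design --out out/          # windings + report JSON
mtmskit plan --tr 2000 --slices 15 --delay 40 --out plan.json
mtmskit synth --scenario emg --out fixtures/
mtmskit mep --emg fixtures/emg.csv --markers fixtures/markers.csv --out mep.json
```

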