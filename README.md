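# hpepi

Metabolite-specific EPI of hyperpolarized [1-¹³C]pyruvate at 4.7 T, as
a fully simulated, desk-scale experiment.

Hyperpolarization boosts ¹³C MR signal by ~10⁵, enough to image the
conversion of injected [1-¹³C]pyruvate into [1-¹³C]lactate in vivo —
but the polarization is non-renewable: it decays with T1 (~65 s for
pyruvate at 4.7 T) and every RF excitation consumes part of it.
Metabolite-specific imaging answers this with spectral-spatial RF
(SSRF) pulses that excite a single resonance within a chosen slice, so
a single-shot flyback EPI readout yields one metabolite image per
excitation, with independent flip angles per metabolite: a gentle 20°
on the pyruvate substrate (preserving magnetization for conversion)
and a full 90° on the lactate product (maximizing its SNR). At
50.7 MHz the spins of interest sit close together — relative to
pyruvate (172.0 ppm): alanine +5.7 ppm (+288.99 Hz), pyruvate hydrate
+8.4 ppm (+425.88 Hz), lactate +12.3 ppm (+623.61 Hz) — so each pulse
must pass a ±0.5 ppm band at ≤1% ripple while rejecting its neighbors
to ≤1% excitation.

`hpepi` implements this whole method chain as a virtual experiment,
for people developing or teaching HP ¹³C methodology without scanner
time:

- **SSRF pulse design** — spectral FIR filter (iteratively reweighted
  complex least squares, flip-angle-aware ripple mapping) weighting a
  train of slice-selective sub-pulses on a flyback gradient train,
  under gradient amplitude/slew and B1 limits.
- **Bloch simulation** — independent hard-pulse simulator for profile
  verification, flip calibration and band metrics, plus an emulation
  of the swept center-frequency profile *measurement* (±600 Hz).
- **Digital rat phantom** — liver/kidneys/chest/vasculature/urea-vial
  compartments, smooth B0 map, gamma-variate inflow and unidirectional
  pyruvate→lactate exchange (kPL) with RF consumption bookkeeping.
- **Virtual scanner** — dynamic flyback EPI (16×16, 80 mm FOV, every
  3 s for 60 s), dynamic CSI (8×8, 10° hard pulse, 25 kHz/2048 pts,
  TR 82 ms, 64 excitations per frame), and the 5° slab pre-scan.
- **Reconstruction** — EPI FFT with subvoxel chemical-shift
  displacement correction (fraction of the per-dimension imaging
  bandwidth), CSI apodization (12 Hz) + peak-height metabolite maps in
  SNR units, ROI curves, kPL fitting.
- **Autocalibration** — finds the pyruvate resonance in the slab
  spectrum (tallest in-window peak, parabolic sub-bin refinement),
  retunes the carrier and derives both pulse offsets and recon shifts
  from the fixed pyruvate–lactate separation.

## Worked example

Design the pyruvate-selective pulse from the packaged configuration
and verify it with the Bloch simulator:

```python
import numpy as np
from hpepi import (load_config, design_ssrf_pulse, simulate_profile,
                   measure_flip, measure_band_metrics, ppm_to_hz)

cfg = load_config()
field = cfg.field                     # 4.7 T, 50.7 MHz, 1070.8 Hz/G
pulse = design_ssrf_pulse(cfg.design_spec_for("pyruvate"), field,
                          metabolite="pyruvate")

f = np.linspace(-700, 700, 2801)      # Hz from the pyruvate carrier
prof = simulate_profile(pulse, np.array([0.0]), f, field)
spec = cfg.design_spec_for("pyruvate")
ph = ppm_to_hz(0.5, field)
stops = [(ppm_to_hz(c - h, field), ppm_to_hz(c + h, field))
         for c, h in spec.stopbands_ppm]
m = measure_band_metrics(prof, (-ph, ph), stops, pulse.flip)
print(f"flip at center   : {measure_flip(prof):.2f} deg")
print(f"passband ripple  : {100*m.pass_ripple:.2f} %")
print(f"stopband ripple  : {100*max(m.stop_ripple):.2f} %")
print(f"passband width   : +/-{m.pass_halfwidth_hz/field.f0:.2f} ppm "
      "at the 1% criterion")
```

prints

```
flip at center   : 20.00 deg
passband ripple  : 0.60 %
stopband ripple  : 0.34 %
passband width   : +/-0.62 ppm at the 1% criterion
```

i.e. the pulse delivers its nominal 20° on resonance, stays within
0.6% of uniform excitation across the ±0.5 ppm passband (in fact out
to ±0.62 ppm), and excites alanine, pyruvate hydrate and lactate at
≤0.34% of full excitation — they are invisible in the pyruvate image.

The same is available from the shell:

```sh
$ hpepi design --metabolite pyruvate --out out/
pyruvate: 10 sub-pulses, 11.22 ms, B1peak 0.121 G -> out/waveforms/pyruvate_rf.txt
$ hpepi design --metabolite lactate --out out/
lactate: 10 sub-pulses, 12.45 ms, B1peak 0.251 G -> out/waveforms/lactate_rf.txt
```

`hpepi run --seed 1 --out out/` executes the full virtual experiment
(design → profile QC → phantom → slab pre-scan + autocalibration →
dynamic EPI and CSI → reconstruction → ROI curves) and writes
waveforms, HDF5 raw data, NIfTI metabolite image series and an
HTML/PNG report. Other subcommands (`profile`, `phantom`, `scan`,
`recon`, `autocal`) run individual stages; see `hpepi --help`.

## Layout

| module | role |
| --- | --- |
| `hpepi.core` | field parameters, metabolite table, geometry, ppm↔Hz |
| `hpepi.pulses` | SSRF design: spectral filter, sub-pulse, assembly, flip scaling |
| `hpepi.bloch` | Bloch simulator, profile metrics, regridding |
| `hpepi.phantom` | digital rat phantom, exchange dynamics, kPL fitting |
| `hpepi.scanner` | flyback trajectory, EPI/CSI/slab acquisition, profile sweep |
| `hpepi.recon` | EPI/CSI reconstruction, displacement correction, ROI curves |
| `hpepi.calibrate` | slab-spectrum peak finding, offset computation, autocal pipeline |
| `hpepi.config` / `hpepi.experiment` / `hpepi.cli` | configuration, orchestration, CLI |
| `hpepi.io` / `hpepi.report` | text/HDF5/NIfTI formats, report figures |

The model details, parameter defaults and their rationale, numerical
choices, and known limitations are documented in
[`docs/methods.md`](docs/methods.md).
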