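# Default run configuration: a desk-scale virtual experiment mirroring a
# metabolite-specific hyperpolarized [1-13C]pyruvate EPI study at 4.7 T.
# All values are config-exposed; see docs/methods.md for rationale.

field:
  b0: 4.7          # tesla
  f0: 50.7         # MHz (Hz per ppm)
  gamma: 1070.8    # Hz/G, 13C
  b1_max: 2.0      # G, volume-coil transmit limit

# ppm position of the scanner carrier before autocalibration; the
# calibration stage retunes it onto the detected pyruvate resonance.
carrier_ppm: 172.0

metabolites:
  pyruvate:         {shift_ppm: 172.0, t1: 65.0, t2: 0.1}
  lactate:          {shift_ppm: 184.3, t1: 33.0, t2: 0.1}
  alanine:          {shift_ppm: 177.7, t1: 40.0, t2: 0.1}
  pyruvate_hydrate: {shift_ppm: 180.4, t1: 40.0, t2: 0.1}
  urea:             {shift_ppm: 163.5, t1: 44.0, t2: 0.1}

# Spectral-spatial excitation pulse designs.  Stopbands are placed on the
# listed species, each +/- stop_halfwidth_ppm wide.
pulse_design:
  pass_halfwidth_ppm: 0.5
  stop_halfwidth_ppm: 0.5
  tbw_spectral: 3.5
  max_ripple: 0.01
  slice_thickness: 20.0    # mm
  tbw_spatial: 4.0
  grad_max: 10.0           # G/cm
  slew_max: 50.0           # G/cm/ms
  dwell: 4.0e-6            # s, waveform raster
  max_duration: 0.025      # s, designer gives up beyond this

pulses:
  pyruvate:
    flip: 20.0
    stopband_targets: [alanine, pyruvate_hydrate, lactate]
  lactate:
    flip: 90.0
    stopband_targets: [pyruvate, alanine, pyruvate_hydrate]

epi:
  matrix: [16, 16]
  fov: [80.0, 80.0]        # mm
  slice_thickness: 20.0    # mm
  read_grad: 5.0           # G/cm readout plateau amplitude
  noise_sigma: 0.002       # complex k-space noise std, polarization units

schedule:
  interval: 3.0            # s between metabolite image pairs
  duration: 60.0           # s of dynamic imaging
  start_delay: 20.0        # s after injection start before imaging
  flips: {pyruvate: 20.0, lactate: 90.0}

csi:
  matrix: [8, 8]
  fov: [80.0, 80.0]
  flip: 10.0               # degrees, hard pulse
  sw: 25000.0              # Hz spectral bandwidth
  n_points: 2048
  tr: 0.082                # s
  n_frames: 6
  noise_sigma: 0.002

slab:
  flip: 5.0                # degrees
  sw: 10000.0              # Hz
  n_points: 2048
  noise_sigma: 0.0005

phantom:
  matrix: [32, 32]
  fov: [80.0, 80.0]
  slice_thickness: 20.0
  b0_rms: 15.0             # Hz over the body
  b0_max: 60.0             # Hz clip
  b0_corr_mm: 12.0         # correlation length of the smooth field
  chest_offset_hz: 60.0    # extra chest off-resonance (illustrative)
  kpl_tissue: 0.02         # 1/s pyruvate->lactate, liver/chest
  kpl_kidney: 0.05         # 1/s, kidneys
  t2star: 0.03             # s, FID decay for spectroscopy
  urea_signal: 0.2         # thermal urea vial amplitude, polarization units
  inflow: {amplitude: 1.0, delay: 0.0, shape: 3.0, scale: 4.0}

calibration:
  search_halfwidth_hz: 300.0
  min_snr: 5.0

recon:
  apodization_hz: 12.0     # exponential line broadening for CSI
  window_halfwidth_ppm: 1.5

profile_qc:
  sweep_hz: 600.0
  n_steps: 121
  z_range_cm: 3.0
  n_z: 121

seed: 0
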