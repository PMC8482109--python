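# Methods

`hpepi` is a desk-scale virtual experiment for metabolite-specific
imaging of hyperpolarized (HP) [1-¹³C]pyruvate and its downstream
product [1-¹³C]lactate at 4.7 T (¹³C carrier 50.7 MHz, so 1 ppm =
50.7 Hz). It reproduces the full method chain of such an experiment in
simulation: spectral-spatial RF (SSRF) pulse design, Bloch-simulated
and "measured" excitation-profile verification, a synthetic rat-abdomen
phantom with two-site exchange dynamics, flyback-EPI and CSI
acquisition under a finite polarization budget, reconstruction with
chemical-shift displacement correction, and an automated center-
frequency calibration. This note records the models, the parameters
that matter, and the design decisions taken where the problem was
genuinely open.

## Field and spin system

The carrier frequency is fixed at the printed 50.7 MHz and governs all
ppm↔Hz conversions, even though γ(¹³C)·4.7 T ≈ 50.3 MHz; using one
self-consistent value keeps every band placement and displacement
calculation exact. Chemical shifts: pyruvate 172.0 ppm, alanine
177.7 ppm, pyruvate hydrate 180.4 ppm, lactate 184.3 ppm; relative to
pyruvate these are +288.99, +425.88 and +623.61 Hz. The urea reference
vial is placed at 163.5 ppm (−430.95 Hz), a configurable default —
the vial is only a fixture for phantom realism and calibration
plausibility, so its exact shift is immaterial to any quantitative
path. Pyruvate T1 defaults to 65 s (aqueous solution at 4.7 T); lactate
T1 to 33 s (literature-typical, not printed anywhere authoritative for
this system); T2 defaults of 0.1 s and a spectroscopic T2* of 30 ms
(~10 Hz linewidths) are synthetic-model parameters, all exposed in the
packaged YAML configuration.

## SSRF pulse design

An SSRF pulse is a train of slice-selective sub-pulses on the flat-tops
of a flyback gradient train. The k-th sub-pulse is weighted by tap k of
a spectral FIR filter; because sub-pulses repeat every τ seconds, the
spectral response is the filter's discrete-time response at sample rate
fs = 1/τ, periodic in frequency with fs.

**Spatial sub-pulse.** Hamming-windowed sinc, spatial time-bandwidth
4, over a trapezoidal lobe obeying the gradient limits (defaults
10 G/cm and 50 G/cm/ms — small-animal class; the true hardware numbers
are not public, so pulse durations can only be matched to a published
design within a band). The slice equation is
G = TBW/(γ·t_flat·Δz); a 20 mm slice is the default. Flyback
rewinders are minimum-time trapezoids; a final lobe refocuses the
through-slice phase accrued from each flat-top center.

**Flat-top selection.** Two competing pressures set the sub-pulse
period: a short τ raises fs (keeping far stopbands inside one spectral
period), while a long flat-top lowers the peak B1. The designer takes
the longest flat-top whose fs still keeps every stopband — after
folding into the fundamental period — at least the unaliased transition
width away from the passband. Folding is not an approximation: the
physical response is periodic, so a stopband beyond Nyquist is
controlled at its aliased position. This yields τ ≈ 1.09 ms
(fs ≈ 916 Hz) for the pyruvate pulse and τ ≈ 1.22 ms (fs ≈ 822 Hz) for
lactate, with B1 peaks of ≈0.12 and ≈0.25 G against a 2 G coil limit.

**Spectral filter.** Complex least-squares with per-band
tolerance-scaled weights, driven toward minimax by Lawson-style
iterative reweighting (40 iterations, update factors clipped to
[0.3, 3]); a 1e-6-scaled ridge tames the don't-care regions. The
passband (±0.5 ppm) targets unity; stopbands (±0.5 ppm around each
rejected species) target zero. The finite sub-pulse envelope multiplies
the tap response; the design compensates for it in the passband.
Tolerances are specified on the magnetization (|Mxy| as a fraction of
full excitation, 1% maximum ripple) and mapped through the sine
nonlinearity of the flip angle into filter-domain tolerances: at 90°
the passband tolerance relaxes to ~9% (sin is flat at its crest) while
the stopband tolerance tightens to ~0.64% (sin is steep at zero). A
fixed 0.8 design margin between the filter-domain targets and the
magnetization spec absorbs large-tip distortion.

**Tap count and flip scaling.** The sub-pulse count starts at the
spectral time-bandwidth bound n ≥ TBW/(2·τ·f_trans) (TBW 3.5, f_trans
the nearest stopband edge) and increases until both the dense-grid
filter check and the final arbiter — a Bloch simulation of the
assembled, flip-scaled pulse — meet the 1% magnetization ripple in
every band; ties break toward shorter pulses. Amplitude scaling to the
target flip (20° pyruvate / 90° lactate) is a fixed-point iteration on
the Bloch-measured slice-center flip (≤20 iterations, 0.05°
tolerance); one step suffices in the small-tip regime.

**Durations.** The designer lands at 10 sub-pulses for both pulses:
11.2 ms (pyruvate) and 12.5 ms (lactate). A 20° pyruvate pulse in the
6–7 ms range is incompatible with ≤1% pass- and stopband ripple over
±0.5 ppm bands: the alanine stopband sits only ≈238 Hz from the
passband edge, and the equiripple transition bound then forces
T ≳ 9 ms for any hardware (duration ≈ D(δp,δs)/Δf + τ, independent of
gradient strength). Empirically the minimax ripple crosses 1% between
9 and 10 taps at fs ≈ 916 Hz. The ripple/flip/passband specifications
are treated as hard and the duration as the free consequence; the test
suite documents the pyruvate-duration band as a known, explained
deviation rather than relaxing the selectivity.

## Bloch simulation

Hard-pulse (piecewise-constant) rotations at the waveform dwell
(4 µs), composed by Rodrigues rotation about the effective field
b = (γ·ReB1, γ·ImB1, γ·G·z + f) in Hz; positive off-resonance
precesses transverse magnetization counterclockwise about +z.
Relaxation during the pulse is neglected (millisecond pulses versus
multi-second T1/T2), so |M| is conserved to rounding; because the
waveform is piecewise constant, sub-sampling the dwell reproduces the
result exactly rather than merely converging. Default verification
grids: z ∈ [−3, 3] cm, f ∈ [−600, 600] Hz (the profile-measurement
sweep range), with denser 0.5 Hz grids for band metrics.

Band metrics define the excitation fraction as |Mxy|/sin(flip
nominal); passband ripple is max|fraction−1| over the band, stopband
ripple the maximum fraction, and the passband half-width the largest
symmetric interval on the grid over which the ripple criterion holds.

**Profile "measurement".** The swept-frequency emulation of a 1D
profile sequence retunes the pulse in steps across ±600 Hz, plays it on
a long uniform cylinder (8 cm, exceeding the ±3 cm plotted range), and
records the spatial projection magnitude per step; a pulse centered
+df above carrier excites spins at −df, so columns are stored
frequency-reversed. Measured maps are bilinearly regridded onto the
simulation grids before comparison. The two paths share the rotation
kernel but differ in how off-resonance enters (RF phase modulation
versus bz term), so their RMS agreement (≪5% of peak) is a real
cross-check of the modulation, projection and regridding machinery.

## Synthetic phantom and HP dynamics

The phantom is a 2D coronal cartoon on an 80×80 mm² FOV: body ellipse,
chest, liver, two kidneys, a central vascular column, and a urea vial
outside the body. Ellipse positions get ±1% seed-controlled jitter;
priority carving keeps compartments pairwise disjoint. The B0 map is
Gaussian noise smoothed to a 12 mm correlation length, scaled to
15 Hz RMS over the body, clipped at ±60 Hz, and zeroed outside the
object; the chest additionally carries a +60 Hz offset — an
illustrative (not mechanistic) stand-in for susceptibility effects that
push chest signal outside the SSRF passband while leaving it inside the
CSI spectral windows.

Dynamics are unidirectional two-site exchange with a gamma-variate
arterial input peaking at 12 s (shape 3, scale 4 s, matching a ~12 s
injection): dMp/dt = w·i(t) − Mp/T1p − kpl·Mp and
dMl/dt = kpl·Mp − Ml/T1l, with kpl = 0.02 s⁻¹ in liver/chest and
0.05 s⁻¹ in kidney, perfusion weights 1.0/0.8/0.6/0.4 for
vessel/kidney/liver/chest. All kinetic parameters are synthetic
choices in a physiologically plausible range; nothing here claims to
reproduce any animal's data. The propagator is exact for the
homogeneous part (lower-triangular matrix exponential in closed form,
with the degenerate equal-rate limit handled explicitly); the inflow is
piecewise-constant over ≤0.25 s substeps, which is exact whenever
inflow is zero — the regime of every closed-form test. RF consumption
is per-voxel: signal mz·sin(θw), remainder mz·cos(θw), with w the
excitation weight from the pulse's Bloch profile at the voxel's
metabolite + B0 offset. The urea vial is thermally polarized with a
Gd-shortened T1, modeled as constant mz (instant recovery between
excitations).

Parameter recovery fits kpl (with a free amplitude absorbing
polarization level) by bounded least squares on log-kpl against the
same propagator; noiseless curves return the generating rate to
machine-level accuracy, and at SNR 20 within a few percent.

## Virtual scanner

**Flyback EPI.** 16×16 matrix over 80×80 mm² (5 mm in-plane), 20 mm
slice. The trajectory is built analytically: sample m of line p sits
exactly on the Cartesian point (index − N/2)·Δk with Δk = 1/FOV,
acquired on the plateau of same-polarity readout lobes (5 G/cm default,
ADC dwell Δk/(γG) ≈ 23 µs → read bandwidth ≈ 43 kHz; echo spacing
≈ 1.03 ms → phase bandwidth ≈ 975 Hz; ≈16.4 ms per image, inside the
~100 ms per-image budget). Raw data are explicit Fourier sums over
phantom voxels with per-sample off-resonance phase exp(i2πΔf·t) and T2
decay, plus complex white Gaussian noise — so chemical-shift
displacement emerges from the sampling physics. Dynamic imaging
alternates pyruvate (20°) and lactate (90°) frames, pyruvate first,
every 3 s for 60 s (20 frames per metabolite), starting 20 s after
injection; the state evolves through the exchange model between
excitations. The intra-pair gap (interval/2) is a convention of this
implementation.

**CSI.** 8×8 over the same FOV (10 mm in-plane), 10° hard pulse per
phase encode, 25 kHz / 2048 points, TR 82 ms: 64 excitations per frame
(frame period 5.248 s), six frames. Every species, including urea, is
excited nonselectively; each excitation consumes cos(10°) of every
HP species' mz and the state evolves by TR between encodes, so the
intra-frame amplitude decay (k-space filtering) and the short signal
lifetime of CSI arise naturally: after six frames RF alone leaves
cos(10°)^384 ≈ 0.28% of the initial polarization, versus
cos(20°)^20 ≈ 28.8% after twenty EPI pyruvate excitations — the
in-model, quantitative form of the EPI-versus-CSI lifetime comparison.
(The in vivo dynamic curves themselves are animal data and are not
reproducible; this budget property is the substitute.)

**Slab pre-scan.** Single 5° excitation of the object excluding the
chest (the axial slab including liver and kidneys), 10 kHz / 2048
points (4.883 Hz bins), summed FID of all in-slab species.

## Reconstruction

EPI frames are inverse-FFT'd with DC at index N/2 (phase-encode axis
first). An off-resonance species appears translated by −(df/bw)·FOV in
each dimension (readout bandwidth along read, 1/esp along phase, the
sign fixed by the exp(+i2πdf·t) acquisition phase against the
exp(−i2πk·r) encoding); the correction applies the opposite
translation as a subvoxel circular Fourier-domain shift. With the
carrier retuned onto pyruvate and each passband centered on its own
metabolite, the correction frequencies are zero and the machinery is
exercised by directed off-resonance tests (a source offset by the
623.61 Hz lactate–pyruvate separation is restored to <0.1 voxel).
Magnitude images are divided by the image-domain noise std propagated
from the known k-space σ (σ/√N_total for the backward-normalized FFT),
giving SNR units; pure-noise images average to the Rayleigh mean
≈1.25.

CSI: spatial inverse DFT over the phase encodes, 12 Hz exponential
apodization exp(−π·lb·t) (adds lb Hz to a Lorentzian FWHM), spectral
FFT, magnitude; each metabolite map is the peak height (maximum
magnitude) in a ±1.5 ppm window around its resonance — windows stay
disjoint because the closest pair of mapped species is ≥3.9 ppm apart.
The noise σ is estimated from the outer 10% of the spectral axis via
the Rayleigh-scaled median of the magnitude. ROI curves are mask means
per timepoint, with block-average mask resampling from the phantom grid
to acquisition grids.

## Center-frequency calibration

The slab magnitude spectrum is searched within ±300 Hz of the nominal
pyruvate position (generous against plausible B0 offsets, and excluding
urea at −431 Hz); the tallest in-window local maximum is refined by
3-point parabolic interpolation (sub-bin on Lorentzian lines,
deterministic), with an SNR gate (default 5) against the spectral-edge
noise floor — below it, calibration fails and no imaging is triggered.
Lactate is never detected directly: its pulse offset is the fixed
+623.61 Hz separation from the detected pyruvate frequency, because
early post-injection lactate is too weak to identify reliably at a 5°
flip. Retuning moves the carrier onto pyruvate; both pulse offsets and
the (zero) reconstruction shifts follow. Injected global shifts across
±300 Hz are recovered to well under one 4.883 Hz bin, and
autocalibrated EPI positions agree with unshifted ground truth to
<0.1 voxel.

## Configuration, determinism, problem sizes

All physical and protocol parameters live in one packaged YAML file;
user files override it with strict unknown-key rejection. A single seed
feeds a `SeedSequence` from which the phantom, each acquisition's noise
stream, and any other stochastic stage draw; deterministic stages are
bit-reproducible for a given (config, seed).

Default problem sizes keep a full run to a few minutes on one core:
32×32 phantom grid, 121×121 profile-QC grids, 16×16 EPI / 8×8 CSI. The
test suite uses a 16×16 phantom and coarser QC sweeps; these sizes are
accuracy-neutral choices for a Fourier-complete simulation (acquisition
sums are exact DFTs at any grid size).

## What the synthetic data do and do not show

Passing tests demonstrate internal physical consistency: selectivity
and flip calibration verified against an independent Bloch oracle,
Fourier/off-resonance bookkeeping closed end to end, magnetization
budgets matching closed forms, calibration recovering injected shifts.
They do not validate the kinetic parameter values, coil/amplifier
behavior, motion, flow, B1 inhomogeneity, or any in vivo amplitude —
the phantom has no such physics, and the report's resemblance to real
rodent images is qualitative only.

## Known limitations

- No relaxation during RF pulses; no B1 maps or adiabatic designs.
- 2D only; through-plane selection reduces to mask weights.
- Flyback sampling on plateaus only; no ramp sampling, gradient
  delays, eddy currents or ghosting (the flyback choice makes the
  latter moot by construction).
- The EPI excitation weight treats only the pulse's named metabolite;
  sub-1% stopband leakage of other species into a frame is neglected.
- Chest-conspicuity contrast between CSI and EPI is an illustrative
  configuration, not a validated susceptibility model.
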