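# Methods

This note documents the models, estimators and design choices behind
`ckcnet`, in the spirit of a package methods appendix. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Detection model

The paradigm assumes a steady-state cortical response phase-locked to a
periodic proprioceptive stimulus delivered at 1.78 Hz, concentrated at its
first harmonic 3.56 Hz (two afferent volleys per inflate/deflate cycle).
Detection asks, per EEG channel: is the instantaneous phase at 3.56 Hz
reproducible across stimulus-locked epochs?

**Preprocessing.** High-pass 0.5 Hz and low-pass 30 Hz Butterworth filters
(order 5), each applied forward and reverse for zero phase. Because the
high-pass corner is far below typical acquisition rates, reflection
padding of about three filter time constants (`padlen_for`) is used
instead of scipy's short default — with the default padding, boundary
transients leak several seconds into the signal. After filtering the data
are resampled to 250 Hz by a polyphase resampler; trigger times are kept
in seconds throughout so resampling never shifts them.

**Epoching.** 1,100 ms windows from −200 to +900 ms around each trigger,
non-overlapping. The selection is greedy earliest-first: scanning triggers
in time order, a trigger is accepted iff its window fits inside the
recording and starts at or after the end of the last accepted window. For
jitter-free 1.78 Hz triggers this accepts every second trigger (one epoch
per ~1.124 s); the enumeration oracle in the tests gives exactly 213
epochs for a 240 s recording. Each epoch is detrended by subtracting its
per-channel mean. Optional amplitude rejection drops epochs exceeding a
configurable absolute threshold (default 250 µV); the threshold is a
config value, not a claim about any particular dataset.

**CSD.** The spherical-spline surface Laplacian (flexibility m = 3, no
smoothing λ = 0, 50 Legendre terms, single sphere of radius 9.2 cm —
an infant-sized head) converts scalp potentials to reference-free current
source density in µV/m². The operator is a fixed matrix per montage;
λ = 0 is used exactly, and an ill-conditioned spline system raises rather
than silently regularising. The implementation is validated against an
independent spherical-spline CSD implementation (MNE-Python) to better
than 1 %.

**Wavelet bank and the CKC metric.** 40 log-spaced complex Morlet kernels
span 0.5–12 Hz with the bin nearest 3.56 Hz replaced by exactly 3.56 Hz.
A constant cycle count n_cycles = 7.0 is used across bins; at the pinned
bin this yields a temporal FWHM of ~737 ms and spectral FWHM of ~1.20 Hz
at 250 Hz sampling — the spectral-resolution-first regime (the two
published calibration values, 740 ms × 1.18 Hz, are mutually inconsistent
with an exact Gaussian product by about 1 %, hence the ±2 % test
tolerance; n_cycles follows from the closed form
2π·f·FWHM_t / 2.355 ≈ 7.08). Kernels are truncated at ±4 temporal SDs and
unit-energy normalised. Epochs are shorter than the pinned kernel, so
convolution is zero-padded and cropped ('same'); the CKC metric therefore
averages ITC only over [0, 700] ms, excluding 200 ms at each epoch edge.
Channel significance is the arithmetic mean of the per-sample Rayleigh P
values over that window (deliberately the mean, not a Fisher-type
combination), thresholded at α = 0.01 with BH-FDR across channels at
q = 0.01. Zero-magnitude wavelet coefficients yield NaN phases rather than
arbitrary angles.

Averaging P over a window of strongly smoothed (hence correlated) samples
makes the end-to-end channel test *conservative* on temporally smooth null
data: with no response embedded, the measured per-channel rate at α = 0.01
is well below 0.01 (the suite asserts it never exceeds the nominal band).
The exact calibration of the underlying statistic is verified separately:
for per-trial phases constant over the window, the aggregated P reduces to
the plain Rayleigh test, whose empirical type-I rate over 2,100 simulated
channels falls in [0.002, 0.025]. The Rayleigh closed form itself is
checked against a 10⁶-draw uniform-phase Monte-Carlo at ITC ∈ {0.1, 0.2,
0.3} × N ∈ {50, 200} within 15 % relative — except (0.3, 200), whose tail
probability (~10⁻⁸) lies beyond Monte-Carlo resolution at that draw count.

**FFT variant.** Epochs are zero-padded to a bin spacing ≤ 0.25 Hz, the
phase at the bin nearest 3.56 Hz is pooled across epochs into an ITC, and
the same Rayleigh/FDR machinery applies. The full (detrended) epoch is
used; unlike the wavelet path there is no kernel-edge attenuation to
exclude. On the stationary synthetic recordings the FFT variant attains
slightly *higher* peak values than the wavelet (it integrates the full
1.1 s epoch); the wavelet advantage reported on clinical recordings is
attributed to response non-stationarity, which the generator deliberately
does not emulate. The two methods' peak CKC values correlate at r > 0.97
across recordings spanning the full phase-locking range.

## Network model

**Phases.** Parcel signals (58 parcels, 29 per hemisphere, lobe labels
F/C/T/O) are filtered to 3.56 ± 0.3 Hz with forward–backward
Hamming-window FIR filters of order 626 and phases extracted by the
Hilbert transform; `fir_order` samples are discarded at each end. PTE is
computed on the continuous (non-epoched) series.

**PTE/dPTE.** For phases x, y and delay δ,

    PTE_xy = H(y_t, y_{t−δ}) + H(y_{t−δ}, x_{t−δ}) − H(y_{t−δ}) − H(y_t, y_{t−δ}, x_{t−δ})

with entropies from joint occurrence histograms (natural log; the base
cancels in dPTE). The delay is the sign-change heuristic — total samples ×
signals / total phase sign changes, ≥ 1 — and the bin count follows
Scott's rule (3.49·SD·n^(−1/3)) on the pooled phase sample; both choices
pin the histogram-estimator formulation popularised by the
Brainstorm/Hillebrand implementation. The estimator is verified against a
brute-force joint-count oracle to 10⁻¹⁰. dPTE = PTE_xy/(PTE_xy + PTE_yx)
is exactly antisymmetric around 0.5; degenerate pairs (PTE sum = 0) and
fidelity-masked pairs carry NaN and are excluded from every downstream
summary. The default fidelity mask is all-valid; a study-specific 58 × 58
0/1 mask can be supplied as CSV.

**Consistent Network.** Per subject, the ⌈k·E⌉ largest-dPTE directed edges
(k = 5 % of the E valid edges; ties broken by raw PTE, then lexicographic
order) are binarised; per-edge appearance counts across n subjects are
tested against Binomial(n, k), right tail, exact, with BH-FDR across valid
edges at α = 0.05. At n = 20 and k = 0.05 the smallest pre-FDR significant
count is 4 (P(X ≥ 3) = 0.075, P(X ≥ 4) = 0.016).

**Spreading Index.** All valid dPTE values of the subject's control
recording form the reference (μ, σ); each stimulation edge gets
z = (dPTE − μ)/σ and a right-tailed test at α = 0.01 (z > 2.326). Within
the requested hemisphere the 4 parcels with the most significant outbound
edges are the source nodes (ties by summed outbound z, then label); SI is
the percentage of significant among valid outbound edges from those
sources. Masked edges count as "not possible". The laterality input for
CKC is the hemisphere maximum channel value by default (mean available),
midline channels excluded.

## Synthetic data: what it emulates and what it does not

The scalp generator reproduces the paradigm's stimulus statistics (1.78 Hz
triggers, ISI jitter SD 2.9 ms), a 21-channel 10-20 montage at 250 Hz,
1/f background (independent per-channel traces plus a 0.3 common-mode
mixture, so the CSD has spatial structure to remove), and a response
modelled as a sinusoid at 3.56 Hz re-phased at every trigger with a
wrapped-Gaussian per-trigger phase offset (SD σ); the offsets' expected
resultant length is exp(−σ²/2), verified on the drawn phase sample.
Because the 740 ms analysis kernel spans adjacent inter-stimulus
intervals, the pipeline ITC mixes neighbouring (independent) offsets and
sits somewhat above exp(−σ²/2) for σ > 0; at σ = 0 the pipeline ITC is
exactly 1.

**Response level.** Clinical recordings do not come with a known SNR, so
the generator's default is a calibrated convention: with
`response_amplitude=None`, the sinusoid's power in the response band
equals `response_band_snr` (default 2.0) times the background power in
3.56 ± 0.5 Hz. This default was chosen as the smallest integer band-power
ratio at which the detection chain reproduces the always-detected regime
(100 % of 20 synthetic recordings significant at 100 epochs, with
aggregated P values orders of magnitude below threshold); at a ratio of
1 the same conditions detect ~95 %, and at 0.5 ~45 %. An explicit
amplitude in µV can always be supplied. Artifact waveforms are
band-limited analogues of their clinical counterparts (the ECG generator
includes 5 % beat-to-beat variability so its spectrum is smeared across
the response band rather than a line spectrum that would accidentally miss
3.56 Hz). Parcel coupling is a convex lagged mixture
(1−s)·own + s·lagged-source, re-normalised, so s = 1 is a pure lagged copy.

Not emulated: neonatal sleep architecture (tracé alternant), volume
conduction/realistic forward models, response non-stationarity, true
cardiac/respiratory physiology. Passing tests therefore demonstrate the
correctness and calibration of the estimators under controlled
conditions, not clinical performance.

## Numerical choices and problem sizes

Detection simulations use 125 s recordings (≥ 100 epochs each after
non-overlap selection) and the method-comparison experiment 175 s
(150 epochs); dPTE null and recovery experiments use 60 s pairs, with
600 s signals for the weak-coupling (strength 0.8, lag 5 samples)
direction-recovery check where the directional bias is small relative to
estimator noise at 60 s. The robustness sweep expresses artifact gain as
target RMS in CSD units and spans multiples of the clean-data RMS, since
the absolute µV/m² scale depends on head radius and spline configuration.
P values are clipped at 10⁻³⁰⁰; detection compares aggregated P to α
before FDR and reports both flags. FFT bin selection takes the nearest
bin after padding. Degenerate inputs (constant phases, zero-variance
controls, all-epochs-rejected) raise typed exceptions rather than
returning arbitrary numbers.

## Known limitations

* The dPTE direction signal for weak partial coupling is small; at 60 s
  recordings the estimator resolves pure copies reliably but needs longer
  signals (or stronger coupling) for subtler flows.
* The EDF writer emits plain 1 s-record EDF (16-bit, µV) with a
  rectangular TRIG pulse channel; the final partial second is zero-padded.
  Sampling rates must be integer for export.
* The Rayleigh approximation assumes enough trials; the package enforces
  N ≥ 2 but accuracy below ~20 trials is the user's responsibility.
* SI requires a control recording; subjects without one are skipped with
  an explicit missing-control result rather than a silent default.
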