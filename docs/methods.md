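# Methods

This note records the models, parameter choices and numerical decisions
behind the package, and what the synthetic test bed does and does not show
about real recordings.

## Signal model and preprocessing

The unit of analysis is a uniformly sampled single-lead voltage trace in
millivolt (`ECGSignal`: samples, fs, lead, t0).  All cleaning assumes a
500 Hz rate; records at other rates (e.g. 80 Hz polysomnography exports)
are polyphase-resampled to 500 Hz first so the wavelet band labels keep
their frequency meaning.  Resampled length follows `round(n·ratio)`; the
record mean is subtracted before the polyphase filter and restored after,
so the DC level survives the rate change exactly.

**Denoising.** A 10-level Daubechies-6 DWT with symmetric extension splits
the record into an approximation band A10 (≲0.24 Hz at 500 Hz) and details
D10…D1 (D1 ≈ 125–250 Hz).  Whole bands A10, D1 and D2 are zeroed and the
transform inverted — no coefficient thresholding, so the operation is
linear and deterministic.  Measured selectivity at 500 Hz: <0.1 % energy
retained at DC and above 150 Hz, >98 % through 1–40 Hz.  Feasibility of a
requested depth is bounded by n ≥ 2^levels; beyond PyWavelets' advisory
`dwt_max_level` the transform still reconstructs perfectly, it merely stops
compressing.  Symmetric extension is not orthogonal at the boundaries, so
energy accounting (Parseval checks) uses the periodized mode, which is an
exact isometry on dyadic lengths.

**Baseline wander.** The residual trend is estimated by LOESS (degree-1
local polynomial, tricube weights, weighted least squares) fitted not to
the raw trace — whose sharp QRS complexes would bias any local regression —
but to its low-frequency wavelet reconstruction (approximation plus detail
levels 8–10, i.e. everything below ≈2 Hz).  Including the approximation
band matters: a linear ramp is annihilated by the details of a
six-vanishing-moment wavelet and lives almost entirely in A10, so a
details-only fit could never remove it.  The window is **3.0 s** by
default (configurable): the smoother's passband must sit below the slowest
physiological heart rate (~0.7 Hz at 40 bpm), and shorter windows (1.5 s)
measurably track the cardiac fundamental itself, removing ~7 % of a
drift-free ECG's RMS versus <5 % at 3 s.  Local regression is biased in
its first and last half-window, so the component is padded with the OLS
line fitted over the terminal windows before smoothing — exact for linear
drift — and the pipeline additionally surrounds the whole record with 2 s
of odd-reflection padding before the wavelet stage, which suppresses the
boundary transients of both stages (a ramp continues smoothly through a
point reflection).  `clean + baseline` reproduces the input to machine
precision by construction.

## Fiducial detection

R peaks are local maxima of a curvature statistic — the squared second
difference of a 5-point-smoothed trace — above an adaptive threshold
(0.4 × the rolling 2 s maximum, floored at 0.1 × the global maximum),
separated by at least 250 ms, refined to the raw-signal maximum within
±40 ms; RR gaps exceeding 1.8 × the median trigger a re-detection pass at
half threshold.  All thresholds are relative, making detection invariant
under positive amplitude rescaling.  Per beat, Q and S are the signed
minima within 80 ms before/after R; T is the largest deviation from the
local median in (S+40 ms, S+400 ms) clipped at the next beat; P is the
maximum in (Q−250 ms, Q−40 ms) clipped past the previous T.  A wave whose
deviation from the search-window median is under 0.05 mV is reported
missing rather than guessed.  The window lengths are physiology-standard
defaults and all configurable; beats lacking the waves a split scheme needs
are dropped (and counted) before splitting.

## Splitting, embedding, projection

Segments are half-open `[start, end)`; for the R–R scheme consecutive
segments are contiguous and the shared boundary sample belongs to the later
segment.  The delay is τ = round(T/3) (half away from zero, minimum 1);
segments shorter than 9 samples (τ < 3) are dropped and logged.  The
default embedding is **circular**: index arithmetic is modulo the cycle
length, treating each cycle as one period of a periodic orbit.  This is the
mode in which the method's symmetry statements are exact: for a
single-cycle periodic segment with T divisible by 3, the orbit is invariant
under cyclic coordinate permutation (= 120° rotation about (1,1,1)), and
τ = T or 2T collapses the embedding onto the diagonal.  A truncated mode
(no wrap, T − 2τ points) is provided for comparison.  Per-cycle τ gives
split-period rescaling invariance: integer-factor resampling of a cycle
with τ scaled along moves the projected point set only by interpolation
error (measured ≪1 % of amplitude).

The projection uses the orthonormal basis u = (x−z)/√2, v = (x−2y+z)/√6,
w = (x+y+z)/√3, computed as explicit differences rather than a matrix
product so diagonal points cancel exactly.  Density maps are plain 2-D
histograms (no line rasterisation) on a 224×224 grid — sized for standard
image classifiers — with half-open bins, top edge inclusive; the default
range is adaptive, ±1.05 × max(|u|,|v|).  Normalisation is linear
(grid/max) or log (log1p ratio); an all-zero map passes through unchanged.

## Drift: what cancels and what does not

A constant offset shifts the embedded trajectory along (1,1,1) and is
cancelled exactly by the projection — density maps are bin-for-bin
identical, asserted with zero tolerance.  A linear ramp is not cancelled:
in circular mode each cycle wraps its own ramp segment, cutting the orbit
into displaced arcs.  One subtlety the ideal-signal analysis exposes: if
every cycle has *identical* length, every cycle wraps the ramp identically
and the drifted orbit is merely deformed, not thickened.  The thickening
seen in practice needs rhythm variability, so the drift demonstration uses
a quasi-periodic carrier (one full sine cycle per lognormal period,
CV 5 %, mean 800 ms — `gen_fm_sine`) split at its exact cycle boundaries:
there the drifted orbit occupies strictly more bins (typically 15–30 %
more), and after the cleaning pipeline the occupied-bin counts of drifted
and drift-free records agree within 5 %.

## Synthetic test bed

`gen_sine`, `gen_mixed_sine` (two phase-local sine pieces per composite
period, defaults 0.1 mV/800 ms followed by 0.4 mV/1200 ms) and the
drift/noise injectors reproduce the ideal analysis signals in closed form;
x is in milliseconds throughout.  `gen_synthetic_ecg` sums five Gaussian
bumps per beat — P(−160 ms, 0.15 mV, σ 25 ms), Q(−35, −0.10, 8),
R(0, 1.00, 12), S(+35, −0.15, 8), T(+250, 0.30, 45) — a plausible lead-I
morphology (R ≈ 1 mV, P < 0.25 mV), with lognormal RR intervals of
configurable mean rate and coefficient of variation, returning exact
fiducials.  Detector scoring uses 120 s records at 70 bpm, RR CV 0.15 and
20 dB additive white noise; 60 bpm/CV 0 is the deterministic default
elsewhere.  All generators are pure functions of their parameters and
seed.

What this emulates: band-limited PQRST morphology, rhythm-level
irregularity, white and mains noise, constant/linear/sinusoidal wander.
What it does not: beat-to-beat morphology change (ectopy, bundle-branch
morphologies, AFIB f-waves), electrode motion artifacts, muscle noise's
1/f structure, or real inter-patient variability.  Detector scores of
~100 % here are therefore an upper bound, not a claim about clinical
recordings; the published delineation literature on real databases is the
reference for that.

## Degenerate inputs and determinism

Empty R-peak lists, all-zero records, segments shorter than the delay, and
empty point sets all return empty-but-valid objects (with warnings) rather
than raising; requesting metrics with a zero denominator reports
`undefined` (`None`), never NaN.  Candidate peaks tied within the minimum
RR keep the larger amplitude, then the earlier index.  The pipeline is
deterministic for a fixed config, input and seed — identical NPZ grids and
PNG bytes on re-run.

## Known limitations

The fiducial windows assume adult resting morphology; extreme tachycardia
(> ~150 bpm) compresses the T/P search windows until waves are reported
missing.  LOESS detrending attenuates genuine sub-0.5 Hz signal content
along with the wander.  Density maps discard temporal ordering within a
record by design; rhythms distinguished only by long-range beat sequencing
will not separate.  WFDB support covers the common format-16 single-frame
layout only.
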