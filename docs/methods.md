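# Methods

This note documents the models, conventions and numerical choices behind
`superlet-toolkit`: what the synthetic benchmark measures, how each
time–frequency engine is defined, and which decisions were genuinely open.

## The synthetic test signal

The benchmark input emulates a pulsed, low-frequency animal call:

- **Carrier** `x_c(t) = sin φ(t)` with linear frequency sweep
  `φ(t) = 2π (f0 t + (f1 − f0) t² / 2T)`, default 50 → 30 Hz (downward).
- **Modulator** `x_m(t)`: a unipolar {0, 1} square wave derived from a
  second linear sweep (2 → 7 Hz), `x_m = (1 + sgn sin φ_m)/2` with
  `sgn(0) := +1` for determinism.
- **Test signal** `x = x_m · x_c`, sampled at fs = 250 Hz for 6 s
  (1500 samples).

Gating a tone with a 50 %-duty square wave leaves a carrier line at half
amplitude and sideband pairs at odd multiples of the momentary modulation
rate; the pair at offset ±(2k−1)·f_m has amplitude `a_k = 2/π(2k−1)`
relative to the carrier. This is verified in the tests by the FFT of a
stationary variant of the signal (modulation rate chosen so the gate's
zero crossings fall between sample instants, keeping the sampled duty at
50 %).

Defaults (all configurable through `SignalConfig`): fs 250 Hz, duration
6 s, carrier 50 → 30 Hz, modulator 2 → 7 Hz, analysis band 10–125 Hz,
grid step 0.2 Hz, 5 sideband pairs. The duration and the downward sweep
direction are the toolkit's own choices where the conventions in the
field's descriptions of this benchmark are ambiguous; both are plain
config fields.

### Ground truth

The reference TFR paints, per time sample, the carrier track (value 1) at
its instantaneous frequency and each sideband pair k (value `a_k`) at
±(2k−1)·f_m(t), each on the single nearest bin of the 0.2-Hz grid; tracks
leaving the analysis band are dropped for those columns. The tracks are
gated by the same square wave as the signal, so the silent spaces between
AM pulses are silence in the reference too (`gate_tracks=False` restores
continuous tracks). Everything outside the tracks is zero, and the matrix
maximum is exactly 1.

Two rendering choices matter for absolute scores and are deliberate:

- **Line width = one bin.** The components are discrete tones; the
  reference assigns each to its nearest grid bin with no spectral spread.
  Every analysis method necessarily spreads a line over its own bandwidth,
  so absolute RMSE contains a method-independent floor from this
  mismatch; comparisons *between* methods (the rank orderings) are the
  robust quantity.
- **One column per signal sample.** The finest grid any engine produces;
  coarser engine outputs are interpolated up rather than the reference
  being blurred down.

## TFR engines

All engines return non-negative linear **magnitude** (not power, not dB),
and benchmark TFRs are normalised to a global maximum of 1 before scoring,
which makes the scores invariant to each engine's overall gain convention.

**STFT** — frames of length `n` (default 50 "short" / 250 "long"),
symmetric Hamming window, hop `round(n(1−overlap))` (75 % overlap → 12
and 62 samples; the non-integer 62.5 is rounded half-to-even), zero-padded
to `nFFT = fs/f_res` (1250 for 0.2 Hz), one-sided magnitude, rows limited
to the analysis band, columns stamped at frame centres. A Hann window is
available via `window_shape`.

**CWT** — generalized Morse wavelets, symmetry parameter γ = 3 (the
symmetric family) and β = P²/γ from the time-bandwidth product P²
(default 120). The filter bank is log-spaced at 48 voices per octave
across the band and applied in the frequency domain on a zero-padded copy
of the signal (padding suppresses circular wrap-around). The wavelet peak
is normalised to 2, so a unit-amplitude tone maps to magnitude ≈ 1 at any
frequency.

**SLT** — per grid frequency f (linear grid, step `f_res`), the order
`o(f)` interpolates linearly from 10 at fmin to 40 at fmax. The engine
convolves with Morlet kernels of `c·i` cycles (multiplicative mode,
base c = 3, i = 1..⌈o⌉) and combines magnitudes by a weighted geometric
mean with unit weights and weight `o − ⌊o⌋` on the last wavelet, computed
in the log domain for numerical stability. The Morlet at frequency f with
`c` cycles has Gaussian envelope SD `σ = c/(k_sd f)` seconds with
k_sd = 5, support ±3σ, and an amplitude-flat normalisation (envelope
scaled to unit integral, ×2 for the one-sided spectrum) so that a unit
tone yields response ≈ 1 at every frequency; a unit-energy normalisation
is available (`norm="energy"`). The amplitude-flat convention follows the
superlet reference implementation; because benchmark TFRs are
max-normalised, the choice shifts scores only marginally.

**Regridding** — bilinear: linear in time, linear in frequency, except
linear in *log*-frequency when the source rows are log-spaced (CWT
scalograms), with constant extrapolation at the edges. Wavelet engines use
zero-padding at signal boundaries and their edge columns are retained in
scoring.

## Agreement scores

With A the method TFR and G the ground truth on identical axes:

- **Mean spectral RMSE** — mean over frequency rows of the per-row RMSE.
- **Mean temporal RMSE** — mean over time columns of the per-column RMSE.
- **Total RMSE** — RMSE over all cells. (Note `total² = mean(row RMSE²)`,
  so total ≥ both means.)
- **SSI** — mean structural similarity between A and G as greyscale
  images: Gaussian window 11×11 with σ = 1.5, stabilisers C1 = (0.01 L)²,
  C2 = (0.03 L)², dynamic range L = 1 (values live in [0, 1]). Computed
  with scikit-image configured to match the canonical formulation.
- **Percent difference** — the symmetric form `100·|a−b| / ((a+b)/2)`.

## The audio chain

`preprocess` trims to `[t0, t1)`, resamples with a polyphase filter
(`scipy.signal.resample_poly`, rational ratio approximated to 1e-4), and
peak-normalises to |x| ≤ 1. Because the per-sample SLT costs
O(rows × wavelets × n log n), recordings are guarded: max 1 kHz sample
rate and max 80 000 samples, each violation raising a `GuardrailError`
naming the limit. Species presets (whale, elephant, whipbird, cassowary,
mulloway, crocodile) bundle the analysis settings appropriate for each
call type; bands quoted down to 0 Hz are clamped at one grid step because
wavelets are undefined at DC. The recordings themselves are
rights-restricted, so tests exercise presets on synthetic stand-ins
generated by `signal_synth`.

## What the generator does and does not emulate

The synthetic signal reproduces the *structure* that defeats fixed-window
analysis — simultaneous FM and hard AM with swept rate, dense sidebands —
but it is noiseless, perfectly stationary in amplitude within pulses, and
exactly band-limited to known components. Passing benchmarks here
demonstrates time–frequency localisation fidelity, not robustness to
recording noise, propagation effects, reverberation or overlapping
callers. Real recordings also rarely have analytically known ground
truth; for them the toolkit's output is a visualisation aid, not a scored
estimate.

## Numerical notes and limitations

- Deterministic throughout: no randomness anywhere in the pipeline
  (`--seed` flags are accepted and ignored for interface uniformity).
- Geometric means are evaluated as `exp(Σ w log r / Σ w)` with responses
  clamped at the smallest positive double; exact zeros (all-zero signals)
  map to exact zeros.
- `nFFT = fs/f_res` is rounded to the nearest integer; the frequency grid
  contains `⌊(fmax−fmin)/f_res⌋ + 1` points with a 1e-6 guard against
  floating-point shortfall.
- The default run (576 × 1500 matrices, ~14 000 wavelet convolutions)
  completes in a few seconds on one CPU; the sizes were chosen to keep a
  full evaluation interactive.
- Absolute RMSE/SSI values are sensitive to conventions that differ
  between implementations of these methods — window family, wavelet
  normalisation, ground-truth line rendering, interpolation — by a few
  hundredths. The method *rankings* produced by the benchmark (SLT best
  on all error measures and on SSI) are stable across such choices, and
  across frequency-grid resolution (tested at 0.2 and 0.4 Hz).
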