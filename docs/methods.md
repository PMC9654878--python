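# Methods

## The hiding scheme

A host ECG trace `S = {s_i}` of length `L` (amplitudes on a 16-bit integer
scale, nominal sample rate `fs`) is decomposed with a k-level orthonormal
Haar DWT (`k = 5` by default).  The level-k approximation band of
`L / 2^k` coefficients is grouped into frames of `n` consecutive
coefficients; each frame carries one payload bit, so the capacity is
`I = L / (n·2^k)` bits.  For a frame with coefficient magnitudes
`|c_1..n|`, mean `m = (1/n)·Σ|c_i|`, and embedding strength `ε`, the two
thresholds are

    h1 = m + ε        h0 = m − ε

and the embedding rule pushes the modified mean magnitude to

    mean(|ĉ|) ≥ h1          to embed a 1,
    mean(|ĉ|) ≤ h0 − δ      to embed a 0,

where `δ` (default `1e-6·ε`) closes the strict bit-0 inequality so the
optimum is attained.  Signs are preserved and reapplied (zero coefficients
take sign +1); the detail bands are never touched.  Because the transform
is an isometry, the time-domain embedding error energy equals the
coefficient-domain error energy, so minimizing the squared coefficient
modification per frame maximizes the whole-signal SNR

    SNR = −10·log10( Σ(ŝ_i − s_i)² / Σ s_i² ).

### The per-frame optimum

Minimizing `Σ(|ĉ_i| − |c_i|)²` under the bit-1 rule has the closed-form
solution of a uniform shift `|ĉ_i| = |c_i| + ε`.  Under the bit-0 rule
the non-negativity of magnitudes can bind; the optimum is the KKT
water-filling solution `|ĉ_i| = max(|c_i| − λ, 0)` with `λ` chosen so the
frame sum meets its cap `n·(m − ε − δ)`.  A frame with
`Σ|c_i| < n·(ε + δ)` cannot reach the bit-0 target at all; it is embedded
at the all-zero point and flagged `infeasible`, which still decodes
correctly under the blind threshold whenever the frame's mean sits below
the global threshold.  Both solutions are exact Euclidean projections of
the original magnitudes onto the feasible set, which is also how the
implementation realizes them.

### The simulated-annealing solver

The stochastic solver (`solver="sa"`, the default) solves the same
constrained problem by Metropolis sampling: energy is `−(frame SNR)` (so
lower is better and "accept when ΔE ≤ 0" performs maximization — on the
dB scale the energy is scale-free), proposals are Gaussian perturbations
of the current magnitudes (sd `0.25·ε` by default) projected back onto the
feasible set, acceptance of a worse candidate happens when a uniform draw
is below `exp(−ΔE/T)`, and the temperature cools geometrically,
`T ← r·T`, from `T0` until `T ≤ Tf` with `D` iterations per temperature.
Defaults: `T0 = 1`, `Tf = 1e-3`, `r = 0.95`, `D = 50` (135 temperatures,
6750 iterations per frame).  The chain starts from the closed-form
optimum perturbed by one proposal step, the best feasible point seen is
returned, and that point passes through the exact projection once more so
its constraint holds under exact floating-point comparison.  One seeded
generator per embed call is split per frame by frame index, so per-frame
results are independent of evaluation order and batching.  The closed
form is the true optimum; the SA path exists to exercise the stochastic
solver and is validated (tests and the acceptance script) to land within
0.5 dB of it — in practice within ~0.001 dB.

### Blind extraction

The embedding thresholds depend on the *original* frame mean `m`, which a
blind receiver lacks.  Blind mode therefore derives a single global
threshold `τ` = mean of all received frame statistics: embedding places
bit-1 and bit-0 statistics symmetrically at `m ± ε`, and payload
whitening keeps the two populations balanced, so `τ` falls between them.
A statistic exactly equal to `τ` decodes as 1.  This is valid when the
per-frame original means are homogeneous — spread less than about `ε/2`
around their global mean — a condition the evaluation report states
explicitly (`frame_mean_spread`, `blind_condition_ok`).  Sidecar mode
preserves the literal per-frame rule (threshold `m` = midpoint of
`h1`/`h0`, read from a CSV written at embed time) and decodes correctly
after noise-free embedding unconditionally; it exists for verification
and diagnostics, never as part of the blind path.

### Payload framing

The payload (free text, or a four-field patient record serialized with an
escape-coded field separator) becomes UTF-8 bytes, MSB-first bits, with a
16-bit big-endian length header; header and body are XORed with a
pseudorandom whitening mask from a fixed public seed (7919).  Whitening
makes the embedded bit stream approximately balanced for any payload
(what the blind threshold needs) and the header lets extraction stop at
the true payload end; frames beyond the payload are never modified.
Whitening can be disabled (`whitening_seed=None`).  An empty body decodes
to the all-empty record.

## The synthetic generator

The unit of all tests and of the acceptance script is a synthetic PQRST
trace: five Gaussian bumps per beat (P, Q, R, S, T) at fixed fractional
offsets/widths of the beat period, scaled so the R deflection above the
baseline equals `r_amplitude`, on a DC pedestal (`baseline`), plus
Gaussian sensor noise.  Defaults: 4096 samples, nominal rate 44.1 kHz,
beat period 128 samples, pedestal 11000, R deflection 1200, noise sd 20,
all on the 16-bit ADC scale.

Why these numbers:

- The audio-rate label makes the attack battery's audio-band parameters
  (3/6 kHz cutoffs, 22050/11025/8000 Hz intermediate rates) directly
  applicable; at an honest acquisition rate of 250 Hz the identical trace
  is a ~117 bpm rhythm.
- The DC pedestal emulates a raw single-supply acquisition front-end and
  places the whole-signal SNR at `ε = 2000–4000` in the mid-20s dB — the
  regime the method is designed for — while keeping every bit-0 frame
  feasible (no clamping, no flags).
- The modest R deflection relative to the pedestal keeps the level-5
  frame means homogeneous (spread well under `ε/2`), i.e. inside the
  validity region of the blind threshold.  This is the main idealization:
  the generator emulates amplitude scale, PQRST morphology, periodicity
  and sensor noise, but *not* baseline wander, beat-to-beat variability,
  arrhythmia, or zero-centered (AC-coupled) recordings.  On
  zero-centered, high-dynamic-range ECGs the frame-mean spread exceeds
  `ε` and blind extraction degrades — the evaluation report's
  `blind_condition_ok` flag is there to detect exactly that.  Passing
  tests therefore demonstrate correctness of the mechanics and the
  claimed trends, not field performance on arbitrary clinical records.

## Numerical choices

- Lengths must divide exactly (`L` by `2^k`, the band by `n`); signals
  are rejected rather than padded, since padding would silently perturb
  frame statistics.  The generator always emits compliant lengths.
- All arithmetic is floating point; quantization occurs only at WAV
  export (round-half-even, overflow is an error, never a silent clip).
  The ≤ 0.5 per-sample rounding perturbation is negligible against the
  default `ε ≥ 2000`.
- Constraint feasibility is enforced under *exact* floating-point
  comparison, in the arithmetic domain each projection works in (frame
  mean for bit 1, frame sum for bit 0), with one-ulp cleanup loops.
- The Haar transform uses PyWavelets (`mode="periodization"`); since
  lengths divide exactly, no boundary extension ever occurs and the
  transform is block-local, making whole-signal transformation with
  contiguous grouping identical to per-frame transformation (asserted
  numerically in the tests).
- The low-pass attack is a zero-phase order-6 Butterworth
  (forward–backward), chosen for a flat passband and no phase distortion
  of the PQRST morphology; the order is configurable.
- The resampling attack uses polyphase anti-aliased decimation and
  interpolation with a beta-12 Kaiser design and linear-extension
  padding, so DC passes with < 1e-6 relative error and the output length
  equals the input length exactly.
- The noise attack's "level in dB" is the noise-to-signal power ratio
  (−40 dB means noise power `1e-4` of signal power).
- In the generic annealer one uniform variate is consumed every
  iteration regardless of the acceptance branch, keeping the random
  stream branch-independent (and aligned with the greedy reference used
  to test the `T0 → 0` limit).

## Problem sizes

Tests and the acceptance script use 4096-sample traces (32 frames at
`n = 4`) throughout, except the parameter-grid round trip which uses
3840 samples so the 120-coefficient band divides by `n = 2, 3, 4`
alike.  Robustness averages use 20 seeds with fresh traces, payloads and
attack noise per seed; the SA–oracle comparison uses 100 traces in the
test suite and 10 in the acceptance script.

## Known limitations

- No resynchronization: time-shift or cropping attacks break frame
  alignment and are out of scope.
- No error-correcting codes and no encryption of the payload.
- Blind extraction's validity condition (frame-mean homogeneity) is
  reported, not enforced; sidecar mode is the fallback when it fails.
- Single-lead signals only; no WFDB/EDF readers (CSV and 16-bit WAV).
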