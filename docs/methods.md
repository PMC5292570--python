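# Methods

This note records the models behind `myobench`, the defaults and why they
were chosen, and what the synthetic bench does and does not establish about
real recordings.

## Source model

Surface EMG is simulated as band-pass-filtered Gaussian white noise
(4th-order Butterworth, zero-phase, 20–450 Hz by default) — the simplest
stationary process with the spectral support of skin-surface EMG — scaled
per channel by a motion-dependent activation amplitude and ramped on with a
raised cosine (50 ms default). The carrier is renormalized to unit RMS over
the post-onset region, so configured amplitudes are exact post-onset RMS
values. No motor-unit physiology (action-potential trains, recruitment,
fatigue) is modelled: the generator reproduces amplitude structure and
spectral support, not EMG microstructure.

Defaults: 3 channels at 1600 Hz; activations in volts RMS at the skin, of
order 1 mV for active classes with a distinct dominant channel per motion
(close → ch1, open → ch2, flexion → ch3, extension → ch1+ch2), and rest at
10 µV (1% of the strongest activation). The five-class problem is therefore
separable *by construction*; a high bench accuracy validates the pipeline's
mechanics, not any claim about real inter-subject EMG variability.

## Electrode transfers

Electrode differences are modelled as linear transfers: a broadband
`gain_scale` and a zero-phase spectral shelf of `hf_tilt_db` decibels at
and above `hf_pivot_hz`, plus optional additive white noise
(`noise_density`, V/√Hz). Defaults — wet gain 1.1 vs dry-fabric (PPy) gain
1.0, PPy +3 dB above 150 Hz — encode the qualitative observations
(wet slightly larger amplitude; PPy relatively more high-frequency power);
the magnitudes are configuration, not measured claims. The bench default
noise density, 0.2 µV/√Hz (≈5.7 µV RMS input-referred over the 800 Hz
band), is a typical instrumentation noise floor and keeps the rest-state
output floor well below the level-1 interference band.

## Impedance imbalance and common-mode coupling

Each differential pair sees complex source impedances `Z₁' = Z₁ + R₁`,
`Z₂' = Z₂ + R₂` (series trim resistors 0–200 kΩ), represented by their
300 Hz magnitude/phase. The two tabulated imbalance indices are the
magnitude difference `| |Z₁'| − |Z₂'| |` and the phase-angle difference
`|arg Z₁' − arg Z₂'|`; the coupling model instead uses the full complex
difference — both are computed and documented separately, because the
tabulated "magnitude" column is the difference of magnitudes, not the
magnitude of the difference.

Imbalance draws per noise level use independent truncated-at-zero normals
for the magnitude and phase differences. The parent parameters are solved
so the *truncated* distribution has exactly the target mean/SD
(moment matching); a lower-truncated normal always has mean/SD > 1, so the
level-1 phase column (mean 1.2°, SD 1.3°) cannot be moment-matched and
falls back to direct truncation of N(1.2, 1.3), whose realized mean sits
near 1.6°. Nothing quantitative downstream depends on that one cell. Drawn
differences are split symmetrically around a 50 kΩ / −20° baseline, a
plausible dry-electrode source impedance; the split makes the imbalance
indices recover the drawn values exactly.

Common-mode interference converts to a differential error with gain

    g = Z_in · (1/(Z_in+Z₁') − 1/(Z_in+Z₂')) + 10^(−CMRR/20)

the textbook potential-divider mechanism plus intrinsic-amplifier leakage.
`|g|` multiplies the real common-mode waveform; the phase of `g` would only
shift the coupled sinusoids in time and changes none of the analyzed power
or amplitude quantities, so it is dropped.

Generic amplifier defaults are `Z_in` = 1 GΩ and 100 dB intrinsic CMRR.
The *bench* configuration instead uses 100 MΩ and 120 dB: with 1 GΩ/100 dB
the intrinsic leakage term (10⁻⁵) dominates the divider term at all three
imbalance levels and the levels become indistinguishable at the output,
whereas a 100 MΩ effective common-mode input impedance — representative
once cable and input capacitance at mains frequencies are considered —
keeps the imbalance mechanism dominant, which is the phenomenon the bench
exists to exhibit. The input-impedance sanity check (|Z_in| > 1000× source
impedance) holds in both configurations.

Mains harmonics are injected as common-mode sinusoids; the default
amplitudes ({50: 1.3, 100: 0.8, 150: 0.25, 200: 0.8, 250: 0.25, 300: 0.8} V
peak) were chosen once so that the three imbalance levels land in the three
defining rest-state output bands: little noise, excursions within ±6 V,
excursions reaching ±9 V. They are configuration values, not measurements.

## Amplifier and filter chain

Chain: 40 dB instrumentation pre-gain → zero-phase 2nd-order Butterworth
band-pass (1–1000 Hz) → 50 Hz notch (Q = 30, zero-phase) → second gain →
hard clip at ±9 V rails. The second-stage default (36 dB) makes a 1 mV RMS
source span roughly two thirds of the rails. At a 1600 Hz sampling rate the
1000 Hz upper band edge lies above Nyquist, so the digital chain realizes
the high-pass section only; the analog low-pass corner is invisible in the
sampled data by construction, and the upper edge is honored whenever the
rate allows it.

The switched impedance-measurement protocol injects the meter's 300 Hz
1 Vrms tone during scheduled intervals; amplified by the full chain it
exceeds the rails by an order of magnitude, so those segments clip hard and
are excluded via the trace mask, extended by a 50 ms settling margin on
each side (conservative, since the whole measurement output is unusable).
A separate run-length detector (`exclude_saturated`) masks sustained
rail-level runs (default threshold just below the rail, minimum run one
stride) for recordings without a known schedule.

## Pattern recognition

Epochs are 128 ms advanced every 10 ms. At 1600 Hz the window is 205
samples, zero-padded to a 256-point FFT; features are the smoothed
(3-bin moving average by default) power-spectrum values at the FFT bin
nearest each of 31, 55, 78, 102, 148, 195, 258, 320 Hz per channel,
concatenated channel-major into 24 values. These eight frequencies are
near-exact multiples of the 128 ms window's 7.8125 Hz bin spacing (bins 4,
7, 10, 13, 19, 25, 33, 41), asserted at import for the default
configuration. Two epoching conventions exist: `offline` (first full
window onward; 188 epochs in 2 s) and `streaming` (one trailing-window
decision per stride with zero pre-roll; exactly 200 decisions in 2 s,
matching an online controller).

The classifier is a 24-32-5 feed-forward network with logistic-sigmoid
activations, MSE loss against one-hot targets, seeded uniform(−0.5, 0.5)
initialization, and full-batch gradient descent. Each epoch takes one step
with a halving line search (the step also grows geometrically after
successes), which guarantees a non-increasing loss without tuning and
converges in a few hundred epochs on the bench (default 600). Inputs are
z-scored with statistics stored in the model. Ties in the output layer
break to the lowest class index. All of these are package choices — the
original training procedure is specified only as "backpropagation".

## Evaluation conventions

- RMS envelopes: 100 ms sliding window, 10 ms step (defaults); excluded
  samples are skipped inside each window, and fully excluded windows are
  NaN (dropped pairwise by the correlation).
- Summaries: arithmetic mean and sample SD (n−1). The n−1 convention is
  fixed package-wide because it reproduces the reference SD cells exactly.
- Rounding happens only at presentation/comparison time, using
  round-half-away-from-zero to the printed precision.
- Two reference cells are known half-rounding artifacts of the printed
  tables: the level-1 phase mean (prints 1.2°, the ten listed values
  average 1.14°; compared with ±0.1°) and the extension/wet accuracy mean
  (the six cells average exactly 83.35, printed 83.3; compared with
  ±0.05). All 36 other summary cells reproduce exactly.
- Noise-level thresholds: level 1 below `v_lo`, level 3 at or beyond 6 V,
  level 2 between. `v_lo` defaults to 1.5 V: the bench rest-state floor
  (rest EMG plus electrode noise ≈ 0.5 V at the output) plus the level-1
  common-mode residual tops out near 1.5 V while level-2 outputs start
  above ≈2.5 V, making 1.5 V the natural separator. Only the qualitative
  level ordering, never `v_lo` itself, enters any quantitative result.

## Reproducibility and problem sizes

One global seed fans out to named child seeds via CRC-hashed
`numpy.random.SeedSequence` parts (`derive_seed(seed, *tags)`, always
< 2³¹), so each stage can be rerun in isolation. The default bench sizes —
8 s of training signal per motion, three 2 s test repetitions per task,
1000 impedance draws, 20 rest-trace repeats per level — keep a full bench
run around ten seconds while leaving sampling error well inside the
tolerances used by the tests. `run_bench` records the seed, a SHA-256
config hash and library versions in its report.

## Known limitations

- The source model is stationary within a motion; no electrode shift,
  motion artifact, sweat/electrochemistry drift, or fatigue.
- Impedances are single-frequency (300 Hz) representative values; real
  electrode-skin impedance is strongly frequency- and amplitude-dependent.
- The amplifier is ideal apart from the rails and the intrinsic-CMRR
  leakage: no input bias currents, 1/f noise, or slew limiting.
- Bench accuracies quantify the pipeline on a separable synthetic task;
  they do not predict human-subject recognition rates, which depend on
  real inter-class overlap the generator deliberately avoids.
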