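# myobench

A synthetic surface-electromyography (sEMG) measurement and
myoelectric-control bench.

Practical prosthetic-hand control hinges on recording stable sEMG — the
sub-millivolt potentials of contracting forearm muscles measured on the
skin — through a differential amplifier chain, and on classifying short
signal windows into motion commands. Two measurement effects dominate
signal quality in daily use: the transfer differences between gelled
Ag/AgCl ("wet") electrodes and dry conductive-fabric (polypyrrole-coated,
"PPy") electrodes, and the common-mode interference (50 Hz mains radiation
and its harmonics, plus a 300 Hz LCR-meter tone in switched impedance
monitoring) that leaks into the differential path when the two
electrode-skin source impedances are unbalanced.

`myobench` is for researchers and engineers who need a fully controlled,
reproducible software stand-in for that measurement chain: every stage of
the bench is simulated, seeded, and testable without any recorded data.

## What the package computes

**Signal model.** Each channel of sEMG is a band-limited Gaussian carrier
(20–450 Hz) amplitude-modulated per motion class (rest, hand close/open,
wrist flexion/extension), at ≤1 mV RMS on the skin. Electrode transfers are
linear: a broadband gain and a high-frequency shelf above 150 Hz
(the dry-fabric electrode carries relatively more power above 150 Hz).

**Interference coupling.** With source impedances `Z₁' = Z₁ + R₁` and
`Z₂' = Z₂ + R₂` against amplifier input impedance `Z_in`, a common-mode
voltage converts to a differential error with gain

    g = Z_in · ( 1/(Z_in + Z₁') − 1/(Z_in + Z₂') ) + 10^(−CMRR/20)

— the potential-divider model of CMRR degradation by impedance imbalance,
plus the amplifier's intrinsic-CMRR leakage. The chain is
40 dB pre-gain → 1–1000 Hz band-pass → 50 Hz notch → second gain →
±9 V rails, with saturated meter-tone segments excluded from analysis.
Impedance imbalance (|‖Z₁'‖ − ‖Z₂'‖| in Ω, |arg Z₁' − arg Z₂'| in degrees,
at 300 Hz) is drawn from moment-matched truncated normals calibrated to
three measured rest-noise levels.

**Pattern recognition.** 128 ms epochs every 10 ms; per channel the FFT
power spectrum is smoothed by a moving average and read at 31, 55, 78, 102,
148, 195, 258 and 320 Hz (24 features over 3 channels); a 24-32-5
feed-forward network trained by backpropagation outputs one of the five
motion classes; session accuracy is correct decisions over total decisions.

**Evaluation.** RMS envelopes and their Pearson correlation between
electrode views, band-power comparison around 150 Hz, mean/sample-SD
summaries, and rest-state noise-level classification (level 1: little
noise; level 2: within ±6 V; level 3: reaching ±9 V). Three packaged
plain-text tables (per-trial correlations, per-subject accuracies,
per-trial impedance imbalances) provide the reference statistics.

## Worked example

Train the classifier on the default synthetic bench and run a five-task
session at imbalance level 1 (one decision every 10 ms, three 2 s
repetitions per task):

```python
from myobench.bench import train_classifier, run_recognition
from myobench.config import default_config, derive_seed

cfg = default_config(seed=1)
model = train_classifier(cfg, "ppy", derive_seed(1, "clf", "ppy"))
table = run_recognition(cfg, model, "ppy", derive_seed(1, "session", "ppy"), level=1)
print(table.to_string(index=False, float_format=lambda v: f"{v:.1f}"))
```

```
     task  n_decisions  n_correct  accuracy_pct
    relax          600        600         100.0
    close          600        577          96.2
     open          600        580          96.7
  flexion          600        583          97.2
extension          600        575          95.8
     mean         3000       2915          97.2
```

Rest is recognized perfectly (it is nearly silent by construction) and the
four active motions sit near 96–97%, for a 97.2% session mean — the
qualitative pattern expected of a separable five-class bench at the lowest
interference level.

The same pipeline is scriptable from the shell:

```sh
myobench simulate --seed 1 --motion close --out close.csv
myobench frontend --seed 1 --level 3 --out rest_l3.csv   # reports noise level
myobench evaluate                                        # fixture summaries
myobench bench --seed 1 --out bench_out                  # full run + report.json
```

`myobench reproduce-tables` prints each packaged summary cell next to its
reference value, e.g.:

```
            quantity     computed   rounded   printed   ok
    table1_corr_mean     0.869167     0.870     0.870 True
      table1_corr_sd     0.064731     0.065     0.065 True
  table2_overall_wet    88.916667    88.900    88.900 True
```

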