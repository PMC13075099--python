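# fecgx

Single-channel fetal ECG extraction by CNN-guided two-stage ensemble
empirical mode decomposition.

The fetal electrocardiogram (FECG) recorded from one abdominal
electrode is buried under the maternal ECG (5–10× larger), EMG noise
and baseline wander, with no spatial diversity to exploit. `fecgx`
implements a fully automatic extraction pipeline for that setting,
aimed at people building or evaluating non-invasive fetal monitoring
methods: biomedical-signal researchers, and anyone who needs a
reproducible, annotation-complete synthetic benchmark for
single-channel maternal–fetal source separation.

## Method

For an abdominal trace x(t), the pipeline computes

1. preprocessing: 50 Hz notch and zero-phase 4th-order Butterworth
   bandpass, 0.1–100 Hz;
2. maternal QRS template subtraction: with maternal R-peaks t_k, the
   template is the coherent average
   `T_m(t) = (1/N_m) Σ_k x(t − t_k)` over fixed-width beat windows,
   and the maternal track (template tiled at every beat) is removed;
3. first EEMD stage: each 10 s window of the residual is decomposed
   into intrinsic mode functions, `x(t) = Σ_{i≤8} IMF_i(t) + r(t)`
   (ensemble 30, added-noise width 0.2 × σ); a 1-D CNN
   (**IMFClassifier1D**: five conv–BN–ReLU–pool blocks, kernels
   [31, 21, 15, 11, 7], channels [32, 64, 128, 256, 512], hybrid
   max/adaptive pooling, 5.91 M parameters) scores each IMF with a
   fetal-relatedness probability and the top-2 are summed;
4. refinement: fetal R-peak detection and a 10–60 Hz zero-phase
   bandpass;
5. second EEMD stage on what stage 1 left behind, keeping the single
   top-scoring IMF; the final output is the 10–60 Hz-filtered sum.

The scorer is trained with leave-one-subject-out cross-validation on
IMFs labeled from reference fetal R-peaks: an IMF is fetal-related iff
its beat-locked peak-to-peak statistic M satisfies `M > 1.4σ` and
`M > 0.75·P_global`. Heuristic (energy × correlation) and oracle
(correlation against known truth) selectors are built in for
comparison. A synthetic generator reproduces a 15-case maternal/fetal
simulator grid (rates, amplitudes, 1:1.17–1:16 amplitude ratios) with
exact R-peak annotations and a noise-augmentation step whose overall
SNR is pinned to 10 dB exactly.

## Worked example

`python examples/04_extract_fecg.py` — extract the fetal ECG from a
noisy 30 s synthetic case (fetal:maternal amplitude 1:1.17, 10 dB
SNR) with oracle IMF selection:

```
sim01: 39 maternal beats subtracted
fetal R-peaks: 70 detected / 70 true -> precision 1.000, recall 1.000, F1 1.000
waveform CC vs clean fetal reference: 0.929
SNR improvement over the raw abdominal trace: 7.0 dB
```

All 70 fetal beats are recovered at ±50 ms tolerance; the waveform
correlates at 0.93 with the clean fetal component (10–60 Hz band) and
the fetal signal-to-noise ratio improves by 7 dB over the raw
abdominal trace. The other examples cover simulation (`01`),
decomposition and labeling (`02`), LOSO training of the scorer
(`03`), and the (n1, n2) selection-strategy grid (`05`).

A thin CLI mirrors the library:

```sh
fecgx --seed 7 simulate --case 1 --duration 60 --out sim/
fecgx --seed 7 extract --input sim/sim01 --mode oracle --out result.json
fecgx --seed 7 grid --mode oracle --out grid.csv
```

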