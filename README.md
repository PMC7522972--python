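# t1t2map

Two-dimensional T1–T2 correlation NMR relaxometry of red-blood-cell
microenvironments: forward simulation of IR-CPMG decay data, regularized
2D inverse Laplace inversion into T1–T2 correlation maps, relaxation-
reservoir analysis, and machine-learning classification of the resulting
"molecular fingerprints".

## The problem

Water protons in packed red blood cells relax at rates set by their local
molecular environment. A benchtop T1–T2 correlation experiment — an
inversion-recovery preparation followed by a CPMG echo train — encodes
both the spin-lattice time T1 (via the waiting time t1) and the spin-spin
time T2 (via the echo time t2):

    M(t1_i, t2_j) = Σ_k A_k (1 − 2 e^(−t1_i/T1_k)) e^(−t2_j/T2_k) + noise

Inverting this doubly exponential Fredholm model yields a non-negative
distribution F(T1, T2) on a log-log grid. For blood the distribution
decomposes into three reservoirs — bulk water (**R**), the intermediate
hydration layer (**S**) and protein-bound water (**T**) — each with a
characteristic **A-ratio** T1/T2 that indexes the strength of
water–protein interaction (free water ≈ 1, protein-bound water in the
hundreds). Hemoglobin oxidation (the methemoglobinemia disease model)
collapses the T-peak into a "relaxation tail" stretching more than a
decade in T1, and structural variants (HbE, HbD, a rare beta-thalassemia)
shift the T-peak; these signatures make the map a subject-specific
fingerprint that simple classifiers can sort into disease, non-disease
and variant classes.

The package is aimed at researchers who want a tested, reproducible
reference pipeline for this kind of low-field relaxometry analysis: a
synthetic-data generator stands in for the spectrometer, so every result
can be regenerated from a seed.

## What is inside

| module | contents |
|---|---|
| `t1t2map.core_model` | reservoir/phenotype/acquisition types, A-ratio arithmetic, published phenotype presets |
| `t1t2map.synthetic_data` | IR-CPMG forward simulator, 32-subject cohort generator |
| `t1t2map.laplace_inversion` | kernels, SVD compression, non-negative Tikhonov FISTA solver |
| `t1t2map.peak_analysis` | peak detection/segmentation, R/S/T labelling, tail metrics |
| `t1t2map.fingerprint_classify` | featurization, MDS/t-SNE/Isomap, clustering, CV metric suite |
| `t1t2map.cli_io` / `t1t2map.cli` | CSV+JSON formats, pipeline config, `t1t2map` command |

## Worked example

Simulate the oxygenated phenotype at the standard acquisition (echo time
200 µs, 4000 echoes, 32 log-spaced inversion times), invert with the
default smoothing (α = 1, 5000 iterations, 100×100 grid) and read off
the reservoirs:

```python
from t1t2map import (AcquisitionScheme, classify_peaks_rst, detect_peaks,
                     invert, preset_phenotype, round_a_ratio,
                     simulate_decay)

data = simulate_decay(preset_phenotype("oxygenated"),
                      AcquisitionScheme(n_echoes=4000, noise_sd=0.0))
spectrum = invert(data, alpha=1.0, n_iterations=5000)
report = classify_peaks_rst(detect_peaks(spectrum))
for p in report.peaks:
    print(f"{p.label}-peak: T1 = {p.t1_ms:6.1f} ms, T2 = {p.t2_ms:7.2f} ms, "
          f"A-ratio = {round_a_ratio(p.a_ratio)}, volume = {p.volume:.3f}")
print(f"tail extent: {report.tail_extent_decades:.2f} decades")
```

prints

```
R-peak: T1 =  555.2 ms, T2 =  140.27 ms, A-ratio = 3.96, volume = 0.704
S-peak: T1 =  348.4 ms, T2 =    4.32 ms, A-ratio = 80.69, volume = 0.214
T-peak: T1 =  186.0 ms, T2 =    1.04 ms, A-ratio = 178.2, volume = 0.070
tail extent: 0.48 decades
```

The three reservoirs land within one grid cell (≈ 4% in T1, ≈ 10% in T2)
of the input coordinates (562, 141), (335, 4.47) and (188, 1.12) ms, the
recovered volumes track the simulated signal fractions 0.70/0.20/0.10,
and the protein-bound band stays compact — repeating the run with the
`oxidized` preset stretches it beyond 1.3 decades and drops the R-peak
A-ratio from ≈ 4 to ≈ 1.8.

The same thing from the shell, plus the full cohort pipeline:

```sh
t1t2map simulate --phenotype oxygenated --noise-sd 0 --out decay.csv
t1t2map invert --in decay.csv --out spectrum.csv --alpha 1 --iters 5000
t1t2map peaks --in spectrum.csv --report report.json
t1t2map run --seed 7 --out results/
```

The pipeline run generates the default 32-subject synthetic cohort
(10 wild type, 8 oxidized, 6 partially oxidized, 8 hemoglobin variants;
5% inter-subject jitter, SNR 500), inverts every subject, extracts peak
reports, embeds the fingerprints with MDS and cross-validates four
classifiers on the binary disease/non-disease task, ending with e.g.

```
logistic_regression: CA=1.000
knn: CA=0.938
neural_network: CA=1.000
naive_bayes: CA=0.938
```

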