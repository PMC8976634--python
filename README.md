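# pvcdetect

Recognition of **premature ventricular contractions (PVCs)** in
single-lead ECG, aimed at people building or evaluating arrhythmia
screening pipelines on PhysioNet-style data.

A PVC is an ectopic beat arising in the ventricle: it appears early
(short preceding RR interval), with a wide (> 120 ms) bizarre QRS
complex, an enlarged T wave, no preceding P wave, and is typically
followed by a compensatory pause.  Rather than classifying beats one at
a time, this package classifies **20-second windows** of ECG: each
window is summarized by a 10-value feature vector and a small two-route
1-D convolutional network decides PVC vs. non-PVC.

## Method

For every 20 s window, with RR intervals $RR_1,\dots,RR_n$ (ms) and
successive differences $d_i = RR_{i+1}-RR_i$:

| feature | definition |
|---|---|
| MeanRR | $\mu = \tfrac1n\sum_i RR_i$ |
| SDRR | population SD of the $RR_i$ |
| SDSD | population SD of the $d_i$ |
| rMSSD | $\sqrt{\operatorname{mean}(d_i^2)}$ |
| pRR10 / pRR50 | % of $\lvert d_i\rvert > 10$ ms / $> 50$ ms |
| Ratio | $(\max RR - \min RR)/\mu$ |
| QRS width | mean Q-to-S fiducial distance (ms) |
| QR / RS amplitude | mean $R-Q$ and $R-S$ amplitude (mV) |

A window is labeled PVC when **at least 95 %** of its beats are
ventricular-ectopic (AAMI class V).  Features are min–max normalized,
$NV = (FV - F_{\min})/(F_{\max} - F_{\min})$, with $F_{\min}, F_{\max}$
learned on training windows only.

The classifier has two parallel convolutional routes over the 10-value
input — four length-3 convolutions (one max-pool at the end) and two
length-3 convolutions (one max-pool) — whose outputs are concatenated
into a fully-connected ReLU layer and a 2-unit softmax head.  Training
uses Adam, learning rate $10^{-4}$ (dropped ×0.2 every 20 epochs),
batch size 200, 40 epochs, cross-entropy loss.  Evaluation reports
PPV = TP/(TP+FP), recall = TP/(TP+FN) and their harmonic mean
(F-score), per record and pooled, with PVC as the positive class.

The package reads WFDB record triplets (`.hea`/`.dat` formats 16 and
212, MIT `.atr` annotations) — e.g. the MIT-BIH Arrhythmia Database,
for which it applies the conventional paced-record exclusion
(102, 104, 107, 217) and the 22/22 inter-patient train/test partition —
and includes a seeded **synthetic ECG generator** (Gaussian-wavelet
beats, controllable PVC burden, prematurity and compensatory pause) so
the whole pipeline is testable without any download.

## Worked example

```python
from pvcdetect.pipeline import run_synthetic_pipeline

result = run_synthetic_pipeline(seed=0)   # 60 records, ~25 s on one CPU
print(result.report.render())
```

This generates 60 synthetic records (30 PVC-dominated, 30 near-normal,
759 training and 757 held-out windows), trains the network, and prints
per-record and aggregate window-level metrics:

```
      Record     PPV  Recall  F-score
       pvc01   100.0   100.0    100.0
       pvc03    94.4   100.0     97.1
       pvc05    93.8    93.8     93.8
        ...
 all (micro)    96.4    99.3     97.8
 all (macro)    96.3    99.2     97.7
```

The micro row pools the confusion counts of all test windows: of the
windows predicted PVC, 96.4 % truly were (PPV); of the true PVC
windows, 99.3 % were found (recall); their harmonic mean is the
F-score 97.8 %.  Records with no true PVC window are pooled but not
listed (their recall is undefined).  The same stages are available as
a CLI:

```bash
pvcdetect simulate --n-beats 750 --pvc-fraction 0.3 --seed 1 --out data/
pvcdetect extract-features --data-dir data/ --out features.csv
pvcdetect train --features features.csv --seed 0 --out model.npz
pvcdetect predict --model model.npz --features features.csv --out pred.csv
pvcdetect evaluate --predictions pred.csv --truth features.csv
# or everything at once:
pvcdetect run-all --seed 0 --out runs/demo
```

With a local MIT-BIH copy, `python scripts/reproduce_mitdb.py
--data-dir <mitdb>` checks the published beat counts of the partition
(6805 V / 94112 non-V over 44 records) and runs the full train/test
evaluation.

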