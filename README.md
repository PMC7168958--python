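# pdwear

Wearable-sensor classification of Parkinson's-disease motor symptoms, built
as a fully synthetic, end-to-end-tested pipeline.  It answers a practical
design question for wearable monitoring systems: **how much measurement can
you remove — sensors, sampling rate, feature complexity — before symptom
detection degrades?**

The pipeline:

1. **Synthetic cohort** — participants with latent tremor/bradykinesia
   severity perform a standardized motor-task battery across an OFF→ON
   medication sweep while wearing a hand sensor (tri-axial accelerometer
   ±4 G + gyroscope ±1000 deg/s, 62.5 Hz) and a wrist watch (accelerometer,
   50 Hz); a simulated clinician scores each task repetition 0–4.  Tremor is
   planted as a 4–6 Hz oscillation whose amplitude tracks the score;
   bradykinesia as slowing of the voluntary movement, carried chiefly by
   angular velocity.
2. **Preprocessing** — cubic-spline regularization to the nominal rate,
   rational polyphase downsampling, zero-phase 0.5 Hz high-pass on the
   accelerometer, segmentation into 5-s clips with 50% overlap, and an 80%
   raw-coverage validity rule.
3. **Features** — 74 per sensor modality per clip (57 tri-axial + 17
   magnitude) in five categories: time moments (T), spectral features (F),
   sample entropy (E), axis cross-correlations (C), derivative moments (D);
   148 with both modalities.
4. **Models** — random forests (50 trees) for binary presence (score ≥ 1)
   and multiclass 0–4 severity, evaluated by AUROC under strict
   leave-one-participant-out (LOPO) cross-validation.
5. **Sensitivity analyses** — sensor sets (Combo/Accel/Gyro/Watch), sampling
   rates (62.5 down to 5 Hz), and all 31 feature-category combinations with
   a computation-cost vs AUROC Pareto filter; repeated-measures ANOVA over
   folds and Holm-corrected paired t-tests throughout.

## Worked example

```python
from pdwear.study import qualitative_replicate

rep = qualitative_replicate(seed=1)
print({k: round(v, 3) for k, v in rep["tremor_rates"]["means"].items()})
print({k: round(v, 3) for k, v in rep["sensors_bradykinesia"]["means"].items()})
print(round(rep["brady_rates"]["anova_p"], 3))
```

prints (seed 1):

```
{'62.5': 0.992, '40': 0.997, '30': 0.995, '10': 0.75, '5': 0.532}
{'Combo': 0.966, 'Accel': 0.695, 'Gyro': 0.969, 'Watch': 0.669}
0.392
```

Reading: binary tremor LOPO AUROC holds near 0.99 down to 30 Hz sampling and
collapses to chance at 5 Hz — the 4–6 Hz tremor band exceeds the 2.5 Hz
Nyquist limit, so the anti-alias filter removes the signal.  With slowing
encoded in angular velocity, bradykinesia models using the gyroscope (Combo,
Gyro) beat accelerometer-only models by ~0.3 AUROC, while bradykinesia is
insensitive to sampling rate (rmANOVA p = 0.39): its voluntary-movement cues
live below 2 Hz and survive even 5 Hz sampling.

The same stages are scriptable from the shell:

```sh
pdwear generate  --seed 7 --out data/
pdwear featurize --data data/ --device hand_sensor --rate 30 --out features.csv
pdwear evaluate  --features features.csv --symptom tremor --mode binary --out results.json
pdwear experiment rates --data data/ --symptom tremor --out reports/rates/
```

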