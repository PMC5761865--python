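# fetalstress

Heart-rate-variability analysis of the fetal RR-interval series around
the **Fetal Stress Index (FSI)**, a continuous [0, 100] index of
parasympathetic tone, for researchers studying fetal adaptation to
hypoxia and acidosis (experimental fetal-lamb models, labor monitoring
research).

High-frequency RR oscillations (HF band, > 0.15 Hz, centered on the
respiratory frequency) are vagally mediated. The FSI measures their
magnitude in the time domain after spectral filtering: each 64 s window
of the 8 Hz-resampled RR series is normalized by its mean, high-pass
filtered above 0.15 Hz with a db4 wavelet filter, and enveloped through
its local extrema; the inter-envelope area is split into four 16 s
subareas A1–A4 and

    AUCmin = min(A1, A2, A3, A4)
    FSI_inst = 100 (a · AUCmin + b) / 12.8        (clamped to [0, 100])
    FSI(t)   = mean of FSI_inst over the trailing 3 min

with configurable constants a, b (defaults 5.1, 1.2). Over the
10 minutes before each blood-gas sampling the package summarizes
FSI_min / FSI_max / FSI_mean, groups samples at the clinical acidosis
threshold pH ≤ 7.20, and runs Wilcoxon rank-sum comparisons, Friedman
time-evolution tests and Spearman rank correlations.

Because no fetal recordings are publicly available, the package ships a
calibrated generator of synthetic cord-occlusion experiments (baseline
160 bpm → occluded 106 bpm, pH 7.40 → 7.12 over 45 min, HF amplitude
coupled to the pH deficit) so the whole chain is testable end to end.
See `docs/methods.md` for the model, assumptions and limitations.

## Worked example

```python
import numpy as np
from fetalstress import ScenarioParams, simulate_experiment, run_study

records = simulate_experiment(ScenarioParams(seed=7))   # 8 simulated subjects
result = run_study(records)
print(result.group_comparison[
    ["variable", "above_7_20", "at_or_below_7_20", "wilcoxon_p"]
].tail(3).to_string(index=False))
print(result.correlations.to_string(index=False))
```

prints (abridged):

```
variable            above_7_20      at_or_below_7_20  wilcoxon_p
 fsi_min    32.42(31.73-37.05)    47.38(45.86-49.13)    0.000148
 fsi_max    43.62(41.56-45.47)    51.86(48.85-53.47)    0.000046
fsi_mean    38.20(36.63-41.50)    50.34(47.08-51.27)    0.000046

    variable       rho            p  n
          ph -0.833043 4.375168e-07 24
     lactate  0.646087 6.483519e-04 24
...
```

Each cell is median(Q1–Q3) over blood-gas sampling events during
occlusion. FSI_min is markedly higher for acidotic samples (pH ≤ 7.20)
and correlates negatively with arterial pH — deeper acidosis drives
larger vagal HF oscillations, which is exactly what the index is built
to detect. Lactate rises in parallel, while heart rate and arterial
pressure do not separate the groups.

The same pipeline runs from the shell:

```sh
fsi simulate --out data/ --seed 7            # per-subject rr.csv + events.csv
fsi analyze data/ --out tables/              # the three result tables
fsi compute data/subject00/rr.csv --out out/ # FSI series for one subject
```

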