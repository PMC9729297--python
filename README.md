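# lipidiff

Differential untargeted LC-MS lipidomics of bacterial strains.

`lipidiff` implements the desk side of a strain-contrast lipidomics
experiment: three bacterial strains (an *E. coli* OP50-like reference and two
lactobacilli) are profiled by LC-QTOF in positive and negative electrospray
with six replicates per strain, and the package turns the per-run peak lists
into aligned features, pairwise differential calls, accurate-mass lipid
annotations, and per-strain lipid-class compositions. It is aimed at
metabolomics/lipidomics analysts who receive vendor-exported feature lists
(m/z, retention time, intensity) and want a reproducible, testable pipeline
rather than a one-off script.

A ground-truthed synthetic-data generator emulating the full study design
(3 strains x 6 replicates, two polarities, class-specific adducts, log-normal
intensities, planted fold changes, dropout, <=5 ppm mass error, RT jitter) is
part of the package, so every stage can be exercised and validated without
any external data.

## The analysis

For each polarity, observations are aligned across runs by greedy
median-anchored clustering (5 ppm m/z gate, 15 s RT gate) into consensus
features. The three-strain feature matrix is then split into the three
pairwise datasets, and each pair is processed in order:

1. **100%-missingness filter** — features with zero detections in one strain
   move to a qualitative *exclusives* table (one-strain-only lipids);
2. **presence filter** — keep features detected in >= 80% of the replicates
   of at least one strain (>= 5 of 6);
3. **imputation** — missing cells become 0.9 x the feature's minimum
   observed intensity (left-censoring assumption);
4. **cyclic loess normalization** on log2 intensities: for every sample pair
   *(j, k)*, M = log2 x_j − log2 x_k is regressed on
   A = (log2 x_j + log2 x_k)/2 with a tri-cube-weighted local linear
   smoother and half the fitted trend is transferred between the samples.

Per feature, log2 intensity is regressed on the two-level strain indicator;
the group-coefficient test equals the pooled-variance two-sample *t*-test.
Multiple testing uses Storey *q*-values: pi0 is estimated from
pi0(lambda) = #{p > lambda} / (m(1 − lambda)) on a 0.05..0.95 grid, spline
smoothed and read at lambda = 0.95, and q_i = pi0 · min_{p_j >= p_i} m p_j /
rank(p_j). A feature is called significant when p < 0.01 and its linear fold
change (strain A mean / strain B mean) is > 1.5 or < 0.667, both strict;
*q* is reported alongside.

Annotation matches each consensus feature against a bundled sum-composition
library at its subclass's required adduct — FFA: [M+NH4]+ / [M−H]−;
PE: [M+H]+ / [M−H]−; PG: [M+NH4]+ / [M−H]−; PC: [M+H]+ / [M+FA−H]−;
MGDG, DGDG: [M+NH4]+ only; lysyl-PG (LPG): [M−H]− only — within 5 ppm.
Dual-polarity classes are confirmed only when both ion forms coelute within
30 s across polarities; multiple confirmed features of one sum composition
get RT-ordered isomer suffixes (a, b, ...). Strain composition counts
confirmed lipids present (pre-imputation) in >= 80% of a strain's replicates,
aggregated by subclass. Six spiked internal standards are tracked as a
detection/ppm QC check only — normalization never uses them.

## Worked example

```sh
lipidiff simulate --output fixture --seed 1
lipidiff run --input fixture --output run
```

prints

```
wrote 2336 observations for 138 species to fixture
HA-114 vs OP50: 71 features tested, 32 significant (14 up, 18 down)
R0011 vs OP50: 73 features tested, 16 significant (9 up, 7 down)
HA-114 vs R0011: 94 features tested, 32 significant (18 up, 14 down)
annotations: 129 confirmed lipids (217 mass-match candidates)
```

The simulated experiment contains 120 library lipids plus unknowns and the
six internal standards. After alignment (122 positive / 101 negative
consensus features) each strain pair retains the 71–94 features shared at
sufficient presence; the planted three-fold changes drive the significant
calls. In `run/report.json` the composition census shows the designed
biology: the OP50-like strain has **no** MGDG/DGDG entries and is PE-rich
(21 of 64 confirmed lipids), while both lactobacilli carry glycolipids
(e.g. 12 MGDG + 12 DGDG for HA-114). Per-comparison volcano tables
(`*_volcano.csv`, with a `total=... significant=...` footer), exclusives
tables, annotations, composition, and internal-standard QC are written next
to the report.

The same API is available from Python:

```python
from lipidiff import SimConfig, generate_ground_truth, simulate_observations
from lipidiff import run_pipeline, write_fixture

cfg = SimConfig(seed=1)
truth = generate_ground_truth(cfg)
obs = simulate_observations(truth, cfg)
write_fixture(obs, truth, "fixture", cfg)
report = run_pipeline("fixture", "run")
```

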