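# Methods

This note documents the models, defaults, and numerical choices behind
`lipidiff`, and what the synthetic validation does and does not establish.

## Data model

A *feature observation* is one detected peak in one chromatographic run:
(sample, strain, polarity, m/z in Th, RT in seconds, intensity in arbitrary
units). A *consensus feature* is the cross-run merge of the same underlying
ion; its representative m/z and RT are the medians of its members. Lipid
identities are carried at sum-composition level (total acyl carbons : double
bonds); chromatographically resolved features sharing one sum composition
are *isomers* and are reported with RT-ordered suffixes, with no claim about
double-bond position (an n-7 vs n-9 distinction is not resolvable here).

## Alignment

Peak-list alignment is greedy median-anchored clustering: observations of
one polarity are scanned in ascending m/z; an observation joins an open
group when it is within `ppm_tolerance` (default 5 ppm) of the group's
running median m/z and `rt_align_tolerance_s` (default 15 s) of its running
median RT; among several qualifying groups the nearest in scaled
(ppm, RT) distance wins. If a group already holds a peak from the same run,
the more intense peak stays and the other seeds a new group — keeping one
peak per run per feature preserves peak semantics (summing was rejected).
The procedure is deterministic and near-linear after sorting; by the
single-linkage bound, all members of a group lie within twice each tolerance
of one another. On well-separated species it provably coincides with
all-pairs connected-components clustering, which the test suite checks
against an independent union-find oracle. The two polarities are aligned
independently and only linked later by annotation, mirroring the workflow
order of acquisition software. No RT warping is attempted; the tolerance is
exposed instead.

## Pairwise preprocessing

The three-strain matrix is split first and filtered second, per pair:

* **100%-missing filter.** A feature never observed in one strain of the
  pair cannot be tested; it is moved to the *exclusives* table with its
  per-strain presence counts and reported qualitatively only. This
  reconciles statistical filtering with the biologically interesting case of
  a lipid entirely absent from one strain.
* **Presence filter.** A feature is kept iff observed in
  >= ceil(0.8 x n) replicates of at least one strain. The ceiling makes
  "80% presence" attainable with n = 6 (>= 5 of 6); any other reading of
  80% with six replicates is not an integer count.
* **Imputation.** Missing cells become `imputation_factor` (0.9) x the
  feature's minimum observed intensity within the pair. This encodes
  left-censoring: what was not detected is assumed to sit just below the
  feature's observed detection level. The observed values are never touched,
  which the tests assert cell-by-cell.
* **Cyclic loess.** "Scale data" is interpreted as log2 intensities — the
  standard domain for M/A normalization (`log_base` is configurable). For
  every ordered sample pair the M-on-A trend is fitted with a tri-cube
  weighted local linear smoother (span 0.7) and half the fitted value is
  transferred between the two samples; a full pass over all pairs is
  repeated 3 times. The full pairwise variant was chosen over the fast
  mean-reference variant for symmetry; span and iteration count are
  conventional defaults, not reported values. The pairwise +/- corrections
  cancel exactly, so the grand log2 mean is conserved (asserted to 1e-6).
  With only two samples one pass removes a constant offset completely; with
  many samples the sequential pairwise sweep contracts between-group offsets
  geometrically rather than eliminating them in one pass, so strongly
  unbalanced designs converge slower — a documented property of the method,
  not an implementation artifact. Loess also assumes most features are
  non-differential; in very small feature sets with dense true signal the
  local fit can absorb some of it.

Imputation precedes normalization (the conventional order, and the order the
stages are described in); `impute_before_normalize` exists for
experimentation. Whether any residual per-sample scaling should precede
loess is left to the data producer; the pipeline applies none, since
injection volumes are assumed equalized upstream.

## Differential statistics

With exactly two groups, "regression analysis" of log2 intensity on a group
indicator is the pooled-variance two-sample t-test; the implementation
computes the closed form vectorized and the suite checks it against an
independent t-test oracle to 1e-10 (a Welch option exists). Zero residual
variance yields p = 1 at zero effect and p = 0 with a degenerate-variance
warning otherwise.

Storey q-values: pi0(lambda) = #{p > lambda}/(m(1 − lambda)) on the grid
0.05, 0.10, ..., 0.95 is smoothed with a cubic spline and evaluated at
lambda = 0.95, clipped into (0, 1]; q is the pi0-scaled step-up adjustment,
monotone in p and bounded by 1. With pi0 = 1 this reduces exactly to
Benjamini-Hochberg, which the tests exploit as an oracle. Below 100
p-values the spline is unstable and the estimator falls back to the
conservative pi0 = 1 with a warning. The estimator is noisy at the tail by
construction (the lambda = 0.95 bin holds ~5% of the p-values), so its
calibration is validated on the 20-seed average, where it sits near 0.92
for uniform inputs.

Significance gates on p < 0.01 (strict) combined with a linear fold change
> 1.5 or < 0.667 (strict); the q-value is reported alongside but is not the
primary gate — the dual p/q thresholds are resolved in favor of the stated
p threshold. Fold changes use arithmetic group means of the normalized,
back-transformed intensities (strain A, the first-named comparison member,
in the numerator); a geometric-mean mode is available. Exclusive features
never appear on volcano tables; they live in the exclusives report.

## Annotation

Step 1 matches every consensus feature against the library at the
class-specific adduct for its polarity within 5 ppm; all candidates are kept
ppm-sorted — no winner is forced, since identifications are not MS/MS
confirmed. Step 2 confirms: dual-polarity classes (FFA, PE, PG, PC) require
the opposite-polarity ion of the same lipid within 30 s; confirmation is
symmetric and evaluated from both sides, with the nearest-RT partner
recorded. Single-polarity classes (MGDG/DGDG positive-only, LPG
negative-only) are confirmed by their single required adduct. "LPG" here is
lysyl-PG (PG esterified with lysine), not lyso-PG. Adduct m/z arithmetic
uses the proton constant 1.007276 Da (electron mass folded in) and
monoisotopic atomic masses.

The bundled library is an editable sum-composition stand-in for a public
database: FFAs C12–C24 with 0–3 double bonds, optionally hydroxylated, plus
PE/PG/PC/MGDG/DGDG/LPG species over even total carbons 26–40 and the six
internal standards (LPC 13:0, PC 19:0/19:0, PC 14:0/14:0, PS 12:0/12:0,
PG 15:0/15:0, PE 17:0/17:0). Standards are tracked as a detected/ppm QC
record only; the PS and LPC standards are probed at generic [M+H]+/[M−H]−
since their classes have no annotation rule.

Composition counts confirmed lipid entities — one (sum composition, isomer
label), pooling its polarities — present pre-imputation in >= 80% of a
strain's replicates (imputed values are a statistics device, not evidence of
presence). Composition defaults to confirmed-only annotation
(`composition_confirmed_only`), since using all candidates would double
count ambiguous masses.

## Synthetic data generator

The generator emulates the study design: 3 strains x 6 replicates, two
polarities, one peak per required adduct per expressed lipid.

* **Composition control.** Each lipid's subclass is drawn from the pooled
  class proportions, and per-strain expression is thinned so that subclass
  frequencies among a strain's expressed lipids are exactly proportional to
  that strain's configured proportions (draws expressed nowhere are rejected
  whole, which preserves the proportionality). The default proportions make
  the OP50-like strain PE-rich with zero glycolipids and give both
  lactobacilli MGDG/DGDG and lysyl-PG. A chi-square goodness-of-fit test
  over 10 seeds at 2000 lipids validates the construction.
* **Intensities.** Log-normal: log2 intensity = per-lipid base (uniform
  14–20) + per-adduct response offset + N(0, sd) with
  sd = log2(1 + noise_cv). The default noise_cv = 0.2 is a modeling choice
  for within-strain variability, not a reported value. Planted effects add
  +/- log2(3) to one strain's base for `n_differential` lipids; all pairwise
  log2 differences are recorded as ground truth.
* **Mass and RT error.** ppm error is Gaussian (default sd 1 ppm) truncated
  at +/-5 ppm so simulated features always satisfy the annotation gate; RT
  jitter is Gaussian (default 3 s) around a per-lipid true RT drawn
  uniformly over a 60–4900 s window; reused sum compositions (isomers) are
  forced >= 120 s apart.
* **Missingness.** Dropout is independent per observation (default 5%) and
  intensity-independent; an optional left-censoring mode raises dropout as
  intensity falls below a reference, to stress the minimum-based imputation.
* **Unknowns and standards.** A configurable fraction of features receives
  m/z values kept > 20 ppm away from every library ion (no annotation
  possible); the six internal standards are spiked into every sample with
  zero dropout.

Determinism: one master seed; the truth and observation stages draw from
deterministically derived child streams, and noise variates are drawn even
for dropped observations so the stream is stable under dropout decisions.
Observations are emitted per run (sample-major), like real peak lists.

What the generator does **not** emulate: chromatographic peak shapes,
isotopologues, in-source fragmentation, adducts beyond the rule table, RT
drift between runs, batch effects, or correlated (compositional) intensity
structure. Passing tests therefore demonstrate the correctness of the
pipeline's logic and its statistical calibration under the stated noise
model — not robustness to every artifact of real LC-MS data.

## Validation scales and known limitations

The acceptance checks run the statistics on 20 seeds x 1000 features
(calibration and power) and the full pipeline on 400 lipids with 60 planted
three-fold effects — sizes chosen to give stable Monte-Carlo estimates while
keeping the suite fast. At those scales the null p < 0.01 rate sits inside
[0.005, 0.02], planted-effect sensitivity is ~0.85–0.92, and the
truth-based empirical FDR of the significant sets is below 0.1.

Known limitations:

* Cyclic loess distorts individual features when the tested set is small
  (tens of features) and a large share carries true signal; the pipeline is
  intended for feature counts in the hundreds and up.
* The pi0 spline estimate is unreliable below ~100 features and falls back
  to 1 (making q-values Benjamini-Hochberg, i.e. conservative).
* Annotation is accurate-mass + coelution only; without MS/MS it cannot
  separate isobaric lipids inside the ppm gate, and candidates are reported
  ranked rather than resolved.
* Alignment assumes jitter well inside the gates; species closer than the
  tolerances in both m/z and RT will merge.
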