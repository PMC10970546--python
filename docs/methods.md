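# Methods

## Data model

A *molecular feature* is an (m/z, retention time) pair with one intensity
per injection, produced upstream by peak picking/alignment (out of scope
here); one table per ESI polarity. Missing cells (empty on disk, NaN in
memory) mean "not detected" and are distinct from measured zeros. The
sample sheet gives each injection a role — `biological` (subject +
timepoint), `qc_pool` (pooled aliquot of all study samples, injected
periodically), `qc_cond` (leading column-conditioning injections, never
used in statistics), or `blank` — and a unique injection order.

## Synthetic studies

The generator emulates the statistical structure the analysis assumes, not
raw spectra. Per feature f and subject s on the log10 scale:

    log10 x_{f,s,t} = mu_f + b_{f,s} + delta_f * 1[t = late] * log10(2) + e

* `mu_f ~ U(4, 7)` — feature baseline (arbitrary area units, typical Q-TOF
  dynamic range).
* `b_{f,s} ~ N(0, 0.15)` — between-subject effect, shared across the
  subject's two timepoints; this is what makes the design paired.
* `delta_f` — planted signed log2 fold change, `|delta| ~ U(1, 3)` for a
  fraction `fraction_discriminant` (default 0.01) of features, 0 otherwise.
* `e` — multiplicative analytical noise with per-feature CV:
  `ln`-scale sd `sqrt(ln(1 + CV^2))`. CVs are log-normal with median 10%
  and sigma 0.25, except a planted 15% of features drawn `U(0.60, 1.00)`
  to represent grossly irreproducible channels. The two groups are placed
  well apart from the 30% filter threshold deliberately: with a realistic
  number of QC injections the sample-CV estimator has chi-square spread,
  and a generator that scattered true CVs across the 25–35% band would
  make filter outcomes near the threshold a coin flip rather than a
  testable contract.

QC pools are the per-feature mean of all biological samples (physical
pooling on the linear scale) plus analytical noise; the five conditioning
injections replicate the first pooled draw and are flagged for exclusion.
One internal-standard feature per mode sits at a constant true level
(default 1e6) with 3% injection noise and an optional linear drift in
injection order; leucine-enkephalin [M+H]+ 556.2766 (ESI+) and reserpine
[M−H]− 607.2661 (ESI−) provide realistic anchor m/z values.

Defaults mirror the study: 6 subjects × 2 timepoints, 4045/9712 features,
≥5 conditioning injections, a pool every 6 biological injections. The
`small_config` preset (80 + 120 features) used in the test suite sets
`qc_pool_every=1` (~14 pools): with only the 2–3 pools of the full-size
spacing, a sample CV over so few replicates is far too noisy to separate
planted 25%/35% CV groups at a 30% threshold.

The generator does **not** model chromatographic peak shape, isotope
envelopes, co-elution, detector saturation, or batch effects beyond linear
drift — so green tests certify the statistics of the pipeline, not its
behaviour under real matrix effects.

## QC normalization and filtering

The ISTD report fits ordinary least squares of area against injection
order (slope, slope-t p-value) and reports the sequence CV%. Normalization
multiplies each sample by `median(ISTD areas) / sample's ISTD area`; the
median reference keeps one bad injection from rescaling the whole
sequence, and the operation is idempotent. The CV filter computes
CV% = 100·sd/mean (sample sd, n−1) over pool injections only
(conditioning QCs excluded), removes features with CV% **≥** the threshold
(inclusive, default 30), and removes features observed in fewer than half
the pool injections as unquantifiable.

## Volcano selection

FC is the ratio of linear-scale means (late/early); the test is a
two-sided paired t-test on log10 intensities so that multiplicative
subject effects cancel. Before testing, missing and non-positive cells are
imputed with half the feature's minimum positive observed intensity (the
usual left-censoring stand-in). Degenerate features whose paired log
differences are all identical get p = 0 when the common difference is
nonzero and p = 1 otherwise, with a flag. No multiple-testing correction
is applied: the volcano is a screen feeding the multivariate model, and
correcting it would change which variables that model sees.

## OPLS-DA

Variables are autoscaled (mean 0, unit variance, sd with n−1); y is coded
−1/+1 and centered. Orthogonal components follow the O-PLS recipe: with
predictive weight `w ∝ X'y` (unit norm) and loading `p`, the orthogonal
weight is `w_o ∝ p − (w'p)w`; X is deflated by the resulting score/loading
pair and the step repeats. The predictive component is then refit on the
filtered matrix. With `n_ortho=0` this is exactly single-component PLS1-DA
(asserted in tests to 1e-10). `n_ortho="auto"` adds components while
cross-validated Q2Y improves by more than 0.01, capped at 5; the pipeline
default is 0, appropriate for the few strongly univariate variables a
volcano screen passes through.

Cross-validation is stratified k-fold (default 7): each class is shuffled
with a seeded generator and dealt round-robin, and scaling parameters are
re-estimated inside every training fold — Q2Y = 1 − PRESS/SS is leakage
free, and the implementation is pinned against an independently coded
per-fold oracle. CV-ANOVA uses F = ((SS − PRESS)/A)/(PRESS/(N − A − 1))
with A = 1 + n_ortho total components; the published formulation leaves
the degrees of freedom partly heuristic, and this convention is committed
and tested for its limits (F = 0/p = 1 when PRESS = SS; p → 0 as
PRESS → 0). The permutation test refits model + CV per permuted y with
identical settings and reports the add-one estimator
p = (1 + #{Q2_perm ≥ Q2_obs})/(n + 1), plus the intercepts of the R2/Q2
regression lines on |corr(y_perm, y)| with the observed point included at
correlation 1 (the usual permutation-plot summary).

VIP on the single predictive component is `VIP_j = sqrt(p)·|w_j|`, which
makes Σ VIP² equal the variable count exactly. Confidence intervals come
from a jackknife over the k CV training subsets (mean ± t_{0.975,k−1}·SE).
Selection keeps variables ranked in the top 30 by full-model VIP whose CI
lower bound is positive — a VIP is nonnegative, so "CI excluding zero" is
read as the lower bound staying above it. Ties in VIP rank break by
variable id for determinism.

The pipeline fits one joint model on the concatenated pos+neg matrix
(after per-mode normalization/filtering), because the printed VIP rankings
mix both polarities in a single list; the two acquisitions come from the
same injections, so sample ids align.

## Annotation

Formulas are parsed by a strict `Element(count?)+` grammar over a bundled
most-abundant-isotope mass table (cross-checked in tests against
pyteomics to 1e-4 Da). Adduct deltas carry the electron correction
(proton 1.00727646 Da). Matching accepts
|1e6·(obs − theo)/theo| ≤ 20 ppm — loose enough for the largest printed
deviation (~5 ppm on this instrument class), tight enough to keep the
worked-example compound counts exact. Theoretical m/z is always
monoisotopic even though library "theory" masses in the source tables are
average molecular weights: a Q-TOF observes the monoisotopic peak. All
hits within tolerance are retained with the smallest-|ppm| hit per feature
flagged best; distinct-compound counts use best assignments only (one
identity per variable, as in an identification table). Hits carry no
MS/MS or retention-time evidence and are therefore annotation level 3.

Known limitation: the printed phosphatidic acid assignment
(C37H71O8P, observed 705.4863) is not reconcilable with any single-charge
adduct in the registry (~4×10^4 ppm off [M+H]+) and brassinolides has no
printed observed m/z; both compounds stay in the library but are excluded
from count contracts.

## Problem sizes and determinism

The test suite runs the full-size configuration (4045 + 9712 features,
1000 permutations on the volcano-selected subset) and asserts byte-level
reproducibility of every artifact across two runs with the same seed; the
statistical calibration suites use 20 replicate null datasets
(20 samples × 50 variables) at 200 permutations and the small preset for
ground-truth recovery. All randomness flows from `numpy.random.default_rng`
seeded explicitly; reports are JSON with sorted keys so equal runs are
byte-equal.
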