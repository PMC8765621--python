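# Methods

This note documents the models and procedures implemented in `facefreq`,
the assumptions behind them, and the choices made where the design was
genuinely open.

## The paradigm being modeled

The pipeline analyzes a two-alternative forced-choice EEG experiment on
*spatial-frequency hybrid faces*: each stimulus combines the
low-spatial-frequency (LSF, < 6 cycles/face) content of one rendering of
a face with the high-spatial-frequency (HSF, > 24 cycles/face) content
of another rendering of the same face, each band carrying either a
happy or an angry expression. Crossing the two bands gives four
conditions — AA, HH (congruent) and AH, HA (incongruent; first letter =
LSF emotion). Two groups of parents are compared: parents of typically
developing children (pTD, n = 18) and parents of children on the autism
spectrum (pASD, n = 25), the latter carrying a per-parent child-severity
score. The analysis questions are (a) whether late ERP activity (LPP,
430–730 ms) is modulated by the emotion content of the two bands and
their congruence, (b) whether that modulation is attenuated in pASD,
and (c) whether the attenuation relates to child symptom severity.

## Stimulus construction

Spatial filtering is done in the Fourier domain with a radially
symmetric Butterworth gain specified in cycles per face *width* (the
horizontal width sets the unit on both axes). The low-pass amplitude
gain is `(1 + (f/fc)^(2n))^(-1/2)`, i.e. squared gain = classic
Butterworth `1/(1+(f/fc)^(2n))` with half power exactly at the cutoff.
The high-pass is defined as the amplitude complement `1 − H_low`, which
guarantees that low-pass + high-pass at the same cutoff reconstructs
the input exactly — a property the tests rely on. Consequences of these
choices, verified analytically in the tests: the attenuation of an
order-2 low-pass at twice the cutoff is 10·log10(1 + 2⁴) ≈ 12.3 dB
(20 dB requires order ≥ 4), and the complement high-pass reaches 90% of
its pass-band gain only well above its cutoff. The Butterworth order is
not fixed by the source description; order 2 is the default and a
parameter. No padding is applied (the FFT treats images as periodic),
so linearity and complementarity hold to machine precision.

At the default display size of 5.30° × 6.80° of visual angle, the 24
and 6 cycles/face cutoffs correspond to 4.53 and 1.13 cycles/degree
("about 4" and "about 1").

Face photographs cannot be redistributed, so `synth_face` draws a
procedural face (oval, eyes, brows, mouth) whose brow angle and mouth
curvature encode the emotion; geometry jitter and texture depend only
on the identity seed, so the two emotions of one identity differ only
in the brow/mouth regions. These images are synthetic stand-ins with
broadband spectra, adequate for exercising the filtering and trial
machinery but not for perceptual claims.

Trial lists: 29 identities × 4 conditions = 116 distinct stimuli, each
shown once per block in random order, two blocks of 116 trials (232
total), response-hand mapping counterbalanced between blocks. (The
source description is internally inconsistent on whether each stimulus
appears once or twice per block; once per block is the reading
compatible with 232 total trials.)

## Synthetic EEG generator

Each participant's epoch is a sum of Gaussian-in-time component
templates with fixed spatial topographies (sums of Gaussian blobs on
the 2-D montage), plus Gaussian noise that is white in time and
spatially correlated across channels with exponential distance decay
(correlation 0.6 at neighbor distance), which makes adjacency-based
clustering meaningful. Defaults, chosen once:

| component | latency | FWHM | amplitude (μV) | topography |
|---|---|---|---|---|
| P1 | 125 ms | 50 ms | +5 (all conditions) | occipital |
| N170 | 180 ms | 50 ms | −6 (all) | bilateral temporo-parietal |
| N250 | 300 ms | 100 ms | −3 (all) | bilateral temporo-parietal |
| LPP | 580 ms | 300 ms | HH +3, AA +1, AH/HA +1.5 | left-frontal + right-parietal |

The study does not report per-condition amplitudes in μV; the LPP
values above are free parameters giving a plausible late modulation.
In pASD the LPP condition *contrast* (deviation from the condition
mean) is multiplied by an attenuation factor, default 0.3. Between-
subject heterogeneity: an additive per-participant amplitude shift per
component (SD 0.75 μV) and a multiplicative jitter on each component's
condition contrast (SD 0.2).

Noise is 5 μV per sample (band-limited single-trial scale), which puts
the condition-mean noise floor at 58 trials around 0.7 μV — typical of
residual ERP noise — and makes the planted group-dispersion contrast
detectable at the study's sample sizes, as the downstream analyses
require. With 10 μV the dispersion test has essentially no power at
n = 18/25; this calibration was fixed once and is part of the study
conditions the generator defines.

What the generator does **not** emulate: 1/f temporal autocorrelation
of EEG noise, ocular/muscle artifacts with realistic waveforms (a
square-pulse injector exists only to exercise rejection), volume-
conduction mixing from actual sources, latency jitter across trials,
and drop-out/unbalanced trial counts. Passing tests therefore
demonstrate correctness of the statistical machinery under its stated
assumptions, not robustness to every property of real recordings.

Behavior: per-trial Bernoulli "happy" responses with per-condition
probabilities (defaults HH 0.74, AA 0.41, AH 0.615, HA 0.553 — chosen
to reproduce congruent accuracies of 0.74/0.59, an emotional bias of
~0.084 and a spatial-frequency bias of ~0.03 in expectation) and
log-normal reaction times (means 607–650 ms, SD 150 ms; log-normal
because RTs are positive and right-skewed).

Severity scores: each pASD parent's realized LPP ROI contrast
(mean HH − mean AA over the right-parietal ROI, 430–730 ms) is
standardized against the cohort and combined with independent noise at
the Pearson correlation `2·sin(π·ρ_s/6)` that corresponds to a target
Spearman ρ_s (default −0.5) under bivariate normality. A plain linear
rule (`intercept − slope·contrast + noise`) is available instead.

Reproducibility: one global seed expands into per-participant
substreams (`SeedSequence` spawn keys), so identical configurations are
bit-identical and single participants can be regenerated.

## Preprocessing

Order: average re-reference (bad channels excluded from the mean) →
zero-phase 0.1–30 Hz Butterworth band-pass (order 4, forward–backward,
maximal odd-reflection padding so the slow high-pass transient does not
leak into the 2-s epoch) → per-trial baseline subtraction over
[−500, 0] ms → artifact rejection → bad-channel interpolation.

Artifact rules: a trial is rejected if any good-channel sample exceeds
150 μV (applied after re-referencing; the source description does not
say before or after), or if its channel-averaged periodogram exceeds
the across-trial mean + 2 SD in more than 10% of the 1–30 Hz bins. The
reference distribution for the spectral rule is across trials within
participant — the only self-contained choice — and zero-SD bins never
flag. Interpolation replaces a bad channel by the inverse-distance
weighted mean of its good layout neighbors (adequate for a synthetic
2-D template; spherical splines would be preferred on a real montage),
and recordings with more than 10% bad channels are refused, mirroring
the study's inclusion rule. Ocular ICA is out of scope; a hook accepts
an externally computed unmixing matrix.

## Sensor layout

A synthetic 64-channel montage on concentric rings in the unit head
circle. Six electrodes used by the a-priori component analyses are
pinned to canonical posterior positions (E27/E30 ≈ P7 region, E44/E45 ≈
P8 region, E35/E39 ≈ PO1/PO2); the exact commercial net geometry is not
reproduced and the name map is overridable. Adjacency is the Delaunay
triangulation of the 2-D positions with edges longer than 1.6× the
median removed; ROI sets (occipital, left-frontal, right-parietal,
temporo-parietal) are defined by position.

## A-priori ERP components and the mixed ANOVA

P1 = maximum over 100–150 ms at E35/E39; N170 = minimum over 160–200 ms
and N250 = mean over 250–350 ms at E27/E30 (left) and E44/E45 (right).
The signal is averaged over the hemisphere's electrode set *before*
taking the window extremum ("mean of the greater peak" is ambiguous
between this and a mean around the extremum; the extremum is
implemented and the aggregation order is isolated in one function).

The condition × laterality × group ANOVA is implemented through
orthonormal within-cell contrasts: for each within effect, the
participants' contrast scores enter a one-way between-group analysis,
yielding the classical split-plot F tests with unequal group sizes
handled exactly. Main within effects use Type II sums of squares
(weighted grand mean) by default, with Type III available. Sphericity
for multi-df effects uses Mauchly's W on the pooled within-group
contrast covariance with Greenhouse–Geisser and Huynh–Feldt corrected
p-values; generalized η² is computed with all error strata in the
denominator, which the orthonormal basis puts on a common scale. The
implementation is cross-checked in the tests against statsmodels
`AnovaRM` (within-only case, exact agreement), pingouin `mixed_anova`
(one within factor, exact agreement) and a hand-rolled balanced
sums-of-squares oracle.

## Cluster-based permutation statistics

Site-wise tests on participant-level values at every (electrode,
time-bin): Friedman (paired, k ≥ 3), signed-rank z (paired, k = 2),
Kruskal–Wallis (unpaired, k ≥ 3), rank-sum z (unpaired, k = 2), all
midrank/tie-corrected; fully tied sites give statistic 0 and p = 1,
never NaN. Supra-threshold sites (p < 0.05 by default) are clustered by
electrode adjacency within a time-bin and temporal contiguity within an
electrode; signed statistics cluster within sign. The cluster statistic
is the mass (sum of member statistics); extent is not used because mass
dominates it for broad effects. Correction uses the distribution of the
*maximum* cluster mass across permutations: condition labels are
shuffled within participant (paired) or group labels across
participants (unpaired). Because tests run on per-participant condition
means, every permutation uses exactly the observed trial counts per
cell. The tests operate on participant-level means rather than pooled
trials — the choice consistent with a Friedman paired design.

Monte-Carlo p-values use the add-one convention `(b+1)/(n_perm+1)`,
which is valid and never zero; when the relabeling space has at most
10,000 arrangements the engine enumerates it exhaustively and reports
the exact rate (identity included). Permutations re-aggregate
precomputed ranks (ranks and tie corrections are invariant under
relabeling), which is what makes the 500-study null calibration run in
about two minutes.

The group × condition interaction test follows the study's construction:
per participant, the SD across the four condition means at every site
("condition dispersion"), compared between groups with the rank-sum
cluster permutation.

## Trial-level mixed model

Single-trial mean amplitudes over a temporal ROI (default 450–630 ms,
the window of the late congruence modulation) at one electrode are
modeled with a linear mixed model: random intercept per participant and
fixed effects int, EmoLSF, EmoHSF, EmoLSF×HSF, pASD, pASD×EmoLSF,
pASD×EmoHSF, pASD×EmoLSF×HSF, Sex (happiness coded 1 in each band;
HH=(1,1), AA=(0,0), HA=(1,0), AH=(0,1); Sex coded 0/1 with 0 =
reference). Trial-level responses are used because a participant
random intercept is only meaningful with replicates. Fits are maximum
likelihood (statsmodels `MixedLM`) with Wald p-values; an OLS route
(`random_intercept=False`) gives the zero-variance limit exactly.
Per-coefficient p-values across electrodes are corrected with
Benjamini–Hochberg FDR at q = 0.05.

Severity correlations are Spearman; the partial variant rank-transforms
all three variables, residualizes the two of interest on the covariate
ranks, and correlates the residuals (t approximation, n − 3 df). This
matches pingouin's partial Spearman exactly (tested).

## Behavioral statistics

Accuracy is defined only on congruent trials. Biases on incongruent
trials: SF bias = P(response matches the HSF emotion) − 0.5, emotional
bias = P("happy") − 0.5, both in [−0.5, 0.5] by construction. The
corrected emotional bias subtracts half the congruent accuracy gap per
participant: `corrected = raw − (acc_HH − acc_AA)/2`; the published
description of this correction is verbal only, so this closed form is
this package's documented reading, isolated in one function, and not
asserted to be the original computation. d′ = Φ⁻¹(hit) − Φ⁻¹(fa) with
the log-linear remedy ((x+0.5)/(n+1)) applied only to degenerate rates.
Wilcoxon tests use the exact null distribution for n ≤ 25 without ties
and the normal approximation with continuity correction otherwise;
the effect size r = |Z|/√n recovers Z from the two-sided p. The
happiness-rate and RT condition × group ANOVAs use pingouin's mixed
ANOVA with generalized η² and GG correction, cross-checked against the
contrast-score implementation.

## Power analysis

For the group × condition interaction of a 2 × 4 mixed ANOVA under
compound symmetry: df1 = (k−1)(m−1)ε, df2 = (N−k)(m−1)ε, noncentrality
λ = f²·N·m·ε/(1−ρ) with f² = η²/(1−η²) from the partial η². Defaults
ρ = 0.5, ε = 1 (the conventional calculator assumptions; the assumed
correlation is rarely reported). Minimum sample size searches N upward
and by default rounds up to a multiple of the group count, as
sample-size calculators do. The analytic power is validated against a
from-scratch Monte-Carlo simulation of the compound-symmetric
split-plot (the oracle builds the interaction F from orthonormal
contrast scores directly). With η² = 0.06, α = 0.05, target 0.95 the
minimum N is 36 (35 before group rounding); the achieved power at
N = 43 computes to 0.982 under these assumptions, and the simulation
confirms the analytic value.

## Problem sizes used by the tests and the acceptance script

Simulated studies run at 16 channels, 125 Hz and the real group/trial
sizes (18 + 25 participants, 58 trials/condition); null-calibration
studies use 12 participants × 16 channels × 100 bins with 200
permutations, 500 studies; the trial-level model recovery uses 40
participants × 200 trials × 200 replicates. All analyses are specified
in milliseconds and are sampling-rate independent, so these sizes probe
the same contracts as a full-resolution run.

## Known limitations

* The montage and its E-number map approximate, not reproduce, the
  commercial net; component electrode choices are config-overridable.
* Source localization is out of scope; everything is sensor-space.
* The spectral artifact rule assumes enough trials per participant for
  a stable across-trial reference distribution.
* Friedman/Kruskal site-wise p-values are asymptotic; at small n they
  are conservative (the cluster permutation correction does not depend
  on their calibration, only on their ordering).
* `ncf`-based power assumes compound symmetry; ε < 1 is an approximate
  correction, not an exact nonsphericity model.
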