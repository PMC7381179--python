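# Methods

## The morphology score

Approximate entropy is computed in its original form: template vectors
of length `m` compared under the Chebyshev norm with tolerance `r`,
self-matches included (which keeps every logarithm finite and is the
classic parameterisation), and `ApEn = Phi^m - Phi^{m+1}`. Defaults are
`m = 2` and `r = 0.2 * SD(series)`; both are configuration, not
constants, since reasonable variants of the statistic differ in exactly
these choices. Defining `r` relative to the series SD makes the score
invariant under amplitude scaling — a trace recorded at a different
gain scores identically — which the test suite asserts to 1e-9.

Per-point contributions `a_i = ln C_i^m - ln C_i^{m+1}` are exposed
over the common index range (length `N - m`), together with an
11-point running mean for plotting. Their average differs from the
final value only by a boundary term of order 1/N (checked empirically
at 5/N). A constant series returns 0 by convention: the definition
degenerates there, and 0 is the natural reading of "perfectly
regular".

The vectorised implementation builds the pairwise closeness matrix
once and derives the m- and (m+1)-dimensional match counts by shifted
conjunction, so one 1920-sample trace costs ~50 ms. A deliberately
naive triple-loop implementation (`apen_bruteforce`) is kept as an
independent oracle; the suite checks agreement to 1e-9 on 100 series
of mixed dynamics.

### Normalisation

The raw value in nats is divided by a reference constant `c` and
clipped to [0, 1]. `c` is the mean raw ApEn of 50 i.i.d. standard
Gaussian series of the same length at the same `(m, r)` (~1.89 nats at
N = 1920), computed once per parameter set from a fixed internal seed
and cached. The choice makes the normalised scale interpretable ("1 =
as irregular as noise") and length-adjusted: shorter recordings have a
smaller noise asymptote, and calibrating at the actual length keeps
the scale comparable. A decision threshold of 0.545 on the normalised
scale ships as the configuration default for users who want a fixed
operating point rather than a fitted one; the pipeline default is to
fit the threshold by the Youden index on training data, since any fixed
cut-point is only meaningful relative to the score distribution of the
cohort at hand.

### Auxiliary features

*Phase count* (`count_peaks`): crossings of the baseline-referenced
zero line, with a hysteresis gate at `4 x` the pre-onset baseline SD so
that baseline noise does not register. Raw zero crossings of a noisy
baseline would count noise, not phases; the gated count is 2 for a
clean biphasic response and grows with polyphasia. It is invariant
under amplitude scaling and sign flips.

*Latency*: first time after the stimulus-artifact window where the
signal leaves the baseline-mean band by more than `3.5 x` the baseline
SD for at least 0.5 ms continuously. The baseline window (5-15 ms)
sits after the artifact and before the earliest physiologic onset.
The threshold scales with the baseline SD, so the result is
gain-invariant; a flat trace yields "absent" rather than a number.

*Peak-to-peak*: max minus min, in uV.

## Trace handling

Traces travel in long ("tidy") delimited text with an explicit
`sample_index`; the format survives ragged trace lengths and is
trivially diffable. Recordings arrive at 19.2 or 20 kHz; 20 kHz traces
are brought to 19.2 kHz by the exact rational factor 24/25 using
polyphase resampling with the standard anti-aliasing filter (a 1 kHz
tone keeps its amplitude to within 1%). Per limb and side, the trace
with the maximal peak-to-peak amplitude is the analysis trace — the
strongest available response is the most informative one. Ties are
broken by higher excitation percentage, then lexicographic trace id,
purely so the selection is deterministic.

## Consensus labels

A trace flagged `bad` by at least one rater in the primary labelling
session is discarded from all analyses and all raters' records; the
rule is idempotent and the discard fraction is logged. Repeat-session
flags do not trigger the discard: the repeat pass exists to measure
intra-rater variability, and letting it veto traces would couple the
two analyses.

The five-vote reference is the plain majority (five votes cannot tie).
Evaluating rater R against a reference that contains R's own vote would
flatter R, and dropping only R leaves four votes that can tie 2-2;
three-vote references therefore leave out R plus one other rater in
turn, giving four sets per rater, and any metric "on the 3-vote" is the
unweighted mean over the four sets (twenty sets panel-wide). Traces
missing a required vote are dropped from that set with a warning rather
than imputed; complete panels never hit this path.

## Agreement statistics

Agreement fraction and Cohen's kappa, evaluated pairwise (each rater
against the other four) and averaged per rater and over the panel;
intra-rater values compare primary and repeat labels on the
twice-labelled traces. Kappa conventions for degenerate tables, which
arise in simulation edge cases only: both raters constant and identical
gives 1; both constant but different gives 0 (logged). When no repeat
sessions exist the intra-rater fields are absent, not zero.

## Screening and threshold selection

Each candidate feature is fitted alone — intercept plus slope — by
unpenalised maximum-likelihood logistic regression against each
individual rater's labels, and ranked by mean held-out AUC over 3-fold
cross-validation. Unpenalised is the faithful default: with one
predictor, a ridge penalty only shrinks the slope and cannot change
the AUC (perfect-separation divergence is capped by the iteration
limit, which again leaves the AUC untouched). Features are
standardised on the fold-train portion for numerical stability;
reported thresholds always live on the raw feature scale. Folds and
the train/test split are grouped by patient, so no patient's traces
straddle a split. Features with missing values or zero variance are
recorded as absent rather than ranked; AUC ties break by feature name.

The operating threshold maximises the Youden index (TPR - FPR) over
midpoints of consecutive sorted unique scores — midpoints make the
boundary data-independent within gaps — with ties resolved toward the
smaller threshold. Fitting per-rater thresholds on the latent scale of
the simulator recovers each simulated rater's true cut-point to within
0.05 at n = 500, which is the package's demonstration that disagreement
between raters is mostly threshold placement, not concept.

Evaluation reports AUC and average precision from scores, and F1,
accuracy, precision, recall and kappa from thresholded predictions;
against a list of three-vote sets each metric is reported as mean and
standard deviation across sets. AUC uses the Mann-Whitney convention
(ties count 1/2); the trapezoidal area under the emitted ROC table
equals the scalar AUC to 1e-12.

## Clinical analyses

EDSS linkage takes the record nearest the visit within +-1 year
(equidistant ties to the earlier record; unlinked visits are dropped).
The 2-year progression rule: an increase of >= 1.0 from a baseline
<= 5.5, or >= 0.5 from a baseline > 5.5, at the follow-up between 1.5
and 3 years closest to the 2-year mark (ties to the earlier record).
The rule is verified exhaustively over all 441 half-step EDSS pairs.

Mutual information uses the Kraskov-Stoegbauer-Grassberger k-NN
estimator (first variant, k = 3 by default), written directly on
`scipy.spatial.cKDTree`: the estimator is symmetric and deterministic
by construction, which the suite asserts to 1e-9 — scikit-learn's
implementation jitters the inputs and is used as a cross-check oracle
instead. Small negative estimates on independent data are clipped to 0
and logged. k-NN was preferred over histogram binning to avoid an
arbitrary bin count; values on near-deterministic relations grow with
n and should be read as "large", not as a calibrated number.
R-squared is ordinary least squares. Distribution summaries per EDSS
level exclude levels above 7.5 (too sparse) and use a Gaussian kernel
of absolute width 0.05 on the normalised ApEn axis.

## The synthetic cohort

The generator exists so that every stage has a ground truth; it
emulates the structure of the clinical study, not the biophysics of
motor conduction.

Each trace carries a latent abnormality `z` in [0, 1]. The waveform is
zero before a drawn onset (hand 18-28 ms, foot 35-50 ms after the
stimulus), then a single biphasic deflection (one sine period over
7-11 ms, amplitude 300-1200 uV), plus `round(z * 6)` Gabor atoms whose
temporal spread (4 + 36z ms) and frequency band (80 Hz to 200 + 600z
Hz) grow with `z`, plus a noise-like desynchronised-activity term
(amplitude `0.25 z` of the base amplitude under an envelope over the
dispersed window) that models the jagged fluctuation of dispersed
motor-unit potentials, plus 4 uV Gaussian baseline noise. Gabor atoms
alone turn out to be too smooth — too *predictable* — to raise ApEn the
way real dispersed responses do; the desynchronised-activity term is
what gives the generator its dynamic range (mean normalised ApEn
0.02 at z = 0 rising monotonically to ~0.46 at z = 1). Artifact
traces (flat line or amplifier-clipped swing, ~1% of traces) exercise
the bad-data path and are flagged bad by every rater.

A simulated rater labels a trace abnormal when `z + eps > tau` with
`eps ~ N(0, 0.05)` drawn per trace, flags bad with probability 0.0055,
and relabels a designated subset (the first 25 visits, i.e. 100
traces) with fresh noise for the intra-rater analysis. The default
panel has thresholds (0.40, 0.45, 0.50, 0.55, 0.60): shared concept,
spread cut-points. Patient-level abnormality is Beta(1.3, 2.6), chosen
so that against this panel roughly 74% of traces are labelled normal;
with the artifact rate, about 3.5% of traces attract at least one bad
flag. Foot traces sit 0.06 above and hand traces 0.06 below the
patient level (the longer peripheral pathway of the foot muscle
accentuates dispersion), trace-level noise is N(0, 0.12), and a
per-patient foot-specific component N(0, 0.15) models independently
varying leg-tract involvement — this last term is what makes foot
traces genuinely more informative about disability than hand traces
rather than both being proxies of the same patient effect.

Baseline EDSS is `7.5 x` mean foot `z` plus N(0, 0.7), rounded to the
half-step grid and capped at 7.5; the baseline record falls within two
months of the visit and the follow-up 580-1020 days later. Each
patient progresses with probability proportional to
`(0.15 + 0.85 x mean foot z)^2`, scaled so 20% of patients progress on
average; follow-up EDSS is then constructed to meet or miss the
progression rule exactly.

All randomness descends from one root seed through
`numpy.random.SeedSequence` spawning (separate streams for cohort
structure, waveforms, labels and EDSS), so identical seeds reproduce
identical cohorts byte for byte.

### What the simulation does and does not establish

Passing tests on this cohort show that the pipeline recovers known
structure: the entropy implementation is exact against its definition,
screening finds the feature that drives the labels, Youden fitting
recovers rater thresholds, the consensus and agreement algebra is
correct, and the clinical analyses detect associations that are present
by construction. They do not show that real MEP morphology is
one-dimensional, that real raters are threshold raters on any latent
scale, or that clinical effect sizes match the synthetic ones — the
synthetic associations (e.g. screening AUCs near 0.99) are cleaner
than clinical data would give, because the simulator's labels are
generated from the same latent score that drives the waveforms.

## Problem sizes and numerical choices

The end-to-end study runs at 300 patients (1,200 traces) with a 50/50
patient-disjoint split — large enough for stable AUCs and kappas,
small enough to run in under a minute; the determinism check reruns
the pipeline at 60 patients. Monte-Carlo checks use 50-100 replicates.
The regularity-ordering property (sine < noisy sine < noise) is
asserted at the native trace length N = 1920: on much shorter series
the (m+1)-dimensional template counts are undersampled and the
noisy-sine vs noise comparison can invert. JSON artifacts are written
with sorted keys and floats rounded to 10 digits so reruns are
byte-identical.

## Known limitations

- The waveform model is phenomenological (Gabor atoms plus enveloped
  noise), not a motor-unit or recruitment-curve model; stimulus
  intensity series are reduced to the retained maximal trace.
- The exact `(m, r)` and normalisation used by any particular clinical
  deployment of ApEn vary; both are configuration here, and normalised
  scores are only comparable across datasets that share them.
- The artifact simulator is a guess at what "bad data" looks like
  (dead channel, clipping); real artifact diversity is larger.
- KSG mutual information values on strongly dependent pairs are
  sample-size-dependent and should be compared only within a dataset.
- Visit dates are generated, not modelled; EDSS trajectories are
  two-point (baseline, ~2-year follow-up) rather than longitudinal.
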