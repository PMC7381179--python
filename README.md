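# mepmorph

Approximate-entropy morphology scoring for motor evoked potentials
(MEPs), with everything needed to validate the score against a panel of
human raters: synthetic MEP cohorts with known ground truth, consensus
label construction, inter-/intra-rater agreement statistics,
one-dimensional feature screening with Youden threshold selection, and
exploratory clinical association analyses.

## The problem

MEPs — the muscle response to transcranial magnetic stimulation of the
motor cortex — are recorded in people with multiple sclerosis to track
disease of the corticospinal pathways. Three variables are read off
each trace: **latency**, **peak-to-peak amplitude**, and the presence of
**morphological abnormality**. The first two are well defined; morphology
is a visual judgement. A healthy response is a single biphasic
deflection; demyelination desynchronises the descending volley and the
response becomes polyphasic and temporally dispersed. Different
neurologists agree on *what* abnormal morphology is but draw the
normal/abnormal line at different places, which makes manually
annotated datasets noisy and mutually incomparable — and manual
annotation does not scale beyond a few hundred traces anyway.

This package implements a reproducible continuous replacement for that
judgement: **approximate entropy** (ApEn), a regularity statistic
computed directly from the sampled trace,

```
ApEn(m, r, N) = Phi^m(r) - Phi^{m+1}(r),
Phi^m(r)      = (N-m+1)^{-1} * sum_i ln C_i^m(r),
C_i^m(r)      = #{ j : max_k |u(i+k) - u(j+k)| <= r } / (N-m+1),
```

with embedding dimension `m = 2`, tolerance `r = 0.2 * SD(u)`
(Chebyshev distance on template vectors, self-matches included). A flat
or smoothly biphasic trace is highly regular (ApEn near 0); steep,
long-lasting fluctuation — the signature of polyphasia and dispersion —
drives it up. The raw value in nats is divided by the mean ApEn of
white Gaussian noise of the same length and clipped to [0, 1], so the
**normalised score** reads "0 = perfectly regular, 1 = as irregular as
noise". Per-point ApEn contributions are also exposed, which localise
*where* on the trace the irregularity lives.

Because real rater labels and clinical traces cannot ship with a code
package, a first-class synthetic module generates the full study
setting: Gabor-atom MEP waveforms driven by a latent abnormality score
`z` in [0, 1], rater panels that threshold `z` with personal cut-points
and decision noise, bad-data artifacts, and EDSS disability
trajectories in which foot-trace abnormality carries most of the
signal. Every downstream stage is validated against this known ground
truth.

## A worked example

```
$ python examples/01_score_a_trace.py
normal (z=0.0)     raw ApEn = 0.041 nats   normalised = 0.022   gated crossings =   2   latency = 25.8 ms (true onset 25.7 ms)
abnormal (z=0.9)   raw ApEn = 0.753 nats   normalised = 0.398   gated crossings = 314   latency = 25.8 ms (true onset 25.7 ms)
```

The clean biphasic trace scores 0.022 on the normalised scale — almost
perfectly regular — while the polyphasic, dispersed trace of the same
amplitude and latency scores 0.398, an order of magnitude higher. The
other examples build on this: `02_rater_panel_agreement.py` prints the
agreement-fraction / Cohen's-kappa table of a simulated five-rater
panel (inter-rater 0.89, intra-rater 0.96 on the default cohort),
`03_screen_and_threshold.py` ranks candidate features per rater and
shows normalised ApEn topping every rater's list (CV AUC 0.99, noise
control at 0.5) before fitting a Youden threshold, and
`04_clinical_associations.py` links visits to EDSS records and shows
foot ApEn predicting 2-year disability progression better than hand
ApEn (AUC 0.843 vs 0.756 on its cohort).

There is also a thin CLI over the same functions:

```
mepmorph simulate --patients 50 --seed 7 --out data/
mepmorph features --in data/traces.csv --out data/features.csv
mepmorph agreement --labels data/labels.csv --out agreement.json
mepmorph run --patients 100 --seed 7 --out run/
```

## Layout

| Module | Contents |
| --- | --- |
| `mepmorph.features` | ApEn (vectorised + brute-force oracle), normalisation calibration, phase count, latency, peak-to-peak |
| `mepmorph.synthetic` | waveform generator, rater panel simulator, cohort/EDSS generator |
| `mepmorph.io` | long-format trace/label/feature/EDSS tables, 24/25 polyphase resampling, max-peak-to-peak trace selection |
| `mepmorph.consensus` | bad-data discard, majority vote, five-/three-/one-vote label sets |
| `mepmorph.agreement` | agreement fraction, Cohen's kappa, panel report |
| `mepmorph.screening` | patient-disjoint splits, per-rater CV screening, Youden thresholds, metric set, ROC/PR curves |
| `mepmorph.clinical` | EDSS linkage, 2-year progression rule, k-NN mutual information, R-squared, distribution summaries |
| `mepmorph.pipeline` / `mepmorph.cli` | end-to-end orchestration and the `mepmorph` command |

See `docs/methods.md` for the modelling choices and their rationale.
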