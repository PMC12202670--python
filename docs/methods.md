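# Methods

`aafkit` re-implements, as a tested pipeline, the analysis of multi-unit
recordings from rat anterior auditory field (AAF) in a three-group design:
saline-exposed controls (SAL), rats prenatally exposed to valproic acid
(VPA, an environmental autism model), and VPA-exposed rats that received
vagus-nerve-stimulation (VNS) speech pairing (VPA+VNS).  Because no
recordings are deposited, the package ships a synthetic spike-response
generator with the same nested cohort structure, so that every analysis
stage can be exercised, calibrated, and shown to recover the effects it is
supposed to measure.

## Stimuli

* **Tone pips.** 25 ms tones on a grid of log-spaced frequencies over
  1-32 kHz by levels 0-75 dB SPL.  The grid density is not part of the
  protocol's printed numbers; the default is 81 frequencies x 5 dB steps
  (1296 tones), standard for dense frequency-response-area mapping, and
  both axes are configurable.  Analyses in the test suite use coarser grids
  (13-25 frequencies) purely as a problem-size choice; every estimator's
  tolerance is stated relative to the grid step it was run with.
* **Noise-burst trains.** Six 25 ms bursts at 7.5, 10, 12.5 or 15 Hz;
  burst k starts at k\*1000/rate ms.
* **Speech proxies.** Seven consonant-vowel tokens (dad, bad, gad, tad,
  sad, rad, lad).  The originals are vocoded human recordings that are not
  redistributable, so `synth_speech_proxy` builds synthetic stand-ins: a
  label-specific 40 ms onset (broadband burst for stop-initial tokens,
  slower narrowband onset otherwise) followed by a shared formant-like
  vowel.  Any waveform with distinct label-conditional onsets satisfies the
  pipeline's needs; these are fixtures, not acoustic models.
* **Level calibration.** dB SPL is `20*log10(rms/ref)` with the package
  reference fixed so a full-scale sine reads 94 dB.  Speech is calibrated
  so the loudest 100 ms window sits at 60 dB SPL; the window search runs at
  one-sample hops (exact), with an optional coarser hop.
* **VNS.** 500 ms, 16 biphasic 100 us pulses at 30 Hz, 0.8 mA; in pairing
  sessions the train leads the sound by exactly 50 ms.
* **Pairing schedule.** Pairing inter-trial intervals are exponential with
  mean 30 s truncated to [10, 90] s; the exponential scale is solved
  numerically so the truncated mean is exactly the requested one, which
  makes a 9000 s session average ~300 pairings.  The 30 s mean is applied
  to pairing events only (the reading consistent with 300 pairings per
  2.5 h); silence catch trials are interleaved into a configurable fraction
  of the gaps, and an alternative mode applies the ITI process to the
  merged pairing+silence stream.

## Spike simulator

Spiking is an inhomogeneous Poisson process: a homogeneous spontaneous
component (default 5 Hz; the protocol reports no group differences in
spontaneous activity and prints no magnitude, so this is a fixture) plus
evoked alpha-kernel bumps `(t/tau)*exp(1-t/tau)` with tau = 5 ms (2 ms for
consonant onsets).  Sampling is exact by superposition: each bump's count
is Poisson with mean equal to its integrated rate and its spike times are
Gamma(2, tau) draws (the alpha kernel is the Gamma(2) density up to
scale); spontaneous spikes are uniform on the analysis window
[-100, +750] ms.  This has the same law as thinning at a fraction of the
cost, which is what makes grid-scale simulation and 200-site recovery
suites affordable.

Sites are nested in animals: site log-gain = group log-gain +
N(0, animal_sd) per animal + N(0, site_sd) per site (defaults 0.15 and
0.30).  CFs are log-uniform on 1-32 kHz, thresholds uniform on the 5 dB
grid in [10, 30] dB, onset latencies normal around the group mean.

Evoked amplitudes:

* **Tones.** Gaussian tuning in log2 frequency around CF (SD =
  `tuning_width`, default 0.5 octaves) times a saturating rate-level term
  `1 - exp(-(L - thr + 5)/20)` for L >= threshold and 0 below it, times the
  realized gain; peak amplitude 3 expected spikes/tone.  The hard zero
  below threshold makes "threshold" well-defined for recovery tests.
* **Trains.** One bump per burst; burst k carries
  `gain * adaptation^(k-1)`, with bursts 3 and 5 further multiplied by
  `odd_burst_suppression`; spike times are jittered by a Gaussian of SD
  `phase_jitter`.  Paired-pulse ratio therefore recovers `adaptation`
  directly, and vector strength decreases monotonically in the jitter.
* **Speech.** Three onset sub-bumps inside the 1-40 ms consonant window
  whose latencies/weights interpolate between a shared pattern and a fixed
  label-specific pattern under a `separability` parameter in [0, 1]
  (0 means all labels share one response distribution), plus a sustained
  vowel component over 60-400 ms with its own gain.

**Group presets** encode the direction and approximate size of the
published group differences and are fixtures, not estimates: SAL gain 1.0,
no latency shift, adaptation 0.50, jitter 4 ms; VPA gain 0.40, +2.5 ms
onset shift, adaptation 0.84, odd-burst suppression 0.60, jitter 12 ms,
lower speech separability; VPA+VNS gain 0.70, +0.5 ms, adaptation 0.54,
jitter 6 ms, vowel gain 1.5.  The latency and paired-pulse magnitudes come
from the published group means (14.4/16.9/14.9 ms onset; 0.49/0.84/0.54
PPR); the remaining magnitudes were set once to produce clearly ordered
group effects at desk scale.

What the generator does **not** emulate: refractoriness and bursting,
rate-history adaptation beyond the per-burst geometric factor, LFP/laminar
structure, tonotopic spatial organization, anesthesia state, and realistic
spectrotemporal receptive fields for speech (label patterns are abstract
onset signatures).  Passing recovery tests therefore demonstrate that the
estimators measure what they claim under the assumed point-process model,
not that the model captures AAF biophysics.

## Receptive-field extraction

The FRA cell value is the trial-mean spike count in the evoked window
(default 5-40 ms, covering the 10-15 ms AAF onset regime) minus the
expected spontaneous count; the spontaneous rate is pooled over the 100 ms
pre-stimulus window of all trials.  No significance criterion is printed
in the protocol, so the package fixes one and surfaces it: 3x3 median
smoothing of the FRA, then cell significance at 2 standard errors of the
null driven-count estimate.  Threshold is the lowest level with any
significant cell; CF is the significant frequency at that level closest to
the response-weighted centroid.  Bandwidths at threshold +10..40 dB are
the log2 span of the contiguous significant column range containing CF
(a single-column response has bandwidth 0; resolution is the grid step),
and are flagged undefined when the probe level leaves the 75 dB grid.
Onset latency is the center of the first 1 ms PSTH bin exceeding the
spontaneous mean + 2 SD for two consecutive bins (pooled over 60 dB tones
within +-0.5 octave of CF); peak latency is the maximum bin at or after
onset within 75 ms.  Null calibration: with evoked amplitude zero, fewer
than 5% of sites pass the response criterion, and exclusion bookkeeping
(analyzed + flagged = input) is tested.

## Temporal metrics

Per-burst driven counts use a 5-45 ms window after each burst onset
(truncation-safe up to the 66.7 ms period at 15 Hz) minus the spontaneous
expectation.  Steady state is the mean of bursts 3-6, with the odd {3, 5}
vs even {4, 6} split reported separately.  The printed parenthetical time
span for the steady-state window ("366-433 ms") cannot be reconciled with
six bursts at 7.5-15 Hz counted from burst three, so the implementation
defines steady state strictly as bursts three onwards and does not guess
window bounds.  Vector strength is the circular resultant of spike phases
(2*pi*rate*t) over spikes pooled across trials from burst-1 onset to one
period past burst-6 onset; Rayleigh statistic is 2nVS^2 and a site is
phase locked when it strictly exceeds 13.8 (p ~ exp(-6.9) ~ 1e-3 under
uniformity, verified by simulation).  PPR is P2/P1 on driven counts,
undefined (excluded, flagged) when P1 <= 0.  As a ratio of noisy 20-trial
means, per-site PPR carries a small positive Jensen bias that grows as
driven counts shrink (about +0.1 at one driven spike per burst); recovery
of the adaptation parameter is therefore exact to within 10% in the
control response regime but overestimates it for very weak responders,
a property of the estimator rather than of the simulation.

## Speech windows and the neural classifier

Driven activity is reported for the consonant onset (1-40 ms), the vowel
(default 40-340 ms; the exact placement is unstated upstream and is
configurable), and the full 0-400 ms token.  The classifier is pairwise
leave-one-out nearest-template: spike trains are binned at 1 ms over
0-40 ms (both configurable and recorded in output); each held-out trial is
assigned to the label whose template - mean PSTH over the 19 remaining
same-label trials versus all 20 other-label trials - is nearer in
Euclidean distance, ties broken by a seeded coin flip; percent correct is
over all 40 folds.  The 19-versus-20 template asymmetry follows the
protocol's "19 of 20" literally; under the null it produces a small
(~1 percentage point) below-chance bias because the other label's template
averages one more trial, which the chance-level tests' +-2% band absorbs.
Site-level accuracy is the mean over the six stop-consonant pairs
(b/d/g/t).

## Group statistics

Per-site metrics are compared across groups with a REML linear mixed
model: fixed effects as specified (group, optionally sex, stimulus
covariates), random intercepts for animal and - when sites contribute
repeated rows - for site within animal (with one row per site the site
variance is unidentifiable and folds into the residual; the result says
so).  The fit takes the better of two optimizer routes (gradient and
Nelder-Mead), since the default route can stall slightly short of the REML
optimum on nested variance surfaces; agreement with lme4 is tested to
1e-4 (fixed effects) and 1e-3 (Wald chi-squares).  Fixed terms get block
Wald chi-square tests from the full fit - equivalent to the
marginality-respecting construction for interaction-free models, which is
what the calibration suites use.  Group EMMs are computed on a balanced
reference grid of the other categorical covariates and back-transformed
through the exact inverse link; pairwise contrasts carry Tukey p-values
from the studentized range on animal-level degrees of freedom.

Non-Gaussian families are honest approximations with identical output
schema, labelled in metadata: `tweedie-approx` fits log(y + c) (c = half
the minimum positive value when zeros are present), `gaussian-log` fits
log(y), `beta-approx`/`binomial-approx` fit logit-transformed responses.
Exact Tweedie/beta/binomial mixed likelihoods are out of scope; the
inferential targets preserved are the direction and significance of group
contrasts.  Model comparison statistics (AIC/BIC) are reported, not used
as an automatic selector.

Normality is tested with Shapiro-Wilk, or Shapiro-Francia (implemented
with Blom scores and Royston's 1993 p-value approximation, cross-checked
against R nortest) when the sample's Pearson kurtosis is >= 3.  Note the
routing itself mildly inflates the composite type-I error (samples that
look heavy-tailed are both routed to Shapiro-Francia and likelier to
reject); each branch test is calibrated at 5%.

Calibration suites: Wald type-I error 0.05 +- 0.02 under the null at the
3 x 10 x 30 cohort scale (1000 replicates); Tukey any-contrast error at
the nominal level within Monte-Carlo error; power > 0.8 for a 1.5
between-animal-SD group shift.  A 1-SD shift is not detectable at
power 0.8 with 10 animals per group - the omnibus noncentrality is capped
at (2/3)*10 regardless of site counts - so the power simulation uses the
smallest clearly-detectable effect instead.

## Behavior

Go/no-go sessions are scored event by event: a poke within the hit window
(4 s early in training, 3 s later) of a target is a hit; a poke on a catch
trial or outside any open hit window starts a 6 s timeout during which
pokes are ignored; percent correct = (hits + correct rejections)/trials.
Proficiency is four consecutive sessions at >= 75%.  Success-paired VNS
stimulation counts equal rewarded hits per session.  Weekly learning
curves are compared with a two-way mixed-design repeated-measures ANOVA
(week within animal, group between; pingouin backend; uncorrected df by
default with Greenhouse-Geisser available), Bonferroni-corrected pairwise
group contrasts on animal means.  The synthetic learning-curve generator
uses a shared saturating curve (55% to 92% over four weeks) with animal
offsets and no group effect, matching the reported outcome that training
week, not exposure group, drives performance.

## Problem sizes and numerical choices

Recovery and calibration suites run at 200 sites per condition (20
trials/stimulus, the protocol's repeat count), tone analyses on 13-25
frequency grids, and the end-to-end ordering check on 3 groups x 4
animals x 6 sites; these sizes were chosen so the whole suite runs on a
single CPU in minutes while keeping every Monte-Carlo band at least 3 SE
wide.  Ties in the classifier are seeded coin flips; undefined quantities
(non-responsive sites, PPR with P1 <= 0, empty spike sets for VS) are
NaN-flagged and excluded with explicit bookkeeping, never silently
dropped.  All randomness flows through `numpy.random.default_rng` seeds;
identical (configuration, seed) pairs reproduce datasets bit for bit.

## Known limitations

* The simulator's group presets are directional fixtures; magnitudes other
  than the published latency/PPR means are not fitted to data.
* The classifier operates per site and pairwise; population decoding and
  multi-class schemes are out of scope.
* Tweedie/beta/binomial models are transformed-Gaussian approximations.
* Type II Wald tests coincide with the textbook construction only for
  interaction-free or balanced designs (the package's standard use).
* Sex is carried as a fixed effect, but desk-scale cohorts are not powered
  for sex contrasts.
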