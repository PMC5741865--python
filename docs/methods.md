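# Methods

## Time and sampling conventions

All times are milliseconds relative to session start; analysis windows are
half-open `[a, b)` so boundary samples are never double-counted. Sample
indexing is 0-based with round-to-nearest ms→index conversion. The default
sampling rate is 1000 Hz on all channels; other rates are accepted, with
ms-quoted windows converted per channel.

## EMG processing and burst-onset detection

The chain is: 40-Hz high-pass (7th-order Butterworth) → full-wave
rectification → 20-ms centered moving-average envelope.

*Zero-phase filtering.* Filters run forward-backward (`sosfiltfilt`).
Causal application would delay every detected onset by the filter's group
delay; since the scientific quantity is a *difference* of onsets measured
on channels with identical filters, either choice largely cancels, but
zero-phase keeps absolute onsets interpretable and is standard for offline
analysis. The effective magnitude response is the square of the single-pass
design (−6 dB at the nominal cutoff).

*Envelope.* A 20-ms centered moving average is the minimal smoother that
still resolves the 50-ms burst-duration criterion; edges use shrinking
windows (no padding), so constant inputs are fixed points. The envelope is
monotone and linear — properties the tests exercise.

*Burst criterion.* Background mean/SD of the envelope are estimated over
150-ms windows (−150..0 ms re target for AD; −300..−150 ms re the refined
AD onset for postural muscles). A burst starts at the earliest sample from
which the envelope exceeds mean + 2 SD continuously for ≥ 50 ms, with the
run's start inside the muscle-specific search window (AD: +200..+500 ms re
target; postural: −150..+100 ms re AD onset). A single sub-threshold sample
breaks a run; the earliest qualifying run wins. Absence of a qualifying run
is a result, not an error.

*Onset refinement.* The envelope-criterion time is refined to where the
deviation began in the rectified wave: if the rectified signal at the
criterion time is still at background (a centered moving average starts
responding up to half a window before the raw rise, which matters for
strong bursts), the walk first moves forward to the nearest above-mean
sample; it then moves backward to the last up-crossing of the background
mean. Both directions are bounded by one envelope window. In the noise-free
limit this recovers a rectangular burst's onset exactly; with noise the
residual bias is a few ms, and — critically — is common to AD and postural
muscles, so it largely cancels in the relative onset (measured bias
< 1 ms, per-trial SD ≈ 5 ms at default amplitudes).

*Self-timing condition.* No target exists, so the AD background window is
anchored to a preliminary envelope rise (first crossing of a loose
5-SD threshold inside the 3-s go window, judged against a 500-ms pre-go
background) and the burst search spans the whole go window. Postural
windows are anchored to the refined (not coarse) AD onset in all
conditions.

## P300 extraction

Pz epochs span −200..+800 ms re target; each epoch's mean over
[−200, 0) ms is subtracted (baseline correction, exact to 1e-12 by
construction). Exactly the first 20 accepted epochs are averaged — fewer is
an explicit error, matching a design that repeats blocks until 20 accepted
trials exist. The average is smoothed with a 30-Hz low-pass before peak
extraction; the cutoff is prescribed, the order is not, and order 4
(zero-phase) was chosen as a conventional smoothing order that leaves the
3-Hz-bandwidth P300 deflection untouched (< 2% amplitude loss on the
noise-free bump). The P300 is the largest strictly positive local maximum
(both neighbors lower) in [250, 500] ms; amplitude is its height above the
zero baseline, ties go to the earliest peak. A monotone rise ending at the
window edge sets a `boundary` flag instead of returning a spurious peak; a
missing positive peak yields a not-found flag and exclusion from statistics
with a warning — the analysis never invents a peak.

## Trial screening

Rules apply per target trial in a fixed order, and only the first failure
is recorded, so rejection counts reconcile exactly:

1. `no_ad_burst` — no detectable focal burst (a miss); nothing else can be
   anchored without it.
2. `cop_out_of_range` — any CoPap sample in the 500 ms before the detected
   AD onset deviating more than ±1 cm from the quiet-standing reference.
   The protocol's criterion is "just before arm flexion"; 500 ms is this
   package's concrete default (configurable) — long enough to catch a
   drifting stance, short enough to stay pre-movement.
3. `artifact` — any EOG/Fz/Cz/Pz sample beyond ±100 μV within −200..+800 ms
   re target. Self-timing trials skip this rule (no stimulus-locked
   averaging exists there).

The accepted list is truncated to the first 20 accepted trials. Rejection
is monotone in both thresholds (loosening never rejects more), a property
the tests verify.

## Statistical battery

Elementary tests (one-sample, paired, and two-sample *t*, Shapiro-Wilk,
Levene with center = mean, Pearson) delegate to scipy behind a uniform
result type; α = 0.05 two-sided throughout. The two-sample comparison is
gated by a two-sided variance-ratio F test (larger variance on top) that
switches to Welch's unequal-variance form on rejection, and records which
path ran.

The two-way mixed ANOVA is implemented from the standard balanced-design
sums-of-squares partition: the grouping effect is tested against
subjects-within-groups, the repeated effect and interaction against the
subject × condition residual. Muscle is deliberately treated as a grouping
factor with repeated measures on condition only — mirroring the source
design — although muscles are physically within-subject; each
(subject, muscle) pair is one unit. Mauchly's W is computed on the
within-group-pooled covariance of the repeated measures (the SPSS
convention for mixed designs) with the chi-square approximation; when its
p < 0.05, the Greenhouse-Geisser epsilon (trace form, same pooled
covariance) deflates the repeated-effect and interaction dfs. Epsilon = 1
reproduces uncorrected results identically. With two within levels
sphericity holds trivially and ε ≡ 1. The implementation is cross-checked
in tests against pingouin (F values to 1e-6; W and ε on group-centered
data, where the two conventions coincide) and against a hand-worked
integer example with exact fractional sums of squares.

Tukey HSD post-hocs are computed from summary statistics
(q = |m_i − m_j| / √(MS_err/2 · (1/n_i + 1/n_j)), studentized-range
reference) using the ANOVA's own error terms: the within error for
condition contrasts, the between error for muscle contrasts.

*Calibration.* Every test's null p-value distribution is verified uniform
by Kolmogorov-Smirnov over 500 seeded replicates, each test family on an
independent child stream. The ANOVA is calibrated on its uncorrected
p-values: under an iid-normal null the sphericity gate still fires at its
5% type-I rate and the resulting ε < 1 correction makes gated p-values
conservative *by design*, so the gated composite is deliberately not the
calibration target; the GG path is instead covered by the ε = 1 identity
and the pingouin cross-check. The Tukey calibration uses the p-value of
the largest pairwise q, which under the complete null is the range
statistic's p and hence uniform.

## The simulator

The generators emulate the paradigm's design: 72-stimulus oddball blocks at
a 2.5-s inter-stimulus interval with exactly round(p·72) targets per block
(11 at 15%, 32 at 45%) placed by seeded shuffle — a fixed count, not
per-slot Bernoulli, because the experiment's budget is trial-count-driven
(blocks repeat until 20 accepted target trials). Tone identities
(2000/1000 Hz) are carried as metadata only; no audio is synthesized.

*EMG.* Zero-mean Gaussian background with variance-step bursts (linear
rise ≤ 10 ms, default duration 150 ms). The burst's rectified amplitude is
parametrized as background rectified mean + k × background rectified SD
(folded-normal moments), so k > 2 is detectable by the 2-SD criterion and
k = 3/5/8 give burst-to-background RMS ratios of 3.3/4.8/7 — the range of
modest-to-strong surface-EMG bursts. Defaults: AD 8 (a strong focal
burst), postural muscles 6. Simulated reaction times are normal
(mean 250, SD 30 ms) truncated to [220, 480] ms — inside the 200–500 ms
search window with margin, because a true onset at the window edge would
make the detector's slightly-anticipating envelope crossing fall outside
the window and produce structural misses that say nothing about the
detector. Self-timed onsets are uniform in 0.5–3 s after the go marker.

*EEG.* Gaussian background (default SD 10 μV) plus a positive
Gaussian-shaped deflection (default width SD 50 ms) time-locked to each
target, parietal-dominant (Pz gain 1.0, Cz 0.8, Fz 0.6); non-targets get
nothing. Single-trial latency jitter is not modeled — the subject-level
average is the analysis target, and jitter would only scale its amplitude.

*EOG/blinks.* Biphasic transients (dominant ~150-ms positive lobe,
amplitude 300 μV) Poisson-placed at 2/min, leaking into EEG channels with
frontal dominance (Fz 0.30, Cz 0.20, Pz 0.12). Spontaneous blinks are
placed outside trial windows — mirroring instructed blink suppression
during trials — so screening outcomes equal the injection log exactly;
artifact injections force a blink inside a chosen trial's window.

*CoP.* An Ornstein-Uhlenbeck drift (stationary SD 0.5 cm, the typical
quiet-stance fluctuation scale; time constant 1 s) around the
quiet-standing reference. In full sessions the pre-flexion window of
non-violation trials is clipped to ±0.95 cm — emulating the online
in-range gate that preceded every real trial — while scheduled +2-cm
excursions create out-of-range trials on demand.

*Seeding.* One global seed expands into per-channel/per-purpose child
streams via `SeedSequence((seed, crc32(tag), ...))`, so adding a channel
never perturbs another and identical configuration is bit-identical across
runs.

## Cohort effect structure and scaling

Group mean offset tables encode the qualitative pattern the battery must
resolve — young: graded GcM anticipation (self −55, 45% −35, 15% −20 ms)
with shorter/smaller P300 at 45% (350 ms/8 μV) than 15% (380 ms/12 μV);
older: no oddball GcM anticipation (0 ms), a uniform self-vs-oddball
condition effect, and no 15-vs-45 differences. Variance components
(between-subject SD 10 ms, subject × condition residual 7 ms, trial jitter
10 ms; P300 latency 25/10 ms, amplitude 2.5/1.2 μV) were fixed a priori by
analytic power calculation so each truly-present effect is detected with
probability ≥ 0.99 at n = 14 per group. The joint pattern probability is
then dominated by its five truly-null components, each of which survives
with probability 0.95–0.975 under exact calibration — an irreducible
ceiling near 0.85 that no effect size can raise. Measured recovery is
~88–92% of 50 replicates.

The 50-replicate pattern study runs the real battery on subject-level
tables drawn directly from this effect structure (with the measurement
noise a 20-trial pipeline average carries, jitter/√20), rather than on
4,200 full signal-level sessions: at roughly 0.7 s per simulated
session-condition, the signal-level version of that study alone would take
hours, while contributing no information beyond what the signal-level
recovery checks already establish per stage. One full signal-level
end-to-end run (session → screening → onsets → ERP → battery) is exercised
separately at reduced cohort size.

## Known limitations

* The simulator's EMG is amplitude-modulated Gaussian noise; real EMG has
  colored spectra, motor-unit structure, and occasionally tonic background
  (which inflates the background SD and can mask weak bursts — flagged,
  not resolved). Passing recovery tests bound algorithmic error, not
  physiological validity.
* EEG is white noise plus a deterministic bump: no alpha rhythm, no
  overlapping components (N1/P2/N2), no latency jitter. The P300 extractor
  is validated for peak localization, not component decomposition.
* The between-group comparisons (young vs older per muscle × condition)
  are implemented and reported but are not part of the encoded pattern;
  the configured group means imply some group differences in the
  self-timing condition that a real replication might not show.
* A single 1000-Hz CoP channel is modeled; the separate low-rate online
  monitoring channel of the original apparatus is out of scope, as are the
  physical apparatus, electrode placement, and audio rendering.
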