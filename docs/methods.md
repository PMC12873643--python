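# Methods

## Task structure and what the generator emulates

Each synthetic trial walks through four epochs — noise, spatial cue,
two-patch delay, change — with epoch durations drawn uniformly from the
task's ranges (noise 0.2–0.3 s, cue 0.36–1.55 s, delay 0.84–3.6 s).  The
wheel-locomotion mechanism that produced those durations in the experiment
is not modeled; only the resulting time ranges matter to the analyses.
Cue sides alternate in interleaved blocks of 10 trials.  Cohorts with
catch trials get an exact half of no-change trials; the stimulus–reward
association (intermediate) cohort has none, matching its training design.
Orientation-change amplitudes are drawn from {9, 12, 15, 20, 30}° and
categorized small {9, 12}, medium {15, 20}, large {30}.

### Spiking model

Each unit fires as an inhomogeneous Poisson process (thinning algorithm):

    r(t) = baseline
         + g_cue    * A_cue    * k(t - t_cue)
         + g_change * A_change * k(t - t_change)      (change trials)
         + g_delay  * B_delay  * 1[delay epoch]       (contra-cue trials)

where `k` is a causal, peak-normalized difference-of-exponentials kernel
(latency 40 ms, rise 10 ms, decay 60 ms — so the transient mass falls in
the 40–140 ms response window used by the analyses) and the gains
`g_(level, layer)` form the **synthetic ground truth**: deep-layer gains
are zero in naive sessions and positive after training; superficial visual
gains are present throughout and grow moderately.  They encode the
qualitative pattern under study and are not estimates from any recording.
Per-unit heterogeneity is lognormal (baseline sd 0.4, amplitudes sd 0.3
on the log scale; baseline ~8 Hz, transient peaks ~20 Hz, delay bias
~3 Hz).  Negative user-supplied rates are clamped at zero and logged.

### Licking and behavior

Lick archetypes are Poisson intensities: `early_peak` (4 Hz burst at trial
start, 0.8 s decay — passive viewing), `ramping` (0.2 → 2.4 Hz linear climb
through the trial — reward association), `change_locked` (0.01 Hz floor,
reactive Gaussian burst centered 450 ms after a real change, sd 90 ms;
no-change trials get a 0.12-scaled burst producing occasional false
alarms).  The magnitudes are free parameters of this package (no published
lick-rate axis to match); they were set once so that the *scored* behavior
lands at the study's scale — nominal hit rate ≈ 0.05 for passive viewing,
≈ 0.7 for reward association, ≈ 0.75 with false-alarm rate ≈ 0.2 and
d′ ≈ 1.5 for change detection — and not revisited.  Scoring: a change
trial is a hit iff a lick falls in [300, 800) ms after the change
(half-open); no-change trials score false alarms in the matching window;
under change-detection rules a lick between cue onset and the opening of
the response window aborts the trial (timeout).  d′ uses the log-linear
correction (counts + 0.5, denominators + 1) and is reported as undefined
where no catch trials exist.  Reaction time is the first in-window lick on
hit trials, summarized by the median for robustness.

### Probe trials

Change-detection sessions can mark a fraction of change trials as
cue-omitted probes (in-memory flag; the fixture schema is unchanged).  On
probe trials the reactive burst is scaled by 0.7 and delayed by 12 ms,
producing a cued-over-probe hit-rate benefit of ~8 percentage points and a
slightly longer reaction time — the behavioral signature of the spatial
cue, tested with the paired Wilcoxon signed-rank comparison.

### Eye traces

240 Hz, 2-D, with scheduled saccades as smoothstep displacements (exact
plateaus, peak speed 1.5·amplitude/duration) in random directions, plus
Gaussian position noise (default sd 0.1°).  Spontaneous saccade rates fall
with training (0.25 / 0.15 / 0.10 Hz naive/intermediate/expert), matching
the direction of the behavioral control analysis.

### What the generator does *not* emulate

No biophysics, spike-sorting artifacts, unit drift, correlated trial-to-
trial noise, saccade-locked firing, pupil dynamics, or wheel kinematics.
Passing tests therefore demonstrate that the *analysis chain* recovers
known ground truth under Poisson variability and realistic trial
statistics — not that it is robust to every pathology of real recordings.

## Analysis choices

* **Windows.**  All event-relative windows are half-open `[a, b)` in ms, so
  20 ms PSTH bins partition a range with no double counting.  Cue onset:
  [40, 140) vs [−100, 0); delay: [−200, 0) before change, contra vs ipsi;
  change onset: [40, 140) vs [−100, 0).  Firing rate in a window is
  count/duration; no smoothing.
* **Trial selection.**  All trials enter regardless of outcome; no-change
  trials are excluded from every AROC contrast.  Cue-onset and
  change-onset contrasts use contralateral-cue trials (the stimulus in the
  recorded field); a config switch can pool both sides.  Units need ≥ 5
  trials per set (configurable) or are excluded with a log entry.
* **AROC.**  Computed by midranks in O(N log N); the pairwise tie-half-
  credit definition is the brute-force oracle the tests compare against.
  All-tied inputs give exactly 0.5.
* **Bootstrap.**  Signal and noise sets resampled independently with
  replacement at their own sizes, 1,000 replicates, 2.5/97.5 percentiles.
  Significance: CI entirely above (positive) or below (negative) 0.5.
* **Mixed model.**  statsmodels `MixedLM`, REML, random intercept per
  session, binary level fixed effect, Wald z on β₁.  With equal-sized
  balanced sessions this estimator coincides with the plain group-mean
  difference (a test asserts it to 1e-6).  All-constant input returns a
  flagged degenerate result instead of a failed fit.
* **Permutation test.**  Statistic: difference of group medians of
  within-session mean AROC.  Exhaustive enumeration (exact p, identity
  included) when the number of label assignments ≤ n_perm, else n_perm
  random shuffles with the add-one correction (1 + extreme)/(n_perm + 1),
  so p can never be 0.  Ties count as extreme (|stat| ≥ |obs| − 1e−12).
* **Joint rule.**  A comparison is significant only when both tests reject
  at α = 0.05 (strict).  Pairwise level comparisons run independently with
  no multiplicity adjustment.
* **Session classification.**  Change-aligned lick counts in [−3000, 1500)
  ms, 100 ms bins, trial-averaged and normalized to unit sum (so overall
  lick rate does not dominate shape); UMAP (2 components, n_neighbors 15 —
  reduce for small session sets — min_dist 0.1, Euclidean, fixed seed);
  2-means on the embedding; the cluster with more lick mass in the
  [300, 800) ms response window is labeled expert.  The trace
  parameterization and normalization are this package's choices; all are
  config-exposed.  Passive-cohort sessions bypass the classifier entirely.
* **Saccade detection.**  2-D speed by central differences after a
  3-sample median prefilter; candidate epochs are runs with speed
  > 50°/s, extended outward while speed > 10°/s (hysteresis) so the
  measured excursion spans the full movement; kept if duration > 15 ms and
  net straight-line displacement > 2° (strict inequalities).  Amplitude is
  measured between the samples flanking the epoch (essentially the pre/post
  plateaus).  The differentiation/smoothing scheme and the
  displacement-not-path-length convention are package choices; the
  thresholds are the task's.  The saccade-free reanalysis drops trials with
  a saccade onset in the union of an epoch's baseline and response windows
  (windows-only, config-switchable to whole-trial).

## Determinism and problem sizes

A single master seed expands through `numpy.random.SeedSequence` into
independent streams per session and per data stream (timeline / spikes /
licks / eye), so any stream reproduces in isolation and two runs with the
same resolved config are byte-identical.  The shipped drivers and the
acceptance script use desk-scale sizes — 6–8 sessions × 150–200 trials ×
8–10 units per cohort, 1,000 bootstrap replicates, 10,000 permutations
(2,000 in the bulk calibration checks), 200 mixed-model replicates —
chosen as the package's standard configuration; the statistical machinery
is size-agnostic and the config scales everything.

## Known limitations

* Bootstrap percentile CIs on heavily tied low-count AROC distributions are
  mildly conservative; measured null significance rates run ~4–6% against
  the nominal 5%.
* The Wald z test on β₁ has no small-sample df correction; with very few
  sessions per level it can be slightly anticonservative (the permutation
  companion, and the joint rule, guard against this).
* The joint dual-test rule applied across three epoch contrasts has a
  union false-positive rate of roughly 5–8% per dataset at α = 0.05;
  calibration experiments over many seeds measure ~93% of null datasets
  with no joint-significant epoch anywhere.
* UMAP determinism is per-seed; embeddings (and rarely, borderline cluster
  assignments) can differ across umap-learn versions.
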