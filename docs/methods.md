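# Methods

## Problem and pipeline

`emoconn` analyzes how EEG functional connectivity relates to eye-movement
behavior while a person views emotion-eliciting video, under the
two-dimensional valence x arousal model of emotion (four conditions:
pleasant-aroused, pleasant-relaxed, unpleasant-relaxed, unpleasant-aroused).
The processing chain is:

1. **Preprocess** — resample EEG to 500 Hz, band-limit to 0.5-30 Hz,
   amplitude-threshold artifact masking.
2. **Connectivity** — complex-Morlet CWT per band (delta 0-4, theta 4-8,
   alpha 8-12, beta 12-30 Hz), instantaneous phase at the band-center scale,
   windowed band power; per electrode pair: phase-locking value (PLV),
   circular mean phase difference, signed power difference, and a
   strong/weak flag.
3. **Eigenvalues** — per window, the mean signed power difference over each
   of three pair-groups: long-distance occipital-frontal (LD_OF),
   long-distance prefrontal-to-temporal/central/parietal (LD_PF), and
   short-distance (< 10 cm, adjacent regions; SD).  "Eigenvalue" is the
   field's name for this scalar summary, not a linear-algebra eigenvalue.
4. **States** — incremental k-means over the chronological eigenvalue
   triplets selects the number of brain states; with two states, the cluster
   farther from the session-start baseline is flagged *emotional*.
5. **Eye tracking** — I-VT fixation/saccade segmentation of 60 Hz gaze,
   percent pupil change from a pre-stimulus baseline, features aggregated by
   condition x state.
6. **Statistics** — participant-level means, one-way ANOVA and Tukey HSD
   across the four conditions, Bonferroni-style adjusted per-test alpha
   (family alpha / number of ANOVAs) reported alongside, and descriptive
   Spearman concordance between eigenvalue and eye-feature condition
   profiles (four points; no inference).

## Montage

The 18-channel subset of the 10-20 system is the 19-electrode set minus Fz:
Fp1/Fp2 (prefrontal), F7/F3/F4/F8 (frontal), T3-T6 (temporal), C3/Cz/C4
(central), P3/Pz/P4 (parietal), O1/O2 (occipital) — 153 unordered pairs.
Electrodes sit on a 9.2 cm sphere with ideal angular placement: the
circumferential ring at the equator in 18-degree azimuth steps, C3/C4/Pz 36
degrees from the vertex, and F3/F4 (P3/P4) as great-circle midpoints between
F7/F8 (T5/T6) and the midline anchors — the spherical idealization of how a
technician places them.  Geodesic distance is head_radius x central angle
(atan2 form, stable at antipodal pairs).  Pair order follows region
precedence occipital > prefrontal > frontal > temporal > central > parietal,
which fixes the sign of every power-difference feature: positive e_LD_OF
means occipital power exceeds frontal power.

## Wavelet and connectivity choices

The mother wavelet is phi(u) = (pi B)^(-1/2) exp(-u^2/B) exp(2 pi i u) with
dimensionless bandwidth B = 1.5 and unit mother frequency (the `cmor1.5-1.0`
convention); a scale a (seconds) probes pseudo-frequency 1/a.  Eight
log-spaced scales span each band, with the grid point nearest the band
midpoint (2, 6, 10, 21 Hz) snapped onto it so the center scale probes the
midpoint exactly; phase is read at that scale, power is the mean squared
magnitude over all band scales.  Interpreting B as seconds-squared at the
band frequency would make the beta wavelet ~50 cycles long, destroying the
temporal resolution the state segmentation needs; the dimensionless
convention gives the usual ~5-6 cycle wavelet in every band.  The CWT is
evaluated by FFT convolution with the kernel truncated at 8 envelope
standard deviations (relative truncation error ~ exp(-32)); a brute-force
Riemann sum of the defining integral reproduces the fast path to ~1e-14.

Windows are 1.0 s with 0.5 s hop; windows more than half masked are dropped.
The strong/weak flag compares each pair's |power difference| with the mean
|power difference| over all 153 pairs of the same window and band — the only
reading of the published rule that yields a per-pair binary marking.  The
eigenvalue is the mean *signed* power difference over a group's pairs
(phase-based PLV is reported as its own column, not folded in), and the
|mean| variant is its absolute value.  Beta is the default reporting band;
all four bands are computable.

## State segmentation

The three eigenvalue series are z-scored (the groups have different pair
counts and magnitudes), then k-means (k-means++, 10 restarts, fixed seed)
runs for k = 1..6.  The chosen k is k-1 for the smallest k whose inertia
improvement, *as a fraction of total variance* inertia(1), falls below 10 %
— normalizing by the previous inertia instead never flattens on noisy data
and over-segments.  A constant series yields one state.  The emotional
cluster is the one whose centroid lies farther (Euclidean, standardized
space) from the mean of the first baseline windows; sessions start before
the stimulus, so early windows anchor the non-emotional state.  With one
state (or more than two) all windows are flagged non-emotional with a
warning.

## Eye movement

I-VT with a 30 deg/s velocity threshold and 100 ms minimum fixation duration
(standard for 60 Hz trackers), after a 3-sample median filter; invalid
samples split events.  Saccade amplitude averages ~3 settled samples on each
side of the detected run to beat fixation jitter.  Pupil change is the
percent change of mean diameter against a pre-stimulus baseline window,
which removes inter-individual diameter offsets (and is invariant to
rescaling both intervals).  Headline features: mean fixation duration and
saccade rate; counts and amplitudes are also emitted.

## Statistics

ANOVA is the standard between/within decomposition (all-constant input
degenerates to F = 0, p = 1 with a warning).  Tukey HSD runs at the family
alpha; the adjusted per-test alpha (0.05/4 = 0.0125 for the four-feature
ANOVA family) is carried for bookkeeping, *not* applied on top of Tukey's
own familywise control — applying both would double-adjust.  ANOVAs treat
the four conditions as independent groups, matching the published table
structure.  Profile concordance across four condition means is Spearman's
rho, descriptive only.

## Synthetic data: what it emulates, what it does not

The generator supplies every input the pipeline needs, with known ground
truth:

* **EEG** — per channel, 1/f background (band-limited 0.5-45 Hz) plus
  independent band-limited oscillations in all four bands, ~10 and ~3 uV RMS.
  A coupling entry plants a pair (or a pair-group) sharing a common
  narrowband source: `sqrt(s*g(t)) * common + sqrt(1 - s*g(t)) * private`,
  where g(t) gates the entry's active states, so planted PLV has the
  closed-form expectation ~ s while active.  The common source is a
  constant-envelope oscillator whose instantaneous frequency wanders (AR(1),
  ~0.5 s correlation) inside the central half of the band, making planted
  power ratios show in windowed band power with little estimator noise.
  Coupled channels have their background band-stopped in the coupling band
  and their amplitude matched (5.4 uV, the band power an uncoupled channel
  carries in beta) so that `power_ratio` — applied to the leading side while
  active — is the only power asymmetry.
* **Study conditions** — each condition multiplies the band power of the
  occipital, prefrontal and frontal channels (lag partners are
  temporal/central/parietal channels at matched power, one entry per channel
  so nothing stacks).  Because prefrontal/frontal channels also sit second
  in occipital-frontal pairs, the realized eigenvalue displacements are the
  documented linear mixtures in `_lead_couplings`.  The multipliers were
  chosen so the realized displacements reproduce the study's qualitative
  pattern — occipital-frontal asymmetry largest in unpleasant-aroused
  (frontal-dominant, negative) and pleasant-relaxed; prefrontal eigenvalue
  positive under pleasant and negative under unpleasant valence, largest in
  magnitude when unpleasant-relaxed; short-distance asymmetry stronger when
  relaxed — while each condition's emotional state stays separable from its
  baseline by several within-state standard deviations at 1 s windows.
  Subjective arousal/valence scores are normal draws on a 9-point scale
  whose means are anchored at pleasant-aroused (5.5, 6.2) and offset by the
  published pairwise mean differences, with residual sd 1.3 (arousal) and
  1.0 (valence) backed out of the published confidence-interval halfwidths
  at n ~ 48 per group.
* **Gaze** — fixations with slow AR(1) positional jitter (phi = 0.8,
  marginal sd 0.2 deg — temporally smooth like fixational drift, so
  velocities stay far below the I-VT threshold), minimum-jerk saccades
  (default 50 ms), pupil = baseline 3.5 mm + scheduled percent excursions +
  AR(1) noise (phi = 0.95, marginal sd 0.03 mm) mimicking slow pupil
  dynamics.
* **Sessions** — default 360 s (a 6-minute viewing), 500 Hz EEG, 60 Hz gaze;
  the default state schedule is a 30 % pre-stimulus/neutral lead-in followed
  by an emotional epoch.  47 participants x 4 conditions is the study-scale
  default, with lognormal (sd 0.1) participant effects on the power
  multipliers and N(0, 0.5 %) offsets on pupil excursions.

Not emulated: volume conduction and reference effects, ocular/muscle
artifacts beyond amplitude spikes, blinks, smooth pursuit, luminance-driven
pupil responses, and any nonstationarity beyond the two-state schedule.
Passing tests therefore demonstrate that the *pipeline* recovers planted
structure of this idealized kind; they do not certify performance on real
recordings, where these nuisance processes and far smaller effect sizes
dominate.

## Problem sizes in tests and the acceptance script

Test and acceptance runs use desk-scale sizes chosen as the package's own
defaults for fast, convincing checks: single sessions of 6-60 s, study
bundles of 2-4 participants at 10-24 s per session for pipeline-level
checks (the 47-participant default is exercised for scores and shapes),
20-seed replications for recovery rates, 30 replicates for the null
calibration, and 180 s sessions with >= 60 s averaging intervals for pupil
recovery (the AR(1) pupil noise has a ~0.65 s correlation time, so percent
changes need long intervals to average it out).

## Numerical and degenerate-input choices

* Zero-phase 4th-order Butterworth filters everywhere (phase is the
  measurement); the delta band is a 4 Hz low-pass since a 0 Hz edge is not
  realizable as a band-pass.
* Artifact masking flags data but never alters sample values; resampling
  OR-pools the mask over contributing input samples.
* Constant eigenvalue columns are left unscaled during z-scoring (zero
  information); k-means on constant data returns one state.
* PLV of identical channels is exactly 1; empty windows warn rather than
  raise; an all-masked recording yields an empty series.
* Pipeline manifests contain parameters, seed and SHA-256 checksums but no
  timestamps, so rerunning a config is byte-identical.

## Known limitations

* The three group eigenvalues are linearly entangled: any single channel's
  power enters several groups with opposite signs, so condition effects on
  one eigenvalue leak into the others (quantified in `_lead_couplings`).
  This is a property of the feature definition, not of the generator.
* The elbow rule at moderate separations (~3 within-state sd) can resolve a
  third state; the labeling contract then flags every window non-emotional
  rather than guessing.
* Tukey HSD assumes equal variances and independent groups; repeated-measures
  structure across the four conditions is not modeled.
* `compare_profiles` correlates four points; it is reported without p-values
  because none would be meaningful.
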