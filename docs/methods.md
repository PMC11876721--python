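# Methods

This note documents the models, numerical choices and known limitations
of `topoperm` at the level of detail a user needs to judge what a
passing test suite does and does not establish.

## The experimental design being modelled

The trial generator reproduces a cued repetition-probability paradigm.
Each trial presents two stimuli (S1, S2) of the same category (written
words, faces, animal pictures). Within a category, the two S1
subcategories cue complementary repetition probabilities: one signals a
75% chance that S2 repeats S1, the other 25%. A repetition under the
high cue or an alternation under the low cue is *expected*; the other
two combinations are *unexpected*. With equiprobable cues and 480
trials per category this yields exact cell counts of 180 expected
repetitions, 180 expected alternations, 60 unexpected repetitions and
60 unexpected alternations; three category blocks give 1440 trials.
20% of trials are targets (categorisation probes) and are excluded from
ERP averaging.

Cells are allocated with exact counts and then shuffled, rather than
sampled per-trial with Bernoulli draws: the design's published totals
are exact, which implies a balanced list, and exact counts remove a
nuisance source of between-dataset variance. The divisibility of every
cell count is validated up front (`trials_per_category × 0.5 × p` must
be integral for both cue probabilities and their complements); an
explicit error names the first offending cell. Target totals must
likewise be integral at the category level; the per-cell share is
floored and the remainder distributed in fixed cell order.

Stimulus identities are drawn from per-subcategory pools of 60 items,
excluding the previous four S1 identities (a sliding no-reuse window);
on alternation trials S2 is a different identity from the same
category. The alternation-pairing rule and the per-exemplar repetition
schedule are simulation policies, not empirical constraints, and are
isolated in one helper so they can be changed without touching the
statistics. The 18% size reduction of S1 or S2 is recorded as a column
but has no simulated consequence (image rendering is out of scope).

## The synthetic ERP forward model

Each trial's signal is a sum of condition-contrast effects. An effect
is a fixed scalp topography (zero-mean across channels, unit GFP — i.e.
expressed against the average reference and normalised so amplitudes
are interpretable), a temporal envelope (raised cosine by default,
boxcar available for tests needing sharp edges), an amplitude in μV and
a contrast (`repetition_main`, `expectation_main`, `interaction`, or a
category-restricted repetition contrast). Signs are coded ±½ for main
effects and ±¼ for the interaction, so that with a unit-GFP map the
noise-free marginal difference (or double difference) equals the
amplitude exactly. This makes the forward model linear by construction,
and that linearity is asserted in tests.

Noise is white Gaussian, filtered along time to a stationary AR(1)
process (the first sample is drawn from the stationary distribution, so
there is no burn-in bias) and mixed across channels by the symmetric
square root of a Gaussian distance kernel over the montage, with rows
rescaled so every channel keeps the requested marginal SD. This
reproduces the two correlations that matter for permutation validity —
temporal smoothness and spatial covariance — at negligible cost.
Defaults: AR(1) coefficient 0.5 at 250 Hz and spatial kernel width 0.4
montage-distance units, values in the range typically reported for
band-limited scalp EEG; trial noise SD 5 μV against effect amplitudes
of 1–4 μV. No public signal-to-noise figures exist for the modelled
paradigm, so these defaults are calibration choices, documented as
such, and every calibration study states its own noise level.

Between-subject variability is a per-subject multiplicative effect
scale, lognormal with median 1 and log-SD 0.3. A lognormal keeps effect
*signs* consistent across subjects, which is what group-level
topographic tests assume; it does not model subjects whose effect
topography differs in kind.

Two generator resolutions exist. `simulate_subject_epochs` /
`simulate_study` produce single-trial epochs tied to a trial table, so
the preprocessing chain has something real to do.
`simulate_condition_erps` draws subject × condition ERP maps directly,
with the same noise structure at a chosen "residual after averaging"
SD (default 1 μV); this is the group-level fast path used by the
calibration studies, since the permutation statistics only ever see
subject-level condition means. What the generator does **not** emulate:
ocular and movement artifacts, bad channels, volume-conducted source
structure, non-stationary noise, latency jitter across subjects. Tests
passing on this generator therefore validate the statistical machinery
under its stated assumptions, not robustness to real-world artifacts.

Sampling defaults to 250 Hz over −150…850 ms (desk-scale; configurable
up to 1000 Hz). All amplitudes are μV throughout; channel order is
fixed by the montage. The default scalp layout is the 64-channel 10-10
set (BioSemi layout from MNE-Python) projected to the unit disc;
synthetic ring layouts serve smaller channel counts.

## Preprocessing

The chain is filter → average reference → baseline correction →
artifact rejection → condition averaging, each step deterministic:

- **Band-pass 0.3–30 Hz**: cascaded 4th-order Butterworth high- and
  low-pass stages, each applied forward–backward (`sosfiltfilt`), which
  squares the magnitude response and cancels phase. Real recordings are
  filtered as continuous data; the simulator only produces epochs, so
  epoch-edge transients of the 0.3 Hz high-pass are controlled by the
  filter's reflection padding and acknowledged as a desk-scale
  compromise rather than hidden.
- **Average reference** subtracts the channel mean per timepoint
  (idempotent, GFP-preserving, commutes with averaging — all asserted).
- **Baseline correction** subtracts each trial/channel's mean over
  −150…0 ms.
- **Rejection** removes a trial iff any sample in any channel exceeds
  ±80 μV *strictly* (a peak of exactly 80 μV is kept; "exceeding"
  read literally). Rejection is applied after baseline correction; the
  order is not empirically constrained and is documented here.
- **Condition averages** use nontarget trials only, with per-cell trial
  counts recorded; an empty cell is an error naming the cell.

## TANOVA

The observed statistic at each timepoint is the GDI between the
grand-mean maps of the tested factor's levels; for the 2×2 interaction
it is the RMS across channels of the grand-mean double-difference map
(any positive scaling of this statistic is permutation-invariant, so
the convention does not affect p-values). Cross-category analyses test
per-subject repetition difference maps: pairwise as two-set GDI
comparisons, jointly as a k-set dispersion statistic (RMS of the
grand-mean maps around their common mean), which reduces to the
pairwise test for k = 2.

The default permutation scheme reassigns **all** condition maps within
each subject uniformly ("full-cell relabelling"), testing each effect
under the global exchangeability null; a restricted scheme (permute the
tested factor's levels within each level of the other factor) is
available for main effects when other effects are genuinely present.
The p estimator is (1 + exceedances)/(1 + n_perm) with ties counted as
exceedances — never zero, slightly conservative. Monte-Carlo p-values
are validated against exhaustive enumeration on 6-subject two-condition
instances (a 64-point sign-flip null).

GFP normalisation (dividing each map by its GFP) is off for the
factorial TANOVAs and on for window-mean topography comparisons,
following the analysis convention the pipeline mirrors: amplitude-scale
differences are part of the factorial question but a confound for
"same topography?" questions. Zero-GFP (flat) maps raise an error
naming the timepoint rather than propagating NaNs.

## Global duration statistics

Each permutation's statistic series is ranked within the full
permutation distribution per timepoint, using the same add-one
estimator with the permutation's own value included in the count (so a
column of total ties yields p = 1 and the smallest reachable value is
2/(1 + n_perm)). The longest sub-α run per permutation forms the null
duration distribution; the threshold is its ceiling-rank 95th
percentile (conservative with heavily tied integer lengths), and an
observed run survives only if **strictly** longer. Runs are maximal
blocks of consecutive p < α samples; a single sample at p ≥ α breaks a
run (no gap bridging). The same permutation set is reused (no nested
resampling), the standard omnibus-duration construction at
O(n_perm × T) cost. The null duration distribution is computed per
effect, not pooled across effects.

## Effect sizes

Partial η² over a window: per-subject contrast maps (weighted cell
combination, window-averaged) are split into grand mean + residual;
SS_effect = N·Σ_ch(grand²), SS_error = Σ_subj Σ_ch(residual²),
η² = SS_effect/(SS_effect + SS_error). This partition is an explicit
design choice: it is the repeated-measures "variance explained by the
design" reading, validated through the η²↔d consistency of reported
values rather than against any external implementation.

Two Cohen's d routes are reported side by side. The deterministic
conversion d = 2·sqrt(η²/(1 − η²)) — the standard F-family relation for
a two-level contrast — reproduces all eleven reported (η², d) pairs
exactly at 2-decimal rounding and is the primary report. The
permutation route (z of the observed window-mean statistic against the
permutation distribution of window-mean statistics, divided by
sqrt(p₁·p₂·N)) is also implemented verbatim as a secondary output; the
two describe different null-referenced quantities and are not expected
to coincide numerically.

## Calibration studies and problem sizes

The desk-scale reference conditions are 20 subjects, 32 channels,
250 timepoints at 250 Hz, 1000 permutations, subject-ERP noise SD 1 μV
(`CalibrationConditions`). Under these conditions the package's own
checks are: family-wise error of the GDS-corrected repetition TANOVA
over 200 global-null replicates within two Monte-Carlo standard errors
of the 5% level; and recovery of a repetition effect injected at
200–300 ms with amplitude 3× the noise SD, requiring Jaccard ≥ 0.5
overlap between surviving and injected timepoints in ≥80% of 50
replicates. The full-scale configuration (33 subjects, 64 channels,
1000 Hz, 5000 permutations) is supported by the same code paths but not
exercised by the default test run.

## Known limitations

- The duration-correction null reuses the permutation set with
  self-inclusive ranking; this is marginally anticonservative relative
  to an independent null, so the empirical FWER can sit slightly above
  the nominal level while staying within the Monte-Carlo band under the
  reference conditions.
- The generator's noise model has no artifact or source structure (see
  above); preprocessing robustness claims are limited accordingly.
- Normalised topography tests assume non-degenerate (non-flat) maps;
  near-flat difference maps make GFP division ill-conditioned before it
  becomes an error.
- The η² partition is one defensible reading of "variance explained";
  alternative partitions (e.g. timepoint-wise rather than
  window-averaged) would give different absolute values.
- TANOVA here handles at most two crossed within-subject factors;
  three-factor designs must be decomposed, as the pipeline does.
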