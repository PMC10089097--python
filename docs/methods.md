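# Methods

This note documents the models, estimators and numerical choices behind
`mipac`, in the spirit of a package reference: what is computed, under
which assumptions, and where the genuinely open design decisions were
made.

## Signal model of the synthetic cohorts

Each trial is

x(t) = cos φθ(t) + A · e(t) · cos φγ(t) + σ · n(t)

where φθ and φγ are the phases of a quasi-rhythmic theta (default 5 Hz)
and gamma (default 32 Hz) oscillation, e(t) is the modulation envelope

e(t) ∝ 1 − m + m · (1 + cos(φθ(t) − φ₀)) / 2,

m ∈ [0, 1] is the ground-truth coupling (modulation depth), φ₀ the
preferred coupling phase, and n(t) is 1/f (pink) noise scaled to a
target SNR (default 0 dB, typical of source-level MEG band power).
Two details matter:

- **Quasi-rhythmicity.** Both instantaneous frequencies are redrawn each
  cycle from Normal(f₀, 0.5 Hz). Real cortical rhythms are not
  sinusoids; without jitter the comodulogram shows implausibly sharp
  single-bin peaks.
- **Envelope normalization.** e(t) is scaled by
  1/√((1 − m/2)² + m²/8) so its RMS — and therefore the mean gamma band
  power — is independent of m. Coupling strength must not leak into band
  power: the design questions "does coupling differ between groups?" and
  "does gamma power differ between groups?" are distinct, and the
  generator keeps them orthogonal.
- **Carrier placement.** The gamma carrier defaults to 32 Hz rather than
  the band center 30 Hz: amplitude modulation at the theta rate puts
  sidebands at f_amp ± fθ, and with a 30 Hz carrier the lower sideband
  (25 Hz) sits exactly on the inclusive edge of the 25–40 Hz power band,
  so part of its jitter-broadened mass falls outside and measured band
  power becomes systematically m-dependent (≈2% between m = 0.1 and
  0.7 — enough to masquerade as a group effect on ssPow). At 32 Hz both
  sidebands (27/37 Hz) are interior and band power is flat in m.

A cohort is three proficiency grades (13/13/12 subjects by default) ×
two languages × two conditions × two hemispheres, 40 trials of 10 s per
recording at 500 Hz. Default modulation depths: L1-natural 0.7 for all
grades; L2-natural 0.3/0.5/0.7 ordered by grade; rotated 0.1 everywhere
(a weak residual rather than zero, so the speech-specific contrast has a
non-degenerate baseline). Behavioral scores are
intercept + slope · m + noise, clipped to [0, 100], with
instrument-specific noise (picture naming the least noisy), linking
proficiency scores to L2 coupling.

What the generator does *not* emulate: evoked transients, artifacts,
non-stationary noise, spatial leakage between sources, or any acoustic
stimulus properties — the condition contrast is injected directly at the
neural level. Passing tests therefore demonstrate correctness of the
estimators and inference under the stated statistical structure, not
robustness to every property of real MEG.

## Filter bank and analytic signal

Bands are Butterworth filters of order 4, realized as second-order
sections (a direct transfer-function realization is numerically unstable
at 1 Hz bandwidth and these sampling rates) and applied forward and
reverse (`sosfiltfilt`): zero phase, squared magnitude response. Phase
bands are center ± 0.5 Hz on the 0.5–10 Hz grid. The lowest band
(0.5 Hz) would have a 0 Hz edge; its low cutoff is floored at center/4.

**Amplitude bands are wider: center ± 5 Hz** (10–50 Hz grid). This is a
deliberate deviation from the narrow ±0.5 Hz convention sometimes quoted
for PAC filter banks, and it is not optional: the Hilbert envelope of a
band-limited signal can only fluctuate at rates below the filter
bandwidth, so a ±0.5 Hz amplitude band is physically unable to transmit
theta-rate (3–7.5 Hz) amplitude modulation — the modulation sidebands at
±fθ around the gamma carrier are attenuated by ~10⁻¹⁶ and the measured
envelope is constant regardless of the true coupling. The amplitude
bandwidth must cover the modulation rates of interest (here the theta
range); ±5 Hz does so while keeping adjacent bands distinguishable. Both
bandwidths are configurable.

Each trial is filtered in full, then 1 s per edge is discarded before
phase/amplitude extraction (filter and Hilbert edge transients); the
2 s/1 s sliding epoching is used only for power spectra. Power spectra
are rectangular-taper periodograms scaled so the one-sided power sums to
the epoch mean square (Parseval); only differences and averages of
like-scaled values are ever compared. Gamma power is the mean over the
25–40 Hz bins, both edges inclusive.

## MI estimation and bias correction

Phase and amplitude samples are pooled across trials within a recording
(maximizing n for the estimator; per-trial averaging is not offered as a
default because the quadratic extrapolation needs large n). Both streams
are quantized into 10 equipopulated bins by rank, ties broken by sample
index — deterministic, and invariant under any strictly monotone
transform of the raw values. Phase is rank-binned like amplitude; with
near-uniform Hilbert phase this nearly coincides with equal-width angle
bins while matching the equipopulation rule exactly.

The plugin estimator I = Σ p̂(x,y) log₂[p̂(x,y)/(p̂(x)p̂(y))] is biased
upward by ≈ (K−1)²/(2n ln 2) bits for K×K bins at sample size n. The
correction evaluates the estimator on the full sample (I₁), two disjoint
halves (I₂, averaged) and four disjoint quarters (I₄, averaged), with
binning recomputed inside every subset, and solves
I(n) = I∞ + a/n + b/n² exactly through the three points; I∞ is reported
and deliberately **not clipped at zero**, so condition differences
(ssPAC) remain unbiased around zero.

**Partitions are contiguous blocks, not random samples.** The index
range is cut into 8 contiguous blocks which are randomly assigned (two
per quarter, four per half) using a dedicated seed. Band-limited streams
are strongly autocorrelated; a sample-level random split produces
subsets whose effective sample size per retained sample is *higher* than
the full record's, which breaks the 1/n scaling the extrapolation
assumes (empirically, sample-level splits leave a residual bias of
~0.03 bits at the 0.5 Hz phase band, a gradient large enough to dominate
a comodulogram). Block assignment preserves the dependence structure, so
a half-subset behaves like a record of half the length. For iid inputs
the two schemes coincide in distribution. Within a comodulogram the
partition is drawn once per recording and shared by all grid cells and
sources (binning is still recomputed per subset per band); the
standalone `qe_corrected_mi` draws its own partition per call.

Multi-source recordings are processed per source and the MI matrices
averaged. ssPAC is the elementwise difference of the natural and rotated
comodulograms on identical grids. Band averages use cells whose centers
fall inside the band, endpoints inclusive (theta phase 3–7.5 Hz: 10
cells; gamma amplitude 22–38 Hz: 33 cells on the default grid).

## Cluster-based permutation test

Per grid cell, a one-sample t across subjects (n−1 sd; zero-variance
cells become ±∞ with a warning). Cluster-forming threshold: the
parametric two-tailed t quantile at the test's α (0.05) with n−1 df —
the conventional default when no threshold is stated. Clusters are
connected components under 4-connectivity (edge-sharing; 8 available),
formed separately for positive and negative cells; mass is the summed t.
The null distribution is the maximum |cluster mass| over sign-flip
permutations (each subject's whole map × ±1, preserving within-map
correlation; subjects are exchangeable under H₀: mean map = 0). Using
one max-|mass| null controls the family-wise error across both signs
jointly. p = (1 + #{null ≥ |mass|})/(n_perm + 1) (add-one estimator, so
p is never 0), significant when p < α. The permutation t statistics are
computed vectorized from the sign-flipped means and the sign-invariant
sums of squares, so the test scales to hundreds of calibration cohorts.

Calibration (recomputed by `scripts/acceptance.py` and the test suite):
over 500 null cohorts of 38 i.i.d. standard-normal maps, the proportion
with any significant cluster is consistent with the nominal 0.05 (the
add-one estimator makes the test very slightly conservative).

## Split-plot ANOVA and the rest of the group statistics

The design is one between-subject factor (Grade, 3 levels, groups may be
mildly unbalanced) and two 2-level within factors (Language,
Hemisphere), complete within subjects. The decomposition uses
orthonormal subject-level contrasts: the between stratum is a one-way
ANOVA on subject means (error: Subject within Grade, df N−3); each
within effect and its Grade interaction form a one-way ANOVA on the
corresponding contrast (error: contrast × Subject within Grade, df N−3
each). Group means are weighted by subject counts. With 2-level within
factors every within effect has 1 df, so no sphericity correction
arises. Effect sizes are partial η² = SS_effect/(SS_effect + SS_error).
The implementation is verified against an independent cell-mean
projection oracle (1e-9) and total-SS conservation.

Post-hoc contrasts are paired when both cells cover the same subjects
(t on the difference, df n−1, Cohen's d = mean diff / sd of diffs) and
independent otherwise (pooled variance, pooled-sd d); both d conventions
are reported because published values are often ambiguous between them.
Bonferroni multiplies p by the family size and caps at 1.

Brain–behavior regressions are per (score, hemisphere) OLS of the score
on band-averaged L2 ssPAC, with Pearson r and a fixed Bonferroni-style
significance threshold p < 0.005 (configurable; the family size behind
a fixed threshold is a reporting convention, so the threshold itself is
the configuration knob).

## Problem sizes used in validation

The test suite validates at desk scale, chosen once as the smallest
sizes at which each property is expected to hold with margin:
coupling-recovery at the full default recording size (40 × 10 s,
fs 500); monotonicity of band ssPAC in m over 10 seeds with 8 × 8 s
trials on the in-band grid; FWER calibration with 500 cohorts × 500
permutations; design recovery over 100 cohorts of full cohort size
(38 subjects × 8 recordings) with 4 × 6 s trials at fs 200 and a coarse
in-band grid. Null-effect assertions use exact binomial upper bounds at
the nominal rates rather than point equality.

## Known limitations

- The comodulogram assumes stationary coupling within a recording;
  time-resolved PAC is out of scope.
- Pooling samples across trials treats trials as exchangeable; slow
  drifts across a session would violate this.
- The QE correction needs n ≫ K² effective samples; with very short
  recordings (under ~40 samples per bin) estimates are noisy and may go
  negative even with true coupling.
- The ANOVA handles unbalanced groups but not missing within-subject
  cells (no imputation; incomplete designs are rejected).
- Equipopulated phase binning discards the circular topology of phase;
  for near-uniform phase distributions this is immaterial, but strongly
  non-uniform phase (e.g. evoked components) would make bins unequal in
  angular width.
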