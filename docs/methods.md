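# Methods

## Ciliary beat-frequency mapping

A recording is a T×H×W intensity stack with frame rate `fps`. Each
pixel trace is detrended (mean removal by default; optional linear
detrend for photobleaching/focus drift) and optionally Hann-windowed,
then transformed with a real FFT to a one-sided power spectrum of
resolution `fps/T`; the zero-frequency bin is always excluded. Spectral
power below a numerical floor proportional to the squared trace
magnitude (relative factor 1e-9 per sample) is snapped to zero so that
constant or drifting traces yield exactly empty spectra rather than
floating-point residue.

**Activity criterion.** Within the analysis band `[band_low,
band_high]` a pixel is called active iff its peak power is at least
`snr_threshold` times the *median* in-band power (inclusive
comparison); its CBF is the peak's frequency. The criterion is a
package choice — the recording supplement describing the original
decision rule is not public — and is deliberately simple and tunable.
Its null behaviour is characterized empirically: periodogram bins of
white noise are approximately i.i.d. exponential, so the max/median
ratio over K in-band bins concentrates near `ln K / ln 2`; with the
typical K ≈ 200–300 a threshold of 8 would fire on roughly half of all
pure-noise pixels, while the default `snr_threshold = 15` holds the
measured per-pixel false-positive rate near 1 %. Tests measure this
null rate directly and verify that all-noise videos stay inside its
binomial fluctuation band.

**Defaults.** Band 2–20 Hz (brackets the physiological 7–10 Hz range
with margin; must stay below Nyquist, so 30-fps analyses narrow it to
2–14 Hz), no window, mean detrending, no spatial smoothing (pixels are
independent). Frame rate and duration of the original recordings are
unknown; the synthetic default of 30 fps × 512 frames (≈17 s, bin width
0.059 Hz) is a package choice. Summaries are `active_area_pct = 100 ·
n_active / n_analyzed` (optionally within an ROI mask) and `mean_cbf`,
the mean frequency over active pixels (undefined, reported as NaN, when
none are active). Rendering maps `[band_low, band_high]` linearly onto
a temperature-style lookup table with inactive pixels black.

## Adjusted-AUC repeated-measures statistics

The adjusted AUC of a series observed at days `d₁ < … < d_k` is the
trapezoidal area divided by `d_k − d₁` — the time average of the
piecewise-linear interpolant, invariant to affine reparametrization of
the day axis. The trapezoid rule is a documented, swappable choice.
For log-analyzed endpoints the natural logarithm is applied to the
adjusted AUC itself, not pointwise.

Adjusted AUCs from a paired design (both treatments applied to cells of
every donor) are modeled with fixed factors group (HC/COPD), treatment
(CS/Air) and their interaction, and a compound-symmetry covariance
within donor. Estimation uses the closed-form balanced-design
(split-plot) moment estimators, which coincide with REML on balanced
two-treatment designs: the within-subject mean square comes from the
per-donor treatment differences pooled across groups, the
between-subject mean square from donor means. Residual degrees of
freedom are partitioned into between-subject (N − g, for the group main
effect) and within-subject portions (N − g, used for treatment and
interaction contrasts because treatment varies within every donor).
The treatment contrast within a group, `μ̂_{g,CS} − μ̂_{g,Air}`, has
standard error `sqrt(2·MS_within/n_g)`; with a single group this is
numerically the paired t-test on that group's differences. Tests are
one-sided with the direction fixed a priori per endpoint (decrease
expected under smoke: log AUC active-cilia area, AUC CBF, log AUC TEER,
KRT5/KRT14/MUC5AC ΔCt; increase expected: SCGB1A1/FOXJ1 ΔCt); p-values
are not adjusted for multiplicity. Donors missing a treatment arm are
rejected by name — no imputation.

Comparative-Ct arithmetic: with `ΔCt = Ct(target) − Ct(control)`,
`fold = 2^|AUC_air − AUC_smoke|`, an *increase* when the smoke AUC is
the lower one.

## Differential expression

Input is a transcripts × samples matrix on log scale, already
normalized upstream (library-size normalization and counting are out of
scope). Each transcript is fit by OLS with cell-means condition coding
plus donor dummy covariates (the paired design; donors are included
automatically when any donor contributes more than one sample). The
condition contrast is the log fold change; p-values are two-sided
t-tests; Benjamini–Hochberg step-up adjustment across transcripts gives
q-values (`q_(i) = min_{j≥i} m·p_(j)/j`, capped at 1). Rank-deficient
designs are rejected naming the confounded columns.

Empirical-Bayes variance moderation is deliberately not reimplemented:
the downstream consumers (signature membership, direction, ranking)
depend on direction and ordering, which plain OLS preserves. Because a
3-donor paired design leaves only 2 residual df per transcript — too
few for any per-transcript call to survive BH — `fit_linear_de` offers
a documented `variance_mode="pooled"` that assumes a common residual
variance across transcripts (pooled residual sum of squares, pooled
df). It serves the same purpose as moderation in the small-n limit and
is the mode the demo pipeline uses for the in vitro cohort; the default
remains per-transcript.

## Signature transfer

*Normalization.* Every transcript is scaled to `[0, 1]` across the
samples of one dataset: `(x − min)/(max − min)`; constant rows map to
all-zero with a warning. Normalizing each dataset independently removes
any per-transcript additive platform offset exactly, which is what
makes joining heterogeneous cohorts meaningful.

*Clustering.* UPGMA (average linkage) on the correlation distance
`d = 1 − r` (range [0, 2]); zero-variance leaves get r defined as 0
(d = 1) with a warning. The linkage is scipy's average-linkage
implementation; tests verify merge order and heights against a naive
recompute-from-scratch UPGMA oracle on small instances. Dendrograms
export to newick.

*Joining.* Two DE results are intersected at `q < q_cut` in **both**
comparisons, with no directionality filter; the two matrices are
normalized independently, samples concatenated, and columns clustered.
An empty intersection is an error; a single shared transcript yields a
valid 1-row matrix without a column dendrogram.

*Classification.* A random forest (default 100 trees, 10 features per
split, mirroring the original classifier settings) is evaluated with
stratified k-fold cross-validation, default 50 folds; when the smaller
class has fewer members than the fold count the scheme degrades to
leave-one-out with a logged notice. Out-of-fold class-vote fractions
are pooled into one ROC curve and AUC; the confusion matrix thresholds
the vote fraction at 0.5. Every stochastic operation takes a required
seed, and per-fold forests draw seeds from a seed sequence, so reports
are bit-reproducible.

*Ablation.* Features are ranked by absolute Pearson correlation with
the 0/1 label (ties broken by transcript id) on the **full** dataset —
before cross-validation, mirroring the two-stage procedure this
emulates; the resulting optimistic bias is accepted and documented.
The top k (default 10) are removed and the identical cross-validation
is rerun.

*Overlap.* Transcripts significant only in A, only in B, and in both
are counted; among shared transcripts, *consistent* means log fold
changes of the same nonzero sign (two exact zeros also count; a zero
against a nonzero is inconsistent). The consistent fraction is NaN when
nothing is shared.

## Synthetic data

The generators define the test conditions; they are plumbing, not
models of optics or sequencing chemistry.

*Videos* — beating is additive sinusoidal intensity (the simplest
signal with a defined CBF): inside a region each pixel follows
`background + A·sin(2πft/fps + φ)` with per-pixel phase φ ~
N(0, phase_jitter_sd) emulating imperfect metachrony, plus white
Gaussian noise everywhere. No point-spread function, motion blur, or
spatially correlated noise is simulated, so recovery rates on synthetic
videos bound only the spectral machinery, not segmentation performance
on real optics.

*Longitudinal tables* — per-day means per (group, treatment) cell; a
donor random intercept shared across both of a donor's series; an
equicorrelated residual vector per series (`residual_sd·(√ρ·z_shared +
√(1−ρ)·z_day)`), which realizes compound symmetry exactly. Defaults:
3 donors per group, days 7/14/21/28.

*Expression cohorts* — a paired in vitro cohort (default 3 donors ×
air/smoke; per-donor per-transcript effects of sd `donor_effect_sd = 1`
make the donor covariate consequential) and an unpaired in vivo cohort
(default 20 smokers vs 20 non-smokers), sharing `n_signature = 50` of
`n_transcripts = 500` deregulated transcripts at ±2 log2 units with a
configurable discordant fraction flipped in vivo, separated by a
per-transcript N(0, 2) additive platform offset that per-dataset
min–max normalization removes exactly. Gaussian noise throughout;
all draws from an explicit per-spec seed.

## Numerical and design notes

- Problem sizes in the test-suite simulations (e.g. 2,000-replicate
  calibration checks at module level, 10,000 in the acceptance suite;
  40×40-pixel recovery videos) are chosen to give three-sigma
  Monte-Carlo resolution on the quantities asserted.
- The type-I calibration, power-monotonicity, and recovery tests run
  the full generate → adjusted-AUC → fit → contrast path, not shortcuts.
- Degenerate inputs are contracts, not crashes: constant traces give
  empty spectra; all-inactive maps give NaN mean CBF; constant
  transcripts normalize to zero rows; zero-variance leaves cluster at
  distance 1; empty overlap gives NaN fraction with counts intact.
- The published cohort-scale numbers for this kind of study (TEER AUC
  means, DE counts, in vivo classification AUCs) depend on the original
  raw cultures and repository cohorts and are not reproducible at desk
  scale; the package instead guarantees the stage-level properties
  above and exposes `q_cut` and all hyperparameters for replication
  runs on downloaded data.

## Limitations

- The activity criterion is a stand-in; detection rates transfer to
  real videos only insofar as real noise resembles the white-noise
  null.
- Per-transcript OLS understates power at 2–3 donors (use pooled mode
  or more donors); no count-model dispersion handling.
- Compound symmetry is assumed, not estimated from alternatives; no
  missing-data handling beyond rejection.
- Feature ranking before cross-validation leaks label information into
  the ablation comparison (documented above).
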