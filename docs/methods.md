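# Methods

## Dose–response model

All single-chemical dose–response relationships are two-parameter Hill
sigmoids, `E(c) = c^p / (c^p + EC50^p)`, with the maximal effect fixed at 1.
Effects are unitless fractions in [0, 1]; percent readouts are divided by
100 at the I/O boundary. `c = 0` maps to effect 0 by continuity. Biphasic
or hormetic shapes and floating asymptotes are out of scope.

The two-point fit is closed-form on the log-logit linearisation:
`p = ln[(x1/(1−x1))/(x2/(1−x2))] / ln(c1/c2)`, EC50 by inverting either
point; it is exact at the two inputs. The full-curve fit minimises squared
effect residuals with bounded Nelder–Mead in log10 parameter space
(EC50 in 10^±8, slope in 10^±2), multi-started from two-point fits of the
extreme point pairs plus seeded perturbations — derivative-free, so it
needs no gradients and reproduces exactly under a fixed seed.

The six flavonoid standards' published EC5–EC50 values (`qpar.standards`)
are internally Hill-consistent: the two-point fit from (EC5, EC50) alone
reproduces each printed EC10–EC40 within 2 % relative (5 % for epimedin C,
whose printed EC5 of 0.02 μg/mL is heavily rounded). Slopes are exposed
per standard; the tabulated values are consistent with per-standard slopes
(fitted range ≈ 0.23–1.71).

## Joint-action predictors

The mixture predictors follow the classical forms: CA pools toxic units
`S = Σ c_i/EC50_i` inside one sigmoid `S^p/(1+S^p)`; RA multiplies survival
fractions; the Olmstead cassette model applies CA within each cassette and
RA across cassettes. One detail is normative here: the cassette model is
implemented in the form that is *increasing* in the toxic-unit sum, so that
a single cassette reduces exactly to CA and singleton cassettes reduce
exactly to RA (verified to 1e-12 in the tests). Within a cassette a single
shared power is used — the "average power" of its members; when per-feature
slopes are known the cassette power defaults to their arithmetic mean.

In screening use, "concentration" is the min–max-normalized feature
abundance, and the fitted EC50s are potencies in normalized-abundance
units, not μg/mL.

## Parameter estimation

`fit_joint_model` estimates per-feature potencies and per-cassette powers
by seeded multi-start bounded search: random starts (log-uniform potencies,
uniform powers; 32 starts by default) are scored in one vectorised pass,
and the best two are refined with bounded Nelder–Mead in log10 space.
Bounds are potencies ∈ [1e-3, 1e3] (normalized-abundance units) and powers
∈ [0.1, 10], spanning the standards' fitted slope range with ample margin.
Samples are split 0.7/0.3 into training and held-out sets; the held-out
RMSE is the reported prediction error. Equal-loss optima are tie-broken by
lexicographically smallest (powers, potencies), so reruns with the same
seed are bit-identical. The test suite checks the search against an
exhaustive 51-point-per-parameter log-spaced grid on small instances.

The PLS baseline is a standard 2-component PLS regression fitted on all
samples; its in-sample R² is the linear model-adequacy comparator.

## Cassette assignment from UV spectra

Features are grouped into cassettes — the mode-of-action groups of the
cassette model — by their UV-DAD spectra (200–400 nm), on the premise that
similar chromophores indicate similar structure and hence similar action.
Spectra are area-normalized (sum to 1) before clustering so that shape,
not peak intensity, drives the grouping. k-means with 20 seeded restarts
produces the assignment; the cassette number is recommended by the mean
silhouette over a scanned range, with the 2-component PCA score-plot
coordinates always returned so a human can override the choice visually
(a flat silhouette profile is flagged with "consider k=1"). The Pearson
correlation matrix of the spectra is provided as the diagnostic heat-map
companion; features with correlations above ~0.9 typically fall in one
cassette.

## The Good2bad screen

The Monte Carlo screen draws 1000 (sample, feature) subsets — each 70 % of
samples (training) × 5 % of features, ceiling-rounded, minimum one feature
— fits the chosen joint-action model on the training samples, and records
the RMSE on the 30 % held-out samples. The lowest and highest 5 % of errors
form the SEM and BEM tails; each feature's score is
`(F_SEM + α)/(F_BEM + α)` with α defaulting to 1/(tail size) (= 0.02 at
the defaults). The raw frequency ratio is undefined at F_BEM = 0; the
pseudocount preserves the ordering while avoiding infinities. Ranking ties
break by higher SEM frequency, then feature id.

Sub-model fits reuse the estimator with a reduced budget: 8 random starts,
of which the top **two** are refined (80 function evaluations per
parameter). Refining only the best start proved fragile — occasional
unconverged sub-fits landed active-containing models in the big-error tail
and displaced a true active from the top ranks even when every active
out-correlated every decoy; the second refinement removes almost all such
failures at roughly 1.6× the cost (~20 s for a full 1000-iteration screen
on 66 × 40 data on one core). Cassette labels are inherited from the full
assignment; cassettes emptied by the feature draw are dropped and labels
relabelled contiguously for that sub-model.

## Mixture-design utilities

The designed-mixture tools mirror the standard workflow for model
comparison: an 8 × 6 level layout (six uniform-design rows over the effect
levels EC5…EC50, plus all-EC50 and all-EC5 equivalent-effect rows) is
hard-coded as the canonical design — generating uniform-design tables for
arbitrary factor/level counts is a non-goal. A level row resolves to
concentration shares `ratio_j = EC_{x_j}(std j) / Σ_k EC_{x_k}(std k)`
(applied uniformly to all eight rows, including the equivalent-effect
ones), scaled to a 500 μg/mL total and expanded into a two-fold,
seven-step dilution series. Pairwise 1:1 blends of n base samples give all
n(n−1)/2 unordered pairs; because block solutions share one concentration,
a blend's profile is the arithmetic mean of its parents. The inhibition
rate is computed exactly as `(A_t − A_b)/(A_c − A_b)`; note this reads 1
for the no-drug control, i.e. as printed it is a viability-style ratio, so
an explicit `complement_rate` (1 − I) is provided as a separately named
transform — never applied silently. Clipping to [0, 1] happens only at the
I/O boundary and always warns.

## Synthetic data generator

No measured fingerprints or activities are deposited for this kind of
study, so the generator emulates the experiment's structure: 12 base
fingerprints (log-normal abundances, σ_log = 0.4, giving blended
per-feature CVs ≈ 0.3, inside the 0.1–1.3 band typical of TIC peak areas),
blended into all 66 pairs; 73 features in 3 cassettes with Gaussian-band
UV archetypes; and activities from a ground-truth Olmstead model over 3
planted active features plus Gaussian noise (sd 0.05), clipped to [0, 1]
with the clip count recorded.

Two generator choices matter for what the tests can show:

- **Active co-variation.** The planted actives share a log-normal common
  factor (loading 0.9; pairwise log-abundance correlation ≈ 0.8), as
  congeneric constituents of one biosynthetic pathway co-vary across
  source plants. This is not cosmetic: with only 12 base extracts, a fully
  independent decoy feature's *chance* correlation with activity
  (≈ 1/√12, maximum ≈ 0.6–0.8 over dozens of decoys) would rival what
  three mutually independent actives could each achieve, and no selector
  could reliably rank the exact active set first. Screening power on real
  data therefore depends on the actives genuinely co-varying — or on more
  base samples — and a passing recovery test here shows power under
  correlated actives, not under arbitrary signal structure.
- **Calibration.** Potency scale (4.2, with a fixed ×0.8/1/1.25 spread)
  and cassette slope (3.0) were set so the blended activities match
  assay-scale summary statistics (max/min/mean/sd ≈ 0.74/0.09/0.33/0.14):
  measured means over seeds 0–19 are 0.67/0.08/0.34/0.15.

The generator returns its full ground truth (parameters, active ids,
noise-free activities), and regenerating with the same seed is
bit-identical.

What the generator does **not** emulate: retention-time drift, peak
overlap or integration error (it produces post-extraction tables only),
heteroscedastic assay noise, plate effects, or correlations between
inactive features. Passing tests demonstrate the method's behaviour under
the stated statistical structure, not performance on raw chromatograms.

## Problem sizes and numerical choices

The stochastic test suites use 20-seed repetitions: active-feature
recovery on 66 blends × 40 features with the full 1000-iteration screen
(the exact top-3 active set required in ≥ 80 % of runs; 8 additional
permuted-activity null runs must stay flat), and the model-ordering
comparison on 56 designed-mixture points (8 mixtures × 7 dilutions,
cassette powers 2.5/3.0) where the Olmstead fit's adequacy R² must exceed
the 2-component PLS R² in ≥ 90 % of runs. Degenerate inputs are handled
explicitly: constant activity is unfittable; constant feature columns
normalize to zero and are flagged; constant spectra have undefined
correlations and are flagged; identical sub-model errors split tails by
stable index order with a warning.

## Known limitations

- The Hill maximum effect is fixed at 1; partial-efficacy components are
  not representable.
- Eq-level mixture slopes: CA uses a single exponent for a heterogeneous
  mixture; when member slopes differ strongly the cassette-average power
  is an approximation.
- The Good2bad score is a marginal (per-feature) statistic; strongly
  collinear features share credit, and the screen reports them jointly
  rather than disentangling them.
- Multi-start search offers no global-optimality guarantee; the grid
  oracle bounds it only on small instances.
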