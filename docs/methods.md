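# Methods

## Models

### Classifier

The classifier is a dense feed-forward network sized for cohorts of a
few hundred samples: two hidden layers of 16 and 8 ReLU units, a single
logistic output, L2 weight penalty (λ = 1e-4), Adam optimiser
(learning rate 1e-3), cross-entropy loss, mini-batches of 16, 200
epochs, no early stopping.  Training runs through scikit-learn's
multilayer perceptron, which implements exactly this architecture and
optimiser.  Four baselines run behind the same contract: linear SVM
(C = 1), RBF SVM (C = 1, kernel width 1/(p·Var X)), random forest
(500 trees), kNN (k = 5).  Every fitted model exposes `score(X)`
returning case-oriented probability-like values in [0, 1]; for margin
classifiers the signed distance is squashed logistically so that the
0.5 threshold coincides with the decision boundary.

Cross-validation is stratified five-fold with shuffled assignment from
the run seed.  Stratification is a deliberate choice (plain random
splits behave almost identically at these sizes but can starve a fold
of minority-class samples); per-feature z-scoring is fitted on the
training folds only, since the NN, SVMs and kNN are scale-sensitive.
Hard-label metrics (accuracy, precision, recall, F1) are evaluated at
score threshold 0.5; a 0/0 metric (e.g. precision with no positive
predictions) is reported as an explicit undefined marker, never as 0,
and excluded from fold aggregation with a logged count.  AUC uses the
package's own trapezoidal ROC, whose tie handling makes it equal to
the pairwise concordance probability P(case > control) + ½P(tie); the
test suite verifies this identity against brute-force enumeration.
AUC is reported on [0, 1] (a worse-than-chance classifier can score
below 0.5).

### Marker selection

Features are ranked by random-forest mean decrease accuracy in its
classical out-of-bag form: for each of 500 bootstrap trees (√p
candidate features per split), the accuracy on that tree's out-of-bag
samples is compared with the accuracy after permuting one feature's
OOB column (10 permutations, averaged); a feature's importance is the
mean drop over trees.  The bagged ensemble is built explicitly from
decision trees so the OOB sample of each tree is exact, and features a
tree never splits on contribute an exact zero.  This per-tree form is
markedly more sensitive than permuting inputs of the whole ensemble:
with 20 mutually redundant markers, ensemble-level permutation barely
changes aggregate predictions, whereas individual trees lean on
whichever markers they sampled.  Ties are broken lexicographically by
feature id for reproducibility.

The marker set is then chosen by a wrapper sweep: for each k in the
grid (default 5, 10, …, 60; a gene-level grid up to 100 is provided),
the NN is cross-validated on the top-k ranked features.  Fold
assignments are drawn once and shared across the whole grid, so the
curve varies only with k.  The smallest k attaining the maximal mean
AUC wins (parsimony on exact ties).  The sweep is not nested in an
outer CV by default, so the curve's maximum is an optimistically
biased estimate of the selected set's AUC; this matches the
procedure's usual field practice, and an unbiased estimate can be
obtained by evaluating the selected markers on an independent split
(`make_holdout_split`, `evaluate_markers`).

### Interaction network

Directed dependencies among markers are scored by per-target
regression forests: feature j (scaled to unit variance) is predicted
from all other features by a 1000-tree random forest with √(p−1)
candidate features per split; the total variance-reduction importance
of feature i, with each target column normalised to sum 1, is the
reliability M(i,j) of the directed link i→j.  The refinement step
multiplies each row i by the population variance of its off-diagonal
entries (diagonals are structural zeros and are excluded from the
variance).  The intuition: a source whose reliability mass concentrates
on a few strong targets has high row variance and is amplified; rows
spreading mass uniformly are damped.  Refinement is applied once,
before edge selection; the literal multiply form is the default and a
divide variant is available behind a flag.  The top-100 refined
off-diagonal entries (ties broken lexicographically by source then
target id) form the reported edge list.  Hub analysis counts distinct
partners regardless of direction — a node reciprocally linked to four
partners has degree 4, not 8 — with default thresholds 5 and 10.

### Covariate regression and stratification

The regressor reuses the classifier architecture with a single linear
output node and mean-square-error loss.  Each covariate is standardised
on the training folds, predicted out-of-fold (plain K-fold; the target
is continuous), and predictions are mapped back to original units.
Samples missing the covariate are dropped listwise per covariate with a
log message.  Pearson r between out-of-fold predictions and observed
values, with the exact two-sided t-transform p-value (n−2 df), ranks
the covariates by ascending p (ties by descending |r|); the top entry
is the leading factor.

Stratification bins samples by linear-interpolation quantiles of a
covariate (FBG quartiles by default).  Bin assignment is half-open
[b(k−1), b(k)) with the last bin closed above, so assignment is total
and deterministic; a sample exactly on a boundary belongs to the upper
bin.  Per-bin mean abundances are min-max normalised per feature;
constant rows map to all zeros with a warning.  Per-feature
case/control testing uses the tie-corrected Kruskal–Wallis H with the
chi-square approximation (1 df for two groups); significance classes
(higher-in-case / higher-in-control by the mean-rank difference at
p < 0.05) are reported without multiple-testing correction by design —
the per-feature colouring convention of the field — and a
Benjamini–Hochberg option exists for users who want controlled FDR.

## Synthetic cohorts

The generator emulates a species-level shotgun-metagenomics
case/control study.  Per feature, a base log-abundance is drawn from
N(0, 1.5²) — a realistic two-to-three-orders-of-magnitude spread of
mean abundances; per sample, unit-variance log-scale residuals are
added, exponentiated, thinned by structural zeros (default probability
0.2), and each row is closed to sum 1.  Defaults are 100 cases + 100
controls, 200 features, 20 markers, matching a mid-sized human cohort.

Planted signal comes in two forms.  *Shifted* markers receive a
±effect/2 group mean shift on the log scale (default total effect 1.0,
one residual standard deviation, sign random per marker).  *Flat*
markers carry scale-only signal: the case group's log-scale residual is
multiplied by (1 + effect), leaving the centre unchanged.  A location
rank test is essentially blind to this (P(case > control) = ½ on the
latent scale), while threshold learners — trees, the NN — can exploit
the widened tails, so these markers are predictive without a marginal
shift.  Closure leaks a small amount of scale signal into location
(the case rows' totals are slightly inflated, depressing other
features), so the realised rank-test rejection rate on flat markers is
slightly above the nominal α — about 0.08 at α = 0.05 pooled over
seeds — a property of compositional data itself, not of the test.

Directed dependencies are planted as target += coefficient × source on
the latent log scale, applied in topological order (the edge list must
be a DAG); the standalone network fixture draws roots from N(0, 1) and
children as parent sums plus Gaussian noise.

Covariates are a weighted sum of the coupled markers' standardised
*observed* relative abundances plus Gaussian noise, with weights signed
by each marker's disease direction, and an additional upward FBG shift
in cases (hyperglycemia).  Coupling on the observable scale is
deliberate: compositional closure makes the absolute latent scale
unobservable (the log row total enters every feature), so a covariate
tied to raw latents would carry mostly unrecoverable variance and its
nominal signal-to-noise ratio would be meaningless.  With the signal
standardised to unit variance, the noise standard deviation is an
exact SNR control: FBG uses noise sd 0.707 (variance ratio 2:1, ceiling
r ≈ 0.82), BMI/age/weight use 1.0/1.2/1.5.  Default output units:
FBG 6.0 ± 1.2 mmol/L with +1.8 in cases, BMI 25 ± 3 kg/m², age
52 ± 9 y, weight 70 ± 11 kg.

What the generator does *not* emulate: phylogenetic correlation
structure, batch effects, sequencing depth variation, overdispersed
zero inflation conditional on abundance, or realistic taxon-taxon
ecological networks.  Passing recovery tests therefore demonstrates
that the machinery extracts the kinds of signal it claims to extract —
not that any particular real cohort contains such signal.

## Numerical choices and degenerate inputs

- Row closure tolerance 1e-9; IO round-trips preserve values to 1e-12.
- Percentage-scale tables ([0, 100]) are auto-detected by row-sum
  magnitude and stored as fractions.
- Constant features: importance exactly 0; as network targets, an
  all-zero adjacency column with a warning; in Kruskal–Wallis, H = 0.
- Zero-variance adjacency rows legitimately refine to zero rows.
- All-zero samples, single-class labels, constant covariates, cyclic
  planted edge lists and empty feature sets are hard errors.
- Every stochastic stage derives its seed from one run seed via fixed
  offsets (see `micromarkers.pipeline.STAGE_OFFSETS`), making full runs
  byte-reproducible.

## Problem sizes in the test suite and acceptance script

End-to-end recovery checks run at the generator's default cohort size
(200 samples × 200 features).  Medians are taken over 7 independent
cohorts for marker recovery, 15 for the flat-marker comparison, 5 for
covariate regression, and 3 + 3 for network recovery/null checks;
the rank-test calibration uses 2000 null features.  These counts were
chosen so the full suite completes in well under half an hour on one
CPU while keeping the medians stable; single-seed examples in the unit
tests use smaller cohorts.

## Known limitations

- The AUC-vs-k curve is flat beyond the planted marker count on easy
  cohorts, so the argmax (selected k) has high seed-to-seed variance
  even when marker recovery is near-perfect; the smallest-k tie rule
  only resolves exact ties.  A one-standard-error selection rule would
  be more stable but would change the stated selection contract.
- The non-nested sweep reports an optimistic AUC at the selected k.
- Permutation importance is computed per tree on OOB samples; with
  strongly correlated features, importance mass is shared and absolute
  values are not comparable across data sets (ranks are what the
  pipeline consumes).
- The network refinement amplifies hub rows cubically in the row scale,
  so refined weights are useful for ranking, not as calibrated
  reliabilities.
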