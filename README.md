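# micromarkers

Identification of disease-associated microbial markers from case/control
relative-abundance profiles, combining a lightweight neural network with
random-forest feature ranking — plus directed marker interaction-network
inference, covariate regression and covariate-quantile stratification.

## The problem

Case/control metagenomic studies (e.g. type 2 diabetes vs healthy gut
microbiomes) profile each stool sample as a vector of species or gene
relative abundances — compositional data: non-negative rows summing
to 1.  Classical differential-abundance tests flag only features whose
marginal distribution shifts between groups.  Yet features that barely
shift marginally can still carry disease signal through nonlinear and
interaction effects.  This package implements a framework that finds
such markers:

1. **Classification.** A dense NN — two hidden layers of 16 and 8 ReLU
   units, L2 penalty, Adam, cross-entropy loss, logistic output —
   classifies case vs control, benchmarked against linear SVM, RBF SVM,
   random forest and kNN under stratified five-fold cross-validation
   (accuracy, precision, recall, F1 at threshold 0.5, and ROC AUC).
2. **Marker selection.** Features are ranked by random-forest *mean
   decrease accuracy* (per-tree out-of-bag permutation importance); the
   NN is then cross-validated on the top-k features for k on a grid
   (5, 10, …, 60 for species; up to 100 for genes), and the smallest k
   maximising mean AUC defines the marker set.
3. **Interaction network.** Each marker in turn is regressed on all
   others with a random forest; importance scores give a directed
   adjacency M where M(i,j) is the reliability of link i→j.  A
   refinement multiplies each row by the variance of its off-diagonal
   entries, M̂(i,:) = M(i,:)·σ²ᵢ, amplifying putative hub sources; the
   top-100 refined links form the reported network, with hub nodes
   (≥ 5, ≥ 10 distinct partners) and TSV/GraphML export.
4. **Covariate regression.** The same NN with a single linear output
   node and MSE loss predicts each clinical covariate (FBG, BMI, age,
   weight) out-of-fold from the marker abundances; Pearson r and its
   t-distribution p-value rank the covariates, the most significant
   being the leading factor.
5. **Stratification.** Samples are binned by covariate quantiles (FBG
   quartiles by default); per-bin mean marker abundances, min-max
   normalised per marker to [0, 1], show where along the covariate
   range each marker peaks.  Per-feature Kruskal–Wallis tests classify
   markers as higher-in-case / higher-in-control / not-significant.

A synthetic-cohort generator (`micromarkers.synthetic`) provides sparse
compositional cohorts with planted shifted markers, planted *flat*
markers (scale-only signal invisible to rank tests), planted directed
dependencies and coupled covariates, so the whole pipeline runs and is
testable without access to any sequencing data.

## Worked example

```bash
python examples/02_select_markers.py
```

prints the AUC-vs-k sweep on a simulated cohort with 20 planted
markers (seed 1):

```
k    mean AUC   sd
5    0.941     0.053
10   0.974     0.024
15   0.983     0.011 <- selected
20   0.982     0.008
25   0.978     0.012
...
selected 15 markers; 15 of 20 planted markers captured (75% recovery)
```

The curve climbs while informative features are added and flattens once
the planted markers are exhausted; the selected set is the smallest k
attaining the maximal mean cross-validated AUC.  The other example
scripts walk through classification benchmarking, network inference on
a planted DAG, covariate regression (FBG, the most tightly coupled
covariate, ranks first), and FBG-quartile stratification.

The same stages are scriptable from the shell:

```bash
micromark simulate --seed 1 --out-prefix sim/
micromark select-markers --profile sim/profile.tsv --metadata sim/metadata.tsv \
    --k-grid 5:60:5 --seed 1 --out sim/markers.json
micromark full-run --seed 1 --out-dir run/     # all stages + manifest
```

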