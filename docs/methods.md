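# Methods

## Overview

`sigspec` analyses the cancer specificity of somatic mutational signatures.
It covers five stages, each usable on its own:

1. **Catalog construction** — somatic SNVs are classified into the 96
   pyrimidine-centered trinucleotide substitution classes (SBS-96) and
   counted per sample.
2. **Signature refitting** — each sample's catalog is decomposed against a
   fixed panel of reference signatures by non-negative least squares.
3. **Collinearity** — Pearson correlation between signatures across all
   samples, and pairwise cosine similarity between samples within each
   cancer type.
4. **Cancer-specificity classification** — one-vs-rest binary classifiers
   (five methods) predict a sample's cancer type from its signature
   exposure profile, trained on one cohort and evaluated on an independent
   one.
5. **Significance** — each matched model's F1 is compared against a
   background of mismatched-cancer F1 scores summarized by a fitted
   negative binomial.

A synthetic-cohort generator provides ground-truth study conditions for all
of this without any external data.

## The SBS-96 motif space

A single-base substitution is always expressed on the pyrimidine strand:
purine-reference records (A/G) are mapped to the reverse complement of
their (context, ref, alt) triple, the standard COSMIC convention. With 6
substitution types (C>A, C>G, C>T, T>A, T>C, T>G) and 4 choices for each
flank this yields 96 classes, ordered canonically by substitution block,
then 5′ flank, then 3′ flank (`index = 16·sub + 4·five + three`). All
matrices in the package share this row order; signature files in either
COSMIC dialect are re-ordered to it on read and column-renormalized when
their sums are within 1e-3 of 1.

Records that cannot be classified (ambiguous N bases, missing context,
non-SNVs) are skipped and counted; a context that *contradicts* the record
(middle base ≠ ref, or inline context ≠ FASTA) is an error, because it
indicates corrupted input rather than missing information.

## Refitting model

For sample j with catalog column m_j and signature matrix S (96×K, columns
summing to 1), exposures solve

    e_j = argmin_{e ≥ 0} ‖ m_j − S e ‖₂ .

The solver is the classical active-set NNLS (`scipy.optimize.nnls`), chosen
over multiplicative-update NMF refits because it is deterministic and
returns *exact* zeros for inactive signatures — which makes the downstream
presence/absence dichotomization ("contribution equals 0" vs "> 0")
well defined. Catalogs are fitted as raw counts, so exposures carry
mutation-count units. Dichotomization treats an exposure as zero when it is
below 1e-8 of the sample's total exposure, a guard against round-off only.
Reconstruction quality is monitored by the cosine between m_j and S e_j.

## Collinearity

Signature–signature correlation uses Pearson's r on continuous exposures
across all samples pooled; a pair is "highly correlated" when r > 0.7
(strictly; ties at the threshold are excluded). Constant exposure rows have
undefined correlation and are marked NaN, never reported as pairs.
Sample–sample similarity uses cosine on exposure columns within each cancer
type; exposures being non-negative, cosines lie in [0, 1]. All-zero columns
are excluded with a warning, and cancer types with fewer than two usable
samples are omitted.

## Classification stage

Features are the K signature exposures per sample, Min–Max scaled to [0, 1]
with parameters fitted on training data only (test values are clipped into
[0, 1]; constant training features map to 0). A `binary_features` option
substitutes the dichotomized presence calls. For each cancer type a binary
one-vs-rest task is formed; the training side is rebalanced with SMOTE
(synthetic points interpolated uniformly between a minority sample and one
of its k = 5 nearest minority neighbors, originals retained, classes
balanced to equal counts). The independent test set is never resampled and
is transformed with the training scaler — this wiring is asserted by tests.

The five methods and their fixed hyperparameters:

| method | implementation | key settings |
|---|---|---|
| RF  | scikit-learn random forest | 100 trees, sqrt features per split, Gini, unlimited depth |
| XGB | XGBoost | 100 rounds, depth 6, learning rate 0.3, logistic loss |
| MLP | scikit-learn MLP | hidden (32, 16), L-BFGS, alpha 1e-4 |
| DNN | numpy feed-forward net (this package) | 32-ReLU + dropout 0.2 + input-concat skip, 8-ReLU + dropout 0.2 + skip, sigmoid out; Adam lr 1e-4, BCE, 100 epochs, batch 8, early stopping patience 10 on a 20% stratified validation split |
| NAS | Bayesian architecture search (this package) | space: 1–3 dense layers of 8–64 units, shared activation ∈ {relu, tanh, sigmoid}, dropout ∈ [0, 0.5], batch norm on/off, optional input-skips into layers 2–3 |

The DNN and the NAS candidate networks run on a compact numpy
implementation (dense layers, batch normalization, inverted dropout, Adam,
early stopping with best-weight restoration); it is single-threaded and
fully deterministic under its seed. NAS evaluates `budget` architectures
(default 25, minimum 5): an initial random phase of 5 trials, then a
Gaussian-process surrogate (Matern ν = 2.5 + white noise) over encoded
architectures proposes the expected-improvement maximizer among 128 random
candidates per iteration. Candidate networks train with lr 1e-3, 60 epochs,
batch 16 — faster settings than the DNN's, since each trial is a probe of
the architecture rather than a final model; the selected trial's trained
network is returned. The objective is F1 on a 20% stratified validation
split carved once per search.

Evaluation reports precision (0 with a warning when nothing is predicted
positive), recall, F1 (harmonic mean), accuracy, and AUC computed as the
Mann–Whitney rank statistic on scores. Label metrics use a 0.5 score
threshold. Feature importance is normalized impurity importance for the
tree models and permutation importance (mean F1 drop over 10 per-feature
shuffles, computed on the held-out test table) for the neural models; ties
are broken by feature id.

## Significance: mismatched-cancer background

For T cancer types and one method, every ordered mismatched pairing — the
model trained for cancer A scored against cancer B's one-vs-rest test
labels, A ≠ B — contributes one background F1, giving T·(T−1) values. The
background is summarized by a negative binomial fitted to the integer
discretization `round(100·F1)` by the method of moments: with count mean m
and (population) variance v, p = m/v and r = m²/(v−m) when v > m; when
v ≤ m the negative binomial is undefined and a Poisson(m) is used; an
all-equal background degenerates to a point mass (with a warning). The
p-value of a matched model is the one-sided upper tail
P(X ≥ round(100·F1)) under the fitted law; models with p < 0.05 are
flagged.

The count discretization is this package's explicit convention — F1 is
continuous and bounded while the negative binomial is a count law, so some
mapping must be chosen; treating percent-F1 as a count is the simplest one
consistent with fitting an NB at all. Because the NB form is a modeling
choice rather than a theorem, the empirical plus-one tail fraction
(1 + #{background ≥ observed}) / (1 + n) is always reported alongside the
parametric p. No multiple-testing correction is applied. Fewer than 10
background values trigger an instability warning.

## Synthetic cohorts

The generator draws exactly from the model the refit assumes, so parameter
recovery is a meaningful end-to-end check:

* **Reference signatures**: K Dirichlet(0.1) draws over the 96 motifs
  (peaked, COSMIC-like); columns closer than cosine 0.9 to an earlier
  column are resampled so the panel is identifiable.
* **Patients**: per-signature activity ~ Bernoulli(activity_prob) (an empty
  draw forces the most probable signature on); active weights ~
  Gamma(shape, scale) with per-signature scales allowed; mutation burden ~
  negative binomial (mean 2,000, dispersion 2 by default) truncated below
  at 50 — NNLS on fewer counts is too degenerate to be informative;
  exposures are the weights rescaled to the burden; the catalog column is
  Multinomial(burden, normalize(S·e)).
* **MAF emission**: catalogs expand to SNV rows with inline contexts at
  synthetic coordinates, ~50% emitted strand-flipped to exercise pyrimidine
  collapsing; rebuilding the catalog from the emitted file is exact.

Gamma-mixture exposures on top of NB burdens produce the heavy-tailed
per-signature abundance spread seen in real cohorts. What the generator
does **not** emulate: real genome positions, exome-vs-genome platform
differences, hypermutator subpopulations, or real cohort compositions —
passing tests demonstrate correctness of the pipeline's computations under
its own model assumptions, not performance on real tumor cohorts.

Three benchmark scenarios package a train/test study design (5 cancer
types, K = 10 signatures, 60 patients per type per split by default; test
profiles get per-signature exposure-scale jitter of ±10% and non-US region
codes to emulate an external cohort):

* `specific_skcm_analogue` — one type (the skin-cancer analogue) carries an
  exclusive signature at activity 0.95 with a 10× exposure scale; the other
  four share overlapping mixtures. Every method should rank this type's
  one-vs-rest F1 first and the NB test should flag it.
* `null_identical_types` — all five types share one generative profile;
  used to check that the NB test's flag rate stays low (≤ 15% across
  replicates; observed ≈ 5%).
* `diverse_mixtures` — each type gets independent random activity
  probabilities; a mid-difficulty setting.

## Pipeline and determinism

`SpecificityStudy.fit()` runs: refit (train and test) → test-group size
filter (groups under 50 samples dropped; training untouched) → label
harmonization (cancer types present in both splits) → scaling → SMOTE →
per-(cancer × method) training → evaluation on the independent test set →
backgrounds and significance → importances → collinearity summaries. All
randomness derives from one top-level seed through named substreams
(`smote`, `split`, `model`, `nas`, `importance`) via `SeedSequence`, so
reruns with the same configuration are numerically identical.

## Problem sizes

Default study conditions (5 types × 60 + 60 patients, ~2,000 mutations
each, NAS budget 10–25) run the full five-method study in well under a
minute per method on one CPU; parameter-recovery checks use 200 patients at
~5,000 mutations. These sizes were chosen as desk-scale analogues of a
cohort study: large enough that the exclusive-signature effect and the null
calibration are stable across seeds, small enough to iterate on.

## Known limitations

* The classification target is one-vs-rest cancer type from exposures; no
  multiclass model is provided.
* The negative-binomial background is fitted per method by pooling all
  mismatched pairs; with few cancer types the fit rests on few values and
  the empirical tail is the safer guide.
* The NAS space is small and dense-layer-only by design; it is a search
  over classifier capacity, not a general NAS framework.
* No variant filtering (e.g., hypermutator exclusion) is applied when
  reading MAF-like input beyond skipping non-SNVs.
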