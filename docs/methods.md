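# Methods

## Scope and model

`toxqsar` implements a classical QSAR classification workflow for binary
activity endpoints: 2D featurization of molecular graphs, univariate
information-gain screening wrapped in backward elimination, seven standard
classifier families, a centroid-distance applicability domain, and
Shapley-style attribution of model scores. Activity is a binary label
(1 = active in the assay, 0 = inactive); no potency regression is
attempted.

## Featurization and cleaning

SMILES are parsed and canonicalized with RDKit; two spellings of one
molecule always produce one canonical string and therefore identical
descriptor rows. Registered families: the full RDKit 2D descriptor list
(~210 values: log P estimates, topological indices, autocorrelations,
E-state aggregates, fragment counts), MACCS keys (167 bits), path-based,
atom-pair and Morgan/circular fingerprints (512 bits each, hashed), and the
79-key E-state fingerprint (counts and sums). `combined` concatenates all
of them with family prefixes keeping names unique.

Cleaning is strictly column-wise: a descriptor with at least one missing or
non-finite value over the dataset is deleted for every compound. The
alternative (dropping compounds) would change the modeled population; with
per-endpoint descriptor survival varying widely in practice, column
deletion keeps n fixed while guaranteeing a fully finite matrix. Salt
stripping and charge neutralization are not performed; inputs are used as
canonicalized.

Min-max normalization stores per-feature training minima and maxima.
Constant features map to 0 (the formula is 0/0 there; an inert constant is
the only sensible reading). Query values are deliberately not clamped to
[0, 1]: compounds outside the training range must acquire large
applicability-domain distances, and clamping would hide exactly the
extrapolation the domain exists to flag.

## Information-gain elimination

Continuous descriptors are discretized into B equal-width bins over
[min, max] (default B = 10; the maximum closes the last bin; constant
features short-circuit to IG = 0). Information gain is
H(Y) − Σ_b p(b)·H(Y|b) in bits, so it is bounded by the label entropy and a
perfect copy of balanced labels scores exactly 1 bit. Equal-width binning
was chosen over quantile binning because it is deterministic, cheap, and
exactly checkable against a brute-force contingency-table oracle.

Backward elimination starts from the full feature set, removes the `step`
lowest-ranked surviving features per round (default 1; larger steps for
wide matrices), retrains the chosen classifier, and records validation AUC
for every subset down to `min_features` (default 2). The ranking is
recomputed on the surviving features each round by default; a rank-once
mode exists for large p. The selected subset is the validation-AUC argmax,
ties toward fewer features; since the full set is itself a candidate,
screening can never do worse than no screening *on the validation split*.

Validation AUC comes from an inner 8:2 split of the training portion, never
from the final test split. Selecting on the reporting split would leak
information and inflate the post-screening advantage; the cost is that on a
finite test set the non-degradation property holds only up to sampling
noise (see Limitations).

## Classifiers

DT, NB (Gaussian), SVM (RBF), kNN, RF, XGB and MLP share one
train/predict-scores contract. Hyperparameters are the library defaults,
overridable per run — no tuning is baked in, and seeds are pinned for every
stochastic learner so the whole pipeline is reproducible end to end.
Scores are probability-like where the estimator provides them (class-1
probability); the SVM margin is squashed through a logistic, which is
rank-preserving and therefore AUC-neutral. Class-imbalance corrections
(weights, resampling) are off by default.

Splits: train size is round(ratio·n) with ratio 0.8; stratification (on by
default, because screening endpoints are typically heavily imbalanced)
apportions train slots per class by largest remainder, keeping prevalence
within one compound of proportional and both classes on both sides. A class
with fewer than two members cannot be stratified and raises.

## Evaluation

ACC = (TP+TN)/total; F1 = 2TP/(2TP+FP+FN) with the 0-convention when
undefined; sensitivity and specificity are reported alongside so every
ingredient of the composite metrics is visible. ROC-AUC is the headline,
threshold-free metric (Mann–Whitney form; ties credited 0.5; class calls
for ACC/F1 use a fixed 0.5 threshold). Banding: ≥0.8 excellent, ≥0.7 good,
≥0.6 fair, below that poor, with a worse-than-random flag under 0.5.

## Applicability domain

Fitted on the selected feature subspace the model actually consumes (a
domain should describe the inputs the model sees; fitting on the full
descriptor space is available by simply passing the uncut matrix). The
centroid is the mean of the min-max-normalized training rows; the reported
distance is the Euclidean norm √((x−μ)ᵀ(x−μ)); the threshold is the maximum
training distance, making 100% training coverage a construction guarantee,
not an empirical result. The boundary is inclusive: only strictly exceeding
the training maximum is out-of-domain. In/out decisions are invariant to
whether the squared or root form is used as long as the threshold is
transformed consistently; the root form is reported because it is the
distance.

## Attribution

Attributions are interventional Shapley values of the model score: the
payoff of coalition S for sample x is the mean score over background rows
with the S-features replaced by x's values. Two estimators:

- **exact** — enumerates all 2^p coalitions with the Shapley weights;
  model-agnostic and exact, used automatically for p ≤ 14.
- **sampling** — seeded permutation sampling; each permutation contributes
  a telescoping chain of marginal effects, so local additivity
  (base + Σφ = score) is exact for any permutation count while individual
  φ_j converge with more permutations (default 30).

The background is up to 100 (default 50 in the CLI) seeded rows of the
explained matrix. The summary is mean |φ_j| over explained samples; the
share table takes the top k (default 6), normalizes to percentages summing
to 100 and rounds to one decimal, the convention used when reporting an
endpoint model's dominant descriptors.

## Synthetic study conditions

The numeric generator emulates a cleaned descriptor table: n = 500 samples,
p = 20 features, 5 informative with class means separated by 2 standard
deviations, 30% active prevalence (screening data lean inactive), Gaussian
class-conditional features. Gaussian columns were chosen because recovery
expectations are closed-form: with 5 independent informative features at
effect 2, the Bayes-optimal AUC is essentially 1, so a held-out RF AUC
≥ 0.90 after screening indicates the selector kept the signal. Column names
flag informative columns for recovery scoring only; nothing in the pipeline
reads them.

The SMILES generator assembles 300 substituted benzenes (1–3 substituents
from ~20 benign fragments); about 40% receive an aromatic nitro group, the
planted toxicophore (a classic mutagenicity alert), and the label is the
substructure match XOR optional noise (default 0, so the structural signal
is exact). Every emitted SMILES is valid by construction and re-validated.
What these fixtures do not emulate: the chemical diversity, descriptor
correlation structure, assay noise and extreme imbalance of real screening
data — passing on them demonstrates mechanical correctness and signal
recovery, not real-endpoint accuracy. Reproducing published per-endpoint
numbers requires the actual endpoint datasets, which are intentionally not
bundled.

Verification problem sizes (5 seeds for the numeric recovery/screening
battery, 3 seeds for the chemistry pipeline, 200-instance oracle sweeps)
were chosen to make the battery minutes-scale on a single CPU while keeping
every property statistically unambiguous at the planted effect sizes.

## Known limitations

- Screening non-degradation is guaranteed on the selection (validation)
  split, not the test split: with ~100 test compounds, test AUC has
  sampling noise of a few hundredths, and a high-variance learner (a single
  decision tree especially) can occasionally score worse after screening
  than before by more than that margin on an unlucky seed. The verification
  battery reports the measured minimum AUC delta rather than asserting a
  universal inequality.
- Information gain is univariate: features informative only in interaction
  can be eliminated early. The elimination wrapper mitigates but does not
  remove this.
- Fingerprint families are RDKit's; other toolkits' same-named fingerprints
  (PubChem, Klekota-Roth, CDK variants) differ bit-for-bit, so feature-level
  comparisons across toolkits are not meaningful.
- The applicability domain is a single centroid ball in normalized space:
  it flags range extrapolation, not density holes inside the training
  envelope.
- Exact attribution is exponential in p and refuses p > 14; the sampling
  estimator's per-feature values (not their sum) carry Monte-Carlo error.
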