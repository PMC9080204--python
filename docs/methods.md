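# Methods

`lggpc` reimplements the downstream proteogenomic analysis of diffuse
low-grade glioma (LGG) molecular subtypes as a tested pipeline. The three
subtypes follow the standard molecular classification: Type I =
IDH-mutant with 1p/19q codeletion (oligodendroglioma), Type II =
IDH-mutant 1p/19q-retained (astrocytoma), Type III = IDH-wildtype. The
pipeline takes a protein abundance matrix (features × samples, TMT-style,
log2 or raw intensity), a sample sheet with subtype labels, a
feature-to-chromosome-arm map, and optionally a matched RNA matrix.

## Missing values

No imputation anywhere. Proteins not quantified in every sample are
removed by a complete-case filter, mirroring the practice of keeping only
proteins identified in all mass-spectrometry runs. The synthetic
missingness model blanks whole feature-by-run blocks (runs of 9
consecutive samples) because identification dropout in multiplexed MS is
a per-run, not per-sample, event. The 9-sample run grouping is a
placeholder for an unknown real multiplexing layout.

## Differential abundance

Per-feature Welch (unequal-variance) t-test on log2 values, for both
proteins and RNA. RNA count models (negative binomial / DESeq2-style) are
deliberately out of scope; Welch-on-log2 is a declared surrogate, and RNA
significant sets will not match count-model output exactly. Multiplicity
is controlled with Benjamini–Hochberg across **all** features tested in a
contrast — the fold-change gate is a separate filter, not a pre-test
screen. A feature is significant iff |log2FC| > log2(1.5) (strict) and
BH-adjusted p < the stage cutoff (0.01 for RNA, 0.05 for protein by
default; the proteome gets the looser gate because TMT ratio compression
attenuates fold changes). Degenerate features: zero variance in both
groups with equal means gives p = 1; zero variance with unequal means is
floored at machine epsilon so the feature reports as extreme rather than
NaN.

CIC variant subgrouping (used when a cohort carries oligodendroglioma
mutation calls): frameshift or stop variants are loss-of-function
regardless of position; missense variants count only in exon 5 (HMG
DNA-binding domain) or the C1-motif exon. Domain annotations disagree on
whether the C1 motif lies in exon 19 or 20; the default is 20 with 19
selectable (`cic_c1_exon`).

## Arm localisation

Significant features are tallied per arm (1p, 1q, 19p, 19q, other;
unannotated features fall into "other" and are logged). Enrichment of
down-regulation on an arm is tested with a two-sided Fisher exact test on
the 2×2 table (on-arm vs off-arm) × (down vs up) among significant
features. Published analyses of this kind usually only plot the up/down
ratio; the Fisher formalisation is this package's choice so the claim is
testable, and the raw ratio is reported alongside. Empty margins return
p = 1 by convention.

## Codeletion z-score

For every protein on a target arm set (default 1p ∪ 19q), z against the
normal-brain reference: z_fs = (x_fs − mean_f(NORMAL)) / sd_f(NORMAL),
with the n−1 sample SD; features with reference SD < 1e-8 are excluded.
The per-sample combined score is the unweighted mean of z_fs over
features (median available via `combine="median"`); "combined z-score"
could also mean a z of summed expression — the per-feature mean is the
simplest estimator and is the documented choice. The score is **not**
invariant to per-sample global shifts (a test asserts this), so any
between-sample normalisation must precede scoring. Group differences are
assessed with pairwise Welch tests, BH-adjusted across pairs.

## RNA–protein dosage attenuation

Per arm, ordinary least squares of per-gene mean protein on per-gene mean
RNA (means over one subtype's samples, genes matched by ID; protein is
the response). R² equals the squared Pearson correlation of the two mean
vectors by construction, and a test holds this to 1e-12. Arms with fewer
than 3 shared genes are skipped. Low per-arm R² (~0.1–0.3) quantifies how
much transcript-level dosage signal is buffered before protein.

## Marker panel

The three pairwise contrasts must be supplied as (I vs II), (I vs III),
(II vs III); orientation is validated, never inferred. Each significant
call is an ordering statement between two subtypes. Under `any_two`
(default) a feature needs ≥ 2 mutually consistent statements; the subtype
that is first (last) in every total order of the three subtypes
consistent with those statements is assigned UP (DOWN). Transitivity is
allowed, so a stepwise feature (monotone across subtypes) earns two
assignments and a subtype's count can exceed any single contrast's
significant count. Under `strict_both` a feature is S-specific only when
both contrasts involving S are significant with the same sign relative to
S; every strict assignment is also an `any_two` assignment (tested).
Published panel counts of this kind are not always reconstructible from a
single strict reading — e.g. a subtype's marker count can exceed the
significant-protein count of one of its contrasts — which is why both
rules ship and the rule used is recorded in the output.

## Classifier

Ridge-penalised multinomial (softmax) logistic regression on the panel
features, fitted with scikit-learn's lbfgs solver (`C = 1/lambda`,
intercept unpenalised). Default `ridge_lambda = 1.0` on standardised
features: with ~50 features and ~48 tumour samples an unpenalised fit can
be separable and divergent, and separable data with `lambda = 0` raises
an error instructing a positive lambda. Evaluation is stratified k-fold
cross-validation (default 10 folds, reduced to the smallest class count
when needed; folds seeded): standardisation is fit on each training
split, held-out class probabilities are pooled across folds, and one ROC
is computed per class one-vs-rest plus one AUC per class pair one-vs-one
(conditional probability p_i/(p_i+p_j) on the two classes' samples). The
pairwise AUCs are the headline numbers; pooling out-of-fold probabilities
into a single curve (rather than averaging per-fold curves) is the
standard choice at this cohort size. AUC uses the Mann–Whitney midrank
formulation (ties count 1/2).

## Unsupervised structure

Features ranked by median absolute deviation across samples (ties broken
lexicographically for determinism), top 500 kept, z-scored per feature,
samples clustered hierarchically. Correlation distance with average
linkage is the default (usual for expression heatmaps); euclidean /
complete / ward are available. The cluster count k for label extraction
has no principled default — dendrograms are normally inspected — so k is
an explicit parameter.

## Synthetic cohort generator

The generator is first-class, tested code: it defines the conditions
under which every downstream property is demonstrated. Per feature f and
sample s (log2 scale):

    x_fs = baseline_f + tissue_f·[tumour] + subtype-shift_{f,g(s)}
           + dosage_f·[f on 1p/19q and g(s) = TYPE_I]
           + marker_f·[f planted for g(s)] + bio_fs + eps_fs

* cohort: 6 normal brain, 21 Type I, 17 Type II, 10 Type III; 6000
  features; 4.5% / 4.0% / 2.0% / 3.5% of features on 1p / 1q / 19p / 19q.
* `baseline_f` ~ N(8, 1) log2 units, shared by RNA and protein; the
  protein baseline additionally carries a per-feature decoupling term
  (below).
* `tissue_f` ~ N(0, 0.5): a tumour tissue programme shared by all three
  tumour subtypes and both omics. It separates tumours from normal brain
  (as real tumour proteomes are) while cancelling exactly in every
  tumour-vs-tumour contrast.
* subtype shifts ~ N(0, 0.1) per (feature, subtype): non-separating
  background structure.
* dosage: mean −0.35 log2 at protein, −1.0 at RNA (±10% per-feature
  spread) on 1p/19q features in Type I only — attenuated at protein,
  near-halving at RNA, reproducing the qualitative finding that
  codeletion is visible but damped in the proteome.
* markers: 20 per tumour subtype, ±1.2 log2 with random sign, planted
  off-arm and disjoint across subtypes.
* noise: biological term N(0, 0.3) shared between the RNA and protein
  measurement of a (feature, sample), plus independent measurement noise
  N(0, 0.5) per omic. Gaussian-in-log2 (log-normal) noise is the standard
  model for TMT intensities and log RNA.
* decoupling: per-feature protein-only baseline noise with SD √5 ≈ 2.236.
  Shared per-gene variance is 1² + 0.5² = 1.25, so the expected per-arm
  mean-RNA vs mean-protein R² is 1.25/(1.25+5) = 0.2, the attenuated
  regime reported for real 1p/1q/19p/19q data (printed values 0.17–0.23).
  Raising the knob lowers R² monotonically (tested on a 3-point grid).

Everything is deterministic given `seed`, and the generator returns the
ground truth (planted markers with signs, arm membership, labels) so that
recovery can be scored exactly.

### What the generator does not emulate

Peptide-level quantification and protein inference, TMT ratio
compression, batch/plex effects, correlated co-regulation between
features (features are independent given the planted structure),
outlier samples, and real missing-not-at-random intensity dependence
(dropout is run-blocked but intensity-independent). Passing synthetic
tests therefore demonstrates the statistical machinery under the stated
model, not performance on any real cohort.

### Marker-recovery scoring

At the default effects, features on the deleted arms legitimately reach
significance in both Type-I contrasts and are assigned TYPE_I/DOWN by the
concordance rule. These are planted signal — the generator put the dosage
shift there — so recovery precision counts a panel entry as correct if it
matches a planted marker (subtype and direction) **or** is a 1p/19q
feature assigned TYPE_I/DOWN. Recall is measured against the planted
markers only. Recall is power-limited at the default conditions: a
Type II or Type III marker must clear BH at 6000 features in both of its
contrasts with group sizes down to 10, which caps joint detection
probability near 0.7–0.8 per marker; the 50-seed median recall observed
is ~0.73. This is a property of the stated effect size and cohort, not of
the implementation (the Welch and BH steps are verified against
independent references to 1e-12).

## Problem sizes used by tests and the acceptance script

Property checks over seeds use 50 replicate cohorts at the full default
size (6000 features × 54 samples); quick structural tests use 200–900
features. The acceptance script runs one full cohort with 5% per-run
dropout (complete-case retention ≈ 0.74, matching the retention observed
in the study this pipeline models), then the entire pipeline at default
thresholds. These sizes are the package's chosen demonstration scale.

## Known limitations

* RNA differential testing is Welch-on-log2, not a count model; results
  on raw counts will differ from DESeq2-style analyses.
* The supplementary-table reproduction checks require the study's own
  protein matrix, which must be supplied locally (see
  `tests/test_acceptance.py`); they fail with instructions otherwise.
* Input matrices are assumed pre-normalised; the only transform offered
  is log2 with a pseudocount, and the codeletion z-score is sensitive to
  per-sample shifts by design.
* The Fisher arm-enrichment test treats features as independent, which
  real co-regulated neighbourhoods violate.
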