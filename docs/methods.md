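# Methods

## Problem setting and assumptions

The pipeline classifies annotated BCR/Ig heavy-chain sequences from
paired normal/tumor tissue samples of the same patients. Its core
assumptions are:

* class signal is carried by *distributional* features shared across
  patients (V/J usage, CDR lengths, SHM load, CDR amino-acid
  composition), not by recurrent public sequences;
* clonal structure must be respected twice — training sequences are
  sampled per clone (3 per dominant clone) so large clones do not
  dominate, and all cross-validation splits are at the patient level so
  no patient's sequences appear on both sides of a split;
* training labels come only from *tissue-specific* clones (≥ 50 reads,
  ≥ 90 % single-tissue read content), because paired samples
  cross-contaminate; evaluation of the tissue stage deliberately uses
  **all** sequences of a sample, mimicking a diagnostic setting.

## Clonotyping

Two sequences of one patient are clone mates iff same V gene, same J
gene (allele suffixes `*NN` stripped first — allele-level calls fragment
true clones; configurable), same CDR3 nucleotide length, and Hamming
distance ≤ 3 on the CDR3 nucleotides. The pairwise relation is closed by
single linkage within each (V, J, length) block, which matches standard
clonal-grouping practice and is tested against a brute-force O(n²)
transitive-closure oracle. Purity is computed on read counts
(`duplicate_count` sums), reading "90 % content" as abundance rather
than unique-sequence counts.

## Per-sequence classifiers

**Patient-averaged Bayes (V/J usage; CDR length triples).** Per class,
each training patient contributes a relative-frequency table over
categories; tables are averaged with equal patient weight (*not* pooled
counts — a regression test pins the difference on unbalanced patients).
The posterior uses a uniform 0.5/0.5 class prior (training data are
class-balanced by the per-clone sampling design; configurable) and a
likelihood floor ε = 1e-9 applied at prediction time, so an unseen
category returns the prior while fitted tables still sum to 1.

**SHM channel.** A linear-kernel max-margin classifier (LinearSVC) on
the 2-d integer feature (shm_fr, shm_cdr), with a logistic link fitted
on the training decision values so the output is a probability.

**Sequence channel.** CDR1/2/3 are fixed to lengths 8/8/17 (median CDR
lengths): longer sequences are center-trimmed keeping the first
⌈t/2⌉ and last ⌊t/2⌋ residues; shorter ones get zero-vector pseudo
residues inserted after position ⌈len/2⌉. When an odd count is trimmed
or padded the N-terminal side keeps/receives the extra position — a
declared convention; an `ends` mode exists for comparison, and the
choice is not performance-critical. Residues map to the 10 Kidera
factors (transcribed from the original published table into
`src/bcrml/data/kidera_factors.tsv`; a test checks the factors are
standardized — mean ≈ 0, sd ≈ 1 across residues — and pins the alanine
row). `X` encodes as a zero row, like the pad sentinel. Classifiers on
the 33×10 encoding:

* a 1-D convnet (numpy implementation in `bcrml.convnet`):
  Conv–LeakyReLU(0.2)–MaxPool units along the position axis, fully
  connected layers with inverted dropout, softmax output, Adam,
  minibatch 100; backprop is verified against finite differences.
  Hyperparameters are drawn by random search from: learning rate
  1e-7…1e-3 (log-uniform), dropout keep-probability 0.4…1.0 ("dropout
  rate 1.0" is read as *keep*-probability, since dropping every unit is
  degenerate), 1–2 conv layers, 80–300 kernels, kernel width 2–3, pool
  width 2–3, 1–3 FC layers of 100–300 units. The search budget defaults
  to 10 draws and is configurable; epochs default to 20.
* an RBF-kernel SVM on the flattened 330-vector, grid
  C ∈ {1,10,100,1000} × γ ∈ {1e-2…1e-5}, Platt-calibrated;
* a random forest, max depth ∈ {√f, log₂f, f} with f = 330.

**Nested CV.** Outer loop: leave-one-patient-out; inner loop: one
patient-level 2-fold split scoring each hyperparameter candidate by mean
held-out AUC (degenerate inner folds skipped). The selected model is
refit on all outer-training patients. A held-out patient whose label set
is single-class gets no AUC and is reported as skipped. All fold
assignments derive from the seed.

## Ensemble and tissue stage

The four channel probabilities feed a linear gradient-boosting machine
(xgboost `gblinear`, default hyperparameters). Because the model is
linear on the logit scale, its coefficients and intercept are recovered
exactly by probing the fitted booster on the zero and unit vectors;
prediction is then the explicit logistic σ(β·x + b), which also absorbs
xgboost's data-estimated base score. The ensemble applied to a patient
is always fitted on the other patients' out-of-fold probabilities.

A tissue sample's score aggregates the ensemble probabilities of all its
unique sequences (each counted once regardless of read count; the
summation runs over the *set* of sequences — read-weighting would be a
trivial extension). Mean is the primary statistic; median and mode are
for comparison. The mode of a continuous score is taken as the midpoint
of the maximal-count bin of a fixed-width histogram on [0, 1] with bin
width 0.02, ties broken toward the lowest midpoint. The
clonal-entropy–augmented variant feeds (score, entropy) through the same
gblinear machinery in a leave-one-patient-out scheme and is compared
against a score-only model fitted the same way, so the comparison is
like for like.

Clonal entropy is the base-2 Shannon entropy of a sample's read
distribution over clonal families, unnormalized (the base and
normalization are declared conventions).

## Statistical evaluation

* **ROC/AUC** via threshold sweep at every distinct score (equivalent to
  the Mann-Whitney pair-concordance statistic, ties credited 0.5;
  tested against O(n²) pair enumeration).
* **Permutation test**: sequence labels shuffled within each patient,
  the mean per-patient AUC recomputed per permutation, and
  p = (1 + #{permuted ≥ observed}) / (1 + B) — the add-one estimator is
  never exactly 0. Default B = 1,000 at desk scale (configurable to
  100,000). Patients with degenerate held-out label sets are skipped and
  logged.
* **Paired comparisons**: two-sided Wilcoxon signed-rank on per-patient
  AUC lists, zero differences dropped (classic handling; with few
  patients ties are likely, and an all-zero difference list returns
  p = 1), Bonferroni-adjusted, significance at 0.05.
* **Motif matrices**: within the four high-confidence groups
  (correct/miscalled × normal/tumor at P > 0.9), only sequences at the
  modal region length (8/8/17) contribute; CDR3 drops its conserved
  flanks (first 3, last 4 residues), leaving 10 positions; per-position
  residue frequencies are returned (rendering logos is out of scope).
  Sequences with `X` inside the retained window are excluded.

### Calibration caveats of the permutation test

Two measured properties matter when interpreting its p-values:

1. With 3 sampled sequences per clone, clone mates share both score and
   label; shuffling at the sequence level understates the null variance
   and the test is anti-conservative (≈ 0.19–0.23 of null runs reach
   p < 0.05). `permutation_test(..., group_col="clone_id")` shuffles
   whole clones instead and is calibrated on such data (≈ 0.05).
2. Pooling leave-one-patient-out predictions adds cross-fold dependence
   that within-patient permutations cannot reproduce, a milder
   inflation (≈ 0.10 at 10 patients) that vanishes for predictions from
   a single fixed train/test split (measured ≈ 0.05).

The sequence-level default is the conventional procedure (shuffling
individual sequence labels); the clone-level option is recommended
whenever rows are clone-replicated.

## Synthetic cohorts

The generator (`bcrml.simulate`) emulates, per patient and tissue, a set
of clones with: a (V, J) pair and a CDR length triple drawn from
tissue-specific categorical distributions; germline CDR amino acids
i.i.d. uniform over the 20 residues except where a tumor CDR3 motif
effect applies; CDR3 nucleotides obtained by random synonymous
back-translation; a zeta-law read count (exponent 1.5, capped at 5,000)
split over a few unique descendants, each at most one non-stop CDR3
nucleotide substitution from the ancestor so clone mates always satisfy
the clonotype criteria; independent Poisson SHM counts for FR and CDR;
and a 5 % per-clone chance of leaking 5–30 % of reads into the opposite
tissue sample. All randomness flows from one integer seed.

Default planted effects (the "study conditions", `study_config`):
a multiplicative tilt of strength 0.8 on tumor V/J usage and CDR-length
triples; tumor SHM means 35 % below normal ((8, 4) → (5.2, 2.6) for
FR/CDR — tumor clones having undergone less affinity maturation); and a
weak CDR3 motif (one residue at probability 0.3 at three positions). The
V/J support is 8 V × 3 J = 24 pairs: at the desk-scale cohort sizes used
throughout (10 patients, 150–200 clones per tissue, ≈ 35 dominant clones
per patient and class after the ≥ 50-read filter), this represents the
well-estimated high-frequency part of real usage and keeps the
patient-averaged estimator in the regime where it recovers the analytic
optimum; a much larger support at this cohort size would measure table
sparsity, not the estimator.

`bayes_optimal_auc` gives the exact AUC of the true likelihood-ratio
classifier between two categorical distributions by summation over
category pairs (ratios compared by cross-multiplication; ties credited
0.5), serving as the analytic target for parameter-recovery checks.

What the generator does **not** emulate — and hence what passing tests
cannot show about real data: no public (shared) clones, so cross-patient
CDR3 sharing is ≈ 0 rather than the ~2 % seen in real cohorts; no
phylogenetic lineage structure beyond one-substitution stars; uniform
germline residue usage rather than biased amino-acid composition; no
isotypes, no V(D)J junction modeling; SHM counts independent of the CDR3
substitutions. Effects are planted per channel and independently, which
is what makes channel-isolation tests possible but is cleaner than
reality, where channels correlate.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen as the sizes
where each property is informative: oracle checks at n ≤ 200;
parameter recovery and null calibration on 10-patient, 200-clone
cohorts (tolerance ±0.03 against the analytic optimum at 10,000 held-out
sequences; 0.5 ± 0.05 for null channels); aggregation checked at ≥ 100
and at 1,000 sequences per sample; the full-pipeline echoes on a
10-patient, 150-clone cohort with a 2-draw convnet search at 15 epochs,
and the strong-motif benchmark (boost 0.9) with a 4-draw search at 30
epochs. At these sizes the tissue-level AUC saturates at 1.0 — the
mean of hundreds of per-sequence probabilities separates classes almost
surely once per-sequence AUC is ≳ 0.6, so the interesting tissue-level
comparisons (mean vs median vs mode, entropy augmentation) are orderings
rather than margins.

Known limitations: the numpy convnet is CPU-scale (thousands of
sequences, not the ~600,000 of a full cohort); variable-length CDR3
handling is by trim/pad only; the permutation-test caveats above; and
none of the synthetic results transfer quantitatively to real
repertoires — the pipeline's claims on real data must be re-established
on real data.
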