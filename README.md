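# bcrml — tumor vs. normal classification of BCR/Ig repertoires

B cells infiltrating a tumor carry B-cell receptors / immunoglobulins
(BCRs/Igs) whose sequences reflect the antigens they matured against.
Because tumor tissue presents tumor-specific antigens, the repertoire of
heavy-chain sequences sampled from tumor tissue can differ *globally*
from the repertoire of adjacent normal tissue — in V/J gene usage, CDR
lengths, somatic hypermutation (SHM) load and CDR amino-acid
composition — even though almost no individual sequence recurs across
patients. `bcrml` implements a supervised pipeline that quantifies these
differences at single-sequence resolution and aggregates them into a
tissue-level diagnostic score. It is aimed at computational
immunologists working with annotated Rep-Seq (immune repertoire
sequencing) data, and ships a synthetic cohort generator with planted,
channel-specific effects so every stage can be validated without patient
data.

## Pipeline

1. **Clonotyping.** Within a patient (both tissue samples pooled),
   sequences belong to one clonal family iff they share V and J gene,
   have equal CDR3 nucleotide length, and differ at ≤ 3 CDR3 nucleotide
   positions (single-linkage closure of the pairwise relation).
2. **Dominant, tissue-specific clones.** Clones with ≥ 50 reads whose
   read content is ≥ 90 % from one tissue are labeled as that tissue's
   specific clones; 3 sequences are sampled per clone as training data,
   removing clone-size bias.
3. **Four per-sequence classifiers**, each emitting P(T | sequence):
   - *V/J usage* and *CDR length triples (L1, L2, L3)* — a Bayes
     classifier whose class likelihoods are per-patient relative
     frequencies averaged with equal patient weight,
     P(V,J|T) = (1/n) Σᵢ Pᵢ(V,J|T), and posterior by Bayes' theorem;
   - *SHM counts* — a linear-kernel SVM on (shm_fr, shm_cdr);
   - *CDR amino acids* — CDR1/2/3 trimmed/padded to lengths 8/8/17 and
     encoded row-wise with the 10 Kidera factors into a 33×10 matrix
     (330 features), classified by a 1-D convolutional network
     (Conv–LeakyReLU(0.2)–MaxPool stack, fully connected layers,
     softmax, Adam, minibatch 100), an RBF-kernel SVM, or a random
     forest.
4. **Ensemble.** A linear gradient-boosting machine (xgboost,
   `gblinear`, default hyperparameters) combines the four channel
   probabilities.
5. **Tissue-level score.** For a sample 𝒜 (all of its sequences, not
   only specific-clone members), P_tissue(T|𝒜) = (1/|𝒜|) Σ_{A∈𝒜}
   P_seq(T|A); median and histogram-mode aggregation are available for
   comparison, as is a clonal-entropy–augmented variant.
6. **Evaluation.** Patient-level nested CV (outer leave-one-patient-out,
   inner 2-fold for hyperparameters; sequences are never split within a
   patient), ROC/AUC, a within-patient label permutation test, and
   Wilcoxon signed-rank comparisons with Bonferroni correction.

## Data format

Input is an AIRR Rearrangement-style TSV. Standard AIRR column names are
used where they exist (`sequence_id`, `v_call`, `j_call`, `cdr1_aa`,
`cdr2_aa`, `cdr3_aa`, `cdr3` for the CDR3 nucleotides,
`duplicate_count`); `patient_id`, `tissue` (`normal`/`tumor`), `shm_fr`,
`shm_cdr` and `clone_id` are custom columns. Unknown extra columns are
preserved on read/write and ignored by the pipeline.

## Worked example

The numbered drivers under `analysis/` run the whole study on a
synthetic cohort (10 patients, 150 clones per tissue sample, modest
effects planted in all four channels):

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_clonotype_summary.py --seed 1
python analysis/03_per_sequence_classifiers.py --seed 1
python analysis/04_tissue_level.py
python analysis/05_evaluation.py --seed 1
```

Step 03 prints the per-sequence discrimination of each channel
(mean per-patient AUC over leave-one-patient-out folds):

```
mean per-patient AUC by channel:
channel
p_ens    0.833
p_len    0.571
p_seq    0.600
p_shm    0.831
p_vj     0.548

ensemble 0.833 vs best single channel p_shm 0.831
```

Under these study conditions the SHM channel carries the strongest
per-sequence signal (tumor clones carry fewer mutations), and the
linear-GBM ensemble matches the best channel. Step 04 then shows the
aggregation gain — averaging thousands of weakly informative
per-sequence probabilities separates whole samples essentially
perfectly at this cohort size:

```
tissue-level AUC by aggregation statistic:
  mean   1.000
  median 1.000
  mode   1.000
```

and step 05 confirms the per-sequence signal is real
(within-patient permutation test, 1,000 permutations):

```
permutation test (observed mean per-patient AUC 0.833):
  sequence-level shuffling p = 0.000999
  clone-level shuffling    p = 0.000999 (calibrated for clone-replicated rows)
```

Tables land in `results/` (per-patient AUCs, per-sequence
probabilities, tissue scores, CDR3 motif frequency matrices).

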