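"""ROC/AUC computation, permutation testing, paired comparison, motifs.

The permutation test shuffles sequence labels *within each patient*
(preserving every patient's label multiset), recomputes the mean
per-patient AUC for each permutation, and reports the add-one p-value
``(1 + #{permuted >= observed}) / (1 + B)``.  Paired classifier
comparisons use the two-sided Wilcoxon signed-rank test on per-patient
AUCs with a Bonferroni adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata, wilcoxon
from sklearn.metrics import roc_curve

AA20 = "ACDEFGHIKLMNPQRSTVWY"

MOTIF_GROUPS = (
    "correct-normal",
    "correct-tumor",
    "miscalled-tumor",
    "miscalled-normal",
)


@dataclass(slots=True)
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    n_pos: int
    n_neg: int


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and AUC (the Mann-Whitney pair-concordance statistic).

    ``labels`` are binary with 1 = tumor (positive).  Curve points are
    computed at every distinct score threshold.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes to be present")
    fpr, tpr, thr = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(auc=auc, fpr=fpr, tpr=tpr, thresholds=thr, n_pos=n_pos, n_neg=n_neg)


def _patient_rank_auc(ranks: np.ndarray, pos_mask: np.ndarray) -> float:
    """AUC from pre-computed average ranks of the scores."""
    n_pos = int(pos_mask.sum())
    n_neg = len(ranks) - n_pos
    return (ranks[pos_mask].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


@dataclass(slots=True)
class PermutationResult:
    p_value: float
    observed: float
    permuted: np.ndarray
    skipped_patients: list[str] = field(default_factory=list)


def permutation_test(
    predictions: pd.DataFrame,
    n_permutations: int = 1000,
    seed: int = 0,
    score_col: str = "prob",
    label_col: str = "label",
    group_col: str | None = None,
) -> PermutationResult:
    """Within-patient label permutation test on the mean per-patient AUC.

    ``predictions`` carries one row per sequence with ``patient_id``, a
    binary label and a score.  Patients whose label set is degenerate
    (single class) carry no AUC and are skipped (and reported).  The
    p-value uses the add-one estimator, so it is never exactly zero.

    By default sequence labels are shuffled individually within each
    patient.  When rows are clustered — e.g. several sampled sequences
    per clone share one label — individual shuffling understates the null
    variance and the test becomes anti-conservative; passing
    ``group_col`` (such as a clone-id column) shuffles labels at the
    group level instead, which restores calibration for clustered rows.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    patients = []
    skipped: list[str] = []
    for patient, grp in predictions.groupby("patient_id", sort=True):
        y = grp[label_col].to_numpy(dtype=int)
        if len(np.unique(y)) < 2:
            skipped.append(str(patient))
            continue
        ranks = rankdata(grp[score_col].to_numpy(dtype=float))
        if group_col is None:
            sizes = np.ones(len(y))
            rank_sums = ranks
            group_labels = y.astype(bool)
        else:
            codes, _ = pd.factorize(grp[group_col])
            n_groups = codes.max() + 1
            sizes = np.bincount(codes).astype(float)
            rank_sums = np.bincount(codes, weights=ranks)
            group_labels = np.zeros(n_groups, dtype=bool)
            group_labels[codes[y.astype(bool)]] = True
            if np.any(group_labels[codes] != y.astype(bool)):
                raise ValueError(
                    f"patient {patient}: labels are not constant within groups"
                )
        patients.append((sizes, rank_sums, group_labels, len(y)))

    if not patients:
        raise ValueError("no patient has both classes")

    def mean_auc(masks) -> float:
        vals = []
        for (sizes, rank_sums, _, n), mask in zip(patients, masks):
            n_pos = sizes[mask].sum()
            n_neg = n - n_pos
            vals.append(
                (rank_sums[mask].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
            )
        return float(np.mean(vals))

    observed = mean_auc([g for _, _, g, _ in patients])
    permuted = np.empty(n_permutations)
    for b in range(n_permutations):
        permuted[b] = mean_auc(
            [g[rng.permutation(len(g))] for _, _, g, _ in patients]
        )
    p = (1.0 + int((permuted >= observed - 1e-12).sum())) / (1.0 + n_permutations)
    return PermutationResult(
        p_value=float(p), observed=observed, permuted=permuted, skipped_patients=skipped
    )


def compare_paired_auc(auc_a, auc_b, n_comparisons: int = 1) -> float:
    """Two-sided Wilcoxon signed-rank p on paired per-patient AUC lists,
    Bonferroni-adjusted by ``n_comparisons``.

    Zero differences are dropped (classic Wilcoxon handling); if every
    difference is zero the p-value is 1.
    """
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired AUC lists must have equal length")
    if len(a) < 6:
        raise ValueError("need at least 6 paired patients")
    if np.allclose(a, b):
        return 1.0
    p = float(wilcoxon(a, b, zero_method="wilcox", alternative="two-sided").pvalue)
    return min(1.0, p * n_comparisons)


# ---------------------------------------------------------------------------
# motif frequency matrices

@dataclass(slots=True)
class MotifMatrix:
    region: str
    group: str
    frequencies: pd.DataFrame  # positions x 20 residues
    n_sequences: int


#: modal lengths used for motif construction, per region
MOTIF_LENGTHS = {"CDR1": 8, "CDR2": 8, "CDR3": 17}
#: conserved CDR3 flanks removed before motif construction
CDR3_TRIM = (3, 4)  # N-terminal, C-terminal


def _group_mask(labels: np.ndarray, probs: np.ndarray, group: str, confidence: float):
    pred_tumor_hi = probs > confidence
    pred_normal_hi = probs < 1.0 - confidence
    if group == "correct-normal":
        return (labels == 0) & pred_normal_hi
    if group == "correct-tumor":
        return (labels == 1) & pred_tumor_hi
    if group == "miscalled-tumor":
        return (labels == 0) & pred_tumor_hi
    if group == "miscalled-normal":
        return (labels == 1) & pred_normal_hi
    raise ValueError(f"unknown group {group!r}; expected one of {MOTIF_GROUPS}")


def motif_frequency_matrix(
    records,
    probs,
    labels,
    region: str = "CDR3",
    group: str = "correct-tumor",
    confidence: float = 0.9,
) -> MotifMatrix:
    """Per-position residue frequencies of one confidence group.

    High-confidence calls are those with class probability above
    ``confidence``.  Only sequences whose region has the modal length
    (8, 8 or 17) contribute; for CDR3 the conserved flanks (first 3 and
    last 4 residues) are removed, leaving 10 positions.  Sequences with
    an unknown residue (X) inside the retained window are excluded.
    """
    if region not in MOTIF_LENGTHS:
        raise ValueError(f"unknown region {region!r}")
    labels = np.asarray(labels, dtype=int)
    probs = np.asarray(probs, dtype=float)
    mask = _group_mask(labels, probs, group, confidence)
    attr = {"CDR1": "cdr1_aa", "CDR2": "cdr2_aa", "CDR3": "cdr3_aa"}[region]
    target = MOTIF_LENGTHS[region]
    windows = []
    for rec, keep in zip(records, mask):
        if not keep:
            continue
        seq = getattr(rec, attr)
        if len(seq) != target:
            continue
        if region == "CDR3":
            seq = seq[CDR3_TRIM[0] : target - CDR3_TRIM[1]]
        if "X" in seq:
            continue
        windows.append(seq)
    if not windows:
        census = {
            g: int(_group_mask(labels, probs, g, confidence).sum())
            for g in MOTIF_GROUPS
        }
        raise ValueError(
            f"no usable sequences for region {region}, group {group!r} "
            f"(group sizes at confidence {confidence}: {census})"
        )
    n_pos = len(windows[0])
    counts = np.zeros((n_pos, len(AA20)))
    aa_index = {aa: i for i, aa in enumerate(AA20)}
    for seq in windows:
        for i, aa in enumerate(seq):
            counts[i, aa_index[aa]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    start = CDR3_TRIM[0] + 1 if region == "CDR3" else 1
    frame = pd.DataFrame(
        freqs, index=[f"pos{start + i}" for i in range(n_pos)], columns=list(AA20)
    )
    return MotifMatrix(
        region=region, group=group, frequencies=frame, n_sequences=len(windows)
    )
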