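import itertools

import numpy as np
import pandas as pd
import pytest

from bcrml import evaluate
from bcrml.evaluate import (
    MotifMatrix,
    compare_paired_auc,
    motif_frequency_matrix,
    permutation_test,
    roc_auc,
)

from conftest import make_record


class TestRocAuc:
    def test_three_of_four_pairs_concordant(self):
        res = roc_auc([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0])
        assert res.auc == pytest.approx(0.75)
        assert res.n_pos == 2 and res.n_neg == 2

    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]).auc == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_matches_pairwise_enumeration_oracle(self, rng):
        """Mann-Whitney equivalence on 200 random scores with ties."""
        scores = rng.choice(np.linspace(0, 1, 40), size=200)  # forces ties
        labels = rng.integers(0, 2, 200)
        res = roc_auc(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        concordant = sum(p > n for p, n in itertools.product(pos, neg))
        tied = sum(p == n for p, n in itertools.product(pos, neg))
        expected = (concordant + 0.5 * tied) / (len(pos) * len(neg))
        assert res.auc == pytest.approx(expected)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.random(100)
        labels = rng.integers(0, 2, 100)
        a = roc_auc(scores, labels).auc
        b = roc_auc(np.exp(3 * scores) - 1, labels).auc
        assert a == pytest.approx(b)

    def test_curve_endpoints_and_monotonicity(self, rng):
        res = roc_auc(rng.random(50), rng.integers(0, 2, 50))
        assert (res.fpr[0], res.tpr[0]) == (0.0, 0.0)
        assert (res.fpr[-1], res.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(res.fpr) >= 0)
        assert np.all(np.diff(res.tpr) >= 0)


def _predictions(rng, n_patients=4, n=40, signal=0.0):
    rows = []
    for p in range(n_patients):
        labels = rng.integers(0, 2, n)
        probs = np.clip(rng.random(n) + signal * (labels - 0.5), 0, 1)
        for i in range(n):
            rows.append(
                {
                    "patient_id": f"P{p}",
                    "label": int(labels[i]),
                    "prob": float(probs[i]),
                    "clone_id": f"P{p}.c{i}",
                }
            )
    return pd.DataFrame(rows)


class TestPermutationTest:
    def test_constant_scores_give_p_one(self, rng):
        df = _predictions(rng)
        df["prob"] = 0.5
        assert permutation_test(df, n_permutations=99, seed=0).p_value == 1.0

    def test_strong_signal_gives_minimal_p(self, rng):
        df = _predictions(rng, signal=2.0)  # perfectly separated
        res = permutation_test(df, n_permutations=999, seed=0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_within_patient_label_multiset_preserved(self, rng):
        """Shuffling is within-patient: permuted statistics must be
        reproducible from each patient's own label counts."""
        df = _predictions(rng, n_patients=2, n=10)
        res = permutation_test(df, n_permutations=50, seed=1)
        # exhaustive bound: the permuted statistic can only take values
        # attainable with each patient's own positive count
        for p, grp in df.groupby("patient_id"):
            y = grp["label"].to_numpy()
            ranks = evaluate.rankdata(grp["prob"].to_numpy())
            n_pos, n_neg = y.sum(), (1 - y).sum()
            attainable = set()
            for idx in itertools.combinations(range(len(y)), int(n_pos)):
                s = ranks[list(idx)].sum()
                attainable.add(round((s - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg), 9))
            assert attainable  # sanity: the orbit is non-empty
        assert res.permuted.shape == (50,)
        assert 0 < res.p_value <= 1

    def test_deterministic_given_seed(self, rng):
        df = _predictions(rng, signal=0.3)
        a = permutation_test(df, n_permutations=99, seed=7)
        b = permutation_test(df, n_permutations=99, seed=7)
        assert a.p_value == b.p_value
        np.testing.assert_array_equal(a.permuted, b.permuted)

    def test_degenerate_patients_skipped_and_logged(self, rng):
        df = _predictions(rng, n_patients=3)
        df.loc[df["patient_id"] == "P0", "label"] = 1
        res = permutation_test(df, n_permutations=49, seed=0)
        assert res.skipped_patients == ["P0"]

    def test_group_shuffle_requires_constant_labels(self, rng):
        df = _predictions(rng, n_patients=2)
        df.loc[0, "clone_id"] = df.loc[1, "clone_id"]  # two labels, one clone
        df.loc[0, "label"] = 1 - df.loc[1, "label"]
        with pytest.raises(ValueError, match="constant within groups"):
            permutation_test(df, n_permutations=9, seed=0, group_col="clone_id")

    def test_group_shuffle_runs_on_clustered_rows(self, rng):
        df = _predictions(rng, signal=1.0)
        res = permutation_test(df, n_permutations=99, seed=0, group_col="clone_id")
        assert res.p_value <= 0.05


class TestComparePairedAuc:
    def test_identical_lists_give_one(self):
        a = [0.6, 0.7, 0.55, 0.8, 0.62, 0.71]
        assert compare_paired_auc(a, a) == 1.0

    def test_uniform_shift_is_significant(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0.5, 0.8, 20)
        assert compare_paired_auc(a + 0.1, a) < 0.001

    def test_bonferroni_clamped_to_one(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0.5, 0.8, 10)
        b = a + rng.normal(0, 0.01, 10)
        assert compare_paired_auc(a, b, n_comparisons=1000) <= 1.0

    def test_symmetric_in_argument_order(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0.4, 0.9, 12)
        b = rng.uniform(0.4, 0.9, 12)
        assert compare_paired_auc(a, b) == pytest.approx(compare_paired_auc(b, a))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_paired_auc([0.5] * 6, [0.5] * 7)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            compare_paired_auc([0.5] * 5, [0.6] * 5)


class TestMotifMatrix:
    def _records_probs(self, n=30, cdr3_len=17, seed=0):
        rng = np.random.default_rng(seed)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        records = []
        labels = []
        probs = []
        for i in range(n):
            cdr3 = "".join(rng.choice(list(aas), cdr3_len))
            records.append(
                make_record(sequence_id=f"s{i}", cdr3_aa=cdr3, cdr3_nt="GCT" * cdr3_len)
            )
            labels.append(1)
            probs.append(0.95)
        return records, np.array(probs), np.array(labels)

    def test_cdr3_window_is_ten_positions(self):
        records, probs, labels = self._records_probs()
        m = motif_frequency_matrix(records, probs, labels, "CDR3", "correct-tumor")
        assert m.frequencies.shape == (10, 20)
        assert list(m.frequencies.index) == [f"pos{i}" for i in range(4, 14)]

    def test_single_sequence_gives_one_hot_columns(self):
        records, probs, labels = self._records_probs(n=1)
        m = motif_frequency_matrix(records, probs, labels, "CDR3", "correct-tumor")
        assert np.all(np.sort(m.frequencies.to_numpy(), axis=1)[:, -1] == 1.0)

    def test_rows_sum_to_one(self):
        records, probs, labels = self._records_probs(n=50)
        m = motif_frequency_matrix(records, probs, labels, "CDR1", "correct-tumor")
        np.testing.assert_allclose(m.frequencies.sum(axis=1), 1.0)

    def test_non_modal_lengths_excluded(self):
        records, probs, labels = self._records_probs(n=5, cdr3_len=17)
        short, sp, sl = self._records_probs(n=5, cdr3_len=12, seed=1)
        m = motif_frequency_matrix(
            records + short,
            np.concatenate([probs, sp]),
            np.concatenate([labels, sl]),
            "CDR3",
            "correct-tumor",
        )
        assert m.n_sequences == 5

    def test_empty_group_raises_with_census(self):
        records, probs, labels = self._records_probs(n=4)
        with pytest.raises(ValueError, match="group sizes"):
            motif_frequency_matrix(records, probs, labels, "CDR3", "miscalled-tumor")

    @pytest.mark.parametrize(
        "group,label,prob,included",
        [
            ("correct-tumor", 1, 0.95, True),
            ("correct-tumor", 1, 0.85, False),  # below confidence
            ("correct-normal", 0, 0.05, True),
            ("miscalled-tumor", 0, 0.95, True),
            ("miscalled-normal", 1, 0.05, True),
        ],
    )
    def test_group_membership(self, group, label, prob, included):
        records, _, _ = self._records_probs(n=1)
        try:
            m = motif_frequency_matrix(
                records, np.array([prob]), np.array([label]), "CDR3", group
            )
            got = m.n_sequences == 1
        except ValueError:
            got = False
        assert got is included
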