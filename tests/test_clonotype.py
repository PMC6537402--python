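import itertools

import networkx as nx
import numpy as np
import pytest

from bcrml import clonotype
from bcrml.clonotype import (
    assign_clonal_families,
    cdr3_sharing_fraction,
    clonal_entropy,
    extract_dominant_clones,
    sample_training_sequences,
)

from conftest import make_record


def _mutate(nt, positions):
    swap = {"A": "C", "C": "G", "G": "T", "T": "A"}
    out = list(nt)
    for p in positions:
        out[p] = swap[out[p]]
    return "".join(out)


class TestAssignClonalFamilies:
    def test_three_mismatches_merge_four_split(self):
        base = "GCTAAGGATCGTGGTTATAGT"
        for n_mm, n_expected in [(3, 1), (4, 2)]:
            records = [
                make_record(sequence_id="a", cdr3_aa="AKDRGYS", cdr3_nt=base),
                make_record(
                    sequence_id="b",
                    cdr3_aa="AKDRGYS",
                    cdr3_nt=_mutate(base, range(n_mm)),
                ),
            ]
            families = assign_clonal_families(records)
            assert len(families) == n_expected

    def test_singleton(self):
        fams = assign_clonal_families([make_record()])
        assert len(fams) == 1 and len(fams[0].members) == 1

    def test_allele_suffix_normalized(self):
        records = [
            make_record(sequence_id="a", v_call="IGHV1-2*01"),
            make_record(sequence_id="b", v_call="IGHV1-2*02"),
        ]
        assert len(assign_clonal_families(records)) == 1

    def test_multiple_patients_rejected(self):
        records = [make_record(patient_id="P0"), make_record(patient_id="P1")]
        with pytest.raises(ValueError, match="per-patient"):
            assign_clonal_families(records)

    def test_matches_brute_force_transitive_closure(self, rng):
        """Partition equals connected components of the pairwise graph."""
        nts = ["".join(rng.choice(list("ACGT"), 12)) for _ in range(20)]
        records = [
            make_record(
                sequence_id=f"s{i}",
                v_call=rng.choice(["IGHV1", "IGHV2"]),
                j_call="IGHJ4",
                cdr3_aa="AKDY",
                cdr3_nt=nts[i],
            )
            for i in range(20)
        ]
        families = assign_clonal_families(records)

        g = nx.Graph()
        g.add_nodes_from(range(20))
        for i, j in itertools.combinations(range(20), 2):
            a, b = records[i], records[j]
            if (
                a.v_call == b.v_call
                and a.j_call == b.j_call
                and len(a.cdr3_nt) == len(b.cdr3_nt)
                and sum(x != y for x, y in zip(a.cdr3_nt, b.cdr3_nt)) <= 3
            ):
                g.add_edge(i, j)
        oracle = {
            frozenset(records[i].sequence_id for i in comp)
            for comp in nx.connected_components(g)
        }
        ours = {
            frozenset(m.sequence_id for m in fam.members) for fam in families
        }
        assert ours == oracle

    def test_output_is_partition(self, small_cohort):
        patient = [r for r in small_cohort if r.patient_id == "P000"]
        families = assign_clonal_families(patient)
        ids = [m.sequence_id for f in families for m in f.members]
        assert sorted(ids) == sorted(r.sequence_id for r in patient)
        assert all(r.clone_id is not None for r in patient)


class TestExtractDominantClones:
    def _family(self, reads_tumor, reads_normal):
        members = []
        if reads_normal:
            members.append(
                make_record(sequence_id="n", tissue="normal", duplicate_count=reads_normal)
            )
        if reads_tumor:
            members.append(
                make_record(sequence_id="t", tissue="tumor", duplicate_count=reads_tumor)
            )
        return clonotype.ClonalFamily(
            clone_id="c0",
            members=members,
            v_call="IGHV1",
            j_call="IGHJ1",
            cdr3_length_nt=45,
            reads_total=reads_tumor + reads_normal,
            reads_tumor=reads_tumor,
        )

    @pytest.mark.parametrize(
        "tumor,normal,kept,label",
        [
            (49, 0, False, None),  # below the 50-read floor
            (50, 0, True, "tumor"),
            (45, 5, True, "tumor"),  # purity exactly 0.90
            (44, 6, False, None),  # purity 0.88
            (25, 25, False, None),  # symmetric, purity 0.5
            (5, 45, True, "normal"),
        ],
    )
    def test_read_and_purity_thresholds(self, tumor, normal, kept, label):
        fam = self._family(tumor, normal)
        out = extract_dominant_clones([fam])
        assert (len(out) == 1) is kept
        if kept:
            assert out[0].specific_label == label

    def test_filter_monotonicity(self, small_cohort):
        patient = [r for r in small_cohort if r.patient_id == "P001"]
        families = assign_clonal_families(patient)
        n_prev = None
        for min_reads in (1, 10, 50, 200):
            n = len(extract_dominant_clones(families, min_reads=min_reads))
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n
        n_prev = None
        for purity in (0.5, 0.7, 0.9, 0.99):
            n = len(
                extract_dominant_clones(families, min_reads=1, purity_threshold=purity)
            )
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n


class TestSampleTrainingSequences:
    def _family(self, n_members, label="tumor"):
        fam = clonotype.ClonalFamily(
            clone_id="c0",
            members=[
                make_record(sequence_id=f"s{i}", tissue="tumor", duplicate_count=60)
                for i in range(n_members)
            ],
            v_call="IGHV1",
            j_call="IGHJ1",
            cdr3_length_nt=45,
            reads_total=60 * n_members,
            reads_tumor=60 * n_members,
            specific_label=label,
        )
        return fam

    def test_samples_k_distinct_members(self):
        fam = self._family(10)
        sampled = sample_training_sequences([fam], k=3, seed=0)
        assert len(sampled) == 3
        ids = [r.sequence_id for r, _ in sampled]
        assert len(set(ids)) == 3
        assert all(l == "tumor" for _, l in sampled)
        member_ids = {m.sequence_id for m in fam.members}
        assert set(ids) <= member_ids

    def test_small_family_returns_all(self):
        sampled = sample_training_sequences([self._family(2)], k=3, seed=0)
        assert len(sampled) == 2

    def test_deterministic_given_seed(self):
        fams = [self._family(10)]
        a = sample_training_sequences(fams, k=3, seed=42)
        b = sample_training_sequences(fams, k=3, seed=42)
        assert [r.sequence_id for r, _ in a] == [r.sequence_id for r, _ in b]

    def test_unlabeled_family_rejected(self):
        fam = self._family(3, label=None)
        with pytest.raises(ValueError, match="label"):
            sample_training_sequences([fam], seed=0)


class TestCdr3Sharing:
    def test_half_shared(self):
        records = [
            make_record(sequence_id="a", patient_id="P0", cdr3_aa="AKDY"),
            make_record(sequence_id="b", patient_id="P0", cdr3_aa="AKEY"),
            make_record(sequence_id="c", patient_id="P1", cdr3_aa="AKDY"),
            make_record(sequence_id="d", patient_id="P1", cdr3_aa="AKFY"),
        ]
        out = cdr3_sharing_fraction(records)
        assert out[("P0", "normal")] == pytest.approx(0.5)
        assert out[("P1", "normal")] == pytest.approx(0.5)

    def test_disjoint_and_identical(self):
        disjoint = [
            make_record(sequence_id="a", patient_id="P0", cdr3_aa="AKDY"),
            make_record(sequence_id="b", patient_id="P1", cdr3_aa="AKEY"),
        ]
        assert set(cdr3_sharing_fraction(disjoint).values()) == {0.0}
        identical = [
            make_record(sequence_id="a", patient_id="P0", cdr3_aa="AKDY"),
            make_record(sequence_id="b", patient_id="P1", cdr3_aa="AKDY"),
        ]
        assert set(cdr3_sharing_fraction(identical).values()) == {1.0}

    def test_single_patient_rejected(self):
        with pytest.raises(ValueError):
            cdr3_sharing_fraction([make_record()])

    def test_sharing_is_within_tissue(self):
        records = [
            make_record(sequence_id="a", patient_id="P0", tissue="normal", cdr3_aa="AKDY"),
            make_record(sequence_id="b", patient_id="P1", tissue="tumor", cdr3_aa="AKDY"),
        ]
        assert set(cdr3_sharing_fraction(records).values()) == {0.0}


class TestClonalEntropy:
    def _families(self, reads):
        return [
            clonotype.ClonalFamily(
                clone_id=f"c{i}",
                members=[make_record(sequence_id=f"s{i}", duplicate_count=r)],
                v_call="IGHV1",
                j_call="IGHJ1",
                cdr3_length_nt=45,
                reads_total=r,
                reads_tumor=0,
            )
            for i, r in enumerate(reads)
        ]

    def test_uniform_four_clones(self):
        assert clonal_entropy(self._families([10, 10, 10, 10])) == pytest.approx(2.0)

    def test_single_clone(self):
        assert clonal_entropy(self._families([7])) == pytest.approx(0.0)

    def test_matches_direct_formula(self, rng):
        reads = rng.integers(1, 500, size=10)
        p = reads / reads.sum()
        expected = float(-(p * np.log2(p)).sum())
        assert clonal_entropy(self._families(list(reads))) == pytest.approx(expected)
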