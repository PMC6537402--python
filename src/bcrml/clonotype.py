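"""Clonal-family assignment and tissue-specific clone extraction.

Two sequences from one patient belong to the same clonal family when they
share V and J gene calls, have CDR3 nucleotide sequences of the same
length, and differ at no more than three CDR3 nucleotide positions.  The
pairwise relation is closed transitively (single linkage) within each
(V, J, length) block, the standard clonal-grouping practice.

V/J calls are normalized to the gene level (allele suffixes such as
``*01`` stripped) before comparison, so that allele-level annotation
noise does not fragment true clones; this is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import entropy as _shannon_entropy

from .io_airr import NORMAL, TUMOR, SequenceRecord

#: CDR3 nucleotide mismatch tolerance for clone membership
MAX_CDR3_MISMATCHES = 3


def normalize_gene(call: str) -> str:
    """Strip the allele suffix from a V/J call (``IGHV1-2*02`` -> ``IGHV1-2``)."""
    return call.split("*", 1)[0]


@dataclass(slots=True)
class ClonalFamily:
    """A group of sequences inferred to share one ancestral rearrangement."""

    clone_id: str
    members: list[SequenceRecord]
    v_call: str
    j_call: str
    cdr3_length_nt: int
    reads_total: int = 0
    reads_tumor: int = 0
    specific_label: str | None = None

    @property
    def purity(self) -> float:
        """Max of the tumor and normal read fractions."""
        frac_t = self.reads_tumor / self.reads_total
        return max(frac_t, 1.0 - frac_t)

    @property
    def majority_tissue(self) -> str:
        return TUMOR if self.reads_tumor * 2 >= self.reads_total else NORMAL


def _hamming_components(seqs: list[str]) -> list[int]:
    """Single-linkage components under Hamming distance <= 3.

    All sequences must share one length.  Returns a component index per
    sequence, via union-find over the pairwise criterion graph.
    """
    n = len(seqs)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    if n > 1:
        mat = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(n, -1)
        # pairwise Hamming distances in blocks to bound memory
        block = max(1, 10_000_000 // max(mat.size, 1))
        for start in range(0, n, block):
            stop = min(n, start + block)
            dist = (mat[start:stop, None, :] != mat[None, :, :]).sum(axis=2)
            ii, jj = np.nonzero(dist <= MAX_CDR3_MISMATCHES)
            for i, j in zip(ii + start, jj):
                if i < j:
                    union(int(i), int(j))
    return [find(i) for i in range(n)]


def assign_clonal_families(
    records: list[SequenceRecord], normalize_alleles: bool = True
) -> list[ClonalFamily]:
    """Partition one patient's sequences (both tissues pooled) into clones.

    Every record receives a ``clone_id``.  Raises ``ValueError`` when the
    records span more than one patient: clonotyping is per-patient.
    """
    if not records:
        return []
    patients = {r.patient_id for r in records}
    if len(patients) > 1:
        raise ValueError(
            f"clonotyping is per-patient; got records from {sorted(patients)}"
        )
    norm = normalize_gene if normalize_alleles else (lambda c: c)
    blocks: dict[tuple[str, str, int], list[int]] = {}
    for idx, rec in enumerate(records):
        if not rec.cdr3_nt:
            raise ValueError(f"record {rec.sequence_id!r} has empty cdr3_nt")
        key = (norm(rec.v_call), norm(rec.j_call), len(rec.cdr3_nt))
        blocks.setdefault(key, []).append(idx)

    patient = records[0].patient_id
    families: list[ClonalFamily] = []
    for (v, j, length), idxs in sorted(blocks.items()):
        comp = _hamming_components([records[i].cdr3_nt for i in idxs])
        by_comp: dict[int, list[int]] = {}
        for local, c in enumerate(comp):
            by_comp.setdefault(c, []).append(idxs[local])
        for members_idx in sorted(by_comp.values()):
            clone_id = f"{patient}.c{len(families):05d}"
            members = [records[i] for i in members_idx]
            reads_total = sum(m.duplicate_count for m in members)
            reads_tumor = sum(
                m.duplicate_count for m in members if m.tissue == TUMOR
            )
            for m in members:
                m.clone_id = clone_id
            families.append(
                ClonalFamily(
                    clone_id=clone_id,
                    members=members,
                    v_call=v,
                    j_call=j,
                    cdr3_length_nt=length,
                    reads_total=reads_total,
                    reads_tumor=reads_tumor,
                )
            )
    return families


def extract_dominant_clones(
    families: list[ClonalFamily],
    min_reads: int = 50,
    purity_threshold: float = 0.9,
) -> list[ClonalFamily]:
    """Keep clones with >= ``min_reads`` reads and tissue purity above threshold.

    Each kept clone's ``specific_label`` is set to its majority tissue:
    a clone whose read content is at least 90% tumor-derived is a
    tumor-specific clone, and symmetrically for normal.
    """
    out = []
    for fam in families:
        if fam.reads_total >= min_reads and fam.purity >= purity_threshold:
            fam.specific_label = fam.majority_tissue
            out.append(fam)
    return out


def sample_training_sequences(
    families: list[ClonalFamily], k: int = 3, seed: int = 0
) -> list[tuple[SequenceRecord, str]]:
    """Sample up to ``k`` member sequences per clone, without replacement.

    Sampling per clone removes the influence of biased clone sizes on the
    classifiers.  Each sampled record is returned with its clone's
    tissue-specificity label.  Clones with fewer than ``k`` members
    contribute all members.
    """
    rng = np.random.default_rng(seed)
    sampled: list[tuple[SequenceRecord, str]] = []
    for fam in families:
        if fam.specific_label not in (NORMAL, TUMOR):
            raise ValueError(
                f"clone {fam.clone_id} has no tissue-specific label; run "
                "extract_dominant_clones first"
            )
        n = len(fam.members)
        take = min(k, n)
        idx = rng.choice(n, size=take, replace=False)
        for i in sorted(idx):
            sampled.append((fam.members[int(i)], fam.specific_label))
    return sampled


def cdr3_sharing_fraction(
    cohort: list[SequenceRecord],
) -> dict[tuple[str, str], float]:
    """Fraction of each sample's unique CDR3 amino-acid sequences seen in
    at least one other patient's same-tissue repertoire.

    Keyed by (patient_id, tissue).  Requires >= 2 patients.
    """
    patients = sorted({r.patient_id for r in cohort})
    if len(patients) < 2:
        raise ValueError("CDR3 sharing requires at least 2 patients")
    sets: dict[tuple[str, str], set[str]] = {}
    for rec in cohort:
        sets.setdefault((rec.patient_id, rec.tissue), set()).add(rec.cdr3_aa)
    out: dict[tuple[str, str], float] = {}
    for (patient, tissue), cdrs in sets.items():
        others: set[str] = set()
        for (p2, t2), s2 in sets.items():
            if p2 != patient and t2 == tissue:
                others |= s2
        out[(patient, tissue)] = len(cdrs & others) / len(cdrs)
    return out


def clonal_entropy(families: list[ClonalFamily]) -> float:
    """Shannon entropy (base 2, bits) of the clone read-count distribution."""
    if not families:
        raise ValueError("clonal entropy requires at least one clone")
    reads = np.array([f.reads_total for f in families], dtype=float)
    return float(_shannon_entropy(reads / reads.sum(), base=2))
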