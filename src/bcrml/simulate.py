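"""Synthetic paired normal/tumor BCR/Ig repertoires with planted effects.

The generator emulates, per patient, a pair of repertoires (normal and
tumor tissue) built from clones: each clone has one ancestral rearranged
sequence — a (V, J) pair, CDR lengths and CDR amino acids drawn from
tissue-specific distributions — and a heavy-tailed read count split over
a few unique descendant sequences that differ from the ancestor by at
most one CDR3 nucleotide substitution, so that clone mates always satisfy
the clonotype criteria (same V/J, same CDR3 length, <= 3 nt mismatches).

Class differences are planted independently in every feature channel the
classifiers use:

* V/J usage — a multiplicative tilt of the tumor usage distribution;
* CDR length triples — the same kind of tilt;
* SHM counts — independent Poisson counts for FR and CDR, with tumor
  means below normal means (tumor clones having undergone less affinity
  maturation);
* CDR3 amino-acid composition — favored residues at chosen positions of
  tumor CDR3s;
* clone-size skew — a different power-law exponent for tumor read
  counts, which shifts clonal entropy.

A ``contamination_rate`` lets a clone's reads leak into the opposite
tissue sample, as happens in real paired specimens.  All randomness flows
from the single integer seed in the config; no global state is touched.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import zipf
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .io_airr import NORMAL, TUMOR, SequenceRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# inverse codon table: amino acid -> sorted list of codons
_CODONS: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
for aa in _CODONS:
    _CODONS[aa].sort()

Categorical = dict[tuple, float]


@dataclass(slots=True)
class MotifEffect:
    """A per-position amino-acid composition shift for tumor CDR3s.

    At each listed 0-based CDR3 position the favored residue is emitted
    with probability ``boost`` (the rest of the mass spread uniformly over
    the other residues); positions beyond a short CDR3 are ignored.
    """

    positions: tuple[int, ...]
    residue: str
    boost: float


@dataclass(slots=True)
class EffectConfig:
    """Generative parameters for one synthetic cohort."""

    n_patients: int = 10
    clones_per_tissue: int = 200
    reads_zipf_a: float = 1.5
    reads_zipf_a_tumor: float | None = None  # entropy effect when it differs
    reads_max: int = 5000
    uniques_mean: float = 2.0
    vj_usage_normal: Categorical = field(default_factory=dict)
    vj_usage_tumor: Categorical = field(default_factory=dict)
    cdrlen_normal: Categorical = field(default_factory=dict)
    cdrlen_tumor: Categorical = field(default_factory=dict)
    shm_normal_mean: tuple[float, float] = (8.0, 4.0)  # (FR, CDR)
    shm_tumor_mean: tuple[float, float] = (5.0, 2.5)
    aa_motif_effect: MotifEffect | None = None
    contamination_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1 or self.clones_per_tissue < 1:
            raise ValueError("n_patients and clones_per_tissue must be >= 1")
        if not 0.0 <= self.contamination_rate < 1.0:
            raise ValueError("contamination_rate must be in [0, 1)")
        for name in ("vj_usage_normal", "vj_usage_tumor", "cdrlen_normal", "cdrlen_tumor"):
            dist = getattr(self, name)
            if not dist:
                raise ValueError(f"{name} is empty")
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} sums to {total}, not 1")
        if any(m < 0 for m in (*self.shm_normal_mean, *self.shm_tumor_mean)):
            raise ValueError("SHM means must be non-negative")


# ---------------------------------------------------------------------------
# distribution builders

def tilt_categorical(base: Categorical, effect: float) -> Categorical:
    """Multiplicatively tilt half the categories up and half down.

    Categories (sorted by key) at even ranks get weight ``(1 + effect)``,
    odd ranks ``1 / (1 + effect)``; the result is renormalized.  ``effect
    = 0`` returns the base distribution; larger effects move the tilted
    distribution monotonically away from the base in total variation.
    """
    if effect < 0:
        raise ValueError("effect must be >= 0")
    keys = sorted(base)
    w = {
        k: base[k] * ((1.0 + effect) if i % 2 == 0 else 1.0 / (1.0 + effect))
        for i, k in enumerate(keys)
    }
    total = sum(w.values())
    return {k: v / total for k, v in w.items()}


def default_vj_usage(n_v: int = 8, n_j: int = 3) -> Categorical:
    """A skewed baseline usage over (V, J) gene pairs."""
    pairs = [
        (f"IGHV{i + 1}", f"IGHJ{j + 1}") for i in range(n_v) for j in range(n_j)
    ]
    w = np.array(
        [1.0 / ((i + 1) * (j + 1)) for i in range(n_v) for j in range(n_j)]
    )
    w /= w.sum()
    return dict(zip(pairs, w.tolist()))


def default_cdrlen_usage() -> Categorical:
    """Length-triple distribution peaked at the (8, 8, 17) medians."""
    l12 = {7: 0.2, 8: 0.6, 9: 0.2}
    cdr3_lengths = np.arange(11, 24)
    w3 = 1.0 / (1.0 + np.abs(cdr3_lengths - 17))
    w3 /= w3.sum()
    dist: Categorical = {}
    for (l1, p1), (l2, p2) in itertools.product(l12.items(), l12.items()):
        for l3, p3 in zip(cdr3_lengths.tolist(), w3.tolist()):
            dist[(l1, l2, l3)] = p1 * p2 * p3
    return dist


def make_config(
    vj_effect: float = 0.0,
    len_effect: float = 0.0,
    shm_effect: float = 0.0,
    motif: MotifEffect | None = None,
    entropy_effect: float = 0.0,
    n_patients: int = 10,
    clones_per_tissue: int = 200,
    contamination_rate: float = 0.05,
    seed: int = 0,
    **overrides,
) -> EffectConfig:
    """Build a cohort config with the requested planted effects.

    ``shm_effect`` is the fractional reduction of the tumor SHM means
    relative to normal (tumor clones have undergone less affinity
    maturation); ``entropy_effect`` lowers the tumor power-law exponent,
    skewing tumor clone sizes and hence clonal entropy.  All effects at
    zero give a null cohort with identical class distributions.
    """
    vj_base = default_vj_usage()
    len_base = default_cdrlen_usage()
    normal_mean = (8.0, 4.0)
    kwargs = dict(
        n_patients=n_patients,
        clones_per_tissue=clones_per_tissue,
        vj_usage_normal=vj_base,
        vj_usage_tumor=tilt_categorical(vj_base, vj_effect),
        cdrlen_normal=len_base,
        cdrlen_tumor=tilt_categorical(len_base, len_effect),
        shm_normal_mean=normal_mean,
        shm_tumor_mean=tuple(m * (1.0 - shm_effect) for m in normal_mean),
        aa_motif_effect=motif,
        reads_zipf_a_tumor=(1.5 - entropy_effect) if entropy_effect else None,
        contamination_rate=contamination_rate,
        seed=seed,
    )
    if "vj_usage_normal" in overrides and "vj_usage_tumor" not in overrides:
        overrides["vj_usage_tumor"] = tilt_categorical(
            overrides["vj_usage_normal"], vj_effect
        )
    if "cdrlen_normal" in overrides and "cdrlen_tumor" not in overrides:
        overrides["cdrlen_tumor"] = tilt_categorical(
            overrides["cdrlen_normal"], len_effect
        )
    kwargs.update(overrides)
    cfg = EffectConfig(**kwargs)
    cfg.validate()
    return cfg


def null_config(**kwargs) -> EffectConfig:
    """A cohort with no class difference in any channel."""
    return make_config(contamination_rate=kwargs.pop("contamination_rate", 0.05), **kwargs)


def study_config(seed: int = 0, **kwargs) -> EffectConfig:
    """The default study conditions: modest effects in every channel."""
    kwargs.setdefault("vj_effect", 0.8)
    kwargs.setdefault("len_effect", 0.8)
    kwargs.setdefault("shm_effect", 0.35)
    kwargs.setdefault("motif", MotifEffect(positions=(5, 8, 11), residue="W", boost=0.3))
    return make_config(seed=seed, **kwargs)


def motif_benchmark_config(seed: int = 0, **kwargs) -> EffectConfig:
    """Strong planted CDR3 motif: one residue boosted to 0.9 at 3 positions."""
    return make_config(
        motif=MotifEffect(positions=(5, 8, 11), residue="W", boost=0.9),
        seed=seed,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# analytic oracle

def bayes_optimal_auc(p_normal: Categorical, p_tumor: Categorical) -> float:
    """Exact AUC of the likelihood-ratio classifier between two categoricals.

    Both distributions must be over the same category set (zero
    probabilities are allowed).  Computed by summation over all category
    pairs: ``P(LR_t > LR_n) + 0.5 P(LR_t = LR_n)`` for independent draws,
    with likelihood ratios compared by cross-multiplication so zero
    probabilities need no special casing.
    """
    if set(p_normal) != set(p_tumor):
        raise ValueError("distributions must share one category support")
    keys = sorted(p_normal)
    t = np.array([p_tumor[k] for k in keys])
    n = np.array([p_normal[k] for k in keys])
    # LR(c) > LR(d)  <=>  t_c * n_d > t_d * n_c
    lhs = np.outer(t, n)  # lhs[c, d] = t_c * n_d
    rhs = lhs.T
    weight = np.outer(t, n)  # P(tumor draw = c) * P(normal draw = d)
    tied = np.isclose(lhs, rhs)  # exact ties land within rounding error
    auc = weight[(lhs > rhs) & ~tied].sum() + 0.5 * weight[tied].sum()
    return float(auc)


# ---------------------------------------------------------------------------
# sequence-level sampling helpers

def _sample_categorical(rng: np.random.Generator, dist: Categorical, size: int):
    keys = sorted(dist)
    probs = np.array([dist[k] for k in keys])
    idx = rng.choice(len(keys), size=size, p=probs / probs.sum())
    return [keys[i] for i in idx]


def _sample_cdr_aa(rng: np.random.Generator, length: int, motif: MotifEffect | None) -> str:
    out = [AA20[i] for i in rng.integers(0, 20, size=length)]
    if motif is not None:
        other = [a for a in AA20 if a != motif.residue]
        p_other = (1.0 - motif.boost) / 19.0
        for pos in motif.positions:
            if pos < length:
                if rng.random() < motif.boost:
                    out[pos] = motif.residue
                else:
                    out[pos] = other[int(rng.integers(0, 19))]
    return "".join(out)


def _back_translate(rng: np.random.Generator, aa_seq: str) -> str:
    return "".join(
        _CODONS[aa][int(rng.integers(0, len(_CODONS[aa])))] for aa in aa_seq
    )


def _mutate_cdr3(rng: np.random.Generator, nt: str) -> tuple[str, str]:
    """One random non-stop substitution; returns (nt, translated aa)."""
    for _ in range(50):
        pos = int(rng.integers(0, len(nt)))
        new = "ACGT"[int(rng.integers(0, 4))]
        if new == nt[pos]:
            continue
        cand = nt[:pos] + new + nt[pos + 1 :]
        aa = str(Seq(cand).translate())
        if "*" not in aa:
            return cand, aa
    return nt, str(Seq(nt).translate())


def _zipf_reads(rng: np.random.Generator, a: float, cap: int) -> int:
    return int(min(zipf.rvs(a, random_state=rng), cap))


# ---------------------------------------------------------------------------
# cohort generation

def simulate_cohort(config: EffectConfig) -> list[SequenceRecord]:
    """Generate records for ``n_patients`` x 2 tissues; deterministic per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[SequenceRecord] = []
    for p in range(config.n_patients):
        patient = f"P{p:03d}"
        for tissue in (NORMAL, TUMOR):
            is_tumor = tissue == TUMOR
            usage = config.vj_usage_tumor if is_tumor else config.vj_usage_normal
            lens = config.cdrlen_tumor if is_tumor else config.cdrlen_normal
            shm_mean = config.shm_tumor_mean if is_tumor else config.shm_normal_mean
            zipf_a = (
                config.reads_zipf_a_tumor
                if (is_tumor and config.reads_zipf_a_tumor is not None)
                else config.reads_zipf_a
            )
            motif = config.aa_motif_effect if is_tumor else None
            vjs = _sample_categorical(rng, usage, config.clones_per_tissue)
            triples = _sample_categorical(rng, lens, config.clones_per_tissue)
            for ci in range(config.clones_per_tissue):
                v_call, j_call = vjs[ci]
                l1, l2, l3 = triples[ci]
                cdr1 = _sample_cdr_aa(rng, l1, None)
                cdr2 = _sample_cdr_aa(rng, l2, None)
                cdr3_aa = _sample_cdr_aa(rng, l3, motif)
                cdr3_nt = _back_translate(rng, cdr3_aa)
                reads = _zipf_reads(rng, zipf_a, config.reads_max)
                n_unique = min(reads, 1 + int(rng.poisson(config.uniques_mean)))
                counts = rng.multinomial(
                    reads - n_unique, np.full(n_unique, 1.0 / n_unique)
                ) + 1
                leak_frac = 0.0
                if config.contamination_rate and rng.random() < config.contamination_rate:
                    leak_frac = rng.uniform(0.05, 0.3)
                for ui in range(n_unique):
                    if ui == 0:
                        nt, aa = cdr3_nt, cdr3_aa
                    else:
                        nt, aa = _mutate_cdr3(rng, cdr3_nt)
                    shm_fr = int(rng.poisson(shm_mean[0]))
                    shm_cdr = int(rng.poisson(shm_mean[1]))
                    count = int(counts[ui])
                    leak = int(rng.binomial(count, leak_frac)) if leak_frac else 0
                    keep = count - leak
                    base_id = f"{patient}_{tissue[0]}_c{ci:04d}_s{ui}"
                    if keep > 0:
                        records.append(
                            SequenceRecord(
                                sequence_id=base_id,
                                patient_id=patient,
                                tissue=tissue,
                                v_call=v_call,
                                j_call=j_call,
                                cdr1_aa=cdr1,
                                cdr2_aa=cdr2,
                                cdr3_aa=aa,
                                cdr3_nt=nt,
                                duplicate_count=keep,
                                shm_fr=shm_fr,
                                shm_cdr=shm_cdr,
                            )
                        )
                    if leak > 0:
                        records.append(
                            SequenceRecord(
                                sequence_id=base_id + "_leak",
                                patient_id=patient,
                                tissue=TUMOR if tissue == NORMAL else NORMAL,
                                v_call=v_call,
                                j_call=j_call,
                                cdr1_aa=cdr1,
                                cdr2_aa=cdr2,
                                cdr3_aa=aa,
                                cdr3_nt=nt,
                                duplicate_count=leak,
                                shm_fr=shm_fr,
                                shm_cdr=shm_cdr,
                            )
                        )
    return records


def sample_test_sequences(
    config: EffectConfig, n_per_class: int, seed: int
) -> list[SequenceRecord]:
    """I.i.d. labeled sequences (no clone structure) for evaluation.

    Each record's ``tissue`` is its generating class; patient_id is the
    synthetic ``HELDOUT`` patient.  Useful for measuring how closely a
    fitted classifier approaches the analytic optimum.
    """
    rng = np.random.default_rng(seed)
    records: list[SequenceRecord] = []
    for tissue in (NORMAL, TUMOR):
        is_tumor = tissue == TUMOR
        usage = config.vj_usage_tumor if is_tumor else config.vj_usage_normal
        lens = config.cdrlen_tumor if is_tumor else config.cdrlen_normal
        shm_mean = config.shm_tumor_mean if is_tumor else config.shm_normal_mean
        motif = config.aa_motif_effect if is_tumor else None
        vjs = _sample_categorical(rng, usage, n_per_class)
        triples = _sample_categorical(rng, lens, n_per_class)
        for i in range(n_per_class):
            v_call, j_call = vjs[i]
            l1, l2, l3 = triples[i]
            cdr3_aa = _sample_cdr_aa(rng, l3, motif)
            records.append(
                SequenceRecord(
                    sequence_id=f"HELDOUT_{tissue[0]}_{i:05d}",
                    patient_id="HELDOUT",
                    tissue=tissue,
                    v_call=v_call,
                    j_call=j_call,
                    cdr1_aa=_sample_cdr_aa(rng, l1, None),
                    cdr2_aa=_sample_cdr_aa(rng, l2, None),
                    cdr3_aa=cdr3_aa,
                    cdr3_nt=_back_translate(rng, cdr3_aa),
                    duplicate_count=1,
                    shm_fr=int(rng.poisson(shm_mean[0])),
                    shm_cdr=int(rng.poisson(shm_mean[1])),
                )
            )
    return records
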