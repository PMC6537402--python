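"""End-to-end harness: cohort -> clones -> classifiers -> tissue scores.

Ties the stages together the way the study design requires:

1. per patient, pool both tissue samples, assign clonal families, keep
   tissue-specific dominant clones (>= 50 reads, >= 90% one-tissue read
   content) and sample 3 sequences per clone as labeled training data;
   patients lacking a tumor- or normal-specific clone are dropped from
   training;
2. run leave-one-patient-out nested CV for each of the four feature
   channels, collecting out-of-fold per-sequence probabilities and the
   per-fold fitted models;
3. for each held-out patient, fit the linear GBM ensemble on the other
   patients' out-of-fold channel probabilities and score the held-out
   sequences — the ensemble a patient is scored with never saw that
   patient;
4. score whole tissue samples by aggregating the ensemble probabilities
   of *all* the sample's sequences (not only specific-clone members)
   with the channel/ensemble models from the fold that held the patient
   out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classify, clonotype, ensemble, evaluate
from .classify import LABELS, ChannelSpec, NestedCvResult
from .io_airr import NORMAL, TUMOR, SequenceRecord


def default_channel_specs(
    seq_algorithm: str = "convnet",
    seq_budget: int = 10,
    seq_epochs: int = 20,
) -> list[ChannelSpec]:
    return [
        classify.VjBayesSpec(),
        classify.LenBayesSpec(),
        classify.ShmSpec(),
        classify.SeqSpec(algorithm=seq_algorithm, budget=seq_budget, epochs=seq_epochs),
    ]


@dataclass(slots=True)
class TrainingSet:
    labeled: list[tuple[SequenceRecord, str]]
    families_by_patient: dict[str, list[clonotype.ClonalFamily]]
    dropped_patients: list[str] = field(default_factory=list)


def build_training_set(
    records: list[SequenceRecord],
    min_reads: int = 50,
    purity_threshold: float = 0.9,
    k: int = 3,
    seed: int = 0,
) -> TrainingSet:
    """Clonotype each patient and sample labeled training sequences.

    Patients with no tumor-specific or no normal-specific dominant clone
    cannot contribute both classes and are dropped from training.
    """
    by_patient: dict[str, list[SequenceRecord]] = {}
    for rec in records:
        by_patient.setdefault(rec.patient_id, []).append(rec)
    labeled: list[tuple[SequenceRecord, str]] = []
    families_by_patient: dict[str, list[clonotype.ClonalFamily]] = {}
    dropped: list[str] = []
    for i, patient in enumerate(sorted(by_patient)):
        families = clonotype.assign_clonal_families(by_patient[patient])
        families_by_patient[patient] = families
        dominant = clonotype.extract_dominant_clones(
            families, min_reads=min_reads, purity_threshold=purity_threshold
        )
        labels_present = {f.specific_label for f in dominant}
        if not {NORMAL, TUMOR} <= labels_present:
            dropped.append(patient)
            continue
        labeled.extend(
            clonotype.sample_training_sequences(dominant, k=k, seed=seed + i)
        )
    return TrainingSet(
        labeled=labeled, families_by_patient=families_by_patient, dropped_patients=dropped
    )


@dataclass(slots=True)
class PerSequenceResult:
    """Out-of-fold per-sequence probabilities and per-patient AUCs."""

    probabilities: pd.DataFrame  # sequence_id, patient_id, label, p_vj.., p_ens
    channel_auc: dict[str, dict[str, float]]  # channel -> patient -> AUC
    ensemble_auc: dict[str, float]
    channel_results: dict[str, NestedCvResult]
    ensemble_models: dict[str, ensemble.EnsembleModel]


def run_per_sequence(
    labeled: list[tuple[SequenceRecord, str]],
    specs: list[ChannelSpec] | None = None,
    seed: int = 0,
) -> PerSequenceResult:
    """Nested CV for all channels, then a leave-one-patient-out ensemble."""
    if specs is None:
        specs = default_channel_specs()
    channel_results: dict[str, NestedCvResult] = {}
    merged: pd.DataFrame | None = None
    for spec in specs:
        res = classify.nested_cv(labeled, spec, seed=seed)
        channel_results[spec.name] = res
        cols = res.predictions
        merged = (
            cols
            if merged is None
            else merged.merge(cols, on=["sequence_id", "patient_id", "clone_id", "label"])
        )
    assert merged is not None
    ens_probs = np.full(len(merged), np.nan)
    ensemble_auc: dict[str, float] = {}
    ensemble_models: dict[str, ensemble.EnsembleModel] = {}
    for patient in sorted(merged["patient_id"].unique()):
        mask = merged["patient_id"] == patient
        model = ensemble.fit_ensemble(merged[~mask])
        ensemble_models[patient] = model
        ens_probs[mask.to_numpy()] = ensemble.predict_ensemble(model, merged[mask])
        y = merged.loc[mask, "label"].to_numpy()
        if len(np.unique(y)) == 2:
            ensemble_auc[patient] = evaluate.roc_auc(
                ens_probs[mask.to_numpy()], y
            ).auc
    merged = merged.assign(p_ens=ens_probs)
    return PerSequenceResult(
        probabilities=merged,
        channel_auc={name: res.per_patient_auc for name, res in channel_results.items()},
        ensemble_auc=ensemble_auc,
        channel_results=channel_results,
        ensemble_models=ensemble_models,
    )


def sample_clonal_entropy(
    families: list[clonotype.ClonalFamily], tissue: str
) -> float:
    """Clonal entropy of one tissue sample's read distribution over clones."""
    reads = []
    for fam in families:
        r = sum(m.duplicate_count for m in fam.members if m.tissue == tissue)
        if r > 0:
            reads.append(r)
    if not reads:
        raise ValueError(f"no reads in tissue {tissue!r}")
    p = np.asarray(reads, dtype=float)
    p /= p.sum()
    return float(-(p * np.log2(p)).sum())


@dataclass(slots=True)
class TissueLevelResult:
    samples: pd.DataFrame  # patient_id, tissue, label, n_sequences, entropy, score_*
    auc: dict[str, float]  # statistic -> AUC over samples


def run_tissue_level(
    records: list[SequenceRecord],
    per_seq: PerSequenceResult,
    training: TrainingSet,
    specs: list[ChannelSpec],
    statistics: tuple[str, ...] = ("mean", "median", "mode"),
) -> TissueLevelResult:
    """Score every tissue sample with models that never saw its patient.

    Uses all of each sample's sequences.  Patients without a
    leave-one-out fold of their own (dropped from training) are skipped,
    since no model excluding them was fitted.
    """
    by_sample: dict[tuple[str, str], list[SequenceRecord]] = {}
    for rec in records:
        by_sample.setdefault((rec.patient_id, rec.tissue), []).append(rec)
    spec_by_name = {spec.name: spec for spec in specs}
    rows = []
    for (patient, tissue), recs in sorted(by_sample.items()):
        if patient not in per_seq.ensemble_models:
            continue  # no leave-this-patient-out model available
        chan = {}
        for name, res in per_seq.channel_results.items():
            model = res.models[patient]
            chan[name] = spec_by_name[name].predict(model, recs)
        frame = pd.DataFrame(chan)
        probs = ensemble.predict_ensemble(per_seq.ensemble_models[patient], frame)
        entropy = sample_clonal_entropy(training.families_by_patient[patient], tissue)
        row = {
            "patient_id": patient,
            "tissue": tissue,
            "label": LABELS[tissue],
            "n_sequences": len(recs),
            "entropy": entropy,
        }
        for stat in statistics:
            row[f"score_{stat}"] = ensemble.aggregate_probabilities(probs, stat)
        rows.append(row)
    samples = pd.DataFrame(rows)
    auc = {
        stat: evaluate.roc_auc(samples[f"score_{stat}"], samples["label"]).auc
        for stat in statistics
    }
    return TissueLevelResult(samples=samples, auc=auc)


def run_study(
    records: list[SequenceRecord],
    specs: list[ChannelSpec] | None = None,
    seed: int = 0,
    min_reads: int = 50,
    purity_threshold: float = 0.9,
    k: int = 3,
) -> tuple[TrainingSet, PerSequenceResult, TissueLevelResult]:
    """The full pipeline on one cohort of records."""
    if specs is None:
        specs = default_channel_specs()
    training = build_training_set(
        records, min_reads=min_reads, purity_threshold=purity_threshold, k=k, seed=seed
    )
    per_seq = run_per_sequence(training.labeled, specs, seed=seed)
    tissue = run_tissue_level(records, per_seq, training, specs)
    return training, per_seq, tissue
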