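"""Per-sequence normal/tumor classifiers and the nested-CV harness.

Four feature channels are modeled:

* V/J gene usage and CDR length triples — a patient-averaged Bayes
  classifier: per-class likelihood tables are computed per training
  patient as relative frequencies and then averaged with equal patient
  weight (not pooled counts), so large repertoires do not dominate;
* SHM counts — a linear-kernel max-margin classifier on the 2-d
  (shm_fr, shm_cdr) feature, with a logistic link fitted on the training
  decision values so outputs are probabilities;
* CDR amino-acid sequences — a convolutional network, an RBF-kernel SVM
  or a random forest over the 33 x 10 Kidera encoding.

Model selection follows nested cross-validation: the outer loop is
leave-one-patient-out, the inner loop a patient-level two-fold split that
chooses hyperparameters; sequences are always split at the patient
level, never individually.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC, LinearSVC

from . import encode
from .clonotype import normalize_gene
from .io_airr import NORMAL, TUMOR, SequenceRecord
from .convnet import ConvNetClassifier, ConvNetConfig

LABELS = {NORMAL: 0, TUMOR: 1}


def _category(record: SequenceRecord, feature_kind: str):
    if feature_kind == "vj_frame":
        return (normalize_gene(record.v_call), normalize_gene(record.j_call))
    if feature_kind == "cdr_length":
        return encode.cdr_length_triple(record)
    raise ValueError(f"unknown feature kind {feature_kind!r}")


# ---------------------------------------------------------------------------
# patient-averaged Bayes classifier (V/J usage, CDR lengths)

@dataclass(slots=True)
class PatientAveragedBayesModel:
    """Per-class likelihood tables averaged over training patients.

    Each table is the equal-weight mean of per-patient relative-frequency
    tables, so it sums to 1 over the categories observed in training.
    """

    feature_kind: str
    likelihood_normal: dict
    likelihood_tumor: dict
    n_patients_train: int
    prior_tumor: float = 0.5
    smoothing_epsilon: float = 1e-9


def fit_patient_averaged_bayes(
    labeled: list[tuple[SequenceRecord, str]],
    feature_kind: str,
    prior_tumor: float = 0.5,
    smoothing_epsilon: float = 1e-9,
) -> PatientAveragedBayesModel:
    """Average per-patient relative-frequency tables for each class.

    A patient missing one class simply does not contribute to that
    class's table.  Raises on an empty training set.
    """
    if not labeled:
        raise ValueError("empty training set")
    per_patient: dict[str, dict[str, dict]] = {}
    for record, label in labeled:
        tables = per_patient.setdefault(record.patient_id, {NORMAL: {}, TUMOR: {}})
        cat = _category(record, feature_kind)
        tables[label][cat] = tables[label].get(cat, 0) + 1
    averaged = {NORMAL: {}, TUMOR: {}}
    n_contrib = {NORMAL: 0, TUMOR: 0}
    for tables in per_patient.values():
        for label in (NORMAL, TUMOR):
            total = sum(tables[label].values())
            if total == 0:
                continue
            n_contrib[label] += 1
            for cat, count in tables[label].items():
                averaged[label][cat] = averaged[label].get(cat, 0.0) + count / total
    for label in (NORMAL, TUMOR):
        if n_contrib[label] == 0:
            raise ValueError(f"no training patient contributes class {label!r}")
        for cat in averaged[label]:
            averaged[label][cat] /= n_contrib[label]
    return PatientAveragedBayesModel(
        feature_kind=feature_kind,
        likelihood_normal=averaged[NORMAL],
        likelihood_tumor=averaged[TUMOR],
        n_patients_train=len(per_patient),
        prior_tumor=prior_tumor,
        smoothing_epsilon=smoothing_epsilon,
    )


def predict_bayes(model: PatientAveragedBayesModel, record: SequenceRecord) -> float:
    """Posterior P(tumor | category) by Bayes' theorem.

    Both class likelihoods are floored at ``smoothing_epsilon`` so that a
    category unseen in training yields the prior.
    """
    cat = _category(record, model.feature_kind)
    eps = model.smoothing_epsilon
    lt = max(model.likelihood_tumor.get(cat, 0.0), eps)
    ln = max(model.likelihood_normal.get(cat, 0.0), eps)
    pt = model.prior_tumor
    return pt * lt / (pt * lt + (1.0 - pt) * ln)


# ---------------------------------------------------------------------------
# SHM classifier

class _PlattCalibrated:
    """Margin classifier + logistic link on its decision values."""

    def __init__(self, base):
        self.base = base

    def fit(self, x: np.ndarray, y: np.ndarray):
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")
        self.base.fit(x, y)
        d = self.base.decision_function(x).reshape(-1, 1)
        self.link = LogisticRegression(C=1e6, max_iter=1000).fit(d, y)
        return self

    def predict_proba1(self, x: np.ndarray) -> np.ndarray:
        d = self.base.decision_function(x).reshape(-1, 1)
        return self.link.predict_proba(d)[:, 1]


class ShmClassifier:
    """Linear-kernel max-margin classifier on (shm_fr, shm_cdr)."""

    def __init__(self, C: float = 1.0, seed: int = 0):
        self._model = _PlattCalibrated(
            LinearSVC(C=C, dual="auto", max_iter=5000, random_state=seed)
        )

    @staticmethod
    def _features(records) -> np.ndarray:
        return np.array([encode.shm_feature(r) for r in records], dtype=float)

    def fit(self, records, labels) -> "ShmClassifier":
        y = np.asarray(labels, dtype=int)
        counts = np.bincount(y, minlength=2)
        if counts.min() < 2:
            raise ValueError("need at least 2 examples per class")
        self._model.fit(self._features(records), y)
        return self

    def predict_proba(self, records) -> np.ndarray:
        return self._model.predict_proba1(self._features(records))


def fit_shm_classifier(labeled: list[tuple[SequenceRecord, str]]) -> ShmClassifier:
    records = [r for r, _ in labeled]
    y = [LABELS[l] for _, l in labeled]
    return ShmClassifier().fit(records, y)


def predict_shm(model: ShmClassifier, record: SequenceRecord) -> float:
    return float(model.predict_proba([record])[0])


# ---------------------------------------------------------------------------
# sequence classifiers on the Kidera encoding

N_FEATURES = 330

#: hyperparameter search space for the convolutional classifier
CONV_SPACE = {
    "learning_rate": (1e-7, 1e-3),  # log-uniform
    "dropout_keep": (0.4, 1.0),  # probability of keeping a unit
    "n_conv_layers": (1, 2),
    "n_kernels": (80, 300),
    "kernel_width": (2, 3),
    "pool_width": (2, 3),
    "n_fc_layers": (1, 3),
    "fc_units": (100, 300),
}
#: grid for the RBF-kernel classifier
SVM_C_GRID = (1.0, 10.0, 100.0, 1000.0)
SVM_GAMMA_GRID = (1e-2, 1e-3, 1e-4, 1e-5)


def forest_depths(n_features: int = N_FEATURES) -> tuple[int, int, int]:
    """Candidate tree depths: sqrt(f), log2(f), f."""
    return (
        int(round(math.sqrt(n_features))),
        int(round(math.log2(n_features))),
        n_features,
    )


def sample_conv_params(rng: np.random.Generator) -> dict:
    lo, hi = CONV_SPACE["learning_rate"]
    return {
        "learning_rate": float(10 ** rng.uniform(np.log10(lo), np.log10(hi))),
        "dropout_keep": float(rng.uniform(*CONV_SPACE["dropout_keep"])),
        "n_conv_layers": int(rng.integers(1, 3)),
        "n_kernels": int(rng.integers(80, 301)),
        "kernel_width": int(rng.integers(2, 4)),
        "pool_width": int(rng.integers(2, 4)),
        "n_fc_layers": int(rng.integers(1, 4)),
        "fc_units": int(rng.integers(100, 301)),
    }


@dataclass
class ChannelSpec:
    """One feature channel's model family, for use inside nested CV."""

    name: str
    search: str = "grid"  # "grid" | "random"
    budget: int = 1

    def prepare(self, records) -> None:  # pragma: no cover - overridden
        pass

    def candidates(self, rng: np.random.Generator) -> list[dict]:
        return [{}]

    def fit(self, params: dict, labeled, seed: int):
        raise NotImplementedError

    def predict(self, model, records) -> np.ndarray:
        raise NotImplementedError


class VjBayesSpec(ChannelSpec):
    def __init__(self):
        super().__init__(name="p_vj")

    def fit(self, params, labeled, seed):
        return fit_patient_averaged_bayes(labeled, "vj_frame")

    def predict(self, model, records):
        return np.array([predict_bayes(model, r) for r in records])


class LenBayesSpec(ChannelSpec):
    def __init__(self):
        super().__init__(name="p_len")

    def fit(self, params, labeled, seed):
        return fit_patient_averaged_bayes(labeled, "cdr_length")

    def predict(self, model, records):
        return np.array([predict_bayes(model, r) for r in records])


class ShmSpec(ChannelSpec):
    def __init__(self):
        super().__init__(name="p_shm")

    def fit(self, params, labeled, seed):
        records = [r for r, _ in labeled]
        y = [LABELS[l] for _, l in labeled]
        return ShmClassifier(seed=seed).fit(records, y)

    def predict(self, model, records):
        return model.predict_proba(records)


class SeqSpec(ChannelSpec):
    """CDR amino-acid channel: convnet, RBF-SVM or random forest."""

    def __init__(
        self,
        algorithm: str = "convnet",
        search: str | None = None,
        budget: int = 10,
        epochs: int = 20,
        length_mode: str = "center",
        targets: tuple[int, int, int] = encode.DEFAULT_TARGETS,
    ):
        if algorithm not in ("convnet", "rbf_svm", "forest"):
            raise ValueError(f"unknown algorithm {algorithm!r}")
        if search is None:
            search = "random" if algorithm == "convnet" else "grid"
        super().__init__(name="p_seq", search=search, budget=budget)
        self.algorithm = algorithm
        self.epochs = epochs
        self.length_mode = length_mode
        self.targets = targets
        self._cache: dict[str, np.ndarray] = {}

    def prepare(self, records) -> None:
        for r in records:
            if r.sequence_id not in self._cache:
                self._cache[r.sequence_id] = encode.kidera_encode(
                    r.cdr1_aa, r.cdr2_aa, r.cdr3_aa, self.targets, self.length_mode
                ).values

    def _matrix(self, records) -> np.ndarray:
        self.prepare(records)
        return np.stack([self._cache[r.sequence_id] for r in records])

    def candidates(self, rng: np.random.Generator) -> list[dict]:
        if self.budget < 1:
            raise ValueError("search budget must be >= 1")
        if self.algorithm == "convnet":
            return [sample_conv_params(rng) for _ in range(self.budget)]
        if self.algorithm == "rbf_svm":
            grid = [{"C": c, "gamma": g} for c in SVM_C_GRID for g in SVM_GAMMA_GRID]
        else:
            grid = [{"max_depth": d} for d in forest_depths()]
        if self.search == "random":
            idx = rng.choice(len(grid), size=min(self.budget, len(grid)), replace=False)
            return [grid[i] for i in idx]
        return grid

    def fit(self, params, labeled, seed):
        records = [r for r, _ in labeled]
        y = np.array([LABELS[l] for _, l in labeled])
        x3 = self._matrix(records)
        if self.algorithm == "convnet":
            cfg = ConvNetConfig(epochs=self.epochs, seed=seed, **params)
            return ConvNetClassifier(cfg).fit(x3, y)
        x2 = x3.reshape(len(x3), -1)
        if self.algorithm == "rbf_svm":
            model = _PlattCalibrated(SVC(kernel="rbf", **params))
            return model.fit(x2, y)
        model = RandomForestClassifier(
            n_estimators=100, random_state=seed, n_jobs=1, **params
        )
        return model.fit(x2, y)

    def predict(self, model, records) -> np.ndarray:
        x3 = self._matrix(records)
        if self.algorithm == "convnet":
            return model.predict_proba(x3)
        x2 = x3.reshape(len(x3), -1)
        if isinstance(model, _PlattCalibrated):
            return model.predict_proba1(x2)
        return model.predict_proba(x2)[:, 1]


def fit_sequence_classifier(
    labeled: list[tuple[SequenceRecord, str]],
    algorithm: str = "convnet",
    search: str | None = None,
    budget: int = 10,
    seed: int = 0,
    epochs: int = 20,
):
    """Fit one sequence-channel model, selecting hyperparameters by an
    inner patient-level two-fold split when more than one candidate is
    drawn.  Returns ``(model, spec)``; predict with ``spec.predict``.
    """
    spec = SeqSpec(algorithm=algorithm, search=search, budget=budget, epochs=epochs)
    rng = np.random.default_rng(seed)
    params_list = spec.candidates(rng)
    if len(params_list) > 1:
        params = _select_params(spec, params_list, labeled, rng)
    else:
        params = params_list[0]
    model = spec.fit(params, labeled, seed=int(rng.integers(2**31)))
    return model, spec


# ---------------------------------------------------------------------------
# nested cross-validation

@dataclass(slots=True)
class NestedCvResult:
    per_patient_auc: dict[str, float]
    predictions: pd.DataFrame  # sequence_id, patient_id, label, prob
    skipped_patients: list[str] = field(default_factory=list)
    models: dict[str, object] = field(default_factory=dict)  # held-out patient -> model


def _split_by_patient(labeled) -> dict[str, list]:
    by_patient: dict[str, list] = {}
    for record, label in labeled:
        by_patient.setdefault(record.patient_id, []).append((record, label))
    return by_patient


def _auc_or_none(y, p) -> float | None:
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        return None
    return float(roc_auc_score(y, p))


def _select_params(spec: ChannelSpec, params_list, labeled, rng) -> dict:
    """Inner two-fold patient-level CV; highest mean AUC wins."""
    by_patient = _split_by_patient(labeled)
    patients = sorted(by_patient)
    order = rng.permutation(len(patients))
    half = len(patients) // 2
    folds = (
        [patients[i] for i in order[:half]],
        [patients[i] for i in order[half:]],
    )
    best, best_auc = params_list[0], -np.inf
    for params in params_list:
        aucs = []
        for hold in (0, 1):
            train = [x for p in folds[1 - hold] for x in by_patient[p]]
            test = [x for p in folds[hold] for x in by_patient[p]]
            if not train or not test:
                continue
            try:
                model = spec.fit(params, train, seed=int(rng.integers(2**31)))
            except ValueError:
                continue
            probs = spec.predict(model, [r for r, _ in test])
            auc = _auc_or_none([LABELS[l] for _, l in test], probs)
            if auc is not None:
                aucs.append(auc)
        mean_auc = float(np.mean(aucs)) if aucs else -np.inf
        if mean_auc > best_auc:
            best, best_auc = params, mean_auc
    return best


def nested_cv(
    labeled: list[tuple[SequenceRecord, str]],
    spec: ChannelSpec,
    seed: int = 0,
) -> NestedCvResult:
    """Leave-one-patient-out outer loop with inner 2-fold model selection.

    The selected model is refit on all outer-training patients and scored
    on the held-out patient.  Patients whose held-out set lacks one class
    get no AUC and are listed in ``skipped_patients`` (their sequence
    probabilities are still returned).
    """
    by_patient = _split_by_patient(labeled)
    patients = sorted(by_patient)
    if len(patients) < 3:
        raise ValueError("nested CV needs at least 3 patients")
    spec.prepare([r for r, _ in labeled])
    per_patient_auc: dict[str, float] = {}
    skipped: list[str] = []
    models: dict[str, object] = {}
    rows = []
    for fold, held_out in enumerate(patients):
        rng = np.random.default_rng([seed, fold])
        train = [x for p in patients if p != held_out for x in by_patient[p]]
        test = by_patient[held_out]
        assert all(r.patient_id != held_out for r, _ in train)
        params_list = spec.candidates(rng)
        if len(params_list) > 1:
            params = _select_params(spec, params_list, train, rng)
        else:
            params = params_list[0]
        model = spec.fit(params, train, seed=int(rng.integers(2**31)))
        models[held_out] = model
        probs = spec.predict(model, [r for r, _ in test])
        y = [LABELS[l] for _, l in test]
        auc = _auc_or_none(y, probs)
        if auc is None:
            skipped.append(held_out)
        else:
            per_patient_auc[held_out] = auc
        for (record, label), prob in zip(test, probs):
            rows.append(
                {
                    "sequence_id": record.sequence_id,
                    "patient_id": held_out,
                    "clone_id": record.clone_id,
                    "label": LABELS[label],
                    spec.name: float(prob),
                }
            )
    return NestedCvResult(
        per_patient_auc=per_patient_auc,
        predictions=pd.DataFrame(rows),
        skipped_patients=skipped,
        models=models,
    )
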