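"""Linear gradient-boosted ensemble and tissue-level aggregation.

The four per-sequence channel probabilities (V/J usage, CDR lengths, SHM
counts, CDR amino acids) are combined by a linear gradient-boosting
machine (xgboost, ``gblinear`` booster, default hyperparameters) into a
single tumor probability per sequence.  A whole tissue sample is then
scored by a descriptive statistic — mean (the primary choice), median or
mode — of the per-sequence ensemble probabilities over *all* of the
sample's sequences, each unique sequence counted once.

Because the boosted model is linear in the inputs, its coefficients and
intercept are recovered exactly by probing the fitted booster on unit
vectors; prediction is then the explicit logistic
``sigmoid(beta . x + b)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from xgboost import XGBClassifier

CHANNELS = ["p_vj", "p_len", "p_shm", "p_seq"]


@dataclass(slots=True)
class EnsembleModel:
    """Linear-logistic combination of the four channel probabilities."""

    coefficients: np.ndarray  # (4,)
    intercept: float

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (len(CHANNELS),):
            raise ValueError(f"expected {len(CHANNELS)} coefficients")

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return expit(x @ self.coefficients + self.intercept)


def _linear_extract(booster_clf, n_features: int) -> tuple[np.ndarray, float]:
    """Recover (coefficients, intercept) of a fitted linear booster.

    The gblinear prediction is ``sigmoid(w . x + c)``; probing the zero
    vector and the unit vectors on the logit scale recovers w and c
    exactly.
    """
    probes = np.vstack([np.zeros(n_features), np.eye(n_features)])
    margins = logit(booster_clf.predict_proba(probes)[:, 1].astype(np.float64))
    intercept = margins[0]
    coefficients = margins[1:] - intercept
    return coefficients, float(intercept)


def fit_ensemble(train: pd.DataFrame, label_col: str = "label") -> EnsembleModel:
    """Fit the linear GBM on the four channel probabilities.

    ``train`` must provide the columns ``p_vj, p_len, p_shm, p_seq`` and
    a binary label column (1 = tumor).  Hyperparameters are the
    defaults of the boosting implementation.
    """
    missing = [c for c in CHANNELS if c not in train.columns]
    if missing:
        raise ValueError(f"missing channel column(s): {', '.join(missing)}")
    x = train[CHANNELS].to_numpy(dtype=float)
    y = train[label_col].to_numpy(dtype=int)
    clf = XGBClassifier(booster="gblinear")
    clf.fit(x, y)
    coefficients, intercept = _linear_extract(clf, len(CHANNELS))
    return EnsembleModel(coefficients=coefficients, intercept=intercept)


def predict_ensemble(model: EnsembleModel, probs) -> np.ndarray:
    """Per-sequence tumor probability from the four channel probabilities."""
    if isinstance(probs, pd.DataFrame):
        missing = [c for c in CHANNELS if c not in probs.columns]
        if missing:
            raise ValueError(f"missing channel column(s): {', '.join(missing)}")
        probs = probs[CHANNELS].to_numpy(dtype=float)
    return model.predict(probs)


# ---------------------------------------------------------------------------
# tissue-level aggregation

MODE_BIN_WIDTH = 0.02


@dataclass(slots=True)
class TissueScore:
    """Aggregate tumor score of one tissue sample."""

    patient_id: str
    tissue: str
    statistic: str
    score: float
    n_sequences: int


def aggregate_probabilities(
    per_sequence: np.ndarray,
    statistic: str = "mean",
    bin_width: float = MODE_BIN_WIDTH,
) -> float:
    """Mean, median or histogram mode of per-sequence tumor probabilities.

    The mode is the midpoint of the maximal-count bin of a fixed-width
    histogram on [0, 1]; ties break toward the lowest midpoint.
    """
    p = np.asarray(per_sequence, dtype=float)
    if p.size == 0:
        raise ValueError("cannot aggregate an empty probability list")
    if statistic == "mean":
        return float(p.mean())
    if statistic == "median":
        return float(np.median(p))
    if statistic == "mode":
        edges = np.arange(0.0, 1.0 + bin_width, bin_width)
        edges[-1] = 1.0 + 1e-12  # right-closed final bin
        counts, _ = np.histogram(p, bins=edges)
        best = int(np.argmax(counts))  # argmax takes the first = lowest midpoint
        return float((edges[best] + min(edges[best + 1], 1.0)) / 2.0)
    raise ValueError(f"unknown statistic {statistic!r}")


def tissue_score(
    patient_id: str,
    tissue: str,
    per_sequence: np.ndarray,
    statistic: str = "mean",
) -> TissueScore:
    """Score one tissue sample from all of its per-sequence probabilities."""
    return TissueScore(
        patient_id=patient_id,
        tissue=tissue,
        statistic=statistic,
        score=aggregate_probabilities(per_sequence, statistic),
        n_sequences=len(per_sequence),
    )


# ---------------------------------------------------------------------------
# clonal-entropy augmentation

def augment_with_entropy(
    samples: pd.DataFrame,
    score_col: str = "score",
    entropy_col: str = "entropy",
    label_col: str = "label",
) -> pd.DataFrame:
    """Tissue-level scores with and without clonal entropy as a feature.

    For each patient, two linear GBMs are fitted on all other patients'
    samples — one on (score, entropy), one on score alone — and applied
    to the held-out patient's samples.  Returns ``samples`` with
    ``score_with_entropy`` and ``score_without_entropy`` columns; the
    pair is the like-for-like comparison of whether entropy helps (an
    uninformative entropy column leaves the ranking unchanged).
    """
    out = samples.copy()
    out["score_with_entropy"] = np.nan
    out["score_without_entropy"] = np.nan
    for patient in samples["patient_id"].unique():
        train = samples[samples["patient_id"] != patient]
        test_idx = samples["patient_id"] == patient
        y = train[label_col].to_numpy(dtype=int)
        for col, feats in (
            ("score_with_entropy", [score_col, entropy_col]),
            ("score_without_entropy", [score_col]),
        ):
            clf = XGBClassifier(booster="gblinear")
            clf.fit(train[feats].to_numpy(dtype=float), y)
            xt = samples.loc[test_idx, feats].to_numpy(dtype=float)
            out.loc[test_idx, col] = clf.predict_proba(xt)[:, 1]
    return out
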