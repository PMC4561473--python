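"""k-nearest-neighbour classification over signature features, with ROC/AUC.

Two entry points mirror the two study designs:

* :func:`knn_classify_external` — a reference cohort of known samples
  defines the expression space; independent test samples are projected
  into it and classified one at a time (full external validation).
* :func:`knn_classify_loocv` — within-cohort leave-one-out classification
  for cohorts that cannot share a reference platform.

Features are the signature probes, z-scored per probe from the reference
(or per-fold training) samples only, and distances are Euclidean.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .containers import (
    ClassificationResult,
    ExpressionMatrix,
    RocCurve,
    SampleTable,
    SignatureModel,
)

logger = logging.getLogger("agesig")


def infer_positive_label(levels) -> str:
    """Pick the case-like label from a two-level set.

    "old" beats "young"; any label beats "control"/"ctrl". Raise when the
    convention is ambiguous so callers must state it explicitly.
    """
    levels = sorted(set(levels))
    if len(levels) != 2:
        raise ValueError(f"need exactly two group levels, got {levels}")
    lowered = [lv.lower() for lv in levels]
    if "old" in lowered:
        return levels[lowered.index("old")]
    for neg in ("young", "control", "ctrl"):
        if neg in lowered:
            return levels[1 - lowered.index(neg)]
    raise ValueError(
        f"cannot infer which of {levels} is the positive (old/case) label; pass positive_label"
    )


def _knn_votes(train_z: np.ndarray, train_pos: np.ndarray, test_z: np.ndarray, k: int):
    """Core vote: features x samples arrays, already standardised.

    Distance ties are broken by the lowest training-sample index (stable
    sort); an even split of votes is resolved by the nearest neighbour's
    label. Returns (predicted_positive, vote_fraction) per test sample.
    """
    n_train = train_z.shape[1]
    if k > n_train:
        raise ValueError(f"k={k} exceeds the {n_train} available reference samples")
    preds = np.empty(test_z.shape[1], dtype=bool)
    votes = np.empty(test_z.shape[1], dtype=float)
    for j in range(test_z.shape[1]):
        d2 = ((train_z - test_z[:, [j]]) ** 2).sum(axis=0)
        nn = np.argsort(d2, kind="stable")[:k]
        pos = train_pos[nn]
        frac = pos.mean()
        if frac > 0.5:
            preds[j] = True
        elif frac < 0.5:
            preds[j] = False
        else:  # even k split: nearest neighbour decides
            preds[j] = pos[0]
        votes[j] = frac
    return preds, votes


def _signature_features(signature: SignatureModel, *matrices: ExpressionMatrix) -> list[str]:
    present = [p for p in signature.probe_ids
               if all(p in m.values.index for m in matrices)]
    if not present:
        raise ValueError("no signature probes present in the expression data")
    if len(present) < 0.5 * len(signature):
        raise ValueError(
            f"only {len(present)} of {len(signature)} signature probes present (<50%); "
            "map the signature onto this platform first"
        )
    return present


def knn_classify_external(
    reference: ExpressionMatrix,
    reference_labels: SampleTable,
    test: ExpressionMatrix,
    signature: SignatureModel,
    k: int = 5,
    positive_label: str | None = None,
    test_labels: SampleTable | None = None,
    exclude_self: bool = False,
) -> ClassificationResult:
    """Classify test samples against an independent reference expression space.

    Each test sample is z-scored per probe with the reference mean and
    standard deviation (ddof=1) and assigned the majority label of its k
    nearest reference samples. The reference is never re-fit per test
    sample. ``exclude_self`` drops a reference sample sharing the test
    sample's id from its own neighbour search (useful when classifying the
    reference cohort against itself).
    """
    if k % 2 == 0:
        warnings.warn("even k can produce vote ties; ties fall to the nearest neighbour")
    features = _signature_features(signature, reference, test)
    y = reference_labels.groups_for(reference.sample_ids)
    if positive_label is None:
        positive_label = infer_positive_label(y.unique())
    negative = [lv for lv in set(y) if lv != positive_label]
    if len(negative) != 1:
        raise ValueError("reference labels must have exactly two levels")
    negative = negative[0]

    ref = reference.values.loc[features].to_numpy(dtype=float)
    mu = ref.mean(axis=1, keepdims=True)
    sd = ref.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    ref_z = (ref - mu) / sd
    test_z = (test.values.loc[features].to_numpy(dtype=float) - mu) / sd

    ref_pos = (y == positive_label).to_numpy()
    if exclude_self:
        ref_ids = list(reference.sample_ids)
        preds = np.empty(test_z.shape[1], dtype=bool)
        votes = np.empty(test_z.shape[1], dtype=float)
        for j, sid in enumerate(test.sample_ids):
            keep = np.array([rid != sid for rid in ref_ids])
            p, v = _knn_votes(ref_z[:, keep], ref_pos[keep], test_z[:, [j]], k)
            preds[j], votes[j] = p[0], v[0]
    else:
        preds, votes = _knn_votes(ref_z, ref_pos, test_z, k)
    frame = pd.DataFrame(
        {
            "predicted_label": np.where(preds, positive_label, negative),
            "vote_score": votes,
        },
        index=pd.Index(test.sample_ids, name="sample_id"),
    )
    if test_labels is not None:
        frame["true_label"] = test_labels.groups_for(test.sample_ids).to_numpy()
    return ClassificationResult(frame, k=k, positive_label=positive_label)


def knn_classify_loocv(
    matrix: ExpressionMatrix,
    labels: SampleTable,
    signature: SignatureModel,
    k: int = 5,
    positive_label: str | None = None,
) -> ClassificationResult:
    """Leave-one-out classification within a single cohort.

    Each sample is held out in turn and classified against the remaining
    n-1 samples; per-probe z-scoring uses only the retained samples.
    """
    if k % 2 == 0:
        warnings.warn("even k can produce vote ties; ties fall to the nearest neighbour")
    features = _signature_features(signature, matrix)
    y = labels.groups_for(matrix.sample_ids)
    if positive_label is None:
        positive_label = infer_positive_label(y.unique())
    negative = [lv for lv in set(y) if lv != positive_label]
    if len(negative) != 1:
        raise ValueError("labels must have exactly two levels")
    negative = negative[0]
    counts = y.value_counts()
    if (counts < k + 1).any():
        raise ValueError(f"each group needs at least k+1={k + 1} samples, got {dict(counts)}")

    X = matrix.values.loc[features].to_numpy(dtype=float)
    pos = (y == positive_label).to_numpy()
    n = X.shape[1]
    preds = np.empty(n, dtype=bool)
    votes = np.empty(n, dtype=float)
    for i in range(n):
        keep = np.arange(n) != i
        tr = X[:, keep]
        mu = tr.mean(axis=1, keepdims=True)
        sd = tr.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        p, v = _knn_votes((tr - mu) / sd, pos[keep], (X[:, [i]] - mu) / sd, k)
        preds[i], votes[i] = p[0], v[0]
    frame = pd.DataFrame(
        {
            "predicted_label": np.where(preds, positive_label, negative),
            "vote_score": votes,
            "true_label": y.to_numpy(),
        },
        index=pd.Index(matrix.sample_ids, name="sample_id"),
    )
    return ClassificationResult(frame, k=k, positive_label=positive_label)


def roc_auc(result: ClassificationResult) -> RocCurve:
    """ROC curve over vote scores; AUC by the rank (Mann-Whitney) formula,
    ties contributing 1/2."""
    if not result.has_truth:
        raise ValueError("ROC needs true labels")
    truth = (result.predictions["true_label"] == result.positive_label).to_numpy()
    scores = result.predictions["vote_score"].to_numpy(dtype=float)
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    ranks = rankdata(scores)
    u = ranks[truth].sum() - n_pos * (n_pos + 1) / 2
    auc = float(u / (n_pos * n_neg))
    fpr, tpr, thresholds = _sk_roc_curve(truth.astype(int), scores)
    return RocCurve(thresholds=thresholds, sensitivity=tpr, specificity=1 - fpr, auc=auc)


def confusion_metrics(result: ClassificationResult) -> dict[str, float | None]:
    """Sensitivity, specificity, accuracy from the 2x2 table.

    A ratio with an empty denominator (e.g. sensitivity with no positives)
    is reported as None, never as 0.
    """
    if not result.has_truth:
        raise ValueError("confusion metrics need true labels")
    p = result.predictions
    truth_pos = p["true_label"] == result.positive_label
    pred_pos = p["predicted_label"] == result.positive_label
    tp = int((truth_pos & pred_pos).sum())
    fn = int((truth_pos & ~pred_pos).sum())
    tn = int((~truth_pos & ~pred_pos).sum())
    fp = int((~truth_pos & pred_pos).sum())
    n = tp + fn + tn + fp
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else None,
        "specificity": tn / (tn + fp) if tn + fp else None,
        "accuracy": (tp + tn) / n if n else None,
    }
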