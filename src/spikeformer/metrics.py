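"""Per-segment classification metrics and per-recording AHI aggregation.

Per-segment: accuracy, sensitivity (recall on the apnea class), specificity,
precision, F1, rank-based AUC and Cohen's kappa from the 2x2 confusion
matrix.  Per-recording: the apnea-hypopnea index

    AHI = 60 * N / T

(N apneic minutes out of T labelled minutes) determines the screening call —
a recording is labelled sleep-apnea when AHI strictly exceeds 5 events/hour —
and the Pearson correlation between predicted and true AHI lists measures
recording-level agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr, rankdata

__all__ = [
    "per_segment_metrics",
    "rank_auc",
    "compute_ahi",
    "classify_recording",
    "RecordingReport",
    "make_recording_report",
    "per_recording_eval",
    "AHI_THRESHOLD",
]

AHI_THRESHOLD = 5.0  # events/hour; strictly greater -> sleep apnea


def rank_auc(y_true: np.ndarray, y_score: np.ndarray) -> float | None:
    """ROC AUC via the Mann-Whitney rank statistic; None if one class only."""
    y_true = np.asarray(y_true).astype(int)
    y_score = np.asarray(y_score, dtype=float)
    n_pos = int(y_true.sum())
    n_neg = len(y_true) - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(y_score)
    u = ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def per_segment_metrics(
    y_true: np.ndarray, y_prob: np.ndarray, threshold: float = 0.5
) -> dict[str, float | None]:
    """Binary classification metrics at the given decision threshold.

    ``y_prob`` are apnea probabilities in [0, 1].  AUC is reported as None
    when ``y_true`` contains a single class.
    """
    y_true = np.asarray(y_true).astype(int).ravel()
    y_prob = np.asarray(y_prob, dtype=float).ravel()
    if not np.all((y_true == 0) | (y_true == 1)):
        raise ValueError("y_true must be binary")
    if np.any(y_prob < 0) or np.any(y_prob > 1):
        raise ValueError("y_prob must lie in [0, 1]")
    y_pred = (y_prob >= threshold).astype(int)
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    n = tp + tn + fp + fn
    acc = (tp + tn) / n
    sen = tp / (tp + fn) if tp + fn else None
    spe = tn / (tn + fp) if tn + fp else None
    pre = tp / (tp + fp) if tp + fp else None
    f1 = (
        2 * pre * sen / (pre + sen)
        if pre is not None and sen is not None and (pre + sen) > 0
        else None
    )
    # Cohen's kappa: (p_o - p_e) / (1 - p_e) with marginal chance agreement
    p_o = acc
    p_e = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / n**2
    kappa = 0.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    return {
        "acc": acc,
        "sen": sen,
        "spe": spe,
        "pre": pre,
        "f1": f1,
        "auc": rank_auc(y_true, y_prob),
        "kappa": kappa,
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
    }


def compute_ahi(T: int, N: int) -> float:
    """Apnea-hypopnea index AHI = 60 * N / T (events per hour)."""
    if T <= 0:
        raise ValueError("T must be positive")
    if not (0 <= N <= T):
        raise ValueError("N must satisfy 0 <= N <= T")
    return 60.0 * N / T


def classify_recording(ahi: float, threshold: float = AHI_THRESHOLD) -> str:
    """Screening call: 'SA' when AHI strictly exceeds the threshold, else 'normal'."""
    return "SA" if ahi > threshold else "normal"


@dataclass
class RecordingReport:
    """Per-recording aggregation of per-minute predictions."""

    record_id: str
    T: int
    N: int
    ahi: float
    call: str
    true_ahi: float | None = None
    true_call: str | None = None


def make_recording_report(
    record_id: str,
    y_pred_minutes: np.ndarray,
    y_true_minutes: np.ndarray | None = None,
) -> RecordingReport:
    y_pred = np.asarray(y_pred_minutes).astype(int)
    T, N = len(y_pred), int(y_pred.sum())
    ahi = compute_ahi(T, N)
    true_ahi = true_call = None
    if y_true_minutes is not None:
        yt = np.asarray(y_true_minutes).astype(int)
        true_ahi = compute_ahi(len(yt), int(yt.sum()))
        true_call = classify_recording(true_ahi)
    return RecordingReport(record_id, T, N, ahi, classify_recording(ahi),
                           true_ahi, true_call)


def per_recording_eval(reports: list[RecordingReport]) -> dict[str, float | None]:
    """Recording-level accuracy/sensitivity/specificity/AUC and AHI correlation.

    The SA call is the positive class.  Pearson correlation between predicted
    and true AHI is None when either list has zero variance.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 recordings")
    if any(r.true_call is None for r in reports):
        raise ValueError("reports lack ground truth")
    y_true = np.array([1 if r.true_call == "SA" else 0 for r in reports])
    y_pred = np.array([1 if r.call == "SA" else 0 for r in reports])
    pred_ahi = np.array([r.ahi for r in reports], dtype=float)
    true_ahi = np.array([r.true_ahi for r in reports], dtype=float)
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    if pred_ahi.std() == 0 or true_ahi.std() == 0:
        corr = None
    else:
        corr = float(pearsonr(true_ahi, pred_ahi).statistic)
    return {
        "acc": (tp + tn) / len(reports),
        "sen": tp / (tp + fn) if tp + fn else None,
        "spe": tn / (tn + fp) if tn + fp else None,
        "auc": rank_auc(y_true, pred_ahi),
        "corr": corr,
    }
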