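"""Validation statistics: segmentation error (RMSE/MAE per curve and per
scenario) and layer-count classification metrics with ROC/AUC.

The positive class of the two/three-layer classification is ``three_layers``
(the sensitivity measures how many genuinely three-layer images are
recognised as such). AUC uses the Mann-Whitney pairwise formulation with
ties counted one half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import LayerCurve, shared_cols

POSITIVE = "three_layers"
CLASSES = ("three_layers", "two_layers")


def rmse(pred, truth) -> float:
    """Root mean squared difference."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("length mismatch")
    if pred.size == 0:
        raise ValueError("empty vectors")
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


def mae(pred, truth) -> float:
    """Mean absolute difference."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("length mismatch")
    if pred.size == 0:
        raise ValueError("empty vectors")
    return float(np.mean(np.abs(pred - truth)))


def curve_error(pred: LayerCurve, truth: LayerCurve) -> tuple[float, float, int]:
    """Per-column row error of a predicted boundary against a reference.

    Returns (rmse, mae, n_excluded) where n_excluded counts reference
    columns outside the predicted span.
    """
    cols = shared_cols(pred, truth)
    if cols.size == 0:
        raise ValueError("curves do not overlap")
    diff = pred.row_at(cols) - truth.row_at(cols)
    excluded = len(truth) - cols.size
    return rmse(diff, np.zeros_like(diff)), mae(diff, np.zeros_like(diff)), int(excluded)


@dataclass
class EvalReport:
    """Aggregate validation report over a ground-truthed image set."""

    rmse_px: float
    mae_px: float
    per_scenario: dict[str, dict[str, float]]
    confusion: dict[str, int]
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    auc: float = float("nan")
    n_images: int = 0
    n_failed: int = 0
    notes: list[str] = field(default_factory=list)


def classification_metrics(predicted: list[str], truth: list[str]) -> dict:
    """Confusion counts and the standard rates; zero-denominator rates NaN."""
    if len(predicted) != len(truth):
        raise ValueError("length mismatch")
    for lab in list(predicted) + list(truth):
        if lab not in CLASSES:
            raise ValueError(f"unknown class label {lab!r}")
    p = np.asarray(predicted)
    t = np.asarray(truth)
    tp = int(np.sum((p == POSITIVE) & (t == POSITIVE)))
    fp = int(np.sum((p == POSITIVE) & (t != POSITIVE)))
    tn = int(np.sum((p != POSITIVE) & (t != POSITIVE)))
    fn = int(np.sum((p != POSITIVE) & (t == POSITIVE)))

    def rate(num, den):
        return float(num) / den if den else float("nan")

    return {
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "accuracy": rate(tp + tn, tp + tn + fp + fn),
        "sensitivity": rate(tp, tp + fn),
        "specificity": rate(tn, tn + fp),
        "ppv": rate(tp, tp + fp),
        "npv": rate(tn, tn + fn),
    }


def roc_auc(scores, truth: list[str]) -> float:
    """Mann-Whitney AUC of a continuous score for the positive class."""
    scores = np.asarray(scores, dtype=float)
    t = np.asarray(truth)
    pos = scores[t == POSITIVE]
    neg = scores[t != POSITIVE]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (pos.size * neg.size))


def evaluate_batch(results: list[dict]) -> EvalReport:
    """Aggregate per-image results into a report.

    Each entry carries ``scenario``, ``truth_class``, ``pred_class`` (or
    None for a failed image), optional ``score`` and a list of per-curve
    (rmse, mae) ``errors``.
    """
    preds, truths, scores = [], [], []
    n_failed = 0
    sq, ab, n_pts = 0.0, 0.0, 0
    per_scen: dict[str, list[tuple[float, float, int]]] = {}
    for r in results:
        truths.append(r["truth_class"])
        if r.get("pred_class") is None:
            n_failed += 1
            # a failed image counts as a miss of the positive class
            preds.append("two_layers")
        else:
            preds.append(r["pred_class"])
        if "score" in r:
            scores.append(r["score"])
        for e_rmse, e_mae, n in r.get("errors", []):
            sq += e_rmse ** 2 * n
            ab += e_mae * n
            n_pts += n
            per_scen.setdefault(r["scenario"], []).append((e_rmse, e_mae, n))
    cm = classification_metrics(preds, truths)
    auc = float("nan")
    if scores and len(set(truths)) == 2 and len(scores) == len(truths):
        auc = roc_auc(scores, truths)
    scen_out = {}
    for scen, entries in per_scen.items():
        w = sum(n for _, _, n in entries)
        scen_out[scen] = {
            "rmse": float(np.sqrt(sum(r ** 2 * n for r, _, n in entries) / w)),
            "mae": float(sum(m * n for _, m, n in entries) / w),
            "n_points": w,
        }
    return EvalReport(
        rmse_px=float(np.sqrt(sq / n_pts)) if n_pts else float("nan"),
        mae_px=float(ab / n_pts) if n_pts else float("nan"),
        per_scenario=scen_out,
        confusion={k: cm[k] for k in ("tp", "fp", "tn", "fn")},
        accuracy=cm["accuracy"], sensitivity=cm["sensitivity"],
        specificity=cm["specificity"], ppv=cm["ppv"], npv=cm["npv"],
        auc=auc, n_images=len(results), n_failed=n_failed,
    )
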