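"""Classification metrics at patch and image level.

Given a prediction table (one row per patch or image with true label,
predicted label, and a class-probability vector) this module computes
overall accuracy, per-class sensitivity/recall, specificity, precision
and F1 from the confusion matrix, plus one-vs-rest ROC AUC per class
and their macro (default) or micro average as the overall AUC. Recall
equals sensitivity by definition; both are reported under "SEN/R".
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, roc_auc_score

from .config import CLASSES

SCORE_COLUMNS = tuple(f"score_{c}" for c in CLASSES)


def make_prediction_table(
    unit_ids,
    true_labels,
    predicted_labels,
    scores,
    level: str = "image",
) -> pd.DataFrame:
    """Assemble the canonical prediction table."""
    scores = np.asarray(scores, dtype=np.float64)
    table = pd.DataFrame(
        {
            "unit_id": list(unit_ids),
            "true_label": list(true_labels),
            "predicted_label": list(predicted_labels),
        }
    )
    for j, col in enumerate(SCORE_COLUMNS):
        table[col] = scores[:, j]
    table.attrs["level"] = level
    return table


def compute_metrics(table: pd.DataFrame, auc_average: str = "macro") -> dict[str, Any]:
    """Metric report keyed like a results table: metric -> class -> value.

    Per-class values for a class absent from the ground truth are
    reported as NaN (missing), not 0. A class never predicted gets
    precision (and F1) 0 with a warning.
    """
    if len(table) == 0:
        raise ValueError("empty prediction table")
    y_true = table["true_label"].to_numpy()
    y_pred = table["predicted_label"].to_numpy()
    scores = table[list(SCORE_COLUMNS)].to_numpy(dtype=np.float64)

    cm = confusion_matrix(y_true, y_pred, labels=list(CLASSES)).astype(np.float64)
    total = cm.sum()
    report: dict[str, Any] = {
        "ACC": {"Overall": float(np.trace(cm) / total)},
        "AUC": {},
        "SEN/R": {},
        "SPE": {},
        "P": {},
        "F1": {},
    }
    aucs = []
    for i, cls in enumerate(CLASSES):
        tp = cm[i, i]
        fn = cm[i, :].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        gt = tp + fn
        predicted = tp + fp
        sen = float(tp / gt) if gt > 0 else float("nan")
        spe = float(tn / (tn + fp)) if (tn + fp) > 0 else float("nan")
        if predicted > 0:
            prec = float(tp / predicted)
        else:
            warnings.warn(f"class {cls} was never predicted; reporting precision 0")
            prec = 0.0
        if np.isnan(sen) or (prec + sen) == 0:
            f1 = 0.0 if not np.isnan(sen) else float("nan")
        else:
            f1 = 2.0 * prec * sen / (prec + sen)
        report["SEN/R"][cls] = sen
        report["SPE"][cls] = spe
        report["P"][cls] = prec
        report["F1"][cls] = f1

        binary = (y_true == cls).astype(int)
        if 0 < binary.sum() < len(binary):
            auc = float(roc_auc_score(binary, scores[:, i]))
        else:
            auc = float("nan")
        report["AUC"][cls] = auc
        aucs.append(auc)

    if auc_average == "macro":
        overall_auc = float(np.mean(aucs))
    elif auc_average == "micro":
        y_bin = np.stack([(y_true == c).astype(int) for c in CLASSES], axis=1)
        overall_auc = float(roc_auc_score(y_bin, scores, average="micro"))
    else:
        raise ValueError(f"auc_average must be 'macro' or 'micro', got {auc_average!r}")
    report["AUC"]["Overall"] = overall_auc
    return report


def format_report(report: dict[str, Any]) -> str:
    """Human-readable rendering of a metric report."""
    lines = [f"{'Index':<8}{'Class':<10}{'Value':>8}"]
    for metric, values in report.items():
        for cls, val in values.items():
            shown = "missing" if isinstance(val, float) and np.isnan(val) else f"{val:.4f}"
            lines.append(f"{metric:<8}{cls:<10}{shown:>8}")
    return "\n".join(lines)


def save_report(report: dict[str, Any], path: str | Path) -> None:
    def _clean(v):
        if isinstance(v, float) and np.isnan(v):
            return None
        return v

    cleaned = {m: {c: _clean(v) for c, v in vals.items()} for m, vals in report.items()}
    Path(path).write_text(json.dumps(cleaned, indent=2))
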