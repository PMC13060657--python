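"""One-vs-rest evaluation metrics and the score + one-hot embedding matrix.

Nine metrics per subtype (accuracy, precision, sensitivity, specificity, AUC,
Jaccard, MCC, G-measure, F1), each computed one-vs-rest from hard predictions
except AUC, which uses the subtype's continuous score as discriminant with
midrank tie handling.  Metrics with a zero denominator are reported as NaN
("undefined") with a warning, never silently as 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import confusion_matrix

from .data_io import DataError
from .classify import SubtypeScoreMatrix

logger = logging.getLogger("ranktype")

METRIC_NAMES = (
    "accuracy", "precision", "sensitivity", "specificity", "auc",
    "jaccard", "mcc", "g_measure", "f1",
)


@dataclass
class MetricsReport:
    """Per-subtype one-vs-rest metrics, overall accuracy, confusion matrix."""

    per_subtype: pd.DataFrame      # subtypes x METRIC_NAMES
    overall_accuracy: float
    confusion: pd.DataFrame        # true x predicted counts

    def to_json_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "per_subtype": {
                s: {m: (None if pd.isna(v) else float(v)) for m, v in row.items()}
                for s, row in self.per_subtype.iterrows()
            },
            "confusion": {s: {t: int(v) for t, v in row.items()}
                          for s, row in self.confusion.iterrows()},
        }


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("compute_metrics: %s undefined (zero denominator)", what)
        return float("nan")
    return num / den


def auc_midrank(scores: np.ndarray, positive: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling."""
    positive = np.asarray(positive, dtype=bool)
    n_pos = int(positive.sum())
    n_neg = len(positive) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    r = rankdata(scores, method="average")
    return float((r[positive].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_metrics(truth, result: SubtypeScoreMatrix) -> MetricsReport:
    """Evaluate hard predictions (and score-based AUC) against true labels.

    ``truth`` maps sample_id -> subtype and must cover every scored sample.
    Subtypes absent from the truth get NaN one-vs-rest metrics with a warning.
    """
    truth = dict(truth)
    missing = [s for s in result.sample_ids if s not in truth]
    if missing:
        raise DataError(f"truth lacks label(s) for sample(s): {', '.join(missing[:10])}")
    subtypes = list(result.subtypes)
    unknown = sorted({truth[s] for s in result.sample_ids} - set(subtypes))
    if unknown:
        raise DataError(f"truth label(s) outside the model's subtypes: {', '.join(unknown)}")

    y_true = [truth[s] for s in result.sample_ids]
    y_pred = list(result.predictions)
    cm = confusion_matrix(y_true, y_pred, labels=subtypes)
    total = cm.sum()
    overall = float(np.trace(cm) / total)

    rows = {}
    for k, s in enumerate(subtypes):
        tp = int(cm[k, k])
        fn = int(cm[k, :].sum() - tp)
        fp = int(cm[:, k].sum() - tp)
        tn = int(total - tp - fn - fp)
        if tp + fn == 0:
            logger.warning("compute_metrics: subtype %s absent from truth; metrics undefined", s)
            rows[s] = {m: float("nan") for m in METRIC_NAMES}
            continue
        precision = _safe_div(tp, tp + fp, f"{s} precision")
        sensitivity = _safe_div(tp, tp + fn, f"{s} sensitivity")
        specificity = _safe_div(tn, tn + fp, f"{s} specificity")
        mcc_den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        mcc = _safe_div(tp * tn - fp * fn, mcc_den, f"{s} MCC")
        f1 = float("nan") if (math.isnan(precision) or precision + sensitivity == 0) \
            else 2 * precision * sensitivity / (precision + sensitivity)
        g = float("nan") if math.isnan(precision) else math.sqrt(precision * sensitivity)
        rows[s] = {
            "accuracy": (tp + tn) / total,
            "precision": precision,
            "sensitivity": sensitivity,
            "specificity": specificity,
            "auc": auc_midrank(result.scores[:, k], np.array([t == s for t in y_true])),
            "jaccard": _safe_div(tp, tp + fp + fn, f"{s} Jaccard"),
            "mcc": mcc,
            "g_measure": g,
            "f1": f1,
        }
    per_subtype = pd.DataFrame.from_dict(rows, orient="index")[list(METRIC_NAMES)]
    confusion = pd.DataFrame(cm, index=pd.Index(subtypes, name="true"),
                             columns=pd.Index(subtypes, name="predicted"))
    return MetricsReport(per_subtype=per_subtype, overall_accuracy=overall,
                         confusion=confusion)


def visualization_matrix(result: SubtypeScoreMatrix) -> np.ndarray:
    """Samples x 2C matrix: continuous scores then one-hot predicted subtype.

    Concatenating prediction confidence with the discrete assignment lets the
    2-D embedding separate subtype clusters even when raw scores are close.
    """
    c = len(result.subtypes)
    onehot = np.zeros((len(result.sample_ids), c))
    col = {s: k for k, s in enumerate(result.subtypes)}
    for i, p in enumerate(result.predictions):
        onehot[i, col[p]] = 1.0
    return np.hstack([result.scores, onehot])


def embed_2d(M: np.ndarray, perplexity: float = 30.0, seed: int = 0) -> np.ndarray:
    """Deterministic 2-D t-SNE embedding of a visualization matrix."""
    from sklearn.manifold import TSNE

    M = np.asarray(M, dtype=float)
    n = M.shape[0]
    if n < 3 * perplexity + 1:
        raise DataError(
            f"t-SNE needs >= 3*perplexity+1 samples ({int(3 * perplexity + 1)}), got {n}; "
            f"use a smaller perplexity"
        )
    if np.ptp(M, axis=0).max() == 0:
        raise DataError("input matrix is constant; embedding is degenerate")
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=int(seed),
                init="pca")
    coords = tsne.fit_transform(M)
    if not np.isfinite(coords).all():
        raise DataError("t-SNE produced non-finite coordinates")
    return coords


def plot_embedding(coords: np.ndarray, colors, path, title: str = "") -> None:
    """Scatter the 2-D embedding coloured by a per-sample category."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = list(colors)
    fig, ax = plt.subplots(figsize=(6, 5))
    for cat in sorted(set(colors)):
        idx = [i for i, c in enumerate(colors) if c == cat]
        ax.scatter(coords[idx, 0], coords[idx, 1], s=12, label=str(cat), alpha=0.8)
    ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
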