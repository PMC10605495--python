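"""Classifier metrics and the transferability-corrected performance score.

The central quantity is the transfer score

    s_XY = (AUC_PR,X + AUC_PR,Y) / 2 − |AUC_PR,X − AUC_PR,Y|

for a model trained on dataset X and tested on dataset Y. It rewards
signatures that perform both *well* and *consistently* across datasets:
algebraically s = min(a, b) − |a − b| / 2, so the score never exceeds the
worse of the two PR AUCs and equals it only when they agree.

PR AUC is step-wise average precision (no trapezoidal interpolation, which
over-estimates PR curves); ROC AUC is the Mann–Whitney statistic with
half-credit for ties. Both delegate to scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_auc_score

from .formula import FormulaModel, evaluate

__all__ = [
    "MetricError",
    "MetricsReport",
    "ResponseSurface",
    "pr_auc",
    "roc_auc",
    "threshold_metrics",
    "compute_metrics",
    "transfer_score",
    "response_surface",
    "round_half_up",
    "pr_curve_points",
]


class MetricError(ValueError):
    """Metric undefined for the given labels (e.g. a single class present)."""


def _check_inputs(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise MetricError(f"labels {y.shape} and scores {s.shape} must be equal-length 1-d")
    if np.unique(y).size < 2:
        raise MetricError("both classes must be present; metric undefined on a single class")
    return y, s


def pr_auc(labels, scores) -> float:
    """Area under the precision–recall curve (step-wise average precision)."""
    y, s = _check_inputs(labels, scores)
    return float(average_precision_score(y, s))


def roc_auc(labels, scores) -> float:
    """ROC AUC = Mann–Whitney U / (n1*n0), half-credit for score ties."""
    y, s = _check_inputs(labels, scores)
    return float(roc_auc_score(y, s))


def threshold_metrics(labels, scores, threshold: float = 0.5) -> tuple[float, float, float]:
    """(accuracy, precision, recall) at a hard threshold.

    Precision is NaN when nothing is predicted positive; recall is NaN when no
    positives exist. Accuracy is always defined (single-class input tolerated).
    """
    y = np.asarray(labels, dtype=float)
    s = np.asarray(scores, dtype=float)
    pred = (s >= threshold).astype(float)
    tp = float(np.sum((pred == 1) & (y == 1)))
    accuracy = float(np.mean(pred == y))
    precision = tp / pred.sum() if pred.sum() > 0 else float("nan")
    recall = tp / y.sum() if y.sum() > 0 else float("nan")
    return accuracy, precision, recall


@dataclass
class MetricsReport:
    """Performance of one model's scores on one labeled slice."""

    pr_auc: float
    roc_auc: float
    accuracy: float
    precision: float
    recall: float
    n_cells: int
    positive_fraction: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def compute_metrics(labels, scores, threshold: float = 0.5) -> MetricsReport:
    y, s = _check_inputs(labels, scores)
    accuracy, precision, recall = threshold_metrics(y, s, threshold)
    return MetricsReport(
        pr_auc=float(average_precision_score(y, s)),
        roc_auc=float(roc_auc_score(y, s)),
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        n_cells=int(y.size),
        positive_fraction=float(np.mean(y == 1)),
    )


def transfer_score(auc_train: float, auc_test: float) -> float:
    """Transferability-corrected performance score s_XY.

    Mean of the two PR AUCs penalized by their absolute difference; symmetric
    in its arguments. A 0.7/0.9 train/test pair scores 0.6, while a uniform
    0.8 scores 0.8 — high *and* stable performance is what transfers.
    """
    return (auc_train + auc_test) / 2.0 - abs(auc_train - auc_test)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero toward +inf (display rounding: 0.935 -> 0.94).

    The value is first snapped to 9 decimals so that scores assembled from
    2-decimal AUCs (exact multiples of 0.005) sit exactly on the boundary
    rather than one float ulp below it.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(f"{x:.9f}").quantize(q, rounding=ROUND_HALF_UP))


def pr_curve_points(labels, scores) -> "np.ndarray":
    """(precision, recall, threshold) triples of the PR curve, for export."""
    y, s = _check_inputs(labels, scores)
    precision, recall, thresholds = precision_recall_curve(y, s)
    thr = np.append(thresholds, np.nan)
    return np.column_stack([precision, recall, thr])


# ---------------------------------------------------------------------------
# response surfaces (median-conditioned partial dependence)


@dataclass
class ResponseSurface:
    """Predicted disease probability as 1–2 genes sweep their observed range
    while the model's remaining genes sit at their per-slice median."""

    varied_features: list[str]
    grid: list[np.ndarray]  # one axis per varied feature
    fixed_values: dict[str, float]
    probabilities: np.ndarray  # (n,) for 1 feature, (n, n) for 2


def response_surface(
    model: FormulaModel, slice_, varied: list[str] | str, n_points: int = 50
) -> ResponseSurface:
    if isinstance(varied, str):
        varied = [varied]
    feats = model.features
    if feats:  # intercept-only models accept any slice gene (flat surface)
        unknown = [v for v in varied if v not in feats]
        if unknown:
            raise ValueError(f"varied feature(s) {unknown} not in model features {feats}")
    if not 1 <= len(varied) <= 2:
        raise ValueError("response surfaces support 1 or 2 varied features")
    if slice_.n_cells < 1:
        raise ValueError("slice is empty")

    span = sorted(set(feats) | set(varied))
    Xs = slice_.feature_matrix(span)
    col = {g: Xs[:, j] for j, g in enumerate(span)}
    axes = [np.linspace(col[v].min(), col[v].max(), n_points) for v in varied]
    fixed = {g: float(np.median(col[g])) for g in feats if g not in varied}

    if not feats:
        shape = (n_points,) if len(varied) == 1 else (n_points, n_points)
        probs = np.broadcast_to(evaluate(model, np.zeros((1, 0))), (int(np.prod(shape)),))
        return ResponseSurface(varied_features=list(varied), grid=axes,
                               fixed_values=fixed, probabilities=probs.reshape(shape).copy())

    if len(varied) == 1:
        X = np.empty((n_points, len(feats)))
        for j, g in enumerate(feats):
            X[:, j] = axes[0] if g == varied[0] else fixed[g]
        probs = evaluate(model, X)
    else:
        g0, g1 = np.meshgrid(axes[0], axes[1], indexing="ij")
        X = np.empty((n_points * n_points, len(feats)))
        for j, g in enumerate(feats):
            if g == varied[0]:
                X[:, j] = g0.ravel()
            elif g == varied[1]:
                X[:, j] = g1.ravel()
            else:
                X[:, j] = fixed[g]
        probs = evaluate(model, X).reshape(n_points, n_points)
    return ResponseSurface(
        varied_features=list(varied), grid=axes, fixed_values=fixed, probabilities=probs
    )


def plot_response_surface(surface: ResponseSurface, path: str | None = None):
    """Optional matplotlib rendering (line for 1 feature, heatmap for 2)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    if len(surface.varied_features) == 1:
        ax.plot(surface.grid[0], surface.probabilities)
        ax.set_xlabel(surface.varied_features[0])
        ax.set_ylabel("P(disease)")
    else:
        im = ax.pcolormesh(surface.grid[0], surface.grid[1], surface.probabilities.T,
                           shading="auto", vmin=0, vmax=1)
        fig.colorbar(im, ax=ax, label="P(disease)")
        ax.set_xlabel(surface.varied_features[0])
        ax.set_ylabel(surface.varied_features[1])
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
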