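"""Classification accuracy assessment: error matrices, overall / producer's /
user's accuracy and Cohen's kappa.

Orientation convention, stated once and labelled on every output: **rows are
predicted classes, columns are ground truth**.  Producer's accuracy is the
per-class recall against the truth column; user's accuracy is the per-class
precision along the prediction row.  Undefined ratios (an empty margin) are
reported as missing (NaN), never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ErrorMatrix",
    "matrix_stats",
    "cohen_kappa",
    "kappa_band",
    "KappaResult",
]


@dataclass
class ErrorMatrix:
    """Square prediction-vs-truth count table (rows = predicted, cols = truth)."""

    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("error matrix must be square")
        if c.shape[0] != len(self.labels):
            raise ValueError("labels must match matrix dimension")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.number):
            raise ValueError("counts must be non-negative numbers")
        if c.sum() == 0:
            raise ValueError("error matrix is all zero")
        self.counts = c.astype(np.int64)

    @classmethod
    def from_pairs(cls, predicted, truth, labels: tuple[str, ...] | None = None) -> "ErrorMatrix":
        predicted = np.asarray(predicted)
        truth = np.asarray(truth)
        if len(predicted) != len(truth):
            raise ValueError("predicted and truth must have equal length")
        if labels is None:
            labels = tuple(sorted(set(predicted) | set(truth)))
        idx = {lab: i for i, lab in enumerate(labels)}
        m = np.zeros((len(labels), len(labels)), dtype=np.int64)
        for p, t in zip(predicted, truth):
            m[idx[p], idx[t]] += 1
        return cls(counts=m, labels=tuple(labels))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.labels, name="predicted"),
            columns=pd.Index(self.labels, name="truth"),
        )


def matrix_stats(m: ErrorMatrix) -> dict:
    """Overall accuracy plus per-class producer's and user's accuracy (%).

    Producer's accuracy of class c = m[c, c] / column total (share of the
    truth correctly found); user's = m[c, c] / row total (share of the
    predictions that were right).  Empty margins give NaN.
    """
    c = m.counts.astype(float)
    total = c.sum()
    overall = 100.0 * np.trace(c) / total
    col = c.sum(axis=0)
    row = c.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        producers = np.where(col > 0, 100.0 * np.diag(c) / col, np.nan)
        users = np.where(row > 0, 100.0 * np.diag(c) / row, np.nan)
    return {
        "overall_accuracy_pct": float(overall),
        "producers_accuracy_pct": {lab: float(v) for lab, v in zip(m.labels, producers)},
        "users_accuracy_pct": {lab: float(v) for lab, v in zip(m.labels, users)},
        "n_samples": int(total),
    }


@dataclass
class KappaResult:
    kappa: float  # NaN when undefined (degenerate single-class margins)
    band: str


def kappa_band(kappa: float) -> str:
    """Interpretation bands: <0.20 poor, <0.40 fair, <0.60 moderate,
    <0.80 good, up to 1 very good; negative values are worse than chance."""
    if np.isnan(kappa):
        return "undefined"
    if kappa < 0:
        return "worse than chance"
    if kappa < 0.20:
        return "poor"
    if kappa < 0.40:
        return "fair"
    if kappa < 0.60:
        return "moderate"
    if kappa < 0.80:
        return "good"
    return "very good"


def cohen_kappa(m: ErrorMatrix) -> KappaResult:
    """Cohen's chance-corrected agreement κ = (p_o − p_e)/(1 − p_e).

    p_o is the observed agreement (trace/total) and p_e the agreement
    expected from the row/column margins alone.  κ = 1 for a perfect
    diagonal, 0 when the matrix equals the outer product of its margins, and
    undefined (NaN) when p_e = 1 (all mass in a single class).
    """
    c = m.counts.astype(float)
    total = c.sum()
    po = np.trace(c) / total
    pe = float((c.sum(axis=1) * c.sum(axis=0)).sum()) / total**2
    if abs(1.0 - pe) < 1e-15:
        return KappaResult(kappa=float("nan"), band="undefined")
    k = (po - pe) / (1.0 - pe)
    return KappaResult(kappa=float(k), band=kappa_band(k))
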