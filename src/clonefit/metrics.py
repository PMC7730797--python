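"""Evaluation metrics: V-measure and mean absolute CCF error.

V-measure scores a predicted partition against a reference one as the
harmonic mean of two conditional-entropy criteria computed from the label
contingency table: homogeneity (each predicted cluster contains members of
a single true cluster) and completeness (all members of a true cluster end
up together).  It is invariant to relabelling on either side and equals 1
exactly when the partitions coincide up to relabelling.

CCF accuracy is the mean absolute deviation of the predicted CCF (a
mutation inherits its assigned cluster's estimate) from the true CCF, over
all (mutation, sample) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EvaluationReport", "v_measure", "mean_abs_ccf_error", "evaluate"]


@dataclass
class EvaluationReport:
    """Summary of one clustering evaluation."""

    v_measure: float
    mean_abs_ccf_error: float
    per_mutation_ccf_error: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": ["v_measure", "mean_abs_ccf_error"],
                "value": [self.v_measure, self.mean_abs_ccf_error],
            }
        )


def _entropy(counts: np.ndarray) -> float:
    """Natural-log entropy of a count vector."""
    total = counts.sum()
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def v_measure(truth_labels, predicted_labels) -> float:
    """V-measure between two partitions, in [0, 1].

    Conventions when a partition is trivial (zero entropy): if both are
    trivial the score is 1; if exactly one is, the corresponding
    homogeneity/completeness term is taken to be 1.
    """
    truth = np.asarray(truth_labels)
    pred = np.asarray(predicted_labels)
    if truth.shape != pred.shape or truth.ndim != 1 or truth.size < 1:
        raise ValueError("label lists must be equal-length 1-d and non-empty")

    table = pd.crosstab(truth, pred).to_numpy()
    h_truth = _entropy(table.sum(axis=1))
    h_pred = _entropy(table.sum(axis=0))
    if h_truth == 0.0 and h_pred == 0.0:
        return 1.0

    total = table.sum()
    # H(truth | pred): entropy of truth within each predicted cluster
    h_truth_given_pred = sum(
        (col.sum() / total) * _entropy(col) for col in table.T
    )
    h_pred_given_truth = sum(
        (row.sum() / total) * _entropy(row) for row in table
    )
    homogeneity = 1.0 if h_truth == 0.0 else 1.0 - h_truth_given_pred / h_truth
    completeness = 1.0 if h_pred == 0.0 else 1.0 - h_pred_given_truth / h_pred
    if homogeneity + completeness == 0.0:
        return 0.0
    return float(2.0 * homogeneity * completeness / (homogeneity + completeness))


def mean_abs_ccf_error(true_ccf, predicted_ccf) -> float:
    """Mean over all (mutation, sample) pairs of |predicted - true|."""
    true_ccf = np.asarray(true_ccf, dtype=float)
    predicted_ccf = np.asarray(predicted_ccf, dtype=float)
    if true_ccf.shape != predicted_ccf.shape:
        raise ValueError(
            f"shape mismatch: {true_ccf.shape} vs {predicted_ccf.shape}"
        )
    return float(np.abs(predicted_ccf - true_ccf).mean())


def evaluate(truth_labels, predicted_labels, true_ccf,
             predicted_ccf) -> EvaluationReport:
    """Joint clustering + CCF evaluation of one fit against ground truth."""
    true_ccf = np.atleast_2d(np.asarray(true_ccf, dtype=float))
    predicted_ccf = np.atleast_2d(np.asarray(predicted_ccf, dtype=float))
    per_mutation = np.abs(predicted_ccf - true_ccf).mean(axis=1)
    return EvaluationReport(
        v_measure=v_measure(truth_labels, predicted_labels),
        mean_abs_ccf_error=mean_abs_ccf_error(true_ccf, predicted_ccf),
        per_mutation_ccf_error=per_mutation,
    )
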