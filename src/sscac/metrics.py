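"""Label-agreement metrics: optimal-mapping accuracy and NMI.

ACC maximizes the fraction of agreements over all one-to-one mappings of
predicted onto true classes (Hungarian assignment on the contingency
table).  NMI is 2 I(A,B) / (H(A) + H(B)) with natural logarithms, defined
as 0 when both entropies vanish.  Both are invariant to relabeling either
argument.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import entropy
from sklearn.metrics import mutual_info_score
from sklearn.metrics.cluster import contingency_matrix


def _check(truth, prediction):
    a = np.asarray(truth).ravel()
    b = np.asarray(prediction).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape[0]} vs {b.shape[0]}")
    if a.size == 0:
        raise ValueError("empty label vectors")
    return a, b


def acc(truth, prediction) -> float:
    """Clustering accuracy under the best one-to-one class mapping."""
    a, b = _check(truth, prediction)
    table = contingency_matrix(a, b)
    # pad to square so unmatched classes map to nothing
    k = max(table.shape)
    padded = np.zeros((k, k), dtype=table.dtype)
    padded[:table.shape[0], :table.shape[1]] = table
    rows, cols = linear_sum_assignment(padded, maximize=True)
    return float(padded[rows, cols].sum() / a.size)


def nmi(truth, prediction) -> float:
    """Normalized mutual information 2I/(H_A + H_B), natural log."""
    a, b = _check(truth, prediction)
    h_a = entropy(np.unique(a, return_counts=True)[1])
    h_b = entropy(np.unique(b, return_counts=True)[1])
    if h_a + h_b == 0:
        return 0.0
    return float(2.0 * mutual_info_score(a, b) / (h_a + h_b))
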