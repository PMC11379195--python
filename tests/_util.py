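"""Shared builders and independent oracles for the test suite."""

import math

import numpy as np
import pandas as pd

from methpanel import CANCER, NORMAL, BinaryMatrix, LabeledBetaMatrix


def make_matrix(values, labels, site_ids=None, positions=None, tissue="toy"):
    """LabeledBetaMatrix from a plain array and a label list."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = [f"P{i + 1}" for i in range(n)]
    site_ids = site_ids or [f"S{j + 1}" for j in range(p)]
    if positions is None:
        positions = pd.DataFrame(
            {"chromosome": ["chr1"] * p, "position": [str(1000 + j) for j in range(p)]},
            index=site_ids,
        )
    return LabeledBetaMatrix(
        values=pd.DataFrame(values, index=sample_ids, columns=site_ids),
        labels=pd.Series(list(labels), index=sample_ids),
        positions=positions,
        tissue=tissue,
    )


def make_binary(calls, labels, site_ids=None):
    """BinaryMatrix from a {0,1} array and a label list."""
    calls = np.asarray(calls, dtype=int)
    n, p = calls.shape
    sample_ids = [f"P{i + 1}" for i in range(n)]
    site_ids = site_ids or [f"S{j + 1}" for j in range(p)]
    positions = pd.DataFrame(
        {"chromosome": ["chr1"] * p, "position": [str(1000 + j) for j in range(p)]},
        index=site_ids,
    )
    return BinaryMatrix(
        values=pd.DataFrame(calls, index=sample_ids, columns=site_ids),
        labels=pd.Series(list(labels), index=sample_ids),
        positions=positions,
    )


def labels_from_int(y):
    return [CANCER if v else NORMAL for v in y]


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def entropy_oracle(y) -> float:
    """Binary entropy in bits by direct base-2 evaluation."""
    y = list(y)
    if not y:
        return 0.0
    p = sum(y) / len(y)
    return -sum(f * math.log2(f) for f in (p, 1 - p) if f > 0)


def best_root_oracle(X, y, allowed=None):
    """Exhaustive information-gain scan; ties break to the lowest index."""
    X = np.asarray(X)
    y = np.asarray(y)
    if allowed is None:
        allowed = np.ones(X.shape[1], dtype=bool)
    parent = entropy_oracle(y)
    best_j, best_gain = None, 0.0
    for j in range(X.shape[1]):
        if not allowed[j]:
            continue
        gain = parent
        for side in (0, 1):
            part = y[X[:, j] == side]
            gain -= len(part) / len(y) * entropy_oracle(part)
        if gain > best_gain + 1e-12:
            best_j, best_gain = j, gain
    return best_j, best_gain


def auc_concordance_oracle(scores, y) -> float:
    """AUC as the fraction of (positive, negative) pairs where the positive
    outranks the negative, ties counted half."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=bool)
    pos = scores[y]
    neg = scores[~y]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))
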