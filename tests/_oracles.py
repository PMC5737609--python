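"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written in plain Python / raw numpy, without
reusing the package's vectorised code paths.
"""

from __future__ import annotations

import itertools

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def brute_force_window_score(freqs, info, window: str) -> float:
    """Info-weighted similarity computed position by position with dicts."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    current = lo = hi = 0.0
    for i, base in enumerate(window):
        weights = [info[i] * freqs[i][b] for b in range(4)]
        if base in idx:
            current += info[i] * freqs[i][idx[base]]
        else:
            current += sum(weights) / 4.0
        lo += min(weights)
        hi += max(weights)
    if hi - lo <= 1e-12:
        return 1.0
    return (current - lo) / (hi - lo)


def brute_force_scan(freqs, info, sequence: str, cutoff: float):
    """All (offset, strand, score) hits by exhaustive window enumeration."""
    L = len(freqs)
    hits = []
    for offset in range(len(sequence) - L + 1):
        window = sequence[offset : offset + L]
        for strand, w in (("+", window), ("-", revcomp(window))):
            score = brute_force_window_score(freqs, info, w)
            if score >= cutoff:
                hits.append((offset, strand, score))
    return hits


def exhaustive_best_split(X: np.ndarray, y: np.ndarray, minbucket: int):
    """Best (column, threshold) by trying every midpoint split directly."""
    n = len(y)
    best = None  # (gain, col, threshold)
    for j in range(X.shape[1]):
        values = sorted(set(X[:, j]))
        for a, b in zip(values, values[1:]):
            thr = (a + b) / 2.0
            left = X[:, j] < thr
            nl = int(left.sum())
            if nl < minbucket or n - nl < minbucket:
                continue
            sse_parent = float(((y - y.mean()) ** 2).sum())
            sse_children = float(((y[left] - y[left].mean()) ** 2).sum())
            sse_children += float(((y[~left] - y[~left].mean()) ** 2).sum())
            gain = sse_parent - sse_children
            if gain <= 1e-12:
                continue
            if best is None or gain > best[0] + 1e-9:
                best = (gain, j, thr)
    return best


def exhaustive_gcv_subset(B: np.ndarray, y: np.ndarray, penalty: float):
    """Best-GCV subset of basis columns (column 0, the intercept, always kept).

    Returns (subset indices, gcv).  Least squares via numpy lstsq, independent
    of the package's Gram-matrix path.
    """
    n, k = B.shape
    best = None
    for r in range(k):
        for combo in itertools.combinations(range(1, k), r):
            idx = (0,) + combo
            sub = B[:, idx]
            beta, *_ = np.linalg.lstsq(sub, y, rcond=None)
            rss = float(((y - sub @ beta) ** 2).sum())
            n_terms = len(idx)
            m_eff = n_terms + penalty * (n_terms - 1) / 2.0
            if m_eff >= n:
                continue
            score = (rss / n) / (1.0 - m_eff / n) ** 2
            if best is None or score < best[1] - 1e-12:
                best = (idx, score)
    return best
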