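"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written the slow, obvious way (explicit
flood fill, pairwise enumeration, exhaustive subset sums) and shares no
code with the package internals it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def _offsets(ndim: int, chebyshev: bool) -> list[tuple[int, ...]]:
    if chebyshev:
        offs = [d for d in itertools.product((-1, 0, 1), repeat=ndim)
                if any(d)]
    else:
        offs = []
        for ax in range(ndim):
            for s in (-1, 1):
                d = [0] * ndim
                d[ax] = s
                offs.append(tuple(d))
    return offs


def flood_fill_components(labels: np.ndarray, chebyshev: bool = True):
    """Per-label (component count, largest size) by explicit BFS flood fill."""
    labels = np.asarray(labels)
    offs = _offsets(labels.ndim, chebyshev)
    seen = np.zeros(labels.shape, dtype=bool)
    stats: dict[int, list[int]] = {}
    for start in np.argwhere(labels > 0):
        start = tuple(start)
        if seen[start]:
            continue
        lab = labels[start]
        stack = [start]
        seen[start] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for off in offs:
                nb = tuple(c + o for c, o in zip(cur, off))
                if any(n < 0 or n >= s for n, s in zip(nb, labels.shape)):
                    continue
                if not seen[nb] and labels[nb] == lab:
                    seen[nb] = True
                    stack.append(nb)
        stats.setdefault(int(lab), []).append(size)
    return {lab: (len(sizes), max(sizes)) for lab, sizes in stats.items()}


def ith_oracle(labels: np.ndarray, chebyshev: bool = True) -> float:
    """Dispersion score evaluated from the flood-fill component statistics."""
    stats = flood_fill_components(labels, chebyshev)
    total = int((np.asarray(labels) > 0).sum())
    return 1.0 - sum(largest / count for count, largest in stats.values()) / total


def score_from_stats(stats: dict[int, list[int]]) -> float:
    """Score from explicit per-cluster component-size lists."""
    total = sum(sum(sizes) for sizes in stats.values())
    return 1.0 - sum(max(s) / len(s) for s in stats.values()) / total


def pairwise_auc(scores, labels) -> float:
    """Concordance probability over all positive-negative pairs, ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def pr_auc_sweep(scores, labels) -> float:
    """Step-interpolated PR area by an explicit threshold sweep."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    precision = tp / (tp + fp)
    recall = tp / labels.sum()
    # collapse tied scores to their final operating point
    s = scores[order]
    keep = np.concatenate([s[1:] != s[:-1], [True]])
    precision, recall = precision[keep], recall[keep]
    prev_r = 0.0
    area = 0.0
    for p, r in zip(precision, recall):
        area += (r - prev_r) * p
        prev_r = r
    return area


def exact_shapley(value_fn, x: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Shapley values by exhaustive 2^k subset enumeration.

    ``value_fn`` maps a full feature vector to a scalar; coalition S plays
    ``x`` on S and ``baseline`` elsewhere.
    """
    k = len(x)
    from math import factorial

    phi = np.zeros(k)
    idx = list(range(k))
    for j in range(k):
        rest = [i for i in idx if i != j]
        for r in range(len(rest) + 1):
            for S in itertools.combinations(rest, r):
                v = baseline.copy()
                v[list(S)] = x[list(S)]
                without = value_fn(v)
                v[j] = x[j]
                with_j = value_fn(v)
                weight = (factorial(len(S)) * factorial(k - len(S) - 1)
                          / factorial(k))
                phi[j] += weight * (with_j - without)
    return phi


def random_label_map(rng: np.random.Generator, ndim: int,
                     max_side: int, max_labels: int = 6) -> np.ndarray:
    """A random small integer label map with background holes."""
    shape = tuple(int(rng.integers(2, max_side + 1)) for _ in range(ndim))
    lab = rng.integers(0, max_labels + 1, size=shape)
    if not (lab > 0).any():
        lab.flat[0] = 1
    return lab
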