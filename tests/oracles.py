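"""Independent brute-force oracles shared across test modules.

These deliberately avoid the code paths they check: exhaustive search for
the histogram threshold, shift-union for dilation, naive O(n^3)
agglomeration for average linkage.
"""

import numpy as np
from scipy.spatial.distance import pdist, squareform


def otsu_brute_force(gray8):
    """Exhaustive search over all 256 candidate thresholds maximizing
    between-class variance; ties resolve to the lowest threshold."""
    hist = np.bincount(gray8.ravel(), minlength=256).astype(float)
    total = hist.sum()
    best_t, best_var = None, -1.0
    for t in range(256):
        w0 = hist[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: t + 1] * np.arange(t + 1)).sum() / w0
        mu1 = (hist[t + 1 :] * np.arange(t + 1, 256)).sum() / w1
        var = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
        if var > best_var + 1e-12:
            best_var, best_t = var, t
    return best_t


def dilate_shift_union(binary, iterations):
    """3x3 dilation as the logical-or of shifted copies, iterated."""
    out = binary.copy()
    for _ in range(iterations):
        acc = np.zeros_like(out)
        padded = np.pad(out, 1)
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                acc |= padded[1 + dy : 1 + dy + out.shape[0], 1 + dx : 1 + dx + out.shape[1]]
        out = acc
    return out


def average_linkage_oracle(X, p):
    """Naive agglomeration: repeatedly merge the closest cluster pair, where
    cluster distance is the mean of all original pairwise distances.

    Returns the merge history as a list of (frozenset-of-leaves, height).
    """
    D = squareform(pdist(X, metric="minkowski", p=p))
    clusters = {i: frozenset([i]) for i in range(len(X))}
    history = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ai, a in enumerate(keys):
            for b in keys[ai + 1 :]:
                d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        merged = clusters.pop(a) | clusters.pop(b)
        new_key = max(keys) + 1 + len(history)
        clusters[new_key] = merged
        history.append((merged, d))
    return history


def scipy_merge_history(Z, n):
    """Re-express a scipy linkage matrix as (leaf-set, height) merges."""
    members = {i: frozenset([i]) for i in range(n)}
    history = []
    for k, (left, right, height, _) in enumerate(Z):
        merged = members[int(left)] | members[int(right)]
        members[n + k] = merged
        history.append((merged, float(height)))
    return history
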