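"""Independent naive-loop oracles used to cross-check the vectorized
implementations. Everything here is written as plain element-wise loops
straight from the defining formulas, deliberately sharing no code with the
package."""

import math

import numpy as np


def dominance(counts):
    """counts: 2-D array taxa x samples -> (Di, fi) lists."""
    S, r = counts.shape
    N = sum(counts[i][j] for i in range(S) for j in range(r))
    di, fi = [], []
    for i in range(S):
        ni = sum(counts[i])
        f = sum(1 for j in range(r) if counts[i][j] > 0) / r
        di.append((ni / N) * f)
        fi.append(f)
    return di, fi


def profiles(counts):
    S, r = counts.shape
    P = np.zeros((S, r))
    for i in range(S):
        ni = sum(counts[i])
        for j in range(r):
            P[i][j] = counts[i][j] / ni
    return P


def niche_width(counts):
    P = profiles(counts)
    S, r = P.shape
    return [1.0 / (r * sum(P[i][j] ** 2 for j in range(r))) for i in range(S)]


def pianka(counts):
    P = profiles(counts)
    S, r = P.shape
    O = np.zeros((S, S))
    for i in range(S):
        for k in range(S):
            num = sum(P[i][j] * P[k][j] for j in range(r))
            den = math.sqrt(
                sum(P[i][j] ** 2 for j in range(r))
                * sum(P[k][j] ** 2 for j in range(r))
            )
            O[i][k] = num / den
    return O


def directed(counts):
    P = profiles(counts)
    S, r = P.shape
    A = np.zeros((S, S))
    for i in range(S):
        for k in range(S):
            A[i][k] = sum(P[i][j] * P[k][j] for j in range(r)) / sum(
                P[k][j] ** 2 for j in range(r)
            )
    return A


def delta_overlap(counts):
    A = directed(counts)
    S = A.shape[0]
    return [
        sum(A[i][k] for k in range(S) if k != i)
        - sum(A[k][i] for k in range(S) if k != i)
        for i in range(S)
    ]


def response_rate(counts):
    B = niche_width(counts)
    dO = delta_overlap(counts)
    return [b * d for b, d in zip(B, dO)]


def bray_curtis(counts):
    S, r = counts.shape
    D = np.zeros((r, r))
    for a in range(r):
        for b in range(r):
            num = sum(abs(counts[i][a] - counts[i][b]) for i in range(S))
            den = sum(counts[i][a] + counts[i][b] for i in range(S))
            D[a][b] = num / den if den > 0 else 0.0
    return D


def beta_pair(x, y):
    a = sum(1 for u, v in zip(x, y) if u > 0 and v > 0)
    b = sum(1 for u, v in zip(x, y) if u > 0 and v == 0)
    c = sum(1 for u, v in zip(x, y) if u == 0 and v > 0)
    sor = (b + c) / (2 * a + b + c)
    sim = min(b, c) / (a + min(b, c)) if (a + min(b, c)) > 0 else 0.0
    return sor, sim, sor - sim


def segmentation_objective(sq, day_groups, boundaries):
    """Within-block sum of squared distances for day-index boundaries."""
    starts = [0] + list(boundaries)
    ends = list(boundaries) + [len(day_groups)]
    total = 0.0
    for s, e in zip(starts, ends):
        idx = [i for d in range(s, e) for i in day_groups[d]]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                total += sq[idx[a]][idx[b]]
    return total


def best_segmentation_bruteforce(sq, day_groups, k):
    """Exhaustive minimum over all contiguous k-partitions (earliest ties)."""
    import itertools

    m = len(day_groups)
    best, best_bounds = None, None
    for bounds in itertools.combinations(range(1, m), k - 1):
        obj = segmentation_objective(sq, day_groups, bounds)
        if best is None or obj < best - 1e-15:
            best, best_bounds = obj, bounds
    return best, best_bounds
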