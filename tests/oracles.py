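"""Naive loop-based reference implementations.

Deliberately written with explicit Python loops and textbook formulas,
independent of the vectorized library code they cross-check.
"""

import math


def normalize_oracle(X, benefit):
    m, n = len(X), len(X[0])
    R = [[0.0] * n for _ in range(m)]
    for j in range(n):
        col = [X[i][j] for i in range(m)]
        lo, hi = min(col), max(col)
        for i in range(m):
            if benefit[j]:
                R[i][j] = (X[i][j] - lo) / (hi - lo)
            else:
                R[i][j] = (hi - X[i][j]) / (hi - lo)
    return R


def pearson_oracle(R):
    """Correlation matrix by explicit summation."""
    m, n = len(R), len(R[0])
    means = [sum(R[i][j] for i in range(m)) / m for j in range(n)]
    rho = [[0.0] * n for _ in range(n)]
    for j in range(n):
        for k in range(n):
            num = sum(
                (R[i][j] - means[j]) * (R[i][k] - means[k]) for i in range(m)
            )
            dj = math.sqrt(sum((R[i][j] - means[j]) ** 2 for i in range(m)))
            dk = math.sqrt(sum((R[i][k] - means[k]) ** 2 for i in range(m)))
            rho[j][k] = num / (dj * dk)
    return rho


def sigma_oracle(R):
    """Sample standard deviation (m-1) per column, by summation."""
    m, n = len(R), len(R[0])
    out = []
    for j in range(n):
        mean = sum(R[i][j] for i in range(m)) / m
        out.append(
            math.sqrt(
                sum((R[i][j] - mean) ** 2 for i in range(m)) / (m - 1)
            )
        )
    return out


def critic_oracle(X, benefit):
    """Full CRITIC chain with loops: returns the weight list."""
    R = normalize_oracle(X, benefit)
    rho = pearson_oracle(R)
    sigma = sigma_oracle(R)
    n = len(R[0])
    C = [sigma[j] * sum(1 - rho[j][k] for k in range(n)) for j in range(n)]
    total = sum(C)
    return [c / total for c in C]


def mairca_oracle(X, benefit, w):
    """Total gap per alternative, straight from the step definitions."""
    m = len(X)
    R = normalize_oracle(X, benefit)
    P = 1.0 / m
    G = []
    for i in range(m):
        total = 0.0
        for j in range(len(w)):
            tp = P * w[j]
            tr = tp * R[i][j]
            total += tp - tr
        G.append(total)
    return G


def marcos_oracle(X, benefit, w):
    """Final compromise utilities, ideal-referenced normalization."""
    m, n = len(X), len(X[0])
    ai = [
        max(X[i][j] for i in range(m)) if benefit[j]
        else min(X[i][j] for i in range(m))
        for j in range(n)
    ]
    aai = [
        min(X[i][j] for i in range(m)) if benefit[j]
        else max(X[i][j] for i in range(m))
        for j in range(n)
    ]

    def row_S(row):
        s = 0.0
        for j in range(n):
            nij = row[j] / ai[j] if benefit[j] else ai[j] / row[j]
            s += nij * w[j]
        return s

    s_ai = row_S(ai)
    s_aai = row_S(aai)
    out = []
    for i in range(m):
        s = row_S(X[i])
        kp = s / s_ai
        km = s / s_aai
        fkp = km / (kp + km)
        fkm = kp / (kp + km)
        f = (kp + km) / (1 + (1 - fkp) / fkp + (1 - fkm) / fkm)
        out.append(f)
    return out


def spearman_oracle(ranks_a, ranks_b):
    """Pearson correlation of the rank vectors, by summation."""
    m = len(ranks_a)
    ma = sum(ranks_a) / m
    mb = sum(ranks_b) / m
    num = sum((a - ma) * (b - mb) for a, b in zip(ranks_a, ranks_b))
    da = math.sqrt(sum((a - ma) ** 2 for a in ranks_a))
    db = math.sqrt(sum((b - mb) ** 2 for b in ranks_b))
    return num / (da * db)
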