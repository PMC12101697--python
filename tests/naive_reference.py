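"""Independent brute-force reference implementations used as oracles.

Everything here is written as literal double loops over template indices,
deliberately ignoring vectorization, so that agreement with the package's
implementations is a meaningful cross-check rather than a tautology.
"""

import math

import numpy as np


def cheb(a, b):
    return max(abs(ai - bi) for ai, bi in zip(a, b))


def naive_cross_sample_entropy(x, y, m, r):
    n = len(x)

    def mean_match(mm):
        nt = n - mm + 1
        total = 0.0
        for i in range(nt):
            count = 0
            for j in range(nt):
                if j == i:
                    continue
                if cheb(x[i:i + mm], y[j:j + mm]) < r:
                    count += 1
            total += count / nt
        return total / nt

    bm = mean_match(m)
    bm1 = mean_match(m + 1)
    if bm == 0 or bm1 == 0:
        return float("nan")
    return -math.log(bm1 / bm)


def naive_cross_fuzzy_entropy(x, y, m, r, kernel="exponential"):
    n = len(x)

    def phi(mm):
        nt = n - mm + 1
        total = 0.0
        for i in range(nt):
            xi = np.asarray(x[i:i + mm], dtype=float)
            xi = xi - xi.mean()
            for j in range(nt):
                if j == i:
                    continue
                yj = np.asarray(y[j:j + mm], dtype=float)
                yj = yj - yj.mean()
                d = cheb(xi, yj)
                if kernel == "exponential":
                    total += math.exp(-d / r)
                else:
                    total += math.exp(-((d / r) ** 2))
        return total / n

    return -math.log(phi(m + 1) / phi(m))


def naive_joint_distribution_entropy(x, y, m, n_bins):
    n = len(x)
    nt = n - m + 1
    dists = []
    for i in range(nt):
        for j in range(nt):
            dists.append(
                math.sqrt(sum((x[i + t] - y[j + t]) ** 2 for t in range(m)))
            )
    lo, hi = min(dists), max(dists)
    if lo == hi:
        return 0.0
    counts = [0] * n_bins
    width = (hi - lo) / n_bins
    for d in dists:
        idx = min(int((d - lo) / width), n_bins - 1)
        counts[idx] += 1
    total = len(dists)
    ent = 0.0
    for c in counts:
        if c:
            p = c / total
            ent -= p * math.log2(p)
    return ent


def naive_euclidean(x, y):
    return math.sqrt(sum((xi - yi) ** 2 for xi, yi in zip(x, y)))


def naive_pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    dx = math.sqrt(sum((xi - mx) ** 2 for xi in x))
    dy = math.sqrt(sum((yi - my) ** 2 for yi in y))
    return num / (dx * dy)


def naive_relieff(values, labels, k):
    """Full-pass ReliefF with max-min scaling, binary or multi-class."""
    values = np.asarray(values, dtype=float)
    n, d = values.shape
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    span = values.max(axis=0) - values.min(axis=0)
    scaled = np.zeros_like(values)
    for f in range(d):
        if span[f] > 0:
            scaled[:, f] = (values[:, f] - values[:, f].min()) / span[f]
    priors = {c: np.mean(labels == c) for c in classes}
    weights = np.zeros(d)
    for i in range(n):
        dists = [math.sqrt(sum((scaled[i, f] - scaled[j, f]) ** 2 for f in range(d))) for j in range(n)]
        order = np.argsort(dists, kind="stable")
        hits = [j for j in order if labels[j] == labels[i] and j != i][:k]
        for f in range(d):
            for j in hits:
                weights[f] -= abs(scaled[i, f] - scaled[j, f]) / (n * k)
        for c in classes:
            if c == labels[i]:
                continue
            misses = [j for j in order if labels[j] == c][:k]
            w_c = priors[c] / (1.0 - priors[labels[i]])
            for f in range(d):
                for j in misses:
                    weights[f] += w_c * abs(scaled[i, f] - scaled[j, f]) / (n * k)
    return weights
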