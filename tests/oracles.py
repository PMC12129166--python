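"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain loops straight from the defining
formulas, deliberately sharing no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


# --- membership metrics ----------------------------------------------------

def bf_euclidean(x, members):
    centroid = [sum(col) / len(members) for col in zip(*members)]
    return math.sqrt(sum((xi - ci) ** 2 for xi, ci in zip(x, centroid)))


def _dist(a, b):
    return math.sqrt(sum((ai - bi) ** 2 for ai, bi in zip(a, b)))


def bf_silhouette(x, members):
    n = len(members)
    scores = [0.0]  # the singleton's own score, by convention
    for i, m in enumerate(members):
        a = sum(_dist(m, o) for j, o in enumerate(members) if j != i) / (n - 1)
        b = _dist(m, x)
        denom = max(a, b)
        scores.append((b - a) / denom if denom > 0 else 0.0)
    return sum(scores) / len(scores)


def bf_cosine(x, members):
    centroid = [sum(col) / len(members) for col in zip(*members)]
    nx = math.sqrt(sum(v * v for v in x))
    nc = math.sqrt(sum(v * v for v in centroid))
    return sum(a * b for a, b in zip(x, centroid)) / (nx * nc)


def bf_knn(x, members, k):
    d = sorted(_dist(x, m) for m in members)
    return sum(d[:k]) / k


def bf_cms(x, members, eps):
    mean_d = sum(_dist(x, m) for m in members) / len(members)
    return 1.0 / (mean_d + eps)


def bf_gaussian(x, members, sigma):
    d = bf_euclidean(x, members)
    return math.exp(-(d ** 2) / (2.0 * sigma ** 2))


# --- spectral features -----------------------------------------------------

def bf_spectral_features(mags, freqs, rolloff_frac=0.95):
    """All 10 spectrum-based features of one frame, from the raw formulas."""
    s = list(map(float, mags))
    f = list(map(float, freqs))
    b = len(s)
    tot = sum(s)
    mu = sum(fk * sk for fk, sk in zip(f, s)) / tot
    var = sum((fk - mu) ** 2 * sk for fk, sk in zip(f, s)) / tot
    sigma = math.sqrt(var)
    if sigma > 0:
        skew = sum((fk - mu) ** 3 * sk for fk, sk in zip(f, s)) / (sigma ** 3 * tot)
        kurt = sum((fk - mu) ** 4 * sk for fk, sk in zip(f, s)) / (sigma ** 4 * tot)
    else:
        skew = kurt = 0.0
    crest = max(s) / (tot / b)
    p = [sk / tot for sk in s]
    entropy = -sum(pk * math.log(pk) for pk in p if pk > 0) / math.log(b)
    if any(sk == 0 for sk in s):
        flatness = 0.0
    else:
        flatness = math.exp(sum(math.log(sk) for sk in s) / b) / (tot / b)
    tail = sum(s[1:])
    decrease = (
        sum((s[k] - s[0]) / k for k in range(1, b)) / tail if tail > 0 else 0.0
    )
    cum = 0.0
    rolloff = f[-1]
    for fk, sk in zip(f, s):
        cum += sk
        if cum >= rolloff_frac * tot - 1e-12 * tot:
            rolloff = fk
            break
    fbar = sum(f) / b
    sbar = tot / b
    slope = sum((fk - fbar) * (sk - sbar) for fk, sk in zip(f, s)) / sum(
        (fk - fbar) ** 2 for fk in f
    )
    return {
        "centroid": mu, "spread": sigma, "skewness": skew, "kurtosis": kurt,
        "crest": crest, "entropy": entropy, "flatness": flatness,
        "decrease": decrease, "rolloff": rolloff, "slope": slope,
    }


# --- rank statistics -------------------------------------------------------

def bf_spearman_no_ties(x, y):
    """Closed form 1 - 6*sum(d^2)/(n(n^2-1)); valid only without ties."""
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0] * len(v)
        for rank, i in enumerate(order, start=1):
            r[i] = rank
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    d2 = sum((a - b) ** 2 for a, b in zip(rx, ry))
    return 1.0 - 6.0 * d2 / (n * (n * n - 1))


def random_cluster_instance(rng: np.random.Generator, max_points=10, max_features=4):
    """A small random control cluster plus one test vector."""
    n = int(rng.integers(2, max_points + 1))
    p = int(rng.integers(1, max_features + 1))
    members = rng.standard_normal((n, p)) * rng.uniform(0.5, 2.0)
    x = rng.standard_normal(p) * rng.uniform(0.5, 3.0)
    return x, members
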