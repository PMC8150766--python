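"""Brute-force reference implementations used only to cross-check the
package's vectorized feature code. Everything here is written with
explicit loops and elementary numpy, independent of the library paths
under test."""

from __future__ import annotations

import math

import numpy as np


def sample_entropy_naive(x, m=2, r_factor=0.2):
    x = np.asarray(x, float)
    n = len(x)
    r = r_factor * x.std()

    def count(mm):
        n_tpl = n - m
        c = 0
        for i in range(n_tpl):
            for j in range(n_tpl):
                if i == j:
                    continue
                d = max(abs(x[i + k] - x[j + k]) for k in range(mm))
                if d <= r:
                    c += 1
        return c

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return 0.0
    return -math.log(a / b)


def permutation_entropy_naive(x, order=3):
    x = np.asarray(x, float)
    counts: dict[tuple, int] = {}
    n = len(x) - order + 1
    for i in range(n):
        pattern = tuple(np.argsort(x[i : i + order], kind="stable"))
        counts[pattern] = counts.get(pattern, 0) + 1
    h = -sum((c / n) * math.log2(c / n) for c in counts.values())
    return h / math.log2(math.factorial(order))


def renyi_entropy_naive(x, alpha=2.0):
    e = np.asarray(x, float) ** 2
    p = e / e.sum()
    return math.log(sum(pi**alpha for pi in p)) / (1 - alpha)


def shannon_entropy_naive(x):
    e = np.asarray(x, float) ** 2
    p = e / e.sum()
    return -sum(pi * math.log(pi) for pi in p if pi > 0)


def kraskov_entropy_naive(x, k=4):
    """Kozachenko-Leonenko estimator via explicitly sorted distances."""
    from scipy.special import digamma

    x = np.asarray(x, float)
    n = len(x)
    total = 0.0
    for i in range(n):
        d = sorted(abs(x[i] - x[j]) for j in range(n) if j != i)
        total += math.log(2 * max(d[k - 1], 1e-12))
    return -digamma(k) + digamma(n) + total / n


def svd_entropy_naive(x, embed_dim=10):
    x = np.asarray(x, float)
    rows = [x[i : i + embed_dim] for i in range(len(x) - embed_dim + 1)]
    X = np.array(rows)
    # eigenvalues of the Gram matrix are the squared singular values
    lam = np.linalg.eigvalsh(X.T @ X)
    lam = np.clip(lam, 0, None)
    p = lam / lam.sum()
    h = -sum(pi * math.log(pi) for pi in p if pi > 0)
    return h / math.log(len(p))


def petrosian_naive(x):
    x = np.asarray(x, float)
    n = len(x)
    d = [x[i + 1] - x[i] for i in range(n - 1)]
    n_delta = sum(1 for i in range(len(d) - 1) if d[i] * d[i + 1] < 0)
    return math.log(n) / (math.log(n) + math.log(n / (n + 0.4 * n_delta)))


def katz_naive(x):
    x = np.asarray(x, float)
    L = sum(abs(x[i + 1] - x[i]) for i in range(len(x) - 1))
    d = max(abs(xi - x[0]) for xi in x)
    n = len(x) - 1
    return math.log(n) / (math.log(d / L) + math.log(n))


def higuchi_naive(x, kmax=10):
    x = np.asarray(x, float)
    n = len(x)
    ks, ls = [], []
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            idx = list(range(m, n, k))
            if len(idx) < 2:
                continue
            s = sum(abs(x[idx[i + 1]] - x[idx[i]]) for i in range(len(idx) - 1))
            lengths.append(s * (n - 1) / ((len(idx) - 1) * k) / k)
        if lengths:
            mean_l = sum(lengths) / len(lengths)
            if mean_l > 0:
                ks.append(k)
                ls.append(mean_l)
    slope, _ = np.polyfit(np.log([1 / k for k in ks]), np.log(ls), 1)
    return slope


def quantile_naive(values, p):
    """Sort-based linear-interpolation quantile (matches numpy's default)."""
    xs = sorted(values)
    h = (len(xs) - 1) * p
    lo = int(math.floor(h))
    hi = min(lo + 1, len(xs) - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def softmax_naive(scores):
    e = [math.exp(s - max(scores)) for s in scores]
    tot = sum(e)
    return [v / tot for v in e]
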