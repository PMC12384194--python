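"""Independent brute-force oracles used only by the tests.

Literal double-loop transcriptions of the defining sums of the fuzzy
entropies, and an exhaustive evaluation of the Benjamini-Hochberg
step-up rule.  Deliberately slow and dependency-free so they stay
independent of the vectorized package kernels they check.
"""

import math

import numpy as np


def mu_quadratic(x: float) -> float:
    if x < 0:
        raise ValueError("negative scaled distance")
    if x <= 1.0:
        return (2.0 - x * x) / 2.0
    if x <= 2.0:
        return (2.0 - x) ** 2 / 2.0
    return 0.0


def _sample_sd(u) -> float:
    n = len(u)
    mean = sum(u) / n
    return math.sqrt(sum((v - mean) ** 2 for v in u) / (n - 1))


def naive_fuzzy_apen(u, m: int = 2, k: float = 0.25, tau: int = 1) -> float:
    u = [float(v) for v in u]
    n = len(u)
    r = k * _sample_sd(u)

    def phi(mm: int) -> float:
        n_vec = n - (mm - 1) * tau
        templates = []
        for i in range(n_vec):
            xi = [u[i + kk * tau] for kk in range(mm)]
            x0 = sum(xi) / mm
            templates.append([v - x0 for v in xi])
        total = 0.0
        for i in range(n_vec):
            c = 0.0
            for j in range(n_vec):  # self-match j == i included
                d = max(abs(a - b) for a, b in zip(templates[i], templates[j]))
                c += mu_quadratic(d / r)
            total += math.log(c / n_vec)
        return total / n_vec

    return phi(m) - phi(m + 1)


def naive_fuzzy_sampen(u, m: int = 2, k: float = 0.25, tau: int = 1) -> float:
    u = [float(v) for v in u]
    n = len(u)
    r = k * _sample_sd(u)
    n_vec = n - m * tau  # same template range for both lengths

    def phi(mm: int) -> float:
        total = 0.0
        for i in range(n_vec):
            s = 0.0
            for j in range(n_vec):
                if j == i:  # self-match excluded
                    continue
                d = max(
                    abs(u[i + kk * tau] - u[j + kk * tau]) for kk in range(mm)
                )
                s += mu_quadratic(d / r)
            total += s / (n_vec - 1)
        return total / n_vec

    return -math.log(phi(m + 1) / phi(m))


def naive_fdr_bh(pvalues, q: float = 0.05):
    """Exhaustive step-up: find the largest k with p_(k) <= q k/n."""
    p = np.asarray(pvalues, float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    k_star = 0
    for k in range(1, n + 1):
        if p[order[k - 1]] <= q * k / n:
            k_star = k
    reject = np.zeros(n, dtype=bool)
    reject[order[:k_star]] = True
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        running = min(running, p[order[rank - 1]] * n / rank)
        adj[order[rank - 1]] = running
    return reject, adj
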