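"""Independent oracles used by the test suite.

Everything here is deliberately naive — dense grids, exhaustive
enumeration, from-scratch rank arithmetic — and shares no code with the
implementations it checks.
"""

from itertools import combinations

import numpy as np
from scipy.special import gammaln, logsumexp


def grid_logml_order0(Y, tau, a0, b0, n_sigma=1201, n_beta=1201,
                      log_s2_range=(-8.0, 8.0), beta_half=40.0):
    """Dense-grid double integration of the order-0 model evidence.

    p(y) = iint prod_i N(y_i | b, s2) . N(b | 0, s2 tau^2) . IG(s2 | a0, b0)
    integrated by trapezoid-on-log-grid over s2 and a uniform grid over b.
    """
    y = np.asarray(Y, dtype=float).ravel()
    n = y.size
    ls = np.linspace(*log_s2_range, n_sigma)
    s2 = np.exp(ls)
    beta = np.linspace(-beta_half, beta_half, n_beta)
    B, S = np.meshgrid(beta, s2, indexing="ij")
    loglik = -0.5 * n * np.log(2 * np.pi * S) - (
        ((y[None, None, :] - B[..., None]) ** 2).sum(-1) / (2 * S)
    )
    log_prior_b = -0.5 * np.log(2 * np.pi * S * tau**2) - B**2 / (2 * S * tau**2)
    log_prior_s = (
        a0 * np.log(b0) - gammaln(a0) - (a0 + 1) * ls[None, :] - b0 / S
    )
    integrand = loglik + log_prior_b + log_prior_s + ls[None, :]  # jacobian e^l
    db = beta[1] - beta[0]
    dl = ls[1] - ls[0]
    return float(logsumexp(integrand) + np.log(db) + np.log(dl))


def set_partitions(items):
    """Yield every partition of ``items`` as a list of lists."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def brute_force_upper_tail(N, K, n, k):
    """P(overlap >= k) by enumerating every size-n draw from N items."""
    hits = total = 0
    term = set(range(K))
    for draw in combinations(range(N), n):
        total += 1
        if len(term & set(draw)) >= k:
            hits += 1
    return hits / total


def _midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = mid
        i = j + 1
    return ranks


def naive_kruskal_h(values, labels):
    """Tie-corrected H from first principles (midranks, correction factor)."""
    ranks = _midranks(list(values))
    N = len(values)
    groups = sorted(set(labels))
    h = 0.0
    for g in groups:
        r = [ranks[i] for i in range(N) if labels[i] == g]
        h += sum(r) ** 2 / len(r)
    h = 12.0 / (N * (N + 1)) * h - 3 * (N + 1)
    uniq = {}
    for v in values:
        uniq[v] = uniq.get(v, 0) + 1
    ties = sum(c**3 - c for c in uniq.values())
    denom = 1.0 - ties / (N**3 - N)
    return 0.0 if denom <= 0 else h / denom


def naive_permutation_p(values, labels):
    """Exact two-group permutation p for H over all C(N, n1) splits."""
    labels = list(labels)
    groups = sorted(set(labels))
    n1 = labels.count(groups[0])
    h_obs = naive_kruskal_h(values, labels)
    hits = total = 0
    for comb in combinations(range(len(values)), n1):
        chosen = set(comb)
        lab = [groups[0] if i in chosen else groups[1] for i in range(len(values))]
        if naive_kruskal_h(values, lab) >= h_obs - 1e-12:
            hits += 1
        total += 1
    return hits / total
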