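"""Independent brute-force reference implementations used as test oracles.

Each function here recomputes a quantity from its definition, by direct
enumeration, without reusing any code path from the package.
"""

from __future__ import annotations

import numpy as np


def brute_force_peaks(values: np.ndarray, min_distance: int = 1) -> list[int]:
    """Local maxima by exhaustive scan: strict rise before, strict fall after.

    A plateau contributes its first index; thinning keeps the larger peak.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    peaks = []
    for i in range(1, n - 1):
        # previous distinct value
        j = i - 1
        while j >= 0 and v[j] == v[i]:
            j -= 1
        if j < 0 or v[j] >= v[i]:
            continue
        if v[i - 1] == v[i]:  # not the first index of its plateau
            continue
        k = i + 1
        while k < n and v[k] == v[i]:
            k += 1
        if k >= n or v[k] >= v[i]:
            continue
        peaks.append(i)
    if min_distance > 1:
        order = sorted(peaks, key=lambda i: (-v[i], i))
        kept: list[int] = []
        for i in order:
            if all(abs(i - j) >= min_distance for j in kept):
                kept.append(i)
        peaks = sorted(kept)
    return peaks


def brute_force_gev(
    data: np.ndarray, maps: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, float]:
    """GEV from its definition, sample by sample.

    Explained variance of sample t = squared Pearson correlation between the
    sample map and its assigned class map, weighted by squared GFP.
    """
    C, n = data.shape
    K = maps.shape[0]
    gfp2 = np.empty(n)
    contrib = np.empty(n)
    for t in range(n):
        x = data[:, t]
        xc = x - x.mean()
        gfp2[t] = (xc**2).mean()
        a = maps[labels[t]] - maps[labels[t]].mean()
        r = float(xc @ a / (np.linalg.norm(xc) * np.linalg.norm(a)))
        contrib[t] = gfp2[t] * r**2
    total = gfp2.sum()
    per_class = np.array([contrib[labels == k].sum() / total for k in range(K)])
    return per_class, float(per_class.sum())


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values by direct enumeration.

    adjusted p(i) = min over j with p(j) >= p(i) of p(j) * m / rank(j),
    computed from the sorted vector as min_{j >= i} p_(j) * m / j, capped
    at 1.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    for i in range(m):
        candidates = [p[order[j]] * m / (j + 1) for j in range(i, m)]
        adj_sorted[i] = min(1.0, min(candidates))
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


def midranks(x: np.ndarray) -> np.ndarray:
    """Mid-ranks (average rank for ties) computed by explicit counting."""
    x = np.asarray(x, dtype=float)
    n = x.size
    r = np.empty(n)
    for i in range(n):
        less = np.sum(x < x[i])
        equal = np.sum(x == x[i])
        r[i] = less + (equal + 1) / 2.0
    return r


def spearman_oracle(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho as Pearson correlation of explicit mid-ranks,
    with the two-sided t-approximation p-value at n - 2 dof."""
    from scipy.stats import t as tdist

    rx, ry = midranks(x), midranks(y)
    rxc, ryc = rx - rx.mean(), ry - ry.mean()
    rho = float(rxc @ ryc / np.sqrt((rxc**2).sum() * (ryc**2).sum()))
    n = len(x)
    if abs(rho) == 1.0:
        return rho, 0.0
    tstat = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = 2.0 * tdist.sf(abs(tstat), n - 2)
    return rho, float(p)


def smoothing_cost_oracle(
    d2: np.ndarray, labels: np.ndarray, b: int, lam: float, C: int
) -> np.ndarray:
    """Per-class per-sample smoothing cost from the documented objective.

    cost[k, t] = d2[k, t] / (2 * mean_t d2[labels_t, t])
                 - lam * N_bkt / (2b + 1)^2
    with N_bkt counting neighbours of t within +/- b labeled k (excluding t).
    """
    K, n = d2.shape
    e_scaled = max(np.mean([d2[labels[t], t] for t in range(n)]), np.finfo(float).tiny)
    W = 2 * b + 1
    cost = np.empty((K, n))
    for t in range(n):
        for k in range(K):
            count = 0
            for s in range(max(0, t - b), min(n, t + b + 1)):
                if s != t and labels[s] == k:
                    count += 1
            cost[k, t] = d2[k, t] / (2.0 * e_scaled) - lam * count / W**2
    return cost


def smoothing_energy_oracle(
    d2: np.ndarray, labels: np.ndarray, b: int, lam: float
) -> float:
    """Global smoothing objective: data term minus lam/2 per same-label pair."""
    K, n = d2.shape
    e_scaled = max(np.mean([d2[labels[t], t] for t in range(n)]), np.finfo(float).tiny)
    W = 2 * b + 1
    total = 0.0
    for t in range(n):
        total += d2[labels[t], t] / (2.0 * e_scaled)
        for s in range(max(0, t - b), min(n, t + b + 1)):
            if s != t and labels[s] == labels[t]:
                total -= 0.5 * lam / W**2
    return total


def smoothing_icm_oracle(
    d2: np.ndarray, labels: np.ndarray, b: int, lam: float, C: int, max_iter: int = 100
) -> np.ndarray:
    """Independent ICM on the smoothing objective (synchronous sweeps).

    A 2-cycle of the synchronous update terminates the iteration with the
    lower-energy of the two states, mirroring the documented algorithm.
    """
    labels = np.asarray(labels, dtype=int).copy()
    prev = labels.copy()
    for it in range(max_iter):
        cost = smoothing_cost_oracle(d2, labels, b, lam, C)
        new = np.argmin(cost, axis=0)
        if np.array_equal(new, labels):
            break
        if it > 0 and np.array_equal(new, prev):
            if smoothing_energy_oracle(d2, prev, b, lam) < smoothing_energy_oracle(
                d2, labels, b, lam
            ):
                labels = prev
            break
        prev = labels
        labels = new
    return labels
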