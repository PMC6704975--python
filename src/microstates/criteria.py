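"""Cluster-validity criteria for choosing the number of microstate classes.

All criteria operate in the polarity-invariant map dissimilarity

    d(x, y) = sqrt(2 - 2 |r(x, y)|)

where ``r`` is the spatial (Pearson) correlation between two
average-referenced maps; for unit-norm centered vectors this is the chordal
distance between the lines spanned by the maps, so a map and its negation
are at distance zero.  Every criterion is returned oriented so that LARGER
is better; criteria whose natural direction is "smaller is better"
(Davies-Bouldin, the cross-validation criterion) are negated.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import silhouette_score

CRITERIA = [
    "gamma",
    "silhouette",
    "davies_bouldin",
    "point_biserial",
    "dunn",
    "krzanowski_lai",
    "cross_validation",
]


def pairwise_distances(Xn: np.ndarray) -> np.ndarray:
    """Polarity-invariant chordal distance matrix of unit-norm centered maps."""
    R = np.clip(np.abs(Xn @ Xn.T), 0.0, 1.0)
    D = np.sqrt(np.maximum(0.0, 2.0 - 2.0 * R))
    np.fill_diagonal(D, 0.0)
    return D


def within_dispersion(Xn: np.ndarray, model) -> float:
    """Within-cluster dispersion W_K = sum_i d^2(map_i, prototype of its class)."""
    labels = model.meta["peak_labels"]
    r = np.abs((Xn * model.maps[labels]).sum(axis=1))
    return float(np.sum(2.0 - 2.0 * np.clip(r, 0.0, 1.0)))


def _pair_split(D: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle distances split into within- and between-cluster pairs."""
    iu, ju = np.triu_indices(D.shape[0], k=1)
    same = labels[iu] == labels[ju]
    d = D[iu, ju]
    return d[same], d[~same]


def gamma_index(D: np.ndarray, labels: np.ndarray) -> float:
    """Baker-Hubert Gamma: concordance of within vs between pair distances.

    A (within, between) pair is concordant when the within distance is the
    smaller one.  Gamma = (s+ - s-) / (s+ + s-).
    """
    w, b = _pair_split(D, labels)
    if w.size == 0 or b.size == 0:
        return np.nan
    bs = np.sort(b)
    less = np.searchsorted(bs, w, side="left")  # per w: count of b < w
    greater = b.size - np.searchsorted(bs, w, side="right")
    s_plus = float(greater.sum())
    s_minus = float(less.sum())
    if s_plus + s_minus == 0:
        return np.nan
    return (s_plus - s_minus) / (s_plus + s_minus)


def point_biserial(D: np.ndarray, labels: np.ndarray) -> float:
    """Point-biserial correlation between pair distance and pair separation."""
    w, b = _pair_split(D, labels)
    if w.size == 0 or b.size == 0:
        return np.nan
    d = np.concatenate([w, b])
    sd = d.std(ddof=0)
    if sd == 0:
        return np.nan
    nt = d.size
    return float((b.mean() - w.mean()) * np.sqrt(w.size * b.size / nt**2) / sd)


def dunn_index(D: np.ndarray, labels: np.ndarray) -> float:
    """Minimum between-cluster distance over maximum within-cluster diameter."""
    w, b = _pair_split(D, labels)
    if b.size == 0:
        return np.nan
    diam = w.max() if w.size else 0.0
    if diam == 0:
        return np.inf
    return float(b.min() / diam)


def davies_bouldin(Xn: np.ndarray, labels: np.ndarray, prototypes: np.ndarray) -> float:
    """Davies-Bouldin index (returned negated: larger is better)."""
    K = prototypes.shape[0]
    r = np.clip(np.abs(Xn @ prototypes.T), 0.0, 1.0)  # (N, K)
    d_to_proto = np.sqrt(np.maximum(0.0, 2.0 - 2.0 * r))
    S = np.array(
        [d_to_proto[labels == k, k].mean() if (labels == k).any() else np.nan for k in range(K)]
    )
    rp = np.clip(np.abs(prototypes @ prototypes.T), 0.0, 1.0)
    M = np.sqrt(np.maximum(0.0, 2.0 - 2.0 * rp))
    ratios = np.full((K, K), -np.inf)
    for k in range(K):
        for l in range(K):
            if k != l:
                ratios[k, l] = (S[k] + S[l]) / M[k, l] if M[k, l] > 0 else np.inf
    db = np.nanmean(np.max(ratios, axis=1))
    return float(-db)


def silhouette(D: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width on the precomputed distance matrix."""
    n_lab = np.unique(labels).size
    if n_lab < 2 or n_lab >= len(labels):
        return np.nan
    return float(silhouette_score(D, labels, metric="precomputed"))


def krzanowski_lai(W: dict[int, float], K: int, p: int) -> float:
    """Krzanowski-Lai index from within-dispersions at K-1, K, K+1.

    ``KL(K) = |DIFF(K) / DIFF(K+1)|`` with
    ``DIFF(K) = (K-1)^(2/p) W(K-1) - K^(2/p) W(K)`` and ``p`` the map
    dimensionality.  Returns NaN when a neighbouring dispersion is missing.
    """
    if (K - 1) not in W or K not in W or (K + 1) not in W:
        return np.nan

    def diff(k: int) -> float:
        return (k - 1) ** (2.0 / p) * W[k - 1] - k ** (2.0 / p) * W[k]

    denom = diff(K + 1)
    if denom == 0:
        return np.inf
    return float(abs(diff(K) / denom))


def cross_validation(norms: np.ndarray, r_assigned: np.ndarray, K: int, C: int) -> float:
    """Predictive-residual cross-validation criterion (negated).

    The residual variance of the K-class model is
    ``sigma^2 = sum_i ||x_i||^2 (1 - r_i^2) / (N (C - 1))`` and the
    criterion is ``sigma^2 ((C - 1)/(C - 1 - K))^2``, penalising model
    complexity; smaller is better, so the negative is returned.
    """
    if K >= C - 1:
        return np.nan
    N = norms.size
    sigma2 = float(np.sum(norms**2 * (1.0 - r_assigned**2)) / (N * (C - 1)))
    return -sigma2 * ((C - 1) / (C - 1 - K)) ** 2


def evaluate_all(
    Xn: np.ndarray,
    norms: np.ndarray,
    D: np.ndarray,
    labels: np.ndarray,
    prototypes: np.ndarray,
    W: dict[int, float],
    K: int,
) -> dict[str, float]:
    """All seven criteria for one fitted model, oriented larger-is-better."""
    C = Xn.shape[1]
    r_assigned = np.clip(np.abs((Xn * prototypes[labels]).sum(axis=1)), 0.0, 1.0)
    return {
        "gamma": gamma_index(D, labels),
        "silhouette": silhouette(D, labels),
        "davies_bouldin": davies_bouldin(Xn, labels, prototypes),
        "point_biserial": point_biserial(D, labels),
        "dunn": dunn_index(D, labels),
        "krzanowski_lai": krzanowski_lai(W, K, C),
        "cross_validation": cross_validation(norms, r_assigned, K, C),
    }
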