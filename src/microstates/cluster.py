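"""Polarity-invariant topographic clustering of EEG maps.

The microstate model is fitted in three steps:

1. Global field power (GFP) peaks are located; the scalp maps at those
   instants have the highest signal-to-noise ratio and are the clustering
   input.
2. A modified k-means groups peak maps into K prototype topographies.  Both
   the assignment step (maximum absolute spatial correlation) and the
   prototype update (dominant spatial mode of the assigned maps) ignore map
   polarity, because spontaneous EEG topographies reverse sign with the
   oscillatory phase of their generators.
3. The number of classes K is chosen by a meta-criterion combining seven
   cluster-validity indices by median rank.

For multi-subject studies :func:`two_level_cluster` first fits a model per
subject and then clusters the pooled subject prototypes at the group level.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import criteria as _criteria
from .preprocess import DEFAULT_EDGE_EXCLUDE_S
from .recording import EEGRecording

__all__ = [
    "GFPSeries",
    "MicrostateModel",
    "MetaCriterionReport",
    "compute_gfp",
    "find_gfp_peaks",
    "extract_peak_maps",
    "modified_kmeans",
    "select_optimal_k",
    "two_level_cluster",
]


# --------------------------------------------------------------------------
# GFP

@dataclass
class GFPSeries:
    """Global field power: per-sample spatial standard deviation.

    ``values[t]`` is the population standard deviation (divide by the number
    of channels N, not N-1) of the scalp potential across all electrodes at
    sample ``t`` -- a reference-free measure of field strength.
    """

    values: np.ndarray
    fs: float
    peak_indices: np.ndarray | None = None


def compute_gfp(rec: EEGRecording) -> GFPSeries:
    """Global field power of a recording.

    Uses the population standard deviation across channels (``ddof=0``),
    the classical GFP definition.  Invariant to polarity flips and, for
    average-referenced data, equal to the spatial RMS.
    """
    values = rec.data.std(axis=0, ddof=0)
    return GFPSeries(values=values, fs=rec.fs)


def find_gfp_peaks(gfp: GFPSeries, min_distance_samples: int = 1) -> np.ndarray:
    """Indices of strict local maxima of the GFP series.

    A sample ``i`` is a peak when ``values[i-1] < values[i] > values[i+1]``;
    a plateau (run of equal values strictly above both neighbours)
    contributes its first index.  Runs touching the series boundary are not
    peaks.  If ``min_distance_samples > 1`` the peaks are thinned greedily by
    decreasing GFP so that surviving peaks are at least that far apart.
    """
    v = np.asarray(gfp.values, dtype=float)
    if v.size < 3:
        raise ValueError(f"series too short for peak detection (length {v.size})")
    # run-length encode equal-value runs
    change = np.flatnonzero(np.diff(v) != 0.0)
    starts = np.concatenate(([0], change + 1))
    run_vals = v[starts]
    # a run is a peak-run if both neighbouring runs exist and are lower
    inner = np.arange(1, len(starts) - 1)
    is_peak = (run_vals[inner] > run_vals[inner - 1]) & (run_vals[inner] > run_vals[inner + 1])
    peaks = starts[inner[is_peak]]

    if min_distance_samples > 1 and peaks.size:
        order = np.lexsort((peaks, -v[peaks]))  # by descending value, ties by index
        kept: list[int] = []
        for idx in peaks[order]:
            if all(abs(idx - k) >= min_distance_samples for k in kept):
                kept.append(int(idx))
        peaks = np.sort(np.array(kept, dtype=int))
    return peaks.astype(int)


def extract_peak_maps(
    rec: EEGRecording,
    min_distance_samples: int = 1,
    exclude_edge_s: float = DEFAULT_EDGE_EXCLUDE_S,
) -> tuple[np.ndarray, np.ndarray]:
    """GFP-peak topographies of a recording.

    Returns ``(maps, peak_indices)`` where ``maps`` has shape
    ``(n_peaks, n_channels)``.  The first and last ``exclude_edge_s`` seconds
    are excluded because zero-phase filtering contaminates the edges.
    """
    gfp = compute_gfp(rec)
    peaks = find_gfp_peaks(gfp, min_distance_samples=min_distance_samples)
    margin = int(round(exclude_edge_s * rec.fs))
    peaks = peaks[(peaks >= margin) & (peaks < rec.n_samples - margin)]
    return rec.data[:, peaks].T.copy(), peaks


# --------------------------------------------------------------------------
# Modified k-means

@dataclass
class MicrostateModel:
    """An ordered set of K microstate prototype maps with fit diagnostics.

    Maps are average-referenced, unit-norm and defined only up to sign;
    model comparisons must use absolute spatial correlation.  Classes are
    ordered by decreasing explained variance and labelled ``A``, ``B``, ...
    by convention.
    """

    maps: np.ndarray  # (K, n_channels), unit norm, zero channel mean
    gev_total: float
    gev_per_class: np.ndarray
    channel_labels: list[str] = field(default_factory=list)
    class_labels: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if not self.class_labels:
            self.class_labels = [chr(ord("A") + i) for i in range(self.maps.shape[0])]

    @property
    def K(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


def _normalize_maps(maps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center each map (average reference) and scale to unit norm.

    Returns ``(unit_maps, norms)``; raises on maps with zero spatial
    variance, whose correlation with anything is undefined.
    """
    X = np.asarray(maps, dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise ValueError(f"maps with zero spatial variance at rows {bad.tolist()}")
    return Xc / norms[:, None], norms


def _canonical_sign(maps: np.ndarray) -> np.ndarray:
    """Flip each map so its largest-magnitude channel is positive."""
    out = maps.copy()
    for k in range(out.shape[0]):
        j = int(np.argmax(np.abs(out[k])))
        if out[k, j] < 0:
            out[k] = -out[k]
    return out


def modified_kmeans(
    peak_maps: np.ndarray,
    K: int,
    n_restarts: int = 100,
    max_iter: int = 1000,
    tol: float = 1e-6,
    seed: int | None = None,
    channel_labels: Sequence[str] | None = None,
    record_history: bool = False,
) -> MicrostateModel:
    """Polarity-invariant k-means on topographic maps.

    Each iteration assigns every map to the prototype with the largest
    absolute spatial correlation (ties go to the lowest class index) and
    re-estimates each prototype as the dominant spatial mode of its assigned
    maps via one power-iteration step on the cluster scatter,
    ``a <- X^T (X a)`` renormalized -- the amplitude-weighted sign-aligned
    mean.  Both steps are non-decreasing in the global explained variance
    (GEV), so the within-restart GEV trace is monotone.  The best of
    ``n_restarts`` random initialisations (by GEV) is returned.

    GEV is the fraction of squared-GFP-weighted variance explained:
    ``sum_t gfp_t^2 r_t^2 / sum_t gfp_t^2`` with ``r_t`` the spatial
    correlation between map ``t`` and its assigned prototype.

    An empty cluster is re-seeded from the currently worst-explained map.
    """
    X = np.asarray(peak_maps, dtype=float)
    if X.ndim != 2:
        raise ValueError("peak_maps must be 2-D (n_maps, n_channels)")
    N, C = X.shape
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if N < K:
        raise ValueError(f"cannot fit K={K} classes to {N} peak maps")
    Xc = X - X.mean(axis=1, keepdims=True)
    Xn, norms = _normalize_maps(Xc)
    w = norms**2  # proportional to squared GFP of each map
    total = w.sum()

    rng = np.random.default_rng(seed)
    best: dict | None = None
    restart_gevs: list[float] = []
    for _ in range(max(1, n_restarts)):
        idx = rng.choice(N, size=K, replace=False)
        A = Xn[idx].copy()
        prev_gev = -np.inf
        history: list[dict] = []
        trace: list[float] = []
        labels = np.zeros(N, dtype=int)
        for _it in range(max_iter):
            corr = Xn @ A.T  # (N, K)
            labels = np.argmax(np.abs(corr), axis=1)  # first max -> lowest index
            r = np.abs(corr[np.arange(N), labels])
            gev = float((w * r**2).sum() / total)
            trace.append(gev)
            if record_history:
                history.append({"labels": labels.copy(), "maps": A.copy(), "gev": gev})
            if gev - prev_gev < tol * max(abs(prev_gev), 1e-12) and _it > 0:
                break
            prev_gev = gev
            # prototype update: one power step on each cluster scatter
            unexplained = w * (1.0 - r**2)
            for k in range(K):
                members = labels == k
                if not members.any():
                    A[k] = Xn[int(np.argmax(unexplained))]
                    continue
                Xm = Xc[members]
                v = Xm.T @ (Xm @ A[k])
                nv = np.linalg.norm(v)
                if nv == 0:  # pathological: scatter orthogonal to prototype
                    A[k] = Xn[int(np.argmax(unexplained))]
                else:
                    A[k] = v / nv
        restart_gevs.append(trace[-1])
        if best is None or trace[-1] > best["gev"]:
            best = {
                "gev": trace[-1],
                "maps": A,
                "labels": labels,
                "trace": trace,
                "history": history,
                "iterations": len(trace),
            }

    assert best is not None
    A = best["maps"]
    labels = best["labels"]
    corr = Xn @ A.T
    r = np.abs(corr[np.arange(N), labels])
    gev_per_class = np.array(
        [(w[labels == k] * r[labels == k] ** 2).sum() / total for k in range(K)]
    )
    order = np.argsort(-gev_per_class, kind="stable")
    A = _canonical_sign(A[order])
    gev_per_class = gev_per_class[order]
    remap = np.empty(K, dtype=int)
    remap[order] = np.arange(K)
    meta = {
        "n_restarts": n_restarts,
        "max_iter": max_iter,
        "tol": tol,
        "seed": seed,
        "iterations": best["iterations"],
        "gev_trace": np.asarray(best["trace"]),
        "restart_gevs": np.asarray(restart_gevs),
        "peak_labels": remap[labels],
    }
    if record_history:
        meta["history"] = best["history"]
    return MicrostateModel(
        maps=A,
        gev_total=float(gev_per_class.sum()),
        gev_per_class=gev_per_class,
        channel_labels=list(channel_labels) if channel_labels else [],
        meta=meta,
    )


# --------------------------------------------------------------------------
# Meta-criterion for the number of classes

@dataclass
class MetaCriterionReport:
    """Score table of the cluster-validity meta-criterion.

    ``scores`` holds the raw value of each criterion (oriented so larger is
    better) for every candidate K; ``normalized`` the min-max normalisation
    of each criterion across the K range; ``ranks`` the per-criterion rank of
    each K (1 = best).  ``selected_k`` is the K with the best median rank,
    ties resolved toward smaller K.
    """

    k_values: list[int]
    criteria: list[str]
    scores: pd.DataFrame
    normalized: pd.DataFrame
    ranks: pd.DataFrame
    median_ranks: pd.Series
    selected_k: int
    models: dict[int, MicrostateModel]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per K, criterion columns plus the median rank."""
        out = self.normalized.copy()
        out.columns = [f"{c}_norm" for c in out.columns]
        out.insert(0, "K", self.k_values)
        out["median_rank"] = self.median_ranks.values
        out["selected"] = [k == self.selected_k for k in self.k_values]
        return out


def select_optimal_k(
    peak_maps: np.ndarray,
    k_range: Iterable[int],
    n_restarts: int = 50,
    max_iter: int = 1000,
    tol: float = 1e-6,
    seed: int | None = None,
    channel_labels: Sequence[str] | None = None,
) -> MetaCriterionReport:
    """Choose the number of microstate classes by a seven-criterion vote.

    A :func:`modified_kmeans` model is fitted for every K in ``k_range`` and
    scored by seven independent cluster-validity criteria (Gamma, Silhouette,
    Davies-Bouldin, Point-Biserial, Dunn, Krzanowski-Lai, and a
    cross-validation criterion), all computed in the polarity-invariant map
    dissimilarity ``d = sqrt(2 - 2|r|)``.  Each criterion is oriented so
    larger is better, min-max normalised across the K range, and converted to
    ranks; the K with the best median rank wins, ties toward smaller K.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range is empty")
    X = np.asarray(peak_maps, dtype=float)
    N = X.shape[0]
    if ks[0] < 2:
        raise ValueError(f"candidate K must be >= 2, got {ks[0]}")
    if ks[-1] > N:
        raise ValueError(f"candidate K={ks[-1]} exceeds number of peak maps ({N})")

    Xc = X - X.mean(axis=1, keepdims=True)
    Xn, norms = _normalize_maps(Xc)
    D = _criteria.pairwise_distances(Xn)

    # Krzanowski-Lai needs within-dispersion at K-1 and K+1 as well.
    fit_ks = sorted(set(ks) | {k - 1 for k in ks} | {k + 1 for k in ks})
    fit_ks = [k for k in fit_ks if 1 <= k <= N]
    ss = np.random.SeedSequence(seed)
    fit_seeds = {k: int(s.generate_state(1)[0] % (2**31)) for k, s in zip(fit_ks, ss.spawn(len(fit_ks)))}
    models: dict[int, MicrostateModel] = {}
    for k in fit_ks:
        models[k] = modified_kmeans(
            X, k, n_restarts=n_restarts, max_iter=max_iter, tol=tol,
            seed=fit_seeds[k], channel_labels=channel_labels,
        )
    W = {k: _criteria.within_dispersion(Xn, models[k]) for k in fit_ks}

    rows = {}
    for k in ks:
        m = models[k]
        labels = m.meta["peak_labels"]
        rows[k] = _criteria.evaluate_all(
            Xn=Xn, norms=norms, D=D, labels=labels, prototypes=m.maps,
            W=W, K=k,
        )
    scores = pd.DataFrame.from_dict(rows, orient="index")[_criteria.CRITERIA]
    if len(ks) > 1:
        rng_ = scores.max() - scores.min()
        normalized = (scores - scores.min()) / rng_.replace(0.0, 1.0)
    else:
        normalized = scores * 0.0 + 1.0
    ranks = scores.rank(axis=0, ascending=False, method="average")
    median_ranks = ranks.median(axis=1)
    # best median rank; ties -> smaller K (index order is ascending)
    selected_k = int(median_ranks.idxmin())
    return MetaCriterionReport(
        k_values=ks,
        criteria=list(_criteria.CRITERIA),
        scores=scores,
        normalized=normalized,
        ranks=ranks,
        median_ranks=median_ranks,
        selected_k=selected_k,
        models={k: models[k] for k in ks},
    )


# --------------------------------------------------------------------------
# Two-level (subject -> group) clustering

def _subject_seed(base_seed: int | None, subject_id: str) -> int:
    """Deterministic per-subject seed independent of subject order."""
    crc = zlib.crc32(subject_id.encode("utf8"))
    ss = np.random.SeedSequence([0 if base_seed is None else int(base_seed), crc])
    return int(ss.generate_state(1)[0] % (2**31))


def two_level_cluster(
    recordings: Sequence[EEGRecording],
    k_range: Iterable[int] = range(2, 9),
    individual_k: int = 6,
    n_restarts: int = 25,
    max_iter: int = 1000,
    tol: float = 1e-6,
    seed: int | None = None,
    min_peak_distance: int = 1,
    exclude_edge_s: float = DEFAULT_EDGE_EXCLUDE_S,
) -> tuple[MicrostateModel, MetaCriterionReport, dict[str, MicrostateModel]]:
    """Individual-then-group microstate clustering.

    Each subject's GFP-peak maps are clustered into ``individual_k``
    prototypes; the pooled subject prototypes are then clustered at the group
    level, with the group K chosen by :func:`select_optimal_k` over
    ``k_range``.  Per-subject seeds are derived from the subject identifier,
    and the pooled prototypes are sorted by subject id, so the global model
    does not depend on the order in which subjects are supplied.

    Returns ``(global_model, meta_criterion_report, subject_models)``.
    """
    if not recordings:
        raise ValueError("need at least one recording")
    subject_models: dict[str, MicrostateModel] = {}
    for i, rec in enumerate(recordings):
        sid = rec.subject if rec.subject is not None else f"S{i:03d}"
        try:
            maps, _ = extract_peak_maps(
                rec, min_distance_samples=min_peak_distance, exclude_edge_s=exclude_edge_s
            )
            subject_models[sid] = modified_kmeans(
                maps,
                individual_k,
                n_restarts=n_restarts,
                max_iter=max_iter,
                tol=tol,
                seed=_subject_seed(seed, sid),
                channel_labels=rec.channel_labels,
            )
        except Exception as exc:
            raise RuntimeError(f"individual-level clustering failed for subject {sid!r}") from exc

    pooled = np.vstack([subject_models[sid].maps for sid in sorted(subject_models)])
    ks = [k for k in k_range if k <= pooled.shape[0]]
    if not ks:
        raise ValueError(
            f"no candidate K <= pooled prototype count ({pooled.shape[0]})"
        )
    report = select_optimal_k(
        pooled,
        ks,
        n_restarts=n_restarts,
        max_iter=max_iter,
        tol=tol,
        seed=seed,
        channel_labels=recordings[0].channel_labels,
    )
    global_model = report.models[report.selected_k]
    return global_model, report, subject_models
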