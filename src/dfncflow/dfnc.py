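"""Sliding-window connectivity, L1 k-means brain states, and occupancy rates.

Windowed correlation uses a tapered window — a rectangle of the requested
width convolved with a Gaussian — slid one TR at a time over the component
time courses.  The pooled window vectors from all subjects are clustered with
k-means under the L1 (city-block) distance and median centroid updates; the
number of states is chosen by an elbow rule on a cluster-validity curve, and
each subject's occupancy rate is the percentage of their windows assigned to
each state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

__all__ = [
    "WindowSeries",
    "StateModel",
    "OccupancyTable",
    "make_taper",
    "windowed_correlation",
    "pair_index",
    "cluster_states",
    "select_k_elbow",
    "match_states",
    "occupancy",
    "subject_state_means",
]


def pair_index(n_components: int) -> list[tuple[int, int]]:
    """Upper-triangle (i < j) component pairs; C components give C(C-1)/2 pairs."""
    iu, ju = np.triu_indices(n_components, k=1)
    return list(zip(iu.tolist(), ju.tolist()))


@dataclass
class WindowSeries:
    """One subject's sequence of vectorized windowed correlation matrices."""

    vectors: np.ndarray                 # (n_windows, n_pairs)
    taper: np.ndarray
    window_tr: int
    step_tr: int
    pairs: list[tuple[int, int]]

    @property
    def n_windows(self) -> int:
        return self.vectors.shape[0]


@dataclass
class StateModel:
    """k-means states over pooled windows, with per-window assignments."""

    k: int
    centroids: np.ndarray               # (k, n_pairs)
    assignments: np.ndarray             # (total_windows,)
    subject_index: np.ndarray           # (total_windows,) subject position
    objective: float
    objective_history: list[float] = field(default_factory=list)
    cvi_curve: dict[int, float] | None = None

    @property
    def n_subjects(self) -> int:
        return int(self.subject_index.max()) + 1 if self.subject_index.size else 0

    def subject_assignments(self, s: int) -> np.ndarray:
        return self.assignments[self.subject_index == s]


@dataclass
class OccupancyTable:
    """Per-subject percentage of windows spent in each state."""

    percentages: np.ndarray             # (n_subjects, k), rows sum to 100
    groups: list[str]
    subject_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        k = self.percentages.shape[1]
        df = pd.DataFrame(self.percentages,
                          columns=[f"state_{i}" for i in range(k)])
        df.insert(0, "group", self.groups)
        df.insert(0, "subject_id", self.subject_ids)
        return df


def make_taper(window_tr: int, sigma_tr: float = 3.0) -> np.ndarray:
    """Rectangle of width ``window_tr`` convolved with a discrete Gaussian
    (support +/- 3 sigma), renormalized to sum 1.  ``sigma_tr -> 0`` recovers
    uniform weights."""
    if window_tr < 3:
        raise ValueError("window_tr must be >= 3")
    rect = np.ones(window_tr)
    if sigma_tr <= 1e-8:
        return rect / window_tr
    half = int(np.ceil(3.0 * sigma_tr))
    x = np.arange(-half, half + 1, dtype=float)
    gauss = np.exp(-(x**2) / (2.0 * sigma_tr**2))
    taper = np.convolve(rect, gauss)
    return taper / taper.sum()


def windowed_correlation(
    tcs: np.ndarray, taper: np.ndarray, step_tr: int = 1,
    window_tr: int | None = None,
) -> WindowSeries:
    """Taper-weighted Pearson correlation of every component pair, per window.

    With taper support L over T frames and unit step there are T - L + 1
    windows.  A component with zero weighted variance inside a window yields
    correlation 0 for its pairs.
    """
    tcs = np.asarray(tcs, dtype=float)
    n_frames, n_comp = tcs.shape
    taper = np.asarray(taper, dtype=float)
    support = taper.size
    if n_frames < support:
        raise ValueError(f"{n_frames} frames cannot hold a {support}-frame taper")
    w = taper / taper.sum()
    starts = np.arange(0, n_frames - support + 1, step_tr)
    iu, ju = np.triu_indices(n_comp, k=1)
    vectors = np.empty((starts.size, iu.size))
    warned = False
    for wi, s in enumerate(starts):
        seg = tcs[s : s + support]
        mu = w @ seg
        centered = seg - mu
        cov = (centered * w[:, None]).T @ centered
        var = np.diag(cov).copy()
        zero = var <= 0
        if zero.any() and not warned:
            warnings.warn("zero-variance component inside a window; correlation set to 0")
            warned = True
        var[zero] = 1.0
        denom = np.sqrt(np.outer(var, var))
        corr = cov / denom
        corr[zero, :] = 0.0
        corr[:, zero] = 0.0
        vectors[wi] = np.clip(corr[iu, ju], -1.0, 1.0)
    return WindowSeries(
        vectors=vectors, taper=w,
        window_tr=window_tr if window_tr is not None else support,
        step_tr=step_tr, pairs=list(zip(iu.tolist(), ju.tolist())),
    )


def _pool(windows) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(windows, np.ndarray):
        return windows, np.zeros(windows.shape[0], dtype=int)
    mats = [w.vectors if isinstance(w, WindowSeries) else np.asarray(w) for w in windows]
    idx = np.concatenate([np.full(m.shape[0], s, dtype=int) for s, m in enumerate(mats)])
    return np.vstack(mats), idx


def _kmeans_l1_once(
    x: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 200
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    n = x.shape[0]
    # k-means++-style seeding under L1
    centroids = np.empty((k, x.shape[1]))
    centroids[0] = x[rng.integers(n)]
    d = cdist(x, centroids[:1], metric="cityblock").ravel()
    for c in range(1, k):
        p = d / d.sum() if d.sum() > 0 else np.full(n, 1.0 / n)
        centroids[c] = x[rng.choice(n, p=p)]
        d = np.minimum(d, cdist(x, centroids[c : c + 1], metric="cityblock").ravel())
    history: list[float] = []
    assign = np.full(n, -1)
    for _ in range(max_iter):
        dist = cdist(x, centroids, metric="cityblock")
        new_assign = dist.argmin(axis=1)
        obj = float(dist[np.arange(n), new_assign].sum())
        history.append(obj)
        for c in range(k):
            members = x[new_assign == c]
            if members.size == 0:
                # re-seed an emptied cluster at the farthest window
                far = dist.min(axis=1).argmax()
                centroids[c] = x[far]
            else:
                centroids[c] = np.median(members, axis=0)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
    dist = cdist(x, centroids, metric="cityblock")
    assign = dist.argmin(axis=1)
    obj = float(dist[np.arange(n), assign].sum())
    history.append(obj)
    return centroids, assign, obj, history


def cluster_states(
    windows, k: int, restarts: int = 5, seed: int = 0
) -> StateModel:
    """L1-distance k-means (median centroid updates), best of ``restarts``
    seeded initializations by total within-cluster L1 objective."""
    x, subject_index = _pool(windows)
    if x.shape[0] < k:
        raise ValueError(f"{x.shape[0]} windows cannot form {k} states")
    best = None
    seeds = np.random.SeedSequence(seed).spawn(restarts)
    for ss in seeds:
        rng = np.random.default_rng(ss)
        cent, assign, obj, hist = _kmeans_l1_once(x, k, rng)
        if best is None or obj < best[2]:
            best = (cent, assign, obj, hist)
    cent, assign, obj, hist = best
    return StateModel(k=k, centroids=cent, assignments=assign,
                      subject_index=subject_index, objective=obj,
                      objective_history=hist)


def select_k_elbow(
    windows,
    k_range: range = range(2, 9),
    restarts: int = 3,
    seed: int = 0,
    flat_tol: float = 0.05,
) -> tuple[int, dict[int, float]]:
    """Elbow rule on a cluster-validity curve.

    The index at each k is the within-cluster L1 dispersion normalized by the
    total (between-subject) dispersion about the grand median, evaluated from
    k = 1 up to one past the requested range; the elbow is the k in the range
    with maximum discrete curvature of the log-index curve.  A flat curve
    (no curvature above ``flat_tol``) falls back to the smallest k.
    """
    ks = sorted(k_range)
    if not ks:
        raise ValueError("empty k range")
    x, _ = _pool(windows)
    grand = np.median(x, axis=0)
    total = float(np.abs(x - grand).sum())
    if total == 0:
        warnings.warn("degenerate windows: all identical; returning smallest k")
        return ks[0], {k: 0.0 for k in ks}
    eval_ks = range(max(1, ks[0] - 1), ks[-1] + 2)
    curve: dict[int, float] = {}
    for k in eval_ks:
        if k == 1:
            obj = total
        else:
            obj = cluster_states(x, k, restarts=restarts, seed=seed + k).objective
        curve[k] = max(obj / total, 1e-12)
    log_c = {k: np.log(v) for k, v in curve.items()}
    curvature = {
        k: log_c[k - 1] - 2.0 * log_c[k] + log_c[k + 1]
        for k in ks if (k - 1) in log_c and (k + 1) in log_c
    }
    if not curvature or max(curvature.values()) < flat_tol:
        warnings.warn("validity curve is flat: no clear elbow, returning smallest k")
        return ks[0], {k: curve[k] for k in ks}
    k_star = max(curvature, key=lambda k: (curvature[k], -k))
    return k_star, {k: curve[k] for k in ks}


def match_states(a: StateModel, b: StateModel) -> np.ndarray:
    """Permutation ``perm`` maximizing total centroid correlation such that
    state i of ``a`` corresponds to state ``perm[i]`` of ``b``."""
    if a.centroids.shape != b.centroids.shape:
        raise ValueError("state models differ in k or pair dimensionality")
    ca = a.centroids - a.centroids.mean(axis=1, keepdims=True)
    cb = b.centroids - b.centroids.mean(axis=1, keepdims=True)
    ca /= np.maximum(np.linalg.norm(ca, axis=1, keepdims=True), 1e-12)
    cb /= np.maximum(np.linalg.norm(cb, axis=1, keepdims=True), 1e-12)
    corr = ca @ cb.T
    rows, cols = linear_sum_assignment(-corr)
    perm = np.empty(a.k, dtype=int)
    perm[rows] = cols
    return perm


def occupancy(
    sm: StateModel,
    groups: list[str],
    subject_ids: list[str] | None = None,
) -> OccupancyTable:
    """Percentage of each subject's windows in each state (rows sum to 100)."""
    n_subj = sm.n_subjects
    if len(groups) != n_subj:
        raise ValueError("one group label per subject required")
    if subject_ids is None:
        subject_ids = [f"sub-{i:03d}" for i in range(n_subj)]
    pct = np.empty((n_subj, sm.k))
    for s in range(n_subj):
        a = sm.subject_assignments(s)
        if a.size == 0:
            raise ValueError(f"subject {s} has no windows")
        pct[s] = 100.0 * np.bincount(a, minlength=sm.k) / a.size
    return OccupancyTable(percentages=pct, groups=list(groups),
                          subject_ids=list(subject_ids))


def subject_state_means(
    windows: list[WindowSeries], sm: StateModel
) -> np.ndarray:
    """Per-subject mean connectivity vector within each state.

    Returns (n_subjects, k, n_pairs); a state a subject never visits is NaN.
    """
    n_subj = len(windows)
    n_pairs = windows[0].vectors.shape[1]
    out = np.full((n_subj, sm.k, n_pairs), np.nan)
    for s, ws in enumerate(windows):
        a = sm.subject_assignments(s)
        for c in range(sm.k):
            sel = ws.vectors[a == c]
            if sel.size:
                out[s, c] = sel.mean(axis=0)
    return out
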