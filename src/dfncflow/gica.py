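"""Desk-scale group spatial ICA with multi-run stability analysis.

The decomposition follows the usual two-stage scheme: each subject's centered
(frames x voxels) matrix is reduced by temporal PCA, the reductions are
concatenated and reduced again to the requested model order, and spatial ICA
(FastICA fixed-point iteration with symmetric decorrelation) unmixes the group
subspace into independent spatial maps.  Repeating the unmixing from several
random starts and clustering the pooled components by absolute spatial
correlation yields a per-component stability index (Iq) and a run-clustering
validity score (R-index) used to pick the model order: keep the candidate
order whose R-index sits near the minimum while at most two components fall
below the Iq floor.

Subject time courses come from spatial regression of each frame onto the
aggregate maps (dual-regression-style back-reconstruction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.signal import periodogram
from scipy.spatial.distance import squareform
from scipy.stats import skew
from sklearn.decomposition import FastICA

from .synthgen import VolumeSeries

__all__ = [
    "ComponentSet",
    "StabilityReport",
    "ComponentPairing",
    "fit_group_ica",
    "select_model_order",
    "back_reconstruct",
    "flag_artifacts",
    "match_components",
    "replicated_components",
    "make_gica_backend",
]


@dataclass
class ComponentSet:
    """Aggregate spatial maps plus per-subject back-reconstructed time courses."""

    maps: np.ndarray                    # (components, voxels), z-scored rows
    subject_tcs: list[np.ndarray]       # each (frames, components)
    labels: list[str] = field(default_factory=list)   # 'rsn' | 'artifact'
    iq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if not self.labels:
            self.labels = ["rsn"] * self.maps.shape[0]

    @property
    def n_components(self) -> int:
        return self.maps.shape[0]

    def rsn_indices(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.labels) == "rsn")


@dataclass
class StabilityReport:
    model_order: int
    r_index: float
    iq_values: np.ndarray

    def __post_init__(self) -> None:
        self.iq_values = np.asarray(self.iq_values, dtype=float)
        if self.iq_values.size != self.model_order:
            raise ValueError("one Iq value per component required")

    def n_low_iq(self, floor: float = 0.7) -> int:
        return int(np.sum(self.iq_values < floor))


@dataclass
class ComponentPairing:
    pairs: list[tuple[int, int, float]]   # (index in a, index in b, |corr|)
    unpaired_a: list[int]
    unpaired_b: list[int]


def _svd(x: np.ndarray):
    """SVD with a fallback to the slower but more robust LAPACK driver when
    the default divide-and-conquer routine fails to converge."""
    try:
        return np.linalg.svd(x, full_matrices=False)
    except np.linalg.LinAlgError:
        from scipy.linalg import svd as scipy_svd
        return scipy_svd(x, full_matrices=False, lapack_driver="gesvd")


def _as_matrix(subject) -> np.ndarray:
    """Centered (frames, voxels) matrix from a VolumeSeries or array."""
    if isinstance(subject, VolumeSeries):
        x = subject.flatten_voxels().T
    else:
        x = np.asarray(subject, dtype=float)
    return x - x.mean(axis=0)


def _zscore_rows(m: np.ndarray) -> np.ndarray:
    m = m - m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, keepdims=True)
    return m / np.where(sd == 0, 1.0, sd)


def _fix_signs(maps: np.ndarray) -> np.ndarray:
    signs = np.where(skew(maps, axis=1) < 0, -1.0, 1.0)
    return maps * signs[:, None]


def _abs_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    za, zb = _zscore_rows(a), _zscore_rows(b)
    return np.abs(za @ zb.T) / a.shape[1]


def fit_group_ica(
    subjects: list,
    model_order: int,
    n_runs: int = 5,
    seed: int = 0,
    subject_pc_factor: float = 1.5,
) -> tuple[ComponentSet, StabilityReport]:
    """Two-stage PCA + multi-run spatial FastICA with component clustering.

    Returns the centrotype map of each across-run cluster (z-scored, skewness
    sign convention), per-subject back-reconstructed time courses, per-cluster
    Iq stability, and the R-index of the run clustering.
    """
    if len(subjects) < 2:
        raise ValueError("group ICA needs at least 2 subjects")
    data = [_as_matrix(s) for s in subjects]
    n_frames, n_voxels = data[0].shape
    max_rank = min(n_frames - 1, n_voxels)
    if model_order > max_rank:
        raise ValueError(f"model_order {model_order} exceeds data rank {max_rank}")

    r1 = min(max_rank, max(model_order, int(np.ceil(subject_pc_factor * model_order))))
    reduced = []
    for x in data:
        u, s, vt = _svd(x)
        reduced.append(s[:r1, None] * vt[:r1])          # (r1, voxels)
    stacked = np.vstack(reduced)
    u, s, vt = _svd(stacked - stacked.mean(axis=0))
    group = s[:model_order, None] * vt[:model_order]     # (model_order, voxels)

    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    seeds = np.random.SeedSequence(seed).spawn(n_runs)
    all_maps = []
    for run_seed in seeds:
        rs = int(run_seed.generate_state(1)[0] % (2**31 - 1))
        ica = FastICA(
            n_components=model_order, random_state=rs,
            whiten="unit-variance", max_iter=1000, tol=1e-6,
        )
        sources = ica.fit_transform(group.T)             # (voxels, model_order)
        all_maps.append(_zscore_rows(sources.T))
    pooled = np.vstack(all_maps)                         # (n_runs*order, voxels)

    if n_runs == 1:
        warnings.warn("single ICA run: stability Iq reported as 1 by convention")
        maps = _fix_signs(_zscore_rows(pooled))
        iq = np.ones(model_order)
        r_index = 0.0
        clusters = np.arange(model_order)
    else:
        sim = _abs_corr(pooled, pooled)
        np.clip(sim, 0.0, 1.0, out=sim)
        dissim = 1.0 - sim
        np.fill_diagonal(dissim, 0.0)
        z = linkage(squareform(dissim, checks=False), method="average")
        clusters = fcluster(z, t=model_order, criterion="maxclust") - 1
        maps_list, iq_list = [], []
        for c in range(model_order):
            members = np.flatnonzero(clusters == c)
            others = np.flatnonzero(clusters != c)
            within = sim[np.ix_(members, members)]
            # centrotype: member most similar to its cluster mates
            centro = members[np.argmax(within.sum(axis=1))]
            maps_list.append(pooled[centro])
            w_avg = (
                (within.sum() - members.size) / (members.size * (members.size - 1))
                if members.size > 1 else 1.0
            )
            b_avg = sim[np.ix_(members, others)].mean() if others.size else 0.0
            iq_list.append(w_avg - b_avg)
        maps = _fix_signs(_zscore_rows(np.array(maps_list)))
        iq = np.clip(np.array(iq_list), 0.0, 1.0)
        r_index = _r_index(dissim, clusters, model_order)

    subject_tcs = [back_reconstruct(x, maps) for x in data]
    cs = ComponentSet(maps=maps, subject_tcs=subject_tcs, iq=iq)
    report = StabilityReport(model_order=model_order, r_index=r_index, iq_values=iq)
    return cs, report


def _r_index(dissim: np.ndarray, clusters: np.ndarray, k: int) -> float:
    """Cluster-validity ratio: mean over clusters of within-cluster
    dissimilarity divided by the distance to the nearest other cluster.
    Lower values mean compact, well-separated run clusters."""
    terms = []
    for c in range(k):
        members = np.flatnonzero(clusters == c)
        if members.size > 1:
            block = dissim[np.ix_(members, members)]
            within = block.sum() / (members.size * (members.size - 1))
        else:
            within = 0.0
        nearest = np.inf
        for c2 in range(k):
            if c2 == c:
                continue
            m2 = np.flatnonzero(clusters == c2)
            if m2.size:
                nearest = min(nearest, dissim[np.ix_(members, m2)].mean())
        if np.isfinite(nearest) and nearest > 0:
            terms.append(within / nearest)
        else:
            terms.append(within)
    return float(np.mean(terms)) if terms else 0.0


def select_model_order(
    reports: list[StabilityReport],
    iq_floor: float = 0.7,
    max_low_iq: int = 2,
    r_tolerance: float = 0.05,
) -> int:
    """Pick the model order whose R-index is within ``r_tolerance`` of the
    minimum among candidates with at most ``max_low_iq`` components below the
    Iq floor; ties resolve to the smaller order."""
    if not reports:
        raise ValueError("no candidate stability reports")
    ok = [r for r in reports if r.n_low_iq(iq_floor) <= max_low_iq]
    if not ok:
        warnings.warn("no candidate satisfies the Iq rule; falling back to min R-index")
        return min(reports, key=lambda r: (r.r_index, r.model_order)).model_order
    r_min = min(r.r_index for r in ok)
    eligible = [r for r in ok if r.r_index <= r_min * (1.0 + r_tolerance) + 1e-12]
    return min(r.model_order for r in eligible)


def back_reconstruct(subject, maps: np.ndarray) -> np.ndarray:
    """Spatial regression of each frame onto the aggregate maps.

    Returns the least-squares time courses (frames, components); equivalent to
    the first half of dual regression.
    """
    x = _as_matrix(subject)                   # (frames, voxels)
    m = np.asarray(maps, dtype=float)         # (components, voxels)
    if m.shape[1] != x.shape[1]:
        raise ValueError("map voxel dimension does not match subject data")
    gram = m @ m.T
    if np.linalg.matrix_rank(gram) < gram.shape[0]:
        warnings.warn("singular map matrix; pseudo-inverse used")
        return x @ np.linalg.pinv(m)
    return np.linalg.solve(gram, m @ x.T).T


def flag_artifacts(
    cs: ComponentSet,
    tr_s: float,
    theta_lf: float = 0.5,
    lf_cutoff_hz: float = 0.10,
) -> ComponentSet:
    """Label a component 'artifact' when the fraction of its time-course power
    below ``lf_cutoff_hz`` falls under ``theta_lf`` (high-frequency dominated).

    The spectrum is the subject-average periodogram of the back-reconstructed
    time courses.  Labels are set in place on a copy; nothing is removed.
    """
    if cs.subject_tcs[0].shape[0] < 8:
        raise ValueError("artifact flagging needs at least 8 frames")
    fs = 1.0 / tr_s
    labels = []
    for c in range(cs.n_components):
        total = low = 0.0
        for tc in cs.subject_tcs:
            f, pxx = periodogram(tc[:, c] - tc[:, c].mean(), fs=fs)
            keep = f > 0
            total += pxx[keep].sum()
            low += pxx[keep & (f <= lf_cutoff_hz)].sum()
        frac = low / total if total > 0 else 1.0
        labels.append("artifact" if frac < theta_lf else "rsn")
    return ComponentSet(maps=cs.maps, subject_tcs=cs.subject_tcs, labels=labels, iq=cs.iq)


def match_components(
    a: ComponentSet | np.ndarray,
    b: ComponentSet | np.ndarray,
    min_corr: float = 0.5,
) -> ComponentPairing:
    """One-to-one pairing of two map sets maximizing total absolute spatial
    correlation; pairs below ``min_corr`` are dropped and reported unpaired."""
    ma = a.maps if isinstance(a, ComponentSet) else np.asarray(a, dtype=float)
    mb = b.maps if isinstance(b, ComponentSet) else np.asarray(b, dtype=float)
    if ma.shape[1] != mb.shape[1]:
        raise ValueError("component sets live on different voxel grids")
    corr = _abs_corr(ma, mb)
    rows, cols = linear_sum_assignment(-corr)
    pairs, pa, pb = [], set(), set()
    for i, j in zip(rows, cols):
        if corr[i, j] >= min_corr:
            pairs.append((int(i), int(j), float(corr[i, j])))
            pa.add(int(i))
            pb.add(int(j))
    return ComponentPairing(
        pairs=pairs,
        unpaired_a=[i for i in range(ma.shape[0]) if i not in pa],
        unpaired_b=[j for j in range(mb.shape[0]) if j not in pb],
    )


def replicated_components(
    sets: list[ComponentSet], min_corr: float = 0.5
) -> list[np.ndarray]:
    """Intersection filter: components of the first set that can be matched in
    every other set at ``min_corr``; returns matched index arrays, one per set,
    aligned so row r refers to the same replicated component everywhere."""
    if not sets:
        return []
    ref = sets[0]
    keep = {i: [i] for i in range(ref.n_components)}
    for other in sets[1:]:
        pairing = match_components(ref, other, min_corr)
        matched = {i: j for i, j, _ in pairing.pairs}
        keep = {i: idxs + [matched[i]] for i, idxs in keep.items() if i in matched}
    if not keep:
        return [np.empty(0, dtype=int) for _ in sets]
    rows = [keep[i] for i in sorted(keep)]
    arr = np.asarray(rows, dtype=int)
    return [arr[:, s] for s in range(len(sets))]


def make_gica_backend(model_order: int, n_runs: int = 3, seed: int = 0):
    """Adapter giving :func:`dfncflow.preprocess.run_pipeline` a gICA callable."""

    def backend(vols: list[VolumeSeries]):
        cs, _ = fit_group_ica(vols, model_order=model_order, n_runs=n_runs, seed=seed)
        return cs, cs.subject_tcs

    return backend
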