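"""Seeded synthetic resting-state cohorts with planted connectivity states.

The generator emits small 4D volumes in which a handful of smooth spatial
sources mix with source time courses whose mutual correlations switch among a
small set of planted covariance "states".  Group membership (healthy control
vs. mTBI) is expressed purely as a difference in how much time each group
spends in each state, which is exactly the quantity the downstream
sliding-window analysis is meant to recover.  Motion-coupled drift, transient
global spikes, and Gaussian noise are layered on top so that every nuisance
step of the preprocessing pipelines has something real to remove.

All randomness flows through a single ``numpy.random.SeedSequence`` so that an
identical configuration (including the seed) reproduces the cohort
bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "VolumeSeries",
    "RealignmentParams",
    "SynthConfig",
    "Subject",
    "CohortTruth",
    "CohortData",
    "generate_cohort",
    "plant_spikes",
    "synth_motion_trace",
]

#: intensity offset so the series behaves like raw EPI (percent-signal-change
#: scaling in DVARS needs a nonzero voxel mean)
BASELINE_INTENSITY = 1000.0

GROUPS = ("HC", "mTBI")


@dataclass
class VolumeSeries:
    """A 4D intensity array (x, y, z, t) with voxel size and repetition time."""

    intensities: np.ndarray
    voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    tr_s: float = 2.0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 4:
            raise ValueError(
                f"VolumeSeries needs a 4D (x,y,z,t) array, got ndim={self.intensities.ndim}"
            )
        if self.intensities.shape[3] < 1:
            raise ValueError("VolumeSeries needs at least one frame")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("VolumeSeries intensities must be finite")

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.intensities.shape[:3]

    def flatten_voxels(self) -> np.ndarray:
        """Return a (voxels, frames) view of the data."""
        return self.intensities.reshape(-1, self.n_frames)

    def copy(self) -> "VolumeSeries":
        return VolumeSeries(self.intensities.copy(), self.voxel_mm, self.tr_s)


@dataclass
class RealignmentParams:
    """Per-frame rigid-body parameters: 3 translations (mm), 3 rotations (rad)."""

    values: np.ndarray  # (frames, 6)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != 6:
            raise ValueError("RealignmentParams must be a (frames, 6) array")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def translations(self) -> np.ndarray:
        return self.values[:, :3]

    @property
    def rotations(self) -> np.ndarray:
        return self.values[:, 3:]


def _default_states() -> list[np.ndarray]:
    """Two planted connectivity states over five sources: a strongly connected
    state with block structure (sources 0-2 and 3-4 form modules with positive
    cross-talk) and a weakly connected state where only the first module keeps
    a faint residual coupling.  Distinct patterns, not just amplitudes, so
    state centroids are identifiable."""
    strong = np.full((5, 5), 0.25)
    strong[:3, :3] = 0.6
    strong[3:, 3:] = 0.4
    np.fill_diagonal(strong, 1.0)
    weak = np.zeros((5, 5))
    weak[:3, :3] = 0.1
    np.fill_diagonal(weak, 1.0)
    return [strong, weak]


@dataclass
class SynthConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the emulated acquisition: matched pairs, 5-minute runs at
    TR = 2 s (150 frames, the first five treated as dummies downstream).
    """

    n_pairs: int = 48
    grid_shape: tuple[int, int, int] = (8, 8, 8)
    n_sources: int = 5
    n_frames: int = 150
    tr_s: float = 2.0
    state_covs: list[np.ndarray] = field(default_factory=_default_states)
    occupancy_by_group: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {"HC": (0.4, 0.6), "mTBI": (0.6, 0.4)}
    )
    dwell_mean_tr: float = 20.0
    motion_amp_mm: float = 0.3
    motion_coupling: float = 0.0
    spike_rate_per_min: float = 1.5
    spike_amp_sd: float = 6.0
    noise_sd: float = 0.2
    voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    seed: int = 0

    @property
    def n_states(self) -> int:
        return len(self.state_covs)

    def validate(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.n_frames < 10:
            raise ValueError("n_frames must be >= 10")
        for m, cov in enumerate(self.state_covs):
            cov = np.asarray(cov, dtype=float)
            if cov.shape != (self.n_sources, self.n_sources):
                raise ValueError(
                    f"state {m}: covariance shape {cov.shape} does not match "
                    f"n_sources={self.n_sources}"
                )
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ValueError(f"state {m}: covariance is not symmetric")
            if not np.allclose(np.diag(cov), 1.0, atol=1e-8):
                raise ValueError(f"state {m}: covariance diagonal must be 1 (correlation form)")
            if np.linalg.eigvalsh(cov).min() < -1e-10:
                raise ValueError(f"state {m}: covariance is not positive semi-definite")
        for group, occ in self.occupancy_by_group.items():
            occ = np.asarray(occ, dtype=float)
            if occ.shape != (self.n_states,):
                raise ValueError(f"group {group}: occupancy length != number of states")
            if np.any(occ < 0) or not math.isclose(occ.sum(), 1.0, rel_tol=0, abs_tol=1e-8):
                raise ValueError(f"group {group}: occupancy must be a probability vector")
        for name in ("dwell_mean_tr", "motion_amp_mm", "motion_coupling",
                     "spike_rate_per_min", "spike_amp_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.dwell_mean_tr < 1:
            raise ValueError("dwell_mean_tr must be >= 1 TR")


@dataclass
class Subject:
    subject_id: str
    group: str
    pair_id: int
    age: float
    gender: str
    volume: VolumeSeries
    realignment: RealignmentParams


@dataclass
class CohortTruth:
    """Ground truth planted by the generator."""

    source_maps: np.ndarray          # (n_sources, voxels)
    source_tcs: dict[str, np.ndarray]        # subject_id -> (frames, n_sources)
    state_sequence: dict[str, np.ndarray]    # subject_id -> (frames,) int
    spike_frames: dict[str, np.ndarray]      # subject_id -> sorted int frames
    state_covs: list[np.ndarray]

    def occupancy(self, subject_id: str, n_states: int | None = None) -> np.ndarray:
        seq = self.state_sequence[subject_id]
        k = n_states if n_states is not None else len(self.state_covs)
        return np.bincount(seq, minlength=k) / seq.size


@dataclass
class CohortData:
    subjects: list[Subject]
    truth: CohortTruth
    config: SynthConfig

    def by_group(self, group: str) -> list[Subject]:
        return [s for s in self.subjects if s.group == group]


# --- spatial sources ---------------------------------------------------------

_CENTER_FRACTIONS = np.array([
    (0.25, 0.25, 0.30),
    (0.75, 0.30, 0.35),
    (0.30, 0.75, 0.45),
    (0.70, 0.70, 0.70),
    (0.35, 0.40, 0.78),
    (0.78, 0.55, 0.22),
    (0.50, 0.18, 0.62),
    (0.20, 0.60, 0.60),
])


def make_source_maps(grid_shape: tuple[int, int, int], n_sources: int) -> np.ndarray:
    """Smooth Gaussian blobs, peak-normalized, pairwise spatial correlation < 0.3.

    Centers sit on a fixed, well-separated layout so independent-component
    recovery is identifiable even on a tiny grid.
    """
    if n_sources > len(_CENTER_FRACTIONS):
        raise ValueError(f"at most {len(_CENTER_FRACTIONS)} planted sources supported")
    grid = np.asarray(grid_shape, dtype=float)
    sigma = 0.13 * grid.min()
    coords = np.stack(np.meshgrid(*[np.arange(n) for n in grid_shape], indexing="ij"), axis=-1)
    maps = np.empty((n_sources, int(np.prod(grid_shape))))
    for s in range(n_sources):
        center = _CENTER_FRACTIONS[s] * (grid - 1)
        d2 = np.sum((coords - center) ** 2, axis=-1)
        blob = np.exp(-d2 / (2.0 * sigma**2))
        maps[s] = blob.ravel()
    return maps


# --- temporal dynamics -------------------------------------------------------

def sample_state_sequence(
    n_frames: int,
    occupancy: np.ndarray,
    dwell_mean_tr: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Semi-Markov state path: at each renewal the next state is drawn from the
    target occupancy distribution and held for a geometric dwell time with the
    given mean, so the expected fraction of frames in state m equals
    ``occupancy[m]``."""
    p_leave = 1.0 / dwell_mean_tr
    seq = np.empty(n_frames, dtype=np.intp)
    t = 0
    while t < n_frames:
        state = rng.choice(occupancy.size, p=occupancy)
        dwell = rng.geometric(p_leave)
        seq[t : t + dwell] = state
        t += dwell
    return seq


def _psd_sqrt(cov: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    return v @ np.diag(np.sqrt(w)) @ v.T


def _whiten_exact(x: np.ndarray) -> np.ndarray:
    """Transform (n, p) draws so the sample covariance is exactly identity."""
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / (x.shape[0] - 1)
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 1e-12, None)
    return xc @ v @ np.diag(1.0 / np.sqrt(w)) @ v.T


def sample_source_tcs(
    state_seq: np.ndarray,
    state_covs: list[np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance source time courses whose correlation, pooled over the
    frames a state occupies, equals that state's planted matrix exactly
    (whenever the state holds enough frames for empirical whitening)."""
    n_frames = state_seq.size
    n_sources = state_covs[0].shape[0]
    tcs = np.zeros((n_frames, n_sources))
    for m, cov in enumerate(state_covs):
        idx = np.flatnonzero(state_seq == m)
        if idx.size == 0:
            continue
        draws = rng.standard_normal((idx.size, n_sources))
        if idx.size > n_sources + 1:
            draws = _whiten_exact(draws)
        tcs[idx] = draws @ _psd_sqrt(np.asarray(cov, dtype=float))
    return tcs


# --- motion ------------------------------------------------------------------

def synth_motion_trace(n_frames: int, amp_mm: float, seed: int) -> RealignmentParams:
    """Smooth random-walk realignment traces with occasional jumps.

    Translations scale as ``amp_mm`` (mm); rotations use the same shape scaled
    to a few hundredths of a radian per mm of amplitude.  Traces start at zero
    (first frame is the reference), and the whole trace is exactly
    proportional to ``amp_mm``.
    """
    if n_frames < 2:
        raise ValueError("motion trace needs at least 2 frames")
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal((n_frames, 6)) * 0.05
    walk = np.cumsum(steps, axis=0)
    walk = gaussian_filter1d(walk, sigma=2.0, axis=0, mode="nearest")
    jumps = rng.random(n_frames) < 0.02
    jump_sizes = rng.standard_normal((n_frames, 6)) * 0.4 * jumps[:, None]
    walk += np.cumsum(jump_sizes, axis=0)
    walk -= walk[0]  # reference frame
    walk[:, 3:] *= 0.02  # rotations in radians
    return RealignmentParams(walk * amp_mm)


def _motion_leak_trace(realign: RealignmentParams) -> np.ndarray:
    # signed sum of translations: lies in the span of the realignment
    # regressors, so nuisance regression can remove the leak exactly
    return realign.translations.sum(axis=1)


def motion_gradient_map(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Rank-1 leak pattern: a linear intensity ramp along x (z-scored)."""
    nx = grid_shape[0]
    ramp = np.linspace(-1.0, 1.0, nx)
    grad = np.broadcast_to(ramp[:, None, None], grid_shape).ravel().astype(float)
    return (grad - grad.mean()) / grad.std()


# --- spikes ------------------------------------------------------------------

def plant_spikes(
    series: VolumeSeries,
    frames: list[int] | np.ndarray,
    amp_sd: float,
    seed: int = 0,
) -> VolumeSeries:
    """Add a global intensity deviation of ``amp_sd`` baseline SDs at the
    listed frames; every other frame is untouched."""
    frames = np.asarray(frames, dtype=int)
    if frames.size == 0 or amp_sd == 0:
        return series.copy()
    bad = frames[(frames < 0) | (frames >= series.n_frames)]
    if bad.size:
        raise IndexError(f"spike frame {bad[0]} outside 0..{series.n_frames - 1}")
    rng = np.random.default_rng(seed)
    data = series.intensities.copy()
    flat = data.reshape(-1, series.n_frames)
    baseline_sd = float(np.mean(flat.std(axis=1)))
    if baseline_sd == 0:
        baseline_sd = 1.0
    signs = rng.choice([-1.0, 1.0], size=frames.size)
    for f, sign in zip(frames, signs):
        flat[:, f] += sign * amp_sd * baseline_sd
    return VolumeSeries(data, series.voxel_mm, series.tr_s)


# --- cohort ------------------------------------------------------------------

def generate_cohort(cfg: SynthConfig) -> CohortData:
    """Generate a matched-pair cohort under the planted-state model.

    Per subject, the voxel signal is the sum of (i) source maps times their
    state-switching time courses, (ii) a rank-1 motion leak proportional to
    the subject's translation trace, (iii) planted global spikes and (iv)
    white Gaussian noise, all riding on a constant baseline intensity.
    """
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    maps = make_source_maps(cfg.grid_shape, cfg.n_sources)
    grad_map = motion_gradient_map(cfg.grid_shape)
    duration_min = cfg.n_frames * cfg.tr_s / 60.0

    subjects: list[Subject] = []
    truth = CohortTruth(
        source_maps=maps,
        source_tcs={},
        state_sequence={},
        spike_frames={},
        state_covs=[np.asarray(c, dtype=float) for c in cfg.state_covs],
    )

    seqs = root.spawn(2 * cfg.n_pairs)
    idx = 0
    for pair in range(cfg.n_pairs):
        pair_rng = np.random.default_rng(root.entropy + 7919 * (pair + 1))
        age = max(18.0, pair_rng.normal(28.0, 9.0))
        gender = "F" if pair % 2 == 0 else "M"
        for group in GROUPS:
            sid = f"sub-{idx:03d}"
            rng = np.random.default_rng(seqs[idx])
            occ = np.asarray(cfg.occupancy_by_group[group], dtype=float)
            seq = sample_state_sequence(cfg.n_frames, occ, cfg.dwell_mean_tr, rng)
            tcs = sample_source_tcs(seq, truth.state_covs, rng)

            signal = maps.T @ tcs.T  # (voxels, frames)
            realign = synth_motion_trace(
                cfg.n_frames, cfg.motion_amp_mm, seed=int(rng.integers(2**31 - 1))
            )
            if cfg.motion_coupling > 0 and cfg.motion_amp_mm > 0:
                leak = _motion_leak_trace(realign)
                signal = signal + cfg.motion_coupling * np.outer(grad_map, leak)
            if cfg.noise_sd > 0:
                signal = signal + rng.normal(0.0, cfg.noise_sd, size=signal.shape)

            data = BASELINE_INTENSITY + signal.reshape(*cfg.grid_shape, cfg.n_frames)
            vol = VolumeSeries(data, cfg.voxel_mm, cfg.tr_s)

            n_spikes = rng.poisson(cfg.spike_rate_per_min * duration_min)
            n_spikes = min(n_spikes, cfg.n_frames // 4)
            if n_spikes > 0 and cfg.spike_amp_sd > 0:
                frames = np.sort(rng.choice(
                    np.arange(1, cfg.n_frames), size=n_spikes, replace=False))
                vol = plant_spikes(vol, frames, cfg.spike_amp_sd,
                                   seed=int(rng.integers(2**31 - 1)))
            else:
                frames = np.empty(0, dtype=int)

            subjects.append(Subject(sid, group, pair, age, gender, vol, realign))
            truth.source_tcs[sid] = tcs
            truth.state_sequence[sid] = seq
            truth.spike_frames[sid] = frames
            idx += 1

    return CohortData(subjects=subjects, truth=truth, config=cfg)
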