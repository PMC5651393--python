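"""Voxel- and component-level preprocessing steps and the four pipeline orderings.

Four pipelines share the same steps — spike regression (SpkReg), motion
regression (MotReg), spatial smoothing, group ICA, cubic-spline spike
interpolation, and band-pass filtering — and differ only in *where* the two
nuisance regressions sit relative to smoothing and group ICA:

    PA: SpkMotReg -> Smoothing -> gICA -> Interp -> Filter
    PB: MotReg    -> Smoothing -> gICA -> SpkReg -> Interp -> Filter
    PC: SpkReg    -> Smoothing -> gICA -> MotReg -> Interp -> Filter
    PD:              Smoothing -> gICA -> SpkMotReg -> Interp -> Filter

Steps placed before gICA act voxel-wise on the 4D series; steps placed after
act on the back-reconstructed component time courses.  Both uses share one
regression operator, so residual orthogonality holds identically in either
position.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter
from scipy.signal import butter, sosfiltfilt

from .synthgen import RealignmentParams, VolumeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeSet",
    "RegressorMatrix",
    "PipelineConfig",
    "PipelineResult",
    "PIPELINE_PLANS",
    "drop_dummy_volumes",
    "detect_spikes_dvars",
    "build_regressors",
    "regress_nuisance",
    "smooth_spatial",
    "interpolate_spikes",
    "bandpass_filter",
    "run_pipeline",
]

PIPELINE_PLANS: dict[str, tuple[str, ...]] = {
    "PA": ("SpkMotReg", "Smoothing", "gICA", "Interp", "Filter"),
    "PB": ("MotReg", "Smoothing", "gICA", "SpkReg", "Interp", "Filter"),
    "PC": ("SpkReg", "Smoothing", "gICA", "MotReg", "Interp", "Filter"),
    "PD": ("Smoothing", "gICA", "SpkMotReg", "Interp", "Filter"),
}

GAUSS_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class SpikeSet:
    """Frames flagged as signal spikes by DVARS thresholding."""

    frames: np.ndarray
    threshold_sd: float
    dvars_trace: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        if self.frames.size and np.any(np.diff(self.frames) <= 0):
            raise ValueError("spike frames must be strictly increasing")
        if self.frames.size and self.frames[0] == 0:
            raise ValueError("frame 0 has no backward difference and cannot be a spike")

    @property
    def n_spikes(self) -> int:
        return int(self.frames.size)


@dataclass
class RegressorMatrix:
    """Nuisance design columns with per-column labels."""

    values: np.ndarray  # (frames, n_regressors)
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.labels):
            raise ValueError("label count does not match regressor columns")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass
class PipelineConfig:
    """One analysis variant: ordering x spike threshold x model order x window."""

    pipeline_id: str
    spike_threshold_sd: float = 3.0
    model_order: int = 70
    window_tr: int = 30

    def __post_init__(self) -> None:
        if self.pipeline_id not in PIPELINE_PLANS:
            raise ValueError(
                f"unknown pipeline {self.pipeline_id!r}; choose from {sorted(PIPELINE_PLANS)}"
            )
        if self.spike_threshold_sd <= 0:
            raise ValueError("spike_threshold_sd must be positive")
        if self.model_order < 1 or self.window_tr < 1:
            raise ValueError("model_order and window_tr must be positive")

    @property
    def step_plan(self) -> tuple[str, ...]:
        return PIPELINE_PLANS[self.pipeline_id]

    @property
    def config_id(self) -> str:
        return (
            f"{self.pipeline_id}_thr{self.spike_threshold_sd:g}"
            f"_ord{self.model_order}_win{self.window_tr}"
        )


# --- individual steps --------------------------------------------------------

def drop_dummy_volumes(series: VolumeSeries, n_dummy: int) -> VolumeSeries:
    """Remove the first ``n_dummy`` frames (T1 equilibration dummies)."""
    if n_dummy < 0:
        raise ValueError("n_dummy must be nonnegative")
    if n_dummy >= series.n_frames:
        raise ValueError(
            f"cannot drop {n_dummy} dummies from a {series.n_frames}-frame series"
        )
    if n_dummy == 0:
        return series.copy()
    return VolumeSeries(series.intensities[..., n_dummy:].copy(),
                        series.voxel_mm, series.tr_s)


def dvars_trace(series: VolumeSeries) -> np.ndarray:
    """DVARS: RMS over voxels of the frame-to-frame difference of the
    percent-signal-change–scaled series.  Index 0 (no backward difference)
    is reported as 0."""
    flat = series.flatten_voxels()
    mean = flat.mean(axis=1, keepdims=True)
    safe = np.where(np.abs(mean) < 1e-12, 1.0, mean)
    psc = 100.0 * (flat - mean) / safe
    diff = np.diff(psc, axis=1)
    trace = np.zeros(series.n_frames)
    trace[1:] = np.sqrt(np.mean(diff**2, axis=0))
    return trace


def detect_spikes_dvars(series: VolumeSeries, threshold_sd: float) -> SpikeSet:
    """Flag frames whose DVARS z-score (against the run's own DVARS mean and
    SD, single pass) exceeds ``threshold_sd``."""
    if series.n_frames < 3:
        raise ValueError("spike detection needs at least 3 frames")
    trace = dvars_trace(series)
    body = trace[1:]
    sd = body.std()
    if sd == 0:
        warnings.warn("constant series: DVARS has zero variance, no spikes flagged")
        return SpikeSet(np.empty(0, dtype=int), threshold_sd, trace)
    z = (body - body.mean()) / sd
    frames = 1 + np.flatnonzero(z > threshold_sd)
    return SpikeSet(frames, threshold_sd, trace)


def build_regressors(
    realign: RealignmentParams | None,
    spikes: SpikeSet | None = None,
    parts: set[str] | frozenset[str] = frozenset({"trends", "motion", "derivatives", "spikes"}),
    n_frames: int | None = None,
) -> RegressorMatrix:
    """Assemble the nuisance design in fixed order: polynomial trends (1-3),
    the six realignment parameters, their backward-difference derivatives
    (zero at frame 0), and one unit indicator per spike frame."""
    parts = set(parts)
    if n_frames is None:
        if realign is None:
            raise ValueError("n_frames required when no realignment parameters given")
        n_frames = realign.n_frames
    if realign is not None and realign.n_frames != n_frames:
        raise ValueError(
            f"realignment length {realign.n_frames} does not match {n_frames} frames"
        )
    cols: list[np.ndarray] = []
    labels: list[str] = []
    if "trends" in parts:
        t = np.linspace(-1.0, 1.0, n_frames)
        for p in (1, 2, 3):
            cols.append(t**p)
            labels.append(f"trend-{p}")
    if "motion" in parts:
        if realign is None:
            raise ValueError("motion part requested without realignment parameters")
        for j, name in enumerate(["x", "y", "z", "pitch", "yaw", "roll"]):
            cols.append(realign.values[:, j])
            labels.append(f"mp-{name}")
    if "derivatives" in parts:
        if realign is None:
            raise ValueError("derivatives part requested without realignment parameters")
        deriv = np.zeros_like(realign.values)
        deriv[1:] = np.diff(realign.values, axis=0)
        for j, name in enumerate(["x", "y", "z", "pitch", "yaw", "roll"]):
            cols.append(deriv[:, j])
            labels.append(f"mpd-{name}")
    if "spikes" in parts and spikes is not None and spikes.n_spikes:
        for f in spikes.frames:
            col = np.zeros(n_frames)
            col[f] = 1.0
            cols.append(col)
            labels.append(f"spike-{f}")
    if not cols:
        return RegressorMatrix(np.empty((n_frames, 0)), [])
    return RegressorMatrix(np.column_stack(cols), labels)


def _residualize(y: np.ndarray, reg: RegressorMatrix) -> np.ndarray:
    """OLS residuals of (frames, channels) data on [intercept | regressors]."""
    n = y.shape[0]
    design = np.column_stack([np.ones(n), reg.values]) if reg.values.size else np.ones((n, 1))
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn("rank-deficient regressor matrix; pseudo-inverse used")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def regress_nuisance(
    signal: VolumeSeries | np.ndarray, reg: RegressorMatrix
) -> VolumeSeries | np.ndarray:
    """Orthogonalize the signal against the regressors (OLS with intercept).

    Applied voxel-wise for a :class:`VolumeSeries`, column-wise for a
    (frames, components) array.  Residuals are orthogonal to every regressor
    column to numerical precision.
    """
    if isinstance(signal, VolumeSeries):
        if reg.n_frames != signal.n_frames:
            raise ValueError("regressor frame count does not match series")
        flat = signal.flatten_voxels().T  # (frames, voxels)
        resid = _residualize(flat, reg)
        data = resid.T.reshape(signal.intensities.shape)
        return VolumeSeries(data, signal.voxel_mm, signal.tr_s)
    signal = np.asarray(signal, dtype=float)
    if reg.n_frames != signal.shape[0]:
        raise ValueError("regressor frame count does not match time courses")
    return _residualize(signal, reg)


def smooth_spatial(series: VolumeSeries, fwhm_mm: float) -> VolumeSeries:
    """Per-frame 3D Gaussian smoothing; sigma in voxels derived from FWHM in mm,
    reflective boundaries."""
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be nonnegative")
    if fwhm_mm == 0:
        return series.copy()
    sigma_vox = [fwhm_mm / (GAUSS_FWHM_TO_SIGMA * vm) for vm in series.voxel_mm]
    out = np.empty_like(series.intensities)
    for t in range(series.n_frames):
        out[..., t] = gaussian_filter(series.intensities[..., t], sigma_vox, mode="reflect")
    return VolumeSeries(out, series.voxel_mm, series.tr_s)


def interpolate_spikes(tc: np.ndarray, spikes: SpikeSet) -> np.ndarray:
    """Replace values at spike frames with a cubic spline through the clean
    frames; clean frames pass through unchanged."""
    tc = np.asarray(tc, dtype=float)
    if spikes.n_spikes == 0:
        return tc.copy()
    n = tc.shape[0]
    if spikes.n_spikes >= n - 3:
        raise ValueError("too few clean frames to fit a cubic spline")
    mask = np.ones(n, dtype=bool)
    mask[spikes.frames] = False
    if not mask[0] or not mask[-1]:
        warnings.warn("spike at series edge: spline extrapolation used")
    good = np.flatnonzero(mask)
    spline = CubicSpline(good, tc[good], axis=0, extrapolate=True)
    out = tc.copy()
    out[spikes.frames] = spline(spikes.frames)
    return out


def bandpass_filter(
    tc: np.ndarray,
    low_hz: float = 0.01,
    high_hz: float = 0.15,
    order: int = 5,
    tr_s: float = 2.0,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the time axis of a
    (frames, components) array."""
    nyquist = 0.5 / tr_s
    if not (0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz must sit inside (0, {nyquist}) Hz at TR={tr_s}s"
        )
    sos = butter(order, [low_hz, high_hz], btype="bandpass", fs=1.0 / tr_s, output="sos")
    return sosfiltfilt(sos, np.asarray(tc, dtype=float), axis=0)


# --- pipeline assembly -------------------------------------------------------

_REG_PARTS = {
    "SpkReg": frozenset({"spikes"}),
    "MotReg": frozenset({"trends", "motion", "derivatives"}),
    "SpkMotReg": frozenset({"trends", "motion", "derivatives", "spikes"}),
}


@dataclass
class PipelineResult:
    """Cleaned per-subject component time courses plus provenance."""

    subject_tcs: list[np.ndarray]            # each (frames, components)
    component_set: object                    # whatever the gICA backend returned
    spike_sets: list[SpikeSet]
    config: PipelineConfig
    provenance: list[dict] = field(default_factory=list)


def run_pipeline(
    subjects: list[tuple[VolumeSeries, RealignmentParams]],
    cfg: PipelineConfig,
    gica_backend,
    n_dummy: int = 5,
    fwhm_mm: float = 6.0,
    band_hz: tuple[float, float] = (0.01, 0.15),
) -> PipelineResult:
    """Execute one pipeline ordering end to end for a cohort.

    ``gica_backend`` is a callable mapping a list of cleaned
    :class:`VolumeSeries` to ``(component_set, subject_tcs)`` where
    ``subject_tcs`` is a list of (frames, components) arrays.  Spike frames
    are detected once on the dummy-trimmed raw series and reused by every
    spike-handling step of the plan.
    """
    provenance: list[dict] = []
    vols: list[VolumeSeries] = []
    realigns: list[RealignmentParams] = []
    for vol, realign in subjects:
        if realign.n_frames != vol.n_frames:
            raise ValueError("realignment length does not match volume frames")
        vols.append(drop_dummy_volumes(vol, n_dummy))
        realigns.append(RealignmentParams(realign.values[n_dummy:]))
    provenance.append({"step": "DropDummies", "n_dummy": n_dummy})

    spike_sets = [detect_spikes_dvars(v, cfg.spike_threshold_sd) for v in vols]
    provenance.append({
        "step": "DetectSpikes", "threshold_sd": cfg.spike_threshold_sd,
        "n_spikes": [s.n_spikes for s in spike_sets],
    })

    tcs: list[np.ndarray] | None = None
    component_set = None
    for step in cfg.step_plan:
        try:
            if step in _REG_PARTS:
                parts = _REG_PARTS[step]
                regs = [
                    build_regressors(realigns[i], spike_sets[i], parts)
                    for i in range(len(vols))
                ]
                if tcs is None:
                    vols = [regress_nuisance(v, r) for v, r in zip(vols, regs)]
                else:
                    tcs = [regress_nuisance(t, r) for t, r in zip(tcs, regs)]
                provenance.append({"step": step, "parts": sorted(parts),
                                   "stage": "voxel" if tcs is None else "component"})
            elif step == "Smoothing":
                vols = [smooth_spatial(v, fwhm_mm) for v in vols]
                provenance.append({"step": step, "fwhm_mm": fwhm_mm})
            elif step == "gICA":
                component_set, tcs = gica_backend(vols)
                provenance.append({"step": step, "model_order": cfg.model_order})
            elif step == "Interp":
                tcs = [interpolate_spikes(t, s) for t, s in zip(tcs, spike_sets)]
                provenance.append({"step": step})
            elif step == "Filter":
                tr = subjects[0][0].tr_s
                tcs = [bandpass_filter(t, *band_hz, tr_s=tr) for t in tcs]
                provenance.append({"step": step, "band_hz": list(band_hz)})
            else:  # pragma: no cover - plans are fixed
                raise ValueError(f"unknown step {step!r}")
        except Exception as exc:
            raise RuntimeError(f"pipeline {cfg.pipeline_id} failed at step {step}: {exc}") from exc

    return PipelineResult(tcs, component_set, spike_sets, cfg, provenance)
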