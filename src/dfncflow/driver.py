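"""End-to-end driver: synthetic cohort -> preprocessing -> group ICA ->
sliding-window states -> occupancy statistics -> nested classification.

One :class:`RunConfig` fixes everything; all randomness descends from its
single seed through stage-scoped substreams, so a repeated run reproduces the
report bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from . import classify, dfnc, gica, preprocess, stats
from .preprocess import PipelineConfig
from .synthgen import SynthConfig, generate_cohort

__all__ = ["RunConfig", "run_all", "report_hash"]


@dataclass
class RunConfig:
    """Factor grid and stage parameters for a full analysis run."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    pipelines: tuple[str, ...] = ("PA", "PB", "PC", "PD")
    thresholds: tuple[float, ...] = (2.5, 3.0, 4.0)
    model_orders: tuple[int, ...] = (60, 70, 80)
    windows: tuple[int, ...] = (15, 30, 45)
    taper_sigma_tr: float = 3.0
    n_dummy: int = 5
    fwhm_mm: float = 6.0
    band_hz: tuple[float, float] = (0.01, 0.15)
    gica_runs: int = 2
    k_states: int | None = None         # None: choose by elbow on the first config
    k_range: tuple[int, int] = (2, 8)
    svm_C: float = 0.01
    null_B: int = 100
    seed: int = 0

    def enumerate(self) -> list[PipelineConfig]:
        return classify.enumerate_configs(
            self.pipelines, self.thresholds, self.model_orders, self.windows
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 12)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def report_hash(report: dict) -> str:
    payload = json.dumps(_jsonable(report), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage for every configuration and aggregate one report.

    Preprocessing + group ICA run once per (pipeline, threshold, order) combo;
    each window size then reuses the cleaned component time courses.  The
    state count is chosen by the elbow rule on the first configuration and
    held fixed so occupancies and features are comparable across the grid.
    """
    synth_cfg = cfg.synth
    if synth_cfg.seed != cfg.seed:
        synth_cfg = SynthConfig(**{**synth_cfg.__dict__, "seed": cfg.seed})
    cohort = generate_cohort(synth_cfg)

    # covariates + matched-pair outlier exclusion, spikes at the first threshold
    trimmed = [preprocess.drop_dummy_volumes(s.volume, cfg.n_dummy)
               for s in cohort.subjects]
    spike_counts = [
        preprocess.detect_spikes_dvars(v, cfg.thresholds[0]).n_spikes for v in trimmed
    ]
    covariates = stats.build_covariate_table(cohort, spike_counts, n_dummy=cfg.n_dummy)
    cohort, covariates, exclusion = stats.exclude_outliers(cohort, covariates)

    subjects = [(s.volume, s.realignment) for s in cohort.subjects]
    groups = [s.group for s in cohort.subjects]
    labels = np.asarray([1 if g == "mTBI" else 0 for g in groups])
    subject_ids = [s.subject_id for s in cohort.subjects]

    report: dict = {
        "seed": cfg.seed,
        "n_subjects": len(cohort.subjects),
        "exclusion": exclusion,
        "configurations": {},
    }

    # one pipeline+gICA pass per (pipeline, threshold, order)
    cleaned: dict[tuple, preprocess.PipelineResult] = {}
    combo_seed = {}
    combos = [(p, t, o) for p in cfg.pipelines for t in cfg.thresholds
              for o in cfg.model_orders]
    for ci, (p, t, o) in enumerate(combos):
        combo_seed[(p, t, o)] = cfg.seed + 1000 + ci
        pc = PipelineConfig(pipeline_id=p, spike_threshold_sd=t, model_order=o,
                            window_tr=cfg.windows[0])
        backend = gica.make_gica_backend(o, n_runs=cfg.gica_runs,
                                         seed=combo_seed[(p, t, o)])
        cleaned[(p, t, o)] = preprocess.run_pipeline(
            subjects, pc, backend, n_dummy=cfg.n_dummy,
            fwhm_mm=cfg.fwhm_mm, band_hz=cfg.band_hz,
        )

    k = cfg.k_states
    features_by_config: dict[str, classify.FeatureSet] = {}
    state_means_by_config: dict[str, np.ndarray] = {}
    # states are matched to a reference model per pair dimensionality
    # (centroids of different model orders are not comparable)
    reference_states: dict[int, dfnc.StateModel] = {}
    for pconf in cfg.enumerate():
        key = (pconf.pipeline_id, pconf.spike_threshold_sd, pconf.model_order)
        result = cleaned[key]
        taper = dfnc.make_taper(pconf.window_tr, cfg.taper_sigma_tr)
        window_series = [
            dfnc.windowed_correlation(tc, taper, window_tr=pconf.window_tr)
            for tc in result.subject_tcs
        ]
        if k is None:
            k, _curve = dfnc.select_k_elbow(
                window_series, k_range=range(cfg.k_range[0], cfg.k_range[1] + 1),
                restarts=3, seed=cfg.seed + 17,
            )
            report["k_states"] = int(k)
        sm = dfnc.cluster_states(window_series, k, restarts=3,
                                 seed=combo_seed[key] + pconf.window_tr)
        n_pairs = sm.centroids.shape[1]
        if n_pairs not in reference_states:
            reference_states[n_pairs] = sm
            perm = np.arange(k)
        else:
            perm = dfnc.match_states(reference_states[n_pairs], sm)
        # align state labels to the reference configuration
        relabel = np.empty(k, dtype=int)
        relabel[perm] = np.arange(k)
        sm = dfnc.StateModel(
            k=sm.k, centroids=sm.centroids[perm],
            assignments=relabel[sm.assignments],
            subject_index=sm.subject_index, objective=sm.objective,
            objective_history=sm.objective_history,
        )
        occ = dfnc.occupancy(sm, groups, subject_ids)
        occ_tests = stats.occupancy_tests(occ)
        means = dfnc.subject_state_means(window_series, sm)
        fs = classify.build_features(means, labels, subject_ids=subject_ids,
                                     config_id=pconf.config_id)
        features_by_config[pconf.config_id] = fs
        state_means_by_config[pconf.config_id] = means
        between = occ_tests.table.query("test == 'between_group'")
        report["configurations"][pconf.config_id] = {
            "pipeline": pconf.pipeline_id,
            "spike_threshold_sd": pconf.spike_threshold_sd,
            "model_order": pconf.model_order,
            "window_tr": pconf.window_tr,
            "mean_occupancy": occ.percentages.mean(axis=0),
            "occupancy_t": between["t"].to_numpy(),
            "occupancy_p": between["p"].to_numpy(),
        }

    # pipeline comparison at the reference parameter combination
    ref = (cfg.thresholds[0], cfg.model_orders[0], cfg.windows[0])
    manova_by_state, beta_tables = {}, {}
    for state in range(k):
        by_pipe = {
            p: state_means_by_config[
                PipelineConfig(p, ref[0], ref[1], ref[2]).config_id][:, state, :]
            for p in cfg.pipelines
        }
        res = stats.manova_pipelines(by_pipe)
        manova_by_state[state] = res.table.iloc[0].to_dict()
        beta_tables[state] = {
            p: stats.beta_strength(x, covariates) for p, x in by_pipe.items()
        }
    report["manova_by_state"] = manova_by_state
    report["beta_anova_by_state"] = {
        state: stats.beta_strength_anova(tabs).table.to_dict(orient="records")
        for state, tabs in beta_tables.items()
    }

    nested = classify.nested_selection(features_by_config, C=cfg.svm_C,
                                       covariates=covariates)
    null = classify.bootstrap_null(
        nested.auc_grid, features_by_config, B=cfg.null_B,
        seed=cfg.seed + 99, C=cfg.svm_C,
    )
    report["nested"] = {
        "final_auc": nested.auc,
        "selection_counts": nested.selection_counts,
        "auc_grid_shape": list(nested.auc_grid.shape),
        "auc_grid_entries": int(nested.auc_grid.size),
        "mean_auc_by_config": {
            name: float(m) for name, m in
            zip(features_by_config, nested.auc_grid.mean(axis=0))
        },
        "null_threshold": null["null_threshold"],
        "significant_configs": [
            name for name, sig in zip(features_by_config, null["significant"]) if sig
        ],
    }
    report = _jsonable(report)
    report["report_hash"] = report_hash(report)
    return report
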