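"""Motion covariates, outlier exclusion, occupancy tests, and pipeline comparisons.

Head motion is summarized per subject by two frame-wise displacement means —
TRN = mean over frames of |d(dx)| + |d(dy)| + |d(dz)| (mm) and ROT likewise for
the three rotations (radians) — plus the detected spike count.  Subjects
extreme on at least two of these measures are excluded together with their
matched pair partners.  Group differences in state occupancy use unpaired
t-tests; differences among pipelines use one-way MANOVA (Wilks lambda with the
Bartlett chi-square approximation) on per-state mean connectivity vectors,
followed by per-edge ANOVAs; covariate influence is quantified by per-edge
absolute regression coefficients |beta|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dfnc import OccupancyTable
from .synthgen import CohortData, RealignmentParams

__all__ = [
    "StatsResult",
    "compute_fwd",
    "build_covariate_table",
    "outlier_mask",
    "exclude_outliers",
    "occupancy_tests",
    "manova_pipelines",
    "anova_per_edge",
    "beta_strength",
    "beta_strength_anova",
]

COVARIATE_COLUMNS = ["diagnosis", "gender", "age", "TRN", "ROT", "spk"]


@dataclass
class StatsResult:
    """A named statistical test with its tidy result table."""

    name: str
    table: pd.DataFrame
    extras: dict | None = None


def compute_fwd(realign: RealignmentParams) -> tuple[float, float]:
    """Frame-wise displacement means: (TRN in mm, ROT in radians).

    Backward differences of the six parameters; the first frame contributes no
    difference, so the mean runs over ``n_frames - 1`` terms.
    """
    if realign.n_frames < 2:
        raise ValueError("FWD needs at least 2 frames")
    d = np.abs(np.diff(realign.values, axis=0))
    trn = float(d[:, :3].sum(axis=1).mean())
    rot = float(d[:, 3:].sum(axis=1).mean())
    return trn, rot


def build_covariate_table(
    cohort: CohortData,
    spike_counts: list[int],
    n_dummy: int = 5,
) -> pd.DataFrame:
    """Subject covariates: diagnosis (HC=0, mTBI=1), gender (F=0, M=1), age,
    TRN, ROT and spike count, with FWD computed on the dummy-trimmed traces."""
    rows = []
    for subj, spk in zip(cohort.subjects, spike_counts):
        realign = RealignmentParams(subj.realignment.values[n_dummy:])
        trn, rot = compute_fwd(realign)
        rows.append({
            "subject_id": subj.subject_id,
            "pair_id": subj.pair_id,
            "diagnosis": 1 if subj.group == "mTBI" else 0,
            "gender": 1 if subj.gender == "M" else 0,
            "age": subj.age,
            "TRN": trn,
            "ROT": rot,
            "spk": int(spk),
        })
    return pd.DataFrame(rows)


def outlier_mask(
    measures: np.ndarray, n_sd: float = 3.0, min_measures: int = 2
) -> np.ndarray:
    """True for subjects exceeding mean + n_sd*SD on at least ``min_measures``
    of the columns (one-sided: only excess motion/spikes is pathological)."""
    m = np.asarray(measures, dtype=float)
    hi = m.mean(axis=0) + n_sd * m.std(axis=0, ddof=1)
    return (m > hi).sum(axis=1) >= min_measures


def exclude_outliers(
    cohort: CohortData,
    covariates: pd.DataFrame,
    measure_columns: tuple[str, ...] = ("TRN", "ROT", "spk"),
    n_sd: float = 3.0,
    min_measures: int = 2,
) -> tuple[CohortData, pd.DataFrame, dict]:
    """Drop motion/spike outliers together with their matched pair partners.

    Returns the retained cohort, the covariate table restricted to it, and an
    exclusion report.
    """
    measures = covariates[list(measure_columns)].to_numpy(dtype=float)
    flagged = outlier_mask(measures, n_sd=n_sd, min_measures=min_measures)
    bad_pairs = set(covariates.loc[flagged, "pair_id"])
    keep = ~covariates["pair_id"].isin(bad_pairs)
    retained = CohortData(
        subjects=[s for s, k in zip(cohort.subjects, keep) if k],
        truth=cohort.truth,
        config=cohort.config,
    )
    report = {
        "n_flagged": int(flagged.sum()),
        "flagged_subjects": covariates.loc[flagged, "subject_id"].tolist(),
        "excluded_pairs": sorted(bad_pairs),
        "n_retained": int(keep.sum()),
    }
    return retained, covariates.loc[keep].reset_index(drop=True), report


def _safe_t(t: float, p: float) -> tuple[float, float]:
    if not np.isfinite(t) or not np.isfinite(p):
        warnings.warn("degenerate variance in t-test; reporting t=0, p=1")
        return 0.0, 1.0
    return float(t), float(p)


def occupancy_tests(tab: OccupancyTable) -> StatsResult:
    """Between-group unpaired t per state (mTBI - HC) and within-group paired t
    for every state pair; two-sided p-values."""
    groups = np.asarray(tab.groups)
    hc = tab.percentages[groups == "HC"]
    tbi = tab.percentages[groups == "mTBI"]
    if hc.size == 0 or tbi.size == 0:
        raise ValueError("both HC and mTBI groups are required")
    k = tab.percentages.shape[1]
    rows = []
    for state in range(k):
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = sps.ttest_ind(tbi[:, state], hc[:, state])
        t, p = _safe_t(t, p)
        rows.append({"test": "between_group", "group": "mTBI-HC", "state_a": state,
                     "state_b": None, "t": t,
                     "df": hc.shape[0] + tbi.shape[0] - 2, "p": p})
    for gname, gdata in (("HC", hc), ("mTBI", tbi)):
        for i, j in combinations(range(k), 2):
            with np.errstate(invalid="ignore", divide="ignore"):
                t, p = sps.ttest_rel(gdata[:, i], gdata[:, j])
            t, p = _safe_t(t, p)
            rows.append({"test": "within_group", "group": gname, "state_a": i,
                         "state_b": j, "t": t, "df": gdata.shape[0] - 1, "p": p})
    return StatsResult(name="occupancy_tests", table=pd.DataFrame(rows))


def _residualize_on(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    x = np.column_stack([np.ones(len(y)), covariates])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def manova_pipelines(
    data_by_pipeline: dict[str, np.ndarray],
    covariates: np.ndarray | None = None,
) -> StatsResult:
    """One-way MANOVA with pipeline as factor on (subjects, edges) matrices.

    Wilks lambda = det(W) / det(W + B) with the Bartlett chi-square
    approximation, df = p*(g-1).  Subjects with any missing edge are dropped
    listwise; an optional covariate matrix is regressed out of each pipeline's
    data first.  A singular within-group scatter is ridge-shrunk with a
    warning.
    """
    if len(data_by_pipeline) < 2:
        raise ValueError("MANOVA needs at least 2 pipelines")
    blocks, labels = [], []
    for name, x in data_by_pipeline.items():
        x = np.asarray(x, dtype=float)
        keep = ~np.isnan(x).any(axis=1)
        x = x[keep]
        if covariates is not None:
            x = _residualize_on(x, np.asarray(covariates, dtype=float)[keep])
        blocks.append(x)
        labels.extend([name] * x.shape[0])
    x = np.vstack(blocks)
    labels = np.asarray(labels)
    n, p = x.shape
    names = list(data_by_pipeline)
    g = len(names)
    grand = x.mean(axis=0)
    w = np.zeros((p, p))
    b = np.zeros((p, p))
    for name in names:
        xg = x[labels == name]
        mu = xg.mean(axis=0)
        xc = xg - mu
        w += xc.T @ xc
        d = (mu - grand)[:, None]
        b += xg.shape[0] * (d @ d.T)
    sign_w, logdet_w = np.linalg.slogdet(w)
    if sign_w <= 0 or np.linalg.matrix_rank(w) < p:
        warnings.warn("singular within-group scatter; shrinkage applied")
        ridge = (np.trace(w) / p if np.trace(w) > 0 else 1.0) * 1e-6
        w = w + ridge * np.eye(p)
        sign_w, logdet_w = np.linalg.slogdet(w)
    sign_t, logdet_t = np.linalg.slogdet(w + b)
    lam = float(np.exp(logdet_w - logdet_t))
    lam = min(max(lam, np.finfo(float).tiny), 1.0)
    chi2 = -(n - 1 - (p + g) / 2.0) * np.log(lam)
    df = p * (g - 1)
    pval = float(sps.chi2.sf(chi2, df))
    table = pd.DataFrame([{
        "wilks_lambda": lam, "chi2": float(chi2), "df": df, "p": pval,
        "n": n, "n_edges": p, "n_pipelines": g,
    }])
    return StatsResult(name="manova_pipelines", table=table)


def anova_per_edge(groups: list[np.ndarray]) -> StatsResult:
    """One-way ANOVA per edge across the given (subjects, edges) level blocks."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 levels")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    arrays = [a[~np.isnan(a).any(axis=1)] for a in arrays]
    with np.errstate(invalid="ignore", divide="ignore"):
        f, p = sps.f_oneway(*arrays, axis=0)
    n = sum(a.shape[0] for a in arrays)
    table = pd.DataFrame({
        "edge": np.arange(arrays[0].shape[1]),
        "F": np.nan_to_num(f, nan=0.0),
        "df_between": len(arrays) - 1,
        "df_within": n - len(arrays),
        "p": np.nan_to_num(p, nan=1.0),
    })
    return StatsResult(name="anova_per_edge", table=table)


def fdr_correct(p: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; reporting defaults to
    uncorrected second-level tests)."""
    from statsmodels.stats.multitest import multipletests
    return multipletests(np.asarray(p, dtype=float), alpha=alpha, method="fdr_bh")[1]


def beta_strength(
    edge_values: np.ndarray,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Per-edge, per-covariate absolute OLS coefficients.

    The linear model includes diagnosis, gender, age, TRN, ROT and spk with an
    intercept; continuous covariates are standardized so |beta| values are on
    comparable scales.  Returns a (covariate x edge) DataFrame of |beta|.
    """
    y = np.asarray(edge_values, dtype=float)
    keep = ~np.isnan(y).any(axis=1)
    y = y[keep]
    cov = covariates.loc[np.asarray(keep)] if keep.size == len(covariates) else covariates
    x_cols = []
    for name in COVARIATE_COLUMNS:
        col = cov[name].to_numpy(dtype=float)
        if name in ("age", "TRN", "ROT", "spk"):
            sd = col.std(ddof=1)
            col = (col - col.mean()) / (sd if sd > 0 else 1.0)
        x_cols.append(col)
    x = np.column_stack([np.ones(y.shape[0])] + x_cols)
    cond = np.linalg.cond(x)
    if cond > 1e8:
        warnings.warn(f"collinear covariates (condition number {cond:.2e}); "
                      "pseudo-inverse fit")
    beta = np.linalg.pinv(x) @ y        # (1 + 6, edges)
    return pd.DataFrame(np.abs(beta[1:]), index=COVARIATE_COLUMNS)


def beta_strength_anova(tables: dict[str, pd.DataFrame]) -> StatsResult:
    """Compare per-edge |beta| distributions among pipelines, one ANOVA per
    covariate, plus the mean |beta| over edges per pipeline."""
    rows = []
    names = list(tables)
    for covar in COVARIATE_COLUMNS:
        samples = [tables[n].loc[covar].to_numpy() for n in names]
        with np.errstate(invalid="ignore", divide="ignore"):
            f, p = sps.f_oneway(*samples)
        row = {"covariate": covar,
               "F": float(np.nan_to_num(f, nan=0.0)),
               "p": float(np.nan_to_num(p, nan=1.0))}
        for n, s in zip(names, samples):
            row[f"mean_abs_beta_{n}"] = float(np.mean(s))
        rows.append(row)
    return StatsResult(name="beta_strength_anova", table=pd.DataFrame(rows))
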