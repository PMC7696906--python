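"""Temporal analysis: log2 fold-change trajectories, K-means archetype
clustering, sustained-cluster redistribution and differential-phosphorylation
(DEP) calling.

The eight archetypes describe the time-course shapes over 5-60 min of cold
exposure: transient peaks at 5/15/30/60 min (A-D), sustained phosphorylation
(E), continuous dephosphorylation (F), fluctuating dephosphorylation (G) and
no response (H). K-means (Euclidean, best of many restarts) groups the
replicate-averaged log2FC profiles; cluster centroids are then labeled by
shape rules, sustained-cluster members are redistributed to early/late by
their peak time, and per-time DEP calls combine a replicate-level fold-change
threshold with a t-test against the 0-min baseline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .io_formats import QuantTable

logger = logging.getLogger(__name__)

EARLY_TIMES = (5, 15)
LATE_TIMES = (30, 60)


@dataclass
class DEPParams:
    """Differential-phosphorylation calling thresholds.

    A peptide is called up at time t when at least ``min_replicates_passing``
    replicate log2FCs reach ``up_threshold`` and the t-test p-value against
    0 min is below ``alpha``; down analogously with ``down_threshold``
    (fold change <= 0.5, i.e. log2FC <= -1, symmetric with the up call).
    """

    up_threshold: float = 1.0
    down_threshold: float = -1.0
    min_replicates_passing: int = 2
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0,1)")
        if not np.isfinite(self.up_threshold) or not np.isfinite(self.down_threshold):
            raise ValueError("thresholds must be finite")


@dataclass
class TemporalProfiles:
    """Replicate-level and mean log2FC trajectories vs the 0-min baseline."""

    times: list[int]                    # cold times only
    replicate_fc: pd.DataFrame          # rows peptides, cols "<t>min_rep<r>"
    mean_fc: pd.DataFrame               # rows peptides, cols cold times
    excluded: list[str] = field(default_factory=list)


@dataclass
class ClusterResult:
    assignments: pd.DataFrame   # peptide_id, kmeans_cluster, archetype, response_class
    centroids: pd.DataFrame     # cluster -> mean log2FC per cold time (unscaled)
    archetype_by_cluster: dict[int, str]
    inertia: float


def compute_profiles(table: QuantTable) -> TemporalProfiles:
    """Per-replicate and mean log2 fold changes vs the 0-min baseline mean.

    log2FC(t, r) = log2(intensity[t, r]) - log2(mean of available 0-min
    replicate intensities). Rows with no 0-min measurement are excluded.
    """
    cold_times = [t for t in table.times if t != 0]
    base = table.intensities[table.sample_columns(0)].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        base_mean = np.nanmean(base, axis=1)
    ok = np.isfinite(base_mean) & (base_mean > 0)
    excluded = [pid for pid, good in zip(table.peptide_ids, ok) if not good]
    if excluded:
        logger.warning("compute_profiles: %d rows excluded (no 0-min baseline)",
                       len(excluded))

    rep_cols = [f"{t}min_rep{r}" for t in cold_times for r in table.replicates]
    rep_fc = pd.DataFrame(index=table.intensities.index, columns=rep_cols,
                          dtype=float)
    with np.errstate(all="ignore"):
        log_base = np.log2(base_mean)
        for col in rep_cols:
            rep_fc[col] = np.log2(table.intensities[col].to_numpy(dtype=float)) - log_base
    rep_fc = rep_fc.loc[ok]

    mean_fc = pd.DataFrame(index=rep_fc.index, columns=cold_times, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for t in cold_times:
            cols = [f"{t}min_rep{r}" for r in table.replicates]
            mean_fc[t] = np.nanmean(rep_fc[cols].to_numpy(dtype=float), axis=1)
    return TemporalProfiles(times=cold_times, replicate_fc=rep_fc,
                            mean_fc=mean_fc, excluded=excluded)


def pairwise_ttests(table: QuantTable, equal_var: bool = True,
                    min_replicates: int = 2) -> pd.DataFrame:
    """Two-sample t-tests of log2 intensities, 0 min vs each cold time point.

    Student's t by default (``equal_var=True``); set ``equal_var=False`` for
    Welch. Cells with fewer than ``min_replicates`` non-missing values in
    either group get NaN. Identical groups yield p = 1.
    """
    cold_times = [t for t in table.times if t != 0]
    base_cols = table.sample_columns(0)
    out = pd.DataFrame(index=table.intensities.index, columns=cold_times,
                       dtype=float)
    log_int = np.log2(table.intensities.to_numpy(dtype=float))
    log_df = pd.DataFrame(log_int, index=table.intensities.index,
                          columns=table.intensities.columns)
    for t in cold_times:
        cols = table.sample_columns(t)
        for pid in log_df.index:
            a = log_df.loc[pid, cols].dropna().to_numpy()
            b = log_df.loc[pid, base_cols].dropna().to_numpy()
            if len(a) < min_replicates or len(b) < min_replicates:
                continue
            if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
                out.loc[pid, t] = 1.0
                continue
            res = stats.ttest_ind(a, b, equal_var=equal_var)
            out.loc[pid, t] = float(res.pvalue)
    return out


def _scale_profiles(X: np.ndarray) -> np.ndarray:
    """Per-profile unit-norm scaling; zero-norm profiles stay zero."""
    norms = np.linalg.norm(X, axis=1)
    out = X.copy()
    nz = norms > 0
    out[nz] = X[nz] / norms[nz, None]
    return out


def kmeans_cluster(profiles: TemporalProfiles, k: int = 8, n_restarts: int = 50,
                   seed: int = 0, scale: bool = False) -> ClusterResult:
    """Euclidean K-means of (optionally unit-norm scaled) mean log2FC profiles.

    Rows with any missing mean log2FC are dropped. Centroids are reported in
    the unscaled mean-log2FC space (per-cluster means), which is what the
    archetype shape rules interpret. Deterministic given ``seed``.
    """
    mean_fc = profiles.mean_fc.dropna(axis=0)
    if k > len(mean_fc):
        raise ValueError(f"k={k} exceeds {len(mean_fc)} complete profiles")
    X = mean_fc.to_numpy(dtype=float)
    Xs = _scale_profiles(X) if scale else X
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(Xs)

    centroids = pd.DataFrame(
        [X[labels == c].mean(axis=0) for c in range(k)],
        columns=profiles.times)
    assignments = pd.DataFrame({
        "peptide_id": mean_fc.index,
        "kmeans_cluster": labels,
    }).set_index("peptide_id")
    return ClusterResult(assignments=assignments, centroids=centroids,
                         archetype_by_cluster={}, inertia=float(km.inertia_))


def classify_archetypes(result: ClusterResult, epsilon: float = 0.3
                        ) -> ClusterResult:
    """Label each K-means centroid with a temporal archetype A-H.

    Shape rules on the unscaled centroid ``c`` over (5, 15, 30, 60) min, with
    tolerance ``epsilon``:

    * H (unresponsive)            max |c| < epsilon
    * F (continuous down)         all c <= -epsilon and non-increasing
    * G (fluctuating down)        all c <= epsilon/4, some c <= -epsilon,
                                  not monotone non-increasing
    * E (sustained up)            all c >= epsilon/2
    * A/B/C/D (transient peak)    otherwise, by argmax time; ties toward the
                                  larger peak value, then the earlier time
    """
    tol = epsilon / 4.0
    labels: dict[int, str] = {}
    times = list(result.centroids.columns)
    peak_label = {5: "A", 15: "B", 30: "C", 60: "D"}
    for cl, row in result.centroids.iterrows():
        c = row.to_numpy(dtype=float)
        non_increasing = np.all(np.diff(c) <= tol)
        if np.max(np.abs(c)) < epsilon:
            labels[cl] = "H"
        elif np.all(c <= -epsilon) and non_increasing:
            labels[cl] = "F"
        elif np.all(c <= tol) and np.any(c <= -epsilon) and not non_increasing:
            labels[cl] = "G"
        elif np.all(c >= epsilon / 2.0):
            labels[cl] = "E"
        else:
            labels[cl] = peak_label[times[int(np.argmax(c))]]
    result.archetype_by_cluster = labels
    result.assignments["archetype"] = result.assignments["kmeans_cluster"].map(labels)
    logger.info("archetype labels: %s", labels)
    return result


def redistribute_cluster_e(result: ClusterResult, profiles: TemporalProfiles
                           ) -> ClusterResult:
    """Assign every peptide a response class; sustained (E) members are
    redistributed to early/late by the time of their highest mean log2FC
    (ties broken toward the earlier time)."""
    base_class = {"A": "early", "B": "early", "C": "late", "D": "late",
                  "F": "dephosphorylated", "G": "dephosphorylated",
                  "H": "unresponsive"}
    classes = []
    mean_fc = profiles.mean_fc
    for pid, row in result.assignments.iterrows():
        arch = row["archetype"]
        if arch != "E":
            classes.append(base_class[arch])
            continue
        prof = mean_fc.loc[pid].to_numpy(dtype=float)
        peak_time = profiles.times[int(np.argmax(prof))]   # argmax takes first max
        classes.append("early" if peak_time in EARLY_TIMES else "late")
    result.assignments["response_class"] = classes
    n_e = int((result.assignments["archetype"] == "E").sum())
    logger.info("redistributed %d sustained-cluster peptides to early/late", n_e)
    return result


def call_deps(profiles: TemporalProfiles, ttests: pd.DataFrame,
              params: DEPParams | None = None) -> pd.DataFrame:
    """Per-(peptide, time) differential-phosphorylation calls.

    ``up`` when >= min_replicates_passing replicate log2FCs >= up_threshold
    and p < alpha; ``down`` analogously with down_threshold; else ``none``.
    Returns a DataFrame of {"up", "down", "none"} indexed like the profiles.
    """
    params = params or DEPParams()
    calls = pd.DataFrame("none", index=profiles.mean_fc.index,
                         columns=profiles.times, dtype=object)
    rep_cols_by_time = {
        t: [c for c in profiles.replicate_fc.columns if c.startswith(f"{t}min_")]
        for t in profiles.times}
    for t in profiles.times:
        fc = profiles.replicate_fc[rep_cols_by_time[t]].to_numpy(dtype=float)
        n_up = np.nansum(fc >= params.up_threshold, axis=1)
        n_down = np.nansum(fc <= params.down_threshold, axis=1)
        p = ttests.reindex(calls.index)[t].to_numpy(dtype=float)
        sig = p < params.alpha
        up = (n_up >= params.min_replicates_passing) & sig
        down = (n_down >= params.min_replicates_passing) & sig & ~up
        col = np.where(up, "up", np.where(down, "down", "none"))
        calls[t] = col
    return calls
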