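"""Identification-quality filters, descriptive site statistics, SVD-based
bias-trend normalization and QC checks.

The normalization follows the EigenMS idea: fit and remove the treatment
(time-point) group structure per peptide, find systematic bias trends in the
residual matrix by singular value decomposition, keep only trends whose
singular values are significant against a within-row column-permutation null,
project them out, and restore the group structure. Fold changes between time
points are therefore preserved while sample-wide drifts are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .io_formats import QuantTable

logger = logging.getLogger(__name__)


@dataclass
class FilterParams:
    """Identification-quality thresholds.

    ``loc_prob_threshold``: class-I phosphosites require a site-localization
    probability strictly greater than this (default 0.75).
    ``min_replicates``: a peptide must be measured in at least this many
    biological replicates at every time point (default 2 of 3).
    """

    loc_prob_threshold: float = 0.75
    min_replicates: int = 2
    require_all_timepoints: bool = True
    min_peptides_per_protein: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.loc_prob_threshold <= 1.0:
            raise ValueError("loc_prob_threshold must lie in [0,1]")
        if self.min_replicates < 1:
            raise ValueError("min_replicates must be >= 1")


@dataclass
class SiteStats:
    residue_counts: dict[str, int]
    residue_percent: dict[str, float]
    multiplicity_hist: dict[str, int]   # keys "1", "2", "3+"
    n_peptides: int
    n_proteins: int
    n_sites: int


def filter_class1(table: QuantTable, threshold: float = 0.75) -> QuantTable:
    """Keep peptides whose every site has localization probability > threshold."""
    keep = [r.peptide_id for r in table.records
            if all(p > threshold for p in r.loc_probability)]
    removed = len(table) - len(keep)
    logger.info("class-I filter (> %.2f): kept %d, removed %d",
                threshold, len(keep), removed)
    if not keep:
        logger.warning("class-I filter removed every peptide")
    return table.subset(keep)


def filter_reproducible(table: QuantTable, min_replicates: int = 2,
                        require_all_timepoints: bool = True) -> QuantTable:
    """Keep peptides quantified in >= min_replicates replicates at every time
    point (including the 0-min baseline)."""
    times = table.times if require_all_timepoints else [0]
    present = table.intensities.notna()
    keep_mask = pd.Series(True, index=table.intensities.index)
    for t in times:
        cols = table.sample_columns(t)
        keep_mask &= present[cols].sum(axis=1) >= min_replicates
    keep = [pid for pid in table.peptide_ids if keep_mask[pid]]
    logger.info("reproducibility filter (>=%d reps at %s): kept %d of %d",
                min_replicates,
                "all time points" if require_all_timepoints else "baseline",
                len(keep), len(table))
    return table.subset(keep)


def site_statistics(table: QuantTable) -> SiteStats:
    """Residue (S/T/Y) frequencies, phosphorylation multiplicity histogram and
    totals over a filtered table."""
    residue_counts = {"S": 0, "T": 0, "Y": 0}
    hist = {"1": 0, "2": 0, "3+": 0}
    proteins = set()
    n_sites = 0
    for rec in table.records:
        proteins.add(rec.protein_id)
        m = rec.multiplicity
        hist["1" if m == 1 else "2" if m == 2 else "3+"] += 1
        for _, res in rec.sites:
            residue_counts[res] += 1
            n_sites += 1
    if n_sites == 0:
        logger.warning("site_statistics: empty table")
        pct = {r: 0.0 for r in residue_counts}
    else:
        pct = {r: 100.0 * c / n_sites for r, c in residue_counts.items()}
    return SiteStats(residue_counts=residue_counts, residue_percent=pct,
                     multiplicity_hist=hist, n_peptides=len(table),
                     n_proteins=len(proteins), n_sites=n_sites)


@dataclass
class BiasReport:
    n_trends_kept: int
    singular_values: np.ndarray
    permutation_quantiles: np.ndarray
    variance_explained: np.ndarray          # fraction of residual variance per kept trend
    trends: np.ndarray                      # kept right singular vectors, shape (t, n_samples)
    all_missing_rows: list = field(default_factory=list)


def _group_mean_matrix(matrix: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Available-case per-row group means, broadcast back to full shape."""
    import warnings as _warnings
    fitted = np.full_like(matrix, np.nan)
    for g in np.unique(groups):
        cols = groups == g
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            gm = np.nanmean(matrix[:, cols], axis=1)
        fitted[:, cols] = gm[:, None]
    return fitted


def eigenms_normalize(matrix: pd.DataFrame, treatment_groups: list,
                      n_permutations: int = 200, alpha: float = 0.05,
                      seed: int = 0) -> tuple[pd.DataFrame, BiasReport]:
    """Remove significant systematic bias trends from a log2 intensity matrix.

    Parameters
    ----------
    matrix
        Log2 intensities, rows = peptides, columns = samples; NaN allowed.
    treatment_groups
        One group label (time point) per column; each group needs >= 2 columns.
    n_permutations, alpha
        Within-row column permutations used to build the null distribution of
        singular values; trend ``k`` is kept while its singular value exceeds
        the (1 - alpha) permutation quantile of the k-th null singular value.

    Returns the normalized matrix (same shape, NaN pattern preserved) and a
    :class:`BiasReport`.
    """
    groups = np.asarray(treatment_groups)
    if len(groups) != matrix.shape[1]:
        raise ValueError("one treatment group label required per column")
    for g, cnt in zip(*np.unique(groups, return_counts=True)):
        if cnt < 2:
            raise ValueError(f"treatment group {g!r} has fewer than 2 columns")

    X = matrix.to_numpy(dtype=float)
    all_missing = np.all(np.isnan(X), axis=1)
    if all_missing.any():
        logger.warning("%d all-missing rows passed through untouched",
                       int(all_missing.sum()))

    fitted = _group_mean_matrix(X, groups)
    resid = X - fitted
    R0 = np.nan_to_num(resid, nan=0.0)
    R0[all_missing] = 0.0

    U, S, Vt = np.linalg.svd(R0, full_matrices=False)

    rng = np.random.default_rng(seed)
    n_sv = len(S)
    group_cols = [np.flatnonzero(groups == g) for g in np.unique(groups)]
    perm_sv = np.empty((n_permutations, n_sv))
    for b in range(n_permutations):
        P = R0.copy()
        # permute residuals independently within each row, but only within
        # treatment groups: the group-mean fit constrains each row's residuals
        # to sum to zero per group, and the null must respect that constraint
        # or every residual dimension looks significant
        for cols in group_cols:
            idx = np.argsort(rng.random((P.shape[0], len(cols))), axis=1)
            P[:, cols] = np.take_along_axis(P[:, cols], idx, axis=1)
        perm_sv[b] = np.linalg.svd(P, compute_uv=False)
    quantiles = np.quantile(perm_sv, 1.0 - alpha, axis=0)

    t = 0
    while t < n_sv and S[t] > quantiles[t]:
        t += 1
    logger.info("bias-trend normalization: %d significant trend(s) removed", t)

    if t > 0:
        R_clean = R0 - (U[:, :t] * S[:t]) @ Vt[:t]
    else:
        R_clean = R0
    total_var = float(np.sum(S ** 2)) or 1.0
    out = fitted + R_clean
    out[np.isnan(X)] = np.nan
    out[all_missing] = X[all_missing]

    report = BiasReport(
        n_trends_kept=t,
        singular_values=S,
        permutation_quantiles=quantiles,
        variance_explained=(S[:t] ** 2) / total_var,
        trends=Vt[:t],
        all_missing_rows=list(matrix.index[all_missing]),
    )
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns), report


def pca_qc(matrix: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Unsupervised PCA over samples for replicate QC.

    Rows (peptides) with any missing value are dropped for this QC only.
    Returns per-sample scores and percent variance explained (sums to 100).
    """
    if matrix.shape[1] < 3:
        raise ValueError("PCA QC needs at least 3 samples")
    complete = matrix.dropna(axis=0)
    if complete.empty:
        raise ValueError("no complete rows available for PCA")
    X = complete.to_numpy(dtype=float).T        # samples x peptides
    pca = PCA()
    scores = pca.fit_transform(X)
    var_pct = pca.explained_variance_ratio_ * 100.0
    score_df = pd.DataFrame(
        scores, index=matrix.columns,
        columns=[f"PC{i+1}" for i in range(scores.shape[1])])
    return score_df, var_pct


def _median_polish(X: np.ndarray, max_iter: int = 10, tol: float = 1e-6
                   ) -> np.ndarray:
    """Tukey median polish column effects of a (peptide x sample) log2 block.

    Returns overall + column effects, i.e. the per-sample protein summary.
    NaN-aware.
    """
    overall = 0.0
    row_eff = np.zeros(X.shape[0])
    col_eff = np.zeros(X.shape[1])
    R = X.copy()
    for _ in range(max_iter):
        with np.errstate(all="ignore"):
            rmed = np.nanmedian(R, axis=1)
        rmed = np.nan_to_num(rmed)
        row_eff += rmed
        R -= rmed[:, None]
        ce_med = np.nanmedian(col_eff) if col_eff.size else 0.0
        overall += ce_med
        col_eff -= ce_med
        with np.errstate(all="ignore"):
            cmed = np.nanmedian(R, axis=0)
        cmed = np.nan_to_num(cmed)
        col_eff += cmed
        R -= cmed[None, :]
        re_med = np.nanmedian(row_eff) if row_eff.size else 0.0
        overall += re_med
        row_eff -= re_med
        if max(np.max(np.abs(rmed)), np.max(np.abs(cmed))) < tol:
            break
    return overall + col_eff


def protein_abundance_check(table: QuantTable, min_peptides_per_protein: int = 2,
                            alpha: float = 0.05) -> pd.DataFrame:
    """Test per-protein abundance stability over the time course.

    Peptide log2 intensities are summarized per protein and sample by median
    polish; each cold time point is compared to 0 min by Welch t-test and the
    p-values are Benjamini-Hochberg adjusted across all (protein, time) tests.
    Returns a table with a ``significant`` column (adjusted p < alpha).
    """
    by_protein: dict[str, list[str]] = {}
    for rec in table.records:
        by_protein.setdefault(rec.protein_id, []).append(rec.peptide_id)

    rows = []
    base_cols = table.sample_columns(0)
    cold_times = [t for t in table.times if t != 0]
    for prot, peps in sorted(by_protein.items()):
        if len(peps) < min_peptides_per_protein:
            continue
        block = np.log2(table.intensities.loc[peps].to_numpy(dtype=float))
        summary = _median_polish(block)
        s = pd.Series(summary, index=table.intensities.columns)
        base = s[base_cols].dropna().to_numpy()
        for t in cold_times:
            vals = s[table.sample_columns(t)].dropna().to_numpy()
            if len(base) < 2 or len(vals) < 2:
                p = np.nan
            else:
                p = float(stats.ttest_ind(vals, base, equal_var=False).pvalue)
            rows.append({"protein_id": prot, "time": t,
                         "log2fc": float(np.nanmean(vals) - np.nanmean(base)),
                         "p_value": p})
    report = pd.DataFrame(rows)
    if report.empty:
        return report.assign(p_adj=pd.Series(dtype=float),
                             significant=pd.Series(dtype=bool))
    ok = report["p_value"].notna()
    adj = np.full(len(report), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = multipletests(report.loc[ok, "p_value"],
                                           method="fdr_bh")[1]
    report["p_adj"] = adj
    report["significant"] = report["p_adj"] < alpha
    n_sig = int(report["significant"].sum())
    if n_sig:
        logger.info("protein abundance check: %d significant (protein, time) pairs",
                    n_sig)
    return report
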