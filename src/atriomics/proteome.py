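"""Differential proteomics statistics per fraction.

The analysis chain mirrors Perseus-style label-free workflows: drop proteins
with too many missing values, log2-transform and Z-score the intensities,
compute an S0-moderated two-sample statistic per protein, then classify
significance with a SAM-style permutation false-discovery rate — the cutoff
on |d| is chosen so that the median number of permutation exceedances,
relative to the observed exceedances, stays below the target FDR.

QC summaries (PCA variance fractions, Pearson sample correlation, K-means /
hierarchical ordering for heatmaps, Venn-style list overlap) live here too.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GROUP_AF, GROUP_SHAM, OmicsMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "VolcanoConfig", "filter_missing", "normalize_matrix", "moderated_t",
    "permutation_volcano", "pca_variance", "sample_correlation",
    "cluster_for_heatmap", "list_overlap",
]


@dataclass
class VolcanoConfig:
    """Permutation-FDR volcano parameters.

    Defaults are the study's: S0 = 0.1, 250 randomizations, 5% FDR, and
    proteins with more than two missing values removed beforehand.
    """

    s0: float = 0.1
    n_permutations: int = 250
    fdr_target: float = 0.05
    max_missing: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValueError("s0 must be non-negative")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be at least 1")
        if not 0 < self.fdr_target < 1:
            raise ValueError("fdr_target must lie in (0, 1)")


def filter_missing(matrix: OmicsMatrix, max_missing: int = 2) -> OmicsMatrix:
    """Keep features with at most ``max_missing`` missing entries.

    Order-preserving and idempotent. An empty result is permitted (logged as
    a warning), matching the convention that filtering is a data decision,
    not an error.
    """
    if max_missing >= matrix.n_samples:
        raise ValueError("max_missing must be smaller than the sample count")
    n_miss = matrix.missing_mask.sum(axis=1)
    keep = matrix.feature_ids[n_miss <= max_missing]
    if len(keep) == 0:
        logger.warning("filter_missing removed every feature (max_missing=%d)",
                       max_missing)
    return matrix.subset_features(keep)


def normalize_matrix(matrix: OmicsMatrix, log_base2: bool = True,
                     zscore: bool = True, axis: str = "feature") -> OmicsMatrix:
    """log2-transform and/or Z-score the matrix.

    Z-scoring standardizes each feature row over its non-missing entries to
    mean 0 and sample SD 1 (``axis="sample"`` standardizes columns instead).
    Rows with zero SD are emitted as all-zero with a warning rather than NaN,
    so constant features survive into clustering.
    """
    values = matrix.values.copy()
    if log_base2:
        nonpos = values.le(0)
        if nonpos.any().any():
            feat = values.index[nonpos.any(axis=1)][0]
            samp = values.columns[nonpos.loc[feat].values.astype(bool)][0]
            raise ValueError(
                f"log2 of non-positive value at feature {feat!r}, sample {samp!r}")
        values = np.log2(values)
    if zscore:
        ax = 1 if axis == "feature" else 0
        mean = values.mean(axis=ax)
        sd = values.std(axis=ax, ddof=1)
        zero_sd = sd.fillna(0.0) == 0.0
        if zero_sd.any():
            warnings.warn(
                f"{int(zero_sd.sum())} zero-SD {axis}(s) emitted as all-zero "
                "during Z-scoring", stacklevel=2)
        safe_sd = sd.replace(0.0, np.nan)
        values = values.sub(mean, axis=1 - ax).div(safe_sd, axis=1 - ax)
        if ax == 1:
            values.loc[zero_sd] = values.loc[zero_sd].where(
                matrix.values.loc[zero_sd].isna(), 0.0)
        else:
            cols = values.columns[zero_sd]
            values[cols] = values[cols].where(matrix.values[cols].isna(), 0.0)
    return matrix.replace_values(values)


def _pooled_t_rows(a: np.ndarray, b: np.ndarray, s0: float
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise pooled two-sample t with NaN-aware groups.

    Returns (t_raw, d_mod, p_raw, valid). Rows with fewer than two observed
    values in either group are invalid (NaN statistics).
    """
    n1 = np.sum(~np.isnan(a), axis=1)
    n2 = np.sum(~np.isnan(b), axis=1)
    valid = (n1 >= 2) & (n2 >= 2)

    with np.errstate(invalid="ignore", divide="ignore"), \
            warnings.catch_warnings():
        # rows with <2 observed values legitimately produce NaN moments and
        # are masked out below
        warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(a, axis=1)
        m2 = np.nanmean(b, axis=1)
        v1 = np.nanvar(a, axis=1, ddof=1)
        v2 = np.nanvar(b, axis=1, ddof=1)
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / np.where(df > 0, df, np.nan)
        se = np.sqrt(sp2 * (1.0 / np.where(n1 > 0, n1, np.nan)
                            + 1.0 / np.where(n2 > 0, n2, np.nan)))
        diff = m1 - m2
        t_raw = np.where(se > 0, diff / se,
                         np.where(diff == 0, 0.0, np.sign(diff) * np.inf))
        d_mod = diff / (se + s0) if s0 > 0 else t_raw
        p_raw = np.where(np.isfinite(t_raw),
                         2.0 * stats.t.sf(np.abs(np.where(np.isfinite(t_raw),
                                                          t_raw, 0.0)), df),
                         0.0)
        p_raw = np.where(t_raw == 0, 1.0, p_raw)

    t_raw = np.where(valid, t_raw, np.nan)
    d_mod = np.where(valid, d_mod, np.nan)
    p_raw = np.where(valid, p_raw, np.nan)
    return t_raw, d_mod, p_raw, valid


def moderated_t(matrix: OmicsMatrix, s0: float = 0.1) -> pd.DataFrame:
    """Per-feature pooled Student t, S0-moderated statistic and two-sided p.

    d_mod = (mean_AF - mean_sham) / (SE_pooled + s0); with s0 = 0 it equals
    the Student t exactly. Features lacking two observed values in either
    group are returned with NaN statistics and a reason.
    """
    af, sham = matrix.group_columns()
    a, b = af.to_numpy(float), sham.to_numpy(float)
    t_raw, d_mod, p_raw, valid = _pooled_t_rows(a, b, s0)
    log2_fc = np.nanmean(a, axis=1) - np.nanmean(b, axis=1)
    out = pd.DataFrame({
        "log2_fc": np.where(valid, log2_fc, np.nan),
        "t_raw": t_raw, "d_mod": d_mod, "p_raw": p_raw,
        "reason": np.where(valid, "", "fewer than 2 observed values per group"),
    }, index=matrix.feature_ids)
    return out


def _balanced_splits(n1: int, n2: int) -> list[tuple[int, ...]]:
    """All distinct relabelings keeping group sizes: AF index sets of size n1."""
    return list(itertools.combinations(range(n1 + n2), n1))


def _fdr_curve(d_obs_abs: np.ndarray, d_perm_abs: np.ndarray,
               cutoffs: np.ndarray) -> np.ndarray:
    """FDR-hat(c) = median over permutations of exceedances / observed hits."""
    obs_hits = (d_obs_abs[None, :] >= cutoffs[:, None]).sum(axis=1)
    perm_hits = (d_perm_abs[None, :, :] >= cutoffs[:, None, None]).sum(axis=2)
    med_false = np.median(perm_hits, axis=1)
    return med_false / np.maximum(1, obs_hits)


def permutation_volcano(matrix: OmicsMatrix,
                        config: VolcanoConfig | None = None) -> pd.DataFrame:
    """SAM-style permutation-FDR classification of a filtered, normalized matrix.

    For the observed labels and for each balanced relabeling, |d_mod| is
    computed per feature; candidate cutoffs are the observed |d_mod| values.
    FDR-hat(c) = median over relabelings of #{|d_perm| >= c} /
    max(1, #{|d_obs| >= c}), monotonized to be non-increasing in c; the
    smallest cutoff with monotonized FDR-hat <= fdr_target is selected and
    features at or above it are significant (ties at the cutoff included).
    When the distinct balanced splits number at most ``n_permutations`` the
    enumeration is exhaustive; otherwise distinct splits are sampled without
    replacement.
    """
    config = config or VolcanoConfig()
    af_ids = matrix.samples_in(GROUP_AF)
    sham_ids = matrix.samples_in(GROUP_SHAM)
    n1, n2 = len(af_ids), len(sham_ids)
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 samples")

    data = matrix.values[af_ids + sham_ids].to_numpy(float)
    a_obs, b_obs = data[:, :n1], data[:, n1:]
    t_raw, d_obs, p_raw, valid = _pooled_t_rows(a_obs, b_obs, config.s0)
    log2_fc = np.nanmean(a_obs, axis=1) - np.nanmean(b_obs, axis=1)

    all_splits = _balanced_splits(n1, n2)
    n_distinct = len(all_splits)
    if n_distinct <= config.n_permutations:
        splits = all_splits
        logger.info("permutation_volcano: exhaustive enumeration of %d "
                    "distinct balanced splits", n_distinct)
    else:
        rng = np.random.default_rng(config.seed)
        idx = rng.choice(n_distinct, size=config.n_permutations, replace=False)
        splits = [all_splits[i] for i in sorted(idx)]

    d_perm = np.empty((len(splits), data.shape[0]))
    cols = set(range(n1 + n2))
    for i, split in enumerate(splits):
        rest = sorted(cols - set(split))
        _, d, _, _ = _pooled_t_rows(data[:, list(split)], data[:, rest], config.s0)
        d_perm[i] = np.abs(d)

    d_obs_abs = np.abs(d_obs)
    finite_obs = d_obs_abs[valid & np.isfinite(d_obs_abs)]
    cutoffs = np.unique(finite_obs)
    significant = np.zeros(data.shape[0], dtype=bool)
    fdr_at_cutoff = math.nan
    chosen_cutoff = math.nan
    if cutoffs.size:
        # NaN statistics (features lacking data under a relabeling) never
        # count as exceedances; infinite ones always do.
        obs_curve = np.where(np.isnan(d_obs_abs), -1.0, d_obs_abs)
        perm_curve = np.where(np.isnan(d_perm), -1.0, d_perm)
        with np.errstate(invalid="ignore"):
            fdr = _fdr_curve(obs_curve, perm_curve, cutoffs)
        # monotonized non-increasing in c (running min from the loose end):
        # a stricter cutoff never reports a worse FDR than a looser one
        mono = np.minimum.accumulate(fdr)
        ok = mono <= config.fdr_target
        if ok.any():
            sel = int(np.argmax(ok))     # smallest qualifying cutoff
            chosen_cutoff = float(cutoffs[sel])
            fdr_at_cutoff = float(mono[sel])
            significant = valid & (d_obs_abs >= chosen_cutoff)

    direction = np.where(~significant, "ns",
                         np.where(log2_fc > 0, "up", "down"))
    out = pd.DataFrame({
        "log2_fc": np.where(valid, log2_fc, np.nan),
        "t_raw": t_raw, "d_mod": d_obs, "p_raw": p_raw,
        "significant": significant, "direction": direction,
    }, index=matrix.feature_ids)
    out.attrs["cutoff"] = chosen_cutoff
    out.attrs["fdr_est"] = fdr_at_cutoff
    out.attrs["n_permutations_used"] = len(splits)
    out.attrs["exhaustive"] = n_distinct <= config.n_permutations
    return out


def pca_variance(matrix: OmicsMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores and variance fractions from a centered SVD.

    Samples are the observations (as in per-sample QC plots); features must
    be complete — filter or subset to complete cases first. Variance
    fractions sum to 1 over all components; a matrix with zero total
    variance returns NaN fractions with a warning.
    """
    if matrix.missing_mask.any().any():
        raise ValueError("pca_variance requires complete data; filter missing "
                         "values first")
    X = matrix.values.to_numpy(float).T        # samples x features
    Xc = X - X.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s ** 2))
    if total == 0.0:
        warnings.warn("zero-variance matrix: PCA fractions undefined",
                      stacklevel=2)
        fractions = np.full(s.shape, np.nan)
    else:
        fractions = s ** 2 / total
    scores = pd.DataFrame(u * s, index=matrix.sample_ids,
                          columns=[f"PC{i+1}" for i in range(s.size)])
    return scores, fractions


def sample_correlation(matrix: OmicsMatrix) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation between samples.

    Symmetric with unit diagonal; a pair sharing fewer than two observed
    features gets NaN (flagged via a warning).
    """
    corr = matrix.values.corr(method="pearson", min_periods=2)
    np.fill_diagonal(corr.values, 1.0)
    if corr.isna().any().any():
        warnings.warn("sample pairs with <2 shared features: correlation "
                      "undefined (NaN)", stacklevel=2)
    return corr


def cluster_for_heatmap(matrix: OmicsMatrix, k: int = 3,
                        seed: int = 0) -> tuple[pd.Series, np.ndarray, np.ndarray]:
    """K-means feature clusters plus hierarchical display orders.

    Euclidean K-means (fixed seed, multiple restarts) labels the features;
    average-linkage hierarchical clustering provides the row and column
    orders used to draw a heatmap. Missing values are mean-imputed for
    clustering geometry only — the matrix itself is untouched.
    """
    from scipy.cluster.hierarchy import leaves_list, linkage
    from sklearn.cluster import KMeans

    if k < 1:
        raise ValueError("k must be at least 1")
    if k > matrix.n_features:
        raise ValueError("k cannot exceed the number of features")

    X = matrix.values.to_numpy(float)
    if np.isnan(X).any():
        row_means = np.nanmean(X, axis=1)
        inds = np.where(np.isnan(X))
        X = X.copy()
        X[inds] = np.take(row_means, inds[0])

    if k == 1:
        labels = np.zeros(X.shape[0], dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(X)

    row_order = (leaves_list(linkage(X, method="average", metric="euclidean"))
                 if X.shape[0] > 1 else np.array([0]))
    col_order = (leaves_list(linkage(X.T, method="average", metric="euclidean"))
                 if X.shape[1] > 1 else np.array([0]))
    return (pd.Series(labels, index=matrix.feature_ids, name="cluster"),
            row_order, col_order)


def list_overlap(set_a, set_b) -> dict:
    """Venn-style overlap: shared percentage of the union plus counts."""
    a, b = set(set_a), set(set_b)
    union = a | b
    shared = a & b
    if not union:
        warnings.warn("both sets empty: overlap undefined", stacklevel=2)
        pct = math.nan
    else:
        pct = 100.0 * len(shared) / len(union)
    return {"shared_pct": pct, "n_shared": len(shared),
            "n_a_only": len(a - b), "n_b_only": len(b - a)}
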